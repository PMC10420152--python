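"""Single-config orchestration of the full analysis chain.

A :class:`StudyConfig` names the inputs for whichever assays were run —
fluorescence titrations at one or more temperatures, a (T, Ka) table,
donor/acceptor spectra for FRET, an amide-I spectrum, a CD measurement, a
peak-shift series — and :func:`run_study` executes every stage that has
inputs, independently: a failing stage is reported and skipped without
aborting the others (the assays are experimentally independent).  The
report is a JSON-serialisable mapping with units in the field names, and
a run log records every default in force.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from . import fret as fret_mod
from . import quenching as quench_mod
from . import secondary_structure as ss_mod
from . import shift as shift_mod
from . import synthetic as synth_mod
from . import thermodynamics as thermo_mod
from .spectra import AxisKind, Spectrum, read_titration_table, write_titration_table

logger = logging.getLogger("albind.pipeline")

__all__ = [
    "StudyConfig",
    "TitrationInput",
    "run_study",
    "simulate_study",
    "read_spectrum_csv",
    "to_jsonable",
]


# ---------------------------------------------------------------------------
# config model
# ---------------------------------------------------------------------------


class TitrationInput(BaseModel):
    path: str
    temperature_K: float


class QuenchSection(BaseModel):
    titrations: list[TitrationInput]
    tau0_s: float = quench_mod.DEFAULT_TAU0_S
    eps_ex_per_M_cm: float = 0.0
    eps_em_per_M_cm: float = 0.0


class ThermoSection(BaseModel):
    #: CSV with header "T_K,Ka_per_M", one row per temperature.
    ka_table: Optional[str] = None
    temperatures_K: Optional[list[float]] = None
    Ka_per_M: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self):
        if self.ka_table is None and (self.temperatures_K is None or self.Ka_per_M is None):
            raise ValueError("thermo stage needs ka_table or inline (T, Ka) lists")
        return self


class FretSection(BaseModel):
    donor_csv: Optional[str] = None
    acceptor_csv: Optional[str] = None
    acceptor_conc_M: Optional[float] = None
    path_cm: float = 1.0
    f_ratio: float = Field(..., description="F/F0 of the donor with acceptor present")
    R0_nm: Optional[float] = None
    K2: float = fret_mod.DEFAULT_K2
    refractive_index: float = fret_mod.DEFAULT_REFRACTIVE_INDEX
    quantum_yield: float = fret_mod.DEFAULT_QUANTUM_YIELD


class FtirSection(BaseModel):
    free_csv: str
    bound_csv: Optional[str] = None
    n_bands: int | str = "auto"


class CdSection(BaseModel):
    observed_mdeg: Optional[float] = None
    spectrum_csv: Optional[str] = None
    Cp_M: float = 2e-6
    n_residues: int = 585
    path_mm: float = 1.0

    @model_validator(mode="after")
    def _check(self):
        if self.observed_mdeg is None and self.spectrum_csv is None:
            raise ValueError("cd stage needs observed_mdeg or spectrum_csv")
        return self


class ShiftSection(BaseModel):
    series_csv: str
    temperature_K: float = 310.0
    window: tuple[float, float]


class StudyConfig(BaseModel):
    """Everything needed to run (a subset of) the analysis chain."""

    quench: Optional[QuenchSection] = None
    thermo: Optional[ThermoSection] = None
    fret: Optional[FretSection] = None
    ftir: Optional[FtirSection] = None
    cd: Optional[CdSection] = None
    shift: Optional[ShiftSection] = None
    output_dir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(exclude_none=True), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# serialisation helpers
# ---------------------------------------------------------------------------


def to_jsonable(obj: Any) -> Any:
    """Dataclasses/enums/ndarrays → plain JSON-serialisable structures."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def read_spectrum_csv(path, axis_kind: AxisKind | None = None) -> Spectrum:
    """Read a 2-column (axis, intensity) CSV as a single Spectrum.

    The axis kind comes from the first header token ("nm" or "cm-1")
    unless given explicitly.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need 2 columns (axis, intensity)")
    if axis_kind is None:
        head = str(df.columns[0]).strip().lower()
        axis_kind = (
            AxisKind.wavenumber_cm1
            if "cm" in head or "waven" in head
            else AxisKind.wavelength_nm
        )
    return Spectrum(
        axis_kind,
        df.iloc[:, 0].to_numpy(dtype=float),
        df.iloc[:, 1].to_numpy(dtype=float),
        label=str(path),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_quench(cfg: QuenchSection) -> dict:
    qres, bres = [], []
    for t in cfg.titrations:
        series = read_titration_table(t.path, temperature_K=t.temperature_K)
        q, b = quench_mod.analyze_titration(
            series, cfg.tau0_s, cfg.eps_ex_per_M_cm, cfg.eps_em_per_M_cm
        )
        qres.append(q)
        bres.append(b)
    mechanism = quench_mod.classify_mechanism(qres)
    for q in qres:
        q.mechanism = mechanism
    return {
        "stern_volmer": [to_jsonable(q) for q in qres],
        "binding": [to_jsonable(b) for b in bres],
        "mechanism": mechanism.value,
    }


def _stage_thermo(cfg: ThermoSection) -> dict:
    if cfg.ka_table is not None:
        import pandas as pd

        df = pd.read_csv(cfg.ka_table)
        T = df.iloc[:, 0].to_numpy(dtype=float)
        Ka = df.iloc[:, 1].to_numpy(dtype=float)
    else:
        T = np.asarray(cfg.temperatures_K, dtype=float)
        Ka = np.asarray(cfg.Ka_per_M, dtype=float)
    return to_jsonable(thermo_mod.vant_hoff_fit(T, Ka))


def _stage_fret(cfg: FretSection) -> dict:
    donor = read_spectrum_csv(cfg.donor_csv, AxisKind.wavelength_nm) if cfg.donor_csv else None
    acceptor = (
        read_spectrum_csv(cfg.acceptor_csv, AxisKind.wavelength_nm)
        if cfg.acceptor_csv
        else None
    )
    res = fret_mod.analyze_fret(
        F=cfg.f_ratio,
        F0=1.0,
        donor_emission=donor,
        acceptor_absorption=acceptor,
        acceptor_conc_M=cfg.acceptor_conc_M,
        path_cm=cfg.path_cm,
        R0_nm=cfg.R0_nm,
        K2=cfg.K2,
        N=cfg.refractive_index,
        phi=cfg.quantum_yield,
    )
    return to_jsonable(res)


def _stage_ftir(cfg: FtirSection) -> dict:
    free = ss_mod.deconvolve_amide_i(
        read_spectrum_csv(cfg.free_csv, AxisKind.wavenumber_cm1), n_bands=cfg.n_bands
    )
    out = {"free": to_jsonable(free)}
    if cfg.bound_csv:
        bound = ss_mod.deconvolve_amide_i(
            read_spectrum_csv(cfg.bound_csv, AxisKind.wavenumber_cm1),
            n_bands=cfg.n_bands,
        )
        out["bound"] = to_jsonable(bound)
        out["change"] = to_jsonable(ss_mod.compare_structures(free, bound))
    return out


def _stage_cd(cfg: CdSection) -> dict:
    if cfg.observed_mdeg is not None:
        observed = cfg.observed_mdeg
    else:
        spec = read_spectrum_csv(cfg.spectrum_csv, AxisKind.wavelength_nm)
        from .spectra import peak_intensity

        observed = peak_intensity(spec, 208.0)
    return to_jsonable(
        ss_mod.cd_helix_content(observed, cfg.Cp_M, cfg.n_residues, cfg.path_mm)
    )


def _stage_shift(cfg: ShiftSection) -> dict:
    series = read_titration_table(cfg.series_csv, temperature_K=cfg.temperature_K)
    return to_jsonable(shift_mod.track_peak(series, cfg.window))


_STAGES = {
    "quench": _stage_quench,
    "thermo": _stage_thermo,
    "fret": _stage_fret,
    "ftir": _stage_ftir,
    "cd": _stage_cd,
    "shift": _stage_shift,
}


def run_study(config: StudyConfig) -> dict:
    """Run every configured stage; never let one failure abort the rest.

    Returns a report mapping stage name → ``{"status": "ok", "result":
    ...}`` or ``{"status": "error", "error": ...}``, plus a ``defaults``
    record of the constants in force.
    """
    report: dict[str, Any] = {
        "defaults": {
            "gas_constant_J_per_mol_K": thermo_mod.GAS_CONSTANT,
            "tau0_s": config.quench.tau0_s if config.quench else quench_mod.DEFAULT_TAU0_S,
            "Kq_static_threshold_per_M_s": quench_mod.KQ_STATIC_THRESHOLD,
            "fret_K2": config.fret.K2 if config.fret else fret_mod.DEFAULT_K2,
            "fret_refractive_index": (
                config.fret.refractive_index if config.fret else fret_mod.DEFAULT_REFRACTIVE_INDEX
            ),
            "fret_quantum_yield": (
                config.fret.quantum_yield if config.fret else fret_mod.DEFAULT_QUANTUM_YIELD
            ),
            "seed": config.seed,
        }
    }
    for name, fn in _STAGES.items():
        section = getattr(config, name)
        if section is None:
            continue
        logger.info("running stage %s", name)
        try:
            report[name] = {"status": "ok", "result": fn(section)}
        except Exception as exc:  # stage isolation by design
            logger.exception("stage %s failed", name)
            report[name] = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# simulation entry point
# ---------------------------------------------------------------------------


def simulate_study(output_dir, seed: int = 0) -> StudyConfig:
    """Generate a complete synthetic study and a config that analyses it.

    Writes titration CSVs at three temperatures (mixed-regime quenching
    with Van't-Hoff-consistent binding constants), donor/acceptor spectra,
    an amide-I envelope and a UV-band shift series, then returns (and
    saves) a StudyConfig pointing at them.  Deterministic for a fixed
    seed.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # binding constants from a chosen (ΔH, ΔS) so thermo closes the loop
    dH, dS = -80e3, -180.0  # J/mol, J/mol/K; gives Ka ~ 1e4–5e4 over 296–310 K
    temps = [296.0, 303.0, 310.0]
    Ka = [float(np.exp(-dH / (thermo_mod.GAS_CONSTANT * T) + dS / thermo_mod.GAS_CONSTANT)) for T in temps]

    titrations = []
    for T, ka in zip(temps, Ka):
        gt = synth_mod.QuenchingGroundTruth(
            Ksv_dynamic_per_M=0.0,
            Ka_per_M=ka,
            n_sites=1.0,
            noise_sd_rel=0.01,
            seed=int(rng.integers(2**31 - 1)),
        )
        conc = synth_mod.titration_design(ka, 1.0)
        series = synth_mod.generate_titration(gt, conc, T)
        path = out / f"titration_{int(T)}K.csv"
        write_titration_table(series, path)
        titrations.append(TitrationInput(path=str(path), temperature_K=T))

    # donor emission / acceptor absorption with genuine spectral overlap
    lam = np.arange(300.0, 500.0, 1.0)
    donor = Spectrum(
        AxisKind.wavelength_nm,
        lam,
        1000.0 * np.exp(-((lam - 337.0) ** 2) / (2 * 25.0**2)),
    )
    acc_conc = 5e-7
    acceptor = Spectrum(
        AxisKind.wavelength_nm,
        lam,
        acc_conc * 1.5e4 * np.exp(-((lam - 330.0) ** 2) / (2 * 30.0**2)),
    )
    import pandas as pd

    pd.DataFrame({"nm": lam, "intensity": donor.intensity}).to_csv(
        out / "donor.csv", index=False
    )
    pd.DataFrame({"nm": lam, "absorbance": acceptor.intensity}).to_csv(
        out / "acceptor.csv", index=False
    )

    grid = np.arange(1580.0, 1720.0 + 1e-9, 1.0)
    bands = [
        (1623.0, 7.0, 0.9),
        (1635.0, 6.0, 0.8),
        (1645.0, 6.0, 0.7),
        (1655.0, 7.0, 1.2),
        (1668.0, 7.0, 0.8),
        (1680.0, 7.0, 0.5),
    ]
    amide = synth_mod.generate_amide_i(
        synth_mod.AmideIGroundTruth(bands, noise_sd_rel=0.005, seed=int(rng.integers(2**31 - 1))),
        grid,
    )
    pd.DataFrame({"cm-1": grid, "absorbance": amide.intensity}).to_csv(
        out / "amide_i.csv", index=False
    )

    shift_conc = np.linspace(0.0, 8e-6, 9)
    shift_series = synth_mod.generate_band_series(
        centers_nm=214.0 + 2.0 * shift_conc / shift_conc[-1],
        amplitudes=1.0 - 0.4 * shift_conc / shift_conc[-1],
        width_nm=8.0,
        concentrations_M=shift_conc,
        grid_nm=np.arange(200.0, 240.0, 0.5),
        seed=int(rng.integers(2**31 - 1)),
    )
    write_titration_table(shift_series, out / "uvvis_series.csv")

    cd_theta = synth_mod.generate_cd(0.5585)

    config = StudyConfig(
        quench=QuenchSection(titrations=titrations),
        thermo=ThermoSection(temperatures_K=temps, Ka_per_M=Ka),
        fret=FretSection(
            donor_csv=str(out / "donor.csv"),
            acceptor_csv=str(out / "acceptor.csv"),
            acceptor_conc_M=acc_conc,
            f_ratio=0.9633,
        ),
        ftir=FtirSection(free_csv=str(out / "amide_i.csv")),
        cd=CdSection(observed_mdeg=cd_theta),
        shift=ShiftSection(
            series_csv=str(out / "uvvis_series.csv"), window=(205.0, 225.0)
        ),
        output_dir=str(out),
        seed=seed,
    )
    config.to_yaml(out / "study.yaml")
    return config
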