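"""Dataset, parameter-file and run-configuration I/O.

The event dataset is a NONMEM-style comma-delimited table, one row per event:

    ID,TIME,EVID,AMT,DV,DVID,BLQ,<covariates...>

* ``EVID`` 1 = dose (AMT in mg, DV empty), 0 = observation (DV in mg/L,
  DVID 1 = VCZ, 2 = VNO).
* ``BLQ`` 1 flags observations below the assay quantification limit
  (0.5 ng/ml = 0.0005 mg/L); they are kept in files and excluded from fits
  with a logged count.
* Any further columns are carried as covariates (sex, age, WT, height, BSA,
  laboratory values, CYP2C19 phenotype, comedication flags, ...).

Parameter files are ``key = value`` structured text mirroring a fit report's
Estimate column, with ``fixed`` markers and the omega-convention flag; they
round-trip exactly (shortest-repr floats).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import LLOQ_MG_L, FixedEffects
from .popsim import OmegaSpec, SigmaSpec

DATASET_SCHEMA = "voripk-dataset v1"
PARAMS_SCHEMA = "voripk-params v1"
MANDATORY_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DV", "DVID")
ANALYTE_CODES = {1: "VCZ", 2: "VNO"}


class DatasetError(ValueError):
    """Validation failure with the offending row number in the message."""


@dataclass
class EventDataset:
    """Dose and dual-analyte observation events for a cohort, plus covariates."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        df = self.df
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise DatasetError(f"missing mandatory column {col!r}")
        if "BLQ" not in df.columns:
            self.df = df = df.assign(BLQ=0)
        for idx, row in df.iterrows():
            rowno = idx + 2  # header is line 1
            if row.TIME < 0:
                raise DatasetError(f"row {rowno}: negative TIME {row.TIME}")
            if row.EVID == 1:
                if not row.AMT > 0:
                    raise DatasetError(f"row {rowno}: dose with AMT {row.AMT}")
                if pd.notna(row.DV):
                    raise DatasetError(f"row {rowno}: dose row carries DV")
            elif row.EVID == 0:
                if int(row.DVID) not in ANALYTE_CODES:
                    raise DatasetError(f"row {rowno}: unknown DVID {row.DVID}")
                if pd.isna(row.DV):
                    raise DatasetError(f"row {rowno}: observation without DV")
            else:
                raise DatasetError(f"row {rowno}: unknown EVID {row.EVID}")
        for sid, sub in df.groupby("ID", sort=False):
            t = sub.TIME.to_numpy()
            if np.any(np.diff(t) < 0):
                raise DatasetError(f"subject {sid}: TIME not nondecreasing")

    # -- accessors ----------------------------------------------------------

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df.ID))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def observations(self, include_blq: bool = False) -> pd.DataFrame:
        obs = self.df[self.df.EVID == 0]
        return obs if include_blq else obs[obs.BLQ == 0]

    @property
    def n_observations(self) -> int:
        return len(self.observations())

    @property
    def n_blq(self) -> int:
        return int((self.df.EVID == 0).sum() - self.n_observations)

    def doses(self) -> pd.DataFrame:
        return self.df[self.df.EVID == 1]

    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns
                if c not in MANDATORY_COLUMNS and c != "BLQ"]

    def subject(self, sid) -> "SubjectData":
        sub = self.df[self.df.ID == sid]
        if sub.empty:
            raise KeyError(f"no subject {sid!r}")
        doses = sub[sub.EVID == 1]
        obs = sub[(sub.EVID == 0) & (sub.BLQ == 0)]
        cov = {c: sub[c].iloc[0] for c in self.covariate_columns()}
        return SubjectData(
            sid=sid,
            dose_times=doses.TIME.to_numpy(float),
            dose_amounts=doses.AMT.to_numpy(float),
            obs_times=obs.TIME.to_numpy(float),
            obs_values=obs.DV.to_numpy(float),
            obs_analytes=obs.DVID.to_numpy(int),
            covariates=cov,
        )

    def subjects(self) -> list["SubjectData"]:
        return [self.subject(sid) for sid in self.subject_ids]

    def resample_subjects(self, rng: np.random.Generator | None = None,
                          picks: np.ndarray | None = None) -> "EventDataset":
        """Bootstrap resample: subjects drawn with replacement, cohort size kept."""
        ids = self.subject_ids
        if picks is None:
            picks = rng.choice(len(ids), size=len(ids), replace=True)
        parts = []
        for new_id, k in enumerate(picks, start=1):
            part = self.df[self.df.ID == ids[k]].copy()
            part["ID"] = new_id
            parts.append(part)
        return EventDataset(pd.concat(parts, ignore_index=True))


@dataclass(frozen=True)
class SubjectData:
    """One subject's events unpacked into arrays, ready for the solver."""

    sid: object
    dose_times: np.ndarray
    dose_amounts: np.ndarray
    obs_times: np.ndarray
    obs_values: np.ndarray
    obs_analytes: np.ndarray  # 1 = VCZ, 2 = VNO
    covariates: dict


def read_dataset(path: str | Path) -> EventDataset:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        has_schema = first.startswith("#")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not has_schema and "ID" not in df.columns:
        raise DatasetError(f"{path}: no header line found")
    return EventDataset(df)


def write_dataset(ds: EventDataset, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {DATASET_SCHEMA}\n")
        ds.df.to_csv(fh, index=False, float_format="%.17g")


def flag_blq(df: pd.DataFrame, lloq: float = LLOQ_MG_L) -> pd.DataFrame:
    """Set BLQ = 1 on observation rows with DV below the quantification limit."""
    df = df.copy()
    is_obs = df.EVID == 0
    df.loc[is_obs, "BLQ"] = (df.loc[is_obs, "DV"] < lloq).astype(int)
    return df


# --- parameter files --------------------------------------------------------

_FIXED_FIELDS = [f.name for f in dataclasses.fields(FixedEffects)
                 if f.name != "fixed_mask"]


def write_params(path: str | Path, fixed: FixedEffects,
                 omega: OmegaSpec | None = None,
                 sigma: dict[str, SigmaSpec] | None = None) -> None:
    lines = [f"# {PARAMS_SCHEMA}"]
    for name in _FIXED_FIELDS:
        mark = "  fixed" if name in fixed.fixed_mask else ""
        lines.append(f"{name} = {getattr(fixed, name)!r}{mark}")
    if omega is not None:
        lines.append(f"omega_convention = {omega.convention}")
        for name in ("omega_V1", "omega_CL1", "omega_CL2", "omega_Vmax"):
            lines.append(f"{name} = {getattr(omega, name)!r}")
    if sigma is not None:
        for analyte, s in sigma.items():
            lines.append(f"sigma_{analyte} = {s.kind} {s.proportional!r} {s.additive!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: str | Path):
    """Read a parameter file; returns ``(FixedEffects, OmegaSpec|None, sigmas|None)``."""
    fixed_kw, fixed_mask = {}, []
    omega_kw: dict = {}
    sigma: dict[str, SigmaSpec] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "omega_convention":
            omega_kw["convention"] = value
        elif key.startswith("omega_"):
            omega_kw[key] = float(value)
        elif key.startswith("sigma_"):
            kind, prop, add = value.split()
            sigma[key.removeprefix("sigma_")] = SigmaSpec(
                kind, proportional=float(prop), additive=float(add))
        elif key in _FIXED_FIELDS:
            parts = value.split()
            fixed_kw[key] = float(parts[0])
            if len(parts) > 1 and parts[1] == "fixed":
                fixed_mask.append(key)
        else:
            raise ValueError(f"{path}: unknown parameter key {key!r}")
    fixed = FixedEffects(**fixed_kw, fixed_mask=tuple(fixed_mask))
    omega = OmegaSpec(**omega_kw) if any(k.startswith("omega_") and k != "omega_convention"
                                         for k in omega_kw) else None
    return fixed, omega, (sigma or None)


# --- run configuration ------------------------------------------------------


@dataclass
class RunConfig:
    """Settings shared by the command-line workflows; key=value text on disk."""

    seed: int = 1
    omega_convention: str = "cv_percent"
    rtol: float = 1e-8
    atol: float = 1e-10
    eta_tol: float = 1e-6
    n_subjects: int = 1000
    out_dir: str = "."
    extras: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        lines = ["# voripk-config v1"]
        for f_ in dataclasses.fields(self):
            if f_.name == "extras":
                continue
            lines.append(f"{f_.name} = {getattr(self, f_.name)}")
        for k, v in self.extras.items():
            lines.append(f"{k} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def read(path: str | Path) -> "RunConfig":
        cfg = RunConfig()
        casts = {f_.name: f_.type for f_ in dataclasses.fields(RunConfig)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("seed", "n_subjects"):
                setattr(cfg, key, int(value))
            elif key in ("rtol", "atol", "eta_tol"):
                setattr(cfg, key, float(value))
            elif key in casts:
                setattr(cfg, key, value)
            else:
                cfg.extras[key] = value
        return cfg
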