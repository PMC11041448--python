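"""Cohort data model, file I/O and the preprocessing/augmentation pipeline.

A cohort is a set of VV-ECMO runs: per patient a handful of static clinical
variables (age, sex, BMI, etiology, cannulation details, ventilation mode), a
binary decannulation outcome, and a multichannel perfusion time series sampled
by the device at ~120-second intervals.  This module turns raw runs into
model-ready samples: ratio-feature derivation, prefix-truncation augmentation,
standardization of every run onto a fixed-length time grid, one-hot encoding of
the static variables, and min-max scaling fitted on the training split only.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASE_CHANNELS",
    "DERIVED_CHANNELS",
    "ALL_CHANNELS",
    "DEFAULT_FRACTIONS",
    "DEFAULT_SCHEMA",
    "CohortFormatError",
    "CohortValidationError",
    "PatientRecord",
    "TruncatedRun",
    "Sample",
    "ScalerParams",
    "StaticSchema",
    "read_cohort",
    "write_cohort",
    "derive_ratio_features",
    "truncate_runs",
    "standardize_length",
    "encode_static",
    "build_samples",
    "fit_scaler",
    "apply_scaler",
]

#: The six device channels, in canonical column order.
BASE_CHANNELS = (
    "delta_pressure",   # pressure change across the membrane lung, mmHg
    "venous_pressure",  # venous drainage pressure, mmHg
    "flow",             # circuit blood flow, L/min
    "pump_speed",       # pump head rotation speed, RPM
    "sweep_flow",       # sweep gas flow, L/min
    "support_time",     # elapsed support time, s
)
#: Per-patient ratio channels appended by :func:`derive_ratio_features`.
DERIVED_CHANNELS = ("flow_per_bmi", "sweep_per_flow")
ALL_CHANNELS = BASE_CHANNELS + DERIVED_CHANNELS

#: Prefix fractions used for truncation augmentation (10% ... 100% of the run).
DEFAULT_FRACTIONS = tuple(round(0.1 * k, 1) for k in range(1, 11))

SECONDS_PER_DAY = 86400.0


class CohortFormatError(ValueError):
    """An input file does not have the expected columns/layout."""


class CohortValidationError(ValueError):
    """Input values violate the cohort contract (references, levels, ranges)."""


@dataclass(frozen=True)
class StaticSchema:
    """Fixed category orderings for the static one-hot encoding.

    The encoded vector is
    ``[age, bmi, reinfusion_size, drainage_size, sex, arrest, shock,
    onehot(cause), onehot(reinfusion_site), onehot(drainage_site),
    onehot(ventilation_type)]``; the outcome label is never encoded.
    """

    sex_levels: tuple = ("female", "male")
    cause_levels: tuple = (
        "ards_covid", "ards_bacterial", "ards_viral", "ards_other",
        "aspiration", "trauma", "pulmonary_embolism", "other",
    )
    reinfusion_site_levels: tuple = (
        "right_ij", "left_ij", "femoral", "subclavian", "dual_lumen",
    )
    drainage_site_levels: tuple = (
        "femoral", "right_ij", "left_ij", "subclavian", "dual_lumen",
    )
    ventilation_levels: tuple = (
        "volume_control", "pressure_control", "pressure_support",
        "aprv", "hfov", "spontaneous", "other",
    )

    @property
    def width(self) -> int:
        return (
            4  # age, bmi, reinfusion_size, drainage_size
            + 3  # sex, arrest_pre_ecmo, shock_pre_ecmo
            + len(self.cause_levels)
            + len(self.reinfusion_site_levels)
            + len(self.drainage_site_levels)
            + len(self.ventilation_levels)
        )


#: Default 32-wide static encoding schema.
DEFAULT_SCHEMA = StaticSchema()

_STATIC_COLUMNS = (
    "patient_id", "outcome", "age", "sex", "bmi", "cause",
    "arrest_pre_ecmo", "shock_pre_ecmo", "reinfusion_site", "drainage_site",
    "reinfusion_size", "drainage_size", "ventilation_type",
)
_NUMERIC_STATIC = ("age", "bmi", "reinfusion_size", "drainage_size")
_PERFUSION_COLUMNS = ("patient_id", "elapsed_seconds", "variable", "value")


@dataclass
class PatientRecord:
    """One VV-ECMO run: static clinical variables plus the raw perfusion series."""

    patient_id: str
    outcome: int
    age: float
    sex: str
    bmi: float
    cause: str
    arrest_pre_ecmo: int
    shock_pre_ecmo: int
    reinfusion_site: str
    drainage_site: str
    reinfusion_size: float
    drainage_size: float
    ventilation_type: str
    times: np.ndarray                      # (K,) elapsed seconds, strictly increasing
    perfusion: np.ndarray                  # (K, C) channel values
    channels: tuple = BASE_CHANNELS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.perfusion = np.asarray(self.perfusion, dtype=float)
        self.channels = tuple(self.channels)
        if self.outcome not in (0, 1):
            raise CohortValidationError(
                f"{self.patient_id}: outcome must be 0 or 1, got {self.outcome!r}")
        if not self.bmi > 0:
            raise CohortValidationError(f"{self.patient_id}: bmi must be > 0")
        if self.times.size == 0:
            raise CohortValidationError(f"{self.patient_id}: empty perfusion series")
        if self.perfusion.shape != (self.times.size, len(self.channels)):
            raise CohortValidationError(
                f"{self.patient_id}: perfusion shape {self.perfusion.shape} does not "
                f"match {self.times.size} time points x {len(self.channels)} channels")
        if np.any(np.diff(self.times) <= 0):
            raise CohortValidationError(
                f"{self.patient_id}: elapsed_seconds must be strictly increasing")

    @property
    def run_seconds(self) -> float:
        return float(self.times[-1])

    @property
    def run_hours(self) -> float:
        return self.run_seconds / 3600.0

    @property
    def run_days(self) -> float:
        return self.run_seconds / SECONDS_PER_DAY


@dataclass
class TruncatedRun:
    """A prefix of one patient's run, before length standardization."""

    patient_id: str
    label: int
    truncation_fraction: float
    times: np.ndarray
    values: np.ndarray
    end_day: float


@dataclass
class Sample:
    """The model's unit of input: one truncation, standardized and encoded."""

    patient_id: str
    truncation_fraction: float
    series: np.ndarray      # (T, V)
    static_vec: np.ndarray  # (width,)
    label: int
    end_day: float

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        self.static_vec = np.asarray(self.static_vec, dtype=float)
        if self.series.ndim != 2:
            raise CohortValidationError("Sample.series must be a T x V matrix")
        if self.end_day < 0:
            raise CohortValidationError("Sample.end_day must be >= 0")

    @property
    def end_hours(self) -> float:
        return self.end_day * 24.0


def _validate_levels(row: pd.Series, schema: StaticSchema) -> None:
    checks = (
        ("sex", schema.sex_levels),
        ("cause", schema.cause_levels),
        ("reinfusion_site", schema.reinfusion_site_levels),
        ("drainage_site", schema.drainage_site_levels),
        ("ventilation_type", schema.ventilation_levels),
    )
    for fieldname, levels in checks:
        value = row[fieldname]
        if value not in levels:
            raise CohortValidationError(
                f"patient {row['patient_id']}: unknown level {value!r} for "
                f"field '{fieldname}' (expected one of {levels})")


def read_cohort(static_path, perfusion_path, schema: StaticSchema = DEFAULT_SCHEMA,
                ) -> list[PatientRecord]:
    """Read a cohort from a static-variables CSV and a long-format perfusion CSV.

    The static CSV has one row per patient; the perfusion CSV has columns
    ``patient_id, elapsed_seconds, variable, value``.  Missing numeric static
    values are imputed with the cohort median (with a warning).  Perfusion rows
    referencing an unknown patient, or a patient with no perfusion rows, raise
    :class:`CohortValidationError`.
    """
    static = pd.read_csv(static_path, float_precision="round_trip")
    missing = [c for c in _STATIC_COLUMNS if c not in static.columns]
    if missing:
        raise CohortFormatError(f"static CSV missing required columns: {missing}")
    perf = pd.read_csv(perfusion_path, float_precision="round_trip")
    missing = [c for c in _PERFUSION_COLUMNS if c not in perf.columns]
    if missing:
        raise CohortFormatError(f"perfusion CSV missing required columns: {missing}")

    static = static.copy()
    static["patient_id"] = static["patient_id"].astype(str)
    perf["patient_id"] = perf["patient_id"].astype(str)

    known = set(static["patient_id"])
    orphans = sorted(set(perf["patient_id"]) - known)
    if orphans:
        raise CohortValidationError(
            f"perfusion rows reference patients absent from the static CSV: {orphans}")

    for col in _NUMERIC_STATIC:
        vals = pd.to_numeric(static[col], errors="coerce")
        if vals.isna().any():
            med = float(vals.median())
            n_bad = int(vals.isna().sum())
            warnings.warn(
                f"{n_bad} missing value(s) in static column '{col}' imputed "
                f"with cohort median {med:g}", stacklevel=2)
            vals = vals.fillna(med)
        static[col] = vals

    channels = sorted(perf["variable"].unique(),
                      key=lambda v: ALL_CHANNELS.index(v) if v in ALL_CHANNELS else 99)
    records = []
    grouped = dict(tuple(perf.groupby("patient_id", sort=False)))
    for _, row in static.iterrows():
        pid = row["patient_id"]
        _validate_levels(row, schema)
        if pid not in grouped:
            raise CohortValidationError(f"patient {pid}: no perfusion rows")
        wide = (grouped[pid]
                .pivot_table(index="elapsed_seconds", columns="variable",
                             values="value", aggfunc="mean")
                .sort_index())
        missing_ch = [c for c in channels if c not in wide.columns]
        if missing_ch:
            raise CohortFormatError(
                f"patient {pid}: perfusion channels {missing_ch} missing")
        records.append(PatientRecord(
            patient_id=pid,
            outcome=int(row["outcome"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            bmi=float(row["bmi"]),
            cause=str(row["cause"]),
            arrest_pre_ecmo=int(row["arrest_pre_ecmo"]),
            shock_pre_ecmo=int(row["shock_pre_ecmo"]),
            reinfusion_site=str(row["reinfusion_site"]),
            drainage_site=str(row["drainage_site"]),
            reinfusion_size=float(row["reinfusion_size"]),
            drainage_size=float(row["drainage_size"]),
            ventilation_type=str(row["ventilation_type"]),
            times=wide.index.to_numpy(dtype=float),
            perfusion=wide[list(channels)].to_numpy(dtype=float),
            channels=tuple(channels),
        ))
    return records


def write_cohort(records: Sequence[PatientRecord], static_path, perfusion_path,
                 manifest_path=None) -> None:
    """Write a cohort in the CSV formats accepted by :func:`read_cohort`."""
    static = pd.DataFrame([
        {c: getattr(r, c) for c in _STATIC_COLUMNS} for r in records
    ])
    static.to_csv(static_path, index=False)
    frames = []
    for r in records:
        k = r.times.size
        frames.append(pd.DataFrame({
            "patient_id": np.repeat(r.patient_id, k * len(r.channels)),
            "elapsed_seconds": np.tile(r.times, len(r.channels)),
            "variable": np.repeat(list(r.channels), k),
            "value": r.perfusion.T.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(perfusion_path, index=False)
    if manifest_path is not None:
        manifest = {
            "n_patients": len(records),
            "n_success": int(sum(r.outcome for r in records)),
            "channels": list(records[0].channels) if records else [],
            "static_columns": list(_STATIC_COLUMNS),
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)


def derive_ratio_features(record: PatientRecord) -> PatientRecord:
    """Append the two per-patient ratio channels flow/BMI and sweep/flow.

    Where the circuit flow is exactly zero the sweep/flow ratio is defined as 0
    (no-support semantics) rather than raising or producing infinities.
    """
    for ch in DERIVED_CHANNELS:
        if ch in record.channels:
            raise ValueError(f"channel '{ch}' already present")
    for ch in ("flow", "sweep_flow"):
        if ch not in record.channels:
            raise ValueError(f"cannot derive ratios: channel '{ch}' missing")
    flow = record.perfusion[:, record.channels.index("flow")]
    sweep = record.perfusion[:, record.channels.index("sweep_flow")]
    flow_per_bmi = flow / record.bmi
    sweep_per_flow = np.divide(sweep, flow, out=np.zeros_like(sweep),
                               where=flow != 0)
    return replace(
        record,
        perfusion=np.column_stack([record.perfusion, flow_per_bmi, sweep_per_flow]),
        channels=record.channels + DERIVED_CHANNELS,
    )


def truncate_runs(records: Sequence[PatientRecord],
                  fractions: Iterable[float] = DEFAULT_FRACTIONS,
                  ) -> list[TruncatedRun]:
    """Prefix-truncation augmentation: one raw sample per (patient, fraction).

    Each fraction ``f`` keeps the first ``ceil(f * K)`` time points of the run,
    so a cohort of N patients and F fractions yields exactly N*F samples.
    """
    fractions = [float(f) for f in fractions]
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"truncation fractions must lie in (0, 1], got {f}")
    out = []
    for r in records:
        k_total = r.times.size
        for f in fractions:
            k = max(1, math.ceil(f * k_total))
            out.append(TruncatedRun(
                patient_id=r.patient_id,
                label=r.outcome,
                truncation_fraction=f,
                times=r.times[:k],
                values=r.perfusion[:k],
                end_day=float(r.times[k - 1]) / SECONDS_PER_DAY,
            ))
    return out


def standardize_length(series: np.ndarray, T: int) -> np.ndarray:
    """Stretch/compress a K x V series onto a fixed T-step grid.

    Raw point ``k`` is assigned to grid slot ``floor(k*T/K)``; slots receiving
    several points take their mean, empty slots are forward-filled from the
    previous filled slot, and slots before the first filled slot are 0.  Every
    input, whatever its raw length, spans the full grid, so the grid position
    carries no information about run length.  An empty series maps to the
    all-zero matrix.
    """
    series = np.asarray(series, dtype=float)
    if int(T) < 1:
        raise ValueError("T must be >= 1")
    T = int(T)
    if series.ndim != 2:
        raise ValueError("series must be a K x V matrix")
    K, V = series.shape
    if K == 0:
        return np.zeros((T, V))
    idx = (np.arange(K) * T) // K
    sums = np.zeros((T, V))
    np.add.at(sums, idx, series)
    counts = np.bincount(idx, minlength=T).astype(float)
    filled = counts > 0
    means = np.zeros((T, V))
    means[filled] = sums[filled] / counts[filled, None]
    pos = np.maximum.accumulate(np.where(filled, np.arange(T), -1))
    out = np.zeros((T, V))
    ok = pos >= 0
    out[ok] = means[pos[ok]]
    return out


def encode_static(record: PatientRecord, schema: StaticSchema = DEFAULT_SCHEMA,
                  ) -> np.ndarray:
    """Encode the static clinical variables as a fixed-width numeric vector.

    Numerics pass through, binaries are 0/1, categoricals are one-hot in the
    schema's level order.  The outcome label is never part of the encoding.
    """
    def onehot(value, levels, fieldname):
        if value not in levels:
            raise CohortValidationError(
                f"patient {record.patient_id}: unknown level {value!r} for "
                f"field '{fieldname}'")
        vec = np.zeros(len(levels))
        vec[levels.index(value)] = 1.0
        return vec

    if record.sex not in schema.sex_levels:
        raise CohortValidationError(
            f"patient {record.patient_id}: unknown level {record.sex!r} for field 'sex'")
    parts = [
        np.array([record.age, record.bmi, record.reinfusion_size,
                  record.drainage_size], dtype=float),
        np.array([float(schema.sex_levels.index(record.sex)),
                  float(record.arrest_pre_ecmo),
                  float(record.shock_pre_ecmo)]),
        onehot(record.cause, schema.cause_levels, "cause"),
        onehot(record.reinfusion_site, schema.reinfusion_site_levels, "reinfusion_site"),
        onehot(record.drainage_site, schema.drainage_site_levels, "drainage_site"),
        onehot(record.ventilation_type, schema.ventilation_levels, "ventilation_type"),
    ]
    vec = np.concatenate(parts)
    assert vec.size == schema.width
    return vec


def build_samples(records: Sequence[PatientRecord],
                  fractions: Iterable[float] = DEFAULT_FRACTIONS,
                  T: int = 2054,
                  schema: StaticSchema = DEFAULT_SCHEMA) -> list[Sample]:
    """Full raw-to-sample pipeline: truncate, standardize length, encode statics."""
    statics = {r.patient_id: encode_static(r, schema) for r in records}
    samples = []
    for run in truncate_runs(records, fractions):
        samples.append(Sample(
            patient_id=run.patient_id,
            truncation_fraction=run.truncation_fraction,
            series=standardize_length(run.values, T),
            static_vec=statics[run.patient_id],
            label=run.label,
            end_day=run.end_day,
        ))
    return samples


@dataclass
class ScalerParams:
    """Per-feature min-max parameters, fitted on the training split only."""

    series_min: np.ndarray = None
    series_max: np.ndarray = None
    static_min: np.ndarray = None
    static_max: np.ndarray = None
    fitted_on: str = ""

    @property
    def is_fitted(self) -> bool:
        return self.series_min is not None


def fit_scaler(train_samples: Sequence[Sample], fitted_on: str = "train",
               ) -> ScalerParams:
    """Fit per-feature min/max on the training samples (series and statics)."""
    if not train_samples:
        raise ValueError("cannot fit a scaler on an empty training split")
    stacked = np.concatenate([s.series for s in train_samples], axis=0)
    statics = np.stack([s.static_vec for s in train_samples])
    return ScalerParams(
        series_min=stacked.min(axis=0), series_max=stacked.max(axis=0),
        static_min=statics.min(axis=0), static_max=statics.max(axis=0),
        fitted_on=fitted_on,
    )


def _minmax(x, lo, hi):
    span = hi - lo
    return np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)


def apply_scaler(params: ScalerParams, samples: Sequence[Sample]) -> list[Sample]:
    """Min-max transform samples with fitted params: x -> (x - min)/(max - min).

    Constant training features map to 0 everywhere; values outside the training
    range are not clipped, so transformed test values may leave [0, 1].
    """
    if not params.is_fitted:
        raise RuntimeError("scaler params are not fitted")
    out = []
    for s in samples:
        out.append(Sample(
            patient_id=s.patient_id,
            truncation_fraction=s.truncation_fraction,
            series=_minmax(s.series, params.series_min, params.series_max),
            static_vec=_minmax(s.static_vec, params.static_min, params.static_max),
            label=s.label,
            end_day=s.end_day,
        ))
    return out


def unscale(params: ScalerParams, series: np.ndarray) -> np.ndarray:
    """Invert the series min-max transform (non-constant features only)."""
    if not params.is_fitted:
        raise RuntimeError("scaler params are not fitted")
    return series * (params.series_max - params.series_min) + params.series_min
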