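"""Parametric generator of ECMO-like raw cohorts.

Stands in for an unavailable clinical cohort: ~118 patients with a ~90/28
success/failure split, runs lasting days to weeks sampled every 120 s, and
jittery, autocorrelated perfusion traces.  Each device channel is a per-patient
baseline plus an Ornstein-Uhlenbeck (AR(1)) noise process; an outcome-dependent
linear ramp over the final quarter of the run encodes weaning (in successful
patients circuit flow, pump speed and sweep gas flow decline; in unsuccessful
patients they stay flat).  The ramp magnitude is ``effect_size`` ramp units,
one unit being the channel's stationary noise SD, so ``effect_size = 0`` makes
the two outcome groups identical in law.  Static variables are always drawn
independently of outcome, so any learnable signal is purely temporal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .cohort import (
    BASE_CHANNELS,
    DEFAULT_SCHEMA,
    PatientRecord,
    StaticSchema,
    derive_ratio_features,
)

__all__ = ["CohortSpec", "generate_patient", "generate_cohort",
           "NOISE_SD", "RAMP_CHANNELS"]

# Per-channel baseline mean, between-patient SD of the baseline, and the
# stationary SD of the within-run noise (plausible adult VV-ECMO magnitudes).
_BASELINES = {
    "delta_pressure": (15.0, 4.0),    # mmHg
    "venous_pressure": (-60.0, 12.0),  # mmHg
    "flow": (4.5, 0.6),               # L/min
    "pump_speed": (3200.0, 300.0),    # RPM
    "sweep_flow": (4.0, 1.0),         # L/min
}
NOISE_SD = {
    "delta_pressure": 3.0,
    "venous_pressure": 8.0,
    "flow": 0.4,
    "pump_speed": 120.0,
    "sweep_flow": 0.5,
}
#: Channels carrying the outcome-dependent weaning ramp (they decline when
#: weaning succeeds); the ramp unit for each is its stationary noise SD.
RAMP_CHANNELS = ("flow", "pump_speed", "sweep_flow")


@dataclass
class CohortSpec:
    """Study conditions for one generated cohort."""

    n_success: int = 90
    n_fail: int = 28
    run_length_range: tuple = (72.0, 504.0)  # hours (3 days to 3 weeks)
    sample_interval: float = 120.0           # seconds
    effect_size: float = 1.0                 # ramp magnitude, noise-SD units
    noise_sd: dict = field(default_factory=lambda: dict(NOISE_SD))
    smoothness: float = 2.0                  # OU correlation time, hours
    seed: int = 0

    def validate(self) -> None:
        if self.n_success < 0 or self.n_fail < 0:
            raise ValueError("patient counts must be >= 0")
        lo, hi = self.run_length_range
        if not (0 < lo <= hi):
            raise ValueError("run_length_range must be positive with min <= max")
        if self.sample_interval <= 0 or self.smoothness <= 0:
            raise ValueError("sample_interval and smoothness must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be positive")


def _ou_noise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1)/discretized-OU noise with lag-1 correlation ``phi``."""
    eps = rng.standard_normal(n)
    innov = eps * sd * np.sqrt(1.0 - phi ** 2)
    innov[0] = eps[0] * sd  # start at the stationary distribution
    return lfilter([1.0], [1.0, -phi], innov)


def generate_patient(outcome: int, spec: CohortSpec, rng: np.random.Generator,
                     patient_id: str = "synthetic",
                     schema: StaticSchema = DEFAULT_SCHEMA) -> PatientRecord:
    """Draw one synthetic patient; randomness comes only from ``rng``.

    The random stream is consumed identically for both outcomes, so with
    ``effect_size = 0`` the generating law (and, for the same generator state,
    the realized record apart from the label) is outcome-independent.
    """
    spec.validate()
    age = float(np.clip(rng.normal(50.0, 15.0), 18.0, 80.0))
    bmi = float(np.clip(rng.normal(28.0, 6.0), 15.0, 60.0))
    statics = dict(
        age=age,
        bmi=bmi,
        sex=str(rng.choice(schema.sex_levels)),
        cause=str(rng.choice(schema.cause_levels)),
        arrest_pre_ecmo=int(rng.random() < 0.2),
        shock_pre_ecmo=int(rng.random() < 0.3),
        reinfusion_site=str(rng.choice(schema.reinfusion_site_levels)),
        drainage_site=str(rng.choice(schema.drainage_site_levels)),
        reinfusion_size=float(rng.choice([19.0, 21.0, 23.0, 25.0])),
        drainage_size=float(rng.choice([23.0, 25.0, 27.0, 29.0])),
        ventilation_type=str(rng.choice(schema.ventilation_levels)),
    )
    hours = rng.uniform(*spec.run_length_range)
    dt = spec.sample_interval
    k = max(2, int(round(hours * 3600.0 / dt)))
    times = (np.arange(k) + 1) * dt
    phi = float(np.exp(-dt / (spec.smoothness * 3600.0)))

    # Linear weaning ramp over the final quarter of the run: 0 until 75% of the
    # run, then down to 2*effect_size ramp units at the end (mean depth over the
    # final quartile = effect_size units).  Zero for unsuccessful weaning.
    rel = times / times[-1]
    ramp_shape = np.clip((rel - 0.75) / 0.25, 0.0, None)
    ramp_sign = -1.0 if outcome == 1 else 0.0

    columns = []
    for ch in BASE_CHANNELS:
        if ch == "support_time":
            columns.append(times.astype(float))
            continue
        mean, between_sd = _BASELINES[ch]
        baseline = rng.normal(mean, between_sd)
        trace = baseline + _ou_noise(k, spec.noise_sd[ch], phi, rng)
        if ch in RAMP_CHANNELS:
            trace = trace + ramp_sign * 2.0 * spec.effect_size * spec.noise_sd[ch] * ramp_shape
        columns.append(trace)
    perfusion = np.column_stack(columns)
    # keep flows/speeds physically non-negative
    for ch in ("flow", "pump_speed", "sweep_flow"):
        j = BASE_CHANNELS.index(ch)
        perfusion[:, j] = np.maximum(perfusion[:, j], 0.0)

    record = PatientRecord(
        patient_id=patient_id, outcome=int(outcome),
        times=times, perfusion=perfusion, channels=BASE_CHANNELS,
        **statics,
    )
    return derive_ratio_features(record)


def generate_cohort(spec: CohortSpec, schema: StaticSchema = DEFAULT_SCHEMA,
                    ) -> list[PatientRecord]:
    """Generate ``n_success + n_fail`` patients, reproducibly under ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = []
    labels = [1] * spec.n_success + [0] * spec.n_fail
    for i, y in enumerate(labels):
        records.append(generate_patient(
            y, spec, rng, patient_id=f"synth{i + 1:04d}", schema=schema))
    return records
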