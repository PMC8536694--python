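"""Synthetic MOS eNose cohorts with the covariance structure of urine-headspace studies.

The simulator produces resistance curves

.. math::

    R_s(t) = R^0_s \\cdot d \\cdot (1 - a_s\\, g(t)) \\cdot (1 + \\varepsilon_s(t)),

where :math:`g(t)` is a first-order exponential on/off response (0 on the
baseline, :math:`1 - e^{-(t - t_\\mathrm{on})/\\tau_\\mathrm{on}}` during
exposure, exponential recovery with :math:`\\tau_\\mathrm{off}` afterwards),
:math:`d` is a per-day log-normal baseline multiplier (the between-day shift
that SNV preprocessing removes), and :math:`\\varepsilon` is iid Gaussian
relative measurement noise.

The fractional response amplitude of sensor *s* factorises as

    a_s = amplitude_control[s] x class_effect[s] (PCa only)
          x temperature_factor x portion_factor x subject_multiplier
          + jitter_s,

with a shared log-normal subject multiplier (donor-to-donor headspace
concentration) and an *additive* per-recording, per-sensor amplitude jitter
(background volatiles and chamber variability, which do not scale with
headspace enrichment).  The additive term is what makes weakly enriched
headspaces (low conditioning temperature, final urination portion) genuinely
harder to classify: the class pattern shrinks with the enrichment factors
while this noise floor does not.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .recording import (
    PORTIONS,
    TEMPERATURES,
    SampleMeta,
    SensorRecording,
    default_phases,
)

__all__ = [
    "CohortConfig",
    "simulate_recording",
    "simulate_cohort",
    "simulate_feature_matrix",
    "effective_amplitude",
]

_AMP_FLOOR = 1e-4
_AMP_CEIL = 0.999


@dataclass
class CohortConfig:
    """Parameters of a simulated urine-headspace eNose study.

    Defaults encode the reference protocol and study conditions: a 6-sensor
    array sampled at 1 Hz, 300 s baseline / 3000 s exposure / 1800 s
    recovery, a modelling cohort of 110 PCa and 54 control subjects, and
    class/temperature/portion effect sizes calibrated so the default cohort
    reaches the diagnostic-performance band reported for 60 degC first-portion
    analyses.

    Parameters
    ----------
    n_pca, n_control : int
        Subjects per diagnostic class.
    repeats_per_subject : int
        Recordings per subject, each on a distinct measurement day.
    amplitude_control : sequence of float
        Per-sensor fractional response amplitude of a control sample at the
        reference condition (60 degC, first portion); must lie in (0, 1).
    class_effect : sequence of float
        Multiplicative amplitude factor applied to PCa samples, per sensor.
        Default raises sensors 1 and 4 (sensor 1 dominant, the zinc-oxide
        analogue of the physical array).
    day_scale_sd : float
        SD of the log-normal per-day baseline multiplier (removed by SNV).
    noise_sd : float
        Relative SD of the multiplicative measurement noise.
    subject_sd : float
        SD of the log-normal per-subject amplitude multiplier, shared by
        all sensors of one subject.
    amplitude_jitter_sd : float
        SD of the additive per-recording, per-sensor amplitude perturbation
        (absolute units; does not scale with the enrichment factors).
    tau_on_s, tau_off_s : float
        Exposure/recovery first-order time constants.
    temperature_factor : mapping
        Amplitude multiplier per conditioning temperature; strictly
        increasing in temperature.
    portion_factor : mapping
        Amplitude multiplier per urination portion; ``final`` is far below
        ``first`` and ``catheter`` is at least ``midstream``.
    temperature_c, portion :
        Condition at which the whole cohort is acquired.
    n_days : int
        Size of the measurement-day pool.
    seed : int
        Master seed; every draw is a deterministic function of it.
    """

    n_pca: int = 110
    n_control: int = 54
    repeats_per_subject: int = 1
    sensors: int = 6
    sampling_hz: float = 1.0
    baseline_s: float = 300.0
    exposure_s: float = 3000.0
    recovery_s: float = 1800.0
    amplitude_control: Sequence[float] = (0.30, 0.22, 0.26, 0.20, 0.24, 0.18)
    class_effect: Sequence[float] = (1.40, 1.0, 1.0, 1.20, 1.0, 1.0)
    baseline_resistance_ohm: Sequence[float] = (
        250e3,
        120e3,
        180e3,
        90e3,
        150e3,
        60e3,
    )
    day_scale_sd: float = 0.2
    noise_sd: float = 0.01
    subject_sd: float = 0.05
    amplitude_jitter_sd: float = 0.04
    tau_on_s: float = 120.0
    tau_off_s: float = 120.0
    temperature_factor: Mapping[int, float] = field(
        default_factory=lambda: {23: 0.12, 37: 0.30, 50: 0.60, 60: 1.0}
    )
    portion_factor: Mapping[str, float] = field(
        default_factory=lambda: {
            "first": 1.0,
            "midstream": 0.85,
            "final": 0.25,
            "catheter": 0.95,
        }
    )
    temperature_c: int = 60
    portion: str = "first"
    n_days: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        self.amplitude_control = np.asarray(self.amplitude_control, dtype=float)
        self.class_effect = np.asarray(self.class_effect, dtype=float)
        self.baseline_resistance_ohm = np.asarray(
            self.baseline_resistance_ohm, dtype=float
        )
        self.validate()

    def validate(self) -> None:
        for name in (
            "sampling_hz",
            "baseline_s",
            "exposure_s",
            "recovery_s",
            "tau_on_s",
            "tau_off_s",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v}")
        for name in ("day_scale_sd", "noise_sd", "subject_sd", "amplitude_jitter_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative finite number")
        for arr_name in ("amplitude_control", "class_effect", "baseline_resistance_ohm"):
            arr = getattr(self, arr_name)
            if arr.shape != (self.sensors,):
                raise ValueError(
                    f"{arr_name} must have one entry per sensor ({self.sensors})"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{arr_name} contains non-finite values")
        if np.any(self.amplitude_control <= 0) or np.any(self.amplitude_control >= 1):
            raise ValueError("amplitude_control entries must lie in (0, 1)")
        if np.any(self.class_effect <= 0):
            raise ValueError("class_effect entries must be positive")
        if np.any(self.baseline_resistance_ohm <= 0):
            raise ValueError("baseline_resistance_ohm entries must be positive")
        temps = sorted(self.temperature_factor)
        if list(temps) != sorted(TEMPERATURES):
            raise ValueError(f"temperature_factor must map exactly {TEMPERATURES}")
        vals = [self.temperature_factor[t] for t in temps]
        if not all(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("temperature_factor must be strictly increasing")
        if sorted(self.portion_factor) != sorted(PORTIONS):
            raise ValueError(f"portion_factor must map exactly {PORTIONS}")
        pf = self.portion_factor
        if not pf["final"] < pf["first"]:
            raise ValueError("portion_factor['final'] must be below ['first']")
        if not pf["catheter"] >= pf["midstream"]:
            raise ValueError("portion_factor['catheter'] must be >= ['midstream']")
        if self.temperature_c not in self.temperature_factor:
            raise ValueError(f"temperature_c must be one of {TEMPERATURES}")
        if self.portion not in self.portion_factor:
            raise ValueError(f"portion must be one of {PORTIONS}")
        if self.n_days < self.repeats_per_subject:
            raise ValueError("n_days must be at least repeats_per_subject")

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        for k in ("amplitude_control", "class_effect", "baseline_resistance_ohm"):
            d[k] = [float(x) for x in d[k]]
        d["temperature_factor"] = {int(k): float(v) for k, v in d["temperature_factor"].items()}
        path = Path(path)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def _sample_rng(config: CohortConfig, sample_id: str) -> np.random.Generator:
    """Per-sample RNG, a pure function of (config.seed, sample_id)."""
    return np.random.default_rng(
        [int(config.seed) % (2**31), zlib.crc32(sample_id.encode())]
    )


def effective_amplitude(config: CohortConfig, meta: SampleMeta) -> np.ndarray:
    """Deterministic per-sensor amplitude before subject/jitter randomness."""
    a = np.array(config.amplitude_control, dtype=float)
    if meta.class_label == "PCa":
        a = a * config.class_effect
    a = a * config.temperature_factor[meta.conditioning_temperature_c]
    a = a * config.portion_factor[meta.urine_portion]
    return a


def _response_shape(config: CohortConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Time vector, normalized response g(t) in [0, 1], and phase windows."""
    phases = default_phases(
        config.baseline_s, config.exposure_s, config.recovery_s, config.sampling_hz
    )
    n = phases["after"][1]
    t = np.arange(n, dtype=float) / config.sampling_hz
    g = np.zeros(n)
    b0, b1 = phases["during"]
    t_on = b0 / config.sampling_hz
    g[b0:b1] = 1.0 - np.exp(-(t[b0:b1] - t_on) / config.tau_on_s)
    a0, a1 = phases["after"]
    t_off = a0 / config.sampling_hz
    g_end = 1.0 - np.exp(-config.exposure_s / config.tau_on_s)
    g[a0:a1] = g_end * np.exp(-(t[a0:a1] - t_off) / config.tau_off_s)
    return t, g, phases


def simulate_recording(
    config: CohortConfig,
    meta: SampleMeta,
    subject_multiplier: float = 1.0,
    day_multiplier: float = 1.0,
) -> SensorRecording:
    """Simulate one recording for a sample with the given metadata.

    The per-sample amplitude jitter and measurement noise are seeded from
    ``(config.seed, meta.sample_id)``, so the call is reproducible and
    independent of call order.

    Raises
    ------
    ValueError
        If a multiplier is not positive/finite, or the deterministic
        amplitude of any sensor reaches 1 (resistance would cross zero).
    """
    for name, v in (("subject_multiplier", subject_multiplier), ("day_multiplier", day_multiplier)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v}")
    a = effective_amplitude(config, meta) * subject_multiplier
    if np.any(a >= 1.0):
        raise ValueError(
            "effective amplitude >= 1 for sensor(s) "
            f"{np.flatnonzero(a >= 1.0) + 1}: resistance would cross zero"
        )
    rng = _sample_rng(config, meta.sample_id)
    if config.amplitude_jitter_sd > 0:
        a = a + rng.normal(0.0, config.amplitude_jitter_sd, size=config.sensors)
    else:
        # keep the RNG stream aligned whether or not jitter is active
        rng.normal(0.0, 1.0, size=config.sensors)
    if np.any(a <= 0) or np.any(a >= 1):
        warnings.warn(
            f"amplitude clipped to ({_AMP_FLOOR}, {_AMP_CEIL}) for sample "
            f"{meta.sample_id}",
            stacklevel=2,
        )
        a = np.clip(a, _AMP_FLOOR, _AMP_CEIL)

    t, g, phases = _response_shape(config)
    clean = 1.0 - a[:, None] * g[None, :]
    R = config.baseline_resistance_ohm[:, None] * day_multiplier * clean
    if config.noise_sd > 0:
        R = R * (1.0 + rng.normal(0.0, config.noise_sd, size=R.shape))
        R = np.maximum(R, 1e-6)  # guard: noise cannot flip resistance sign
    return SensorRecording(
        time_s=t,
        resistance=R,
        sampling_hz=config.sampling_hz,
        phases=phases,
        meta=meta,
    )


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[SensorRecording], list[SampleMeta]]:
    """Simulate a full cohort of recordings.

    Each subject contributes ``repeats_per_subject`` recordings on distinct
    measurement days; per-subject and per-day multipliers are drawn once and
    shared by all recordings of that subject/day.  Deterministic under
    ``config.seed``.
    """
    if config.n_pca < 1 or config.n_control < 1:
        raise ValueError("both classes need at least one subject")
    rng = np.random.default_rng(int(config.seed) % (2**31))
    day_multipliers = np.exp(rng.normal(0.0, config.day_scale_sd, size=config.n_days))

    subjects: list[tuple[str, str]] = [
        (f"PCa{i + 1:04d}", "PCa") for i in range(config.n_pca)
    ] + [(f"S{i + 1:04d}", "S") for i in range(config.n_control)]

    recordings: list[SensorRecording] = []
    metas: list[SampleMeta] = []
    for subject_id, label in subjects:
        subject_multiplier = float(np.exp(rng.normal(0.0, config.subject_sd)))
        days = rng.choice(config.n_days, size=config.repeats_per_subject, replace=False)
        for r, day in enumerate(sorted(int(d) for d in days)):
            meta = SampleMeta(
                sample_id=f"{subject_id}_r{r + 1}",
                subject_id=subject_id,
                class_label=label,
                day_index=day,
                conditioning_temperature_c=config.temperature_c,
                urine_portion=config.portion,
            )
            rec = simulate_recording(
                config,
                meta,
                subject_multiplier=subject_multiplier,
                day_multiplier=float(day_multipliers[day]),
            )
            recordings.append(rec)
            metas.append(meta)
    return recordings, metas


def simulate_feature_matrix(
    n_samples: int = 200,
    n_informative: int = 10,
    n_noise: int = 140,
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian feature matrix with a known informative/noise split.

    Informative columns are shifted by ``effect`` standard deviations in the
    PCa class; noise columns are pure N(0, 1).  Used to probe feature
    selection against ground truth.

    Returns
    -------
    X : DataFrame, columns ``inf_1.. / noise_1..``
    y : ndarray of ``"PCa"``/``"S"`` labels (balanced).
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    n_pos = n_samples // 2
    y = np.array(["PCa"] * n_pos + ["S"] * (n_samples - n_pos))
    shift = np.where(y == "PCa", effect, 0.0)[:, None]
    X_inf = rng.normal(size=(n_samples, n_informative)) + shift
    X_noise = rng.normal(size=(n_samples, n_noise))
    cols = [f"inf_{i + 1}" for i in range(n_informative)] + [
        f"noise_{i + 1}" for i in range(n_noise)
    ]
    X = pd.DataFrame(np.hstack([X_inf, X_noise]), columns=cols)
    perm = rng.permutation(n_samples)
    return X.iloc[perm].reset_index(drop=True), y[perm]
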