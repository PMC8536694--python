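"""Response-curve feature extraction (steady-state and transient descriptors).

Eight descriptor families are computed per sensor, on either the raw or the
SNV-standardized curve:

====  =======================================================================
A     ``C = R_during / R_0`` — relative resistance at an exposure timepoint
B     ``delta = R_during - R_0`` — absolute drop at an exposure timepoint
C     ``delta = R_after - R_0`` — recovery residual at a recovery timepoint
D     ``R_min`` — minimum resistance reached during exposure
E     ``DR = (R(t3) - R(t2)) / (R(t2) - R(t1))`` — derivative ratio
F     ``LD = R(t2) - R(t1)`` — local difference on the exposure transient
G     extremum of the smoothed difference filter
      ``y[k] = (1 - alpha) y[k-1] + alpha (x[k] - x[k-1])``, ``y[0] = 0``
H     ``R_0 / R_min`` — response intensity (always on the raw curve)
====  =======================================================================

Under the default grids each sensor yields 5 (A) + 5 (B) + 3 (C) + 1 (D) +
4 (E) + 4 (F) + 2 (G) + 1 (H) = 25 descriptors, i.e. a 150-dimensional
feature space for the 6-sensor array.

Timepoints are offsets in seconds into the owning phase window; the value at
a timepoint is the median over a +/-15 s neighbourhood (configurable), for
robustness against sample-level noise.  An offset equal to the phase
duration refers to the last sample of the phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import response_intensity, snv
from .recording import SampleMeta, SensorRecording

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "extract_features",
    "extract_feature_matrix",
    "feature_A",
    "feature_B",
    "feature_C",
    "feature_D",
    "feature_E",
    "feature_F",
    "feature_G",
    "feature_H",
]

logger = logging.getLogger(__name__)

#: |R(t2) - R(t1)| below this is treated as a degenerate denominator for E.
E_DENOM_TOL = 1e-12


@dataclass
class FeatureConfig:
    """Timepoint grids and options of the feature extractor.

    All offsets are seconds into the owning phase window.  The default grids
    give exactly 25 descriptors per sensor (150 for a 6-sensor array).
    """

    during_points: Sequence[float] = (600, 1200, 1800, 2400, 3000)
    after_points: Sequence[float] = (600, 1200, 1800)
    triples: Sequence[tuple[float, float, float]] = (
        (60, 300, 600),
        (60, 600, 1200),
        (300, 900, 1800),
        (600, 1800, 3000),
    )
    pairs: Sequence[tuple[float, float]] = (
        (60, 300),
        (300, 900),
        (600, 1800),
        (1200, 3000),
    )
    alphas: Sequence[float] = (0.1, 0.5)
    use_snv: bool = True
    halfwidth_s: float = 15.0

    def __post_init__(self) -> None:
        for t1, t2, t3 in self.triples:
            if not t1 < t2 < t3:
                raise ValueError(f"triple {(t1, t2, t3)} must be strictly increasing")
        for t1, t2 in self.pairs:
            if not t1 < t2:
                raise ValueError(f"pair {(t1, t2)} must be strictly increasing")
        for a in self.alphas:
            if not 0 < a < 1:
                raise ValueError(f"alpha must lie in (0, 1), got {a}")
        if self.halfwidth_s < 0:
            raise ValueError("halfwidth_s must be non-negative")

    @property
    def n_per_sensor(self) -> int:
        return (
            len(self.during_points)
            + len(self.during_points)
            + len(self.after_points)
            + 1
            + len(self.triples)
            + len(self.pairs)
            + len(self.alphas)
            + 1
        )

    def n_features(self, n_sensors: int = 6) -> int:
        return n_sensors * self.n_per_sensor


@dataclass
class FeatureVector:
    """Named feature values of one recording."""

    values: pd.Series
    meta: SampleMeta

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# curve access helpers
# ---------------------------------------------------------------------------

def _working_curves(rec: SensorRecording, use_snv: bool) -> np.ndarray:
    return snv(rec).signal if use_snv else rec.resistance


def _point_value(
    x: np.ndarray,
    phases,
    phase: str,
    offset_s: float,
    hz: float,
    halfwidth_s: float,
) -> float:
    lo, hi = phases[phase]
    idx = lo + int(round(offset_s * hz))
    if not lo <= idx <= hi:
        raise ValueError(
            f"timepoint {offset_s} s outside the {phase} window "
            f"(0..{(hi - lo) / hz:g} s)"
        )
    idx = min(idx, hi - 1)
    w = int(round(halfwidth_s * hz))
    a = max(lo, idx - w)
    b = min(hi, idx + w + 1)
    return float(np.median(x[a:b]))


def _r0(x: np.ndarray, phases) -> float:
    lo, hi = phases["baseline"]
    if hi <= lo:
        raise ValueError("empty baseline window")
    return float(np.median(x[lo:hi]))


# ---------------------------------------------------------------------------
# per-feature operations
# ---------------------------------------------------------------------------

def feature_A(
    rec: SensorRecording,
    sensor: int,
    t_during: float,
    *,
    use_snv: bool = True,
    halfwidth_s: float = 15.0,
) -> float:
    """A: ratio ``R_during / R_0`` at an exposure timepoint."""
    x = _working_curves(rec, use_snv)[sensor]
    r0 = _r0(x, rec.phases)
    if r0 == 0:
        raise ValueError("R_0 is zero; ratio feature undefined")
    return _point_value(x, rec.phases, "during", t_during, rec.sampling_hz, halfwidth_s) / r0


def feature_B(
    rec: SensorRecording,
    sensor: int,
    t_during: float,
    *,
    use_snv: bool = True,
    halfwidth_s: float = 15.0,
) -> float:
    """B: difference ``R_during - R_0`` at an exposure timepoint."""
    x = _working_curves(rec, use_snv)[sensor]
    return (
        _point_value(x, rec.phases, "during", t_during, rec.sampling_hz, halfwidth_s)
        - _r0(x, rec.phases)
    )


def feature_C(
    rec: SensorRecording,
    sensor: int,
    t_after: float,
    *,
    use_snv: bool = True,
    halfwidth_s: float = 15.0,
) -> float:
    """C: recovery residual ``R_after - R_0`` at a recovery timepoint."""
    x = _working_curves(rec, use_snv)[sensor]
    return (
        _point_value(x, rec.phases, "after", t_after, rec.sampling_hz, halfwidth_s)
        - _r0(x, rec.phases)
    )


def feature_D(rec: SensorRecording, sensor: int, *, use_snv: bool = True) -> float:
    """D: minimum value reached during exposure (R_min)."""
    lo, hi = rec.phases["during"]
    if hi <= lo:
        raise ValueError("empty exposure window")
    x = _working_curves(rec, use_snv)[sensor]
    return float(x[lo:hi].min())


def feature_E(
    rec: SensorRecording,
    sensor: int,
    t1: float,
    t2: float,
    t3: float,
    *,
    use_snv: bool = True,
    halfwidth_s: float = 15.0,
) -> float:
    """E: derivative ratio ``(R(t3) - R(t2)) / (R(t2) - R(t1))``.

    A denominator below ``E_DENOM_TOL`` in magnitude yields 0.0 with a
    logged warning, keeping the feature matrix finite.
    """
    if not t1 < t2 < t3:
        raise ValueError("feature E requires t1 < t2 < t3")
    x = _working_curves(rec, use_snv)[sensor]
    v = [
        _point_value(x, rec.phases, "during", t, rec.sampling_hz, halfwidth_s)
        for t in (t1, t2, t3)
    ]
    denom = v[1] - v[0]
    if abs(denom) < E_DENOM_TOL:
        logger.warning(
            "feature E: degenerate denominator |R(t2)-R(t1)| < %g for sensor %d; "
            "returning 0",
            E_DENOM_TOL,
            sensor + 1,
        )
        return 0.0
    return (v[2] - v[1]) / denom


def feature_F(
    rec: SensorRecording,
    sensor: int,
    t1: float,
    t2: float,
    *,
    use_snv: bool = True,
    halfwidth_s: float = 15.0,
) -> float:
    """F: local difference ``R(t2) - R(t1)`` on the exposure transient."""
    if not t1 < t2:
        raise ValueError("feature F requires t1 < t2")
    x = _working_curves(rec, use_snv)[sensor]
    return _point_value(
        x, rec.phases, "during", t2, rec.sampling_hz, halfwidth_s
    ) - _point_value(x, rec.phases, "during", t1, rec.sampling_hz, halfwidth_s)


def feature_G(
    rec: SensorRecording, sensor: int, alpha: float, *, use_snv: bool = True
) -> float:
    """G: extremum of the exponentially smoothed first difference.

    ``y[k] = (1 - alpha) y[k-1] + alpha (x[k] - x[k-1])`` with ``y[0] = 0``,
    over baseline + exposure; the scalar reported is ``min_k y[k]`` (the
    steepest smoothed descent, most negative for a responding MOS sensor).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    stop = rec.phases["during"][1]
    x = _working_curves(rec, use_snv)[sensor, :stop]
    if x.size < 2:
        return 0.0
    dx = np.diff(x)
    y = lfilter([alpha], [1.0, -(1.0 - alpha)], dx)
    return float(min(0.0, y.min()))


def feature_H(rec: SensorRecording, sensor: int) -> float:
    """H: response intensity ``R_0 / R_min`` on the raw curve.

    Always computed on raw resistance: as a ratio it is invariant to the
    multiplicative day/baseline scale, while carrying the absolute response
    amplitude that SNV deliberately discards.
    """
    return response_intensity(rec, sensor)


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_features(
    rec: SensorRecording, config: FeatureConfig | None = None
) -> FeatureVector:
    """Extract the full named descriptor set from one recording.

    Under the default configuration the result has exactly 150 entries
    (6 sensors x 25 descriptors).  Names encode sensor, family and
    timepoint(s), e.g. ``s1_A_t600`` or ``s3_E_300_900_1800``.
    """
    cfg = config or FeatureConfig()
    work = _working_curves(rec, cfg.use_snv)
    names: list[str] = []
    values: list[float] = []

    def add(name: str, fn, *args, **kwargs):
        try:
            values.append(fn(*args, **kwargs))
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc
        names.append(name)

    hw = cfg.halfwidth_s
    for s in range(rec.n_sensors):
        x = work[s]
        r0 = _r0(x, rec.phases)
        tag = f"s{s + 1}"
        for t in cfg.during_points:
            add(
                f"{tag}_A_t{t:g}",
                lambda t=t, x=x, r0=r0: _point_value(
                    x, rec.phases, "during", t, rec.sampling_hz, hw
                )
                / r0,
            )
        for t in cfg.during_points:
            add(
                f"{tag}_B_t{t:g}",
                lambda t=t, x=x, r0=r0: _point_value(
                    x, rec.phases, "during", t, rec.sampling_hz, hw
                )
                - r0,
            )
        for t in cfg.after_points:
            add(
                f"{tag}_C_t{t:g}",
                lambda t=t, x=x, r0=r0: _point_value(
                    x, rec.phases, "after", t, rec.sampling_hz, hw
                )
                - r0,
            )
        add(f"{tag}_D", feature_D, rec, s, use_snv=cfg.use_snv)
        for t1, t2, t3 in cfg.triples:
            add(
                f"{tag}_E_{t1:g}_{t2:g}_{t3:g}",
                feature_E,
                rec,
                s,
                t1,
                t2,
                t3,
                use_snv=cfg.use_snv,
                halfwidth_s=hw,
            )
        for t1, t2 in cfg.pairs:
            add(
                f"{tag}_F_{t1:g}_{t2:g}",
                feature_F,
                rec,
                s,
                t1,
                t2,
                use_snv=cfg.use_snv,
                halfwidth_s=hw,
            )
        for a in cfg.alphas:
            add(f"{tag}_G_a{a:g}", feature_G, rec, s, a, use_snv=cfg.use_snv)
        add(f"{tag}_H", feature_H, rec, s)

    series = pd.Series(values, index=names, dtype=float)
    if series.index.has_duplicates:
        raise ValueError("duplicate feature names in configuration")
    if not np.all(np.isfinite(series.to_numpy())):
        bad = series.index[~np.isfinite(series.to_numpy())].tolist()
        raise ValueError(f"non-finite feature values: {bad}")
    return FeatureVector(values=series, meta=rec.meta)


def extract_feature_matrix(
    recordings: Sequence[SensorRecording], config: FeatureConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract features for a cohort.

    Returns
    -------
    X : DataFrame
        Samples x features, indexed by sample_id.
    meta : DataFrame
        Per-sample metadata aligned with ``X``.
    """
    cfg = config or FeatureConfig()
    rows = [extract_features(rec, cfg) for rec in recordings]
    X = pd.DataFrame(
        [fv.values for fv in rows],
        index=[fv.meta.sample_id for fv in rows],
    )
    X.index.name = "sample_id"
    meta = pd.DataFrame(
        [
            {
                "sample_id": fv.meta.sample_id,
                "subject_id": fv.meta.subject_id,
                "class_label": fv.meta.class_label,
                "day_index": fv.meta.day_index,
                "conditioning_temperature_c": fv.meta.conditioning_temperature_c,
                "urine_portion": fv.meta.urine_portion,
            }
            for fv in rows
        ]
    ).set_index("sample_id")
    return X, meta
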