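"""Standard Normal Variate (SNV) preprocessing and response intensity.

SNV standardizes each sensor curve independently (subtract its mean, divide
by its standard deviation).  Because a between-day baseline shift in MOS
recordings is well described by a multiplicative (plus additive) distortion
of the whole curve, SNV removes it exactly: two curves differing only by a
positive affine map have identical SNV output.

The response intensity of a sensor is the ratio ``R_0 / R_min`` between the
baseline reference resistance and the minimum resistance reached while the
sensor is exposed to the urine headspace; for a responding n-type MOS sensor
(resistance drops on reducing volatiles) it is >= 1 and grows with the
headspace concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .recording import SampleMeta, SensorRecording

__all__ = ["NormalizedRecording", "snv", "baseline_reference", "response_intensity"]

#: Denominator convention for the SNV standard deviation (sample sd).
SNV_DDOF = 1


@dataclass
class NormalizedRecording:
    """A SensorRecording after per-sensor SNV standardization.

    ``signal`` holds the standardized curves (mean 0, sd 1 per sensor);
    ``mean`` and ``sd`` are the per-sensor statistics of the raw curve, so
    ``signal * sd[:, None] + mean[:, None]`` reconstructs it exactly.
    """

    time_s: np.ndarray
    signal: np.ndarray
    sampling_hz: float
    phases: Mapping[str, tuple[int, int]]
    meta: SampleMeta
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_sensors(self) -> int:
        return self.signal.shape[0]

    def to_raw(self) -> np.ndarray:
        """Reconstruct the raw resistance matrix."""
        return self.signal * self.sd[:, None] + self.mean[:, None]


def snv(rec: SensorRecording | NormalizedRecording) -> NormalizedRecording:
    """Standard Normal Variate transform, per sensor over the full curve.

    Accepts an already-normalized recording, on which it is the identity up
    to floating-point tolerance (idempotence).

    Raises
    ------
    ValueError
        If any sensor curve is constant (sd = 0), which indicates a dead
        sensor.
    """
    R = rec.signal if isinstance(rec, NormalizedRecording) else rec.resistance
    mean = R.mean(axis=1)
    sd = R.std(axis=1, ddof=SNV_DDOF)
    dead = ~(sd > 0)
    if np.any(dead):
        raise ValueError(
            f"constant curve for sensor(s) {np.flatnonzero(dead) + 1}: "
            "dead sensor, SNV undefined"
        )
    signal = (R - mean[:, None]) / sd[:, None]
    return NormalizedRecording(
        time_s=rec.time_s,
        signal=signal,
        sampling_hz=rec.sampling_hz,
        phases=rec.phases,
        meta=rec.meta,
        mean=mean,
        sd=sd,
    )


def baseline_reference(rec: SensorRecording, sensor: int) -> float:
    """R_0: median resistance over the baseline window (robust to noise)."""
    lo, hi = rec.phases["baseline"]
    if hi <= lo:
        raise ValueError("empty baseline window")
    return float(np.median(rec.resistance[sensor, lo:hi]))


def response_intensity(rec: SensorRecording, sensor: int) -> float:
    """Response intensity R_0 / R_min of one sensor.

    R_0 is the baseline reference (median of the baseline window) and R_min
    the minimum resistance over the exposure window.
    """
    lo, hi = rec.phases["during"]
    if hi <= lo:
        raise ValueError("empty exposure window")
    r0 = baseline_reference(rec, sensor)
    r_min = float(rec.resistance[sensor, lo:hi].min())
    if r_min <= 0:
        raise ValueError(f"non-positive R_min for sensor {sensor + 1}")
    return r0 / r_min
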