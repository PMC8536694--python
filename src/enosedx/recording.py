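"""Data model and text I/O for eNose sensor recordings.

A recording is the resistance of an array of metal-oxide-semiconductor (MOS)
gas sensors sampled at a fixed rate (1 Hz in the reference protocol) over
three phases:

``baseline``
    reference air, before the urine headspace reaches the chamber;
``during``
    exposure to the sample headspace (resistance of an n-type MOS sensor
    drops on adsorption of reducing volatiles);
``after``
    odourless air flushing, while the sensors recover toward the reference
    line.

Phase windows are half-open index intervals ``[start, stop)`` in 0-based
sample coordinates.  The time column is authoritative; the nominal sampling
frequency is validated against it.

Recordings are exchanged as plain CSV (``time_s, sensor_1..sensor_n``) with a
cohort-level sidecar table carrying the sample metadata and phase boundaries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "PORTIONS",
    "TEMPERATURES",
    "SampleMeta",
    "SensorRecording",
    "default_phases",
    "read_recording",
    "write_recording",
    "read_cohort",
    "write_cohort",
]

#: Valid diagnostic class labels: prostate-cancer patients vs controls.
CLASS_LABELS = ("PCa", "S")

#: Urination portions distinguished by the collection protocol.
PORTIONS = ("first", "midstream", "final", "catheter")

#: Headspace conditioning temperatures investigated by the protocol (deg C).
TEMPERATURES = (23, 37, 50, 60)

_PHASE_ORDER = ("baseline", "during", "after")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata attached to one headspace analysis.

    Parameters
    ----------
    sample_id : str
        Unique identifier of the analysis.
    subject_id : str
        Identifier of the donor; repeats of the same subject share it.
    class_label : str
        ``"PCa"`` (prostate cancer) or ``"S"`` (control).
    day_index : int
        Index of the measurement day (day-to-day baseline shifts are tied
        to this).
    conditioning_temperature_c : int
        Temperature at which the liquid sample was conditioned to enrich
        the static headspace; one of 23, 37, 50, 60.
    urine_portion : str
        Which portion of urination the sample represents.
    """

    sample_id: str
    subject_id: str
    class_label: str = "S"
    day_index: int = 0
    conditioning_temperature_c: int = 60
    urine_portion: str = "first"

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if self.urine_portion not in PORTIONS:
            raise ValueError(
                f"urine_portion must be one of {PORTIONS}, got {self.urine_portion!r}"
            )
        if self.conditioning_temperature_c not in TEMPERATURES:
            raise ValueError(
                "conditioning_temperature_c must be one of "
                f"{TEMPERATURES}, got {self.conditioning_temperature_c!r}"
            )


def default_phases(
    baseline_s: float = 300.0,
    exposure_s: float = 3000.0,
    recovery_s: float = 1800.0,
    sampling_hz: float = 1.0,
) -> dict[str, tuple[int, int]]:
    """Phase windows for the reference protocol (5 min / 50 min / 30 min)."""
    nb = int(round(baseline_s * sampling_hz))
    nd = int(round(exposure_s * sampling_hz))
    na = int(round(recovery_s * sampling_hz))
    return {
        "baseline": (0, nb),
        "during": (nb, nb + nd),
        "after": (nb + nd, nb + nd + na),
    }


@dataclass
class SensorRecording:
    """One multi-sensor resistance recording with phase annotations.

    Attributes
    ----------
    time_s : ndarray, shape (T,)
        Strictly increasing, uniformly spaced sample times in seconds.
    resistance : ndarray, shape (n_sensors, T)
        Sensor resistances in ohm; finite and strictly positive.
    sampling_hz : float
        Nominal sampling frequency; validated against ``time_s``.
    phases : dict
        ``{"baseline": (lo, hi), "during": ..., "after": ...}`` half-open
        index windows, disjoint, ordered, covering ``[0, T)``.
    meta : SampleMeta
    """

    time_s: np.ndarray
    resistance: np.ndarray
    sampling_hz: float
    phases: Mapping[str, tuple[int, int]]
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        self.validate()

    # -- container protocol -------------------------------------------------
    @property
    def n_sensors(self) -> int:
        return self.resistance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.resistance.shape[1]

    def phase_slice(self, name: str) -> slice:
        lo, hi = self.phases[name]
        return slice(lo, hi)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        t = self.time_s
        R = self.resistance
        if t.ndim != 1 or R.ndim != 2:
            raise ValueError("time_s must be 1-D and resistance 2-D")
        if R.shape[1] != t.size:
            raise ValueError(
                f"resistance has {R.shape[1]} samples but time has {t.size}"
            )
        if t.size == 0:
            raise ValueError("empty recording")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite time values")
        dt = np.diff(t)
        if t.size > 1:
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValueError(f"time not strictly increasing at row {row + 1}")
            step = 1.0 / self.sampling_hz
            if np.any(np.abs(dt - step) > 1e-6 * step):
                row = int(np.argmax(np.abs(dt - step) > 1e-6 * step)) + 1
                raise ValueError(
                    f"time spacing deviates from 1/{self.sampling_hz} Hz at row {row + 1}"
                )
        bad = ~(np.isfinite(R) & (R > 0))
        if np.any(bad):
            row = int(np.argwhere(bad.any(axis=0)).ravel()[0])
            raise ValueError(
                f"non-positive or non-finite resistance at row {row + 1}"
            )
        prev_hi = 0
        for name in _PHASE_ORDER:
            if name not in self.phases:
                raise ValueError(f"missing phase window {name!r}")
            lo, hi = self.phases[name]
            if not (0 <= lo <= hi <= t.size):
                raise ValueError(f"phase {name!r} window {lo, hi} out of range")
            if lo != prev_hi:
                raise ValueError("phase windows must be contiguous and ordered")
            prev_hi = hi
        if prev_hi != t.size:
            raise ValueError("phase windows must cover the whole recording")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _sensor_columns(n: int) -> list[str]:
    return [f"sensor_{i + 1}" for i in range(n)]


def write_recording(rec: SensorRecording, path: str | Path) -> Path:
    """Write one recording to CSV (``time_s, sensor_1..sensor_n``).

    Values are written at full float precision so that
    ``read_recording(write_recording(rec))`` round-trips bit-exactly.
    """
    rec.validate()
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.time_s})
    for i, col in enumerate(_sensor_columns(rec.n_sensors)):
        df[col] = rec.resistance[i]
    # shortest round-trip float representation: read-back is bit-exact
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path


def read_recording(
    path: str | Path,
    phases: Mapping[str, tuple[int, int]] | None = None,
    meta: SampleMeta | None = None,
) -> SensorRecording:
    """Read a recording CSV back into a :class:`SensorRecording`.

    Parameters
    ----------
    path : path
    phases : dict, optional
        Phase windows; when omitted, the reference-protocol windows
        (300 s / 3000 s / 1800 s) are assumed and must match the file length.
    meta : SampleMeta, optional
        Metadata; a placeholder is attached when omitted (cohort readers
        supply the real one from the sidecar table).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    sensor_cols = [c for c in df.columns if c.startswith("sensor_")]
    if not sensor_cols:
        raise ValueError(f"{path}: no sensor_* columns found")
    t = df["time_s"].to_numpy(dtype=float)
    R = df[sensor_cols].to_numpy(dtype=float).T
    if t.size == 0:
        raise ValueError(f"{path}: empty recording")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2  # header + 1-based
        raise ValueError(f"{path}: time not strictly increasing at line {row + 1}")
    bad = ~(np.isfinite(R) & (R > 0))
    if np.any(bad):
        row = int(np.argwhere(bad.any(axis=0)).ravel()[0]) + 2
        raise ValueError(f"{path}: non-positive resistance at line {row}")
    hz = 1.0 / float(np.median(dt)) if t.size > 1 else 1.0
    if phases is None:
        phases = default_phases(sampling_hz=hz)
        if phases["after"][1] != t.size:
            raise ValueError(
                f"{path}: length {t.size} does not match the default protocol; "
                "pass explicit phase windows"
            )
    if meta is None:
        meta = SampleMeta(sample_id=path.stem, subject_id=path.stem)
    return SensorRecording(
        time_s=t, resistance=R, sampling_hz=hz, phases=phases, meta=meta
    )


_COHORT_COLUMNS = [
    "sample_id",
    "subject_id",
    "class_label",
    "day_index",
    "conditioning_temperature_c",
    "urine_portion",
    "sampling_hz",
    "baseline_end",
    "during_end",
    "after_end",
]


def write_cohort(recordings: list[SensorRecording], out_dir: str | Path) -> Path:
    """Write per-recording CSVs plus a ``cohort.csv`` metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        write_recording(rec, out_dir / f"{rec.meta.sample_id}.csv")
        m = rec.meta
        rows.append(
            {
                "sample_id": m.sample_id,
                "subject_id": m.subject_id,
                "class_label": m.class_label,
                "day_index": m.day_index,
                "conditioning_temperature_c": m.conditioning_temperature_c,
                "urine_portion": m.urine_portion,
                "sampling_hz": rec.sampling_hz,
                "baseline_end": rec.phases["baseline"][1],
                "during_end": rec.phases["during"][1],
                "after_end": rec.phases["after"][1],
            }
        )
    table = pd.DataFrame(rows, columns=_COHORT_COLUMNS)
    path = out_dir / "cohort.csv"
    table.to_csv(path, index=False)
    return path


def read_cohort(in_dir: str | Path) -> list[SensorRecording]:
    """Read a cohort directory written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "cohort.csv")
    recordings = []
    for row in table.itertuples(index=False):
        meta = SampleMeta(
            sample_id=str(row.sample_id),
            subject_id=str(row.subject_id),
            class_label=str(row.class_label),
            day_index=int(row.day_index),
            conditioning_temperature_c=int(row.conditioning_temperature_c),
            urine_portion=str(row.urine_portion),
        )
        phases = {
            "baseline": (0, int(row.baseline_end)),
            "during": (int(row.baseline_end), int(row.during_end)),
            "after": (int(row.during_end), int(row.after_end)),
        }
        recordings.append(
            read_recording(in_dir / f"{meta.sample_id}.csv", phases=phases, meta=meta)
        )
    return recordings


def cohort_metadata_frame(recordings: list[SensorRecording]) -> pd.DataFrame:
    """Metadata of a list of recordings as a DataFrame (one row per sample)."""
    return pd.DataFrame(
        [dataclasses.asdict(rec.meta) for rec in recordings]
    ).set_index("sample_id")
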