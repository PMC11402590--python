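"""Reading, resampling and epoching of raw triaxial accelerometer recordings.

The raw input of the whole pipeline is a uniformly sampled triaxial
acceleration trace in gravitational units (g).  Recordings arrive as
long-form CSV (``time,x,y,z``); the sample rate is either declared by the
caller or inferred from the median timestamp interval.  Downstream stages
work on fixed-length, non-overlapping 10-s epochs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AccelRecording",
    "EpochSet",
    "FormatError",
    "DataError",
    "read_recording",
    "write_recording",
    "resample",
    "epoch_split",
]


class FormatError(ValueError):
    """Input file does not match the declared column layout."""


class DataError(ValueError):
    """Input data violate a structural precondition (ordering, alignment)."""


@dataclass
class AccelRecording:
    """A uniformly sampled triaxial acceleration trace.

    Parameters
    ----------
    samples
        Array of shape ``(n, 3)`` with per-axis acceleration in g.
    sample_rate_hz
        Sampling rate in Hz; must be positive.
    start_time
        Recording start in seconds (seconds since local midnight of the
        first day for multi-day recordings; time zones are out of scope).
    participant_id
        Identifier used for grouping in cross-validation.
    """

    samples: np.ndarray
    sample_rate_hz: float
    start_time: float = 0.0
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DataError("samples must have shape (n, 3)")
        if self.samples.shape[0] < 1:
            raise DataError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples must be finite")
        if not self.sample_rate_hz > 0:
            raise DataError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds (absolute, from ``start_time``)."""
        return self.start_time + np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class EpochSet:
    """Contiguous equal-length windows cut from one recording.

    ``epochs`` has shape ``(n_epochs, samples_per_epoch, 3)``.  ``labels``
    (when present) is a binary vector, 1 = walk, 0 = non-walk.
    """

    epochs: np.ndarray
    epoch_length_s: float
    sample_rate_hz: float
    start_time: float = 0.0
    labels: np.ndarray | None = None
    group_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        expected = round(self.epoch_length_s * self.sample_rate_hz)
        if self.n_epochs and self.epochs.shape[1] != expected:
            raise DataError(
                f"epochs have {self.epochs.shape[1]} samples, expected {expected}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != self.n_epochs:
                raise DataError("labels misaligned with epochs")
        if self.group_ids is None:
            self.group_ids = np.array([""] * self.n_epochs, dtype=object)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[1] if self.n_epochs else round(
            self.epoch_length_s * self.sample_rate_hz
        )

    def epoch_start_times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_epochs) * self.epoch_length_s


def read_recording(
    path,
    *,
    time_col: str | None = "time",
    axis_cols: tuple[str, str, str] = ("x", "y", "z"),
    sample_rate_hz: float | None = None,
    participant_id: str = "",
    header: bool = True,
) -> AccelRecording:
    """Read a long-form CSV accelerometer file.

    The sample rate is ``sample_rate_hz`` when declared, otherwise inferred
    as ``1 / median(dt)`` from the time column.  When both are available and
    disagree by more than 1%, the declared rate wins and a warning is logged.
    """
    if header:
        df = pd.read_csv(path)
    else:
        names = ([time_col] if time_col else []) + list(axis_cols)
        df = pd.read_csv(path, header=None, names=names)

    missing = [c for c in axis_cols if c not in df.columns]
    if missing:
        raise FormatError(f"missing axis columns: {missing}")
    samples = df[list(axis_cols)].to_numpy(dtype=float)

    start_time = 0.0
    inferred = None
    if time_col is not None and time_col in df.columns:
        t = df[time_col].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise DataError("timestamps must be strictly increasing")
            inferred = 1.0 / float(np.median(dt))
        start_time = float(t[0])
    elif sample_rate_hz is None:
        raise FormatError("no time column and no declared sample rate")

    if sample_rate_hz is not None:
        if inferred is not None and abs(inferred - sample_rate_hz) > 0.01 * sample_rate_hz:
            logger.warning(
                "declared rate %.3f Hz overrides inferred %.3f Hz",
                sample_rate_hz, inferred,
            )
        rate = float(sample_rate_hz)
    else:
        if inferred is None:
            raise FormatError("cannot infer sample rate from a single row")
        rate = inferred

    return AccelRecording(samples, rate, start_time=start_time,
                          participant_id=participant_id)


def write_recording(recording: AccelRecording, path) -> None:
    """Write a recording in the CSV dialect :func:`read_recording` accepts."""
    df = pd.DataFrame(
        {
            "time": recording.times(),
            "x": recording.samples[:, 0],
            "y": recording.samples[:, 1],
            "z": recording.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def resample(recording: AccelRecording, target_hz: float) -> AccelRecording:
    """Linearly interpolate onto a uniform grid at ``target_hz``.

    The output grid spans the original duration; a recording already at the
    target rate is returned unchanged.
    """
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if recording.n_samples == 0:
        raise DataError("cannot resample an empty recording")
    if target_hz == recording.sample_rate_hz:
        return recording
    t_old = np.arange(recording.n_samples) / recording.sample_rate_hz
    n_new = int(round(recording.duration_s * target_hz))
    t_new = np.arange(n_new) / target_hz
    t_new = t_new[t_new <= t_old[-1] + 1e-12]
    out = np.column_stack(
        [np.interp(t_new, t_old, recording.samples[:, k]) for k in range(3)]
    )
    return replace(recording, samples=out, sample_rate_hz=float(target_hz))


def epoch_split(recording: AccelRecording, epoch_length_s: float = 10.0) -> EpochSet:
    """Cut a recording into contiguous fixed-length epochs.

    The trailing partial window is discarded (the classifier expects
    fixed-length inputs); a recording shorter than one epoch yields an
    empty set with a warning.
    """
    spe = round(epoch_length_s * recording.sample_rate_hz)
    if spe < 1:
        raise ValueError("epoch shorter than one sample")
    n_epochs = recording.n_samples // spe
    if n_epochs == 0:
        warnings.warn("recording shorter than one epoch; empty EpochSet")
    epochs = recording.samples[: n_epochs * spe].reshape(n_epochs, spe, 3)
    return EpochSet(
        epochs=epochs,
        epoch_length_s=epoch_length_s,
        sample_rate_hz=recording.sample_rate_hz,
        start_time=recording.start_time,
        group_ids=np.array([recording.participant_id] * n_epochs, dtype=object),
    )
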