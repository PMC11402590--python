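"""Step counting by constrained peak detection on the conditioned VM signal.

Steps appear as local peaks of the conditioned vector-magnitude signal.
A candidate peak must be a strict local maximum with topographic
prominence of at least ``prominence_g``, a half-prominence width within
the width constraint, and at least ``distance_s`` separation from every
other reported peak; when two candidates are closer than that, the taller
one wins (greedy suppression by descending height).

The paper-style convention treats the width heuristic as a *maximum*
("maximum peak width"); ``width_mode="min"`` switches to the common
library convention of a minimum width.

The three heuristics are tuned by exhaustive grid search minimising the
mean absolute step-count error on a validation set, over prominence
0.1-1 g, distance 0.2-2 s and width 10 ms-1 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import peak_prominences, peak_widths

from .preprocess import VMSignal, conditioned_vm
from .signal_io import AccelRecording, DataError

__all__ = [
    "DetectorParams",
    "StepEvents",
    "find_peaks_1d",
    "detect_steps",
    "tune_detector",
    "default_grid",
]

TUNING_RANGES = {
    "prominence_g": (0.1, 1.0),
    "distance_s": (0.2, 2.0),
    "width_s": (0.01, 1.0),
}


@dataclass(frozen=True)
class DetectorParams:
    """Peak-detection heuristics: prominence (g), distance (s), width (s)."""

    prominence_g: float = 0.3
    distance_s: float = 0.4
    width_s: float = 1.0
    width_mode: str = "max"

    def __post_init__(self) -> None:
        if self.prominence_g <= 0 or self.distance_s <= 0 or self.width_s <= 0:
            raise ValueError("detector parameters must be positive")
        if self.width_mode not in ("max", "min"):
            raise ValueError("width_mode must be 'max' or 'min'")
        for name, (lo, hi) in TUNING_RANGES.items():
            val = getattr(self, name)
            if not lo <= val <= hi:
                warnings.warn(f"{name}={val} outside the tuning range [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {
            "prominence_g": self.prominence_g,
            "distance_s": self.distance_s,
            "width_s": self.width_s,
            "width_mode": self.width_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorParams":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(**d)


@dataclass
class StepEvents:
    """Ordered step timestamps (s) with the epoch each came from."""

    times: np.ndarray
    epoch_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise DataError("step times must be strictly increasing")
        if self.epoch_indices is None:
            self.epoch_indices = np.full(self.times.shape, -1, dtype=int)
        else:
            self.epoch_indices = np.asarray(self.epoch_indices, dtype=int)

    @property
    def count(self) -> int:
        return self.times.size


def _strict_local_maxima(v: np.ndarray) -> np.ndarray:
    """Indices i with v[i-1] < v[i] > v[i+1] (plateaus are not peaks)."""
    if v.size < 3:
        return np.empty(0, dtype=int)
    return np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1


def peak_geometry(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(indices, prominences, half-prominence widths in samples) of all
    strict local maxima — the parameter-independent part of detection,
    computed once per signal so grid search can reuse it."""
    v = np.asarray(v, dtype=float)
    idx = _strict_local_maxima(v)
    if idx.size == 0:
        return idx, np.empty(0), np.empty(0)
    prom = peak_prominences(v, idx)
    width = peak_widths(v, idx, rel_height=0.5, prominence_data=prom)[0]
    return idx, prom[0], width


def _select_peaks(
    idx: np.ndarray,
    heights: np.ndarray,
    prom: np.ndarray,
    width_samples: np.ndarray,
    sample_rate_hz: float,
    params: DetectorParams,
) -> np.ndarray:
    keep = prom >= params.prominence_g
    wlim = params.width_s * sample_rate_hz
    if params.width_mode == "max":
        keep &= width_samples <= wlim
    else:
        keep &= width_samples >= wlim
    idx, heights = idx[keep], heights[keep]
    if idx.size == 0:
        return idx

    # greedy suppression: taller peaks claim their exclusion zone first
    min_gap = params.distance_s * sample_rate_hz
    order = np.lexsort((idx, -heights))
    chosen: list[int] = []
    for j in order:
        i = idx[j]
        if all(abs(i - c) >= min_gap for c in chosen):
            chosen.append(int(i))
    return np.array(sorted(chosen), dtype=int)


def find_peaks_1d(
    v: np.ndarray, sample_rate_hz: float, params: DetectorParams
) -> np.ndarray:
    """Indices of detected step peaks in a 1-D conditioned VM signal."""
    v = np.asarray(v, dtype=float)
    idx, prom, width = peak_geometry(v)
    return _select_peaks(idx, v[idx], prom, width, sample_rate_hz, params)


def _label_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) epoch ranges of maximal walk runs."""
    runs = []
    start = None
    for i, lab in enumerate(labels):
        if lab and start is None:
            start = i
        elif not lab and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs


def detect_steps(
    recording: AccelRecording,
    walk_labels: np.ndarray,
    params: DetectorParams,
    epoch_length_s: float = 10.0,
    merge_runs: bool = True,
) -> StepEvents:
    """Detect steps in the predicted-walking portions of a recording.

    Peak detection runs on the conditioned VM of each maximal run of
    consecutive walking epochs, concatenated so a step straddling an epoch
    boundary is not lost (``merge_runs=False`` gives strictly per-epoch
    windows).  Non-walking spans contribute no steps.
    """
    walk_labels = np.asarray(walk_labels, dtype=int)
    spe = round(epoch_length_s * recording.sample_rate_hz)
    n_epochs = recording.n_samples // spe
    if walk_labels.size != n_epochs:
        raise DataError(
            f"{walk_labels.size} labels for {n_epochs} epochs"
        )

    times: list[float] = []
    epochs: list[int] = []
    runs = _label_runs(walk_labels)
    if not merge_runs:
        runs = [(i, i + 1) for a, b in runs for i in range(a, b)]
    for a, b in runs:
        seg = recording.samples[a * spe : b * spe]
        vm = conditioned_vm(seg, recording.sample_rate_hz)
        for i in find_peaks_1d(vm.values, recording.sample_rate_hz, params):
            t = recording.start_time + (a * spe + i) / recording.sample_rate_hz
            times.append(t)
            epochs.append(a + int(i // spe))
    order = np.argsort(times)
    return StepEvents(
        times=np.asarray(times, dtype=float)[order],
        epoch_indices=np.asarray(epochs, dtype=int)[order],
    )


def default_grid() -> list[DetectorParams]:
    """The tuning grid: prominence 0.1-1 g (step 0.1), distance 0.2-2 s
    (step 0.2), width {10 ms, 0.1-1 s step 0.1}."""
    proms = np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 10)
    dists = np.round(np.arange(0.2, 2.0 + 1e-9, 0.2), 10)
    widths = [0.01] + list(np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 10))
    return [
        DetectorParams(prominence_g=float(p), distance_s=float(d), width_s=float(w))
        for p in proms
        for d in dists
        for w in widths
    ]


def tune_detector(
    validation: Sequence[tuple[VMSignal, int]],
    grid: Iterable[DetectorParams] | None = None,
) -> DetectorParams:
    """Exhaustive grid search minimising mean absolute step-count error.

    Ties are broken toward the most conservative cell: larger prominence,
    then larger distance, then larger width.
    """
    grid = list(default_grid() if grid is None else grid)
    if not grid:
        raise ValueError("empty parameter grid")
    if not validation:
        raise ValueError("empty validation set")

    cached = []
    for vm, true_count in validation:
        idx, prom, width = peak_geometry(vm.values)
        cached.append((idx, vm.values[idx], prom, width, vm.sample_rate_hz, true_count))

    best_key = None
    best_params = None
    for params in grid:
        err = 0.0
        for idx, h, prom, width, fs, true_count in cached:
            n = _select_peaks(idx, h, prom, width, fs, params).size
            err += abs(n - true_count)
        mae = err / len(cached)
        key = (mae, -params.prominence_g, -params.distance_s, -params.width_s)
        if best_key is None or key < best_key:
            best_key, best_params = key, params
    return best_params
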