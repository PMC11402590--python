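"""Conditioning of triaxial samples into the 1-D vector-magnitude signal.

Step detection operates on the Euclidean norm of acceleration minus 1 g
(removing the static gravity component regardless of wrist orientation),
clipped to ±2 g and low-pass filtered with a fourth-order Butterworth at
5 Hz.  Filtering is zero-phase (forward-backward) so that detected peak
times are not shifted relative to the underlying steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "VMSignal",
    "vector_magnitude",
    "clip_signal",
    "butterworth_lowpass",
    "conditioned_vm",
]

CLIP_BOUND_G = 2.0
LOWPASS_CUTOFF_HZ = 5.0
LOWPASS_ORDER = 4


@dataclass
class VMSignal:
    """Conditioned 1-D vector-magnitude signal, in g."""

    values: np.ndarray
    sample_rate_hz: float


def vector_magnitude(samples: np.ndarray) -> np.ndarray:
    """Euclidean norm of the triaxial samples minus 1 g.

    Subtracting unit gravity makes a stationary device read ~0 in any
    orientation; the result is orientation invariant.
    """
    samples = np.asarray(samples, dtype=float)
    return np.linalg.norm(samples, axis=-1) - 1.0


def clip_signal(v: np.ndarray, bound: float = CLIP_BOUND_G) -> np.ndarray:
    """Limit values to ``[-bound, +bound]`` g."""
    if not bound > 0:
        raise ValueError("clip bound must be positive")
    return np.clip(np.asarray(v, dtype=float), -bound, bound)


def butterworth_lowpass(
    v: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = LOWPASS_CUTOFF_HZ,
    order: int = LOWPASS_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Applied forward and backward (``filtfilt`` with odd-reflection edge
    padding), which squares the magnitude response and cancels phase, so
    output length equals input length and peaks are not displaced.
    """
    if not 0 < cutoff_hz < sample_rate_hz / 2:
        raise ValueError("cutoff must lie strictly below the Nyquist rate")
    b, a = butter(order, cutoff_hz, btype="low", fs=sample_rate_hz)
    v = np.asarray(v, dtype=float)
    if v.size <= 3 * max(len(a), len(b)):
        # too short for default padding; fall back to shortest valid padlen
        return filtfilt(b, a, v, padlen=max(0, v.size - 1))
    return filtfilt(b, a, v)


def conditioned_vm(samples: np.ndarray, sample_rate_hz: float) -> VMSignal:
    """Norm−1 g, then clip to ±2 g, then 5 Hz zero-phase low-pass.

    Clipping precedes filtering so that a large transient is bounded before
    its energy can spread through the filter's impulse response.
    """
    v = vector_magnitude(samples)
    v = clip_signal(v)
    v = butterworth_lowpass(v, sample_rate_hz)
    return VMSignal(values=v, sample_rate_hz=sample_rate_hz)
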