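"""Two-state hidden Markov label smoother.

The epoch classifier makes independent per-epoch decisions, so its output
contains implausible isolated flips (a single "walk" epoch inside minutes
of sitting).  A two-state HMM — hidden truth (walk / non-walk), observed
classifier label — is fitted by supervised counting on the validation
split and applied to test predictions by Viterbi decoding.

States and observations are coded 0 = non-walk, 1 = walk.  All counts are
add-one (Laplace) smoothed; probabilities are floored at 1e-12 in log
space so no observation sequence has zero likelihood.  Score ties during
decoding resolve toward non-walk, so smoothing never fabricates steps.
Sequences must not cross participant or nonwear boundaries; decoding
restarts from the initial distribution after any gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_io import DataError

__all__ = ["HMMParams", "fit_hmm", "viterbi_smooth"]

_FLOOR = 1e-12


@dataclass
class HMMParams:
    """initial[s], transition[s, s'], emission[s, o]; rows sum to 1."""

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        for name, arr, axis in (
            ("initial", self.initial, 0),
            ("transition", self.transition, 1),
            ("emission", self.emission, 1),
        ):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            s = arr.sum(axis=axis)
            if not np.allclose(s, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")

    def to_dict(self) -> dict:
        return {
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            np.asarray(d["initial"]),
            np.asarray(d["transition"]),
            np.asarray(d["emission"]),
        )


def fit_hmm(
    true_sequences: Sequence[np.ndarray],
    predicted_sequences: Sequence[np.ndarray],
) -> HMMParams:
    """Supervised counting fit from aligned (truth, prediction) sequences.

    Transition probabilities are add-one-smoothed bigram frequencies of the
    true labels within each sequence (no transitions across sequence
    boundaries); emissions are the add-one-smoothed confusion of predicted
    given true; the initial distribution is the smoothed marginal of each
    sequence's first true label.
    """
    if len(true_sequences) == 0:
        raise DataError("need at least one sequence")
    init_c = np.ones(2)
    trans_c = np.ones((2, 2))
    emis_c = np.ones((2, 2))
    for t_seq, p_seq in zip(true_sequences, predicted_sequences, strict=True):
        t = np.asarray(t_seq, dtype=int)
        p = np.asarray(p_seq, dtype=int)
        if t.shape != p.shape:
            raise DataError("true and predicted sequences misaligned")
        if t.size == 0:
            continue
        init_c[t[0]] += 1
        for a, b in zip(t[:-1], t[1:]):
            trans_c[a, b] += 1
        for a, o in zip(t, p):
            emis_c[a, o] += 1
    return HMMParams(
        initial=init_c / init_c.sum(),
        transition=trans_c / trans_c.sum(axis=1, keepdims=True),
        emission=emis_c / emis_c.sum(axis=1, keepdims=True),
    )


def viterbi_smooth(params: HMMParams, predicted_sequence: np.ndarray) -> np.ndarray:
    """Maximum a posteriori state path for an observed label sequence.

    Standard log-space Viterbi over the two states.  ``np.argmax`` returns
    the first maximiser, so exact score ties resolve toward state 0
    (non-walk) both in back-pointers and at the final step.
    """
    obs = np.asarray(predicted_sequence, dtype=int)
    if obs.size == 0:
        raise DataError("empty observation sequence")
    log_pi = np.log(np.maximum(params.initial, _FLOOR))
    log_a = np.log(np.maximum(params.transition, _FLOOR))
    log_b = np.log(np.maximum(params.emission, _FLOOR))

    T = obs.size
    delta = np.empty((T, 2))
    psi = np.empty((T, 2), dtype=int)
    delta[0] = log_pi + log_b[:, obs[0]]
    for t in range(1, T):
        # cand[s', s] = delta[t-1, s'] + log_a[s', s]
        cand = delta[t - 1][:, None] + log_a
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], np.arange(2)] + log_b[:, obs[t]]

    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def smooth_sequences(
    params: HMMParams, sequences: Sequence[np.ndarray]
) -> list[np.ndarray]:
    """Viterbi-decode each sequence independently (restart after gaps)."""
    return [viterbi_smooth(params, s) for s in sequences]
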