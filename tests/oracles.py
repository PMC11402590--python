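"""Independent brute-force oracles used by the test suite.

These deliberately re-derive peak detection and Viterbi decoding from
first principles (naive scans and exhaustive enumeration) so they share
no code path with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_peaks(v, sample_rate_hz, prominence_g, distance_s, width_s,
                      width_mode="max"):
    """Naive peak detector: scan for strict local maxima, measure
    prominence by explicit left/right minima search, half-prominence width
    by linear interpolation, apply the constraints, then greedily suppress
    close peaks by descending height."""
    v = np.asarray(v, dtype=float)
    n = v.size
    candidates = []
    for i in range(1, n - 1):
        if not (v[i] > v[i - 1] and v[i] > v[i + 1]):
            continue
        # left window: walk left until a sample higher than the peak
        left_min, left_argmin = v[i], i
        j = i - 1
        while j >= 0 and v[j] <= v[i]:
            if v[j] < left_min:
                left_min, left_argmin = v[j], j
            j -= 1
        right_min, right_argmin = v[i], i
        j = i + 1
        while j < n and v[j] <= v[i]:
            if v[j] < right_min:
                right_min, right_argmin = v[j], j
            j += 1
        prom = v[i] - max(left_min, right_min)

        # width at height = peak - prom/2, within [left_base, right_base]
        h = v[i] - 0.5 * prom
        k = i
        while k > left_argmin and v[k] > h:
            k -= 1
        left_ip = float(k)
        if v[k] < h:
            left_ip = k + (h - v[k]) / (v[k + 1] - v[k])
        k = i
        while k < right_argmin and v[k] > h:
            k += 1
        right_ip = float(k)
        if v[k] < h:
            right_ip = k - (h - v[k]) / (v[k - 1] - v[k])
        width = right_ip - left_ip
        candidates.append((i, v[i], prom, width))

    wlim = width_s * sample_rate_hz
    kept = [
        c
        for c in candidates
        if c[2] >= prominence_g
        and (c[3] <= wlim if width_mode == "max" else c[3] >= wlim)
    ]
    # greedy suppression, taller first, lower index on height ties
    kept.sort(key=lambda c: (-c[1], c[0]))
    min_gap = distance_s * sample_rate_hz
    chosen = []
    for i, h, _, _ in kept:
        if all(abs(i - j) >= min_gap for j in chosen):
            chosen.append(i)
    return np.array(sorted(chosen), dtype=int)


def enumerate_path_scores(params, obs):
    """Score every state path for one observation sequence.

    Scores accumulate in time order (init, emit, then transition + emit per
    step), matching the floating-point order of a left-to-right decoder, so
    score comparisons are exact.  Returns (paths (2^T, T), scores (2^T,)).
    """
    obs = np.asarray(obs, dtype=int)
    T = obs.size
    log_pi = np.log(np.maximum(params.initial, 1e-12))
    log_a = np.log(np.maximum(params.transition, 1e-12))
    log_b = np.log(np.maximum(params.emission, 1e-12))
    paths = np.array(list(itertools.product((0, 1), repeat=T)), dtype=int)
    scores = log_pi[paths[:, 0]] + log_b[paths[:, 0], obs[0]]
    for t in range(1, T):
        scores = scores + log_a[paths[:, t - 1], paths[:, t]]
        scores = scores + log_b[paths[:, t], obs[t]]
    return paths, scores


def best_paths(params, obs):
    """All maximum-score state paths (exact float comparison)."""
    paths, scores = enumerate_path_scores(params, obs)
    best = scores.max()
    return paths[scores == best]
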