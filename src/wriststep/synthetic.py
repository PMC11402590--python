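"""Synthetic wrist-accelerometer recordings with known per-step ground truth.

The simulator is the package's test bed: it produces free-living-like
triaxial recordings in which every step's timestamp, every epoch's
walk/non-walk label and every minute's wear status are known exactly.

A walking bout places one half-sine acceleration impulse per step on the
vertical body axis (peak at the step time), adds an arm-swing sinusoid at
half the step frequency, the 1-g gravity vector, an arbitrary rigid
orientation of the whole device frame, and Gaussian sensor noise.
Inter-step intervals are ``60/cadence × (1 + jitter·z)``.  Non-walking
bouts are sedentary (gravity + wrist micro-movement noise), fidgeting
(sedentary plus sparse sub-threshold transients) or nonwear (exactly
constant gravity, so the stationarity detector flags it).

Presets mirror the shapes of the validation datasets the method is aimed
at: ~1-h free-living sessions at 25 Hz, three-session lab protocols
(regular / semiregular / irregular gait) at 15 Hz, and 7-day cohort
recordings at 15 Hz with nonwear gaps.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import label_epochs_from_steps
from .detector import StepEvents
from .signal_io import AccelRecording, EpochSet, epoch_split, write_recording

__all__ = [
    "GaitProfile",
    "SyntheticRecording",
    "random_rotation",
    "simulate_walk_bout",
    "simulate_nonwalk_bout",
    "simulate_participant",
    "make_fixture_cohort",
    "REGULAR",
    "SEMIREGULAR",
    "IRREGULAR",
]

GRAVITY = np.array([0.0, 0.0, 1.0])
SEDENTARY_NOISE_SD_G = 0.02  # wrist micro-movement keeps sedentary time "worn"


@dataclass(frozen=True)
class GaitProfile:
    """Parameters of one walking style.

    cadence in steps/min; ``cadence_jitter`` is the CV of the inter-step
    interval; ``step_impulse_g`` the half-sine amplitude on the vertical
    axis; ``arm_swing_ratio`` the arm-swing amplitude relative to the
    impulse; ``noise_sd_g`` the per-axis sensor noise SD.
    """

    cadence_spm: float = 100.0
    cadence_jitter: float = 0.05
    step_impulse_g: float = 0.5
    arm_swing_ratio: float = 0.2
    noise_sd_g: float = 0.03
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 40 <= self.cadence_spm <= 200:
            raise ValueError("cadence must lie in [40, 200] steps/min")
        if min(self.step_impulse_g, self.arm_swing_ratio, self.noise_sd_g) < 0:
            raise ValueError("amplitudes must be non-negative")


#: the three lab gait styles: steady laps, stop-and-go building walk,
#: short shuffling bursts
REGULAR = GaitProfile(cadence_spm=105, cadence_jitter=0.03)
SEMIREGULAR = GaitProfile(cadence_spm=95, cadence_jitter=0.08, step_impulse_g=0.45)
IRREGULAR = GaitProfile(cadence_spm=80, cadence_jitter=0.15, step_impulse_g=0.40)


@dataclass
class SyntheticRecording:
    """A recording plus every layer of ground truth the pipeline predicts."""

    recording: AccelRecording
    truth_steps: StepEvents
    truth_epoch_labels: np.ndarray
    truth_wear_mask: np.ndarray  # per minute of the recording span

    @property
    def epoch_set(self) -> EpochSet:
        es = epoch_split(self.recording)
        es.labels = self.truth_epoch_labels
        return es


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random rotation matrix (axis uniform on sphere, angle
    uniform on [0, 2π))."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, 2 * np.pi)
    x, y, z = axis
    c, s, C = np.cos(angle), np.sin(angle), 1 - np.cos(angle)
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _step_times(profile: GaitProfile, duration_s: float, rng) -> np.ndarray:
    base = 60.0 / profile.cadence_spm
    times = []
    t = base / 2.0
    while t < duration_s:
        times.append(t)
        iv = base * (1.0 + profile.cadence_jitter * rng.standard_normal())
        t += max(iv, 0.3 * base)  # keep intervals positive and ordered
    return np.asarray(times)


def simulate_walk_bout(
    profile: GaitProfile,
    duration_s: float,
    sample_rate_hz: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One walking bout; returns (samples (n, 3) in g, exact step times)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = round(duration_s * sample_rate_hz)
    t = np.arange(n) / sample_rate_hz
    step_times = _step_times(profile, duration_s, rng)

    vertical = np.zeros(n)
    imp_dur = min(0.3, 0.5 * 60.0 / profile.cadence_spm)
    for ts in step_times:
        m = np.abs(t - ts) <= imp_dur / 2
        vertical[m] += profile.step_impulse_g * np.cos(np.pi * (t[m] - ts) / imp_dur)

    swing_hz = profile.cadence_spm / 60.0 / 2.0
    swing = profile.arm_swing_ratio * profile.step_impulse_g * np.sin(
        2 * np.pi * swing_hz * t + rng.uniform(0, 2 * np.pi)
    )

    body = np.column_stack([swing, np.zeros(n), vertical]) + GRAVITY
    R = profile.orientation if profile.orientation is not None else random_rotation(rng)
    samples = body @ R.T + rng.normal(0.0, profile.noise_sd_g, size=(n, 3))
    return samples, step_times


def simulate_nonwalk_bout(
    kind: str,
    duration_s: float,
    sample_rate_hz: float,
    rng: np.random.Generator,
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Sedentary, fidget or nonwear samples (no steps).

    Fidget transients stay below 0.1 g prominence after conditioning —
    under the tuning grid's prominence floor, so they never read as steps.
    Nonwear is exactly constant gravity (zero variance).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = round(duration_s * sample_rate_hz)
    R = orientation if orientation is not None else random_rotation(rng)
    base = np.broadcast_to(GRAVITY @ R.T, (n, 3)).copy()
    if kind == "nonwear":
        return base
    if kind not in ("sedentary", "fidget"):
        raise ValueError(f"unknown bout kind {kind!r}")
    samples = base + rng.normal(0.0, SEDENTARY_NOISE_SD_G, size=(n, 3))
    if kind == "fidget":
        t = np.arange(n) / sample_rate_hz
        n_events = rng.poisson(duration_s * 0.2)
        for _ in range(n_events):
            ts = rng.uniform(0, duration_s)
            amp = rng.uniform(0.02, 0.06)
            dur = rng.uniform(0.2, 0.5)
            m = np.abs(t - ts) <= dur / 2
            axis = rng.integers(0, 3)
            samples[m, axis] += amp * np.cos(np.pi * (t[m] - ts) / dur)
    return samples


def simulate_participant(
    day_plan: list[tuple],
    sample_rate_hz: float = 25.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    participant_id: str = "P000",
    start_time: float = 0.0,
    epoch_length_s: float = 10.0,
) -> SyntheticRecording:
    """Concatenate a plan of bouts into one fully annotated recording.

    ``day_plan`` entries are ``(kind, profile_or_None, duration_s)`` with
    kind in {walk, sedentary, fidget, nonwear}.  Epoch labels are derived
    from the exact step times via the ≥4-steps rule; the wear mask marks
    minutes lying entirely inside nonwear bouts.
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    chunks = []
    all_steps: list[np.ndarray] = []
    nonwear_spans: list[tuple[float, float]] = []
    offset = 0.0
    for kind, profile, duration in day_plan:
        if kind == "walk":
            samples, st = simulate_walk_bout(
                profile or GaitProfile(), duration, sample_rate_hz, rng
            )
            all_steps.append(st + offset)
        else:
            samples = simulate_nonwalk_bout(kind, duration, sample_rate_hz, rng)
            if kind == "nonwear":
                nonwear_spans.append((offset, offset + duration))
        chunks.append(samples)
        offset += samples.shape[0] / sample_rate_hz

    recording = AccelRecording(
        samples=np.vstack(chunks),
        sample_rate_hz=sample_rate_hz,
        start_time=start_time,
        participant_id=participant_id,
    )
    step_times = (
        np.sort(np.concatenate(all_steps)) if all_steps else np.empty(0)
    ) + start_time

    es = epoch_split(recording, epoch_length_s)
    labels = label_epochs_from_steps(step_times, es)
    spe = round(epoch_length_s * sample_rate_hz)
    epoch_idx = np.minimum(
        ((step_times - start_time) // epoch_length_s).astype(int),
        max(es.n_epochs - 1, 0),
    )
    steps = StepEvents(times=step_times, epoch_indices=epoch_idx)

    n_min = int(np.ceil(recording.duration_s / 60.0))
    worn = np.ones(n_min, dtype=bool)
    for a, b in nonwear_spans:
        for m in range(n_min):
            if m * 60.0 >= a - 1e-9 and (m + 1) * 60.0 <= b + 1e-9:
                worn[m] = False
    return SyntheticRecording(recording, steps, labels, worn)


def _participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    """Stable per-participant substream: master seed + CRC32 of the id."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(participant_id.encode())])
    )


def _oxwalk_like_plan(rng) -> list[tuple]:
    """~1 h of free living: sedentary and fidget time with scattered
    walking bouts (~10-15% of epochs walking)."""
    plan: list[tuple] = []
    total = 0.0
    while total < 3600.0:
        plan.append(("sedentary", None, float(rng.uniform(120, 300))))
        plan.append(
            (
                "walk",
                GaitProfile(
                    cadence_spm=float(rng.uniform(90, 115)),
                    cadence_jitter=0.05,
                    step_impulse_g=float(rng.uniform(0.45, 0.6)),
                    noise_sd_g=0.03,
                ),
                float(rng.uniform(40, 90)),
            )
        )
        plan.append(("fidget", None, float(rng.uniform(100, 220))))
        total = sum(d for _, _, d in plan)
    return plan


def _clemson_like_plan(rng) -> list[tuple]:
    """Three lab sessions (regular / semiregular / irregular), ~37 min."""
    plan: list[tuple] = [("sedentary", None, 60.0)]
    plan += [("walk", REGULAR, 600.0), ("sedentary", None, 120.0)]
    for _ in range(8):  # stop-and-go object search
        plan.append(("walk", SEMIREGULAR, float(rng.uniform(40, 70))))
        plan.append(("sedentary", None, float(rng.uniform(15, 30))))
    plan.append(("sedentary", None, 120.0))
    for _ in range(12):  # short shuffling bursts
        plan.append(("walk", IRREGULAR, float(rng.uniform(15, 30))))
        plan.append(("fidget", None, float(rng.uniform(20, 40))))
    return plan


def _week_long_plan(rng, n_days: int = 7) -> list[tuple]:
    """7 × 24 h with a daytime walking routine and nonwear gaps."""
    plan: list[tuple] = []
    for day in range(n_days):
        plan.append(("sedentary", None, 7 * 3600.0))  # night
        daytime: list[tuple] = []
        for _ in range(10):
            daytime.append(
                (
                    "walk",
                    GaitProfile(
                        cadence_spm=float(rng.uniform(95, 115)),
                        cadence_jitter=0.05,
                    ),
                    float(rng.uniform(240, 600)),
                )
            )
            daytime.append(("sedentary", None, float(rng.uniform(1200, 2400))))
        if day == 2:  # one afternoon off-wrist
            daytime.insert(10, ("nonwear", None, 2 * 3600.0))
        used = sum(d for _, _, d in daytime)
        remaining = 17 * 3600.0 - used
        if remaining < 0:  # trim the last sedentary blocks to fit the day
            for i in range(len(daytime) - 1, -1, -1):
                kind, prof, dur = daytime[i]
                if kind == "sedentary":
                    cut = min(dur - 60.0, -remaining)
                    daytime[i] = (kind, prof, dur - cut)
                    remaining += cut
                    if remaining >= 0:
                        break
        plan += daytime
        if remaining > 0:
            plan.append(("sedentary", None, remaining))
    return plan


PRESETS = {
    "oxwalk_like": (_oxwalk_like_plan, 25.0),
    "clemson_like": (_clemson_like_plan, 15.0),
    "week_long": (_week_long_plan, 15.0),
}


def make_fixture_cohort(
    n_participants: int,
    preset: str = "oxwalk_like",
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[SyntheticRecording]:
    """Deterministic cohort of synthetic recordings, optionally written
    to CSV (recording + truth steps / labels / wear mask per participant)."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    plan_fn, rate = PRESETS[preset]
    cohort = []
    for i in range(n_participants):
        pid = f"P{i:03d}"
        rng = _participant_rng(seed, pid)
        plan = plan_fn(rng)
        rec = simulate_participant(
            plan, sample_rate_hz=rate, rng=rng, participant_id=pid
        )
        cohort.append(rec)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: list[SyntheticRecording], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort:
        pid = rec.recording.participant_id
        write_recording(rec.recording, out / f"{pid}_accel.csv")
        pd.DataFrame(
            {"time": rec.truth_steps.times, "epoch_index": rec.truth_steps.epoch_indices}
        ).to_csv(out / f"{pid}_steps.csv", index=False, float_format="%.6f")
        pd.DataFrame({"walk": rec.truth_epoch_labels}).to_csv(
            out / f"{pid}_labels.csv", index=False
        )
        pd.DataFrame({"worn": rec.truth_wear_mask.astype(int)}).to_csv(
            out / f"{pid}_wear.csv", index=False
        )
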