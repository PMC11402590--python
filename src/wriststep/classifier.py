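"""Walk / non-walk classification of 10-s epochs.

Each epoch is labelled *walk* when it contains at least four annotated
steps.  The classifier is a pluggable backend behind a fixed contract —
per-epoch walk probability — trained with the full protocol used for the
hybrid step counter: random rotation + axis-permutation augmentation,
class reweighting to a 10%/90% walk/non-walk balance, an 80/20 grouped
training/validation split, early stopping (for iterative backends) with
patience 5, and grouped, stratified k-fold assignment for evaluation.

The default backend is a logistic model on hand-crafted vector-magnitude
features (frequency, autocorrelation and amplitude descriptors of gait);
an iterative SGD backend demonstrates the early-stopping path.  Deep
pretrained encoders can be slotted in by implementing the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import log_loss

from .preprocess import vector_magnitude
from .signal_io import DataError, EpochSet

__all__ = [
    "TrainConfig",
    "ClassifierModel",
    "WALK",
    "NON_WALK",
    "MIN_STEPS_PER_WALK_EPOCH",
    "label_epochs_from_steps",
    "augment_epoch",
    "extract_features",
    "class_weights",
    "train_classifier",
    "predict_epochs",
    "grouped_stratified_kfold",
]

WALK = 1
NON_WALK = 0
#: an epoch is "walking" when it contains at least this many steps
MIN_STEPS_PER_WALK_EPOCH = 4

FEATURE_NAMES = (
    "vm_mean",
    "vm_sd",
    "vm_q25",
    "vm_q50",
    "vm_q75",
    "dom_freq_hz",
    "dom_power",
    "spectral_entropy",
    "autocorr_peak",
    "zero_cross_rate",
)


@dataclass
class TrainConfig:
    """Training protocol parameters.

    ``target_class_balance`` is the (walk, non-walk) balance the class
    weights emulate — 10%/90%, matching 24-h free-living observation.
    ``learning_rate`` applies to iterative backends only.
    """

    val_fraction: float = 0.20
    patience_epochs: int = 5
    target_class_balance: tuple[float, float] = (0.10, 0.90)
    learning_rate: float = 0.0001
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if abs(sum(self.target_class_balance) - 1.0) > 1e-9:
            raise ValueError("target_class_balance must sum to 1")


@dataclass
class ClassifierModel:
    """Fitted linear walk classifier plus its recorded validation split.

    The validation predictions (``val_true``/``val_pred``/``val_groups``)
    are retained because the label smoother is fitted on them.
    """

    backend: str
    coef: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    threshold: float = 0.5
    val_true: np.ndarray | None = None
    val_pred: np.ndarray | None = None
    val_groups: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "backend": self.backend,
            "coef": np.asarray(self.coef, dtype=float).tolist(),
            "intercept": float(self.intercept),
            "scaler_mean": np.asarray(self.scaler_mean, dtype=float).tolist(),
            "scaler_scale": np.asarray(self.scaler_scale, dtype=float).tolist(),
            "feature_names": list(self.feature_names),
            "threshold": self.threshold,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            backend=d["backend"],
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
            feature_names=tuple(d["feature_names"]),
            threshold=float(d.get("threshold", 0.5)),
        )


def label_epochs_from_steps(step_times: np.ndarray, epoch_set: EpochSet) -> np.ndarray:
    """Binary walk labels: 1 iff >= 4 steps fall inside the epoch.

    Step times are compared against half-open windows
    ``[epoch_start, epoch_start + epoch_length)``.
    """
    step_times = np.asarray(step_times, dtype=float)
    starts = epoch_set.epoch_start_times()
    length = epoch_set.epoch_length_s
    counts = np.array(
        [np.count_nonzero((step_times >= s) & (step_times < s + length)) for s in starts]
    )
    return (counts >= MIN_STEPS_PER_WALK_EPOCH).astype(int)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def augment_epoch(epoch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate every sample about a random axis, then permute the axes.

    The rotation angle is uniform on ``[0, 2π)``, the axis uniform on the
    sphere, and the permutation uniform over the six axis orderings; both
    isometries preserve the per-sample Euclidean norm.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, 2.0 * np.pi)
    rotated = np.asarray(epoch, dtype=float) @ _rotation_matrix(axis, angle).T
    perm = rng.permutation(3)
    return rotated[:, perm]


def extract_features(epoch: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Deterministic gait descriptors of one epoch's vector magnitude.

    Amplitude (mean/SD/quartiles), the dominant frequency and its power in
    the 0.5-4 Hz gait band, spectral entropy, the autocorrelation maximum
    over step-period lags (0.3-1.2 s) and the zero-crossing rate.  All
    features are computed from the VM, so they are rotation invariant.
    """
    vm = vector_magnitude(epoch)
    n = vm.size
    sd = float(np.std(vm))
    q25, q50, q75 = np.quantile(vm, [0.25, 0.50, 0.75])

    freqs, power = periodogram(vm, fs=sample_rate_hz)
    band = (freqs >= 0.5) & (freqs <= 4.0)
    if np.any(band) and power[band].max() > 0:
        i = np.argmax(power[band])
        dom_freq = float(freqs[band][i])
        dom_power = float(power[band][i])
    else:
        dom_freq = 0.0
        dom_power = 0.0
    p = power[1:]  # drop DC
    total = p.sum()
    if total > 0:
        q = p / total
        q = q[q > 0]
        entropy = float(-(q * np.log(q)).sum() / np.log(len(p)))
    else:
        entropy = 0.0

    centred = vm - vm.mean()
    denom = float(centred @ centred)
    lo = max(1, int(round(0.3 * sample_rate_hz)))
    hi = min(n - 1, int(round(1.2 * sample_rate_hz)))
    ac_peak = 0.0
    if denom > 0 and hi >= lo:
        ac = np.correlate(centred, centred, mode="full")[n - 1 :] / denom
        ac_peak = float(ac[lo : hi + 1].max())

    signs = np.sign(centred)
    signs = signs[signs != 0]
    zcr = float(np.count_nonzero(np.diff(signs) != 0)) / n if signs.size > 1 else 0.0

    return np.array(
        [vm.mean(), sd, q25, q50, q75, dom_freq, dom_power, entropy, ac_peak, zcr]
    )


def extract_feature_matrix(epoch_set: EpochSet) -> np.ndarray:
    return np.vstack(
        [extract_features(e, epoch_set.sample_rate_hz) for e in epoch_set.epochs]
    ) if epoch_set.n_epochs else np.empty((0, len(FEATURE_NAMES)))


def class_weights(
    labels: np.ndarray, target_balance: tuple[float, float] = (0.10, 0.90)
) -> dict[int, float]:
    """Per-class weights rescaling empirical frequencies to the target.

    ``w_c ∝ target_c / empirical_c``, normalised so the mean sample weight
    is 1.  ``target_balance`` is (walk, non-walk).
    """
    labels = np.asarray(labels)
    n = labels.size
    f_walk = np.count_nonzero(labels == WALK) / n
    f_non = 1.0 - f_walk
    if f_walk == 0 or f_non == 0:
        raise ValueError("both classes must be present")
    t_walk, t_non = target_balance
    w = {WALK: t_walk / f_walk, NON_WALK: t_non / f_non}
    mean_w = f_walk * w[WALK] + f_non * w[NON_WALK]
    return {c: v / mean_w for c, v in w.items()}


def _grouped_holdout(
    groups: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (train, val) splitting whole participants."""
    uniq = np.array(sorted(set(groups.tolist())), dtype=object)
    if uniq.size < 2:
        raise DataError("grouped split needs at least two participants")
    order = rng.permutation(uniq.size)
    n_val = max(1, int(round(val_fraction * uniq.size)))
    n_val = min(n_val, uniq.size - 1)
    val_groups = set(uniq[order[:n_val]].tolist())
    val_mask = np.array([g in val_groups for g in groups])
    return ~val_mask, val_mask


def train_classifier(
    epoch_set: EpochSet,
    config: TrainConfig | None = None,
    backend: str = "logistic",
    rng: np.random.Generator | None = None,
    augment: bool = True,
) -> ClassifierModel:
    """Fit the walk classifier with the standard protocol.

    Splits participants 80/20 into training and validation, augments each
    training epoch once (random rotation + axis permutation — a no-op for
    VM features, retained so any raw-signal backend trains on the same
    protocol), reweights classes to the 10/90 target balance, fits the
    backend and records hard validation predictions for the HMM smoother.
    """
    config = config or TrainConfig()
    rng = rng or np.random.default_rng(config.seed)
    if epoch_set.labels is None:
        raise DataError("training requires labelled epochs")
    labels = epoch_set.labels
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires both classes")

    train_mask, val_mask = _grouped_holdout(
        epoch_set.group_ids, config.val_fraction, rng
    )
    if len(set(labels[train_mask].tolist())) < 2:
        raise ValueError("training split lost a class; use more participants")

    train_epochs = np.stack(
        [augment_epoch(e, rng) if augment else e for e in epoch_set.epochs[train_mask]]
    )
    X_train = np.vstack(
        [extract_features(e, epoch_set.sample_rate_hz) for e in train_epochs]
    )
    y_train = labels[train_mask]
    X_val = np.vstack(
        [extract_features(e, epoch_set.sample_rate_hz) for e in epoch_set.epochs[val_mask]]
    )
    y_val = labels[val_mask]

    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X_train - mean) / scale

    weights = class_weights(y_train, config.target_class_balance)
    sample_w = np.array([weights[int(c)] for c in y_train])

    if backend == "logistic":
        clf = LogisticRegression(max_iter=2000)
        clf.fit(Xs, y_train, sample_weight=sample_w)
        coef, intercept = clf.coef_[0], float(clf.intercept_[0])
    elif backend == "sgd":
        coef, intercept = _fit_sgd(
            Xs, y_train, (X_val - mean) / scale, y_val, sample_w, weights, config
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")

    model = ClassifierModel(
        backend=backend,
        coef=coef,
        intercept=intercept,
        scaler_mean=mean,
        scaler_scale=scale,
    )
    val_set = EpochSet(
        epochs=epoch_set.epochs[val_mask],
        epoch_length_s=epoch_set.epoch_length_s,
        sample_rate_hz=epoch_set.sample_rate_hz,
        group_ids=epoch_set.group_ids[val_mask],
    )
    _, val_pred = predict_epochs(model, val_set)
    model.val_true = y_val
    model.val_pred = val_pred
    model.val_groups = epoch_set.group_ids[val_mask]
    return model


def _fit_sgd(Xs, y, Xv, yv, sample_w, weights, config: TrainConfig):
    """Iterative logistic fit with patience-based early stopping.

    Stops when validation log-loss has not decreased for
    ``patience_epochs`` consecutive passes; the best-validation weights
    are restored.
    """
    clf = SGDClassifier(
        loss="log_loss",
        learning_rate="constant",
        eta0=config.learning_rate,
        random_state=config.seed,
        alpha=0.0,
    )
    classes = np.array([NON_WALK, WALK])
    best = (np.inf, None, None)
    stall = 0
    for _ in range(config.max_epochs):
        clf.partial_fit(Xs, y, classes=classes, sample_weight=sample_w)
        p = 1.0 / (1.0 + np.exp(-(Xv @ clf.coef_[0] + clf.intercept_[0])))
        vloss = log_loss(yv, np.column_stack([1 - p, p]), labels=classes)
        if vloss < best[0] - 1e-12:
            best = (vloss, clf.coef_[0].copy(), float(clf.intercept_[0]))
            stall = 0
        else:
            stall += 1
            if stall >= config.patience_epochs:
                break
    if best[1] is None:
        return clf.coef_[0].copy(), float(clf.intercept_[0])
    return best[1], best[2]


def predict_epochs(
    model: ClassifierModel, epoch_set: EpochSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch walk probability and hard label (p >= threshold)."""
    if model.coef is None:
        raise RuntimeError("model is not fitted")
    X = np.vstack(
        [extract_features(e, epoch_set.sample_rate_hz) for e in epoch_set.epochs]
    ) if epoch_set.n_epochs else np.empty((0, len(model.feature_names)))
    Xs = (X - model.scaler_mean) / model.scaler_scale
    z = Xs @ model.coef + model.intercept
    prob = 1.0 / (1.0 + np.exp(-z))
    return prob, (prob >= model.threshold).astype(int)


def grouped_stratified_kfold(
    epoch_set: EpochSet, k: int = 10, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Fold index per epoch; participants never straddle folds.

    Participants are assigned greedily in order of decreasing epoch count
    (random tie order): each goes to the fold with the fewest participants,
    breaking ties toward the fold whose walk-epoch fraction after the
    assignment is closest to the global fraction.  Fold sizes therefore
    differ by at most one participant.
    """
    rng = rng or np.random.default_rng(0)
    groups = epoch_set.group_ids
    labels = epoch_set.labels if epoch_set.labels is not None else np.zeros(
        epoch_set.n_epochs, dtype=int
    )
    uniq = sorted(set(groups.tolist()))
    if len(uniq) < k:
        raise ValueError(f"need at least k={k} participants, got {len(uniq)}")

    stats = {}
    for g in uniq:
        m = groups == g
        stats[g] = (int(np.count_nonzero(m)), int(labels[m].sum()))
    global_frac = labels.mean() if epoch_set.n_epochs else 0.0

    order = list(rng.permutation(len(uniq)))
    participants = sorted(
        (uniq[i] for i in order),
        key=lambda g: -stats[g][0],
    )

    fold_total = np.zeros(k)
    fold_walk = np.zeros(k)
    fold_groups = np.zeros(k, dtype=int)
    assignment: dict[object, int] = {}
    for g in participants:
        n_g, w_g = stats[g]
        candidates = np.flatnonzero(fold_groups == fold_groups.min())
        cost = [
            abs((fold_walk[f] + w_g) / (fold_total[f] + n_g) - global_frac)
            for f in candidates
        ]
        f = int(candidates[int(np.argmin(cost))])
        assignment[g] = f
        fold_total[f] += n_g
        fold_walk[f] += w_g
        fold_groups[f] += 1

    return np.array([assignment[g] for g in groups], dtype=int)
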