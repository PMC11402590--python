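"""End-to-end orchestration: train, apply and cross-validate the hybrid
step counter.

The fitted artifact bundles three parts — the epoch walk classifier, the
HMM label smoother fitted on the classifier's validation predictions, and
the peak-detector heuristics tuned to minimise validation step-count MAE
— and is serialised as a single plain-JSON archive so that training is
byte-reproducible given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .classifier import (
    ClassifierModel,
    TrainConfig,
    grouped_stratified_kfold,
    label_epochs_from_steps,
    predict_epochs,
    train_classifier,
)
from .daily import DailySummary, MinuteSeries, summarize_recording
from .detector import DetectorParams, StepEvents, detect_steps, tune_detector
from .evaluation import AgreementReport, ClassificationReport, agreement_report, classification_metrics
from .hmm import HMMParams, fit_hmm, viterbi_smooth
from .preprocess import conditioned_vm
from .signal_io import AccelRecording, EpochSet, epoch_split

__all__ = [
    "StepModel",
    "AnnotatedRecording",
    "build_epoch_set",
    "train_pipeline",
    "process_recording",
    "crossvalidate",
]


@dataclass
class AnnotatedRecording:
    """A recording together with its ground-truth step timestamps."""

    recording: AccelRecording
    step_times: np.ndarray


@dataclass
class StepModel:
    """The full fitted pipeline: classifier + HMM smoother + detector."""

    classifier: ClassifierModel
    hmm: HMMParams
    detector: DetectorParams
    sample_rate_hz: float
    epoch_length_s: float = 10.0
    seed: int = 0

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "wriststep-model",
            "version": __version__,
            "seed": self.seed,
            "sample_rate_hz": self.sample_rate_hz,
            "epoch_length_s": self.epoch_length_s,
            "classifier": self.classifier.to_dict(),
            "hmm": self.hmm.to_dict(),
            "detector": self.detector.to_dict(),
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "StepModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "wriststep-model":
            raise ValueError(f"{path} is not a wriststep model archive")
        return cls(
            classifier=ClassifierModel.from_dict(doc["classifier"]),
            hmm=HMMParams.from_dict(doc["hmm"]),
            detector=DetectorParams.from_dict(doc["detector"]),
            sample_rate_hz=float(doc["sample_rate_hz"]),
            epoch_length_s=float(doc["epoch_length_s"]),
            seed=int(doc["seed"]),
        )


def build_epoch_set(
    items: list[AnnotatedRecording], epoch_length_s: float = 10.0
) -> EpochSet:
    """Epoch and label a cohort, concatenated with participant group ids."""
    all_epochs, all_labels, all_groups = [], [], []
    rate = items[0].recording.sample_rate_hz
    for item in items:
        if item.recording.sample_rate_hz != rate:
            raise ValueError("cohort recordings must share one sample rate")
        es = epoch_split(item.recording, epoch_length_s)
        labels = label_epochs_from_steps(np.asarray(item.step_times), es)
        all_epochs.append(es.epochs)
        all_labels.append(labels)
        all_groups.append(es.group_ids)
    return EpochSet(
        epochs=np.concatenate(all_epochs),
        epoch_length_s=epoch_length_s,
        sample_rate_hz=rate,
        labels=np.concatenate(all_labels),
        group_ids=np.concatenate(all_groups),
    )


def _sequences_by_group(groups: np.ndarray, *arrays) -> list[tuple]:
    """Split aligned arrays into per-participant sequences, epoch order kept."""
    out = []
    for g in sorted(set(groups.tolist())):
        m = groups == g
        out.append(tuple(a[m] for a in arrays))
    return out


def _walk_run_validation_items(
    items: list[AnnotatedRecording],
    epoch_length_s: float,
) -> list:
    """(conditioned VM of each true walking run, its true step count)."""
    from .detector import _label_runs

    val = []
    for item in items:
        rec = item.recording
        es = epoch_split(rec, epoch_length_s)
        labels = label_epochs_from_steps(np.asarray(item.step_times), es)
        spe = round(epoch_length_s * rec.sample_rate_hz)
        for a, b in _label_runs(labels):
            seg = rec.samples[a * spe : b * spe]
            t0 = rec.start_time + a * epoch_length_s
            t1 = rec.start_time + b * epoch_length_s
            n_true = int(
                np.count_nonzero(
                    (np.asarray(item.step_times) >= t0)
                    & (np.asarray(item.step_times) < t1)
                )
            )
            val.append((conditioned_vm(seg, rec.sample_rate_hz), n_true))
    return val


def train_pipeline(
    items: list[AnnotatedRecording],
    config: TrainConfig | None = None,
    backend: str = "logistic",
    epoch_length_s: float = 10.0,
    detector_grid=None,
) -> StepModel:
    """Train the classifier, fit the smoother, tune the detector.

    The classifier uses an internal 80/20 grouped split; the HMM is fitted
    on its validation predictions vs truth, and the peak-detector grid
    search minimises MAE on the validation participants' true walking runs.
    """
    config = config or TrainConfig()
    if len(items) < 2:
        raise ValueError("training needs at least two participants")
    epoch_set = build_epoch_set(items, epoch_length_s)
    model = train_classifier(epoch_set, config=config, backend=backend)

    seqs = _sequences_by_group(model.val_groups, model.val_true, model.val_pred)
    hmm = fit_hmm([s[0] for s in seqs], [s[1] for s in seqs])

    val_ids = set(model.val_groups.tolist())
    val_items = [
        it for it in items if it.recording.participant_id in val_ids
    ]
    validation = _walk_run_validation_items(val_items, epoch_length_s)
    if not validation:  # no walking among validation participants
        raise ValueError("validation participants contain no walking runs")
    detector = tune_detector(validation, grid=detector_grid)

    return StepModel(
        classifier=model,
        hmm=hmm,
        detector=detector,
        sample_rate_hz=epoch_set.sample_rate_hz,
        epoch_length_s=epoch_length_s,
        seed=config.seed,
    )


@dataclass
class ProcessResult:
    probabilities: np.ndarray
    raw_labels: np.ndarray
    smoothed_labels: np.ndarray
    steps: StepEvents
    summary: DailySummary
    minute_series: MinuteSeries


def process_recording(model: StepModel, recording: AccelRecording) -> ProcessResult:
    """Classify epochs, smooth the label sequence, detect steps, summarise."""
    es = epoch_split(recording, model.epoch_length_s)
    prob, raw = predict_epochs(model.classifier, es)
    smoothed = viterbi_smooth(model.hmm, raw) if raw.size else raw
    steps = detect_steps(
        recording, smoothed, model.detector, epoch_length_s=model.epoch_length_s
    )
    summary, series = summarize_recording(recording, steps, include_partial_days=True)
    return ProcessResult(prob, raw, smoothed, steps, summary, series)


def crossvalidate(
    items: list[AnnotatedRecording],
    k: int = 10,
    config: TrainConfig | None = None,
    backend: str = "logistic",
    epoch_length_s: float = 10.0,
    detector_grid=None,
) -> dict:
    """Grouped, stratified k-fold evaluation of the whole pipeline.

    For each fold the classifier, smoother and detector are trained on the
    remaining participants and applied to the held-out ones.  Returns the
    participant-level agreement report, pooled classification report and
    per-participant table.
    """
    config = config or TrainConfig()
    full = build_epoch_set(items, epoch_length_s)
    folds = grouped_stratified_kfold(
        full, k=k, rng=np.random.default_rng(config.seed)
    )
    by_pid = {it.recording.participant_id: it for it in items}
    pid_fold = {}
    for g, f in zip(full.group_ids, folds):
        pid_fold[g] = int(f)

    rows = []
    all_true_labels, all_pred_labels = [], []
    for fold in range(k):
        test_pids = sorted(p for p, f in pid_fold.items() if f == fold)
        if not test_pids:
            continue
        train_items = [by_pid[p] for p in sorted(by_pid) if pid_fold[p] != fold]
        model = train_pipeline(
            train_items,
            config=config,
            backend=backend,
            epoch_length_s=epoch_length_s,
            detector_grid=detector_grid,
        )
        for pid in test_pids:
            item = by_pid[pid]
            res = process_recording(model, item.recording)
            es = epoch_split(item.recording, epoch_length_s)
            truth = label_epochs_from_steps(np.asarray(item.step_times), es)
            rows.append(
                {
                    "participant_id": pid,
                    "fold": fold,
                    "true_steps": int(np.asarray(item.step_times).size),
                    "pred_steps": int(res.steps.count),
                }
            )
            all_true_labels.append(truth)
            all_pred_labels.append(res.smoothed_labels)

    true_counts = [r["true_steps"] for r in rows]
    pred_counts = [r["pred_steps"] for r in rows]
    agreement = agreement_report(true_counts, pred_counts)
    classification = classification_metrics(
        np.concatenate(all_true_labels), np.concatenate(all_pred_labels)
    )
    return {
        "agreement": agreement,
        "classification": classification,
        "per_participant": rows,
    }
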