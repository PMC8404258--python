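"""Subject-exclusive cross-validation and classification metrics.

Heart-sound frames from one animal are strongly correlated, so frames of
the same subject must never straddle the training and test sets.  The
evaluation backbone is therefore a grouped, group-stratified 5-fold
cross-validation at the subject level: subjects are partitioned into k
test folds (each fold's test set is about 20% of subjects), and within
each fold a fraction of the remaining training subjects is held out as
the validation set that drives early stopping.

Performance is reported as accuracy, sensitivity and specificity from the
confusion counts, with sudden death as the positive class.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import (ModelSpec, ShapeError, TrainConfig, encode_labels,
                         output_shapes, predict, train)
from .segmentation import EnvelopeParams, FrameSet, frames_from_manifest

logger = logging.getLogger("pcgnet")


class UndefinedMetricError(ValueError):
    """Raised when a requested rate has an empty denominator."""


class LeakageError(AssertionError):
    """Raised when a subject appears on both sides of a split."""


@dataclass
class FoldSplit:
    train_subjects: tuple
    val_subjects: tuple
    test_subjects: tuple

    def __post_init__(self) -> None:
        tr, va, te = (set(self.train_subjects), set(self.val_subjects),
                      set(self.test_subjects))
        if tr & va or tr & te or va & te:
            raise LeakageError("subject appears in more than one of train/val/test")


@dataclass
class SplitPlan:
    """Per-fold subject assignments for grouped k-fold cross-validation."""

    folds: list[FoldSplit]
    k: int
    seed: int

    def __post_init__(self) -> None:
        test_sets = [set(f.test_subjects) for f in self.folds]
        all_test: set = set()
        for ts in test_sets:
            if all_test & ts:
                raise LeakageError("a subject is tested in more than one fold")
            all_test |= ts

    def to_json(self) -> str:
        import json

        return json.dumps({
            "k": self.k, "seed": self.seed,
            "folds": [{"train": list(f.train_subjects), "val": list(f.val_subjects),
                       "test": list(f.test_subjects)} for f in self.folds]
        }, indent=2)


@dataclass
class MetricsReport:
    """Confusion counts and the derived accuracy / sensitivity / specificity."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float = field(init=False)
    sens: float = field(init=False)
    spec: float = field(init=False)
    sens_defined: bool = field(init=False)
    spec_defined: bool = field(init=False)

    def __post_init__(self) -> None:
        total = self.tp + self.tn + self.fp + self.fn
        if total == 0:
            raise ValueError("empty confusion matrix")
        self.acc = (self.tp + self.tn) / total
        self.sens_defined = (self.tp + self.fn) > 0
        self.spec_defined = (self.tn + self.fp) > 0
        if not self.sens_defined:
            warnings.warn("sensitivity undefined: no positive ground truth",
                          stacklevel=2)
        if not self.spec_defined:
            warnings.warn("specificity undefined: no negative ground truth",
                          stacklevel=2)
        self.sens = self.tp / (self.tp + self.fn) if self.sens_defined else math.nan
        self.spec = self.tn / (self.tn + self.fp) if self.spec_defined else math.nan


def compute_metrics(y_true, y_pred, positive_class: int = 1) -> MetricsReport:
    """Confusion counts and Acc/Sens/Spec for binary label sequences."""
    y_true = encode_labels(y_true)
    y_pred = encode_labels(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label sequences")
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn)


def aggregate_metrics(reports: list[MetricsReport]) -> dict:
    """Mean and SD of Acc/Sens/Spec across folds."""
    out = {}
    for name in ("acc", "sens", "spec"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[f"{name}_mean"] = float(np.nanmean(vals))
        out[f"{name}_sd"] = float(np.nanstd(vals))
    return out


# ---------------------------------------------------------------------------
# Grouped k-fold splitting
# ---------------------------------------------------------------------------

def grouped_kfold(subject_groups: dict | pd.DataFrame, k: int = 5,
                  val_fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Subject-level, group-stratified k-fold split plan.

    ``subject_groups`` maps subject id -> group label (a manifest
    DataFrame with ``subject_id`` / ``group`` columns is also accepted).
    Subjects of each group are shuffled and dealt round-robin into k test
    folds, so the folds partition the subjects and every fold contains
    both classes whenever each group has at least k subjects.  Within each
    fold, ``val_fraction`` of the training subjects (at least one per
    group) is held out for validation.
    """
    if isinstance(subject_groups, pd.DataFrame):
        pairs = subject_groups[["subject_id", "group"]].drop_duplicates()
        subject_groups = dict(zip(pairs.subject_id, pairs.group))
    groups: dict[str, list] = {}
    for subj, grp in subject_groups.items():
        groups.setdefault(grp, []).append(subj)
    for grp, members in groups.items():
        if len(members) < k:
            raise ValueError(f"group {grp!r} has {len(members)} subjects, "
                             f"fewer than k={k}")
    rng = np.random.default_rng(seed)
    test_folds: list[list] = [[] for _ in range(k)]
    for grp in sorted(groups):
        members = sorted(groups[grp])
        rng.shuffle(members)
        for i, subj in enumerate(members):
            test_folds[i % k].append(subj)
    folds = []
    for i in range(k):
        test = sorted(test_folds[i])
        pool = {grp: [s for s in sorted(groups[grp]) if s not in test]
                for grp in sorted(groups)}
        val: list = []
        for grp, members in pool.items():
            members = list(members)
            rng.shuffle(members)
            n_val = max(1, int(round(val_fraction * len(members))))
            val.extend(members[:n_val])
        val = sorted(val)
        train = sorted(s for members in pool.values() for s in members
                       if s not in val)
        folds.append(FoldSplit(train_subjects=tuple(train),
                               val_subjects=tuple(val),
                               test_subjects=tuple(test)))
    return SplitPlan(folds=folds, k=k, seed=seed)


def _mask(subjects: np.ndarray, chosen) -> np.ndarray:
    return np.isin(subjects, np.asarray(list(chosen)))


def cross_validate(frames: FrameSet, spec: ModelSpec, cfg: TrainConfig,
                   k: int = 5, val_fraction: float = 0.2,
                   seed: int = 0) -> list[MetricsReport]:
    """Grouped k-fold cross-validation of one architecture on a frame set.

    Subject exclusivity is re-checked programmatically on every fold
    before training.  Folds whose test set received no frames are
    skipped with a warning (small groups can leave a fold empty).
    """
    subject_groups = {s: l for s, l in zip(frames.subjects, frames.labels)}
    plan = grouped_kfold(subject_groups, k=k, val_fraction=val_fraction, seed=seed)
    y = encode_labels(frames.labels)
    reports = []
    for i, fold in enumerate(plan.folds):
        m_tr = _mask(frames.subjects, fold.train_subjects)
        m_va = _mask(frames.subjects, fold.val_subjects)
        m_te = _mask(frames.subjects, fold.test_subjects)
        if (m_tr & m_te).any() or (m_va & m_te).any() or (m_tr & m_va).any():
            raise LeakageError("frame masks overlap across the split")
        if not m_te.any():
            warnings.warn(f"fold {i}: no test frames; skipped", stacklevel=2)
            continue
        model, history = train(spec, frames.frames[m_tr], y[m_tr],
                               frames.frames[m_va], y[m_va], cfg)
        _, pred = predict(model, frames.frames[m_te], spec.input_len)
        report = compute_metrics(y[m_te], pred)
        logger.info("fold %d: %d epochs, acc=%.3f sens=%.3f spec=%.3f",
                    i, len(history["train_loss"]), report.acc, report.sens,
                    report.spec)
        reports.append(report)
    return reports


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def run_time_node_experiment(manifest: pd.DataFrame, spec: ModelSpec,
                             cfg: TrainConfig | None = None, k: int = 5,
                             seed: int = 0,
                             env_params: EnvelopeParams | None = None) -> pd.DataFrame:
    """Segment and cross-validate each time node independently.

    Returns one row per node with the fold-mean and SD of accuracy,
    sensitivity and specificity - the progression of class separability
    across the exercise protocol.
    """
    cfg = cfg or TrainConfig(seed=seed)
    nodes = ("A", "B", "C", "D")
    missing = set(nodes) - set(manifest.time_node.unique())
    if missing:
        raise ValueError(f"manifest lacks time nodes: {sorted(missing)}")
    rows = []
    for node in nodes:
        sub = manifest[manifest.time_node == node]
        frames = frames_from_manifest(sub, env_params)
        for label in ("survival", "sudden_death"):
            if not (frames.labels == label).any():
                raise ValueError(f"node {node}: segmentation yielded no "
                                 f"frames for group {label!r}")
        reports = cross_validate(frames, spec, cfg, k=k, seed=seed)
        agg = aggregate_metrics(reports)
        logger.info("node %s: acc=%.3f+-%.3f over %d folds", node,
                    agg["acc_mean"], agg["acc_sd"], len(reports))
        rows.append({"time_node": node, "n_frames": len(frames), **agg})
    return pd.DataFrame(rows)


def run_architecture_comparison(frames: FrameSet, arch_list: list[tuple[str, ModelSpec]],
                                cfg: TrainConfig | None = None, k: int = 5,
                                seed: int = 0) -> pd.DataFrame:
    """Cross-validate several architectures under identical splits and seeds.

    Architectures that fail shape propagation are reported in the table
    (``error`` column) rather than raised.
    """
    cfg = cfg or TrainConfig(seed=seed)
    rows = []
    for name, spec in arch_list:
        try:
            output_shapes(spec)
        except ShapeError as exc:
            rows.append({"arch": name, "error": str(exc)})
            continue
        reports = cross_validate(frames, spec, cfg, k=k, seed=seed)
        rows.append({"arch": name, "error": "", **aggregate_metrics(reports)})
    return pd.DataFrame(rows)
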