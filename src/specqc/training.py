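"""Network optimization and subject-grouped cross-validation.

Two cross-validation schemes, both strictly subject-grouped so no voxel of a
test subject ever reaches training or validation:

* ``ND_rotating`` — per fold, one test subject and one validation subject are
  reserved from each of the four neuro/control cohort tags (healthy, MDD, MS,
  PD); the rest train.  Repeated (default 10 times) with test subjects drawn
  without replacement within each tag, so each subject is tested at most once.
* ``BT_leave_one_out`` — one fold per subject: that subject tests, two other
  randomly drawn subjects validate, the rest train.

Networks train with Adam (lr 1e-4), categorical cross-entropy, batch 64,
15 epochs, no early stopping — final-epoch weights are used and per-epoch
loss/accuracy curves on the training and validation sets are recorded as
diagnostics.  Random forests fit the aggregated training voxels directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _nn
from .metrics import MetricsReport, aggregate_folds, compute_report, subset_report
from .models import (
    GOOD_CLASS,
    NETWORK_KINDS,
    ModelSpec,
    NetworkModel,
    RFModel,
    build_hybrid,
)
from .spectra import CohortDataset, PreprocessConfig, preprocess_dataset

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "CVResult",
    "make_split_plan",
    "train_network",
    "train_rf",
    "run_cross_validation",
]

ND_TAGS = ("healthy", "MDD", "MS", "PD")
SCHEMES = ("ND_rotating", "BT_leave_one_out")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 15
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "categorical_cross_entropy"

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam" or self.loss != "categorical_cross_entropy":
            raise ValueError("only adam + categorical cross-entropy are supported")


@dataclass(frozen=True)
class SplitPlan:
    scheme: str
    folds: list[tuple[list[str], list[str], list[str]]]  # (train, val, test)
    n_repeats: int

    def validate(self) -> None:
        for k, (train, val, test) in enumerate(self.folds):
            tr, va, te = set(train), set(val), set(test)
            if tr & va or tr & te or va & te:
                raise ValueError(f"fold {k}: train/val/test subjects overlap")
            if not te:
                raise ValueError(f"fold {k}: empty test set")


def _subjects_by_tag(dataset: CohortDataset) -> dict[str, list[str]]:
    by_tag: dict[str, list[str]] = {}
    for sid, tag in dataset.subject_tags.items():
        by_tag.setdefault(tag, []).append(sid)
    return by_tag


def make_split_plan(
    dataset: CohortDataset, scheme: str, seed: int = 0, n_repeats: int = 10
) -> SplitPlan:
    """Build a subject-grouped split plan; deterministic given the seed."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    rng = np.random.default_rng(seed)
    subjects = dataset.subjects

    if scheme == "ND_rotating":
        by_tag = _subjects_by_tag(dataset)
        for tag in ND_TAGS:
            n = len(by_tag.get(tag, []))
            if n < 2:
                raise ValueError(
                    f"ND_rotating needs >= 2 subjects per cohort tag; tag {tag!r} has {n}"
                )
            if n < n_repeats:
                raise ValueError(
                    f"cannot rotate {n_repeats} folds without replacement: "
                    f"tag {tag!r} has only {n} subjects"
                )
        # seeded permutation per tag; fold k tests the k-th subject of each tag
        perms = {tag: list(rng.permutation(by_tag[tag])) for tag in ND_TAGS}
        folds = []
        for k in range(n_repeats):
            test = [perms[tag][k] for tag in ND_TAGS]
            val = []
            for tag in ND_TAGS:
                remaining = [s for s in by_tag[tag] if s != perms[tag][k]]
                val.append(remaining[rng.integers(len(remaining))])
            train = [s for s in subjects if s not in set(test) | set(val)]
            folds.append((train, val, test))
        plan = SplitPlan(scheme, folds, n_repeats)

    else:  # BT_leave_one_out
        if len(subjects) < 4:
            raise ValueError("BT_leave_one_out needs >= 4 subjects (1 test, 2 val, >=1 train)")
        folds = []
        for sid in subjects:
            others = [s for s in subjects if s != sid]
            val = list(rng.choice(others, size=2, replace=False))
            train = [s for s in others if s not in set(val)]
            folds.append((train, val, [sid]))
        plan = SplitPlan(scheme, folds, len(subjects))

    plan.validate()
    return plan


def _xy(dataset: CohortDataset) -> tuple[np.ndarray, np.ndarray]:
    return dataset.spectra.astype(np.float32), dataset.labels


def _eval_set(model: NetworkModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    logits = model.logits(X)
    loss, _ = _nn.softmax_cross_entropy(logits, y)
    acc = float(np.mean(logits.argmax(axis=1) == y))
    return loss, acc


def train_network(
    model: NetworkModel,
    train_set: CohortDataset,
    val_set: CohortDataset,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[NetworkModel, dict[str, list[float]]]:
    """Train a CNN/ICNN; returns the model and per-epoch loss/accuracy curves.

    Refuses subject overlap between the training and validation sets.
    """
    overlap = set(train_set.subjects) & set(val_set.subjects)
    if overlap:
        raise ValueError(f"subject leakage between train and validation sets: {sorted(overlap)}")
    Xtr, ytr = _xy(train_set)
    Xva, yva = _xy(val_set)
    opt = _nn.Adam(model.net.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    curves: dict[str, list[float]] = {k: [] for k in ("train_loss", "train_acc", "val_loss", "val_acc")}

    n = Xtr.shape[0]
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):  # last partial batch kept
            idx = perm[start : start + cfg.batch_size]
            logits = model.net.forward(Xtr[idx, None, :])
            _, dlogits = _nn.softmax_cross_entropy(logits, ytr[idx])
            model.net.backward(dlogits)
            opt.step()
        tl, ta = _eval_set(model, Xtr, ytr)
        vl, va = _eval_set(model, Xva, yva)
        curves["train_loss"].append(tl)
        curves["train_acc"].append(ta)
        curves["val_loss"].append(vl)
        curves["val_acc"].append(va)

    model.trained = True
    return model, curves


def train_rf(model: RFModel, train_set: CohortDataset, seed: int | None = None) -> RFModel:
    """Fit a random forest on the aggregated training voxels."""
    if seed is not None:
        model.forest.set_params(random_state=seed)
    X, y = _xy(train_set)
    return model.fit(X, y)


@dataclass
class CVResult:
    """Per-fold and aggregate metrics for one model kind under one split plan."""

    model_kind: str
    fold_reports: list[MetricsReport]
    lesion_reports: list[MetricsReport]
    aggregate: dict[str, tuple[float, float]]
    lesion_aggregate: dict[str, tuple[float, float]] | None
    curves: list[dict[str, list[float]]] = field(default_factory=list)


def _fit_fold(
    spec: ModelSpec,
    train_ds: CohortDataset,
    val_ds: CohortDataset,
    cfg: TrainConfig,
    seed: int,
):
    if spec.kind == "RF":
        model = RFModel(spec, seed=seed)
        return train_rf(model, train_ds), None
    base_kind = spec.kind.split("+")[0]
    net = NetworkModel(replace(spec, kind=base_kind), seed=seed)
    net, curves = train_network(net, val_set=val_ds, train_set=train_ds, cfg=replace(cfg, seed=seed))
    if spec.kind in NETWORK_KINDS:
        return net, curves
    # hybrid: forward penultimate features into an RF
    X, y = _xy(train_ds)
    rf_spec = replace(spec, kind="RF")
    hybrid = build_hybrid(net, rf_spec, X, y, seed=seed)
    return hybrid, curves


def run_cross_validation(
    dataset: CohortDataset,
    model_spec: ModelSpec,
    train_cfg: TrainConfig,
    plan: SplitPlan,
    preprocess: bool = True,
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
) -> CVResult:
    """Run one model kind through every fold of a split plan.

    Metrics are computed on test subjects only; lesion-only reports are added
    for folds whose test set contains lesion voxels of both classes.
    """
    plan.validate()
    if preprocess:
        dataset = preprocess_dataset(dataset, preprocess_cfg)

    fold_reports: list[MetricsReport] = []
    lesion_reports: list[MetricsReport] = []
    curves_all: list[dict[str, list[float]]] = []
    for k, (train_subj, val_subj, test_subj) in enumerate(plan.folds):
        train_ds = dataset.subset_subjects(train_subj)
        val_ds = dataset.subset_subjects(val_subj)
        test_ds = dataset.subset_subjects(test_subj)
        if len(test_ds) == 0:
            raise ValueError(f"fold {k}: no voxels in the test subjects")

        seed = (train_cfg.seed * 100003 + 7919 * k) % (2**31)
        model, curves = _fit_fold(model_spec, train_ds, val_ds, train_cfg, seed)
        if curves is not None:
            curves_all.append(curves)

        scores = model.predict_proba(test_ds.spectra.astype(np.float32))[:, GOOD_CLASS]
        labels = test_ds.labels
        fold_reports.append(compute_report(labels, scores))

        mask = test_ds.lesion_mask
        if mask.any() and np.unique(labels[mask]).size == 2:
            lesion_reports.append(subset_report(labels, scores, mask))

    return CVResult(
        model_kind=model_spec.kind,
        fold_reports=fold_reports,
        lesion_reports=lesion_reports,
        aggregate=aggregate_folds(fold_reports),
        lesion_aggregate=aggregate_folds(lesion_reports) if lesion_reports else None,
        curves=curves_all,
    )
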