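"""High-level modelling interface: build an experiment from a cohort, fit it,
inspect a results object.

Follows the familiar model/results split::

    exp = QCExperiment(cohort, model_spec=ModelSpec(kind="CNN"),
                       train_config=TrainConfig(epochs=15))
    res = exp.fit(scheme="ND_rotating", seed=7)
    print(res.summary())

``fit`` runs the subject-grouped cross-validation; the returned
:class:`QCResults` carries the per-fold metrics, their mean +/- standard
deviation across folds (the uncertainty reported in the summary table),
training diagnostics, and plotting/attribution helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import MetricsReport
from .models import ModelSpec
from .spectra import CohortDataset, PreprocessConfig, read_cohort
from .training import CVResult, SplitPlan, TrainConfig, make_split_plan, run_cross_validation

__all__ = ["QCExperiment", "QCResults"]


class QCExperiment:
    """A QC classification experiment on one labeled cohort."""

    def __init__(
        self,
        dataset: CohortDataset,
        model_spec: ModelSpec = ModelSpec(kind="RF"),
        train_config: TrainConfig = TrainConfig(),
        preprocess_config: PreprocessConfig = PreprocessConfig(),
    ):
        self.dataset = dataset
        self.model_spec = model_spec
        self.train_config = train_config
        self.preprocess_config = preprocess_config

    @classmethod
    def from_cohort_file(cls, path, **kwargs) -> "QCExperiment":
        return cls(read_cohort(path), **kwargs)

    def fit(
        self,
        scheme: str = "ND_rotating",
        seed: int = 0,
        n_repeats: int = 10,
        plan: SplitPlan | None = None,
    ) -> "QCResults":
        if plan is None:
            plan = make_split_plan(self.dataset, scheme, seed=seed, n_repeats=n_repeats)
        cv = run_cross_validation(
            self.dataset, self.model_spec, self.train_config, plan,
            preprocess_cfg=self.preprocess_config,
        )
        return QCResults(experiment=self, plan=plan, cv=cv)


@dataclass
class QCResults:
    """Cross-validated metrics for one model kind, with a summary table."""

    experiment: QCExperiment
    plan: SplitPlan
    cv: CVResult

    @property
    def fold_reports(self) -> list[MetricsReport]:
        return self.cv.fold_reports

    @property
    def aggregate(self) -> dict[str, tuple[float, float]]:
        return self.cv.aggregate

    def fold_table(self) -> pd.DataFrame:
        rows = [
            {"fold": k, "auc": r.auc, "auc_pr": r.auc_pr, "accuracy": r.accuracy,
             "n_voxels": r.n_voxels}
            for k, r in enumerate(self.cv.fold_reports)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Mean +/- std table across folds, with a lesion-only block when present."""
        lines = [
            "Spectral QC cross-validation results",
            "=" * 52,
            f"model kind : {self.cv.model_kind}",
            f"scheme     : {self.plan.scheme} ({len(self.plan.folds)} folds)",
            f"voxels     : {len(self.experiment.dataset)}",
            "-" * 52,
            f"{'metric':<12}{'mean':>10}{'std':>10}",
        ]
        for name, (mean, std) in self.cv.aggregate.items():
            lines.append(f"{name:<12}{mean:>10.3f}{std:>10.3f}")
        if self.cv.lesion_aggregate:
            lines.append("-" * 52)
            lines.append(f"lesion-only voxels ({len(self.cv.lesion_reports)} folds)")
            for name, (mean, std) in self.cv.lesion_aggregate.items():
                lines.append(f"{name:<12}{mean:>10.3f}{std:>10.3f}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def plot_curves(self, fold: int = 0, ax=None):
        """Training/validation loss and accuracy curves for one fold (networks)."""
        if not self.cv.curves:
            raise ValueError("no training curves: the RF has no optimization trajectory")
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        curves = self.cv.curves[fold]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        epochs = np.arange(1, len(curves["train_loss"]) + 1)
        ax.plot(epochs, curves["train_loss"], color="tab:blue", label="train loss")
        ax.plot(epochs, curves["val_loss"], color="tab:green", label="val loss")
        ax2 = ax.twinx()
        ax2.plot(epochs, curves["train_acc"], color="tab:blue", ls="--", label="train acc")
        ax2.plot(epochs, curves["val_acc"], color="tab:green", ls="--", label="val acc")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax2.set_ylabel("accuracy")
        ax.legend(loc="upper right", fontsize=8)
        return ax
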