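"""Model/Results interface over the full pipeline.

`SavPhenotypeModel` holds a labelled feature matrix and a run
configuration; `fit` runs stability selection (optionally) followed by
SVM training and returns a `SavPhenotypeResults` carrying the selection
report, the trained scorer, in-sample diagnostics and a `summary()`
table. This mirrors the model/results split of the mainstream
statistical-modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureMatrix, Label, RunConfig, child_seed, logger
from .errors import DegenerateInputError, ValidationError
from .evalstats import EvalReport
from .learner import (
    SelectionReport,
    TrainedModel,
    predict_score,
    stability_select,
    train_svm,
)


class SavPhenotypeModel:
    """Disease-vs-neutral scorer for single amino acid variants.

    Parameters
    ----------
    features : FeatureMatrix
        Per-variant feature vectors. Rows with an ``unknown`` label are
        dropped from training.
    labels : array-like, optional
        Binary labels (1 = disease, 0 = neutral). Defaults to the labels
        carried by the SAVs themselves.
    config : RunConfig, optional
        Selection/SVM/score parameters; defaults are the published ones
        (C=128, gamma=0.01, 100 half-subsets, alpha=0.5, 30 picks,
        keep-all rule, cutoff 50).
    """

    def __init__(
        self,
        features: FeatureMatrix,
        labels: np.ndarray | None = None,
        config: RunConfig | None = None,
    ):
        if labels is None:
            labels = features.labels
        labels = np.asarray(labels, int)
        if len(labels) != features.n_savs:
            raise ValidationError("labels length != number of SAVs")
        known = labels >= 0
        if not known.all():
            logger.info("dropping %d unlabeled SAVs from training", (~known).sum())
            features = features.select_rows(np.flatnonzero(known))
            labels = labels[known]
        if len(np.unique(labels)) < 2:
            raise DegenerateInputError("training requires both classes")
        self.features = features
        self.labels = labels
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(cls, df, feature_cols=None, config: RunConfig | None = None):
        """Build from a tidy frame with protein_id/position/wt/mut/label
        columns plus feature columns (all remaining numeric columns by
        default)."""
        from .core import feature_matrix_from_dataframe

        if feature_cols is not None:
            meta = [c for c in ("protein_id", "position", "wt", "mut", "label") if c in df.columns]
            df = df[meta + list(feature_cols)]
        return cls(feature_matrix_from_dataframe(df), config=config)

    def fit(self, select: bool = True) -> "SavPhenotypeResults":
        """Run (optional) stability selection, then train the SVM."""
        cfg = self.config
        report = None
        matrix = self.features
        if select:
            report = stability_select(
                self.features, self.labels, cfg.selection, seed=cfg.seed
            )
            if report.chosen:
                matrix = self.features.select_features(report.chosen)
            else:
                logger.warning(
                    "stability selection chose no feature at threshold %.2f; "
                    "training on all features",
                    cfg.selection.keep_threshold,
                )
        trained = train_svm(matrix, self.labels, cfg.svm, seed=child_seed(cfg.seed, 30))
        return SavPhenotypeResults(self, report, trained)


@dataclass
class SavPhenotypeResults:
    """Fitted scorer plus diagnostics."""

    model: SavPhenotypeModel
    selection: SelectionReport | None
    trained: TrainedModel

    def predict(self, features: FeatureMatrix | None = None, cutoff: float | None = None):
        """Score SAVs: disease probability, 0-100 score, binary call."""
        if features is None:
            features = self.model.features
        if cutoff is None:
            cutoff = self.model.config.score_cutoff
        return predict_score(self.trained, features, cutoff=cutoff)

    def evaluate(
        self,
        features: FeatureMatrix | None = None,
        labels: np.ndarray | None = None,
        cutoff: float | None = None,
    ) -> EvalReport:
        if features is None:
            features, labels = self.model.features, self.model.labels
        if labels is None:
            labels = features.labels
        if cutoff is None:
            cutoff = self.model.config.score_cutoff
        scores = self.predict(features, cutoff)["score"].to_numpy()
        return EvalReport.from_scores(scores, np.asarray(labels, int), cutoff)

    def summary(self) -> str:
        """Human-readable fit summary (selection, SVM, in-sample metrics)."""
        cfg = self.model.config
        n1 = int((self.model.labels == 1).sum())
        n0 = int((self.model.labels == 0).sum())
        lines = [
            "SAV phenotype model",
            "=" * 55,
            f"variants: {self.model.features.n_savs} (disease {n1}, neutral {n0})",
            f"candidate features: {len(self.model.features.feature_names)}",
            f"SVM: RBF kernel, C={self.trained.config.C:g}, gamma={self.trained.config.gamma:g}",
            f"score cutoff: {cfg.score_cutoff:g}",
        ]
        if self.selection is not None:
            lines.append(
                f"stability selection: {self.selection.n_subsets} subsets, "
                f"keep threshold {self.selection.keep_threshold:g}"
            )
            lines.append(f"chosen features ({len(self.selection.chosen)}):")
            for name in self.selection.chosen:
                lines.append(f"  {name:<24s} frequency {self.selection.frequencies[name]:.2f}")
        else:
            lines.append("feature selection: none (all features used)")
        rep = self.evaluate()
        lines.append("-" * 55)
        lines.append("in-sample performance:")
        for key in ("accuracy", "recall", "precision", "balanced_accuracy", "mcc", "f_measure"):
            lines.append(f"  {key:<20s} {rep.metrics[key]:.3f}")
        lines.append(f"  {'auc':<20s} {rep.auc:.3f}")
        return "\n".join(lines)
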