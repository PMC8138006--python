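"""Model/Results interface over the discriminant analysis.

`CanonicalDiscriminantModel` is constructed from a per-cell feature table
(a DataFrame with ``patient_id``/``field_id``/``cell_id``/``group_label``
identity columns plus feature columns).  ``fit()`` runs feature ranking,
selection and the Fisher canonical projection and returns a
`DiscriminantResults` object carrying the fitted axes, per-feature scores,
training ROC, a ``summary()`` table, held-out validation via
``cross_validate()`` and the four-panel figure via ``plot_panels()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import feature_columns, validate_feature_table
from .discriminant import (
    CanonicalProjection,
    SelectionPolicy,
    fit_canonical_projection,
    project,
    rank_features,
    select_features,
)
from .validation import (
    CVConfig,
    TrainedClassifier,
    ValidationReport,
    make_report,
    mann_whitney_u,
    nested_cv,
    roc_auc,
    train_classifier,
)


class CanonicalDiscriminantModel:
    """Binary-group canonical discriminant analysis of a cell feature table."""

    def __init__(self, table: pd.DataFrame, features=None):
        self.table = validate_feature_table(table)
        self.features = list(features) if features is not None else feature_columns(self.table)
        y = self.table["group_label"].to_numpy()
        self.n_cells = len(self.table)
        self.group_sizes = (int((y == 0).sum()), int((y == 1).sum()))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, features=None) -> "CanonicalDiscriminantModel":
        return cls(df, features=features)

    def fit(self, n_features: int = 6, redundancy_rho: float = 0.95) -> "DiscriminantResults":
        """Rank, select ``n_features`` (guarded below min group size N), and project."""
        scores = rank_features(self.table, self.features)
        policy = SelectionPolicy(n=n_features, redundancy_rho=redundancy_rho)
        selected = select_features(scores, policy, self.table)
        classifier = train_classifier(self.table, selected)
        return DiscriminantResults(self, scores, selected, classifier)

    def cross_validate(self, cfg: CVConfig = CVConfig(), **kw) -> ValidationReport:
        return nested_cv(self.table, cfg, feature_cols=self.features, **kw)


@dataclass
class DiscriminantResults:
    """Fitted discriminant: selected features, axes, training performance."""

    model: CanonicalDiscriminantModel
    feature_scores: list
    selected_features: list
    classifier: TrainedClassifier

    @property
    def projection(self) -> CanonicalProjection:
        return self.classifier.projection

    @property
    def params(self) -> pd.Series:
        """First canonical axis weights over the selected features."""
        return pd.Series(self.projection.w1, index=self.selected_features, name="w1")

    def scores(self, table: pd.DataFrame | None = None) -> np.ndarray:
        return self.classifier.score(table if table is not None else self.model.table)

    def predict(self, table: pd.DataFrame | None = None) -> np.ndarray:
        return self.classifier.predict(table if table is not None else self.model.table)

    def training_roc(self):
        return roc_auc(self.scores(), self.model.table["group_label"].to_numpy())

    def group_test(self):
        s = self.scores()
        y = self.model.table["group_label"].to_numpy()
        return mann_whitney_u(s[y == 1], s[y == 0])

    def summary(self) -> str:
        roc = self.training_roc()
        gt = self.group_test()
        n0, n1 = self.model.group_sizes
        lines = [
            "Canonical discriminant analysis (binary groups)",
            "=" * 56,
            f"cells: {self.model.n_cells}  (group 1: n = {n0}, group 2: n = {n1})",
            f"candidate features: {len(self.model.features)}   "
            f"selected: {len(self.selected_features)}",
            f"shrinkage gamma: {self.projection.gamma:.2f}   "
            f"Fisher criterion: {self.projection.fisher_criterion:.3f}",
            f"training AUC: {roc.auc:.3f}   training error: "
            f"{self.classifier.training_error:.3f}",
            f"Mann-Whitney U = {gt.U:.1f}, p = {gt.p_two_sided:.2e} [{gt.tier}]",
            "-" * 56,
            f"{'feature':<22}{'min_error':>10}{'w1':>10}{'w2':>10}",
        ]
        score_by_name = {s.name: s for s in self.feature_scores}
        for i, name in enumerate(self.selected_features):
            s = score_by_name[name]
            lines.append(
                f"{name:<22}{s.min_error:>10.3f}"
                f"{self.projection.w1[i]:>10.3f}{self.projection.w2[i]:>10.3f}"
            )
        return "\n".join(lines)

    def cross_validate(self, cfg: CVConfig = CVConfig(), **kw) -> ValidationReport:
        return self.model.cross_validate(cfg, **kw)

    def plot_panels(self, out_dir, report: ValidationReport | None = None) -> dict:
        if report is None:
            report = self.cross_validate()
        return make_report(report, self.projection, self.model.table, out_dir)
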