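"""Diagnosis model facade: selection + random-forest CV behind a
``Model.fit() -> Results`` interface.

``DiagnosisModel`` wraps a feature matrix and class labels;
:meth:`DiagnosisModel.fit` runs shadow-feature selection followed by
stratified 10-fold cross-validation of a random forest, returning a
``DiagnosisResults`` object carrying the confusion matrix, the diagnostic
metrics with exact 95% CIs, the selection report, and per-fold detail, plus
a text ``summary()``.

``run_cohort_pipeline`` is the end-to-end convenience: simulate (or accept)
a cohort, extract features, fit, evaluate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluate import (
    ConfusionMatrix,
    DiagnosticMetrics,
    confusion_metrics,
    cross_validate,
    pca_scores,
)
from .features import FeatureConfig, extract_feature_matrix
from .selection import BorutaParams, BorutaResult, boruta_select, reduce_matrix
from .simulate import CohortConfig, simulate_cohort

__all__ = ["DiagnosisModel", "DiagnosisResults", "run_cohort_pipeline"]


class DiagnosisModel:
    """Binary diagnosis model over a named feature matrix.

    Parameters
    ----------
    X : DataFrame
        Samples x features (e.g. the 150-dimensional descriptor matrix).
    y : sequence
        Class labels, ``"PCa"`` / ``"S"``.

    Examples
    --------
    >>> model = DiagnosisModel.from_dataframe(df, label_col="class_label")
    >>> results = model.fit(seed=1)
    >>> print(results.summary())
    """

    def __init__(self, X: pd.DataFrame, y: Sequence[str]):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have mismatched lengths")
        self.X = X
        self.y = y

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "class_label"
    ) -> "DiagnosisModel":
        """Build from a single table whose non-label columns are features."""
        if label_col not in df.columns:
            raise ValueError(f"missing label column {label_col!r}")
        y = df[label_col].to_numpy()
        X = df.drop(columns=[label_col]).select_dtypes(include=[np.number])
        return cls(X, y)

    def fit(
        self,
        select: bool = True,
        selection_params: BorutaParams | None = None,
        k: int = 10,
        seed: int = 0,
        rf_params: Mapping | None = None,
        tentative_policy: str = "drop",
    ) -> "DiagnosisResults":
        """Select features and cross-validate the random-forest classifier."""
        selection: BorutaResult | None = None
        X_used = self.X
        if select:
            params = selection_params or BorutaParams(seed=seed)
            selection = boruta_select(self.X, self.y, params)
            try:
                X_used = reduce_matrix(self.X, selection, tentative_policy)
            except ValueError:
                X_used = self.X  # empty selection: fall back to full matrix
        cm, folds = cross_validate(X_used, self.y, k=k, seed=seed, rf_params=rf_params)
        return DiagnosisResults(
            model=self,
            selection=selection,
            retained_features=list(X_used.columns),
            confusion_matrix=cm,
            metrics=confusion_metrics(cm),
            fold_records=folds,
            k=k,
            seed=seed,
        )


@dataclass
class DiagnosisResults:
    """Fitted diagnosis results: estimates, uncertainty and diagnostics."""

    model: DiagnosisModel
    selection: BorutaResult | None
    retained_features: list[str]
    confusion_matrix: ConfusionMatrix
    metrics: DiagnosticMetrics
    fold_records: pd.DataFrame
    k: int
    seed: int

    def summary(self) -> str:
        """Plain-text summary table."""
        cm = self.confusion_matrix
        m = self.metrics
        lines = [
            "Urine-headspace eNose diagnosis — cross-validated results",
            "=" * 58,
            f"samples: {cm.total}   folds: {self.k}   seed: {self.seed}",
            f"features: {self.model.X.shape[1]} extracted, "
            f"{len(self.retained_features)} used"
            + (
                f" ({len(self.selection.confirmed)} confirmed by shadow-feature selection)"
                if self.selection is not None
                else " (no selection)"
            ),
            "",
            "Confusion matrix (rows = classification, cols = condition)",
            self.confusion_matrix.to_frame().to_string(),
            "",
        ]
        for name in ("accuracy", "sensitivity", "specificity"):
            est = getattr(m, name)
            lines.append(
                f"{name:>12}: {est}" if est is not None else f"{name:>12}: undefined"
            )
        return "\n".join(lines)

    def score_plot(self, ax=None):
        """PCA score plot of the retained features, coloured by class."""
        import matplotlib.pyplot as plt

        res = pca_scores(self.model.X[self.retained_features])
        if ax is None:
            _, ax = plt.subplots()
        for label, color in (("S", "tab:blue"), ("PCa", "tab:red")):
            mask = self.model.y == label
            ax.scatter(
                res.scores[mask, 0], res.scores[mask, 1], label=label, c=color, s=18
            )
        ax.set_xlabel(f"PC1 ({100 * res.explained_variance_ratio[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * res.explained_variance_ratio[1]:.1f}%)")
        ax.legend()
        return ax

    def to_report(self, out_dir: str | Path) -> Path:
        """Write a JSON+CSV report (metrics, folds, selection, features)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cm = self.confusion_matrix
        payload = {
            "n_samples": cm.total,
            "k": self.k,
            "seed": self.seed,
            "confusion_matrix": {"tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp},
            "metrics": {
                name: (
                    {
                        "point": est.point,
                        "percent": est.percent,
                        "ci95": [est.lower, est.upper],
                    }
                    if est is not None
                    else None
                )
                for name, est in (
                    ("accuracy", self.metrics.accuracy),
                    ("sensitivity", self.metrics.sensitivity),
                    ("specificity", self.metrics.specificity),
                )
            },
            "retained_features": self.retained_features,
        }
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
        self.fold_records.to_csv(out_dir / "folds.csv", index=False)
        if self.selection is not None:
            self.selection.to_frame().to_csv(out_dir / "selection.csv")
        return out_dir / "report.json"


def run_cohort_pipeline(
    config: CohortConfig,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    selection_params: BorutaParams | None = None,
    k: int = 10,
    rf_params: Mapping | None = None,
) -> DiagnosisResults:
    """Simulate a cohort and run the full analysis pipeline on it.

    ``seed`` drives simulation, selection and cross-validation; identical
    seeds give identical reports.
    """
    cfg = replace(config, seed=seed)
    recordings, _ = simulate_cohort(cfg)
    X, meta = extract_feature_matrix(recordings, feature_config)
    model = DiagnosisModel(X, meta["class_label"].to_numpy())
    return model.fit(
        select=True,
        selection_params=selection_params or BorutaParams(seed=seed),
        k=k,
        seed=seed,
        rf_params=rf_params,
    )
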