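"""Random-forest diagnosis evaluation: stratified CV, exact binomial CIs,
PCA scores, repeatability, and protocol-condition comparisons.

The diagnostic question is binary: prostate cancer (``"PCa"``, the positive
class) versus control (``"S"``).  Performance is summarized by the pooled
out-of-fold confusion matrix of a stratified 10-fold cross-validation and by
accuracy, sensitivity and specificity with exact (Clopper-Pearson) 95%
binomial confidence intervals — the convention of clinical diagnostic-test
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "ConfusionMatrix",
    "ProportionEstimate",
    "DiagnosticMetrics",
    "cross_validate",
    "confusion_metrics",
    "clopper_pearson",
    "PCAScores",
    "pca_scores",
    "repeatability_index",
    "compare_conditions",
    "portion_sensitivity",
]

POSITIVE_LABEL = "PCa"
NEGATIVE_LABEL = "S"

DEFAULT_RF_PARAMS: dict = {"n_estimators": 500, "max_features": "sqrt"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 diagnostic confusion matrix, PCa positive.

    Orientation follows the classification-report convention: predictions
    in rows, true condition in columns.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str]
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred have mismatched lengths")
        pos = y_true == POSITIVE_LABEL
        pred_pos = y_pred == POSITIVE_LABEL
        return cls(
            tp=int(np.sum(pos & pred_pos)),
            fn=int(np.sum(pos & ~pred_pos)),
            tn=int(np.sum(~pos & ~pred_pos)),
            fp=int(np.sum(~pos & pred_pos)),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
        )

    def to_frame(self) -> pd.DataFrame:
        """Rows = eNose classification, columns = clinical condition."""
        return pd.DataFrame(
            [[self.tn, self.fn], [self.fp, self.tp]],
            index=pd.Index([NEGATIVE_LABEL, POSITIVE_LABEL], name="classified"),
            columns=pd.Index([NEGATIVE_LABEL, POSITIVE_LABEL], name="condition"),
        )


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its exact 95% confidence interval."""

    successes: int
    trials: int
    point: float
    lower: float
    upper: float

    @property
    def percent(self) -> int:
        """Point estimate rounded to integer percent."""
        return int(round(100.0 * self.point))

    def __str__(self) -> str:
        return (
            f"{100 * self.point:.1f}% "
            f"(95% CI {100 * self.lower:.0f}-{100 * self.upper:.0f}%)"
        )


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05) -> ProportionEstimate:
    """Exact binomial proportion estimate (Clopper-Pearson interval)."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    lower, upper = proportion_confint(successes, trials, alpha=alpha, method="beta")
    return ProportionEstimate(
        successes=successes,
        trials=trials,
        point=successes / trials,
        lower=float(lower),
        upper=float(upper),
    )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy, sensitivity and specificity with exact binomial CIs.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """

    accuracy: ProportionEstimate | None
    sensitivity: ProportionEstimate | None
    specificity: ProportionEstimate | None

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name in ("accuracy", "sensitivity", "specificity"):
            est = getattr(self, name)
            rows[name] = (
                {
                    "point": est.point,
                    "percent": est.percent,
                    "ci_lower": est.lower,
                    "ci_upper": est.upper,
                    "successes": est.successes,
                    "trials": est.trials,
                }
                if est is not None
                else {
                    "point": np.nan,
                    "percent": np.nan,
                    "ci_lower": np.nan,
                    "ci_upper": np.nan,
                    "successes": 0,
                    "trials": 0,
                }
            )
        return pd.DataFrame(rows).T.rename_axis("metric")


def confusion_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Diagnostic metrics of a confusion matrix.

    accuracy = (tp + tn) / total, sensitivity = tp / (tp + fn),
    specificity = tn / (tn + fp); each with a Clopper-Pearson 95% CI.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def safe(successes: int, trials: int) -> ProportionEstimate | None:
        return clopper_pearson(successes, trials) if trials > 0 else None

    return DiagnosticMetrics(
        accuracy=safe(cm.tp + cm.tn, cm.total),
        sensitivity=safe(cm.tp, cm.tp + cm.fn),
        specificity=safe(cm.tn, cm.tn + cm.fp),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[str],
    k: int = 10,
    seed: int = 0,
    rf_params: Mapping | None = None,
) -> tuple[ConfusionMatrix, pd.DataFrame]:
    """Stratified k-fold cross-validation of a random-forest classifier.

    Out-of-fold predictions are pooled into a single confusion matrix (so
    the cell counts sum to the cohort size).  Deterministic under ``seed``.

    Returns
    -------
    (ConfusionMatrix, DataFrame)
        Pooled matrix and per-fold records (fold, n_test, tp, fn, tn, fp).
    """
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes for cross-validation")
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} samples < k={k}; lower k"
        )
    params = dict(DEFAULT_RF_PARAMS)
    if rf_params:
        params.update(rf_params)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    pooled = ConfusionMatrix(0, 0, 0, 0)
    records = []
    for fold, (train, test) in enumerate(skf.split(X, y), start=1):
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {fold}: a class is absent from training; lower k")
        rf = RandomForestClassifier(
            random_state=(seed * 100 + fold) % (2**31), n_jobs=1, **params
        )
        rf.fit(X[train], y[train])
        cm = ConfusionMatrix.from_predictions(y[test], rf.predict(X[test]))
        pooled = pooled + cm
        records.append(
            {
                "fold": fold,
                "n_test": len(test),
                "tp": cm.tp,
                "fn": cm.fn,
                "tn": cm.tn,
                "fp": cm.fp,
            }
        )
    return pooled, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# PCA scores and repeatability
# ---------------------------------------------------------------------------

@dataclass
class PCAScores:
    """PCA projection of a feature matrix."""

    scores: np.ndarray  # samples x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # components x features


def pca_scores(
    X: pd.DataFrame | np.ndarray,
    n_components: int = 2,
    standardize: bool = True,
) -> PCAScores:
    """Principal-component scores of a feature matrix.

    Columns are centred and (by default) scaled to unit sample variance —
    the descriptor families live on very different scales.  The sign of
    each component is fixed so that its largest-magnitude loading is
    positive, making the projection deterministic.
    """
    A = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    n, p = A.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)={min(n, p)}")
    A = A - A.mean(axis=0)
    if standardize:
        sd = A.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant columns carry no variance either way
        A = A / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(A)
    loadings = pca.components_
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0
    return PCAScores(
        scores=scores,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
    )


def repeatability_index(
    scores: np.ndarray, subject_ids: Sequence[str]
) -> float:
    """Within- over between-subject mean distance in leading-2-PC space.

    Values well below 1 mean repeat analyses of the same subject cluster
    together more tightly than analyses of different subjects; ~1 means no
    subject-level clustering.

    Raises
    ------
    ValueError
        If fewer than two subjects have at least two samples each.
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    ids = np.asarray(subject_ids)
    if scores.shape[0] != ids.shape[0]:
        raise ValueError("scores and subject_ids have mismatched lengths")
    uniq, counts = np.unique(ids, return_counts=True)
    if np.sum(counts >= 2) < 2:
        raise ValueError("need >= 2 subjects with >= 2 samples each")
    d = squareform(pdist(scores))
    same = ids[:, None] == ids[None, :]
    iu = np.triu_indices_from(d, k=1)
    within = d[iu][same[iu]]
    between = d[iu][~same[iu]]
    if between.size == 0 or between.mean() == 0:
        raise ValueError("between-subject distances degenerate")
    return float(within.mean() / between.mean())


# ---------------------------------------------------------------------------
# protocol-condition experiments
# ---------------------------------------------------------------------------

def compare_conditions(
    configs: Mapping[str, "CohortConfig"],
    seed: int = 0,
    feature_config=None,
    selection_params=None,
    k: int = 10,
    rf_params: Mapping | None = None,
) -> pd.DataFrame:
    """Run the full pipeline per condition and tabulate diagnostic metrics.

    Each entry of ``configs`` (e.g. one per conditioning temperature) is
    simulated, feature-extracted, shadow-feature-selected and evaluated by
    stratified k-fold CV independently.

    Returns
    -------
    DataFrame indexed by condition name with point estimates and CI bounds
    for accuracy / sensitivity / specificity.
    """
    from .model import run_cohort_pipeline

    rows = {}
    for name, config in configs.items():
        res = run_cohort_pipeline(
            config,
            seed=seed,
            feature_config=feature_config,
            selection_params=selection_params,
            k=k,
            rf_params=rf_params,
        )
        m = res.metrics
        rows[name] = {
            "accuracy": m.accuracy.point,
            "accuracy_lo": m.accuracy.lower,
            "accuracy_hi": m.accuracy.upper,
            "sensitivity": m.sensitivity.point,
            "sensitivity_lo": m.sensitivity.lower,
            "sensitivity_hi": m.sensitivity.upper,
            "specificity": m.specificity.point,
            "specificity_lo": m.specificity.lower,
            "specificity_hi": m.specificity.upper,
            "n_selected": len(res.retained_features),
        }
    return pd.DataFrame(rows).T.rename_axis("condition")


def portion_sensitivity(
    config: "CohortConfig",
    portions: Sequence[str] = ("first", "midstream", "final", "catheter"),
    seed: int = 0,
    feature_config=None,
    selection_params=None,
    rf_params: Mapping | None = None,
) -> pd.DataFrame:
    """Per-portion diagnostic sensitivity against the standard model.

    Mirrors the protocol-investigation design: the diagnosis model is
    trained on a standard cohort (first-portion samples, both classes), and
    urine samples of each portion, collected from a fresh set of PCa
    subjects, are classified against it.  Sensitivity per portion is the
    fraction of those PCa samples classified as PCa, with an exact binomial
    CI.  With far weaker headspace enrichment in the final portion, its
    samples fall into the control range and sensitivity collapses.
    """
    from dataclasses import replace as _replace

    from .features import extract_feature_matrix
    from .selection import BorutaParams, boruta_select, reduce_matrix
    from .simulate import simulate_cohort

    train_cfg = _replace(config, portion="first", seed=seed)
    recs, _ = simulate_cohort(train_cfg)
    X, meta = extract_feature_matrix(recs, feature_config)
    y = meta["class_label"].to_numpy()
    sel_params = selection_params or BorutaParams(seed=seed)
    sel = boruta_select(X, y, sel_params)
    X_sel = reduce_matrix(X, sel, tentative_policy="drop")
    params = dict(DEFAULT_RF_PARAMS)
    if rf_params:
        params.update(rf_params)
    rf = RandomForestClassifier(random_state=seed % (2**31), n_jobs=1, **params)
    rf.fit(X_sel.to_numpy(dtype=float), y)

    rows = {}
    eval_seed = (seed + 104729) % (2**31)  # fresh subjects for every portion
    for portion in portions:
        eval_cfg = _replace(config, portion=portion, seed=eval_seed)
        eval_recs, _ = simulate_cohort(eval_cfg)
        pca_recs = [r for r in eval_recs if r.meta.class_label == POSITIVE_LABEL]
        Xp, _ = extract_feature_matrix(pca_recs, feature_config)
        pred = rf.predict(Xp[X_sel.columns].to_numpy(dtype=float))
        est = clopper_pearson(int(np.sum(pred == POSITIVE_LABEL)), len(pred))
        rows[portion] = {
            "sensitivity": est.point,
            "ci_lower": est.lower,
            "ci_upper": est.upper,
            "n": est.trials,
        }
    return pd.DataFrame(rows).T.rename_axis("portion")
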