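"""Shadow-feature (Boruta-style) all-relevant feature selection.

The selector decides, for every feature, whether it carries more information
about the class label than random chance, by competing it against "shadow"
features — permuted copies of the real ones:

1. append one independently shuffled shadow copy of every candidate feature;
2. fit a random forest and record its importance measure;
3. a feature scores a *hit* when its importance exceeds the maximum shadow
   importance of that iteration;
4. after each iteration, one-sided binomial tests compare each undecided
   feature's hit count with Binomial(n_iter, 1/2), Bonferroni-corrected
   across the currently undecided features: significantly many hits confirm
   the feature, significantly few reject it;
5. rejected features (and their shadows) are dropped; iteration stops when
   nothing is tentative or ``max_iter`` is reached.

The procedure is deterministic under its seed.  Shadow permutations are
seeded per feature name, so decisions do not depend on column order beyond
the forest's own tie-breaking.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

__all__ = ["BorutaParams", "BorutaResult", "boruta_select", "reduce_matrix"]

Decision = Literal["confirmed", "tentative", "rejected"]


@dataclass
class BorutaParams:
    """Tunable parameters of the shadow-feature selector.

    ``p_threshold`` is the per-test significance level (applied after
    Bonferroni correction across undecided features).  ``importance``
    selects the forest importance measure:

    ``"mdi_z"`` (default)
        Z-score of the per-tree mean-decrease-in-impurity (mean over trees
        divided by its sd).  Standardizing by the tree-to-tree spread is
        what keeps features that are only *sporadically* useful — e.g.
        chance correlations in a fixed finite sample — from persistently
        out-ranking the freshly permuted shadows.
    ``"mdi"``
        Raw mean-decrease-in-impurity.
    ``"permutation"``
        Scikit-learn permutation importance (slow; small matrices only).
    """

    max_iter: int = 100
    p_threshold: float = 0.01
    n_estimators: int = 100
    importance: Literal["mdi_z", "mdi", "permutation"] = "mdi_z"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.importance not in ("mdi_z", "mdi", "permutation"):
            raise ValueError("importance must be 'mdi_z', 'mdi' or 'permutation'")


@dataclass
class BorutaResult:
    """Outcome of a shadow-feature selection run."""

    decisions: pd.Series  # feature -> {confirmed, tentative, rejected}
    hit_counts: pd.Series  # feature -> hits over the iterations it was alive
    n_iterations: int
    importance_history: pd.DataFrame  # iterations x features (NaN once dropped)
    params: BorutaParams

    @property
    def confirmed(self) -> list[str]:
        return list(self.decisions.index[self.decisions == "confirmed"])

    @property
    def tentative(self) -> list[str]:
        return list(self.decisions.index[self.decisions == "tentative"])

    @property
    def rejected(self) -> list[str]:
        return list(self.decisions.index[self.decisions == "rejected"])

    def to_frame(self) -> pd.DataFrame:
        """Selection report: decision, hit count and median importance."""
        return pd.DataFrame(
            {
                "decision": self.decisions,
                "hit_count": self.hit_counts,
                "median_importance": self.importance_history.median(axis=0),
            }
        ).rename_axis("feature")


def _shadow_rng(seed: int, iteration: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        [int(seed) % (2**31), iteration, zlib.crc32(name.encode())]
    )


def _importances(
    X: np.ndarray,
    y: np.ndarray,
    params: BorutaParams,
    iteration: int,
) -> np.ndarray:
    rf = RandomForestClassifier(
        n_estimators=params.n_estimators,
        max_features="sqrt",
        random_state=(params.seed * 1000 + iteration) % (2**31),
        n_jobs=1,
    )
    rf.fit(X, y)
    if params.importance == "mdi":
        return rf.feature_importances_
    if params.importance == "mdi_z":
        per_tree = np.array([t.feature_importances_ for t in rf.estimators_])
        mean = per_tree.mean(axis=0)
        sd = per_tree.std(axis=0, ddof=1)
        z = np.zeros_like(mean)
        used = sd > 0
        z[used] = mean[used] / sd[used]
        return z
    res = permutation_importance(
        rf,
        X,
        y,
        n_repeats=5,
        random_state=(params.seed * 1000 + iteration) % (2**31),
        n_jobs=1,
    )
    return res.importances_mean


def boruta_select(
    X: pd.DataFrame,
    y: Sequence[str],
    params: BorutaParams | None = None,
) -> BorutaResult:
    """Run shadow-feature selection on a feature matrix.

    Parameters
    ----------
    X : DataFrame
        Samples x features; all values finite.  Constant features are
        allowed (they cannot out-rank shadows and self-reject).
    y : sequence
        Class labels; at least two classes and ten samples.
    params : BorutaParams, optional

    Returns
    -------
    BorutaResult
    """
    params = params or BorutaParams()
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have mismatched lengths")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    values = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("X contains non-finite values")

    features = list(X.columns)
    n_feat = len(features)
    decisions = pd.Series("tentative", index=features, dtype=object)
    hits = pd.Series(0, index=features, dtype=int)
    alive_iters = pd.Series(0, index=features, dtype=int)
    history = np.full((params.max_iter, n_feat), np.nan)

    col_of = {f: i for i, f in enumerate(features)}
    n_done = 0
    for it in range(1, params.max_iter + 1):
        undecided = decisions.index[decisions == "tentative"].tolist()
        active = decisions.index[decisions != "rejected"].tolist()
        if not undecided:
            break
        n_done = it
        X_act = values[:, [col_of[f] for f in active]]
        shadows = np.empty_like(X_act)
        for j, f in enumerate(active):
            rng = _shadow_rng(params.seed, it, f)
            shadows[:, j] = rng.permutation(X_act[:, j])
        # keep the shadow pool at its initial size: with only a handful of
        # shadows left, the max-shadow bar would weaken and borderline
        # features would start beating it by attrition rather than merit
        n_pad = n_feat - len(active)
        if n_pad > 0:
            pick = _shadow_rng(params.seed, it, "__pad__").choice(
                len(active), size=n_pad, replace=True
            )
            pads = np.empty((values.shape[0], n_pad))
            for i, j in enumerate(pick):
                rng = _shadow_rng(params.seed, it, f"__pad{i}__")
                pads[:, i] = rng.permutation(X_act[:, j])
            shadows = np.hstack([shadows, pads])
        imp = _importances(np.hstack([X_act, shadows]), y, params, it)
        real_imp = imp[: len(active)]
        shadow_max = imp[len(active):].max()
        for j, f in enumerate(active):
            history[it - 1, col_of[f]] = real_imp[j]
        for j, f in enumerate(active):
            if real_imp[j] > shadow_max:
                hits[f] += 1
            alive_iters[f] += 1

        # binomial decision step, Bonferroni across currently undecided
        n_tests = len(undecided)
        for f in undecided:
            k, n = int(hits[f]), int(alive_iters[f])
            p_upper = stats.binom.sf(k - 1, n, 0.5)
            p_lower = stats.binom.cdf(k, n, 0.5)
            if p_upper * n_tests < params.p_threshold:
                decisions[f] = "confirmed"
            elif p_lower * n_tests < params.p_threshold:
                decisions[f] = "rejected"

    return BorutaResult(
        decisions=decisions,
        hit_counts=hits,
        n_iterations=n_done,
        importance_history=pd.DataFrame(
            history[:n_done], columns=features, index=range(1, n_done + 1)
        ),
        params=params,
    )


def reduce_matrix(
    X: pd.DataFrame,
    result: BorutaResult,
    tentative_policy: Literal["drop", "keep"] = "drop",
) -> pd.DataFrame:
    """Project a feature matrix onto the selected features.

    Confirmed features are always retained; tentative ones only under
    ``tentative_policy="keep"``.  Column order is preserved.
    """
    if list(result.decisions.index) != list(X.columns):
        raise ValueError("selection result does not match the matrix columns")
    keep_labels = {"confirmed"}
    if tentative_policy == "keep":
        keep_labels.add("tentative")
    elif tentative_policy != "drop":
        raise ValueError("tentative_policy must be 'drop' or 'keep'")
    cols = [c for c in X.columns if result.decisions[c] in keep_labels]
    if not cols:
        raise ValueError(
            "no features selected; consider tentative_policy='keep' or "
            "classifying on the full matrix"
        )
    return X[cols]
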