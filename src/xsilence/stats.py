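"""Statistics for silencing-efficiency analysis.

Houses the random-forest silencing-efficiency predictor (a Model/Results
pair: build :class:`SilencingEfficiencyModel` from a feature matrix and
High/Low labels, ``fit()`` returns :class:`SilencingEfficiencyResults`
with out-of-fold AUC, normalised feature importances and a ``summary()``
table), plus the supporting tests: Wilcoxon rank-sum with the exact /
normal-approximation branch rule, the size-matched 180-permutation group
comparison, hypergeometric set overlap, one-way ANOVA and replicate PCA.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

DEFAULT_N_TREES = 50
DEFAULT_N_FOLDS = 5
DEFAULT_N_PERM = 180
DEFAULT_SUBSAMPLE = 45


# ---------------------------------------------------------------------------
# labels, AUC and the random-forest predictor


def median_split_labels(z) -> np.ndarray:
    """Label genes 'High' (z below the median, i.e. more silenced) or 'Low'.

    Genes exactly at the median go to 'Low', so an all-equal vector is all
    'Low'.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 genes for a median split")
    if np.isnan(z).any():
        raise ValueError("silencing scores contain NaN; drop uninformative genes first")
    med = np.median(z)
    return np.where(z < med, "High", "Low")


def auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    The probability that a random positive outscores a random negative,
    with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool) if np.asarray(labels).dtype != bool else np.asarray(labels)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


class SilencingEfficiencyModel:
    """Random-forest classifier of High vs Low gene-silencing efficiency.

    Parameters
    ----------
    features : DataFrame
        Per-gene feature matrix (all features expected in [0, 1]).
    labels : array-like
        Binary labels; 'High'/'Low' strings or 1/0.
    n_trees, n_folds : int
        Forest size and stratified cross-validation folds.
    """

    def __init__(self, features: pd.DataFrame, labels, n_trees: int = DEFAULT_N_TREES,
                 n_folds: int = DEFAULT_N_FOLDS):
        self.features = pd.DataFrame(features)
        y = np.asarray(labels)
        if y.dtype.kind in "UOS":
            y = (y == "High").astype(int)
        self.labels = np.asarray(y, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present to train")
        if len(self.labels) < 2 * n_folds:
            raise ValueError(f"need at least {2 * n_folds} genes for {n_folds}-fold CV")
        self.n_trees = n_trees
        self.n_folds = n_folds

    @classmethod
    def from_silencing(cls, features: pd.DataFrame, z, **kwargs) -> "SilencingEfficiencyModel":
        """Build the model from silencing scores via the median split."""
        return cls(features, median_split_labels(z), **kwargs)

    def fit(self, seed: int = 0, importance: str = "impurity") -> "SilencingEfficiencyResults":
        """Cross-validated fit; AUC from pooled out-of-fold probabilities.

        ``importance`` is 'impurity' (mean decrease in impurity of a forest
        trained on all genes, normalised to sum 1) or 'permutation'
        (out-of-bag permutation importance, clipped at 0 and normalised).
        """
        X = self.features.to_numpy(dtype=float)
        y = self.labels
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=seed)
        oof = np.full(len(y), np.nan)
        fold_of = np.full(len(y), -1)
        for k, (train, test) in enumerate(skf.split(X, y)):
            forest = RandomForestClassifier(
                n_estimators=self.n_trees, random_state=seed + k, n_jobs=1
            ).fit(X[train], y[train])
            oof[test] = forest.predict_proba(X[test])[:, 1]
            fold_of[test] = k
        full = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=seed, n_jobs=1
        ).fit(X, y)
        if importance == "impurity":
            imp = full.feature_importances_
        elif importance == "permutation":
            r = permutation_importance(full, X, y, n_repeats=10, random_state=seed, n_jobs=1)
            imp = np.clip(r.importances_mean, 0, None)
        else:
            raise ValueError(f"unknown importance kind: {importance!r}")
        total = imp.sum()
        imp = imp / total if total > 0 else np.full_like(imp, 1 / len(imp))
        return SilencingEfficiencyResults(
            auc=auc(oof, y.astype(bool)),
            importance=pd.Series(imp, index=self.features.columns, name="importance"),
            n_trees=self.n_trees,
            n_folds=self.n_folds,
            seed=seed,
            fold_assignment=pd.Series(fold_of, index=self.features.index, name="fold"),
            oof_probability=pd.Series(oof, index=self.features.index, name="p_high"),
            model=self,
        )


@dataclass
class SilencingEfficiencyResults:
    """Cross-validated classifier report: AUC, importances, fold assignments."""

    auc: float
    importance: pd.Series
    n_trees: int
    n_folds: int
    seed: int
    fold_assignment: pd.Series = field(repr=False)
    oof_probability: pd.Series = field(repr=False)
    model: SilencingEfficiencyModel | None = field(default=None, repr=False)

    def top_features(self, k: int = 4) -> list[str]:
        return list(self.importance.sort_values(ascending=False).index[:k])

    def summary(self) -> str:
        lines = [
            "Silencing-efficiency random forest",
            "==================================",
            f"trees: {self.n_trees}   folds: {self.n_folds}   seed: {self.seed}",
            f"out-of-fold AUC: {self.auc:.3f}",
            "",
            "feature importance (sums to 1):",
        ]
        for name, value in self.importance.sort_values(ascending=False).items():
            lines.append(f"  {name:<18s} {value:.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        out = self.importance.rename("importance").to_frame()
        out["rank"] = out["importance"].rank(ascending=False, method="first").astype(int)
        return out.sort_values("rank")


def train_rf(features: pd.DataFrame, labels, n_trees: int = DEFAULT_N_TREES,
             n_folds: int = DEFAULT_N_FOLDS, seed: int = 0,
             importance: str = "impurity") -> SilencingEfficiencyResults:
    """Functional wrapper: build and fit the silencing-efficiency classifier."""
    return SilencingEfficiencyModel(features, labels, n_trees=n_trees, n_folds=n_folds).fit(
        seed=seed, importance=importance
    )


# ---------------------------------------------------------------------------
# rank-based tests

_ALTERNATIVES = {"less": "less", "greater": "greater", "two_sided": "two-sided"}


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration when the combined sample has at most 20 values
    and no ties; otherwise the normal approximation with tie and
    continuity corrections. Alternatives refer to x versus y.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[alternative], method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


@dataclass
class PermutationReport:
    """Size-matched permutation comparison of two gene classes.

    ``neglog10_p`` holds the per-permutation one-sided rank-sum
    significance (-log10 p) of a subsample of the large class against the
    reference scores; ``small_neglog10_p`` is the same statistic for the
    small class at its native size.
    """

    n_perm: int
    subsample_size: int
    neglog10_p: np.ndarray = field(repr=False)
    small_neglog10_p: float
    seed: int

    @property
    def mean(self) -> float:
        return float(self.neglog10_p.mean())

    @property
    def sd(self) -> float:
        # shift by the first value: mathematically a no-op, but keeps the
        # degenerate all-equal case at exactly zero
        centred = self.neglog10_p - self.neglog10_p[0]
        return float(centred.std(ddof=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"permutation": np.arange(1, self.n_perm + 1),
                             "neglog10_p": self.neglog10_p})


def matched_permutation_test(
    scores_large,
    scores_small,
    reference_scores,
    n_perm: int = DEFAULT_N_PERM,
    subsample_size: int | None = None,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationReport:
    """Compare gene classes of unequal size by repeated subsampling.

    Each permutation draws ``subsample_size`` scores (default: the small
    class size) without replacement from the large class and runs the
    one-sided rank-sum test against ``reference_scores`` (deficiency
    hypothesis: subsample scores are greater); the spread (sd) of the
    -log10 p values across permutations is the significance range.
    """
    large = np.asarray(scores_large, dtype=float)
    small = np.asarray(scores_small, dtype=float)
    ref = np.asarray(reference_scores, dtype=float)
    if subsample_size is None:
        subsample_size = small.size
    if subsample_size > large.size:
        raise ValueError(
            f"subsample_size {subsample_size} exceeds large-group size {large.size}"
        )
    rng = np.random.default_rng(seed)
    neglog = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(large, size=subsample_size, replace=False)
        p = wilcoxon_rank_sum(draw, ref, alternative=alternative)
        neglog[i] = -np.log10(max(p, np.finfo(float).tiny))
    p_small = wilcoxon_rank_sum(small, ref, alternative=alternative)
    return PermutationReport(
        n_perm=n_perm,
        subsample_size=int(subsample_size),
        neglog10_p=neglog,
        small_neglog10_p=-float(np.log10(max(p_small, np.finfo(float).tiny))),
        seed=seed,
    )


def hypergeometric_overlap(universe_n: int, set_a_n: int, set_b_n: int, overlap_n: int) -> float:
    """Upper-tail hypergeometric overlap p: P[X >= overlap_n]."""
    if not (0 <= set_a_n <= universe_n and 0 <= set_b_n <= universe_n):
        raise ValueError("set sizes must lie within the universe")
    if not 0 <= overlap_n <= min(set_a_n, set_b_n):
        raise ValueError("overlap must be within both sets")
    return float(sps.hypergeom.sf(overlap_n - 1, universe_n, set_a_n, set_b_n))


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance in every group; F undefined")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# replicate PCA


def replicate_pca(matrix: pd.DataFrame, n_components: int | None = None) -> pd.DataFrame:
    """Principal-component scores of a replicate x gene silencing matrix.

    Columns are centred; component signs are fixed by making each
    component's largest-magnitude loading positive, so scores are
    reproducible. Requested components beyond the matrix rank are
    truncated.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s.max(initial=0) * 1e-12).sum())
    k = rank if n_components is None else min(n_components, rank)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] *= -1
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    return pd.DataFrame(scores, index=index, columns=[f"PC{j + 1}" for j in range(k)])
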