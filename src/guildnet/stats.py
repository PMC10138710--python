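"""Statistical battery used throughout the pipeline.

Covers the non-parametric tests (Wilcoxon signed-rank, Mann-Whitney U,
Kruskal-Wallis, Fisher's exact), Benjamini-Hochberg FDR, Spearman
association with small-sample exact p-values, community-ecology distances
(Bray-Curtis, Jensen-Shannon), PERMANOVA, principal coordinates analysis
and Huber robust regression.

Scalar tests delegate to scipy/statsmodels; PERMANOVA, PCoA and BH-FDR are
implemented here because the pipeline needs seeded vectorised permutations
and explicit control of the partitioning, binning and step-up conventions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "PcoaResult",
    "bray_curtis",
    "jensen_shannon",
    "permanova",
    "pcoa",
    "fisher_exact",
    "bh_fdr",
    "rank_tests",
    "kruskal_wallis",
    "robust_linreg",
    "spearman",
]


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample-by-sample distance matrix.

    Bray-Curtis is a semimetric, so the triangle inequality is not assumed.
    Undefined pairs (e.g. two all-zero abundance profiles) are stored as NaN.
    """

    ids: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.nanmin(self.values) < -1e-12:
            raise ValueError("negative distances")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x-y| / sum(x+y).

    Rows are samples.  A pair of all-zero samples has no defined
    dissimilarity and is reported as NaN.
    """
    x = np.asarray(table, dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.index, d)


def jensen_shannon(table: pd.DataFrame) -> DistanceMatrix:
    """Jensen-Shannon distance between per-sample abundance profiles.

    Rows are renormalised to probability vectors; the returned value is the
    square root of the Jensen-Shannon divergence (a metric), the convention
    used in microbiome enterotyping.
    """
    x = np.asarray(table, dtype=float)
    if (x < 0).any():
        raise ValueError("Jensen-Shannon requires non-negative abundances")
    rowsum = x.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("all-zero sample profile")
    p = x / rowsum
    n = p.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sps.entropy(
                np.stack([p[i], p[j]]).mean(axis=0)
            ) - 0.5 * (sps.entropy(p[i]) + sps.entropy(p[j]))
    d = np.sqrt(np.clip(d, 0.0, None))
    return DistanceMatrix(table.index, d)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("R^2 outside [0, 1]")


def _ss_partition(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Anderson's sums-of-squares partition from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA (permutational multivariate ANOVA).

    Pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)); the p-value counts
    label permutations with F at least as large as observed, with the +1
    correction, so p >= 1/(n_perm+1).
    """
    labels = np.asarray(labels)
    if len(labels) != d.n:
        raise ValueError("labels do not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValueError("each group needs at least two samples")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains undefined (NaN) pairs")
    n, g = d.n, len(uniq)
    d2 = d.values**2

    # Vectorised F over permutations: encode each permuted labelling as
    # boolean group masks and contract against d^2.
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, n), dtype=np.intp)
    perms[0] = np.arange(n)
    for i in range(1, n_perm + 1):
        perms[i] = rng.permutation(n)
    codes = np.searchsorted(uniq, labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = np.zeros(n_perm + 1)
    for gi in range(g):
        mask = (codes[perms] == gi).astype(float)  # (n_perm+1, n)
        # within-group sum over ordered pairs = mask @ d2 @ mask^T diagonal
        within = np.einsum("pi,ij,pj->p", mask, d2, mask) / 2.0
        ss_within += within / counts[gi]
    ss_between = ss_total - ss_within
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    p = (1 + np.sum(f[1:] >= f[0])) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f[0]),
        r2=float(ss_between[0] / ss_total),
        p=float(p),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical principal coordinates analysis (Gower double centering).

    Negative eigenvalues (possible for semimetric input such as
    Bray-Curtis) are reported but excluded from the coordinates.
    """
    n = d.n
    if n_axes is not None and n_axes > n - 1:
        raise ValueError("n_axes must be at most n_samples - 1")
    a = -0.5 * d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10 * abs(evals[0]), 1e-12) if evals[0] > 0 else evals > 0
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    total = evals[evals > 0].sum()
    prop = np.where(evals > 0, evals / total, 0.0) if total > 0 else np.zeros_like(evals)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=d.ids, columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# classical tests


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 count table.

    Two-sidedness by the probability-mass method: sum hypergeometric
    probabilities of all tables no more probable than the observed one
    (the `fisher.test` convention).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if (t < 0).any():
        raise ValueError("counts must be non-negative integers")
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1, returned in the
    original input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def rank_tests(x, y=None, paired: bool = False) -> tuple[float, float]:
    """Two-sided rank tests from the study's battery.

    Unpaired: Mann-Whitney U with tie-corrected normal approximation, exact
    when both groups have at most 8 observations and no ties.  Paired:
    Wilcoxon signed-rank with zero differences dropped.
    """
    x = np.asarray(x, dtype=float)
    if paired:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        diffs = x - y
        if np.all(diffs == 0):
            raise ValueError("all paired differences are zero")
        res = sps.wilcoxon(x, y, zero_method="wilcox", correction=False,
                           alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (g-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class RobustFit:
    params: np.ndarray
    bse: np.ndarray
    n_iter: int


def robust_linreg(X, y, max_iter: int = 100, tol: float = 1e-8) -> RobustFit:
    """Huber M-estimation (c = 1.345) by iteratively reweighted least squares."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345))
    res = model.fit(maxiter=max_iter, tol=tol)
    return RobustFit(params=np.asarray(res.params), bse=np.asarray(res.bse),
                     n_iter=int(getattr(res, "fit_history", {"iteration": max_iter})
                                .get("iteration", max_iter)
                                if hasattr(res, "fit_history") else max_iter))


# ---------------------------------------------------------------------------
# Spearman association


def _spearman_exact_p(rho_obs: float, n: int) -> float:
    """Exact two-sided p for Spearman's rho by permutation enumeration.

    Feasible for n <= 9 (9! = 362 880 permutations); assumes the observed
    statistic was computed as Pearson on mid-ranks, which is reproduced for
    every permutation so ties are handled consistently.
    """
    base = np.arange(n, dtype=float)
    base = (base - base.mean()) / base.std()
    perms = np.array(list(itertools.permutations(range(n))))
    rs = (base[perms] @ base) / n
    return float(np.mean(np.abs(rs) >= abs(rho_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Mid-ranks for ties.  p from the t approximation, or exact enumeration
    of rank permutations when n <= ``exact_max_n`` and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n < 3:
        raise ValueError("need at least three paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input to Spearman correlation")
    rho = float(sps.spearmanr(x, y)[0])
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_max_n and not ties:
        return rho, _spearman_exact_p(rho, n)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(p)
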