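"""Expression and trait statistics.

Quantile normalization, two-group differential expression with
Benjamini-Hochberg correction and a fold-change filter, broad-sense
heritability from parental replicates, fermentation-kinetics trait
extraction from cumulative CO2 curves, trait-expression correlation, and
hierarchical clustering with a permutation-derived correlation cutoff.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def quantile_normalize(matrix):
    """Quantile-normalize an expression matrix across samples.

    After normalization every sample column carries the identical sorted
    value vector (the mean of the per-rank values across samples) while the
    within-sample ranking is preserved.  Missing values are not handled
    here; impute before calling.
    """
    X = np.asarray(matrix.values, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(X.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows + np.zeros_like(order[:1]), axis=0)
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    return dataclasses.replace(matrix, values=out)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    matrix,
    groupA: list[str],
    groupB: list[str],
    alpha: float = 0.01,
    fc_threshold: float = 0.7,
    method: str = "welch",
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-gene two-sample t test on log2 values with BH correction.

    ``logFC`` is mean(A) - mean(B).  A gene passes the filter when its
    BH-adjusted p-value is below ``alpha`` and |logFC| exceeds
    ``fc_threshold``.  ``method='welch'`` uses Welch's unequal-variance t;
    ``method='moderated'`` shrinks per-gene variances toward the genome-wide
    mean with ``prior_df`` pseudo-degrees of freedom before a pooled t test,
    stabilizing small-sample estimates.
    """
    if set(groupA) & set(groupB):
        raise ValueError("groups overlap")
    if len(groupA) < 2 or len(groupB) < 2:
        raise ValueError("each group needs at least two samples")
    A = matrix.values[:, matrix.sample_index(list(groupA))]
    B = matrix.values[:, matrix.sample_index(list(groupB))]
    logfc = A.mean(axis=1) - B.mean(axis=1)

    if method == "welch":
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    elif method == "moderated":
        na, nb = A.shape[1], B.shape[1]
        df = na + nb - 2
        sp2 = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / df
        s0 = float(np.mean(sp2))
        s2 = (prior_df * s0 + df * sp2) / (prior_df + df)
        se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / se
        p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.where(np.isnan(p), 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "p": p,
            "adjPv": adj,
            "passes_filter": (adj < alpha) & (np.abs(logfc) > fc_threshold),
        },
        index=list(matrix.gene_ids),
    )
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


def heritability(
    segregant_values: np.ndarray,
    parent1_reps: np.ndarray,
    parent2_reps: np.ndarray,
) -> float:
    """Broad-sense heritability in percent.

    H2 = 100 * (Var_seg - Var_env) / Var_seg, where Var_seg is the sample
    variance across segregant values and Var_env is the replicate variance
    pooled over the two parents.  A negative estimate (environmental
    variance exceeding the segregant variance) is returned as-is with a
    warning; it is a flag for an unreliable trait, not a quantity to clip.
    """
    seg = np.asarray(segregant_values, dtype=float)
    p1 = np.asarray(parent1_reps, dtype=float)
    p2 = np.asarray(parent2_reps, dtype=float)
    if len(seg) < 2:
        raise ValueError("need at least two segregant values")
    if len(p1) < 2 or len(p2) < 2:
        raise ValueError("need at least two replicates per parent")
    var_seg = float(np.var(seg, ddof=1))
    if var_seg == 0:
        raise ValueError("segregant variance is zero; heritability undefined")
    v1, v2 = np.var(p1, ddof=1), np.var(p2, ddof=1)
    var_env = float(((len(p1) - 1) * v1 + (len(p2) - 1) * v2) / (len(p1) + len(p2) - 2))
    h2 = 100.0 * (var_seg - var_env) / var_seg
    if h2 < 0:
        warnings.warn(f"negative heritability estimate ({h2:.1f}%)", stacklevel=2)
    return h2


# ---------------------------------------------------------------------------
# fermentation kinetics
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class KineticTraits:
    """Summary kinetics of one fermentation (CO2-release) curve."""

    lag_time: float  # h
    Rmax: float  # g CO2 / l / h, maximum release rate
    R70: float  # rate at 70% of total CO2 release
    total_CO2: float  # g / l

    def __post_init__(self):
        if self.lag_time < 0:
            raise ValueError("lag time cannot be negative")
        if not 0 <= self.R70 <= self.Rmax + 1e-9:
            raise ValueError("R70 must lie between 0 and Rmax")


def extract_kinetics(
    time_h: np.ndarray,
    co2_g_per_l: np.ndarray,
    window: int = 11,
    degree: int = 3,
    lag_fraction: float = 0.05,
) -> KineticTraits:
    """Extract kinetic traits from a cumulative CO2-release curve.

    The curve is resampled to a uniform time grid and smoothed with a local
    polynomial (Savitzky-Golay, ``window`` points of ``degree``); the
    smoothed derivative gives Rmax (its maximum) and R70 (its value at the
    first time cumulative CO2 reaches 70% of the total release).  The lag
    time is the first time the rate exceeds ``lag_fraction`` of Rmax.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(co2_g_per_l, dtype=float)
    if len(t) < 20:
        raise ValueError("need at least 20 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    if window % 2 == 0:
        window += 1
    # uniform grid at the original median sampling density
    dt = float(np.median(np.diff(t)))
    grid = np.arange(t[0], t[-1] + dt / 2, dt)
    yg = np.interp(grid, t, y)
    smooth = signal.savgol_filter(yg, window, degree)
    rate = signal.savgol_filter(yg, window, degree, deriv=1, delta=dt)
    rate = np.maximum(rate, 0.0)

    total = float(smooth[-1])
    rmax = float(rate.max())
    target = 0.70 * total
    reached = np.flatnonzero(smooth >= target)
    if len(reached) == 0:
        raise ValueError("curve never reaches 70% of its final value")
    i = reached[0]
    if i == 0:
        t70 = float(grid[0])
    else:
        f = (target - smooth[i - 1]) / (smooth[i] - smooth[i - 1])
        t70 = float(grid[i - 1] + f * dt)
    r70 = float(np.interp(t70, grid, rate))
    r70 = min(r70, rmax)

    above = np.flatnonzero(rate > lag_fraction * rmax)
    lag = float(grid[above[0]] - grid[0]) if len(above) else float(grid[-1] - grid[0])
    return KineticTraits(lag_time=lag, Rmax=rmax, R70=r70, total_CO2=total)


# ---------------------------------------------------------------------------
# trait-expression correlation
# ---------------------------------------------------------------------------


def correlate_with_trait(matrix, trait_values: np.ndarray) -> pd.DataFrame:
    """Per-gene Pearson correlation with a trait, with BH-adjusted p-values.

    p-values come from the t transform of r on n-2 degrees of freedom.
    Genes with zero variance (or a zero-variance trait) get missing r/p.
    """
    y = np.asarray(trait_values, dtype=float)
    X = np.asarray(matrix.values, dtype=float)
    n = X.shape[1]
    if len(y) != n:
        raise ValueError("trait length must match sample count")
    if n < 4:
        raise ValueError("need at least four samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xn = np.sqrt((Xc**2).sum(axis=1))
    yn = float(np.sqrt((yc**2).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (xn * yn)
    r = np.where((xn == 0) | (yn == 0), np.nan, np.clip(r, -1.0, 1.0))
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r**2))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, 2.0 * stats.t.sf(np.abs(tstat), df))
    valid = ~np.isnan(r)
    adj = np.full_like(p, np.nan)
    if valid.any():
        adj[valid] = multipletests(p[valid], method="fdr_bh")[1]
    out = pd.DataFrame({"r": r, "p": np.where(valid, p, np.nan), "adjPv": adj},
                       index=list(matrix.gene_ids))
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# clustering with a permutation-calibrated correlation cutoff
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ClusterSet:
    """Gene clusters in which all pairwise correlations exceed ``threshold_r``."""

    clusters: list[set[str]]
    threshold_r: float
    n_permutations: int


def _complete_linkage_clusters(X: np.ndarray, threshold_r: float) -> list[np.ndarray]:
    """Clusters of size >= 2 from complete-linkage clustering at centered
    Pearson distance 1 - r, cut so every within-cluster pairwise r exceeds
    ``threshold_r``."""
    n = X.shape[0]
    if n < 2:
        return []
    R = np.corrcoef(X)
    D = np.clip(1.0 - R, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    labels = hierarchy.fcluster(Z, t=1.0 - threshold_r, criterion="distance")
    out = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) >= 2:
            out.append(members)
    return out


def cluster_genes(
    matrix,
    n_permutations: int = 10,
    max_chance_clusters: float = 3.0,
    candidate_thresholds: np.ndarray | None = None,
    seed: int = 0,
) -> ClusterSet:
    """Hierarchical clustering with a permutation-derived correlation cutoff.

    Genes are clustered by complete linkage on centered-Pearson distance.
    The cutoff is calibrated under a per-gene permutation null: each gene's
    values are shuffled independently across samples ``n_permutations``
    times, and the smallest candidate r for which the mean number of chance
    clusters of size >= 2 falls below ``max_chance_clusters`` is chosen.
    Only clusters respecting the all-pairwise rule at that cutoff are
    reported.
    """
    X = np.asarray(matrix.values, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 genes")
    if X.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    if candidate_thresholds is None:
        candidate_thresholds = np.arange(0.50, 0.995, 0.01)
    rng = np.random.default_rng(seed)

    null_counts = np.zeros(len(candidate_thresholds))
    for _ in range(n_permutations):
        perm = np.array([rng.permutation(row) for row in X])
        R = np.corrcoef(perm)
        D = np.clip(1.0 - R, 0.0, 2.0)
        np.fill_diagonal(D, 0.0)
        Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
        for k, thr in enumerate(candidate_thresholds):
            labels = hierarchy.fcluster(Z, t=1.0 - thr, criterion="distance")
            _, sizes = np.unique(labels, return_counts=True)
            null_counts[k] += int((sizes >= 2).sum())
    null_counts /= n_permutations

    ok = np.flatnonzero(null_counts < max_chance_clusters)
    threshold_r = float(candidate_thresholds[ok[0]]) if len(ok) else float(
        candidate_thresholds[-1]
    )

    ids = np.asarray(matrix.gene_ids)
    clusters = [set(ids[m]) for m in _complete_linkage_clusters(X, threshold_r)]
    return ClusterSet(clusters=clusters, threshold_r=threshold_r, n_permutations=n_permutations)
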