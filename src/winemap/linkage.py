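"""Single-locus genome scans by Haley-Knott regression on haploid segregants.

The scan grid holds every genotyped marker plus pseudo-markers every
``step_cM``; genotype probabilities at each grid locus are conditioned on
the nearest informative flanking markers under the Haldane map function.
LOD scores are the log10 likelihood ratio of the single-locus regression
against the null mean model, LOD = (n/2) log10(RSS0/RSS1), computed via the
squared trait-probability correlation.  Significance uses permutations:
genome-wide maximum-LOD quantiles for single traits, and an average null
linked-transcript count for transcriptome-wide FDR.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import genome
from .simulate import MISSING, P1, GenotypeMatrix

# LOD cap: RSS1 is floored at 1e-12 * RSS0 (perfect fits happen in small
# haploid panels), i.e. LOD <= 6 n.
_R2_CEIL = 1.0 - 1e-12


@dataclasses.dataclass
class GenotypeProbabilities:
    """P(wine-parent allele) per grid locus and segregant."""

    grid: pd.DataFrame  # columns: chrom, pos_kbp, pos_cM, is_marker
    probs: np.ndarray  # (n_loci, n_segregants)
    segregant_ids: list[str]

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.grid), len(self.segregant_ids)):
            raise ValueError("probability matrix shape inconsistent with grid/ids")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.grid)

    def subset_segregants(self, ids: list[str]) -> "GenotypeProbabilities":
        cols = [self.segregant_ids.index(s) for s in ids]
        return GenotypeProbabilities(self.grid, self.probs[:, cols], list(ids))


@dataclasses.dataclass
class LODProfile:
    """LOD score per grid locus for one trait or transcript."""

    trait: str
    grid: pd.DataFrame
    lod: np.ndarray

    def __post_init__(self):
        self.lod = np.asarray(self.lod, dtype=float)
        if len(self.lod) != len(self.grid):
            raise ValueError("LOD vector length must match grid")

    def max_lod(self) -> float:
        return float(self.lod.max()) if len(self.lod) else 0.0


@dataclasses.dataclass
class LinkageRecord:
    """One called QTL/eQTL: peak locus, LOD, and 1-LOD support interval."""

    trait: str
    peak_chrom: int
    peak_kbp: float
    lod: float
    ci_lo_kbp: float
    ci_hi_kbp: float
    gene_chrom: int | None = None
    gene_kbp: float | None = None
    local_flag: str | None = None
    venn_group: str | None = None
    analysis: int | None = None


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------


def _build_grid(marker_map, step_cM: float) -> pd.DataFrame:
    rows = []
    for c in marker_map.chromosomes:
        idx = marker_map.chrom_indices(c)
        cm = marker_map.table["pos_cM"].to_numpy(dtype=float)[idx]
        kbp = marker_map.table["pos_kbp"].to_numpy(dtype=float)[idx]
        pseudo = np.arange(cm[0], cm[-1], step_cM)
        allcm = np.unique(np.round(np.concatenate([cm, pseudo]), 9))
        is_marker = np.isin(allcm, np.round(cm, 9))
        # markers keep their mapped physical position; pseudo-markers use the
        # fixed conversion
        kbp_lookup = dict(zip(np.round(cm, 9), kbp))
        allkbp = np.array([kbp_lookup.get(v, v * genome.KBP_PER_CM) for v in allcm])
        for p_cm, p_kbp, m in zip(allcm, allkbp, is_marker):
            rows.append((c, float(p_kbp), float(p_cm), bool(m)))
    return pd.DataFrame(rows, columns=["chrom", "pos_kbp", "pos_cM", "is_marker"])


def genotype_probabilities(
    genotypes: GenotypeMatrix, step_cM: float = 2.5, error_rate: float = 0.0
) -> GenotypeProbabilities:
    """Conditional P(P1) on a marker + pseudo-marker grid.

    For each segregant and chromosome the probability at a grid locus is
    conditioned on the nearest non-missing flanking markers under Haldane
    recombination; beyond the outermost informative marker only that flank
    conditions the locus.  A chromosome with no informative marker for a
    segregant gets probability 0.5 everywhere (with a warning).  A nonzero
    ``error_rate`` shrinks all probabilities toward 0.5 by ``1 - 2e``,
    so typed markers get probability ``1 - e`` / ``e`` instead of 1/0.
    """
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    mm = genotypes.map
    grid = _build_grid(mm, step_cM)
    n_seg = genotypes.n_segregants
    probs = np.full((len(grid), n_seg), 0.5)

    grid_chrom = grid["chrom"].to_numpy()
    grid_cm = grid["pos_cM"].to_numpy(dtype=float)
    uninformative = []
    for c in mm.chromosomes:
        midx = mm.chrom_indices(c)
        m_cm = mm.table["pos_cM"].to_numpy(dtype=float)[midx]
        gsel = np.flatnonzero(grid_chrom == c)
        g_cm = grid_cm[gsel]
        calls_c = genotypes.calls[midx, :]
        for s in range(n_seg):
            info = np.flatnonzero(calls_c[:, s] != MISSING)
            if len(info) == 0:
                uninformative.append((c, genotypes.segregant_ids[s]))
                continue
            mk = m_cm[info]
            al = (calls_c[info, s] == P1).astype(float)
            probs[gsel, s] = _flank_probabilities(g_cm, mk, al)
    if uninformative:
        warnings.warn(
            f"{len(uninformative)} segregant-chromosome pairs with no informative "
            "markers; probabilities set to 0.5",
            stacklevel=2,
        )
    if error_rate > 0:
        probs = 0.5 + (probs - 0.5) * (1.0 - 2.0 * error_rate)
    return GenotypeProbabilities(grid, probs, list(genotypes.segregant_ids))


def _flank_probabilities(g_cm: np.ndarray, mk_cm: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """P(P1) at grid points ``g_cm`` given informative markers at ``mk_cm``
    with observed P1-indicator ``alleles`` (exact calls), Haldane model."""
    left = np.searchsorted(mk_cm, g_cm, side="right") - 1
    out = np.empty_like(g_cm)

    only_right = left < 0
    if only_right.any():
        r = genome.haldane_r(mk_cm[0] - g_cm[only_right])
        out[only_right] = np.where(alleles[0] == 1.0, 1.0 - r, r)

    only_left = left >= len(mk_cm) - 1
    # points exactly on the last marker are handled by the interior formula
    # when flanked; here "only_left" includes the last marker itself (d=0)
    sel = only_left & ~only_right
    if sel.any():
        r = genome.haldane_r(g_cm[sel] - mk_cm[left[sel]])
        gl = alleles[left[sel]]
        out[sel] = np.where(gl == 1.0, 1.0 - r, r)

    interior = ~(only_right | only_left)
    if interior.any():
        li = left[interior]
        d1 = g_cm[interior] - mk_cm[li]
        d2 = mk_cm[li + 1] - g_cm[interior]
        r1 = genome.haldane_r(d1)
        r2 = genome.haldane_r(d2)
        r12 = genome.haldane_r(d1 + d2)
        gl, gr = alleles[li], alleles[li + 1]
        num = np.where(gl == 1.0, 1.0 - r1, r1) * np.where(gr == 1.0, 1.0 - r2, r2)
        den = np.where(gl == gr, 1.0 - r12, r12)
        out[interior] = num / den
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def lod_matrix(probs: GenotypeProbabilities, Y: np.ndarray) -> np.ndarray:
    """LOD scores for many traits at once.

    ``Y`` is (n_traits, n_segregants) with no missing values.  Returns
    (n_traits, n_loci).  Uses LOD = -(n/2) log10(1 - r^2), algebraically
    identical to the residual-sum-of-squares form for simple regression.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[1]
    if n != len(probs.segregant_ids):
        raise ValueError("trait width must equal segregant count")
    Pc = probs.probs - probs.probs.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    pn = np.sqrt((Pc**2).sum(axis=1))
    yn = np.sqrt((Yc**2).sum(axis=1))
    pn_safe = np.where(pn == 0, np.inf, pn)
    yn_safe = np.where(yn == 0, np.inf, yn)
    R = (Yc @ Pc.T) / np.outer(yn_safe, pn_safe)
    r2 = np.minimum(R**2, _R2_CEIL)
    return -(n / 2.0) * np.log10(1.0 - r2)


def hk_scan(probs: GenotypeProbabilities, trait: np.ndarray, trait_id: str = "trait") -> LODProfile:
    """Haley-Knott scan of one trait over the grid.

    Missing trait values are dropped pairwise (the corresponding segregants
    are excluded from every locus).  A zero-variance trait yields an
    all-zero profile with a warning.
    """
    y = np.asarray(trait, dtype=float)
    if len(y) != len(probs.segregant_ids):
        raise ValueError("trait length must equal segregant count")
    ok = ~np.isnan(y)
    n_ok = int(ok.sum())
    if n_ok < 3:
        raise ValueError("need at least three non-missing trait values")
    if n_ok < 8:
        warnings.warn("fewer than eight non-missing trait values; scan is fragile", stacklevel=2)
    sub = probs if ok.all() else GenotypeProbabilities(
        probs.grid, probs.probs[:, ok], [s for s, k in zip(probs.segregant_ids, ok) if k]
    )
    if np.var(y[ok]) == 0:
        warnings.warn(f"trait {trait_id!r} has zero variance; LOD profile is all zero",
                      stacklevel=2)
        return LODProfile(trait_id, probs.grid, np.zeros(probs.n_loci))
    lod = lod_matrix(sub, y[ok][None, :])[0]
    return LODProfile(trait_id, probs.grid, lod)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------


def permutation_threshold_trait(
    probs: GenotypeProbabilities,
    trait: np.ndarray,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from trait permutations.

    The trait is shuffled across segregants ``n_perm`` times (genotypes
    fixed); the threshold is the (1 - fdr) quantile of the genome-wide
    maximum LOD over permutations.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    y = np.asarray(trait, dtype=float)
    ok = ~np.isnan(y)
    y = y[ok]
    sub = probs if ok.all() else GenotypeProbabilities(
        probs.grid, probs.probs[:, ok], [s for s, k in zip(probs.segregant_ids, ok) if k]
    )
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y) for _ in range(n_perm)])
    maxima = lod_matrix(sub, perms).max(axis=1)
    return float(np.quantile(maxima, 1.0 - fdr))


def fdr_table(
    observed_max: np.ndarray, null_max: np.ndarray, lod_grid: np.ndarray
) -> pd.DataFrame:
    """Transcriptome FDR table from observed and permuted per-transcript
    maximum LODs.

    For each grid threshold t: ``observed`` counts transcripts with max LOD
    >= t, ``null_mean`` averages the same count over permutation rounds,
    and FDR(t) = null_mean / observed, clipped to [0, 1] and missing where
    nothing is observed.
    """
    observed_max = np.asarray(observed_max, dtype=float)
    null_max = np.atleast_2d(np.asarray(null_max, dtype=float))
    obs = np.array([(observed_max >= t).sum() for t in lod_grid], dtype=float)
    null = np.array([[(row >= t).sum() for t in lod_grid] for row in null_max], dtype=float)
    null_mean = null.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.clip(null_mean / obs, 0.0, 1.0)
    fdr[obs == 0] = np.nan
    return pd.DataFrame({"lod": lod_grid, "observed": obs, "null_mean": null_mean, "fdr": fdr})


def permutation_fdr_transcriptome(
    probs: GenotypeProbabilities,
    matrix,
    n_perm: int = 20,
    lod_grid: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Transcriptome-wide permutation FDR for eQTL scans.

    Each permutation applies one shared shuffle of segregant labels to the
    whole expression matrix (preserving transcript-transcript correlation),
    rescans every transcript, and counts transcripts whose genome-wide
    maximum LOD clears each grid threshold; FDR(t) is the mean null count
    over the observed count.
    """
    if n_perm < 2:
        raise ValueError("need at least two permutations")
    if lod_grid is None:
        lod_grid = np.round(np.arange(2.0, 8.01, 0.1), 10)
    Y = np.asarray(matrix.values, dtype=float)
    obs_max = lod_matrix(probs, Y).max(axis=1)
    rng = np.random.default_rng(seed)
    null_max = np.empty((n_perm, Y.shape[0]))
    for k in range(n_perm):
        shuffle = rng.permutation(Y.shape[1])
        null_max[k] = lod_matrix(probs, Y[:, shuffle]).max(axis=1)
    return fdr_table(obs_max, null_max, lod_grid)


def threshold_at_fdr(table: pd.DataFrame, target: float = 0.05) -> float:
    """Smallest grid LOD whose estimated FDR is at or below ``target``.

    Returns +inf when no threshold qualifies (nothing can be called)."""
    ok = table.dropna(subset=["fdr"])
    ok = ok[ok["fdr"] <= target]
    return float(ok["lod"].iloc[0]) if len(ok) else float("inf")


# ---------------------------------------------------------------------------
# linkage calling
# ---------------------------------------------------------------------------


def call_linkages(profile: LODProfile, threshold: float, drop: float = 1.0) -> list[LinkageRecord]:
    """Call at most one linkage per chromosome from a LOD profile.

    A chromosome whose maximum LOD reaches ``threshold`` yields one record
    at the peak locus (leftmost on ties), with the support interval being
    the contiguous region around the peak where LOD stays within ``drop``
    of the peak.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out: list[LinkageRecord] = []
    chrom = profile.grid["chrom"].to_numpy()
    kbp = profile.grid["pos_kbp"].to_numpy(dtype=float)
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        lod = profile.lod[sel]
        peak = int(np.argmax(lod))  # leftmost maximum
        if lod[peak] < threshold:
            continue
        lo = peak
        while lo > 0 and lod[lo - 1] >= lod[peak] - drop:
            lo -= 1
        hi = peak
        while hi < len(lod) - 1 and lod[hi + 1] >= lod[peak] - drop:
            hi += 1
        out.append(
            LinkageRecord(
                trait=profile.trait,
                peak_chrom=int(c),
                peak_kbp=float(kbp[sel[peak]]),
                lod=float(lod[peak]),
                ci_lo_kbp=float(kbp[sel[lo]]),
                ci_hi_kbp=float(kbp[sel[hi]]),
            )
        )
    return out
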