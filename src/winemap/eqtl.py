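"""eQTL pipeline: the three-analysis disomy-bypass design, cis/trans and
Venn classification, and trans-eQTL hotspot detection.

A partial disomy confounds linkage mapping: every amplified gene tracks the
markers that tag the duplication, producing spurious linkage clusters.  The
bypass design scans the data three ways -- (1) everything as-is, (2) only
non-disomic segregants, (3) all segregants with the duplicated-region
genotypes of disomic segregants blanked and disomy-responsive transcripts
excluded -- and classifies each eQTL by the subset of analyses that detect
it (its Venn group).  Linkages confined to analysis 1 are disomy artifacts;
linkages present in all three are robust.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import genome
from .linkage import (
    GenotypeProbabilities,
    LinkageRecord,
    LODProfile,
    call_linkages,
    genotype_probabilities,
    lod_matrix,
    permutation_fdr_transcriptome,
    threshold_at_fdr,
)
from .simulate import MISSING, ExpressionMatrix, GenotypeMatrix

#: eQTLs closer than this to their gene are classified local (cis).
CIS_WINDOW_KBP = 40.0


@dataclasses.dataclass
class Hotspot:
    """A genomic bin where trans-eQTL peaks for many transcripts pile up."""

    chrom: int
    start_kbp: float
    end_kbp: float
    count: int
    members: list[str]


# ---------------------------------------------------------------------------
# scanning helpers
# ---------------------------------------------------------------------------


def scan_transcriptome(
    probs: GenotypeProbabilities,
    matrix: ExpressionMatrix,
    lod_threshold: float,
    drop: float = 1.0,
) -> list[LinkageRecord]:
    """Scan every transcript and call linkages above ``lod_threshold``."""
    Y = np.asarray(matrix.values, dtype=float)
    lods = lod_matrix(probs, Y)
    records: list[LinkageRecord] = []
    for i, gene in enumerate(matrix.gene_ids):
        if lods[i].max() < lod_threshold:
            continue
        profile = LODProfile(gene, probs.grid, lods[i])
        records.extend(call_linkages(profile, lod_threshold, drop=drop))
    annotate_records(records, matrix.gene_annot)
    return records


def annotate_records(records: list[LinkageRecord], gene_annot: pd.DataFrame) -> None:
    """Attach gene coordinates and the cis/trans flag to linkage records."""
    for rec in records:
        if rec.trait in gene_annot.index:
            rec.gene_chrom = int(gene_annot.loc[rec.trait, "chrom"])
            rec.gene_kbp = float(gene_annot.loc[rec.trait, "pos_kbp"])
        rec.local_flag = classify_cis_trans(rec)


def classify_cis_trans(record: LinkageRecord, window_kbp: float = CIS_WINDOW_KBP) -> str:
    """Local (cis) when the peak lies on the gene's chromosome within
    ``window_kbp`` of the annotated gene start; distant (trans) otherwise.

    Records without gene coordinates are classified trans with a warning.
    """
    if record.gene_chrom is None or record.gene_kbp is None:
        warnings.warn(f"no gene annotation for {record.trait}; classified trans", stacklevel=2)
        return "trans"
    if record.peak_chrom == record.gene_chrom and abs(
        record.peak_kbp - record.gene_kbp
    ) < window_kbp:
        return "cis"
    return "trans"


# ---------------------------------------------------------------------------
# the three-analysis bypass
# ---------------------------------------------------------------------------


def run_disomy_bypass(
    matrix: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    disomic_ids: set[str],
    disomy_region: tuple[int, float, float],
    affected_genes: set[str],
    lod_threshold: float | None = None,
    fdr: float = 0.05,
    n_perm: int = 20,
    step_cM: float = 2.5,
    drop: float = 1.0,
    seed: int = 0,
) -> dict[int, list[LinkageRecord]]:
    """Run the three disomy-bypass eQTL analyses.

    Analysis 1 uses all segregants, markers and transcripts.  Analysis 2
    restricts to non-disomic segregants.  Analysis 3 keeps every segregant
    but blanks duplicated-region genotypes for the disomic ones (their calls
    there are ambiguous; the normals' remain valid) and drops the
    disomy-affected transcripts.  Each analysis is called at
    ``lod_threshold`` when given, otherwise at its own permutation-FDR
    threshold (``n_perm`` rounds, target ``fdr``).
    """
    normal_ids = [s for s in genotypes.segregant_ids if s not in disomic_ids]
    analyses: dict[int, list[LinkageRecord]] = {}

    def one_analysis(gm: GenotypeMatrix, mat: ExpressionMatrix, tag: int) -> list[LinkageRecord]:
        probs = genotype_probabilities(gm, step_cM=step_cM)
        thr = lod_threshold
        if thr is None:
            table = permutation_fdr_transcriptome(probs, mat, n_perm=n_perm, seed=seed + tag)
            thr = threshold_at_fdr(table, target=fdr)
        if not np.isfinite(thr):
            return []
        recs = scan_transcriptome(probs, mat, thr, drop=drop)
        for r in recs:
            r.analysis = tag
        return recs

    # analysis 1: everything
    analyses[1] = one_analysis(genotypes, matrix, 1)

    # analysis 2: non-disomic segregants only
    if len(normal_ids) == 0:
        warnings.warn("no non-disomic segregants; analysis 2 skipped", stacklevel=2)
        analyses[2] = []
    else:
        cols = [genotypes.segregant_ids.index(s) for s in normal_ids]
        gm2 = GenotypeMatrix(genotypes.map, genotypes.calls[:, cols], normal_ids)
        analyses[2] = one_analysis(gm2, matrix.subset_samples(normal_ids), 2)

    # analysis 3: blank duplicated-region genotypes of disomic segregants,
    # drop affected transcripts
    chrom, start, end = disomy_region
    mtab = genotypes.map.table
    region_markers = np.flatnonzero(
        (mtab["chrom"].to_numpy() == chrom)
        & (mtab["pos_kbp"].to_numpy(dtype=float) >= start)
        & (mtab["pos_kbp"].to_numpy(dtype=float) <= end)
    )
    calls3 = genotypes.calls.copy()
    dcols = [genotypes.segregant_ids.index(s) for s in disomic_ids]
    calls3[np.ix_(region_markers, dcols)] = MISSING
    gm3 = GenotypeMatrix(genotypes.map, calls3, list(genotypes.segregant_ids))
    keep = [g for g in matrix.gene_ids if g not in affected_genes]
    analyses[3] = one_analysis(gm3, matrix.subset_genes(keep), 3)

    return analyses


# ---------------------------------------------------------------------------
# Venn classification
# ---------------------------------------------------------------------------


def venn_classify(analysis_sets: dict[int, list[LinkageRecord]]) -> list[LinkageRecord]:
    """Merge the three analyses' linkages and label each with its Venn group.

    Records from different analyses merge when they concern the same
    transcript, peak on the same chromosome, and their support intervals
    overlap (peak positions move when the pseudo-marker grid or segregant
    subset changes, so exact equality is too strict).  The merged record
    keeps the analysis-1 peak when present, else analysis-3, else
    analysis-2; its venn_group is the set of analyses containing it, e.g.
    "123" or "13".
    """
    tagged: list[LinkageRecord] = []
    for a, recs in analysis_sets.items():
        for r in recs:
            if r.analysis is None:
                r = dataclasses.replace(r, analysis=a)
            tagged.append(r)

    merged: list[LinkageRecord] = []
    by_trait: dict[str, list[LinkageRecord]] = {}
    for r in tagged:
        by_trait.setdefault(r.trait, []).append(r)

    priority = {1: 0, 3: 1, 2: 2}
    for trait, recs in by_trait.items():
        # union-find over records of one transcript
        parent = list(range(len(recs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                if a.peak_chrom == b.peak_chrom and a.ci_lo_kbp <= b.ci_hi_kbp and b.ci_lo_kbp <= a.ci_hi_kbp:
                    parent[find(i)] = find(j)

        groups: dict[int, list[LinkageRecord]] = {}
        for i in range(len(recs)):
            groups.setdefault(find(i), []).append(recs[i])
        for members in groups.values():
            rep = min(members, key=lambda r: priority[r.analysis])
            analyses = sorted({r.analysis for r in members})
            out = dataclasses.replace(rep, venn_group="".join(str(a) for a in analyses))
            merged.append(out)
    merged.sort(key=lambda r: (r.peak_chrom, r.peak_kbp, r.trait))
    return merged


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------


def detect_hotspots(
    records: list[LinkageRecord],
    bin_kbp: float = 50.0,
    alpha: float = 0.001,
    chrom_lengths_kbp: dict[int, float] | None = None,
) -> list[Hotspot]:
    """Detect trans-eQTL hotspots by Poisson-thresholded binning.

    Trans peaks are binned per ``bin_kbp``; under uniform scatter the
    per-bin count is Poisson with mean total/bins, and a bin is significant
    when its count exceeds the (1 - alpha) Poisson quantile.  Adjacent
    significant bins merge into one hotspot.  Non-trans records are
    ignored.
    """
    trans = [r for r in records if r.local_flag == "trans"]
    if not trans:
        return []
    if chrom_lengths_kbp is None:
        chrom_lengths_kbp = genome.CHROM_LENGTHS_KBP

    n_bins_per_chrom = {c: int(np.ceil(length / bin_kbp)) for c, length in chrom_lengths_kbp.items()}
    total_bins = sum(n_bins_per_chrom.values())
    lam = len(trans) / total_bins
    cutoff = stats.poisson.ppf(1.0 - alpha, lam)

    bins: dict[tuple[int, int], list[LinkageRecord]] = {}
    for r in trans:
        b = int((r.peak_kbp - 1e-9) // bin_kbp)
        bins.setdefault((r.peak_chrom, b), []).append(r)

    significant = {k for k, v in bins.items() if len(v) > cutoff}
    hotspots: list[Hotspot] = []
    for c in sorted({k[0] for k in significant}):
        chrom_bins = sorted(b for cc, b in significant if cc == c)
        run: list[int] = []
        for b in chrom_bins:
            if run and b != run[-1] + 1:
                hotspots.append(_make_hotspot(c, run, bins, bin_kbp))
                run = []
            run.append(b)
        if run:
            hotspots.append(_make_hotspot(c, run, bins, bin_kbp))
    return hotspots


def _make_hotspot(chrom, run, bins, bin_kbp) -> Hotspot:
    members = [r for b in run for r in bins[(chrom, b)]]
    members.sort(key=lambda r: (r.peak_kbp, r.trait))
    return Hotspot(
        chrom=int(chrom),
        start_kbp=run[0] * bin_kbp,
        end_kbp=(run[-1] + 1) * bin_kbp,
        count=len(members),
        members=[r.trait for r in members],
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def records_frame(records: list[LinkageRecord]) -> pd.DataFrame:
    rows = [
        {
            "transcript": r.trait,
            "gene_chrom": r.gene_chrom,
            "gene_kbp": r.gene_kbp,
            "peak_chrom": r.peak_chrom,
            "peak_kbp": r.peak_kbp,
            "lod": r.lod,
            "ci_lo": r.ci_lo_kbp,
            "ci_hi": r.ci_hi_kbp,
            "local_flag": r.local_flag,
            "venn_group": r.venn_group,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "transcript",
            "gene_chrom",
            "gene_kbp",
            "peak_chrom",
            "peak_kbp",
            "lod",
            "ci_lo",
            "ci_hi",
            "local_flag",
            "venn_group",
        ],
    )
    return df.sort_values(["peak_chrom", "peak_kbp", "transcript"]).reset_index(drop=True)


def hotspots_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    rows = [
        {
            "chrom": h.chrom,
            "bin_start_kbp": h.start_kbp,
            "bin_end_kbp": h.end_kbp,
            "count": h.count,
            "members": ",".join(h.members),
        }
        for h in hotspots
    ]
    df = pd.DataFrame(rows, columns=["chrom", "bin_start_kbp", "bin_end_kbp", "count", "members"])
    return df.sort_values(["chrom", "bin_start_kbp"]).reset_index(drop=True)


def write_results(
    records: list[LinkageRecord], hotspots: list[Hotspot], outdir: str | Path
) -> tuple[Path, Path]:
    """Write deterministic, sorted TSVs for eQTL records and hotspots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eqtl_path = outdir / "eqtls.tsv"
    hs_path = outdir / "hotspots.tsv"
    records_frame(records).to_csv(eqtl_path, sep="\t", index=False)
    hotspots_frame(hotspots).to_csv(hs_path, sep="\t", index=False)
    return eqtl_path, hs_path


def read_results(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    outdir = Path(outdir)
    eqtls = pd.read_csv(outdir / "eqtls.tsv", sep="\t", dtype={"venn_group": str})
    hotspots = pd.read_csv(outdir / "hotspots.tsv", sep="\t", dtype={"members": str})
    return eqtls, hotspots
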