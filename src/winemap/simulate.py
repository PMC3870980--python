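"""Synthetic segregant populations with a translocation-derived partial disomy.

This module generates every input the analysis pipeline consumes: a marker
map, genotypes from a haploid two-parent cross, log2 expression matrices
with planted cis/trans eQTLs and gene-dosage effects, heritable traits with
parental replicates, and aCGH-style probe tracks.

The cross emulates a wine-strain x laboratory-strain mating in which the
wine parent (P1) carries a reciprocal translocation that moved the left arm
of chromosome 16 onto chromosome 8.  Because the two rearranged chromosomes
segregate independently, four gamete classes arise in equal proportion:
parental-like with one copy of the arm (two classes), a class carrying two
copies of the arm (partial disomy), and a class with no copy, which is
inviable and is rejected during sampling.  Among viable spores one third is
therefore expected to be disomic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import genome
from .cnv import ProbeTrack

#: Genotype call codes: laboratory-parent allele, wine-parent allele, no call.
P2, P1, MISSING = 0, 1, -1


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Dedicated RNG substream per operation, so each generator is
    reproducible independently of call order."""
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MarkerMap:
    """Genetic map: one row per marker with physical (kbp, 1-based) and
    genetic (cM) coordinates, sorted by chromosome then position."""

    table: pd.DataFrame  # columns: marker_id, chrom, pos_kbp, pos_cM

    def __post_init__(self):
        t = self.table
        required = {"marker_id", "chrom", "pos_kbp", "pos_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        for c, sub in t.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos_kbp"].to_numpy(dtype=float)) <= 0):
                raise ValueError(f"marker positions not strictly increasing on chromosome {c}")
            if np.any(np.diff(sub["pos_cM"].to_numpy(dtype=float)) < 0):
                raise ValueError(f"cM positions decrease on chromosome {c}")
        self.table = t.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[int]:
        return list(dict.fromkeys(self.table["chrom"].tolist()))

    def chrom_indices(self, chrom: int) -> np.ndarray:
        return np.flatnonzero(self.table["chrom"].to_numpy() == chrom)

    def nearest_marker(self, chrom: int, pos_kbp: float) -> int:
        """Global row index of the marker nearest ``pos_kbp`` on ``chrom``."""
        idx = self.chrom_indices(chrom)
        if len(idx) == 0:
            raise ValueError(f"no markers on chromosome {chrom}")
        pos = self.table["pos_kbp"].to_numpy(dtype=float)[idx]
        return int(idx[np.argmin(np.abs(pos - pos_kbp))])

    def first_marker_at_or_after(self, chrom: int, pos_kbp: float) -> int:
        idx = self.chrom_indices(chrom)
        pos = self.table["pos_kbp"].to_numpy(dtype=float)[idx]
        after = np.flatnonzero(pos >= pos_kbp)
        return int(idx[after[0]]) if len(after) else int(idx[-1])


@dataclasses.dataclass
class GenotypeMatrix:
    """Parental-origin calls (markers x segregants), coded P1/P2/MISSING."""

    map: MarkerMap
    calls: np.ndarray  # int8, shape (n_markers, n_segregants)
    segregant_ids: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (self.map.n_markers, len(self.segregant_ids)):
            raise ValueError("genotype matrix shape inconsistent with map / ids")
        bad = ~np.isin(self.calls, [P1, P2, MISSING])
        if bad.any():
            raise ValueError("genotype calls must be P1, P2 or MISSING")

    @property
    def n_segregants(self) -> int:
        return len(self.segregant_ids)

    def column(self, segregant_id: str) -> np.ndarray:
        return self.calls[:, self.segregant_ids.index(segregant_id)]

    def p1_frequency(self) -> np.ndarray:
        """Per-marker frequency of the wine-parent allele among non-missing calls."""
        obs = self.calls != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs.any(axis=1), (self.calls == P1).sum(axis=1) / obs.sum(axis=1), np.nan)


@dataclasses.dataclass
class TranslocationSpec:
    """Reciprocal translocation placing ``region`` of ``chrom`` onto
    ``partner_chrom`` of the wine parent (junction at ``junction_kbp``)."""

    chrom: int = 16
    start_kbp: float = 1.0
    end_kbp: float = 373.0
    partner_chrom: int = 8
    junction_kbp: float = 20.0

    @property
    def region(self) -> tuple[int, float, float]:
        return (self.chrom, self.start_kbp, self.end_kbp)

    @property
    def length_kbp(self) -> float:
        return self.end_kbp - self.start_kbp + 1.0


@dataclasses.dataclass
class CrossTruth:
    """Ground truth of one simulated cross, filled in by the generators."""

    disomic_segregants: set[str]
    disomy_region: tuple[int, float, float] | None
    labels: dict[str, str]  # segregant -> normal | translocated | disomic
    planted_eqtls: list[tuple[str, int, float, float]] = dataclasses.field(default_factory=list)
    planted_qtls: list[tuple[str, int, float, float]] = dataclasses.field(default_factory=list)
    dosage_genes: set[str] = dataclasses.field(default_factory=set)


@dataclasses.dataclass
class ExpressionMatrix:
    """log2 expression (genes x samples) plus gene genomic coordinates."""

    values: np.ndarray
    gene_ids: list[str]
    gene_annot: pd.DataFrame  # index gene_id, columns chrom, pos_kbp
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape inconsistent with ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if list(self.gene_annot.index) != list(self.gene_ids):
            raise ValueError("gene annotation must have exactly one row per gene, in order")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sample_index(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset_samples(self, ids: list[str]) -> "ExpressionMatrix":
        cols = self.sample_index(ids)
        return ExpressionMatrix(self.values[:, cols], self.gene_ids, self.gene_annot, list(ids))

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        rows = [self.gene_ids.index(g) for g in keep]
        return ExpressionMatrix(
            self.values[rows, :], keep, self.gene_annot.loc[keep], self.sample_ids
        )


@dataclasses.dataclass
class TraitTable:
    """Quantitative traits: one value per segregant, plus replicated
    parental measurements used to estimate environmental variance."""

    segregants: pd.DataFrame  # index segregant_id, one column per trait
    parental: dict[str, dict[str, np.ndarray]]  # trait -> {"P1": reps, "P2": reps}

    def trait(self, name: str) -> np.ndarray:
        return self.segregants[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------


def simulate_marker_map(
    n_chrom: int = 16,
    chrom_lengths_kbp: list[float] | None = None,
    density_per_10kbp: float = 1.81,
    seed: int = 0,
    jitter_frac: float = 0.45,
) -> MarkerMap:
    """Simulate a marker map at a target genome-wide density.

    Each chromosome receives ``round(density * length / 10)`` markers placed
    on an even grid with positional jitter, which keeps positions strictly
    increasing while realizing the requested density within rounding error.
    Genetic positions use the fixed 3 kbp/cM conversion.
    """
    if chrom_lengths_kbp is None:
        chrom_lengths_kbp = [genome.CHROM_LENGTHS_KBP[c] for c in range(1, n_chrom + 1)]
    if len(chrom_lengths_kbp) != n_chrom:
        raise ValueError("chrom_lengths_kbp length must equal n_chrom")
    if density_per_10kbp <= 0:
        raise ValueError("density must be positive")
    if any(length <= 0 for length in chrom_lengths_kbp):
        raise ValueError("chromosome lengths must be positive")
    rng = _rng(seed, 0)
    rows = []
    for c, length in enumerate(chrom_lengths_kbp, start=1):
        n = int(round(density_per_10kbp * length / 10.0))
        if n == 0:
            continue
        spacing = length / n
        base = (np.arange(n) + 0.5) * spacing
        pos = base + rng.uniform(-jitter_frac, jitter_frac, size=n) * spacing
        pos = np.clip(np.sort(pos), 1.0, length)
        # jitter below half-spacing keeps order; guard against clip collisions
        pos = np.maximum.accumulate(pos + np.arange(n) * 1e-9)
        for i, p in enumerate(pos):
            rows.append((f"m{c:02d}_{i + 1:04d}", c, float(p), float(p) / genome.KBP_PER_CM))
    table = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_kbp", "pos_cM"])
    return MarkerMap(table)


# ---------------------------------------------------------------------------
# meiosis and the cross
# ---------------------------------------------------------------------------


def _simulate_gametes(marker_map: MarkerMap, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` haploid gametes under independent-chromosome meiosis with
    Haldane (no-interference) recombination.  Returns int8 (markers x n)."""
    calls = np.empty((marker_map.n_markers, n), dtype=np.int8)
    pos_cM = marker_map.table["pos_cM"].to_numpy(dtype=float)
    for c in marker_map.chromosomes:
        idx = marker_map.chrom_indices(c)
        r = genome.haldane_r(np.diff(pos_cM[idx]))
        first = rng.integers(0, 2, size=n, dtype=np.int8)
        if len(idx) > 1:
            rec = (rng.random((len(idx) - 1, n)) < r[:, None]).astype(np.int8)
            state = np.concatenate([first[None, :], rec], axis=0).cumsum(axis=0) % 2
        else:
            state = first[None, :]
        calls[idx, :] = state
    return calls


def simulate_cross(
    marker_map: MarkerMap,
    n_segregants: int = 44,
    translocation: TranslocationSpec | None = TranslocationSpec(),
    seed: int = 0,
    missing_rate: float = 0.01,
) -> tuple[GenotypeMatrix, CrossTruth]:
    """Simulate viable haploid segregants from the wine x lab cross.

    Gametes are drawn by Haldane meiosis; when a ``translocation`` is
    present, the structural type of the rearranged chromosomes is read off
    the parental origin at the junction markers, the inviable class (no copy
    of the translocated arm) is rejected and redrawn, and the surviving
    spores are labelled ``normal`` (one lab-type arm), ``translocated`` (one
    wine-type arm riding on the partner chromosome) or ``disomic`` (both).
    Arm markers are recoded to the allele actually carried: P2 for normal
    spores and P1 for translocated and disomic spores (the wine allele is
    present in both of the latter, making the call ambiguous for disomics --
    which is exactly why the bypass analyses blank these markers).
    """
    if n_segregants < 2:
        raise ValueError("n_segregants must be >= 2")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _rng(seed, 1)

    if translocation is not None:
        if translocation.chrom not in marker_map.chromosomes:
            raise ValueError("translocation region not on a mapped chromosome")
        if translocation.partner_chrom not in marker_map.chromosomes:
            raise ValueError("translocation partner chromosome not on the map")
        j_partner = marker_map.nearest_marker(
            translocation.partner_chrom, translocation.junction_kbp
        )
        j_break = marker_map.first_marker_at_or_after(translocation.chrom, translocation.end_kbp)

    kept: list[np.ndarray] = []
    labels: list[str] = []
    need = n_segregants
    while need > 0:
        batch = _simulate_gametes(marker_map, max(2 * need, 8), rng)
        if translocation is None:
            take = batch[:, :need]
            kept.append(take)
            labels.extend(["normal"] * take.shape[1])
            need = 0
            continue
        arm_origin = batch[j_break, :]  # origin of the resident chromosome near the breakpoint
        partner_origin = batch[j_partner, :]  # carries the translocated arm when P1
        viable = ~((arm_origin == P1) & (partner_origin == P2))
        cols = np.flatnonzero(viable)[:need]
        for col in cols:
            if arm_origin[col] == P2 and partner_origin[col] == P1:
                labels.append("disomic")
            elif arm_origin[col] == P1:
                labels.append("translocated")
            else:
                labels.append("normal")
        kept.append(batch[:, cols])
        need -= len(cols)

    calls = np.concatenate(kept, axis=1)
    ids = [f"seg{i + 1:03d}" for i in range(n_segregants)]

    region = None
    if translocation is not None:
        region = translocation.region
        chrom_col = marker_map.table["chrom"].to_numpy()
        pos_col = marker_map.table["pos_kbp"].to_numpy(dtype=float)
        arm = (chrom_col == translocation.chrom) & (pos_col >= translocation.start_kbp) & (
            pos_col <= translocation.end_kbp
        )
        for j, lab in enumerate(labels):
            calls[arm, j] = P2 if lab == "normal" else P1

    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING

    truth = CrossTruth(
        disomic_segregants={i for i, lab in zip(ids, labels) if lab == "disomic"},
        disomy_region=region,
        labels=dict(zip(ids, labels)),
    )
    return GenotypeMatrix(marker_map, calls, ids), truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _place_genes(
    marker_map: MarkerMap, n_genes: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Scatter genes over the mapped chromosomes proportionally to length."""
    chroms = marker_map.chromosomes
    lengths = np.array(
        [marker_map.table.loc[marker_map.chrom_indices(c), "pos_kbp"].max() for c in chroms]
    )
    counts = np.maximum(1, np.round(n_genes * lengths / lengths.sum()).astype(int))
    # adjust to hit n_genes exactly
    while counts.sum() > n_genes:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_genes:
        counts[np.argmax(lengths / counts)] += 1
    rows = []
    for c, length, k in zip(chroms, lengths, counts):
        pos = np.sort(rng.uniform(1.0, length, size=k))
        rows += [(c, float(p)) for p in pos]
    annot = pd.DataFrame(rows, columns=["chrom", "pos_kbp"])
    annot.index = [f"g{i + 1:04d}" for i in range(len(annot))]
    return annot


def simulate_expression(
    genotypes: GenotypeMatrix,
    truth: CrossTruth,
    n_genes: int = 1000,
    cis_frac: float = 0.2,
    trans_frac: float = 0.1,
    effect_size_log2: float = 1.0,
    dosage_log2: float = 1.0,
    noise_sd: float = 0.1,
    baseline: float = 8.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate a log2 expression matrix with planted regulatory structure.

    ``cis_frac`` of the genes get an eQTL at the marker nearest the gene,
    ``trans_frac`` at a random marker elsewhere in the genome; genes inside
    the disomy region additionally gain ``dosage_log2`` in disomic
    segregants (1.0 = the log2 of a doubled copy number).  Everything else
    is i.i.d. Gaussian noise.  Planted eQTLs and dosage genes are recorded
    in ``truth``.
    """
    if not (0 <= cis_frac <= 1 and 0 <= trans_frac <= 1 and cis_frac + trans_frac <= 1):
        raise ValueError("cis_frac and trans_frac must be fractions summing to <= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = _rng(seed, 2)
    mm = genotypes.map
    annot = _place_genes(mm, n_genes, rng)
    gene_ids = list(annot.index)

    values = baseline + rng.normal(0.0, noise_sd, size=(n_genes, genotypes.n_segregants))

    dosage_active = (
        truth.disomy_region is not None and dosage_log2 != 0 and bool(truth.disomic_segregants)
    )
    if dosage_active:
        chrom, start, end = truth.disomy_region
        in_region_mask = (
            (annot["chrom"] == chrom) & annot["pos_kbp"].between(start, end)
        ).to_numpy()
    else:
        in_region_mask = np.zeros(n_genes, dtype=bool)

    # regulatory eQTLs are planted outside the amplified region, so that
    # dosage-driven and sequence-driven signals stay separable
    n_cis = int(round(cis_frac * n_genes))
    n_trans = int(round(trans_frac * n_genes))
    eligible = np.flatnonzero(~in_region_mask)
    order = rng.permutation(eligible)
    cis_rows, trans_rows = order[:n_cis], order[n_cis : n_cis + n_trans]

    truth.planted_eqtls = []
    mtab = mm.table
    for row in cis_rows:
        g = gene_ids[row]
        m = mm.nearest_marker(int(annot.iloc[row]["chrom"]), float(annot.iloc[row]["pos_kbp"]))
        _add_marker_effect(values, genotypes, row, m, effect_size_log2)
        truth.planted_eqtls.append(
            (g, int(mtab.iloc[m]["chrom"]), float(mtab.iloc[m]["pos_kbp"]), effect_size_log2)
        )
    for row in trans_rows:
        g = gene_ids[row]
        gc = int(annot.iloc[row]["chrom"])
        other = np.flatnonzero(mtab["chrom"].to_numpy() != gc)
        m = int(rng.choice(other)) if len(other) else int(rng.integers(mm.n_markers))
        _add_marker_effect(values, genotypes, row, m, effect_size_log2)
        truth.planted_eqtls.append(
            (g, int(mtab.iloc[m]["chrom"]), float(mtab.iloc[m]["pos_kbp"]), effect_size_log2)
        )

    truth.dosage_genes = set()
    if dosage_active:
        disomic_cols = [
            i for i, s in enumerate(genotypes.segregant_ids) if s in truth.disomic_segregants
        ]
        rows = np.flatnonzero(in_region_mask)
        values[np.ix_(rows, disomic_cols)] += dosage_log2
        truth.dosage_genes = set(annot.index[in_region_mask])

    return ExpressionMatrix(values, gene_ids, annot, list(genotypes.segregant_ids))


def _add_marker_effect(
    values: np.ndarray, genotypes: GenotypeMatrix, row: int, marker: int, effect: float
) -> None:
    call = genotypes.calls[marker, :].astype(float)
    dose = np.where(call == MISSING, 0.5, call)
    values[row, :] += effect * dose


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def simulate_traits(
    genotypes: GenotypeMatrix,
    truth: CrossTruth,
    target_H2: float = 90.0,
    parental_reps: int = 4,
    n_qtls: int = 2,
    qtl_effect: float = 1.0,
    disomy_effect: float = 1.0,
    seed: int = 0,
) -> TraitTable:
    """Simulate heritable traits with replicated parental measurements.

    The genetic value of the ``polygenic`` trait is the sum of ``n_qtls``
    planted additive marker effects; the environmental variance is set from
    the realized genetic variance so that the expected broad-sense
    heritability (segregant variance minus pooled parental-replicate
    variance, over segregant variance) equals ``target_H2`` percent.  When a
    disomy segregates, a second ``disomy_bimodal`` trait mimics a
    fermentation-rate phenotype driven by the amplification: the disomy
    indicator plus noise at the same target heritability, which yields the
    characteristic bimodal distribution across segregants.
    """
    if not 0 <= target_H2 < 100:
        raise ValueError("target_H2 must lie in [0, 100)")
    if parental_reps < 2:
        raise ValueError("need at least two parental replicates")
    rng = _rng(seed, 3)
    h = target_H2 / 100.0
    mm = genotypes.map

    loci = rng.choice(mm.n_markers, size=min(n_qtls, mm.n_markers), replace=False)
    calls = genotypes.calls[loci, :].astype(float)
    dose = np.where(calls == MISSING, 0.5, calls)
    genetic = qtl_effect * dose.sum(axis=0)
    truth.planted_qtls = [
        (
            "polygenic",
            int(mm.table.iloc[m]["chrom"]),
            float(mm.table.iloc[m]["pos_kbp"]),
            qtl_effect,
        )
        for m in loci
    ]

    traits: dict[str, np.ndarray] = {}
    parental: dict[str, dict[str, np.ndarray]] = {}

    def build(name: str, gvals: np.ndarray, parent_g: dict[str, float]) -> None:
        var_g = float(np.var(gvals, ddof=1))
        if h == 0.0:
            gvals = np.zeros_like(gvals)
            noise_var = 1.0
        else:
            if var_g == 0:
                raise ValueError(f"trait {name!r} has no genetic variance; cannot hit target H2")
            noise_var = var_g * (1.0 - h) / h
        sd = float(np.sqrt(noise_var))
        traits[name] = gvals + rng.normal(0.0, sd, size=len(gvals))
        parental[name] = {
            p: parent_g[p] + rng.normal(0.0, sd, size=parental_reps) for p in ("P1", "P2")
        }

    build("polygenic", genetic, {"P1": qtl_effect * len(loci), "P2": 0.0})

    if truth.disomic_segregants:
        indicator = np.array(
            [s in truth.disomic_segregants for s in genotypes.segregant_ids], dtype=float
        )
        # both parents are euploid for the arm (one copy each)
        build("disomy_bimodal", disomy_effect * indicator, {"P1": 0.0, "P2": 0.0})

    seg = pd.DataFrame(traits, index=list(genotypes.segregant_ids))
    return TraitTable(seg, parental)


# ---------------------------------------------------------------------------
# probe tracks
# ---------------------------------------------------------------------------


def simulate_probe_tracks(
    truth: CrossTruth,
    segregant_ids: list[str],
    chrom_lengths_kbp: dict[int, float] | None = None,
    probes_per_10kbp: float = 15.0,
    gain_log2: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, ProbeTrack], ProbeTrack]:
    """Simulate per-segregant probe-level log-signal tracks plus a euploid
    reference track.

    Probes sit on an even grid; disomic segregants gain ``gain_log2`` on
    probes inside the amplified region; all probes carry i.i.d. Gaussian
    noise of ``noise_sd`` (per track, including the reference).
    """
    if chrom_lengths_kbp is None:
        chrom_lengths_kbp = genome.CHROM_LENGTHS_KBP
    rng = _rng(seed, 4)
    rows = []
    for c, length in chrom_lengths_kbp.items():
        n = max(1, int(round(probes_per_10kbp * length / 10.0)))
        spacing = length / n
        for i in range(n):
            rows.append((f"p{c:02d}_{i + 1:05d}", c, (i + 0.5) * spacing))
    probes = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos_kbp"])

    gain = np.zeros(len(probes))
    if truth.disomy_region is not None:
        chrom, start, end = truth.disomy_region
        sel = (probes["chrom"] == chrom) & probes["pos_kbp"].between(start, end)
        gain[sel.to_numpy()] = gain_log2

    tracks = {}
    for sid in segregant_ids:
        sig = rng.normal(0.0, noise_sd, size=len(probes))
        if sid in truth.disomic_segregants:
            sig = sig + gain
        tracks[sid] = ProbeTrack(probes, sig, sample_id=sid)
    reference = ProbeTrack(
        probes, rng.normal(0.0, noise_sd, size=len(probes)), sample_id="euploid_reference"
    )
    return tracks, reference
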