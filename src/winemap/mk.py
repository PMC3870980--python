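"""McDonald-Kreitman polymorphism/divergence counting and the neutrality index.

The test contrasts non-synonymous vs synonymous variation segregating
within a species (Pn, Ps) against that fixed between species (Dn, Ds) on a
codon alignment of several ingroup alleles and one outgroup sequence.
Under neutrality the two ratios match; a neutrality index
NI = (Pn/Ps)/(Dn/Ds) above one points to segregating slightly deleterious
or balanced variation, below one to adaptive divergence.  Significance
comes from a two-sided Fisher exact test on the 2x2 count table.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from scipy import stats

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, standard nuclear code; stops map to "*".
CODON_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_AA.update({c: "*" for c in _STANDARD.stop_codons})

_BASES = "ACGT"


@dataclasses.dataclass
class CodonAlignment:
    """Aligned coding sequences: >=2 ingroup alleles plus one outgroup."""

    ingroup_ids: list[str]
    ingroup_seqs: list[str]
    outgroup_id: str
    outgroup_seq: str

    def __post_init__(self):
        if len(self.ingroup_seqs) < 2:
            raise ValueError("need at least two ingroup sequences")
        self.ingroup_seqs = [s.upper() for s in self.ingroup_seqs]
        self.outgroup_seq = self.outgroup_seq.upper()
        lengths = {len(s) for s in self.ingroup_seqs} | {len(self.outgroup_seq)}
        if len(lengths) != 1:
            raise ValueError("sequences are not aligned to equal length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.outgroup_seq) // 3

    def codon_column(self, k: int) -> tuple[list[str], str]:
        sl = slice(3 * k, 3 * k + 3)
        return [s[sl] for s in self.ingroup_seqs], self.outgroup_seq[sl]

    @classmethod
    def from_fasta(cls, path: str | Path, outgroup: str) -> "CodonAlignment":
        """Read an aligned multi-FASTA; ``outgroup`` names the outgroup record."""
        records = list(SeqIO.parse(str(path), "fasta"))
        ids = [r.id for r in records]
        if outgroup not in ids:
            raise ValueError(f"outgroup id {outgroup!r} not found in {ids}")
        out = next(r for r in records if r.id == outgroup)
        ins = [r for r in records if r.id != outgroup]
        return cls(
            ingroup_ids=[r.id for r in ins],
            ingroup_seqs=[str(r.seq) for r in ins],
            outgroup_id=out.id,
            outgroup_seq=str(out.seq),
        )


@dataclasses.dataclass
class MKTable:
    """Polymorphism/divergence counts with the neutrality index."""

    Pn: float
    Ps: float
    Dn: float
    Ds: float
    NI: float | None
    p_value: float | None
    interpretation: str = ""


def _clean_codon(codon: str) -> bool:
    return all(b in _BASES for b in codon)


def path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) substitution counts between two codons,
    averaged over all shortest mutational pathways.

    Each pathway changes one differing position at a time; pathways passing
    through a stop codon are excluded unless every pathway does.  Codons
    that are themselves stops, or carry gaps/ambiguity, must be filtered by
    the caller.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        syn = nonsyn = 0
        cur = c1
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_AA[nxt] == "*" and nxt != c2:
                through_stop = True
            if CODON_AA[cur] == CODON_AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((syn, nonsyn, through_stop))
    usable = [p for p in paths if not p[2]] or paths
    syn = sum(p[0] for p in usable) / len(usable)
    nonsyn = sum(p[1] for p in usable) / len(usable)
    return syn, nonsyn


def _parsimony_center(distinct: list[str]) -> str:
    """The segregating codon with the fewest total nucleotide differences to
    the other segregating codons (lexicographically first on ties)."""
    def cost(c: str) -> int:
        return sum(sum(a != b for a, b in zip(c, d)) for d in distinct)

    return min(sorted(distinct), key=cost)


def count_poly_div(aln: CodonAlignment, polymorphism_precedence: bool = True) -> MKTable:
    """Codon-by-codon polymorphism and divergence counts.

    For each codon column: distinct ingroup codons segregating in the
    sample contribute to Pn/Ps (each scored against the parsimony center of
    the distinct-allele set, pathway-averaged; the center depends only on
    which codons segregate, never on their frequencies, so duplicated
    sequences cannot change the counts); a column where the ingroup is
    monomorphic but differs from the outgroup contributes the
    pathway-averaged steps to Dn/Ds.  Columns containing gaps, ambiguity
    codes or stop codons are skipped (stops with a warning).  When
    ``polymorphism_precedence`` is set (default), a column that is both
    polymorphic and divergent is counted as polymorphic only -- the ingroup
    is not fixed there.
    """
    pn = ps = dn = ds = 0.0
    stop_seen = False
    for k in range(aln.n_codons):
        ingroup, out = aln.codon_column(k)
        codons = ingroup + [out]
        if not all(_clean_codon(c) for c in codons):
            continue
        if any(CODON_AA[c] == "*" for c in codons):
            stop_seen = True
            continue
        distinct = sorted(set(ingroup))
        if len(distinct) > 1:
            center = _parsimony_center(distinct)
            for c in distinct:
                if c == center:
                    continue
                s, n = path_counts(center, c)
                ps += s
                pn += n
            if polymorphism_precedence:
                continue
        if len(distinct) == 1 and distinct[0] != out:
            s, n = path_counts(distinct[0], out)
            ds += s
            dn += n
        elif not polymorphism_precedence and len(distinct) > 1 and out not in distinct:
            s, n = path_counts(_parsimony_center(distinct), out)
            ds += s
            dn += n
    if stop_seen:
        warnings.warn("stop codon(s) in alignment; those columns were skipped", stacklevel=2)
    ni, p = neutrality_index(pn, ps, dn, ds)
    return MKTable(Pn=pn, Ps=ps, Dn=dn, Ds=ds, NI=ni, p_value=p, interpretation=_interpret(ni))


def _interpret(ni: float | None) -> str:
    if ni is None:
        return "undefined"
    if ni > 1:
        return "excess polymorphism (negative or balancing selection)"
    if ni < 1:
        return "excess divergence (positive selection)"
    return "neutral expectation"


def neutrality_index(
    Pn: float, Ps: float, Dn: float, Ds: float
) -> tuple[float | None, float | None]:
    """NI = (Pn/Ps)/(Dn/Ds) with a two-sided Fisher exact p-value.

    NI is undefined (None) when Ps or Dn is zero; the p-value is still
    computed whenever the 2x2 table [[Pn, Ps], [Dn, Ds]] is non-degenerate.
    Fractional pathway-averaged counts are rounded to integers for the
    exact test.
    """
    if min(Pn, Ps, Dn, Ds) < 0:
        raise ValueError("counts must be non-negative")
    ni = None
    if Ps > 0 and Dn > 0:
        ni = (Pn / Ps) / (Dn / Ds) if Ds > 0 else None
    table = [[int(round(Pn)), int(round(Ps))], [int(round(Dn)), int(round(Ds))]]
    p = None
    if (table[0][0] + table[0][1]) > 0 and (table[1][0] + table[1][1]) > 0:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return ni, p


def mk_test(aln: CodonAlignment) -> MKTable:
    """Full McDonald-Kreitman test on a codon alignment."""
    return count_poly_div(aln)


# ---------------------------------------------------------------------------
# neutral simulation (for calibration)
# ---------------------------------------------------------------------------


def simulate_neutral_alignment(
    n_codons: int = 150,
    n_ingroup: int = 6,
    poly_mutations: int = 12,
    div_mutations: int = 25,
    seed: int = 0,
) -> CodonAlignment:
    """Neutral star-genealogy alignment: every single-base mutation is
    accepted regardless of its coding effect, so Pn/Ps and Dn/Ds share the
    same expectation and NI centers on one.

    Polymorphic mutations each hit one random ingroup allele; divergent
    mutations accumulate on the outgroup lineage.  Mutations creating stop
    codons are redrawn (stop columns would be skipped by the counter).
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    sense = sorted(set(CODON_AA) - set(_STANDARD.stop_codons))
    ancestor = "".join(rng.choice(sense) for _ in range(n_codons))

    def mutate(seq: str) -> str:
        for _ in range(100):
            i = int(rng.integers(len(seq)))
            b = _BASES[int(rng.integers(4))]
            if b == seq[i]:
                continue
            new = seq[:i] + b + seq[i + 1 :]
            codon = new[3 * (i // 3) : 3 * (i // 3) + 3]
            if CODON_AA[codon] != "*":
                return new
        return seq

    ingroup = [ancestor] * n_ingroup
    for _ in range(poly_mutations):
        j = int(rng.integers(n_ingroup))
        ingroup[j] = mutate(ingroup[j])
    outgroup = ancestor
    for _ in range(div_mutations):
        outgroup = mutate(outgroup)
    return CodonAlignment(
        ingroup_ids=[f"allele{i + 1}" for i in range(n_ingroup)],
        ingroup_seqs=ingroup,
        outgroup_id="outgroup",
        outgroup_seq=outgroup,
    )
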