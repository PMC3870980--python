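# winemap

Genetical genomics of a wine-yeast segregant population, as a tested Python
library: simulation of a haploid wine × lab cross carrying a
translocation-derived partial disomy, expression and fermentation-trait
statistics, aCGH-style disomy detection, Haley–Knott QTL/eQTL genome scans
with permutation significance, a three-analysis design that bypasses the
confounding effect of the disomy, trans-eQTL hotspot detection, and
McDonald–Kreitman neutrality tests.

## The problem

Wine strains of *Saccharomyces cerevisiae* commonly carry a reciprocal 8–16
translocation that moves the left arm of chromosome 16 onto chromosome 8.
In a cross between a translocated wine strain and a normal laboratory
strain the two rearranged chromosomes segregate independently, producing
four spore classes: two parental-like classes with one copy of the arm, a
class with two copies (**partial disomy**), and a class with none, which
dies.  A third of viable segregants is therefore disomic: every gene on the
373-kbp arm is present at double dose in those spores, their transcripts
rise by ~1 log2 unit, and fermentation kinetics change.  For expression-QTL
mapping this segregating aneuploidy is a massive confounder — amplified
transcripts show spurious linkage to the markers tagging the duplication.

`winemap` implements the full analysis chain for such a population and, at
its core, the bypass design that separates dosage artifacts from genuine
regulatory variation:

1. **analysis 1** — all segregants, markers and transcripts;
2. **analysis 2** — non-disomic segregants only;
3. **analysis 3** — all segregants, with duplicated-region genotypes
   blanked for the disomic spores and disomy-responsive transcripts
   removed.

Each eQTL is labeled by the subset of analyses that detect it (its *Venn
group*): "123" marks robust linkages, "1" marks disomy artifacts.

Scans use Haley–Knott regression of the trait on conditional genotype
probabilities P(P1) at markers and pseudo-markers every 2.5 cM (Haldane
map function), with LOD = (n/2)·log₁₀(RSS₀/RSS₁).  Trait thresholds come
from 1000 permutations of the trait; transcriptome-wide FDR from 20
whole-matrix permutations, FDR(t) = mean null linked-transcript count /
observed count.  eQTLs within 40 kbp of their gene are *local* (cis),
others *distant* (trans); trans peaks are binned (50 kbp) and tested
against a Poisson null to call hotspots.  The McDonald–Kreitman module
counts Pn/Ps/Dn/Ds on codon alignments and reports the neutrality index
NI = (Pn/Ps)/(Dn/Ds) with Fisher exact significance.

## Worked example

```python
from winemap import simulate, cnv, eqtl

marker_map = simulate.simulate_marker_map(density_per_10kbp=1.81, seed=1)
genotypes, truth = simulate.simulate_cross(marker_map, n_segregants=44, seed=1)
matrix = simulate.simulate_expression(genotypes, truth, n_genes=1000, seed=1)

tracks, reference = simulate.simulate_probe_tracks(truth, genotypes.segregant_ids, seed=1)
disomic, calls = cnv.classify_segregants(tracks, reference)

analyses = eqtl.run_disomy_bypass(
    matrix, genotypes, disomic, truth.disomy_region,
    affected_genes=truth.dosage_genes, lod_threshold=4.0,
)
merged = eqtl.venn_classify(analyses)
hotspots = eqtl.detect_hotspots(merged)
```

Running the narrated version of this (`python examples/01_simulate_population.py`
and `python examples/03_disomy_calling.py`) prints:

```
marker map: 2184 markers, 1.81 markers / 10 kbp
segregant classes: {'translocated': 15, 'normal': 13, 'disomic': 16}
disomic fraction: 0.36 (expected 1/3 of viable spores)
...
truth: 5 disomic of 12; called disomic: 5; match: True
  seg001: chr16 0-378 kbp, copy number 2 (mean log2 ratio 0.98)
```

The map realizes the genome-wide density of 1.81 markers per 10 kbp over
the 12,071-kbp genome; roughly a third of viable spores carry the disomy;
and the aCGH-style caller recovers the planted 1–373 kbp amplification with
copy number 2 from probe signals with noise sd 0.3.  The other scripts in
`examples/` walk through trait QTL scans with permutation thresholds, the
disomy-bypass eQTL design, fermentation-kinetics traits and heritability,
and the McDonald–Kreitman test; each prints the numbers it computes and a
line on how to read them.

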