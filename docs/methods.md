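# Methods

`winemap` re-implements, as a tested library, the analysis chain of a
genetical-genomics study of a haploid yeast cross between a wine strain
(P1) and a laboratory strain (P2) phenotyped under wine-fermentation
conditions.  Because the original microarray and sequence data are not part
of the package, every stage is validated against synthetic data with known
truth; the generator is therefore a first-class module, not a fixture.

## The cross and the partial disomy

The wine parent carries a reciprocal 8–16 translocation that moved the left
arm of chromosome 16 (here modelled as positions 1–373 kbp) onto chromosome
8 (junction at 20 kbp).  Because chromosomes 8 and 16 segregate
independently, gametes fall into four equally likely classes: lab-like
(one arm, on chromosome 16), wine-like (one arm, riding on chromosome 8),
disomic (both), and a class with no copy of the arm, which is inviable
because the arm carries essential genes.  `simulate_cross` rejects and
redraws the inviable class, so the requested number of segregants is always
delivered and a third of the survivors is expected to be disomic.

Meiosis uses the Haldane map function, r = (1 − e^(−2d/100))/2 for a
distance of d cM, with no crossover interference — the same assumption the
interval-mapping regression makes.  Physical and genetic coordinates are
interconverted by a single genome-wide constant of 3 kbp/cM (so the
2.5-cM pseudo-marker step equals 7.5 kbp); a chromosome-specific
recombination map would be more realistic but adds nothing to what the
pipeline tests.  Structural class is read off the parental origin at the
marker nearest each junction.  Genotype calls are parental-origin codes
(P1/P2) with missing calls injected at a configurable rate (default 1%) to
exercise the genotype-probability code.  On the translocated arm the call
reflects the allele actually carried: P2 for normal spores, P1 for
translocated spores, and P1 for disomic spores — the wine allele is present
in the latter two, which is precisely why those calls are ambiguous for
disomics and why analysis 3 blanks them.

Defaults mirror the study population: 44 segregants, 16 chromosomes
totalling 12,071 kbp, marker density 1.81 per 10 kbp (≈2,186 markers), a
373-kbp amplified arm present in about a third of segregants.

## Synthetic expression, traits and probe tracks

`simulate_expression` scatters genes across chromosomes proportionally to
length and plants three kinds of structure on a baseline of i.i.d. Gaussian
noise (default sd 0.1 log2 units): cis eQTLs (effect at the marker nearest
the gene), trans eQTLs (effect at a random marker on another chromosome),
and gene dosage — every gene inside the amplified region gains
`dosage_log2` (default 1.0 = log2 of a doubled copy number) in disomic
segregants.  Regulatory eQTLs are planted only outside the amplified
region, so dosage-driven and sequence-driven signal stay separable and the
bypass analyses can be validated against an unambiguous truth.

`simulate_traits` builds a polygenic trait as a sum of additive marker
effects and sets the environmental variance from the realized genetic
variance so that the expected broad-sense heritability
H² = 100·(Var_seg − Var_env)/Var_seg equals the target; parental replicate
measurements (default four per parent, matching the replication scheme the
H² estimator assumes) share the same noise variance.  When a disomy
segregates, a second trait — the disomy indicator plus noise — mimics the
fermentation-rate phenotype and shows the characteristic bimodal
distribution.

`simulate_probe_tracks` lays probes on an even grid (default 15 per
10 kbp), adds the dosage gain inside the amplified region for disomic
segregants, and draws i.i.d. Gaussian probe noise (default sd 0.3,
representative of single-array log-signal scatter); the euploid reference
track carries its own noise.

What the generator does **not** emulate: linkage disequilibrium decay
beyond the Haldane model, array spatial artifacts, intensity-dependent
(banana-shaped) bias, probe GC effects, batch structure, correlated
residual expression, or segregation distortion away from the translocation.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated model, not robustness to every artifact of real
arrays.

## Expression and trait statistics

- **Quantile normalization** replaces each sample's values by the mean of
  the per-rank values across samples, preserving within-sample ranks; it is
  idempotent and leaves identical columns untouched.
- **Differential expression** is a per-gene two-sample t test on log2
  values with Benjamini–Hochberg adjustment; a gene is called when
  adjPv < 0.01 and |logFC| > 0.7 (both configurable).  The default
  estimator is Welch's t; a variance-moderated mode (per-gene variances
  shrunk toward the genome-wide mean with a prior of 4 df) is available for
  very small groups.
- **Heritability** is 100·(Var_seg − Var_env)/Var_seg with Var_env pooled
  over the two parents' replicate variances.  Negative estimates are
  returned with a warning rather than clipped: they flag traits whose
  measurement noise swamps genetic signal.  Downstream filtering treats
  50% as the usual lower bound for a usable trait.
- **Kinetics**: cumulative CO2 curves are resampled to a uniform grid and
  smoothed with a Savitzky–Golay local polynomial (window 11 points,
  degree 3).  Rmax is the maximum smoothed release rate; R70 the rate at
  the first crossing of 70% of total release (66 g/l for a 94.3 g/l
  fermentation); the lag ends when the rate first exceeds 5% of Rmax (the
  5% rule is a package choice; any small fraction works).
- **Clustering** uses complete linkage on centered-Pearson distance 1 − r.
  The correlation cutoff is calibrated under a per-gene permutation null
  (default 10 rounds): the smallest r for which fewer than three chance
  clusters of size ≥ 2 are expected.  Complete linkage cut at distance
  1 − r guarantees the all-pairwise rule inside every reported cluster.
  Note the calibration bounds the *expected* number of chance clusters by
  three; it does not make noise-only clusterings empty.

## Disomy detection from probe signals

Sample-minus-reference log ratios are smoothed with a 200-probe moving
average, centered and truncated at chromosome edges, never crossing a
chromosome boundary.  Maximal runs where the smoothed ratio exceeds half
the expected gain (0.5 × 1.0 log2 by default) and spanning ≥ 50 kbp are
reported; boundaries are the interpolated half-gain crossings and the copy
number is round(2^mean-ratio × base ploidy), with haploid base ploidy by
default (set 2 for trisomy calling in diploids).  The 50-kbp minimum
length suppresses noise runs; at the default probe density and noise the
smoothed null ratio has sd ≈ 0.03, so false segments are essentially
impossible while boundary error stays within a few kbp.  When no euploid
control is available, the per-probe median across samples serves as a
pseudo-reference (valid while amplified samples are a minority).

## Linkage mapping

Genotype probabilities P(P1) are computed on a grid of markers plus
pseudo-markers every 2.5 cM, conditioning each locus on the nearest
non-missing flanking markers under Haldane recombination; past the
outermost informative marker a single flank conditions the locus, and a
chromosome with no informative marker yields 0.5 everywhere.  A genotyping
error rate e (default 0) shrinks probabilities toward 0.5 by 1 − 2e.

Haley–Knott regression of the trait on P(P1) gives
LOD = (n/2)·log10(RSS0/RSS1), computed through the squared
trait–probability correlation; RSS1 is floored at 1e-12·RSS0 because
perfect fits occur in small haploid panels.  At fully informative markers
this is exactly the two-group least-squares likelihood ratio (tested to
1e-9 against an explicit OLS oracle).

Significance: for single traits, the genome-wide maximum-LOD null
distribution from 1000 trait permutations, thresholded at the 95% quantile
for a 5% genome-wide error rate.  For the transcriptome, 20 permutation
rounds each apply one shared segregant shuffle to the whole matrix
(preserving transcript–transcript correlation), and
FDR(t) = mean null linked-transcript count / observed count; the working
threshold is the smallest grid LOD with FDR at or below the target.
Transcripts, not linkage records, are counted.  Support intervals are
1-LOD drops around the peak, one linkage per chromosome per trait, leftmost
peak on ties.  Missing trait values are dropped pairwise.

## The three-analysis bypass, Venn groups and hotspots

Analysis 1 scans everything; analysis 2 only the non-disomic segregants;
analysis 3 all segregants with duplicated-region genotypes blanked *for the
disomic segregants only* (their calls there are ambiguous, the normals'
remain informative) and disomy-responsive transcripts excluded.  Records
from different analyses merge when transcript, peak chromosome and
overlapping support intervals agree — exact peak equality is too strict
because the pseudo-marker grid and the segregant subset differ between
analyses.  The merged record keeps the analysis-1 peak when available
(else 3, else 2) and is labeled by the set of analyses that found it
("123", "13", ...).  An eQTL is local (cis) when its peak lies within
40 kbp of the gene start on the same chromosome; distances use 1-based kbp
and the annotated gene start.

Hotspots: trans-eQTL peaks are binned in 50-kbp bins; under uniform
scatter the per-bin count is Poisson(total/bins), and bins above the
1 − 0.001 quantile are significant, adjacent significant bins merging into
one hotspot.  The rule (bin size, Poisson null, alpha) is this package's
own; hotspot reporting in the source analysis had no stated threshold.

## McDonald–Kreitman test

Counting is codon-by-codon on an alignment of ≥2 ingroup alleles plus one
outgroup (standard nuclear code only).  Codons with gaps, ambiguity or
stops are skipped.  Segregating codons contribute to Pn/Ps, each scored
against the parsimony center of the distinct-allele set — a
frequency-independent choice, so duplicated alleles never change the
counts.  Ingroup-monomorphic codons differing from the outgroup contribute
to Dn/Ds.  Codons differing at multiple positions are averaged over all
shortest mutational pathways, excluding pathways through stop codons unless
all pass through one.  Columns both polymorphic and divergent count as
polymorphic only (the ingroup is not fixed there); a switch restores
divergence counting for such columns.  NI = (Pn/Ps)/(Dn/Ds); the p-value
is a two-sided Fisher exact test on [[Pn, Ps], [Dn, Ds]] with
pathway-averaged counts rounded to integers.

## Problem sizes and numerical choices

Test and acceptance runs use the study-scale population (44 segregants,
full 2,186-marker map) where the quantity under test depends on it — FDR
calibration, disomy calling — and deliberately smaller maps or populations
where it does not (heritability recovery uses a two-chromosome map at
n = 200 with 1000 replicates; the bypass demonstration uses 120 segregants
and a 0.3 markers/10 kbp map so the planted contrast is unambiguous at a
LOD-4 threshold).  All generators take explicit seeds and draw from
per-operation RNG substreams, so any artifact can be regenerated
independently of call order.

## Known limitations

- Single-QTL scans only: no multiple-QTL models, composite interval
  mapping or epistasis.
- One linkage per chromosome per trait; multi-peak chromosomes keep only
  the strongest peak.
- The disomy caller does binary gain detection with a fixed expected gain;
  it is not a general segmentation (no HMM or circular binary
  segmentation) and reports no base-pair-resolution breakpoints.
- MK counting has no polarization against multiple outgroups and no
  adaptive-substitution (alpha) estimators.
- The permutation "FDR 0.05" threshold for single traits is a genome-wide
  error-rate quantile, as is conventional for one-trait scans.
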