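"""The three-analysis disomy-bypass eQTL design with Venn classification.

A segregating partial disomy doubles the dose of every gene it covers, so
those transcripts show spurious linkage to the markers tagging the
duplication.  Analysis 1 scans everything; analysis 2 drops the disomic
segregants; analysis 3 blanks their duplicated-region genotypes and
excludes disomy-responsive transcripts.  Genuine eQTLs survive all three
(Venn group 123); disomy artifacts are confined to analysis 1.
"""

from collections import Counter

from winemap import cnv, eqtl, simulate

marker_map = simulate.simulate_marker_map(density_per_10kbp=0.3, seed=4)
genotypes, truth = simulate.simulate_cross(marker_map, n_segregants=120, seed=4)
matrix = simulate.simulate_expression(
    genotypes, truth, n_genes=150, cis_frac=0.1, trans_frac=0.05,
    effect_size_log2=1.2, dosage_log2=1.0, noise_sd=0.1, seed=4,
)

normal = [s for s in genotypes.segregant_ids if s not in truth.disomic_segregants]
inside_up, outside = cnv.disomy_affected_transcripts(
    matrix, sorted(truth.disomic_segregants), normal, region=truth.disomy_region
)
print(f"disomy-affected transcripts: {len(inside_up)} up inside the region, "
      f"{len(outside)} deregulated elsewhere")

analyses = eqtl.run_disomy_bypass(
    matrix, genotypes, truth.disomic_segregants, truth.disomy_region,
    inside_up | outside, lod_threshold=4.0, seed=4,
)
for a, recs in sorted(analyses.items()):
    print(f"analysis {a}: {len(recs)} linkages "
          f"({sum(r.local_flag == 'cis' for r in recs)} cis)")

merged = eqtl.venn_classify(analyses)
print("Venn groups:", dict(Counter(r.venn_group for r in merged)))
hotspots = eqtl.detect_hotspots(merged)
for h in hotspots:
    print(f"  hotspot chr{h.chrom}:{h.start_kbp:.0f}-{h.end_kbp:.0f} kbp, "
          f"{h.count} trans-eQTLs")
eqtl.write_results(merged, hotspots, "eqtl_results")
print("groups confined to '1' are disomy artifacts; '123' marks robust eQTLs; "
      "results written to eqtl_results/")
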