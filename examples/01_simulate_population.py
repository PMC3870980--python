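"""Simulate a wine x lab segregant population with the 8-16 translocation.

Builds a genome-wide marker map, draws 44 viable haploid segregants, and
prints the composition of the population.  About a third of viable spores
carry two copies of the chromosome-16 left arm (partial disomy) because the
class with no copy is inviable.
"""

from collections import Counter

from winemap import genome, io, simulate

marker_map = simulate.simulate_marker_map(density_per_10kbp=1.81, seed=1)
print(f"marker map: {marker_map.n_markers} markers, "
      f"{genome.marker_density(marker_map.n_markers):.2f} markers / 10 kbp")

genotypes, truth = simulate.simulate_cross(marker_map, n_segregants=44, seed=1)
counts = Counter(truth.labels.values())
print("segregant classes:", dict(counts))
print(f"disomic fraction: {counts['disomic'] / 44:.2f} (expected 1/3 of viable spores)")

io.write_marker_map(marker_map, "marker_map.tsv")
io.write_genotypes(genotypes, "genotypes.tsv")
print("wrote marker_map.tsv and genotypes.tsv")
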