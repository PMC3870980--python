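"""McDonald-Kreitman test on a codon alignment.

Counts non-synonymous and synonymous changes segregating within the ingroup
(Pn, Ps) and fixed against the outgroup (Dn, Ds), and reports the
neutrality index NI = (Pn/Ps)/(Dn/Ds) with a Fisher exact p-value.  A
neutral simulation shows NI centering on one; an excess of amino-acid
polymorphism pushes NI above one.
"""

import numpy as np

from winemap import mk

aln = mk.simulate_neutral_alignment(n_codons=300, n_ingroup=8,
                                    poly_mutations=30, div_mutations=60, seed=6)
t = mk.mk_test(aln)
print(f"neutral gene: Pn={t.Pn:.1f} Ps={t.Ps:.1f} Dn={t.Dn:.1f} Ds={t.Ds:.1f} "
      f"NI={t.NI:.2f} (p={t.p_value:.2f}) -> {t.interpretation}")

nis = []
for s in range(200):
    r = mk.mk_test(mk.simulate_neutral_alignment(seed=s))
    if r.NI is not None:
        nis.append(r.NI)
print(f"median NI over {len(nis)} neutral genes: {np.median(nis):.2f} (expected 1)")

# reading a real alignment instead:
#   aln = mk.CodonAlignment.from_fasta("war1_alleles.fa", outgroup="S_paradoxus")
#   print(mk.mk_test(aln))
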