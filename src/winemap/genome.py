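"""Genome constants for the Saccharomyces cerevisiae nuclear genome.

Chromosome sizes are rounded to the kilobase and are used for marker-map
simulation, gene placement, and hotspot binning.  Physical and genetic
coordinates are interconverted with a single genome-wide constant of
3 kbp per centimorgan (the average relation in laboratory yeast crosses).
"""

from __future__ import annotations

import numpy as np

#: Chromosome lengths in kbp (chromosomes I..XVI), total 12,071 kbp.
CHROM_LENGTHS_KBP: dict[int, float] = {
    1: 230.0,
    2: 813.0,
    3: 317.0,
    4: 1532.0,
    5: 577.0,
    6: 270.0,
    7: 1091.0,
    8: 563.0,
    9: 440.0,
    10: 746.0,
    11: 667.0,
    12: 1078.0,
    13: 924.0,
    14: 784.0,
    15: 1091.0,
    16: 948.0,
}

TOTAL_KBP: float = float(sum(CHROM_LENGTHS_KBP.values()))

#: Fixed physical-to-genetic conversion: 2.5 cM corresponds to 7.5 kbp.
KBP_PER_CM: float = 3.0


def kbp_to_cm(pos_kbp):
    """Convert physical position (kbp) to genetic position (cM)."""
    return np.asarray(pos_kbp, dtype=float) / KBP_PER_CM


def cm_to_kbp(pos_cm):
    """Convert genetic position (cM) to physical position (kbp)."""
    return np.asarray(pos_cm, dtype=float) * KBP_PER_CM


def marker_density(n_markers: int, total_kbp: float = TOTAL_KBP) -> float:
    """Average marker density in markers per 10 kbp."""
    if total_kbp <= 0:
        raise ValueError("total_kbp must be positive")
    return n_markers / (total_kbp / 10.0)


def haldane_r(d_cM):
    """Haldane recombination fraction for a genetic distance of ``d_cM``.

    r = (1 - exp(-2 d / 100)) / 2; no crossover interference is assumed.
    """
    return 0.5 * (1.0 - np.exp(-0.02 * np.asarray(d_cM, dtype=float)))
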