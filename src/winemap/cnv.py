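"""Segmental-amplification (partial disomy) detection from probe-level signals.

The detector mimics an array-CGH workflow: per-probe log ratios between a
sample and a euploid reference are smoothed with a 200-probe moving average
within each chromosome, and maximal runs of elevated smoothed ratio are
reported as amplified segments.  On a haploid base ploidy a single extra
copy of a segment doubles the dose, i.e. a log2 ratio of 1.0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class ProbeTrack:
    """Ordered probe-level log signal for one sample.

    ``probes`` holds columns ``probe_id``, ``chrom``, ``pos_kbp`` in genome
    order; ``log_signal`` is one value per probe.
    """

    probes: pd.DataFrame
    log_signal: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.log_signal = np.asarray(self.log_signal, dtype=float)
        if len(self.probes) != len(self.log_signal):
            raise ValueError("probe table and signal length differ")
        if not np.all(np.isfinite(self.log_signal)):
            raise ValueError("probe signals must be finite")
        chrom = self.probes["chrom"].to_numpy()
        pos = self.probes["pos_kbp"].to_numpy(dtype=float)
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"probes not sorted within chromosome {c}")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("probes not in genome order")

    def same_grid(self, other: "ProbeTrack") -> bool:
        return (
            len(self.probes) == len(other.probes)
            and np.array_equal(self.probes["chrom"].to_numpy(), other.probes["chrom"].to_numpy())
            and np.allclose(
                self.probes["pos_kbp"].to_numpy(dtype=float),
                other.probes["pos_kbp"].to_numpy(dtype=float),
            )
        )


@dataclasses.dataclass
class DisomyCall:
    """One amplified segment in one segregant."""

    segregant_id: str
    chromosome: int
    start_kbp: float
    end_kbp: float
    copy_number: int
    mean_log2_ratio: float

    def __post_init__(self):
        if not self.start_kbp < self.end_kbp:
            raise ValueError("segment start must precede its end")

    @property
    def length_kbp(self) -> float:
        return self.end_kbp - self.start_kbp


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window is truncated at the edges."""
    n = len(x)
    half = window // 2
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + (window - half))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_signal(track: ProbeTrack, window: int = 200) -> ProbeTrack:
    """Moving average over ``window`` probes, computed within each chromosome.

    Edge probes use a truncated window; signal never mixes across
    chromosome boundaries.  ``window`` must not exceed the probe count of
    any chromosome present in the track.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    chrom = track.probes["chrom"].to_numpy()
    out = np.empty_like(track.log_signal)
    for c in np.unique(chrom):
        sel = chrom == c
        n = int(sel.sum())
        if window > n:
            raise ValueError(f"window {window} exceeds probe count {n} on chromosome {c}")
        out[sel] = _moving_average(track.log_signal[sel], window)
    return ProbeTrack(track.probes, out, sample_id=track.sample_id)


def _crossing(pos: np.ndarray, val: np.ndarray, i: int, j: int, thr: float) -> float:
    """Linear interpolation of the position where ``val`` crosses ``thr``
    between probe indices i and j."""
    if val[j] == val[i]:
        return float(pos[j])
    f = (thr - val[i]) / (val[j] - val[i])
    return float(pos[i] + f * (pos[j] - pos[i]))


def call_disomy(
    sample: ProbeTrack,
    reference: ProbeTrack,
    gain_log2: float = 1.0,
    call_fraction: float = 0.5,
    min_length_kbp: float = 50.0,
    window: int = 200,
    base_ploidy: int = 1,
) -> list[DisomyCall]:
    """Call amplified segments from sample-vs-reference probe log ratios.

    The per-probe log ratio (sample minus reference) is smoothed over
    ``window`` probes; maximal runs where the smoothed ratio exceeds
    ``call_fraction * gain_log2`` and spanning at least ``min_length_kbp``
    are emitted.  Segment boundaries are placed at the half-gain crossings
    of the smoothed ratio, and the copy number is
    ``round(2**mean_ratio * base_ploidy)``.
    """
    if not sample.same_grid(reference):
        raise ValueError("sample and reference probe grids differ")
    ratio = ProbeTrack(
        sample.probes, sample.log_signal - reference.log_signal, sample_id=sample.sample_id
    )
    sm = smooth_signal(ratio, window=window)
    thr = call_fraction * gain_log2

    calls: list[DisomyCall] = []
    chrom = sample.probes["chrom"].to_numpy()
    pos_all = sample.probes["pos_kbp"].to_numpy(dtype=float)
    for c in np.unique(chrom):
        sel = chrom == c
        pos = pos_all[sel]
        s = sm.log_signal[sel]
        raw = ratio.log_signal[sel]
        above = s > thr
        if not above.any():
            continue
        # maximal runs of probes above threshold
        edges = np.flatnonzero(np.diff(above.astype(int)))
        starts = [0] if above[0] else []
        starts += [e + 1 for e in edges if above[e + 1]]
        ends = [e for e in edges if above[e]]
        if above[-1]:
            ends.append(len(s) - 1)
        for i0, i1 in zip(starts, ends):
            start = _crossing(pos, s, i0 - 1, i0, thr) if i0 > 0 else float(pos[0])
            end = _crossing(pos, s, i1, i1 + 1, thr) if i1 < len(s) - 1 else float(pos[-1])
            if end - start < min_length_kbp:
                continue
            mean_ratio = float(np.mean(raw[i0 : i1 + 1]))
            copy = int(round(2.0**mean_ratio * base_ploidy))
            calls.append(
                DisomyCall(
                    segregant_id=sample.sample_id,
                    chromosome=int(c),
                    start_kbp=start,
                    end_kbp=end,
                    copy_number=copy,
                    mean_log2_ratio=mean_ratio,
                )
            )
    return calls


def median_reference(tracks: list[ProbeTrack]) -> ProbeTrack:
    """Per-probe median of a set of tracks, usable as a pseudo-reference
    when no explicit euploid control is available.

    Valid while amplified segregants remain a minority at every probe.
    """
    if not tracks:
        raise ValueError("need at least one track")
    for t in tracks[1:]:
        if not t.same_grid(tracks[0]):
            raise ValueError("tracks do not share a probe grid")
    sig = np.median(np.vstack([t.log_signal for t in tracks]), axis=0)
    return ProbeTrack(tracks[0].probes, sig, sample_id="median_reference")


def classify_segregants(
    tracks: dict[str, ProbeTrack],
    reference: ProbeTrack | None = None,
    **call_kwargs,
) -> tuple[set[str], list[DisomyCall]]:
    """Call disomy for every segregant and return (disomic ids, all calls)."""
    if reference is None:
        reference = median_reference(list(tracks.values()))
    calls: list[DisomyCall] = []
    disomic: set[str] = set()
    for sid, track in tracks.items():
        c = call_disomy(track, reference, **call_kwargs)
        for rec in c:
            rec.segregant_id = sid
        if c:
            disomic.add(sid)
        calls.extend(c)
    return disomic, calls


def disomy_affected_transcripts(
    matrix,
    disomic: list[str],
    normal: list[str],
    region: tuple[int, float, float] | None = None,
    alpha: float = 0.05,
    alpha_genome: float = 0.01,
) -> tuple[set[str], set[str]]:
    """Genes whose expression responds to the disomy.

    Runs a disomic-vs-normal differential-expression test across the whole
    matrix (BH-adjusted genome wide) and reports two sets: genes inside the
    amplified ``region`` that are up-regulated at ``alpha``, and genes
    outside the region deregulated (either direction) at ``alpha_genome``.
    """
    from .traits import differential_expression

    de = differential_expression(
        matrix, list(disomic), list(normal), alpha=alpha, fc_threshold=0.0
    )
    annot = matrix.gene_annot
    if region is None:
        in_region = pd.Series(False, index=de.index)
    else:
        chrom, start, end = region
        in_region = (annot["chrom"] == chrom) & annot["pos_kbp"].between(start, end)
        in_region = in_region.reindex(de.index, fill_value=False)
    inside_up = set(de.index[in_region & (de["adjPv"] < alpha) & (de["logFC"] > 0)])
    outside = set(de.index[~in_region & (de["adjPv"] < alpha_genome)])
    return inside_up, outside
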