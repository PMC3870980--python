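"""Tab-separated readers and writers for every pipeline artifact.

All files carry a single header line; physical positions are 1-based kbp.
Genotype calls serialize as P1/P2/NA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import DisomyCall, ProbeTrack
from .simulate import (
    MISSING,
    P1,
    P2,
    ExpressionMatrix,
    GenotypeMatrix,
    MarkerMap,
    TraitTable,
)

_CALL_TO_STR = {P1: "P1", P2: "P2", MISSING: "NA"}
_STR_TO_CALL = {"P1": P1, "P2": P2, "NA": MISSING}


# -- marker map -------------------------------------------------------------


def write_marker_map(mm: MarkerMap, path: str | Path) -> None:
    mm.table.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


# -- genotypes --------------------------------------------------------------


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        np.vectorize(_CALL_TO_STR.get)(gm.calls),
        index=gm.map.table["marker_id"],
        columns=gm.segregant_ids,
    )
    df.index.name = "marker_id"
    df.to_csv(path, sep="\t")


def read_genotypes(path: str | Path, marker_map: MarkerMap) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="marker_id", keep_default_na=False)
    df = df.loc[marker_map.table["marker_id"]]
    calls = np.vectorize(_STR_TO_CALL.get)(df.to_numpy()).astype(np.int8)
    return GenotypeMatrix(marker_map, calls, list(df.columns))


# -- expression -------------------------------------------------------------


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(em.values, index=em.gene_ids, columns=em.sample_ids)
    df.insert(0, "pos_kbp", em.gene_annot["pos_kbp"].to_numpy())
    df.insert(0, "chrom", em.gene_annot["chrom"].to_numpy())
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    annot = df[["chrom", "pos_kbp"]].copy()
    values = df.drop(columns=["chrom", "pos_kbp"])
    return ExpressionMatrix(
        values.to_numpy(dtype=float), list(df.index), annot, list(values.columns)
    )


# -- traits -----------------------------------------------------------------


def write_traits(tt: TraitTable, path: str | Path) -> None:
    """Segregant and parental values in one long-format table.

    Columns: sample, role (segregant|parent_P1|parent_P2), trait, value."""
    rows = []
    for trait in tt.segregants.columns:
        for sid, val in tt.segregants[trait].items():
            rows.append((sid, "segregant", trait, val))
        for parent, reps in tt.parental.get(trait, {}).items():
            for i, val in enumerate(reps, start=1):
                rows.append((f"{parent}_rep{i}", f"parent_{parent}", trait, val))
    pd.DataFrame(rows, columns=["sample", "role", "trait", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t")
    seg = df[df["role"] == "segregant"].pivot(index="sample", columns="trait", values="value")
    seg.columns.name = None
    seg.index.name = None
    parental: dict[str, dict[str, np.ndarray]] = {}
    for trait in seg.columns:
        parental[trait] = {}
        for parent in ("P1", "P2"):
            sel = df[(df["role"] == f"parent_{parent}") & (df["trait"] == trait)]
            if len(sel):
                parental[trait][parent] = sel["value"].to_numpy(dtype=float)
    return TraitTable(seg, parental)


# -- probe tracks and disomy calls ------------------------------------------


def write_probe_track(track: ProbeTrack, path: str | Path) -> None:
    df = track.probes.copy()
    df["log_signal"] = track.log_signal
    df.to_csv(path, sep="\t", index=False)


def read_probe_track(path: str | Path, sample_id: str = "") -> ProbeTrack:
    df = pd.read_csv(path, sep="\t")
    return ProbeTrack(
        df[["probe_id", "chrom", "pos_kbp"]], df["log_signal"].to_numpy(dtype=float), sample_id
    )


def write_disomy_calls(calls: list[DisomyCall], path: str | Path) -> None:
    """BED-like TSV: chrom, start_kbp, end_kbp, segregant, copy_number, mean_ratio."""
    rows = [
        (c.chromosome, c.start_kbp, c.end_kbp, c.segregant_id, c.copy_number, c.mean_log2_ratio)
        for c in sorted(calls, key=lambda c: (c.chromosome, c.start_kbp, c.segregant_id))
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start_kbp", "end_kbp", "segregant", "copy_number", "mean_ratio"]
    ).to_csv(path, sep="\t", index=False)


# -- kinetics ---------------------------------------------------------------


def read_kinetic_curve(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column TSV (time_h, co2_g_per_l)."""
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)


def write_lod_profile(profile, path: str | Path) -> None:
    df = profile.grid[["chrom", "pos_kbp"]].copy()
    df.insert(0, "trait", profile.trait)
    df["lod"] = profile.lod
    df.to_csv(path, sep="\t", index=False)
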