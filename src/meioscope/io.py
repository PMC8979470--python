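"""Readers and writers for the pipeline's tabular formats.

Internal coordinates are 1-based inclusive (matching VCF-style inputs
upstream); BED export converts to 0-based half-open flanking intervals.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .calling import ChromatidGenotype, CrossoverEvent, events_to_frame
from .geometry import ArmGeometry

__all__ = [
    "read_genotype_table", "write_genotype_table",
    "write_events", "read_events",
    "read_class_counts", "write_class_counts",
    "load_arm_geometries", "load_yakuba_table1",
]

GENOTYPE_COLUMNS = ["chromatid_id", "arm", "pos", "parent"]


def read_genotype_table(path) -> list[ChromatidGenotype]:
    """Read a genotype TSV (``chromatid_id, arm, pos, parent``) into grouped,
    validated per-chromatid streams."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chromatid_id": str, "arm": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty genotype table {path}", stacklevel=2)
        return []
    if list(df.columns) != GENOTYPE_COLUMNS:
        raise ValueError(f"expected columns {GENOTYPE_COLUMNS}, "
                         f"got {list(df.columns)}")
    if df.empty:
        warnings.warn(f"genotype table {path} has no rows", stacklevel=2)
        return []
    bad = ~df["parent"].isin(("A", "B"))
    if bad.any():
        line = int(df.index[bad][0]) + 2   # 1-based, after header
        raise ValueError(f"unknown parent label {df.loc[bad, 'parent'].iloc[0]!r} "
                         f"at line {line} of {path}")
    dup = df.duplicated(subset=["chromatid_id", "arm", "pos"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"duplicate (chromatid, arm, pos) at line {line} of {path}")
    out = []
    for (cid, arm), grp in df.groupby(["chromatid_id", "arm"], sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) < 0):
            k = int(np.flatnonzero(np.diff(pos) < 0)[0]) + 1
            line = int(grp.index[k]) + 2
            raise ValueError(f"positions not sorted for chromatid {cid!r} arm "
                             f"{arm!r} at line {line} of {path}")
        out.append(ChromatidGenotype(cid, arm, pos,
                                     grp["parent"].to_numpy()))
    return out


def write_genotype_table(genotypes, path) -> None:
    if isinstance(genotypes, pd.DataFrame):
        df = genotypes[GENOTYPE_COLUMNS]
    else:
        df = pd.concat(
            [pd.DataFrame({"chromatid_id": g.chromatid_id, "arm": g.arm,
                           "pos": g.positions, "parent": g.parents})
             for g in genotypes],
            ignore_index=True) if genotypes else pd.DataFrame(
                columns=GENOTYPE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_events(events, path, format: str = "tsv") -> None:
    """Write crossover events.

    ``tsv`` keeps 1-based point positions; ``bed`` writes the flanking
    diagnostic-SNP interval 0-based half-open
    (``arm, flank_left - 1, flank_right, chromatid_id, position``).
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "bed":
        bed = pd.DataFrame({
            "arm": df["arm"],
            "start": df["flank_left"] - 1,
            "end": df["flank_right"],
            "chromatid_id": df["chromatid_id"],
            "position": df["position"],
        })
        bed.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown event format {format!r}")


def read_events(path, format: str = "tsv") -> list[CrossoverEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chromatid_id": str, "arm": str})
    if format == "bed":
        df = pd.DataFrame({
            "chromatid_id": df["chromatid_id"], "arm": df["arm"],
            "position": df["position"],
            "flank_left": df["start"] + 1, "flank_right": df["end"],
        })
    return [CrossoverEvent(chromatid_id=r.chromatid_id, arm=r.arm,
                           position=int(r.position),
                           flank_left=int(r.flank_left),
                           flank_right=int(r.flank_right))
            for r in df.itertuples()]


def read_class_counts(path) -> pd.DataFrame:
    """Class-count TSV (``arm, n0..n4``), one row per arm, indexed by arm."""
    df = pd.read_csv(path, sep="\t", dtype={"arm": str}).set_index("arm")
    cols = sorted((c for c in df.columns
                   if c.startswith("n") and c[1:].isdigit()),
                  key=lambda c: int(c[1:]))
    if not cols:
        raise ValueError(f"no class-count columns in {path}")
    return df[cols]


def write_class_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def load_arm_geometries(path) -> list[ArmGeometry]:
    """Arm geometry YAML: a list of mappings with name/length/detectable
    interval/centromere side."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return [ArmGeometry.from_dict(d) for d in spec]


def load_yakuba_table1() -> pd.DataFrame:
    """Bundled observed chromatid crossover-class counts for the five
    *D. yakuba* chromosome arms (X, 2L, 2R, 3L, 3R)."""
    with resources.files("meioscope.data").joinpath(
            "yakuba_table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"arm": str}).set_index("arm")
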