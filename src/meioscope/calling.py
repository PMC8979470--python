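"""Crossover calling from per-chromatid diagnostic-SNP genotype streams.

A recovered F2 chromatid is observed as an ordered sequence of diagnostic-SNP
calls, each assigned to one parental genome.  Crossovers appear as switches in
the parent-of-origin label.  The filter cascade applied before calling:

1. arms with fewer than ``min_snps`` diagnostic SNPs are rejected;
2. 100-kb windows (25-kb step) with a strongly biased A:B call ratio
   (< 0.1 or > 10, computed from calls pooled across chromatids) are masked;
3. parent-label runs ("blocks") spanning less than ``min_block`` bp are
   removed and their flanks merged (suppressing gene-conversion-like tracts);
4. events closer than ``min_sep`` bp are resolved by deleting the enclosed
   block together with both boundary events and re-merging.

Each surviving block boundary yields one crossover event with a point
position drawn uniformly (seeded per chromatid) inside the flanking
inter-SNP gap.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ChromatidGenotype", "Block", "CrossoverEvent", "compute_bias_mask",
    "filter_and_mask", "call_crossovers", "call_dataset",
    "summarize_classes", "summarize_class_table", "events_to_frame",
]

PARENTS = ("A", "B")


@dataclass
class ChromatidGenotype:
    """Ordered diagnostic-SNP calls of one chromatid on one arm."""

    chromatid_id: str
    arm: str
    positions: np.ndarray
    parents: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.parents = np.asarray(self.parents)
        if self.positions.shape != self.parents.shape:
            raise ValueError("positions and parents must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            bad = int(np.flatnonzero(np.diff(self.positions) <= 0)[0]) + 1
            raise ValueError(
                f"positions not strictly increasing for chromatid "
                f"{self.chromatid_id!r} arm {self.arm!r} at call index {bad} "
                f"(pos {self.positions[bad]})")
        if not set(np.unique(self.parents)) <= set(PARENTS):
            raise ValueError(f"unknown parent label in chromatid "
                             f"{self.chromatid_id!r}; expected A or B")

    @property
    def n_snps(self) -> int:
        return int(self.positions.size)


@dataclass
class Block:
    """A run of consecutive diagnostic SNPs mapping to one parent."""

    arm: str
    start: int
    end: int
    parent: str
    n_snps: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class CrossoverEvent:
    """A called crossover with its flanking diagnostic-SNP interval."""

    chromatid_id: str
    arm: str
    position: int
    flank_left: int
    flank_right: int

    def __post_init__(self) -> None:
        if not (self.flank_left < self.position <= self.flank_right):
            raise ValueError("event position must lie in (flank_left, flank_right]")


# ---------------------------------------------------------------------------
# filtering


def compute_bias_mask(genotypes, window: int = 100_000, step: int = 25_000,
                      ratio_lo: float = 0.1, ratio_hi: float = 10.0) -> dict:
    """Identify windows with a strongly biased A:B call ratio.

    Calls are pooled across all supplied chromatids per arm (a single
    chromatid is legitimately single-parent over megabases; systematic
    mapping bias only shows up in the pooled counts).  Returns
    ``{arm: [(start, end), ...]}`` of merged masked intervals, windows
    half-open ``[s, s + window)`` anchored at the arm origin.
    """
    pooled: dict[str, list] = {}
    for g in genotypes:
        pooled.setdefault(g.arm, []).append(g)
    mask: dict[str, list[tuple[int, int]]] = {}
    for arm, gs in pooled.items():
        pos = np.concatenate([g.positions for g in gs])
        is_a = np.concatenate([g.parents == "A" for g in gs])
        order = np.argsort(pos, kind="stable")
        pos, is_a = pos[order], is_a[order]
        cum_a = np.concatenate([[0], np.cumsum(is_a)])
        last = int(pos[-1]) if pos.size else 0
        intervals = []
        start = 0
        while start <= last:
            i = np.searchsorted(pos, start, side="left")
            j = np.searchsorted(pos, start + window, side="left")
            n_a = cum_a[j] - cum_a[i]
            n_b = (j - i) - n_a
            if (j - i) > 0:
                biased = (n_b == 0 and n_a > 0) or (
                    n_b > 0 and not (ratio_lo <= n_a / n_b <= ratio_hi))
                if biased:
                    intervals.append((start, start + window))
            start += step
        mask[arm] = _merge_intervals(intervals)
    return mask


def _merge_intervals(intervals):
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def filter_and_mask(g: ChromatidGenotype, min_snps: int = 100,
                    mask: dict | None = None):
    """Apply the per-arm SNP-count filter and the bias mask to one chromatid.

    Returns ``(cleaned_genotype, None)`` on acceptance or ``(None, reason)``
    on rejection (reason codes ``"too_few_snps"`` / ``"empty_after_mask"``).
    ``mask`` is a precomputed interval dict from :func:`compute_bias_mask`.
    """
    if g.n_snps < min_snps:
        return None, "too_few_snps"
    keep = np.ones(g.n_snps, dtype=bool)
    for s, e in (mask or {}).get(g.arm, []):
        keep &= ~((g.positions >= s) & (g.positions < e))
    if not keep.any():
        return None, "empty_after_mask"
    if keep.all():
        return g, None
    return ChromatidGenotype(g.chromatid_id, g.arm,
                             g.positions[keep], g.parents[keep]), None


# ---------------------------------------------------------------------------
# calling


def _runs_to_blocks(g: ChromatidGenotype) -> list[Block]:
    if g.n_snps == 0:
        return []
    switch = np.flatnonzero(g.parents[1:] != g.parents[:-1]) + 1
    bounds = np.concatenate([[0], switch, [g.n_snps]])
    return [Block(g.arm, int(g.positions[i]), int(g.positions[j - 1]),
                  str(g.parents[i]), int(j - i))
            for i, j in zip(bounds[:-1], bounds[1:])]


def _merge_adjacent(blocks: list[Block]) -> list[Block]:
    out: list[Block] = []
    for b in blocks:
        if out and out[-1].parent == b.parent:
            prev = out[-1]
            out[-1] = Block(b.arm, prev.start, b.end, b.parent,
                            prev.n_snps + b.n_snps)
        else:
            out.append(b)
    return out


def _remove_short_blocks(blocks, min_block, min_block_snps):
    """Iteratively drop the shortest under-sized block and re-merge flanks."""
    def short(b: Block) -> bool:
        if b.span < min_block:
            return True
        return min_block_snps is not None and b.n_snps < min_block_snps

    blocks = _merge_adjacent(blocks)
    while len(blocks) > 1:
        cand = [i for i, b in enumerate(blocks) if short(b)]
        if not cand:
            break
        i = min(cand, key=lambda k: (blocks[k].span, k))
        del blocks[i]
        blocks = _merge_adjacent(blocks)
    return blocks


def _chromatid_rng(seed: int, chromatid_id: str) -> np.random.Generator:
    key = zlib.crc32(chromatid_id.encode())
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def call_crossovers(g: ChromatidGenotype, min_block: int = 100_000,
                    min_sep: int = 250_000, min_block_snps: int | None = None,
                    seed: int = 0) -> list[CrossoverEvent]:
    """Call crossover events on one filtered chromatid.

    ``min_block_snps`` enables the dot-chromosome preset (block support
    measured in SNPs instead of physical span).  Event positions are drawn
    uniformly in the flanking inter-SNP gap from a substream keyed by
    ``(seed, chromatid_id)``, so calls are reproducible per chromatid
    regardless of processing order.
    """
    blocks = _remove_short_blocks(_runs_to_blocks(g), min_block, min_block_snps)
    if len(blocks) < 2:
        return []
    rng = _chromatid_rng(seed, g.chromatid_id)
    events = [
        CrossoverEvent(
            chromatid_id=g.chromatid_id, arm=g.arm,
            position=int(rng.integers(left.end + 1, right.start + 1)),
            flank_left=left.end, flank_right=right.start)
        for left, right in zip(blocks[:-1], blocks[1:])
    ]
    # resolve event pairs closer than min_sep: drop the enclosed block and
    # both boundary events, then re-merge the (same-parent) outer flanks
    while len(events) >= 2:
        gaps = [events[i + 1].position - events[i].position
                for i in range(len(events) - 1)]
        i = int(np.argmin(gaps))
        if gaps[i] >= min_sep:
            break
        del events[i:i + 2]
        del blocks[i + 1]
        blocks = _merge_adjacent(blocks)
    return events


def call_dataset(genotypes, min_snps: int = 100, min_block: int = 100_000,
                 min_sep: int = 250_000, min_block_snps: int | None = None,
                 seed: int = 0, mask: dict | None = None):
    """Filter and call a whole collection of chromatid genotype streams.

    Computes the pooled bias mask (unless one is supplied), applies the
    filter cascade to every chromatid and returns
    ``(events, genotyped, rejections)`` where ``genotyped`` lists the
    ``(chromatid_id, arm)`` pairs that passed filtering (the denominator for
    class counting) and ``rejections`` maps rejected pairs to reason codes.
    """
    genotypes = list(genotypes)
    if mask is None:
        mask = compute_bias_mask(genotypes)
    events: list[CrossoverEvent] = []
    genotyped: list[tuple[str, str]] = []
    rejections: dict[tuple[str, str], str] = {}
    for g in genotypes:
        cleaned, reason = filter_and_mask(g, min_snps=min_snps, mask=mask)
        if cleaned is None:
            rejections[(g.chromatid_id, g.arm)] = reason
            continue
        genotyped.append((g.chromatid_id, g.arm))
        events.extend(call_crossovers(cleaned, min_block=min_block,
                                      min_sep=min_sep,
                                      min_block_snps=min_block_snps, seed=seed))
    return events, genotyped, rejections


# ---------------------------------------------------------------------------
# summaries


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chromatid_id": e.chromatid_id, "arm": e.arm, "position": e.position,
          "flank_left": e.flank_left, "flank_right": e.flank_right}
         for e in events],
        columns=["chromatid_id", "arm", "position", "flank_left", "flank_right"])


def summarize_class_table(table: pd.DataFrame):
    """Map statistics from a per-arm class-count table (columns ``n0..nK``).

    Returns ``(table_with_stats, summary)``: per-arm event totals, mean
    crossovers per chromatid and map length (cM = 100 x mean), plus the
    genome-wide summary (total events, genome mean = sum of per-arm means,
    total map length in cM).
    """
    cols = sorted((c for c in table.columns if c.startswith("n")
                   and c[1:].isdigit()), key=lambda c: int(c[1:]))
    counts = table[cols].to_numpy(dtype=float)
    ks = np.array([int(c[1:]) for c in cols], dtype=float)
    out = table.copy()
    out["n_total"] = counts.sum(axis=1).astype(int)
    out["n_events"] = (counts * ks).sum(axis=1).astype(int)
    out["mean_co"] = out["n_events"] / out["n_total"]
    out["map_cM"] = 100.0 * out["mean_co"]
    summary = {
        "total_events": int(out["n_events"].sum()),
        "genome_mean_co": float(out["mean_co"].sum()),
        "total_map_cM": float(out["map_cM"].sum()),
    }
    return out, summary


def summarize_classes(events, genotyped, max_class: int = 4):
    """Tabulate chromatid crossover classes and map statistics per arm.

    ``genotyped`` is the list of ``(chromatid_id, arm)`` pairs that were
    successfully genotyped (chromatids with zero called events count as NCO).
    Chromatids with more than ``max_class`` events are counted in the top
    class.  Returns ``(table, summary)``: a per-arm frame with class counts
    ``n0..n{max_class}``, chromatid totals, mean crossovers per chromatid and
    map length in cM, plus a genome-wide summary dict (total events, genome
    mean = sum of per-arm means, total map length).
    """
    ev = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    per_chromatid: dict[tuple[str, str], int] = {tuple(k): 0 for k in genotyped}
    if len(ev):
        counted = ev.groupby(["chromatid_id", "arm"]).size()
        for (cid, arm), k in counted.items():
            if (cid, arm) not in per_chromatid:
                raise ValueError(f"event for unlisted chromatid {(cid, arm)}")
            per_chromatid[(cid, arm)] = int(k)
    arms = list(dict.fromkeys(arm for _, arm in genotyped))
    rows = []
    for arm in arms:
        ks = np.array([min(k, max_class) for (cid, a), k in per_chromatid.items()
                       if a == arm])
        counts = np.bincount(ks, minlength=max_class + 1)
        n_events = sum(k for (cid, a), k in per_chromatid.items() if a == arm)
        mean = n_events / ks.size
        rows.append({"arm": arm,
                     **{f"n{j}": int(counts[j]) for j in range(max_class + 1)},
                     "n_total": int(ks.size), "n_events": int(n_events),
                     "mean_co": mean, "map_cM": 100.0 * mean})
    table = pd.DataFrame(rows).set_index("arm")
    summary = {
        "total_events": int(table["n_events"].sum()),
        "genome_mean_co": float(table["mean_co"].sum()),
        "total_map_cM": float(table["map_cM"].sum()),
    }
    return table, summary
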