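"""Two-marker haplotype frequency curves as a viability diagnostic.

Differential egg-to-adult viability of parental or recombinant genotypes
distorts the haplotypes observed in surviving adults.  With no viability
bias, the two parental two-marker haplotypes (AA, BB) occur at equal
frequencies at every genetic distance, as do the two recombinant ones
(AB, BA); systematic departures flag survival bias.  This module classifies
all ordered pairs of 1-kb genotype bins per chromatid, converts their
physical separation to genetic distance through an empirical map, and
averages class frequencies in sliding 1-cM windows (0.1-cM steps).

Recombinant haplotypes are oriented telomere-proximal marker first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ArmGeometry

__all__ = ["HaplotypeCurves", "build_genetic_map", "haplotype_frequency_curves"]


@dataclass
class HaplotypeCurves:
    """Haplotype-class frequencies vs genetic distance (window centers, cM)."""

    distance_cM: np.ndarray
    f_AA: np.ndarray
    f_BB: np.ndarray
    f_AB: np.ndarray     # telomere-proximal A, centromere-proximal B
    f_BA: np.ndarray
    n_pairs: np.ndarray

    @property
    def recombinant(self) -> np.ndarray:
        return self.f_AB + self.f_BA


def build_genetic_map(crossover_positions, n_chromatids: int):
    """Empirical genetic map from pooled crossover positions.

    Returns a callable ``cM(pos)``: cumulative crossovers to the left of
    ``pos`` x 100 / ``n_chromatids`` — monotone non-decreasing by
    construction.
    """
    pos = np.sort(np.asarray(crossover_positions, dtype=float))
    if n_chromatids <= 0:
        raise ValueError("n_chromatids must be positive")

    def cm(x):
        return 100.0 * np.searchsorted(pos, np.asarray(x, dtype=float),
                                       side="right") / n_chromatids

    return cm


def _genotype_matrix(chromatids, length: int, resolution: int) -> np.ndarray:
    """0/1 (A/B) genotype per 1-kb bin for each chromatid.

    ``chromatids`` is a sequence of ``(start_parent, crossover_positions)``
    with ``start_parent`` in {"A", "B"} at the left end of the arm.
    """
    centers = (np.arange(length // resolution) + 0.5) * resolution
    G = np.empty((len(chromatids), centers.size), dtype=np.int8)
    for i, (start, xo) in enumerate(chromatids):
        if start not in ("A", "B"):
            raise ValueError("start parent must be 'A' or 'B'")
        flips = np.searchsorted(np.sort(np.asarray(xo, dtype=float)), centers)
        G[i] = ((0 if start == "A" else 1) + flips) % 2
    return G


def haplotype_frequency_curves(
    chromatids,
    geometry: ArmGeometry,
    genetic_map=None,
    resolution: int = 1000,
    window_cM: float = 1.0,
    step_cM: float = 0.1,
    bin_stride: int = 1,
) -> HaplotypeCurves:
    """Frequencies of the four two-marker haplotypes vs genetic distance.

    ``chromatids`` holds ``(start_parent, crossover_positions)`` per
    chromatid.  ``genetic_map`` is a monotone callable pos -> cM; by default
    it is built from the supplied chromatids' own crossovers.  ``bin_stride``
    subsamples genotype bins deterministically (every k-th bin) to bound the
    quadratic pair enumeration on long arms.
    """
    chromatids = list(chromatids)
    if genetic_map is None:
        pooled = np.concatenate(
            [np.asarray(xo, dtype=float) for _, xo in chromatids]
            or [np.empty(0)])
        genetic_map = build_genetic_map(pooled, len(chromatids))
    G = _genotype_matrix(chromatids, geometry.length, resolution)
    centers = (np.arange(G.shape[1]) + 0.5) * resolution
    keep = np.arange(0, G.shape[1], bin_stride)
    G, centers = G[:, keep], centers[keep]

    cm = np.asarray(genetic_map(centers), dtype=float)
    if np.any(np.diff(cm) < 0):
        raise ValueError("genetic map must be monotone non-decreasing")
    # orient pairs telomere -> centromere
    if geometry.centromere_side == "left":
        G, cm = G[:, ::-1], cm[::-1]

    A = (G == 0).astype(np.float64)
    B = 1.0 - A
    n_aa = A.T @ A
    n_bb = B.T @ B
    n_ab = A.T @ B          # [i, j]: left bin A, right bin B
    n_ba = B.T @ A
    iu, ju = np.triu_indices(centers.size, k=1)
    d = np.abs(cm[ju] - cm[iu])

    bins = np.floor(d / step_cM + 0.5).astype(int)
    n_bins = int(bins.max()) + 1 if bins.size else 1
    acc = {name: np.bincount(bins, weights=mat[iu, ju], minlength=n_bins)
           for name, mat in (("AA", n_aa), ("BB", n_bb),
                             ("AB", n_ab), ("BA", n_ba))}
    half = max(int(round(window_cM / step_cM)) // 2, 0)
    kernel = np.ones(2 * half + 1)
    smooth = {k: np.convolve(v, kernel, mode="same") for k, v in acc.items()}
    total = sum(smooth.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = {k: np.where(total > 0, v / total, np.nan)
                 for k, v in smooth.items()}
    return HaplotypeCurves(
        distance_cM=np.arange(n_bins) * step_cM,
        f_AA=freqs["AA"], f_BB=freqs["BB"],
        f_AB=freqs["AB"], f_BA=freqs["BA"],
        n_pairs=total)
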