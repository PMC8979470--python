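"""Synthetic meiosis generator.

Emulates the data-generating process behind single-chromatid crossover
studies: tetrads draw a crossover number ``r`` from frequencies ``E_0..E_4``,
crossover positions are placed along the arm with optional interference
(gamma-renewal spacing) and centromere/telomere suppression, each crossover is
assigned to one sister chromatid of the transmitted dyad (optionally with
positive chromatid interference), and meiosis II recovers one sister into the
oocyte nucleus (optionally with crossover-associated drive ``b``).  Recovered
chromatids are then serialized as diagnostic-SNP genotype streams so the
whole downstream pipeline can be exercised against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ArmGeometry
from .tetrad import N_CLASSES

__all__ = ["SimulationConfig", "MeiosisTruth", "simulate_meioses",
           "emit_genotype_streams", "recovered_class_counts"]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cross.

    Parameters
    ----------
    arms
        Arm geometries to simulate.
    tetrad_dist
        Tetrad frequencies ``E_0..E_4``; either one vector applied to every
        arm or a mapping from arm name to vector.
    drive_bias
        Probability ``b`` in [0.5, 1] that a recombinant chromatid enters the
        oocyte nucleus when its sister carries no crossover (0.5 = no drive).
    pci_bias
        Probability in [0.5, 1] that each successive crossover is assigned to
        the sister chromatid with fewer previous crossovers (0.5 = random).
    interference_shape
        Gamma-renewal shape ``nu`` for inter-crossover spacing; 1 gives
        no interference (uniform placement), larger values space crossovers
        more evenly.
    suppression_profile
        Relative crossover intensity multipliers over equal-width bins
        spanning the detectable interval (one vector for all arms or a
        per-arm mapping); ``None`` means flat.
    snp_spacing_mean
        Mean diagnostic-SNP spacing in bp (exponential gaps); the default
        matches a density of about one SNP per 1.3 kb.
    """

    arms: list[ArmGeometry]
    tetrad_dist: object
    drive_bias: float = 0.5
    pci_bias: float = 0.5
    interference_shape: float = 1.0
    suppression_profile: object = None
    snp_spacing_mean: float = 1300.0
    n_meioses: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("at least one arm is required")
        if not (0.5 <= self.drive_bias <= 1.0):
            raise ValueError("drive_bias must lie in [0.5, 1]")
        if not (0.5 <= self.pci_bias <= 1.0):
            raise ValueError("pci_bias must lie in [0.5, 1]")
        if self.interference_shape <= 0:
            raise ValueError("interference_shape must be positive")
        if self.snp_spacing_mean <= 0:
            raise ValueError("snp_spacing_mean must be positive")
        for arm in self.arms:
            self.tetrad_for(arm.name)  # validates
            prof = self.suppression_for(arm.name)
            if prof is not None:
                prof = np.asarray(prof, dtype=float)
                if np.any(prof < 0) or not np.any(prof > 0):
                    raise ValueError(
                        "suppression multipliers must be >= 0 with at least one > 0")

    def tetrad_for(self, arm_name: str) -> np.ndarray:
        E = self.tetrad_dist
        if isinstance(E, dict):
            E = E[arm_name]
        E = np.asarray(E, dtype=float)
        if E.shape != (N_CLASSES,):
            raise ValueError(f"tetrad_dist must have {N_CLASSES} entries")
        if np.any(E < 0) or abs(E.sum() - 1.0) > 1e-9:
            raise ValueError("tetrad_dist entries must be >= 0 and sum to 1")
        return E

    def suppression_for(self, arm_name: str):
        prof = self.suppression_profile
        if isinstance(prof, dict):
            prof = prof.get(arm_name)
        return None if prof is None else np.asarray(prof, dtype=float)


@dataclass
class MeiosisTruth:
    """Ground truth for one meiosis on one arm."""

    meiosis: int
    arm: str
    r: int
    positions: np.ndarray          # all r crossovers of the tetrad, increasing
    dyad_split: tuple              # (k, r - k) crossovers on the two sisters
    recovered_count: int
    recovered_positions: np.ndarray

    @property
    def chromatid_id(self) -> str:
        return f"f2_{self.meiosis:06d}"


def _place_positions(rng, m, r, geom: ArmGeometry, nu, profile) -> np.ndarray:
    """Place r crossovers in each of m meioses on the detectable interval.

    Gamma-renewal gaps of shape ``nu`` are rescaled to the interval (for
    ``nu`` = 1 this reproduces uniform order statistics exactly), then each
    candidate set is accepted or rejected as a whole against the suppression
    profile.
    """
    span = geom.detectable_span
    if span <= 0:
        raise ValueError(f"empty detectable interval on arm {geom.name}")
    out = np.empty((m, r))
    todo = np.arange(m)
    max_mult = profile.max() if profile is not None else 1.0
    for _ in range(10000):
        k = todo.size
        if k == 0:
            break
        gaps = rng.gamma(nu, 1.0, size=(k, r + 1))
        frac = np.cumsum(gaps[:, :r], axis=1) / gaps.sum(axis=1, keepdims=True)
        pos = geom.detectable_start + span * frac
        if profile is None:
            out[todo] = pos
            todo = todo[:0]
            break
        bins = np.clip(((pos - geom.detectable_start) / span
                        * profile.size).astype(int), 0, profile.size - 1)
        accept_p = np.prod(profile[bins] / max_mult, axis=1)
        acc = rng.random(k) < accept_p
        out[todo[acc]] = pos[acc]
        todo = todo[~acc]
    else:
        raise RuntimeError("accept-reject placement failed to converge; "
                           "suppression profile may be (almost) everywhere zero")
    return out


def _assign_and_recover(rng, pos, pci_bias, drive_bias):
    """Assign crossovers to the transmitted dyad's sisters and recover one.

    Returns (k on sister A, recovered_is_A, assignment matrix to sister A).
    """
    m, r = pos.shape
    a = np.zeros(m, dtype=int)
    c = np.zeros(m, dtype=int)
    to_a = np.zeros((m, r), dtype=bool)
    for j in range(r):
        p_a = np.where(a == c, 0.5, np.where(a < c, pci_bias, 1.0 - pci_bias))
        pick_a = rng.random(m) < p_a
        to_a[:, j] = pick_a
        a += pick_a
        c += ~pick_a
    one_sided = (a == 0) != (c == 0)          # exactly one sister recombinant
    co_is_a = a > 0
    u = rng.random(m)
    recovered_a = np.where(one_sided,
                           np.where(u < drive_bias, co_is_a, ~co_is_a),
                           u < 0.5)
    return a, recovered_a, to_a


def simulate_meioses(config: SimulationConfig) -> list[MeiosisTruth]:
    """Simulate ``config.n_meioses`` meioses for every configured arm.

    Deterministic under a fixed ``config.seed``; each arm consumes an
    independent child stream of the master seed.
    """
    root = np.random.SeedSequence(config.seed)
    arm_seeds = root.spawn(len(config.arms))
    truths: list[MeiosisTruth] = []
    n = config.n_meioses
    for arm, ss in zip(config.arms, arm_seeds):
        rng = np.random.default_rng(ss)
        E = config.tetrad_for(arm.name)
        profile = config.suppression_for(arm.name)
        r_all = rng.choice(N_CLASSES, size=n, p=E)
        records: list[tuple] = [None] * n
        for r in range(N_CLASSES):
            idx = np.flatnonzero(r_all == r)
            if idx.size == 0:
                continue
            if r == 0:
                for i in idx:
                    records[i] = (0, np.empty(0), (0, 0), 0, np.empty(0))
                continue
            pos = _place_positions(rng, idx.size, r, arm,
                                   config.interference_shape, profile)
            pos.sort(axis=1)
            k, rec_a, to_a = _assign_and_recover(
                rng, pos, config.pci_bias, config.drive_bias)
            for row, i in enumerate(idx):
                sel = to_a[row] if rec_a[row] else ~to_a[row]
                rec_pos = pos[row][sel]
                records[i] = (r, pos[row], (int(k[row]), r - int(k[row])),
                              int(sel.sum()), rec_pos)
        for i, (r, pos, split, rc, rp) in enumerate(records):
            truths.append(MeiosisTruth(meiosis=i, arm=arm.name, r=int(r),
                                       positions=pos, dyad_split=split,
                                       recovered_count=rc,
                                       recovered_positions=rp))
    return truths


def recovered_class_counts(truths: list[MeiosisTruth],
                           arm: str | None = None) -> np.ndarray:
    """Chromatid-class counts (0..4 crossovers) of recovered chromatids."""
    counts = np.zeros(N_CLASSES, dtype=int)
    for t in truths:
        if arm is None or t.arm == arm:
            counts[min(t.recovered_count, N_CLASSES - 1)] += 1
    return counts


def emit_genotype_streams(truths: list[MeiosisTruth],
                          config: SimulationConfig) -> pd.DataFrame:
    """Serialize recovered chromatids as diagnostic-SNP genotype streams.

    SNP sites are placed with exponential spacing of mean
    ``config.snp_spacing_mean`` along each arm; the parent-of-origin label
    alternates exactly at each recovered crossover position.  Returns a frame
    with columns ``chromatid_id, arm, pos, parent`` sorted by position within
    each chromatid.
    """
    arms = {a.name: a for a in config.arms}
    root = np.random.SeedSequence((config.seed, 0x5e1f))
    rng = np.random.default_rng(root)
    frames = []
    for t in truths:
        geom = arms[t.arm]
        n_draw = int(geom.length / config.snp_spacing_mean * 1.4) + 30
        sites = np.cumsum(rng.exponential(config.snp_spacing_mean, size=n_draw))
        sites = np.unique(np.ceil(sites[sites <= geom.length]).astype(np.int64))
        if sites.size == 0:
            warnings.warn(f"no diagnostic SNPs on arm {t.arm} for "
                          f"chromatid {t.chromatid_id}", stacklevel=2)
            continue
        start = int(rng.integers(0, 2))
        # a site exactly at a crossover position lies right of the exchange
        phase = (start + np.searchsorted(t.recovered_positions, sites,
                                         side="right")) % 2
        frames.append(pd.DataFrame({
            "chromatid_id": t.chromatid_id,
            "arm": t.arm,
            "pos": sites,
            "parent": np.where(phase == 0, "A", "B"),
        }))
    if not frames:
        return pd.DataFrame(columns=["chromatid_id", "arm", "pos", "parent"])
    return pd.concat(frames, ignore_index=True)
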