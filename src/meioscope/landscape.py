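"""Centromere/telomere effects and recombination-rate profiles.

Two complementary quantifications of crossover suppression near a chromosome
end:

* a randomization test comparing the observed crossover count in a fixed
  proximal fraction of the arm (one third by convention) against uniform
  placement over the detectable span;
* a sliding binomial scan (1-Mb windows, 100-kb steps, moving inward from the
  scanned end) that measures the physical *extent* of the suppressed region —
  the distance to the first run of consecutive non-significant windows.

Rates are expressed in cM/Mb: 100 x (events per chromatid) per megabase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .geometry import ArmGeometry

__all__ = ["WindowScan", "proximal_region_test", "effect_extent_scan",
           "rate_profile"]


@dataclass
class WindowScan:
    """Result of a sliding binomial suppression scan from one chromosome end."""

    arm: str
    side: str
    windows: pd.DataFrame        # start, end, n_obs, p_window, p_value (ordered
    extent_bp: float             # from the scanned end inward)
    extent_fraction: float
    alpha: float
    stop_rule: int


def _positions_on_arm(events, arm: str) -> np.ndarray:
    if isinstance(events, (list, tuple)):
        pos = np.array([e.position for e in events if e.arm == arm], dtype=float)
    elif isinstance(events, pd.DataFrame):
        pos = events.loc[events["arm"] == arm, "position"].to_numpy(dtype=float)
    else:
        pos = np.asarray(events, dtype=float)
    return pos


def proximal_region_test(events, geometry: ArmGeometry, side: str = "centromere",
                         fraction: float = 1.0 / 3.0, reps: int = 1_000_000,
                         seed: int = 0) -> float:
    """Randomization test for a crossover deficit in the proximal ``fraction``
    of the detectable span nearest the given chromosome end.

    The null places the same total number of events uniformly over the
    detectable span; the p-value is the fraction of replicates whose proximal
    count is <= the observed one (small p = fewer proximal crossovers than
    expected).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    pos = _positions_on_arm(events, geometry.name)
    n = pos.size
    if n == 0:
        raise ValueError("proximal-region test undefined with zero events")
    span = geometry.detectable_span
    end = geometry.end_position(side)
    dist = np.abs(pos - end)
    obs = int(np.count_nonzero(dist <= fraction * span))
    # uniform placement => proximal count is Binomial(n, fraction); sampling
    # the replicate counts directly is equivalent to placing points
    rng = np.random.default_rng(seed)
    sims = rng.binomial(n, fraction, size=int(reps))
    return float(np.mean(sims <= obs))


def effect_extent_scan(events, geometry: ArmGeometry, side: str = "centromere",
                       window: int = 1_000_000, step: int = 100_000,
                       alpha: float = 1e-2, stop_rule: int = 5) -> WindowScan:
    """Measure the extent of crossover suppression from one chromosome end.

    Windows of ``window`` bp advance inward by ``step`` from the scanned end
    across the detectable span.  Each window's p-value is the binomial
    probability of observing at most the window's event count given ``n``
    total events on the arm and success probability equal to the window's
    share of the detectable span (the final partial window keeps its true,
    smaller share).  The suppressed extent ends at the first run of
    ``stop_rule`` consecutive windows with p >= ``alpha``.
    """
    span = geometry.detectable_span
    if window > span:
        raise ValueError("scan window larger than the detectable span")
    pos = _positions_on_arm(events, geometry.name)
    n = pos.size
    if n == 0:
        raise ValueError("extent scan undefined with zero events")
    end = geometry.end_position(side)
    dist = np.sort(np.abs(pos - end))          # distance inward from the end

    rows = []
    offset = 0
    while offset < span:
        w_end = min(offset + window, span)
        n_obs = int(np.searchsorted(dist, w_end, side="right")
                    - np.searchsorted(dist, offset, side="left"))
        p_window = (w_end - offset) / span
        p_value = float(binom.cdf(n_obs, n, p_window))
        rows.append((offset, w_end, n_obs, p_window, p_value))
        offset += step
    win = pd.DataFrame(rows, columns=["start", "end", "n_obs", "p_window",
                                      "p_value"])

    nonsig = (win["p_value"].to_numpy() >= alpha)
    extent = float(span)
    run = 0
    for i, ns in enumerate(nonsig):
        run = run + 1 if ns else 0
        if run >= stop_rule:
            extent = float(win["start"].iloc[i - stop_rule + 1])
            break
    return WindowScan(arm=geometry.name, side=side, windows=win,
                      extent_bp=extent, extent_fraction=extent / span,
                      alpha=alpha, stop_rule=stop_rule)


def rate_profile(events, geometry: ArmGeometry, n_chromatids: int,
                 window: int = 250_000, step: int | None = None) -> pd.DataFrame:
    """Crossover rate in cM/Mb along the arm.

    ``step=None`` (or ``step == window``) gives non-overlapping windows; a
    smaller step gives the overlapping presets.  The final partial window is
    normalized by its true length, so for non-overlapping windows
    ``sum(rate * window_Mb)`` equals the arm map length exactly.
    """
    if window <= 0:
        raise ValueError("window length must be positive")
    if n_chromatids <= 0:
        raise ValueError("n_chromatids must be positive")
    step = window if step is None else step
    pos = np.sort(_positions_on_arm(events, geometry.name))
    rows = []
    start = 0
    while start < geometry.length:
        end = min(start + window, geometry.length)
        n_obs = int(np.searchsorted(pos, end, side="right")
                    - np.searchsorted(pos, start, side="left"))
        mb = (end - start) / 1e6
        rows.append((start, end, n_obs, 100.0 * (n_obs / n_chromatids) / mb))
        start += step
    return pd.DataFrame(rows, columns=["start", "end", "n_obs", "cM_per_Mb"])
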