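"""Tetrad-frequency inference from single-chromatid crossover classes.

In female *Drosophila* only one of the four meiotic products is recovered, so
the frequencies ``E_0 .. E_4`` of tetrads with 0..4 crossovers must be inferred
from the observed distribution of crossovers per chromatid (NCO, 1CO, ... 4CO).
This module implements:

* the classical Weinstein algebraic inversion (which may return negative
  tetrad frequencies),
* forward chromatid-class probabilities under three meiotic models —
  ``weinstein`` (random chromatid choice and segregation), ``md_co``
  (crossover-associated meiotic drive: a recombinant chromatid enters the
  oocyte nucleus with probability ``b >= 0.5`` when its sister carries no
  crossover) and ``pci`` (positive chromatid interference: each successive
  crossover prefers the sister chromatid with fewer previous crossovers with
  probability ``b``),
* constrained maximum-likelihood fitting of these models to class counts,
  with explicit handling of the flat likelihood ridge that the
  over-parameterized drive models produce,
* Monte-Carlo exact goodness of fit, likelihood-ratio tests, profile
  surfaces, and the negative-``E0`` resampling experiment.

Tetrads are modeled up to ``E_4`` (quadruple-crossover chromatids are observed,
rarely, in real data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

MAX_CO = 4
N_CLASSES = MAX_CO + 1

MODELS = ("weinstein", "constrained", "md_co", "pci")

__all__ = [
    "MAX_CO",
    "N_CLASSES",
    "MODELS",
    "TetradDistribution",
    "ModelFit",
    "weinstein_invert",
    "conditional_matrix",
    "class_probs",
    "multinomial_logpmf",
    "saturated_loglik",
    "fit_tetrad_model",
    "goodness_of_fit",
    "likelihood_ratio",
    "profile_surface",
    "e0_sampling_experiment",
    "combine_arms",
]


# ---------------------------------------------------------------------------
# basic containers


@dataclass
class TetradDistribution:
    """Frequencies ``E_0 .. E_4`` of tetrads by crossover number.

    ``E`` sums to 1 but individual entries may be negative when produced by
    the raw Weinstein inversion; ``feasible`` reports whether all entries are
    non-negative (i.e. interpretable as probabilities).
    """

    E: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (N_CLASSES,):
            raise ValueError(f"E must have length {N_CLASSES}")
        if abs(self.E.sum() - 1.0) > 1e-9:
            raise ValueError("tetrad frequencies must sum to 1")

    @property
    def feasible(self) -> bool:
        return bool(np.all(self.E >= -1e-12))

    def __getitem__(self, r: int) -> float:
        return float(self.E[r])


@dataclass
class ModelFit:
    """Result of a maximum-likelihood tetrad-model fit.

    When the model is over-parameterized the maximum-likelihood set is a
    one-dimensional ridge in ``(E, b)`` rather than a point.  ``ridge`` then
    holds the maximum-likelihood interval of each parameter, and the reported
    point estimates (``b_hat``, ``e0_hat``) are the midpoints of those
    intervals; ``E_hat`` is the exact ridge solution at ``b_hat``.
    """

    model: str
    E_hat: TetradDistribution
    logL: float
    n: int
    counts: np.ndarray
    b_hat: float | None = None
    gof_p: float | None = None
    ci: dict = field(default_factory=dict)
    ridge: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)

    @property
    def e0_hat(self) -> float:
        """Point estimate of ``E0`` (ridge-interval midpoint when on a ridge)."""
        if "E0" in self.ridge:
            lo, hi = self.ridge["E0"]
            return 0.5 * (lo + hi)
        return float(self.E_hat.E[0])

    @property
    def probs(self) -> np.ndarray:
        """Fitted chromatid-class probabilities at the point estimate."""
        return class_probs(self.E_hat.E, self.model, self.b_hat)

    @property
    def n_free_params(self) -> int:
        base = {"weinstein": 4, "constrained": 4, "md_co": 5, "pci": 5}[self.model]
        return base - len(self.fixed)


# ---------------------------------------------------------------------------
# Weinstein inversion and forward class probabilities


def _as_freqs(counts) -> tuple[np.ndarray, float]:
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} crossover classes (0..{MAX_CO})")
    n = c.sum()
    if n <= 0:
        raise ValueError("total chromatid count must be positive")
    return c / n, n


def weinstein_invert(counts) -> TetradDistribution:
    """Invert observed chromatid-class counts (or frequencies) to tetrad
    frequencies with Weinstein's triangular system.

    With class frequencies ``f_j`` (fraction of chromatids with j crossovers)::

        E4 = 16 f4
        E3 = 8 (f3 - E4/4)
        E2 = 4 (f2 - 3 E3/8 - 3 E4/8)
        E1 = 2 (f1 - E2/2 - 3 E3/8 - E4/4)
        E0 = 1 - (E1 + E2 + E3 + E4)

    Negative entries are permitted (flagged via ``feasible``); they arise from
    sampling error or violations of the model's assumptions.
    """
    f, _ = _as_freqs(counts)
    E4 = 16.0 * f[4]
    E3 = 8.0 * (f[3] - E4 / 4.0)
    E2 = 4.0 * (f[2] - 3.0 * E3 / 8.0 - 3.0 * E4 / 8.0)
    E1 = 2.0 * (f[1] - E2 / 2.0 - 3.0 * E3 / 8.0 - E4 / 4.0)
    E0 = 1.0 - (E1 + E2 + E3 + E4)
    return TetradDistribution(np.array([E0, E1, E2, E3, E4]))


def _pci_conditional(r: int, b: float) -> np.ndarray:
    """P(recovered chromatid carries j crossovers | tetrad has r) under PCI.

    Crossovers are assigned sequentially to the two sisters of the transmitted
    dyad; each goes to the sister with fewer previous crossovers with
    probability ``b`` (fair coin on ties).  The recovered sister is uniform.
    Exact enumeration by dynamic programming over sister-count states.
    """
    states = {(0, 0): 1.0}
    for _ in range(r):
        new: dict[tuple[int, int], float] = {}
        for (a, c), p in states.items():
            if a == c:
                lo_a, lo_c = 0.5, 0.5
            elif a < c:
                lo_a, lo_c = b, 1.0 - b
            else:
                lo_a, lo_c = 1.0 - b, b
            new[(a + 1, c)] = new.get((a + 1, c), 0.0) + p * lo_a
            new[(a, c + 1)] = new.get((a, c + 1), 0.0) + p * lo_c
        states = new
    out = np.zeros(N_CLASSES)
    for (a, c), p in states.items():
        out[a] += 0.5 * p
        out[c] += 0.5 * p
    return out


def conditional_matrix(model: str, b: float | None = None) -> np.ndarray:
    """Matrix ``M[j, r] = P(recovered chromatid has j crossovers | tetrad has r)``.

    * ``weinstein`` — each crossover hits one sister of the transmitted dyad
      with probability 1/2 and the recovered sister is uniform:
      ``M[j, r] = C(r, j) / 2**r``.
    * ``md_co`` — as Weinstein, but when exactly one sister is recombinant it
      is recovered with probability ``b``:
      ``M[0, r] = 2 (1 - b) / 2**r`` and ``M[r, r] = 2 b / 2**r`` for r >= 1.
    * ``pci`` — exact enumeration of biased sequential sister assignment
      (bias ``b`` toward the sister with fewer crossovers), uniform recovery.

    ``constrained`` is the Weinstein matrix (the constraint lives in the fit).
    """
    if model in ("weinstein", "constrained"):
        M = np.zeros((N_CLASSES, N_CLASSES))
        for r in range(N_CLASSES):
            for j in range(r + 1):
                M[j, r] = comb(r, j) / 2.0**r
        return M
    if b is None:
        raise ValueError(f"model {model!r} requires a bias b")
    if not (0.5 - 1e-9 <= b <= 1.0 + 1e-9):
        raise ValueError("bias b must lie in [0.5, 1]")
    b = min(max(b, 0.5), 1.0)
    if model == "md_co":
        M = np.zeros((N_CLASSES, N_CLASSES))
        M[0, 0] = 1.0
        for r in range(1, N_CLASSES):
            for j in range(1, r):
                M[j, r] = comb(r, j) / 2.0**r
            M[0, r] = 2.0 * (1.0 - b) / 2.0**r
            M[r, r] = 2.0 * b / 2.0**r
        return M
    if model == "pci":
        return np.column_stack([_pci_conditional(r, b) for r in range(N_CLASSES)])
    raise ValueError(f"unknown model {model!r}")


def class_probs(E, model: str = "weinstein", b: float | None = None) -> np.ndarray:
    """Chromatid-class probabilities implied by tetrad frequencies ``E``.

    ``E`` must be a proper distribution (all entries >= 0); project or refit
    raw Weinstein output before calling.
    """
    E = E.E if isinstance(E, TetradDistribution) else np.asarray(E, dtype=float)
    if np.any(E < -1e-12):
        raise ValueError("class_probs requires non-negative tetrad frequencies")
    if abs(E.sum() - 1.0) > 1e-9:
        raise ValueError("tetrad frequencies must sum to 1")
    p = conditional_matrix(model, b) @ np.clip(E, 0.0, None)
    return p / p.sum()


# ---------------------------------------------------------------------------
# likelihood machinery


def multinomial_logpmf(counts, p) -> float:
    counts = np.asarray(counts, dtype=float)
    p = np.asarray(p, dtype=float)
    logp = np.where(counts > 0, np.log(np.clip(p, 1e-300, None)), 0.0)
    return float(
        gammaln(counts.sum() + 1) - gammaln(counts + 1).sum() + (counts * logp).sum()
    )


def saturated_loglik(counts) -> float:
    """Log-likelihood of the saturated multinomial (p = observed frequencies)."""
    f, _ = _as_freqs(counts)
    return multinomial_logpmf(counts, f)


def _em_fit(M: np.ndarray, counts: np.ndarray, fixed_E: dict[int, float],
            tol: float = 1e-11, maxit: int = 50000) -> tuple[np.ndarray, float]:
    """Maximize the multinomial log-likelihood over the tetrad simplex for a
    fixed conditional matrix, by EM on mixture weights (globally concave)."""
    n = counts.sum()
    free = np.array([r for r in range(N_CLASSES) if r not in fixed_E])
    pin_mass = sum(fixed_E.values())
    if pin_mass > 1.0 + 1e-9:
        raise ValueError("pinned tetrad frequencies exceed 1")
    free_mass = max(1.0 - pin_mass, 0.0)
    E = np.zeros(N_CLASSES)
    for r, v in fixed_E.items():
        E[r] = v
    if free.size:
        E[free] = free_mass / free.size
    ll_old = -np.inf
    for _ in range(maxit):
        p = M @ E
        if np.any((p <= 0) & (counts > 0)):
            # a pinned configuration can zero out an observed class
            return E, -np.inf
        w = np.where(p > 0, counts / np.clip(p, 1e-300, None), 0.0)
        resp = E * (M.T @ w)
        if free.size and resp[free].sum() > 0:
            E[free] = free_mass * resp[free] / resp[free].sum()
        ll = multinomial_logpmf(counts, (M @ E) / (M @ E).sum())
        if ll - ll_old < tol * max(1.0, abs(ll)):
            break
        ll_old = ll
    p = M @ E
    return E, multinomial_logpmf(counts, p / p.sum())


def _parse_fixed(fixed: dict | None) -> tuple[dict[int, float], float | None]:
    """Split parameter pins into tetrad-frequency pins and a bias pin."""
    fixed_E: dict[int, float] = {}
    fixed_b: float | None = None
    for key, val in (fixed or {}).items():
        k = str(key).lower()
        if k == "b":
            fixed_b = float(val)
        elif k.startswith("e") and k[1:].isdigit() and int(k[1:]) < N_CLASSES:
            fixed_E[int(k[1:])] = float(val)
        else:
            raise ValueError(f"unknown parameter pin {key!r}")
    return fixed_E, fixed_b


def fit_tetrad_model(
    counts,
    model: str = "constrained",
    fixed: dict | None = None,
    b_step: float = 0.002,
    ridge_policy: str = "midpoint",
    ridge_tol: float = 1e-7,
    compute_ci: bool = True,
) -> ModelFit:
    """Fit a tetrad model to chromatid-class counts by maximum likelihood.

    The multinomial log-likelihood is maximized over the tetrad simplex
    (EM; the problem is concave in ``E`` for fixed ``b``) on a deterministic
    grid of the bias ``b`` with local refinement.  ``fixed`` pins parameters,
    e.g. ``{"E0": 0.0}`` or ``{"b": 0.75}``.

    The drive models are over-parameterized against five observed classes, so
    the likelihood maximum is typically a flat ridge.  The ridge is detected
    (profile log-likelihood within ``ridge_tol`` of the maximum), its
    per-parameter maximum-likelihood intervals are stored in ``fit.ridge``,
    and the point estimate follows ``ridge_policy``:

    * ``"midpoint"`` (default) — midpoint of each parameter's ML interval,
      matching how a central ridge value is conventionally quoted;
    * ``"min_b"`` — the smallest ``b`` on the ridge.
    """
    counts = np.asarray(counts, dtype=float)
    f, n = _as_freqs(counts)
    fixed_E, fixed_b = _parse_fixed(fixed)

    if model == "weinstein" and not fixed_E:
        # unconstrained model: equivalent to the saturated fit via inversion
        E = weinstein_invert(counts)
        fit = ModelFit(model=model, E_hat=E, logL=saturated_loglik(counts),
                       n=int(n), counts=counts)
        if compute_ci:
            fit.ci = {}
        return fit

    if model in ("weinstein", "constrained"):
        M = conditional_matrix("constrained")
        E, ll = _em_fit(M, counts, fixed_E)
        if not np.isfinite(ll):
            raise ValueError("infeasible parameter pins: zero likelihood")
        fit = ModelFit(model="constrained" if model == "constrained" else model,
                       E_hat=TetradDistribution(E), logL=ll, n=int(n),
                       counts=counts, fixed=dict(fixed or {}))
        if compute_ci:
            fit.ci = _profile_cis(counts, model, fixed_E, fixed_b, ll)
        return fit

    if model not in ("md_co", "pci"):
        raise ValueError(f"unknown model {model!r}")

    if fixed_b is not None:
        b_grid = np.array([fixed_b])
    else:
        b_grid = np.clip(np.arange(0.5, 1.0 + 1e-12, b_step), 0.5, 1.0)
        if b_grid[-1] < 1.0:
            b_grid = np.append(b_grid, 1.0)

    lls = np.empty(b_grid.size)
    Es = np.empty((b_grid.size, N_CLASSES))
    for i, b in enumerate(b_grid):
        Es[i], lls[i] = _em_fit(conditional_matrix(model, b), counts, fixed_E)
    if not np.any(np.isfinite(lls)):
        raise ValueError("infeasible parameter pins: zero likelihood")
    ll_max = np.nanmax(lls)
    on_ridge = lls >= ll_max - ridge_tol

    ridge: dict = {}
    if fixed_b is None and on_ridge.sum() > 1:
        idx = np.flatnonzero(on_ridge)
        b_lo = _refine_edge(model, counts, fixed_E, ll_max, ridge_tol,
                            b_grid[idx[0]], b_grid[max(idx[0] - 1, 0)])
        b_hi = _refine_edge(model, counts, fixed_E, ll_max, ridge_tol,
                            b_grid[idx[-1]], b_grid[min(idx[-1] + 1, b_grid.size - 1)])
        ridge["b"] = (b_lo, b_hi)
        for r in range(N_CLASSES):
            vals = Es[idx, r]
            ridge[f"E{r}"] = (float(vals.min()), float(vals.max()))
        if ridge_policy == "midpoint":
            b_hat = 0.5 * (b_lo + b_hi)
        elif ridge_policy == "min_b":
            b_hat = b_lo
        else:
            raise ValueError(f"unknown ridge_policy {ridge_policy!r}")
        E_hat, ll_hat = _em_fit(conditional_matrix(model, b_hat), counts, fixed_E)
    else:
        i0 = int(np.nanargmax(lls))
        b_hat, E_hat, ll_best = float(b_grid[i0]), Es[i0], lls[i0]
        if fixed_b is None:
            # local refinement around the grid argmax
            lo = max(0.5, b_hat - b_step)
            hi = min(1.0, b_hat + b_step)
            for b in np.linspace(lo, hi, 21):
                E, ll = _em_fit(conditional_matrix(model, b), counts, fixed_E)
                if ll > ll_best:
                    b_hat, E_hat, ll_best = float(b), E, ll
        ll_max = max(ll_max, ll_best)

    fit = ModelFit(model=model, E_hat=TetradDistribution(np.clip(E_hat, 0, None) /
                                                         np.clip(E_hat, 0, None).sum()),
                   logL=float(ll_max), n=int(n), counts=counts,
                   b_hat=float(b_hat), ridge=ridge, fixed=dict(fixed or {}))
    if compute_ci:
        fit.ci = _profile_cis(counts, model, fixed_E, fixed_b, float(ll_max))
    return fit


def _refine_edge(model, counts, fixed_E, ll_max, ridge_tol, b_in, b_out,
                 iters: int = 25) -> float:
    """Bisect the boundary of the likelihood plateau between an on-ridge and
    an off-ridge bias value."""
    if b_in == b_out:
        return float(b_in)
    for _ in range(iters):
        mid = 0.5 * (b_in + b_out)
        _, ll = _em_fit(conditional_matrix(model, mid), counts, fixed_E)
        if ll >= ll_max - ridge_tol:
            b_in = mid
        else:
            b_out = mid
        if abs(b_in - b_out) < 1e-6:
            break
    return float(b_in)


def _profile_cis(counts, model, fixed_E, fixed_b, ll_max,
                 cutoff: float = None, grid_step: float = 0.02) -> dict:
    """Profile-likelihood confidence intervals at the chi-square(1) cutoff."""
    if cutoff is None:
        cutoff = chi2.ppf(0.95, df=1) / 2.0  # 1.9207 on the logL scale
    ci: dict = {}
    with_b = model in ("md_co", "pci") and fixed_b is None
    b_grid = np.arange(0.5, 1.0 + 1e-12, grid_step) if with_b else [fixed_b]

    if 0 not in fixed_E:
        xs = np.arange(0.0, 1.0 + 1e-12, grid_step)
        prof = np.full(xs.size, -np.inf)
        for i, x in enumerate(xs):
            pins = dict(fixed_E)
            pins[0] = float(x)
            if model in ("weinstein", "constrained"):
                _, prof[i] = _em_fit(conditional_matrix("constrained"), counts, pins)
            else:
                for b in b_grid:
                    _, ll = _em_fit(conditional_matrix(model, b), counts, pins)
                    prof[i] = max(prof[i], ll)
        ok = prof >= ll_max - cutoff
        if ok.any():
            ci["E0"] = (float(xs[ok].min()), float(xs[ok].max()))
    if with_b:
        bs = np.asarray(b_grid)
        prof = np.array([
            _em_fit(conditional_matrix(model, b), counts, fixed_E)[1] for b in bs
        ])
        ok = prof >= ll_max - cutoff
        if ok.any():
            ci["b"] = (float(bs[ok].min()), float(bs[ok].max()))
    return ci


# ---------------------------------------------------------------------------
# goodness of fit, model comparison, profiles


def goodness_of_fit(fit: ModelFit, counts=None, reps: int = 100000,
                    seed: int = 0) -> float:
    """Monte-Carlo exact multinomial goodness-of-fit probability.

    Simulates ``reps`` datasets of the observed size from the fitted class
    probabilities and returns the fraction whose multinomial log-probability
    is <= that of the observed counts (ties count).  A value near 1 means the
    observed table is as probable as data generated by the model itself.
    """
    counts = fit.counts if counts is None else np.asarray(counts, dtype=float)
    if reps < 1000:
        warnings.warn("goodness_of_fit with reps < 1000 is noisy", stacklevel=2)
    p = fit.probs
    n = int(counts.sum())
    obs_ll = multinomial_logpmf(counts, p)
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, p, size=reps)
    logp = np.where(sims > 0, np.log(np.clip(p, 1e-300, None)), 0.0)
    sim_ll = gammaln(n + 1) - gammaln(sims + 1).sum(axis=1) + (sims * logp).sum(axis=1)
    frac = float(np.mean(sim_ll <= obs_ll + 1e-9))
    fit.gof_p = frac
    return frac


def likelihood_ratio(fit_a: ModelFit, fit_b: ModelFit) -> tuple[float, float]:
    """Likelihood-ratio statistic ``2 (logL_a - logL_b)`` and its chi-square
    p-value.

    Degrees of freedom are the difference in free parameters, floored at 1 —
    the floor covers the non-nested drive-vs-chromatid-interference
    comparison, where both models spend the same number of parameters.
    """
    if not np.array_equal(fit_a.counts, fit_b.counts):
        raise ValueError("fits were made on different data")
    stat = 2.0 * (fit_a.logL - fit_b.logL)
    df = max(abs(fit_a.n_free_params - fit_b.n_free_params), 1)
    return float(stat), float(chi2.sf(max(stat, 0.0), df))


def profile_surface(
    counts,
    model: str = "md_co",
    e0_grid=None,
    b_grid=None,
    gof_reps: int = 0,
    seed: int = 0,
) -> dict:
    """Profile the likelihood over a grid of (E0, b), re-optimizing the
    remaining tetrad frequencies in every cell.

    Returns relative likelihoods (normalized to the grid maximum), optional
    Monte-Carlo goodness-of-fit probabilities per cell (``gof_reps`` > 0),
    and the argmax cell.  With ``b_grid=None`` and a bias-free model this is a
    one-dimensional ``E0`` profile.
    """
    counts = np.asarray(counts, dtype=float)
    e0_grid = np.atleast_1d(np.asarray(
        np.arange(0.0, 0.51, 0.02) if e0_grid is None else e0_grid, dtype=float))
    if model in ("md_co", "pci"):
        b_grid = np.atleast_1d(np.asarray(
            np.arange(0.5, 1.0 + 1e-12, 0.02) if b_grid is None else b_grid,
            dtype=float))
    else:
        b_grid = np.array([np.nan])
    logl = np.full((e0_grid.size, b_grid.size), -np.inf)
    gof = np.full_like(logl, np.nan) if gof_reps else None
    for i, e0 in enumerate(e0_grid):
        for j, b in enumerate(b_grid):
            pins = {0: float(e0)}
            if model in ("md_co", "pci"):
                M = conditional_matrix(model, float(b))
            else:
                M = conditional_matrix("constrained")
            E, ll = _em_fit(M, counts, pins)
            logl[i, j] = ll
            if gof_reps and np.isfinite(ll):
                cell = ModelFit(model=model, E_hat=TetradDistribution(
                    np.clip(E, 0, None) / np.clip(E, 0, None).sum()),
                    logL=ll, n=int(counts.sum()), counts=counts,
                    b_hat=None if np.isnan(b) else float(b))
                gof[i, j] = goodness_of_fit(cell, reps=gof_reps, seed=seed)
    if not np.any(np.isfinite(logl)):
        raise ValueError("empty feasible region on the requested grid")
    rel = np.exp(logl - np.nanmax(logl[np.isfinite(logl)]))
    i0, j0 = np.unravel_index(int(np.nanargmax(logl)), logl.shape)
    return {
        "e0_grid": e0_grid,
        "b_grid": b_grid,
        "loglik": logl,
        "rel_likelihood": rel,
        "gof_p": gof,
        "argmax": (float(e0_grid[i0]),
                   None if np.isnan(b_grid[j0]) else float(b_grid[j0])),
    }


# ---------------------------------------------------------------------------
# the negative-E0 sampling experiment


def e0_sampling_experiment(probs, n: int, reps: int = 10000,
                           seed: int = 0) -> float:
    """Fraction of resampled studies of size ``n`` whose raw Weinstein
    inversion yields a negative ``E0``.

    Draws ``reps`` multinomial class-count tables from ``probs``, inverts each,
    and returns the fraction with ``E0 < 0`` — the chance a finite study of a
    given size reports an impossible (negative) zero-crossover tetrad class.
    """
    p = np.zeros(N_CLASSES)
    probs = np.asarray(probs, dtype=float)
    p[: probs.size] = probs
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(int(n), p, size=int(reps)).astype(float)
    f = sims / n
    # linear inversion, vectorized over replicates
    E4 = 16.0 * f[:, 4]
    E3 = 8.0 * (f[:, 3] - E4 / 4.0)
    E2 = 4.0 * (f[:, 2] - 3.0 * E3 / 8.0 - 3.0 * E4 / 8.0)
    E1 = 2.0 * (f[:, 1] - E2 / 2.0 - 3.0 * E3 / 8.0 - E4 / 4.0)
    E0 = 1.0 - (E1 + E2 + E3 + E4)
    return float(np.mean(E0 < 0.0))


def combine_arms(counts_by_arm: dict, method: str = "pooled") -> TetradDistribution:
    """Combine per-arm class counts into a single tetrad estimate.

    ``method="pooled"`` sums the count tables before inversion;
    ``method="mean"`` averages the per-arm inversions weighted by chromatid
    number.  The two differ whenever arms have unequal class distributions;
    neither is privileged.
    """
    tables = {k: np.asarray(v, dtype=float) for k, v in counts_by_arm.items()}
    if method == "pooled":
        return weinstein_invert(sum(tables.values()))
    if method == "mean":
        ns = {k: v.sum() for k, v in tables.items()}
        total = sum(ns.values())
        E = sum(weinstein_invert(v).E * (ns[k] / total) for k, v in tables.items())
        return TetradDistribution(E)
    raise ValueError(f"unknown method {method!r}")
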