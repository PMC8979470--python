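"""Tetrad inference: Weinstein inversion, forward models, ML fitting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

import meioscope as ms
from meioscope.tetrad import (conditional_matrix, multinomial_logpmf,
                              saturated_loglik)


def simplex5(draw_floats):
    raw = np.array(draw_floats)
    return raw / raw.sum()


simplex_strategy = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=5, max_size=5
).map(simplex5)


class TestWeinsteinInversion:
    @pytest.mark.parametrize("counts, e0", [
        ([447, 901, 200, 74, 0], -0.2022),     # strong 1CO excess -> negative
        ([0.50, 0.45, 0.05, 0, 0], 0.10),
        ([123, 0, 0, 0, 0], 1.0),
    ])
    def test_e0(self, counts, e0):
        assert ms.weinstein_invert(counts).E[0] == pytest.approx(e0, abs=5e-4)

    def test_full_vector_on_x(self, x_counts):
        E = ms.weinstein_invert(x_counts)
        assert not E.feasible
        # forward oracle: the inversion must reproduce the observed class
        # frequencies exactly when pushed back through the linear system
        f = x_counts / x_counts.sum()
        M = conditional_matrix("weinstein")
        np.testing.assert_allclose(M @ E.E, f, atol=1e-12)

    @given(E=simplex_strategy)
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_forward_inverse_identity(self, E):
        probs = ms.class_probs(E, "weinstein")
        back = ms.weinstein_invert(probs * 1000.0)
        np.testing.assert_allclose(back.E, E, atol=1e-9)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            ms.weinstein_invert([0, 0, 0, 0, 0])


def brute_force_pci(r, b):
    """Independent PCI oracle: enumerate all 2^r sister-assignment sequences."""
    probs = np.zeros(r + 1)
    for seq in itertools.product([0, 1], repeat=r):
        a = c = 0
        p = 1.0
        for chromatid in seq:
            if a == c:
                p *= 0.5
            elif chromatid == 0:
                p *= b if a < c else 1.0 - b
            else:
                p *= b if c < a else 1.0 - b
            a += chromatid == 0
            c += chromatid == 1
        probs[a] += 0.5 * p
        probs[c] += 0.5 * p
    return probs


class TestClassProbs:
    def test_weinstein_e2(self):
        p = ms.class_probs([0, 0, 1, 0, 0], "weinstein")
        np.testing.assert_allclose(p, [0.25, 0.5, 0.25, 0, 0], atol=1e-12)

    @given(E=simplex_strategy)
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_mdco_reduces_to_weinstein_at_half(self, E):
        np.testing.assert_allclose(ms.class_probs(E, "md_co", 0.5),
                                   ms.class_probs(E, "weinstein"), atol=1e-12)

    def test_pci_extreme_two_crossovers(self):
        p = ms.class_probs([0, 0, 1, 0, 0], "pci", 1.0)
        np.testing.assert_allclose(p, [0, 1, 0, 0, 0], atol=1e-12)

    @pytest.mark.parametrize("b", [0.5, 0.63, 0.8, 1.0])
    def test_pci_matches_bruteforce_enumeration(self, b):
        M = conditional_matrix("pci", b)
        for r in range(5):
            np.testing.assert_allclose(M[: r + 1, r], brute_force_pci(r, b),
                                       atol=1e-12)

    @given(E=simplex_strategy, b=st.floats(min_value=0.5, max_value=1.0))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_normalization_and_means(self, E, b):
        r = np.arange(5)
        for model in ("weinstein", "md_co", "pci"):
            p = ms.class_probs(E, model, b)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0)
        mean_md = (ms.class_probs(E, "md_co", b) * r).sum()
        expect_md = (E * (r / 2 + r * (2 * b - 1) / 2.0**r)).sum()
        assert mean_md == pytest.approx(expect_md, abs=1e-12)
        # chromatid interference redistributes crossovers without changing
        # the mean number transmitted
        mean_pci = (ms.class_probs(E, "pci", b) * r).sum()
        assert mean_pci == pytest.approx((E * r / 2).sum(), abs=1e-12)

    def test_negative_e_rejected(self):
        with pytest.raises(ValueError):
            ms.class_probs([-0.1, 1.1, 0, 0, 0], "weinstein")


class TestFitting:
    def test_self_consistency_exact_counts(self):
        E_true = np.array([0.10, 0.55, 0.20, 0.12, 0.03])
        b_true = 0.8
        counts = ms.class_probs(E_true, "md_co", b_true) * 1e6
        fit = ms.fit_tetrad_model(counts, "md_co", compute_ci=False)
        # the drive model is ridge-degenerate: the truth must lie inside the
        # maximum-likelihood intervals and the fit must be saturated
        assert fit.logL == pytest.approx(saturated_loglik(counts), abs=1e-5)
        lo, hi = fit.ridge["b"]
        assert lo - 1e-3 <= b_true <= hi + 1e-3
        lo, hi = fit.ridge["E0"]
        assert lo - 1e-3 <= E_true[0] <= hi + 1e-3
        # pinning E0 restores identifiability of the drive parameter
        pinned = ms.fit_tetrad_model(counts, "md_co",
                                     fixed={"E0": E_true[0]},
                                     compute_ci=False)
        assert pinned.b_hat == pytest.approx(b_true, abs=0.03)
        np.testing.assert_allclose(pinned.E_hat.E, E_true, atol=0.03)

    def test_constrained_fit_x_hits_boundary(self, x_counts):
        fit = ms.fit_tetrad_model(x_counts, "constrained", compute_ci=False)
        assert fit.E_hat.E[0] == pytest.approx(0.0, abs=1e-6)

    def test_mdco_ridge_on_x(self, x_fit_mdco, x_counts):
        fit = x_fit_mdco
        assert fit.logL == pytest.approx(saturated_loglik(x_counts), abs=1e-6)
        b_lo, b_hi = fit.ridge["b"]
        assert b_lo == pytest.approx(0.6375, abs=0.002)
        assert b_hi == pytest.approx(1.0, abs=1e-6)
        e_lo, e_hi = fit.ridge["E0"]
        assert e_lo == pytest.approx(0.0, abs=0.002)
        assert e_hi == pytest.approx(0.2756, abs=0.002)

    def test_infeasible_pin_errors(self):
        # all mass pinned into a class that cannot produce the observed 1COs
        with pytest.raises(ValueError):
            ms.fit_tetrad_model([0, 100, 0, 0, 0], "constrained",
                                fixed={"E0": 1.0}, compute_ci=False)

    def test_weinstein_free_model_is_saturated(self, x_counts):
        fit = ms.fit_tetrad_model(x_counts, "weinstein", compute_ci=False)
        assert fit.logL == pytest.approx(saturated_loglik(x_counts), abs=1e-9)
        assert not fit.E_hat.feasible


class TestGoodnessOfFit:
    def test_observed_equals_expected_gives_one(self):
        counts = np.array([250, 500, 250, 0, 0], dtype=float)
        fit = ms.fit_tetrad_model(counts, "constrained", compute_ci=False)
        assert ms.goodness_of_fit(fit, reps=5000, seed=3) == 1.0

    def test_gross_mismatch_is_extreme(self):
        counts = np.array([0, 0, 0, 1000, 0], dtype=float)
        fit = ms.fit_tetrad_model(np.array([495, 495, 10, 0, 0.0]),
                                  "constrained", compute_ci=False)
        fit.counts = counts
        assert ms.goodness_of_fit(fit, counts, reps=5000, seed=3) < 1e-3

    def test_matches_exhaustive_enumeration(self):
        # toy case small enough to enumerate every multinomial outcome
        p3 = np.array([0.5, 0.3, 0.2])
        obs3 = np.array([3, 3, 4], dtype=float)
        n = 10
        exact = 0.0
        obs_ll = multinomial_logpmf(obs3, p3)
        for a in range(n + 1):
            for b in range(n - a + 1):
                x = np.array([a, b, n - a - b], dtype=float)
                ll = multinomial_logpmf(x, p3)
                if ll <= obs_ll + 1e-9:
                    exact += np.exp(ll)
        mc = _gof_with_probs(obs3, p3, reps=40000, seed=9)
        sd = np.sqrt(exact * (1 - exact) / 40000)
        assert mc == pytest.approx(exact, abs=3.5 * sd)

    def test_small_reps_warns(self, x_fit_mdco):
        with pytest.warns(UserWarning):
            ms.goodness_of_fit(x_fit_mdco, reps=500, seed=0)


def _gof_with_probs(counts, p, reps, seed):
    """Monte-Carlo GOF against explicit class probabilities (duck-typed fit,
    padded so the 3-class toy case runs through the library routine)."""
    from types import SimpleNamespace

    from meioscope.tetrad import N_CLASSES

    pad = N_CLASSES - len(p)
    p5 = np.concatenate([np.asarray(p, float), np.zeros(pad)])
    c5 = np.concatenate([np.asarray(counts, float), np.zeros(pad)])
    fit = SimpleNamespace(counts=c5, probs=p5, model="constrained",
                          gof_p=None)
    return ms.goodness_of_fit(fit, c5, reps=reps, seed=seed)


class TestModelComparison:
    def test_lrt_self_is_zero(self, x_fit_mdco):
        stat, p = ms.likelihood_ratio(x_fit_mdco, x_fit_mdco)
        assert stat == 0.0
        assert p == 1.0

    def test_lrt_requires_same_data(self, x_fit_mdco):
        other = ms.fit_tetrad_model([100, 100, 10, 0, 0.0], "constrained",
                                    compute_ci=False)
        with pytest.raises(ValueError):
            ms.likelihood_ratio(x_fit_mdco, other)

    def test_drive_beats_no_drive_on_x(self, x_counts, x_fit_mdco):
        con = ms.fit_tetrad_model(x_counts, "constrained", compute_ci=False)
        stat, p = ms.likelihood_ratio(x_fit_mdco, con)
        assert stat > 0
        assert p < 1e-13


class TestProfileSurface:
    def test_degenerate_single_cell(self, x_counts):
        surf = ms.profile_surface(x_counts, "md_co",
                                  e0_grid=[0.14], b_grid=[0.82])
        assert surf["argmax"] == (0.14, 0.82)
        assert surf["rel_likelihood"].shape == (1, 1)

    def test_1d_profile_peaks_at_truth(self):
        E_true = np.array([0.2, 0.5, 0.2, 0.1, 0.0])
        counts = ms.class_probs(E_true, "weinstein") * 1e5
        surf = ms.profile_surface(counts, "constrained",
                                  e0_grid=np.arange(0.0, 0.41, 0.02))
        assert surf["argmax"][0] == pytest.approx(0.2, abs=1e-9)

    def test_x_ridge_spans_wide_parameter_range(self, x_counts):
        # the drive model fits the X data essentially perfectly along a whole
        # curve of (E0, b) combinations, not at an isolated point
        e0s = []
        for b in (0.65, 0.75, 0.85, 0.95):
            fit = ms.fit_tetrad_model(x_counts, "md_co", fixed={"b": b},
                                      compute_ci=False)
            assert ms.goodness_of_fit(fit, reps=3000, seed=4) > 0.99
            e0s.append(fit.E_hat.E[0])
        assert max(e0s) - min(e0s) > 0.15


class TestE0Sampling:
    def test_no_single_crossover_mass_never_negative(self):
        frac = ms.e0_sampling_experiment([0.6, 0.0, 0.4], n=200, reps=2000,
                                         seed=5)
        assert frac == 0.0

    def test_matches_binomial_tail_oracle(self):
        # with classes <= 2CO, E0 = 1 - 2 f1, so E0 < 0 iff the 1CO count
        # exceeds n/2: an exact binomial tail
        n, reps = 250, 40000
        frac = ms.e0_sampling_experiment([0.50, 0.45, 0.05], n=n, reps=reps,
                                         seed=7)
        exact = float(binom.sf(n // 2, n, 0.45))
        sd = np.sqrt(exact * (1 - exact) / reps)
        assert frac == pytest.approx(exact, abs=3.5 * sd)

    def test_smaller_studies_go_negative_more_often(self):
        f250 = ms.e0_sampling_experiment([0.50, 0.45, 0.05], 250, 20000, 1)
        f100 = ms.e0_sampling_experiment([0.50, 0.45, 0.05], 100, 20000, 1)
        assert f100 > f250 > 0


class TestCombiners:
    def test_pooled_vs_mean_both_sum_to_one(self, table1):
        tables = {a: table1.loc[a].to_numpy(float) for a in table1.index}
        pooled = ms.combine_arms(tables, "pooled")
        mean = ms.combine_arms(tables, "mean")
        assert pooled.E.sum() == pytest.approx(1.0, abs=1e-9)
        assert mean.E.sum() == pytest.approx(1.0, abs=1e-9)
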