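"""Information density, RS length choice, loss-model fits and alpha selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dnachannel.redundancy import (
    ErrorProfile,
    LostModel,
    PermittedModel,
    choose_alpha,
    choose_rs_length,
    failure_probability,
    fit_lost,
    fit_permitted,
    information_density,
    total_lost,
)


def make_profile(n_lost=0, n_e=None, m=100, payload=20, beta=0.05):
    n_e = dict(n_e or {})
    n_e[0] = m - n_lost - sum(n_e.get(i, 0) for i in n_e if i != 0)
    return ErrorProfile(n_lost=n_lost, n_e=n_e, m=m, payload_bytes=payload, beta=beta)


class TestInformationDensity:
    def test_perfect_channel_is_lossless(self):
        profile = make_profile(beta=0.0)
        assert information_density(0, profile) == 1.0

    def test_printed_form_arithmetic(self):
        # L_d=32, k=2, N=100, beta=0.05, N_l=3, tail(>=2)=7: (32/36)(100/115)
        profile = ErrorProfile(
            n_lost=3, n_e={0: 90, 2: 7}, m=100, payload_bytes=32, beta=0.05
        )
        d = information_density(2, profile, tail_mode="printed")
        assert d == pytest.approx((32 / 36) * (100 / 115), abs=1e-12)
        # capacity mode keeps the exactly-2-error sequences
        assert information_density(2, profile) == pytest.approx(
            (32 / 36) * (100 / 108), abs=1e-12
        )

    def test_strictly_decreasing_in_lost_count(self):
        ds = [
            information_density(1, make_profile(n_lost=nl, n_e={2: 5}))
            for nl in (0, 5, 10, 20)
        ]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_scale_invariance_in_counts(self):
        p1 = make_profile(n_lost=4, n_e={1: 10, 3: 2}, m=100)
        p5 = make_profile(n_lost=20, n_e={1: 50, 3: 10}, m=500)
        for k in range(4):
            assert information_density(k, p1) == pytest.approx(
                information_density(k, p5), rel=1e-12
            )


class TestChooseRsLength:
    def test_error_free_pool_needs_no_parity(self):
        assert choose_rs_length(make_profile()) == 0

    def test_dominant_single_error_class_selects_two_bytes(self):
        # discarding the 20% one-error sequences costs more than 2 parity bytes
        profile = make_profile(n_e={1: 20}, beta=0.0)
        d0 = information_density(0, profile)
        d1 = information_density(1, profile)
        assert d1 > d0  # verified by hand: 20/22 > 100/120 * 20/20
        assert choose_rs_length(profile) == 2

    def test_invariant_to_count_scaling(self):
        a = make_profile(n_lost=6, n_e={1: 25, 2: 8}, m=200)
        b = make_profile(n_lost=18, n_e={1: 75, 2: 24}, m=600)
        assert choose_rs_length(a) == choose_rs_length(b)


class TestTotalLost:
    def test_clean_channel(self):
        assert total_lost(make_profile(), l_rs=2) == 0

    def test_capacity_rule_example(self):
        profile = make_profile(n_lost=4, n_e={1: 10, 2: 3}, m=100)
        assert total_lost(profile, l_rs=2) == 4 + 3  # corrects 1 byte
        assert total_lost(profile, l_rs=0) == 4 + 13

    def test_non_increasing_in_l_rs(self):
        profile = make_profile(n_lost=2, n_e={1: 9, 2: 5, 4: 3}, m=100)
        ntl = [total_lost(profile, l_rs) for l_rs in range(0, 10, 2)]
        assert all(a >= b for a, b in zip(ntl, ntl[1:]))


class TestFitLost:
    def test_mle_is_the_mean(self):
        assert fit_lost([2, 4, 3, 3]).lam == pytest.approx(3.0)

    def test_all_zero_degenerates_to_point_mass(self):
        model = fit_lost([0, 0, 0, 0])
        assert model.lam == 0
        assert model.sf(0) == 0.0

    def test_estimator_standard_error(self, rng):
        samples = rng.poisson(8, size=200)
        assert abs(fit_lost(samples).lam - 8) < 3 * np.sqrt(8 / 200)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fit_lost([3])
        with pytest.raises(ValueError):
            fit_lost([1, -2])


class TestFitPermitted:
    def test_degenerate_point_mass(self):
        with pytest.warns(UserWarning):
            model = fit_permitted([110] * 6, m=100)
        assert model.degenerate
        assert model.needed_cdf(109.9) == 0 and model.needed_cdf(110) == 1

    def test_parameter_recovery_within_five_percent_rms(self):
        mu, sigma, n, trials = 1100.0, 25.0, 500, 50
        rng = np.random.default_rng(77)
        errs_loc, errs_scale = [], []
        for _ in range(trials):
            x = stats.gumbel_r.rvs(loc=mu, scale=sigma, size=n, random_state=rng)
            fit = fit_permitted(np.maximum(x, 1000), m=1000)
            errs_loc.append((fit.loc - mu) / mu)
            errs_scale.append((fit.scale - sigma) / sigma)
        assert np.sqrt(np.mean(np.square(errs_loc))) < 0.05
        assert np.sqrt(np.mean(np.square(errs_scale))) < 0.05

    def test_gumbel_beats_normal_on_skewed_data(self):
        rng = np.random.default_rng(42)
        wins = 0
        for _ in range(50):
            x = stats.gumbel_r.rvs(loc=550, scale=12, size=200, random_state=rng)
            ad_g = stats.anderson(x, dist="gumbel_r").statistic
            ad_n = stats.anderson(x, dist="norm").statistic
            wins += ad_g < ad_n
        assert wins > 25


class _FinitePmf:
    """Duck-typed permitted-lost model with explicit pmf (test double)."""

    def __init__(self, pmf: dict[int, float], m: int = 100):
        self.pmf_map = pmf
        self.m = m
        self.degenerate = False

    def needed_cdf(self, x):
        # droplets-needed = (1+alpha)m - permitted, evaluated only through the
        # helpers below in these tests
        raise NotImplementedError

    def permitted_pmf(self, alpha, t_max):
        out = np.zeros(t_max + 1)
        for j, p in self.pmf_map.items():
            if 0 <= j <= t_max:
                out[j] = p
        return out / out.sum()

    def p_infeasible(self, alpha):
        return sum(p for j, p in self.pmf_map.items() if j < 0)

    def permitted_quantile(self, alpha, q):
        return max(self.pmf_map)


class _FiniteLost:
    def __init__(self, pmf: dict[int, float]):
        self.pmf_map = pmf

    def sf(self, j):
        j = np.atleast_1d(j)
        return np.array([
            sum(p for i, p in self.pmf_map.items() if i > jj) for jj in j
        ])


def brute_force_pf(lost_pmf, perm_pmf):
    return sum(
        pl * pp
        for i, pl in lost_pmf.items()
        for j, pp in perm_pmf.items()
        if i > j or j < 0
    )


class TestFailureProbability:
    def test_no_losses_never_fails(self):
        lost = LostModel(0.0)
        perm = _FinitePmf({0: 0.3, 5: 0.7})
        assert failure_probability(0.1, lost, perm) == 0.0

    def test_certain_failure_when_losses_exceed_permitted(self):
        lost = _FiniteLost({5: 1.0})
        perm = _FinitePmf({3: 1.0})
        assert failure_probability(0.1, lost, perm) == pytest.approx(1.0)

    def test_enumeration_example(self):
        lost = _FiniteLost({0: 0.5, 2: 0.5})
        perm = _FinitePmf({1: 0.5, 3: 0.5})
        assert failure_probability(0.1, lost, perm) == pytest.approx(0.25)

    @given(
        st.dictionaries(st.integers(0, 8), st.floats(0.05, 1), min_size=1, max_size=5),
        st.dictionaries(st.integers(0, 8), st.floats(0.05, 1), min_size=1, max_size=5),
    )
    def test_matches_exhaustive_enumeration(self, lost_w, perm_w):
        zl = sum(lost_w.values())
        zp = sum(perm_w.values())
        lost_pmf = {k: v / zl for k, v in lost_w.items()}
        perm_pmf = {k: v / zp for k, v in perm_w.items()}
        got = failure_probability(0.1, _FiniteLost(lost_pmf), _FinitePmf(perm_pmf))
        assert got == pytest.approx(brute_force_pf(lost_pmf, perm_pmf), abs=1e-9)


class TestChooseAlpha:
    @staticmethod
    def fitted_permitted(m=500, beta=0.06, scale=6.0):
        loc = (1 + beta) * m - np.euler_gamma * scale
        return PermittedModel(loc, scale, m)

    def test_target_one_accepts_entire_grid(self):
        grid, pf, rng_ok = choose_alpha(1.0, 0.05, 500, self.fitted_permitted())
        assert rng_ok == (float(grid[0]), float(grid[-1]))

    def test_zero_loss_accepts_from_feasibility_point(self):
        grid = np.arange(0.10, 0.31, 0.01)
        g, pf, rng_ok = choose_alpha(0.01, 0.0, 500, self.fitted_permitted(), grid=grid)
        assert rng_ok is not None
        # with no losses, alpha only needs to cover the decoding overhead
        assert rng_ok[0] <= 0.11

    def test_pf_non_increasing_along_grid(self):
        g, pf, _ = choose_alpha(0.01, 0.08, 500, self.fitted_permitted())
        assert all(a >= b - 1e-8 for a, b in zip(pf, pf[1:]))

    def test_crossing_matches_dense_grid_oracle(self):
        perm = self.fitted_permitted(m=400, beta=0.05, scale=8.0)
        coarse = np.arange(0.05, 0.41, 0.01)
        dense = np.arange(0.05, 0.41, 0.0005)
        _, _, ok_c = choose_alpha(0.01, 0.07, 400, perm, grid=coarse)
        _, pf_d, _ = choose_alpha(0.01, 0.07, 400, perm, grid=dense)
        crossing = dense[np.flatnonzero(pf_d <= 0.01)[0]]
        assert ok_c is not None
        assert ok_c[0] == pytest.approx(coarse[np.searchsorted(coarse, crossing - 1e-9)], abs=1e-9)

    def test_unreachable_target_returns_empty(self):
        grid = np.arange(0.05, 0.071, 0.01)
        _, _, rng_ok = choose_alpha(1e-9, 0.5, 500, self.fitted_permitted(), grid=grid)
        assert rng_ok is None


def test_lost_model_rescaling():
    base = LostModel(10.0)
    scaled = base.rescaled(p_tl=0.02, alpha=0.25, n=1000)
    assert scaled.lam == pytest.approx(0.02 * 1.25 * 1000)


def test_end_to_end_lambda_recovery(rng):
    """fit_lost recovers lambda ~ p_tl (1+alpha) N from channel replicates."""
    from dnachannel.pool import ErrorRates
    from dnachannel.stages import SamplingConfig, SynthesisConfig, sample, synthesis

    M, mean_depth, ratio = 300, 100, 0.02
    # per-sequence loss probability under ~Poisson(mean_depth) counts
    p_lost = float(np.exp(-mean_depth * ratio))
    refs = ["ACGTACGTACGTACGTACGT"] * M
    cfg = SynthesisConfig(mean_depth=mean_depth, rates=ErrorRates.uniform())
    samples = []
    for r in range(50):
        pool = synthesis(refs, cfg, np.random.default_rng(1000 + r))
        thinned = sample(pool, SamplingConfig(ratio=ratio), np.random.default_rng(2000 + r))
        samples.append(int(thinned.lost.sum()))
    lam_hat = fit_lost(samples).lam
    expected = M * p_lost
    se = np.sqrt(expected / 50) + 0.05 * expected  # sampling + Poisson-approx slack
    assert abs(lam_hat - expected) < 3 * se
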