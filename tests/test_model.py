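import math

import numpy as np
import pytest
from scipy.stats import norm

from ibsancestry import model
from ibsancestry.model import (
    ANCESTRY_STATES,
    STATES,
    ModelParams,
    build_emissions,
    build_transitions,
    distribution_overlap,
    max_pairwise_overlap,
    minimum_window,
    recommend_window_size,
    resample_prob_z,
    separate_emissions,
)
from ibsancestry.popstats import DiversityEstimates

from wf_oracle import wf_z_monte_carlo


class TestResampleProbZ:
    def test_zero_generations(self):
        assert resample_prob_z(10, 0, 1e-3) == 0.0

    def test_one_generation_exact(self):
        # a single event at frequency 1/(2N) must land on both homologues
        for N in (1, 5, 100):
            assert resample_prob_z(N, 1, 1e-3) == pytest.approx(1e-3 / (2 * N), rel=1e-9)

    def test_monotone_in_g_and_r_decreasing_in_n(self):
        assert resample_prob_z(50, 20, 1e-3) > resample_prob_z(50, 10, 1e-3)
        assert resample_prob_z(50, 20, 2e-3) > resample_prob_z(50, 20, 1e-3)
        assert resample_prob_z(50, 20, 1e-3) > resample_prob_z(500, 20, 1e-3)

    def test_forward_wf_monte_carlo_small(self, rng):
        N, g, r = 5, 10, 1e-3
        z_mc, se = wf_z_monte_carlo(N, g, r, n_reps=200_000, rng=rng)
        assert abs(resample_prob_z(N, g, r) - z_mc) < 3 * se

    def test_drift_term_dominates_recombination_squared(self):
        # at the validation-run parameters the shared-event term must exceed
        # the (g*r)^2 double-recombination term
        z = resample_prob_z(3000, 1000, 1e-8)
        assert z > (1000 * 1e-8) ** 2


def _params(div, **kw):
    defaults = dict(g=1000, p=0.5, N=3000, a=5, b=5, diversity=div, w=10_000)
    defaults.update(kw)
    return ModelParams(**defaults)


class TestBuildTransitions:
    def test_double_recombination_worked_case(self, bear_div):
        # with drift negligible (huge N), per-site AA->BB is (g*r)^2 * (1-p)^2
        params = _params(bear_div, N=1e12, w=1, p=0.5)
        tm = build_transitions(params, n_windows=100, s=0.0)
        expected = (1000 * 1e-8) ** 2 * 0.25
        assert tm.probs[0, 2] == pytest.approx(expected, rel=1e-3)

    def test_start_vector_hardy_weinberg(self, bear_div):
        tm = build_transitions(_params(bear_div, p=0.5), n_windows=10, s=0.0)
        assert tm.start.tolist() == pytest.approx([0.25, 0.5, 0.25, 0, 0, 0])

    def test_het_to_homozygous_matches_event_enumeration(self, bear_div):
        """AB->AA equals an exhaustive enumeration over the two-homologue
        event space: each homologue recombines (prob R) or not, a recombined
        homologue lands in A with prob p; plus the shared-drift event."""
        params = _params(bear_div, N=3000, g=1000, w=10_000, p=0.3)
        tm = build_transitions(params, n_windows=50, s=0.0)
        R, Z, p = tm.R, tm.Z, params.p

        def homologue_outcomes(current: str):
            # (probability, resulting ancestry) for one homologue per step
            yield (1 - R), current
            yield R * p, "A"
            yield R * (1 - p), "B"

        # current state AB: homologue 1 carries A, homologue 2 carries B.
        # independent-event part: enumerate both homologues' outcomes;
        # shared-drift part: one ancestral event copied onto both homologues.
        total = sum(
            p1 * p2
            for p1, end1 in homologue_outcomes("A")
            for p2, end2 in homologue_outcomes("B")
            if end1 == "A" and end2 == "A"
        )
        total += Z * p
        assert tm.probs[1, 0] == pytest.approx(total, rel=1e-12)

    def test_rows_sum_to_one_for_random_draws(self, rng):
        for _ in range(10_000):
            div = DiversityEstimates(
                pi_A=rng.uniform(1e-5, 0.01), pi_B=rng.uniform(1e-5, 0.01),
                pi_AB=rng.uniform(1e-4, 0.02),
            )
            # valid (non-saturated) regime: g*r*w well below 1
            g = rng.uniform(0, 3000)
            r = 10 ** rng.uniform(-9, -7.5)
            w_cap = max(2.0, min(50_000.0, 0.05 / (g * r + 1e-300)))
            params = ModelParams(
                g=g, p=rng.uniform(0.001, 0.999),
                N=rng.uniform(1, 1e6), a=1, b=1, diversity=div,
                w=int(rng.integers(1, w_cap)), r=r,
            )
            tm = build_transitions(params, n_windows=int(rng.integers(3, 1000)), s=rng.uniform(0, 0.5))
            np.testing.assert_allclose(tm.probs.sum(axis=1) + tm.end, 1.0, atol=1e-12)
            assert tm.probs.min() >= 0 and tm.probs.max() <= 1

    def test_skip_states_copy_parent_cross_transitions(self, bear_div):
        tm = build_transitions(_params(bear_div, p=0.3), n_windows=20, s=0.1)
        idx = {s: i for i, s in enumerate(STATES)}
        for anc in ANCESTRY_STATES:
            for other in ANCESTRY_STATES:
                if other != anc:
                    assert tm.probs[idx["s" + anc], idx[other]] == tm.probs[idx[anc], idx[other]]
            assert tm.probs[idx[anc], idx["s" + anc]] == 0.1
            assert tm.probs[idx["s" + anc], idx["s" + anc]] == 0.1

    def test_g_zero_forbids_switching(self, bear_div):
        tm = build_transitions(_params(bear_div, g=0), n_windows=10, s=0.0)
        off = tm.probs[:3, :3].copy()
        np.fill_diagonal(off, 0.0)
        assert off.max() == 0.0

    def test_saturated_window_errors(self, bear_div):
        params = _params(bear_div, g=5000, r=1e-6, w=10_000_000)
        with pytest.raises(ValueError, match="smaller window"):
            build_transitions(params, n_windows=1, s=0.5)


class TestBuildEmissions:
    def test_no_differentiation_gives_zero_mean(self):
        div = DiversityEstimates(pi_A=0.002, pi_B=0.002, pi_AB=0.002)
        params = _params(div, w=20_000)
        spec = build_emissions(params, mode="analytic")
        assert spec.mu[0] == pytest.approx(0.0, abs=1e-12)

    def test_mean_ordering(self, bear_div):
        spec = build_emissions(_params(bear_div), mode="analytic")
        assert spec.mu[0] > spec.mu[1] > spec.mu[2]

    def test_sigma_decreases_with_window_size(self, bear_div):
        s1 = build_emissions(_params(bear_div, w=10_000), mode="analytic").sigma
        s2 = build_emissions(_params(bear_div, w=20_000), mode="analytic").sigma
        s3 = build_emissions(_params(bear_div, w=40_000), mode="analytic").sigma
        assert (s2 < s1).all() and (s3 < s2).all()

    def test_doubling_window_roughly_halves_variance(self, bear_div):
        s1 = build_emissions(_params(bear_div, w=20_000), mode="analytic").sigma
        s2 = build_emissions(_params(bear_div, w=40_000), mode="analytic").sigma
        ratio = (s2 / s1) ** 2
        assert np.allclose(ratio, 0.5, atol=0.06)

    def test_window_below_minimum_errors(self, bear_div):
        w_min = minimum_window(bear_div, 5, 5)
        with pytest.raises(ValueError, match="minimum"):
            build_emissions(_params(bear_div, w=w_min - 1), mode="analytic")

    def test_monte_carlo_mode_close_to_analytic(self, bear_div, rng):
        params = _params(bear_div, p=0.2)
        an = build_emissions(params, mode="analytic")
        mc = build_emissions(params, mode="monte_carlo", rng=rng, n_windows_mc=500)
        assert np.abs(an.mu - mc.mu).max() < 0.05
        assert mc.mode == "monte_carlo" and an.mode == "analytic"


class TestDistributionOverlap:
    def test_identical_distributions(self):
        assert distribution_overlap(0.3, 0.7, 0.3, 0.7) == pytest.approx(1.0, abs=1e-6)

    def test_equal_variance_closed_form(self):
        assert distribution_overlap(0, 1, 2, 1) == pytest.approx(2 * norm.cdf(-1), abs=1e-4)

    def test_widely_separated(self):
        assert distribution_overlap(0, 1, 100, 1) == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_and_monotone_in_separation(self):
        assert distribution_overlap(0, 1, 2, 3) == pytest.approx(distribution_overlap(2, 3, 0, 1))
        prev = 1.0
        for d in (0.5, 1.0, 2.0, 4.0):
            ov = distribution_overlap(0, 1, d, 1)
            assert ov < prev
            prev = ov


class TestRecommendWindowSize:
    def test_well_separated_returns_smallest_grid_value(self):
        div = DiversityEstimates(pi_A=0.001, pi_B=0.002, pi_AB=0.05)
        params = ModelParams(g=1000, p=0.5, N=3000, a=5, b=5, diversity=div)
        grid = [4000, 8000, 16000]
        rec = recommend_window_size(params, grid=grid)
        assert rec.satisfied and rec.w == 4000

    def test_indistinguishable_populations_warning_path(self, caplog):
        div = DiversityEstimates(pi_A=0.002, pi_B=0.002, pi_AB=0.002)
        params = ModelParams(g=1000, p=0.5, N=3000, a=5, b=5, diversity=div)
        grid = [2000, 4000]
        with caplog.at_level("WARNING", logger="ibsancestry.model"):
            rec = recommend_window_size(params, grid=grid)
        assert not rec.satisfied and rec.w == 4000
        assert any("differentiated" in m for m in caplog.messages)

    def test_matches_brute_force_grid_scan(self, bear_div):
        """The recommended window equals the one found by scanning the grid
        with an independent Riemann-sum overlap integrator."""
        params = ModelParams(g=1000, p=0.5, N=3000, a=2, b=2, diversity=bear_div)
        grid = list(range(9000, 60_001, 3000))
        rec = recommend_window_size(params, grid=grid)

        def riemann_overlap(m1, s1, m2, s2):
            lo = min(m1 - 9 * s1, m2 - 9 * s2)
            hi = max(m1 + 9 * s1, m2 + 9 * s2)
            xs = np.linspace(lo, hi, 60_000)
            h = xs[1] - xs[0]
            return float(np.minimum(norm.pdf(xs, m1, s1), norm.pdf(xs, m2, s2)).sum() * h)

        chosen = None
        for w in grid:
            spec = build_emissions(params.with_window(w), mode="analytic")
            pairs = [(0, 1), (0, 2), (1, 2)]
            mx = max(riemann_overlap(spec.mu[i], spec.sigma[i], spec.mu[j], spec.sigma[j]) for i, j in pairs)
            if mx <= 0.5:
                chosen = w
                break
        assert rec.w == chosen

    def test_forced_window_shrinks_sds(self):
        div = DiversityEstimates(pi_A=0.002, pi_B=0.0021, pi_AB=0.00215)
        params = ModelParams(g=1000, p=0.5, N=3000, a=5, b=5, diversity=div, w=5000)
        spec = build_emissions(params, mode="analytic")
        assert max_pairwise_overlap(spec) > 0.5
        shrunk = separate_emissions(spec)
        assert shrunk.shrink_count >= 1
        assert max_pairwise_overlap(shrunk) < 0.5
        np.testing.assert_allclose(shrunk.sigma, spec.sigma * 0.5**shrunk.shrink_count)

    def test_minimum_window_matches_tract_count_bound(self, bear_div):
        # >= 10 expected tracts per panel comparison on each side
        w = minimum_window(bear_div, 5, 5)
        assert 5 * w * bear_div.pi_A >= 10
        assert 5 * (w - 1) * bear_div.pi_A < 10
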