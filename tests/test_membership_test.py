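"""Distance vector, z-statistic, decision rule, and analytic corrections."""

import itertools
import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import microprivacy as mp


def _profile(y):
    return mp.TaxonProfile(y=np.asarray(y))


def _summary(freq, n=10, label="R"):
    return mp.GroupSummary(freq=np.asarray(freq, dtype=float), n=n, label=label)


class TestComputeDistances:
    def test_direct_substitution(self):
        d = mp.compute_distances(
            _profile([0, 0]), _summary([0.3, 0.3]), _summary([0.7, 0.7], label="C")
        )
        np.testing.assert_allclose(d, [-0.4, -0.4])

    def test_identical_summaries_give_zero(self):
        freq = np.linspace(0, 1, 8)
        for y in ([0] * 8, [1] * 8, [0, 1] * 4):
            d = mp.compute_distances(_profile(y), _summary(freq), _summary(freq, label="C"))
            np.testing.assert_allclose(d, 0.0)

    def test_closed_form_oracle_exhaustive(self):
        # For binary y, |y-r| - |y-c| == (1-2y)(r-c); enumerate the full grid.
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        for y, r, c in itertools.product([0, 1], levels, levels):
            d = mp.compute_distances(
                _profile([y, y]), _summary([r, r]), _summary([c, c], label="C")
            )
            expected = (1 - 2 * y) * (r - c)
            np.testing.assert_allclose(d, expected, atol=1e-15)
            assert -1.0 <= d[0] <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(mp.AlignmentError):
            mp.compute_distances(_profile([0, 1]), _summary([0.5]), _summary([0.5], label="C"))

    def test_otu_id_mismatch(self):
        q = mp.TaxonProfile(y=np.array([0, 1]), otu_ids=["a", "b"])
        r = mp.GroupSummary(freq=np.array([0.5, 0.5]), n=5, label="R", otu_ids=["a", "b"])
        c = mp.GroupSummary(freq=np.array([0.5, 0.5]), n=5, label="C", otu_ids=["a", "x"])
        with pytest.raises(mp.AlignmentError, match="x"):
            mp.compute_distances(q, r, c)


class TestZStatistic:
    def test_symmetric_vector_gives_zero(self):
        d = np.tile([0.2, -0.2], 50)
        z, d_mean, _ = mp.z_statistic(d)
        assert z == 0.0 and d_mean == 0.0

    def test_degenerate_variance(self):
        with pytest.raises(mp.DegenerateVarianceError):
            mp.z_statistic(np.full(100, 0.1))

    def test_against_independent_oracle(self):
        d = list(np.random.default_rng(99).normal(0.01, 0.2, size=100))
        z, d_mean, d_sd = mp.z_statistic(d)
        # oracle: plain mean / sample stdev / scaling via the stdlib
        mean_o = statistics.fmean(d)
        sd_o = statistics.stdev(d)
        z_o = (mean_o - 0.0) / (sd_o / math.sqrt(len(d)))
        assert z == pytest.approx(z_o, rel=1e-12)
        assert d_mean == pytest.approx(mean_o, rel=1e-12)
        assert d_sd == pytest.approx(sd_o, rel=1e-12)

    def test_nonzero_mu0_shifts(self):
        d = np.random.default_rng(1).normal(0.5, 0.1, size=200)
        z0, m, s = mp.z_statistic(d)
        z1, _, _ = mp.z_statistic(d, mu0=0.5)
        assert z1 == pytest.approx(z0 - 0.5 / (s / math.sqrt(200)))

    def test_small_t_warns(self):
        with pytest.warns(mp.SmallOtuCountWarning):
            mp.z_statistic(np.arange(10, dtype=float))

    def test_too_short(self):
        with pytest.raises(mp.InputError):
            mp.z_statistic([0.1])


class TestDecide:
    def test_standard_normal_quantiles(self):
        q = stats.norm.ppf
        assert mp.decide(2.0, 0.05, q) == "HC"  # 2.0 > 1.6449
        assert mp.decide(0.0, 0.05, q) == "H0"
        assert mp.decide(-3.0, 0.05, q) == "HR"
        assert mp.decide(1.6, 0.05, q) == "H0"

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.7, -0.1])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(mp.ParameterError):
            mp.decide(1.0, alpha, stats.norm.ppf)


class TestEffectiveOtus:
    def test_negative_correlation_inflates(self):
        adj = mp.effective_otus(1000, -0.001)
        assert adj.t_e == pytest.approx(1_000_000, rel=1e-9)

    def test_positive_correlation_shrinks(self):
        adj = mp.effective_otus(1000, 0.001)
        assert adj.t_e == pytest.approx(1000 / 1.999)
        assert round(adj.t_e) == 500

    @pytest.mark.parametrize("t", [2, 50, 12345])
    def test_zero_correlation_identity(self, t):
        assert mp.effective_otus(t, 0.0).t_e == t

    def test_lower_bound_is_infinite(self):
        assert mp.effective_otus(11, -0.1).t_e == math.inf

    def test_below_lower_bound_rejected(self):
        with pytest.raises(mp.ParameterError):
            mp.effective_otus(11, -0.11)
        with pytest.raises(mp.ParameterError):
            mp.effective_otus(100, 1.5)

    @given(st.integers(2, 10_000), st.data())
    def test_strictly_decreasing_in_rho(self, t, data):
        lower = -1.0 / (t - 1)
        r1 = data.draw(st.floats(lower + 1e-6, 1.0, allow_nan=False))
        r2 = data.draw(st.floats(lower + 1e-6, 1.0, allow_nan=False))
        lo, hi = sorted((r1, r2))
        if hi - lo > 1e-12:
            assert mp.effective_otus(t, hi).t_e < mp.effective_otus(t, lo).t_e


class TestAdjustedVariance:
    def test_endpoints(self):
        v = 0.37
        assert mp.adjusted_variance(v, 100, 0.0) == pytest.approx(v / 100)
        assert mp.adjusted_variance(v, 100, 1.0) == pytest.approx(v)
        assert mp.adjusted_variance(v, 100, -1 / 99) == pytest.approx(0.0, abs=1e-15)

    def test_equals_v_over_te(self):
        v, t, rho = 0.5, 200, 0.02
        assert mp.adjusted_variance(v, t, rho) == pytest.approx(
            v / mp.effective_otus(t, rho).t_e
        )


class TestShiftedNullMean:
    def test_zero_delta(self):
        for ep in (0.1, 0.5, 1.0):
            assert mp.shifted_null_mean(0.0, ep).mu0_star == 0.0

    def test_balanced_presence_cancels(self):
        for ed in (-1.0, -0.3, 0.4, 1.0):
            assert mp.shifted_null_mean(ed, 0.5).mu0_star == 0.0

    def test_grid_maximum_magnitude(self):
        # brute-force |mu0*| over the admissible rectangle
        best = max(
            abs(mp.shifted_null_mean(ed, ep).mu0_star)
            for ed in np.linspace(-1, 1, 201)
            for ep in np.linspace(0.005, 1, 200)
        )
        assert best == pytest.approx(1.0)

    def test_out_of_range(self):
        with pytest.raises(mp.ParameterError):
            mp.shifted_null_mean(1.5, 0.5)
        with pytest.raises(mp.ParameterError):
            mp.shifted_null_mean(0.5, 0.0)

    @given(
        st.floats(-1, 1, allow_nan=False),
        st.floats(0.001, 1.0, allow_nan=False),
    )
    def test_bounded_by_one(self, ed, ep):
        assert abs(mp.shifted_null_mean(ed, ep).mu0_star) <= 1.0 + 1e-12


@pytest.fixture(scope="module")
def scenario():
    pop = mp.sample_population(2000, 1, 1, seed=21)
    sr = mp.draw_sample(pop, 10, "R", seed=21)
    sc = mp.draw_sample(pop, 10, "C", seed=22)
    return pop, mp.summarize_sample(sr), mp.summarize_sample(sc), sc


class TestRunMembershipTest:
    def test_swap_antisymmetry(self, scenario):
        pop, ref, case, _ = scenario
        q = mp.draw_microbiome(pop, seed=30)
        a = mp.run_membership_test(q, ref, case)
        b = mp.run_membership_test(q, case, ref)
        assert b.z == pytest.approx(-a.z, rel=1e-12)
        mapping = {"HC": "HR", "HR": "HC", "H0": "H0"}
        assert b.decision == mapping[a.decision]

    def test_case_member_is_detected(self, scenario):
        _, ref, case, sample_c = scenario
        member = mp.TaxonProfile(y=sample_c.rows[3])
        res = mp.run_membership_test(member, ref, case)
        assert res.decision == "HC"
        assert res.z > res.crit_high > 0

    def test_case_members_detected_in_bulk(self):
        # nearly every true case member should be flagged HC at these settings
        cfg = mp.SimulationConfig(
            t=2000, n_R=10, n_C=10, n_null_draws=1000, n_tp_draws=1000, seed=17
        )
        dists, power = mp.unequal_size_run(cfg)
        detected = np.mean(dists.z_tp_C > power.crit_high)
        assert detected > 0.99

    def test_outsider_calibration(self, scenario):
        pop, ref, case, _ = scenario
        decisions = [
            mp.run_membership_test(mp.draw_microbiome(pop, seed=1000 + s), ref, case).decision
            for s in range(100)
        ]
        # size of the two-sided procedure is 2*alpha = 0.10 against H0
        assert np.mean([d == "H0" for d in decisions]) > 0.75

    def test_empirical_null_route(self, scenario):
        pop, ref, case, _ = scenario
        q = mp.draw_microbiome(pop, seed=55)
        z_null = np.random.default_rng(0).normal(size=500)
        res = mp.run_membership_test(q, ref, case, null_spec=z_null)
        assert res.null_source == "empirical"
        assert res.crit_high == pytest.approx(np.quantile(z_null, 0.95))

    def test_invalid_alpha(self, scenario):
        pop, ref, case, _ = scenario
        q = mp.draw_microbiome(pop, seed=56)
        with pytest.raises(mp.ParameterError):
            mp.run_membership_test(q, ref, case, alpha=0.6)
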