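"""Probabilistic sensitivity analysis: samplers, quadrants, CEAC."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from varicea import (
    ConfigError,
    DomainError,
    ceac,
    evaluate_scenario,
    quadrant_fractions,
    run_psa,
    triangular_from_quartiles,
    triangular_from_sd,
)
from varicea.params import SCENARIO_IDS
from varicea.psa import DistributionSpec


class TestTriangularFromQuartiles:
    def test_doubling_rule(self):
        spec = triangular_from_quartiles(10, 8, 13)
        assert (spec.minimum, spec.mode, spec.maximum) == (6, 10, 16)
        spec = triangular_from_quartiles(0.36, 0.30, 0.40)
        assert spec.minimum == pytest.approx(0.24)
        assert spec.maximum == pytest.approx(0.44)

    def test_zero_width_rejected(self):
        with pytest.raises(DomainError, match="zero-width"):
            triangular_from_quartiles(5, 5, 5)

    def test_ordering_violation_rejected(self):
        with pytest.raises(DomainError):
            triangular_from_quartiles(10, 12, 13)

    @given(st.floats(-50, 50), st.floats(0.01, 10), st.floats(0.01, 10))
    def test_mean_is_mode_and_spread_doubles(self, mean, low_arm, high_arm):
        spec = triangular_from_quartiles(mean, mean - low_arm, mean + high_arm)
        assert spec.mode == mean
        assert spec.maximum - mean == pytest.approx(2 * high_arm)
        assert mean - spec.minimum == pytest.approx(2 * low_arm)


class TestTriangularFromSd:
    def test_half_width_is_sd_root6(self):
        spec = triangular_from_sd(100, 0.5)
        assert spec.maximum - spec.mode == pytest.approx(50 * math.sqrt(6))
        assert spec.minimum == pytest.approx(100 - 50 * math.sqrt(6))
        assert math.sqrt(spec.variance) == pytest.approx(50.0)

    def test_negative_mean_ordered(self):
        spec = triangular_from_sd(-0.28, 0.5)
        assert spec.minimum < spec.mode == -0.28 < spec.maximum
        assert math.sqrt(spec.variance) == pytest.approx(0.14)

    def test_zero_mean_rejected(self):
        with pytest.raises(DomainError):
            triangular_from_sd(0.0)

    def test_sampled_moments_match_closed_form(self):
        n = 100_000
        spec = triangular_from_sd(100, 0.5)
        x = spec.sample(np.random.default_rng(12345), n)
        se_mean = math.sqrt(spec.variance / n)
        assert abs(x.mean() - spec.mean) < 3 * se_mean
        # SE of the sample variance via the fourth central moment bound
        se_var = spec.variance * math.sqrt(2.0 / n) * 2
        assert abs(x.var(ddof=1) - spec.variance) < 3 * se_var
        assert abs(x.var(ddof=1) - 2500.0) / 2500.0 < 0.02


class TestQuadrantFractions:
    def test_pure_northwest(self):
        frac = quadrant_fractions(np.array([[1.0, -1.0]] * 5), 50_000)
        assert frac.nw == 1.0 and frac.total == 1.0

    def test_ne_split_at_wtp(self):
        frac = quadrant_fractions(np.array([[100.0, 0.01]]), 50_000)
        assert frac.ne_below == 1.0  # ICER 10,000 ≤ 50,000
        frac = quadrant_fractions(np.array([[1000.0, 0.01]]), 50_000)
        assert frac.ne_above == 1.0  # ICER 100,000 > 50,000

    def test_boundary_conventions(self):
        # equal effect, EVLT costlier: the comparator dominates (NW)
        assert quadrant_fractions(np.array([[10.0, 0.0]]), 50_000).nw == 1.0
        # origin: comparator retained
        assert quadrant_fractions(np.array([[0.0, 0.0]]), 50_000).nw == 1.0

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            quadrant_fractions(np.empty((0, 2)), 50_000)

    @given(st.integers(0, 2**31 - 1))
    def test_partition_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        samples = rng.normal(size=(257, 2)) * [500.0, 0.05]
        frac = quadrant_fractions(samples, 50_000)
        assert frac.total == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in frac.as_dict().values())


class TestCeac:
    def test_zero_wtp_is_cost_minimisation(self):
        rng = np.random.default_rng(7)
        samples = np.column_stack([rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)])
        p0 = ceac(samples, [0.0])[0]
        assert p0 == pytest.approx((samples[:, 0] < 0).mean())

    def test_monotone_when_evlt_costlier_and_better(self):
        rng = np.random.default_rng(11)
        samples = np.column_stack(
            [rng.uniform(1, 100, 500), rng.uniform(0.001, 0.01, 500)]
        )
        grid = np.arange(0, 100_001, 1000.0)
        p = ceac(samples, grid)
        assert (np.diff(p) >= 0).all()
        assert p[0] == 0.0 and p[-1] == 1.0

    def test_dominated_point_mass_never_accepted(self):
        samples = np.array([[466.66, -0.0075]] * 10)
        p = ceac(samples, np.arange(0, 100_001, 1000.0))
        assert (p == 0.0).all()

    def test_complement_is_hls(self):
        samples = np.array([[100.0, 0.004], [-50.0, -0.001]])
        p = ceac(samples, [0, 30_000, 60_000])
        assert np.all((0 <= p) & (p <= 1))


class TestRunPsa:
    def test_seed_determinism_bit_identical(self, registry):
        a = run_psa(registry, "base1", n_iter=500, seed=42)
        b = run_psa(registry, "base1", n_iter=500, seed=42)
        assert np.array_equal(a.samples, b.samples)
        assert a.certainty_ce == b.certainty_ce
        c = run_psa(registry, "base1", n_iter=500, seed=43)
        assert not np.array_equal(a.samples, c.samples)

    def test_single_iteration(self, registry):
        res = run_psa(registry, "base2", n_iter=1, seed=5)
        assert res.samples.shape == (1, 2)
        values = set(res.quadrants.as_dict().values())
        assert values <= {0.0, 1.0}

    def test_certainty_equals_ceac_at_threshold(self, registry):
        res = run_psa(registry, "alt10", n_iter=2000, seed=9, wtp=50_000)
        idx = int(np.where(res.ceac_wtp == 50_000)[0][0])
        assert res.certainty_ce == res.ceac_p_evlt[idx]

    @pytest.mark.parametrize("sid", SCENARIO_IDS)
    def test_zero_uncertainty_collapses_to_deterministic(self, registry, sid):
        res = run_psa(registry, sid, n_iter=3, seed=1, sd_fraction=0.0)
        det = evaluate_scenario(registry, sid)
        by_name = {o.strategy: o for o in (det.cheaper, det.costlier)}
        expected_dc = by_name["EVLT"].expected_cost - by_name["HLS"].expected_cost
        expected_de = by_name["EVLT"].expected_qaly - by_name["HLS"].expected_qaly
        assert np.allclose(res.samples[:, 0], expected_dc, atol=1e-9)
        assert np.allclose(res.samples[:, 1], expected_de, atol=1e-9)

    def test_unknown_scenario_rejected(self, registry):
        with pytest.raises(ConfigError):
            run_psa(registry, "alt99", n_iter=10)

    def test_degenerate_spec_samples_point_mass(self):
        spec = DistributionSpec(2.0, 2.0, 2.0)
        x = spec.sample(np.random.default_rng(0), 8)
        assert (x == 2.0).all()
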