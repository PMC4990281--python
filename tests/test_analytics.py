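"""Closed-form mean and noise-decomposition formulas."""

import math

import numpy as np
import pytest

from cyclenoise import analytics as an
from cyclenoise.models import BurstModel, DuplicationSchedule, PartitionModel
from cyclenoise.timing import (
    ErlangMixture,
    TimingMoments,
    erlang_mixture_from_target,
    timing_moments,
)
from conftest import random_mixture


def _moments(cv2, ratio, mean=1.0):
    return TimingMoments(mean=mean, cv2=cv2, skewness=ratio - 1 - 3 * cv2,
                         third_moment_ratio=ratio)


class TestMeanProtein:
    def test_delta_and_exponential_timing(self):
        b = BurstModel.point_mass(1.0, 1.0)
        assert an.mean_protein(b, _moments(0.0, 1.0)) == 1.5
        assert an.mean_protein(b, _moments(1.0, 6.0)) == 2.0

    def test_periodic_timing_reduces_mean_by_25_percent(self):
        b = BurstModel.point_mass(1.0, 1.0)
        hi = an.mean_protein(b, _moments(1.0, 6.0))
        lo = an.mean_protein(b, _moments(0.0, 1.0))
        assert 100 * (hi - lo) / hi == pytest.approx(25.0)

    def test_mean_increases_with_timing_noise(self):
        b = BurstModel.geometric(2.0, 1.5)
        means = [
            an.mean_protein(b, timing_moments(erlang_mixture_from_target(1.0, c)))
            for c in np.linspace(0.05, 1.0, 10)
        ]
        assert np.all(np.diff(means) > 0)


class TestExtrinsicNoise:
    def test_delta_timing_floor(self):
        assert an.extrinsic_noise(0.0, 1.0) == pytest.approx(1 / 27, abs=1e-15)

    def test_lognormal_matches_hand_polynomial(self):
        # independent evaluation: 1/27 + 4(21c + 20c^2 + 9c^3)/(27 (3+c)^2)
        c = 0.05
        expected = 1 / 27 + 4 * (21 * c + 20 * c**2 + 9 * c**3) / (27 * (3 + c) ** 2)
        assert an.extrinsic_noise_lognormal(c) == pytest.approx(expected, rel=1e-14)

    def test_taylor_agrees_with_exact_at_small_cv(self):
        c = 0.01
        clock = erlang_mixture_from_target(1.0, c)
        exact = an.extrinsic_noise_from_clock(clock)
        taylor = an.extrinsic_noise(c, taylor=True)
        assert taylor == pytest.approx(1 / 27 + 28 * c / 81)
        assert abs(taylor / exact - 1) < 1e-3

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="third_moment_ratio"):
            an.extrinsic_noise(0.5, 0.9)


class TestIntrinsicNoise:
    def test_partitioning_trivial_and_limits(self):
        assert an.partitioning_noise(PartitionModel(0.0), 0.3, 10.0) == 0.0
        m = 7.0
        assert an.partitioning_noise(PartitionModel(1.0), 0.0, m) == pytest.approx(
            4 / (9 * m)
        )
        v0 = an.partitioning_noise(PartitionModel(1.0), 0.0, m)
        v1 = an.partitioning_noise(PartitionModel(1.0), 1.0, m)
        assert v1 / v0 == pytest.approx(3 / 4)

    def test_constant_variance_law_scales_with_mean_squared(self):
        p = PartitionModel(2.0, variance_law="constant")
        assert an.partitioning_noise(p, 0.7, 10.0) == pytest.approx(8 / 3 / 100)

    def test_production_delta_timing_prefactor(self):
        b = BurstModel.geometric(1.0, 1.5)  # <B^2>/<B> = 1 + 2*1.5 = 4
        assert b.burst_moment_ratio == pytest.approx(4.0)
        assert an.production_noise(b, 0.0, 9.0) == pytest.approx(5 / 9 * 4 / 9)

    @pytest.mark.parametrize("cv2_T", [0.0, 0.3, 1.0])
    def test_unit_bursts_binomial_partition_fano_one(self, cv2_T):
        # B = 1, alpha = 1: intrinsic noise is exactly 1/mean for any clock
        b = BurstModel.point_mass(1.0, 1.0)
        p = PartitionModel(1.0)
        m = 42.0
        total = an.partitioning_noise(p, cv2_T, m) + an.production_noise(b, cv2_T, m)
        assert total == pytest.approx(1 / m, rel=1e-14)

    def test_monotonicity_in_timing_noise(self):
        cs = np.linspace(0.0, 1.0, 21)
        part = [an.partitioning_noise(PartitionModel(1.0), c, 10.0) for c in cs]
        prod = [(3 * c + 5) / (3 * (3 + c)) for c in cs]
        assert np.all(np.diff(part) < 0)
        assert np.all(np.diff(prod) > 0)


class TestDecompose:
    def test_additivity_exact(self, geometric_burst, mixed_clock, binomial_partition):
        d = an.decompose(geometric_burst, mixed_clock, binomial_partition)
        assert d.cv2_total == d.cv2_ext + d.cv2_part + d.cv2_prod

    def test_total_approaches_extrinsic_at_high_mean(self, erlang20, binomial_partition):
        b = BurstModel.geometric(1e6, 1.5)
        d = an.decompose(b, erlang20, binomial_partition)
        assert d.cv2_total == pytest.approx(d.cv2_ext, rel=1e-4)

    def test_intrinsic_prefactors_along_mean_sweep(self, erlang20, binomial_partition):
        # intrinsic components are (prefactor)/mean with the stated prefactors
        c = 0.05
        for kx in (5.0, 50.0, 500.0):
            b = BurstModel.geometric(kx, 1.5)
            d = an.decompose(b, erlang20, binomial_partition)
            assert d.cv2_part * d.mean_x == pytest.approx(4 / (3 * (3 + c)))
            assert d.cv2_prod * d.mean_x == pytest.approx(
                (3 * c + 5) / (3 * (3 + c)) * 4.0
            )


class TestDuplication:
    def test_mean_endpoint_reductions(self):
        b = BurstModel.point_mass(1.0, 1.0)
        single = an.mean_protein(b, timing_moments(erlang_mixture_from_target(1.0, 0.2)))
        # beta -> 1: pure T1 cycle; beta -> 0: dosage f applies throughout
        t_tiny = erlang_mixture_from_target(1e-9, 0.2)
        t_main = erlang_mixture_from_target(1.0, 0.2)
        late = DuplicationSchedule(2.0, t_main, t_tiny)
        early = DuplicationSchedule(2.0, t_tiny, t_main)
        assert an.duplication_mean(b, late) == pytest.approx(single, rel=1e-6)
        assert an.duplication_mean(b, early) == pytest.approx(2 * single, rel=1e-6)

    def test_mean_halfway_deterministic_example(self):
        # f = 2, beta = 0.5, no timing noise, kx<B><T> = 1 gives 2.125
        t1 = erlang_mixture_from_target(0.5, 1e-4)
        t2 = erlang_mixture_from_target(0.5, 1e-4)
        b = BurstModel.point_mass(1.0, 1.0)
        d = DuplicationSchedule(2.0, t1, t2)
        assert an.duplication_mean(b, d) == pytest.approx(2.125, rel=1e-3)

    @pytest.mark.parametrize("beta", [0.0, 1.0])
    def test_f2_intrinsic_reduces_to_single_phase(self, beta):
        rng = np.random.default_rng(11)
        for _ in range(200):
            alpha = rng.uniform(0.0, 4.0)
            bmean = rng.uniform(0.5, 8.0)
            c1, c2 = rng.uniform(0.0, 1.0, 2)
            mean_x = rng.uniform(5.0, 500.0)
            b = BurstModel.geometric(1.0, bmean)
            p = PartitionModel(alpha)
            cr, cp = an.duplication_intrinsic_f2(b, p, beta, c1, c2, mean_x)
            c = c1 if beta == 1.0 else c2
            assert cr == pytest.approx(an.partitioning_noise(p, c, mean_x), abs=1e-12)
            assert cp == pytest.approx(an.production_noise(b, c, mean_x), abs=1e-12)

    def test_f2_unit_burst_binomial_fano_one_for_all_beta(self):
        b = BurstModel.point_mass(1.0, 1.0)
        p = PartitionModel(1.0)
        rng = np.random.default_rng(3)
        for _ in range(100):
            beta = rng.uniform()
            c1, c2 = rng.uniform(0, 1, 2)
            cr, cp = an.duplication_intrinsic_f2(b, p, beta, c1, c2, 33.0)
            assert cr + cp == pytest.approx(1 / 33.0, rel=1e-12)

    def test_production_minimum_at_two_minus_sqrt2(self):
        beta_star, _ = an.optimize_beta(an.duplication_production_factor, minimize=True)
        assert beta_star == pytest.approx(2 - math.sqrt(2), abs=1e-6)

    def test_partitioning_maximum_at_two_minus_sqrt2_for_equal_cvs(self):
        for c in (0.0, 0.3, 1.0):
            beta_star, _ = an.optimize_beta(
                lambda x: an.duplication_partition_factor(x, c, c), minimize=False
            )
            assert beta_star == pytest.approx(2 - math.sqrt(2), abs=1e-5)

    def test_extrinsic_limit_endpoints(self):
        assert an.duplication_extrinsic_limit(0.0) == pytest.approx(1 / 27)
        assert an.duplication_extrinsic_limit(1.0) == pytest.approx(1 / 27)


class TestUnstable:
    def test_extrinsic_vanishes_without_mid_cycle_dosage_change(self):
        b = BurstModel.geometric(5.0, 2.0)
        assert an.unstable_noise(b, 0.0, 10.0).cv2_ext == 0.0
        assert an.unstable_noise(b, 1.0, 10.0).cv2_ext == 0.0

    def test_extrinsic_maximum_one_eighth(self):
        b = BurstModel.geometric(5.0, 2.0)
        assert an.unstable_noise(b, 2 / 3, 10.0).cv2_ext == pytest.approx(1 / 8)
        grid = np.linspace(0, 1, 1001)
        vals = [(1 - x) * x / (2 - x) ** 2 for x in grid]
        assert max(vals) <= 1 / 8 + 1e-12

    def test_unit_burst_production_fano_invariant_of_beta(self):
        b = BurstModel.point_mass(5.0, 1.0)
        for beta in (0.0, 0.4, 0.9):
            d = an.unstable_noise(b, beta, 10.0)
            assert d.cv2_prod * d.mean_x == pytest.approx(1.0)
            assert d.cv2_part == 0.0


class TestSynchronized:
    def test_conditional_mean_and_stage_limits(self):
        b = BurstModel.geometric(3.0, 2.0)
        p = PartitionModel(1.5)
        n = 500
        ratio = b.burst_moment_ratio
        m1, _, cr1, cp1 = an.synchronized_moments(n, 1, b, p)
        mn, _, crn, cpn = an.synchronized_moments(n, n, b, p)
        assert m1 == pytest.approx(3.0 * 2.0 * (1 + 1 / n))
        # birth-stage prefactors (2 alpha/3, ratio/3); division (alpha/3, 2 ratio/3)
        assert cr1 * m1 == pytest.approx(2 * p.alpha / 3, rel=5e-3)
        assert cp1 * m1 == pytest.approx(ratio / 3, rel=5e-3)
        assert crn * mn == pytest.approx(p.alpha / 3, rel=5e-3)
        assert cpn * mn == pytest.approx(2 * ratio / 3, rel=5e-3)

    @pytest.mark.parametrize("j", [1, 5, 10])
    def test_unit_burst_binomial_fano_one_every_stage(self, j):
        b = BurstModel.point_mass(2.0, 1.0)
        p = PartitionModel(1.0)
        m, _, cr, cp = an.synchronized_moments(10, j, b, p)
        assert (cr + cp) * m == pytest.approx(1.0, rel=1e-12)

    def test_stage_index_validated(self):
        b = BurstModel.point_mass(1.0, 1.0)
        with pytest.raises(ValueError, match="stage index"):
            an.synchronized_moments(5, 6, b, PartitionModel(1.0))
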