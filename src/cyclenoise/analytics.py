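"""Closed-form steady-state statistics of the expression model.

All formulas are exact single-lineage steady states of the hybrid Markov
model: bursty production at rate ``k_x`` (doubled-dosage rate ``f*k_x``
after genome duplication), a phase-type cell-cycle clock, and noisy
binomial-like partitioning at division.  The total protein CV^2 splits
additively into an extrinsic term set by the timing distribution alone and
two intrinsic terms (partitioning and production) that scale inversely
with the mean.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy import optimize

from .models import BurstModel, DuplicationSchedule, NoiseDecomposition, PartitionModel
from .timing import (
    ErlangMixture,
    TimingMoments,
    lognormal_third_moment_ratio,
    timing_moments,
)

__all__ = [
    "mean_protein",
    "second_moment",
    "extrinsic_noise",
    "extrinsic_noise_from_clock",
    "extrinsic_noise_lognormal",
    "partitioning_noise",
    "production_noise",
    "decompose",
    "duplication_mean",
    "duplication_intrinsic_f2",
    "duplication_extrinsic_limit",
    "duplication_partition_factor",
    "duplication_production_factor",
    "optimize_beta",
    "unstable_noise",
    "synchronized_moments",
]


def mean_protein(b: BurstModel, t: TimingMoments) -> float:
    """Steady-state mean copy number ``k_x <B> <T> (3 + CV_T^2) / 2``.

    Holds for any phase-type clock; randomness in the cycle length raises
    the mean because high-CV phase-type clocks are positively skewed, so
    long cycles (with more accumulation) are over-represented.
    """
    return b.kx * b.burst_mean * t.mean * (3.0 + t.cv2) / 2.0


def second_moment(
    b: BurstModel,
    t: TimingMoments,
    p: PartitionModel | None = None,
    *,
    burst_noise: bool = True,
) -> float:
    """Steady-state ``<x^2>`` of the full or hybrid models.

    The division-timing-only hybrid gives
    ``k_x^2 <B>^2 <T>^2 (<T^3>/<T>^3 + 4 CV_T^2 + 6) / 3``; partitioning
    errors add ``2 alpha k_x <B> <T> / 3`` and burst noise adds
    ``k_x <B^2> <T> (3 CV_T^2 + 5) / 6``.
    """
    kxB = b.kx * b.burst_mean
    x2 = kxB**2 * t.mean**2 * (t.third_moment_ratio + 4.0 * t.cv2 + 6.0) / 3.0
    if p is not None and p.alpha > 0:
        if p.variance_law != "proportional":
            raise ValueError("closed-form second moment covers the proportional law only")
        x2 += 2.0 * p.alpha * kxB * t.mean / 3.0
    if burst_noise:
        x2 += b.kx * b.burst_second_moment * t.mean * (3.0 * t.cv2 + 5.0) / 6.0
    return x2


def extrinsic_noise(
    cv2_T: float,
    third_moment_ratio: float | None = None,
    *,
    taylor: bool = False,
) -> float:
    """Extrinsic noise CV_E^2 from random division timing.

    Exact form: ``4 (<T^3>/<T>^3 + 4 CV_T^2 + 6) / (3 (3 + CV_T^2)^2) - 1``.
    Equals 1/27 when T is a delta distribution.  With ``taylor=True`` the
    small-CV expansion ``1/27 + 28 CV_T^2 / 81`` is returned and the third
    moment is not needed.
    """
    if cv2_T < 0:
        raise ValueError("cv2_T must be non-negative")
    if taylor:
        return 1.0 / 27.0 + 28.0 * cv2_T / 81.0
    if third_moment_ratio is None:
        raise ValueError("third_moment_ratio required unless taylor=True")
    if third_moment_ratio < 1.0 - 1e-12:
        raise ValueError("third_moment_ratio must be >= 1")
    c = cv2_T
    return 4.0 * (third_moment_ratio + 4.0 * c + 6.0) / (3.0 * (3.0 + c) ** 2) - 1.0


def extrinsic_noise_from_clock(m: ErlangMixture) -> float:
    """CV_E^2 with the third moment supplied by a phase-type clock."""
    t = timing_moments(m)
    return extrinsic_noise(t.cv2, t.third_moment_ratio)


def extrinsic_noise_lognormal(cv2_T: float) -> float:
    """CV_E^2 for a lognormally distributed cycle time."""
    return extrinsic_noise(cv2_T, lognormal_third_moment_ratio(cv2_T))


def partitioning_noise(p: PartitionModel, cv2_T: float, mean_x: float) -> float:
    """Partitioning-error noise CV_R^2.

    Proportional law: ``4 alpha / (3 (3 + CV_T^2)) / <x>``; the constant
    law loses the timing dependence: ``4 alpha / 3 / <x>^2``.
    """
    if not (mean_x > 0):
        raise ValueError("mean_x must be positive")
    if p.variance_law == "constant":
        return 4.0 * p.alpha / 3.0 / mean_x**2
    return 4.0 * p.alpha / (3.0 * (3.0 + cv2_T)) / mean_x


def production_noise(b: BurstModel, cv2_T: float, mean_x: float) -> float:
    """Production noise CV_P^2 = ``(3 CV_T^2 + 5)/(3 (3 + CV_T^2)) * <B^2>/<B> / <x>``."""
    if not (mean_x > 0):
        raise ValueError("mean_x must be positive")
    return (
        (3.0 * cv2_T + 5.0)
        / (3.0 * (3.0 + cv2_T))
        * b.burst_moment_ratio
        / mean_x
    )


def decompose(
    b: BurstModel,
    clock: ErlangMixture,
    p: PartitionModel,
) -> NoiseDecomposition:
    """Full three-way noise decomposition for a non-duplicating gene."""
    t = timing_moments(clock)
    mean = mean_protein(b, t)
    return NoiseDecomposition(
        mean_x=mean,
        cv2_ext=extrinsic_noise(t.cv2, t.third_moment_ratio),
        cv2_part=partitioning_noise(p, t.cv2, mean),
        cv2_prod=production_noise(b, t.cv2, mean),
    )


# ---------------------------------------------------------------------------
# genome duplication


def duplication_mean(b: BurstModel, d: DuplicationSchedule) -> float:
    """Steady-state mean with a duplication phase (any dosage factor f).

    ``<x> = k_x <B> <T1> (2 f (1-b) + 3 b + b CV_T1^2)/2
          + k_x <B> <T2> (3 f (1-b) + 4 b + f (1-b) CV_T2^2)/2``
    with ``b = beta``; reduces to the single-phase mean at beta = 1 and to
    f times it at beta = 0.
    """
    kxB = b.kx * b.burst_mean
    f = d.f
    beta = d.beta
    c1 = d.t1_clock.cv2
    c2 = d.t2_clock.cv2
    T1 = d.t1_clock.mean
    T2 = d.t2_clock.mean
    term1 = kxB * T1 * (2.0 * f * (1.0 - beta) + 3.0 * beta + beta * c1) / 2.0
    term2 = kxB * T2 * (3.0 * f * (1.0 - beta) + 4.0 * beta + f * (1.0 - beta) * c2) / 2.0
    return term1 + term2


def _dup_denominator(beta: float, cv2_T1: float, cv2_T2: float) -> float:
    return 3.0 * (
        (beta**2 - 4.0 * beta + 6.0)
        + beta**2 * cv2_T1
        + 2.0 * (1.0 - beta) ** 2 * cv2_T2
    )


def duplication_partition_factor(
    beta: float, cv2_T1: float = 0.0, cv2_T2: float = 0.0
) -> float:
    """Dimensionless CV_R^2 prefactor for f = 2: multiply by ``alpha/<x>``."""
    return 4.0 * (2.0 - beta) / _dup_denominator(beta, cv2_T1, cv2_T2)


def duplication_production_factor(
    beta: float, cv2_T1: float = 0.0, cv2_T2: float = 0.0
) -> float:
    """Dimensionless CV_P^2 prefactor for f = 2: multiply by ``<B^2>/<B>/<x>``."""
    num = (
        (10.0 - 8.0 * beta + 3.0 * beta**2)
        + 6.0 * (1.0 - beta) ** 2 * cv2_T2
        + 3.0 * beta**2 * cv2_T1
    )
    return num / _dup_denominator(beta, cv2_T1, cv2_T2)


def duplication_intrinsic_f2(
    b: BurstModel,
    p: PartitionModel,
    beta: float,
    cv2_T1: float,
    cv2_T2: float,
    mean_x: float,
) -> tuple[float, float]:
    """Intrinsic noise components (CV_R^2, CV_P^2) for dosage factor f = 2.

    Closed form exists only for f = 2; for other f use the numeric
    steady-state solve in :mod:`cyclenoise.moments`.
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    if not (mean_x > 0):
        raise ValueError("mean_x must be positive")
    cv2_part = p.alpha * duplication_partition_factor(beta, cv2_T1, cv2_T2) / mean_x
    cv2_prod = (
        b.burst_moment_ratio
        * duplication_production_factor(beta, cv2_T1, cv2_T2)
        / mean_x
    )
    return cv2_part, cv2_prod


def duplication_extrinsic_limit(beta: float) -> float:
    """Extrinsic noise CV_E^2 for f = 2 in the precise-timing limit.

    ``(4 - 3 beta^2 (beta - 2)^2) / (3 (beta^2 - 4 beta + 6)^2)``; equals
    1/27 at beta = 0 and beta = 1 (no mid-cycle dosage change).
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    num = 4.0 - 3.0 * beta**2 * (beta - 2.0) ** 2
    den = 3.0 * (beta**2 - 4.0 * beta + 6.0) ** 2
    return num / den


def optimize_beta(
    factor: Callable[[float], float],
    *,
    minimize: bool = True,
    grid_step: float = 1e-4,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Locate an extremum of a scalar factor over beta in [0, 1].

    Dense-grid scan at ``grid_step`` followed by golden-section refinement;
    returns ``(beta_star, factor(beta_star))``.
    """
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    vals = np.array([factor(float(x)) for x in grid])
    idx = int(np.argmin(vals) if minimize else np.argmax(vals))
    lo = grid[max(idx - 1, 0)]
    hi = grid[min(idx + 1, len(grid) - 1)]
    sign = 1.0 if minimize else -1.0
    res = optimize.minimize_scalar(
        lambda x: sign * factor(float(x)),
        bounds=(float(lo), float(hi)),
        method="bounded",
        options={"xatol": tol},
    )
    beta_star = float(res.x)
    return beta_star, factor(beta_star)


def unstable_noise(b: BurstModel, beta: float, gamma_x: float) -> NoiseDecomposition:
    """Noise for a rapidly degraded protein with duplication (f = 2).

    Fast turnover (``gamma_x <T> >> 1``) lets the level equilibrate within
    each phase: mean ``k_x <B> (2 - beta)/gamma_x``, extrinsic noise
    ``(1-beta) beta/(2-beta)^2`` (maximal 1/8 at beta = 2/3), production
    noise ``(<B^2>/<B> + 1)/2 / <x>``, and no partitioning contribution
    since division errors are corrected immediately.
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    if not (gamma_x > 0):
        raise ValueError("gamma_x must be positive")
    mean = b.kx * b.burst_mean * (2.0 - beta) / gamma_x
    cv2_ext = (1.0 - beta) * beta / (2.0 - beta) ** 2
    cv2_prod = (b.burst_moment_ratio + 1.0) / 2.0 / mean
    return NoiseDecomposition(mean_x=mean, cv2_ext=cv2_ext, cv2_part=0.0, cv2_prod=cv2_prod)


# ---------------------------------------------------------------------------
# synchronized cells


def synchronized_moments(
    n_stages: int,
    j: int,
    b: BurstModel,
    p: PartitionModel,
    mean_T: float = 1.0,
) -> tuple[float, float, float, float]:
    """Moments conditioned on cell-cycle stage j of a pure Erlang-n clock.

    Returns ``(cond_mean, cv2_ext, cv2_part, cv2_prod)`` with

    * ``cond_mean = k_x <B> <T> (1 + j/n)``
    * ``cv2_ext  = (n + 3 j) / (3 (n + j)^2)``
    * ``cv2_part = 2 n alpha / (3 (n + j)) / cond_mean``
    * ``cv2_prod = (n + 3 j) / (3 (n + j)) * <B^2>/<B> / cond_mean``

    At large n these reduce to the birth-stage prefactors
    ``(2 alpha/3, <B^2>/<B>/3)`` and division-stage prefactors
    ``(alpha/3, 2 <B^2>/<B>/3)``.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    if not (1 <= j <= n_stages):
        raise ValueError(f"stage index j must lie in 1..{n_stages}")
    n = n_stages
    cond_mean = b.kx * b.burst_mean * mean_T * (1.0 + j / n)
    cv2_ext = (n + 3.0 * j) / (3.0 * (n + j) ** 2)
    cv2_part = 2.0 * n * p.alpha / (3.0 * (n + j)) / cond_mean
    cv2_prod = (n + 3.0 * j) / (3.0 * (n + j)) * b.burst_moment_ratio / cond_mean
    return cond_mean, cv2_ext, cv2_part, cv2_prod
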