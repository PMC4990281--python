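"""Core model ingredients: bursts, partitioning, duplication, noise output.

These dataclasses parameterise the expression model: proteins are made in
random bursts arriving at rate ``k_x``, divisions split molecules between
daughters with tunable error ``alpha``, and an optional genome-duplication
phase multiplies the burst arrival rate by a dosage factor ``f`` partway
through the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .timing import ErlangMixture, timing_moments

__all__ = [
    "BurstModel",
    "PartitionModel",
    "DuplicationSchedule",
    "NoiseDecomposition",
]

BurstFamily = Literal["geometric0", "geometric1", "point_mass", "custom"]


@dataclass(frozen=True)
class BurstModel:
    """Burst arrival rate and burst-size distribution.

    ``burst_mean`` and ``burst_second_moment`` are ``<B>`` and ``<B^2>``;
    the ratio ``<B^2>/<B>`` is what enters every production-noise formula.
    ``burst_family`` identifies the distribution used when sampling:

    * ``geometric0`` -- geometric on {0, 1, 2, ...}; ``<B^2>/<B> = 1 + 2<B>``
      (the default convention used by the burst-size inference formulas)
    * ``geometric1`` -- geometric shifted to {1, 2, ...}; ``<B^2>/<B> = 2<B> - 1``
    * ``point_mass`` -- every burst makes exactly ``<B>`` molecules
    * ``custom``     -- moments supplied directly; no sampler available
    """

    kx: float
    burst_mean: float
    burst_second_moment: float
    burst_family: BurstFamily = "custom"

    def __post_init__(self) -> None:
        if self.kx < 0:
            raise ValueError("kx must be non-negative")
        if not (self.burst_mean > 0):
            raise ValueError("burst_mean must be positive")
        if self.burst_second_moment < self.burst_mean**2 - 1e-12:
            raise ValueError("<B^2> >= <B>^2 violated")

    @property
    def burst_moment_ratio(self) -> float:
        """``<B^2>/<B>``."""
        return self.burst_second_moment / self.burst_mean

    @classmethod
    def geometric(cls, kx: float, burst_mean: float, *, shifted: bool = False) -> "BurstModel":
        """Geometric burst sizes; support {0,...} by default, {1,...} if shifted."""
        b = burst_mean
        if shifted:
            if b < 1:
                raise ValueError("shifted geometric needs burst_mean >= 1")
            return cls(kx, b, b * (2 * b - 1), "geometric1")
        return cls(kx, b, b * (1 + 2 * b), "geometric0")

    @classmethod
    def point_mass(cls, kx: float, burst_size: float) -> "BurstModel":
        return cls(kx, burst_size, burst_size**2, "point_mass")


@dataclass(frozen=True)
class PartitionModel:
    """Division-time partitioning error.

    Each daughter receives on average half the mother's molecules; the
    conditional variance of the allotment is ``alpha * x / 4`` under the
    ``proportional`` law (``alpha = 1`` is binomial partitioning, 0 is a
    deterministic split, > 1 over-dispersed) or a constant ``alpha`` under
    the ``constant`` law.
    """

    alpha: float
    variance_law: Literal["proportional", "constant"] = "proportional"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.variance_law not in ("proportional", "constant"):
            raise ValueError(f"unknown variance law {self.variance_law!r}")


@dataclass(frozen=True)
class DuplicationSchedule:
    """Genome duplication at a random point within the cycle.

    The cycle is split into a pre-duplication phase of duration ``T1`` and
    a post-duplication phase ``T2``, each with its own phase-type clock.
    During ``T2`` the burst arrival rate is multiplied by the dosage
    factor ``f``.  ``beta = <T1>/<T>`` locates the mean duplication time
    within the cycle.
    """

    f: float
    t1_clock: ErlangMixture
    t2_clock: ErlangMixture

    def __post_init__(self) -> None:
        if self.f < 1:
            raise ValueError("dosage factor f must be >= 1")

    @property
    def mean_T(self) -> float:
        return self.t1_clock.mean + self.t2_clock.mean

    @property
    def beta(self) -> float:
        return self.t1_clock.mean / self.mean_T

    @property
    def cv2_T(self) -> float:
        """CV^2 of the total cycle time T = T1 + T2 (independent phases)."""
        b = self.beta
        return b**2 * self.t1_clock.cv2 + (1 - b) ** 2 * self.t2_clock.cv2


@dataclass(frozen=True)
class NoiseDecomposition:
    """Steady-state mean and the three-way split of protein CV^2.

    ``cv2_ext`` is the extrinsic contribution from random division (and
    duplication) timing; ``cv2_part`` and ``cv2_prod`` are the intrinsic
    contributions from partitioning errors and stochastic production.
    Additivity is exact: ``cv2_total`` is their sum by construction.
    """

    mean_x: float
    cv2_ext: float
    cv2_part: float
    cv2_prod: float

    @property
    def cv2_total(self) -> float:
        return self.cv2_ext + self.cv2_part + self.cv2_prod

    def to_dict(self) -> dict:
        return {
            "mean_x": self.mean_x,
            "cv2_ext": self.cv2_ext,
            "cv2_part": self.cv2_part,
            "cv2_prod": self.cv2_prod,
            "cv2_total": self.cv2_total,
        }
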