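"""Phase-type (mixture-of-Erlang) cell-cycle clocks.

The time between successive cell divisions is modelled as a mixture of
Erlang distributions: with probability ``p_i`` the cycle passes through
``i`` exponential stages, each with rate ``i*k``, so that the mean cycle
length is ``1/k`` regardless of the mixing probabilities.  Any
positively-valued distribution with CV <= 1 can be approximated within
this class, which is what makes the moment equations of the expression
model exactly closable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ErlangMixture",
    "TimingMoments",
    "erlang_mixture_from_target",
    "timing_moments",
    "sample_times",
    "lognormal_third_moment_ratio",
]

_PROB_TOL = 1e-12

#: Erlang order used to stand in for a deterministic (CV^2 = 0) clock in
#: sampling and stage-chain contexts, where an exact delta is unreachable.
DETERMINISTIC_ORDER = 200


@dataclass(frozen=True)
class ErlangMixture:
    """Mixture of Erlang distributions sharing the rate scale ``k``.

    Parameters
    ----------
    orders
        Strictly increasing Erlang shape parameters ``i >= 1``.
    probs
        Mixing probabilities aligned with ``orders``; must sum to one.
    rate_scale
        Common rate scale ``k`` (1/time).  Stage ``G_ij`` has exit rate
        ``i * k``, so the mean of every component -- and of the mixture --
        is exactly ``1/k``.
    """

    orders: tuple[int, ...]
    probs: tuple[float, ...]
    rate_scale: float

    def __post_init__(self) -> None:
        orders = tuple(int(i) for i in self.orders)
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "orders", orders)
        object.__setattr__(self, "probs", probs)
        if len(orders) == 0 or len(orders) != len(probs):
            raise ValueError("orders and probs must be non-empty and aligned")
        if any(i < 1 for i in orders):
            raise ValueError("Erlang orders must be >= 1")
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise ValueError("orders must be strictly increasing")
        if any(p < 0 for p in probs):
            raise ValueError("mixing probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ValueError(f"mixing probabilities must sum to 1, got {sum(probs)}")
        if not (self.rate_scale > 0):
            raise ValueError("rate_scale must be positive")

    @property
    def mean(self) -> float:
        """Mean cycle time ``<T> = 1/k`` (independent of the probs)."""
        return 1.0 / self.rate_scale

    @property
    def cv2(self) -> float:
        """Squared coefficient of variation ``sum_i p_i / i``."""
        return float(sum(p / i for i, p in zip(self.orders, self.probs)))

    @property
    def skewness(self) -> float:
        """Normalised central third moment ``<(T-<T>)^3>/<T>^3 = 2 sum p_i/i^2``."""
        return float(2.0 * sum(p / i**2 for i, p in zip(self.orders, self.probs)))

    def to_dict(self) -> dict:
        return {
            "orders": list(self.orders),
            "probs": list(self.probs),
            "rate_scale": self.rate_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErlangMixture":
        return cls(tuple(d["orders"]), tuple(d["probs"]), float(d["rate_scale"]))


@dataclass(frozen=True)
class TimingMoments:
    """First three moments of a cell-cycle time distribution.

    ``third_moment_ratio`` is ``<T^3>/<T>^3``; for a mixture of Erlangs it
    equals ``1 + 3*cv2 + 2 sum_i p_i/i**2``.
    """

    mean: float
    cv2: float
    skewness: float
    third_moment_ratio: float

    def __post_init__(self) -> None:
        if not (self.mean > 0):
            raise ValueError("mean must be positive")
        if self.cv2 < 0:
            raise ValueError("cv2 must be non-negative")
        if self.third_moment_ratio < 1.0 - 1e-12:
            raise ValueError("third_moment_ratio must be >= 1")


def erlang_mixture_from_target(mean_T: float, cv2_T: float) -> ErlangMixture:
    """Construct a mixture of Erlangs with given mean and CV^2.

    If ``1/cv2_T`` is an integer ``m`` the pure Erlang of order ``m`` is
    returned.  Otherwise the two adjacent orders ``m = floor(1/cv2_T)`` and
    ``m+1`` are mixed, with weight solving ``p/m + (1-p)/(m+1) = cv2_T``.
    This is the minimal-state construction; other mixtures with the same
    first two moments exist.

    A ``cv2_T = 0`` request falls back to a pure Erlang of order
    ``DETERMINISTIC_ORDER`` with a warning, since the phase-type class
    cannot represent a delta distribution exactly.
    """
    if not (mean_T > 0):
        raise ValueError("mean_T must be positive")
    if cv2_T < 0 or cv2_T > 1:
        raise ValueError(
            "cv2_T must lie in (0, 1]: a mixture of Erlang (phase-type) "
            "distributions cannot have CV^2 outside that range"
        )
    k = 1.0 / mean_T
    if cv2_T == 0:
        warnings.warn(
            "cv2_T = 0 requested: a phase-type clock cannot be a delta; "
            f"using a pure Erlang of order {DETERMINISTIC_ORDER}",
            stacklevel=2,
        )
        return ErlangMixture((DETERMINISTIC_ORDER,), (1.0,), k)
    inv = 1.0 / cv2_T
    m = int(round(inv))
    if abs(inv - m) < 1e-9:
        return ErlangMixture((m,), (1.0,), k)
    m = int(math.floor(inv))
    # p/m + (1-p)/(m+1) = cv2  =>  p = m*(m+1)*cv2 - m
    p = m * (m + 1) * cv2_T - m
    if not (0.0 <= p <= 1.0):  # pragma: no cover - algebraically impossible
        raise AssertionError("adjacent-order weight outside [0, 1]")
    return ErlangMixture((m, m + 1), (p, 1.0 - p), k)


def timing_moments(m: ErlangMixture) -> TimingMoments:
    """Exact closed-form moments of a mixture-of-Erlang clock."""
    cv2 = m.cv2
    skew = m.skewness
    return TimingMoments(
        mean=m.mean,
        cv2=cv2,
        skewness=skew,
        third_moment_ratio=1.0 + 3.0 * cv2 + skew,
    )


def lognormal_third_moment_ratio(cv2: float) -> float:
    """``<T^3>/<T>^3 = (1 + cv2)^3`` for a lognormal cycle-time distribution."""
    if cv2 < 0:
        raise ValueError("cv2 must be non-negative")
    return (1.0 + cv2) ** 3


def sample_times(
    m: ErlangMixture,
    n_draws: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw i.i.d. cycle times from the mixture.

    Each draw picks an order ``i`` with probability ``p_i`` and then sums
    ``i`` exponentials of rate ``i*k`` (drawn as a Gamma(i, 1/(i*k))
    variate, which is the same distribution).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    orders = np.asarray(m.orders)
    idx = rng.choice(len(orders), size=n_draws, p=np.asarray(m.probs))
    shapes = orders[idx]
    return rng.gamma(shape=shapes, scale=1.0 / (shapes * m.rate_scale))
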