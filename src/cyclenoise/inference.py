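"""Parameter inference from protein mean and intrinsic-noise measurements.

The intrinsic noise of an asynchronous population under the full model is

    intrinsic CV^2 = [ 4a/(3(3+c)) + (3c+5)/(3(3+c)) * <B^2>/<B> ] / <x>

with ``a`` the partitioning-error parameter, ``c = CV_T^2`` the noise in
cycle length, and ``<B^2>/<B> = 1 + 2<B>`` for geometric bursts on
{0, 1, ...}.  With ``c << 1`` this is the familiar ``(4a/9 + 5(1+2<B>)/9)/<x>``.
A single (mean, intrinsic-noise) pair identifies ``<B>`` only if ``a`` is
assumed; measuring the intrinsic Fano factor a second time after scaling
the burst size (e.g. a ribosome-binding-site mutation that halves the
mean) identifies ``<B>`` and ``a`` jointly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "NoiseObservation",
    "InfeasibleObservationError",
    "intrinsic_fano",
    "estimate_burst",
    "estimate_B_alpha_two_condition",
    "two_condition_standard_errors",
]


class InfeasibleObservationError(ValueError):
    """Observed noise is below the floor implied by the assumed model."""


@dataclass(frozen=True)
class NoiseObservation:
    """A (mean, intrinsic-noise) measurement for one condition.

    Either ``intrinsic_cv2`` or ``fano`` may be given; when both are
    supplied they must satisfy ``fano = intrinsic_cv2 * mean_x``.
    ``cv2_T`` is the (assumed known) cell-cycle time noise.
    """

    mean_x: float
    intrinsic_cv2: float | None = None
    fano: float | None = None
    cv2_T: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.mean_x > 0):
            raise ValueError("mean_x must be positive")
        if self.intrinsic_cv2 is None and self.fano is None:
            raise ValueError("supply intrinsic_cv2 or fano")
        if self.intrinsic_cv2 is not None and self.fano is not None:
            if abs(self.fano - self.intrinsic_cv2 * self.mean_x) > 1e-6 * max(
                1.0, abs(self.fano)
            ):
                raise ValueError("fano and intrinsic_cv2 * mean_x disagree")
        if self.cv2_T < 0:
            raise ValueError("cv2_T must be non-negative")

    @property
    def fano_factor(self) -> float:
        if self.fano is not None:
            return self.fano
        return self.intrinsic_cv2 * self.mean_x


def _coefficients(cv2_T: float) -> tuple[float, float]:
    """(alpha coefficient, burst-ratio coefficient) of the intrinsic Fano factor."""
    d = 3.0 * (3.0 + cv2_T)
    return 4.0 / d, (3.0 * cv2_T + 5.0) / d


def intrinsic_fano(burst_mean: float, alpha: float, cv2_T: float = 0.0) -> float:
    """Forward map: intrinsic Fano factor for geometric bursts on {0, 1, ...}."""
    ca, cb = _coefficients(cv2_T)
    return ca * alpha + cb * (1.0 + 2.0 * burst_mean)


def estimate_burst(
    obs: NoiseObservation,
    alpha_assumed: float,
    clock_mean_T: float,
) -> tuple[float, float]:
    """Estimate mean burst size and burst arrival rate from one condition.

    Inverts the intrinsic Fano factor for ``<B>`` under an assumed
    partitioning parameter, then recovers ``k_x`` from the mean protein
    level ``k_x <B> <T> (3 + CV_T^2)/2``.  Ignoring the partitioning term
    (assuming ``alpha = 0`` when it is not) inflates the burst-size
    estimate by ``c_a * alpha_true / (2 c_b)``.
    """
    if alpha_assumed < 0:
        raise ValueError("alpha_assumed must be non-negative")
    if not (clock_mean_T > 0):
        raise ValueError("clock_mean_T must be positive")
    ca, cb = _coefficients(obs.cv2_T)
    fano = obs.fano_factor
    floor = ca * alpha_assumed + cb
    resid = fano - floor
    tol = 1e-12 * max(1.0, abs(fano))
    if resid < -tol:
        raise InfeasibleObservationError(
            f"Fano factor {fano:.6g} is below the floor {floor:.6g} implied by "
            f"alpha = {alpha_assumed} (partitioning alone exceeds the observed noise)"
        )
    burst_mean = max(resid, 0.0) / (2.0 * cb)
    if burst_mean == 0.0:
        warnings.warn(
            "observation sits on the zero-burst-size boundary; k_x is undefined",
            stacklevel=2,
        )
        return 0.0, math.inf
    kx = obs.mean_x / (burst_mean * clock_mean_T * (3.0 + obs.cv2_T) / 2.0)
    return burst_mean, kx


def estimate_B_alpha_two_condition(
    fano_ref: float,
    fano_perturbed: float,
    mean_ratio: float,
    cv2_T: float = 0.0,
) -> tuple[float, float]:
    """Jointly estimate ``<B>`` and ``alpha`` from a burst-size perturbation.

    The perturbation (e.g. an RBS mutation) scales the burst size by
    ``mean_ratio`` while leaving ``alpha`` and the cycle-time statistics
    unchanged, giving the linear pair

        fano_ref       = c_a alpha + c_b (1 + 2 B)
        fano_perturbed = c_a alpha + c_b (1 + 2 B * mean_ratio)

    solved exactly.  Negative estimates are returned as-is with a warning:
    they indicate the observations are inconsistent with the model, which
    clipping would hide.
    """
    if not (0.0 < mean_ratio < 1.0):
        if mean_ratio == 1.0:
            raise ValueError("mean_ratio = 1 makes the two conditions identical (singular)")
        raise ValueError("mean_ratio must lie in (0, 1)")
    ca, cb = _coefficients(cv2_T)
    burst_mean = (fano_ref - fano_perturbed) / (2.0 * cb * (1.0 - mean_ratio))
    alpha = (fano_ref - cb * (1.0 + 2.0 * burst_mean)) / ca
    if burst_mean < 0 or alpha < 0:
        warnings.warn(
            f"model-inconsistent estimates (B = {burst_mean:.4g}, alpha = {alpha:.4g}); "
            "the observations violate the assumed intrinsic-noise model",
            stacklevel=2,
        )
    return burst_mean, alpha


def two_condition_standard_errors(
    se_fano_ref: float,
    se_fano_perturbed: float,
    mean_ratio: float,
    cv2_T: float = 0.0,
) -> tuple[float, float]:
    """Delta-method standard errors for the two-condition estimator.

    The estimator is linear in the two (independent) Fano measurements, so
    the propagation is exact.
    """
    ca, cb = _coefficients(cv2_T)
    dB = 1.0 / (2.0 * cb * (1.0 - mean_ratio))
    se_B = dB * math.hypot(se_fano_ref, se_fano_perturbed)
    da1 = (1.0 - 2.0 * cb * dB) / ca
    da2 = 2.0 * cb * dB / ca
    se_alpha = math.hypot(da1 * se_fano_ref, da2 * se_fano_perturbed)
    return se_B, se_alpha
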