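"""Parameter sweeps: noise versus mean, and versus duplication timing."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import analytics
from .models import BurstModel, DuplicationSchedule, NoiseDecomposition, PartitionModel
from .moments import decompose_numeric
from .timing import ErlangMixture, erlang_mixture_from_target, timing_moments

__all__ = ["scan_mean", "duplication_decompose_fixed_mean", "scan_beta"]

#: below this distance from an endpoint the duplication phase is dropped
#: and the single-phase model (with the appropriate dosage) is used
_BETA_EDGE = 1e-9


def scan_mean(
    kx_grid: np.ndarray,
    b_template: BurstModel,
    clock: ErlangMixture,
    p: PartitionModel,
) -> pd.DataFrame:
    """Closed-form noise decomposition along a transcription-rate sweep.

    The extrinsic component is constant across the sweep; both intrinsic
    components scale as 1/mean.
    """
    kx_grid = np.asarray(kx_grid, dtype=float)
    if np.any(kx_grid <= 0):
        raise ValueError("kx grid must be positive")
    rows = []
    for kx in kx_grid:
        b = BurstModel(
            kx, b_template.burst_mean, b_template.burst_second_moment,
            b_template.burst_family,
        )
        dec = analytics.decompose(b, clock, p)
        rows.append({"kx": kx, **dec.to_dict()})
    return pd.DataFrame(
        rows, columns=["kx", "mean_x", "cv2_ext", "cv2_part", "cv2_prod", "cv2_total"]
    )


def duplication_decompose_fixed_mean(
    beta: float,
    mean_target: float,
    b_template: BurstModel,
    p: PartitionModel,
    f: float = 2.0,
    cv2_T1: float = 0.05,
    cv2_T2: float = 0.05,
    mean_T: float = 1.0,
) -> NoiseDecomposition:
    """Noise decomposition at duplication fraction ``beta``, mean held fixed.

    The burst arrival rate is rescaled analytically so the steady-state
    mean equals ``mean_target`` at every ``beta`` (the mean is linear in
    ``k_x``).  Near the endpoints the model degenerates to a single phase
    with dosage ``f`` (beta = 0) or 1 (beta = 1) and the closed forms
    apply; in between the moment-ODE solve handles any ``f``.
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    if beta < _BETA_EDGE or beta > 1.0 - _BETA_EDGE:
        cv2 = cv2_T2 if beta < _BETA_EDGE else cv2_T1
        clock = erlang_mixture_from_target(mean_T, cv2)
        dosage = f if beta < _BETA_EDGE else 1.0
        t = timing_moments(clock)
        unit = BurstModel(
            dosage * 1.0, b_template.burst_mean, b_template.burst_second_moment,
            b_template.burst_family,
        )
        kx = mean_target / analytics.mean_protein(unit, t)
        b = BurstModel(
            dosage * kx, b_template.burst_mean, b_template.burst_second_moment,
            b_template.burst_family,
        )
        return analytics.decompose(b, clock, p)
    t1 = erlang_mixture_from_target(beta * mean_T, cv2_T1)
    t2 = erlang_mixture_from_target((1.0 - beta) * mean_T, cv2_T2)

    def schedule(kx: float) -> tuple[BurstModel, DuplicationSchedule]:
        b = BurstModel(
            kx, b_template.burst_mean, b_template.burst_second_moment,
            b_template.burst_family,
        )
        return b, DuplicationSchedule(f, t1, t2)

    b_unit, d = schedule(1.0)
    kx = mean_target / analytics.duplication_mean(b_unit, d)
    b, d = schedule(kx)
    return decompose_numeric(None, b, p, duplication=d)


def scan_beta(
    beta_grid: np.ndarray,
    mean_target: float,
    b_template: BurstModel,
    p: PartitionModel,
    f: float = 2.0,
    cv2_T1: float = 0.05,
    cv2_T2: float = 0.05,
    mean_T: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Noise components versus duplication timing at fixed mean.

    With ``normalize=True`` every component is divided by its value at
    ``beta = 0``.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    rows = []
    for beta in beta_grid:
        dec = duplication_decompose_fixed_mean(
            float(beta), mean_target, b_template, p,
            f=f, cv2_T1=cv2_T1, cv2_T2=cv2_T2, mean_T=mean_T,
        )
        rows.append({"beta": beta, **dec.to_dict()})
    df = pd.DataFrame(
        rows, columns=["beta", "mean_x", "cv2_ext", "cv2_part", "cv2_prod", "cv2_total"]
    )
    if normalize:
        ref = duplication_decompose_fixed_mean(
            0.0, mean_target, b_template, p,
            f=f, cv2_T1=cv2_T1, cv2_T2=cv2_T2, mean_T=mean_T,
        )
        for col, val in (
            ("cv2_ext", ref.cv2_ext),
            ("cv2_part", ref.cv2_part),
            ("cv2_prod", ref.cv2_prod),
            ("cv2_total", ref.cv2_total),
        ):
            df[col + "_norm"] = df[col] / val
    return df
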