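"""Event-driven stochastic simulation along a single-cell lineage.

Simulates the full model exactly (integer protein counts, stochastic
bursts, stage transitions of the phase-type cell-cycle chain, optional
single-molecule decay, and noisy partitioning at division) as well as the
two hybrid variants in which production is a deterministic drift between
stochastic timing events.  One daughter is followed after each division;
under symmetric partitioning the choice is statistically irrelevant and is
made uniformly at random.  Long-run lineage time averages estimate the
same steady-state expectations that the moment equations compute, which
makes the simulator an independent Monte-Carlo cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import BurstModel, PartitionModel
from .moments import ModelFlags
from .timing import ErlangMixture

__all__ = [
    "LineageTrace",
    "MomentEstimate",
    "sample_partition",
    "simulate_lineage",
    "lineage_moments",
    "synchronized_sample",
]

# event codes recorded in LineageTrace.event_type
EV_INIT, EV_BURST, EV_STAGE, EV_DUPLICATION, EV_DIVISION, EV_DECAY = range(6)
_EVENT_NAMES = ("init", "burst", "stage", "duplication", "division", "decay")


@dataclass
class LineageTrace:
    """Piecewise protein path along a lineage.

    ``protein[k]`` is the level immediately after the event at
    ``event_times[k]``; on the epoch up to the next event the level is
    constant in the full model and grows at ``growth_rate[k]`` in the
    hybrid models.  Stage labels refer to the epoch that starts at the
    event.
    """

    event_times: np.ndarray
    protein: np.ndarray
    growth_rate: np.ndarray
    stage_phase: np.ndarray
    stage_order: np.ndarray
    stage_step: np.ndarray
    event_type: np.ndarray
    division_times: np.ndarray
    duplication_times: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "x": self.protein,
                "phase": self.stage_phase,
                "stage_i": self.stage_order,
                "stage_j": self.stage_step,
                "event_type": [_EVENT_NAMES[e] for e in self.event_type],
            }
        )


@dataclass(frozen=True)
class MomentEstimate:
    """Time-averaged mean and CV^2 with batch-means standard errors."""

    mean: float
    cv2: float
    se_mean: float
    se_cv2: float
    n_effective: float


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_partition(x: int, p: PartitionModel, seed) -> int:
    """Draw a daughter's allotment from ``x`` molecules.

    The partitioning law fixes only the first two conditional moments
    (mean ``x/2``, variance ``alpha*x/4``); the sampling scheme matches
    both exactly wherever possible:

    * ``alpha = 0``: deterministic split, a fair coin on the odd molecule
    * ``0 < alpha <= 1``: with probability alpha a Binomial(x, 1/2) draw,
      otherwise the deterministic split (odd-molecule randomisation adds
      variance 1/4, negligible relative to ``alpha*x/4`` for large x)
    * ``alpha > 1``: beta-binomial with intra-class correlation
      ``(alpha-1)/(x-1)``; for ``x < 2`` (or ``alpha >= x``, where the
      requested variance is unreachable) the maximal-variance fallback is
      used.
    """
    if p.variance_law != "proportional":
        raise ValueError("discrete partitioning implements the proportional law only")
    if x < 0:
        raise ValueError("x must be non-negative")
    x = int(x)
    if x == 0:
        return 0
    rng = _as_rng(seed)
    alpha = p.alpha

    def even_split() -> int:
        half, odd = divmod(x, 2)
        return half + (int(rng.integers(2)) if odd else 0)

    if alpha == 0.0:
        return even_split()
    if alpha <= 1.0:
        if rng.random() < alpha:
            return int(rng.binomial(x, 0.5))
        return even_split()
    if x < 2 or alpha >= x:
        # variance alpha*x/4 exceeds the maximum x^2/4 attainable on [0, x]
        if x < 2:
            return int(rng.binomial(x, 0.5))
        return int(x * rng.integers(2))
    a = ((x - 1) / (alpha - 1) - 1) / 2.0
    if a <= 0:  # pragma: no cover - excluded by alpha < x
        return int(x * rng.integers(2))
    return int(rng.binomial(x, rng.beta(a, a)))


def _continuous_partition(x: float, p: PartitionModel, rng: np.random.Generator) -> float:
    """Partition draw for the continuous (hybrid) state variable."""
    if x <= 0:
        return 0.0
    if p.alpha == 0:
        return x / 2.0
    if p.variance_law == "constant":
        # truncated normal on [0, x] with target mean x/2, variance alpha
        while True:
            draw = rng.normal(x / 2.0, np.sqrt(p.alpha))
            if 0.0 <= draw <= x:
                return draw
    # proportional law: x * Beta(a, a) has mean x/2 and variance
    # x^2/(4(2a+1)) = alpha*x/4 when 2a+1 = x/alpha
    if x > p.alpha:
        a = (x / p.alpha - 1.0) / 2.0
        return x * rng.beta(a, a)
    return x * rng.random()  # sub-alpha levels: bounded fallback


def _burst_sampler(b: BurstModel, discrete: bool):
    if b.burst_family == "geometric0":
        prob = 1.0 / (1.0 + b.burst_mean)
        return lambda rng: rng.geometric(prob) - 1
    if b.burst_family == "geometric1":
        prob = 1.0 / b.burst_mean
        return lambda rng: rng.geometric(prob)
    if b.burst_family == "point_mass":
        size = b.burst_mean
        if discrete:
            if abs(size - round(size)) > 1e-9:
                raise ValueError("point-mass burst size must be an integer for the full model")
            size = int(round(size))
        return lambda rng: size
    raise ValueError(f"burst family {b.burst_family!r} has no sampler")


def simulate_lineage(
    clock: ErlangMixture | None,
    b: BurstModel,
    p: PartitionModel,
    flags: ModelFlags,
    n_cycles: int,
    seed: int,
    x0: float = 0.0,
) -> LineageTrace:
    """Simulate ``n_cycles`` cell cycles of a single lineage.

    Competing exponential clocks drive bursts (rate ``k_x``, or ``f k_x``
    after duplication), stage transitions (rate ``i k`` in a branch of
    order ``i``) and, if enabled, decay events (rate ``gamma_x * x``,
    full model only).  In the hybrid models bursts are replaced by the
    deterministic drift ``dx/dt = k_x <B>``.  Independent random streams
    are used for the clock, production and partitioning.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    discrete = flags.include_burst_noise
    gamma = flags.degradation or 0.0
    if gamma > 0 and not discrete:
        raise NotImplementedError("degradation is simulated in the full model only")

    dup = flags.duplication
    if dup is not None:
        phases = [(dup.t1_clock, b.kx), (dup.t2_clock, dup.f * b.kx)]
    else:
        if clock is None:
            raise ValueError("a cell-cycle clock is required when duplication is absent")
        phases = [(clock, b.kx)]

    ss = np.random.SeedSequence(seed)
    clock_rng, prod_rng, part_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    draw_burst = _burst_sampler(b, discrete) if discrete else None

    times = [0.0]
    protein = [float(x0) if not discrete else float(int(x0))]
    growth = []
    ph_l, i_l, j_l = [], [], []
    ev_l = [EV_INIT]
    division_times: list[float] = []
    duplication_times: list[float] = []

    def pick_branch(phase: int) -> int:
        pclock = phases[phase][0]
        return int(
            pclock.orders[clock_rng.choice(len(pclock.orders), p=np.asarray(pclock.probs))]
        )

    t = 0.0
    x = protein[0]
    phase = 0
    order = pick_branch(0)
    step = 1
    cycles = 0
    inf = np.inf

    while cycles < n_cycles:
        pclock, burst_rate = phases[phase]
        stage_rate = order * pclock.rate_scale
        drift = 0.0 if discrete else burst_rate * b.burst_mean
        ph_l.append(phase)
        i_l.append(order)
        j_l.append(step)
        growth.append(drift)

        dt_stage = clock_rng.exponential(1.0 / stage_rate)
        dt_burst = (
            prod_rng.exponential(1.0 / burst_rate) if discrete and burst_rate > 0 else inf
        )
        dt_decay = (
            prod_rng.exponential(1.0 / (gamma * x)) if gamma > 0 and x > 0 else inf
        )
        dt = min(dt_stage, dt_burst, dt_decay)
        t += dt
        x += drift * dt

        if dt == dt_burst:
            x += draw_burst(prod_rng)
            ev = EV_BURST
        elif dt == dt_decay:
            x -= 1
            ev = EV_DECAY
        else:
            if step < order:
                step += 1
                ev = EV_STAGE
            elif phase == 0 and len(phases) == 2:
                phase = 1
                order = pick_branch(1)
                step = 1
                ev = EV_DUPLICATION
                duplication_times.append(t)
            else:
                if discrete:
                    x = float(sample_partition(int(x), p, part_rng))
                elif flags.include_partition_noise:
                    x = _continuous_partition(x, p, part_rng)
                else:
                    x = x / 2.0
                phase = 0
                order = pick_branch(0)
                step = 1
                ev = EV_DIVISION
                division_times.append(t)
                cycles += 1
        times.append(t)
        protein.append(x)
        ev_l.append(ev)

    # close the trailing epoch labels (final state, no further events)
    ph_l.append(phase)
    i_l.append(order)
    j_l.append(step)
    growth.append(0.0 if discrete else phases[phase][1] * b.burst_mean)

    return LineageTrace(
        event_times=np.asarray(times),
        protein=np.asarray(protein),
        growth_rate=np.asarray(growth),
        stage_phase=np.asarray(ph_l, dtype=np.int32),
        stage_order=np.asarray(i_l, dtype=np.int32),
        stage_step=np.asarray(j_l, dtype=np.int32),
        event_type=np.asarray(ev_l, dtype=np.int8),
        division_times=np.asarray(division_times),
        duplication_times=np.asarray(duplication_times),
    )


def _epoch_integrals(trace: LineageTrace) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative integrals of x and x^2 at event times (linear epochs)."""
    dt = np.diff(trace.event_times)
    x0 = trace.protein[:-1]
    g = trace.growth_rate[:-1]
    x1 = x0 + g * dt
    ix = dt * (x0 + x1) / 2.0
    ix2 = dt * (x0 * x0 + x0 * x1 + x1 * x1) / 3.0
    return np.concatenate([[0.0], np.cumsum(ix)]), np.concatenate([[0.0], np.cumsum(ix2)])


def lineage_moments(
    trace: LineageTrace,
    burn_in_cycles: int,
    n_batches: int = 20,
) -> MomentEstimate:
    """Time-weighted steady-state mean and CV^2 from a lineage trace.

    The first ``burn_in_cycles`` cycles are discarded; standard errors come
    from non-overlapping batch means over whole cycles.
    """
    n_div = len(trace.division_times)
    avail = n_div - burn_in_cycles
    if avail < 3:
        raise ValueError(
            f"only {max(avail, 0)} post-burn-in cycles: need at least 3 batches; "
            "simulate more cycles or reduce burn_in_cycles"
        )
    n_batches = min(n_batches, avail)
    cum_x, cum_x2 = _epoch_integrals(trace)
    div_idx = np.searchsorted(trace.event_times, trace.division_times)
    # batch boundaries at division events, starting after burn-in
    bounds = [burn_in_cycles + round(k * avail / n_batches) for k in range(n_batches + 1)]
    edges = div_idx[np.asarray(bounds) - 1] if burn_in_cycles > 0 else np.concatenate(
        [[0], div_idx[np.asarray(bounds[1:]) - 1]]
    )
    t_edges = trace.event_times[edges]
    dT = np.diff(t_edges)
    bx = np.diff(cum_x[edges]) / dT
    bx2 = np.diff(cum_x2[edges]) / dT
    bcv2 = bx2 / bx**2 - 1.0

    total_T = t_edges[-1] - t_edges[0]
    mean = float((cum_x[edges[-1]] - cum_x[edges[0]]) / total_T)
    second = float((cum_x2[edges[-1]] - cum_x2[edges[0]]) / total_T)
    cv2 = second / mean**2 - 1.0
    se_mean = float(np.std(bx, ddof=1) / np.sqrt(n_batches))
    se_cv2 = float(np.std(bcv2, ddof=1) / np.sqrt(n_batches))
    return MomentEstimate(
        mean=mean, cv2=float(cv2), se_mean=se_mean, se_cv2=se_cv2, n_effective=n_batches
    )


def synchronized_sample(
    clock: ErlangMixture,
    j: int,
    b: BurstModel,
    p: PartitionModel,
    flags: ModelFlags,
    n_cells: int,
    seed: int,
    n_cycles: int = 2000,
    burn_in_cycles: int = 50,
) -> np.ndarray:
    """Sample protein levels conditioned on cell-cycle stage ``j``.

    Requires a pure Erlang clock of order ``n`` (cells synchronised by
    stage).  Levels are read at times drawn uniformly over the total
    post-burn-in occupancy of stage ``(n, j)``, which weights stage visits
    by their duration exactly as the stationary conditional expectation
    does.
    """
    if len(clock.orders) != 1:
        raise ValueError("synchronized sampling requires a pure Erlang clock")
    n = clock.orders[0]
    if not (1 <= j <= n):
        raise ValueError(f"stage index j must lie in 1..{n}")
    if flags.duplication is not None:
        raise ValueError("synchronized sampling is defined for the non-duplicating model")
    trace = simulate_lineage(clock, b, p, flags, n_cycles, seed)
    t0 = trace.division_times[burn_in_cycles - 1] if burn_in_cycles > 0 else 0.0

    in_stage = (trace.stage_step[:-1] == j) & (trace.event_times[:-1] >= t0)
    starts = trace.event_times[:-1][in_stage]
    durs = np.diff(trace.event_times)[in_stage]
    xs = trace.protein[:-1][in_stage]
    gs = trace.growth_rate[:-1][in_stage]
    if len(starts) == 0:
        raise RuntimeError("no post-burn-in occupancy of the requested stage")
    cum = np.concatenate([[0.0], np.cumsum(durs)])
    rng = np.random.default_rng(seed + 1)
    u = rng.uniform(0.0, cum[-1], size=n_cells)
    idx = np.searchsorted(cum, u, side="right") - 1
    offset = u - cum[idx]
    return xs[idx] + gs[idx] * offset
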