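# Methods

## Model and assumptions

The package computes single-lineage steady-state statistics of a stable
protein whose count x(t) evolves under three coupled stochastic
processes:

1. **Bursty production.** Transcription events arrive as a Poisson
   process with rate k_x; each event makes a burst of B proteins
   (short-lived mRNA limit). Only ⟨B⟩ and ⟨B²⟩ enter the moment
   formulas. Two geometric conventions are supported for sampling and
   inference: support {0, 1, …} (default, ⟨B²⟩/⟨B⟩ = 1 + 2⟨B⟩) and the
   shifted geometric on {1, 2, …} (⟨B²⟩/⟨B⟩ = 2⟨B⟩ − 1). The {0, …}
   convention is the default because it is the one the burst-size
   inference formulas assume; the choice matters whenever ⟨B⟩ is small.
2. **Phase-type cell-cycle clock.** The cycle time is a mixture of
   Erlang distributions: with probability p_i the cycle traverses i
   exponential stages of rate i·k. The mean is 1/k independent of the
   mixture, CV_T² = Σ p_i/i ∈ (0, 1], and the normalised central third
   moment is 2 Σ p_i/i², giving ⟨T³⟩/⟨T⟩³ = 1 + 3CV_T² + 2Σp_i/i².
   Within this class CV and skewness cannot be tuned independently —
   noisier clocks are necessarily more positively skewed, which is why
   the mean protein level grows with CV_T².
3. **Noisy partitioning.** At division a daughter receives a random
   share with conditional mean x/2 and variance α·x/4 (proportional
   law). A constant-variance variant (variance α independent of x) is
   available in the closed forms and the continuous simulator; it
   removes the dependence of partitioning noise on CV_T².

Optionally, **genome duplication** splits the cycle into phases T₁
(burst rate k_x) and T₂ (rate f·k_x), each with its own phase-type
clock; β = ⟨T₁⟩/⟨T⟩ locates the mean duplication time. **Protein
turnover** at rate γ_x can be added (discrete decay events in the full
model; a deterministic decay term in the hybrids); the fast-turnover
closed forms assume γ_x⟨T⟩ ≫ 1.

All statistics are long-run time averages along one line of descent
(mother → one daughter). These differ in general from
population-snapshot averages over a growing tree of cells; the package
deliberately computes the former.

## Noise decomposition strategy

Three model variants isolate the noise sources: a hybrid with
deterministic production and partitioning (timing noise only), a hybrid
that adds partitioning noise, and the full stochastic model. The total
CV² of the full model splits exactly into

    CV² = CV_E² (timing) + CV_R² (partitioning) + CV_P² (production),

where each component is the increment in CV² from switching one more
source from deterministic to stochastic. The numeric engine
(`moments.decompose_numeric`) performs this subtraction on exact
steady states, so additivity holds by construction for any dosage
factor f and any clocks; the closed forms in `analytics` are the same
quantities evaluated symbolically (f = 2 only, for duplication).

Exactness rests on the stage indicators g_ij being binary: products
like g_ij·x^m need no closure, so the joint moments ⟨g_ij⟩, ⟨x g_ij⟩,
⟨x² g_ij⟩ obey a finite linear ODE system assembled term-by-term from
the event rates (division transfers carry 1/2 on first moments, 1/4 on
second moments, and an α/4 cross term). No moment-closure approximation
is applied anywhere.

## Parameters

| Parameter | Meaning | Units | Default / typical |
| --- | --- | --- | --- |
| k_x | burst (transcription) arrival rate | 1/time | free; swept in mean scans |
| ⟨B⟩ | mean burst size | molecules | 0.5–10 (1.5 in validation runs) |
| α | partitioning-error scale | – | 1 (binomial) |
| ⟨T⟩ | mean cell-cycle length | time | 1 (time unit) |
| CV_T² | cycle-length noise | – | 0.05 (low-noise validation clock) |
| f | dosage factor after duplication | – | 2 |
| β | mean duplication time / ⟨T⟩ | – | scanned over [0, 1] |
| γ_x | decay rate (optional) | 1/time | 0 (stable protein) |

Simulation controls: default 2×10⁴ cycles with a 50-cycle burn-in and
20 non-overlapping batches for standard errors; validation tests use
2.5–5×10³ cycles where 3–4 SE agreement suffices.

## Numerical choices

- **Steady states** are obtained by replacing one redundant occupancy
  balance row with the normalisation Σ⟨g_ij⟩ = 1 and solving the dense
  linear system directly — exact up to machine precision and far
  cheaper than long-time integration. Closed forms and the ODE engine
  agree to better than 1e-8 relative over wide random parameter draws.
- **Transients** use a stiff-capable implicit integrator (BDF) at
  rtol 1e-10, since high-order Erlang chains make the system stiff.
- **Clock construction for a target (mean, CV²)** uses the pure Erlang
  of order 1/CV² when that is an integer, otherwise the minimal
  two-component mixture of adjacent orders. Other mixtures with the
  same first two moments exist; they share the mean and CV² but differ
  in the third moment, so extrinsic noise can differ slightly between
  equally valid constructions. A CV² = 0 request is honoured exactly by
  the closed forms but mapped to a pure Erlang of order 200 (with a
  warning) for sampling and stage-chain calculations.
- **β-extrema** are located by a dense grid (step 1e-4) refined by
  bounded golden-section search to 1e-8.
- **Partition sampling** matches the prescribed conditional mean and
  variance exactly where mathematically possible: a
  binomial/deterministic mixture for 0 < α ≤ 1, a moment-matched
  beta-binomial for α > 1, and x·Beta(a, a) in the continuous hybrid.
  Unavoidable edge cases are documented in the sampler: the odd-molecule
  coin adds variance 1/4, and for x ≤ α the requested variance α·x/4
  exceeds the maximum attainable on [0, x], so a maximal-variance
  fallback is used. These affect only trajectories that visit very low
  copy numbers.
- **Degenerate inputs**: zero production (k_x = 0) is allowed in the
  simulator (x stays at its initial value pattern) but the noise
  formulas require a positive mean and say so; infeasible inference
  inputs raise identifiability errors rather than returning clipped
  estimates.

## What the simulator does and does not emulate

The simulator generates exact realisations of the model above, so
agreement between its time averages and the analytic/ODE results (the
spine of the test suite) validates the mathematics, not the biology.
Real single-cell data additionally contain mother–daughter cycle-length
correlations, cell-size control ("adder"-type feedback) with
size-dependent transcription, promoter on/off switching, and
measurement noise — none of which are modelled. Passing tests therefore
show that the formulas are correct for the stated model class, not that
the model captures every feature of a given organism.

## Design choices

- Intrinsic noise on simulated data is defined operationally as the
  total CV² minus the timing-only hybrid's CV² at the same parameters,
  consistent with the decomposition; a dual-reporter measurement is out
  of scope.
- Fixed-mean comparisons (noise versus β) rescale k_x analytically at
  each grid point, since the mean is linear in k_x.
- Negative parameter estimates from the two-condition inversion are
  returned with a warning instead of being clipped: they are evidence
  against the assumed noise model and should be visible.
- The CLI is a thin layer over the library; every run writes a JSON
  manifest (config, seed, package version, config hash) sufficient to
  replay deterministic paths bit-identically.

## Known limitations

- Phase-type clocks cannot represent CV_T² > 1 or an exact delta.
- Closed-form duplication noise exists for f = 2 only; other dosage
  factors go through the numeric engine.
- The constant-variance partitioning law has no discrete sampler (the
  distribution is under-determined at integer counts); it is supported
  in the closed forms and the continuous hybrid simulator.
- Lineage statistics are not population-snapshot statistics; comparing
  against flow-cytometry or imaging snapshots of growing populations
  requires a tree-weighting correction that this package does not
  implement.
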