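# cyclenoise

Cell-to-cell variability in protein copy numbers comes from more than
bursty transcription: division times are random, molecules are partitioned
noisily between daughter cells, and genome duplication changes gene dosage
partway through the cell cycle. `cyclenoise` is a toolkit for quantifying
how these mechanisms combine to set the steady-state mean and noise
(squared coefficient of variation, CV²) of a stable protein along a
single-cell lineage. It is aimed at quantitative/systems biologists who
want to decompose measured protein noise into mechanistic components or
design single-cell experiments to estimate burst and partitioning
parameters.

## Model

Proteins are produced in bursts of random size *B* arriving at rate *k_x*
(the short-lived mRNA limit of transcription–translation). The cell-cycle
time *T* follows a mixture of Erlang distributions — a phase-type clock
with states G_ij that can represent any positively valued distribution
with CV ≤ 1 — with mean ⟨T⟩ = 1/k and CV_T² = Σᵢ pᵢ/i. At division each
daughter inherits on average half the molecules, with conditional variance
α·x/4 (α = 1: binomial partitioning; α = 0: deterministic split; α > 1:
over-dispersed, e.g. protein aggregates). Optionally, genome duplication
at a random point β·⟨T⟩ into the cycle multiplies the burst arrival rate
by a dosage factor *f*.

Key closed forms (single lineage, steady state):

- Mean: ⟨x⟩ = k_x⟨B⟩⟨T⟩(3 + CV_T²)/2 — randomness in division timing
  *raises* the mean.
- Total noise decomposes additively, CV² = CV_E² + CV_R² + CV_P²:
  - extrinsic (timing) noise CV_E² = 4(⟨T³⟩/⟨T⟩³ + 4CV_T² + 6)/(3(3+CV_T²)²) − 1,
    which tends to 1/27 for clockwork division and is independent of the mean;
  - partitioning noise CV_R² = 4α/(3(3+CV_T²)) · 1/⟨x⟩;
  - production noise CV_P² = (3CV_T²+5)/(3(3+CV_T²)) · (⟨B²⟩/⟨B⟩) · 1/⟨x⟩.

Because the stage indicators of the phase-type clock are binary, the
moment hierarchy closes *exactly*: the package also ships a moment-ODE
engine (exact linear solve, no closure approximation) and an event-driven
stochastic simulator, so every closed form is cross-validated by two
independent computational routes.

## Worked example

```python
from cyclenoise import BurstModel, PartitionModel, ErlangMixture, analytics

clock = ErlangMixture(orders=(20,), probs=(1.0,), rate_scale=1.0)  # CV_T² = 0.05
burst = BurstModel.geometric(kx=20.0, burst_mean=1.5)              # ⟨B²⟩/⟨B⟩ = 4
dec = analytics.decompose(burst, clock, PartitionModel(alpha=1.0))
print(dec.to_dict())
```

prints

```
{'mean_x': 45.75, 'cv2_ext': 0.05419690047478287,
 'cv2_part': 0.009555376392248202, 'cv2_prod': 0.04921018842007825,
 'cv2_total': 0.11296246528710932}
```

i.e. at a mean of ~46 molecules roughly half the noise is extrinsic
(division timing), most of the rest is bursty production, and binomial
partitioning errors contribute least. Raising *k_x* leaves `cv2_ext`
unchanged while both intrinsic terms fall as 1/mean.

The same is available from the shell, along with figure-style scans and a
three-engine cross-validation:

```bash
cyclenoise decompose --kx 20 --burst-mean 1.5 --alpha 1 --clock-mean 1 --clock-cv2 0.05
cyclenoise scan-beta --mean-target 170 --burst-mean 10   # noise vs duplication timing
cyclenoise infer --fano-ref 6 --fano-perturbed 4 --mean-ratio 0.5
cyclenoise validate --config my_model.yaml
```

The `infer` call above reproduces the two-condition design: if the
intrinsic Fano factor drops from 6 to 4 when a ribosome-binding-site
mutation halves the burst size, then ⟨B⟩ = 3.6 and α = 3.25 — evidence of
partitioning errors well above binomial.

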