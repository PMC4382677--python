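# Methods

## The model

`catcircuit` implements a three-circuit mean-field network that learns a
motion-categorization task by trial and error.  Twelve motion directions,
at ±15°, ±45° and ±75° on either side of an arbitrary boundary axis, are
assigned to two categories C1/C2.  On each trial one direction is shown
for 1 s (after a 200-ms pre-stimulus period and followed by a 500-ms
intertrial interval), the network commits to a category, and a binary
reward follows.

Each excitatory population is reduced to a single gating variable `s`
(the fraction of activated slow NMDA-like conductance),

    ds/dt = -s/τ_s + (1 - s) γ r(I),     γ = 0.641, τ_s = 60 ms,

with the firing rate given by the standard current–frequency curve

    r(I) = (aI - b) / (1 - exp(-d(aI - b))),
    a = 270 Hz/nA, b = 108 Hz, d = 0.154 s.

Three circuits are connected in series with plastic inter-circuit
pathways:

* **Sensory ring** (128 units, preferred directions spanning 360°):
  periodic-Gaussian recurrent coupling (σ = 43.2°), driven during the
  stimulus by a Gaussian input current (peak 0.1 nA, σ = 43.2°).
* **Association ring** (128 units): receives the plastic feedforward
  pathway `c_SA` from the sensory ring and plastic top-down feedback
  `c_DA` from the decision pair.
* **Decision pair** (C1/C2): self-excitation 0.3725 nA, cross-inhibition
  −0.1137 nA, pooling the association ring through the plastic pathway
  `c_AD`.  A 0.01-nA nonselective gating current during the stimulus puts
  the pair in its winner-take-all regime; a −0.08-nA reset current during
  the first 300 ms of the intertrial interval returns it to rest.

Every unit receives a zero-mean Ornstein–Uhlenbeck background current
(τ_n = 2 ms, stationary SD 0.009 nA) plus a constant background drive.
The background drive (`i_bg_*`) is required by the arithmetic of the
transfer function: with b = 108 Hz the firing threshold sits near 0.4 nA,
so a 0.1-nA stimulus cannot ignite an otherwise undriven network.  It is
the analogue of the ~0.3255-nA I₀ of the reduced two-variable decision
model this circuit family descends from.

The choice is read out by comparing the two decision rates with a 20-Hz
threshold over the last 25 ms of the stimulus; trials are invalid when
both or neither population is above threshold, or when either crossed it
before stimulus onset.

### Plasticity

At the end of each valid trial every plastic synapse updates as

    c ← clip(c + q (R - ⟨R|θ⟩) r_pre r_post, 0, 1),    q = 3·10⁻⁵,

with trial-averaged stimulus-period rates, and ⟨R|θ⟩ a per-stimulus
running average of reward, E ← E + (R - E)/τ_R with τ_R = 5 trials,
initialized at 0.5 for unseen stimuli and updated after the weight
update.  Invalid trials trigger no plasticity.  The expected per-trial
weight change equals q·Cov[R, r_pre·r_post | θ]; conditioning on the
(binary) choice factorizes the covariance into
P₁P₂(R₁-R₂)(N₁-N₂), which ties learning to choice probability — the
analytical core verified by `catcircuit.theory` against Monte-Carlo
oracles.

Variants: `feedback` (full model), `no_feedback` (no `c_DA` pathway),
`fixed_tuning` (no `c_DA`, `c_SA` frozen — a two-layer model).

## Calibrated parameters

The published account fixes the kinetic, noise and decision-circuit
constants but leaves the ring couplings, the three maximal pathway
strengths, the background drives and the width of the initial `c_SA`
profile unstated.  These were set by the behavioural calibration scan in
`catcircuit.calibrate` (outcome in `docs/calibration.md`), anchored to:
chance performance before learning, ~80% correct after a few thousand
trials with near-boundary (15°) stimuli least accurate, and a high
valid-trial fraction.  Key choices:

| parameter | value | note |
|---|---|---|
| sensory ring J₊/J₋ | 2.4 / −2.0 nA | stimulus-evoked bump ~25 Hz, FWHM ~68°, extinguished after stimulus offset |
| association ring J₊/J₋ | 0.2 / −0.5 nA | weak recurrence: association tuning stays broad and shallow |
| c_SA initial profile σ | 70° | broad initial association tuning, like naive parietal neurons |
| g_max (S→A, A→D, D→A) | 1.15 / 0.45 / 0.10 nA | A→D drive in the canonical low-input band of the decision attractor |
| backgrounds (sens/assoc/dec) | 0.25 / 0.255 / 0.33 nA | rings quiescent at rest; decision pair spontaneously active (~1 Hz) |

Two design points deserve emphasis.  First, the decision pair must
operate in its attractor regime (background ≈ 0.33 nA, feedforward drive
a few hundredths of a nA): weaker-drive regimes either fail the validity
rule or make choices quasi-deterministic, in which case a stimulus wired
to the wrong category stops generating reward-prediction errors
(⟨R|θ⟩ → 0) and never recovers.  Second, association tuning must be broad
and shallow for the psychometric function to plateau near 80% rather than
saturate: the categorical drive difference for 15° stimuli is then a
fraction of the decision noise.  Strong association-ring inhibition
(a "normalization regime") sharpens tuning through the iceberg effect of
the steep f-I curve and pushes accuracy to ~99%; the shipped calibration
therefore uses weak recurrence, and total association activity remains
stimulus-invariant by ring symmetry instead.

## Analysis toolkit

All estimators act on trial × neuron tables of stimulus-period mean
rates:

* **ROC area**: rank-sum formulation, half credit for ties.
* **CTI**: contrast of between- vs within-category mean-rate differences
  over direction pairs, compared at matched angular separations
  (per-separation means, averaged over separations at which both pair
  types exist).  Without separation matching any unimodal tuning curve
  scores ≈ +0.2 because between-category pairs are farther apart on
  average; with it, bell curves score ≈ 0 and step tuning 1.
* **CS**: ROC area between correct-trial rates of the two categories.
* **CP**: per-stimulus ROC area between rates preceding C1 and C2
  choices; stimuli need ≥3 valid trials per choice, neurons need a valid
  estimate in both categories; the neuron CP is the unweighted mean.
  Significance by within-stimulus choice shuffles, with the observed CP
  reduced to a t-statistic against the null sample (the conventional
  "two-sample t-test" read for a singleton observation).
* **Tuning fits**: least-squares exponential-cosine
  r₀ + r_max·exp((cos(θ-θ₀)-1)/w_rad²) with the population two-pass width
  constraint (unconstrained fit per neuron, then widths box-constrained
  to the 10-percentile band around the population median); step profile =
  per-category means.
* **Ridge GLM**: design = (fitted direction profile, category profile,
  constant); λ by exact leave-one-trial-out CV (leverage identity) on a
  log grid 10⁻⁴…10²; β significance against 1,000 trial-shuffled refits;
  labels direction/category/mixed/nonselective.
* **Noise correlations**: per-stimulus Pearson on correct trials,
  averaged over stimuli.
* **Dip test**: Hartigan's dip via the greatest-convex-minorant /
  least-concave-majorant iteration; p-values by uniform-null bootstrap;
  preferred directions are unwrapped to (−180°, 180°] about the boundary
  first.  The dip depends on spacings (it is affine- but not general
  monotone-invariant).
* **Classical MDS**: Torgerson double-centering, top-2 eigenvector
  coordinates, full eigenvalue spectrum reported.

## Synthetic fixtures

`catcircuit.fixtures` generates labelled rate tables with analytically
known structure: exponential-cosine / step / mixed / flat tuning,
choice-conditioned mean shifts chosen from the inverse Gaussian-ROC
relation (prescribed CP), a shared gain factor (prescribed noise
correlations), and a shallow logistic psychometric choice rule with a
lapse floor so error trials exist at every boundary distance.  They
validate estimator recovery without the simulator, but do not emulate
circuit dynamics: rates are conditionally Gaussian and i.i.d. across
trials, there is no temporal structure, and choices do not feed back on
rates.  Passing recovery tests therefore certifies the estimators, not
the circuit model.

## Numerical and performance choices

The trial integrator (numba-compiled) matches the NumPy reference
dynamics (Heun predictor-corrector at dt = 1 ms; OU noise updated once
per step, held across the two Heun stages; rates recorded at the
step-start state) with the following controlled approximations, each far
below the 0.009-nA noise scale: float32 state; the f-I curve from a
4096-point lookup table (error < 2·10⁻³ Hz); rates truncated to zero
below 0.36 Hz, which makes the quiescent rings exactly silent; silent
ring stretches of the pre-stimulus and intertrial windows advanced in
closed form (exact exponential gating decay and OU jump) while the
decision pair keeps integrating step by step; gating values flushed to
zero below 10⁻¹² (float32 denormals).  Noise innovations come from a
counter-based generator with a 128-layer ziggurat sampler, validated
against SciPy's normal distribution in the test suite.  In the
strongly amplifying sensory ring the recurrent gain multiplies these
small approximations, so kernel-vs-reference agreement is asserted at
2% in a moderate-gain configuration and 10% at the default couplings.

## Scales used in the tests

The published learning landmarks sit at 65,000–420,000 trials.  The test
suite runs desk-scale proxies: 10,000-trial trainings for the learning
criteria, 6,000 trials for the associative-learning plateau, 1,400–2,000
frozen trials per evaluation (the original protocol used 10,000).  At 10,000 trials
the behavioural separation of the variants has not yet developed (the
unstructured drift of `c_SA` that degrades the no-feedback network
operates on a ~10⁵-trial horizon at the calibrated rates), so the variant
ordering is asserted with a 3-percentage-point tolerance, and the
category-tuning trajectory (CTI ≈ 0 before learning, rising strongly
with training) qualitatively.  At the calibrated (deliberately low)
firing rates the unstructured sensory→association drift of the
no-feedback network is slow — mean |Δc| ≈ 2·10⁻³ per synapse over 10⁴
trials — so its behavioural deterioration lies orders of magnitude beyond
desk scale; the suite asserts the structured-vs-unstructured contrast
(category tuning develops with feedback, none without, while the weights
drift) rather than the behavioural decline itself.  The model's choice-probability magnitudes are stronger
than the recorded ones (top-down feedback is a larger fraction of
association-rate variability here); all CP-dependent results are
asserted as signs/orderings, not magnitudes.  One estimator interaction
is worth knowing: at chance performance, category sensitivity — computed
from correct trials only — conditions on the choice exactly as CP does,
so an untrained network with random top-down weights shows a weak
positive CP–CS correlation (r ≈ 0–0.3 depending on the weight draw); the
learned correlation is far larger, and the tests assert the increase,
not a sharp null.

## Known limitations

* The calibration targets the behavioural milestones, not the
  physiological rate distributions; association rates are lower than LIP
  averages.
* The CTI/CP landmark *values* at 65,000 trials are not reproduced at
  desk scale (see above).
* Ring sizes, timings and the twelve-direction stimulus set are fixed by
  the protocol; other geometries are untested.
* The experimental match-to-category design (sample/test intervals,
  choice inference from match responses) is supported only through
  `infer_choice_from_match`; no attempt is made to simulate it.
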