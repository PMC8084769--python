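# Methods

## Observer model

A trial presents a standard grating (explored with n₁ strokes, optionally
with a mask between strokes) followed by a comparison grating (n₂ strokes,
free exploration). The model propagates only variances; response means are
realised by the simulator's probit rule.

**Standard phase.** The first stroke initialises the estimate with the
single-stroke variance σ² (mm²). Every subsequent stroke first adds process
noise σ²_w to the running estimate — the degradation of the stored trace,
larger when a mask intervenes — then combines it with a fresh σ²
observation by inverse-variance (Kalman) weighting. With zero process noise
this reduces exactly to the σ²/n₁ sample-mean law, which the tests use as a
closed-form oracle.

**Comparison phase.** On comparison stroke *i* the stored standard
representation has decayed: its variance is multiplied by i^0.442 (i = 1
gives factor 1; no decay occurs within the standard phase). The stroke's
difference score therefore has variance `i^0.442 · v_standard + σ²`;
difference scores are treated as conditionally independent given the stored
representation and are serially integrated like the standard phase, with
process noise between steps. The predicted JND is the square root of the
final integrated difference variance.

**Comparison-phase process noise.** Two conventions are implemented.
In `condition` mode (the default) the condition's own process-noise level
applies in both phases — each masking condition has a single noise
parameter, which is how the three-parameter fit is defined and what gives
masked conditions a precision cost even at n₁ = 1 (the integration of the
mask into the ongoing stream also perturbs the difference integration). In
`control` mode the comparison phase always uses the no-mask level, on the
physical argument that the comparison stimulus itself is never masked; then
masked and unmasked predictions coincide at n₁ = 1. We made `condition` the
package default because it matches the published three-parameter model and
produces the robust masked-above-unmasked ordering that the directional
checks quantify; `control` mode remains available as an explicit argument
everywhere.

**Parameters.** Defaults are the values fitted to the second experiment's
condition means: σ² = 0.075 mm², σ²_w = 0.031 mm² (mask), σ²_w = 0.012 mm²
(no mask); decay exponent 0.442 and n₂ = 4 are fixed constants (n₂ from
observed free exploration of comparable gratings). Variances are floored at
1e−12 mm² so degenerate sweeps cannot divide by zero. Fitting the decay
exponent is deliberately unsupported.

## Synthetic experiments

The generator reproduces the two designs' structure: two standards (1.69
and 1.95 mm) each with nine equally spaced comparisons (1.35–2.03 and
1.61–2.29 mm; step exactly 0.085 mm), 10 repetitions per pair, 720 trials
per participant for the four-condition design and 1,440 for the eight-
condition design; condition blocks ordered by a cyclic Latin square across
participants, trial order randomised within block, trials split over 2
resp. 4 sessions (sessions carry no modelled effect). The standard is
always the first interval; side is metadata.

Responses are Bernoulli draws from
`p = lapse/2 + (1−lapse)·Φ((comparison − (standard + bias)) / σ_D)` with
σ_D the model-predicted JND. Defaults: lapse 0 (none was reported; small
values are available for robustness checks); PSE bias +0.02 mm everywhere
(adaptation-like order effect, PSEs slightly above the standard) plus an
extra −0.10 mm for masked conditions at the 1.95-mm standard (the mask's
high-frequency content pulling the percept), matching the qualitative
pattern of the reference PSE tables; between-participant heterogeneity as a
log-normal factor on σ² with spread 0.2 — enough to make the exclusion rule
and between-participant error bars meaningful without dominating the
within-participant effects. The generator does not emulate sequential
dependencies, learning/fatigue, kinematic variability, or Weber scaling
between the two standards (argued negligible at these periods), so passing
tests certify the analysis chain under the stated observer, not those
aspects of real data.

## Psychometric analysis

Cumulative Gaussians are fitted by binomial maximum likelihood
(L-BFGS-B; μ free, σ bounded in [1e−4, 10 × stimulus range]; probabilities
clipped at 1e−9 for stability). The lapse rate is fixed at 0 by default and
can be freed up to 0.05; the JND is always reported as σ of the underlying
Gaussian (the 84%−50% distance), not of the lapse-compressed curve.
Degenerate data (all responses identical) return a flagged, unconverged fit
rather than raising. Convergence requires optimiser success with no
parameter at a bound.

Pooling across the two standards fits each standard first, re-expresses
every trial as comparison-minus-PSE, and refits the merged data with μ free;
a pooled |μ| beyond one comparison step flags misalignment instead of being
clamped. Participants are excluded when their mean JND across conditions
exceeds the grand mean by 2.5 between-participant SDs — a single pass over
all participants, upper tail only (the rule targets outlyingly *bad*
precision); with fewer than three participants the rule is skipped with a
warning. The mean (not per-condition) summary is used because the exclusion
criterion is a participant-level precision screen.

## Model fitting

The three free variances are fitted to condition-mean JNDs (means over
retained participants, unweighted across the 8 conditions) by trust-region
least squares with non-negativity bounds, from 32 seeded starts drawn
log-uniformly over [1e−4, 1] mm²; ties break by lowest SSE then lowest
parameter norm. R² = 1 − SSE/SS_total, reported as NaN when the condition
means have zero variance. The design validator requires both masking levels
and at least two stroke numbers, naming the missing factor otherwise. The
parameter-recovery harness perturbs the noiseless condition JNDs with
Gaussian noise, refits, and reports bias, RMSE and ±2-SD coverage per
parameter. Conditions from the four-condition design are never fitted (the
smooth condition has no principled noise level; predictions for it are
illustrative only).

## Inferential statistics

Paired t tests report Cohen's d_z = mean(Δ)/sd(Δ) (identically t/√n);
zero-variance differences with nonzero mean raise instead of returning an
infinite statistic. The stroke-number linear contrast uses centered weights
(−3, −1, 1, 3); because the stroke counts 1, 3, 5, 7 are themselves equally
spaced, weights proportional to the raw counts are identical up to scale,
so no separate option exists. The masking × stroke interaction contrasts
the masked-minus-unmasked difference with the same weights.
Cousineau–Morey within-participant SEMs remove each participant's mean,
restore the grand mean, and inflate by √(C/(C−1)). The repeated-measures
ANOVA delegates to pingouin (one or two within factors; the three-factor
design is analysed as standard × condition); the Huynh–Feldt epsilon is
obtained from the Greenhouse–Geisser estimate by the standard
transformation and applied only when below 1. Bonferroni correction is
plain p × m capped at 1.

## Problem sizes and determinism

The directional end-to-end checks simulate the full eight-condition design
(11 participants, 1,440 trials each) 40 times in the test suite and 30
times in the acceptance script; the psychometric-recovery checks use 200
replicates at 10× the per-cell repetitions, and parameter recovery 200
noisy refits — sizes chosen so Monte-Carlo error is comfortably below the
tolerances being checked. All randomness flows from explicit seeds
(per-participant streams are split from the experiment seed), and the
hypothesis profile is derandomised, so runs are reproducible.

## Known limitations

Predictions for the smooth (low-energy) intermediate surface depend on an
arbitrary mapping to a noise level; the model was designed for mask/no-mask
contrasts. The observer has no sequential dependencies or criterion drift,
so empirical t statistics from simulations cannot be compared to real-data
ones — only directions and recovery properties are claimed. Reproducing the
original fit on the deposited raw data (doi:10.5281/zenodo.3907325),
including its R² = 74%, requires downloading that deposit and converting it
to the trials CSV schema; no downloader ships.
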