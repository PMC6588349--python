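# Methods

## Photobleaching step counting

A spot's intensity trace is modeled as piecewise constant plus white Gaussian
read noise. The noise scale is estimated first, from the median absolute
deviation of first differences scaled by 1/(√2·0.6745); bleaching steps are
sparse outliers among the differences and do not perturb the MAD, and a
constant trace yields exactly 0.

Steps are found by greedy binary change-point splitting: at each stage the
single split giving the largest reduction in squared error is added, after
which every change point is re-optimized between its neighbors until stable
(at most five sweeps). The refinement matters: greedy splits can land one
frame off a true transition, and the stranded sample would otherwise demand a
spurious extra step. The model order k (number of steps) minimizes

    SSE(k) + penalty_scale · k · σ̂² · ln N,

a BIC-like criterion with `penalty_scale = 2.0` by default; ties within
floating-point tolerance resolve to the smaller k. In photobleaching mode,
candidate splits that would create an up-step larger than 2σ̂ are rejected,
enforcing monotone-decreasing levels without a hard constraint on the fit.

Spots are classified by step count (1, 2, 3+) and rejected when no step is
found, when the final level is more than 3σ̂ from zero (incomplete
bleaching), or when any step is smaller than 3σ̂ (not a credible fluorophore
loss). Published work in this area rarely states its trace-acceptance
criteria; these rules are this package's operational definition, and they are
deliberately symmetric across conditions so that between-condition
comparisons are unaffected by the exact thresholds. Percentages are computed
among accepted spots only. The movie is the unit of replication: conditions
are compared on per-movie two-step percentages (unpaired t-test for two
groups, one-way ANOVA for three or more).

## Stoichiometry model

Complexes are monomers or dimers (fraction `f`); each subunit is labeled
independently with efficiency `p`; only spots with ≥ 1 fluorophore are
visible. Among visible spots the two-step probability is
θ₂ = f·p²/(f·(2p−p²) + (1−f)·p). With probability `b` a visible spot gains
one extra labeled monomer (chance colocalization plus antibody/streptavidin
bivalency, lumped into a single background term), shifting its category up by
one; this is capped at one extra molecule because the background is small
(5–10%) and double coincidences are second order. Three-or-more-step spots
therefore arise only from background — higher-order oligomers are not a model
class, consistent with the observation that the >3-step fraction does not
change across conditions.

`b` is held fixed, not estimated: a three-category table cannot identify
`p`, `b` and `f` jointly. Defaults are p = 0.80 (SNAP-tag labeling
efficiency), b = 0.075 (midpoint of the 5–10% background range) for general
use and b = 0 when reproducing the closed-form inversion arithmetic.

The maximum-likelihood estimator maximizes the multinomial likelihood of the
{1, 2, 3+} counts over f ∈ [0, 1] (bounded scalar minimization, tolerance
1e-10) and builds a 95% interval by profile likelihood (2·ΔlogL = 3.84,
brentq on each side). With b = 0 and no 3+ counts it coincides with the
closed form. Estimates at the boundary are flagged with one-sided intervals.
Dimer fractions are echoed at nearest-ten-percent precision alongside full
precision, matching how such distributions are reported.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated:

* **SiMPull cohorts** — 20 Hz sampling (standard sCMOS frame rate for this
  recording mode), bleaching time constant 10 s with a 60 s record (six time
  constants, so ~99.8% of fluorophores bleach within the movie), SNR 5
  (unit step height ÷ Gaussian read-noise s.d.; no literature value exists
  for this, it is a fixture choice), and i.i.d. exponential bleach times with
  no blinking. Unlabeled complexes are discarded before emission, as in the
  real assay where they are invisible.
* **FRET recordings** — true FRET relaxes exponentially toward
  baseline + ΔFRET during drug epochs (τ_on) and back (τ_off); acceptor =
  total·FRET, donor = total·(1 − FRET), each plus independent Gaussian noise,
  so the two channels are perfectly anticorrelated in expectation and total
  intensity is conserved — the idealized signature of a pure FRET change.
* **Dose–response tables** — Hill model plus replicate noise, with a preset
  bank of published EC50s (0.23 µM for PAM-evoked GIRK currents; 1.2, 0.9,
  3.5, 3.1 µM for LY48/TASP/CBiPES/BINA inter-TMD FRET; 2.1 µM for Ro 64)
  used as regression anchors.
* **Quench trials** — nine quencher trials following the stretched
  exponential and four flat no-quencher controls per experiment (the standard
  trial structure for this assay), plus a compound-only reference trace
  carrying the drug's own fluorescence offset.

What the generators do **not** emulate: fluorophore blinking and partial-frame
bleaching (camera integration across a step), focus drift and background
ramps, the acceptor-only photoswitching artifact, bleed-through between FRET
channels, and correlated (non-white) noise. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every pathology of real recordings; the step detector's
penalty and rejection rules are the knobs that would absorb such effects.

## FRET and pharmacology conventions

FRET gaps (zero total intensity) propagate as NaN, never interpolated or
zero-filled. Response plateaus are means over the last 25% of an epoch —
epochs are expected to reach steady state before washout, and no published
window convention exists. No bleed-through or direct-excitation corrections
are applied, matching the relative-change use of the assay. Hill fits fix
the baseline at 0 (responses are baseline-subtracted upstream), initialize
EC50 at the concentration nearest half-max and n = 1, and report
curvature-based standard errors; an EC50 outside the tested range is flagged
extrapolated rather than rejected. 10–90% times interpolate threshold
crossings linearly between samples and use raw (unsmoothed) traces by
default, with an optional moving-average window; the amplitude must exceed
3× the baseline s.d. or the measurement errors out as "no response".

## Quench-rate analysis

Fits use the 2–100 ms window only, excluding the < 2 ms instrument dead time.
The compound-fluorescence correction is additive-offset removal against a
compound-only reference; an additive form was chosen because a fluorophore
background free of inner-filter effects adds linearly to the detected signal
(the alternative, multiplicative normalization, would distort F∞).
Initialization: F0/F∞ from the first/last window samples, β = 0.8, τ₀ from
the 1/e crossing; β is constrained to (0, 1]. Non-decaying traces return a
flagged fit instead of raising, so batch processing can skip dead trials.
Rates are ms⁻¹ internally and reported relative to the control rate.

## Numerical notes and limitations

* Step detection is O(N · max_steps) per trace via prefix sums; 5,000 traces
  of 1,200 frames take a few seconds. The exhaustive segmentation oracle used
  in tests enumerates all change-point sets at N ≤ 80, k ≤ 3, where the
  property is the same as at any larger N.
* The full-pipeline dimer-fraction estimate carries a small (~1 pp) downward
  bias at the default conditions: near-coincident bleach events merge into
  single steps, and incomplete bleaching rejects dimers slightly more often
  than monomers. Both effects are inherent to the assay, not to the
  estimator, and are well inside the nearest-ten-percent reporting precision.
* The (τ₀, β) likelihood surface is a correlated ridge; coordinate-wise
  comparisons with grid searches are ill-posed, so the grid oracle in the
  test suite checks global optimality (fit SSE ≤ best grid SSE) plus
  closeness to truth on noiseless data.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical configs give bit-identical outputs.
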