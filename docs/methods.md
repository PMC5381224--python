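# Methods

## The experimental design being modelled

A target Landolt C (diameter 2°, line width 0.4°, gap width 0.4°) is centred
10° right of fixation for 500 ms. On flanked trials a concentric ring
surrounds it at one of five edge-to-edge separations (0.4°, 0.92°, 1.62°,
2.58°, 3.9°); the ring is featureless (*no-gap*), has one gap (*one-gap*), or
two gaps (*two-gap*). Spacing is reported as the flanker's outer radius over
the eccentricity of its centre: `(target_diameter/2 + separation) / 10°`,
giving 0.14–0.49. The line-width-midpoint alternative does not reproduce
those printed values, so the outer-radius reading is adopted. An observer
completes 20 repetitions of each of the 16 conditions per session over five
sessions: 1600 trials, 100 per condition.

Flanker-gap orientations are the crux of the design: the one-gap offset is
drawn `N(target, 22.5°)`, placing the flanker gap near — but rarely at — the
target orientation, so target, average and substitution reports are
distinguishable trial by trial. The two-gap condition adds a second gap at
`N(gap1 + 180°, 22.5°)`, whose substitution produces errors near ±180°.

## The synthetic observer

`ObserverModel` draws each report from a mixture over strategies: target
(mean 0 error), average (mean `w·δ1` along the short arc, `w = 0.5` by
default), near/far substitution (mean `δ1`/`δ2`), and a uniform guess.
Components requiring an absent gap get zero probability and the rest are
renormalised, so one model specification covers all four flanker types.
Circular noise (SD in degrees) is added to every component except the guess;
both wrapped-normal and von Mises noise are supported — the validation
generator defaults to wrapped-normal ("Gaussian noise"), the analyses fit
von Mises, and below SD ≈ 30° the two are practically indistinguishable.
Target orientations are uniform on [0°, 360°): the only non-informative
choice for a full-circle task, though not explicitly part of the stated
design. Ground-truth strategy labels are stored per trial (`truth_label`)
so estimators can be scored against the realised composition.

What the generator does **not** emulate: separation-dependent strategy
probabilities within one run (a single `ObserverModel` is constant across
conditions; separation-dependent behaviour is composed in tests by
concatenating per-condition simulations), response-time dynamics,
orientation anisotropies, and session effects (learning, fatigue). A green
test therefore establishes that an estimator recovers known mixtures under
the design's sampling structure — not that real observers satisfy the
mixture model.

## Circular statistics

Errors and offsets are wrapped to (−180°, 180°], with −180° mapping to +180°
(one fixed boundary convention everywhere; positive = clockwise). Perceptual
error is the circular SD `sqrt(−2 ln R)` of report errors (the Circular
Statistics Toolbox convention, matching `scipy.stats.circstd`), **not** the
angular deviation `sqrt(2(1−R))`; the two diverge for dispersed samples, and
the measure is unbounded as R → 0 (returned as `inf` with a warning).
Confidence intervals are percentile bootstrap (resampling trials, n_boot =
1000 default, explicit seed); whether the original analyses used percentile
or bias-corrected intervals is not stated, so percentile is chosen and
flagged here.

## Error taxonomy

Each error is labelled by its circular distance to the predictions 0, δ/2
and δ; exact ties resolve by the fixed priority target > average >
substitution. For |δ| < 90° circular and linear distances coincide, but the
contract is circular so re-centred far-gap data behave identically. Two-gap
trials split at |e| > 90° (strictly greater, per the stated rule; a trial at
exactly 90° is near); the far subset has 180° subtracted from both error and
δ2, after which 0 means "reported the target's polar opposite".

Known, deliberate bias: when the generative mixture is nearly pure target
and offsets are small relative to the noise, noise-only trials land nearer
δ/2 or δ than 0, so labelled p_target underestimates the true rate. This is
a property of the labelling scheme itself; the recovery harness quantifies
it rather than hiding it, and the tests assert it as expected behaviour.

## Mixture estimation

The standard mixture is the working-memory-style MLE with three adaptations:
(1) the orientation space is the full 360° circle (a Landolt-C gap position
is unique on the circle), so von Mises densities use period 360°; (2) the
distractor offset δ_i enters per trial, since it varies trial-to-trial in
this design; (3) κ is shared across components (following the cited model
family — which two parameters the averaging extension added is not stated;
p_avg and w are assumed).

Numerics: proportions are optimised through a softmax, κ through its log,
and w through a logistic, with L-BFGS-B from 20 (standard) / 50 (averaging)
random restarts; the best restart is returned and same-seed runs are
bit-identical. κ is clamped to [2, 500] during fitting — the floor
(circular SD ≈ 44°, far broader than plausible report noise) is required
for identifiability, because a near-zero-κ von Mises is indistinguishable
from the uniform guess component; without it, uniform data are absorbed
into p_target instead of γ → 1. The κ ↔ SD conversions accept the wider
range [0.01, 500] and clamp outside it with a warning.

The averaging-extended fit carries an instability diagnostic motivated by
its known ridge (w → 0 mimics target, w → 1 mimics substitution): the fit is
flagged `unstable` when restarts within 2 log-likelihood units of the best
disagree on p_average by more than 0.25, or the central-difference Hessian
at the optimum has condition number above 1e8. On 100-trial two-component
data this flag fires on the large majority of replicates — the expected
"unreliable" behaviour, asserted in the acceptance suite.

The Monte Carlo estimator assumes reports are target + substitution only
(its role is the two-component sensitivity analysis), so the simplex grid is
one-dimensional: p_target ∈ {0, 0.05, …, 1}. Each cell pools 200 simulated
datasets of the observed size (offsets resampled from the observed δ's,
Gaussian noise of the supplied SD) and scores the pooled error distribution
against the observed one with the two-sample Kuiper statistic — the
rotation-invariant Kolmogorov–Smirnov variant appropriate for angles
(implemented in-package; no installed library provides it). The original
procedure's details are not available, so this reconstruction is a
documented stand-in.

Linear slopes are ordinary least squares of error on offset; a 50/50
target+substitution mixture has `E[e|δ] = 0.5·δ` and hence slope ≈ 0.5 with
zero generative averaging, so slope fits are reported with that caveat and
offsets beyond ±90° trigger a wrap warning.

## Pipeline and recovery study

`run_analysis` routes conditions to their analyses and stamps outputs with a
config hash and seeds; (trial table, config) determines every output
exactly. Far-gap label analyses pool observers by default (the far subset is
small; cells with one or two trials are reported with their n, unsmoothed);
pooling is a config switch. `run_recovery_study` simulates replicate
datasets from the 100-trial validation design, runs each estimator, and
tabulates bias, MAE and RMSE against the generative rate, plus MAE against
each replicate's realised trial-level composition (exact recovery is only
defined against the latter: the realised binomial draw differs from the
generative rate by ~0.05 at n = 100).

## Numerical and scale choices

- Test-suite simulations are scaled to keep the default run around a minute:
  bootstrap coverage uses 300 replications × 300 resamples (band widened
  accordingly), qualitative-pattern checks use 4000 trials/condition instead
  of 10,000. The acceptance checks keep their stated sizes (10,000-draw
  calibration, 100 × 100-trial validation batches, n = 100,000 SD recovery).
- `bootstrap_ci` is a small in-package percentile implementation (the
  contract — arbitrary statistic of a sequence, explicit seed, small result
  record — fits awkwardly through `scipy.stats.bootstrap`); the circular
  primitives are cross-checked against `scipy.stats.circstd`/`circmean` in
  the tests.
- Degenerate inputs: empty samples raise; zero resultant yields `inf`
  (circular SD) or an error (circular mean); an observer model whose entire
  mass sits on components absent from a condition raises a configuration
  error; slope fits require n ≥ 3 and non-degenerate offsets.

## Limitations

- The original study's empirical per-observer proportions cannot be
  reproduced (raw trials were never deposited); all quantitative validation
  is against synthetic ground truth.
- The mixture's shared-κ assumption and the Monte Carlo reconstruction are
  reasoned choices where the source procedure is underspecified.
- Nearest-model labelling is a hard assignment; its small-offset bias is
  characterised, not corrected. Soft (responsibility-based) assignment is
  the mixture model's job, not the labeller's.
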