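# Methods

`remap` implements the analysis chain of a two-phase sensory-preconditioning
fMRI paradigm: 72 face–object pairs are encoded incidentally (two 12-min
runs), each face is then re-paired with an aversive scream or a neutral voice
(36/36, one 16.8-min run), and three 8-min rest scans (240 volumes at
TR = 2 s) flank the learning phases. The analyses quantify how emotional
learning retroactively strengthens the initially neutral associations:
trial-level pattern reinstatement, condition-dependent seed–target coupling
(gPPI), post-encoding rest connectivity changes, brain–behavior prediction,
and serial mediation. Everything runs end to end on a synthetic-data
generator whose parameters encode the study's design and the statistical
structure the analyses assume.

## Synthetic-data generator

### Designs

Trial timing follows the protocol exactly. Initial learning: 4 s pair
presentation + 2 s vividness rating, inter-trial intervals jittered over
{2, 4, 6} s; emotional learning: 2 s face cue + 2 s face–voice association +
2 s rating, ITIs over {6, 8, 10} s. ITIs are *counterbalanced* (equal counts
of each jitter value, shuffled) rather than drawn i.i.d., so the realized
mean ITI is exactly 4 s / 8 s and run durations are exact closed forms:
72 × 10 s = 720 s and 72 × 14 s = 1008 s. The trial count must be divisible
by the three jitter cells.

Condition sequences never contain more than two consecutive trials of the
same condition. A rejection sampler is hopeless here — the acceptance
probability of a random 36/36 arrangement with no triple run is on the order
of 10⁻⁹ — so sequences are drawn sequentially: at each position a label is
sampled with probability proportional to its remaining count, restricted to
choices from which a valid completion provably exists (an exact, memoized
feasibility recursion over the small state space). The sampler is seeded and
validated against a brute-force run-length checker.

### Trial patterns

Per pair *p* in condition *c* (voxel vectors of length `n_voxels`, default
100):

    init(p) = f_p + o_p         + gamma * g_c + noise
    emo(p)  = f_p + rho_c * o_p + gamma * g_c + noise

with pair-unique unit-norm components `f_p` (face) and `o_p` (object), a
condition-shared component `g_c`, and i.i.d. Normal(0, sigma_noise²) voxel
noise. `rho_c` is the reinstatement gain — the fraction of the initial
object representation re-expressed when the face reappears during emotional
learning; the emotion effect of interest is `rho_aversive > rho_neutral`.

Defaults (`rho` = 0.6/0.2, `gamma` = 0.3, `sigma_noise` = 0.2) were chosen
once, analytically: with unit-norm signal components spread over 100 voxels,
per-voxel noise of 0.2 puts pair-specific correlations near 0.2–0.3 — the
range trial-level reactivation analyses typically report — with a
condition difference of ~0.05 in Fisher z that is reliably detectable at 36
trials per condition but far from saturated.

### Behavior

Memory follows a logistic link on per-pair reinstatement,
P(correct) = logistic(beta0 + beta1·r), with beta0 = −1, beta1 = 6: over the
realistic reinstatement range this yields accuracies around 0.65–0.75 and an
aversive-vs-neutral accuracy difference of a few percentage points, matching
the size of emotion-charged memory benefits in this kind of paradigm.
Vividness and confidence ratings come from a latent standard normal
correlated 0.5 with standardized reinstatement, cut at equally spaced
thresholds (−1, 0, 1) into the 1–4 scale.

In the pipeline's multi-subject stage, subjects additionally differ in their
reinstatement gains (`rho_aversive` ~ Normal(0.6, 0.25) truncated to [0, 1],
`rho_neutral` ~ Normal(0.2, 0.15)): these individual differences are exactly
what the subject-level prediction and mediation analyses feed on. With 36
trials per condition the binomial noise floor on a subject's accuracy is
about 0.08, which caps attainable brain–behavior correlations near 0.4–0.6 —
the same ceiling real studies face at this trial count.

### Time series

Task runs are generated at TR resolution: neural seed activity is the 2-s
stimulus boxcar plus unit-SD spontaneous fluctuations, convolved with the
canonical HRF; the target adds baseline coupling (0.3 × seed) plus
condition-gated coupling `coupling_c · (hrf * (neural × boxcar_c))`, the
exact generative form a gPPI analysis inverts. The spontaneous component is
essential: with purely task-driven seed activity the PPI regressor is
collinear with the psychological regressor and condition-specific coupling
is unidentifiable. Rest runs are correlated Gaussian pairs with specified
population correlation (defaults 0.3/0.5/0.6, emulating a post-encoding
increase); confounds are slow sinusoidal drifts plus white noise for the six
motion parameters, CSF and WM.

## First-level GLM

The HRF is the SPM-style canonical double-gamma (response peak 6 s,
undershoot peak 16 s, dispersions 1 s, ratio 6:1, 32 s support), normalized
to unit peak; regressors are boxcars convolved at microtime (default 16×
oversampling) and sampled at the TR. All events are modeled with 2 s from
stimulus onset regardless of on-screen duration. Condition-level designs
contain one regressor per condition (plus per-condition cue regressors of no
interest in the emotional phase); trial-level designs contain one regressor
per pair — spanning every presentation, so repeated viewings collapse into a
single column — plus one pooled cue regressor (72 + 1 regressors for the
emotional run). Estimation is OLS with t = beta/SE and df = n − rank(X); a
discrete-cosine drift basis (128 s cutoff) and supplied nuisance columns are
optional. No AR(1) prewhitening is applied.

## Pattern similarity

Patterns are z-scored across voxels (removing mean activation), correlated
with Pearson's r, clipped at |r| = 1 − 10⁻⁷, and Fisher-transformed.
Trial-level measures: pair-specific (same pair across phases), across-pair
within/between/combined (other pairs' initial patterns, the self-pair always
excluded), and within-encoding / within-arousal (same-phase consistency).
Per-trial values are averaged within condition in r-space and then
transformed by default; `average_before_transform=False` transforms first —
the two orderings differ by a Jensen-gap term that is negligible at these
correlation magnitudes, and the default follows the natural reading of the
procedure. The searchlight applies any trial-level measure over the in-mask
voxels of a sphere (Euclidean center distance ≤ radius, voxel centers, no
partial-volume weighting) around every in-mask voxel and stores the
aversive − neutral z contrast; spheres with fewer than two usable voxels
yield NaN with a warning.

## Behavioral statistics

The chance level of matching *n* pairings sequentially without replacement
is mean(1/n + 1/(n−1) + … + 1), i.e. 52.08% for n = 4. Accuracy is binned by
rating (high = {3, 4}, low = {1, 2}); empty bins propagate as missing, never
zero. The 2×2 repeated-measures ANOVA tests each effect through its
within-subject contrast (so F = t² of the paired contrast and partial
η² = F/(F + df_error)); covariates of no interest are mean-centered and the
contrast intercept is tested, the convention mainstream statistics packages
use for repeated-measures ANCOVA. Paired tests report d_av (mean difference
over the average of the two SDs). The trial-level vividness–confidence
relationship is a random-intercept linear mixed model (statsmodels MixedLM,
REML) with a Wald 95% CI — the CI method is a choice the procedure leaves
open. SCL means are window averages over [onset, onset + 6 s).

## Prediction

Balanced fourfold CV is implemented as rank stratification on the outcome:
subjects are ranked, consecutive rank blocks of size k each contribute one
subject per fold (residual randomness seeded). "Balanced" is not otherwise
defined in the source procedure; rank stratification is the most common
reading. Per fold a simple linear regression is fit on the training folds
and applied to the held-out fold; r(predicted, observed) is the Pearson
correlation of pooled predictions with the outcome. Significance: y-labels
shuffled n_perm times (default 1000), p = #(r_perm > r_obs)/n_perm — the
strictly-greater, one-sided count exactly as the procedure states, so the
minimum attainable p is 0; an add-one variant and a two-sided option are
flags. Under the null the CV r itself is biased negative (≈ −0.08 at n = 28)
— a generic property of cross-validated correlations — but the permutation
comparison is unaffected and its p-values are uniform. Steiger's Z compares
two dependent, non-overlapping correlations using the Pearson–Filon
covariance evaluated at the pooled correlation (the full 4×4 correlation
matrix is required and checked for positive semidefiniteness).

## Connectivity

gPPI: the seed is deconvolved to neural resolution by ridge-regularized
inversion of the Toeplitz HRF operator (penalty fixed or chosen by GCV). The
TR-resolution kernel is bin-integrated rather than point-sampled — point
sampling starts at h(0) = 0 and makes the operator singular. Deconvolution
is intrinsically ill-posed at the HRF's spectral zeros and at the very end
of the run (the final neural samples barely influence the observed window),
so neural-space recovery is assessed on the interior; the data-space
identity (re-convolving the estimate reproduces the seed) holds everywhere.
One PPI regressor per cell — plain conditions or condition-by-memory cells —
is formed as hrf ∗ (neural × cell indicator), with the psychological
regressors and the seed series included to absorb common driving input and
overall task activation; cells must not overlap. OLS contrasts on PPI betas
(default aversive − neutral) carry t and p.

Rest: both data and confounds are demeaned and band-pass filtered
(0.008–0.10 Hz, 4th-order Butterworth, zero-phase with Gustafsson edge
handling — reflective padding leaks stopband power into 240-volume runs
through the slow high-pass edge), then the data are residualized on the
filtered confounds; filtering the confounds with the same band avoids
reintroducing out-of-band energy. Seed–target correlations are
Fisher-transformed per rest run, consecutive runs are differenced in
z-space, and the per-subject differences are regressed on the two
per-condition memory scores; the interaction contrast tests
β_aversive − β_neutral.

## Mediation

The serial two-mediator model (M1 = a1·X; M2 = a2·X + d21·M1;
Y = c′·X + b1·M1 + b2·M2) is fit as three OLS equations on standardized
variables, so c = c′ + a1·b1 + a2·b2 + a1·d21·b2 exactly. The b1 path is
freely estimated (full serial model); a parallel variant is available by
reading the individual products. Indirect effects get case-resampling
bootstrap CIs with the bias-corrected (BC, not accelerated) percentile
adjustment: z0 from the fraction of bootstrap draws below the point
estimate, percentile points Φ(2z0 ± z₀.₉₇₅). Degenerate resamples are
redrawn.

A calibration caveat documented deliberately: bootstrap tests of a
three-path product under a *complete* null (all paths zero) are extremely
conservative — the bootstrap distribution of a1·d21·b2 concentrates at
zero and the CI essentially never excludes it — while under a boundary null
(one path zero, the others large) the BC interval over-rejects somewhat.
Both behaviors are well known in the mediation literature and are properties
of the method, not of this implementation (which calibrates correctly on a
sample-mean bootstrap). The test suite asserts the nominal 5% band against
the complete-null generator and therefore documents this as a failing
calibration check rather than hiding it.

## Pipeline

`remap run` executes synth → firstlevel → similarity → behav → predict →
connectivity → mediation on synthetic data, with per-stage seeds derived
from a master seed by hashing, and writes tidy TSVs plus a JSON manifest of
inputs, seeds, versions and output hashes; identical configs produce
byte-identical outputs. Problem sizes in the default demo (24 subjects, 72
pairs, 1000 permutations/bootstrap draws) mirror the study scale. The
config round-trips losslessly through JSON.

## What passing tests do and do not show

The generator plants exactly the structure the analyses assume: linear
coupling, Gaussian noise, HRF-conformant hemodynamics, no physiological
noise or motion artifacts beyond the supplied confound columns, no
SCR waveform shapes, and no spatial autocorrelation beyond the component
structure. Passing recovery tests therefore demonstrates that the
implementations invert their own generative models and calibrate correctly
under them — not that the assumptions hold in real BOLD data. Conversely,
the design numbers, the estimator algebra (F = t², the effect
decomposition, searchlight/ROI equivalence) and the calibration of the
permutation machinery are model-free and transfer as-is.
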