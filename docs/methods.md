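# Methods

## The model

`attngain` implements a dynamic causal model of evoked MEG responses in a
spatial-cueing (Posner) task, built around the idea that attention is the
gain — the expected precision — of superficial pyramidal populations that
report prediction error in a cortical hierarchy.

### Microcircuit

Each cortical source contains four neural-mass populations: spiny stellate
(ss), superficial pyramidal (sp), inhibitory interneurons (ii) and deep
pyramidal (dp) cells.  Every population obeys second-order (alpha-kernel)
convolution kinetics

    dv/dt = i,    di/dt = kappa*u - 2*kappa*i - kappa^2*v

with rate constants kappa = 1/4 ms^-1 (ss, sp, ii) and 1/16 ms^-1 (dp).
Firing rates are a logistic function of depolarization, sigma(v) =
1/(1 + exp(-0.56*v)), bounded in [0, 1] with baseline sigma0 = sigma(0) =
0.5.  All couplings act on rate *deviations* sigma(v) - sigma0, which makes
the all-zero state an exact fixed point of the autonomous dynamics and
gives a clean resting baseline.

The sp population's recurrent self-inhibition is exp(gamma).  gamma is the
negative log precision of the prediction-error channel: Pi = exp(-gamma).
Descending (modulatory) afferents change it dynamically,

    gamma(t) = gamma0 + [invalid]*delta_gamma
               - c * sum_k M_k * (sigma(V_dp,k) - sigma0),      c = 3/2,

so that above-baseline firing in modulatory afferents (deep pyramidal
cells of higher sources) *disinhibits* the target population —
activity-dependent top-down gain control.  The coefficient c is
configurable because its printed source is typographically ambiguous; 3/2
is the default reading.  A stand-alone error-unit integrator
(`microcircuit.error_unit_trajectory`) realises the underlying
predictive-coding steady state xi = Pi * (mu - prediction) and is used as
an analytic oracle in the tests.

### Network

Eight sources form two mirror-symmetric hierarchies: V2 -> {V3, V5} -> PC
per hemisphere.  Extrinsic connections follow the laminar convention:
forward connections run sp -> ss one level up; backward driving
connections run dp -> sp (and, with weight 0.75, dp -> ii) one level down;
backward *modulatory* connections run dp -> gamma of sp on the same edges.
Homologous sources are additionally linked by interhemispheric (callosal)
driving connections (sp -> ss of the mirror source).  These lateral
connections are essential to the study design: the visual target drives
one V2 only, yet the empirical phenomenon of interest — reorienting of
gain toward the opposite hemisphere — requires the un-stimulated
hemisphere to be active.  With no interhemispheric route the contralateral
hierarchy would be exactly silent and the time-resolved gain effects could
not exist.

Exogenous input is a Gaussian bump of drive, peak 120 ms, standard
deviation 16 ms, delivered to the spiny stellate cells of the V2
contralateral to the target hemifield (right V2 for the left-hemifield
targets modeled here).

Conditions (valid/invalid cueing) differ only through three effect sets:
an additive shift delta_gamma of each source's baseline gain, a
log-scaling delta_M of the modulatory weights, and (for the provisional
comparison only) a log-scaling delta_B of the backward driving weights.
With all effects zero, the two conditions are computationally identical —
bit-identical outputs, which the tests assert exactly.

Integration is fixed-step classical RK4 at dt = 1 ms over -50..400 ms,
initialized at rest.  The integrator is written over a *batch* of
parameter sets; this is what makes finite-difference Jacobians affordable
(one batched integration per Jacobian).  Halving dt changes trajectories
by ~1e-5 relative sup-norm at defaults.

### Default parameter values

Population coupling constants, extrinsic weights and the stimulus
amplitude are not constrained by the phenomena being modeled beyond sign
and laminar pattern, so they are package defaults chosen to satisfy two
requirements: (i) a spectrally stable resting point (largest Jacobian
eigenvalue real part about -0.009/ms at defaults) with transient,
physiologically-shaped responses, and (ii) enough *expression* of the
condition effects in sensor data that they are statistically identifiable
at the study's 10 dB signal-to-noise ratio.  The second requirement was
made quantitative: defaults were selected by maximizing the smallest
Fisher information of the condition-effect parameters (equivalently the
fraction of linearized posterior draws recovering the true effect vector)
over the stable region of parameter space.  The chosen values are

| group | value |
| --- | --- |
| intrinsic couplings | sp<-ss +4, dp<-sp +1.5, ii<-ss +2, ii<-dp +0.75, sp<-ii -4, ss<-ii -2, dp<-ii -0.4, ss<-ss -2, ii<-ii -2 |
| forward | 2.4 (into PC: 3.2) |
| backward driving | 0.12 (from PC: 0.10) |
| backward modulatory | 1.8 (from PC: 2.5) |
| lateral (interhemispheric) | V2 3.5, V3/V5 2.7, PC 1.7 |
| gamma0 | 0 (unit baseline self-inhibition) |
| stimulus amplitude | 3.0 a.u. |

All are configurable through `build_posner_network` overrides.

## Observation model

Source depolarizations reach sensors through a lead field with population
contribution weights (ss, sp, dp) = (0.2, 1.0, 0.5) — superficial
pyramidal cells dominating, interneurons contributing nothing.  The lead
field is synthetic: 64 channels on a ring, one smooth random topography
per source (Gaussian-kernel-smoothed white noise, unit norm, fixed seed),
mixed with a shared topography at correlation 0.3 to emulate MEG field
spread.  No head geometry is implied; this replaces an anatomical forward
solution, which is out of scope.

For fitting, data are compressed to the first eight canonical modes: the
leading principal components of the condition-concatenated sensor data
after projection onto the column space of the lead field.  With 8 sources
the lead-field range is 8-dimensional, so the modes retain the entire
modelable subspace while discarding the noise components orthogonal to
it.

## Synthetic data

`default_validity_scenario` encodes the study conditions for
left-hemifield targets: input to right V2; in the invalid condition left
V2 is strongly disinhibited (delta_gamma = -ln 2), left V3 slightly
inhibited (+ln 1.25), right V5 slightly disinhibited (-ln 1.25), backward
modulation strengthened by ln 1.5 on all edges except those from right PC
(weakened by ln 1.25), and parietal gain unchanged — so the generating
model is "1 0 1" in the factorial space.  The magnitudes are declared
package defaults — the sign pattern is what the scenario is committed to —
and all are configurable.

Datasets are condition-averaged evoked responses at 200 Hz over
-50..400 ms with white sensor noise at 10 dB dataset-level SNR (noise
variance set from the mean signal power over channels, samples and
conditions).  Raw trials are simulated at 600 Hz on a padded window with
per-trial lognormal amplitude jitter (sd 0.1), Gaussian latency jitter
(sd 8 ms), per-trial noise scaled so that averaging n trials recovers the
dataset-level SNR, and an optional seeded fraction of artifact trials
(20x RMS in-band oscillations, indices recorded in the truth record).

What the generator does *not* emulate: correlated (spatially structured
or temporally autocorrelated) sensor noise, cue-target-interval structure,
subject-level variability, eye movements, or any anatomical realism in the
lead field.  Passing recovery tests therefore show that the estimation
machinery is correct and well-calibrated under the model's own
assumptions (an "inverse crime" by design), not that the method would
recover effects from real MEG recordings at this SNR.

## Preprocessing

Bandpass: 5th-order Butterworth, 2-32 Hz, applied forward-backward
(zero phase).  Downsampling: polyphase FIR anti-aliasing and rational
resampling to 200 Hz.  Epoching: closed interval -50..400 ms
(round(0.45 * rate) + 1 samples), per-channel baseline mean over -50..0 ms
removed.  Robust averaging: per-sample bisquare (Tukey) reweighting across
trials, tuning constant 4.685 on MAD-scaled residuals, at most 20
iterations.  The residual scale is estimated per sample across trials and
floored by the pooled per-channel scale: a purely pooled scale
misclassifies legitimate trial-to-trial latency variability at response
peaks as artifact and progressively collapses the average (observed
during development), whereas the per-sample scale tracks it.

## Inversion (variational Laplace)

The generative model is y = g(theta) + e with e ~ N(0, exp(-lambda) I)
over the stacked mode-space responses of both conditions, and a Gaussian
prior over theta.  All positive structural quantities are estimated as
log-scalings of their defaults (Gaussian priors N(0, 1/16)); gamma0
offsets are additive N(0, 1/16); condition effects are additive/log-scale
N(0, 1/4); the stimulus peak keeps its experimental prior N(120, 16^2) ms.
Zero prior variance fixes a parameter exactly and removes it from the
free set.  The full factorial model has 62 free parameters.

The objective is the Laplace free energy

    F = -N/2 ln 2pi + N/2 lambda - 1/2 exp(lambda) ||e||^2
        - 1/2 (m - mu0)' P0 (m - mu0) - 1/2 ln|P0 + exp(lambda) J'J|
        + 1/2 ln|P0|    (+ hyperprior terms when lambda is free),

with J the central finite-difference Jacobian of g (step 1e-3, computed
as one batched integration).  For a linear g and fixed lambda this equals
the exact log evidence, which the tests verify to 1e-6 against the
conjugate closed form.  The expected-uncertainty term
exp(lambda) tr(J S J')/2 is deliberately omitted from both F and the
lambda update; this keeps the linear-Gaussian case exact and the M-step
closed-form, at the cost of a slightly optimistic noise estimate for
strongly nonlinear fits.

Optimization is Gauss-Newton with Levenberg-Marquardt diagonal damping.
A proposed step is evaluated under its *own* linearization (new Jacobian,
M-stepped lambda) and accepted only if it increases F; rejected steps
raise the damping.  The accepted-iteration F trace is therefore
non-decreasing by construction — asserted as a hard invariant.
Convergence: improvement below 0.01 nats for 3 consecutive accepted
iterations, cap 64 iterations; failure to improve from the prior mean is
reported as a non-converged flag, not an exception.  An unstable
integration during a proposal is treated as a rejected step.

The noise log-precision lambda has a weak Gaussian hyperprior N(0, 32)
and is updated between parameter steps by Newton's method on dF/dlambda =
N/2 - exp(lambda)||e||^2/2 - (lambda - lambda0)/v = 0.  Setting the
hyperprior variance to 0 fixes lambda (used by the oracle tests).

## Model comparison

The factorial space crosses three binary factors — condition effects on
extrastriate gain (delta_gamma on V2/V3/V5), parietal gain (delta_gamma
on PC) and backward modulation (delta_M) — into 8 models labelled
"e p m".  The provisional space crosses backward *driving* (delta_B)
against backward *modulatory* (delta_M) condition effects into 4 models;
gain effects remain free in all four so that each model can express the
validity effect somehow.

Reduced models are scored by Bayesian model reduction from the full
model's posterior: for Gaussian priors/posteriors, the evidence of a model
whose priors only shrink follows in closed form.  The implementation
works in canonical (precision, linear, constant) form and handles exact
zero-variance reductions by slicing the Gaussians at the fixed values, so
no large-precision limits are involved; on the linear oracle it matches a
direct refit to 1e-6, and on the nonlinear network fit it agrees with
refitting to within 2 nats (tested).  Refitting remains available as an
audit path.  Posterior model probabilities are the softmax of free
energies under a uniform model prior; exact ties break toward the model
with fewer free factors.

Time-resolved gain is reconstructed by re-integrating the fitted network
and evaluating -gamma(t) per source from the same deep-pyramidal afferent
depolarizations the integrator uses.  With M = 0 the trajectories are
exactly flat at -(gamma0 + [invalid] delta_gamma).

## Problem sizes and numerical choices

The packaged analyses run at desk scale: 64 channels, 8 modes, 91 time
samples per condition, 451-step integrations, 62-parameter fits (a full
inversion takes seconds on one core).  Recovery and selection checks use
5 fixed seeds at the scenario defaults; the acceptance script replicates
over 3 derived seeds.  Fixed tolerances used in tests: 1e-6 for analytic
oracles, 1 % sup-norm for step-halving, 0.5 dB for realized SNR, 2 nats
for nonlinear reduction-vs-refit agreement.

## Known limitations

- Conduction delays are omitted; all extrinsic influences are
  instantaneous at the integration step.
- A single white-noise precision is shared across modes and time;
  temporal autocorrelation of MEG noise is not modeled.
- Bayesian model reduction inherits the local Gaussian (Laplace)
  approximation of the full fit; strongly multimodal posteriors would
  invalidate both.
- The lead field is statistical, not anatomical; absolute source
  amplitudes and topographies carry no physiological meaning.
- Right-hemifield target conditions and behavioral (reaction-time)
  analyses are out of scope.
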