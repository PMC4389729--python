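# Methods

## The sensor and its models

The system modeled here is a whole-cell malonyl-CoA biosensor: the
*Bacillus subtilis* transcription factor FapR represses a synthetic promoter
driving RFP in *E. coli*; malonyl-CoA binds FapR and relieves the
repression, so fluorescence reports the intracellular malonyl-CoA made by a
co-transformed production construct.  The measured signals are culture
density X(t) (OD600) and fluorescence R(t), read every 12 minutes in a
96-well plate.

### Mechanistic cascade

Three mass balances link biomass to fluorescence (`fapsense.cascade`):

    dM/dt = vm X - vg dX/dt - gamma_m M          (malonyl-CoA)
    dC/dt = kf F M - kr C                        (FapR:malonyl-CoA complex)
    dR/dt = kappa C - gamma_r R                  (reporter)

with production rate vm (construct- and induction-specific), turnover
gamma_m, mass-action binding to a constant FapR pool F with dissociation
constant Kd = kr/kf = 2.4 uM, promoter strength kappa and reporter decay
gamma_r.  Chaining the three equilibria under constant X gives the
steady-state gain

    R/X = kappa F vm / (Kd gamma_m gamma_r),

implemented in `steady_state_gain`.  This is the form that follows from the
stage equilibria; note it is proportional to F and inversely proportional
to Kd — a grouping sometimes typeset ambiguously, so the derivation is kept
explicit here.  The growth-drain term vg dX/dt is implemented but defaults
to zero: plate data cannot separate it from vm, and none of the analyses
depend on it.

### Filter approximations

Because the three stages operate on separated time scales, the cascade is
summarized by zero-pole filters of order 1-3 (`fapsense.transfer`):

    R(s)/X(s) = K (1 - tau_z s) / prod_i (1 + tau_pi s),   i = 1..order

All orders share DC gain K (fluorescence per OD), a derivative constant
tau_z coupling dX/dt into the response, and integral constants tau_p
(minutes) setting the response lag.  Time is in minutes throughout; with
the 12-min sampling period this puts the identified slow constants at
roughly 2.5-9 h, consistent with a reporter maturing over hours.

## Identification

The discrete model is obtained by the bilinear (Tustin) substitution
s = (2/Ts)(z-1)/(z+1), expanded to an ARX difference equation

    R[k] = sum_i a_i R[k-i] + sum_j b_j X[k-j],

whose coefficients are linear in the data (`fapsense.arx`).  Fitting is
ordinary least squares of R[k] on its own lags and the biomass lags, with
no intercept and the first `order` (incomplete) rows dropped
(`fapsense.sysid.fit_discrete`).  The numerator is fit unconstrained
(order+1 coefficients) even though the continuous model has two numerator
degrees of freedom; K is always extracted as the DC gain and tau_z from the
mapped numerator root, with surplus non-artifact roots counted as
unmodeled zeros.

Continuous parameters come from inverting the map on the roots:
s_i = (2/Ts)(z_i - 1)/(z_i + 1), tau_i = -1/s_i, reported descending so
tau_1 is always the slow constant.  Numerator roots within 1e-6 of z = -1
are clearing artifacts of the substitution (a first-order numerator cleared
by (z+1)^(order-1)) and are discarded; the genuine zero is the real root
farthest from z = -1.  Estimates with complex or unstable poles are never
coerced: the fit carries validity flags (`stable`, `real_poles`,
`positive_gain`, unmodeled-zero count) and continuous parameters are absent
when the flags fail.  `compare_orders` fits all three orders on a common
sample (dropping max-order initial rows) so the model classes are nested
and in-sample residual variance is non-increasing with order.

Numerical notes:

* The bilinear map fixes s = 0 <-> z = 1, so DC gain is preserved exactly
  in exact arithmetic.  In floating point the check (sum b)/(1 - sum a)
  cancels almost completely for poles slow relative to Ts; `dc_gain`
  therefore uses exactly-rounded summation.  For the physically relevant
  parameter class (one slow pole, fast remaining stages) the identity holds
  to 1e-12 relative; hypothetical order-3 models with three poles of
  several hundred minutes each amplify coefficient round-off to ~1e-10 and
  are outside the class used here.
* A sampling period Ts >= 2 min(tau_p) triggers a warning (frequency
  warping); fits remain defined.
* A constant biomass input carries no dynamic information and raises an
  identifiability error.  Rank-deficient but perfectly fitting regressions
  (an overparameterized order) return the minimum-norm coefficients.
* Identified tau_z may come out slightly negative when the true zero is
  near the origin; it is reported as computed rather than clamped, so
  `TransferModelParams` accepts any finite tau_z while integral constants
  must be positive.
* Coincident poles are allowed; the closed-form step response switches to
  the repeated-root formula, and the discretize/invert round trip loses
  about half its digits there (root extraction at a double root is
  square-root sensitive), which the tests acknowledge.

## Synthetic plates

No raw plate data accompany the study conditions, so
`fapsense.generator` produces plates with the structure the analyses
assume.  Per well: a lagged logistic growth curve (X0 = 0.05, Xmax = 1.2,
mu = 0.01/min, 60 min lag — a typical minimal-medium run reaching
stationary phase within 48 h), the mechanistic cascade driven by its
analytic dX/dt, and multiplicative Gaussian noise (sigma = 0.02, a typical
plate-reader CV) clipped at zero.  Readings are every 12 min, 240 samples.

Induction enters through saturating Hill maps (the dose-to-rate law is not
part of the measured model, so a monotone saturating form is the natural
choice): IPTG -> vm with Kh = 0.3 mM, basal 5% of the 1 mM level; arabinose
-> FapR pool with 1 uM at the working 0.01%.  Construct kinetics derive
from the reference order-2 table: gamma_m = 1/tau_1, gamma_r = 1/tau_2,
fast binding kr = 1/min at Kd = 2.4 uM, and vm scaled so the cascade's
steady-state gain matches the construct's reference K.  Only vm varies with
dose; time constants are construct properties — this is the generator truth
behind the gain-correlates/time-constants-don't analyses.

What the generator does not emulate: burden-relieving mutational sweeps,
plasmid copy-number drift, growth arrest of toxic constructs, medium
background fluorescence, or the stationary-phase derepression surge.  The
optional FapR-depletion scenario steps the repressor pool down at a set OD;
within this cascade (reporter production proportional to the complex, no
basal transcription term) that *lowers* the late signal, so the scenario is
a mechanism switch for robustness studies, not a reproduction of the
surge's sign.  Passing tests on these plates therefore validate the
identification and statistics machinery under the stated noise model, not
robustness to every artifact of real cultures.

## Response analyses

Wells are compared at the fluorescence interpolated at the first upward
crossing of OD 0.6 (log phase, before arabinose catabolism perturbs FapR);
later crossings are ignored and wells that never cross are flagged rather
than dropped.  RFP/OD normalization masks samples below an OD floor (0.05)
instead of dividing by near-zero densities.  Dose-response curves report
per-concentration mean, sample SD and n.  Parameter-induction structure
uses Pearson correlation against log10(IPTG) (doses span three decades);
the time-constant clustering summary compares mean within-construct scatter
with mean pairwise centroid separation in log-tau space.  Substrate effects
use Welch's unequal-variance t-test at alpha = 0.05 per comparison, with no
multiple-testing correction across constructs or doses (each comparison is
reported individually, as the per-comparison significance marks it
summarizes); the effect direction distinguishes substrate boosts from
hindrances.  Reproducibility is the coefficient of variation with the
sample (n-1) SD, appropriate at small replicate counts.

Welch's test is itself conservative at triplicate scale (true type-I error
near 0.035 at n = 3); its calibration is therefore assessed at the
six-culture replication level used for run-level reproducibility, where the
rejection rate is within Monte-Carlo tolerance of the nominal 0.05.

## Problem sizes

The analysis drivers and tests run one 96-well plate (240 time points),
order-2 fits on all wells, 1000-simulation null calibrations, and
round-trip benchmarks on five parameter sets — sizes chosen so the full
chain reruns from scratch in well under a minute on one core while keeping
every statistical check at its stated scale.
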