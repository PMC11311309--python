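# Methods

This note records the modelling choices, conventions and limitations of
`freshshelf`, in the spirit of a statistical package's model documentation.

## Growth models and numerics

All counts are base-10 logarithms of CFU per gram; natural logarithms
appear only inside the model algebra where the equations themselves use
them.  The four primary models share the parameter vector
(N0, Nmax, mu_max, lag) with invariants Nmax > N0, mu_max > 0, lag ≥ 0.
`h0 = lag · mu_max` is a derived property (the Baranyi physiological
state), not a free parameter.

The Baranyi and Huang right-hand sides contain `exp(Nmax)`-type terms that
overflow for ordinary log counts if coded literally.  Both are evaluated
in shifted log-sum-exp form; the grouping is chosen so that the analytic
identities A(0) = 0 and B(0) = 0 make N(0) = N0 hold *exactly* in floating
point (the Huang recombination is written `n0 + (nmax − log_term)` because
`log_term == nmax` exactly at t = 0).  The evaluation contract is finite
output for t up to 10³ d; negative times are rejected rather than
extrapolated.

Inversion (time to a count limit) uses the closed forms for
Gompertz/Logistic and Brent root-finding (xtol 1e-12) for Baranyi/Huang on
a bracket doubled from 10 d; all four curves are non-decreasing so the
root is unique.  Limits at or below N(0) raise "already exceeded", limits
at or above Nmax raise "never reached" (the bracket gives up at 10⁶ d).

## Quality kinetics and the sign convention

Zero order is `A0 + k·t`, first order `A0·e^{k·t}`, with a single signed
rate: k < 0 encodes decline.  Published rate tables in this field often
print signed slopes while writing the equations with a leading minus sign
(`A0 − kt`); `k_from_literal`/`k_to_literal` negate between the two
conventions.  A0 is always a fitted parameter.  Both orders invert in
closed form; a first-order decay never reaches a non-positive limit and
says so explicitly.

## Fitting

Growth fits run bounded nonlinear least squares (`scipy` trust-region
reflective) from a deterministic three-point start grid: N0 = min count,
Nmax = max count, mu_max = the steepest pairwise secant slope (clipped to
[0.01, 10]), and lag ∈ {0, ¼, ½} of the observation window.  Bounds:
N0 ∈ [0, min+1], Nmax ∈ [max−1, max+3], mu_max ∈ (0, 10], lag ∈ [0, t_max].
The best of the three starts is reported; failure of every start raises,
and a fit that never signalled optimizer success is flagged
`converged=False` with the best-so-far estimate returned.

Fits use per-day replicate means (n = 6 on the default design).  With
p = 4 parameters this is the only convention under which the
degrees-of-freedom RMSE `sqrt(RSS/(n−p))` reproduces published growth-fit
tables for this trial design to 3 decimals on several rows and ±0.002 on
all of them, which is why "dof" is the default (a per-observation
`sqrt(RSS/n)` is selectable).  R² uses the centred total sum of squares
and is undefined (raises) for constant observations.  Model ranking is
descending R², ties broken by ascending RMSE then ascending parameter
count, stable on full ties.

Zero-order fits are exact linear least squares; first-order fits start
from the log-linear estimate and refine on the original scale so the
reported RSS is the minimised one.

## Indicator selection

Candidates are correlated against the bacterial count on per-day means.
The default pairing is **within-treatment**: one Pearson r per arm,
summarised by the plain mean across arms.  The pooled all-pairs
alternative is available but not the default, for a structural reason
worth recording: an effective antimicrobial treatment separates the TBC
curves between arms by two or more log units at day 0 while quality
attributes start nearly identical, so pooled correlations are dominated by
that between-arm offset and stay below ~0.87 even for attributes that
track growth perfectly within every arm.  The within-treatment summary
measures the thing the screen is actually asking — does this attribute
move with microbial growth over storage time — and cleanly separates the
constructed trackers (mean |r| ≈ 0.92–0.94) from near-misses such as
lightness (≈ 0.89).  Plain averaging (not Fisher-z) is used; z-averaging
up-weights near-perfect arms and blurs exactly that separation.

The sensory score is excluded from the default candidate set: it is the
acceptability response the indicators are meant to replace.  The
significance flag (t test on r, alpha 0.05) is reported for information;
selection uses |r| > threshold alone, and raising the threshold can only
shrink the selected set.

## Shelf-life determination

Sensory shelf life defaults to the **discrete** convention — the last
sampling day with mean score ≥ 3 — matching how such panels are usually
read; linear interpolation of the crossing is opt-in.  Scores entirely
above the limit yield a right-censored estimate at the last day; entirely
below, an "exceeded at t = 0" estimate.

Quality cut-offs with no external standard are data-derived: the
attribute's mean value at the treatment's sensory shelf-life day
(interpolated if that day was not sampled), with direction inferred from
the trajectory (first vs last mean).  The safety limit defaults to
5 log10 CFU/g, overridable.  Overall shelf life per treatment is the
minimum across bases: the product is unacceptable as soon as any limit is
crossed.  Inversion failures become explicit statuses, never numbers.

## Synthetic trial generator

The generator emulates a 10-day trial at 4 °C / 90 % RH: arms CK (control),
NaClO (hypochlorite wash) and PDT (curcumin photodynamic treatment), days
0–10 in steps of 2, three replicates, Gaussian homoscedastic noise per
attribute, counts clamped at 0 and sensory scores to [1, 5].

Truth curves: TBC is modified-Gompertz per arm with published fitted
parameters for this design; weight loss, firmness and b\* are zero-order;
ascorbic acid is first-order; total phenolics (TPC) and DPPH are
piecewise-linear rise-then-fall curves; L\* and a\* interpolate tabulated
colour means; sensory declines linearly, crossing score 3 after day 6
(CK, NaClO) and day 8 (PDT).

Where initial values were never published they are **synthetic**
back-derivations, chosen once: firmness starts at a shared 600 N (the
published per-arm percentage declines are mutually inconsistent with the
published slopes, so a common initial value is the physically sensible
repair); ascorbic A0 is set so the curves hit the published day-10 values
(130.0/140.3/149.9 mg/kg); weight-loss slopes reproduce the published
day-10 endpoints (4.1/2.6/1.5 %).  TPC peaks at day 1 — *between* sampling
days — then declines convexly (steep to day 6, flat tail).  This shape is
deliberate: a visible peak at a sampling day caps the within-arm
correlation with a monotone TBC below the 0.9 screen, whereas real trials
of this kind report TPC both as rise-then-fall and as a selected
indicator; placing the brief wound-response peak between samples
reconciles the two.  DPPH keeps a pronounced mid-storage hump and is
therefore constructed *not* to pass the screen.  Neither TPC nor DPPH is
given a kinetic fit target.

What a green test on this generator does establish: the estimation,
selection and inversion machinery is self-consistent (noise-free data
return the configured truths exactly, and the constructed trackers are
exactly the selected set).  What it does not establish: anything about
real produce — the generator has no replicate covariance, no
heteroscedasticity, no measurement floor/ceiling except the explicit
clamps, and its non-kinetic curves are idealised polylines.

## Known limitations

- No confidence intervals on fitted parameters or predicted shelf lives
  (a bootstrap would sit naturally on the Results objects).
- No secondary (temperature-dependent) modelling; all kinetics assume the
  trial's fixed storage conditions.
- Published shelf-life columns for this trial design are not reproducible
  from their own printed growth parameters under any of the four model
  equations (the control arm inverts to ≈0.7 d where 1.5 d is printed);
  the package reports its own analytically consistent inversions and
  verifies them by round-trip instead.
- At realistic noise levels the |r| > 0.9 screen is knife-edge for
  attributes constructed near the threshold (b\*, L\*): selected sets vary
  across seeds.  That is a property of the screen, not a bug.
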