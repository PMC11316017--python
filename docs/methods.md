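# Methods

## The measurement model

The package analyses priming/challenge radio-adaptation studies of the
classic design: animals receive a small acute "priming" equivalent dose
D_p (5 or 10 mSv thermal neutrons), a 14-day interval, a 50 mSv
"challenge" dose D_c, and a fixed readout delay; parallel groups receive
each single dose alone. All doses are equivalent doses in mSv; the
interval and readout delay are held fixed by design and are carried as
metadata, never as model covariates.

For each biomarker the acute single-dose groups (0, 5, 10, 50 mSv)
define a calibration curve g(dose) fitted to the four group means. A
primed+challenged group's mean reading N_{p+c} is mapped back through g
to the RAR equivalent dose D_RAR = g⁻¹(N_{p+c}): the single acute dose
producing the same biological change. Adaptation is quantified by

    f_RAR = 1 − (D_RAR − D_p) / D_{p+c},    D_{p+c} = D_p + D_c,

and by the priming-dose difference δ = 1 − N_{p+c}/N_c against the
challenge-only group. Both are computed unclamped; f_RAR carries an
`in_unit_interval` flag instead of being forced into [0, 1], because
values outside the nominal range are diagnostic of data problems (or,
at f_RAR slightly above 1, of readings below the priming-dose response)
and clamping would destroy invertibility. Note an asymmetry inherited
from the defining formula: a completely unadapted animal
(D_RAR = D_{p+c}) yields f_RAR = D_p/D_{p+c}, not 0; the formula is
implemented verbatim rather than re-anchored.

The accumulated dose is the arithmetic sum D_p + D_c (55 and 60 mSv for
the two conditions). This is the only reading of the published factor
table under which its dose and factor columns are mutually consistent,
verified cell by cell in the built-in cross-check.

## Calibration families and diagnostics

Three families cover the panel: linear (SOD, EPR, DNA%, Hb, RDWs),
exponential approach to an asymptote (GSH, CAT, TM, OTM, also CA% and
MCV), and quadratic (MDA, TL). The family per marker is configuration,
not data-driven model selection — with four design points, information
criteria would be noise.

* Linear and quadratic fits are ordinary (optionally weighted) least
  squares via the normal equations (numpy lstsq on a Vandermonde basis),
  with standard errors from the residual-variance-scaled inverse Gram
  matrix when residual degrees of freedom exist.
* Exponential fits y = A·e^(R₀x) + y₀ use Levenberg–Marquardt
  (scipy.optimize.least_squares) from a deterministic, derivative-free
  start: y₀ is seeded at the response nearest the asymptote nudged 1% of
  the response range outward (keeping log arguments one-signed),
  A from the zero-dose response, R₀ from the slope of log|y − y₀| vs
  dose. Convergence tolerance is 1e-12 on relative cost (tighter than
  the 1e-10 contract), capped at 2000 function evaluations;
  non-convergence raises with the last iterate attached.
* Diagnostics follow small-n dosimetry convention: linear fits report
  the signed Pearson r between dose and response and its two-sided
  p-value from t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom;
  nonlinear fits report the non-negative correlation between observed
  and fitted responses plus a categorical convergence status (no
  correlation p is meaningful for 3 constants on 4 points). This mixed
  convention reproduces the sign pattern of the reference study's
  R-value columns (negative for decreasing linear fits, positive for
  decreasing exponentials). Two published goodness entries (Hb, DNA%)
  do not match the two-sided recomputation and are treated as errata;
  they are not asserted anywhere.

## Inversion

Each family inverts in closed form. The exponential inverse is defined
only while (reading − y₀)/A > 0; readings at or beyond the asymptote
raise. Quadratics invert on the **data-bearing branch**: the side of the
vertex containing the domain's lower edge. Both fitted quadratics (MDA,
TL) have vertices just inside the 0–50 mSv span (≈39.6 and ≈49.6 mSv),
so they are flagged non-monotone and inversion is restricted to the
rising branch; the mirror root across the vertex is reported as rejected
in the result's branch note. Roots are the standard quadratic formula
with a small negative-discriminant tolerance for readings grazing the
vertex. Extrapolation beyond the fitted span is permitted to 2× the
upper dose bound with `in_domain=False` (the reference data never needed
more than 0.82×); beyond the cap the inversion refuses. Negative doses
are returned unclamped with a `negative-dose` note.

The inversion input is the combined group's **mean** reading; per-animal
inversion (a dose distribution) is possible through the same functions
but is not the default, since the study design reports one equivalent
dose per marker. No uncertainty is propagated onto D_RAR; bootstrap
propagation over animals is the documented extension point.

## Pipeline

`run_study` composes: per-cell mean/SD/n summaries (sample SD, n−1) →
calibration on acute groups only (combined and challenge-only groups
never enter fits) → per marker × condition inversion, factor and δ →
aggregate table with per-condition mean and n−1 SD over markers →
two-sided Welch t-tests of every exposed group against the sham control
at the p ≤ 0.05 working threshold (Welch chosen as the robust default
for n = 5 comparisons; no multiple-testing correction is applied, a
deliberate fidelity-over-rigor limitation). Markers with no configured
family (HCT, MCHC, whose dose response merely fluctuates) flow through
summaries and testing but get no RAR row. On noisy data a cell whose
reading falls outside its curve's invertible range is dropped with an
annotation rather than aborting the run; the per-cell API still raises.

Rounding happens once, at the reporting layer: half-away-from-zero on
the value's shortest decimal representation (doses at 1 decimal, factors
at 2). This makes decimal-tie inputs — e.g. a factor of exactly 0.485
arising from 1-decimal dose inputs — round the way a hand calculation
would, instead of inheriting the binary double's side of the tie.

## Synthetic studies and what they do(n't) show

The generator emulates the seven-group design: 11 markers × 5 animals
per group. Per-animal readings are Normal(g(dose), CV·g(dose)) truncated
at zero — constant coefficient of variation is the simplest noise model
consistent with error bars that scale with the mean, default CV 0.05
(real per-marker CVs are not recoverable from published figures, so this
is a configuration, not a claim). Combined groups are centred on
g(D_eff) with D_eff = D_p + (1 − f*)·D_{p+c}, encoding a chosen true
adaptation factor f*; default f* values are the reference study's
published factors so a default simulation resembles it. The challenge-
only group is centred on g(D_c) with the same CV.

Because adaptation is encoded purely as an effective-dose shift through
the factor formula's own algebra, noiseless recovery of f* is an exact
identity test of calibration + inversion + arithmetic (verified to
≤1e-6), not evidence about biology; the generator contains no repair
kinetics, no interval or readout-time dependence, no inter-animal
heterogeneity beyond the CV, and no marker covariance. Passing recovery
tests therefore validates the estimator chain, and nothing more, about
real data. A quadratic marker whose configured effective dose falls past
its vertex is refused at generation time (the factor would be
unrecoverable on the data-bearing branch).

Problem sizes used in the test suite: noiseless identities on the full
11-marker study; stochastic recovery as a 500-replicate single-marker
(GSH) study at CV 0.05, n = 5, whose median recovered factor was
pre-verified unbiased (0.9099 vs truth 0.91); standard-error calibration
as 200 noisy 4-point exponential fits, where the joint ±3 SE coverage is
only ≈75% because the error estimate has a single degree of freedom — the
test asserts coverage ≥60% rather than a single-seed hit. The type-I
error of the Welch test is checked at 2000 null replicates (±0.02).

## Known limitations

* Four calibration points per curve: constants of the 3-parameter
  exponentials are weakly identified, and their standard errors (1 dof)
  are themselves noisy; shallow curves (CAT) invert erratically at 5%
  noise. This mirrors the design being modelled, not a numerical defect.
* One published factor cell (EPR at 5+50) is internally inconsistent
  with the defining formula; it is flagged everywhere it appears and the
  affected published row aggregate is reported alongside the recomputed
  one, never corrected.
* No dose-rate, interval, or readout-time modelling; no per-animal
  inversion by default; no RARED uncertainty intervals.
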