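# Methods

## Scope and data model

`aqdyn` analyzes four linked measurements from mouse cohorts in an
IOP-lowering cell-therapy design: per-eye rebound tonometry (8 readings),
ex vivo pressure-step perfusion traces, section-level TM cellularity counts,
and annotator-level BMM contact lengths.  Ten cohorts are modelled: naive
wild-type (WT), transgenic (Tg), and sham / hAMSC / iPSC-TM arms at short
(~1 month), mid (3–4 months) and long (9 months) time points.  All stages
accept the same delimited-text schemas the synthetic generator writes, so
real data in those shapes can be substituted directly.

## Facility estimation

* **Per-step facility** is `C = Q_ss / P_ss` with zero downstream pressure
  (enucleated eye in a bath).  Steady-state windows are found by sliding
  linear regression of inflow vs. time: window 60 s, minimum dwell 30 s,
  threshold 3 nl/min/min (protocol constants; window and dwell are knobs the
  protocol does not pin down and are configurable).  The slope estimate is
  attributed to the window's **center** time.  For an exponential transient
  with time constant tau this attribution carries a bias of roughly
  `w^2/(36 tau)` seconds (~1.5 s at w = 60 s, tau = 60 s); it is irrelevant
  for steady-mean estimation, and exact-crossing checks use a 10 s window
  where the bias is ~0.05 s.  Steps that never settle are dropped; an eye
  needs at least 3 settled steps or it is excluded as a failed perfusion.
* **Power-law fit.**  `ln C = ln Cr + beta (ln P - ln Pr)` by unweighted
  least squares (log space linearizes the model and matches the log-normal
  error structure); inverse-variance weighting from the per-step CIs is
  available but off by default, since whether the original analysis weighted
  steps is unstated.  CIs on `Cr` are formed on the log scale and
  exponentiated.

## Goldmann cross-validation

`Q` is calibrated from the reference cohort as
`Q = C_ref((IOP_ref - Pe)/Pr)^beta (IOP_ref - Pe)` with `Pe = 7 mmHg`,
`Pr = 8 mmHg`, and treated as identical across cohorts.  The pressure drop
driving facility is `IOP - Pe`, which makes the expected IOP an implicit
equation solved by `brentq` on `[Pe + 1e-9, 100]` mmHg (the left side is
monotone for `beta > -1`; `beta <= -1` raises).  Closed forms exist at
`beta = 0` and `beta = 1` and agree with the solver to 1e-9 mmHg.

Two exponent modes are provided and always recorded: `beta = 0`
(constant-facility arithmetic, reproducible from summary tables alone) and
the cohort-mean fitted beta.  The residual sign convention is
**experimental minus expected** (the convention of the study's Bland-Altman
panel; its methods prose orders the difference the other way, an ambiguity
we resolve in favor of the figure).  Expected-IOP CIs use the delta method on the
implicit solution — partials `dIOP/dlnCr = -dp/(1+beta)`,
`dIOP/dbeta = -dp ln(dp/Pr)/(1+beta)`, `dIOP/dQ = dp/((1+beta)Q)` — with an
optional Monte-Carlo resampling check that flags >10% first-order error.
Whether the original propagation included beta uncertainty is unstated; the
beta term is included whenever a beta SE is available and is zero otherwise.

An important structural fact, used by the closure tests: a shift applied
uniformly to *all* measured IOPs (including the reference cohort) largely
cancels out of the residuals, because the calibrated `Q` absorbs it; only
shifts that differ from the reference cohort's produce residuals.  The
reference cohort's own residual is identically zero by construction.

## Morphometry

Cellularity is `nuclei / IW length` per section; the BMM index is
`sum(contact segments) / total IW length`, validated to lie in [0, 1].
Mixed models are fit by REML through `statsmodels` MixedLM with variance
components under a single trivial grouping, which accommodates the crossed
annotator effect alongside nested eye and section-within-eye intercepts.
Identifiability rules: section-within-eye enters only when sections are
observed more than once (two annotators); with one observation per section
(cellularity) the section level is the residual; a cohort with a single eye
raises (eye effect confounded with the cohort effect).  Negative component
estimates cannot occur (the optimizer is bounded); exactly identical
annotations pin the annotator component at zero and it is reported as such.
The annotator test is a REML likelihood-ratio test between models with and
without the annotator component, with the boundary-corrected
`0.5 chi2(0) + 0.5 chi2(1)` reference (p = 1 at a zero statistic).
Contrast inference is Wald (normal); with ~8 eyes per cohort its 95% CIs
achieve ≥90% empirical coverage in the test-suite simulations — the small
undercoverage is the usual z-vs-t effect at these sizes.

## Cohort statistics

Shapiro-Wilk per cohort (facility after log transform).  One-way ANOVA with
planned post hoc contrasts sharing the pooled within-group variance
(df = N − k), the canonical construction for "post hoc comparisons after
ANOVA"; the 20 pre-specified pairs are shipped as a replaceable data file
and Bonferroni-corrected to a critical p of 0.05/20 = 0.0025.  The
Bonferroni family is the 20 comparisons for one outcome variable, mirroring
the published correction.  Treatment effects against injection controls use
Welch t (unequal variances): mean differences for IOP and cellularity, and
log-scale differences back-transformed to fold-ratios for facility.  The
cellularity–IOP correlation pools one (mean section density, IOP) pair per
eye.

## The synthetic world

The generator's defaults are calibrated to the published cohort summary
table: facility geometric means per cohort; eye-level SDs back-calculated
from the printed 95% CI half-widths at the study's ~10 eyes per cohort (the
per-panel n's are not in the running text; 10 per cohort tracks the 114
perfused eyes); a shared `facility_log_sd = 0.3` (the cross-cohort average
of the CI-implied values, as the configuration carries a single value);
`beta ~ N(0.3, 0)` — the study never reports beta, and 0.3 keeps facility
positive and realistic over 4.5–16.5 mmHg; tonometer SD 1 mmHg; flow noise
0.5 nl/min; exponential flow transients with tau = 60 s; perfusion failure
probability 9/114.

True IOP is **derived** from true facility through the Goldmann balance
(shared Q calibrated from the WT row), then shifted by a per-cohort offset
chosen so the simulated cohort means reproduce the printed IOPs exactly.
Consequences worth knowing:

* within a cohort, IOP variation is driven by facility variation (SD about
  `dp * facility_log_sd / (1+beta)`), which is somewhat larger than the
  printed IOP CIs imply — the pooled cellularity–IOP correlation through the
  full pipeline is therefore attenuated (about −0.3 to −0.45 at realistic
  sizes) relative to a direct pair simulation at printed CI widths (about
  −0.4 to −0.55) and to the study's real-data value of −0.63;
* with all noise and offsets zeroed and tau = 0, the full pipeline closes
  exactly: Q is recovered to <0.1% and every cohort's expected-IOP residual
  is below 1e-6 mmHg.  With tau > 0 the steady-window mean retains an
  O(tau/T_step) transient tail (the window extends to the end of the step by
  definition), so exact closure checks state tau = 0;
* the default annotator SD (0.02) is a deliberately nonzero measurement
  effect; at cohort scale the LRT detects it decisively, unlike the study's
  reported p ≈ 1 — set `annotator_sd = 0` to emulate that finding (the two
  annotators then agree exactly);
* randomness uses one master seed with per-eye substreams keyed by a SHA-256
  hash of the eye id, so enlarging a cohort never changes existing eyes.

What the generator does **not** emulate: images (counts and lengths are
generated directly), tumor incidence, diurnal/anesthesia IOP physiology,
perfusion hardware artifacts beyond a usable flag, and any real-data
idiosyncrasy beyond the published summary table.  A green pipeline test
therefore establishes internal consistency and parameter recovery under the
stated world, not agreement with unpublished per-eye data; in particular the
published per-eye regression (slope 0.94, R² 0.99) and mean residual
(1.2 [1.1, 1.3] mmHg) depend on unpublished per-eye values and are replaced
by the closure properties above.

## Numerical conventions

Root finding tolerance 1e-6 mmHg (1e-9 internally for ground-truth
generation); t-based CIs with n−1 df for summaries; degenerate inputs
(zero-variance groups, zero-width windows) return degenerate intervals or
flagged NaNs rather than raising, except where the quantity is undefined
(empty cohorts, constant samples in Shapiro-Wilk, non-positive facility).
Synthetic nuclei counts are integers; the recorded inner-wall length is
adjusted so count/length reproduces the drawn density exactly, keeping
zero-noise worlds exactly closed.
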