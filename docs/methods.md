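# Methods

## Quantal dose–response model

The unit of observation is a dose group: `n_subjects` animals receive the
same total dose `d` (mg/kg) of a drug or of a fixed-ratio mixture treated
as a single agent, and `n_responders` of them show the all-or-none
protective effect.  The model is binomial with a probit-linear response on
log dose,

    n_responders ~ Binomial(n_subjects, Φ(β₀ + β₁·log₁₀ d)),

and results are reported in the classical probit convention
`probit = 5 + Φ⁻¹(p)`, in which 50% response sits at 5 probits and the
16–84% band spans 4–6 probits.  The ED₅₀ is the dose at 5 probits,
`log₁₀ ED₅₀ = −β₀/β₁`.

**Estimation.** Maximum likelihood via iteratively reweighted least squares
(statsmodels GLM, binomial family, probit link), with the analytic
parameter covariance from the Fisher information.  Groups at 0% or 100%
response enter the likelihood directly; no correction is needed or applied.
A legacy `working-probit` mode implements the classical iterative weighted
regression on working probits with the 1/(4n) correction for extreme
groups, for comparison with historical hand calculations only — it is not
the default and not used anywhere in the pipeline.

**Identifiability.** A fit requires at least two distinct dose levels and at
least one group with a partial (0 < k < n) response; otherwise the ML slope
diverges and the fit is refused (`NonIdentifiableError`).  All-0% or
all-100% datasets, and datasets whose response decreases with dose (fitted
slope ≤ 0), are likewise refused rather than silently fitted.

**Standard errors.** `SE(log₁₀ ED₅₀)` comes from the delta method on
g(β) = −β₀/β₁ with the fit covariance; the mg/kg-scale SEM is the second
delta step `SEM = ED₅₀ · ln 10 · SE(log₁₀ ED₅₀)`.  Both transformations are
exact identities in the code and are tested to 1e-12 relative.

**Informative animals.** The n attached to an ED₅₀ counts animals from dose
groups whose effect lies in the closed 4–6 probit band.  Whether the band
membership is judged by the *fitted* line at the tested doses or by the
*observed* proportions is a genuinely open convention; the default is
`fitted` (stable under 0/8 and 8/8 outcomes, which have infinite observed
probits), with `observed` available as a policy switch.

**Parallelism.** Fixed-ratio additivity presumes the single-drug lines are
parallel, so `test_parallelism` is provided: a two-sided Welch test of
slope equality with Satterthwaite df built from per-fit df = n_total − 2.

## Fixed-ratio Loewe additivity

A mixture in fixed ratio assigns drug i the fraction fᵢ of its own ED₅₀
(1:1:1 = equal thirds in ED₅₀-fraction units, *not* equal mg/kg — at any
total dose the composition is `doseᵢ = total · fᵢ·ED₅₀ᵢ / Σⱼ fⱼ·ED₅₀ⱼ`).
Under dose-equivalence (Loewe) additivity the mixture's expected median
effective total dose is

    ED₅₀,add = Σᵢ fᵢ · ED₅₀,ᵢ ,   SEM_add = √(Σᵢ fᵢ² · SEMᵢ²),

the variance propagated assuming independence, which holds by design when
each component ED₅₀ comes from a separate animal cohort.  The animal count
`n_add` attached to the prediction defaults to the sum of the components'
informative counts; published tables whose n_add derivation cannot be
reconstructed (single-drug appendix data unavailable) can supply it
verbatim via the `supplied` policy, and the bundled re-analysis does so.

Curved additive isoboles for non-parallel lines are out of scope: the
intended workflow checks parallelism first.

## Interaction test, classification, index

Experimental and additive ED₅₀s are compared with the unpaired t test in
the Welch form computed directly from the standard errors of the two
*estimates*:

    t  = |ED₅₀,add − ED₅₀,exp| / √(SEM²_exp + SEM²_add)
    df = (SEM²_exp + SEM²_add)² / (SEM⁴_exp/(n_exp−1) + SEM⁴_add/(n_add−1))

with a two-sided p from the t distribution at that non-integer df.  This
form is what reproduces published non-integer dfs in this literature; a
pooled-variance variant (integer df) is provided for sensitivity analysis
but is not the default.  Classification: Synergy if p < α and
ED₅₀,exp < ED₅₀,add; Antagonism if p < α and ED₅₀,exp > ED₅₀,add;
Additivity otherwise.  α defaults to 0.05.  No multiplicity correction is
applied across combinations by default, matching field practice for these
six-way screens.

The interaction index `ED₅₀,exp / ED₅₀,add` is kept at full precision
internally and reported at 2 decimals; t is reported at 3 decimals, df at
2, p at 3 significant figures.

## Synthetic experiments

The generator emulates the design of the motivating screen: groups of 8
animals (default), a 5-dose geometric ladder whose ends sit at the true
10% and 90% response doses (so mid-curve doses exist for the
informative-animal rule), binomial protection counts from the probit curve.
A mixture is simulated as a single probit agent with true
`ED₅₀ = index_true × Σ fᵢ·ED₅₀ᵢ,true` and slope equal to the
fraction-weighted mean of the component slopes — with parallel component
lines (the design precondition) any reasonable pooling coincides.
`index_true = 1` makes the mixture exactly Loewe-additive.

Randomness: numpy `default_rng`, one child stream per dataset derived from
the scenario seed plus a CRC32 of the dataset label, so datasets are
mutually independent and byte-identical across runs for a fixed seed.

The canonical validation scenario uses three drugs with parallel slopes of
3 probits per log₁₀ dose and ED₅₀s of 8, 25 and 60 mg/kg — potencies and
steepness representative of anticonvulsants in this assay.  Study sizes
used by the validation suite and the acceptance script: 200 replicates per
recovery scenario (ED₅₀ ∈ {5, 20, 80} × slope ∈ {2, 4}), 1,000 replicates
for type-I calibration, 10⁶ draws for the Monte-Carlo propagation check.

What the generator does **not** emulate: pharmacokinetics (absorption,
brain levels, pretreatment-time effects), inter-litter or inter-day
variability, observer error, or any departure from the probit-linear form.
Passing simulation checks therefore validates the *statistical* chain under
its own assumptions, not the biological model.

## Numerical and design notes

- IRLS runs to tolerance 1e-12 (≤200 iterations); the acceptance suite
  checks the attained log-likelihood against a brute-force grid-refinement
  oracle to 1e-6.
- Boundary fitted probabilities at extreme doses routinely trigger
  separation warnings inside the GLM machinery; they are suppressed because
  identifiability is checked explicitly beforehand.
- Quasi-separated datasets (partial response present but the slope weakly
  determined) yield finite estimates with large standard errors.  In
  replicate studies these replicates deflate the t statistic, which makes
  the dose-scale comparison mildly conservative at small group sizes — the
  type-I rate the acceptance script measures typically lands a little below
  the nominal 5%.  This conservatism is intrinsic to comparing dose-scale
  estimates whose SEMs co-vary with the estimates themselves.
- Kruskal–Wallis with every observation identical (the all-at-ceiling
  rotarod case) returns H = 0, p = 1 with a warning instead of failing on
  the undefined tie correction.  One-way ANOVA with zero pooled
  within-group variance is refused as degenerate.
- Rotarod times are validated against the [0, 120] s ceiling and the
  ceiling ties are handled by mid-ranks; no survival-style censoring model
  is attempted, matching how these data are analysed in practice.
- SVG output is byte-deterministic (fixed hash salt, no timestamps); report
  CSV/JSON keep full float precision (`repr` round-trip) while the
  human-readable table applies the reporting precision above.
- CSV I/O is strict comma/point/UTF-8 with a mandatory header;
  locale-flexible parsing is deliberately not offered, for
  reproducibility.  Metadata columns (pretreatment time, route, vehicle)
  pass through untouched and never affect computation.

## Limitations

- Dose-equivalence additivity with straight-line (parallel) probit fits is
  the only supported interaction model; Bliss independence and
  median-effect (Chou–Talalay) analyses are out of scope.
- The comparison test is frequentist and analytic; no bootstrap or Bayesian
  alternatives.
- Summary-level re-analysis inherits the printed rounding of its inputs;
  with published ED₅₀ ± SEM rows the package reproduces printed statistics
  exactly, but cannot reconstruct unpublished raw counts or the exact
  historical n_add derivations.
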