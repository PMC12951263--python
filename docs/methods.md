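# Methods

This note records the statistical model behind `tetradscreen`, the
assumptions and defaults it ships with, and the design choices made
where the problem was genuinely open.

## Dating and centile model

Gestational age (GA) is counted in completed days from the notional last
menstrual period. Three anchors are supported: the LMP itself
(`GA = scan − lmp`), a known conception date (`GA = scan − conception +
14`), and an embryo transfer (`GA = scan − transfer + 14 +
transfer_day`, the standard ART convention with `transfer_day` the
embryo's age in days at transfer, typically 3 or 5). "≤ 10 weeks" is
interpreted inclusively as GA ≤ 70 days.

Each marker's reference distribution at GA *t* is modelled as Gaussian
on a chosen measurement scale: the centile of measurement *x* is
`100·Φ(z)` with `z = (T(x) − m(t))/s(t)`, where *T* is the identity
(natural scale) or the natural log, and *m*, *s* are polynomials in *t*.
The Gaussian quantile mapping is an assumption — published growth charts
rarely state a distributional form — but every categorical analysis
downstream consumes only centiles and is therefore invariant to it as
long as the mapping is monotone.

The packaged default curves are smooth, clinically plausible
approximations, labelled as such in their `provenance` fields, not the
published chart coefficients (which are not reproducible from the
source material): lognormal GSMD growing ≈ 1 mm/day from day 30,
lognormal YSMD between ≈ 4 and 7 mm, lognormal CRL following the
Robinson-style dating relation `GA = 8.052·√CRL + 23.73`, and
natural-scale HR peaking near 170 bpm around nine weeks (SD 14 bpm).
All four are defined on GA 35–100 days. Log-scale SDs (0.30, 0.22,
0.25) correspond to coefficients of variation of roughly 20–30%, wide
enough that low centiles always map to positive measurements. Users
with access to chart coefficients supply them as JSON
(`load_curves`); the centile ↔ measurement round-trip is exact to
1e-9 by construction and enforced by tests.

## Cut-off derivation

Centiles are binned into twenty half-open 5-point bins (`[0,5)` …
`[95,100]`, the last closed). Per bin the statistic is the percentage
frequency among abnormal karyotypes divided by the percentage frequency
among normal karyotypes; the bin maximising it names the cut-off (low
bins give a "below upper edge" rule, high bins "at or above lower
edge"). Three numerical policies are ours: bins with zero normal-group
mass are excluded (the ratio is undefined and a pseudo-infinite ratio
from a single case would be unstable), ties break to the lower bin
index, and the interior-bin direction rule above generalises what in
practice only the extreme bins win. The preselected clinical cut-offs
(< 5th for GSMD, CRL, HR; ≥ 95th for YSMD) are the pipeline default;
empirical derivation is opt-in (`--derive-cutoffs`) because the
derivation subset is a study-level choice, not a property of the data
format.

Flag boundary semantics are strict for "below" (centile 5.0 is *not*
small) and inclusive for "at or above" (95.0 *is* enlarged). A record
missing a measurement codes that flag — and hence the tetrad — as 0,
with a logged warning; a strict mode raises instead. All four
measurements come from the same last live scan, so post-mortem
degeneration does not contaminate the morphology.

## 2×2 inference

Odds ratios are `ad/bc` with 0.5 added to **all four** cells whenever
any cell is zero (Haldane–Anscombe); intervals are Woolf logit,
`exp(ln OR ± z·√(Σ 1/cell))` on the corrected cells. The
asymptotic-score interval of Koopman is provided as a labelled
alternative, but note it targets the **risk ratio**: the two are not
interchangeable, and the logit interval is the default because it is
the standard companion of the corrected OR. Fisher's exact two-sided
p-value uses the probability rule (sum of hypergeometric tables no more
probable than the observed one); degenerate margins return p = 1.
McNemar's test on paired classifications uses the continuity-corrected
χ² `(|b − c| − 1)²/(b + c)` when discordant pairs ≥ 10 (inclusive) and
the exact two-sided binomial `min(1, 2·P(X ≤ min(b,c) | b+c, ½))`
below. Binomial proportions (sensitivity, specificity, PPV, NPV,
accuracy) get exact Clopper–Pearson beta-quantile intervals; a metric
with an empty denominator is reported as undefined rather than
poisoning the rest.

The r×c Fisher exact test (needed for ethnicity-style tables) is
computed by full enumeration of margin-consistent tables for grand
totals up to 200 and by seeded Monte-Carlo permutation (20 000 draws,
add-one estimator) beyond. Chi-square is the uncorrected Pearson
statistic and is used only when every expected count is ≥ 5.

## Logistic modelling

Fits are maximum likelihood via iteratively reweighted least squares:
convergence at max coefficient change < 1e-8, cap 100 iterations, and
the Bernoulli log-likelihood is tracked per iteration (it must be
non-decreasing — a property test). Entry is forced: no selection.
Wald 95% CIs are reported on the OR scale. Complete-case analysis per
model; no imputation. Complete separation — fitted probabilities
within 1e-6 of 0/1 together with a coefficient magnitude above 15 — is
flagged and the diverging terms get unbounded CIs instead of
meaningless Wald ones; this matters because the tetrad indicator can
perfectly predict the outcome in-sample. Diagnostics: Tjur's R² (mean
fitted probability among events minus non-events), Hosmer–Lemeshow over
g = 10 fitted-probability groups (ties kept together, df = groups − 2,
variance form `n·p̄(1−p̄)`; skipped with a warning under 3 distinct
fitted values), and VIF per covariate (`1/(1−R²)` against the others;
rank deficiency raises naming the collinear set). The four-way
interaction term is the product of the four 0/1 flags and equals the
tetrad indicator record-by-record.

## Synthetic cohorts

The sampled generator is the package's test bed. Per karyotype group,
each marker's centile follows a two-component mixture: probability
`extreme_prob` uniform on the extreme region beyond the cut-off, the
rest a Beta body rescaled to the remaining centile range, so the
configured extreme probability **is** the marginal flag probability.
Co-occurrence is induced by a Gaussian copula with a shared per-record
severity variable (equicorrelation ρ, default 0.5), oriented so the
same severity tail drives every marker toward its own extreme; the
source cohort reports no joint distribution, so ρ is a modelling
choice, and the implied tetrad rate is *not* calibrated to any
published count. Default parameters are the published-cohort marginals:
n = 158, abnormal fraction 112/158, extreme probabilities 5/46 vs
42/112 (GSMD), 2/46 vs 19/112 (YSMD), 11/46 vs 71/112 (CRL), 16/46 vs
61/112 (HR); maternal age and BMI are lognormals matched to the
published median/IQR per group; 78/158 of last live scans fall beyond
49 days, where the amniotic sac is assessable with group-specific
presence probabilities; BMI is missing completely at random at 40/158.
What the generator does **not** emulate: GA-dependence of the extreme
probabilities, scan-to-scan growth trajectories, measurement error in
the crude biometry, and informative missingness — so green simulation
tests certify the statistical machinery, not clinical
transportability.

The deterministic fixture is different in kind: a block allocation of
flags to 158 records that hits every published cross-tabulation
exactly (including nine tetrad cases, all abnormal, nested within all
four component flags, and none in the normal group), with the joint
cells beyond the published margins filled by a documented deterministic
scheme. Its crude measurements are synthesised from the assigned
centiles through the default curves, so the pipeline's centile
conversion recovers the intended flags exactly; the construction is
frozen in the packaged CSV and the builder/CSV identity is a test.
Inclusive-boundary yolk-sac centiles are placed at 95.2+, clear of the
95.0 boundary, so flags survive the measurement round-trip at CSV
precision.

## Problem sizes and tolerances

Exhaustive Fisher-vs-enumeration agreement is checked on all 2×2
tables with n ≤ 30 (rational-arithmetic oracle); logistic parameter
recovery on one simulated cohort of 5 000 (within 3 SE); generator
odds-ratio convergence on 50 000 records (within 10% of the configured
values); Hosmer–Lemeshow calibration on 300 replicates of n = 400;
Clopper–Pearson coverage on 2 000 seeded binomial replicates. Monte
Carlo p-values and the generator are seeded everywhere; reports are
byte-identical under fixed inputs and seed.

## Known limitations

* Default reference curves are plausible stand-ins; absolute millimetre
  values in the fixture and simulations are only as realistic as those
  curves, though every centile-level result is curve-invariant.
* The ≤ 10-weeks subgroup composition of the fixture follows the
  amniotic-sac accounting (78 records beyond 49 days) and therefore
  does not reproduce subgroup-specific estimates published elsewhere in
  the source tables, whose denominators are mutually inconsistent; the
  report carries a note instead of silently resolving the conflict.
* Koopman's interval is implemented for the risk ratio only; no mid-p
  Fisher variants, profile-likelihood CIs, Firth penalisation or
  stratified (Mantel–Haenszel) estimators.
* The empirical cut-off search considers single one-sided bins per
  marker; no two-sided or multi-bin composites, no ROC optimisation.
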