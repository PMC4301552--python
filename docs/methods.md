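# Methods

## Scope and data model

`genemeta` analyses corpora of case-control studies of a single biallelic
variant. The unit of analysis is a *study arm*: one row of genotype counts
(AA, Aa, aa; `a` the variant allele) for cases and one for controls, plus
metadata (author, year, country, ethnicity from the closed set
{Caucasian, African, Asian, Mixed}, cancer type). A publication reporting
separate ethnic strata contributes one arm per stratum. Counts are stored
per genotype and all five contrasts are derived from the same record, so
the contrasts can never drift out of sync with the source data. Ethnicity
and cancer-type labels are title-cased on load so subgrouping is robust to
capitalisation.

The variant allele is always the exposure. Counts are used exactly as
reported, with no minor-allele re-orientation: in the bundled rs1417938
corpus the variant (T) allele is the major allele in two study
populations, and flipping it would silently invert those odds ratios.

## Per-study estimation

Each contrast collapses a record to a 2×2 table (exposed/unexposed ×
case/control). The allele contrast counts each subject's two alleles as
independent observations — the standard convention for "allele" or
"additive" columns in genetic meta-analyses; its tables therefore have
twice the subject margins. The codominant contrasts drop the unused
genotype class.

The effect is the crude log odds ratio ln(ad/bc) with Woolf (delta-method)
variance 1/a+1/b+1/c+1/d and Wald interval exp(θ̂ ± z·√v); intervals are
always constructed on the log scale, hence asymmetric around the OR.
z is the standard-normal quantile of the requested level (1.959964 at
95%).

**Zero cells.** A table containing a zero cell receives the
Haldane–Anscombe correction: 0.5 added to all four cells of that table
(not the whole corpus), before effect estimation. A table whose entire
case or control margin is zero carries no information about the contrast
and is excluded with an explicit error. The increment is configurable
(`increment=` in the pipeline); 0.5 is the default used by the major
meta-analysis packages.

## Pooling and model selection

Three pooling estimators are implemented:

* **Inverse-variance fixed effect** (`pool_fixed`): θ̂ = Σwθ̂ᵢ/Σw,
  w = 1/vᵢ, se = 1/√Σw.
* **DerSimonian–Laird random effects** (`pool_random`): the moment
  estimator τ² = max(0, (Q−df)/(Σw−Σw²/Σw)) added to each study variance;
  identical to the fixed estimate whenever τ² = 0.
* **Mantel–Haenszel fixed effect** (`pool_mh`):
  θ̂ = ln[Σ(aᵢdᵢ/Nᵢ)/Σ(bᵢcᵢ/Nᵢ)] with the Robins–Breslow–Greenland
  variance. The MH point estimate tolerates zero cells without
  correction; the pipeline nevertheless pools the corrected tables so the
  pooled value and the per-study displays are computed from identical
  cells, which is also what the dominant field software (Stata `metan`,
  RevMan) does by default.

Cochran's Q is always computed in its standard form — inverse-variance
weights around the inverse-variance fixed pooled value — regardless of
which pooling method is ultimately reported; its p-value P_h (χ², k−1 df)
drives model selection: random effects iff P_h < 0.05 (`alpha_h`
configurable). I² is reported but plays no role in selection. For a
single study P_h is undefined and reported as missing (`None`, rendered
"NA").

**Choice of fixed-effect method.** The pipeline default is
Mantel–Haenszel. On sparse corpora the IV and MH estimates differ in the
second decimal (0.87 vs 0.86 on the bundled rs2808630 recessive total),
because IV weights are noisy for small corrected tables; MH is the
better-behaved sparse-data estimator and matches the output of the
standard tooling on the bundled corpus, which is why it is the default.
`fixed_method="iv"` switches the fixed branch to inverse variance; the two
agree asymptotically (tested at 10⁵ subjects per arm, |Δ log OR| < 0.01).

## Pipeline, subgroups, sensitivity

`run_meta` evaluates every contrast in every stratum of a grouping
variable (cancer type by default; strata are taken from the data in
first-appearance order, plus a "Total" stratum pooling everything). Each
cell runs collapse → continuity correction → per-study effects →
heterogeneity → model selection independently; permuting the input order
changes nothing. `leave_one_out` re-runs the full selection rule on each
k−1 subset, so the fixed/random choice may flip after an exclusion; the
qualitative stability criterion is that every leave-one-out interval
overlaps the full-corpus interval. `format_report` rounds for display at
two decimals (IEEE half-even via `format`); all numeric comparisons in the
test-suite are made on unrounded values.

## Publication bias

`funnel_data` emits (log OR, SE) points with the pooled centre line and
pseudo-95% limits θ̂ ± z·se over an SE grid. `begg_test` standardises each
effect against the inverse-variance fixed pooled value,
tᵢ = (θ̂ᵢ−θ̂_F)/√(vᵢ−1/Σw), and computes Kendall's score between tᵢ and
vᵢ; tau uses tau-b tie handling while the null variance k(k−1)(2k+5)/18 is
the untied formula (ties in continuous variances are rare; when *all*
variances tie the test is degenerate and returns τ = 0, p = 1 with a
flag). The z statistic applies a one-unit continuity correction toward
zero and the p-value is two-sided normal. k = 2 is accepted but flagged
low-power. Egger-type regressions and trim-and-fill are deliberately out
of scope.

## Synthetic corpora

The generator draws control genotypes multinomially from Hardy–Weinberg
proportions ((1−p)², 2p(1−p), p²) at variant-allele frequency p, and case
genotypes from the same proportions tilted by genotype odds ratios:
P_case(g) ∝ P_ctrl(g)·ψ_g with ψ_AA = 1. This retrospective tilting is
equivalent to a prospective logistic disease model and gives exact control
of the population odds ratio of each collapsed contrast — in particular
the recessive OR equals ψ_hom whenever ψ_het = 1.

Between-study heterogeneity with standard deviation `tau` perturbs
log ψ_hom per study (the heterozygote effect stays fixed), so with
ψ_het = 1 the per-study recessive log OR is N(ln ψ_hom, τ²) and the
DerSimonian–Laird τ̂² is directly comparable to τ². The optional selection
rule publishes a small study (cases ≤ cutoff) only when its crude OR
exceeds a threshold — the minimal mechanism that produces funnel
asymmetry for exercising the Begg test. All randomness flows from the
config's `seed` through one `numpy` generator; there is no global state.

Default validation conditions, chosen to mirror a well-powered candidate-
gene literature at desk scale: k = 20 studies, 2000 subjects per arm,
p = 0.3 (a common variant, so the homozygote class is well populated),
ψ_hom = 1.5, ψ_het = 1. Under these conditions the test-suite checks that
the mean pooled recessive log OR over 500 replicates is within three
Monte-Carlo standard errors of ln 1.5, that the Q test rejects at
0.03–0.07 under the null, and that the Begg test's type-I error lies in
0.02–0.08 (it is mildly conservative by construction). τ² recovery is
checked at k = 50, τ = 0.3. What the generator does **not** emulate:
genotyping error, departures from HWE in controls, covariate confounding,
linkage disequilibrium, or population stratification — passing tests
certify the estimators, not robustness of real corpora to those
artefacts.

## Bundled corpus and known discrepancies

The bundled *CRP* corpus (rs2808630: 5 arms, 888 cases / 3,167 controls;
rs1417938: 6 arms, 3,110 cases / 5,951 controls) is embedded verbatim and
guarded by a checksum test. Two caveats, documented rather than patched:

* In the published rs2808630 summary, the lung and colorectal subgroup
  rows are swapped relative to the study labels (each printed row matches
  the recomputed values of the *other* subgroup). `run_meta` reports
  strata by their data labels; the rs2808630 subgroup rows are therefore
  excluded from quantitative comparisons.
* Two published subgroup heterogeneity p-values differ from recomputation
  by ±0.01 at the second decimal (rs1417938 prostate recessive 0.82 vs
  0.81; lung het-codominant 0.79 vs 0.78). Recomputed values are the
  tested truth at a correspondingly looser tolerance.

## Numerical notes and limitations

Effects and weights are accumulated in double precision; corpora of
interest (k ≤ 10³) are far from any conditioning limit. τ² is truncated
at zero, as is I². The package does not implement Hartung–Knapp
adjustment, REML/Paule–Mandel τ² estimators, meta-regression,
Hardy–Weinberg testing of control arms, or exact (conditional) odds-ratio
intervals; asymptotic intervals can undercover for very sparse tables
even after continuity correction.
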