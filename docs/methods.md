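# Methods

## Model and procedure

`decigene` formalises a whole-literature screening workflow for candidate
gene loci in case-control data. The unit of analysis is one locus
(rs-number) within one ethnicity stratum; strata are analysed fully
independently because reference minor-allele frequencies, and therefore
information sizes, differ across ancestries.

**Effect model.** Inheritance is analysed under the allele model only:
each subject contributes two alleles, a study is reduced to a 2×2
minor/major × case/control table, and association is measured by the
Woolf log odds ratio with SE √(1/a+1/b+1/c+1/d). A Haldane–Anscombe 0.5
is added to all four cells only when a zero cell occurs; a study with an
entirely empty arm is unusable and rejected. The minor allele is fixed by
the design reference (e.g. 1000 Genomes) — a study whose observed control
minor-allele frequency exceeds 0.5 is flagged as a coding conflict, never
silently re-oriented, so the pooled OR direction has a single meaning
across studies.

**Pooling.** Cumulative DerSimonian–Laird random-effects pooling in look
order (publication year, ties broken by study id — the order matters
because boundary crossing is checked look by look). Alongside Q, τ² and
I², each look carries the diversity D² = 1 − v_F/v_R, the fraction of the
random-effects pooled variance attributable to heterogeneity. DL rather
than REML is used because the sequential-monitoring literature this
workflow belongs to standardised on it; the pooling entry points are pure
functions and another estimator could be swapped without touching the
sequential layer. p-values are two-sided normal-theory; no Hartung–Knapp
small-k correction is applied.

**Information size.** The fixed-sample subject requirement is the
two-proportion normal-approximation sample size on the allele scale,
comparing the reference MAF p_c against the case proportion implied by
the assumed design odds ratio (default 1.5, the typical candidate-gene
effect size), p_t = OR·p_c/(1 + p_c(OR−1)). Because each subject
contributes two alleles split across two equal arms, the per-group allele
count and the total subject count coincide, so

    n_fixed = ⌈(z₁₋α/₂ + z₁₋β)² (p_c q_c + p_t q_t) / (p_t − p_c)²⌉

with α = 0.05 two-sided and power 0.80 by default. Heterogeneity inflates
this to RIS = ⌈n_fixed/(1 − D²)⌉. D² is either fixed at 0.80 (the
conservative screening default) or estimated from the accumulated studies
(`heterogeneity_mode: estimate`); the value applied is recorded in the
design and the run manifest. The ceiling is taken with a 1e-9 slack so
that exact ratios (389/0.2) do not round up through floating point.

**Accumulated information is counted in subjects** (cases + controls),
not alleles; allele tables are internal to effect estimation. Published
per-locus accumulated-sample magnitudes match subject counting.

## Sequential boundaries

Looks are placed at every cumulative study, at information fraction
min(1, subjects/RIS). The verdict is final at the first look whose
fraction reaches 1: studies accumulated beyond the RIS are not additional
hypothesis tests (re-testing them at the final threshold would spend
type-I error with no budget left; in simulation this inflates the null
crossing rate from ≈0.04 to ≈0.11 at 20 looks).

**Monitoring.** Alpha spending follows the Lan–DeMets
O'Brien–Fleming-type shape α*(t) = 2(1 − Φ(z₁₋α/₂/√t)). The two-sided
symmetric thresholds are realised as two mirrored one-sided halves, each
spending α*(t) evaluated at budget α/2 — the construction behind the
published Lan–DeMets tables (two equal looks at two-sided 0.05 give
2.963/1.969; five give 4.877/3.357/2.680/2.290/2.031, which the
implementation reproduces to ≤2×10⁻³). Thresholds are solved by recursive
numerical integration of the non-crossing sub-density over the
independent-increment Brownian representation: the stored sub-density is
a 1001-point trapezoid grid on the continuation region, and all masses
integrate the Gaussian increment analytically (normal-CDF differences),
so quadrature error enters only through the smooth stored density.
Crossing probabilities are accurate to well below 10⁻⁴; the reported
spent-alpha balances to α at t = 1 within 10⁻⁴. When a look's incremental
spend is below 10⁻¹², its threshold is reported capped at Z = 8.

**Futility.** The inner wedge |Z| ≤ f_k spends the type-II budget β under
the alternative with Brownian drift θ = z₁₋α/₂ + z₁₋β at full
information. The beta-spending function uses the same OF-family shape
under the identical halved-budget-and-doubled construction as alpha
(2·α-shape at β/2). This matched construction makes the wedge close onto
the monitoring boundary near t = 1 (gap ≈0.04 at two looks, verified
against an exact bivariate-normal oracle); spending the full β through
the raw shape leaves a gap of ≈0.08. The wedge is computed one-sided
(non-binding with respect to the monitoring boundary) and mirrored; looks
where the computed value is not positive report it as undefined — with
the default design the wedge typically exists only from roughly 40% of
the RIS onward. Crossing at exactly a threshold counts as crossed, for
both boundaries.

**Verdicts.** Significance crossing ⇒ conclusive risk or protective by
the sign of the pooled log-OR at the crossing look (direction labels
attach to the minor allele as coded in the design; each verdict carries a
note recording that orientation). Futility entry or RIS completion
without crossing ⇒ conclusively unassociated — RIS completion alone
suffices even if the wedge was never entered, matching how screening
conclusions of "enough samples, no association" are declared in practice.
Otherwise inconclusive, reporting exactly RIS − subjects remaining. A
final pooled p below α without any boundary crossing stays inconclusive
(the note records the nominal significance); no separate category is
introduced.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes:
control genotypes Hardy–Weinberg at the control MAF; per-study log-OR
ln(OR) + N(0, τ²); case allele frequency from the odds transform of the
perturbed OR; case genotypes Hardy–Weinberg at that frequency. Defaults
mirror the screening context: assumed design OR 1.5, α 0.05, power 0.8,
fixed D² 0.8, study streams of ~10–20 articles with a few hundred
subjects per arm. One scenario seed; per-study substreams are spawned by
study index, so appending a study never reshuffles earlier ones, and
replicate seeds are spawned from the scenario seed by replicate index.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real literatures: publication bias and
time-varying effects across the stream, deviation of case genotypes from
HWE under strong ORs (second-order at these effect sizes), linkage
disequilibrium between loci, covariate or population-stratification
confounding, and misclassified or flipped allele codings beyond the flag
the reader layer raises.

Because per-study arm sizes fix the subject schedule, operating
characteristics compute one boundary set per scenario and share it across
replicates; 1,000 null replicates at 20 looks run in a few seconds. The
Monte-Carlo problem sizes used by the acceptance script (1,000 null
replicates, 300 strong-effect replicates) put the 2-SE band at about ±1.3
and ±0.1 percentage points on the respective rates.

## Numerical and design notes

- Monitoring thresholds are non-increasing across looks for
  well-separated fractions, but **not** for near-coincident looks (e.g.
  grid {0.5, 0.515625}): the Brownian-scale boundary must rise while √t
  barely grows, so the Z-scale threshold can locally rise. This is a
  property of alpha-spending designs, not an artefact.
- Higher design power lowers the futility wedge at interim looks (harder
  to declare futility) but slightly raises it at the final look, where
  closure pins it near z₁₋α/₂ for any power.
- Published per-locus "still need N more samples" figures from the
  packaged summary table are display fixtures only; they are not
  reproducible from the stated design parameters (loci with near-identical
  MAF and I² carry very different printed values), so this package's RIS
  is internally consistent and documented rather than calibrated to them.
- The published summary fixture's pooled ORs/CIs likewise cannot be
  recomputed here (the per-study extraction tables are not part of the
  package); they exercise the report, label and cross-tab layers.
- Heterogeneity is labelled high only for I² strictly greater than 50%;
  I² = 50 is low.
- Report formatting: OR and CI to 2 decimals in a single cell, p to 4
  decimals, I² as integer percent; `read_report` inverts the format, and
  write–read–write round-trips are byte-identical.

## Known limitations

Allele model only (no dominant/recessive/trend analyses); no Pocock or
power-family spending (the spending function is an internal seam where a
hook could be added); no exact conditional sequential tests; no
cross-stratum borrowing or meta-regression. The futility wedge does not
close exactly onto the monitoring boundary for many-look designs because
the drift is fixed at z₁₋α/₂ + z₁₋β rather than solved jointly with both
boundaries; the resulting futility declarations are conservative.
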