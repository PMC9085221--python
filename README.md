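# decigene

Sequential meta-analysis verdicts for candidate-gene case-control studies.

Candidate-gene association literature accumulates study by study, and
meta-analysts face a multiplicity problem: every time a new primary study
is pooled into a cumulative meta-analysis and re-tested at p < 0.05, the
chance of a false-positive association grows. `decigene` treats the
cumulative meta-analysis of one gene locus as a group-sequential trial.
For each locus (an rs-number) and ethnicity stratum it

1. converts per-study genotype counts into allele-model 2×2 tables and
   Woolf log odds ratios,
2. pools them cumulatively in publication order with DerSimonian–Laird
   random effects (Q, τ², I², and the diversity D²),
3. computes a **required information size** (RIS) from a reference minor
   allele frequency, an assumed odds ratio (default 1.5), α = 0.05 and
   power 0.80, inflated for heterogeneity by 1/(1 − D²),
4. monitors the cumulative Z curve against Lan–DeMets O'Brien–Fleming-type
   alpha-spending boundaries and a beta-spending futility wedge, and
5. declares the locus a **conclusive risk factor**, **conclusive
   protective factor**, **conclusively unassociated**, or **inconclusive**
   with the exact number of additional subjects still needed.

It is aimed at genetic epidemiologists compiling whole-literature maps of
which loci are settled and which still need samples.

## The statistics

Per study, the allele model gives a 2×2 table (minor/major × case/control)
with log odds ratio ŷ = ln(ad/bc) and SE √(1/a + 1/b + 1/c + 1/d)
(0.5 added to all cells only when a zero cell occurs). DerSimonian–Laird
pooling uses Q = Σwᵢ(yᵢ − ŷ_F)², τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)),
random-effects weights 1/(seᵢ² + τ²), I² = max(0, (Q − (k−1))/Q) and
D² = 1 − v_F/v_R.

The fixed-sample information size compares the control minor-allele
proportion p_c (the reference MAF) with the case proportion implied by the
assumed odds ratio, p_t = OR·p_c / (1 + p_c(OR − 1)):

    n = (z₁₋α/₂ + z₁₋β)² · (p_c(1−p_c) + p_t(1−p_t)) / (p_t − p_c)²

counted in subjects (each subject contributes two alleles split across the
two arms), then RIS = ⌈n / (1 − D²)⌉. Each added study is an interim look
at information fraction min(1, accumulated subjects / RIS). Monitoring
thresholds solve the alpha-spending equation α*(t) = 2(1 − Φ(z₁₋α/₂/√t))
by recursive numerical integration over the Brownian representation of
the Z process; the futility wedge spends the type-II budget the same way
under the alternative drift z₁₋α/₂ + z₁₋β. See `docs/methods.md` for the
exact constructions and their accuracy.

## Worked example

Simulate a six-study stream at a locus with true allelic OR 2.0 and
control MAF 0.30 (300 cases / 300 controls per study), then run the full
pipeline against the standard design (assumed OR 1.5, α 0.05, power 0.8,
fixed D² 0.8):

```
$ decigene simulate --true-or 2.0 --maf 0.30 --k 6 --case-n 300 \
      --ctrl-n 300 --seed 5 --locus-id rs0000001 --out studies.csv
$ printf 'rs0000001:\n  maf: 0.30\n  assumed_or: 1.5\n  d2: 0.8\n' > loci.yaml
$ decigene -v run --input studies.csv --locus-config loci.yaml --out out --no-plot
INFO decigene: rs0000001/caucasian: k=6 subjects=3600 RIS=2110 (d2=0.80) verdict=conclusive_risk
wrote 1 verdict(s) to out

$ cat out/verdicts.csv
locus_id,ethnicity,articles,maf,accumulated_samples,verdict,remaining_samples,odds_ratio_ci,p_value,i2_percent
rs0000001,caucasian,6,0.30,3600,conclusive_risk,0,2.09 (1.88 to 2.31),0.0000,11
```

Reading the row: six pooled articles accumulated 3,600 subjects against a
required information size of 2,110 (422 fixed-sample subjects × 5 for the
80% heterogeneity adjustment); the cumulative Z curve crossed the
monitoring boundary, so the minor allele is declared a conclusive risk
factor with pooled OR 2.09 (95% CI 1.88–2.31) and low heterogeneity
(I² = 11%). The per-ethnicity cross-tab (`out/crosstab_caucasian.txt`)
places the locus in the low-heterogeneity × risk cell, and
`out/manifest.json` records the run configuration. Dropping `--no-plot`
also writes one Z-curve figure per stratum with the boundaries and RIS
marked.

Boundary tables are available directly:

```
$ decigene boundaries --fractions 0.25,0.5,0.75,1.0
fraction,monitor_upper,...   # Z thresholds, futility wedge, spent alpha/beta
0.25,4.3326,...              # wedge undefined this early
0.5,2.9631,...,0.2246,...
1.0,2.0141,...,1.8700,...
```

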