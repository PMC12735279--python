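# vtepanel

Case-control SNP-panel analysis for venous thromboembolism (VTE): per-variant
quality control and association statistics, genetic-model analysis, a
log-odds-ratio-weighted polygenic risk score with control-referenced
standardization, retrospective power calculation, and PRS-stratified
recurrence survival analysis.

The package is aimed at biostatisticians and clinical-genetics groups running
targeted thrombophilia panels on modest case-control cohorts. It ships a
38-variant, 26-gene VTE susceptibility panel (curated coagulation,
anticoagulation, fibrinolysis, platelet and vascular loci such as *PROC*
p.Arg189Trp, *FGG* rs2066865, the *ABO* exon variants, *F5* rs4524, *F11* and
*HIVEP1* loci) together with the case/control effect-allele frequencies
observed in a Thai cohort of 122 VTE patients and 87 healthy controls, which
drive a fully synthetic cohort generator — so the entire pipeline is testable
and demonstrable without any patient-level data.

## The statistics at the core

For each panel variant with effect-allele frequency $p_1$ in cases and $p_0$
in controls, the allelic odds ratio is the cross-product ratio of the
allele-count 2×2 table, equivalently

$$\mathrm{OR} = \frac{p_1/(1-p_1)}{p_0/(1-p_0)},$$

with a Woolf (log-scale) 95% CI
$\exp(\ln\mathrm{OR} \pm 1.96\sqrt{1/a+1/b+1/c+1/d})$ when all cells are
positive and a conditional-exact (Cornfield-type) interval otherwise.
P-values use the χ² test without continuity correction when all expected
cell counts are ≥ 5, else the two-sided Fisher exact test. Dominant and
recessive models collapse genotypes to carrier / homozygous-effect subject
counts; covariate-adjusted ORs come from maximum-likelihood logistic
regression on age, sex and BMI. Hardy-Weinberg QC in controls uses the exact
conditional test.

The polygenic risk score is the weighted dosage sum

$$\mathrm{PRS}_j = \sum_i \beta_i \,\mathrm{SNP}_{ij}, \qquad \beta_i = \ln \mathrm{OR}_i,$$

where $\mathrm{SNP}_{ij} \in \{0,1,2\}$ counts effect alleles, standardized
against controls: $z = (\mathrm{PRS} - \mu_{\text{controls}})/\sigma_{\text{controls}}$.
Recurrence over a 24-month window after anticoagulant discontinuation is
compared between high- and low-PRS patients (median split) within provoked
and unprovoked strata via Kaplan-Meier curves, the log-rank test, and a Cox
proportional-hazards hazard ratio. Retrospective power for the allelic test
is computed exactly by enumerating the two binomial allele-count
distributions under the same test-selection rule.

## Worked example

Generate a study-shaped synthetic cohort (122 cases / 87 controls, genotypes
drawn in Hardy-Weinberg proportions at the panel's observed frequencies) and
run the full pipeline:

```sh
vtepanel simulate --out fixture --seed 7
vtepanel all --genotypes fixture/cohort.vcf --phenotypes fixture/phenotypes.tsv --out report --seed 7
```

`report/association_allelic.tsv` then contains one row per variant, e.g. for
the fibrinogen-gamma variant (columns abridged):

```
gene  rsid        eaf_case  eaf_control  or_ci             p_value  test_used
FGG   rs2066865   0.4836    0.4138       1.33 (0.90-1.96)  0.1576   chi_square
```

The generator draws cases at frequency 0.52 and controls at 0.36 (true
allelic OR ≈ 1.93), but this particular 122/87 realization lands at
0.48/0.41, OR 1.33, p 0.16 — a concrete illustration of sampling noise at
this cohort size, and exactly what the power module quantifies:

```python
>>> from vtepanel import PowerQuery, power_of
>>> power_of(PowerQuery(n_case=122, n_control=87, eaf=0.36, or_alt=1.94))
0.9101152063832513
```

meaning a cohort of this size has 91% power to detect an allelic OR of 1.94
at a control frequency of 0.36 (α = 0.05, two-sided) — comfortably above the
80% convention. The corresponding smallest detectable OR:

```python
>>> from vtepanel import detectable_or
>>> detectable_or(122, 87, eaf=0.36)
1.7575225830078125
```

`report/survival_summary.tsv` reports, per stratum, the log-rank χ²/p and
the Cox hazard ratio of high- versus low-PRS patients with its Wald 95% CI.

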