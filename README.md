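# tsaorta

Genetic risk analysis for bicuspid aortic valve (BAV) and aortopathy in
Turner syndrome cohorts.

Turner syndrome (complete or partial loss of the second sex chromosome,
~1 in 2,000 female births) carries a greatly elevated risk of BAV, thoracic
aortic dilation (TAD), aneurysm and dissection. A leading genetic model is
dosage of the tissue inhibitors of metalloproteinases: *TIMP1* on Xp11.23 is
hemizygous in subjects lacking a complete second X, and common variants in
its autosomal paralogue *TIMP3* (chromosome 22) reduce TIMP3 expression;
together they tip the MMP/TIMP balance that protects the aortic wall.
`tsaorta` implements the full analysis chain needed to study this model in
an exome-sequenced cohort:

- **Karyotype inference** — per-subject X-chromosome allele-balance profiles
  (from VCF `AD` fields or plain tables), second-sex-chromosome
  classification (45,X / 46,XX / mosaic / XY material), and a 45,X mosaic
  cell-fraction estimator. At a heterozygous site with 45,X cell fraction
  *f*, the alternate-allele fraction is `1/(2−f)` or `(1−f)/(2−f)` depending
  on which haplotype carries the variant; the estimator inverts the
  displacement of these two bands.
- **ISCN parsing and locus copy number** — clinical karyotype strings
  (`45,X[30%]/46,XX[70%]`, isochromosomes, rings, deletions, markers) parsed
  into cell lines, with fraction-weighted copy number of any Xp locus
  (default: *TIMP1*, X:47442814–47446090, hg19) and the 1-copy / >1-copy
  dichotomization used in risk tables.
- **Turner-specific aortic z-scores** — Haycock body surface area,
  disease-specific expected aortic-root/ascending-aorta diameters
  (quadratics in BSA), and `z = (√actual − √expected)/√MSE`; TAD is any
  z ≥ 1.9 after rounding to one decimal.
- **Variant QC** — call-rate and sample-missingness filters, exact
  Hardy–Weinberg test, windowed LD pruning, and genotype PCA with iterative
  population-outlier removal, with full removal bookkeeping.
- **Gene-based association** — a SKAT-O-style omnibus test interpolating
  between a variance-component kernel statistic and a burden statistic over
  a ρ grid, calibrated by joint residual permutation (min-p null), plus the
  Bonferroni exome-wide threshold and Q-Q data.
- **Candidate ranking and risk models** — Xp candidate-gene ranking (XCI
  escape, no Y homologue, aortic expression, valve-development role),
  CADD-based deleteriousness flags, case/control allele tests, 2×2 odds
  ratios with Woolf intervals and Haldane–Anscombe correction,
  chi-squared/Fisher decision rule, and the four-group *TIMP1* × *TIMP3*
  combinatorial analysis.
- **Synthetic cohorts** — a generator reproducing the statistical structure
  above (karyotype spectrum, three-band allele balance, Hardy–Weinberg
  *TIMP3* genotypes, logistic BAV risk, invertible z-scores) so the entire
  pipeline is testable without access-controlled registry data.

## Worked example

```python
from tsaorta import (parse_iscn, locus_copy_number, dichotomize_copy_number,
                     haycock_bsa, expected_dimension, aortic_z, Vessel,
                     ContingencyTable, odds_ratio, association_test)

k = parse_iscn("45,X[30%]/46,XX[70%]")
copies = locus_copy_number(k)
print("TIMP1 copies:", copies, "->", dichotomize_copy_number(copies))

bsa = haycock_bsa(147.0, 58.0)
exp_ar = expected_dimension(bsa, Vessel.AR)
z = aortic_z(3.1, exp_ar, mse=0.01)
print(f"BSA {bsa:.3f} m^2, expected AR {exp_ar:.3f} cm, z = {z:.2f}")

t = ContingencyTable(81, 72, 7, 28)   # BAV by TIMP1 copy group
res = odds_ratio(t)
p, test = association_test(t)
print(f"OR {res.or_point:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"p = {p:.4f} [{test}]")
```

prints

```
TIMP1 copies: 1.7 -> >1 copy
BSA 1.558 m^2, expected AR 1.639 cm, z = 4.80
OR 4.50 (95% CI 1.85-10.93), p = 0.0009 [chi2_yates]
```

The mosaic karyotype carries 0.3·1 + 0.7·2 = 1.7 *TIMP1* copies, placing the
subject in the protective >1-copy group. The z-score uses the package's
placeholder MSE of 0.01 (√cm scale); absolute z values against real
echocardiograms require the published regression MSEs, supplied via
configuration. The 2×2 table shows subjects with a single *TIMP1* copy at
4.50-fold odds of BAV relative to the >1-copy group.

A full synthetic run from the shell:

```
tsaorta all --seed 3 --outdir run/
```

writes phenotypes, genotypes (VCF), karyotype calls, z-scores, QC logs,
association results, the Xp ranking and the risk tables under `run/`, plus a
`manifest.json` recording the configuration hash and per-stage counts.

## Documentation

`docs/methods.md` describes the statistical models, their assumptions,
parameter defaults and known limitations.
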