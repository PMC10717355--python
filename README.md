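# sgaburden

Gene-based rare-variant collapsing analysis and prognosis prediction for
small-for-gestational-age (SGA) newborn cohorts.

SGA newborns (birth weight below the 10th percentile for gestational age) in
neonatal intensive care are at high risk of death, physical growth delay and
neurodevelopmental delay. Beyond diagnosable monogenic and chromosomal
disorders, part of that risk is carried by rare variants (minor allele
frequency < 1%) that no single-variant test can detect. `sgaburden`
implements the analysis stack used to find such risk genes and to fold them
into a clinical prognosis model:

- **Collapsing burden scan.** Variants are classified as protein-truncating
  (PTV), missense (MIS), synonymous (SYN) or non-coding (NON). Per gene,
  one-sided Fisher's exact tests compare carrier counts between cases and
  controls for each class. Genes enriched at the SYN or NON level — a
  near-neutral background where true signal should not live — are flagged as
  confounded and excluded.
- **Risk score and permutation null.** Gene-level evidence is combined as

  ```
  risk score = 2 · (−log10 P_PTV) + (−log10 P_MIS)
  ```

  and referred to a null distribution built by shuffling case/control labels
  (B permutations, add-one estimator `perm_p = (1 + r)/(1 + B)`). Genes with
  `P_PTV < 0.05` or `P_MIS < 0.05` are *risk genes*; genes with
  `P_PTV < 0.01` or `P_MIS < 0.01` **and** Benjamini–Hochberg FDR of the
  permutation p below 0.01 are *potential causative genes*.
- **Propensity-score matching** of cases to controls on gestational age, sex
  and maternal gestational hypertension (logistic propensity, greedy
  nearest-neighbour without replacement, balance diagnostics).
- **Cohort statistics.** Baseline-table machinery: Pearson chi-square without
  continuity correction, Fisher's exact test for sparse tables, Welch
  t / Wilcoxon, uni- and multivariable logistic odds ratios.
- **Prognosis models.** Per-risk-gene 2/1/0 burden features (2 = carries a
  PTV, 1 = missense only, 0 = otherwise), univariable screening of clinical
  factors, two gradient-boosting classifiers (clinical-only vs
  clinical+genetic) tuned by repeated cross-validated AUC and compared with
  DeLong's paired test.
- **Synthetic cohorts.** A seeded generator producing case/control cohorts
  with planted risk genes at configurable carrier odds ratios and a logistic
  poor-prognosis outcome, so every stage is testable without access to
  controlled patient data.

## Worked example

`examples/02_burden_scan.py` simulates 300 cases / 600 controls over a
100-gene panel with 12 planted PTV risk genes (carrier odds ratio 8) and two
SYN-confounded genes, then runs the full scan:

```
 gene  case_carriers_PTV  control_carriers_PTV    p_PTV  p_MIS  risk_score   perm_p   fdr_q                tier
G0008                 64                    10 5.56e-23  0.518        44.8 0.000999 0.00909 potential_causative
G0005                 51                     7    6e-19  0.474        36.8 0.000999 0.00909 potential_causative
G0004                 40                     6 1.49e-14 0.0141        29.5 0.000999 0.00909 potential_causative
G0009                 41                     7 2.51e-14  0.893        27.3 0.000999     NaN                none

planted risk genes recovered as potential causative: 10/12
```

Planted genes top the risk-score ranking with permutation p at the 1/(B+1)
floor and clear the FDR gate; `G0009` happens to also be enriched in
synonymous variants in this replicate, so the background filter removes it —
the filter doing its job at its ~5% type-I cost. `examples/05_prognosis_model.py`
continues to the modelling stage:

```
held-out AUC, clinical-only model:     0.642
held-out AUC, clinical+genetic model:  0.899
DeLong paired p for the AUC difference: 1.889e-05
```

Adding per-gene burden features to the screened clinical factors lifts the
held-out AUC by ~0.26 — genetics carrying prognostic signal the clinical
flags do not.

The other examples cover simulation (`01`), baseline tables and the published
reference statistics (`03`), matching (`04`) and the end-to-end pipeline with
a content-hashed manifest (`06`). A thin CLI wraps the pipeline:

```
sga-burden run-all --config config.yaml --outdir results/ --seed 17
```

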