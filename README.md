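# mfrsig — prognostic gene signatures from tumor/normal mutation-frequency ratios

Somatic mutation profiles are usually binary (a gene is mutated or it is
not) and extremely sparse, which makes them poor material for survival
modelling: prognostic signatures built on binary calls tend to overfit the
training cohort and fail on held-out patients. `mfrsig` implements an
alternative representation that keeps the *quantitative* information in
paired tumor/normal sequencing: for each missense mutation *j* of patient
*i*, the tumor and normal mutation frequencies are the alternate/reference
read-count ratios

```
TMF_ij = TAC_ij / TRC_ij        NMF_ij = NAC_ij / NRC_ij
MFR_ij = TMF_ij / NMF_ij
```

and a patient's gene-level **MFR profile** is the per-gene arithmetic mean
of these ratios, log2-transformed. When any of the four read counts is
zero, a Haldane–Anscombe continuity correction (+0.5 to all four counts)
keeps the ratio finite and positive.

On top of these profiles the package runs a complete discovery/validation
pipeline for overall survival:

1. random train/validation cohort split;
2. profile construction — MFR, plus three comparator representations:
   TMF, binary mutation calls (BM), and NetNorM-style network-normalized
   binary profiles (every patient forced to exactly *k* mutated genes
   using gene–gene network degree ranking);
3. rare-gene filter (genes mutated in <1% of training patients dropped);
4. per-gene univariate Cox proportional-hazards screen with
   Benjamini–Hochberg FDR ≤ 0.05 shortlisting;
5. bidirectional stepwise multivariate Cox selection by AIC → the final
   signature (genes with coefficients);
6. Schoenfeld-residual proportional-hazards diagnostics;
7. risk scoring by the signature's linear predictor, stratification at
   the training 75th-percentile score, and Kaplan–Meier / log-rank
   comparison of high- vs low-risk groups on both splits.

The package is aimed at statistical-genomics researchers who want to
evaluate continuous mutation representations for risk stratification, on
their own MAF-format cohorts or on fully synthetic cohorts with known
ground truth (the built-in generator plants signature genes with chosen
log2-MFR hazard coefficients, so recovery can be measured exactly).

## Worked example

```python
from mfrsig import (SimulationConfig, generate_cohort, split_cohort,
                    build_profile, filter_rare_genes, log2_transform,
                    SignatureCoxModel)

# simulate a 900-patient exome cohort with 5 planted prognostic genes
cfg = SimulationConfig(seed=11)
records, clinical, truth = generate_cohort(cfg)

ids = {c.patient_id for c in clinical}
split = split_cohort(ids, train_fraction=600 / 900, seed=11)
profile = build_profile(records, tuple(sorted(ids)), "MFR")
profile = filter_rare_genes(profile, split.train_ids, 0.01)
profile = log2_transform(profile)

clin = {c.patient_id: c for c in clinical}
train_prof = profile.subset_patients(split.train_ids)
valid_prof = profile.subset_patients(split.validation_ids)

model = SignatureCoxModel(train_prof, [clin[p] for p in train_prof.patients])
results = model.fit()
print(results.summary())

strat = results.evaluate(valid_prof, [clin[p] for p in valid_prof.patients],
                         split_label="validation")
print(f"validation log-rank p = {strat.logrank_p:.3g}")
```

prints

```
Somatic-mutation prognostic signature (Cox PH)
====================================================
profile kind:        MFR    patients: 600    genes: 200
events: 422    FDR cutoff: 0.05    shortlisted genes: 5
selected signature: 5 gene(s), AIC = 4003.45
----------------------------------------------------
           coefficient     HR  Lower .95  Upper .95      p
Gene
GENE_0000       0.6654 1.9452     1.8339     2.0633 0.0000
GENE_0040      -0.5907 0.5539     0.5123     0.5990 0.0000
GENE_0080       0.4732 1.6051     1.5280     1.6861 0.0000
GENE_0120       0.3816 1.4646     1.4013     1.5308 0.0000
GENE_0160      -0.3496 0.7049     0.6642     0.7482 0.0000
----------------------------------------------------
PH check (Schoenfeld, global): chi2 = 7.793 on 5 df, p = 0.1680
validation log-rank p = 6.45e-65
```

All five planted genes (`truth.coefficients`) are recovered; the hazard
ratios estimate the planted log2-MFR effects (e.g. 0.8 → HR ≈ e^0.67,
slightly attenuated by read-count noise); the PH check does not reject
proportional hazards (the generator satisfies it exactly); and the
high-/low-risk split separates survival on the held-out patients.

## Command line

```bash
mfrsig simulate --out sim/ --n-patients 900 --n-genes 200 --seed 11
mfrsig run --config pipeline.yaml          # one profile kind, end to end
mfrsig compare --config pipeline.yaml      # all four kinds + overlap table
mfrsig profiles|discover|evaluate ...      # stage-wise operation on files
```

`pipeline.yaml` holds `maf_path`, `clinical_path`, optional
`network_path`, `profile_kind`, `train_fraction`, `seed`, and the
thresholds (rare-gene fraction, FDR cutoff, threshold percentile). Each
run writes the screen table, the signature table (gene, HR, 95% CI,
p), per-split stratification JSONs, Kaplan–Meier tables, and a manifest;
identical config + seed reproduces every output byte for byte.

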