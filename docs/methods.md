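# Methods

## The mutation-frequency-ratio representation

For patient *i* and missense mutation *j*, the MAF file carries four read
counts: tumor reference/alternate (`TRC`, `TAC`) and paired-normal
reference/alternate (`NRC`, `NAC`). The representation implemented here is

* tumor mutation frequency `TMF = TAC/TRC`,
* normal mutation frequency `NMF = NAC/NRC`,
* mutation frequency ratio `MFR = TMF/NMF`.

These are alternate/**reference** count ratios (odds), not
alternate/depth fractions, and are implemented exactly as such. Mutations
are aggregated to gene level by the arithmetic mean of the per-mutation
ratios within a (patient, gene) cell, and the continuous matrices (MFR,
TMF) are then log2-transformed. Aggregation order matters and is fixed:
mean of ratios first, log second.

**Zero counts.** `NAC = 0` is the common case in a clean normal, and
makes the raw ratio infinite. Whenever any of the four counts is zero the
record gets the Haldane–Anscombe continuity correction (+0.5 to all four
counts) and is flagged. This keeps MFR finite, positive and monotone in
NAC. (The correction also triggers on `TAC = 0`, which otherwise would
produce a ratio of exactly 0 and break the positivity invariant of the
type.)

**Unmutated cells.** A patient–gene cell with no mutation is 0 in every
representation, before and after the log2 transform. A consequence worth
knowing: a mutated cell whose mean ratio is exactly 1 (tumor frequency
equal to normal) also maps to log2(1) = 0 and is indistinguishable from
"no mutation" in the continuous matrices. This is a deliberate
convention — sparse profile matrices need a single "absent" value, and 0
is the only choice consistent with both the binary and the log-scale
continuous representations.

## Comparator representations

* **BM** — binary: 1 iff the gene carries ≥ 1 missense mutation.
* **TMF** — tumor-only ratio profile (no normal-sample information).
* **NETNORM** — network normalization of BM in which every patient ends
  up with exactly *k* mutated genes: patients above *k* have their
  lowest-ranked mutated genes switched off, patients below *k* gain proxy
  genes. The ranking is: mutated genes always precede unmutated genes;
  mutated genes order by descending network degree; unmutated genes by
  descending count of mutated network neighbours in that patient, then by
  descending degree; all remaining ties break by ascending gene symbol,
  so the transform is deterministic. *k* defaults to the training-split
  median mutated-gene count. This module canonicalizes a published
  normalization idea from its short prose description; it makes no claim
  of being a line-for-line port of the original implementation, and the
  direction of the degree ordering among a patient's own mutated genes is
  the one choice the prose leaves open (descending is used here).

## Discovery pipeline

Patients are split at random (unstratified) into training and validation;
the default training fraction 0.663 reproduces a 328/167 division at
n = 495. All modelling choices are made on the training split only:

1. **Rare-gene filter.** Genes with nonzero entries in fewer than 1% of
   *training* patients are dropped, and the surviving gene set is applied
   to both splits — filtering on the pooled cohort would leak validation
   information into gene selection.
2. **Univariate Cox screen.** One single-covariate Cox proportional-
   hazards fit per gene (Efron tie handling, Breslow available). The
   reported p-value is the partial-likelihood-ratio test; on sparse,
   heavily skewed mutation covariates the Wald test is anti-conservative
   (near-monotone likelihoods give large coefficients with deceptively
   small Wald p), and in global-null simulations the likelihood-ratio
   screen keeps the BH false-discovery proportion at the nominal level
   where the Wald screen exceeds it several-fold. Confidence intervals
   are the usual Wald intervals. Genes whose fit cannot converge
   (constant columns, separation) are retained with p = 1 and a flag, so
   gene bookkeeping is exact.
3. **Shortlist.** Benjamini–Hochberg FDR ≤ 0.05, boundary inclusive.
4. **Stepwise selection.** Bidirectional greedy search over add/drop
   moves scored by partial-likelihood AIC, starting from the full
   shortlist model (empty start available). The search stops when no
   single move improves AIC; dropping to the empty model is a legal move.
   Exactly collinear candidate columns are detected by incremental rank
   and the later column dropped before the search. The selection
   criterion (AIC) is a documented choice: stepwise Cox tooling in the
   R ecosystem defaults to it, and at ≤ 8 candidates the greedy search
   provably matched exhaustive enumeration in every test cohort.
5. **PH diagnostics.** Scaled Schoenfeld-residual tests per gene
   (lifelines, rank time-transform) plus a global Grambsch–Therneau
   chi-square computed from the unscaled residuals,
   `T = d · uᵀVu / Σ(g−ḡ)²` with `u = Σ(gₖ−ḡ)sₖ`. The global test was
   checked against R `survival::cox.zph` and is calibrated (type-I error
   0.05 at α = 0.05 over 200 proportional-hazards replicates). Results
   are reported, never used to alter the signature automatically.

The fitted signature is the ordered gene/coefficient list; a patient's
**risk score** is the linear predictor Σ coefficient_g × profile value_g.

## Risk stratification and evaluation

The high-risk threshold is the 75th percentile (linear-interpolation
quantile) of the *training* risk scores and is applied unchanged to the
validation split. Scores strictly above the threshold are high-risk, so
at most 25% of training patients (plus exact ties) are high-risk.
Kaplan–Meier curves and the two-sample log-rank test (standard
hypergeometric variance, 1 df) compare the groups per split. Training
p-values are reported but are expected to be optimistic — the signature
was selected on that split; the validation p-value is the honest
measure. If a split degenerates to a single risk group, the comparison
is reported as statistic 0, p = 1 with a warning rather than failing the
run.

## Numerical implementation of the Cox fits

Screening fits hundreds of genes across many simulation replicates, so
the univariate fits use an in-package Newton solver for the Cox partial
likelihood, vectorized across genes (risk sets as descending-time
cumulative sums; Efron or Breslow ties; per-gene step-halving to keep
each likelihood monotone; |β| > 25 treated as monotone likelihood and
flagged). The same solver in multivariate form scores the stepwise
search. It reproduces lifelines' `CoxPHFitter` log-likelihoods and
estimates to ~1e-5 (the residual difference is lifelines' looser stopping
rule), and lifelines remains the independent cross-check in the test
suite and performs the final signature refit reported in
`summary()` — with an in-package fallback when lifelines' own Newton
iterations fail on nearly-separated columns.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

* **Mutations.** Per patient and gene, Bernoulli mutation indicators:
  background rate 0.03, planted signature genes boosted to prevalence
  0.2. Five signature genes among 200 with log2-MFR hazard coefficients
  (0.8, −0.6, 0.6, 0.5, −0.4).
* **Read counts.** Per mutation, a latent tumor VAF (uniform 0.05–0.40
  background; 0.05–0.85 for signature genes, so ratio *magnitude* — not
  mere mutation presence — carries the prognostic signal) and a latent
  normal VAF (uniform 0.005–0.05, nonzero so both the corrected and
  uncorrected ratio branches are exercised; a flag forces NAC = 0).
  Depths are Poisson with mean 100 (typical whole-exome coverage) and
  alt counts binomial at the latent VAF; the true per-mutation MFR is
  the latent alt/ref odds ratio, which is recorded.
* **Survival.** Exponential proportional-hazards model: hazard =
  0.001/day × exp(Σ coefficient_g × log2 true MFR_g) over the patient's
  mutated signature genes (unmutated genes contribute 0, matching the
  pipeline's zero convention, so the Cox model is correctly specified).
  Independent exponential censoring whose rate is solved numerically so
  the expected censoring fraction equals the target (default 30%);
  realized fractions land within a percentage point or two at n = 1000.
* **PH-violation mode.** For diagnostics power tests only: the covariate
  effect flips sign at the median of the patients' individual median
  survival times, so roughly half the events occur under each regime.
* **Network.** Barabási–Albert preferential attachment over the gene
  universe (scale-free, like curated interaction networks).

Default cohort sizes for the end-to-end experiments are 600 training /
300 validation patients and 200 genes — large enough for the planted
effects (|coef| 0.4–0.8) to be recoverable, small enough that the full
validation study runs in about a minute.

**What the generator does not emulate:** real mutation-burden spectra,
trinucleotide signature structure, gene length or expression effects on
mutation rates, inter-gene mutation correlation, and real gene symbols'
biology. Passing tests therefore demonstrate the statistical machinery
(calibration, recovery, selection optimality, leakage-free evaluation),
not performance on real tumor cohorts.

**Known attenuation.** The pipeline regresses survival on the *measured*
log2 MFR, a noisy version of the generating value; the noise is dominated
by the normal-sample alt count (variance ≈ 1/NAC, and NAC averages ~3 at
100× coverage with sub-5% normal VAFs). Errors-in-variables therefore
attenuate recovered coefficients by ~10% on the log scale: a planted
coefficient ln 2 (HR 2.0) is recovered around HR 1.78 ± 0.05 at n = 1000.
For the same reason, the per-mutation ratio estimate is consistent but
slow: at 10,000× depth its median relative error is ~5%, and claims about
per-mutation precision should be phrased in terms of the error
distribution, not a uniform bound.

## Tunable parameters

| parameter | default | units / meaning |
|---|---|---|
| `train_fraction` | 0.663 | training share of the cohort |
| `rare_gene_min_fraction` | 0.01 | training-prevalence floor per gene |
| `fdr_cutoff` | 0.05 | BH threshold for the shortlist |
| `threshold_percentile` | 75 | training risk-score percentile for high risk |
| `ties` | efron | Cox tie handling (breslow available) |
| `stepwise_start` | full | stepwise start point (empty available) |
| `netnorm_k` | training median | mutated genes per normalized patient |
| `SimulationConfig.baseline_hazard` | 0.001/day | null median survival ≈ 693 d |
| `SimulationConfig.censoring_rate` | 0.30 | expected censored fraction |

## Degenerate inputs and tie-breaks

* Duplicate patients (clinical or profile) are validation errors.
* MAF rows with unparseable counts or zero tumor coverage are dropped and
  counted, never silently ignored.
* Quantile convention is linear interpolation between order statistics
  and is recorded in the stratification output.
* Shortlist ordering breaks q ties by p then gene symbol; NetNorM breaks
  all ranking ties lexicographically; the cohort split sorts patient ids
  before shuffling — every stochastic step is a pure function of the
  config seed, and pipeline outputs are byte-identical across reruns.

## Limitations

* Gene-level analysis only; no sub-gene (mutation-site) profiles.
* No demographic or clinical covariates in the Cox models, and no
  penalized (lasso/ridge) alternatives to stepwise selection.
* MAF input only (no VCF), and no download client for controlled-access
  data; real-cohort claims require the user's own data.
* Greedy stepwise selection is optimal in the tested small-candidate
  regime but carries no global-optimality guarantee at large shortlists.
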