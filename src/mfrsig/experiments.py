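"""Reference simulation experiments for the package's own validation study.

Each function runs one self-contained experiment on synthetic cohorts with
known ground truth and returns the measured quantity: effect-size
recovery, shortlist recall of planted genes, end-to-end validation
significance rates per profile representation, log-rank type-I error, and
stepwise-vs-exhaustive model-selection agreement.  The test suite and the
reproduction script both call these, so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .discovery import model_aic, shortlist, stepwise_cox, univariate_cox_screen
from .maf_io import MutationRecord
from .pipeline import PipelineConfig, run_from_records
from .profiles import ProfileKind, build_profile, filter_rare_genes, log2_transform, mutation_frequencies
from .synthetic import SimulationConfig, generate_cohort, gene_name

logger = logging.getLogger(__name__)


def exact_ratio_example() -> float:
    """MFR of the canonical read-count quadruple (70, 30, 98, 2)."""
    rec = MutationRecord(
        patient_id="P1", gene="G1", variant_classification="Missense_Mutation",
        trc=70, tac=30, nrc=98, nac=2,
    )
    return mutation_frequencies(rec).mfr


def _mfr_profile(records, clinical):
    patients = tuple(c.patient_id for c in clinical)
    prof = build_profile(records, patients, ProfileKind.MFR)
    prof = filter_rare_genes(prof, patients, 0.01)
    return log2_transform(prof)


def planted_hr_recovery(seed: int = 0, n: int = 1000) -> float:
    """Univariate HR estimate for one planted gene with true coefficient ln 2."""
    cfg = SimulationConfig(
        n_patients=n,
        signature_genes=((gene_name(0), float(np.log(2))),),
        seed=seed,
    )
    records, clinical, _ = generate_cohort(cfg)
    prof = _mfr_profile(records, clinical)
    res = {r.gene: r for r in univariate_cox_screen(prof, clinical)}
    return res[gene_name(0)].hr


def shortlist_recall(n_seeds: int = 50, n: int = 600, seed0: int = 0) -> list[int]:
    """Planted genes (of 5) recovered by the FDR <= 0.05 shortlist, per seed."""
    recalls = []
    for i in range(n_seeds):
        cfg = SimulationConfig(n_patients=n, seed=seed0 + i)
        records, clinical, truth = generate_cohort(cfg)
        prof = _mfr_profile(records, clinical)
        hits = set(shortlist(univariate_cox_screen(prof, clinical)))
        recalls.append(len(hits & set(truth.coefficients)))
    return recalls


def null_shortlist_fdp(n_seeds: int = 50, n: int = 600, seed0: int = 0) -> float:
    """Mean false-discovery proportion of the shortlist under the global null."""
    fdps = []
    for i in range(n_seeds):
        cfg = SimulationConfig(n_patients=n, signature_genes=(), seed=seed0 + i)
        records, clinical, _ = generate_cohort(cfg)
        prof = _mfr_profile(records, clinical)
        hits = shortlist(univariate_cox_screen(prof, clinical))
        fdps.append(1.0 if hits else 0.0)  # every hit is false under the null
    return float(np.mean(fdps))


def endtoend_validation(
    n_seeds: int = 25,
    kinds=("MFR", "BM"),
    n_train: int = 600,
    n_valid: int = 300,
    seed0: int = 0,
) -> dict:
    """Full-pipeline validation log-rank p per profile kind on shared cohorts.

    Returns ``{kind: {"pvalues": [...], "significant_rate": float}}``; a run
    that halts with an empty shortlist/signature counts as not significant.
    """
    n = n_train + n_valid
    out = {k: [] for k in kinds}
    for i in range(n_seeds):
        cohort_seed = seed0 + i
        records, clinical, _ = generate_cohort(SimulationConfig(n_patients=n, seed=cohort_seed))
        for kind in kinds:
            cfg = PipelineConfig(
                maf_path="-", clinical_path="-", output_dir="-",
                profile_kind=kind, log2=kind in ("MFR", "TMF"),
                train_fraction=n_train / n, seed=cohort_seed,
            )
            report = run_from_records(records, clinical, cfg)
            p = report.validation.logrank_p if report.validation is not None else 1.0
            out[kind].append(p)
    return {
        k: {
            "pvalues": ps,
            "significant_rate": float(np.mean([p < 0.05 for p in ps])),
        }
        for k, ps in out.items()
    }


def logrank_type1_error(n_seeds: int = 200, n_per_arm: int = 100, seed0: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of the log-rank test when both arms share one exponential."""
    from .evaluation import logrank_test
    from .maf_io import ClinicalRecord

    rejections = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(seed0 + i)
        times = rng.exponential(1.0, size=2 * n_per_arm)
        clin = [
            ClinicalRecord(patient_id=f"P{j}", time=float(t), event=True)
            for j, t in enumerate(times)
        ]
        groups = {f"P{j}": ("high" if j < n_per_arm else "low") for j in range(2 * n_per_arm)}
        _, p = logrank_test(groups, clin)
        rejections += p < alpha
    return rejections / n_seeds


STEPWISE_COHORT = dict(
    n_patients=200,
    n_genes=8,
    signature_genes=((gene_name(0), 0.7), (gene_name(3), -0.7), (gene_name(6), 0.6)),
    background_mutation_rate=0.25,
    signature_prevalence=0.35,
)


def stepwise_exhaustive_agreement(n_cohorts: int = 20, seed0: int = 0) -> int:
    """Cohorts (of ``n_cohorts``) where stepwise = exhaustive AIC minimizer."""
    agree = 0
    for i in range(n_cohorts):
        cfg = SimulationConfig(seed=seed0 + i, **STEPWISE_COHORT)
        records, clinical, _ = generate_cohort(cfg)
        patients = tuple(c.patient_id for c in clinical)
        prof = log2_transform(build_profile(records, patients, ProfileKind.MFR))
        candidates = list(prof.genes)
        best_set, best_aic = frozenset(), np.inf
        for r in range(1, len(candidates) + 1):
            for combo in itertools.combinations(candidates, r):
                aic = model_aic(prof, clinical, list(combo))
                if aic < best_aic:
                    best_set, best_aic = frozenset(combo), aic
        selected = frozenset(stepwise_cox(prof, clinical, candidates).genes)
        agree += selected == best_set
        if selected != best_set:
            logger.warning("stepwise/exhaustive mismatch at seed %d", seed0 + i)
    return agree
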