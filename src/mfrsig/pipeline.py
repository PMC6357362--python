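"""End-to-end orchestration: files in, signature + stratification out.

``run_pipeline`` executes the full discovery/evaluation chain for one
profile representation: read MAF and clinical tables, filter to missense
calls, split the cohort, build the profile matrix (with network
normalization when requested), filter rare genes on the training split,
log2-transform continuous kinds, fit the signature model on training,
then score, stratify and log-rank-test both splits at the training
75th-percentile threshold.  All randomness flows from the single config
seed and outputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from . import evaluation, maf_io, netnorm, profiles
from .model import SignatureCoxModel, SignatureCoxResults
from .profiles import ProfileKind

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run depends on."""

    maf_path: str
    clinical_path: str
    output_dir: str
    network_path: str | None = None
    profile_kind: str = "MFR"
    train_fraction: float = maf_io.DEFAULT_TRAIN_FRACTION
    seed: int = 0
    rare_gene_min_fraction: float = 0.01
    fdr_cutoff: float = 0.05
    stepwise_criterion: str = "aic"
    stepwise_start: str = "full"
    ties: str = "efron"
    threshold_percentile: float = 75.0
    netnorm_k: int | None = None  # None -> training median mutated genes
    log2: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 <= self.rare_gene_min_fraction <= 1:
            raise ValueError("rare_gene_min_fraction must be in [0, 1]")
        if not 0 < self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff must be in (0, 1]")
        if not 0 <= self.threshold_percentile <= 100:
            raise ValueError("threshold_percentile must be in [0, 100]")
        if self.stepwise_criterion != "aic":
            raise ValueError("only AIC stepwise selection is implemented")
        kind = ProfileKind(self.profile_kind)
        if kind is ProfileKind.NETNORM and self.network_path is None:
            raise ValueError("NETNORM profiles need a network_path")
        if self.log2 and kind in (ProfileKind.BM, ProfileKind.NETNORM):
            raise ValueError(f"log2 transform is not applicable to {kind.value} profiles")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Outcome of one pipeline run."""

    status: str  # "completed" | "halted_empty_shortlist" | "halted_empty_signature"
    config: PipelineConfig
    results: SignatureCoxResults | None = None
    threshold: float | None = None
    training: evaluation.RiskStratification | None = None
    validation: evaluation.RiskStratification | None = None
    n_patients: int = 0
    netnorm_k: int | None = None
    outputs: dict = field(default_factory=dict)


def _build_profiles(records, split, all_patients, config: PipelineConfig, network=None):
    """Profile matrices for both splits (identical gene set), plus the k used."""
    kind = ProfileKind(config.profile_kind)
    k_used = None
    if kind is ProfileKind.NETNORM:
        bm = profiles.build_profile(records, all_patients, ProfileKind.BM)
        if network is None:
            network = netnorm.GeneNetwork.read_edge_list(config.network_path)
        k_used = config.netnorm_k or netnorm.median_mutated_genes(bm, split.train_ids)
        k_used = min(k_used, len(bm.genes))
        prof = netnorm.netnorm_profiles(bm, network, netnorm.NetNormParams(k=k_used))
        # the rare-gene filter runs on the normalized matrix (profile
        # build, then filter), so a normalized row can end up below k if a
        # rarely-used proxy column is dropped
        prof = profiles.filter_rare_genes(prof, split.train_ids, config.rare_gene_min_fraction)
    else:
        prof = profiles.build_profile(records, all_patients, kind)
        prof = profiles.filter_rare_genes(prof, split.train_ids, config.rare_gene_min_fraction)
        if config.log2 and kind in (ProfileKind.TMF, ProfileKind.MFR):
            prof = profiles.log2_transform(prof)
    return prof.subset_patients(split.train_ids), prof.subset_patients(split.validation_ids), k_used


def run_pipeline(config: PipelineConfig, write: bool = True) -> RunReport:
    """Execute the full discovery/evaluation pipeline for one profile kind."""
    logger.info("stage read: %s", config.maf_path)
    maf = maf_io.read_maf(config.maf_path)
    clin = maf_io.read_clinical(config.clinical_path)
    logger.info("read %d mutation rows (%d dropped), %d patients", len(maf), maf.n_dropped, len(clin))
    return run_from_records(maf.records, clin.records, config, write=write)


def run_from_records(records, clinical, config: PipelineConfig, network=None, write: bool = False) -> RunReport:
    """The pipeline from in-memory records (what :func:`run_pipeline` delegates to)."""
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage missense filter")
    records = maf_io.filter_missense(records)
    clin = list(clinical)
    clinical_ids = {c.patient_id for c in clin}
    records = [r for r in records if r.patient_id in clinical_ids]

    logger.info("stage split (seed=%d)", config.seed)
    split = maf_io.split_cohort(clinical_ids, config.train_fraction, config.seed)
    all_patients = tuple(sorted(clinical_ids))
    clin_by_id = {c.patient_id: c for c in clin}
    clin_train = [clin_by_id[p] for p in sorted(split.train_ids)]
    clin_valid = [clin_by_id[p] for p in sorted(split.validation_ids)]

    logger.info("stage profiles (%s)", config.profile_kind)
    train_prof, valid_prof, k_used = _build_profiles(records, split, all_patients, config, network=network)

    logger.info("stage discovery")
    model = SignatureCoxModel(
        train_prof,
        clin_train,
        fdr_cutoff=config.fdr_cutoff,
        ties=config.ties,
        start=config.stepwise_start,
    )
    results = model.fit()

    report = RunReport(
        status="completed",
        config=config,
        results=results,
        n_patients=len(all_patients),
        netnorm_k=k_used,
    )
    if not results.shortlisted:
        report.status = "halted_empty_shortlist"
    elif not results.converged:
        report.status = "halted_empty_signature"
    if report.status != "completed":
        logger.warning("pipeline halted cleanly: %s", report.status)
        if write:
            _write_outputs(report, outdir, results)
        return report

    logger.info("stage evaluation")
    threshold = results.training_threshold(config.threshold_percentile)
    report.threshold = threshold
    report.training = results.evaluate(train_prof, clin_train, threshold, "training")
    report.validation = results.evaluate(valid_prof, clin_valid, threshold, "validation")

    if write:
        _write_outputs(report, outdir, results, clin_train, clin_valid)
    return report


def _strat_payload(strat: evaluation.RiskStratification, percentile: float) -> dict:
    return {
        "split": strat.split_label.value,
        "threshold": strat.threshold,
        "threshold_percentile": percentile,
        "quantile_convention": "linear interpolation between order statistics",
        "n_high": strat.n_high,
        "n_low": strat.n_low,
        "logrank_statistic": strat.logrank_statistic,
        "logrank_p": strat.logrank_p,
        "groups": dict(sorted(strat.groups.items())),
    }


def _write_outputs(report: RunReport, outdir: Path, results, clin_train=None, clin_valid=None) -> None:
    cfg = report.config
    paths = {}

    paths["screen"] = outdir / "screen.tsv"
    results.screen_frame.to_csv(paths["screen"], sep="\t")

    if results.converged:
        paths["signature"] = outdir / "signature.tsv"
        results.signature_table.to_csv(paths["signature"], sep="\t")

    if report.training is not None:
        for label, strat, clin in (
            ("training", report.training, clin_train),
            ("validation", report.validation, clin_valid),
        ):
            paths[f"stratification_{label}"] = outdir / f"stratification_{label}.json"
            with open(paths[f"stratification_{label}"], "w") as fh:
                json.dump(_strat_payload(strat, cfg.threshold_percentile), fh, indent=1, sort_keys=True)
            curves = results.kaplan_meier(strat, clin)
            for grp, curve in curves.items():
                key = f"km_{label}_{grp}"
                paths[key] = outdir / f"{key}.tsv"
                curve.to_frame().to_csv(paths[key], sep="\t", index=False)

    manifest = {
        "package": "mfrsig",
        "version": _pkg_version,
        "status": report.status,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_patients": report.n_patients,
        "netnorm_k": report.netnorm_k,
        "signature_genes": list(results.signature.genes),
        "library_versions": _library_versions(),
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    report.outputs = {k: str(v) for k, v in paths.items()}


def _library_versions() -> dict:
    import lifelines
    import pandas
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "lifelines": lifelines.__version__,
    }


ALL_KINDS = ("MFR", "TMF", "BM", "NETNORM")


def compare_kinds(base_config: PipelineConfig, kinds=ALL_KINDS, write: bool = True) -> dict:
    """Run the pipeline once per profile kind and tabulate signature overlap."""
    reports = {}
    for kind in kinds:
        cfg = dataclasses.replace(
            base_config,
            profile_kind=kind,
            log2=kind in ("MFR", "TMF"),
            output_dir=str(Path(base_config.output_dir) / kind.lower()),
        )
        reports[kind] = run_pipeline(cfg, write=write)

    genes = sorted({g for r in reports.values() if r.results for g in r.results.signature.genes})
    overlap = {
        g: {k: g in (reports[k].results.signature.genes if reports[k].results else ()) for k in kinds}
        for g in genes
    }
    if write:
        import pandas as pd

        table = pd.DataFrame(overlap).T
        table.index.name = "Gene"
        out = Path(base_config.output_dir) / "signature_overlap.tsv"
        out.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out, sep="\t")
    return {"reports": reports, "overlap": overlap}
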