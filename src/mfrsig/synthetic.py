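"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure the discovery pipeline
assumes: per-patient missense mutations with paired tumor/normal read
counts drawn binomially around latent variant allele frequencies (VAFs),
overall survival drawn from an exponential proportional-hazards model
whose linear predictor is driven by the planted signature genes'
log2 mutation-frequency ratios, independent exponential right-censoring
calibrated to a target censoring fraction, and a scale-free gene-gene
network.  Because the latent VAFs are recorded, the true per-mutation
MFR (the tumor/normal alt-ref odds ratio) is known exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .maf_io import MISSENSE_LABEL, ClinicalRecord, MutationRecord, MafDialect, GDC_DIALECT
from .netnorm import GeneNetwork


def gene_name(i: int) -> str:
    return f"GENE_{i:04d}"


def patient_name(i: int) -> str:
    return f"SIM-{i:04d}"


#: planted log2-MFR hazard coefficients (|coef| in [0.4, 0.8])
_SIGNATURE_COEFS = (0.8, -0.6, 0.6, 0.5, -0.4)


def default_signature(n_genes: int = 200) -> tuple:
    """Five planted signature genes spread evenly over the gene universe."""
    if n_genes < len(_SIGNATURE_COEFS):
        raise ValueError("need at least 5 genes to plant the default signature")
    step = n_genes // len(_SIGNATURE_COEFS)
    return tuple((gene_name(i * step), c) for i, c in enumerate(_SIGNATURE_COEFS))


DEFAULT_SIGNATURE = default_signature(200)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults model a mid-sized exome study: 900 patients (intended for a
    600/300 train-validation division), 200 genes of which 5 carry
    planted prognostic effects, ~100x tumor and normal coverage, and 30%
    right-censoring.
    """

    n_patients: int = 900
    n_genes: int = 200
    signature_genes: tuple = DEFAULT_SIGNATURE
    background_mutation_rate: float = 0.03
    signature_prevalence: float = 0.2
    mean_depth_tumor: int = 100
    mean_depth_normal: int = 100
    tumor_vaf_range: tuple = (0.05, 0.40)
    signature_tumor_vaf_range: tuple = (0.05, 0.85)
    normal_vaf_range: tuple = (0.005, 0.05)
    baseline_hazard: float = 0.001  # per day
    censoring_rate: float = 0.30
    force_zero_nac: bool = False
    time_varying_effects: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.mean_depth_tumor < 1 or self.mean_depth_normal < 1:
            raise ValueError("sequencing depths must be positive")
        genes = {g for g, _ in self.signature_genes}
        universe = {gene_name(i) for i in range(self.n_genes)}
        if not genes <= universe:
            raise ValueError("signature genes must lie in the gene universe")
        for lo, hi in (self.tumor_vaf_range, self.signature_tumor_vaf_range, self.normal_vaf_range):
            if not 0 < lo <= hi < 1:
                raise ValueError("VAF ranges must satisfy 0 < lo <= hi < 1")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(gene_name(i) for i in range(self.n_genes))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    coefficients: dict          # gene -> true log2-MFR hazard coefficient
    true_mfr: dict              # (patient, gene) -> true alt-ref odds ratio
    linear_predictor: dict      # patient -> sum(coef * log2 true MFR)
    risk_group: dict            # patient -> "high"/"low" by the 75th lp percentile
    hazard: dict                # patient -> true event hazard
    censoring_fraction: float   # realized

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "true_mfr": {f"{p}|{g}": v for (p, g), v in self.true_mfr.items()},
            "linear_predictor": self.linear_predictor,
            "risk_group": self.risk_group,
            "hazard": self.hazard,
            "censoring_fraction": self.censoring_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _odds(v: float) -> float:
    return v / (1.0 - v)


def generate_network(n_genes: int, edges_per_node: int = 2, seed: int = 0) -> GeneNetwork:
    """Scale-free (preferential attachment) gene-gene network."""
    if n_genes < edges_per_node + 1:
        raise ValueError("need n_genes >= edges_per_node + 1")
    g = nx.barabasi_albert_graph(n_genes, edges_per_node, seed=int(seed))
    g = nx.relabel_nodes(g, {i: gene_name(i) for i in range(n_genes)})
    return GeneNetwork.from_networkx(g)


def _calibrate_censoring(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+h_i) = target."""
    if target <= 0:
        return 0.0
    lo = 1e-12 * hazards.min()
    hi = 1e9 * hazards.max()

    def frac(c):
        return float(np.mean(c / (c + hazards))) - target

    if frac(lo) > 0 or frac(hi) < 0:
        raise ValueError("censoring calibration infeasible for these hazards")
    return float(brentq(frac, lo, hi, xtol=1e-15, rtol=1e-12, maxiter=200))


def generate_cohort(config: SimulationConfig):
    """Draw one cohort: mutation records, clinical records, ground truth."""
    rng = np.random.default_rng(config.seed)
    n, genes = config.n_patients, config.genes
    sig_coef = dict(config.signature_genes)

    rates = np.full(len(genes), config.background_mutation_rate)
    is_sig = np.array([g in sig_coef for g in genes])
    rates[is_sig] = config.signature_prevalence
    mutated = rng.random((n, len(genes))) < rates[None, :]

    records: list[MutationRecord] = []
    true_mfr: dict = {}
    lp = np.zeros(n)
    for i in range(n):
        pid = patient_name(i)
        for j in np.flatnonzero(mutated[i]):
            g = genes[j]
            lo, hi = (
                config.signature_tumor_vaf_range if is_sig[j] else config.tumor_vaf_range
            )
            v_t = rng.uniform(lo, hi)
            v_n = rng.uniform(*config.normal_vaf_range)
            depth_t = max(int(rng.poisson(config.mean_depth_tumor)), 2)
            depth_n = max(int(rng.poisson(config.mean_depth_normal)), 2)
            tac = int(rng.binomial(depth_t, v_t))
            tac = min(max(tac, 1), depth_t)  # a called mutation has >= 1 alt read
            trc = depth_t - tac
            if config.force_zero_nac:
                nac, nrc = 0, depth_n
            else:
                nac = int(rng.binomial(depth_n, v_n))
                nrc = depth_n - nac
            records.append(
                MutationRecord(
                    patient_id=pid,
                    gene=g,
                    variant_classification=MISSENSE_LABEL,
                    trc=trc,
                    tac=tac,
                    nrc=nrc,
                    nac=nac,
                )
            )
            mfr = _odds(v_t) / _odds(v_n)
            true_mfr[(pid, g)] = mfr
            if is_sig[j]:
                lp[i] += sig_coef[g] * np.log2(mfr)

    hazards = config.baseline_hazard * np.exp(lp)
    if config.time_varying_effects:
        event_times = _piecewise_reversing_times(rng, lp, config.baseline_hazard)
    else:
        event_times = rng.exponential(1.0 / hazards)
    c_rate = _calibrate_censoring(hazards, config.censoring_rate)
    if c_rate > 0:
        censor_times = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = event_times <= censor_times

    clinical = [
        ClinicalRecord(patient_id=patient_name(i), time=float(observed[i]), event=bool(event[i]))
        for i in range(n)
    ]

    lp_threshold = float(np.percentile(lp, 75))
    truth = GroundTruth(
        coefficients={g: float(c) for g, c in config.signature_genes},
        true_mfr=true_mfr,
        linear_predictor={patient_name(i): float(lp[i]) for i in range(n)},
        risk_group={
            patient_name(i): ("high" if lp[i] > lp_threshold else "low") for i in range(n)
        },
        hazard={patient_name(i): float(hazards[i]) for i in range(n)},
        censoring_fraction=float(1.0 - event.mean()),
    )
    return records, clinical, truth


def _piecewise_reversing_times(rng: np.random.Generator, lp: np.ndarray, baseline: float) -> np.ndarray:
    """Event times whose covariate effect flips sign mid-follow-up.

    Hazard is baseline*exp(+lp) before t0 and baseline*exp(-lp) after,
    where t0 is the median of the patients' individual median survival
    times, so roughly half the events occur under each regime.  Violates
    proportional hazards by construction (used to power the
    Schoenfeld-test checks).
    """
    h1 = baseline * np.exp(lp)
    t0 = float(np.median(np.log(2.0) / h1))
    h2 = baseline * np.exp(-lp)
    u = rng.random(lp.size)
    target = -np.log(u)  # cumulative hazard to reach
    h1_t0 = h1 * t0
    before = target <= h1_t0
    times = np.where(before, target / h1, t0 + (target - h1_t0) / h2)
    return times


def write_fixture_maf(records, path, dialect: MafDialect = GDC_DIALECT) -> None:
    """Write records as a GDC-dialect MAF readable by :func:`mfrsig.maf_io.read_maf`."""
    cols = dialect.required_columns
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.gene,
                        r.patient_id,
                        r.variant_classification,
                        str(r.trc),
                        str(r.tac),
                        str(r.nrc),
                        str(r.nac),
                    )
                )
                + "\n"
            )


def write_clinical(clinical, path) -> None:
    """Write clinical records as TSV (patient_id, time, vital_status)."""
    with open(path, "w") as fh:
        fh.write("patient_id\ttime\tvital_status\n")
        for c in clinical:
            status = "dead" if c.event else "alive"
            fh.write(f"{c.patient_id}\t{c.time!r}\t{status}\n")


def write_network(network: GeneNetwork, path) -> None:
    """Write the network as a 2-column TSV edge list (sorted, reproducible)."""
    rows = sorted(tuple(sorted(e)) for e in network.edges)
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")
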