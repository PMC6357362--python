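import numpy as np
import pytest

from mfrsig.maf_io import ClinicalRecord, MutationRecord
from mfrsig.profiles import ProfileKind, ProfileMatrix


def make_record(patient="P1", gene="GENE_A", vc="Missense_Mutation", trc=70, tac=30, nrc=98, nac=2):
    return MutationRecord(
        patient_id=patient, gene=gene, variant_classification=vc, trc=trc, tac=tac, nrc=nrc, nac=nac
    )


def make_profile(values, kind=ProfileKind.MFR, log2_applied=False, patients=None, genes=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ProfileMatrix(
        kind=ProfileKind(kind),
        patients=tuple(patients or (f"P{i:03d}" for i in range(n))),
        genes=tuple(genes or (f"G{j:03d}" for j in range(g))),
        values=values,
        log2_applied=log2_applied,
    )


def make_clinical(times, events, patients=None):
    patients = list(patients or (f"P{i:03d}" for i in range(len(times))))
    return [
        ClinicalRecord(patient_id=p, time=float(t), event=bool(e))
        for p, t, e in zip(patients, times, events)
    ]


def gaussian_survival_cohort(seed, n=200, n_genes=4, beta=None, baseline=0.02, censor_scale=60.0):
    """Continuous-covariate cohort with exponential PH survival (test helper)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, n_genes))
    beta = np.zeros(n_genes) if beta is None else np.asarray(beta, dtype=float)
    h = baseline * np.exp(x @ beta)
    t = rng.exponential(1.0 / h)
    c = rng.exponential(censor_scale, size=n)
    obs = np.minimum(t, c)
    event = t <= c
    prof = make_profile(x, kind=ProfileKind.MFR, log2_applied=True)
    clin = make_clinical(obs, event)
    return prof, clin


def brute_force_bh(p):
    """Step-up BH oracle: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@pytest.fixture
def toy_maf_path(tmp_path):
    """3-row MAF with the canonical read-count examples."""
    header = "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tt_ref_count\tt_alt_count\tn_ref_count\tn_alt_count"
    rows = [
        "GENE_A\tTCGA-AB-0001-01A\tMissense_Mutation\t70\t30\t98\t2",
        "GENE_B\tTCGA-AB-0002-01A\tMissense_Mutation\t50\t0\t100\t0",
        "GENE_A\tTCGA-AB-0003-01A\tNonsense_Mutation\t10\t5\t20\t1",
    ]
    p = tmp_path / "toy.maf"
    p.write_text("#version 1.0\n" + header + "\n" + "\n".join(rows) + "\n")
    return p
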