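"""Patient x gene somatic-mutation profile matrices.

Four representations of the same missense-mutation calls are supported:

* **BM** — binary: 1 iff the gene carries any missense mutation.
* **TMF** — tumor mutation frequency: the tumor alternate/reference
  read-count ratio ``TAC/TRC`` per mutation, mean-aggregated per gene.
* **MFR** — mutation frequency ratio: the tumor-to-normal ratio
  ``(TAC/TRC) / (NAC/NRC)`` per mutation, mean-aggregated per gene.
* **NETNORM** — network-normalized binary profiles (see
  :mod:`mfrsig.netnorm`; constructed from BM, not from records).

Unmutated patient-gene cells are 0 in every representation, before and
after the log2 transform of the continuous kinds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction

import numpy as np
import pandas as pd

from .maf_io import MutationRecord

logger = logging.getLogger(__name__)


class ProfileKind(str, Enum):
    BM = "BM"
    TMF = "TMF"
    MFR = "MFR"
    NETNORM = "NETNORM"


@dataclass(frozen=True)
class MutationFrequencies:
    """Per-mutation tumor/normal frequencies and their ratio.

    ``tmf = TAC/TRC`` and ``nmf = NAC/NRC`` are alternate/reference
    read-count ratios; ``mfr = tmf/nmf``.  When any of the four counts is
    zero the ratio is undefined or degenerate, so a Haldane–Anscombe
    continuity correction (+0.5 to all four counts) is applied and
    ``corrected`` is set.
    """

    tmf: float
    nmf: float
    mfr: float
    corrected: bool


def mutation_frequencies(record: MutationRecord) -> MutationFrequencies:
    """Compute TMF, NMF and their ratio MFR for one mutation.

    Uses exact rational arithmetic, so e.g. counts (70, 30, 98, 2) give
    MFR = 21 exactly.  Raises if the record has no tumor coverage.
    """
    if record.trc + record.tac < 1:
        raise ValueError("mutation has no tumor reads (trc + tac == 0)")
    corrected = min(record.trc, record.tac, record.nrc, record.nac) == 0
    if corrected:
        trc = Fraction(2 * record.trc + 1, 2)
        tac = Fraction(2 * record.tac + 1, 2)
        nrc = Fraction(2 * record.nrc + 1, 2)
        nac = Fraction(2 * record.nac + 1, 2)
    else:
        trc, tac, nrc, nac = (Fraction(v) for v in (record.trc, record.tac, record.nrc, record.nac))
    tmf = tac / trc
    nmf = nac / nrc
    mfr = tmf / nmf
    return MutationFrequencies(tmf=float(tmf), nmf=float(nmf), mfr=float(mfr), corrected=corrected)


@dataclass(frozen=True)
class ProfileMatrix:
    """A patient x gene profile matrix with its representation kind."""

    kind: ProfileKind
    patients: tuple[str, ...]
    genes: tuple[str, ...]
    values: np.ndarray
    log2_applied: bool = False

    def __post_init__(self) -> None:
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patient ids in profile matrix")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in profile matrix")
        if self.values.shape != (len(self.patients), len(self.genes)):
            raise ValueError("values shape does not match patients x genes")
        if self.kind in (ProfileKind.BM, ProfileKind.NETNORM):
            if self.log2_applied:
                raise ValueError("binary profiles cannot be log2-transformed")
            if self.values.size and not np.isin(self.values, (0, 1)).all():
                raise ValueError("binary profile contains non-0/1 values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.patients), columns=list(self.genes))

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.genes.index(gene)]

    def row(self, patient: str) -> np.ndarray:
        return self.values[self.patients.index(patient), :]

    def subset_patients(self, keep) -> "ProfileMatrix":
        keep = set(keep)
        idx = [i for i, p in enumerate(self.patients) if p in keep]
        return replace(
            self,
            patients=tuple(self.patients[i] for i in idx),
            values=self.values[idx, :],
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t")


def read_profile_tsv(path, kind: ProfileKind | str, log2_applied: bool = False) -> ProfileMatrix:
    """Read a profile matrix written by :meth:`ProfileMatrix.to_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ProfileMatrix(
        kind=ProfileKind(kind),
        patients=tuple(str(p) for p in df.index),
        genes=tuple(str(g) for g in df.columns),
        values=df.to_numpy(dtype=float),
        log2_applied=log2_applied,
    )


def build_profile(records, patients, kind: ProfileKind | str) -> ProfileMatrix:
    """Aggregate missense mutation records into a patient x gene matrix.

    BM: 1 iff the patient has >= 1 record in the gene.  TMF / MFR: the
    arithmetic mean of the per-mutation frequency / ratio over that
    patient-gene's records.  Genes are all genes observed in ``records``,
    sorted lexicographically; patients keep the given order and patients
    without records get all-zero rows.
    """
    kind = ProfileKind(kind)
    if kind is ProfileKind.NETNORM:
        raise ValueError("NETNORM profiles are derived from BM profiles; use mfrsig.netnorm")
    records = list(records)
    patients = tuple(patients)
    patient_index = {p: i for i, p in enumerate(patients)}
    for r in records:
        if r.patient_id not in patient_index:
            raise ValueError(f"record patient {r.patient_id!r} not in patient list")

    genes = tuple(sorted({r.gene for r in records}))
    gene_index = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(patients), len(genes)))

    if kind is ProfileKind.BM:
        for r in records:
            values[patient_index[r.patient_id], gene_index[r.gene]] = 1.0
    else:
        sums = np.zeros_like(values)
        counts = np.zeros_like(values)
        for r in records:
            f = mutation_frequencies(r)
            v = f.tmf if kind is ProfileKind.TMF else f.mfr
            i, j = patient_index[r.patient_id], gene_index[r.gene]
            sums[i, j] += v
            counts[i, j] += 1
        mask = counts > 0
        values[mask] = sums[mask] / counts[mask]

    return ProfileMatrix(kind=kind, patients=patients, genes=genes, values=values)


def filter_rare_genes(matrix: ProfileMatrix, reference_patients, min_fraction: float = 0.01) -> ProfileMatrix:
    """Drop genes mutated in fewer than ``min_fraction`` of reference patients.

    The threshold count is computed on ``reference_patients`` only (e.g.
    the training split) and the surviving gene set is what should be
    applied to both splits, so no validation information leaks into gene
    selection.  A gene is retained iff its nonzero count among reference
    patients is >= ``min_fraction * n_reference``.
    """
    reference_patients = set(reference_patients)
    if not reference_patients:
        raise ValueError("reference patient set is empty")
    if not reference_patients <= set(matrix.patients):
        raise ValueError("reference patients must be a subset of matrix patients")
    ref_idx = [i for i, p in enumerate(matrix.patients) if p in reference_patients]
    counts = (matrix.values[ref_idx, :] != 0).sum(axis=0)
    # tiny tolerance so 3 >= 0.01 * 300 holds despite binary float rounding
    threshold = min_fraction * len(ref_idx) - 1e-9
    keep = np.flatnonzero(counts >= threshold)
    logger.info("filter_rare_genes: kept %d of %d genes", len(keep), len(matrix.genes))
    return replace(
        matrix,
        genes=tuple(matrix.genes[j] for j in keep),
        values=matrix.values[:, keep],
    )


def log2_transform(matrix: ProfileMatrix) -> ProfileMatrix:
    """log2-transform the nonzero entries of a continuous profile.

    Zero cells mean "no mutation" and stay 0; a mutated cell with value 1
    (tumor frequency equal to normal) therefore also maps to 0.
    """
    if matrix.kind not in (ProfileKind.TMF, ProfileKind.MFR):
        raise ValueError(f"log2 transform applies to TMF/MFR profiles, not {matrix.kind.value}")
    if matrix.log2_applied:
        raise ValueError("profile is already log2-transformed")
    values = matrix.values.copy()
    nz = values != 0
    values[nz] = np.log2(values[nz])
    return replace(matrix, values=values, log2_applied=True)
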