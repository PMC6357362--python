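"""Reading somatic variant calls (MAF dialect), clinical tables, and cohort splitting.

MAF (Mutation Annotation Format) files are tab-separated, one somatic
mutation per row, with paired tumor/normal reference- and alternate-allele
read counts.  Only five semantic columns are required here: gene symbol,
sample barcode, variant classification, and the four read-count columns.
Column names follow the GDC convention by default and can be remapped via
:class:`MafDialect`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSENSE_LABEL = "Missense_Mutation"


class MafConfigurationError(ValueError):
    """A required column is missing or the dialect is inconsistent."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


@dataclass(frozen=True)
class MutationRecord:
    """One called somatic mutation for one patient.

    ``trc``/``tac`` are tumor reads supporting the reference/alternate
    allele; ``nrc``/``nac`` the same for the paired normal sample.
    """

    patient_id: str
    gene: str
    variant_classification: str
    trc: int
    tac: int
    nrc: int
    nac: int

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        for name in ("trc", "tac", "nrc", "nac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trc + self.tac < 1:
            raise ValueError("a called tumor mutation needs >= 1 covering read")


@dataclass(frozen=True)
class ClinicalRecord:
    """Overall-survival endpoint for one patient (time in days)."""

    patient_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("follow-up time must be >= 0")


@dataclass(frozen=True)
class CohortSplit:
    """Random train/validation partition of a patient cohort."""

    train_ids: frozenset[str]
    validation_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_ids & self.validation_ids:
            raise ValueError("train and validation sets must be disjoint")


@dataclass(frozen=True)
class MafDialect:
    """Mapping from semantic columns to physical MAF column names."""

    gene: str = "Hugo_Symbol"
    sample_barcode: str = "Tumor_Sample_Barcode"
    variant_classification: str = "Variant_Classification"
    t_ref_count: str = "t_ref_count"
    t_alt_count: str = "t_alt_count"
    n_ref_count: str = "n_ref_count"
    n_alt_count: str = "n_alt_count"
    # TCGA barcodes identify the patient in the first 12 characters
    # (TCGA-XX-YYYY); set to None to keep the full barcode.
    patient_id_length: int | None = 12

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (
            self.gene,
            self.sample_barcode,
            self.variant_classification,
            self.t_ref_count,
            self.t_alt_count,
            self.n_ref_count,
            self.n_alt_count,
        )

    def truncate(self, barcode: str) -> str:
        if self.patient_id_length is None:
            return barcode
        return barcode[: self.patient_id_length]


GDC_DIALECT = MafDialect()


@dataclass
class ParsedTable:
    """Records plus bookkeeping of rows dropped during parsing.

    Iterates and indexes like the underlying record list.
    """

    records: list
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def read_maf(path, dialect: MafDialect = GDC_DIALECT) -> ParsedTable:
    """Read a MAF-dialect file into :class:`MutationRecord` objects.

    Comment lines starting with ``#`` are skipped.  Rows whose read counts
    are missing or not non-negative integers are dropped and counted, as
    are rows with zero total tumor coverage (not a callable mutation).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required_columns if c not in df.columns]
    if missing:
        raise MafConfigurationError(
            f"MAF file {path} lacks required column(s): {', '.join(missing)}"
        )
    if df.empty:
        raise EmptyInputError(f"MAF file {path} contains no data rows")

    count_cols = [
        dialect.t_ref_count,
        dialect.t_alt_count,
        dialect.n_ref_count,
        dialect.n_alt_count,
    ]
    counts = df[count_cols].apply(pd.to_numeric, errors="coerce")
    ok = counts.notna().all(axis=1)
    ok &= (counts.fillna(-1) >= 0).all(axis=1)
    ok &= counts[dialect.t_ref_count].fillna(0) + counts[dialect.t_alt_count].fillna(0) >= 1
    ok &= df[dialect.gene].str.len() > 0

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("read_maf: dropped %d unparseable row(s) from %s", n_dropped, path)

    kept = df[ok]
    kept_counts = counts[ok].astype(np.int64)
    records = [
        MutationRecord(
            patient_id=dialect.truncate(row_barcode),
            gene=row_gene,
            variant_classification=row_vc,
            trc=int(trc),
            tac=int(tac),
            nrc=int(nrc),
            nac=int(nac),
        )
        for row_gene, row_barcode, row_vc, trc, tac, nrc, nac in zip(
            kept[dialect.gene],
            kept[dialect.sample_barcode],
            kept[dialect.variant_classification],
            kept_counts[dialect.t_ref_count],
            kept_counts[dialect.t_alt_count],
            kept_counts[dialect.n_ref_count],
            kept_counts[dialect.n_alt_count],
        )
    ]
    return ParsedTable(records=records, n_dropped=n_dropped)


def filter_missense(records, label: str = MISSENSE_LABEL) -> list[MutationRecord]:
    """Keep only missense calls (order preserved)."""
    records = list(records)
    kept = [r for r in records if r.variant_classification == label]
    if records and not kept:
        logger.warning("filter_missense: no %s records among %d inputs", label, len(records))
    return kept


@dataclass(frozen=True)
class ClinicalDialect:
    patient_id: str = "patient_id"
    time: str = "time"
    vital_status: str = "vital_status"
    # values (case-insensitive) mapped to event = True (death observed)
    event_labels: tuple[str, ...] = ("dead", "deceased", "1", "true", "yes")
    censored_labels: tuple[str, ...] = ("alive", "0", "false", "no")


def read_clinical(path, dialect: ClinicalDialect = ClinicalDialect(), sep: str | None = None) -> ParsedTable:
    """Read a clinical table into :class:`ClinicalRecord` objects.

    Patients with a missing or unparseable follow-up time, or an
    unrecognised vital status, are dropped and counted.  Duplicate patient
    identifiers raise a validation error.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in (dialect.patient_id, dialect.time, dialect.vital_status) if c not in df.columns]
    if missing:
        raise MafConfigurationError(
            f"clinical table {path} lacks required column(s): {', '.join(missing)}"
        )

    times = pd.to_numeric(df[dialect.time], errors="coerce")
    status = df[dialect.vital_status].str.strip().str.lower()
    is_event = status.isin(dialect.event_labels)
    is_censored = status.isin(dialect.censored_labels)
    ok = times.notna() & (times >= 0) & (is_event | is_censored)

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("read_clinical: dropped %d row(s) from %s", n_dropped, path)

    ids = df[dialect.patient_id][ok]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate patient id(s) in clinical table: {sorted(set(dup))}")

    records = [
        ClinicalRecord(patient_id=pid, time=float(t), event=bool(ev))
        for pid, t, ev in zip(ids, times[ok], is_event[ok])
    ]
    return ParsedTable(records=records, n_dropped=n_dropped)


#: training fraction implied by a 328/495 train/validation division
DEFAULT_TRAIN_FRACTION = 0.663


def split_cohort(patient_ids, train_fraction: float = DEFAULT_TRAIN_FRACTION, seed: int = 0) -> CohortSplit:
    """Random unstratified train/validation partition.

    ``floor(train_fraction * N)`` patients go to training.  Deterministic
    for a given seed (ids are sorted before shuffling so the result does
    not depend on input order).
    """
    ids = sorted(set(patient_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids)))
    train = frozenset(ids[i] for i in order[:n_train])
    validation = frozenset(ids[i] for i in order[n_train:])
    return CohortSplit(train_ids=train, validation_ids=validation, seed=seed)
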