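"""Ingest diagnosis tables, map codes to phecodes, and encode examples.

A participant is a set of phecodes plus age and sex (ethnicity is carried
for regressions but is not a model input). For a given query phecode, each
participant has exactly one of three statuses:

* **case** — the query phecode is in their record;
* **unknown** — the query is absent but an exclusion phecode of the query
  is present, or (for sex-restricted queries) the participant is the wrong
  sex to serve as a control;
* **control** — neither the query nor any exclusion is present and the sex
  restriction (if any) is satisfied.

Encoding hides the query phecode and all of its exclusions from the
many-hot diagnosis vector in every example — case, control, unknown, and
inference inputs alike — so the model can never read off the answer
(``mask_all_statuses=False`` restores hiding for cases only). Dates and
recurrence of codes are ignored: a code is a binary present/absent
indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vocabulary import SEX_ANY, SEX_FEMALE, SEX_MALE, PhecodeVocabulary, VocabularyError

STATUS_CASE = "case"
STATUS_CONTROL = "control"
STATUS_UNKNOWN = "unknown"


class FormatError(ValueError):
    """Raised when an input table lacks required columns."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One person's demographics plus their set of recorded phecodes."""

    id: str
    age: float
    sex: str  # "F" | "M"
    ethnicity: str
    phecodes: frozenset[str]

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        object.__setattr__(self, "phecodes", frozenset(self.phecodes))


@dataclass(frozen=True)
class EncodedExample:
    """Model-ready encoding of one (participant, query) pair."""

    diagnoses: np.ndarray  # many-hot (V,), query+exclusion positions zeroed
    query: np.ndarray  # one-hot (V,)
    demographics: np.ndarray  # (normalized age, sex indicator)
    label: int | None = None  # 1 case, 0 control, None at inference


@dataclass(frozen=True)
class AgeScaler:
    """Z-score scaler for age, fit on training participants and persisted
    with the model so inference uses the training-split statistics."""

    mean: float
    sd: float

    @classmethod
    def fit(cls, ages: np.ndarray) -> "AgeScaler":
        ages = np.asarray(ages, dtype=float)
        sd = float(ages.std())
        return cls(mean=float(ages.mean()), sd=sd if sd > 0 else 1.0)

    def transform(self, age) -> np.ndarray:
        return (np.asarray(age, dtype=float) - self.mean) / self.sd


def load_mapping(path) -> tuple[pd.DataFrame, list[str]]:
    """Load a source-code -> phecode mapping CSV.

    Returns the mapping (columns ``source_code``, ``phecode``; may be
    many-to-many) and an empty placeholder list filled in by
    :func:`map_diagnoses` with unmapped source codes.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"source_code", "phecode"} - set(df.columns)
    if missing:
        raise FormatError(f"mapping file missing columns: {sorted(missing)}")
    return df[["source_code", "phecode"]].dropna().drop_duplicates(ignore_index=True), []


def map_diagnoses(diagnoses: pd.DataFrame, mapping: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Apply a code mapping to a long diagnosis table.

    ``diagnoses`` has columns (participant_id, code). Returns the mapped
    long table (participant_id, phecode), deduplicated per participant,
    plus the sorted list of source codes with no mapping row (dropped).
    """
    missing = {"participant_id", "code"} - set(diagnoses.columns)
    if missing:
        raise FormatError(f"diagnosis table missing columns: {sorted(missing)}")
    merged = diagnoses.merge(mapping, left_on="code", right_on="source_code", how="left")
    unmapped = sorted(merged.loc[merged["phecode"].isna(), "code"].unique())
    mapped = (
        merged.dropna(subset=["phecode"])[["participant_id", "phecode"]]
        .drop_duplicates(ignore_index=True)
    )
    return mapped, unmapped


def records_from_tables(
    demographics: pd.DataFrame, diagnoses: pd.DataFrame, vocab: PhecodeVocabulary
) -> list[ParticipantRecord]:
    """Assemble ParticipantRecords from demographics + long phecode table."""
    missing = {"participant_id", "age", "sex"} - set(demographics.columns)
    if missing:
        raise FormatError(f"demographics table missing columns: {sorted(missing)}")
    by_pid: dict[str, set[str]] = {}
    for pid, code in zip(diagnoses["participant_id"], diagnoses["phecode"]):
        if code not in vocab:
            raise VocabularyError(f"diagnosis phecode {code!r} not in vocabulary")
        by_pid.setdefault(pid, set()).add(code)
    records = []
    for _, row in demographics.iterrows():
        pid = row["participant_id"]
        records.append(
            ParticipantRecord(
                id=pid,
                age=float(row["age"]),
                sex=str(row["sex"]),
                ethnicity=str(row.get("ethnicity", "unknown")),
                phecodes=frozenset(by_pid.get(pid, set())),
            )
        )
    return records


def status(record: ParticipantRecord, query: str, vocab: PhecodeVocabulary) -> str:
    """Case/control/unknown status of a record for a query phecode."""
    vocab.index(query)
    if query in record.phecodes:
        return STATUS_CASE
    if record.phecodes & vocab.exclusions_of(query):
        return STATUS_UNKNOWN
    restriction = vocab.sex_of(query)
    if restriction == SEX_FEMALE and record.sex != "F":
        return STATUS_UNKNOWN
    if restriction == SEX_MALE and record.sex != "M":
        return STATUS_UNKNOWN
    return STATUS_CONTROL


def status_matrix(code_matrix: np.ndarray, sex: np.ndarray, vocab: PhecodeVocabulary) -> np.ndarray:
    """Vectorized statuses for all (participant, phecode) pairs.

    Returns an int8 matrix (n, V): 1 case, 0 control, -1 unknown. Used by
    corpus construction and evaluation, where per-record calls would be
    quadratically slow.
    """
    n, v = code_matrix.shape
    excl = vocab.exclusion_matrix()  # (V, V): [q, e]
    has_exclusion = code_matrix @ excl.T.astype(np.int64) > 0  # (n, V)
    out = np.zeros((n, v), dtype=np.int8)
    out[code_matrix] = 1
    unknown = ~code_matrix & has_exclusion
    sex_f = sex == "F"
    for qi, code in enumerate(vocab.codes):
        restriction = vocab.sex_of(code)
        if restriction == SEX_FEMALE:
            unknown[:, qi] |= ~code_matrix[:, qi] & ~sex_f
        elif restriction == SEX_MALE:
            unknown[:, qi] |= ~code_matrix[:, qi] & sex_f
    out[unknown] = -1
    return out


def many_hot(phecodes, vocab: PhecodeVocabulary) -> np.ndarray:
    vec = np.zeros(len(vocab), dtype=np.float64)
    for code in phecodes:
        vec[vocab.index(code)] = 1.0
    return vec


def encode(
    record: ParticipantRecord,
    query: str,
    vocab: PhecodeVocabulary,
    scaler: AgeScaler,
    label: int | None = None,
    mask_all_statuses: bool = True,
) -> EncodedExample:
    """Encode one (record, query) pair for the model.

    The query position and all exclusion positions are zeroed in the
    diagnosis vector regardless of status (set ``mask_all_statuses=False``
    to mask cases only). Deterministic and independent of input code order.
    """
    diag = many_hot(record.phecodes, vocab)
    if mask_all_statuses or status(record, query, vocab) == STATUS_CASE:
        diag[vocab.masked_positions(query)] = 0.0
    qvec = np.zeros(len(vocab), dtype=np.float64)
    qvec[vocab.index(query)] = 1.0
    demo = np.asarray([float(scaler.transform(record.age)), 1.0 if record.sex == "F" else 0.0])
    return EncodedExample(diagnoses=diag, query=qvec, demographics=demo, label=label)


def decode(example: EncodedExample, vocab: PhecodeVocabulary) -> set[str]:
    """Recover the visible phecode set from an encoded example."""
    codes = np.asarray(vocab.codes, dtype=object)
    return set(codes[example.diagnoses > 0])


def encode_batch(
    code_matrix: np.ndarray,
    query_index: np.ndarray,
    ages: np.ndarray,
    sex: np.ndarray,
    vocab: PhecodeVocabulary,
    scaler: AgeScaler,
    mask_all_statuses: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized encoding: (diagnoses, query indices, demographics).

    ``code_matrix`` rows correspond to the examples (one row per example,
    already selected); masking zeroes each example's query + exclusion
    columns. When ``mask_all_statuses`` is False only rows carrying the
    query code are masked.
    """
    diag = code_matrix.astype(np.float64).copy()
    for qi in np.unique(query_index):
        rows = np.nonzero(query_index == qi)[0]
        if not mask_all_statuses:
            rows = rows[code_matrix[rows, qi]]
        cols = vocab.masked_positions(vocab.codes[qi])
        diag[np.ix_(rows, cols)] = 0.0
    demo = np.column_stack([scaler.transform(ages), (sex == "F").astype(np.float64)])
    return diag, np.asarray(query_index, dtype=np.intp), demo
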