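"""Balanced masked-diagnosis-modeling corpus and grouped CV splits.

For each eligible query phecode the corpus holds exactly ``k`` randomly
sampled cases and ``k`` randomly sampled controls (the reference design
uses k = 100). Phecodes with fewer than k cases or k eligible controls are
never used as queries but remain in the diagnosis features. Cross-validation
folds partition *participants*, not examples: a person who appears under
several queries contributes all of their examples to a single fold, so a
model can never score a held-out example by recognizing an individual from
training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotypes import status_matrix
from .synthetic import SyntheticCohort
from .vocabulary import PhecodeVocabulary


class CorpusError(ValueError):
    pass


@dataclass(frozen=True)
class CorpusConfig:
    k: int = 100  # cases per query = controls per query
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class TrainingExample:
    participant_id: str
    query: str
    label: int  # 1 case, 0 control
    fold: int | None = None


def eligible_phecodes(
    cohort: SyntheticCohort, k: int, vocab: PhecodeVocabulary | None = None
) -> list[str]:
    """Phecodes with at least ``k`` cases and ``k`` eligible controls.

    Excluded phecodes stay in the vocabulary as diagnosis features; they
    are only barred from serving as queries.
    """
    vocab = vocab or cohort.vocab
    st = status_matrix(cohort.code_matrix, cohort.sex_array(), vocab)
    n_cases = (st == 1).sum(axis=0)
    n_controls = (st == 0).sum(axis=0)
    keep = (n_cases >= k) & (n_controls >= k)
    return [code for code, ok in zip(vocab.codes, keep) if ok]


def sample_balanced(
    cohort: SyntheticCohort, queries: list[str], k: int, seed: int
) -> pd.DataFrame:
    """Sample exactly k cases and k controls per query, uniformly without
    replacement within each (query, label) stratum.

    A participant may appear under several queries. Returns a DataFrame
    with columns (participant_id, row, query, query_index, label).
    """
    vocab = cohort.vocab
    st = status_matrix(cohort.code_matrix, cohort.sex_array(), vocab)
    ids = cohort.participant_ids
    rng = np.random.default_rng(seed)
    frames = []
    for query in queries:
        qi = vocab.index(query)
        case_rows = np.nonzero(st[:, qi] == 1)[0]
        control_rows = np.nonzero(st[:, qi] == 0)[0]
        if len(case_rows) < k or len(control_rows) < k:
            raise CorpusError(
                f"query {query!r} is not eligible at k={k}: "
                f"{len(case_rows)} cases, {len(control_rows)} controls"
            )
        chosen_cases = np.sort(rng.choice(case_rows, size=k, replace=False))
        chosen_controls = np.sort(rng.choice(control_rows, size=k, replace=False))
        rows = np.concatenate([chosen_cases, chosen_controls])
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": ids[rows],
                    "row": rows,
                    "query": query,
                    "query_index": qi,
                    "label": np.concatenate([np.ones(k, np.int8), np.zeros(k, np.int8)]),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["participant_id", "row", "query", "query_index", "label"])
    return pd.concat(frames, ignore_index=True)


def split_cv(
    examples: pd.DataFrame,
    n_folds: int,
    seed: int = 0,
    tolerance: float = 0.10,
) -> pd.DataFrame:
    """Assign a fold to every example such that folds partition participants.

    Greedy longest-processing-time assignment: participants are sorted by
    their number of examples (descending, ties broken by id) and each is
    placed in the fold whose (case, control) tallies stay most balanced —
    the fold minimizing the summed squared tallies after the addition,
    ties broken by fold index. The assignment is deterministic; ``seed``
    is accepted for interface parity.

    Raises :class:`CorpusError` when the resulting per-fold case or control
    counts deviate from the uniform share by more than ``tolerance``,
    naming the heaviest participants (the usual culprits).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = (
        examples.groupby("participant_id")["label"]
        .agg(n_cases="sum", n_total="count")
        .reset_index()
    )
    counts["n_controls"] = counts["n_total"] - counts["n_cases"]
    counts = counts.sort_values(
        ["n_total", "participant_id"], ascending=[False, True], kind="mergesort"
    )
    fold_cases = np.zeros(n_folds, dtype=np.int64)
    fold_controls = np.zeros(n_folds, dtype=np.int64)
    assignment: dict[str, int] = {}
    for pid, n_cases, n_total, n_controls in counts[
        ["participant_id", "n_cases", "n_total", "n_controls"]
    ].itertuples(index=False):
        cost = (fold_cases + n_cases) ** 2 + (fold_controls + n_controls) ** 2
        f = int(np.argmin(cost))  # argmin keeps the lowest index on ties
        assignment[pid] = f
        fold_cases[f] += n_cases
        fold_controls[f] += n_controls
    out = examples.copy()
    out["fold"] = out["participant_id"].map(assignment).astype(np.int64)

    total_cases = int(examples["label"].sum())
    total_controls = len(examples) - total_cases
    share_cases = total_cases / n_folds
    share_controls = total_controls / n_folds
    per_fold = out.groupby("fold")["label"].agg(cases="sum", total="count")
    bad = []
    for f in range(n_folds):
        c = int(per_fold["cases"].get(f, 0))
        t = int(per_fold["total"].get(f, 0))
        if abs(c - share_cases) > tolerance * share_cases + 0.5 or abs(
            (t - c) - share_controls
        ) > tolerance * share_controls + 0.5:
            bad.append(f)
    if bad:
        heavy = counts.head(min(5, len(counts)))["participant_id"].tolist()
        raise CorpusError(
            f"cannot balance folds {bad} within ±{tolerance:.0%}; "
            f"heaviest participants: {heavy}"
        )
    return out


def build_corpus(cohort: SyntheticCohort, config: CorpusConfig) -> pd.DataFrame:
    """eligible queries -> balanced sample -> grouped folds, in one call."""
    queries = eligible_phecodes(cohort, config.k)
    examples = sample_balanced(cohort, queries, config.k, config.seed)
    if examples.empty:
        raise CorpusError(f"no eligible query phecodes at k={config.k}")
    return split_cv(examples, config.n_folds, config.seed)
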