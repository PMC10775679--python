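"""Screening-test metrics: confusion counts, diagnostic OR, and PPV.

Scores are binarized at a fixed probability threshold (0.95 by default in
the reference analysis): strictly greater than the threshold is a
predicted case, at-or-below is a predicted control. The diagnostic odds
ratio uses a 0.5 continuity correction on every cell,

    OR = ((TP + 0.5) / (FP + 0.5)) / ((FN + 0.5) / (TN + 0.5)),

so it is finite and positive for every count table. PPV is offered in two
modes: ``as_worded`` is the standard precision TP/(TP+FP) (the probability
that a positive prediction is a case), while ``as_printed`` reproduces the
sensitivity-form expression TP/(TP+FN) exactly as the source analysis
prints it; neither is asserted as the intended one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotypes import status_matrix
from .synthetic import SyntheticCohort

DEFAULT_THRESHOLD = 0.95


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def binarize(scores: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Predicted-case indicator: score strictly above the threshold."""
    return np.asarray(scores) > threshold


def confusion_counts(truth: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    truth = np.asarray(truth, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(truth & predicted)),
        fp=int(np.sum(~truth & predicted)),
        fn=int(np.sum(truth & ~predicted)),
        tn=int(np.sum(~truth & ~predicted)),
    )


def diagnostic_or(c: ConfusionCounts) -> float:
    """Continuity-corrected diagnostic odds ratio; always finite, positive."""
    return ((c.tp + 0.5) / (c.fp + 0.5)) / ((c.fn + 0.5) / (c.tn + 0.5))


def ppv(c: ConfusionCounts, mode: str = "as_worded") -> float:
    """Positive predictive value; returns NaN when the denominator is zero."""
    if mode == "as_worded":
        denom = c.tp + c.fp
    elif mode == "as_printed":
        denom = c.tp + c.fn
    else:
        raise ValueError("mode must be 'as_worded' or 'as_printed'")
    return c.tp / denom if denom else float("nan")


def evaluate_phecode(
    scores: pd.DataFrame,
    cohort: SyntheticCohort,
    query: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict:
    """Confusion counts, OR, and PPV for one query phecode.

    The evaluation set drops unknown-status participants (exclusion-code
    holders and sex-mismatched non-cases) and everyone flagged as a
    training-set member in the score table.
    """
    sub = scores[scores["query"] == query]
    if sub.empty:
        raise ValueError(f"query {query!r} absent from the score table")
    st = status_matrix(cohort.code_matrix, cohort.sex_array(), cohort.vocab)
    qi = cohort.vocab.index(query)
    status_by_id = pd.Series(st[:, qi], index=cohort.participant_ids)
    sub = sub[~sub["in_training"].astype(bool)]
    stat = status_by_id.reindex(sub["participant_id"]).to_numpy()
    keep = stat != -1
    truth = stat[keep] == 1
    predicted = binarize(sub["score"].to_numpy()[keep], threshold)
    c = confusion_counts(truth, predicted)
    return {
        "query": query,
        "counts": c,
        "odds_ratio": diagnostic_or(c),
        "ppv": ppv(c, "as_worded"),
        "ppv_as_printed": ppv(c, "as_printed"),
        "n_excluded": int(len(sub) - keep.sum()) + int(scores["query"].eq(query).sum() - len(sub)),
    }


def cross_phecode_matrix(
    models: list[tuple],
    cohort: SyntheticCohort,
    queries: list[str],
    threshold: float = DEFAULT_THRESHOLD,
    both_cases: str = "case_of_a",
) -> pd.DataFrame:
    """Odds-ratio matrix for distinguishing cases of one phecode from cases
    of another.

    ``models`` is a list of (params, training_ids) pairs (for example the
    cross-validation models); each cell reports the median OR across them.
    Cell (A, B) restricts to diagnosed cases of A or B (excluding each
    model's own training set), queries the model with A, and treats B's
    cases as controls. The diagonal and cells where B is an exclusion of A
    are blank (NaN). Participants who are cases of both A and B count as
    cases of A (``both_cases='case_of_a'``) or are dropped
    (``both_cases='dropped'``).
    """
    from .model import predict_all

    if len(queries) < 2:
        raise ValueError("cross-phecode matrix needs at least two queries")
    if both_cases not in ("case_of_a", "dropped"):
        raise ValueError("both_cases must be 'case_of_a' or 'dropped'")
    vocab = cohort.vocab
    diagnosed = {q: cohort.diagnosed(q) for q in queries}
    score_tables = [predict_all(params, cohort, queries, train_ids) for params, train_ids in models]
    mat = pd.DataFrame(np.nan, index=queries, columns=queries)
    for a in queries:
        excl_a = vocab.exclusions_of(a)
        for b in queries:
            if a == b or b in excl_a:
                continue
            ors = []
            for table in score_tables:
                sub = table[(table["query"] == a) & ~table["in_training"].astype(bool)]
                by_id = sub.set_index("participant_id")["score"]
                case_a = diagnosed[a]
                case_b = diagnosed[b]
                if both_cases == "dropped":
                    sel = case_a ^ case_b
                else:
                    sel = case_a | case_b
                ids = cohort.participant_ids[sel]
                truth = case_a[sel]
                s = by_id.reindex(ids)
                ok = s.notna().to_numpy()
                c = confusion_counts(truth[ok], binarize(s.to_numpy()[ok], threshold))
                ors.append(diagnostic_or(c))
            mat.loc[b, a] = float(np.median(ors))  # columns = case phecode A, rows = control phecode B
    return mat


def per_phecode_table(
    scores: pd.DataFrame,
    cohort: SyntheticCohort,
    queries: list[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    rows = []
    for q in queries:
        r = evaluate_phecode(scores, cohort, q, threshold)
        c = r["counts"]
        rows.append(
            {
                "phecode": q, "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                "odds_ratio": r["odds_ratio"], "ppv": r["ppv"],
                "ppv_as_printed": r["ppv_as_printed"], "n_excluded": r["n_excluded"],
            }
        )
    return pd.DataFrame(rows)
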