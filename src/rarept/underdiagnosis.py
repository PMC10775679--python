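"""Misclassification-corrected estimation of undiagnosed rare-disease cases.

For a disease phecode with associated laboratory tests, participants split
into three strata:

* **diagnosed cases** — the phecode is recorded;
* **confirmed controls** — labeled controls whose every associated test
  value lies inside the sex-specific reference range AND within one
  population SD of the sex-specific population mean (very unlikely to be
  undiagnosed cases);
* **unknowns** — everyone else, a mixture of undiagnosed cases and
  unconfirmed controls in unknown proportion.

Assuming the classifier's positive-prediction rate among unknowns is the
corresponding mixture of its rate on true cases (TPR, estimated from
diagnosed cases) and on true controls (FPR, estimated from confirmed
controls), the number of undiagnosed cases among the unknowns is

    Pu = (UP - FPR * U) / (TPR - FPR),

where U is the number of unknowns and UP the number of unknowns predicted
positive. Pu is clamped to [0, U] after the identifiability gate TPR > FPR;
TPR <= FPR means the classifier carries no signal and the estimator is
non-identifiable (raised, never silently clamped). Confidence intervals
come from a stratified participant bootstrap (resampling with replacement
within each of the three strata); replicates with TPR <= FPR are dropped
and counted, and estimation aborts if more than half degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import DEFAULT_THRESHOLD, binarize
from .phenotypes import status_matrix
from .synthetic import SyntheticCohort


class NonIdentifiableError(RuntimeError):
    """TPR <= FPR: the mixture proportion cannot be recovered."""


class EstimationUnstableError(RuntimeError):
    """More than half of bootstrap replicates were non-identifiable."""


@dataclass(frozen=True)
class UndiagnosedEstimate:
    phecode: str
    n_diagnosed: int
    n_confirmed_controls: int
    u: int  # unknown-status participants
    up: int  # unknowns predicted case
    tpr: float
    fpr: float
    pu: float  # estimated undiagnosed cases among unknowns
    fraction_undiagnosed: float  # Pu / (Pu + diagnosed)
    ci_low: float | None = None
    ci_high: float | None = None
    fraction_ci_low: float | None = None
    fraction_ci_high: float | None = None
    n_degenerate_reps: int = 0


def population_moments(cohort: SyntheticCohort, test_id: str) -> pd.DataFrame:
    """Per-sex mean and SD of a test over the full cohort ("population")."""
    values = cohort.test_results[test_id].to_numpy()
    sex = cohort.sex_array()
    rows = []
    for s in ("F", "M"):
        v = values[sex == s]
        rows.append({"sex": s, "mean": float(v.mean()), "sd": float(v.std())})
    return pd.DataFrame(rows).set_index("sex")


def confirmed_controls(
    cohort: SyntheticCohort, relationships: pd.DataFrame, query: str
) -> np.ndarray:
    """Boolean mask of biomarker-confirmed controls for ``query``.

    A participant qualifies iff their status is control and every test
    associated with the query is inside the sex-specific reference range
    and within 1 sex-specific population SD of the sex-specific mean.
    """
    rel = relationships[relationships["phecode"] == query]
    if rel.empty:
        raise ValueError(f"no test relationships for phecode {query!r}: estimation impossible")
    st = status_matrix(cohort.code_matrix, cohort.sex_array(), cohort.vocab)
    qi = cohort.vocab.index(query)
    mask = st[:, qi] == 0
    sex = cohort.sex_array()
    ranges = cohort.reference_ranges.set_index(["test_id", "sex"])
    for test_id in rel["test_id"].unique():
        values = cohort.test_results[test_id].to_numpy()
        moments = population_moments(cohort, test_id)
        ok = np.zeros(cohort.n, dtype=bool)
        for s in ("F", "M"):
            low, high = ranges.loc[(test_id, s), ["low", "high"]]
            mu, sd = moments.loc[s, "mean"], moments.loc[s, "sd"]
            sel = sex == s
            ok[sel] = (
                (values[sel] >= low)
                & (values[sel] <= high)
                & (np.abs(values[sel] - mu) <= sd)
            )
        mask &= ok
    return mask


def calibrate_rates(
    case_predictions: np.ndarray, control_predictions: np.ndarray
) -> tuple[float, float]:
    """TPR from diagnosed cases, FPR from confirmed controls (both as
    positive-prediction fractions)."""
    if len(case_predictions) == 0:
        raise ValueError("no diagnosed cases available to estimate TPR")
    if len(control_predictions) == 0:
        raise ValueError("no confirmed controls available to estimate FPR")
    return float(np.mean(case_predictions)), float(np.mean(control_predictions))


def estimate_undiagnosed(u: int, up: int, tpr: float, fpr: float) -> float:
    """Invert the mixture: Pu = (UP - FPR*U) / (TPR - FPR), clamped to [0, U]."""
    if not 0 <= up <= u:
        raise ValueError("UP must lie in [0, U]")
    if tpr <= fpr:
        raise NonIdentifiableError(
            f"TPR ({tpr:.4f}) must exceed FPR ({fpr:.4f}) for the estimator to be identifiable"
        )
    pu = (up - fpr * u) / (tpr - fpr)
    return float(min(max(pu, 0.0), u))


def _strata(cohort, scores, query, threshold):
    """Per-stratum predicted-positive indicator arrays for one query."""
    sub = scores[(scores["query"] == query) & ~scores["in_training"].astype(bool)]
    by_id = sub.set_index("participant_id")["score"]
    s = by_id.reindex(cohort.participant_ids)
    scored = s.notna().to_numpy()
    pred = binarize(np.where(scored, s.to_numpy(), 0.0), threshold)

    diagnosed = cohort.diagnosed(query) & scored
    confirmed = confirmed_controls(cohort, cohort.relationships, query) & scored & ~diagnosed
    unknown = scored & ~diagnosed & ~confirmed
    return pred[diagnosed], pred[confirmed], pred[unknown]


def estimate_for_query(
    cohort: SyntheticCohort,
    scores: pd.DataFrame,
    query: str,
    threshold: float = DEFAULT_THRESHOLD,
    n_boot: int = 0,
    seed: int = 0,
) -> UndiagnosedEstimate:
    """Full estimate for one phecode, optionally with bootstrap CIs."""
    pred_cases, pred_confirmed, pred_unknown = _strata(cohort, scores, query, threshold)
    tpr, fpr = calibrate_rates(pred_cases, pred_confirmed)
    u = len(pred_unknown)
    up = int(pred_unknown.sum())
    pu = estimate_undiagnosed(u, up, tpr, fpr)
    n_diag = len(pred_cases)
    est = UndiagnosedEstimate(
        phecode=query,
        n_diagnosed=n_diag,
        n_confirmed_controls=len(pred_confirmed),
        u=u,
        up=up,
        tpr=tpr,
        fpr=fpr,
        pu=pu,
        fraction_undiagnosed=pu / (pu + n_diag) if (pu + n_diag) > 0 else 0.0,
    )
    if n_boot:
        lo, hi, flo, fhi, n_degen = bootstrap_ci(
            pred_cases, pred_confirmed, pred_unknown, n_boot=n_boot, seed=seed
        )
        est = UndiagnosedEstimate(
            **{**est.__dict__, "ci_low": lo, "ci_high": hi,
               "fraction_ci_low": flo, "fraction_ci_high": fhi,
               "n_degenerate_reps": n_degen}
        )
    return est


def bootstrap_ci(
    pred_cases: np.ndarray,
    pred_confirmed: np.ndarray,
    pred_unknown: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float, float, int]:
    """Stratified participant bootstrap for (Pu, fraction undiagnosed).

    Resamples participants with replacement within each stratum, recomputes
    TPR, FPR, UP, and Pu per replicate, and returns percentile bounds.
    Replicates where TPR <= FPR are excluded and counted; more than 50%
    such replicates raises :class:`EstimationUnstableError`.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n_case, n_conf, n_unk = len(pred_cases), len(pred_confirmed), len(pred_unknown)
    # resampling a binary vector with replacement: draw indices explicitly
    tpr = pred_cases[rng.integers(0, n_case, size=(n_boot, n_case))].mean(axis=1)
    fpr = pred_confirmed[rng.integers(0, n_conf, size=(n_boot, n_conf))].mean(axis=1)
    up = pred_unknown[rng.integers(0, n_unk, size=(n_boot, n_unk))].sum(axis=1)
    ok = tpr > fpr
    n_degen = int(n_boot - ok.sum())
    if n_degen > n_boot // 2:
        raise EstimationUnstableError(
            f"{n_degen}/{n_boot} bootstrap replicates had TPR <= FPR"
        )
    pu = (up[ok] - fpr[ok] * n_unk) / (tpr[ok] - fpr[ok])
    pu = np.clip(pu, 0.0, n_unk)
    frac = np.where(pu + n_case > 0, pu / (pu + n_case), 0.0)
    lo, hi = np.percentile(pu, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    flo, fhi = np.percentile(frac, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), float(flo), float(fhi), n_degen


def estimates_table(
    cohort: SyntheticCohort,
    scores: pd.DataFrame,
    queries: list[str],
    threshold: float = DEFAULT_THRESHOLD,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    rows = []
    for i, q in enumerate(queries):
        est = estimate_for_query(cohort, scores, q, threshold, n_boot=n_boot, seed=seed + i)
        rows.append(est.__dict__)
    return pd.DataFrame(rows)
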