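"""Association scans linking case predictions to laboratory test results.

Each phecode-test relationship carries an expected direction (above,
below, or outside the reference range). Two regressions per relationship,
both controlling for age, sex, and self-reported ethnicity:

* ``logistic_abnormal`` — logistic regression of an abnormal-result
  indicator (abnormal in the expected direction) on the binary case
  prediction;
* ``linear_quantitative`` — linear regression of the quantitative value,
  z-scored per sex within the in-range subpopulation and sign-aligned so
  the expected direction of association is always positive.

Both can be run on everyone (``population='all'``) or excluding labeled
cases and exclusion-code holders (``'controls_only'``; the linear variant
additionally excludes abnormal results), which tests whether predictions
carry signal about people *not* yet diagnosed. A permutation null rewires
the phecode-test pairing uniformly at random and re-runs the scan; the
empirical p-value is (1 + #permutations with at least as many
Bonferroni-significant expected-direction associations) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .evaluation import DEFAULT_THRESHOLD, binarize
from .phenotypes import status_matrix
from .synthetic import SyntheticCohort

ALPHA = 0.05


class DegenerateStratumError(ValueError):
    pass


@dataclass(frozen=True)
class AssociationResult:
    phecode: str
    test_id: str
    analysis: str  # logistic_abnormal | linear_quantitative
    population: str  # all | controls_only
    coefficient: float
    p_value: float
    expected_direction: bool  # coefficient positive (outcomes are aligned)
    significant: bool  # p < 0.05 and expected direction
    bonferroni_significant: bool  # p < 0.05/family and expected direction
    family_size: int
    estimable: bool = True


def abnormal_indicator(values, direction: str, low: float, high: float) -> np.ndarray:
    """Abnormal-in-expected-direction indicator; range boundaries count as
    normal (strict inequalities)."""
    v = np.asarray(values, dtype=float)
    if direction == "above":
        return v > high
    if direction == "below":
        return v < low
    if direction == "outside":
        return (v < low) | (v > high)
    raise ValueError(f"unknown direction {direction!r}")


def _ranges_for(cohort: SyntheticCohort, test_id: str) -> dict[str, tuple[float, float]]:
    r = cohort.reference_ranges
    out = {}
    for s in ("F", "M"):
        row = r[(r["test_id"] == test_id) & (r["sex"] == s)]
        if row.empty:
            raise ValueError(f"no reference range for test {test_id!r}, sex {s!r}")
        out[s] = (float(row["low"].iloc[0]), float(row["high"].iloc[0]))
    return out


def abnormal_for_cohort(cohort: SyntheticCohort, test_id: str, direction: str) -> np.ndarray:
    ranges = _ranges_for(cohort, test_id)
    sex = cohort.sex_array()
    values = cohort.test_results[test_id].to_numpy()
    out = np.zeros(cohort.n, dtype=bool)
    for s, (low, high) in ranges.items():
        sel = sex == s
        out[sel] = abnormal_indicator(values[sel], direction, low, high)
    return out


def normalize_quantitative(cohort: SyntheticCohort, test_id: str, direction: str) -> np.ndarray:
    """Per-sex z-score using in-range statistics, then sign-align.

    The mean/SD are computed after excluding out-of-range individuals, but
    the resulting transform is applied to every value. Alignment: above ->
    unchanged, below -> negated, outside -> absolute value (so larger
    always means "more in the expected direction").
    """
    ranges = _ranges_for(cohort, test_id)
    sex = cohort.sex_array()
    values = cohort.test_results[test_id].to_numpy().astype(float)
    z = np.empty_like(values)
    for s, (low, high) in ranges.items():
        sel = sex == s
        in_range = sel & (values >= low) & (values <= high)
        if in_range.sum() < 2:
            raise DegenerateStratumError(f"fewer than 2 in-range values for sex {s!r}")
        mu = values[in_range].mean()
        sd = values[in_range].std(ddof=0)
        if sd == 0:
            raise DegenerateStratumError(f"zero variance in-range stratum for sex {s!r}")
        z[sel] = (values[sel] - mu) / sd
    if direction == "above":
        return z
    if direction == "below":
        return -z
    if direction == "outside":
        return np.abs(z)
    raise ValueError(f"unknown direction {direction!r}")


def _covariates(cohort: SyntheticCohort) -> pd.DataFrame:
    demo = cohort.participants
    cov = pd.DataFrame(
        {"age": demo["age"].to_numpy(), "sex_f": (demo["sex"] == "F").astype(float)}
    )
    eth = demo["ethnicity"].astype(str)
    largest = eth.value_counts().idxmax()  # reference category
    for level in sorted(eth.unique()):
        if level != largest:
            cov[f"eth_{level}"] = (eth == level).astype(float)
    return cov


def _fit(outcome, design, logistic: bool):
    import warnings

    try:
        with warnings.catch_warnings():
            # rare-outcome logistic fits routinely sit near quasi-separation;
            # non-convergence shows up as a huge SE, not a spurious positive
            warnings.simplefilter("ignore")
            if logistic:
                model = sm.Logit(outcome, design)
                res = model.fit(disp=0, maxiter=200)
            else:
                res = sm.OLS(outcome, design).fit()
        coef = float(res.params["prediction"])
        p = float(res.pvalues["prediction"])
        if not (np.isfinite(coef) and np.isfinite(p)):
            return None
        return coef, p
    except Exception:
        return None


def association_scan(
    predictions: pd.DataFrame,
    cohort: SyntheticCohort,
    relationships: pd.DataFrame,
    population: str = "all",
    analysis: str = "logistic_abnormal",
    threshold: float = DEFAULT_THRESHOLD,
) -> list[AssociationResult]:
    """Run one regression per phecode-test relationship.

    ``predictions`` is a score table from ``predict_all``; rows flagged
    ``in_training`` are dropped. Separation or non-convergence flags the
    result unestimable rather than dropping it. The Bonferroni family is
    the number of relationships scanned.
    """
    if population not in ("all", "controls_only"):
        raise ValueError("population must be 'all' or 'controls_only'")
    if analysis not in ("logistic_abnormal", "linear_quantitative"):
        raise ValueError("unknown analysis")
    logistic = analysis == "logistic_abnormal"
    family = len(relationships)
    st = status_matrix(cohort.code_matrix, cohort.sex_array(), cohort.vocab)
    cov = _covariates(cohort)
    id_to_row = pd.Series(np.arange(cohort.n), index=cohort.participant_ids)

    results = []
    for rel in relationships.itertuples(index=False):
        sub = predictions[
            (predictions["query"] == rel.phecode) & ~predictions["in_training"].astype(bool)
        ]
        rows = id_to_row.reindex(sub["participant_id"]).to_numpy()
        pred = binarize(sub["score"].to_numpy(), threshold).astype(float)

        if logistic:
            outcome_full = abnormal_for_cohort(cohort, rel.test_id, rel.direction).astype(float)
        else:
            outcome_full = normalize_quantitative(cohort, rel.test_id, rel.direction)
        keep = np.ones(len(rows), dtype=bool)
        if population == "controls_only":
            stat = st[rows, cohort.vocab.index(rel.phecode)]
            keep &= stat == 0  # drop cases and exclusion-holders
            if not logistic:
                keep &= ~abnormal_for_cohort(cohort, rel.test_id, rel.direction)[rows]
        if keep.sum() == 0:
            raise ValueError(
                f"empty analysis set for {rel.phecode}/{rel.test_id} with population={population!r}"
            )
        design = cov.iloc[rows[keep]].reset_index(drop=True).copy()
        design.insert(0, "prediction", pred[keep])
        design = sm.add_constant(design, has_constant="add")
        fit = _fit(pd.Series(outcome_full[rows[keep]]), design, logistic)
        if fit is None:
            results.append(
                AssociationResult(rel.phecode, rel.test_id, analysis, population,
                                  float("nan"), float("nan"), False, False, False,
                                  family, estimable=False)
            )
            continue
        coef, p = fit
        direction_ok = coef > 0
        results.append(
            AssociationResult(
                rel.phecode, rel.test_id, analysis, population, coef, p,
                direction_ok,
                significant=direction_ok and p < ALPHA,
                bonferroni_significant=direction_ok and p < ALPHA / family,
                family_size=family,
            )
        )
    return results


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def count_bonferroni_significant(results: list[AssociationResult]) -> int:
    return sum(r.bonferroni_significant for r in results)


def permutation_null(
    relationships: pd.DataFrame,
    predictions: pd.DataFrame,
    cohort: SyntheticCohort,
    n_perm: int = 100,
    seed: int = 0,
    population: str = "all",
    analysis: str = "logistic_abnormal",
    threshold: float = DEFAULT_THRESHOLD,
) -> dict:
    """Permutation null for the association scan.

    The phecode column of the relationship table is permuted uniformly at
    random ``n_perm`` times and the scan re-run; returns the observed
    Bonferroni-significant count, the per-permutation counts, and the
    empirical p-value (1 + #perm >= observed) / (n_perm + 1).
    """
    if relationships["phecode"].nunique() < 2 or relationships["test_id"].nunique() < 2:
        raise ValueError("permutation null needs >= 2 distinct phecodes and tests")
    observed = count_bonferroni_significant(
        association_scan(predictions, cohort, relationships, population, analysis, threshold)
    )
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_perm):
        perm = relationships.copy()
        perm["phecode"] = perm["phecode"].to_numpy()[rng.permutation(len(perm))]
        counts.append(
            count_bonferroni_significant(
                association_scan(predictions, cohort, perm, population, analysis, threshold)
            )
        )
    counts = np.asarray(counts)
    return {
        "observed": observed,
        "permutation_counts": counts,
        "empirical_p": float((1 + np.sum(counts >= observed)) / (n_perm + 1)),
    }
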