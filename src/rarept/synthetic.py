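"""Synthetic EHR cohort generator with known latent disease truth.

Real phecode-coded biobank data are access-restricted, so every downstream
stage (masked-diagnosis-model training, diagnostic OR/PPV evaluation, and
underdiagnosis estimation) is exercised here on generated cohorts in which
the latent true disease status of every participant is known exactly.

The generative model, per participant:

1. Sex ~ Bernoulli(female_prob); age ~ Uniform(age_range); ethnicity
   categorical (no effect on anything by default — present so
   covariate-adjusted regressions are exercisable).
2. For each disease spec, latent truth ~ Bernoulli(prevalence) among
   sex-eligible participants.
3. The disease's own phecode is recorded iff truth is 1 AND a
   Bernoulli(1 - underdiagnosis_rate) draw succeeds: underdiagnosis is
   Bernoulli thinning of the diagnosis process. By default no false
   diagnoses are emitted (diagnosed implies truth); an optional
   ``miscoding_rate`` adds false-positive codes for robustness studies.
4. Signature comorbidity codes are emitted independently given truth:
   Bernoulli(conditional) for true cases, Bernoulli(background) otherwise.
5. Test results are sex-specific unit-variance normals, shifted by the
   configured effect size (in population-SD units) for true cases:
   "above" shifts up, "below" shifts down, "outside" shifts by a random
   sign. Every participant has every test (recruitment-time assay model).

All draws come from one ``numpy`` Generator, so a (specs, n, vocab, seed)
tuple reproduces the cohort bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocabulary import SEX_ANY, SEX_FEMALE, SEX_MALE, PhecodeVocabulary, VocabularyError

DIRECTIONS = ("above", "below", "outside")


@dataclass(frozen=True)
class SignatureCode:
    """A comorbidity code emitted preferentially in true cases."""

    phecode: str
    conditional: float  # P(code | true disease)
    background: float  # P(code | no disease)

    def __post_init__(self) -> None:
        for p in (self.conditional, self.background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("signature probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class BiomarkerEffect:
    """Shift of a test value (in population SD units) in true cases."""

    test_id: str
    direction: str
    effect_size: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass(frozen=True)
class DiseaseSpec:
    """Data-generating assumptions for one (typically rare) disease."""

    phecode: str
    prevalence: float
    sex_restriction: str = SEX_ANY
    exclusion_phecodes: frozenset[str] = frozenset()
    signature: tuple[SignatureCode, ...] = ()
    underdiagnosis_rate: float = 0.0
    biomarker_effects: tuple[BiomarkerEffect, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if not 0.0 <= self.underdiagnosis_rate <= 1.0:
            raise ValueError("underdiagnosis_rate must lie in [0, 1]")
        if self.sex_restriction not in (SEX_ANY, SEX_FEMALE, SEX_MALE):
            raise ValueError(f"invalid sex_restriction {self.sex_restriction!r}")
        if self.phecode in self.exclusion_phecodes:
            raise ValueError("a phecode cannot be its own exclusion")
        object.__setattr__(self, "exclusion_phecodes", frozenset(self.exclusion_phecodes))
        object.__setattr__(self, "signature", tuple(self.signature))
        object.__setattr__(self, "biomarker_effects", tuple(self.biomarker_effects))


@dataclass
class SyntheticCohort:
    """A generated cohort with full latent ground truth.

    ``code_matrix`` is the recorded-diagnosis many-hot matrix (n, V) in
    vocabulary order; ``truth`` holds one boolean column per disease
    phecode. ``diagnosed`` status of a disease is simply its column of
    ``code_matrix``.
    """

    participants: pd.DataFrame  # participant_id, age, sex, ethnicity
    vocab: PhecodeVocabulary
    code_matrix: np.ndarray  # bool (n, V)
    truth: pd.DataFrame  # bool, one column per disease phecode
    test_results: pd.DataFrame  # one column per test id
    reference_ranges: pd.DataFrame  # test_id, sex, low, high
    relationships: pd.DataFrame  # phecode, test_id, direction
    specs: tuple[DiseaseSpec, ...] = field(default=())

    @property
    def n(self) -> int:
        return len(self.participants)

    @property
    def participant_ids(self) -> np.ndarray:
        return self.participants["participant_id"].to_numpy()

    def diagnosed(self, phecode: str) -> np.ndarray:
        return self.code_matrix[:, self.vocab.index(phecode)]

    def sex_array(self) -> np.ndarray:
        return self.participants["sex"].to_numpy()

    def phecode_sets(self) -> list[set[str]]:
        """Per-participant sets of recorded phecodes (vocabulary order)."""
        codes = np.asarray(self.vocab.codes, dtype=object)
        return [set(codes[row]) for row in self.code_matrix]

    def diagnoses_long(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.code_matrix)
        return pd.DataFrame(
            {
                "participant_id": self.participant_ids[rows],
                "phecode": np.asarray(self.vocab.codes, dtype=object)[cols],
            }
        )


DEFAULT_ETHNICITIES = ("white", "black", "asian", "mixed", "other")
DEFAULT_ETHNICITY_PROBS = (0.85, 0.05, 0.04, 0.03, 0.03)


def generate_cohort(
    specs: list[DiseaseSpec] | tuple[DiseaseSpec, ...],
    n: int,
    vocab: PhecodeVocabulary,
    seed: int,
    *,
    age_range: tuple[float, float] = (40.0, 70.0),
    female_prob: float = 0.5,
    ethnicities: tuple[str, ...] = DEFAULT_ETHNICITIES,
    ethnicity_probs: tuple[float, ...] = DEFAULT_ETHNICITY_PROBS,
    ref_range_sd: float = 1.5,
    sex_mean_shift: float = 0.0,
    miscoding_rate: float = 0.0,
) -> SyntheticCohort:
    """Generate a cohort of ``n`` participants under the given disease specs.

    ``ref_range_sd`` sets each test's sex-specific reference range to
    mean +/- ref_range_sd population SDs. ``sex_mean_shift`` offsets male
    test means to exercise sex-specific reference ranges. Deterministic
    given identical arguments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for spec in specs:
        for code in {spec.phecode, *spec.exclusion_phecodes, *(s.phecode for s in spec.signature)}:
            if code not in vocab:
                raise VocabularyError(f"spec references phecode {code!r} not in vocabulary")
        if n * spec.prevalence < 1:
            warnings.warn(
                f"expected case count for {spec.phecode} is below 1 "
                f"(n={n}, prevalence={spec.prevalence})",
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < female_prob, "F", "M")
    age = rng.uniform(age_range[0], age_range[1], size=n)
    ethnicity = rng.choice(np.asarray(ethnicities, dtype=object), size=n, p=ethnicity_probs)
    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
        }
    )

    code_matrix = np.zeros((n, len(vocab)), dtype=bool)
    truth = pd.DataFrame(index=participants.index)
    # signature codes may be shared between diseases: OR their draws together
    for spec in specs:
        eligible = np.ones(n, dtype=bool)
        if spec.sex_restriction == SEX_FEMALE:
            eligible = sex == "F"
        elif spec.sex_restriction == SEX_MALE:
            eligible = sex == "M"
        is_case = eligible & (rng.random(n) < spec.prevalence)
        truth[spec.phecode] = is_case
        diagnosed = is_case & (rng.random(n) >= spec.underdiagnosis_rate)
        if miscoding_rate > 0.0:
            diagnosed |= ~is_case & (rng.random(n) < miscoding_rate)
        code_matrix[:, vocab.index(spec.phecode)] |= diagnosed
        for sig in spec.signature:
            p = np.where(is_case, sig.conditional, sig.background)
            code_matrix[:, vocab.index(sig.phecode)] |= rng.random(n) < p

    # tests: sex-specific unit normals, shifted in true cases
    test_ids = sorted({e.test_id for spec in specs for e in spec.biomarker_effects})
    base_mean = {"F": 0.0, "M": sex_mean_shift}
    test_results = pd.DataFrame(index=participants.index)
    rel_rows = []
    for tid in test_ids:
        values = np.where(sex == "F", base_mean["F"], base_mean["M"]) + rng.standard_normal(n)
        for spec in specs:
            for eff in spec.biomarker_effects:
                if eff.test_id != tid:
                    continue
                is_case = truth[spec.phecode].to_numpy()
                if eff.direction == "above":
                    shift = eff.effect_size
                elif eff.direction == "below":
                    shift = -eff.effect_size
                else:  # outside: random sign per case
                    shift = np.where(rng.random(n) < 0.5, eff.effect_size, -eff.effect_size)
                values = values + np.where(is_case, 1.0, 0.0) * shift
                rel_rows.append({"phecode": spec.phecode, "test_id": tid, "direction": eff.direction})
        test_results[tid] = values

    reference_ranges = pd.DataFrame(
        [
            {
                "test_id": tid,
                "sex": s,
                "low": base_mean[s] - ref_range_sd,
                "high": base_mean[s] + ref_range_sd,
            }
            for tid in test_ids
            for s in ("F", "M")
        ],
        columns=["test_id", "sex", "low", "high"],
    )
    relationships = pd.DataFrame(rel_rows, columns=["phecode", "test_id", "direction"]).drop_duplicates(
        ignore_index=True
    )

    return SyntheticCohort(
        participants=participants,
        vocab=vocab,
        code_matrix=code_matrix,
        truth=truth,
        test_results=test_results,
        reference_ranges=reference_ranges,
        relationships=relationships,
        specs=tuple(specs),
    )


def ground_truth_summary(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-disease table of true, diagnosed, and undiagnosed case counts.

    ``undiagnosed = true - diagnosed`` and the underdiagnosis fraction is
    undiagnosed/true (0 when there are no true cases). Serves as the oracle
    against which the underdiagnosis estimator is validated.
    """
    rows = []
    for phecode in cohort.truth.columns:
        true_cases = int(cohort.truth[phecode].sum())
        diagnosed = int(cohort.diagnosed(phecode).sum())
        undiagnosed = true_cases - diagnosed
        rows.append(
            {
                "phecode": phecode,
                "true_cases": true_cases,
                "diagnosed_cases": diagnosed,
                "undiagnosed_cases": undiagnosed,
                "underdiagnosis_fraction": undiagnosed / true_cases if true_cases else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=[
        "phecode", "true_cases", "diagnosed_cases", "undiagnosed_cases", "underdiagnosis_fraction",
    ])


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write the cohort as the flat CSV files downstream commands read."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.csv", index=False)
    cohort.diagnoses_long().to_csv(out / "diagnoses.csv", index=False)
    truth = cohort.truth.copy()
    truth.insert(0, "participant_id", cohort.participant_ids)
    truth.to_csv(out / "truth.csv", index=False)
    results = cohort.test_results.copy()
    results.insert(0, "participant_id", cohort.participant_ids)
    results.to_csv(out / "test_results.csv", index=False)
    cohort.reference_ranges.to_csv(out / "reference_ranges.csv", index=False)
    cohort.relationships.to_csv(out / "relationships.csv", index=False)
    cohort.vocab.to_definitions().to_csv(out / "phecode_definitions.csv", index=False)
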