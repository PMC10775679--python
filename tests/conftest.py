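import numpy as np
import pandas as pd
import pytest

from rarept import (
    BiomarkerEffect,
    DiseaseSpec,
    PhecodeVocabulary,
    SignatureCode,
    generate_cohort,
)


def make_vocab(n: int, exclusions=None, sex_restriction=None) -> PhecodeVocabulary:
    codes = tuple(f"{i:05.1f}" for i in np.arange(1, n + 1))
    return PhecodeVocabulary(codes, exclusions or {}, sex_restriction or {})


def signature_specs(vocab, n_diseases, n_sig=5, prevalence=0.02, conditional=0.9,
                    background=0.05, underdiagnosis=0.0, biomarker_effect=None):
    """Diseases occupy the first vocabulary positions; each gets a disjoint
    block of signature codes after position n_diseases."""
    codes = list(vocab.codes)
    specs = []
    for d in range(n_diseases):
        sig = tuple(
            SignatureCode(codes[n_diseases + d * n_sig + j], conditional, background)
            for j in range(n_sig)
        )
        effects = ()
        if biomarker_effect is not None:
            effects = (BiomarkerEffect(f"test_{d}", "above", biomarker_effect),)
        specs.append(
            DiseaseSpec(
                phecode=codes[d],
                prevalence=prevalence,
                signature=sig,
                underdiagnosis_rate=underdiagnosis,
                biomarker_effects=effects,
            )
        )
    return specs


def signature_count_scores(cohort, specs, threshold_count=3):
    """Rule-based classifier: predicted case iff at least ``threshold_count``
    of the disease's signature codes are recorded. Emitted as a score table
    (1.0 / 0.0) compatible with the model's output format."""
    frames = []
    for spec in specs:
        idx = [cohort.vocab.index(s.phecode) for s in spec.signature]
        count = cohort.code_matrix[:, idx].sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": cohort.participant_ids,
                    "query": spec.phecode,
                    "score": (count >= threshold_count).astype(float),
                    "in_training": False,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_signature_cohort():
    """3 diseases, 40-code vocabulary, 2,000 participants; no underdiagnosis."""
    vocab = make_vocab(40)
    specs = signature_specs(vocab, 3, prevalence=0.05)
    cohort = generate_cohort(specs, 2000, vocab, seed=11)
    return cohort, specs
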