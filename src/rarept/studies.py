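"""End-to-end validation studies on synthetic cohorts with known truth.

These are the package's standard self-checks, each pairing a generated
cohort (whose latent disease status is known exactly) with a stage of the
pipeline and measuring how well the stage recovers the planted truth:

* :func:`learnability_study` — can the transformer learn planted
  comorbidity signatures well enough to yield high held-out diagnostic
  odds ratios at the 0.95 score threshold?
* :func:`no_signal_study` — the negative control: with training labels
  shuffled, held-out AUROC must sit at chance and ORs near 1.
* :func:`calibration_study` — does the 95% bootstrap interval of the
  undiagnosed-case estimator cover the true undiagnosed count at its
  nominal rate?
* :func:`estimator_identity_checks` — closed-form identities and
  forward-simulation inversion of the Pu estimator.
* :func:`permutation_null_study` — under a generator with no real
  phecode-test relationships, the scan's permutation p-value must be
  super-uniform.
* :func:`determinism_study` — every stage reproduces bit-identical output
  under a fixed seed.

Problem sizes are chosen so the whole battery runs in minutes on one CPU;
they are scaled-down analogues of the biobank-scale analysis, not
reproductions of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .corpus import CorpusConfig, build_corpus
from .evaluation import evaluate_phecode
from .model import ModelConfig, forward, predict_all, train
from .model import _encode_corpus
from .synthetic import (
    BiomarkerEffect,
    DiseaseSpec,
    SignatureCode,
    SyntheticCohort,
    generate_cohort,
)
from .underdiagnosis import confirmed_controls, estimate_for_query, estimate_undiagnosed
from .biomarkers import permutation_null
from .vocabulary import PhecodeVocabulary

# Shared study conditions: 10 rare diseases, each marked by a 5-code
# comorbidity signature (carried with probability 0.9 by true cases vs 0.05
# background); half the diseases also carry an exclusion phecode (their
# first signature code) so exclusion masking and unknown-status handling
# are exercised end to end.
N_DISEASES = 10
N_SIGNATURE = 5
SIGNATURE_CONDITIONAL = 0.9
SIGNATURE_BACKGROUND = 0.05


def _standard_vocab(size: int, with_exclusions: bool) -> PhecodeVocabulary:
    codes = tuple(f"{i:05.1f}" for i in np.arange(1, size + 1))
    exclusions = {}
    if with_exclusions:
        for d in range(N_DISEASES // 2):
            exclusions[codes[d]] = frozenset({codes[N_DISEASES + d * N_SIGNATURE]})
    return PhecodeVocabulary(codes, exclusions)


def standard_disease_specs(
    vocab: PhecodeVocabulary,
    prevalence: float = 0.02,
    underdiagnosis: float = 0.0,
    biomarker_effect: float | None = None,
) -> list[DiseaseSpec]:
    codes = list(vocab.codes)
    specs = []
    for d in range(N_DISEASES):
        sig = tuple(
            SignatureCode(
                codes[N_DISEASES + d * N_SIGNATURE + j],
                SIGNATURE_CONDITIONAL,
                SIGNATURE_BACKGROUND,
            )
            for j in range(N_SIGNATURE)
        )
        effects = ()
        if biomarker_effect is not None:
            effects = (BiomarkerEffect(f"test_{d}", "above", biomarker_effect),)
        specs.append(
            DiseaseSpec(
                phecode=codes[d],
                prevalence=prevalence,
                sex_restriction="any",
                exclusion_phecodes=vocab.exclusions_of(codes[d]),
                signature=sig,
                underdiagnosis_rate=underdiagnosis,
                biomarker_effects=effects,
            )
        )
    return specs


def standard_cohort(seed: int, n: int = 5000, vocab_size: int = 200,
                    with_exclusions: bool = True) -> tuple[SyntheticCohort, list[DiseaseSpec]]:
    vocab = _standard_vocab(vocab_size, with_exclusions)
    specs = standard_disease_specs(vocab)
    return generate_cohort(specs, n, vocab, seed=seed), specs


def signature_count_rule(cohort: SyntheticCohort, specs, threshold_count: int = 3) -> pd.DataFrame:
    """Score table from the rule `case iff >= threshold_count signature codes`.

    A transparent stand-in classifier used where a study validates the
    estimator rather than the transformer."""
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


def learnability_study(seed: int, n: int = 5000, vocab_size: int = 200, k: int = 50,
                       n_folds: int = 5, threshold: float = 0.95) -> dict:
    """Train the default small model on one CV split and evaluate held-out
    diagnostic ORs for the ten signatured disease queries."""
    cohort, specs = standard_cohort(seed, n=n, vocab_size=vocab_size)
    corpus = build_corpus(cohort, CorpusConfig(k=k, n_folds=n_folds, seed=seed))
    test_fold = 0
    train_corpus = corpus[corpus["fold"] != test_fold].reset_index(drop=True)
    params, history = train(ModelConfig(seed=seed), cohort, train_corpus,
                            seed=seed, test_fold=test_fold)
    queries = [s.phecode for s in specs]
    scores = predict_all(params, cohort, queries, set(train_corpus["participant_id"]))
    ors = {}
    for q in queries:
        ors[q] = evaluate_phecode(scores, cohort, q, threshold)["odds_ratio"]
    values = np.array(list(ors.values()))
    return {
        "per_query_or": ors,
        "n_or_above_5": int((values > 5).sum()),
        "median_or": float(np.median(values)),
        "history": history,
        "corpus": corpus,
        "cohort": cohort,
        "specs": specs,
        "scores": scores,
    }


def no_signal_study(seeds=(0, 1, 2), n: int = 5000, vocab_size: int = 200, k: int = 50,
                    threshold: float = 0.95) -> dict:
    """Shuffled-label negative control: held-out AUROC and per-query ORs."""
    aurocs = []
    all_ors = []
    for seed in seeds:
        cohort, specs = standard_cohort(seed, n=n, vocab_size=vocab_size)
        corpus = build_corpus(cohort, CorpusConfig(k=k, n_folds=5, seed=seed))
        test_fold = 0
        tr = corpus[corpus["fold"] != test_fold].reset_index(drop=True)
        te = corpus[corpus["fold"] == test_fold].reset_index(drop=True)
        rng = np.random.default_rng(seed)
        shuffled = rng.permutation(tr["label"].to_numpy()).astype(float)
        params, _ = train(ModelConfig(seed=seed), cohort, tr, seed=seed,
                          test_fold=test_fold, labels_override=shuffled)
        diag, qidx, demo, _ = _encode_corpus(cohort, te, params.scaler)
        s = forward(params, diag, qidx, demo)
        aurocs.append(float(roc_auc_score(te["label"].to_numpy(), s)))
        queries = [spec.phecode for spec in specs]
        scores = predict_all(params, cohort, queries, set(tr["participant_id"]))
        for q in queries:
            r = evaluate_phecode(scores, cohort, q, threshold)
            all_ors.append((r["odds_ratio"], r["counts"].tp + r["counts"].fp))
    # the continuity-corrected OR degenerates to (TN+.5)/(FN+.5) when the
    # classifier makes no confident positive prediction; enrichment is only
    # measurable on queries with a nonempty positive margin
    informative = [o for o, n_pos in all_ors if n_pos > 0]
    return {
        "aurocs": aurocs,
        "median_auroc": float(np.median(aurocs)),
        "n_queries_with_positives": len(informative),
        "median_or": float(np.median(informative)) if informative else float("nan"),
        "ors": all_ors,
    }


def calibration_study(seed: int, n_replicates: int = 100, n: int = 10_000,
                      prevalence: float = 0.02, underdiagnosis: float = 0.5,
                      biomarker_effect: float = 2.0, n_boot: int = 200) -> dict:
    """Coverage of the 95% bootstrap CI for the undiagnosed-case count.

    One disease per cohort; the classifier is the signature-count rule, so
    the study isolates the estimator (not the transformer). The coverage
    target is the count of true undiagnosed cases inside the unknown
    stratum — the estimand Pu addresses (unknowns exclude
    biomarker-confirmed controls by construction).
    """
    codes = tuple([f"{i:05.1f}" for i in range(1, 2 + N_SIGNATURE)])
    vocab = PhecodeVocabulary(codes)
    sig = tuple(SignatureCode(c, SIGNATURE_CONDITIONAL, SIGNATURE_BACKGROUND)
                for c in codes[1:])
    spec = DiseaseSpec(
        phecode=codes[0], prevalence=prevalence, signature=sig,
        underdiagnosis_rate=underdiagnosis,
        biomarker_effects=(BiomarkerEffect("biomarker", "above", biomarker_effect),),
    )
    covered = 0
    estimates, truths, fractions = [], [], []
    for rep in range(n_replicates):
        cohort = generate_cohort([spec], n, vocab, seed=seed + rep)
        scores = signature_count_rule(cohort, [spec])
        est = estimate_for_query(cohort, scores, spec.phecode, n_boot=n_boot,
                                 seed=seed + rep)
        truth = cohort.truth[spec.phecode].to_numpy()
        diagnosed = cohort.diagnosed(spec.phecode)
        confirmed = confirmed_controls(cohort, cohort.relationships, spec.phecode)
        true_pu = int((truth & ~diagnosed & ~confirmed).sum())
        if est.ci_low <= true_pu <= est.ci_high:
            covered += 1
        estimates.append(est.pu)
        truths.append(true_pu)
        fractions.append(est.fraction_undiagnosed)
    return {
        "n_replicates": n_replicates,
        "n_covered": covered,
        "coverage": covered / n_replicates,
        "mean_estimated_pu": float(np.mean(estimates)),
        "mean_true_pu": float(np.mean(truths)),
        "median_fraction_undiagnosed": float(np.median(fractions)),
    }


def estimator_identity_checks(seed: int, u: int = 10_000) -> dict:
    """Closed-form identities and forward-simulated inversion of Pu."""
    tpr, fpr = 0.9, 0.05
    at_fpr = estimate_undiagnosed(1000, int(round(fpr * 1000)), tpr, fpr)
    at_tpr = estimate_undiagnosed(1000, int(round(tpr * 1000)), tpr, fpr)
    rng = np.random.default_rng(seed)
    pu_true = 3000
    up = int(rng.binomial(pu_true, tpr) + rng.binomial(u - pu_true, fpr))
    pu_hat = estimate_undiagnosed(u, up, tpr, fpr)
    return {
        "pu_at_fpr_mixture": at_fpr,  # exact 0
        "pu_at_tpr_mixture": at_tpr,  # exact U
        "u": u,
        "planted_pu": pu_true,
        "recovered_pu": pu_hat,
        "relative_error": abs(pu_hat - pu_true) / pu_true,
    }


def permutation_null_study(seed: int, n_replicates: int = 50, n: int = 2000,
                           n_perm: int = 19) -> dict:
    """Empirical permutation p-values under a generator null.

    Four diseases with relationship rows but zero biomarker effect; the
    classifier is informative about the diseases, so the scan has realistic
    prediction structure yet no phecode-test signal. Super-uniformity of
    the empirical p across replicates is the validity property.
    """
    codes = tuple(f"{i:05.1f}" for i in range(1, 30))
    vocab = PhecodeVocabulary(codes)
    specs = []
    for d in range(4):
        sig = tuple(SignatureCode(codes[6 + d * N_SIGNATURE + j],
                                  SIGNATURE_CONDITIONAL, SIGNATURE_BACKGROUND)
                    for j in range(N_SIGNATURE))
        specs.append(DiseaseSpec(phecode=codes[d], prevalence=0.03, signature=sig,
                                 biomarker_effects=(BiomarkerEffect(f"t{d}", "above", 0.0),)))
    ps = []
    for rep in range(n_replicates):
        cohort = generate_cohort(specs, n, vocab, seed=seed + rep)
        scores = signature_count_rule(cohort, specs)
        null = permutation_null(cohort.relationships, scores, cohort,
                                n_perm=n_perm, seed=seed + rep)
        ps.append(null["empirical_p"])
    ps = np.asarray(ps)
    return {
        "p_values": ps,
        "mean_p": float(ps.mean()),
        "frac_p_le_005": float((ps <= 0.05).mean()),
        "frac_p_le_025": float((ps <= 0.25).mean()),
        "frac_p_le_05": float((ps <= 0.5).mean()),
    }


def determinism_study(seed: int) -> dict:
    """Re-run every stage twice with one seed; record bitwise equality."""
    from .underdiagnosis import bootstrap_ci

    checks = {}
    a, specs = standard_cohort(seed, n=1500, vocab_size=60)
    b, _ = standard_cohort(seed, n=1500, vocab_size=60)
    checks["cohort"] = bool(
        np.array_equal(a.code_matrix, b.code_matrix)
        and a.participants.equals(b.participants)
        and a.test_results.equals(b.test_results)
    )
    ca = build_corpus(a, CorpusConfig(k=20, n_folds=3, seed=seed))
    cb = build_corpus(b, CorpusConfig(k=20, n_folds=3, seed=seed))
    checks["corpus_and_folds"] = ca.equals(cb)
    cfg = ModelConfig(seed=seed, max_final_epochs=4)
    pa, ha = train(cfg, a, ca, seed=seed)
    pb, hb = train(cfg, b, cb, seed=seed)
    checks["training"] = ha["train_loss"] == hb["train_loss"] and all(
        np.array_equal(pa.weights[k], pb.weights[k]) for k in pa.weights
    )
    q = [specs[0].phecode]
    sa = predict_all(pa, a, q, set())
    sb = predict_all(pb, b, q, set())
    checks["scores"] = bool(np.array_equal(sa["score"].to_numpy(), sb["score"].to_numpy()))
    rng = np.random.default_rng(seed)
    strata = (rng.random(80) < 0.8, rng.random(300) < 0.05, rng.random(600) < 0.2)
    strata = tuple(s.astype(float) for s in strata)
    checks["bootstrap_ci"] = bootstrap_ci(*strata, n_boot=200, seed=seed) == bootstrap_ci(
        *strata, n_boot=200, seed=seed
    )
    checks["all"] = all(checks.values())
    return checks
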