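"""Query-conditioned transformer for masked diagnosis modeling.

The architecture treats a participant's whole many-hot diagnosis vector as
a *single* sequence position: the vector is projected to the embedding
dimension and passed through a stack of decoder blocks, each consisting of
a self-attention sublayer (no causal mask — there is no temporal order to
respect), a cross-attention sublayer attending to the embedded query
phecode, and a position-wise feed-forward sublayer, all with residual
connections and layer normalization. Demographics (z-scored age, sex
indicator) pass through one dense layer into vocabulary dimension, are
added to the output projection of the transformer stack, and the sum is
normalized. The scalar logit is the dot product of that adjusted output
with the one-hot query, and the probability score is its logistic
transform (the two-class softmax with a zero reference logit).

With one sequence position, softmax attention weights are identically 1,
so the query/key projections of both attention sublayers drop out of the
computation (they receive zero gradient); each attention sublayer is
implemented as its algebraic reduction, a value projection followed by an
output projection. Self-attention thus contributes a learned linear map of
the stream and cross-attention injects a learned per-query vector; the
feed-forward sublayer supplies the diagnosis-by-query interactions.

Everything is plain numpy with hand-written reverse-mode gradients and an
Adam optimizer; at the vocabulary sizes this package targets (hundreds of
phecodes, embedding widths in the tens) a CPU trains a model in seconds.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .phenotypes import AgeScaler, encode_batch
from .synthetic import SyntheticCohort
from .vocabulary import PhecodeVocabulary

_CHECKPOINT_TAG = "rarept-checkpoint-1"
_LN_EPS = 1e-5


class ModelError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are a small CPU-scale configuration; every field is tunable.
    The epoch budgets mirror the reference training procedure: up to 18
    epochs per candidate during tuning, up to 54 for the final model,
    early stopping when validation loss fails to improve for 5 consecutive
    epochs, and a 20% validation split drawn inside the training data.
    """

    embed_dim: int = 32
    n_decoder_blocks: int = 1
    n_heads: int = 2
    feedforward_dim: int = 64
    dropout: float = 0.0
    learning_rate: float = 1e-2
    batch_size: int = 64
    max_tuning_epochs: int = 18
    max_final_epochs: int = 54
    patience: int = 5
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        for name in ("embed_dim", "n_decoder_blocks", "n_heads", "feedforward_dim",
                     "batch_size", "max_tuning_epochs", "max_final_epochs", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def stable_hash(self) -> int:
        """Order-stable hash of the configuration (used to derive
        per-candidate seeds during tuning, so selection cannot depend on
        candidate ordering)."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return zlib.crc32(payload) & 0x7FFFFFFF


@dataclass
class RarePTParams:
    """Learned weights plus everything needed to reproduce the encoding:
    the architecture config, the vocabulary, and the age scaler."""

    config: ModelConfig
    vocab: PhecodeVocabulary
    scaler: AgeScaler
    weights: dict[str, np.ndarray] = field(default_factory=dict)

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights.items()}


def init_params(
    config: ModelConfig, vocab: PhecodeVocabulary, scaler: AgeScaler, rng: np.random.Generator
) -> RarePTParams:
    v, e, f = len(vocab), config.embed_dim, config.feedforward_dim

    def glorot(n_in, n_out):
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, size=(n_in, n_out))

    w: dict[str, np.ndarray] = {
        "W_in": glorot(v, e),
        "b_in": np.zeros(e),
        "W_out": glorot(e, v),
        "b_out": np.zeros(v),
        "W_dem": glorot(2, v),
        "b_dem": np.zeros(v),
        "lno_g": np.ones(v),
        "lno_b": np.zeros(v),
    }
    for i in range(config.n_decoder_blocks):
        w[f"b{i}_sa_Wv"] = glorot(e, e)
        w[f"b{i}_sa_Wo"] = glorot(e, e)
        w[f"b{i}_sa_bo"] = np.zeros(e)
        w[f"b{i}_ca_Wv"] = glorot(e, e)
        w[f"b{i}_ca_Wo"] = glorot(e, e)
        w[f"b{i}_ca_bo"] = np.zeros(e)
        w[f"b{i}_ff_W1"] = glorot(e, f)
        w[f"b{i}_ff_b1"] = np.zeros(f)
        w[f"b{i}_ff_W2"] = glorot(f, e)
        w[f"b{i}_ff_b2"] = np.zeros(e)
        for j in (1, 2, 3):
            w[f"b{i}_ln{j}_g"] = np.ones(e)
            w[f"b{i}_ln{j}_b"] = np.zeros(e)
    return RarePTParams(config=config, vocab=vocab, scaler=scaler, weights=w)


def _ln_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, (dy * xhat).sum(axis=0), dy.sum(axis=0)


def forward(
    params: RarePTParams,
    diag: np.ndarray,
    query_index: np.ndarray,
    demo: np.ndarray,
    *,
    train: bool = False,
    rng: np.random.Generator | None = None,
    want_cache: bool = False,
):
    """Probability scores in [0, 1] for a batch of encoded examples.

    Deterministic in evaluation mode; per-row, so batching cannot change
    the scores. Raises :class:`ModelError` on a non-finite activation,
    naming the block where it appeared.
    """
    w = params.weights
    cfg = params.config
    B = diag.shape[0]
    if diag.shape[1] != len(params.vocab):
        raise ModelError(
            f"diagnosis vectors have width {diag.shape[1]}, vocabulary has {len(params.vocab)}"
        )
    drop = cfg.dropout if train else 0.0
    cache: dict[str, object] = {"diag": diag, "qidx": query_index, "demo": demo, "blocks": []}

    h = diag @ w["W_in"] + w["b_in"]
    qe = w["W_in"][query_index] + w["b_in"]
    cache["h0"] = h
    cache["qe"] = qe
    for i in range(cfg.n_decoder_blocks):
        blk: dict[str, object] = {}
        sa = (h @ w[f"b{i}_sa_Wv"])
        blk["sv"] = sa
        sa = sa @ w[f"b{i}_sa_Wo"] + w[f"b{i}_sa_bo"]
        if drop > 0.0:
            mask = (rng.random(sa.shape) >= drop) / (1.0 - drop)
            sa = sa * mask
            blk["sa_mask"] = mask
        blk["h_pre"] = h
        h1, blk["ln1"] = _ln_forward(h + sa, w[f"b{i}_ln1_g"], w[f"b{i}_ln1_b"])
        cv = qe @ w[f"b{i}_ca_Wv"]
        blk["cv"] = cv
        ca = cv @ w[f"b{i}_ca_Wo"] + w[f"b{i}_ca_bo"]
        h2, blk["ln2"] = _ln_forward(h1 + ca, w[f"b{i}_ln2_g"], w[f"b{i}_ln2_b"])
        u = h2 @ w[f"b{i}_ff_W1"] + w[f"b{i}_ff_b1"]
        r = np.maximum(u, 0.0)
        f = r @ w[f"b{i}_ff_W2"] + w[f"b{i}_ff_b2"]
        if drop > 0.0:
            mask = (rng.random(f.shape) >= drop) / (1.0 - drop)
            f = f * mask
            blk["ff_mask"] = mask
        blk["h2"] = h2
        blk["u"] = u
        blk["r"] = r
        h3, blk["ln3"] = _ln_forward(h2 + f, w[f"b{i}_ln3_g"], w[f"b{i}_ln3_b"])
        if not np.isfinite(h3).all():
            raise ModelError(f"non-finite activation in decoder block {i}")
        h = h3
        cache["blocks"].append(blk)

    out = h @ w["W_out"] + w["b_out"]
    dadj = demo @ w["W_dem"] + w["b_dem"]
    z, cache["lno"] = _ln_forward(out + dadj, w["lno_g"], w["lno_b"])
    cache["h_final"] = h
    logit = z[np.arange(B), query_index]
    if not np.isfinite(logit).all():
        raise ModelError("non-finite logit at the output head")
    score = 1.0 / (1.0 + np.exp(-logit))
    cache["logit"] = logit
    return (score, cache) if want_cache else score


def _backward(params: RarePTParams, cache: dict, dlogit: np.ndarray) -> dict[str, np.ndarray]:
    w = params.weights
    cfg = params.config
    B = dlogit.shape[0]
    qidx = cache["qidx"]
    g: dict[str, np.ndarray] = {}

    dZ = np.zeros((B, len(params.vocab)))
    dZ[np.arange(B), qidx] = dlogit
    dsum, g["lno_g"], g["lno_b"] = _ln_backward(dZ, cache["lno"])
    g["W_dem"] = cache["demo"].T @ dsum
    g["b_dem"] = dsum.sum(axis=0)
    h = cache["h_final"]
    g["W_out"] = h.T @ dsum
    g["b_out"] = dsum.sum(axis=0)
    dh = dsum @ w["W_out"].T
    dqe = np.zeros_like(cache["qe"])

    for i in reversed(range(cfg.n_decoder_blocks)):
        blk = cache["blocks"][i]
        dx, g[f"b{i}_ln3_g"], g[f"b{i}_ln3_b"] = _ln_backward(dh, blk["ln3"])
        df = dx
        if "ff_mask" in blk:
            df = df * blk["ff_mask"]
        g[f"b{i}_ff_W2"] = blk["r"].T @ df
        g[f"b{i}_ff_b2"] = df.sum(axis=0)
        du = (df @ w[f"b{i}_ff_W2"].T) * (blk["u"] > 0)
        g[f"b{i}_ff_W1"] = blk["h2"].T @ du
        g[f"b{i}_ff_b1"] = du.sum(axis=0)
        dh2 = dx + du @ w[f"b{i}_ff_W1"].T
        dx2, g[f"b{i}_ln2_g"], g[f"b{i}_ln2_b"] = _ln_backward(dh2, blk["ln2"])
        dca = dx2
        g[f"b{i}_ca_Wo"] = blk["cv"].T @ dca
        g[f"b{i}_ca_bo"] = dca.sum(axis=0)
        dcv = dca @ w[f"b{i}_ca_Wo"].T
        g[f"b{i}_ca_Wv"] = cache["qe"].T @ dcv
        dqe += dcv @ w[f"b{i}_ca_Wv"].T
        dh1 = dx2
        dx1, g[f"b{i}_ln1_g"], g[f"b{i}_ln1_b"] = _ln_backward(dh1, blk["ln1"])
        dsa = dx1
        if "sa_mask" in blk:
            dsa = dsa * blk["sa_mask"]
        g[f"b{i}_sa_Wo"] = blk["sv"].T @ dsa
        g[f"b{i}_sa_bo"] = dsa.sum(axis=0)
        dsv = dsa @ w[f"b{i}_sa_Wo"].T
        g[f"b{i}_sa_Wv"] = blk["h_pre"].T @ dsv
        dh = dx1 + dsv @ w[f"b{i}_sa_Wv"].T

    g["W_in"] = cache["diag"].T @ dh
    np.add.at(g["W_in"], qidx, dqe)
    g["b_in"] = dh.sum(axis=0) + dqe.sum(axis=0)
    return g


def bce_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy (natural log)."""
    eps = 1e-12
    s = np.clip(scores, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(s) + (1 - labels) * np.log(1 - s)))


class _Adam:
    def __init__(self, weights: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr * gr
            weights[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _encode_corpus(cohort: SyntheticCohort, corpus: pd.DataFrame, scaler: AgeScaler,
                   mask_all_statuses: bool = True):
    rows = corpus["row"].to_numpy()
    qidx = corpus["query_index"].to_numpy(dtype=np.intp)
    ages = cohort.participants["age"].to_numpy()[rows]
    sex = cohort.sex_array()[rows]
    diag, qidx, demo = encode_batch(
        cohort.code_matrix[rows], qidx, ages, sex, cohort.vocab, scaler,
        mask_all_statuses=mask_all_statuses,
    )
    labels = corpus["label"].to_numpy(dtype=np.float64)
    return diag, qidx, demo, labels


def _run_epochs(params, opt, rng, diag, qidx, demo, labels, idx_train, idx_val,
                max_epochs, patience, batch_size):
    """Adam training loop with early stopping on validation loss.

    Returns (best_weights, history). history has per-epoch train/val loss
    and the selected best epoch (1-based).
    """
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = {k: v.copy() for k, v in params.weights.items()}
    best_epoch = 0
    since_best = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(idx_train)
        epoch_loss = 0.0
        for start in range(0, len(order), batch_size):
            b = order[start : start + batch_size]
            scores, cache = forward(
                params, diag[b], qidx[b], demo[b], train=True, rng=rng, want_cache=True
            )
            y = labels[b]
            epoch_loss += bce_loss(scores, y) * len(b)
            dlogit = (scores - y) / len(b)
            grads = _backward(params, cache, dlogit)
            opt.step(params.weights, grads)
        history["train_loss"].append(epoch_loss / len(order))
        if len(idx_val):
            val_scores = forward(params, diag[idx_val], qidx[idx_val], demo[idx_val])
            val_loss = bce_loss(val_scores, labels[idx_val])
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = {k: v.copy() for k, v in params.weights.items()}
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    return best_weights, history


def train(
    config: ModelConfig,
    cohort: SyntheticCohort,
    corpus: pd.DataFrame,
    seed: int | None = None,
    *,
    max_epochs: int | None = None,
    retrain_full: bool = False,
    test_fold: int | None = None,
    labels_override: np.ndarray | None = None,
) -> tuple[RarePTParams, dict]:
    """Train on a balanced corpus; returns best-epoch weights and history.

    A validation split of ``validation_fraction`` is drawn (by example)
    inside the provided corpus; early stopping monitors its binary
    cross-entropy with the configured patience and the weights of the best
    epoch are restored. With ``retrain_full=True`` the model is then
    re-initialized and trained on the complete corpus for the selected
    number of epochs. Pass ``test_fold`` to train on the complement of one
    CV fold; supplying a corpus that still contains that fold raises an
    error (leakage guard). ``labels_override`` substitutes training labels
    (used by permutation controls).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if test_fold is not None:
        if "fold" not in corpus.columns:
            raise ModelError("corpus has no fold column; run split_cv first")
        if (corpus["fold"] == test_fold).any():
            raise ModelError(f"corpus passed to train() still contains test fold {test_fold}")
    if corpus.empty:
        raise ModelError("corpus is empty")

    scaler = AgeScaler.fit(
        cohort.participants["age"].to_numpy()[corpus["row"].unique()]
    )
    diag, qidx, demo, labels = _encode_corpus(cohort, corpus, scaler)
    if labels_override is not None:
        labels = np.asarray(labels_override, dtype=np.float64)
        if labels.shape != (len(corpus),):
            raise ModelError("labels_override has the wrong length")

    n = len(corpus)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n))) if n > 1 else 0
    idx_val, idx_train = perm[:n_val], perm[n_val:]
    if len(idx_train) == 0:
        idx_train, idx_val = perm, np.array([], dtype=int)

    params = init_params(config, cohort.vocab, scaler, rng)
    opt = _Adam(params.weights, config.learning_rate)
    cap = config.max_final_epochs if max_epochs is None else max_epochs
    best_weights, history = _run_epochs(
        params, opt, rng, diag, qidx, demo, labels, idx_train, idx_val,
        cap, config.patience, config.batch_size,
    )
    params.weights = best_weights

    if retrain_full and history["best_epoch"] >= 1:
        rng2 = np.random.default_rng(seed + 1)
        params = init_params(config, cohort.vocab, scaler, rng2)
        opt = _Adam(params.weights, config.learning_rate)
        _, full_history = _run_epochs(
            params, opt, rng2, diag, qidx, demo, labels,
            np.arange(n), np.array([], dtype=int),
            history["best_epoch"], config.patience + history["best_epoch"], config.batch_size,
        )
        params.weights = {k: v.copy() for k, v in params.weights.items()}
        history["retrain_train_loss"] = full_history["train_loss"]
    return params, history


def tune(
    search_space: list[ModelConfig],
    cohort: SyntheticCohort,
    corpus: pd.DataFrame,
    budget_epochs: int | None = None,
) -> ModelConfig:
    """Successive-halving hyperparameter selection.

    All candidates are trained for a small epoch budget; the top third by
    validation loss survive, the budget triples, and the process repeats
    until one candidate remains. Per-candidate seeds derive from a stable
    hash of the candidate configuration, so the selection is invariant to
    the order in which candidates are listed.
    """
    if not search_space:
        raise ModelError("search space is empty")
    candidates = list(search_space)
    if len(candidates) == 1:
        return candidates[0]
    budget = budget_epochs or max(c.max_tuning_epochs for c in candidates)
    n_rounds = int(np.ceil(np.log(len(candidates)) / np.log(3)))
    epochs = max(1, budget // (3**n_rounds))
    while len(candidates) > 1:
        scored = []
        for cand in candidates:
            _, hist = train(cand, cohort, corpus, seed=cand.stable_hash(),
                            max_epochs=min(epochs, budget))
            scored.append((hist["best_val_loss"], cand.stable_hash(), cand))
        scored.sort(key=lambda t: (t[0], t[1]))
        keep = max(1, int(np.ceil(len(scored) / 3)))
        candidates = [c for _, _, c in scored[:keep]]
        epochs = min(budget, epochs * 3)
    return candidates[0]


def predict_all(
    params: RarePTParams,
    cohort: SyntheticCohort,
    queries: list[str],
    training_ids,
    batch_size: int = 4096,
) -> pd.DataFrame:
    """Score every participant for every query phecode.

    Rows for participants in ``training_ids`` are emitted but flagged
    ``in_training`` so downstream evaluation can exclude them. Prediction
    is batched to bound memory; batching does not change the scores.
    """
    training_ids = set(training_ids)
    vocab = params.vocab
    ids = cohort.participant_ids
    ages = cohort.participants["age"].to_numpy()
    sex = cohort.sex_array()
    in_training = np.fromiter((pid in training_ids for pid in ids), dtype=bool, count=len(ids))
    frames = []
    for query in queries:
        qi = vocab.index(query)
        scores = np.empty(cohort.n)
        for start in range(0, cohort.n, batch_size):
            sl = slice(start, min(start + batch_size, cohort.n))
            diag, qb, demo = encode_batch(
                cohort.code_matrix[sl],
                np.full(sl.stop - sl.start, qi, dtype=np.intp),
                ages[sl], sex[sl], vocab, params.scaler,
            )
            scores[sl] = forward(params, diag, qb, demo)
        frames.append(
            pd.DataFrame(
                {"participant_id": ids, "query": query, "score": scores, "in_training": in_training}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["participant_id", "query", "score", "in_training"])
    return pd.concat(frames, ignore_index=True)


def save_checkpoint(params: RarePTParams, path) -> None:
    """Single self-describing archive: weights + config + vocabulary + scaler."""
    meta = {
        "format": _CHECKPOINT_TAG,
        "config": asdict(params.config),
        "vocab": {
            "codes": list(params.vocab.codes),
            "exclusions": {k: sorted(v) for k, v in params.vocab.exclusions.items()},
            "sex_restriction": dict(params.vocab.sex_restriction),
        },
        "scaler": {"mean": params.scaler.mean, "sd": params.scaler.sd},
    }
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **params.weights)


def load_checkpoint(path) -> RarePTParams:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != _CHECKPOINT_TAG:
            raise ModelError(f"unrecognized checkpoint format: {meta.get('format')!r}")
        weights = {k: data[k] for k in data.files if k != "__meta__"}
    vocab = PhecodeVocabulary(
        tuple(meta["vocab"]["codes"]),
        {k: frozenset(v) for k, v in meta["vocab"]["exclusions"].items()},
        dict(meta["vocab"]["sex_restriction"]),
    )
    cfg = ModelConfig(**meta["config"])
    scaler = AgeScaler(**meta["scaler"])
    return RarePTParams(config=cfg, vocab=vocab, scaler=scaler, weights=weights)
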