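"""Gated attention-based multiple-instance learning for bag classification.

A bag (patient) is a variable-size set of instances (stool samples).  Each
instance is embedded by a two-layer fully connected network f_psi; the
embeddings are pooled by a weighted mean whose weights come from a gated
attention mechanism

    a_k = softmax_k( w^T ( tanh(V h_k) (*) sigm(U h_k) ) )

and the pooled embedding z = sum_k a_k h_k feeds a final linear layer with
a sigmoid, giving the Bernoulli parameter theta(X) for the bag label.
Training minimizes the (optionally class-weighted) Bernoulli negative
log-likelihood of the bag labels with Adam, early-stopped on a held-out
validation split.

The network is small enough that the whole forward/backward pass is
written directly in numpy; gradients are analytic and checked against
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from necmil.bags import PatientBag

__all__ = [
    "MILConfig",
    "MILParams",
    "MILEnsemble",
    "BagPrediction",
    "init_params",
    "embed",
    "gated_attention",
    "pool",
    "predict_bag",
    "bag_loss_and_grads",
    "train_mil",
    "train_ensemble",
    "cross_validate",
]

_PARAM_NAMES = ("W1", "b1", "W2", "b2", "V", "U", "w", "wc", "bc")


@dataclass
class MILConfig:
    """Hyperparameters of the MIL system.

    ``hidden`` and ``embed_dim`` (M) set the embedding network widths,
    ``attn_dim`` (L) the attention space.  ``gated=False`` removes the
    sigmoid gate, reducing the attention logit to w^T tanh(V h_k).
    """

    hidden: int = 128
    embed_dim: int = 64     # M
    attn_dim: int = 32      # L
    gated: bool = True
    lr: float = 5e-4
    weight_decay: float = 1e-2
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 16
    val_fraction: float = 0.15
    class_weight: bool = True
    seed: int = 0


@dataclass
class MILParams:
    W1: np.ndarray  # (d, hidden)
    b1: np.ndarray
    W2: np.ndarray  # (hidden, M)
    b2: np.ndarray
    V: np.ndarray   # (L, M)
    U: np.ndarray   # (L, M)
    w: np.ndarray   # (L,)
    wc: np.ndarray  # (M,)
    bc: float
    gated: bool = True

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "MILParams":
        return MILParams(
            **{n: np.array(getattr(self, n), dtype=float, copy=True) for n in _PARAM_NAMES},
            gated=self.gated,
        )

    def check_finite(self) -> None:
        for n in _PARAM_NAMES:
            if not np.all(np.isfinite(getattr(self, n))):
                raise ValueError(f"non-finite values in parameter {n}")


@dataclass
class BagPrediction:
    confidence: float
    attention: np.ndarray

    def __post_init__(self) -> None:
        self.attention = np.asarray(self.attention, dtype=float)
        if np.any(self.attention < 0) or abs(self.attention.sum() - 1.0) > 1e-6:
            raise ValueError("attention weights must be non-negative and sum to 1")


def init_params(n_features: int, config: MILConfig, rng: Optional[np.random.Generator] = None) -> MILParams:
    """He-scaled random initialization, deterministic per seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, m, l = config.hidden, config.embed_dim, config.attn_dim
    return MILParams(
        W1=rng.normal(0, np.sqrt(2.0 / n_features), (n_features, h)),
        b1=np.zeros(h),
        W2=rng.normal(0, np.sqrt(2.0 / h), (h, m)),
        b2=np.zeros(m),
        V=rng.normal(0, np.sqrt(1.0 / m), (l, m)),
        U=rng.normal(0, np.sqrt(1.0 / m), (l, m)),
        w=rng.normal(0, np.sqrt(1.0 / l), l),
        wc=rng.normal(0, np.sqrt(1.0 / m), m),
        bc=0.0,
        gated=config.gated,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def embed(x: np.ndarray, params: MILParams) -> np.ndarray:
    """Instance embedding h = f_psi(x); accepts one vector or a (k, d) matrix."""
    x = np.asarray(x, dtype=float)
    was_vector = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != params.n_features:
        raise ValueError(f"expected {params.n_features} features, got {x.shape[1]}")
    h1 = np.maximum(x @ params.W1 + params.b1, 0.0)
    h = np.maximum(h1 @ params.W2 + params.b2, 0.0)
    return h[0] if was_vector else h


def _attention_logits(H: np.ndarray, params: MILParams) -> np.ndarray:
    T = np.tanh(H @ params.V.T)
    if params.gated:
        T = T * _sigmoid(H @ params.U.T)
    return T @ params.w


def gated_attention(embeddings: np.ndarray, params: MILParams) -> np.ndarray:
    """Softmax attention weights over a bag's embeddings (max-subtracted)."""
    H = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if H.shape[0] == 0:
        raise ValueError("empty bag")
    e = _attention_logits(H, params)
    e = e - e.max()
    a = np.exp(e)
    return a / a.sum()


def pool(embeddings: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention-weighted mean z = sum_k a_k h_k."""
    H = np.atleast_2d(np.asarray(embeddings, dtype=float))
    a = np.asarray(a, dtype=float)
    if len(a) != H.shape[0]:
        raise ValueError("attention/embedding length mismatch")
    return a @ H


@dataclass
class MILEnsemble:
    """Average of independently initialized MIL models.

    Confidences and attention vectors are averaged member-wise; with a
    handful of members this damps the run-to-run variability of training
    on small cohorts without changing the model class.
    """

    members: List[MILParams]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty ensemble")


def predict_bag(bag, params) -> BagPrediction:
    """Bag confidence theta(X) in (0, 1) plus the attention vector.

    ``bag`` may be a :class:`PatientBag` or a (k, d) instance matrix, and
    ``params`` a :class:`MILParams` or :class:`MILEnsemble` (member-wise
    averaged prediction).  Permutation-invariant: shuffling instances
    permutes the attention and leaves the confidence unchanged.
    """
    if isinstance(params, MILEnsemble):
        preds = [predict_bag(bag, m) for m in params.members]
        att = np.mean([p.attention for p in preds], axis=0)
        return BagPrediction(
            confidence=float(np.mean([p.confidence for p in preds])),
            attention=att / att.sum(),
        )
    X = bag.matrix() if isinstance(bag, PatientBag) else np.atleast_2d(np.asarray(bag, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty bag")
    H = embed(X, params)
    a = gated_attention(H, params)
    z = pool(H, a)
    logit = float(z @ params.wc + params.bc)
    return BagPrediction(confidence=float(_sigmoid(np.array([logit]))[0]), attention=a)


# ---------------------------------------------------------------------------
# Batched training machinery.  Bags are concatenated instance-wise; per-bag
# reductions use np.add.reduceat over contiguous segments.


def _stack(bag_matrices: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    sizes = np.array([m.shape[0] for m in bag_matrices])
    X = np.concatenate(bag_matrices, axis=0)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    bag_id = np.repeat(np.arange(len(sizes)), sizes)
    return X, starts, bag_id


def _segment_softmax(e: np.ndarray, starts: np.ndarray, bag_id: np.ndarray) -> np.ndarray:
    m = np.maximum.reduceat(e, starts)
    ex = np.exp(e - m[bag_id])
    denom = np.add.reduceat(ex, starts)
    return ex / denom[bag_id]


def _forward(params: MILParams, X: np.ndarray, starts: np.ndarray, bag_id: np.ndarray) -> Dict[str, np.ndarray]:
    h1_pre = X @ params.W1 + params.b1
    h1 = np.maximum(h1_pre, 0.0)
    h_pre = h1 @ params.W2 + params.b2
    H = np.maximum(h_pre, 0.0)
    T = np.tanh(H @ params.V.T)
    if params.gated:
        S = _sigmoid(H @ params.U.T)
        G = T * S
    else:
        S = np.ones_like(T)
        G = T
    e = G @ params.w
    a = _segment_softmax(e, starts, bag_id)
    n_bags = len(starts)
    Z = np.zeros((n_bags, H.shape[1]))
    np.add.at(Z, bag_id, a[:, None] * H)
    logit = Z @ params.wc + params.bc
    p = _sigmoid(logit)
    return dict(h1_pre=h1_pre, h1=h1, h_pre=h_pre, H=H, T=T, S=S, G=G,
                a=a, Z=Z, logit=logit, p=p)


def bag_loss_and_grads(
    params: MILParams,
    bag_matrices: Sequence[np.ndarray],
    y: np.ndarray,
    sample_weight: Optional[np.ndarray] = None,
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Mean weighted Bernoulli NLL over bags plus analytic gradients."""
    X, starts, bag_id = _stack(bag_matrices)
    y = np.asarray(y, dtype=float)
    B = len(bag_matrices)
    wt = np.ones(B) if sample_weight is None else np.asarray(sample_weight, dtype=float)

    f = _forward(params, X, starts, bag_id)
    logit, p, a, H, Z = f["logit"], f["p"], f["a"], f["H"], f["Z"]
    # numerically stable BCE from logits
    bce = np.maximum(logit, 0) - logit * y + np.log1p(np.exp(-np.abs(logit)))
    loss = float(np.mean(wt * bce))

    dlogit = wt * (p - y) / B
    g: Dict[str, np.ndarray] = {}
    g["wc"] = Z.T @ dlogit
    g["bc"] = np.array(dlogit.sum())
    dZ = dlogit[:, None] * params.wc[None, :]
    dZi = dZ[bag_id]
    dH = a[:, None] * dZi
    da = np.einsum("ij,ij->i", H, dZi)
    s = np.add.reduceat(a * da, starts)
    de = a * (da - s[bag_id])
    dG = de[:, None] * params.w[None, :]
    g["w"] = f["G"].T @ de
    T, S = f["T"], f["S"]
    if params.gated:
        dT = dG * S
        dS = dG * T
        dS_pre = dS * S * (1.0 - S)
        g["U"] = dS_pre.T @ H
        dH += dS_pre @ params.U
    else:
        dT = dG
        g["U"] = np.zeros_like(params.U)
    dT_pre = dT * (1.0 - T * T)
    g["V"] = dT_pre.T @ H
    dH += dT_pre @ params.V
    dh_pre = dH * (f["h_pre"] > 0)
    g["W2"] = f["h1"].T @ dh_pre
    g["b2"] = dh_pre.sum(axis=0)
    dh1 = dh_pre @ params.W2.T
    dh1_pre = dh1 * (f["h1_pre"] > 0)
    g["W1"] = X.T @ dh1_pre
    g["b1"] = dh1_pre.sum(axis=0)
    return loss, g


def _batch_loss(params: MILParams, bag_matrices, y, wt) -> float:
    X, starts, bag_id = _stack(bag_matrices)
    f = _forward(params, X, starts, bag_id)
    logit = f["logit"]
    bce = np.maximum(logit, 0) - logit * y + np.log1p(np.exp(-np.abs(logit)))
    return float(np.mean(wt * bce))


class _Adam:
    def __init__(self, params: MILParams, lr: float, weight_decay: float) -> None:
        self.lr = lr
        self.wd = weight_decay
        self.t = 0
        self.m = {n: np.zeros_like(np.asarray(getattr(params, n), dtype=float)) for n in _PARAM_NAMES}
        self.v = {n: np.zeros_like(np.asarray(getattr(params, n), dtype=float)) for n in _PARAM_NAMES}

    def step(self, params: MILParams, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for n in _PARAM_NAMES:
            g = np.asarray(grads[n], dtype=float)
            if self.wd and not n.startswith("b"):
                g = g + self.wd * np.asarray(getattr(params, n), dtype=float)
            self.m[n] = b1 * self.m[n] + (1 - b1) * g
            self.v[n] = b2 * self.v[n] + (1 - b2) * g * g
            mhat = self.m[n] / (1 - b1 ** self.t)
            vhat = self.v[n] / (1 - b2 ** self.t)
            new = np.asarray(getattr(params, n), dtype=float) - self.lr * mhat / (np.sqrt(vhat) + eps)
            setattr(params, n, new if new.ndim else float(new))


def _class_weights(labels: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled:
        return np.ones(len(labels))
    n, n_pos = len(labels), labels.sum()
    n_neg = n - n_pos
    w = np.where(labels == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w


def train_mil(
    train_bags: Sequence[PatientBag],
    config: Optional[MILConfig] = None,
    seed: Optional[int] = None,
) -> MILParams:
    """Fit the gated-attention MIL classifier on labeled bags.

    Minimizes the class-weighted Bernoulli negative log-likelihood with
    Adam over shuffled minibatches of bags; early stopping tracks the loss
    on an internal stratified validation split (patience epochs without
    improvement) and the best-validation parameters are returned.  Fully
    deterministic given the seed.
    """
    config = config or MILConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    labels = np.array([b.label for b in train_bags], dtype=float)
    if labels.min() == labels.max():
        raise ValueError("training bags must include both classes")
    rng = np.random.default_rng(config.seed)
    mats = [b.matrix() for b in train_bags]
    n = len(mats)

    # internal stratified validation split for early stopping
    n_val = int(round(config.val_fraction * n))
    can_split = n_val >= 2 and labels.sum() >= 2 and (n - labels.sum()) >= 2
    if can_split:
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=n_val, random_state=int(rng.integers(2**31 - 1))
        )
        tr_idx, va_idx = next(splitter.split(np.zeros(n), labels))
    else:
        tr_idx, va_idx = np.arange(n), np.arange(n)

    tr_mats = [mats[i] for i in tr_idx]
    tr_y = labels[tr_idx]
    va_mats = [mats[i] for i in va_idx]
    va_y = labels[va_idx]
    tr_wt = _class_weights(tr_y, config.class_weight)
    va_wt = _class_weights(va_y, config.class_weight)
    if tr_y.min() == tr_y.max():  # degenerate split; fall back to all bags
        tr_mats, tr_y = mats, labels
        tr_wt = _class_weights(tr_y, config.class_weight)

    params = init_params(mats[0].shape[1], config, rng)
    opt = _Adam(params, config.lr, config.weight_decay)
    best = params.copy()
    best_val = np.inf
    stale = 0
    order = np.arange(len(tr_mats))
    for _epoch in range(config.max_epochs):
        rng.shuffle(order)
        for i0 in range(0, len(order), config.batch_size):
            idx = order[i0 : i0 + config.batch_size]
            _, grads = bag_loss_and_grads(
                params, [tr_mats[i] for i in idx], tr_y[idx], tr_wt[idx]
            )
            opt.step(params, grads)
        val = _batch_loss(params, va_mats, va_y, va_wt)
        if val < best_val - 1e-6:
            best_val = val
            best = params.copy()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    best.check_finite()
    return best


def train_ensemble(
    train_bags: Sequence[PatientBag],
    config: Optional[MILConfig] = None,
    seed: int = 0,
    n_models: int = 3,
) -> MILEnsemble:
    """Train ``n_models`` independently seeded MIL models on the same bags."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return MILEnsemble([
        train_mil(train_bags, config=config, seed=seed + 997 * m)
        for m in range(n_models)
    ])


def cross_validate(
    bags: Sequence[PatientBag],
    n_trials: int = 5,
    seed: int = 0,
    test_fraction: float = 0.2,
    config: Optional[MILConfig] = None,
) -> Tuple[pd.DataFrame, List[Dict]]:
    """Stratified repeated train/test evaluation of the MIL classifier.

    Runs ``n_trials`` independent stratified splits (default 80/20), trains
    on each training portion (model selection via the internal validation
    split of :func:`train_mil`) and scores the held-out bags.  Returns a
    per-trial metrics table (with mean and 95% CI rows accessible via
    ``df.attrs``) and, per trial, the fitted parameters and split indices.
    """
    from necmil.evaluate import roc_pr  # deferred to avoid import cycle

    labels = np.array([b.label for b in bags])
    if labels.sum() < 2 or (len(labels) - labels.sum()) < 2:
        raise ValueError("need at least two bags of each class for stratified trials")
    splitter = StratifiedShuffleSplit(n_splits=n_trials, test_size=test_fraction, random_state=seed)
    rows = []
    details: List[Dict] = []
    for trial, (tr, te) in enumerate(splitter.split(np.zeros(len(bags)), labels)):
        params = train_mil([bags[i] for i in tr], config=config, seed=seed * 1000 + trial)
        scores = np.array([predict_bag(bags[i], params).confidence for i in te])
        roc, pr = roc_pr(scores, labels[te])
        rows.append({"trial": trial, "roc_auc": roc.auc, "pr_auc": pr.auc})
        details.append({"params": params, "train_idx": tr, "test_idx": te, "scores": scores})
    df = pd.DataFrame(rows)
    for col in ("roc_auc", "pr_auc"):
        vals = df[col].to_numpy()
        mean = vals.mean()
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        df.attrs[f"{col}_mean"] = mean
        df.attrs[f"{col}_ci95"] = (mean - half, mean + half)
    return df, details
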