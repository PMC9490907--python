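"""Attention-based multiple-instance learning for slide classification.

A slide is a bag of tile feature vectors h_k with one bag-level label
(cognitively impaired or not) and no tile labels.  A shared projection
embeds each tile, a gated attention network scores it,

    e_k = w^T ( tanh(V h_k) (*) sigmoid(U h_k) ),     a = softmax(e),

and the slide representation z = sum_k a_k h_k feeds a linear classifier.
Training minimizes bag cross-entropy plus an optional instance-clustering
term: the top-B and bottom-B attention tiles receive binary pseudo-labels
(top tiles of an impaired bag positive, bottom tiles and top tiles of
unimpaired bags negative) under an auxiliary instance classifier, which
regularizes the shared embedding.

The network is small, so forward and backward passes are written directly
in numpy and optimized with Adam (one bag per step).  Input features are
standardized per dimension (statistics fitted on the training bags and
stored with the model), and a decoupled per-step weight decay keeps the
attention logits moderate so attention spreads over the evidence-bearing
compartment instead of collapsing onto a single tile.  Evaluation uses
Monte Carlo cross-validation: independent stratified 80/10/10 splits per
fold, early stopping on the validation set, AUC and balanced accuracy on
the test set, and a one-sample Wilcoxon signed-rank test (normal
approximation with continuity correction) of the per-fold AUCs against the
chance value 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve

from .config import MILConfig
from .tiling import FeatureBag

__all__ = [
    "AttentionMILModel",
    "attention_pool",
    "predict_slide",
    "SplitPlan",
    "make_splits",
    "train",
    "auc_score",
    "balanced_accuracy",
    "evaluate",
    "FoldEval",
    "EvalResult",
    "aggregate_folds",
    "run_cross_validation",
    "wilcoxon_vs_null",
]


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class AttentionMILModel:
    """Weights of the attention-MIL network; see the module docstring.

    Parameters: shared projection ``W_p, b_p`` (D -> M, ReLU), attention
    ``V, U`` (M -> A) and ``w`` (A,), bag classifier ``W_c, b_c`` (M -> 2),
    instance classifier ``W_i, b_i`` (M -> 2).
    """

    params: dict[str, np.ndarray]
    config: MILConfig
    trained: bool = False

    @classmethod
    def init(cls, input_dim: int, config: MILConfig, seed: int = 0) -> "AttentionMILModel":
        rng = np.random.default_rng(seed)
        m, a = config.embed_dim, config.attn_dim

        def glorot(shape):
            scale = np.sqrt(2.0 / sum(shape))
            return rng.normal(0.0, scale, size=shape)

        params = {
            "W_p": glorot((m, input_dim)), "b_p": np.zeros(m),
            "V": glorot((a, m)), "U": glorot((a, m)), "w": glorot((a,)),
            "W_c": np.zeros((2, m)), "b_c": np.zeros(2),
            "W_i": np.zeros((2, m)), "b_i": np.zeros(2),
            # per-dimension feature standardization, fitted on the training
            # bags (identity until then); not touched by the optimizer
            "feat_mu": np.zeros(input_dim), "feat_sd": np.ones(input_dim),
        }
        return cls(params=params, config=config)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {"config": self.config.__dict__ | {"fractions": list(self.config.fractions)},
                "trained": self.trained}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AttentionMILModel":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = dict(meta["config"])
        cfg["fractions"] = tuple(cfg["fractions"])
        return cls(params={k: arrays[k] for k in arrays.files},
                   config=MILConfig(**cfg), trained=meta["trained"])


def _forward(model: AttentionMILModel, features: np.ndarray,
             dropout_mask: Optional[np.ndarray] = None) -> dict:
    """Forward pass; returns all intermediates needed for backprop."""
    if not np.all(np.isfinite(features)):
        raise ValueError("NaN or Inf in bag features")
    p = model.params
    features = (features - p["feat_mu"]) / p["feat_sd"]
    pre = features @ p["W_p"].T + p["b_p"]       # (K, M)
    hidden = np.maximum(pre, 0.0)
    if dropout_mask is not None:
        hidden = hidden * dropout_mask
    t = np.tanh(hidden @ p["V"].T)               # (K, A)
    if model.config.gated:
        s = _sigmoid(hidden @ p["U"].T)
        gate = t * s
    else:
        s = None
        gate = t
    logits_k = gate @ p["w"]                     # (K,)
    attn = _softmax(logits_k)
    z = attn @ hidden                            # (M,)
    bag_logits = p["W_c"] @ z + p["b_c"]         # (2,)
    prob = _softmax(bag_logits)
    return {"x": features, "pre": pre, "hidden": hidden, "t": t, "s": s, "gate": gate,
            "e": logits_k, "attn": attn, "z": z,
            "bag_logits": bag_logits, "prob": prob}


def attention_pool(bag: FeatureBag, model: AttentionMILModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-tile attention weights (sum to 1) and the slide representation z."""
    out = _forward(model, bag.features)
    return out["attn"], out["z"]


def predict_slide(bag: FeatureBag, model: AttentionMILModel) -> float:
    """Probability that the slide comes from a cognitively impaired donor."""
    if not model.trained:
        raise ValueError("model has not been trained")
    return float(_forward(model, bag.features)["prob"][1])


def _loss_and_grads(model: AttentionMILModel, features: np.ndarray, label: int,
                    rng: np.random.Generator, training: bool = True,
                    class_weight: float = 1.0) -> tuple[float, dict]:
    """Bag cross-entropy + instance-clustering loss and exact gradients.

    ``class_weight`` rescales the bag term (inverse-frequency weighting for
    imbalanced cohorts); the instance-clustering term is unweighted.
    """
    cfg = model.config
    p = model.params
    k_tiles = len(features)
    mask = None
    if training and cfg.dropout > 0:
        mask = (rng.random((k_tiles, cfg.embed_dim)) >= cfg.dropout) / (1.0 - cfg.dropout)
    f = _forward(model, features, dropout_mask=mask)
    hidden, attn = f["hidden"], f["attn"]

    onehot = np.zeros(2)
    onehot[label] = 1.0
    bag_loss = class_weight * -np.log(max(f["prob"][label], 1e-12))

    grads = {name: np.zeros_like(arr) for name, arr in p.items()}

    # classifier head
    dlogits = class_weight * (f["prob"] - onehot)      # (2,)
    grads["W_c"] = np.outer(dlogits, f["z"])
    grads["b_c"] = dlogits
    dz = p["W_c"].T @ dlogits                          # (M,)

    # attention-weighted pooling: z = attn @ hidden
    dattn = hidden @ dz                                # (K,)
    dhidden = np.outer(attn, dz)                       # (K, M)
    de = attn * (dattn - attn @ dattn)                 # softmax backward

    # attention logits e = gate @ w
    grads["w"] = f["gate"].T @ de
    dgate = np.outer(de, p["w"])                       # (K, A)
    if cfg.gated:
        dt = dgate * f["s"]
        ds = dgate * f["t"]
        dpre_s = ds * f["s"] * (1.0 - f["s"])
        grads["U"] = dpre_s.T @ hidden
        dhidden += dpre_s @ p["U"]
    else:
        dt = dgate
    dpre_t = dt * (1.0 - f["t"] ** 2)
    grads["V"] = dpre_t.T @ hidden
    dhidden += dpre_t @ p["V"]

    # instance-clustering loss on top-B / bottom-B attention tiles
    total_loss = bag_loss
    if cfg.instance_loss_weight > 0 and k_tiles >= 2:
        b = max(1, min(cfg.instance_k, k_tiles // 2))
        order = np.argsort(f["e"], kind="stable")
        top, bottom = order[-b:], order[:b]
        if label == 1:
            sel = np.concatenate([top, bottom])
            pseudo = np.concatenate([np.ones(b, dtype=int), np.zeros(b, dtype=int)])
        else:
            sel = top
            pseudo = np.zeros(b, dtype=int)
        h_sel = hidden[sel]
        inst_logits = h_sel @ p["W_i"].T + p["b_i"]    # (n_sel, 2)
        shifted = inst_logits - inst_logits.max(axis=1, keepdims=True)
        inst_prob = np.exp(shifted)
        inst_prob /= inst_prob.sum(axis=1, keepdims=True)
        n_sel = len(sel)
        inst_loss = -np.mean(np.log(np.maximum(inst_prob[np.arange(n_sel), pseudo], 1e-12)))
        total_loss += cfg.instance_loss_weight * inst_loss

        dinst = inst_prob.copy()
        dinst[np.arange(n_sel), pseudo] -= 1.0
        dinst *= cfg.instance_loss_weight / n_sel
        grads["W_i"] = dinst.T @ h_sel
        grads["b_i"] = dinst.sum(axis=0)
        dhidden[sel] += dinst @ p["W_i"]

    if mask is not None:
        dhidden = dhidden * mask
    dpre = dhidden * (f["pre"] > 0)
    grads["W_p"] = dpre.T @ f["x"]
    grads["b_p"] = dpre.sum(axis=0)
    grads.pop("feat_mu"), grads.pop("feat_sd")  # standardization is not trained
    return float(total_loss), grads


@dataclass
class SplitPlan:
    """Monte Carlo cross-validation plan: independent stratified splits."""

    folds: list[dict[str, list[str]]]  # keys train/val/test -> donor ids
    seed: int

    def indices(self, donor_ids: Sequence[str]) -> list[dict[str, np.ndarray]]:
        pos = {d: i for i, d in enumerate(donor_ids)}
        return [{part: np.array([pos[d] for d in fold[part]], dtype=int)
                 for part in ("train", "val", "test")} for fold in self.folds]


def make_splits(donor_ids: Sequence[str], labels: Sequence[int], n_folds: int = 10,
                fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                seed: int = 0) -> SplitPlan:
    """Label-stratified random 80/10/10 splits, drawn independently per fold.

    Within each class, split sizes follow largest-remainder rounding of the
    fractions, so every split's class mix is within one donor of the
    overall mix.
    """
    donor_ids = list(donor_ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 donors")

    folds = []
    for _ in range(n_folds):
        parts: dict[str, list[str]] = {"train": [], "val": [], "test": []}
        for c in classes:
            members = [donor_ids[i] for i in np.flatnonzero(labels == c)]
            rng.shuffle(members)
            n_c = len(members)
            ideal = np.array(fractions) * n_c
            counts = np.floor(ideal).astype(int)
            remainder = ideal - counts
            for j in np.argsort(-remainder)[: n_c - counts.sum()]:
                counts[j] += 1
            start = 0
            for part, cnt in zip(("train", "val", "test"), counts):
                parts[part].extend(members[start:start + cnt])
                start += cnt
        folds.append(parts)
    return SplitPlan(folds=folds, seed=seed)


def train(bags: Sequence[FeatureBag], labels: Sequence[int],
          train_idx: Sequence[int], val_idx: Sequence[int],
          config: MILConfig = MILConfig(), seed: int = 0) -> AttentionMILModel:
    """Train one attention-MIL model with Adam and early stopping.

    One bag per optimization step; training stops when the validation
    metric (loss by default, AUC optionally) fails to improve for
    ``patience`` epochs, and the weights from the best validation epoch are
    returned.
    """
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels[list(train_idx)])) == {0, 1}:
        raise ValueError("training set must contain both classes")
    # inverse-frequency class weights keep the implied prior at 0.5 under
    # cohort imbalance, so the fixed probability threshold stays meaningful
    train_labels = labels[list(train_idx)]
    counts = np.bincount(train_labels, minlength=2)
    class_w = len(train_labels) / (2.0 * counts)
    rng = np.random.default_rng(seed)
    dim = bags[0].features.shape[1]
    model = AttentionMILModel.init(dim, config, seed=int(rng.integers(2**31)))

    # per-dimension standardization fitted on the training tiles; constant
    # (e.g. zero-padded) dimensions are left unscaled
    train_feats = np.vstack([bags[i].features for i in train_idx])
    model.params["feat_mu"] = train_feats.mean(axis=0)
    sd = train_feats.std(axis=0)
    sd[sd < 1e-8] = 1.0
    model.params["feat_sd"] = sd

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def val_metric() -> float:
        # lower is better for both metrics (AUC is negated)
        if config.early_stopping_metric == "auc":
            probs = [_forward(model, bags[i].features)["prob"][1] for i in val_idx]
            y = labels[list(val_idx)]
            if len(np.unique(y)) < 2:
                raise ValueError("validation set must contain both classes for AUC stopping")
            return -float(roc_auc_score(y, probs))
        total = 0.0
        for i in val_idx:
            loss, _ = _loss_and_grads(model, bags[i].features, labels[i],
                                      rng, training=False,
                                      class_weight=class_w[labels[i]])
            total += loss
        return total / max(len(val_idx), 1)

    best = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    since_best = 0
    order = np.array(train_idx, dtype=int)
    for _epoch in range(config.max_epochs):
        rng.shuffle(order)
        for i in order:
            _, grads = _loss_and_grads(model, bags[i].features, labels[i], rng,
                                       class_weight=class_w[labels[i]])
            step += 1
            for k, g in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                m_hat = adam_m[k] / (1 - beta1 ** step)
                v_hat = adam_v[k] / (1 - beta2 ** step)
                # decay regularizes the embedding/attention branch; the
                # classifier heads stay undecayed so probabilities remain
                # calibrated around the 0.5 decision threshold
                decay = config.weight_decay if k in ("W_p", "b_p", "V", "U", "w") else 0.0
                model.params[k] = (model.params[k] * (1.0 - decay)
                                   - config.lr * m_hat / (np.sqrt(v_hat) + eps))
        metric = val_metric()
        if metric < best - 1e-9:
            best = metric
            best_params = {k: v.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.params = best_params
    # recenter the classifier bias so the midpoint of the two classes' mean
    # training logit differences sits at probability 0.5 (intercept-only
    # calibration; a strictly monotone shift, so rankings and AUC are
    # untouched)
    diffs = np.array([
        (lambda f: f["bag_logits"][1] - f["bag_logits"][0])(
            _forward(model, bags[i].features))
        for i in train_idx])
    midpoint = (diffs[train_labels == 1].mean() + diffs[train_labels == 0].mean()) / 2.0
    model.params["b_c"] = model.params["b_c"] + np.array([midpoint / 2, -midpoint / 2])
    model.trained = True
    return model


@dataclass
class FoldEval:
    auc: float
    balanced_accuracy: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_test: int


def auc_score(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AUC as Mann-Whitney concordance of scores (ties count 1/2)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for a single class")
    return float(roc_auc_score(labels, scores))


def balanced_accuracy(labels: Sequence[int], probs: Sequence[float],
                      threshold: float = 0.5) -> float:
    """(TPR + TNR) / 2 at a fixed probability threshold."""
    labels = np.asarray(labels, dtype=int)
    pred = (np.asarray(probs, dtype=float) >= threshold).astype(int)
    tpr = (pred[labels == 1] == 1).mean()
    tnr = (pred[labels == 0] == 0).mean()
    return float((tpr + tnr) / 2)


def evaluate(model: AttentionMILModel, bags: Sequence[FeatureBag],
             labels: Sequence[int]) -> FoldEval:
    """Test-set AUC (Mann-Whitney concordance, ties count 1/2), balanced
    accuracy at probability threshold 0.5, and ROC points."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("test set contains a single class; fold flagged")
    probs = np.array([predict_slide(b, model) for b in bags])
    fpr, tpr, _ = roc_curve(labels, probs)
    return FoldEval(auc=auc_score(labels, probs),
                    balanced_accuracy=balanced_accuracy(labels, probs),
                    fpr=fpr, tpr=tpr, n_test=len(labels))


def wilcoxon_vs_null(values: Sequence[float], null: float = 0.5) -> dict:
    """One-sample Wilcoxon signed-rank test against ``null``.

    Normal approximation with continuity correction: with W the sum of
    ranks of positive differences over n non-zero differences,
    z = (W - n(n+1)/4 -/+ 1/2) / sqrt(n(n+1)(2n+1)/24), two-sided p.
    """
    d = np.asarray(values, dtype=float) - null
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return {"W": 0.0, "z": 0.0, "p": 1.0, "n": 0}
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    shift = w_plus - mu
    if abs(shift) <= 0.5:
        z = 0.0
    else:
        z = (shift - 0.5 * np.sign(shift)) / sigma
    return {"W": w_plus, "z": float(z), "p": float(2 * scipy.stats.norm.sf(abs(z))), "n": n}


@dataclass
class EvalResult:
    """Aggregate of the Monte Carlo cross-validation folds."""

    fold_auc: list[float]
    fold_balanced_accuracy: list[float]
    mean_auc: float
    mean_balanced_accuracy: float
    wilcoxon_auc: dict
    wilcoxon_balanced_accuracy: dict
    roc_fpr_grid: np.ndarray
    roc_mean_tpr: np.ndarray
    best_fold: int

    def to_dict(self) -> dict:
        return {
            "fold_auc": self.fold_auc,
            "fold_balanced_accuracy": self.fold_balanced_accuracy,
            "mean_auc": self.mean_auc,
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "wilcoxon_auc": self.wilcoxon_auc,
            "wilcoxon_balanced_accuracy": self.wilcoxon_balanced_accuracy,
            "roc_fpr_grid": self.roc_fpr_grid.tolist(),
            "roc_mean_tpr": self.roc_mean_tpr.tolist(),
            "best_fold": self.best_fold,
        }


def aggregate_folds(folds: Sequence[FoldEval], n_grid: int = 101) -> EvalResult:
    """Combine per-fold evaluations.

    Mean AUC and balanced accuracy; Wilcoxon signed-rank tests of each
    against chance (0.5); vertically averaged ROC (per-fold TPR linearly
    interpolated onto a common FPR grid, then averaged); best fold by the
    arithmetic mean of AUC and balanced accuracy.
    """
    if len(folds) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    aucs = [f.auc for f in folds]
    baccs = [f.balanced_accuracy for f in folds]
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.vstack([np.interp(grid, f.fpr, f.tpr) for f in folds])
    combined = (np.asarray(aucs) + np.asarray(baccs)) / 2.0
    return EvalResult(
        fold_auc=[float(a) for a in aucs],
        fold_balanced_accuracy=[float(b) for b in baccs],
        mean_auc=float(np.mean(aucs)),
        mean_balanced_accuracy=float(np.mean(baccs)),
        wilcoxon_auc=wilcoxon_vs_null(aucs),
        wilcoxon_balanced_accuracy=wilcoxon_vs_null(baccs),
        roc_fpr_grid=grid,
        roc_mean_tpr=tprs.mean(axis=0),
        best_fold=int(np.argmax(combined)),
    )


def run_cross_validation(bags: Sequence[FeatureBag], labels: Sequence[int],
                         config: MILConfig = MILConfig(), seed: int = 0,
                         ) -> tuple[EvalResult, list[AttentionMILModel], SplitPlan]:
    """Train and evaluate across all Monte Carlo folds."""
    donor_ids = [b.donor_id for b in bags]
    plan = make_splits(donor_ids, labels, n_folds=config.n_folds,
                       fractions=config.fractions, seed=seed)
    labels = np.asarray(labels, dtype=int)
    models, fold_evals = [], []
    for fold_no, idx in enumerate(plan.indices(donor_ids)):
        model = train(bags, labels, idx["train"], idx["val"], config,
                      seed=seed * 1000 + fold_no)
        models.append(model)
        fold_evals.append(evaluate(model, [bags[i] for i in idx["test"]],
                                   labels[idx["test"]]))
    return aggregate_folds(fold_evals), models, plan
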