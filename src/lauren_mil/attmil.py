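"""Attention-based multiple-instance learning for slide-level subtyping.

A slide is a *bag* of per-tile feature vectors with a single label
(intestinal vs diffuse).  Each tile k is embedded, h_k = relu(W_e x_k); a
gated attention head scores it,

    a_k ∝ exp( wᵀ ( tanh(V h_k) ⊙ σ(U h_k) ) ),   Σ_k a_k = 1,

and the bag representation z = Σ_k a_k h_k goes through a linear classifier
to a two-class probability.  The attention weights expose which tiles drove
the call.

Training minimizes the bag-level cross-entropy plus an attention-weighted
instance loss: a tile-level classifier head is trained against the bag
label, weighted by each tile's attention, L_inst = Σ_k a_k CE(inst(h_k), y).
Tiles that occur identically in both classes (ordinary stroma) cannot be
classified either way, so their instance loss stays near log 2 and attention
is pushed onto tiles that genuinely support the slide label — the same idea
as the instance-clustering losses used in clustering-constrained attention
MIL, in a differentiable form.  Because the bag loss saturates quickly on
separable data while the attention geometry is still settling, training runs
a small number of seeded restarts and keeps the model with the lowest total
training loss.  Everything — forward pass, analytic gradients, AdamW,
early stopping on the total validation loss — is implemented in numpy and
is deterministic for a fixed seed.

Evaluation follows patient-level stratified five-fold cross-validation:
every case is predicted exactly once, out of fold, and performance is the
mean ± SD of the per-fold AUROC (Mann–Whitney form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .features import FeatureBag
from .synthetic import DIFFUSE, INTESTINAL

LABELS = (INTESTINAL, DIFFUSE)  # class index 0, 1


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AttMILConfig:
    """Hyperparameters of the model and its training loop."""

    dim: int = 2048          # input feature dimension d
    hidden: int = 256        # embedding width h
    attention: int = 128     # attention width a
    lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 32
    batch_size: int = 16
    val_fraction: float = 0.15
    patience: int = 5
    bag_cap: int = 512       # seeded per-bag tile subsample during training
    class_weighting: bool = True
    instance_weight: float = 0.5   # λ of the attention-weighted instance loss
    restarts: int = 4              # seeded inits; keep lowest training loss


@dataclass
class PredictionRecord:
    """Slide-level prediction plus the per-tile evidence behind it."""

    case_id: str
    prob_diffuse: float
    label: str
    fold: int
    attention: np.ndarray       # (n_tiles,) softmax weights
    tile_scores: np.ndarray     # (n_tiles, 2) per-tile class probabilities
    grid_coords: np.ndarray | None = None
    grid_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_diffuse <= 1.0:
            raise ValueError("prob_diffuse must lie in [0, 1]")
        if self.label != classify(self.prob_diffuse):
            raise ValueError("label inconsistent with probability threshold")

    @property
    def confidence(self) -> float:
        return max(self.prob_diffuse, 1.0 - self.prob_diffuse)


@dataclass
class FoldAssignment:
    """Patient-level fold membership for stratified cross-validation."""

    mapping: dict[str, int]
    n_folds: int = 5

    def fold_of(self, case_id: str) -> int:
        return self.mapping[case_id]

    def cases_in(self, fold: int) -> list[str]:
        return [c for c, f in self.mapping.items() if f == fold]


def assign_folds(
    case_ids: list[str],
    labels: list[str],
    n_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Stratified patient-level fold assignment.

    Each patient lands in exactly one fold and per-fold class counts differ
    from perfect proportionality by at most one case.
    """
    y = np.array([LABELS.index(l) for l in labels])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mapping: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            mapping[case_ids[i]] = fold
    return FoldAssignment(mapping, n_folds)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _glorot(rng, n_in, n_out):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


class AttMILModel:
    """Gated attention-MIL network with analytic gradients (numpy)."""

    PARAM_NAMES = ("We", "be", "V", "bV", "U", "bU", "w", "bw", "Wc", "bc",
                   "Wi", "bi")

    def __init__(self, config: AttMILConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, h, a = config.dim, config.hidden, config.attention
        self.params = {
            "We": _glorot(rng, d, h), "be": np.zeros(h),
            "V": _glorot(rng, h, a), "bV": np.zeros(a),
            "U": _glorot(rng, h, a), "bU": np.zeros(a),
            "w": _glorot(rng, a, 1)[:, 0], "bw": np.zeros(1),
            "Wc": _glorot(rng, h, 2), "bc": np.zeros(2),
            "Wi": _glorot(rng, h, 2), "bi": np.zeros(2),  # instance head
        }
        # feature standardization, fitted on training tiles
        self.mu = np.zeros(d)
        self.sigma = np.ones(d)
        self.history: dict[str, list[float]] = {}

    # -- forward ------------------------------------------------------------

    def fit_standardizer(self, bags: list[FeatureBag]) -> None:
        tiles = np.concatenate([b.features for b in bags])
        self.mu = tiles.mean(axis=0)
        self.sigma = np.maximum(tiles.std(axis=0), 1e-6)

    def _embed(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.mu) / self.sigma
        return np.maximum(Xs @ self.params["We"] + self.params["be"], 0.0)

    def _forward_parts(self, X: np.ndarray):
        p = self.params
        Xs = (X - self.mu) / self.sigma
        H = np.maximum(Xs @ p["We"] + p["be"], 0.0)
        T = np.tanh(H @ p["V"] + p["bV"])
        S = 1.0 / (1.0 + np.exp(-(H @ p["U"] + p["bU"])))
        G = T * S
        s = G @ p["w"] + p["bw"][0]
        alpha = _softmax(s)
        z = alpha @ H
        logits = z @ p["Wc"] + p["bc"]
        probs = _softmax(logits)
        return Xs, H, T, S, G, alpha, z, probs

    def attention_scores(self, bag: FeatureBag | np.ndarray) -> np.ndarray:
        """Per-tile softmax attention weights (non-negative, sum to 1)."""
        X = bag.features if isinstance(bag, FeatureBag) else bag
        if X.shape[0] == 0:
            raise ValueError("empty bag")
        self._check_dim(X)
        *_, alpha, _, _ = self._forward_parts(X)
        return alpha

    def forward(self, bag: FeatureBag | np.ndarray) -> np.ndarray:
        """Slide-level class probabilities (intestinal, diffuse)."""
        X = bag.features if isinstance(bag, FeatureBag) else bag
        if X.shape[0] == 0:
            raise ValueError("empty bag")
        self._check_dim(X)
        *_, probs = self._forward_parts(X)
        return probs

    def tile_scores(self, bag: FeatureBag | np.ndarray) -> np.ndarray:
        """Per-tile class probabilities from the instance head."""
        X = bag.features if isinstance(bag, FeatureBag) else bag
        self._check_dim(X)
        H = self._embed(X)
        logits = H @ self.params["Wi"] + self.params["bi"]
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def _check_dim(self, X: np.ndarray) -> None:
        if X.shape[1] != self.config.dim:
            raise ValueError(
                f"bag feature dim {X.shape[1]} != model dim {self.config.dim}"
            )

    # -- backward -----------------------------------------------------------

    def total_loss(self, X: np.ndarray, y: int, class_weight: float = 1.0):
        """Bag cross-entropy plus the attention-weighted instance loss."""
        p = self.params
        _, H, _, _, _, alpha, _, probs = self._forward_parts(X)
        lam = self.config.instance_weight
        li = H @ p["Wi"] + p["bi"]
        le = np.exp(li - li.max(axis=1, keepdims=True))
        pi = le / le.sum(axis=1, keepdims=True)
        inst = float(alpha @ -np.log(pi[:, y] + 1e-12))
        return class_weight * (-np.log(probs[y] + 1e-12) + lam * inst)

    def loss_and_grads(self, X: np.ndarray, y: int, class_weight: float = 1.0):
        """Total training loss of one bag and its analytic gradients."""
        p = self.params
        lam = self.config.instance_weight
        Xs, H, T, S, G, alpha, z, probs = self._forward_parts(X)
        # instance head: per-tile CE against the bag label, attention-weighted
        li = H @ p["Wi"] + p["bi"]
        le = np.exp(li - li.max(axis=1, keepdims=True))
        pi = le / le.sum(axis=1, keepdims=True)
        inst_ce = -np.log(pi[:, y] + 1e-12)
        loss = class_weight * (
            -np.log(probs[y] + 1e-12) + lam * float(alpha @ inst_ce)
        )

        dlogits = class_weight * probs.copy()
        dlogits[y] -= class_weight
        g = {}
        g["Wc"] = np.outer(z, dlogits)
        g["bc"] = dlogits
        dz = p["Wc"] @ dlogits
        dalpha = H @ dz + lam * class_weight * inst_ce
        dH = np.outer(alpha, dz)
        dli = pi.copy()
        dli[:, y] -= 1.0
        dli *= (lam * class_weight * alpha)[:, None]
        g["Wi"] = H.T @ dli
        g["bi"] = dli.sum(axis=0)
        dH += dli @ p["Wi"].T
        ds = alpha * (dalpha - alpha @ dalpha)
        dG = np.outer(ds, p["w"])
        g["w"] = G.T @ ds
        g["bw"] = np.array([ds.sum()])
        dT = dG * S
        dS = dG * T
        dpre_v = dT * (1.0 - T * T)
        g["V"] = H.T @ dpre_v
        g["bV"] = dpre_v.sum(axis=0)
        dH += dpre_v @ p["V"].T
        dpre_u = dS * S * (1.0 - S)
        g["U"] = H.T @ dpre_u
        g["bU"] = dpre_u.sum(axis=0)
        dH += dpre_u @ p["U"].T
        dpre_e = dH * (H > 0)
        g["We"] = Xs.T @ dpre_e
        g["be"] = dpre_e.sum(axis=0)
        return float(loss), g


def predict(model: AttMILModel, bag: FeatureBag, fold: int = -1) -> PredictionRecord:
    """Full prediction record (probability, label, per-tile evidence)."""
    probs = model.forward(bag)
    prob_diffuse = float(probs[1])
    return PredictionRecord(
        case_id=bag.slide_id,
        prob_diffuse=prob_diffuse,
        label=classify(prob_diffuse),
        fold=fold,
        attention=model.attention_scores(bag),
        tile_scores=model.tile_scores(bag),
        grid_coords=bag.grid_coords,
        grid_shape=bag.grid_shape,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _AdamW:
    def __init__(self, params, lr, weight_decay, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * (mh / (np.sqrt(vh) + self.eps)
                                    + self.wd * params[k])


def _class_weights(y: np.ndarray) -> np.ndarray:
    counts = np.bincount(y, minlength=2)
    return len(y) / (2.0 * np.maximum(counts, 1))


def _mean_loss(model, bags, ys, cw):
    total = 0.0
    for b, y in zip(bags, ys):
        X = b.features if isinstance(b, FeatureBag) else b
        total += model.total_loss(X, int(y), cw[y])
    return total / max(len(bags), 1)


def _train_single(
    bags: list[FeatureBag],
    labels: list[str],
    config: AttMILConfig,
    seed: int = 0,
) -> AttMILModel:
    """One training run: AdamW, early-stopped on a held-out split.

    A ``val_fraction`` stratified subset of the training cases monitors the
    total loss; training stops once it has not improved for ``patience``
    epochs and the best parameters are restored.  Bags larger than
    ``bag_cap`` tiles are subsampled per epoch with a seeded generator.
    Fully deterministic in (bags, labels, config, seed).
    """
    y = np.array([LABELS.index(l) for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    rng = np.random.default_rng(seed)
    model = AttMILModel(config, seed=int(rng.integers(2**31 - 1)))
    model.fit_standardizer(bags)
    cw = _class_weights(y) if config.class_weighting else np.ones(2)

    # stratified validation split for early stopping
    n_val = int(round(config.val_fraction * len(bags)))
    val_idx: list[int] = []
    if n_val >= 2:
        for cls in (0, 1):
            cls_idx = np.flatnonzero(y == cls)
            k = max(1, int(round(config.val_fraction * len(cls_idx))))
            val_idx += list(rng.choice(cls_idx, size=k, replace=False))
    val_set = set(val_idx)
    train_idx = [i for i in range(len(bags)) if i not in val_set]

    opt = _AdamW(model.params, config.lr, config.weight_decay)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    bad_epochs = 0
    history = {"train_loss": [], "val_loss": []}
    for _ in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            grads = None
            batch_loss = 0.0
            for i in batch:
                X = bags[i].features
                if X.shape[0] > config.bag_cap:
                    sel = rng.choice(X.shape[0], config.bag_cap, replace=False)
                    X = X[sel]
                loss_i, g = model.loss_and_grads(X, int(y[i]), cw[y[i]])
                batch_loss += loss_i
                if grads is None:
                    grads = g
                else:
                    for k in grads:
                        grads[k] += g[k]
            for k in grads:
                grads[k] /= len(batch)
            opt.step(model.params, grads)
            epoch_loss += batch_loss
        history["train_loss"].append(epoch_loss / max(len(order), 1))
        if val_idx:
            vl = _mean_loss(model, [bags[i] for i in val_idx], y[val_idx], cw)
            history["val_loss"].append(vl)
            if vl < best_val - 1e-6:
                best_val = vl
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    break
    if val_idx:
        model.params = best_params
    model.history = history
    return model


def train_model(
    bags: list[FeatureBag],
    labels: list[str],
    config: AttMILConfig,
    seed: int = 0,
) -> AttMILModel:
    """Train with seeded restarts; keep the lowest-training-loss model.

    The bag loss saturates long before the attention geometry settles, so
    independent inits can land in basins whose attention ranks uninformative
    tiles highly; those basins keep a visibly higher instance loss.
    ``config.restarts`` runs are trained and the one with the lowest total
    loss over the full training set wins.  Deterministic in (inputs, seed).
    """
    y = np.array([LABELS.index(l) for l in labels])
    cw = _class_weights(y) if config.class_weighting else np.ones(2)
    best_model = None
    best_loss = np.inf
    for r in range(max(1, config.restarts)):
        model = _train_single(bags, labels, config, seed=seed + 10007 * r)
        loss = _mean_loss(model, bags, y, cw)
        if loss < best_loss:
            best_loss, best_model = loss, model
    return best_model


@dataclass
class CVResult:
    """Out-of-fold predictions and per-fold AUROC of one cross-validation."""

    fold_models: list[AttMILModel]
    predictions: list[PredictionRecord]
    fold_aurocs: np.ndarray
    folds: FoldAssignment

    @property
    def mean_auroc(self) -> float:
        return float(self.fold_aurocs.mean())

    @property
    def sd_auroc(self) -> float:
        return float(self.fold_aurocs.std(ddof=1))


def train_crossval(
    bags: list[FeatureBag],
    labels: dict[str, str],
    config: AttMILConfig,
    folds: FoldAssignment | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Patient-level stratified k-fold cross-validation of the classifier.

    For each fold a model is trained on the remaining folds and predicts the
    held-out cases, so every case receives exactly one out-of-fold
    prediction.  Raises before training if any fold misses a class.
    """
    case_ids = [b.slide_id for b in bags]
    y_list = [labels[c] for c in case_ids]
    if folds is None:
        folds = assign_folds(case_ids, y_list, n_folds=n_folds, seed=seed)
    by_fold: dict[int, list[int]] = {}
    for i, c in enumerate(case_ids):
        by_fold.setdefault(folds.fold_of(c), []).append(i)
    for f, idx in sorted(by_fold.items()):
        present = {y_list[i] for i in idx}
        if len(present) < 2:
            raise ValueError(f"fold {f} is missing a class: only {present}")

    fold_models: list[AttMILModel] = []
    predictions: list[PredictionRecord] = []
    aurocs = []
    for f in sorted(by_fold):
        test_idx = by_fold[f]
        train_idx = [i for ff, idx in by_fold.items() if ff != f for i in idx]
        model = train_model(
            [bags[i] for i in train_idx],
            [y_list[i] for i in train_idx],
            config,
            seed=seed * 1000 + f,
        )
        fold_models.append(model)
        scores, truth = [], []
        for i in test_idx:
            rec = predict(model, bags[i], fold=f)
            predictions.append(rec)
            scores.append(rec.prob_diffuse)
            truth.append(LABELS.index(y_list[i]))
        aurocs.append(evaluate_auroc(np.array(scores), np.array(truth)))
    predictions.sort(key=lambda r: r.case_id)
    return CVResult(fold_models, predictions, np.array(aurocs), folds)


def refit_all(
    bags: list[FeatureBag],
    labels: dict[str, str],
    config: AttMILConfig,
    seed: int = 0,
) -> AttMILModel:
    """Final deployment model, refitted on every case (post-gate)."""
    case_ids = [b.slide_id for b in bags]
    return train_model(bags, [labels[c] for c in case_ids], config, seed=seed)


# ---------------------------------------------------------------------------
# Metrics and decision rule
# ---------------------------------------------------------------------------

def evaluate_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the Mann–Whitney pairwise-win fraction (ties count ½)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def classify(prob_diffuse: float, threshold: float = 0.5) -> str:
    """Binarize a diffuse-probability; ties at the threshold go to diffuse."""
    if not 0.0 <= prob_diffuse <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return DIFFUSE if prob_diffuse >= threshold else INTESTINAL
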