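"""Training objective, imbalance handling, and cross-validation harness.

The objective is ``L = L_C + lambda_eff * E[H(g)]``: a classification
loss (cross-entropy by default, focal loss optionally) plus an
entropy-sparsity term on the fusion gate, where ``lambda_eff`` is zero
during a warm-up phase and equals the configured sparsity weight
afterwards. ``E[H(g)]`` is estimated as the within-batch mean.

Model selection follows stratified k-fold cross-validation with
identical folds shared by all model variants; augmentation is applied
on the fly to training folds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .branches import BranchConfig, ImageBatch
from .fusion import GateWeights, HMCTAFModel, gate_entropy
from .data.pipeline import AugmentationSpec, augment
from .evaluation import confusion_matrix, macro_f1, overall_accuracy
from .nn import SGD, Adam, Tensor
from .utils import substream

logger = logging.getLogger("leafgate.training")

__all__ = [
    "TrainConfig", "FoldSplit", "cross_entropy", "focal_loss", "total_loss",
    "lambda_schedule", "stratified_kfold", "class_aware_batches",
    "shuffled_batches", "train_single", "evaluate_model", "cross_validate",
    "FoldResult", "CVResult",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol.

    Defaults follow the published training recipe: SGD with learning
    rate 0.001, momentum 0.9, weight decay 0.0005, batch size 32,
    sparsity weight lambda = 0.10 at temperature tau = 1 with a 5-epoch
    warm-up at lambda = 0. The epoch count has no published default and
    must be chosen per experiment.
    """

    epochs: int = 10
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 32
    lambda_sparsity: float = 0.10
    tau: float = 1.0
    warmup_epochs: int = 5
    optimizer: str = "sgd"
    loss: str = "cross_entropy"
    focal_gamma: float = 2.0
    class_aware_sampling: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        for name in ("learning_rate", "momentum", "tau"):
            if getattr(self, name) <= 0 and name != "momentum":
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lambda_sparsity < 0:
            raise ValueError("lambda_sparsity must be nonnegative")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be nonnegative")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError("loss must be 'cross_entropy' or 'focal'")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be nonnegative")

    def with_(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# losses and schedule
# ---------------------------------------------------------------------------

def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from raw logits (fused stable log-softmax)."""
    z = logits.data
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite logits")
    labels = np.asarray(labels)
    zmax = z.max(axis=-1, keepdims=True)
    zs = z - zmax
    lse = np.log(np.exp(zs).sum(axis=-1, keepdims=True))
    logp = zs - lse
    n = len(labels)
    value = -logp[np.arange(n), labels].mean()
    out = Tensor(np.asarray(value, dtype=z.dtype),
                 requires_grad=logits.requires_grad, parents=(logits,))

    def _backward(g: np.ndarray) -> None:
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits.accumulate(g * p / n)

    out._backward = _backward if logits.requires_grad else None
    return out


def focal_loss(probabilities, labels, gamma: float = 2.0,
               eps: float = 1e-12):
    """Focal loss ``mean(-(1 - p_true)^gamma * log(p_true))``.

    At ``gamma = 0`` this is exactly cross-entropy on the same
    probabilities. Accepts a probability Tensor (differentiable path)
    or a plain array; the true-class probability is clamped at ``eps``.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    labels = np.asarray(labels)
    n = len(labels)
    if isinstance(probabilities, Tensor):
        pt = probabilities[np.arange(n), labels]
        logpt = pt.log(eps=eps)
        if gamma == 0:
            return -logpt.mean()
        return -(((1.0 - pt) ** gamma) * logpt).mean()
    p = np.asarray(probabilities, dtype=float)
    pt = np.clip(p[np.arange(n), labels], eps, 1.0)
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt)))


def total_loss(class_logits: Tensor, labels: np.ndarray,
               gates: GateWeights | None, lambda_eff: float,
               loss: str = "cross_entropy", focal_gamma: float = 2.0) -> Tensor:
    """Fusion objective ``L = L_C + lambda_eff * mean_batch H(g)``.

    With ``lambda_eff == 0`` (or no gate) the regularizer is not added at
    all, so its gradient contribution is exactly zero during warm-up.
    """
    if lambda_eff < 0:
        raise ValueError("lambda_eff must be nonnegative")
    if loss == "focal":
        l_c = focal_loss(class_logits.softmax(axis=-1), labels, gamma=focal_gamma)
    else:
        l_c = cross_entropy(class_logits, labels)
    if gates is None or lambda_eff == 0:
        return l_c
    return l_c + lambda_eff * gate_entropy(gates.g).mean()


def lambda_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Effective sparsity weight: 0 during warm-up, lambda afterwards."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return 0.0 if epoch < cfg.warmup_epochs else cfg.lambda_sparsity


# ---------------------------------------------------------------------------
# folds and samplers
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """Per-sample fold assignment for stratified k-fold cross-validation."""

    fold_assignments: np.ndarray
    k: int

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> FoldSplit:
    """Disjoint, exhaustive folds preserving per-class proportions.

    Every class must have at least ``k`` members; within each fold each
    class count differs from the stratified ideal by at most one.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for c, n in zip(classes, counts):
        if n < k:
            raise ValueError(f"class {c} has only {n} samples; need >= {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    assignments = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldSplit(fold_assignments=assignments, k=k)


def shuffled_batches(n: int, batch_size: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def class_aware_batches(labels: np.ndarray, batch_size: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Round-robin over classes so each batch covers every class.

    Per-class index queues are shuffled and consumed cyclically,
    reshuffling (i.e. oversampling minorities) when a queue empties;
    with ``batch_size >= n_classes`` every batch contains each class at
    least once. One epoch yields roughly ``n / batch_size`` batches.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    queues = {c: list(rng.permutation(np.flatnonzero(labels == c)))
              for c in classes}
    n_batches = max(1, int(np.ceil(len(labels) / batch_size)))
    batches = []
    ci = 0
    for _ in range(n_batches):
        batch = []
        for _ in range(batch_size):
            c = classes[ci % len(classes)]
            ci += 1
            if not queues[c]:
                queues[c] = list(rng.permutation(np.flatnonzero(labels == c)))
            batch.append(queues[c].pop())
        batches.append(np.asarray(batch))
    return batches


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    macro_f1: float
    accuracy: float
    mean_gate_entropy: float | None
    confusion: np.ndarray
    gate_report: list[dict] = field(repr=False, default_factory=list)
    history: list[dict] = field(repr=False, default_factory=list)


@dataclass
class CVResult:
    strategy: str
    folds: list[FoldResult]
    fold_split: FoldSplit

    def summary(self) -> dict:
        f1 = np.array([f.macro_f1 for f in self.folds])
        acc = np.array([f.accuracy for f in self.folds])
        return {
            "strategy": self.strategy,
            "macro_f1_mean": float(f1.mean()),
            "macro_f1_sd": float(f1.std(ddof=1)) if len(f1) > 1 else 0.0,
            "accuracy_mean": float(acc.mean()),
            "accuracy_sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        }

    def pooled_predictions(self) -> tuple[np.ndarray, np.ndarray]:
        """Held-out (true, predicted) labels pooled over folds, in
        dataset order."""
        n = len(self.fold_split.fold_assignments)
        true = np.full(n, -1, dtype=np.int64)
        pred = np.full(n, -1, dtype=np.int64)
        for fr in self.folds:
            idx = self.fold_split.test_indices(fr.fold)
            true[idx] = fr._true
            pred[idx] = fr._pred
        return true, pred


def _make_optimizer(model: HMCTAFModel, cfg: TrainConfig):
    if cfg.optimizer == "adam":
        return Adam(model.parameters(), lr=cfg.learning_rate,
                    weight_decay=cfg.weight_decay)
    return SGD(model.parameters(), lr=cfg.learning_rate,
               momentum=cfg.momentum, weight_decay=cfg.weight_decay)


def _batch_tensor(pixels: np.ndarray) -> Tensor:
    return Tensor(np.ascontiguousarray(pixels.transpose(0, 3, 1, 2)))


def train_single(model: HMCTAFModel, train_images: ImageBatch,
                 cfg: TrainConfig, augmentation: AugmentationSpec | None = None,
                 rng_name: str = "train") -> list[dict]:
    """Train one model in place; returns the per-epoch history.

    For the ``gsaf`` strategy ``lambda_eff`` follows the warm-up
    schedule; ``gsaf_no_sparsity`` trains the identical architecture
    with the regularizer permanently off.
    """
    if len(train_images) == 0:
        raise ValueError("empty training set")
    uses_sparsity = model.strategy == "gsaf"
    history = []
    opt = _make_optimizer(model, cfg)
    labels = train_images.labels
    for epoch in range(cfg.epochs):
        lambda_eff = lambda_schedule(epoch, cfg) if uses_sparsity else 0.0
        rng = substream(cfg.seed, f"{rng_name}/epoch{epoch}")
        if cfg.class_aware_sampling:
            batches = class_aware_batches(labels, cfg.batch_size, rng)
        else:
            batches = shuffled_batches(len(labels), cfg.batch_size, rng)
        model.train()
        losses, entropies = [], []
        for bi, idx in enumerate(batches):
            pix = train_images.pixels[idx]
            if augmentation is not None:
                arng = substream(cfg.seed, f"{rng_name}/aug/e{epoch}b{bi}")
                pix = np.stack([augment(p, augmentation, arng) for p in pix])
            logits, gates = model(_batch_tensor(pix))
            loss = total_loss(logits, labels[idx], gates, lambda_eff,
                              loss=cfg.loss, focal_gamma=cfg.focal_gamma)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            if gates is not None:
                entropies.append(float(gate_entropy(gates.gate_array).mean()))
        record = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "lambda_eff": lambda_eff,
            "mean_gate_entropy": float(np.mean(entropies)) if entropies else None,
        }
        history.append(record)
        logger.info("epoch %d: loss=%.4f lambda=%.3g H(g)=%s", epoch,
                    record["loss"], lambda_eff, record["mean_gate_entropy"])
    return history


def evaluate_model(model: HMCTAFModel, images: ImageBatch, n_classes: int,
                   batch_size: int = 64):
    """Deterministic evaluation pass: predictions, confusion, gates."""
    model.eval()
    preds, gate_rows = [], []
    for i in range(0, len(images), batch_size):
        pix = images.pixels[i:i + batch_size]
        logits, gates = model(_batch_tensor(pix))
        preds.append(logits.data.argmax(axis=-1))
        if gates is not None:
            gate_rows.append(gates.gate_array)
    pred = np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)
    gates_arr = np.concatenate(gate_rows) if gate_rows else None
    cm = confusion_matrix(images.labels, pred, n_classes)
    result = {
        "macro_f1": macro_f1(cm),
        "accuracy": overall_accuracy(cm) if cm.sum() else 0.0,
        "confusion": cm,
        "predictions": pred,
        "gates": gates_arr,
        "mean_gate_entropy": (float(gate_entropy(gates_arr).mean())
                              if gates_arr is not None else None),
    }
    return result


def cross_validate(images: ImageBatch, n_classes: int, model_cfg: BranchConfig,
                   train_cfg: TrainConfig, strategy: str = "gsaf",
                   folds: FoldSplit | None = None, k: int = 5,
                   augmentation: AugmentationSpec | None = None,
                   keep_models: bool = False) -> CVResult:
    """Stratified k-fold cross-validation of one fusion strategy.

    Pass the same ``folds`` object to every strategy in an ablation so
    all variants see identical train/test partitions. Augmentation, when
    given, is applied only to the training portion of each fold; the
    held-out fold is always evaluated on clean images.
    """
    if len(images) == 0:
        raise ValueError("empty dataset")
    if folds is None:
        folds = stratified_kfold(images.labels, k=k, seed=train_cfg.seed)
    fold_results = []
    for fold in range(folds.k):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        model = HMCTAFModel(model_cfg, n_classes, strategy=strategy,
                            seed=substream(train_cfg.seed,
                                           f"fold{fold}/init").integers(2**31),
                            tau=train_cfg.tau)
        history = train_single(model, images.subset(tr), train_cfg,
                               augmentation=augmentation,
                               rng_name=f"fold{fold}")
        ev = evaluate_model(model, images.subset(te), n_classes)
        fr = FoldResult(
            fold=fold, macro_f1=ev["macro_f1"], accuracy=ev["accuracy"],
            mean_gate_entropy=ev["mean_gate_entropy"], confusion=ev["confusion"],
            history=history,
        )
        fr._true = images.labels[te]
        fr._pred = ev["predictions"]
        if keep_models:
            fr.model = model
        if ev["gates"] is not None:
            fr.gate_report = [
                {"id": images.ids[j], "true_label": int(t), "predicted_label":
                 int(p), "g_detail": float(g[0]), "g_global": float(g[1]),
                 "g_trans": float(g[2])}
                for j, t, p, g in zip(te, images.labels[te], ev["predictions"],
                                      ev["gates"])
            ]
        fold_results.append(fr)
    return CVResult(strategy=strategy, folds=fold_results, fold_split=folds)
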