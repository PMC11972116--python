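"""Training protocol: BCE-with-logits, Adam, protein-grouped CV, early stop.

The upstream encoders are frozen by construction (the embedding stage is
a pure function of sequence and seed), so only the Conv+BiGRU+Wav-KAN
parameters are optimized.  Training minimizes binary cross-entropy on
logits with Adam (base step 9e-4, moment decays 0.9/0.999, batch 1024 by
default), monitors validation loss each epoch, and stops once it has
failed to improve by ``min_delta`` for ``patience`` consecutive epochs,
returning the best-validation parameter snapshot.

Cross-validation folds are assigned at protein granularity: all sites of
a protein land in one fold, and fold label proportions are kept close to
the global proportion (grouped stratification), the best achievable
compromise between per-site stratification and protein exclusivity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold

from phoskan.errors import PhosKANError
from phoskan.nn.autograd import Tensor, bce_with_logits
from phoskan.nn.model import PhosKANModel
from phoskan.nn.optim import Adam


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    ``precision_mode`` selects numeric storage: "full" (IEEE single
    precision throughout, the deterministic default), "double" (float64,
    used by gradient-verification work), or "mixed" (single-precision
    storage with loss scaling applied before backpropagation so small
    gradients stay representable when a reduced-precision backend is in
    play).
    """

    learning_rate: float = 9e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 1024
    max_epochs: int = 50
    patience: int = 5
    min_delta: float = 0.0
    seed: int = 0
    precision_mode: str = "full"
    loss_scale: float = 1024.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise PhosKANError("learning_rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise PhosKANError("moment decays must lie in (0, 1)")
        if self.batch_size < 1:
            raise PhosKANError("batch_size must be >= 1")
        if self.precision_mode not in ("full", "double", "mixed"):
            raise PhosKANError(
                "precision_mode must be 'full', 'double' or 'mixed'"
            )


class WindowDataset:
    """Windows (n, W, D), binary labels (n,), and per-sample protein ids."""

    def __init__(self, windows: np.ndarray, labels: np.ndarray,
                 protein_ids: Optional[Sequence[str]] = None):
        self.windows = np.asarray(windows)
        self.labels = np.asarray(labels).astype(int)
        if self.windows.shape[0] != self.labels.shape[0]:
            raise PhosKANError("windows and labels differ in length")
        self.protein_ids = (list(protein_ids) if protein_ids is not None
                            else [""] * len(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "WindowDataset":
        idx = np.asarray(idx)
        return WindowDataset(self.windows[idx], self.labels[idx],
                             [self.protein_ids[int(i)] for i in idx])


def bce_logits_loss(logits, labels) -> float:
    """Mean binary cross-entropy of raw logits against 0/1 labels."""
    z = np.asarray(logits, dtype=np.float64).ravel()
    if z.size == 0:
        raise PhosKANError("empty input to BCE loss")
    return float(bce_with_logits(Tensor(z), np.asarray(labels)).item())


@dataclass
class TrainResult:
    model: PhosKANModel
    history: Dict[str, List[float]]
    best_epoch: int
    best_val_loss: float


def recalibrate_batchnorm(model: PhosKANModel, windows: np.ndarray,
                          batch_size: int = 256) -> None:
    """Recompute batch-norm population statistics with a dedicated pass.

    Training-mode batches normalize by their own statistics, so the
    exponential running average can drift from the statistics the
    features actually have under the current parameters — especially
    with small batches.  This "precise" pass replaces the running
    mean/variance with the cumulative average over the given windows,
    making eval-mode inference consistent with the trained model.
    """
    was_training = model.training
    flags = [(p, p.requires_grad) for p in model.parameters()]
    for p, _ in flags:
        p.requires_grad = False  # forward only: skip graph construction
    for norm in model.norms:
        norm.begin_calibration()
    model.train()
    try:
        for lo in range(0, len(windows), batch_size):
            batch = windows[lo : lo + batch_size]
            if len(batch) < 2:
                continue
            model.forward(batch)
    finally:
        for norm in model.norms:
            norm.end_calibration()
        for p, flag in flags:
            p.requires_grad = flag
        if was_training:
            model.train()
        else:
            model.eval()


def _epoch_eval(model: PhosKANModel, data: WindowDataset,
                batch_size: int) -> Tuple[float, float]:
    """(mean BCE loss, accuracy) in eval mode."""
    probs = model.predict_proba(data.windows, batch_size=batch_size)
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    y = data.labels
    loss = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
    acc = float(((probs >= 0.5).astype(int) == y).mean())
    return loss, acc


def train(model: PhosKANModel, train_set: WindowDataset,
          val_set: Optional[WindowDataset] = None,
          config: Optional[TrainConfig] = None,
          verbose: bool = False) -> TrainResult:
    """Optimize a model with early stopping on validation loss.

    When ``val_set`` is omitted a 10% protein-grouped tail of the training
    set is held out.  Returns the best-validation checkpoint and the full
    per-epoch history (train/val loss and accuracy).
    """
    config = config or TrainConfig()
    if len(set(train_set.labels.tolist())) < 2:
        raise PhosKANError("training set must contain both classes")
    if val_set is None:
        rng = np.random.default_rng(config.seed)
        uniq = list(dict.fromkeys(train_set.protein_ids))
        order = rng.permutation(len(uniq))
        n_val = max(1, len(uniq) // 10)
        val_ids = {uniq[k] for k in order[:n_val]}
        val_idx = [i for i, p in enumerate(train_set.protein_ids)
                   if p in val_ids]
        tr_idx = [i for i, p in enumerate(train_set.protein_ids)
                  if p not in val_ids]
        val_set = train_set.subset(val_idx)
        train_set = train_set.subset(tr_idx)

    dtype = (np.float64 if config.precision_mode == "double"
             else np.float32)
    scale = config.loss_scale if config.precision_mode == "mixed" else 1.0
    for p in model.parameters():
        p.data = p.data.astype(dtype)
    X = train_set.windows.astype(dtype, copy=False)
    y = train_set.labels

    opt = Adam(model.parameters(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng(config.seed + 1)
    history: Dict[str, List[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }
    best_val = np.inf
    best_epoch = -1
    best_state = None
    stale = 0

    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(y))
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least two samples
            opt.zero_grad()
            logits = model.forward(X[idx])
            loss = bce_with_logits(logits, y[idx])
            if not np.isfinite(loss.item()):
                raise PhosKANError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            (loss * scale).backward() if scale != 1.0 else loss.backward()
            opt.step(grad_scale=scale)
            epoch_losses.append(loss.item())

        recalibrate_batchnorm(model, X, batch_size=max(config.batch_size,
                                                       256))
        train_loss, train_acc = _epoch_eval(model, train_set,
                                            config.batch_size)
        val_loss, val_acc = _epoch_eval(model, val_set, config.batch_size)
        history["train_loss"].append(train_loss)
        history["train_acc"].append(train_acc)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}/{train_acc:.3f}"
                  f"  val {val_loss:.4f}/{val_acc:.3f}")

        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            best_epoch = epoch
            best_state = {k: v.copy()
                          for k, v in model.state_arrays().items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_loss=float(best_val))


# ---------------------------------------------------------------------------
# Protein-grouped stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Protein-to-fold assignment for k-fold CV; a protein's sites never
    straddle folds."""

    k: int
    fold_assignments: Dict[str, int]
    seed: int

    def fold_of(self, protein_id: str) -> int:
        return self.fold_assignments[protein_id]

    def fold_indices(self, protein_ids: Sequence[str],
                     fold: int) -> Tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx) over samples for one fold."""
        assign = np.asarray([self.fold_assignments[p] for p in protein_ids])
        return np.flatnonzero(assign != fold), np.flatnonzero(assign == fold)


def make_fold_plan(protein_ids: Sequence[str], labels: Sequence,
                   k: int = 10, seed: int = 0) -> FoldPlan:
    """Grouped stratified k-fold assignment at protein granularity.

    ``protein_ids`` and ``labels`` are per-site; the assignment keeps the
    per-fold positive fraction close to the global one while holding all
    sites of a protein in the same fold.
    """
    pids = list(protein_ids)
    y = np.asarray([1 if v in (1, "P", True) else 0 for v in labels])
    uniq = list(dict.fromkeys(pids))
    if len(uniq) < k:
        raise PhosKANError(
            f"{len(uniq)} proteins cannot fill {k} folds"
        )
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                    random_state=seed)
    assignments: Dict[str, int] = {}
    groups = np.asarray(pids)
    for fold, (_, val_idx) in enumerate(
        splitter.split(np.zeros(len(y)), y, groups)
    ):
        for pid in np.unique(groups[val_idx]):
            assignments[str(pid)] = fold
    return FoldPlan(k=k, fold_assignments=assignments, seed=seed)
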