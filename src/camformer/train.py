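"""Training loop, seed ensembles, subsampling curves and grid generation.

Training follows the recipe used for the competition model: minibatch descent
on a robust regression loss (L1 by default), AdamW, a cap of 50 epochs, and
early stopping on the sum of Pearson and Spearman correlation (r + rho) on a
held-out validation split, restoring the best epoch's weights.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import EncodingScheme, PromoterRecord, encode_batch
from .metrics import correlations
from .nn import LOSSES, OPTIMIZERS, SCHEDULERS, loss_and_grad, lr_at_epoch, \
    make_optimizer
from .zoo import Model, ModelConfig, build_model, load_preset


@dataclass
class TrainConfig:
    loss: str = "L1"
    optimizer: str = "AdamW"
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 128
    max_epochs: int = 50
    val_fraction: float = 0.10
    patience: int = 5
    seed: int = 0
    scheduler: str = "none"

    def __post_init__(self) -> None:
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if self.scheduler not in SCHEDULERS:
            raise ValueError(f"scheduler must be one of {SCHEDULERS}")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_r: list[float] = field(default_factory=list)
    val_rho: list[float] = field(default_factory=list)
    val_score: list[float] = field(default_factory=list)  # r + rho
    best_epoch: int = 0          # 1-based
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def split_train_val(records: list, val_fraction: float, seed: int
                    ) -> tuple[list, list]:
    """Disjoint uniform random split; validation size = round(n * fraction)."""
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_val = int(round(n * val_fraction))
    n_val = min(max(n_val, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    val_idx = set(perm[:n_val].tolist())
    train = [records[i] for i in perm[n_val:]]
    val = [records[i] for i in perm[:n_val]]
    return train, val


def _safe_corr(y, p) -> tuple[float, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _, rho = correlations(y, p)
    return r, rho


def train(model: Model, train_records: list[PromoterRecord],
          val_records: list[PromoterRecord], config: TrainConfig,
          scheme: EncodingScheme | str = "onehot",
          ) -> tuple[Model, TrainHistory]:
    """Fit ``model`` in place; returns it with best-epoch weights restored."""
    if isinstance(scheme, str):
        scheme = EncodingScheme(scheme)
    x = encode_batch(train_records, scheme).to_ncl()
    y = np.array([r.expression for r in train_records], dtype=np.float64)
    xv = encode_batch(val_records, scheme).to_ncl()
    yv = np.array([r.expression for r in val_records], dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    opt = make_optimizer(config.optimizer, model.net.parameter_refs(),
                         lr=config.learning_rate,
                         weight_decay=config.weight_decay)
    history = TrainHistory()
    best_score = -np.inf
    best_state = model.net.copy_state()
    since_best = 0
    n = x.shape[0]
    for epoch in range(config.max_epochs):
        opt.lr = lr_at_epoch(config.learning_rate, epoch, config.scheduler,
                             config.max_epochs)
        model.train_mode()
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            if idx.size < 2:
                continue  # batch-norm needs at least two samples
            model.net.zero_grad()
            pred = model.net.forward(x[idx], train=True)
            val, dpred = loss_and_grad(config.loss, pred, y[idx])
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    f"try a lower learning rate")
            model.net.backward(dpred)
            opt.step()
            losses.append(val)
        model.eval_mode()
        pv = model.forward(xv)
        r, rho = _safe_corr(yv, pv)
        score = r + rho
        history.train_loss.append(float(np.mean(losses)))
        history.val_r.append(r)
        history.val_rho.append(rho)
        history.val_score.append(score)
        if score > best_score:
            best_score = score
            best_state = model.net.copy_state()
            history.best_epoch = epoch + 1
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                history.stopped_early = True
                break
    model.net.load_state_dict(best_state)
    model.eval_mode()
    return model, history


def ensemble_predict(prediction_vectors: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of k prediction vectors (a seed ensemble)."""
    if not prediction_vectors:
        raise ValueError("need at least one prediction vector")
    arrs = [np.asarray(v, dtype=float).ravel() for v in prediction_vectors]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("prediction vectors differ in length")
    return np.mean(arrs, axis=0)


def subsample_curve(records: list[PromoterRecord], fractions: list[float],
                    model_config: ModelConfig, train_config: TrainConfig,
                    scheme: EncodingScheme | str = "onehot",
                    holdout_fraction: float = 0.2) -> pd.DataFrame:
    """Held-out performance as a function of training-set size.

    A single held-out set is fixed first; the training subsets are nested
    (each larger fraction's subset contains every smaller one's), so the
    curve isolates the effect of data volume.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    pool, held = split_train_val(records, holdout_fraction,
                                 seed=train_config.seed)
    order = np.random.default_rng(train_config.seed + 1).permutation(len(pool))
    yh = [r.expression for r in held]
    rows = []
    for frac in sorted(fractions):
        m = int(round(frac * len(pool)))
        if m < train_config.batch_size:
            raise ValueError(
                f"fraction {frac} yields {m} < batch_size examples")
        subset = [pool[i] for i in order[:m]]
        tr, va = split_train_val(subset, train_config.val_fraction,
                                 seed=train_config.seed)
        model = build_model(model_config, seed=train_config.seed)
        model, _ = train(model, tr, va, train_config, scheme)
        pred = model.forward(encode_batch(held, scheme))
        r, rho = _safe_corr(yh, pred)
        rows.append({"fraction": frac, "n_train": m, "r": r, "rho": rho})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# grid search configuration generation

DEFAULT_AXES = {
    "encoding": ["onehot", "onehotWithP", "onehotWithN", "onehotWithInt",
                 "onehotWithBoth"],
    "loss": ["L1", "MSE", "Huber"],
    "optimizer": ["AdamW", "Lion"],
    "scheduler": ["none", "step", "cosine"],
}
DEFAULT_STRUCTURES = ["camformer", "camformer_small", "camformer_mini"]


def generate_grid(option_sets: dict[str, list[str]] | None = None,
                  structures: list[str | ModelConfig] | None = None,
                  base_train_config: TrainConfig | None = None,
                  ) -> list[tuple[ModelConfig, TrainConfig, EncodingScheme]]:
    """Cartesian product of structures x encodings x losses x optimizers x
    schedulers, in deterministic lexicographic order over the option axes."""
    axes = dict(DEFAULT_AXES)
    if option_sets:
        axes.update(option_sets)
    for k, v in axes.items():
        if not v:
            raise ValueError(f"empty option set for axis {k!r}")
    structures = structures if structures is not None else DEFAULT_STRUCTURES
    if not structures:
        raise ValueError("need at least one model structure")
    base = base_train_config or TrainConfig()
    out = []
    for struct, enc, loss, optim, sched in itertools.product(
            structures, axes["encoding"], axes["loss"], axes["optimizer"],
            axes["scheduler"]):
        scheme = EncodingScheme(enc)
        if isinstance(struct, str):
            mcfg = load_preset(struct, encoding=scheme)
        else:
            mcfg = replace(struct, input_channels=scheme.channels)
        tcfg = replace(base, loss=loss, optimizer=optim, scheduler=sched)
        out.append((mcfg, tcfg, scheme))
    return out
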