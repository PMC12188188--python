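"""Scikit-learn style regressor wrapping the full preprocessing + training
stack: sequences in, expression out."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import EncodingScheme, PromoterRecord, encode_batch, \
    filter_standardize
from .train import TrainConfig, split_train_val, train
from .zoo import ModelConfig, build_model, load_preset


class CamformerRegressor(BaseEstimator, RegressorMixin):
    """Residual-CNN promoter expression regressor.

    Parameters mirror the training recipe: architecture preset (or explicit
    :class:`ModelConfig`), sequence encoding scheme, loss, optimizer, learning
    rate, and the early-stopping setup (validation fraction, patience,
    monitored score r + rho).

    Fitted attributes
    -----------------
    model_ : the realised network with best-epoch weights
    history_ : per-epoch training loss and validation correlations
    filter_report_ : counts from sequence standardisation
    """

    def __init__(self, preset: str = "camformer_tiny",
                 model_config: ModelConfig | None = None,
                 encoding: str = "onehot", loss: str = "L1",
                 optimizer: str = "AdamW", learning_rate: float = 1e-3,
                 weight_decay: float = 0.01, batch_size: int = 128,
                 max_epochs: int = 50, val_fraction: float = 0.10,
                 patience: int = 5, scheduler: str = "none",
                 random_state: int = 0):
        self.preset = preset
        self.model_config = model_config
        self.encoding = encoding
        self.loss = loss
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.patience = patience
        self.scheduler = scheduler
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    def _records(self, X, y=None) -> list[PromoterRecord]:
        seqs = list(X)
        if y is None:
            y = np.full(len(seqs), np.nan)
        y = np.asarray(y, dtype=float).ravel()
        if len(seqs) != y.size:
            raise ValueError("X and y differ in length")
        recs = [PromoterRecord(str(s).upper(), float(v))
                for s, v in zip(seqs, y)]
        kept, report = filter_standardize(recs)
        if y is not None:
            self.filter_report_ = report
        return kept

    def fit(self, X, y) -> "CamformerRegressor":
        """Fit on promoter sequences X (iterable of strings) and expression y."""
        records = self._records(X, y)
        if len(records) < 2:
            raise ValueError("fewer than 2 usable sequences after filtering")
        scheme = EncodingScheme(self.encoding)
        cfg = self.model_config or load_preset(self.preset, encoding=scheme)
        tcfg = TrainConfig(
            loss=self.loss, optimizer=self.optimizer,
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            val_fraction=self.val_fraction, patience=self.patience,
            seed=self.random_state, scheduler=self.scheduler)
        tr, va = split_train_val(records, self.val_fraction,
                                 seed=self.random_state)
        model = build_model(cfg, seed=self.random_state)
        self.model_, self.history_ = train(model, tr, va, tcfg, scheme)
        self.scheme_ = scheme
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        recs = self._records(X)
        return self.model_.forward(encode_batch(recs, self.scheme_))
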