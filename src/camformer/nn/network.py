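"""Residual 1-D convolutional network for sequence-to-scalar regression.

The architecture family: a stack of same-length conv layers (each followed by
optional batch normalisation and ReLU), additive identity skips over selected
two-layer blocks, an optional single max pooling before flattening, and a
fully connected head ending in one scalar output.

A skip over the block ending at conv layer *i* adds the input of layer *i-1*
to the pre-activation output of layer *i*.  When the skip source has fewer
channels than the target (only possible in the first block, whose input is the
encoded sequence), the source is zero-padded along the channel axis — a
parameter-free projection in the style of ResNet option A.
"""

from __future__ import annotations

import copy

import numpy as np

from .layers import (BatchNorm1d, Conv1d, Dropout, Flatten, Linear,
                     MaxPool1d, ReLU)


class ConvNet:
    def __init__(self, input_channels: int, conv_channels: list[int],
                 kernel_sizes: list[int], residual_after: list[int],
                 batchnorm: bool, pool_width: int | None,
                 fc_dims: list[int], dropout: list[float],
                 seq_len: int = 110, seed: int = 0,
                 dtype: np.dtype = np.float32) -> None:
        if len(conv_channels) != len(kernel_sizes):
            raise ValueError("conv_channels and kernel_sizes length mismatch")
        n_conv = len(conv_channels)
        self.residual_after = sorted(set(residual_after))
        for i in self.residual_after:
            if not 2 <= i <= n_conv:
                raise ValueError(
                    f"residual skip after layer {i} needs two preceding "
                    f"conv layers (model has {n_conv})")
        for a, b in zip(self.residual_after, self.residual_after[1:]):
            if b - a < 2:
                raise ValueError("residual two-layer blocks must not overlap")
        # skip target channel width must not be narrower than its source
        for i in self.residual_after:
            src = conv_channels[i - 3] if i >= 3 else input_channels
            if src > conv_channels[i - 1]:
                raise ValueError(
                    f"residual skip into layer {i}: source has {src} channels "
                    f"but target only {conv_channels[i - 1]}")
        rng = np.random.default_rng(seed)
        self.input_channels = input_channels
        self.seq_len = seq_len
        self.dtype = dtype
        self.convs: list[Conv1d] = []
        self.bns: list[BatchNorm1d | None] = []
        self.relus: list[ReLU] = []
        c_in = input_channels
        for c_out, k in zip(conv_channels, kernel_sizes):
            self.convs.append(Conv1d(c_in, c_out, k, rng=rng, dtype=dtype))
            self.bns.append(BatchNorm1d(c_out, dtype=dtype) if batchnorm else None)
            self.relus.append(ReLU())
            c_in = c_out
        self.pool = MaxPool1d(pool_width) if pool_width else None
        self.flatten = Flatten()
        pooled_len = seq_len // pool_width if pool_width else seq_len
        flat = pooled_len * conv_channels[-1]
        self.fc: list[Linear] = []
        self.fc_relus: list[ReLU] = []
        self.fc_drops: list[Dropout] = []
        d_in = flat
        drop = list(dropout) + [0.0] * max(0, len(fc_dims) - len(dropout))
        for width, rate in zip(fc_dims, drop):
            self.fc.append(Linear(d_in, width, rng=rng, dtype=dtype))
            self.fc_relus.append(ReLU())
            self.fc_drops.append(Dropout(rate, rng=np.random.default_rng(
                rng.integers(2 ** 31))))
            d_in = width
        self.out = Linear(d_in, 1, rng=rng, dtype=dtype)
        # caches populated by forward(capture=...) / backward(capture=...)
        self.block_outputs: list[np.ndarray] | None = None
        self.block_grads: dict[int, np.ndarray] | None = None

    # ------------------------------------------------------------------ #
    @property
    def n_conv(self) -> int:
        return len(self.convs)

    def layers(self):
        for lyr in self.convs + [b for b in self.bns if b is not None]:
            yield lyr
        yield from self.fc
        yield self.out

    def parameter_refs(self) -> list[tuple[object, str]]:
        return [(lyr, name) for lyr in self.layers() if lyr.trainable
                for name in lyr.params]

    def n_parameters(self) -> int:
        return sum(lyr.n_parameters() for lyr in self.layers())

    def zero_grad(self) -> None:
        for lyr in self.layers():
            lyr.zero_grad()

    # ------------------------------------------------------------------ #
    @staticmethod
    def _pad_channels(x: np.ndarray, channels: int) -> np.ndarray:
        if x.shape[1] == channels:
            return x
        return np.pad(x, ((0, 0), (0, channels - x.shape[1]), (0, 0)))

    def forward(self, x: np.ndarray, train: bool = False,
                capture: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.input_channels:
            raise ValueError(
                f"expected input of shape (n, {self.input_channels}, L), "
                f"got {x.shape}")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        layer_inputs: list[np.ndarray] = []
        outputs: list[np.ndarray] = []
        self._skip_sources: dict[int, np.ndarray] = {}
        act = x
        for i in range(1, self.n_conv + 1):
            layer_inputs.append(act)
            pre = self.convs[i - 1].forward(act, train)
            if self.bns[i - 1] is not None:
                pre = self.bns[i - 1].forward(pre, train)
            if i in self.residual_after:
                src = layer_inputs[i - 2]
                self._skip_sources[i] = src
                pre = pre + self._pad_channels(src, pre.shape[1])
            act = self.relus[i - 1].forward(pre, train)
            outputs.append(act)
        self.block_outputs = outputs if capture else None
        h = self.pool.forward(act, train) if self.pool else act
        h = self.flatten.forward(h, train)
        for lin, relu, dp in zip(self.fc, self.fc_relus, self.fc_drops):
            h = dp.forward(relu.forward(lin.forward(h, train), train), train)
        y = self.out.forward(h, train)
        return y[:, 0]

    def backward(self, dpred: np.ndarray, capture: bool = False) -> np.ndarray:
        """Backpropagate d(loss)/d(prediction); returns gradient w.r.t. the
        encoded input. With ``capture``, also stores the gradient of the
        objective w.r.t. each conv block's (post-activation) output."""
        g = self.out.backward(np.asarray(dpred, dtype=self.dtype)[:, None])
        for lin, relu, dp in zip(reversed(self.fc), reversed(self.fc_relus),
                                 reversed(self.fc_drops)):
            g = lin.backward(relu.backward(dp.backward(g)))
        g = self.flatten.backward(g)
        if self.pool:
            g = self.pool.backward(g)
        self.block_grads = {} if capture else None
        skip_into_input_of: dict[int, np.ndarray] = {}
        for i in range(self.n_conv, 0, -1):
            if capture:
                self.block_grads[i] = g
            d_pre = self.relus[i - 1].backward(g)
            if i in self.residual_after:
                src = self._skip_sources[i]
                skip_into_input_of[i - 1] = d_pre[:, :src.shape[1], :]
            if self.bns[i - 1] is not None:
                d_pre = self.bns[i - 1].backward(d_pre)
            g = self.convs[i - 1].backward(d_pre)
            if i in skip_into_input_of:
                g = g + skip_into_input_of.pop(i)
        return g

    # ------------------------------------------------------------------ #
    def state_dict(self) -> dict:
        state = {}
        for j, lyr in enumerate(self.layers()):
            for name, arr in lyr.params.items():
                state[f"{j}.{name}"] = arr.copy()
        for j, bn in enumerate(b for b in self.bns if b is not None):
            state[f"bn{j}.running_mean"] = bn.running_mean.copy()
            state[f"bn{j}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for j, lyr in enumerate(self.layers()):
            for name in lyr.params:
                lyr.params[name] = state[f"{j}.{name}"].copy()
        for j, bn in enumerate(b for b in self.bns if b is not None):
            bn.running_mean = state[f"bn{j}.running_mean"].copy()
            bn.running_var = state[f"bn{j}.running_var"].copy()

    def copy_state(self) -> dict:
        return copy.deepcopy(self.state_dict())
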