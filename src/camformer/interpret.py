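"""Model explainability: in-silico saturation mutagenesis (ISM), Grad-CAM for
1-D convolutions, saliency aggregation and activation embeddings.

ISM evaluates the model on every single-base substitution across the variable
region (positions 18-97, 1-based): 3 variants per position, 240 for an N-free
promoter.  The per-position importance is the *negative* mean effect of the
three substitutions, so a positive importance marks a base whose mutation
lowers predicted expression (an activating base), and vice versa.

Grad-CAM for this regression model weights each channel of a conv block's
feature map by the position-averaged gradient of the (raw scalar) output with
respect to that feature map, sums, rectifies, and linearly interpolates the
result back to input coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import (BASES, EncodingScheme, PromoterRecord, SEQ_LEN,
                   VARIABLE_REGION, encode_batch)
from .zoo import Model, layer_output


@dataclass
class ISMResult:
    delta: np.ndarray        # (region length, 4): f(variant) - f(reference)
    importance: np.ndarray   # (region length,): -mean of non-reference deltas
    reference: str
    region: tuple[int, int]
    skipped: list[int] = field(default_factory=list)  # N positions (1-based)

    @property
    def n_variants(self) -> int:
        return 3 * ((self.region[1] - self.region[0] + 1) - len(self.skipped))


@dataclass
class SaliencyMap:
    scores: np.ndarray       # length 110, nonnegative
    layer: int
    sequence_id: int


def ism(model: Model, record: PromoterRecord | str,
        region: tuple[int, int] = VARIABLE_REGION,
        scheme: EncodingScheme | str = "onehot",
        batch_size: int = 256) -> ISMResult:
    """Saturation mutagenesis of one standardised promoter.

    Positions holding N are skipped (no reference prediction to compare
    against) and recorded in ``skipped``.  Results are independent of
    ``batch_size`` because predictions run in eval mode.
    """
    if isinstance(record, str):
        record = PromoterRecord(record, float("nan"))
    seq = record.sequence
    if len(seq) != SEQ_LEN:
        raise ValueError(f"sequence must be standardised to {SEQ_LEN} nt")
    lo, hi = region
    if not 1 <= lo <= hi <= SEQ_LEN:
        raise ValueError(f"region {region} outside 1..{SEQ_LEN}")
    width = hi - lo + 1
    variants: list[PromoterRecord] = [record]
    slots: list[tuple[int, int]] = []
    skipped: list[int] = []
    for pos in range(lo, hi + 1):
        ref = seq[pos - 1]
        if ref == "N":
            skipped.append(pos)
            continue
        for b_i, base in enumerate(BASES):
            if base == ref:
                continue
            variants.append(PromoterRecord(
                seq[:pos - 1] + base + seq[pos:], record.expression,
                record.support))
            slots.append((pos - lo, b_i))
    preds = model.forward(encode_batch(variants, scheme),
                          batch_size=batch_size)
    f0 = preds[0]
    delta = np.zeros((width, 4))
    for (row, col), fv in zip(slots, preds[1:]):
        delta[row, col] = fv - f0
    importance = np.zeros(width)
    for pos in range(lo, hi + 1):
        if pos in skipped:
            continue
        ref_i = BASES.index(seq[pos - 1])
        others = [delta[pos - lo, j] for j in range(4) if j != ref_i]
        importance[pos - lo] = -float(np.mean(others))
    return ISMResult(delta=delta, importance=importance, reference=seq,
                     region=region, skipped=skipped)


def ism_entropy(result: ISMResult, base: float = np.e) -> float:
    """Entropy of the normalised absolute importance profile.

    Low entropy means the importance is concentrated on few positions (a
    sharp motif); the maximum, log(region length), means a flat profile.
    An all-zero profile is defined as that maximum, with a warning.
    """
    a = np.abs(result.importance)
    total = a.sum()
    if total == 0:
        warnings.warn("all-zero importance; entropy set to log(region length)",
                      stacklevel=2)
        return float(np.log(a.size) / np.log(base))
    p = a / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(base))


def gradcam(model: Model, batch, layer_index: int,
            chunk_size: int = 256) -> list[SaliencyMap]:
    """Grad-CAM saliency of the scalar output w.r.t. one conv block's
    feature map, one nonnegative length-110 map per input sequence."""
    if not 1 <= layer_index <= model.net.n_conv:
        raise ValueError(
            f"layer_index must be in 1..{model.net.n_conv}")
    x = model._as_ncl(batch)
    maps: list[SaliencyMap] = []
    for start in range(0, x.shape[0], chunk_size):
        xb = x[start:start + chunk_size]
        model.net.forward(xb, train=False, capture=True)
        feats = model.net.block_outputs[layer_index - 1]       # (n, c, L)
        model.net.backward(np.ones(xb.shape[0]), capture=True)
        grads = model.net.block_grads[layer_index]             # (n, c, L)
        w = grads.mean(axis=2)                                 # (n, c)
        cam = np.maximum((w[:, :, None] * feats).sum(axis=1), 0.0)
        Lp = cam.shape[1]
        src = np.arange(Lp) * (SEQ_LEN - 1) / max(Lp - 1, 1)
        dst = np.arange(SEQ_LEN)
        for i in range(cam.shape[0]):
            up = np.interp(dst, src, cam[i]) if Lp > 1 \
                else np.full(SEQ_LEN, cam[i, 0])
            maps.append(SaliencyMap(scores=up, layer=layer_index,
                                    sequence_id=start + i))
    return maps


def average_saliency(maps: list[SaliencyMap]) -> np.ndarray:
    """Positionwise mean saliency over maps from a single layer."""
    if not maps:
        raise ValueError("need at least one saliency map")
    layers = {m.layer for m in maps}
    if len(layers) != 1:
        raise ValueError(f"maps come from mixed layers {sorted(layers)}")
    return np.mean([m.scores for m in maps], axis=0)


def activation_embedding(model: Model, batch, layer_index: int) -> np.ndarray:
    """Flattened conv-block activations, one row per sequence
    (d = positions x 1 x channels)."""
    act = layer_output(model, batch, layer_index)
    return act.reshape(act.shape[0], -1)


def gc_content(sequence: str, region: tuple[int, int] | None = None) -> float:
    """(G+C) / called bases within the 1-based inclusive region."""
    if region is not None:
        lo, hi = region
        if not 1 <= lo <= hi <= len(sequence):
            raise ValueError(f"region {region} outside sequence")
        sequence = sequence[lo - 1:hi]
    called = sum(sequence.count(b) for b in BASES)
    if called == 0:
        raise ValueError("region contains no called bases")
    return (sequence.count("G") + sequence.count("C")) / called


def write_ism_table(result: ISMResult, path) -> None:
    """Per-position TSV: position, ref base, dA, dC, dG, dT, importance."""
    lo, hi = result.region
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("position\tref\tdA\tdC\tdG\tdT\timportance\n")
        for pos in range(lo, hi + 1):
            i = pos - lo
            d = "\t".join(f"{v:.6g}" for v in result.delta[i])
            fh.write(f"{pos}\t{result.reference[pos - 1]}\t{d}\t"
                     f"{result.importance[i]:.6g}\n")


def plot_ism(result: ISMResult, path) -> None:
    """Render the importance profile and substitution-effect heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = result.region
    pos = np.arange(lo, hi + 1)
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(10, 4), sharex=True,
                                   height_ratios=[1, 1])
    ax0.bar(pos, result.importance, color="#33557a")
    ax0.set_ylabel("importance")
    im = ax1.imshow(result.delta.T, aspect="auto", cmap="RdBu_r",
                    extent=(lo - 0.5, hi + 0.5, 3.5, -0.5))
    ax1.set_yticks(range(4), list(BASES))
    ax1.set_xlabel("position")
    fig.colorbar(im, ax=ax1, label="delta prediction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
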