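"""PWM scanning, expression-extreme enrichment, and cis-regulatory
interaction analyses over model predictions.

The scanner is a log-odds sliding-window matcher over both strands (an
in-repo analogue of FIMO); enrichment contrasts motif presence in the top
versus bottom expression quantile with Fisher's exact test and
Benjamini-Hochberg correction (an in-repo analogue of SEA).  Results are
method-analogous to the MEME-suite tools, not bit-compatible with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import BASES, SEQ_LEN
from .interpret import ISMResult
from .simulate import reverse_complement

_RC_ROWS = [3, 2, 1, 0]  # A<->T, C<->G


@dataclass
class PWM:
    name: str
    probs: np.ndarray                    # 4 x w, rows A,C,G,T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError(f"PWM {self.name}: probs must be 4 x w")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"PWM {self.name}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """4 x w log-odds matrix with pseudocount-renormalised probabilities."""
        p = (self.probs + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log(p / self.background[:, None])

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[_RC_ROWS, ::-1],
                   self.background[_RC_ROWS].copy(), self.pseudocount)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())


@dataclass
class MotifHit:
    sequence_id: int | str
    motif: str
    start: int          # 1-based position of the window on the + sequence
    strand: str         # '+' or '-'
    score: float
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width - 1


# --------------------------------------------------------------------------- #
# MEME minimal format

def read_meme(path, pseudocount: float = 0.001) -> list[PWM]:
    """Read PWMs from a MEME minimal motif file."""
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    bg = np.array([parsed.background.get(b, 0.25) for b in BASES]) \
        if getattr(parsed, "background", None) else np.full(4, 0.25)
    out = []
    for m in parsed:
        w = m.length
        probs = np.array([[m.pwm[b][j] for j in range(w)] for b in BASES])
        probs = probs / probs.sum(axis=0, keepdims=True)
        out.append(PWM(m.name, probs, bg / bg.sum(), pseudocount))
    return out


def write_meme(pwms: list[PWM], path) -> None:
    """Write PWMs in MEME minimal motif format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n"
                 "strands: + -\n\n"
                 "Background letter frequencies\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write(" ".join(f"{b} {v:.5f}" for b, v in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 1000000 E= 0\n")
            for j in range(pwm.width):
                fh.write(" ".join(f"{pwm.probs[i, j]:.6f}"
                                  for i in range(4)) + "\n")
            fh.write("\n")


# --------------------------------------------------------------------------- #
# scanning

def _window_scores(seq: str, lo: np.ndarray) -> np.ndarray:
    """Score every window of width w under a 4 x w log-odds matrix; N
    contributes zero information."""
    w = lo.shape[1]
    if w > len(seq):
        raise ValueError(f"motif width {w} exceeds sequence length {len(seq)}")
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    arr = lut[idx]
    lo_ext = np.vstack([lo, np.zeros((1, w))])        # row 4: N -> 0
    from numpy.lib.stride_tricks import sliding_window_view
    wins = sliding_window_view(arr, w)
    return lo_ext[wins, np.arange(w)].sum(axis=1)


def scan(sequence: str, pwm: PWM, threshold: float = 0.0,
         sequence_id: int | str = 0) -> list[MotifHit]:
    """All windows on either strand scoring >= threshold (log-odds units)."""
    sequence = sequence.upper()
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm.log_odds()),
                        ("-", pwm.reverse_complement().log_odds())):
        scores = _window_scores(sequence, mat)
        for s in np.flatnonzero(scores >= threshold):
            hits.append(MotifHit(sequence_id=sequence_id, motif=pwm.name,
                                 start=int(s) + 1, strand=strand,
                                 score=float(scores[s]), width=pwm.width))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_library(sequences: list[str], pwms: list[PWM],
                 threshold: float = 0.0) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for i, seq in enumerate(sequences):
        for pwm in pwms:
            hits.extend(scan(seq, pwm, threshold, sequence_id=i))
    return hits


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sequence_id": h.sequence_id, "motif": h.motif, "start": h.start,
          "strand": h.strand, "score": h.score, "width": h.width}
         for h in hits],
        columns=["sequence_id", "motif", "start", "strand", "score", "width"])


# --------------------------------------------------------------------------- #
# enrichment in expression extremes

def enrichment(sequences: list[str], expressions, pwms: list[PWM],
               quantiles: int = 10, threshold: float = 0.0) -> pd.DataFrame:
    """Fisher's exact test of motif presence in the top versus bottom
    expression quantile, BH-adjusted across motifs."""
    expr = np.asarray(expressions, dtype=float)
    if expr.size != len(sequences):
        raise ValueError("sequences and expressions differ in length")
    if quantiles < 2:
        raise ValueError("need at least 2 quantiles")
    q = np.asarray(pd.qcut(expr, quantiles, labels=False,
                           duplicates="drop"), dtype=float)
    finite = q[np.isfinite(q)]
    if finite.size == 0 or finite.max() == finite.min():
        raise ValueError("empty extreme quantile: all records fall in one "
                         "expression quantile")
    top = q == finite.max()
    bottom = q == finite.min()
    rows = []
    for pwm in pwms:
        present = np.array([len(scan(s, pwm, threshold)) > 0
                            for s in sequences])
        a = int((present & top).sum())
        b = int((~present & top).sum())
        c = int((present & bottom).sum())
        d = int((~present & bottom).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        rows.append({"motif": pwm.name, "top_with": a, "bottom_with": c,
                     "odds_ratio": float(odds), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# --------------------------------------------------------------------------- #
# pairwise co-occurrence and feature correlations

def cooccurrence_expression(predictions, hits: list[MotifHit],
                            min_n: int = 5
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean prediction for sequences carrying pairs of motifs.

    Pair matrix M[i, j] = mean prediction over sequences with at least one
    hit of motif i and one of motif j (diagonal: motif i alone, the baseline);
    difference matrix D[i, j] = M[i, j] - M[i, i].  Cells supported by fewer
    than ``min_n`` sequences are NaN.
    """
    pred = dict(predictions) if isinstance(predictions, dict) else \
        {i: float(v) for i, v in enumerate(np.asarray(predictions).ravel())}
    by_motif: dict[str, set] = {}
    for h in hits:
        by_motif.setdefault(h.motif, set()).add(h.sequence_id)
    names = sorted(by_motif)
    M = pd.DataFrame(np.nan, index=names, columns=names)
    support = pd.DataFrame(0, index=names, columns=names)
    for i in names:
        for j in names:
            ids = by_motif[i] & by_motif[j]
            vals = [pred[s] for s in ids if s in pred]
            support.loc[i, j] = len(vals)
            if len(vals) >= min_n:
                M.loc[i, j] = float(np.mean(vals))
    D = M.sub(np.diag(M.values.astype(float)), axis=0)
    return M, D


def feature_correlations(predictions, hits: list[MotifHit]) -> pd.DataFrame:
    """Pearson r between prediction and per-sequence motif count, best hit
    score, and best-hit position, per motif (over sequences with >= 1 hit).
    Zero-variance features (e.g. all hits at the consensus score) are NaN."""
    pred = dict(predictions) if isinstance(predictions, dict) else \
        {i: float(v) for i, v in enumerate(np.asarray(predictions).ravel())}
    per: dict[str, dict] = {}
    for h in hits:
        if h.sequence_id not in pred:
            continue
        d = per.setdefault(h.motif, {})
        e = d.setdefault(h.sequence_id, {"count": 0, "score": -np.inf,
                                         "position": 0})
        e["count"] += 1
        if h.score > e["score"]:
            e["score"] = h.score
            e["position"] = h.start
    rows = []
    for motif in sorted(per):
        entries = per[motif]
        ids = sorted(entries)
        y = np.array([pred[s] for s in ids])
        row = {"motif": motif, "n": len(ids)}
        for feat in ("count", "score", "position"):
            x = np.array([entries[s][feat] for s in ids], dtype=float)
            if len(ids) < 2 or x.std() == 0 or y.std() == 0:
                row[feat] = np.nan
            else:
                row[feat] = float(np.corrcoef(x, y)[0, 1])
        rows.append(row)
    return pd.DataFrame(rows, columns=["motif", "n", "count", "score",
                                       "position"]).set_index("motif")


# --------------------------------------------------------------------------- #
# overlap-grouped ISM profiles

@dataclass
class GroupedISMProfile:
    alone_mean: np.ndarray     # positionwise mean importance, motif coords
    overlap_mean: np.ndarray   # NaN-filled when the group is empty
    n_alone: int
    n_overlap: int


def grouped_ism_profile(ism_results: dict, hits_a: list[MotifHit],
                        hits_b: list[MotifHit]) -> GroupedISMProfile:
    """Mean ISM importance across motif-A windows, grouped by whether the
    window overlaps (shares >= 1 position with) a motif-B hit.

    Windows are strand-oriented so all instances align 5'->3' along the
    motif.  A-hits whose window leaves the ISM region are skipped.
    """
    if not hits_a:
        raise ValueError("no hits for motif A")
    b_by_seq: dict = {}
    for h in hits_b:
        b_by_seq.setdefault(h.sequence_id, []).append((h.start, h.end))
    alone, overlap = [], []
    for h in hits_a:
        res: ISMResult | None = ism_results.get(h.sequence_id)
        if res is None:
            continue
        lo, hi = res.region
        if h.start < lo or h.end > hi:
            continue
        sub = res.importance[h.start - lo: h.end - lo + 1].astype(float)
        if h.strand == "-":
            sub = sub[::-1]
        has_overlap = any(not (e < h.start or s > h.end)
                          for s, e in b_by_seq.get(h.sequence_id, []))
        (overlap if has_overlap else alone).append(sub)
    w = hits_a[0].width
    alone_mean = np.mean(alone, axis=0) if alone else np.full(w, np.nan)
    overlap_mean = np.mean(overlap, axis=0) if overlap else np.full(w, np.nan)
    return GroupedISMProfile(alone_mean=alone_mean, overlap_mean=overlap_mean,
                             n_alone=len(alone), n_overlap=len(overlap))
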