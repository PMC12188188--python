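"""Evaluation suite: correlation metrics, per-category weighted scores,
baseline-normalised improvement, and bootstrap model comparison.

Per-category evaluation mirrors challenge-style scoring: Pearson r and
Spearman rho are computed within each promoter category, and the *Pearson
Score* / *Spearman Score* are weighted averages of the per-category values.
Category weights are a config input (the organisers' weights are not public);
the default is uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def _as_vec(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    return a


def correlations(y_true, y_pred) -> tuple[float, float, float]:
    """(Pearson r, r^2, Spearman rho); zero-variance input gives 0 + warning.

    Spearman uses average ranks for ties.
    """
    yt, yp = _as_vec(y_true, "y_true"), _as_vec(y_pred, "y_pred")
    if yt.size != yp.size:
        raise ValueError(f"length mismatch: {yt.size} vs {yp.size}")
    if yt.size < 2:
        raise ValueError("need at least 2 observations")
    if yt.std() == 0 or yp.std() == 0:
        warnings.warn("zero-variance input; correlation defined as 0",
                      stacklevel=2)
        return 0.0, 0.0, 0.0
    r = float(stats.pearsonr(yt, yp).statistic)
    rho = float(stats.spearmanr(yt, yp).statistic)
    return r, r * r, rho


def delta_norm(rho_baseline: float, rho_model: float) -> float:
    """Baseline-normalised improvement (rho2 - rho1) / (1 - rho1): the
    fraction of the remaining headroom above the baseline that is closed."""
    if rho_baseline >= 1:
        raise ValueError("rho_baseline must be < 1")
    return (rho_model - rho_baseline) / (1.0 - rho_baseline)


@dataclass
class EvalReport:
    per_category: dict[str, tuple[float, float, float, int]]
    overall: tuple[float, float, float]
    pearson_score: float
    spearman_score: float
    weights: dict[str, float]
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_category": {k: {"r": v[0], "r2": v[1], "rho": v[2], "n": v[3]}
                             for k, v in self.per_category.items()},
            "overall": {"r": self.overall[0], "r2": self.overall[1],
                        "rho": self.overall[2]},
            "pearson_score": self.pearson_score,
            "spearman_score": self.spearman_score,
            "weights": self.weights,
            "excluded": self.excluded,
        }


def category_report(y_true, y_pred, categories,
                    weights: dict[str, float] | None = None) -> EvalReport:
    """Per-category correlations plus weighted Pearson/Spearman scores.

    Categories with fewer than 2 observations are excluded from the weighted
    means and flagged in ``excluded``.
    """
    yt, yp = _as_vec(y_true, "y_true"), _as_vec(y_pred, "y_pred")
    cats = np.asarray(list(categories))
    if cats.size != yt.size:
        raise ValueError("categories must label every observation")
    names = sorted(set(cats.tolist()))
    if weights is None:
        weights = {c: 1.0 for c in names}
    unknown = set(weights) - set(names)
    if unknown:
        raise ValueError(f"weights reference unknown categories: "
                         f"{sorted(unknown)}")
    if any(w < 0 for w in weights.values()) or sum(weights.values()) == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    per, excluded = {}, []
    for c in names:
        mask = cats == c
        n = int(mask.sum())
        if n < 2:
            per[c] = (float("nan"), float("nan"), float("nan"), n)
            excluded.append(c)
            continue
        r, r2, rho = correlations(yt[mask], yp[mask])
        per[c] = (r, r2, rho, n)
    wsum = rsum = rhosum = 0.0
    for c, w in weights.items():
        if c in excluded or w == 0:
            continue
        wsum += w
        rsum += w * per[c][0]
        rhosum += w * per[c][2]
    if wsum == 0:
        raise ValueError("no category with >= 2 observations and weight > 0")
    overall = correlations(yt, yp)
    return EvalReport(per_category=per, overall=overall,
                      pearson_score=rsum / wsum,
                      spearman_score=rhosum / wsum,
                      weights=dict(weights), excluded=excluded)


# --------------------------------------------------------------------------- #

@dataclass
class BootstrapComparison:
    delta_r: np.ndarray       # per-replicate r(A) - r(B)
    delta_rho: np.ndarray
    p_value_r: float
    p_value_rho: float
    n_redrawn: int


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    return num / den


def bootstrap_compare(y_true, pred_a, pred_b, n_boot: int = 10_000,
                      seed: int = 0) -> BootstrapComparison:
    """Paired bootstrap comparison of two prediction sets.

    Each replicate resamples observation indices with replacement and computes
    Pearson r and Spearman rho of both prediction sets on the resample; a
    paired t-test is applied to the per-replicate differences.  Degenerate
    resamples (zero variance) are redrawn and counted.
    """
    yt = _as_vec(y_true, "y_true")
    pa, pb = _as_vec(pred_a, "pred_a"), _as_vec(pred_b, "pred_b")
    if not yt.size == pa.size == pb.size:
        raise ValueError("length mismatch")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = yt.size
    ra = np.empty(n_boot)
    rb = np.empty(n_boot)
    rhoa = np.empty(n_boot)
    rhob = np.empty(n_boot)
    n_redrawn = 0
    todo = np.arange(n_boot)
    while todo.size:
        idx = rng.integers(0, n, size=(todo.size, n))
        ys, pas, pbs = yt[idx], pa[idx], pb[idx]
        ok = (ys.std(axis=1) > 0) & (pas.std(axis=1) > 0) \
            & (pbs.std(axis=1) > 0)
        keep = todo[ok]
        ra[keep] = _rowwise_pearson(ys[ok], pas[ok])
        rb[keep] = _rowwise_pearson(ys[ok], pbs[ok])
        ranks_y = stats.rankdata(ys[ok], axis=1)
        rhoa[keep] = _rowwise_pearson(ranks_y, stats.rankdata(pas[ok], axis=1))
        rhob[keep] = _rowwise_pearson(ranks_y, stats.rankdata(pbs[ok], axis=1))
        n_redrawn += int((~ok).sum())
        todo = todo[~ok]
    if np.allclose(ra, rb):
        p_r = 1.0
    else:
        p_r = float(stats.ttest_rel(ra, rb).pvalue)
    if np.allclose(rhoa, rhob):
        p_rho = 1.0
    else:
        p_rho = float(stats.ttest_rel(rhoa, rhob).pvalue)
    return BootstrapComparison(delta_r=ra - rb, delta_rho=rhoa - rhob,
                               p_value_r=p_r, p_value_rho=p_rho,
                               n_redrawn=n_redrawn)
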