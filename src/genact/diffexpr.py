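"""Precision-weighted differential expression with moderated statistics.

Log2-CPM observations get inverse mean-variance-trend precision weights,
per-gene weighted least squares on a treatment(+block) design, an
empirical-Bayes moderated t against the pooled variance prior, and
Benjamini-Hochberg FDR control.  Filtering and summary rules mirror the
source pipeline exactly: activity in at least one sample type AND median
log2 expression strictly above the threshold for inclusion; q <= fdr
(inclusive) for significance; |log2FC| strictly above the cutoff for the
fold-change-filtered tally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .normalization import NormFactors, logcpm

__all__ = [
    "DEFilterSpec",
    "VoomData",
    "ModeratedResult",
    "build_design",
    "filter_expressed",
    "voom_transform",
    "fit_models",
    "moderate",
    "bh_adjust",
    "de_summary",
]


@dataclass(frozen=True)
class DEFilterSpec:
    median_threshold: float = 3.71
    fdr: float = 0.01
    lfc_cutoff: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")
        if not np.isfinite([self.median_threshold, self.lfc_cutoff]).all():
            raise ValueError("thresholds must be finite")


@dataclass
class VoomData:
    log2cpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray  # average log2 count grid of the lowess trend
    trend_y: np.ndarray  # sqrt(residual sd) on that grid


@dataclass
class ModeratedResult:
    table: pd.DataFrame  # gene_id idx; log2fc, mod_t, p, q, df, s2, s2_post
    d0: float
    s0_sq: float


def build_design(meta: pd.DataFrame, treatment_col: str = "sample_type",
                 block_col: str | None = "replicate") -> tuple[np.ndarray, int, list[str]]:
    """Intercept + treatment indicator (+ block dummies) design matrix.

    Returns (X, treatment column index, column names); the treatment
    indicator is 1 for the first sample-type level so its coefficient is
    type_a minus type_b.
    """
    levels = list(pd.unique(meta[treatment_col]))
    if len(levels) != 2:
        raise ValueError("exactly two treatment levels are required")
    cols = [np.ones(len(meta)), (meta[treatment_col] == levels[0]).to_numpy(dtype=float)]
    names = ["intercept", f"treatment[{levels[0]}]"]
    if block_col is not None and block_col in meta.columns:
        blocks = list(pd.unique(meta[block_col]))
        for b in blocks[1:]:
            cols.append((meta[block_col] == b).to_numpy(dtype=float))
            names.append(f"block[{b}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"design is rank deficient (rank {rank} < {X.shape[1]} columns): "
                         + ", ".join(names))
    return X, 1, names


def filter_expressed(log2cpm: pd.DataFrame, calls: pd.DataFrame,
                     spec: DEFilterSpec | None = None) -> pd.Index:
    """Genes active in >= 1 sample type with median log2 expression
    strictly greater than the threshold."""
    spec = spec or DEFilterSpec()
    if not log2cpm.index.equals(calls.index):
        calls = calls.reindex(log2cpm.index)
        if calls.isna().any().any():
            raise ValueError("activity calls do not cover the expression gene universe")
    active_any = calls.any(axis=1)
    med = log2cpm.median(axis=1)
    keep = active_any & (med > spec.median_threshold)
    return log2cpm.index[keep]


def voom_transform(counts, norm: NormFactors, design: np.ndarray,
                   span: float = 0.5, prior_count: float = 0.5) -> VoomData:
    """Mean-variance precision weights for log2-CPM observations.

    An unweighted first-pass fit per gene gives residual SDs; a lowess
    trend of sqrt(SD) against average log2 count is interpolated at each
    observation's predicted log2 count (constant extrapolation beyond the
    fitted range) and the weight is trend^-4.
    """
    y = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    G, n = y.shape
    if n < design.shape[1] or n - design.shape[1] < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    eff = norm.effective_library_size.to_numpy(dtype=float)
    logc = np.log2((y + prior_count) / (eff[None, :] + 2 * prior_count) * 1e6)

    # unweighted first pass
    Q, _ = np.linalg.qr(design)
    coef_proj = logc @ Q  # G x p
    fitted = coef_proj @ Q.T
    resid = logc - fitted
    df = n - design.shape[1]
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df)

    # trend in average log2-count space
    mean_lib = np.exp(np.mean(np.log(eff + 1.0)))
    sx = logc.mean(axis=1) + np.log2(mean_lib + 1.0) - np.log2(1e6)
    sy = np.sqrt(sigma)
    pos = sigma > 1e-10  # genes with exactly-zero residual variance carry no trend information
    order = np.argsort(sx[pos], kind="stable")
    tx = sx[pos][order]
    ty = lowess(sy[pos][order], tx, frac=span, it=0, return_sorted=False)

    # predicted log2 counts per observation from the first-pass fit
    pred = fitted + (np.log2(eff + 1.0) - np.log2(1e6))[None, :]
    w = np.interp(pred, tx, ty) ** -4  # np.interp extrapolates by holding the ends
    w = np.clip(w, 1e-12, None)
    genes = list(counts.index) if isinstance(counts, pd.DataFrame) else list(range(G))
    samples = list(counts.columns) if isinstance(counts, pd.DataFrame) else list(range(n))
    return VoomData(
        log2cpm=pd.DataFrame(logc, index=genes, columns=samples),
        weights=pd.DataFrame(w, index=genes, columns=samples),
        trend_x=tx,
        trend_y=np.asarray(ty, dtype=float),
    )


def fit_models(voom: VoomData, design: np.ndarray, contrast_col: int = 1) -> pd.DataFrame:
    """Per-gene weighted least squares; returns the treatment contrast.

    Columns: coef, stderr (at the per-gene residual SD), s2, df.
    """
    Y = voom.log2cpm.to_numpy(dtype=float)
    W = voom.weights.to_numpy(dtype=float)
    G, n = Y.shape
    p = design.shape[1]
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("design is rank deficient")
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")

    # batched normal equations: (X^T W X) b = X^T W y per gene
    Xw = W[:, :, None] * design[None, :, :]        # G x n x p
    XtWX = np.einsum("nj,gnk->gjk", design, Xw)    # G x p x p
    XtWy = np.einsum("gnj,gn->gj", Xw, Y)
    coef = np.linalg.solve(XtWX, XtWy[:, :, None])[:, :, 0]  # G x p
    fitted = coef @ design.T
    resid = Y - fitted
    rss = (W * resid ** 2).sum(axis=1)
    s2 = rss / df
    XtWX_inv = np.linalg.inv(XtWX)
    unscaled = np.sqrt(XtWX_inv[:, contrast_col, contrast_col])
    out = pd.DataFrame(
        {
            "coef": coef[:, contrast_col],
            "stderr": unscaled * np.sqrt(s2),
            "stdev_unscaled": unscaled,
            "s2": s2,
            "df": float(df),
        },
        index=voom.log2cpm.index,
    )
    return out


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to the sample variances: returns
    (d0, s0_sq); d0 = inf when the observed log-variance spread does not
    exceed its sampling component."""
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = len(z)
    excess = (((e - e_mean) ** 2).sum() * n / (n - 1.0)) / n - polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = excess by Newton on x = d0/2
    x = 0.5 + 1.0 / excess
    for _ in range(100):
        tri = polygamma(1, x)
        delta = tri * (excess - tri) / (excess * polygamma(2, x))
        x = x + delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * float(x)
    s0 = float(np.exp(e_mean + digamma(x) - np.log(x)))
    return d0, s0


def moderate(fits: pd.DataFrame, d0: float | None = None,
             s0_sq: float | None = None) -> ModeratedResult:
    """Empirical-Bayes moderated t-test for the fitted contrast.

    The prior (d0, s0^2) is estimated by moment matching of log s^2
    unless given; posterior variance s~2 = (d0*s0^2 + df*s2)/(d0 + df),
    mod_t = coef/(stdev_unscaled * s~), two-sided p on d0 + df degrees of
    freedom.
    """
    if len(fits) < 10 and d0 is None:
        raise ValueError("need >= 10 genes to estimate the variance prior")
    s2 = fits["s2"].to_numpy(dtype=float)
    df = fits["df"].to_numpy(dtype=float)
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = _fit_f_dist(s2, float(df[0]))
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df.copy()
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    coef = fits["coef"].to_numpy(dtype=float)
    unscaled = fits["stdev_unscaled"].to_numpy(dtype=float)
    mod_t = coef / (unscaled * np.sqrt(s2_post))
    with np.errstate(invalid="ignore"):
        p = np.where(
            np.isinf(df_total),
            2.0 * stats.norm.sf(np.abs(mod_t)),
            2.0 * stats.t.sf(np.abs(mod_t), df_total),
        )
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2fc": coef,
            "mod_t": mod_t,
            "p": p,
            "q": q,
            "df": df,
            "s2": s2,
            "s2_post": s2_post,
        },
        index=fits.index,
    )
    return ModeratedResult(table=table, d0=float(d0), s0_sq=float(s0_sq))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_summary(result: ModeratedResult, spec: DEFilterSpec | None = None) -> pd.Series:
    """DE tallies at q <= fdr, the strict |log2FC| filter, and per-direction
    average linear fold change of significant genes."""
    spec = spec or DEFilterSpec()
    t = result.table
    sig = t["q"] <= spec.fdr
    up = sig & (t["log2fc"] > 0)
    down = sig & (t["log2fc"] < 0)
    big = t["log2fc"].abs() > spec.lfc_cutoff
    mean_fc = lambda m: float(np.mean(2.0 ** t.loc[m, "log2fc"].abs())) if m.any() else float("nan")
    return pd.Series(
        {
            "n_tested": int(len(t)),
            "n_sig": int(sig.sum()),
            "n_up": int(up.sum()),
            "n_down": int(down.sum()),
            "n_up_lfc": int((up & big).sum()),
            "n_down_lfc": int((down & big).sum()),
            "avg_fc_up": mean_fc(up),
            "avg_fc_down": mean_fc(down),
        }
    )
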