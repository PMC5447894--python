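"""Between-sample and across-gene normalization.

TMM (trimmed mean of M-values) scaling factors, prior-count log2-CPM, and
a centered additive smooth of mean log expression on gene length and GC
content used as a per-gene offset in the count models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["NormFactors", "tmm_factors", "logcpm", "length_gc_offsets", "offset_matrix"]

_LN2 = np.log(2.0)


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors (geometric mean 1)."""

    library_size: pd.Series
    tmm_factor: pd.Series

    @property
    def effective_library_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


def _as_matrix(counts) -> tuple[np.ndarray, list, list]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index), list(counts.columns)
    arr = np.asarray(counts, dtype=float)
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def tmm_factors(counts, ref_sample=None, trim_m: float = 0.3, trim_a: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-M-values factors, rescaled to geometric mean 1.

    M/A values are computed per sample against a reference column (the one
    whose 75th-percentile CPM is closest to the mean of those percentiles,
    unless ``ref_sample`` is given); genes zero in either member of the
    pair are excluded; the upper/lower ``trim_m`` of M-values and ``trim_a``
    of A-values are trimmed; the mean of the surviving M-values is weighted
    by the inverse asymptotic binomial variance.
    """
    x, genes, samples = _as_matrix(counts)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("counts must be finite and non-negative")
    lib = x.sum(axis=0)
    zero_cols = np.where(lib == 0)[0]
    if zero_cols.size:
        names = ", ".join(str(samples[j]) for j in zero_cols)
        raise ValueError(f"sample(s) with all-zero counts: {names}")

    if ref_sample is None:
        q75 = np.array([np.quantile(x[:, j] / lib[j] * 1e6, 0.75) for j in range(x.shape[1])])
        ref = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref = samples.index(ref_sample)

    log_f = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        log_f[j] = _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a)
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        library_size=pd.Series(lib, index=samples, name="library_size"),
        tmm_factor=pd.Series(factors, index=samples, name="tmm_factor"),
    )


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    # doubly trimmed: keep genes inside both the M and the A trim bands
    keep_m = _trim_mask(m, trim_m)
    keep_a = _trim_mask(a, trim_a)
    keep = keep_m & keep_a
    if not keep.any() or np.abs(m[keep]).max() < 1e-10:
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def _trim_mask(v: np.ndarray, frac: float) -> np.ndarray:
    # rank-based two-sided trim matching the classical definition
    n = v.size
    lo = int(np.floor(n * frac)) + 1
    hi = n + 1 - lo
    rank = v.argsort(kind="stable").argsort(kind="stable") + 1
    return (rank >= lo) & (rank <= hi)


def _aligned(series: pd.Series, labels) -> np.ndarray:
    """Align a labeled series to ``labels``; fall back to positional order
    when the labels do not match (e.g. bare arrays)."""
    if len(series) != len(labels) and not all(l in series.index for l in labels):
        raise ValueError("cannot align normalization factors to the count matrix")
    if all(l in series.index for l in labels):
        return series.reindex(labels).to_numpy(dtype=float)
    return series.to_numpy(dtype=float)


def logcpm(counts, norm: NormFactors | None = None, prior_count: float = 0.5) -> pd.DataFrame:
    """log2((count + prior) / (effective library size + 2*prior) * 1e6)."""
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    x, genes, samples = _as_matrix(counts)
    if norm is None:
        eff = x.sum(axis=0)
    else:
        eff = _aligned(norm.effective_library_size, samples)
    if np.any(eff <= 0):
        raise ValueError("effective library sizes must be positive")
    out = np.log2((x + prior_count) / (eff[None, :] + 2.0 * prior_count) * 1e6)
    return pd.DataFrame(out, index=genes, columns=samples)


def length_gc_offsets(counts, features: pd.DataFrame, norm: NormFactors | None = None,
                      span: float = 0.5, n_backfit: int = 2) -> pd.Series:
    """Centered per-gene offsets (natural log) from an additive smooth of
    mean log2-CPM on z-scored log length and GC content.

    Fitted by ``n_backfit`` rounds of lowess backfitting; the result is
    constant across samples and sums to zero over genes (within fp error).
    """
    x, genes, _ = _as_matrix(counts)
    feats = features.set_index("gene_id") if "gene_id" in features.columns else features
    missing = [g for g in genes if g not in feats.index]
    if missing:
        shown = ", ".join(str(g) for g in missing[:10])
        raise ValueError(f"features missing for gene_id(s): {shown}")
    feats = feats.loc[genes]
    if (feats["length"] < 1).any():
        raise ValueError("gene lengths must be >= 1")
    if ((feats["gc"] < 0) | (feats["gc"] > 1)).any():
        raise ValueError("gc must lie in [0, 1]")

    y = logcpm(counts, norm).to_numpy().mean(axis=1)
    zl = _zscore(np.log(feats["length"].to_numpy(dtype=float)))
    zg = _zscore(feats["gc"].to_numpy(dtype=float))

    f_l = np.zeros_like(y)
    f_g = np.zeros_like(y)
    for _ in range(n_backfit):
        f_l = _smooth(zl, y - y.mean() - f_g, span)
        f_l -= f_l.mean()
        f_g = _smooth(zg, y - y.mean() - f_l, span)
        f_g -= f_g.mean()
    offset_log2 = f_l + f_g
    offset_log2 -= offset_log2.mean()
    return pd.Series(offset_log2 * _LN2, index=genes, name="length_gc_offset")


def _smooth(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    if np.ptp(x) == 0:
        return np.zeros_like(y)
    fitted = lowess(y, x, frac=span, it=0, return_sorted=False)
    return np.asarray(fitted, dtype=float)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def offset_matrix(counts, norm: NormFactors, gene_offsets: pd.Series | None = None) -> pd.DataFrame:
    """Gene x sample additive natural-log offsets for the count models:
    log(effective library size / 1e6) per sample plus the centered
    length/GC component per gene (so fixed effects live on the ln-CPM
    scale)."""
    x, genes, samples = _as_matrix(counts)
    eff = _aligned(norm.effective_library_size, samples)
    off = np.tile(np.log(eff / 1e6)[None, :], (len(genes), 1))
    if gene_offsets is not None:
        off = off + _aligned(gene_offsets, genes)[:, None]
    return pd.DataFrame(off, index=genes, columns=samples)
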