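"""qPCR utilities: dilution-series amplification efficiency and
reference-gene-normalized relative expression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "fit_standard_curve", "primer_efficiency", "relative_expression"]


@dataclass(frozen=True)
class StandardCurve:
    """Cq-vs-log10(dilution) regression: slope must be negative for a
    valid curve (Cq falls as template rises)."""

    slope: float
    r_squared: float = float("nan")


def fit_standard_curve(log10_dilution, cq) -> StandardCurve:
    res = stats.linregress(np.asarray(log10_dilution, dtype=float), np.asarray(cq, dtype=float))
    return StandardCurve(slope=float(res.slope), r_squared=float(res.rvalue ** 2))


def primer_efficiency(curve: StandardCurve | float) -> float:
    """Amplification efficiency 10^(-1/slope) - 1 (1.0 == perfect doubling)."""
    slope = curve.slope if isinstance(curve, StandardCurve) else float(curve)
    if not np.isfinite(slope) or slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope!r}")
    return 10.0 ** (-1.0 / slope) - 1.0


def relative_expression(cq_target, cq_refs, eff_target: float, eff_refs) -> np.ndarray:
    """Efficiency-corrected level of a target relative to the geometric mean
    of one or more reference genes, per sample.

    level = (1+E_t)^(-Cq_t) / geomean_r (1+E_r)^(-Cq_r); samples with any
    missing reference Cq come back NaN.
    """
    cq_t = np.asarray(cq_target, dtype=float)
    cq_r = np.atleast_2d(np.asarray(cq_refs, dtype=float))  # refs x samples
    if cq_r.shape[1] != cq_t.shape[0]:
        cq_r = cq_r.T
    eff_r = np.broadcast_to(np.asarray(eff_refs, dtype=float).ravel(), (cq_r.shape[0],))
    for e in (eff_target, *eff_r):
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"efficiencies must lie in [0, 1], got {e!r}")
    target_q = (1.0 + eff_target) ** (-cq_t)
    ref_q = (1.0 + eff_r)[:, None] ** (-cq_r)
    with np.errstate(invalid="ignore"):
        geo = np.exp(np.log(ref_q).mean(axis=0))
    out = target_q / geo
    out[np.any(~np.isfinite(cq_r), axis=0)] = np.nan
    return out
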