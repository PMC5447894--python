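"""Gene activity calling from a hierarchical negative-binomial model.

Each gene's counts follow an NB law whose log mean is a per-sample-type
fixed effect plus a per-sample random effect plus a known offset.  Fixed
effects carry a normal prior with unknown mean/variance per sample type,
the random-effect precision a gamma prior, and the log NB dispersion a
normal prior; the prior parameters are estimated by empirical Bayes over
all genes, and each gene's posterior is approximated by a Laplace fit at
the joint mode (the random-effect precision is integrated out
analytically).  A gene is called active in a sample type when the
posterior probability that its fixed effect exceeds a threshold ``T`` is
above ``call_cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, ndtr, polygamma

__all__ = [
    "ActivityModelSpec",
    "Hyperparameters",
    "GenePosterior",
    "VennPartition",
    "fit_hyperpriors",
    "fit_posteriors",
    "gene_posterior",
    "call_activity",
    "venn_partition",
]

_ETA_CLIP = 50.0


@dataclass(frozen=True)
class ActivityModelSpec:
    threshold_T: float = 0.0  # ln-CPM scale; 0 == 1 count per million
    call_cutoff: float = 0.5
    max_iterations: int = 50
    tolerance: float = 1e-6
    newton_max_iter: int = 100
    newton_tol: float = 1e-6

    def __post_init__(self):
        if not (0.0 < self.call_cutoff < 1.0):
            raise ValueError("call_cutoff must lie in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class Hyperparameters:
    """Empirical-Bayes prior parameters shared across genes."""

    fixed_effect_mean: np.ndarray  # one per sample type
    fixed_effect_var: np.ndarray
    ranef_shape: float
    ranef_rate: float
    log_dispersion_mean: float
    log_dispersion_var: float

    def validate(self) -> None:
        if np.any(self.fixed_effect_var <= 0) or self.log_dispersion_var <= 0:
            raise ValueError("prior variances must be positive")
        if self.ranef_shape <= 0 or self.ranef_rate <= 0:
            raise ValueError("gamma shape and rate must be positive")


@dataclass
class GenePosterior:
    """Laplace posterior summaries, genes x sample types."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    p_active: pd.DataFrame
    converged: pd.Series
    log_dispersion: pd.Series = field(default=None, repr=False)


@dataclass(frozen=True)
class VennPartition:
    exclusive_a: int
    exclusive_b: int
    shared: int
    union_total: int

    def percentages(self) -> tuple[int, int, int]:
        """Class shares of the active union, rounded to whole percent."""
        tot = self.union_total
        if tot == 0:
            return (0, 0, 0)
        return tuple(
            int(round(100.0 * v / tot))
            for v in (self.exclusive_a, self.exclusive_b, self.shared)
        )


def _prepare(counts, offsets, design):
    y = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    o = offsets.to_numpy(dtype=float) if isinstance(offsets, pd.DataFrame) else np.asarray(offsets, dtype=float)
    if y.shape != o.shape:
        raise ValueError("offsets must conform to counts")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("counts must be finite and non-negative")
    if np.any(y != np.round(y)):
        raise ValueError("counts must be integers")
    if isinstance(design, pd.DataFrame):
        types = list(pd.unique(design["sample_type"]))
        type_idx = np.array([types.index(t) for t in design["sample_type"]])
    else:
        type_idx = np.asarray(design, dtype=int)
        types = list(range(type_idx.max() + 1))
    counts_per_type = np.bincount(type_idx, minlength=len(types))
    if np.any(counts_per_type < 2):
        bad = [str(types[i]) for i in np.where(counts_per_type < 2)[0]]
        raise ValueError(f"need >= 2 replicates per sample type; offending: {', '.join(bad)}")
    return y, o, type_idx, types


def _neg_log_joint(theta, y, o, type_idx, S, hyper):
    """Vectorized negative log joint; theta shape (G, S + n + 1)."""
    G, n = y.shape
    beta = theta[:, :S]
    u = theta[:, S:S + n]
    lphi = theta[:, -1]
    lnr = -np.clip(lphi, -30.0, 30.0)[:, None]
    r = np.exp(lnr)
    eta = np.clip(beta[:, type_idx] + u + o, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * lnr + y * eta - (y + r) * np.log(r + mu)
    ).sum(axis=1)
    lp_beta = -0.5 * ((beta - hyper.fixed_effect_mean) ** 2 / hyper.fixed_effect_var).sum(axis=1)
    a, b = hyper.ranef_shape, hyper.ranef_rate
    c = a + 0.5 * n
    q = b + 0.5 * (u ** 2).sum(axis=1)
    lp_u = a * np.log(b) - gammaln(a) + gammaln(c) - 0.5 * n * np.log(2 * np.pi) - c * np.log(q)
    lp_phi = -0.5 * (lphi - hyper.log_dispersion_mean) ** 2 / hyper.log_dispersion_var
    return -(ll + lp_beta + lp_u + lp_phi)


def _grad_hess(theta, y, o, type_idx, S, hyper, want_hess=True):
    G, n = y.shape
    P = S + n + 1
    beta = theta[:, :S]
    u = theta[:, S:S + n]
    lphi = theta[:, -1]
    lnr = -np.clip(lphi, -30.0, 30.0)[:, None]
    r = np.exp(lnr)
    eta = np.clip(beta[:, type_idx] + u + o, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    rm = r + mu

    d_eta = y - (y + r) * mu / rm  # dl/deta_j
    f = digamma(y + r) - digamma(r) + lnr + 1.0 - np.log(rm) - (y + r) / rm
    d_lphi = -(r * f).sum(axis=1)  # dl/dlphi

    grad = np.zeros((G, P))
    for s in range(S):
        grad[:, s] = d_eta[:, type_idx == s].sum(axis=1)
    grad[:, S:S + n] = d_eta
    grad[:, -1] = d_lphi

    # priors
    grad[:, :S] += -(beta - hyper.fixed_effect_mean) / hyper.fixed_effect_var
    a, b = hyper.ranef_shape, hyper.ranef_rate
    c = a + 0.5 * n
    q = b + 0.5 * (u ** 2).sum(axis=1)
    grad[:, S:S + n] += -c * u / q[:, None]
    grad[:, -1] += -(lphi - hyper.log_dispersion_mean) / hyper.log_dispersion_var
    grad = -grad  # gradient of the NEGATIVE log joint

    if not want_hess:
        return grad, None

    w = (y + r) * r * mu / rm ** 2            # -d2l/deta2
    cross = r * mu * (mu - y) / rm ** 2       # d2l/(deta dlphi)
    fp = polygamma(1, y + r) - polygamma(1, r) + 1.0 / r - 1.0 / rm - (mu - y) / rm ** 2
    d2_lphi = (r * f + r ** 2 * fp).sum(axis=1)  # d2l/dlphi2

    H = np.zeros((G, P, P))
    for s in range(S):
        m = type_idx == s
        ws = w[:, m].sum(axis=1)
        H[:, s, s] = ws + 1.0 / hyper.fixed_effect_var[s]
        idx = np.where(m)[0]
        H[:, s, S + idx] = w[:, idx]
        H[:, S + idx, s] = w[:, idx]
        cs = cross[:, m].sum(axis=1)
        H[:, s, -1] = -cs
        H[:, -1, s] = -cs
    # u block: NB curvature on the diagonal plus the integrated-precision
    # prior contribution  c/q * I - c/q^2 * u u^T
    ui = np.arange(n)
    outer = u[:, :, None] * u[:, None, :]
    H[:, S:S + n, S:S + n] = -c * outer / q[:, None, None] ** 2
    H[:, S + ui, S + ui] += w + c / q[:, None]
    H[:, S:S + n, -1] = -cross
    H[:, -1, S:S + n] = -cross
    H[:, -1, -1] = -d2_lphi + 1.0 / hyper.log_dispersion_var
    return grad, H


def _fit_modes(y, o, type_idx, S, hyper, spec, theta0=None):
    """Batch Newton to the joint posterior mode; returns modes, covariances
    (Laplace), convergence mask."""
    G, n = y.shape
    P = S + n + 1
    if theta0 is None:
        theta = np.zeros((G, P))
        for s in range(S):
            m = type_idx == s
            theta[:, s] = np.log((y[:, m].sum(axis=1) + 0.5) / np.exp(o[:, m]).sum(axis=1))
        theta[:, -1] = hyper.log_dispersion_mean
    else:
        theta = theta0.copy()

    fval = _neg_log_joint(theta, y, o, type_idx, S, hyper)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)
    lam = np.zeros(G)  # persistent Levenberg ridge; grows at saddles/failed steps
    eye = np.eye(P)[None]
    for _ in range(spec.newton_max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        g, H = _grad_hess(theta[idx], y[idx], o[idx], type_idx, S, hyper)
        step = np.zeros_like(g)
        ridge = lam[idx].copy()
        for _attempt in range(8):
            Hr = H + ridge[:, None, None] * eye
            try:
                step = np.linalg.solve(Hr, g[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step = np.full_like(g, np.nan)
            # require a finite descent direction (guards indefinite Hessians)
            descent = (g * step).sum(axis=1)
            bad = ~np.all(np.isfinite(step), axis=1) | (descent <= 0)
            if not bad.any():
                break
            ridge[bad] = np.maximum(ridge[bad] * 10.0, 1e-3)
        step = np.where(np.isfinite(step), step, 0.0)
        lam[idx] = ridge

        # backtracking line search, vectorized over genes
        alpha = np.ones(len(idx))
        new_theta = theta[idx] - step
        new_f = _neg_log_joint(new_theta, y[idx], o[idx], type_idx, S, hyper)
        for _ in range(25):
            worse = ~(new_f <= fval[idx] + 1e-12) | ~np.isfinite(new_f)
            if not worse.any():
                break
            alpha[worse] *= 0.5
            new_theta[worse] = theta[idx][worse] - alpha[worse, None] * step[worse]
            new_f[worse] = _neg_log_joint(
                new_theta[worse], y[idx][worse], o[idx][worse], type_idx, S, hyper
            )
        improved = new_f <= fval[idx]
        theta[idx[improved]] = new_theta[improved]
        fval[idx[improved]] = new_f[improved]
        lam[idx[improved]] *= 0.25
        lam[idx[~improved]] = np.maximum(lam[idx[~improved]] * 10.0, 1e-3)

        gnorm = np.abs(g).max(axis=1)
        step_size = alpha * np.abs(step).max(axis=1)
        done = (gnorm < spec.newton_tol * (1.0 + np.abs(fval[idx]))) | (
            improved & (step_size < 1e-10 * (1.0 + np.abs(theta[idx]).max(axis=1)))
        )
        converged[idx[done]] = True
        active[idx[done]] = False

    _, H = _grad_hess(theta, y, o, type_idx, S, hyper)
    cov = np.full((G, P, P), np.nan)
    ok = np.zeros(G, dtype=bool)
    try:
        cov_all = np.linalg.inv(H)
        diag = np.diagonal(cov_all, axis1=1, axis2=2)
        ok = np.all(np.isfinite(cov_all), axis=(1, 2)) & np.all(diag > 0, axis=1)
        cov[ok] = cov_all[ok]
    except np.linalg.LinAlgError:
        for i in range(G):
            try:
                ci = np.linalg.inv(H[i])
                if np.all(np.isfinite(ci)) and np.all(np.diag(ci) > 0):
                    cov[i] = ci
                    ok[i] = True
            except np.linalg.LinAlgError:
                pass
    converged &= ok
    return theta, cov, converged


def _mom_dispersion(y, type_idx, S):
    phis = []
    for s in range(S):
        ys = y[:, type_idx == s]
        m = ys.mean(axis=1)
        v = ys.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (v - m) / m ** 2
        phis.append(phi)
    phi = np.nanmedian(np.column_stack(phis), axis=1)
    return np.clip(np.where(np.isfinite(phi), phi, 0.1), 1e-3, 10.0)


def _omean(x: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """Order-independent mean (sorts before summing) so hyperparameter
    estimates are bit-identical under gene permutation."""
    return np.sort(x, axis=axis).mean(axis=axis)


def _gamma_mle(mean_tau: float, mean_log_tau: float) -> tuple[float, float]:
    d = np.log(mean_tau) - mean_log_tau
    d = max(d, 1e-8)
    a = (3.0 - d + np.sqrt((d - 3.0) ** 2 + 24.0 * d)) / (12.0 * d)
    for _ in range(50):
        g = np.log(a) - digamma(a) - d
        gp = 1.0 / a - polygamma(1, a)
        a_new = a - g / gp
        if not np.isfinite(a_new) or a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-10 * (1.0 + a):
            a = a_new
            break
        a = a_new
    a = float(np.clip(a, 0.1, 1e3))
    return a, float(max(a / mean_tau, 1e-4))


def fit_hyperpriors(counts, offsets, design, spec: ActivityModelSpec | None = None,
                    init: Hyperparameters | None = None) -> Hyperparameters:
    """Estimate the shared prior parameters by EM-style coordinate ascent.

    E-step: Laplace fit of every gene at the current priors. M-step:
    closed-form normal-prior updates for the fixed effects and log
    dispersion, gamma MLE for the random-effect precision from the
    conditional Gamma(a + n/2, b + ||u||^2/2) sufficient statistics.
    Deterministic given inputs.
    """
    spec = spec or ActivityModelSpec()
    y, o, type_idx, types = _prepare(counts, offsets, design)
    G, n = y.shape
    S = len(types)

    if init is None:
        beta0 = np.zeros((G, S))
        for s in range(S):
            m = type_idx == s
            beta0[:, s] = np.log((y[:, m].sum(axis=1) + 0.5) / np.exp(o[:, m]).sum(axis=1))
        lphi0 = np.log(_mom_dispersion(y, type_idx, S))
        b0_mean = _omean(beta0)
        l0_mean = float(_omean(lphi0))
        hyper = Hyperparameters(
            fixed_effect_mean=b0_mean,
            fixed_effect_var=np.maximum(_omean((beta0 - b0_mean) ** 2), 1e-2),
            ranef_shape=2.0,
            ranef_rate=0.1,
            log_dispersion_mean=l0_mean,
            log_dispersion_var=float(max(_omean((lphi0 - l0_mean) ** 2), 1e-2)),
        )
    else:
        hyper = init
    hyper.validate()

    theta = None
    for _ in range(spec.max_iterations):
        theta, cov, conv = _fit_modes(y, o, type_idx, S, hyper, spec, theta0=theta)
        use = conv if conv.any() else np.ones(G, dtype=bool)
        diag = np.diagonal(cov, axis1=1, axis2=2)

        beta_m = theta[use, :S]
        beta_v = np.nan_to_num(diag[use, :S], nan=0.0)
        new_mean = _omean(beta_m)
        new_var = np.clip(_omean(beta_v + (beta_m - new_mean) ** 2), 1e-4, 1e3)

        lphi_m = theta[use, -1]
        lphi_v = np.nan_to_num(diag[use, -1], nan=0.0)
        new_lmean = float(_omean(lphi_m))
        new_lvar = float(np.clip(_omean(lphi_v + (lphi_m - new_lmean) ** 2), 1e-4, 25.0))

        a, b = hyper.ranef_shape, hyper.ranef_rate
        c = a + 0.5 * n
        q = b + 0.5 * (theta[use, S:S + n] ** 2).sum(axis=1)
        mean_tau = float(_omean(c / q))
        mean_log_tau = float(_omean(digamma(c) - np.log(q)))
        new_a, new_b = _gamma_mle(mean_tau, mean_log_tau)

        old = np.array([*hyper.fixed_effect_mean, *hyper.fixed_effect_var,
                        hyper.ranef_shape, hyper.ranef_rate,
                        hyper.log_dispersion_mean, hyper.log_dispersion_var])
        hyper = Hyperparameters(
            fixed_effect_mean=new_mean,
            fixed_effect_var=new_var,
            ranef_shape=new_a,
            ranef_rate=new_b,
            log_dispersion_mean=new_lmean,
            log_dispersion_var=new_lvar,
        )
        new = np.array([*hyper.fixed_effect_mean, *hyper.fixed_effect_var,
                        hyper.ranef_shape, hyper.ranef_rate,
                        hyper.log_dispersion_mean, hyper.log_dispersion_var])
        if np.max(np.abs(new - old) / (1.0 + np.abs(old))) < spec.tolerance:
            break
    return hyper


def fit_posteriors(counts, offsets, design, hyper: Hyperparameters,
                   spec: ActivityModelSpec | None = None) -> GenePosterior:
    """Laplace posterior of every gene's fixed effects at fixed hyperpriors.

    ``p_active`` is ``P(beta_gs > T) = Phi((mean - T)/sd)`` under the
    Gaussian approximation; genes whose Newton fit fails to converge are
    flagged and reported with ``p_active = 0`` (never called active).
    """
    spec = spec or ActivityModelSpec()
    hyper.validate()
    y, o, type_idx, types = _prepare(counts, offsets, design)
    G, n = y.shape
    S = len(types)
    theta, cov, conv = _fit_modes(y, o, type_idx, S, hyper, spec)
    mean = theta[:, :S]
    sd = np.sqrt(np.abs(np.diagonal(cov, axis1=1, axis2=2)[:, :S]))
    with np.errstate(invalid="ignore"):
        p = ndtr((mean - spec.threshold_T) / sd)
    p = np.where(conv[:, None], p, 0.0)
    sd = np.where(conv[:, None], sd, np.nan)
    genes = list(counts.index) if isinstance(counts, pd.DataFrame) else list(range(G))
    return GenePosterior(
        mean=pd.DataFrame(mean, index=genes, columns=types),
        sd=pd.DataFrame(sd, index=genes, columns=types),
        p_active=pd.DataFrame(p, index=genes, columns=types),
        converged=pd.Series(conv, index=genes, name="converged"),
        log_dispersion=pd.Series(theta[:, -1], index=genes, name="log_dispersion"),
    )


def gene_posterior(gene_counts, offsets_row, design, hyper: Hyperparameters,
                   spec: ActivityModelSpec | None = None) -> pd.DataFrame:
    """Posterior summary for a single gene (one row of the batch fit)."""
    y = np.asarray(gene_counts, dtype=float)[None, :]
    o = np.asarray(offsets_row, dtype=float)[None, :]
    post = fit_posteriors(y, o, design, hyper, spec)
    out = pd.DataFrame({
        "sample_type": post.mean.columns,
        "post_mean": post.mean.iloc[0].to_numpy(),
        "post_sd": post.sd.iloc[0].to_numpy(),
        "p_active": post.p_active.iloc[0].to_numpy(),
    })
    out["converged"] = bool(post.converged.iloc[0])
    return out


def call_activity(post: GenePosterior, spec: ActivityModelSpec | None = None) -> pd.DataFrame:
    """Boolean calls: active iff ``p_active`` strictly exceeds the cutoff
    (ties at the cutoff are inactive)."""
    spec = spec or ActivityModelSpec()
    return post.p_active > spec.call_cutoff


def venn_partition(calls: pd.DataFrame, type_a=None, type_b=None) -> VennPartition:
    """Two-set partition of the active union from per-type boolean calls."""
    if calls.shape[1] != 2 and (type_a is None or type_b is None):
        raise ValueError("need exactly two sample types (or name them explicitly)")
    cols = list(calls.columns)
    type_a = type_a if type_a is not None else cols[0]
    type_b = type_b if type_b is not None else cols[1]
    a = calls[type_a].to_numpy(dtype=bool)
    b = calls[type_b].to_numpy(dtype=bool)
    if a.shape != b.shape:
        raise ValueError("call vectors must cover the same gene universe")
    only_a = int(np.sum(a & ~b))
    only_b = int(np.sum(b & ~a))
    both = int(np.sum(a & b))
    return VennPartition(only_a, only_b, both, only_a + only_b + both)
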