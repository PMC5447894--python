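"""Synthetic RNA-seq count generator with known ground truth.

Generates gene-by-sample negative-binomial count matrices with the
structure the downstream stages assume: per-sample-type fixed effects on
the log scale, per-replicate random effects, per-gene NB dispersion,
tissue-specific inactive genes with a small leak mean, a configurable
differentially-expressed fraction, and a multiplicative length/GC capture
bias.  Every run also emits the exact generating parameters (``SimTruth``)
so parameter-recovery and error-rate experiments can be scored against
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_counts",
    "simulate_go_annotation",
]

_LN2 = math.log(2.0)

# fixed stream ids so each random quantity has its own substream; gene-level
# streams additionally mix in the gene index so growing n_genes only appends
_STREAM_GENE = 1
_STREAM_LIB = 2
_STREAM_ASSIGN = 3
_STREAM_COUNTS = 4
_STREAM_REP = 5


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``baseline_mean``/``baseline_sd`` give the normal law of the per-gene
    fixed effect on the natural-log CPM scale; ``lfc_magnitude`` is the
    absolute log2 fold change given to DE genes (split symmetrically
    between the two sample types).
    """

    n_genes: int = 2000
    sample_types: tuple[str, ...] = ("A", "B")
    n_replicates: int = 4
    frac_inactive: float = 0.0
    frac_de: float = 0.0
    lfc_magnitude: float = 2.0
    baseline_mean: float = 4.0
    baseline_sd: float = 1.0
    inactive_leak_cpm: float = 0.1
    dispersion_mean: float = 0.1
    dispersion_log_sd: float = 0.0
    replicate_sd: float = 0.0
    lib_size_range: tuple[float, float] = (1e6, 1e6)
    length_range: tuple[int, int] = (500, 8000)
    gc_range: tuple[float, float] = (0.3, 0.7)
    bias_length: float = 0.0
    bias_gc: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.sample_types) < 1:
            raise ValueError("need at least one sample type")
        if self.n_replicates < 2:
            raise ValueError(
                "n_replicates must be >= 2 (replicate random effects are "
                "inestimable otherwise)"
            )
        for name in ("frac_inactive", "frac_de"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v!r}")
        if self.lib_size_range[0] > self.lib_size_range[1]:
            raise ValueError("lib_size_range min must be <= max")
        if self.lib_size_range[0] <= 0:
            raise ValueError("library sizes must be positive")
        if self.dispersion_mean <= 0:
            raise ValueError("dispersion_mean must be positive")
        if self.inactive_leak_cpm <= 0:
            raise ValueError("inactive_leak_cpm must be positive")
        scalars = [
            self.lfc_magnitude, self.baseline_mean, self.baseline_sd,
            self.inactive_leak_cpm, self.dispersion_mean,
            self.dispersion_log_sd, self.replicate_sd,
            self.bias_length, self.bias_gc,
            *self.lib_size_range, *self.length_range, *self.gc_range,
        ]
        if not all(np.isfinite(scalars)):
            raise ValueError("SimConfig contains non-finite values")


@dataclass
class SimTruth:
    """Per-gene generating parameters, aligned with the count matrix rows."""

    table: pd.DataFrame  # gene_id, active_<type>..., true_log2fc, dispersion, baseline_log_mean
    active_by_type: pd.DataFrame  # boolean, genes x sample types
    true_offsets: pd.DataFrame  # exact log-scale offsets used per gene x sample


@dataclass
class SimResult:
    counts: pd.DataFrame  # genes x samples, integer
    features: pd.DataFrame  # gene_id, length, gc
    meta: pd.DataFrame  # sample_id, sample_type, replicate
    truth: SimTruth
    config: SimConfig = field(repr=False, default=None)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, *key))))


def simulate_counts(config: SimConfig) -> SimResult:
    """Draw one dataset; bit-identical for identical ``config``.

    Counts are NB with log mean = fixed effect (per sample type) +
    replicate effect + length/GC bias + per-sample scale chosen so each
    expected column sum equals that sample's drawn library size.  The scale
    actually applied is recorded in ``truth.true_offsets``.
    """
    config.validate()
    G = config.n_genes
    types = list(config.sample_types)
    S = len(types)
    R = config.n_replicates
    n_samples = S * R

    gene_ids = np.array([f"gene{i:06d}" for i in range(G)])
    sample_ids = [f"{t}_rep{r + 1}" for t in types for r in range(R)]
    type_of = np.repeat(np.arange(S), R)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sample_type": [types[i] for i in type_of],
            "replicate": [r + 1 for _ in types for r in range(R)],
        }
    )

    # gene-level draws: one substream per gene so existing genes are stable
    # when n_genes grows
    baseline = np.empty(G)
    log_disp = np.empty(G)
    length = np.empty(G, dtype=np.int64)
    gc = np.empty(G)
    u_assign = np.empty((G, 3))
    mu_ld = math.log(config.dispersion_mean) - 0.5 * config.dispersion_log_sd**2
    for g in range(G):
        rg = _rng(config.seed, _STREAM_GENE, g)
        baseline[g] = rg.normal(config.baseline_mean, config.baseline_sd)
        log_disp[g] = rg.normal(mu_ld, config.dispersion_log_sd)
        length[g] = rg.integers(config.length_range[0], config.length_range[1] + 1)
        gc[g] = rg.uniform(*config.gc_range)
        u_assign[g] = rg.uniform(size=3)
    dispersion = np.exp(log_disp)

    # class assignment: inactive-in-one-tissue genes, then DE among the rest
    inactive_gene = u_assign[:, 0] < config.frac_inactive
    inactive_type = (u_assign[:, 1] * S).astype(int).clip(0, S - 1)
    de_gene = (~inactive_gene) & (u_assign[:, 2] < config.frac_de)
    de_sign = np.where(_rng(config.seed, _STREAM_ASSIGN).uniform(size=G) < 0.5, 1.0, -1.0)

    beta = np.tile(baseline[:, None], (1, S))
    true_log2fc = np.zeros(G)
    if S >= 2:
        half = 0.5 * config.lfc_magnitude * _LN2
        beta[de_gene, 0] += de_sign[de_gene] * half
        beta[de_gene, 1] -= de_sign[de_gene] * half
        true_log2fc[de_gene] = de_sign[de_gene] * config.lfc_magnitude
    leak = math.log(config.inactive_leak_cpm)
    for s in range(S):
        sel = inactive_gene & (inactive_type == s)
        beta[sel, s] = leak
        true_log2fc[sel] = 0.0

    active = np.ones((G, S), dtype=bool)
    active[np.where(inactive_gene)[0], inactive_type[inactive_gene]] = False

    lib_sizes = _rng(config.seed, _STREAM_LIB).uniform(
        config.lib_size_range[0], config.lib_size_range[1], size=n_samples
    )
    meta["expected_library_size"] = lib_sizes

    zl = _zscore(np.log(length.astype(float)))
    zg = _zscore(gc)
    bias = config.bias_length * zl + config.bias_gc * zg

    rep_effects = _rng(config.seed, _STREAM_REP).normal(
        0.0, config.replicate_sd, size=(G, n_samples)
    ) if config.replicate_sd > 0 else np.zeros((G, n_samples))

    # rate_gj on the exp(beta + bias + u) scale; per-sample renormalization so
    # E[column sum] equals the drawn library size exactly
    log_rate = beta[:, type_of] + bias[:, None] + rep_effects
    rate = np.exp(log_rate)
    col_tot = rate.sum(axis=0)
    scale = lib_sizes / col_tot  # per sample
    mu = rate * scale[None, :]

    # offset such that log mu = beta_gs + u_gj + offset_gj exactly
    true_offsets = bias[:, None] + np.log(scale)[None, :]

    r_nb = 1.0 / dispersion
    rng_counts = _rng(config.seed, _STREAM_COUNTS)
    # NB as gamma-Poisson for vectorized draws with per-gene dispersion
    lam = rng_counts.gamma(shape=r_nb[:, None], scale=mu / r_nb[:, None])
    counts = rng_counts.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "gene_id"
    features = pd.DataFrame({"gene_id": gene_ids, "length": length, "gc": gc})
    truth_tbl = pd.DataFrame({"gene_id": gene_ids})
    for s, t in enumerate(types):
        truth_tbl[f"active_{t}"] = active[:, s]
    truth_tbl["true_log2fc"] = true_log2fc
    truth_tbl["dispersion"] = dispersion
    truth_tbl["baseline_log_mean"] = baseline
    active_df = pd.DataFrame(active, index=gene_ids, columns=types)
    offsets_df = pd.DataFrame(true_offsets, index=gene_ids, columns=sample_ids)
    truth = SimTruth(table=truth_tbl, active_by_type=active_df, true_offsets=offsets_df)
    return SimResult(counts=counts_df, features=features, meta=meta, truth=truth, config=config)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_go_annotation(
    n_terms: int,
    gene_ids,
    enriched_terms: dict[str, set] | None = None,
    seed: int = 0,
    term_size_range: tuple[int, int] = (10, 80),
) -> dict[str, set]:
    """Random flat term->gene annotation with optional planted enrichment.

    Background terms are uniform random gene subsets; each entry of
    ``enriched_terms`` maps a term id to the exact gene set it should carry
    (e.g. the true DE set), so downstream enrichment has a known positive.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    if n_terms < 0:
        raise ValueError("n_terms must be >= 0")
    enriched_terms = enriched_terms or {}
    universe = set(gene_ids)
    for term, members in enriched_terms.items():
        if not set(members) <= universe:
            raise ValueError(f"term {term!r} contains genes outside gene_ids")
        if not members:
            raise ValueError(f"term {term!r} has an empty gene set")
    rng = _rng(seed, 7)
    annotation: dict[str, set] = {}
    for i in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        size = min(size, len(gene_ids))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        annotation[f"TERM:{i:04d}"] = {gene_ids[j] for j in members}
    for term, members in enriched_terms.items():
        annotation[term] = set(members)
    return annotation
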