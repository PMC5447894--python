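"""Singular enrichment analysis of a gene list against a background.

Flat term->gene annotation, one-sided hypergeometric upper-tail test per
term, odds ratios from the 2x2 table, Benjamini-Hochberg across tested
terms.  No ontology graph handling: terms are taken as given.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

__all__ = ["read_annotation", "hypergeom_tail", "sea"]


def read_annotation(path) -> dict[str, set]:
    """Two-column TSV (term_id, gene_id[, term_name]) -> term->genes map."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["term_id", "gene_id", "term_name"][: 3], dtype=str)
    ann: dict[str, set] = {}
    for term, sub in df.groupby("term_id", sort=True):
        ann[term] = set(sub["gene_id"])
    return ann


def hypergeom_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n); vectorized."""
    return hypergeom.sf(np.asarray(k) - 1, N, K, n)


def sea(foreground, background, annotation: dict[str, set],
        min_term_size: int = 5) -> pd.DataFrame:
    """Per-term over-representation of ``foreground`` within ``background``.

    Terms are intersected with the background first; terms with fewer than
    ``min_term_size`` background genes (or none) are dropped.  Columns:
    k, n, K, N, odds_ratio, p, q — the 2x2 test uses a 0.5 continuity
    correction for the odds ratio only when a cell is zero.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("foreground gene set is empty")
    if not bg:
        raise ValueError("background gene set is empty")
    stray = fg - bg
    if stray:
        shown = ", ".join(sorted(stray)[:10])
        raise ValueError(f"foreground genes missing from background: {shown}")

    N = len(bg)
    n = len(fg)
    rows = []
    for term in sorted(annotation):
        members = annotation[term] & bg
        K = len(members)
        if K < max(min_term_size, 1):
            continue
        k = len(members & fg)
        p = float(hypergeom_tail(k, N, K, n))
        rows.append((term, k, n, K, N, _odds_ratio(k, n, K, N), p))
    if not rows:
        return pd.DataFrame(columns=["term_id", "k", "n", "K", "N", "odds_ratio", "p", "q"])
    out = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "odds_ratio", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a = float(k)
    b = float(n - k)
    c = float(K - k)
    d = float(N - K - n + k)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)
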