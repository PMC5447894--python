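"""Plain-text readers/writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_counts(path) -> pd.DataFrame:
    """Gene x sample TSV with a gene_id index column and sample header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"no counts in {path}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    from scipy.io import mmread

    m = mmread(mtx_path)
    genes = [l.strip() for l in Path(genes_path).read_text().splitlines() if l.strip()]
    samples = [l.strip() for l in Path(samples_path).read_text().splitlines() if l.strip()]
    df = pd.DataFrame(np.asarray(m.todense() if hasattr(m, "todense") else m),
                      index=genes, columns=samples)
    return df.astype(np.int64)


def write_counts_mtx(df: pd.DataFrame, outdir, stem: str = "counts") -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    outdir = Path(outdir)
    mmwrite(outdir / f"{stem}.mtx", csr_matrix(df.to_numpy()))
    (outdir / f"{stem}.genes.txt").write_text("\n".join(map(str, df.index)) + "\n")
    (outdir / f"{stem}.samples.txt").write_text("\n".join(map(str, df.columns)) + "\n")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = {"gene_id", "length", "gc"} - set(df.columns)
    if missing:
        raise ValueError(f"features file lacks columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in features")
    return df


def read_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "sample_type"} - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
    return df


def read_gene_list(path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
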