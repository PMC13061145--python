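"""Readers and writers for the pipeline's tabular formats.

Counts travel as a genes x samples integer DataFrame (gene ids on the index,
sample ids as columns) either in TSV or MatrixMarket (MTX with sidecar
gene/sample lists).  Metadata is CSV, gene sets are GMT, interaction edges are
3-column TSV (node1, node2, combined_score), reference expression is a
cell-type x gene TSV, and Ct tables are long-format CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check count-matrix invariants: unique gene/sample ids, non-negative
    integer-valued entries."""
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative entries in count matrix")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("non-integer entries in count matrix")
    return counts


def read_counts_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return validate_counts(df)


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(mtx_path: str, genes_path: str | None = None,
                    samples_path: str | None = None) -> pd.DataFrame:
    """Read MatrixMarket counts with sidecar row (gene) and column (sample)
    label files, defaulting to <stem>.genes.txt / <stem>.samples.txt."""
    from scipy.io import mmread

    stem = mtx_path[:-4] if mtx_path.endswith(".mtx") else mtx_path
    genes_path = genes_path or stem + ".genes.txt"
    samples_path = samples_path or stem + ".samples.txt"
    raw = mmread(mtx_path)
    mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
    genes = [line.strip() for line in open(genes_path) if line.strip()]
    samples = [line.strip() for line in open(samples_path) if line.strip()]
    df = pd.DataFrame(mat.astype(np.int64), index=genes, columns=samples)
    df.index.name = "gene_id"
    return validate_counts(df)


def write_counts_mtx(counts: pd.DataFrame, mtx_path: str) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    stem = mtx_path[:-4] if mtx_path.endswith(".mtx") else mtx_path
    mmwrite(stem + ".mtx", csr_matrix(counts.to_numpy()))
    with open(stem + ".genes.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.index)) + "\n")
    with open(stem + ".samples.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.columns)) + "\n")


def read_metadata_csv(path: str) -> pd.DataFrame:
    md = pd.read_csv(path)
    if "sample_id" not in md.columns:
        raise ValueError("metadata must have a sample_id column")
    md["sample_id"] = md["sample_id"].astype(str)
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return md


def write_metadata_csv(md: pd.DataFrame, path: str) -> None:
    md.to_csv(path, index=False)


def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path: str,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


def read_edges_tsv(path: str) -> pd.DataFrame:
    """Read a 3-column interaction edge list (node1, node2, combined_score).

    A header row is accepted if its third field is not numeric.  Malformed
    rows raise with their line numbers.
    """
    rows, bad = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                bad.append(lineno)
                continue
            try:
                score = float(parts[2])
            except ValueError:
                if lineno == 1:  # header
                    continue
                bad.append(lineno)
                continue
            rows.append((parts[0], parts[1], score))
    if bad:
        raise ValueError(f"{path}: malformed edge rows at lines {bad}")
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def write_edges_tsv(edges: pd.DataFrame, path: str) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_reference_tsv(path: str) -> pd.DataFrame:
    """Cell-type x gene reference expression matrix."""
    ref = pd.read_csv(path, sep="\t", index_col=0)
    if (ref.to_numpy() < 0).any():
        raise ValueError("negative values in reference expression matrix")
    ref.index.name = "cell_type"
    return ref


def write_reference_tsv(ref: pd.DataFrame, path: str) -> None:
    ref.to_csv(path, sep="\t", index_label="cell_type")


def read_ct_csv(path: str) -> pd.DataFrame:
    """Long-format Ct table: sample_id, gene, ct."""
    ct = pd.read_csv(path)
    missing = {"sample_id", "gene", "ct"} - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    ct["sample_id"] = ct["sample_id"].astype(str)
    return ct


def write_ct_csv(ct: pd.DataFrame, path: str) -> None:
    ct.to_csv(path, index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
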