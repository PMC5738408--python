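"""Reading and writing the pipeline's plain-text formats.

Canonical inter-stage format is TSV with a ``gene_id`` index column for
gene-level tables and a ``sample_id`` index column for sample-level tables;
floats are serialized at 10 significant digits so reruns are byte-stable.
Counts can also be read/written as MatrixMarket triplets with sidecar row and
column name files.  Gene sets use GMT, genomic regions BED, and gene lists
one id per line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "read_counts", "write_counts", "read_table", "write_table",
    "read_gene_list", "write_gene_list", "read_bed", "write_gmt",
]

FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_counts(counts: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write a gene x sample count matrix as TSV or MatrixMarket triplet.

    MatrixMarket writes ``<stem>.mtx`` plus ``<stem>.rows`` / ``<stem>.cols``
    name files.
    """
    path = Path(path)
    if fmt == "tsv":
        counts.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "mtx":
        stem = path.with_suffix("")
        scipy.io.mmwrite(str(stem) + ".mtx",
                         scipy.sparse.csr_matrix(counts.to_numpy()))
        Path(str(stem) + ".rows").write_text("\n".join(map(str, counts.index)) + "\n")
        Path(str(stem) + ".cols").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_counts(path) -> pd.DataFrame:
    """Read counts from TSV or MatrixMarket (with .rows/.cols sidecars)."""
    path = Path(path)
    if path.suffix == ".mtx":
        m = scipy.io.mmread(str(path)).tocsr().toarray()
        stem = path.with_suffix("")
        rows = Path(str(stem) + ".rows").read_text().split()
        cols = Path(str(stem) + ".cols").read_text().split()
        return pd.DataFrame(m.astype(np.int64), index=rows, columns=cols)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_gene_list(path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def write_gene_list(genes: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open): chrom, start, end, optional name."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
        if len(parts) > 3:
            row["name"] = parts[3]
        rows.append(row)
    return pd.DataFrame(rows)


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, sorted(genes))]) + "\n")
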