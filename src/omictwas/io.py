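"""Plain-text readers and writers for the pipeline's artifacts.

Counts travel as TSV (features x individuals, header row of individual
ids) or Matrix Market; feature annotation as GTF gene features carrying
``gene_id``, ``gene_biotype``, ``novel`` and ``level`` attributes;
phenotypes as TSV; the relationship matrix as a square TSV with an id
header or as GRM-style lower-triangle text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .expression import CountMatrix, ExpressionMatrix
from .relationship import RelationshipMatrix

__all__ = [
    "write_counts_tsv", "read_counts_tsv",
    "write_counts_mtx", "read_counts_mtx",
    "write_gtf", "read_gtf",
    "write_phenotypes_tsv", "read_phenotypes_tsv",
    "write_expression_tsv", "write_factors_tsv",
    "write_orm_tsv", "read_orm_tsv", "write_orm_lower_triangle",
]


def write_counts_tsv(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path: str | Path, gtf_path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = read_gtf(gtf_path).reindex(df.index)
    if meta.isna().any().any():
        raise ValueError("annotation is missing features present in the count matrix")
    return CountMatrix(
        counts=df.to_numpy(),
        feature_meta=meta,
        individual_ids=[str(c) for c in df.columns],
    )


def write_counts_mtx(counts: CountMatrix, prefix: str | Path) -> None:
    """Matrix Market triplet plus sidecar row/column id files."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(counts.counts))
    prefix.with_suffix(".rows.txt").write_text("\n".join(counts.feature_ids) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(counts.individual_ids) + "\n")


def read_counts_mtx(prefix: str | Path, gtf_path: str | Path) -> CountMatrix:
    prefix = Path(prefix)
    mat = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    rows = prefix.with_suffix(".rows.txt").read_text().split()
    cols = prefix.with_suffix(".cols.txt").read_text().split()
    meta = read_gtf(gtf_path).reindex(rows)
    return CountMatrix(counts=mat, feature_meta=meta, individual_ids=cols)


def write_gtf(feature_meta: pd.DataFrame, path: str | Path) -> None:
    lines = []
    for fid, row in feature_meta.iterrows():
        attrs = (
            f'gene_id "{fid}"; gene_biotype "{row.biotype}"; '
            f'novel "{str(bool(row.novel)).lower()}"; level "{row.level}";'
        )
        lines.append(
            f"{row.chromosome}\tomictwas\tgene\t{row.start}\t{row.end}"
            f"\t.\t+\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Gene-feature annotation from a GTF file.

    Only ``gene`` features are used; attributes ``gene_id`` (required),
    ``gene_biotype``, ``novel`` and ``level`` are read, with sensible
    defaults when absent.
    """
    records = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = _parse_attrs(parts[8])
            fid = attrs.get("gene_id")
            if fid is None:
                raise ValueError("GTF gene feature without gene_id attribute")
            records[fid] = {
                "chromosome": int(parts[0]) if parts[0].isdigit() else parts[0],
                "start": int(parts[3]),
                "end": int(parts[4]),
                "biotype": attrs.get("gene_biotype", "protein_coding"),
                "novel": attrs.get("novel", "false") == "true",
                "level": attrs.get("level", "gene"),
            }
    meta = pd.DataFrame.from_dict(records, orient="index")
    meta.index.name = "feature_id"
    return meta


def write_phenotypes_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="feature_id", float_format="%.8g")


def write_factors_tsv(individual_ids, factors, path: str | Path) -> None:
    pd.DataFrame({"individual": individual_ids, "tmm_factor": factors}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_orm_tsv(orm: RelationshipMatrix, path: str | Path) -> None:
    pd.DataFrame(orm.A, index=orm.individual_ids, columns=orm.individual_ids).to_csv(
        path, sep="\t", index_label="id", float_format="%.10g"
    )


def read_orm_tsv(path: str | Path, m_features: int = 0) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(
        A=df.to_numpy(), m_features=m_features, individual_ids=[str(c) for c in df.columns]
    )


def write_orm_lower_triangle(orm: RelationshipMatrix, path: str | Path) -> None:
    """GRM-style text: one line per (j, k<=j) pair: j k m A_jk (1-based)."""
    lines = []
    for j in range(orm.n):
        for k in range(j + 1):
            lines.append(f"{j + 1}\t{k + 1}\t{orm.m_features}\t{orm.A[j, k]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
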