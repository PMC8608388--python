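"""Readers and writers for protein-group quantification tables and metadata.

The quantification dialect is the MaxQuant ``proteinGroups.txt`` convention:
a tab-separated table with one row per protein group, per-sample intensity
columns named ``iBAQ <sample>``, a ``Score`` column, and marker columns
(``Potential contaminant``, ``Reverse``, ``Only identified by site``) where
any non-empty cell, conventionally ``+``, flags the row.
"""

from __future__ import annotations

import json
import os
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .data import (
    AbundanceMatrix,
    FormatError,
    IntegrityError,
    ProteinRecord,
    SampleAnnotation,
    TrophoError,
)

__all__ = [
    "read_protein_groups",
    "filter_proteins",
    "read_metadata",
    "write_results",
    "write_json_report",
    "write_protein_groups",
    "write_metadata",
]

IBAQ_PREFIX = "iBAQ "
#: iBAQ-prefixed columns of proteinGroups.txt that are not per-sample columns
_NON_SAMPLE_IBAQ = {"iBAQ", "iBAQ peptides"}
_ID_COLUMN = "Majority protein IDs"
_FLAG_COLUMNS = {
    "is_contaminant": "Potential contaminant",
    "is_reverse": "Reverse",
    "is_only_by_site": "Only identified by site",
}


def _flag_series(df: pd.DataFrame, column: str) -> pd.Series:
    if column not in df.columns:
        return pd.Series(False, index=df.index)
    s = df[column].astype("string")
    return (~s.isna()) & (s.str.strip() != "")


def read_protein_groups(
    path: str | os.PathLike, id_policy: str = "first-accession"
) -> tuple[AbundanceMatrix, list[ProteinRecord]]:
    """Parse a proteinGroups-dialect TSV into a matrix plus protein records.

    Empty or NaN iBAQ cells become 0 (not detected).  ``id_policy`` selects
    whether the protein id is the first accession of "Majority protein IDs"
    (``"first-accession"``, the default: results are reported per protein
    group under its leading accession) or the full semicolon-joined group
    (``"full"``).
    """
    if id_policy not in ("first-accession", "full"):
        raise ValueError(f"unknown id_policy {id_policy!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    ibaq_cols = [
        c for c in df.columns if c.startswith(IBAQ_PREFIX) and c not in _NON_SAMPLE_IBAQ
    ]
    if not ibaq_cols:
        raise FormatError(f"no 'iBAQ <sample>' columns found in {path}")
    if _ID_COLUMN in df.columns:
        ids = df[_ID_COLUMN].fillna("")
    elif "Protein IDs" in df.columns:
        ids = df["Protein IDs"].fillna("")
    else:
        raise FormatError(f"no protein id column ('{_ID_COLUMN}') in {path}")
    if id_policy == "first-accession":
        ids = ids.str.split(";").str[0]
    ids = ids.str.strip()
    if (ids == "").any():
        raise IntegrityError("empty protein id encountered")
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise IntegrityError(f"duplicate protein ids: {dups[:5]}")

    values = (
        df[ibaq_cols]
        .apply(pd.to_numeric, errors="coerce")
        .fillna(0.0)
        .to_numpy(dtype=float)
    )
    samples = [c[len(IBAQ_PREFIX):] for c in ibaq_cols]
    matrix = AbundanceMatrix.from_arrays(values, ids.tolist(), samples)

    scores = (
        pd.to_numeric(df["Score"], errors="coerce")
        if "Score" in df.columns
        else pd.Series(np.inf, index=df.index)
    )
    gene_names = df["Gene names"] if "Gene names" in df.columns else None
    flags = {k: _flag_series(df, col) for k, col in _FLAG_COLUMNS.items()}
    records = [
        ProteinRecord(
            protein_id=ids.iloc[i],
            score=float(scores.iloc[i]) if pd.notna(scores.iloc[i]) else float("inf"),
            gene_name=(
                None
                if gene_names is None or pd.isna(gene_names.iloc[i])
                else str(gene_names.iloc[i])
            ),
            **{k: bool(v.iloc[i]) for k, v in flags.items()},
        )
        for i in range(len(df))
    ]
    return matrix, records


def filter_proteins(
    matrix: AbundanceMatrix,
    records: Sequence[ProteinRecord],
    min_score: float = 70.0,
) -> AbundanceMatrix:
    """Drop contaminant/reverse/only-by-site groups and scores below ``min_score``.

    The score rule is a strict less-than: a protein scoring exactly
    ``min_score`` is retained.  The sample axis is unchanged.
    """
    by_id = {r.protein_id: r for r in records}
    missing = [p for p in matrix.proteins if p not in by_id]
    if missing:
        raise IntegrityError(f"no record for matrix proteins: {missing[:5]}")
    keep = [
        p
        for p in matrix.proteins
        if not by_id[p].flagged and not by_id[p].score < min_score
    ]
    return matrix.select_proteins(keep)


_METADATA_REQUIRED = ("sample_id", "sample_type")
_METADATA_OPTIONAL = ("colony_id", "volume_ul", "pair_key", "scale")


def read_metadata(path: str | os.PathLike) -> list[SampleAnnotation]:
    """Read the sample-metadata CSV (required: sample_id, sample_type)."""
    df = pd.read_csv(path, dtype=str)
    for col in _METADATA_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"metadata column {col!r} missing in {path}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise IntegrityError(f"duplicate sample ids in metadata: {dups[:5]}")
    annotations = []
    for _, row in df.iterrows():
        kwargs: dict[str, Any] = {
            "sample_id": row["sample_id"],
            "sample_type": row["sample_type"],
        }
        for col in _METADATA_OPTIONAL:
            if col in df.columns and pd.notna(row[col]) and str(row[col]).strip() != "":
                kwargs[col] = float(row[col]) if col == "volume_ul" else str(row[col])
        annotations.append(SampleAnnotation(**kwargs))
    return annotations


def write_results(table: pd.DataFrame, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write a result table as TSV (lossless float round-trip) or JSON."""
    if table is None or len(table) == 0:
        raise TrophoError("refusing to write an empty result table")
    if format == "tsv":
        table.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "json":
        table.reset_index().to_json(path, orient="records", indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_json_report(report: dict, path: str | os.PathLike) -> None:
    """Write a JSON run report (configuration echo plus results)."""
    if not report:
        raise TrophoError("refusing to write an empty report")

    def _default(o: Any) -> Any:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_default)


def write_protein_groups(
    matrix: AbundanceMatrix,
    path: str | os.PathLike,
    records: Sequence[ProteinRecord] | None = None,
) -> None:
    """Write a matrix back out in the proteinGroups dialect (inverse of read)."""
    by_id = {r.protein_id: r for r in records} if records else {}
    out = pd.DataFrame({_ID_COLUMN: matrix.proteins})
    out["Score"] = [
        by_id[p].score if p in by_id and np.isfinite(by_id[p].score) else 200.0
        for p in matrix.proteins
    ]
    for key, col in _FLAG_COLUMNS.items():
        out[col] = ["+" if p in by_id and getattr(by_id[p], key) else "" for p in matrix.proteins]
    for s in matrix.samples:
        out[IBAQ_PREFIX + s] = matrix.data[s].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_metadata(annotations: Sequence[SampleAnnotation], path: str | os.PathLike) -> None:
    from .data import annotation_frame

    annotation_frame(annotations).to_csv(path)
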