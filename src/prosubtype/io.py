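"""Readers and writers for the pipeline's text formats.

Formats handled here:

* expression matrices — tab-separated (genes in rows, first column = gene
  ID) or MatrixMarket triplets with ``.rows.txt`` / ``.cols.txt`` ID
  sidecars;
* GMT gene-set files (name, description, genes...);
* CSV clinical and purity tables;
* the subtype-call table written after deconvolution.

Duplicate gene rows are collapsed by the per-sample maximum, the common
convention for multi-probe genes.  An optional symbol-to-ID map may be
applied at read time; unmapped genes are dropped with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ExpressionMatrix,
    GeneSet,
    ParseError,
    SubtypeCall,
    ValidationError,
)

logger = logging.getLogger("prosubtype")

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "write_subtype_table",
    "read_subtype_table",
    "read_clinical",
    "read_purity",
    "load_config",
]


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by per-sample maximum", n_dup)
        df = df.groupby(level=0, sort=False).max()
    return df


def _apply_id_map(df: pd.DataFrame, id_map: Mapping[str, str]) -> pd.DataFrame:
    mapped = df.index.map(lambda g: id_map.get(g))
    n_drop = int(pd.isna(mapped).sum())
    if n_drop:
        logger.warning("dropping %d genes absent from the ID map", n_drop)
    keep = ~pd.isna(mapped)
    out = df.loc[keep].copy()
    out.index = pd.Index(mapped[keep])
    return _collapse_duplicate_genes(out)


def read_expression(
    path: str | Path,
    format: str = "tsv",
    scale: str = "linear",
    id_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from ``path``.

    ``format='tsv'`` expects gene IDs in the first column and sample IDs
    in the header.  ``format='mtx_triplet'`` expects a MatrixMarket file
    plus ``<stem>.rows.txt`` and ``<stem>.cols.txt`` sidecars with one ID
    per line.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        sample_cols = pd.Index(header.split("\t")[1:])
        if sample_cols.has_duplicates:
            dups = sample_cols[sample_cols.duplicated()].unique().tolist()
            raise ParseError(f"{path}: duplicate sample IDs {dups[:5]}")
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise ParseError(f"{path}: empty file") from exc
        bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
        if len(bad):
            col = bad[0]
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = df.index[coerced.isna() & df[col].notna()]
            where = row[0] if len(row) else "?"
            raise ParseError(f"{path}: malformed numeric cell at gene {where!r}, sample {col!r}")
    elif format == "mtx_triplet":
        from scipy.io import mmread

        rows_f = path.with_suffix(".rows.txt")
        cols_f = path.with_suffix(".cols.txt")
        for side in (rows_f, cols_f):
            if not side.exists():
                raise ParseError(f"missing sidecar index file: {side}")
        try:
            mat = mmread(path)
        except Exception as exc:  # pragma: no cover - scipy error text varies
            raise ParseError(f"{path}: {exc}") from exc
        genes = rows_f.read_text().split()
        samples = cols_f.read_text().split()
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if dense.shape != (len(genes), len(samples)):
            raise ParseError(
                f"{path}: matrix shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        if pd.Index(samples).has_duplicates:
            raise ParseError(f"{path}: duplicate sample IDs in {cols_f}")
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")

    df = _collapse_duplicate_genes(df)
    if id_map is not None:
        df = _apply_id_map(df, id_map)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT gene sets; one set per tab-separated line."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
        name = fields[0]
        genes = [g for g in fields[2:] if g]
        if len(set(genes)) < len(genes):
            logger.warning("%s:%d: duplicate genes in set %r deduplicated", path, lineno, name)
        sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.direction] + sorted(gs.genes)) + "\n")


def write_subtype_table(calls: Sequence[SubtypeCall], path: str | Path) -> None:
    """Write deconvolution calls as CSV (PEs with 6 decimals).

    An empty call list produces a header-only file with the generic
    columns; otherwise cluster columns follow the first call's order.
    """
    if not calls:
        pd.DataFrame(columns=["sample_id", "pe_max", "p_value", "label"]).to_csv(
            path, index=False
        )
        return
    clusters = list(calls[0].pe.index)
    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id}
        for k in clusters:
            row[f"PE_{k}"] = float(c.pe[k])
        row["pe_max"] = c.pe_max
        row["p_value"] = c.p_value
        row["label"] = c.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_subtype_table(path: str | Path) -> list[SubtypeCall]:
    df = pd.read_csv(path)
    pe_cols = [c for c in df.columns if c.startswith("PE_")]
    calls = []
    for _, row in df.iterrows():
        pe = pd.Series({c[3:]: float(row[c]) for c in pe_cols})
        pe = pe / pe.sum()
        calls.append(
            SubtypeCall(
                sample_id=str(row["sample_id"]),
                pe=pe,
                p_value=float(row["p_value"]),
                label=str(row["label"]),
            )
        )
    return calls


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical CSV and validate the serum/survival columns.

    Required columns: ``patient_id``, ``time_days``, ``event``.  Optional:
    ``psa``, ``pap``, ``pap_assay`` and arbitrary covariate columns
    (e.g. per-gene alteration status).
    """
    df = pd.read_csv(path)
    required = {"patient_id", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing clinical columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate patient IDs")
    if (df["time_days"] < 0).any():
        raise ValidationError("time_days must be non-negative")
    for col in ("psa", "pap"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"{col} must be non-negative")
    df["event"] = df["event"].astype(bool)
    return df


_PURITY_COLS = ("dna_1", "dna_2", "rna_1", "rna_2")


def read_purity(path: str | Path) -> pd.DataFrame:
    """Read per-sample purity scores (columns among dna_1/dna_2/rna_1/rna_2)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    unknown = [c for c in df.columns if c not in _PURITY_COLS]
    if unknown:
        raise ParseError(f"{path}: unknown purity columns {unknown}")
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
    if not ok.all():
        raise ValidationError("purity scores must lie in [0, 1]")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML (or flat key: value) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg
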