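"""Readers, writers and schema validation for every on-disk format the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention): the span
``[start, end)`` has length ``end - start``.  Tables are TSV with a header
row, UTF-8, '.' decimal.  Unknown extra columns are preserved on read but
never interpreted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

DEFAULT_CONDITIONS = ("terrestrial", "submerged", "submerged_ABA")
SUBGENOMES = ("A", "B", "unassigned")


class SchemaError(ValueError):
    """An input file violates the documented schema.

    The message names the offending column, value or row so the file can be
    fixed without reading source code.
    """


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with id sidecars."""

    gene_ids: list[str]
    cell_ids: list[str]
    matrix: sp.csr_matrix  # genes x cells, non-negative integers

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise SchemaError(f"duplicate gene id {dup!r}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dup = _first_duplicate(self.cell_ids)
            raise SchemaError(f"duplicate cell id {dup!r}")
        if self.matrix.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise SchemaError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.matrix.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            bad = data[(data < 0) | (data != np.floor(data))][0]
            raise SchemaError(f"count matrix entry {bad} is not a non-negative integer")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def read_count_matrix(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read a Matrix Market count matrix with gene/cell id sidecar TSVs.

    The sidecars carry one id per line (first column if tab-separated);
    rows of the matrix are genes, columns are cells.
    """
    mat = scipy.io.mmread(str(matrix_path))
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    return CountMatrix(genes, cells, sp.csr_matrix(mat))


def _read_id_column(path) -> list[str]:
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def write_count_matrix(cm: CountMatrix, matrix_path, genes_path, cells_path) -> None:
    scipy.io.mmwrite(str(matrix_path), cm.matrix.tocoo(), field="integer")
    for path, ids in ((genes_path, cm.gene_ids), (cells_path, cm.cell_ids)):
        with open(path, "w", encoding="utf-8") as fh:
            for x in ids:
                fh.write(f"{x}\n")


# ---------------------------------------------------------------------------
# generic table reading with per-schema validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _check_enum(df: pd.DataFrame, col: str, vocab, what: str) -> None:
    bad = ~df[col].isin(vocab)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{what} row {row}: invalid {col} {df[col].iloc[row]!r}; "
            f"expected one of {sorted(vocab)}"
        )


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    bad = df["start"].to_numpy() >= df["end"].to_numpy()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"{what} row {row}: start {df['start'].iloc[row]} >= end {df['end'].iloc[row]} "
            "(coordinates are 0-based half-open)"
        )


def read_cell_annotation(path, conditions=DEFAULT_CONDITIONS) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_cell_annotation(df, conditions=conditions)


def validate_cell_annotation(df: pd.DataFrame, conditions=DEFAULT_CONDITIONS) -> pd.DataFrame:
    _require_columns(df, ("cell_id", "cell_type", "condition", "replicate"), "cell annotation")
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise SchemaError(f"cell annotation: duplicate cell_id {dup!r}")
    _check_enum(df, "condition", conditions, "cell annotation")
    return df.reset_index(drop=True)


def read_gene_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "subgenome": str, "family": str})
    return validate_gene_annotation(df)


def validate_gene_annotation(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ("gene_id", "subgenome"), "gene annotation")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise SchemaError(f"gene annotation: duplicate gene_id {dup!r}")
    _check_enum(df, "subgenome", SUBGENOMES, "gene annotation")
    if {"start", "end"}.issubset(df.columns):
        coords = df.dropna(subset=["start", "end"])
        if len(coords):
            _check_intervals(coords, "gene annotation")
    return df.reset_index(drop=True)


def read_homeolog_table(path, gene_annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_homeolog_table(df, gene_annotation)


def validate_homeolog_table(df: pd.DataFrame, gene_annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    _require_columns(df, ("gene_A", "gene_B", "family"), "homeolog table")
    all_genes = pd.concat([df["gene_A"], df["gene_B"]])
    if all_genes.duplicated().any():
        dup = all_genes[all_genes.duplicated()].iloc[0]
        raise SchemaError(f"homeolog table: gene {dup!r} appears in more than one pair")
    if gene_annotation is not None:
        sub = gene_annotation.set_index("gene_id")["subgenome"]
        for col, want in (("gene_A", "A"), ("gene_B", "B")):
            for row, g in enumerate(df[col]):
                if g not in sub.index:
                    raise SchemaError(f"homeolog table row {row}: unknown gene {g!r}")
                if sub[g] != want:
                    raise SchemaError(
                        f"homeolog table row {row}: gene {g!r} is in subgenome "
                        f"{sub[g]!r}, expected {want!r}"
                    )
    return df.reset_index(drop=True)


def read_peak_links(path, conditions=DEFAULT_CONDITIONS) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={
        "element_id": str, "chromosome": str, "gene_id": str,
        "motif_family": str, "cell_type": str, "condition": str,
    })
    return validate_peak_links(df, conditions=conditions)


def validate_peak_links(df: pd.DataFrame, conditions=DEFAULT_CONDITIONS) -> pd.DataFrame:
    _require_columns(
        df,
        ("element_id", "chromosome", "start", "end", "gene_id",
         "motif_family", "cell_type", "condition"),
        "peak link table",
    )
    _check_intervals(df, "peak link table")
    if conditions is not None:
        _check_enum(df, "condition", conditions, "peak link table")
    return df.reset_index(drop=True)


def read_ortholog_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_sp1": str, "gene_sp2": str})
    return validate_ortholog_scores(df)


def validate_ortholog_scores(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ("gene_sp1", "gene_sp2", "score"), "ortholog score table")
    dup = df.duplicated(subset=["gene_sp1", "gene_sp2"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(
            f"ortholog score table row {row}: duplicate pair "
            f"({df['gene_sp1'].iloc[row]!r}, {df['gene_sp2'].iloc[row]!r})"
        )
    if (df["score"] < 0).any():
        raise SchemaError("ortholog score table: negative score")
    if "evalue" in df.columns and (df["evalue"].dropna() < 0).any():
        raise SchemaError("ortholog score table: negative e-value")
    return df.reset_index(drop=True)


#: schema name -> validator, used by the generic entry point
_SCHEMAS = {
    "cell_annotation": validate_cell_annotation,
    "gene_annotation": validate_gene_annotation,
    "homeolog_table": validate_homeolog_table,
    "peak_links": validate_peak_links,
    "ortholog_scores": validate_ortholog_scores,
}


def read_table(path, schema: str, **kwargs) -> pd.DataFrame:
    """Read a TSV and validate it against one of the named schemas.

    ``schema`` is one of ``cell_annotation``, ``gene_annotation``,
    ``homeolog_table``, ``peak_links``, ``ortholog_scores``.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(_SCHEMAS)}")
    df = pd.read_csv(path, sep="\t", dtype=str if schema in
                     ("cell_annotation", "homeolog_table") else None)
    return _SCHEMAS[schema](df, **kwargs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, float_format: str = "%.10g", sort_by=None) -> None:
    """Write a TSV deterministically: fixed column order, optional row sort."""
    out = df.sort_values(list(sort_by)).reset_index(drop=True) if sort_by else df
    out.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_matrix_tsv(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a families x groups matrix; row index is the first column."""
    flat = df.copy()
    if isinstance(flat.columns, pd.MultiIndex):
        flat.columns = ["|".join(map(str, c)) for c in flat.columns]
    flat.sort_index().to_csv(path, sep="\t", index=True, float_format=float_format)


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if any("|" in str(c) for c in df.columns):
        df.columns = pd.MultiIndex.from_tuples([tuple(str(c).split("|")) for c in df.columns])
    return df


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
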