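"""Readers and writers for every on-disk format the pipeline touches.

Formats: MatrixMarket triplet directories (matrix.mtx + features.tsv +
barcodes.tsv) for UMI counts, TSV with a header row for bulk matrices and all
tabular outputs, GMT for gene sets, and a two-column TSV for the ortholog
map. MatrixMarket files follow the gene-expression convention of
features-as-rows on disk; in memory cells are always rows. Orientation is
inferred from the barcode count, so either on-disk orientation reads
correctly.

All read/write pairs are lossless round trips for values, identifiers and
metadata. Output writers accept an optional ``header`` comment (used by the
pipeline to stamp the config hash and seed into every file).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .containers import CountMatrix, ExpressionMatrix, FormatError, GeneSet, MetadataError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# single-cell counts (MatrixMarket triplet)

def read_count_matrix(path_triplet: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a matrix.mtx/features.tsv/barcodes.tsv directory plus a cell-metadata TSV.

    The metadata TSV must have a ``barcode`` column plus ``cell_type``,
    ``genotype`` and ``animal``; every barcode in the matrix must appear in it.
    """
    d = Path(path_triplet)
    mtx_path = d / "matrix.mtx"
    try:
        mat = spio.mmread(mtx_path)
    except Exception as exc:  # scipy raises bare ValueError on truncation
        raise FormatError(f"{mtx_path}: not a valid MatrixMarket file ({exc})") from exc
    mat = sp.coo_matrix(mat)

    features = _read_id_column(d / "features.tsv")
    barcodes = _read_id_column(d / "barcodes.tsv")

    n_rows, n_cols = mat.shape
    if (n_rows, n_cols) == (len(features), len(barcodes)):
        counts = mat.T  # features-as-rows on disk (the usual convention)
    elif (n_rows, n_cols) == (len(barcodes), len(features)):
        counts = mat
    else:
        raise FormatError(
            f"{mtx_path}: shape {mat.shape} matches neither "
            f"{len(features)} features x {len(barcodes)} barcodes nor its transpose"
        )

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "barcode" not in meta.columns:
        raise FormatError(f"{meta_path}: missing 'barcode' column")
    meta = meta.set_index("barcode")
    missing = [b for b in barcodes if b not in meta.index]
    if missing:
        raise MetadataError(f"barcodes absent from {meta_path}: {missing[:10]}")

    dense = np.asarray(counts.todense())
    return CountMatrix(dense, features, barcodes, meta.loc[barcodes])


def write_count_matrix(cm: CountMatrix, path_triplet: str | Path, meta_path: str | Path) -> None:
    """Write the MatrixMarket triplet (features-as-rows on disk) and metadata TSV."""
    d = Path(path_triplet)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(d / "matrix.mtx", sp.coo_matrix(cm.counts.T))
    (d / "features.tsv").write_text("".join(g + "\n" for g in cm.gene_ids))
    (d / "barcodes.tsv").write_text("".join(c + "\n" for c in cm.cell_ids))
    cm.cell_meta.rename_axis("barcode").to_csv(meta_path, sep="\t")


def _read_id_column(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    ids = [line.split("\t")[0] for line in path.read_text().splitlines() if line.strip()]
    return ids


# ---------------------------------------------------------------------------
# bulk expression TSV

def read_expression(path: str | Path, meta_path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene id) and a sample-metadata TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str, comment="#")
    return ExpressionMatrix(values, meta, scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path, meta_path: str | Path,
                     header: str | None = None) -> None:
    write_table(expr.values.rename_axis("gene"), path, header=header)
    write_table(expr.sample_meta.rename_axis("sample"), meta_path, header=header)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    The description field is discarded. Duplicate genes within a line are
    deduplicated with a logged warning; a line with fewer than three fields is
    a format error.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            log.warning("GMT set %r line %d: %d duplicate genes removed",
                        name, lineno, len(genes) - len(deduped))
        sets.append(GeneSet(name, deduped))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# ortholog map

def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Read the rat/mouse ortholog TSV (columns rat_gene, mouse_gene, extras kept)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("rat_gene", "mouse_gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# generic tabular output

def write_table(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a TSV, optionally preceded by '#'-prefixed comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")
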