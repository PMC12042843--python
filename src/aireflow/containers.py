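"""Core in-memory containers shared by every pipeline stage.

Three containers cover the pipeline's inputs: :class:`ExpressionMatrix` for
bulk gene-by-sample tables (linear or log2 scale), :class:`CountMatrix` for
single-cell UMI counts with per-cell metadata, and :class:`GeneSet` for named
gene lists with optional boolean labels (for example a ``tonic_sensitive``
flag on an interferon-stimulated-gene list).

Gene and cell identifiers are opaque, case-sensitive strings; no symbol
normalization is performed anywhere — cross-species harmonization is the job
of the explicit ortholog map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GENOTYPES = {"KO", "HE", "WT"}
VALID_SCALES = {"linear", "log2"}


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class MetadataError(ValueError):
    """Identifiers in a data matrix are missing from the metadata table."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample. Entries are
        non-negative reals on the scale declared by ``scale``.
    sample_meta
        DataFrame indexed by sample id with columns ``genotype`` (one of
        KO/HE/WT), ``group`` (tissue or cell-type label) and ``animal``.
    scale
        ``"linear"`` or ``"log2"`` (meaning log2(expression + 1)).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {sorted(VALID_SCALES)}, got {self.scale!r}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains NaN")
        if (arr < 0).any():
            raise ValueError("expression matrix contains negative values")
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise MetadataError(f"samples without metadata: {sorted(missing)[:5]}")
        bad = set(self.sample_meta["genotype"]) - VALID_GENOTYPES
        if bad:
            raise ValueError(f"unknown genotypes {sorted(bad)}; expected {sorted(VALID_GENOTYPES)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (unlogging log2(x+1) values if needed)."""
        if self.scale == "linear":
            return self
        lin = np.exp2(self.values) - 1.0
        lin[lin < 0] = 0.0
        return ExpressionMatrix(lin, self.sample_meta, scale="linear")

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2(x+1)-scale copy."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), self.sample_meta, scale="log2")


@dataclass
class CountMatrix:
    """Cell-by-gene UMI counts with per-cell metadata.

    ``counts`` is cells-as-rows in memory regardless of on-disk orientation.
    ``cell_meta`` is indexed by cell barcode and carries ``cell_type``,
    ``genotype`` and ``animal`` columns.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise MetadataError(f"cells without metadata: {sorted(missing)[:5]}")
        self.cell_meta = self.cell_meta.loc[self.cell_ids]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def lognorm(self, target_sum: float = 1e4) -> np.ndarray:
        """Per-cell library-size normalized log2(1 + target_sum * x / libsize)."""
        lib = self.counts.sum(axis=1, keepdims=True).astype(float)
        lib[lib == 0] = 1.0
        return np.log2(1.0 + target_sum * self.counts / lib)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        ids = [c for c, m in zip(self.cell_ids, mask) if m]
        return CountMatrix(self.counts[mask], list(self.gene_ids), ids, self.cell_meta.loc[ids])


@dataclass
class GeneSet:
    """A named gene list with optional per-gene boolean labels."""

    name: str
    genes: list[str]
    labels: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.genes, f"genes in set {self.name!r}")
        if self.labels is not None:
            stray = set(self.labels) - set(self.genes)
            if stray:
                raise ValueError(f"labels for non-member genes in {self.name!r}: {sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersect(self, universe) -> "GeneSet":
        """Restrict the set (and its labels) to genes present in ``universe``."""
        keep = [g for g in self.genes if g in set(universe)]
        labels = None
        if self.labels is not None:
            labels = {g: v for g, v in self.labels.items() if g in set(keep)}
        return GeneSet(self.name, keep, labels)


@dataclass
class DETable:
    """Per-gene differential-expression results (KO minus control on log2 scale)."""

    table: pd.DataFrame  # index gene; columns lfc, p, padj
    method: str = "BH"

    def __post_init__(self) -> None:
        for col in ("lfc", "p", "padj"):
            if col not in self.table.columns:
                raise ValueError(f"DE table missing column {col!r}")
        p = self.table["p"].to_numpy()
        padj = self.table["padj"].to_numpy()
        ok = ~np.isnan(p)
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("raw p outside [0, 1]")
        ok2 = ~(np.isnan(p) | np.isnan(padj))
        if (padj[ok2] + 1e-12 < p[ok2]).any():
            raise ValueError("adjusted p below raw p")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class TruthRecord:
    """Machine-readable ground truth emitted by every synthetic generator."""

    planted_tra: dict[str, int] = field(default_factory=dict)  # gene -> expressing-group count
    planted_aire_dep: dict[str, float] = field(default_factory=dict)  # gene -> true log2 effect
    planted_isg: dict[str, dict] = field(default_factory=dict)  # gene -> {tonic_sensitive, lfc}
    planted_modules: dict[str, int] = field(default_factory=dict)  # gene -> module id

    def to_json_dict(self) -> dict:
        return {
            "planted_tra": self.planted_tra,
            "planted_aire_dep": self.planted_aire_dep,
            "planted_isg": self.planted_isg,
            "planted_modules": self.planted_modules,
        }
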