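"""Core in-memory domain types shared by every pipeline stage.

All genomic coordinates are 0-based half-open throughout the package; format
readers convert at the boundary (GTF's 1-based closed intervals included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


class FormatError(ValueError):
    """A file violates its format contract (rejected, never silently repaired)."""


class InputError(ValueError):
    """Inputs are well-formed but semantically unusable (e.g. disjoint barcodes)."""


class ConfigError(ValueError):
    """A configuration object or file is invalid."""


class NormalizationError(ValueError):
    """Size-factor normalization is impossible for the given matrix."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CellExperiment:
    """A multiplexed single-cell experiment: gene counts paired with hashtag counts.

    Rows of ``gene_counts`` and ``hto_counts`` are the same cells in the same
    order. ``cell_meta`` is indexed by barcode and accumulates per-cell calls
    (``qc_pass``, ``hashtag_call``, ``condition``, ``genotype_call``) as the
    pipeline stages run.
    """

    gene_counts: sparse.csr_matrix
    hto_counts: np.ndarray
    gene_ids: list[str]
    hto_ids: list[str]
    barcode_ids: list[str]
    mito_mask: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_counts = sparse.csr_matrix(self.gene_counts)
        self.hto_counts = np.asarray(self.hto_counts)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        n_cells, n_genes = self.gene_counts.shape
        if self.hto_counts.shape[0] != n_cells:
            raise InputError(
                f"gene matrix has {n_cells} cells but HTO matrix has "
                f"{self.hto_counts.shape[0]}"
            )
        if len(self.gene_ids) != n_genes:
            raise InputError("gene_ids length does not match gene matrix columns")
        if len(self.barcode_ids) != n_cells:
            raise InputError("barcode_ids length does not match matrix rows")
        if len(self.hto_ids) != self.hto_counts.shape[1]:
            raise InputError("hto_ids length does not match HTO matrix columns")
        if self.mito_mask.shape != (n_genes,):
            raise InputError("mito_mask must be one boolean per gene")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.barcode_ids, "barcodes")
        for m, what in ((self.gene_counts.data, "gene"), (self.hto_counts, "HTO")):
            arr = np.asarray(m)
            if arr.size and (arr < 0).any():
                raise FormatError(f"negative {what} counts")
            if arr.size and not np.allclose(arr, np.round(arr)):
                raise FormatError(f"non-integral {what} counts")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcode_ids, name="barcode"))
        else:
            self.cell_meta = self.cell_meta.copy()
            if list(self.cell_meta.index) != list(self.barcode_ids):
                raise InputError("cell_meta index must equal barcode_ids")

    @property
    def n_cells(self) -> int:
        return self.gene_counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.gene_counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise InputError(f"gene {gene_id!r} not present in experiment") from None

    def subset_cells(self, mask_or_idx) -> "CellExperiment":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellExperiment(
            gene_counts=self.gene_counts[idx],
            hto_counts=self.hto_counts[idx],
            gene_ids=list(self.gene_ids),
            hto_ids=list(self.hto_ids),
            barcode_ids=[self.barcode_ids[i] for i in idx],
            mito_mask=self.mito_mask.copy(),
            cell_meta=self.cell_meta.iloc[idx],
        )

    def to_anndata(self):
        """Bridge to an AnnData (HTO counts in ``obsm['hto_counts']``)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.gene_counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame({"mito": self.mito_mask}, index=self.gene_ids),
        )
        adata.obs_names = self.barcode_ids
        adata.obsm["hto_counts"] = self.hto_counts.copy()
        adata.uns["hto_ids"] = list(self.hto_ids)
        return adata


@dataclass(frozen=True)
class GeneModel:
    """One gene: 0-based half-open span plus strand-derived TSS.

    The TSS is the biological 5' end: ``start`` on the plus strand, ``end - 1``
    (the last base of the interval) on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise FormatError(f"gene {self.gene_id}: start must be < end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-chromosome nonnegative read-density vectors at fixed resolution (bp)."""

    chroms: dict[str, np.ndarray]
    resolution: int = 1

    def __post_init__(self) -> None:
        for name, values in self.chroms.items():
            arr = np.asarray(values, dtype=float)
            if arr.size and arr.min() < 0:
                raise FormatError(f"negative coverage on {name}")
            self.chroms[name] = arr

    @property
    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.chroms.values()) * self.resolution)

    def values(self, chrom: str) -> np.ndarray:
        if chrom not in self.chroms:
            raise InputError(f"chromosome {chrom!r} not in track")
        return self.chroms[chrom]

    def scaled(self, factor: float) -> "CoverageTrack":
        if factor < 0:
            raise InputError("scale factor must be nonnegative")
        return CoverageTrack(
            {c: v * factor for c, v in self.chroms.items()}, self.resolution
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> ordered unique members."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(str(m) for m in members))
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())
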