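"""Readers and writers for every external format the pipeline touches.

Supported formats: CellRanger-style MTX triplets (matrix.mtx + barcodes.tsv +
features.tsv, one directory for gene expression and one for hashtag counts),
BED6 and gene-level GTF annotations, bedGraph coverage, and GMT gene sets.
Readers validate strictly and raise :class:`~chromstress.models.FormatError`
rather than repairing malformed input; every writer/reader pair round-trips
valid data exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .models import (
    CellExperiment,
    CoverageTrack,
    FormatError,
    GeneModel,
    GeneSetCollection,
    InputError,
)

# ---------------------------------------------------------------------------
# MTX triplet directories (CellRanger layout)
# ---------------------------------------------------------------------------


def _read_mtx_dir(directory):
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    barcodes = directory / "barcodes.tsv"
    features = directory / "features.tsv"
    for p in (mtx, barcodes, features):
        if not p.exists():
            raise InputError(f"missing {p.name} in {directory}")
    try:
        matrix = sparse.csc_matrix(spio.mmread(str(mtx)))
    except ValueError as exc:
        raise FormatError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    bc = pd.read_csv(barcodes, sep="\t", header=None, dtype=str)
    feat = pd.read_csv(features, sep="\t", header=None, dtype=str)
    barcode_ids = bc[0].tolist()
    feature_ids = feat[0].tolist()
    symbols = feat[1].tolist() if feat.shape[1] > 1 else feature_ids
    # CellRanger stores features x barcodes
    if matrix.shape != (len(feature_ids), len(barcode_ids)):
        raise FormatError(
            f"{mtx}: matrix shape {matrix.shape} does not match "
            f"{len(feature_ids)} features x {len(barcode_ids)} barcodes"
        )
    if pd.Index(feature_ids).has_duplicates:
        raise FormatError(f"{features}: duplicate feature ids")
    if pd.Index(barcode_ids).has_duplicates:
        raise FormatError(f"{barcodes}: duplicate barcodes")
    if matrix.data.size and matrix.data.min() < 0:
        raise FormatError(f"{mtx}: negative counts")
    if matrix.data.size and not np.allclose(matrix.data, np.round(matrix.data)):
        raise FormatError(f"{mtx}: non-integral counts")
    return sparse.csr_matrix(matrix.T), feature_ids, symbols, barcode_ids


def read_cell_experiment(mtx_dir_expr, mtx_dir_hto, mito_prefix: str = "MT-") -> CellExperiment:
    """Load a paired expression + hashtag experiment from two MTX directories.

    Barcodes present in only one matrix are dropped; the returned experiment is
    restricted to the intersection, preserving the expression matrix's barcode
    order. Genes whose symbol starts with ``mito_prefix`` form the
    mitochondrial mask.
    """
    expr, gene_ids, symbols, expr_bc = _read_mtx_dir(mtx_dir_expr)
    hto, hto_ids, _, hto_bc = _read_mtx_dir(mtx_dir_hto)
    hto_pos = {b: i for i, b in enumerate(hto_bc)}
    keep = [(i, hto_pos[b]) for i, b in enumerate(expr_bc) if b in hto_pos]
    if not keep:
        raise InputError("no barcodes shared between expression and HTO matrices")
    expr_idx, hto_idx = zip(*keep)
    mito_mask = np.array([s.startswith(mito_prefix) for s in symbols], dtype=bool)
    return CellExperiment(
        gene_counts=expr[list(expr_idx)],
        hto_counts=np.asarray(hto[list(hto_idx)].todense()),
        gene_ids=list(gene_ids),
        hto_ids=list(hto_ids),
        barcode_ids=[expr_bc[i] for i in expr_idx],
        mito_mask=mito_mask,
    )


def _write_mtx_dir(directory, matrix, feature_ids, symbols, barcodes, feature_type):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        str(directory / "matrix.mtx"),
        sparse.coo_matrix(matrix.T).astype(np.int64),
        field="integer",
    )
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.write("".join(f"{b}\n" for b in barcodes))
    with open(directory / "features.tsv", "w") as fh:
        for fid, sym in zip(feature_ids, symbols):
            fh.write(f"{fid}\t{sym}\t{feature_type}\n")


def write_cell_experiment(experiment: CellExperiment, mtx_dir_expr, mtx_dir_hto) -> None:
    """Write an experiment back to the two-directory MTX triplet layout."""
    _write_mtx_dir(
        mtx_dir_expr,
        experiment.gene_counts,
        experiment.gene_ids,
        experiment.gene_ids,
        experiment.barcode_ids,
        "Gene Expression",
    )
    _write_mtx_dir(
        mtx_dir_hto,
        sparse.csr_matrix(experiment.hto_counts),
        experiment.hto_ids,
        experiment.hto_ids,
        experiment.barcode_ids,
        "Antibody Capture",
    )


# ---------------------------------------------------------------------------
# Gene annotations: BED6 and gene-level GTF
# ---------------------------------------------------------------------------


def read_gene_models(path, format: str = "BED") -> list[GeneModel]:
    """Read gene models from BED6 or gene-level GTF.

    BED coordinates are already 0-based half-open; GTF's 1-based closed
    intervals are converted (start-1, end) at this boundary.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GTF"):
        raise InputError(f"unknown annotation format {format!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "BED":
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns")
                chrom, start, end, name, _score, strand = fields[:6]
                start, end = int(start), int(end)
            else:
                if len(fields) < 9:
                    raise FormatError(f"{path}:{lineno}: GTF requires 9 columns")
                chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
                if feature != "gene":
                    continue
                name = None
                for token in attrs.split(";"):
                    token = token.strip()
                    if token.startswith("gene_id"):
                        name = token.split(None, 1)[1].strip().strip('"')
                        break
                if not name:
                    raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
                start, end = int(start) - 1, int(end)
            if strand in (".", ""):
                raise FormatError(f"{path}:{lineno}: missing strand")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand, start=start, end=end))
    return genes


def write_gene_models(genes, path) -> None:
    """Write gene models as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


def read_coverage(path, chrom_sizes: dict[str, int] | None = None) -> CoverageTrack:
    """Read a bedGraph into a 1-bp-resolution track.

    Intervals may appear in any order and may overlap; overlaps are summed and
    gaps are zero, so ingestion is invariant to line permutation.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    maxend: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph requires 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage value")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            intervals.setdefault(chrom, []).append((start, end, value))
            maxend[chrom] = max(maxend.get(chrom, 0), end)
    chroms: dict[str, np.ndarray] = {}
    sizes = dict(chrom_sizes or {})
    for chrom, ivs in intervals.items():
        size = sizes.pop(chrom, maxend[chrom])
        if size < maxend[chrom]:
            raise InputError(f"{chrom}: interval extends past declared size {size}")
        arr = np.zeros(size, dtype=float)
        for start, end, value in ivs:
            arr[start:end] += value
        chroms[chrom] = arr
    for chrom, size in sizes.items():  # declared but absent from the file
        chroms[chrom] = np.zeros(size, dtype=float)
    return CoverageTrack(chroms, resolution=1)


def write_coverage(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph, run-length encoding equal adjacent values."""
    if track.resolution != 1:
        raise InputError("bedGraph output requires 1-bp resolution")
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            values = track.chroms[chrom]
            if values.size == 0:
                continue
            # boundaries of runs of identical values
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = float(values[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Uniform TSV output (header row, fixed float formatting) for all stages."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
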