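"""Readers, writers and shared configuration for the screen pipeline.

External formats handled here:

* design tables (TSV/CSV) mapping shRNA names to 8-nt barcodes and target
  genes, with optional control flags and hairpin sequences;
* paired FASTQ (optionally gzipped) from barcode-enrichment libraries;
* per-cell annotation tables (TSV) and Matrix-Market expression triplets
  with sidecar barcode/feature lists (the de-facto 10X dialect);
* YAML configuration bundling a read layout with assignment thresholds.

Missing values in TSVs are encoded as empty strings, never as sentinel
numerals.
"""

from __future__ import annotations

import gzip
import io as _stdio
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import hamming, is_dna

# 23-mer from the 3' end of the constitutive repressor transcript; reads
# carrying the shRNA cassette start with ANCHOR on read 2, reads from
# cassettes lacking an shRNA carry EMPTY_ANCHOR (last two bases differ).
ANCHOR = "CGGCTCCCCCAGATGAACGCGCC"
EMPTY_ANCHOR = "CGGCTCCCCCAGATGAACGCGTA"


class DataError(Exception):
    """Malformed or inconsistent input data."""


class FormatError(DataError):
    """A file does not conform to its expected format."""


# ---------------------------------------------------------------------------
# Design table


@dataclass(frozen=True)
class DesignEntry:
    shrna: str
    gene: str
    barcode: str
    is_control: bool = False
    hairpin: str | None = None  # hairpin-defining sequence, for pool QC


class DesignTable:
    """The known shRNA <-> barcode <-> gene map for one screen library."""

    def __init__(self, entries: Sequence[DesignEntry], bc_len: int | None = None):
        if not entries:
            raise FormatError("design table: no entries")
        lengths = {len(e.barcode) for e in entries}
        if len(lengths) != 1:
            raise FormatError(f"design table: mixed barcode lengths {sorted(lengths)}")
        self.bc_len = lengths.pop()
        if bc_len is not None and self.bc_len != bc_len:
            raise FormatError(
                f"design table: barcode length {self.bc_len} != expected {bc_len}"
            )
        seen_bc: dict[str, str] = {}
        seen_name: set[str] = set()
        for i, e in enumerate(entries):
            row = f"row {i + 1} ({e.shrna})"
            if not is_dna(e.barcode):
                raise FormatError(f"design table: non-ACGT barcode at {row}")
            if e.barcode in seen_bc:
                raise FormatError(
                    f"design table: duplicate barcode {e.barcode} at {row} "
                    f"(already used by {seen_bc[e.barcode]})"
                )
            if e.shrna in seen_name:
                raise FormatError(f"design table: duplicate shRNA name at {row}")
            seen_bc[e.barcode] = e.shrna
            seen_name.add(e.shrna)
        self.entries = list(entries)
        self.by_barcode = {e.barcode: e for e in entries}
        self.by_name = {e.shrna: e for e in entries}
        if not any(e.is_control for e in entries):
            warnings.warn("design table has no control entries", stacklevel=2)

    def __len__(self) -> int:
        return len(self.entries)

    def shrna_for_barcode(self, bc: str) -> str | None:
        e = self.by_barcode.get(bc)
        return e.shrna if e is not None else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shrna": [e.shrna for e in self.entries],
                "gene": [e.gene for e in self.entries],
                "barcode": [e.barcode for e in self.entries],
                "control": [int(e.is_control) for e in self.entries],
                "hairpin": [e.hairpin or "" for e in self.entries],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_TRUE = {"1", "true", "yes", "y", "t"}


def read_design_table(path: str | Path, expected_bc_len: int | None = 8) -> DesignTable:
    """Read a design table (TSV or CSV; columns shrna, gene, barcode[, control[, hairpin]])."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"design table {path}: no entries") from None
    required = {"shrna", "gene", "barcode"}
    if not required <= set(df.columns):
        raise FormatError(
            f"design table {path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df.empty:
        raise FormatError(f"design table {path}: no entries")
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        bc = row.barcode.strip().upper()
        if expected_bc_len is not None and len(bc) != expected_bc_len:
            raise FormatError(
                f"design table {path}: barcode of length {len(bc)} at row {i + 1}, "
                f"expected {expected_bc_len}"
            )
        if not is_dna(bc):
            raise FormatError(f"design table {path}: non-ACGT barcode {bc!r} at row {i + 1}")
        ctrl = getattr(row, "control", "").strip().lower() in _TRUE
        hairpin = getattr(row, "hairpin", "").strip().upper() or None
        entries.append(DesignEntry(row.shrna.strip(), row.gene.strip(), bc, ctrl, hairpin))
    return DesignTable(entries, bc_len=expected_bc_len)


# ---------------------------------------------------------------------------
# Read layout, thresholds, filter spec


@dataclass(frozen=True)
class ReadLayout:
    """Where cell ID, UMI, barcode and clonal identifier live on a read pair.

    ``cell_id_spec`` is a list of ``(source, offset, length)`` pieces that are
    concatenated to form the cell ID. ``source`` is ``"read1"`` (slice of the
    read-1 sequence) or ``"name"`` (slice of the final colon-separated field
    of the read name, where split-pool PCR indexes are carried).
    """

    platform: str = "tenx"
    cell_id_spec: tuple[tuple[str, int, int], ...] = (("read1", 0, 16),)
    umi_offset: int = 16
    umi_len: int = 12
    anchor: str = ANCHOR
    empty_anchor: str = EMPTY_ANCHOR
    bc_len: int = 8
    uci_len: int = 6
    field_order_after_anchor: str = "bc_then_uci"

    def __post_init__(self) -> None:
        if len(self.anchor) != len(self.empty_anchor):
            raise ValueError("anchor and empty_anchor must have equal length")
        if hamming(self.anchor, self.empty_anchor) == 0:
            raise ValueError("anchor and empty_anchor must differ")
        if self.field_order_after_anchor not in ("bc_then_uci", "uci_then_bc"):
            raise ValueError(f"bad field order {self.field_order_after_anchor!r}")

    @property
    def read1_min_len(self) -> int:
        ends = [o + l for src, o, l in self.cell_id_spec if src == "read1"]
        ends.append(self.umi_offset + self.umi_len)
        return max(ends)

    @property
    def read2_min_len(self) -> int:
        return len(self.anchor) + self.bc_len + self.uci_len

    def cell_id(self, read1: str, name: str) -> str:
        parts = []
        for src, off, length in self.cell_id_spec:
            if src == "read1":
                parts.append(read1[off : off + length])
            elif src == "name":
                token = name.rsplit(":", 1)[-1].split()[0] if name else ""
                parts.append(token[off : off + length])
            else:  # pragma: no cover - guarded at construction
                raise ValueError(f"unknown cell-id source {src!r}")
        return "".join(parts)

    def umi(self, read1: str) -> str:
        return read1[self.umi_offset : self.umi_offset + self.umi_len]


@dataclass(frozen=True)
class AssignmentThresholds:
    """The three per-cell filters gating confident perturbation assignment.

    ``min_umi`` is a strict lower bound on supporting UMIs ("more than");
    ``min_fraction`` is a strict lower bound on the UCI-BC's share of the
    cell's UMIs; ``min_ratio`` is an inclusive lower bound on the ratio to
    the second most abundant UCI-BC. ``empty_min_umi`` is the strict bound
    on empty-cassette UMIs for labelling a cell as carrying no shRNA.
    """

    min_umi: int = 10
    min_fraction: float = 0.15
    min_ratio: float = 5.0
    empty_min_umi: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction < 1:
            raise ValueError("min_fraction must lie in (0, 1)")
        if self.min_ratio < 1:
            raise ValueError("min_ratio must be >= 1")
        if self.min_umi < 0 or self.empty_min_umi < 0:
            raise ValueError("UMI thresholds must be non-negative")


@dataclass(frozen=True)
class FilterSpec:
    """Expression-matrix and clone-level QC gates applied before statistics."""

    min_total_umi: int = 200  # strict: keep cells with MORE than this
    min_genes: int = 200  # strict
    max_pct_mito: float = 20.0  # strict: keep cells with LESS than this
    min_gene_total: int = 10  # inclusive: at least this many counts
    protein_coding_only: bool = True
    min_clone_cells: int = 20  # inclusive, per timepoint/condition grouping
    sci_min_umi: int = 500  # inclusive floor for split-pool data
    sci_doublet_sd: float = 2.0  # cells above mean + k*sd are doublets

    def __post_init__(self) -> None:
        for name in ("min_total_umi", "min_genes", "max_pct_mito", "min_gene_total",
                     "min_clone_cells", "sci_min_umi", "sci_doublet_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Preset:
    name: str
    layout: ReadLayout
    thresholds: AssignmentThresholds
    filters: FilterSpec


def _sci_layout() -> ReadLayout:
    # Split-pool oligo layout: read 1 = [8 N UMI][RT index]; the PCR (i5/i7)
    # indexes complete the cell ID and travel in the read name. The RT-index
    # length is not fixed by the chemistry description and stays overridable.
    return ReadLayout(
        platform="sci",
        cell_id_spec=(("read1", 8, 10), ("name", 0, 20)),
        umi_offset=0,
        umi_len=8,
    )


_PRESETS = {
    "tenx": Preset(
        "tenx",
        ReadLayout(platform="tenx"),
        AssignmentThresholds(min_umi=10, min_fraction=0.15, min_ratio=5.0, empty_min_umi=5),
        FilterSpec(max_pct_mito=20.0),
    ),
    "sci": Preset(
        "sci",
        _sci_layout(),
        AssignmentThresholds(min_umi=5, min_fraction=0.15, min_ratio=5.0, empty_min_umi=5),
        FilterSpec(max_pct_mito=30.0),
    ),
    # Joint RNA+ATAC nuclei are noisier; the relaxed gate asks for at least
    # 6 supporting UMIs (counts are integral, so ">5" == ">=6") and a
    # dominance ratio of 3.
    "multiome": Preset(
        "multiome",
        ReadLayout(platform="multiome"),
        AssignmentThresholds(min_umi=5, min_fraction=0.15, min_ratio=3.0, empty_min_umi=5),
        FilterSpec(max_pct_mito=20.0),
    ),
}


def get_preset(name: str) -> Preset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise DataError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


def load_config(path: str | Path) -> Preset:
    """Load a YAML config; a ``preset`` key seeds defaults, other keys override.

    Recognized sections: ``layout``, ``thresholds``, ``filters`` whose keys
    mirror the dataclass fields.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = get_preset(cfg.get("preset", "tenx"))
    layout, thresholds, filters = base.layout, base.thresholds, base.filters
    if "layout" in cfg:
        lay = dict(cfg["layout"])
        if "cell_id_spec" in lay:
            lay["cell_id_spec"] = tuple(tuple(p) for p in lay["cell_id_spec"])
        layout = replace(layout, **lay)
    if "thresholds" in cfg:
        thresholds = replace(thresholds, **cfg["thresholds"])
    if "filters" in cfg:
        filters = replace(filters, **cfg["filters"])
    return Preset(cfg.get("preset", base.name), layout, thresholds, filters)


# ---------------------------------------------------------------------------
# FASTQ streaming


def _open_text(path: str | Path) -> _stdio.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def stream_read_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read1_seq, read2_seq, pair_name)`` from two FASTQ files.

    Files may be gzipped. Record order must match; an unpaired trailing
    record raises a :class:`FormatError` naming the record index.
    """
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        idx = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            idx += 1
            if rec1 is None or rec2 is None:
                which = r2_path if rec2 is None else r1_path
                raise FormatError(
                    f"unpaired FASTQ records: {which} ends at record {idx}"
                )
            name1, seq1, _ = rec1
            _, seq2, _ = rec2
            yield seq1.upper(), seq2.upper(), name1


def write_fastq_record(fh, name: str, seq: str, qual: str | None = None) -> None:
    if qual is None:
        qual = "I" * len(seq)
    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Cell annotation tables

ANNOTATION_COLUMNS = [
    "cell_id",
    "total_umi",
    "n_genes",
    "pct_mito",
    "cluster",
    "condition",
    "timepoint",
    "clone_id",
    "shrna",
    "pseudotime",
    "batch",
]

_NUMERIC_ANN = {"total_umi": "Int64", "n_genes": "Int64", "pct_mito": float, "pseudotime": float}


def read_cell_annotation(path: str | Path) -> pd.DataFrame:
    """Read a per-cell annotation table.

    ``path`` may be a flat TSV (column ``cell_id`` required; known columns
    coerced, unknown columns preserved) or a directory holding a
    Matrix-Market triplet matrix (``matrix.mtx``) with sidecar
    ``barcodes.tsv`` / ``features.tsv``, in which case per-cell totals are
    computed from the matrix (genes as rows, cells as columns).
    """
    path = Path(path)
    if path.is_dir():
        df = _annotation_from_mtx(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "cell_id" not in df.columns:
            raise FormatError(f"annotation {path}: missing cell_id column")
        df = df.replace({"": np.nan})
        for col, dtype in _NUMERIC_ANN.items():
            if col in df.columns:
                df[col] = pd.to_numeric(df[col]).astype(dtype)
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise FormatError(f"annotation: cell listed twice ({dup})")
    return df.reset_index(drop=True)


def _annotation_from_mtx(mtx_dir: Path) -> pd.DataFrame:
    from scipy.io import mmread

    matrix_path = mtx_dir / "matrix.mtx"
    barcodes_path = mtx_dir / "barcodes.tsv"
    features_path = mtx_dir / "features.tsv"
    for p in (matrix_path, barcodes_path, features_path):
        if not p.exists():
            raise FormatError(f"matrix directory {mtx_dir}: missing {p.name}")
    mat = mmread(matrix_path).tocsc()  # genes x cells
    barcodes = [line.split("\t")[0].strip() for line in open(barcodes_path) if line.strip()]
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix directory {mtx_dir}: {mat.shape[1]} matrix columns vs "
            f"{len(barcodes)} barcodes"
        )
    totals = np.asarray(mat.sum(axis=0)).ravel()
    n_genes = np.asarray((mat > 0).sum(axis=0)).ravel()
    return pd.DataFrame(
        {
            "cell_id": barcodes,
            "total_umi": pd.array(totals.astype(int), dtype="Int64"),
            "n_genes": pd.array(n_genes.astype(int), dtype="Int64"),
        }
    )


def read_matrix(mtx_dir: str | Path):
    """Load a Matrix-Market expression matrix as (csr genes x cells, genes, cells)."""
    from scipy.io import mmread

    mtx_dir = Path(mtx_dir)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (mtx_dir / name).exists():
            raise FormatError(f"matrix directory {mtx_dir}: missing {name}")
    mat = mmread(mtx_dir / "matrix.mtx").tocsr()
    cells = [ln.split("\t")[0].strip() for ln in open(mtx_dir / "barcodes.tsv") if ln.strip()]
    genes = [ln.split("\t")[0].strip() for ln in open(mtx_dir / "features.tsv") if ln.strip()]
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix directory {mtx_dir}: shape {mat.shape} does not match "
            f"{len(genes)} features x {len(cells)} barcodes"
        )
    return mat, genes, cells


def write_annotation_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell table as TSV; missing values become empty strings."""
    df.to_csv(path, sep="\t", index=False, na_rep="")
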