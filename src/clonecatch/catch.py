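"""Per-cell perturbation and clone assignment from barcode-enrichment reads.

Each shRNA cassette emits a polyadenylated transcript whose 3' UTR carries
an 8-nt shRNA barcode (BC) and a random 6-nt unique clonal identifier
(UCI), directly downstream of a fixed 23-nt anchor from the repressor
transcript's 3' end. The enrichment library reads the cell ID and UMI from
read 1 and the anchor+BC+UCI from read 2. The pipeline:

1. reverse-complement read 2 and concatenate it to read 1;
2. keep reads whose read-2 prefix matches the anchor (the end of the
   concatenated read); an alternative anchor differing in its last two
   bases marks cassettes lacking an shRNA ("empty");
3. positionally slice cell ID, UMI, BC and UCI; discard invalid barcodes
   and cell IDs outside the expression-matrix whitelist;
4. collapse duplicates on (cell ID, UMI, UCI, BC) and resolve PCR chimeras
   (same cell+UMI, different UCI-BC) by keeping the most duplicated record;
5. count distinct UMIs per UCI-BC per cell and apply three filters
   (supporting UMIs, fraction of the cell's UMIs, ratio to the second most
   abundant UCI-BC) to call each cell's clone;
6. optionally annotate empty-cassette cells and repair barcode-swapped
   clones using the pool-QC pairing table.

A cell's clone identity is ``shrna + ":" + uci``. Cells where two UCI-BCs
pass the depth and fraction gates (genetic doublets) are labelled
``multiple`` and excluded from downstream statistics.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from ._dna import revcomp
from .io import AssignmentThresholds, DesignTable, ReadLayout, stream_read_pairs

ASSIGNMENT_COLUMNS = [
    "cell_id", "status", "shrna", "bc", "uci", "clone_id", "umis", "fraction", "ratio",
]


@dataclass(frozen=True)
class UciBcRecord:
    """One deduplicated barcode observation for a cell."""

    cell_id: str
    umi: str
    bc: str
    uci: str
    shrna: str | None  # resolved iff bc appears in the design table
    dup_count: int = 1


@dataclass(frozen=True)
class Rejected:
    """A read that dropped out of the pipeline, with the stage responsible."""

    reason: str  # no_anchor | short_read | invalid_bc


def concatenate_pair(read1: str, read2: str) -> str:
    """Reverse-complement read 2 and append it to read 1."""
    return read1 + revcomp(read2)


def match_anchor(read2_prefix: str, anchor: str, max_mismatch: int = 0) -> bool:
    """True iff the read-2 prefix matches the anchor within ``max_mismatch``.

    N bases never match. A prefix shorter than the anchor never matches.
    """
    if len(read2_prefix) < len(anchor):
        return False
    mism = 0
    for x, y in zip(read2_prefix, anchor):
        if x != y or x == "N":
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def slice_record(
    concatenated: str,
    layout: ReadLayout,
    r1_len: int,
    name: str = "",
    design: DesignTable | None = None,
    max_mismatch: int = 0,
) -> UciBcRecord | Rejected:
    """Slice one concatenated read pair into a :class:`UciBcRecord`.

    ``r1_len`` marks the boundary between the read-1 part and the
    reverse-complemented read-2 part. The anchor is checked at the start of
    read 2 (i.e., the end of the concatenated read); the BC and UCI are the
    bases immediately following it, in ``layout.field_order_after_anchor``.
    Returns ``Rejected`` with reason ``short_read``, ``no_anchor`` or
    ``invalid_bc`` when the read cannot be used.
    """
    read1 = concatenated[:r1_len]
    read2 = revcomp(concatenated[r1_len:])
    if r1_len < layout.read1_min_len or len(read2) < layout.read2_min_len:
        return Rejected("short_read")
    if not match_anchor(read2, layout.anchor, max_mismatch):
        return Rejected("no_anchor")
    a = len(layout.anchor)
    if layout.field_order_after_anchor == "bc_then_uci":
        bc = read2[a : a + layout.bc_len]
        uci = read2[a + layout.bc_len : a + layout.bc_len + layout.uci_len]
    else:
        uci = read2[a : a + layout.uci_len]
        bc = read2[a + layout.uci_len : a + layout.uci_len + layout.bc_len]
    shrna = None
    if design is not None:
        shrna = design.shrna_for_barcode(bc)
        if shrna is None:
            return Rejected("invalid_bc")
    return UciBcRecord(layout.cell_id(read1, name), layout.umi(read1), bc, uci, shrna)


def dedup_records(records: Iterable[UciBcRecord]) -> list[UciBcRecord]:
    """Collapse records sharing (cell ID, UMI, UCI, BC); dup counts sum."""
    counts: dict[tuple, UciBcRecord] = {}
    totals: Counter = Counter()
    for rec in records:
        key = (rec.cell_id, rec.umi, rec.uci, rec.bc)
        totals[key] += rec.dup_count
        counts.setdefault(key, rec)
    return [replace(rec, dup_count=totals[key]) for key, rec in counts.items()]


def resolve_umi_collisions(
    records: Iterable[UciBcRecord],
) -> tuple[list[UciBcRecord], list[UciBcRecord]]:
    """Resolve PCR chimeras: same cell+UMI, different UCI-BC.

    Within each (cell ID, UMI) group only the record with the strictly
    largest duplicate count survives; on a tie for the maximum all tied
    records are discarded (no evidence favours either molecule). Returns
    ``(kept, discarded)``.
    """
    groups: dict[tuple[str, str], list[UciBcRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.cell_id, rec.umi)].append(rec)
    kept: list[UciBcRecord] = []
    lost: list[UciBcRecord] = []
    for group in groups.values():
        if len(group) == 1:
            kept.append(group[0])
            continue
        best = max(r.dup_count for r in group)
        top = [r for r in group if r.dup_count == best]
        if len(top) == 1:
            kept.append(top[0])
            lost.extend(r for r in group if r is not top[0])
        else:
            lost.extend(group)
    return kept, lost


def count_umis_per_ucibc(
    records: Iterable[UciBcRecord],
) -> dict[str, dict[tuple[str, str], int]]:
    """Count distinct surviving UMIs per (BC, UCI) per cell.

    After deduplication and collision resolution each record carries a
    unique (cell, UMI), so the UMI count is the number of records.
    """
    counts: dict[str, dict[tuple[str, str], int]] = defaultdict(lambda: defaultdict(int))
    for rec in records:
        counts[rec.cell_id][(rec.bc, rec.uci)] += 1
    return {cell: dict(d) for cell, d in counts.items()}


def filter_uci_bcs(
    per_cell_counts: Mapping[str, Mapping[tuple[str, str], int]],
    thresholds: AssignmentThresholds,
    design: DesignTable | None = None,
) -> pd.DataFrame:
    """Call each cell's perturbation from its per-UCI-BC UMI counts.

    A UCI-BC is a *candidate* iff its UMIs exceed ``min_umi`` (strict) and
    its fraction of the cell's UMIs exceeds ``min_fraction`` (strict). A
    cell is ``assigned`` iff it has exactly one candidate whose ratio to
    the second most abundant UCI-BC in the cell is at least ``min_ratio``
    (infinite, hence passing, when the cell has a single UCI-BC);
    ``multiple`` iff two or more candidates pass the depth and fraction
    gates (genetic doublets); ``unassigned`` otherwise.
    """
    rows = []
    for cell_id in sorted(per_cell_counts):
        counts = per_cell_counts[cell_id]
        total = sum(counts.values())
        candidates = [
            k for k, n in counts.items()
            if n > thresholds.min_umi and n / total > thresholds.min_fraction
        ]
        status, best, umis, fraction, ratio = "unassigned", None, np.nan, np.nan, np.nan
        if len(candidates) >= 2:
            status = "multiple"
        elif len(candidates) == 1:
            best = candidates[0]
            umis = counts[best]
            fraction = umis / total
            second = max((n for k, n in counts.items() if k != best), default=0)
            ratio = math.inf if second == 0 else umis / second
            if ratio >= thresholds.min_ratio:
                status = "assigned"
            else:
                best = None
        if best is not None:
            bc, uci = best
            shrna = design.shrna_for_barcode(bc) if design is not None else None
            shrna = shrna or ""
            clone_id = f"{shrna}:{uci}" if shrna else f"{bc}:{uci}"
            rows.append((cell_id, status, shrna, bc, uci, clone_id, umis, fraction, ratio))
        else:
            rows.append((cell_id, status, "", "", "", "", np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def detect_empty(
    empty_umis_per_cell: Mapping[str, int],
    empty_min_umi: int,
    assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate empty-cassette cells (internal unperturbed controls).

    A cell becomes ``empty`` iff it has strictly more than ``empty_min_umi``
    empty-cassette UMIs and no UCI-BC passed the main depth/fraction gates
    (status ``unassigned``). Assigned and multiple cells are never
    overwritten; cells with only empty-cassette evidence are appended.
    """
    out = assignments.copy()
    known = set(out["cell_id"])
    eligible = set(out.loc[out["status"] == "unassigned", "cell_id"])
    new_rows = []
    for cell_id, n in sorted(empty_umis_per_cell.items()):
        if n <= empty_min_umi:
            continue
        if cell_id in eligible:
            out.loc[out["cell_id"] == cell_id, "status"] = "empty"
        elif cell_id not in known:
            new_rows.append(
                (cell_id, "empty", "", "", "", "", np.nan, np.nan, np.nan)
            )
    if new_rows:
        out = pd.concat(
            [out, pd.DataFrame(new_rows, columns=ASSIGNMENT_COLUMNS)], ignore_index=True
        )
        out = out.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    return out


def reassign_swaps(
    assignments: pd.DataFrame, pairing: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Relabel cells of barcode-swapped clones to the shRNA their UCI proves.

    ``pairing`` is a step1 pool-QC table. For every assigned cell whose
    UCI+BC key is flagged as a swap, the shRNA label is replaced by the
    pairing's dominant shRNA; the UCI part of the clone identity is
    untouched. Swap entries whose shRNA could not be resolved leave their
    cells alone, with a warning. Returns the updated table and the number
    of reassigned cells.
    """
    swaps = pairing.loc[pairing["is_swap"].astype(bool)]
    mapping: dict[str, str] = {}
    for row in swaps.itertuples(index=False):
        if row.assigned_shrna:
            mapping[row.uci_bc] = row.assigned_shrna
        else:
            warnings.warn(
                f"swap entry {row.uci_bc} has no resolved shRNA; cells left untouched",
                stacklevel=2,
            )
    if not mapping:
        return assignments.copy(), 0
    out = assignments.copy()
    keys = out["uci"].fillna("") + out["bc"].fillna("")
    hit = (out["status"] == "assigned") & keys.isin(mapping)
    for idx in out.index[hit]:
        new_shrna = mapping[keys[idx]]
        out.at[idx, "shrna"] = new_shrna
        out.at[idx, "clone_id"] = f"{new_shrna}:{out.at[idx, 'uci']}"
    return out, int(hit.sum())


def assign_cells(
    reads: Iterable[tuple[str, str, str]] | tuple[str | Path, str | Path],
    design: DesignTable,
    layout: ReadLayout,
    thresholds: AssignmentThresholds,
    whitelist: Iterable[str] | None = None,
    pairing: pd.DataFrame | None = None,
    max_mismatch: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Run the full assignment pipeline on a read-pair stream or FASTQ pair.

    ``reads`` is either an iterable of ``(read1, read2, name)`` or a
    ``(r1_path, r2_path)`` FASTQ pair. Returns the per-cell assignment
    table (sorted by cell ID) and a run report with per-stage read counts;
    every input read lands in exactly one report bin.
    """
    if (
        isinstance(reads, tuple)
        and len(reads) == 2
        and isinstance(reads[0], (str, Path))
    ):
        reads = stream_read_pairs(reads[0], reads[1])
    wl = set(whitelist) if whitelist is not None else None

    bins = Counter()
    main_records: list[UciBcRecord] = []
    empty_pairs: set[tuple[str, str]] = set()
    n_empty_reads = 0
    anchor_len = len(layout.anchor)
    for read1, read2, name in reads:
        bins["total"] += 1
        if len(read1) < layout.read1_min_len or len(read2) < layout.read2_min_len:
            bins["short_read"] += 1
            continue
        prefix = read2[:anchor_len]
        if match_anchor(prefix, layout.anchor, max_mismatch):
            rec = slice_record(
                concatenate_pair(read1, read2), layout, len(read1), name,
                design=design, max_mismatch=max_mismatch,
            )
            if isinstance(rec, Rejected):
                bins[rec.reason] += 1
                continue
            if wl is not None and rec.cell_id not in wl:
                bins["off_whitelist"] += 1
                continue
            main_records.append(rec)
        elif match_anchor(prefix, layout.empty_anchor, max_mismatch):
            cell_id = layout.cell_id(read1, name)
            umi = layout.umi(read1)
            if wl is not None and cell_id not in wl:
                bins["off_whitelist"] += 1
                continue
            bins["empty_read"] += 1
            n_empty_reads += 1
            empty_pairs.add((cell_id, umi))
        else:
            bins["no_anchor"] += 1

    deduped = dedup_records(main_records)
    bins["duplicate"] = len(main_records) - len(deduped)
    resolved, lost = resolve_umi_collisions(deduped)
    bins["collision_loss"] = sum(r.dup_count for r in lost)
    bins["kept"] = sum(r.dup_count for r in resolved)

    per_cell = count_umis_per_ucibc(resolved)
    assignments = filter_uci_bcs(per_cell, thresholds, design=design)

    empty_umis: Counter = Counter()
    for cell_id, _umi in empty_pairs:
        empty_umis[cell_id] += 1
    assignments = detect_empty(empty_umis, thresholds.empty_min_umi, assignments)

    n_reassigned = 0
    if pairing is not None:
        assignments, n_reassigned = reassign_swaps(assignments, pairing)

    assignments = assignments.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    status_counts = assignments["status"].value_counts().to_dict()
    report = {
        "reads": dict(bins),
        "records_after_dedup": len(deduped),
        "records_after_collision_resolution": len(resolved),
        "cells": {
            "total": len(assignments),
            "assigned": status_counts.get("assigned", 0),
            "multiple": status_counts.get("multiple", 0),
            "unassigned": status_counts.get("unassigned", 0),
            "empty": status_counts.get("empty", 0),
        },
        "reassigned_swap_cells": n_reassigned,
    }
    return assignments, report
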