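"""Quality control of barcoded plasmid pools and DNA-based clone tracking.

The pooled cloning of an inducible-shRNA library is checked by NGS twice:
after the first step (``step1_qc``), to verify that each clonal-identifier/
barcode key (UCI-BC) is paired with the shRNA its barcode encodes, and after
the second step (``step2_qc``), to measure the representation of each
retained plasmid. Sequencing libraries carry a 12-nt diversity index (DI)
from the low-cycle PCR, used here for partial deduplication: identical
(DI, payload) pairs are collapsed with their multiplicity retained.

``clone_drift`` turns per-sample UCI-BC counts from genomic DNA sequencing
into clone and phenotype percentages across passages, the readout used to
follow selective expansion or depletion of clones in culture.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import DataError, DesignTable


@dataclass(frozen=True)
class DedupRecord:
    di: str
    payload: str
    count: int


def dedup_by_diversity_index(
    records: Iterable[tuple[str, str]]
) -> list[DedupRecord]:
    """Collapse reads sharing the same (diversity index, payload) pair.

    Returns one record per distinct pair with the number of collapsed
    duplicates; the counts sum to the input size.
    """
    counts = Counter(records)
    return [DedupRecord(di, payload, n) for (di, payload), n in counts.items()]


def step1_qc(
    reads: Iterable[tuple[str, str, str]],
    design: DesignTable,
    min_count: int = 100,
    dominance: float = 10.0,
) -> pd.DataFrame:
    """Verify shRNA / UCI-BC pairing in first-step plasmid pools.

    ``reads`` are pre-sliced ``(diversity_index, shrna_seq, uci_bc)`` tuples.
    shRNA recognition is exact match of the hairpin-defining sequence against
    the design table's ``hairpin`` column; unmatched reads are tallied under
    the ``unmatched`` column but are not fatal.

    After DI-deduplication, UCI-BCs counted more than ``min_count`` times are
    retained. A UCI-BC is assigned to shRNA *s* iff *s* is observed at least
    ``dominance`` times more often than every other shRNA for that UCI-BC
    (ties at exactly the factor pass; a single observed shRNA trivially
    dominates); otherwise it is left unresolved. ``is_swap`` flags UCI-BCs
    whose dominant shRNA differs from the shRNA encoded by the embedded
    barcode, enabling later reassignment of the affected clones.

    Returns a frame indexed by ``uci_bc`` with columns ``count``,
    ``assigned_shrna`` (empty when unresolved), ``design_shrna``,
    ``is_swap``, ``unmatched`` and one count column per design shRNA.
    """
    hairpin_to_name = {
        e.hairpin: e.shrna for e in design.entries if e.hairpin is not None
    }
    if not hairpin_to_name:
        raise DataError("step1_qc: design table has no hairpin sequences")
    deduped = dedup_by_diversity_index(
        (di, shrna_seq + "\x00" + uci_bc) for di, shrna_seq, uci_bc in reads
    )
    per_key: dict[str, Counter] = defaultdict(Counter)
    unmatched: Counter = Counter()
    totals: Counter = Counter()
    for rec in deduped:
        shrna_seq, uci_bc = rec.payload.split("\x00")
        totals[uci_bc] += rec.count
        name = hairpin_to_name.get(shrna_seq)
        if name is None:
            unmatched[uci_bc] += rec.count
        else:
            per_key[uci_bc][name] += rec.count

    bc_len = design.bc_len
    rows = []
    shrna_names = [e.shrna for e in design.entries]
    for uci_bc, total in totals.items():
        if total <= min_count:
            continue
        counts = per_key.get(uci_bc, Counter())
        assigned = ""
        if counts:
            (best, best_n), = counts.most_common(1)
            if all(best_n >= dominance * n for s, n in counts.items() if s != best):
                assigned = best
        embedded_bc = uci_bc[-bc_len:]
        design_shrna = design.shrna_for_barcode(embedded_bc) or ""
        row = {
            "uci_bc": uci_bc,
            "count": total,
            "assigned_shrna": assigned,
            "design_shrna": design_shrna,
            "is_swap": bool(assigned) and bool(design_shrna) and assigned != design_shrna,
            "unmatched": unmatched.get(uci_bc, 0),
        }
        for s in shrna_names:
            row[s] = counts.get(s, 0)
        rows.append(row)
    columns = ["uci_bc", "count", "assigned_shrna", "design_shrna", "is_swap",
               "unmatched", *shrna_names]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("count", ascending=False).reset_index(drop=True)


def step2_qc(
    reads: Iterable[tuple[str, str]],
    design: DesignTable,
    min_count: int = 1000,
) -> pd.DataFrame:
    """Measure plasmid representation in the final pool.

    ``reads`` are ``(diversity_index, uci_bc)`` tuples. After DI
    deduplication, UCI-BCs counted at or below ``min_count`` are removed as
    NGS artifacts. Retained entries are aggregated per shRNA via barcode
    lookup; unknown barcodes are binned under shRNA ``"invalid"``.

    Returns a frame with columns ``uci_bc``, ``shrna``, ``count``,
    ``fraction`` (of the retained total).
    """
    deduped = dedup_by_diversity_index(reads)
    totals: Counter = Counter()
    for rec in deduped:
        totals[rec.payload] += rec.count
    retained = {k: n for k, n in totals.items() if n > min_count}
    if not retained:
        warnings.warn("step2_qc: no UCI-BC above the count threshold", stacklevel=2)
        return pd.DataFrame(columns=["uci_bc", "shrna", "count", "fraction"])
    grand = sum(retained.values())
    bc_len = design.bc_len
    rows = [
        {
            "uci_bc": k,
            "shrna": design.shrna_for_barcode(k[-bc_len:]) or "invalid",
            "count": n,
            "fraction": n / grand,
        }
        for k, n in retained.items()
    ]
    df = pd.DataFrame(rows).sort_values("count", ascending=False).reset_index(drop=True)
    return df


def shrna_distribution(pool: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a step2 pool table per shRNA (counts and fractions)."""
    if pool.empty:
        return pd.DataFrame(columns=["shrna", "count", "fraction"])
    agg = pool.groupby("shrna", as_index=False)["count"].sum()
    agg["fraction"] = agg["count"] / agg["count"].sum()
    return agg.sort_values("count", ascending=False).reset_index(drop=True)


def clone_drift(
    count_tables: Mapping[str, Mapping[str, int] | pd.DataFrame],
    phenotype_map: Mapping[str, str],
) -> pd.DataFrame:
    """Track clone and phenotype percentages across samples (e.g., passages).

    ``count_tables`` maps sample name to per-clone counts (a mapping or a
    step2-style frame with ``uci_bc``/``count`` columns). Only clones present
    in ``phenotype_map`` (previously annotated with a phenotype) are
    retained; per-sample percentages are computed over the retained clones
    and sum to 100. Clones absent from a sample are listed at 0%.

    Returns a long frame with columns ``sample``, ``clone_id``,
    ``phenotype``, ``count``, ``pct`` plus per-phenotype aggregate rows in a
    companion column ``level`` (``clone`` or ``phenotype``).
    """
    clones = sorted(phenotype_map)
    rows = []
    for sample, table in count_tables.items():
        if isinstance(table, pd.DataFrame):
            counts = dict(zip(table["uci_bc"], table["count"]))
        else:
            counts = dict(table)
        retained = {c: counts.get(c, 0) for c in clones}
        total = sum(retained.values())
        if total == 0:
            raise DataError(f"clone_drift: sample {sample!r} has no retained clones")
        for c in clones:
            rows.append(
                {
                    "level": "clone",
                    "sample": sample,
                    "clone_id": c,
                    "phenotype": phenotype_map[c],
                    "count": retained[c],
                    "pct": 100.0 * retained[c] / total,
                }
            )
        pheno_counts: Counter = Counter()
        for c in clones:
            pheno_counts[phenotype_map[c]] += retained[c]
        for p, n in sorted(pheno_counts.items()):
            rows.append(
                {
                    "level": "phenotype",
                    "sample": sample,
                    "clone_id": "",
                    "phenotype": p,
                    "count": n,
                    "pct": 100.0 * n / total,
                }
            )
    return pd.DataFrame(rows)
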