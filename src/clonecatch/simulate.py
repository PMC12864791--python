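"""Ground-truth simulator for every pipeline stage.

Two layers:

* **read-level** — a barcoded clone pool (shRNAs x random clonal
  identifiers) and the enrichment FASTQ pair it would produce, with
  substitution sequencing errors, template-switching barcode swaps,
  ambient molecules, empty-cassette cells and genetic doublets;
* **cell-level** — per-cell annotations (cluster label, condition,
  pseudotime, gene-module scores) with planted clone-by-cluster
  enrichments, pseudotime shifts and module-score shifts, against which
  the Fisher and KS frameworks can be calibrated.

Everything is deterministic under a seed. Defaults mirror the study
conditions of the platform the pipeline targets: 23 shRNAs in a pool,
~8% of cells carrying a cassette without an shRNA, and an overdispersed
(negative binomial) number of enrichment reads per cell around 20.
Quality strings are constant (the pipeline never reads base qualities).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._dna import hamming
from .io import DesignEntry, DesignTable, ReadLayout, write_fastq_record

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = rng.random(len(arr)) < error_rate
    if not hits.any():
        return seq
    for i in np.flatnonzero(hits):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Pool simulation


def simulate_pool(
    n_shrnas: int = 23,
    ucis_per_shrna: int = 3,
    seed: int = 0,
    bc_len: int = 8,
    uci_len: int = 6,
    min_bc_hamming: int = 2,
    n_controls: int = 2,
) -> tuple[DesignTable, list[tuple[str, str]]]:
    """Draw a barcoded shRNA library and its clone pool.

    Barcodes are unique random ``bc_len``-mers at pairwise Hamming distance
    of at least ``min_bc_hamming``; each shRNA also gets a random 21-nt
    hairpin-defining sequence (for pool QC) and ``ucis_per_shrna`` distinct
    clonal identifiers. The last ``n_controls`` shRNAs are flagged as
    controls (named ``SCR``/``B2M`` style). Returns the design table and
    the clone list as ``(shrna, uci)`` pairs.
    """
    rng = np.random.default_rng(seed)
    if n_shrnas > 4 ** bc_len / 4:
        raise ValueError("too many shRNAs for the barcode length")
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n_shrnas:
        attempts += 1
        if attempts > 10_000 * n_shrnas:
            raise ValueError("could not draw enough barcodes at the required distance")
        cand = _random_seq(rng, bc_len)
        if all(hamming(cand, b) >= min_bc_hamming for b in barcodes):
            barcodes.append(cand)
    hairpins: set[str] = set()
    entries = []
    control_names = ["SCR", "B2M"]
    for i, bc in enumerate(barcodes):
        while True:
            hp = _random_seq(rng, 21)
            if hp not in hairpins:
                hairpins.add(hp)
                break
        is_control = i >= n_shrnas - n_controls
        if is_control and (n_shrnas - 1 - i) < len(control_names):
            name = control_names[n_shrnas - 1 - i]
        else:
            name = f"sh{i + 1:02d}"
        gene = name if is_control else f"GENE{(i // 4) + 1}"
        entries.append(DesignEntry(name, gene, bc, is_control, hp))
    design = DesignTable(entries)
    clones: list[tuple[str, str]] = []
    for e in entries:
        seen: set[str] = set()
        while len(seen) < ucis_per_shrna:
            uci = _random_seq(rng, uci_len)
            if uci not in seen:
                seen.add(uci)
                clones.append((e.shrna, uci))
    return design, clones


# ---------------------------------------------------------------------------
# Read-level simulation


@dataclass
class SimTruth:
    """Ground truth for one simulated enrichment library."""

    design: DesignTable
    layout: ReadLayout
    cells: pd.DataFrame  # cell_id, shrna, uci, clone_id, is_empty, is_doublet, shrna2, uci2
    error_rate: float = 0.0
    swap_rate: float = 0.0
    ambient_rate: float = 0.0
    reads_per_cell_mean: float = 20.0
    reads_per_cell_disp: float = 10.0
    seed: int = 0


def make_truth(
    design: DesignTable,
    clones: Sequence[tuple[str, str]],
    cells_per_clone: int = 100,
    empty_fraction: float = 0.08,
    doublet_rate: float = 0.0,
    error_rate: float = 0.0,
    swap_rate: float = 0.0,
    ambient_rate: float = 0.0,
    reads_per_cell_mean: float = 20.0,
    reads_per_cell_disp: float = 10.0,
    layout: ReadLayout | None = None,
    seed: int = 0,
) -> SimTruth:
    """Assign simulated cells to clones, empties and doublets.

    ``empty_fraction`` is the share of *all* simulated cells whose cassette
    carries no shRNA; ``doublet_rate`` of the clone-bearing cells receive a
    second clone whose reads mix ~1:1 with the first.
    """
    rng = np.random.default_rng(seed)
    layout = layout or ReadLayout()
    cell_id_len = sum(l for src, _o, l in layout.cell_id_spec if src == "read1")
    n_single = len(clones) * cells_per_clone
    n_empty = int(round(empty_fraction / (1.0 - empty_fraction) * n_single))
    n_total = n_single + n_empty

    ids: set[str] = set()
    while len(ids) < n_total:
        ids.add(_random_seq(rng, cell_id_len))
    id_list = sorted(ids)
    rng.shuffle(id_list)

    rows = []
    k = 0
    for shrna, uci in clones:
        for _ in range(cells_per_clone):
            is_doublet = rng.random() < doublet_rate
            shrna2 = uci2 = ""
            if is_doublet and len(clones) > 1:
                while True:
                    j = rng.integers(len(clones))
                    if clones[j] != (shrna, uci):
                        shrna2, uci2 = clones[j]
                        break
            else:
                is_doublet = False
            rows.append((id_list[k], shrna, uci, f"{shrna}:{uci}", False,
                         is_doublet, shrna2, uci2))
            k += 1
    for _ in range(n_empty):
        rows.append((id_list[k], "", "", "", True, False, "", ""))
        k += 1
    cells = pd.DataFrame(
        rows,
        columns=["cell_id", "shrna", "uci", "clone_id", "is_empty", "is_doublet",
                 "shrna2", "uci2"],
    )
    return SimTruth(
        design, layout, cells, error_rate, swap_rate, ambient_rate,
        reads_per_cell_mean, reads_per_cell_disp, seed,
    )


def _build_read1(layout: ReadLayout, rng: np.random.Generator, cell_id: str, umi: str):
    length = layout.read1_min_len
    arr = list(_random_seq(rng, length))
    pos = 0
    for src, off, l in layout.cell_id_spec:
        if src == "read1":
            arr[off : off + l] = cell_id[pos : pos + l]
        pos += l
    arr[layout.umi_offset : layout.umi_offset + layout.umi_len] = umi
    return "".join(arr)


def simulate_fastq(
    truth: SimTruth,
    r1_path: str | Path | None = None,
    r2_path: str | Path | None = None,
    fixed_reads_per_cell: int | None = None,
) -> list[tuple[str, str, str]]:
    """Emit the enrichment read pairs implied by a :class:`SimTruth`.

    Read 1 is ``[cell ID | UMI]`` per the layout; read 2 is
    ``anchor + BC + UCI`` (or the empty-cassette anchor plus filler for
    empty cells), with iid substitution errors at ``error_rate``. A
    ``swap_rate`` fraction of non-empty reads carries another shRNA's
    barcode with the cell's own clonal identifier (template switching);
    an ``ambient_rate`` fraction carries a random other clone's full
    UCI-BC. Returns the pairs, and writes FASTQ (gzip if the path ends in
    .gz) when paths are given.
    """
    rng = np.random.default_rng(truth.seed + 1)
    layout = truth.layout
    clone_pool = truth.cells.loc[~truth.cells["is_empty"], ["shrna", "uci"]]
    clone_pool = list(clone_pool.drop_duplicates().itertuples(index=False, name=None))
    bc_of = {e.shrna: e.barcode for e in truth.design.entries}
    other_bcs = {
        s: [e.barcode for e in truth.design.entries if e.shrna != s]
        for s in bc_of
    }
    mean, disp = truth.reads_per_cell_mean, truth.reads_per_cell_disp
    pairs: list[tuple[str, str, str]] = []
    n = 0
    for cell in truth.cells.itertuples(index=False):
        if fixed_reads_per_cell is not None:
            n_reads = fixed_reads_per_cell
        else:
            n_reads = int(rng.negative_binomial(disp, disp / (disp + mean)))
        for _ in range(n_reads):
            n += 1
            umi = _random_seq(rng, layout.umi_len)
            read1 = _build_read1(layout, rng, cell.cell_id, umi)
            if cell.is_empty:
                read2 = layout.empty_anchor + _random_seq(
                    rng, layout.bc_len + layout.uci_len
                )
            else:
                shrna, uci = cell.shrna, cell.uci
                if cell.is_doublet and rng.random() < 0.5:
                    shrna, uci = cell.shrna2, cell.uci2
                if truth.ambient_rate > 0 and rng.random() < truth.ambient_rate:
                    shrna, uci = clone_pool[rng.integers(len(clone_pool))]
                bc = bc_of[shrna]
                if truth.swap_rate > 0 and rng.random() < truth.swap_rate:
                    bc = other_bcs[shrna][rng.integers(len(other_bcs[shrna]))]
                if layout.field_order_after_anchor == "bc_then_uci":
                    read2 = layout.anchor + bc + uci
                else:
                    read2 = layout.anchor + uci + bc
            read1 = _mutate(rng, read1, truth.error_rate)
            read2 = _mutate(rng, read2, truth.error_rate)
            pairs.append((read1, read2, f"sim:{n}"))
    if r1_path is not None and r2_path is not None:
        for path, which in ((r1_path, 0), (r2_path, 1)):
            path = Path(path)
            opener = gzip.open if path.suffix == ".gz" else open
            with opener(path, "wt") as fh:
                for pair in pairs:
                    write_fastq_record(fh, pair[2], pair[which])
    return pairs


# ---------------------------------------------------------------------------
# Cell-level simulation (annotation tables for the statistics frameworks)


@dataclass
class ClonePopulation:
    """One clone's cells in the annotation-level simulator.

    ``n_cells``, ``composition``, ``pseudotime_shift`` and
    ``module_shifts`` may each be a single value (shared by every
    condition) or a mapping keyed by condition label. ``composition`` is a
    probability vector over clusters.
    """

    clone_id: str
    shrna: str
    n_cells: int | Mapping[str, int] = 100
    composition: Sequence[float] | Mapping[str, Sequence[float]] | None = None
    pseudotime_shift: float | Mapping[str, float] = 0.0
    module_shifts: Mapping[str, float] | Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )

    def _per_condition(self, value, cond, default):
        if isinstance(value, Mapping):
            return value.get(cond, default)
        return value if value is not None else default


def simulate_cells(
    populations: Sequence[ClonePopulation],
    n_clusters: int = 4,
    conditions: Sequence[str] = ("control", "tet"),
    modules: Sequence[str] = (),
    clone_baseline_sd: float = 0.3,
    timepoint: str = "d12",
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-cell annotation table with planted effects.

    Cluster labels are multinomial per clone/condition composition
    (uniform unless planted); pseudotime is standard normal plus a
    clone-level baseline offset (shared across conditions, sd
    ``clone_baseline_sd``, modelling clonal variability that a paired
    design cancels) plus any planted per-condition shift; module scores
    are unit-variance Gaussian with clone baselines and planted mean
    shifts. Cell IDs are synthetic and unique.
    """
    rng = np.random.default_rng(seed)
    cluster_labels = [f"c{i}" for i in range(n_clusters)]
    rows = []
    counter = 0
    for pop in populations:
        baseline_pt = rng.normal(0.0, clone_baseline_sd)
        baseline_mod = {m: rng.normal(0.0, clone_baseline_sd) for m in modules}
        for cond in conditions:
            n = pop._per_condition(pop.n_cells, cond, 0)
            comp = pop._per_condition(pop.composition, cond, None)
            if comp is None:
                comp = np.full(n_clusters, 1.0 / n_clusters)
            comp = np.asarray(comp, dtype=float)
            if abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
                raise ValueError(f"composition for {pop.clone_id}/{cond} is not a distribution")
            pt_shift = pop._per_condition(pop.pseudotime_shift, cond, 0.0)
            mod_shifts = pop.module_shifts
            if mod_shifts and all(isinstance(v, Mapping) for v in mod_shifts.values()):
                mod_shifts = {m: mod_shifts.get(m, {}).get(cond, 0.0) for m in modules}
            clusters = rng.choice(cluster_labels, size=n, p=comp)
            pts = rng.normal(baseline_pt + pt_shift, 1.0, size=n)
            mods = {
                m: rng.normal(baseline_mod[m] + float(mod_shifts.get(m, 0.0)), 1.0, size=n)
                for m in modules
            }
            for i in range(n):
                counter += 1
                row = {
                    "cell_id": f"cell{counter:07d}",
                    "clone_id": pop.clone_id,
                    "shrna": pop.shrna,
                    "condition": cond,
                    "timepoint": timepoint,
                    "cluster": clusters[i],
                    "pseudotime": pts[i],
                }
                for m in modules:
                    row[f"module_{m}"] = mods[m][i]
                rows.append(row)
    return pd.DataFrame(rows)
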