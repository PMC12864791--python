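"""Clone- and treatment-aware Fisher framework.

Two families of tests, both built on the exact two-sided Fisher test with
Benjamini-Hochberg correction within each invocation:

* **enrichment/depletion** — per clone, does its fraction of
  shRNA-expressing cells change between a baseline and a target sample
  (e.g., a differentiation time point)? The 2x2 table crosses
  "clone of interest vs other clones" with "target vs baseline".
* **cell-type representation** — per cluster, does membership differ
  between a condition of interest and a control? The 2x2 table crosses
  "cluster of interest vs all other clusters" with
  "interest vs control". The control may be the same clones without
  induction (the paired, clone-aware design) or a designated control
  shRNA; ``benchmark_controls`` tallies how consistent each comparison is
  across control choices.

Numerosity filters are applied before the correction to avoid spending
the error budget on underpowered comparisons.
"""

from __future__ import annotations

import math
import warnings
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DataError


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Computed by exhaustive hypergeometric enumeration in exact integer
    arithmetic: with margins fixed, the p-value is the total probability of
    all tables at most as probable as the observed one. Probabilities share
    the denominator C(N, c1), so the comparison is exact on integer
    numerators and free of floating-point tie ambiguity. A zero margin
    leaves the test undefined; p = 1 is returned with a warning.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise DataError("fisher_exact_2x2: negative count")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        warnings.warn("fisher_exact_2x2: zero margin, p undefined (returning 1)", stacklevel=2)
        return 1.0
    obs = comb(r1, a) * comb(r2, c)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    num = 0
    for k in range(kmin, kmax + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            num += w
    return num / comb(r1 + r2, c1)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    ``adj_i = min_{j >= i} (m * p_(j) / j)`` over the sorted values, capped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DataError("bh_adjust: p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def clone_counts_from_annotation(
    table: pd.DataFrame, sample_col: str = "timepoint"
) -> pd.DataFrame:
    """Build a clone x sample cell-count table from a per-cell annotation.

    Only cells with a clone identity contribute (empty-cassette and
    unassigned/doublet cells carry none and are excluded, so fractions are
    over shRNA-expressing cells).
    """
    sub = table.dropna(subset=["clone_id"])
    sub = sub[sub["clone_id"] != ""]
    counts = sub.groupby(["clone_id", sample_col]).size().unstack(fill_value=0)
    counts.columns.name = None
    counts.index.name = "clone_id"
    return counts


def _fold_of_fractions(f_target: float, f_baseline: float) -> float:
    if f_baseline == 0:
        return math.nan if f_target == 0 else math.inf
    return f_target / f_baseline


def clone_enrichment(
    counts: pd.DataFrame,
    baseline_sample: str,
    target_sample: str,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-clone enrichment/depletion between two samples.

    ``counts`` is a clone x sample table of cell counts over
    shRNA-expressing cells. For each clone present in at least one of the
    two samples, a Fisher test is run on
    ``[[clone@target, others@target], [clone@baseline, others@baseline]]``;
    p-values are adjusted across the clones tested in this invocation.
    Fold change is the ratio of clone fractions (target / baseline); an
    absent-baseline clone reports ``inf``.
    """
    for s in (baseline_sample, target_sample):
        if s not in counts.columns:
            raise DataError(f"clone_enrichment: sample {s!r} not in count table")
    tgt = counts[target_sample]
    base = counts[baseline_sample]
    total_t, total_b = int(tgt.sum()), int(base.sum())
    rows = []
    for clone in counts.index:
        a, c = int(tgt[clone]), int(base[clone])
        if a == 0 and c == 0:
            continue
        b, d = total_t - a, total_b - c
        p = fisher_exact_2x2([[a, b], [c, d]])
        fold = _fold_of_fractions(
            a / total_t if total_t else 0.0, c / total_b if total_b else 0.0
        )
        rows.append((clone, a, c, total_t, total_b, fold, p))
    out = pd.DataFrame(
        rows,
        columns=["clone_id", "n_target", "n_baseline", "total_target",
                 "total_baseline", "fold_change", "p_raw"],
    )
    out["p_adj"] = bh_adjust(out["p_raw"]) if len(out) else []
    out["significant"] = out["p_adj"] <= cutoff
    return out


def cluster_representation(
    table: pd.DataFrame,
    unit: str,
    interest: str,
    control: str,
    mode: str = "condition",
    condition_col: str = "condition",
    min_unit_cells: int = 70,
    min_cluster_cells: int = 40,
    cutoff: float = 0.05,
    family: str = "joint",
) -> pd.DataFrame:
    """Per-(unit, cluster) Fisher tests of cluster membership.

    ``unit`` names the grouping column (``"shrna"``, ``"gene"`` or
    ``"clone_id"``). Two control designs are supported:

    * ``mode="condition"`` — paired, clone-aware: for each unit, cells at
      ``condition == interest`` are compared with the *same* unit's cells
      at ``condition == control`` (e.g., induced vs untreated).
    * ``mode="unit"`` — unmatched: each unit's cells are compared with the
      cells of a designated control unit (e.g., a scrambled shRNA).

    Units below ``min_unit_cells`` (in every time point, when a
    ``timepoint`` column exists) and clusters below ``min_cluster_cells``
    in both compared groups are excluded before testing. Adjustment is
    across all performed tests (``family="joint"``) or within each unit
    (``family="per_unit"``).
    """
    if unit not in table.columns:
        raise DataError(f"cluster_representation: missing unit column {unit!r}")
    if "cluster" not in table.columns:
        raise DataError("cluster_representation: missing cluster column")
    sub = table.dropna(subset=[unit, "cluster"]).copy()
    sub = sub[sub[unit] != ""]

    if mode == "condition":
        if condition_col not in sub.columns:
            raise DataError(f"cluster_representation: missing condition column {condition_col!r}")
        present = set(sub[condition_col].dropna())
        missing = {interest, control} - present
        if missing:
            raise DataError(f"cluster_representation: condition(s) {sorted(missing)} absent")
        sub = sub[sub[condition_col].isin([interest, control])]
        units = [u for u in sorted(sub[unit].unique())]
    elif mode == "unit":
        units = [u for u in sorted(sub[unit].unique()) if u != control]
        if control not in set(sub[unit]):
            raise DataError(f"cluster_representation: control unit {control!r} absent")
    else:
        raise DataError(f"cluster_representation: unknown mode {mode!r}")

    # numerosity filter on units: enough cells in at least one time point
    if "timepoint" in sub.columns and sub["timepoint"].notna().any():
        unit_max = sub.groupby([unit, "timepoint"]).size().groupby(level=0).max()
    else:
        unit_max = sub.groupby(unit).size()
    units = [u for u in units if unit_max.get(u, 0) >= min_unit_cells]

    clusters = sorted(sub["cluster"].unique())
    rows = []
    for u in units:
        if mode == "condition":
            grp_i = sub[(sub[unit] == u) & (sub[condition_col] == interest)]
            grp_c = sub[(sub[unit] == u) & (sub[condition_col] == control)]
        else:
            grp_i = sub[sub[unit] == u]
            grp_c = sub[sub[unit] == control]
        n_i, n_c = len(grp_i), len(grp_c)
        if n_i == 0 or n_c == 0:
            continue
        ci = grp_i["cluster"].value_counts()
        cc = grp_c["cluster"].value_counts()
        for cl in clusters:
            a = int(ci.get(cl, 0))
            c = int(cc.get(cl, 0))
            if max(a, c) < min_cluster_cells:
                continue
            b, d = n_i - a, n_c - c
            p = fisher_exact_2x2([[a, b], [c, d]])
            fold = _fold_of_fractions(a / n_i, c / n_c)
            rows.append((u, cl, a, b, c, d, fold, p))
    out = pd.DataFrame(
        rows, columns=[unit, "cluster", "a", "b", "c", "d", "fold_change", "p_raw"]
    )
    if len(out) == 0:
        out["p_adj"] = []
        out["significant"] = []
        return out
    if family == "joint":
        out["p_adj"] = bh_adjust(out["p_raw"])
    elif family == "per_unit":
        out["p_adj"] = np.nan
        for u in out[unit].unique():
            mask = out[unit] == u
            out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p_raw"])
    else:
        raise DataError(f"cluster_representation: unknown family {family!r}")
    out["significant"] = out["p_adj"] <= cutoff
    return out


def benchmark_controls(
    results_by_control: Mapping[str, pd.DataFrame],
    key_cols: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally, per comparison, in how many control settings it is significant.

    Each value of ``results_by_control`` is a representation-test frame
    with a ``significant`` column. Comparisons are matched on ``key_cols``
    (default: all columns up to and including ``cluster``). Keys absent
    from some settings are restricted to the intersection, with a warning.
    Returns ``(per_comparison, summary)`` where the summary counts
    comparisons significant in 0..k settings.
    """
    if not results_by_control:
        raise DataError("benchmark_controls: no result sets")
    frames = {}
    for name, df in results_by_control.items():
        cols = key_cols
        if cols is None:
            cols = list(df.columns[: list(df.columns).index("cluster") + 1])
        frames[name] = df.set_index(list(cols))["significant"]
    keysets = [set(s.index) for s in frames.values()]
    common = set.intersection(*keysets)
    if any(ks != common for ks in keysets):
        warnings.warn(
            "benchmark_controls: comparison keys differ across control settings; "
            "restricting to the intersection",
            stacklevel=2,
        )
    common_sorted = sorted(common)
    data = {name: s.loc[common_sorted].astype(bool).to_numpy() for name, s in frames.items()}
    per = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(common_sorted) if common_sorted
                       and isinstance(common_sorted[0], tuple) else common_sorted)
    per["n_significant_settings"] = per.sum(axis=1).astype(int)
    k = len(frames)
    summary = (
        per["n_significant_settings"].value_counts().reindex(range(k + 1), fill_value=0)
        .rename_axis("n_settings").rename("n_comparisons").reset_index()
    )
    return per.reset_index(), summary
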