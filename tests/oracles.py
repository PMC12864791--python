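"""Independent brute-force oracles used to validate the pipeline.

These re-derive each result from the rules with the most literal possible
bookkeeping (plain dicts, exhaustive enumeration, exact rational
arithmetic) and share no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from fractions import Fraction

import numpy as np
import pandas as pd

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_assign(
    pairs,
    design_map,  # barcode -> shrna
    anchor: str,
    empty_anchor: str,
    whitelist,
    cell_len: int = 16,
    umi_len: int = 12,
    bc_len: int = 8,
    uci_len: int = 6,
    min_umi: int = 10,
    min_fraction: float = 0.15,
    min_ratio: float = 5.0,
    empty_min_umi: int = 5,
) -> pd.DataFrame:
    """Literal re-implementation of the assignment rules on full tuples."""
    wl = set(whitelist) if whitelist is not None else None
    tuples = Counter()
    empty_umis = defaultdict(set)
    for r1, r2, _name in pairs:
        if len(r1) < cell_len + umi_len or len(r2) < len(anchor) + bc_len + uci_len:
            continue
        cell, umi = r1[:cell_len], r1[cell_len : cell_len + umi_len]
        head = r2[: len(anchor)]
        if head == anchor and "N" not in head:
            bc = r2[len(anchor) : len(anchor) + bc_len]
            uci = r2[len(anchor) + bc_len : len(anchor) + bc_len + uci_len]
            if bc not in design_map:
                continue
            if wl is not None and cell not in wl:
                continue
            tuples[(cell, umi, uci, bc)] += 1
        elif head == empty_anchor and "N" not in head:
            if wl is not None and cell not in wl:
                continue
            empty_umis[cell].add(umi)
    # collision resolution on (cell, umi)
    by_cell_umi = defaultdict(list)
    for (cell, umi, uci, bc), n in tuples.items():
        by_cell_umi[(cell, umi)].append(((bc, uci), n))
    surviving = defaultdict(Counter)
    for (cell, umi), lst in by_cell_umi.items():
        best = max(n for _k, n in lst)
        top = [k for k, n in lst if n == best]
        if len(top) == 1:
            surviving[cell][top[0]] += 1
    rows = []
    cells = set(surviving)
    for cell in cells:
        counts = surviving[cell]
        total = sum(counts.values())
        cands = [k for k, n in counts.items()
                 if n > min_umi and n / total > min_fraction]
        if len(cands) >= 2:
            rows.append((cell, "multiple", "", "", "", "",
                         math.nan, math.nan, math.nan))
        elif len(cands) == 1:
            k = cands[0]
            n = counts[k]
            others = [v for kk, v in counts.items() if kk != k]
            second = max(others) if others else 0
            ratio = math.inf if second == 0 else n / second
            if ratio >= min_ratio:
                bc, uci = k
                sh = design_map[bc]
                rows.append((cell, "assigned", sh, bc, uci, f"{sh}:{uci}",
                             float(n), n / total, ratio))
            else:
                rows.append((cell, "unassigned", "", "", "", "",
                             math.nan, math.nan, math.nan))
        else:
            rows.append((cell, "unassigned", "", "", "", "",
                         math.nan, math.nan, math.nan))
    # empty annotation
    status_by_cell = {r[0]: r for r in rows}
    for cell, umis in empty_umis.items():
        if len(umis) <= empty_min_umi:
            continue
        row = status_by_cell.get(cell)
        if row is None:
            status_by_cell[cell] = (cell, "empty", "", "", "", "",
                                    math.nan, math.nan, math.nan)
        elif row[1] == "unassigned":
            status_by_cell[cell] = (cell, "empty", *row[2:])
    out = pd.DataFrame(
        sorted(status_by_cell.values()),
        columns=["cell_id", "status", "shrna", "bc", "uci", "clone_id",
                 "umis", "fraction", "ratio"],
    )
    return out.reset_index(drop=True)


def fisher_exact_rational(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration in exact rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    f = math.factorial

    def pmf(k: int) -> Fraction:
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return Fraction(0)
        return Fraction(
            f(r1) * f(r2) * f(c1) * f(n - c1),
            f(k) * f(r1 - k) * f(c1 - k) * f(r2 - (c1 - k)) * f(n),
        )

    obs = pmf(a)
    total = Fraction(0)
    for k in range(0, c1 + 1):
        p = pmf(k)
        if p > 0 and p <= obs:
            total += p
    return total


def ks_permutation_p(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Exact two-sample KS p by enumerating all group assignments.

    Valid for tie-free pooled samples of small size. Returns (D, p) with
    p = fraction of assignments whose statistic is >= the observed one.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def stat(xs, ys):
        pts = np.sort(np.concatenate([xs, ys]))
        fx = np.searchsorted(np.sort(xs), pts, side="right") / len(xs)
        fy = np.searchsorted(np.sort(ys), pts, side="right") / len(ys)
        if alternative == "two_sided":
            return np.max(np.abs(fx - fy))
        if alternative == "greater":
            return np.max(fx - fy)
        return np.max(fy - fx)

    obs = stat(x, y)
    hits = 0
    combos = list(itertools.combinations(range(nx + ny), nx))
    for idx in combos:
        mask = np.zeros(nx + ny, dtype=bool)
        mask[list(idx)] = True
        if stat(pooled[mask], pooled[~mask]) >= obs - 1e-12:
            hits += 1
    return float(obs), hits / len(combos)
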