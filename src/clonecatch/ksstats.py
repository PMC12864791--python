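"""Signed Kolmogorov-Smirnov comparisons of continuous per-cell variables.

Pseudotime along a differentiation trajectory, or per-cell gene-module
scores, are compared between a condition of interest and a control with a
two-sided two-sample KS test, adjusted across the units tested. For
significant units, directionality comes from two one-sided KS tests (each
side adjusted across units). Sign convention: the statistic is reported
positive when the condition of interest has a significantly *higher*
cumulative distribution than the control (its values are lower), and
negative when its cumulative distribution is lower (its values, e.g.
pseudotime, are higher).

Gene-module machinery: per-cell module scores are the mean of
library-size-normalized, log-transformed counts over the module's genes;
module variability across perturbation targets is ranked by the maximum
absolute Z-score of target-vs-control differences.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats

from .io import DataError

# above this product of sample sizes the exact null distribution of D is
# replaced by the asymptotic approximation
EXACT_LIMIT = 10_000


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Two-sample KS test; returns ``(D, p)``.

    ``alternative="greater"`` tests whether x's empirical CDF lies above
    y's (x stochastically smaller), with statistic ``sup(F_x - F_y)``;
    ``"less"`` is the mirror. The p-value is exact when
    ``len(x) * len(y) <= 10_000`` and asymptotic otherwise. Ties are
    handled by evaluating the empirical CDFs at the data points (no
    jitter).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("ks_two_sample: empty sample")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(alternative)
    if alt is None:
        raise DataError(f"ks_two_sample: unknown alternative {alternative!r}")
    method = "exact" if x.size * y.size <= EXACT_LIMIT else "asymp"
    res = stats.ks_2samp(x, y, alternative=alt, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_distributions(
    table: pd.DataFrame,
    variable: str,
    unit: str,
    interest: str | None = None,
    control: str = "",
    mode: str = "unit",
    condition_col: str = "condition",
    min_cells: int = 20,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Signed KS comparison of ``variable`` per unit against a control.

    * ``mode="unit"``: each unit's cells vs the cells of the designated
      control unit (e.g., a scrambled-shRNA clone). When ``interest`` is
      given and a condition column exists, both groups are restricted to
      that condition first.
    * ``mode="condition"``: paired design — each unit's cells at
      ``condition == interest`` vs the same unit's cells at
      ``condition == control``.

    Units with fewer than ``min_cells`` cells in either group are skipped.
    Two-sided p-values are adjusted across units; both one-sided tests are
    run and adjusted the same way, and a direction (``higher_cdf`` /
    ``lower_cdf``) is reported only for units whose two-sided test is
    significant. ``signed_d`` is ``+D`` for ``higher_cdf`` (interest values
    lower) and ``-D`` for ``lower_cdf`` (interest values higher).
    """
    for col in (variable, unit):
        if col not in table.columns:
            raise DataError(f"compare_distributions: missing column {col!r}")
    sub = table.dropna(subset=[variable, unit]).copy()
    sub = sub[sub[unit] != ""]

    groups: list[tuple[str, np.ndarray, np.ndarray]] = []
    if mode == "unit":
        if interest is not None and condition_col in sub.columns:
            sub = sub[sub[condition_col] == interest]
        if control not in set(sub[unit]):
            raise DataError(f"compare_distributions: control unit {control!r} absent")
        y_all = sub.loc[sub[unit] == control, variable].to_numpy(float)
        for u in sorted(sub[unit].unique()):
            if u == control:
                continue
            groups.append((u, sub.loc[sub[unit] == u, variable].to_numpy(float), y_all))
    elif mode == "condition":
        if condition_col not in sub.columns:
            raise DataError(f"compare_distributions: missing column {condition_col!r}")
        for u in sorted(sub[unit].unique()):
            usub = sub[sub[unit] == u]
            x = usub.loc[usub[condition_col] == interest, variable].to_numpy(float)
            y = usub.loc[usub[condition_col] == control, variable].to_numpy(float)
            groups.append((u, x, y))
    else:
        raise DataError(f"compare_distributions: unknown mode {mode!r}")

    rows = []
    for u, x, y in groups:
        if len(x) < min_cells or len(y) < min_cells:
            continue
        d2, p2 = ks_two_sample(x, y, "two_sided")
        dg, pg = ks_two_sample(x, y, "greater")
        dl, pl = ks_two_sample(x, y, "less")
        rows.append((u, len(x), len(y), d2, p2, dg, pg, dl, pl))
    out = pd.DataFrame(
        rows,
        columns=["unit", "n_interest", "n_control", "d", "p_raw",
                 "d_greater", "p_greater_raw", "d_less", "p_less_raw"],
    )
    if len(out) == 0:
        for col in ("p_adj", "p_greater_adj", "p_less_adj", "signed_d"):
            out[col] = []
        out["direction"] = []
        out["significant"] = []
        return out
    from .fisher import bh_adjust

    out["p_adj"] = bh_adjust(out["p_raw"])
    out["p_greater_adj"] = bh_adjust(out["p_greater_raw"])
    out["p_less_adj"] = bh_adjust(out["p_less_raw"])
    out["significant"] = out["p_adj"] <= cutoff

    directions, signed = [], []
    for row in out.itertuples(index=False):
        direction, sd = "none", 0.0
        if row.p_adj <= cutoff:
            g_sig = row.p_greater_adj <= cutoff
            l_sig = row.p_less_adj <= cutoff
            if g_sig and (not l_sig or row.p_greater_adj <= row.p_less_adj):
                direction, sd = "higher_cdf", row.d
            elif l_sig:
                direction, sd = "lower_cdf", -row.d
        directions.append(direction)
        signed.append(sd)
    out["direction"] = directions
    out["signed_d"] = signed
    cols = ["unit", "n_interest", "n_control", "d", "p_raw", "p_adj", "direction",
            "signed_d", "p_greater_adj", "p_less_adj", "significant"]
    return out[cols]


# ---------------------------------------------------------------------------
# Gene modules


def aggregate_module_expression(
    matrix,
    genes: Sequence[str],
    module_membership: Mapping[str, str],
    normalize: bool = True,
    agg: str = "mean",
    transform: str = "log1p",
    scale: float = 1e4,
) -> pd.DataFrame:
    """Per-cell aggregated expression score for each gene module.

    ``matrix`` is genes x cells (sparse or dense), ``genes`` the row names.
    The default score is the mean over the module's genes of
    ``log1p(counts-per-10k)``, which is invariant to a cell's library size.
    Genes listed in ``module_membership`` but absent from the matrix are
    dropped with a warning; a module with no present gene yields NaN.
    Cells with zero total counts score 0.
    """
    if agg not in ("mean", "median"):
        raise DataError(f"aggregate_module_expression: unknown agg {agg!r}")
    if transform not in ("log1p", "linear"):
        raise DataError(f"aggregate_module_expression: unknown transform {transform!r}")
    gene_index = {g: i for i, g in enumerate(genes)}
    missing = [g for g in module_membership if g not in gene_index]
    if missing:
        warnings.warn(
            f"{len(missing)} module gene(s) absent from the matrix, dropped", stacklevel=2
        )
    mat = matrix.tocsr() if sparse.issparse(matrix) else np.asarray(matrix, dtype=float)
    n_cells = mat.shape[1]
    if normalize:
        totals = np.asarray(mat.sum(axis=0)).ravel().astype(float)
        totals[totals == 0] = 1.0  # all-zero cells keep a score of 0
    modules = sorted(set(module_membership.values()))
    scores = {}
    for module in modules:
        idx = [gene_index[g] for g, m in module_membership.items()
               if m == module and g in gene_index]
        if not idx:
            scores[module] = np.full(n_cells, np.nan)
            continue
        block = mat[idx]
        block = np.asarray(block.todense()) if sparse.issparse(block) else np.asarray(block, float)
        if normalize:
            block = block / totals * scale
        if transform == "log1p":
            block = np.log1p(block)
        scores[module] = block.mean(axis=0) if agg == "mean" else np.median(block, axis=0)
    return pd.DataFrame(scores)


def module_score_table(
    scores: pd.DataFrame,
    units: Sequence[str],
    control: str = "",
    condition: Sequence[str] | None = None,
    interest_label: str = "tet",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-(module, unit) aggregated scores, deltas vs control, and Z-scores.

    ``scores`` is cells x modules; ``units`` assigns each cell to a
    perturbation target. Without ``condition``, a unit's delta is its mean
    score minus the control unit's mean (unmatched design). With
    ``condition``, the delta is the unit's mean under ``interest_label``
    minus its own mean under ``control_label`` (paired design). Deltas are
    Z-scored across units within each module; ``max_abs_z`` summarizes a
    module's variability across the experiment.
    """
    units = pd.Series(list(units), index=scores.index, name="unit")
    rows = []
    if condition is None:
        if control not in set(units):
            raise DataError(f"module_score_table: control unit {control!r} absent")
        ctrl_means = scores[units == control].mean(axis=0)
        for u in sorted(set(units) - {control}):
            m = scores[units == u].mean(axis=0)
            for module in scores.columns:
                rows.append((module, u, m[module], ctrl_means[module],
                             m[module] - ctrl_means[module]))
    else:
        condition = pd.Series(list(condition), index=scores.index)
        for u in sorted(set(units)):
            sel = units == u
            mi = scores[sel & (condition == interest_label)].mean(axis=0)
            mc = scores[sel & (condition == control_label)].mean(axis=0)
            for module in scores.columns:
                rows.append((module, u, mi[module], mc[module], mi[module] - mc[module]))
    out = pd.DataFrame(
        rows, columns=["module", "unit", "score_interest", "score_control", "delta"]
    )
    if out["unit"].nunique() < 2:
        raise DataError("module_score_table: Z-scoring needs at least two units")
    zs = []
    for module, grp in out.groupby("module"):
        d = grp["delta"].to_numpy(float)
        sd = d.std()
        if sd == 0 or np.isnan(sd):
            zs.append(pd.Series(np.nan, index=grp.index))
        else:
            zs.append(pd.Series((d - d.mean()) / sd, index=grp.index))
    out["z"] = pd.concat(zs).sort_index()
    return out


def rank_modules(score_table: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Rank modules by variability (max |Z| across units), descending.

    Ties break on the module label (stable). Modules whose Z-scores are
    undefined (zero variance across units) rank last, with a warning.
    Returns the top ``top_n`` rows with columns ``module``, ``max_abs_z``.
    """
    agg = (
        score_table.assign(abs_z=score_table["z"].abs())
        .groupby("module")["abs_z"].max()
        .rename("max_abs_z").reset_index()
    )
    if agg["max_abs_z"].isna().any():
        warnings.warn("some modules have undefined Z (no variance); ranked last", stacklevel=2)
    agg = agg.sort_values(
        ["max_abs_z", "module"], ascending=[False, True], na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return agg.head(top_n)
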