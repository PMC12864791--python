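import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonecatch.fisher import (
    benchmark_controls,
    bh_adjust,
    clone_counts_from_annotation,
    clone_enrichment,
    cluster_representation,
    fisher_exact_2x2,
)
from clonecatch.io import DataError

from oracles import fisher_exact_rational


class TestFisherExact:
    def test_matches_exact_rational_enumeration(self):
        assert fisher_exact_2x2([[1, 9], [11, 3]]) == pytest.approx(
            float(fisher_exact_rational(1, 9, 11, 3)), abs=1e-14)
        assert fisher_exact_2x2([[1, 9], [11, 3]]) == pytest.approx(2.76e-3, rel=5e-3)

    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_extreme_table(self):
        expect = float(fisher_exact_rational(0, 10, 10, 0))
        assert fisher_exact_2x2([[0, 10], [10, 0]]) == pytest.approx(expect, abs=1e-15)

    def test_cross_check_against_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            a, b, c, d = (int(v) for v in rng.integers(0, 40, size=4))
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            ours = fisher_exact_2x2([[a, b], [c, d]])
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_row_and_column_swap_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 25, size=4))
            p = fisher_exact_2x2([[a, b], [c, d]])
            assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p, abs=1e-14)
            assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p, abs=1e-14)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.random(50)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_sorted_adjusted_non_decreasing_and_geq_raw(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()

    def test_invalid_p_raises(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.2])


class TestCloneEnrichment:
    def _counts(self, data):
        return pd.DataFrame(data).set_index("clone_id")

    def test_fold_and_p_from_hand_table(self):
        counts = self._counts({
            "clone_id": ["x", "rest"],
            "d0": [10, 90],
            "d23": [30, 70],
        })
        out = clone_enrichment(counts, "d0", "d23")
        row = out.set_index("clone_id").loc["x"]
        assert row["fold_change"] == pytest.approx(3.0)
        expect = float(fisher_exact_rational(30, 70, 10, 90))
        assert row["p_raw"] == pytest.approx(expect, abs=1e-12)

    def test_identical_samples_null(self):
        counts = self._counts({"clone_id": ["a", "b", "c"],
                               "d0": [10, 20, 30], "d23": [10, 20, 30]})
        out = clone_enrichment(counts, "d0", "d23")
        assert (out["fold_change"] == 1.0).all()
        assert (out["p_raw"] == 1.0).all()
        assert not out["significant"].any()

    def test_absent_clone_skipped_and_new_clone_inf_fold(self):
        counts = self._counts({"clone_id": ["gone", "new", "base"],
                               "d0": [0, 0, 50], "d23": [0, 20, 40]})
        out = clone_enrichment(counts, "d0", "d23")
        assert "gone" not in set(out["clone_id"])
        assert math.isinf(out.set_index("clone_id").loc["new", "fold_change"])

    def test_counts_from_annotation_excludes_cells_without_clone(self):
        table = pd.DataFrame({
            "cell_id": list("abcdef"),
            "clone_id": ["c1", "c1", "c2", None, "", "c2"],
            "timepoint": ["d0", "d23", "d0", "d0", "d23", "d0"],
        })
        counts = clone_counts_from_annotation(table)
        assert counts.loc["c1", "d0"] == 1
        assert counts.loc["c2", "d0"] == 2
        assert counts.to_numpy().sum() == 4


def _representation_table(rng, n_per_group=300, shift_shrna=None, factor=3.0,
                          n_clusters=3, shrnas=("sh1", "sh2", "SCR")):
    rows = []
    base = np.full(n_clusters, 1.0 / n_clusters)
    for sh in shrnas:
        for cond in ("control", "tet"):
            comp = base.copy()
            if sh == shift_shrna and cond == "tet":
                comp[0] *= factor
                comp /= comp.sum()
            labels = rng.choice([f"c{i}" for i in range(n_clusters)],
                                size=n_per_group, p=comp)
            rows += [(f"{sh}_{cond}_{i}", sh, cond, lab)
                     for i, lab in enumerate(labels)]
    return pd.DataFrame(rows, columns=["cell_id", "shrna", "condition", "cluster"])


class TestClusterRepresentation:
    def test_planted_shift_detected_in_paired_mode(self):
        rng = np.random.default_rng(0)
        table = _representation_table(rng, shift_shrna="sh1")
        out = cluster_representation(table, "shrna", "tet", "control")
        hit = out[(out["shrna"] == "sh1") & (out["cluster"] == "c0")]
        assert hit["significant"].all()
        assert hit["fold_change"].iloc[0] > 2.0

    def test_numerosity_filters_exclude_small_units_and_clusters(self):
        rng = np.random.default_rng(1)
        table = _representation_table(rng, n_per_group=100)
        small = pd.DataFrame(
            [(f"tiny{i}", "tiny", "tet" if i % 2 else "control", "c0")
             for i in range(69)],
            columns=["cell_id", "shrna", "condition", "cluster"])
        out = cluster_representation(pd.concat([table, small]), "shrna",
                                     "tet", "control", min_cluster_cells=40)
        assert "tiny" not in set(out["shrna"])
        rare = cluster_representation(table, "shrna", "tet", "control",
                                      min_cluster_cells=10_000)
        assert rare.empty

    def test_unit_mode_uses_control_shrna(self):
        rng = np.random.default_rng(2)
        table = _representation_table(rng, shift_shrna="sh1")
        sub = table[table["condition"] == "tet"]
        out = cluster_representation(sub, "shrna", "tet", "SCR", mode="unit")
        assert "SCR" not in set(out["shrna"])
        hit = out[(out["shrna"] == "sh1") & (out["cluster"] == "c0")]
        assert hit["significant"].all()

    def test_missing_condition_errors(self):
        table = _representation_table(np.random.default_rng(3))
        with pytest.raises(DataError, match="absent"):
            cluster_representation(table, "shrna", "tet", "nope")


class TestBenchmarkControls:
    def _result(self, sig_pairs):
        rows = [("sh1", "c0"), ("sh1", "c1"), ("sh2", "c0")]
        return pd.DataFrame(
            [{"shrna": u, "cluster": c, "significant": (u, c) in sig_pairs}
             for u, c in rows])

    def test_identical_sets_count_k(self):
        res = self._result({("sh1", "c0")})
        per, summary = benchmark_controls({"a": res, "b": res, "c": res})
        assert per.loc[per["n_significant_settings"] == 3].shape[0] == 1
        assert summary.set_index("n_settings").loc[3, "n_comparisons"] == 1

    def test_one_empty_setting_caps_counts(self):
        per, _ = benchmark_controls({
            "a": self._result({("sh1", "c0"), ("sh2", "c0")}),
            "b": self._result(set()),
        })
        assert per["n_significant_settings"].max() <= 1

    def test_mismatched_keys_restrict_with_warning(self):
        full = self._result({("sh1", "c0")})
        partial = full.iloc[:2].copy()
        with pytest.warns(UserWarning, match="intersection"):
            per, _ = benchmark_controls({"a": full, "b": partial})
        assert len(per) == 2
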