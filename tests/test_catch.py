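import math

import numpy as np
import pandas as pd
import pytest

from clonecatch.catch import (
    Rejected,
    UciBcRecord,
    assign_cells,
    concatenate_pair,
    count_umis_per_ucibc,
    dedup_records,
    detect_empty,
    filter_uci_bcs,
    match_anchor,
    reassign_swaps,
    resolve_umi_collisions,
    slice_record,
)
from clonecatch.io import ANCHOR, EMPTY_ANCHOR, AssignmentThresholds

from conftest import make_read_pair


class TestConcatenatePair:
    @pytest.mark.parametrize("r1, r2, expect", [
        ("ACGT", "AAAA", "ACGTTTTT"),
        ("ACGT", "AANA", "ACGTTNTT"),
        ("ACGT", "", "ACGT"),
    ])
    def test_reverse_complement_concatenation(self, r1, r2, expect):
        assert concatenate_pair(r1, r2) == expect


class TestMatchAnchor:
    def test_exact_anchor_matches(self):
        assert match_anchor(ANCHOR, ANCHOR, 0)

    def test_empty_cassette_anchor_needs_two_mismatches(self):
        # the two anchors differ only in their final two bases
        assert not match_anchor(EMPTY_ANCHOR, ANCHOR, 0)
        assert not match_anchor(EMPTY_ANCHOR, ANCHOR, 1)
        assert match_anchor(EMPTY_ANCHOR, ANCHOR, 2)

    def test_single_substitution_tolerated_at_one(self):
        mutated = "T" + ANCHOR[1:]
        assert not match_anchor(mutated, ANCHOR, 0)
        assert match_anchor(mutated, ANCHOR, 1)

    def test_n_never_matches(self):
        assert not match_anchor("N" + ANCHOR[1:], ANCHOR, 0)

    def test_short_prefix_never_matches(self):
        assert not match_anchor(ANCHOR[:-1], ANCHOR, 5)


class TestSliceRecord:
    def test_round_trip_of_planted_fields(self, tenx_layout, small_design):
        cell, umi, bc, uci = "G" * 16, "T" * 12, "AAAACCCC", "ACGTAC"
        r1, r2, name = make_read_pair(tenx_layout, cell, umi, bc, uci)
        rec = slice_record(concatenate_pair(r1, r2), tenx_layout, len(r1), name,
                           design=small_design)
        assert rec == UciBcRecord(cell, umi, bc, uci, "shA")

    def test_invalid_barcode_rejected(self, tenx_layout, small_design):
        r1, r2, name = make_read_pair(tenx_layout, "G" * 16, "T" * 12,
                                      "CCCCCCCC", "ACGTAC")
        rec = slice_record(concatenate_pair(r1, r2), tenx_layout, len(r1), name,
                           design=small_design)
        assert rec == Rejected("invalid_bc")

    def test_short_read_rejected(self, tenx_layout):
        rec = slice_record("ACGT", tenx_layout, 2)
        assert rec == Rejected("short_read")

    def test_uci_then_bc_order(self, tenx_layout, small_design):
        from dataclasses import replace
        layout = replace(tenx_layout, field_order_after_anchor="uci_then_bc")
        r1, r2, name = make_read_pair(layout, "G" * 16, "T" * 12, "AAAACCCC", "ACGTAC")
        rec = slice_record(concatenate_pair(r1, r2), layout, len(r1), name,
                           design=small_design)
        assert (rec.bc, rec.uci) == ("AAAACCCC", "ACGTAC")


class TestDedupRecords:
    def _rec(self, cell="c", umi="u", bc="b", uci="x", n=1):
        return UciBcRecord(cell, umi, bc, uci, None, n)

    def test_identical_quadruples_collapse(self):
        out = dedup_records([self._rec()] * 4)
        assert len(out) == 1 and out[0].dup_count == 4

    def test_distinct_uci_kept(self):
        out = dedup_records([self._rec(uci="x"), self._rec(uci="y")])
        assert len(out) == 2

    def test_conservation_of_read_counts(self):
        recs = [self._rec(umi=f"u{i % 3}") for i in range(10)]
        out = dedup_records(recs)
        assert sum(r.dup_count for r in out) == 10


class TestResolveUmiCollisions:
    def _rec(self, key, n):
        return UciBcRecord("c", "u", key, "x", None, n)

    def test_more_duplicated_record_wins(self):
        kept, lost = resolve_umi_collisions([self._rec("X", 7), self._rec("Y", 2)])
        assert [r.bc for r in kept] == ["X"]
        assert [r.bc for r in lost] == ["Y"]

    def test_single_record_untouched(self):
        kept, lost = resolve_umi_collisions([self._rec("X", 3)])
        assert len(kept) == 1 and not lost

    def test_tie_discards_all(self):
        kept, lost = resolve_umi_collisions([self._rec("X", 3), self._rec("Y", 3)])
        assert kept == [] and len(lost) == 2


class TestFilterUciBcs:
    TENX = AssignmentThresholds(min_umi=10, min_fraction=0.15, min_ratio=5.0)

    def _assign(self, counts):
        return filter_uci_bcs({"cell": {(k, "ACGTAC"): v for k, v in counts.items()}},
                              self.TENX)

    def test_clear_winner_assigned(self):
        out = self._assign({"AAAACCCC": 12, "GGGGTTTT": 1})
        row = out.iloc[0]
        assert row["status"] == "assigned"
        assert row["umis"] == 12
        assert row["fraction"] == pytest.approx(12 / 13)
        assert row["ratio"] == 12.0

    def test_insufficient_ratio_unassigned(self):
        out = self._assign({"AAAACCCC": 12, "GGGGTTTT": 4})
        assert out.iloc[0]["status"] == "unassigned"

    def test_exactly_min_umi_fails_strict_bound(self):
        out = self._assign({"AAAACCCC": 10})
        assert out.iloc[0]["status"] == "unassigned"

    def test_single_ucibc_has_infinite_ratio(self):
        out = self._assign({"AAAACCCC": 11})
        row = out.iloc[0]
        assert row["status"] == "assigned"
        assert math.isinf(row["ratio"])

    def test_two_candidates_is_multiple(self):
        out = self._assign({"AAAACCCC": 20, "GGGGTTTT": 18})
        assert out.iloc[0]["status"] == "multiple"


class TestDetectEmpty:
    def _base(self, status="unassigned"):
        return pd.DataFrame(
            [("cell", status, "", "", "", "", np.nan, np.nan, np.nan)],
            columns=["cell_id", "status", "shrna", "bc", "uci", "clone_id",
                     "umis", "fraction", "ratio"],
        )

    def test_above_threshold_becomes_empty(self):
        out = detect_empty({"cell": 8}, 5, self._base())
        assert out.iloc[0]["status"] == "empty"

    def test_boundary_count_stays_unassigned(self):
        out = detect_empty({"cell": 5}, 5, self._base())
        assert out.iloc[0]["status"] == "unassigned"

    def test_assigned_cell_never_overwritten(self):
        out = detect_empty({"cell": 100}, 5, self._base(status="assigned"))
        assert out.iloc[0]["status"] == "assigned"

    def test_unknown_cell_appended(self):
        out = detect_empty({"other": 9}, 5, self._base())
        assert set(out["cell_id"]) == {"cell", "other"}
        assert out.set_index("cell_id").loc["other", "status"] == "empty"


class TestReassignSwaps:
    def _assignments(self):
        return pd.DataFrame(
            [
                ("c1", "assigned", "shA", "AAAACCCC", "ACGTAC", "shA:ACGTAC", 12.0, 0.9, 12.0),
                ("c2", "assigned", "shB", "GGGGTTTT", "TTTTTT", "shB:TTTTTT", 15.0, 1.0, math.inf),
            ],
            columns=["cell_id", "status", "shrna", "bc", "uci", "clone_id",
                     "umis", "fraction", "ratio"],
        )

    def _pairing(self, assigned="shC", is_swap=True):
        return pd.DataFrame(
            [{"uci_bc": "ACGTAC" + "AAAACCCC", "count": 500,
              "assigned_shrna": assigned, "design_shrna": "shA", "is_swap": is_swap}]
        )

    def test_swapped_clone_relabelled(self):
        out, n = reassign_swaps(self._assignments(), self._pairing())
        assert n == 1
        assert out.iloc[0]["shrna"] == "shC"
        assert out.iloc[0]["clone_id"] == "shC:ACGTAC"
        assert out.iloc[0]["uci"] == "ACGTAC"  # UCI part untouched
        assert out.iloc[1]["shrna"] == "shB"

    def test_no_swaps_is_identity(self):
        out, n = reassign_swaps(self._assignments(), self._pairing(is_swap=False))
        assert n == 0
        pd.testing.assert_frame_equal(out, self._assignments())

    def test_unresolved_swap_warns_and_skips(self):
        with pytest.warns(UserWarning, match="no resolved shRNA"):
            out, n = reassign_swaps(self._assignments(), self._pairing(assigned=""))
        assert n == 0


class TestAssignCellsPipeline:
    def _noiseless_pairs(self, layout, design, n_cells=30, reads_per_cell=15):
        from clonecatch.simulate import make_truth, simulate_fastq, simulate_pool

        d, clones = simulate_pool(4, 2, seed=3)
        truth = make_truth(d, clones, cells_per_clone=n_cells // len(clones) + 1,
                           empty_fraction=0.1, layout=layout, seed=3)
        return d, truth, simulate_fastq(truth, fixed_reads_per_cell=reads_per_cell)

    def test_noiseless_recovery_and_conservation(self, tenx_layout, tenx_thresholds):
        design, truth, pairs = self._noiseless_pairs(tenx_layout, None)
        table, report = assign_cells(pairs, design, tenx_layout, tenx_thresholds,
                                     whitelist=truth.cells["cell_id"])
        merged = table.merge(truth.cells, on="cell_id", suffixes=("", "_true"))
        assigned = merged[merged["status"] == "assigned"]
        assert (assigned["clone_id"] == assigned["clone_id_true"]).all()
        empties = merged[merged["status"] == "empty"]
        assert set(empties["cell_id"]) == set(
            truth.cells.loc[truth.cells["is_empty"], "cell_id"])
        bins = report["reads"]
        read_bins = sum(v for k, v in bins.items() if k != "total")
        assert read_bins == bins["total"]

    def test_permutation_invariance(self, tenx_layout, tenx_thresholds):
        design, truth, pairs = self._noiseless_pairs(tenx_layout, None)
        rng = np.random.default_rng(0)
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        t1, _ = assign_cells(pairs, design, tenx_layout, tenx_thresholds)
        t2, _ = assign_cells(shuffled, design, tenx_layout, tenx_thresholds)
        pd.testing.assert_frame_equal(t1, t2)

    def test_tightening_thresholds_is_monotone(self, tenx_layout):
        design, truth, pairs = self._noiseless_pairs(tenx_layout, None,
                                                     reads_per_cell=12)
        loose = AssignmentThresholds(min_umi=5, min_fraction=0.15, min_ratio=2.0)
        tight = AssignmentThresholds(min_umi=11, min_fraction=0.3, min_ratio=6.0)
        t_loose, _ = assign_cells(pairs, design, tenx_layout, loose)
        t_tight, _ = assign_cells(pairs, design, tenx_layout, tight)
        assigned_tight = set(t_tight.loc[t_tight["status"] == "assigned", "cell_id"])
        assigned_loose = set(t_loose.loc[t_loose["status"] == "assigned", "cell_id"])
        assert assigned_tight <= assigned_loose

    def test_doublets_called_multiple(self, tenx_layout, tenx_thresholds):
        from clonecatch.simulate import make_truth, simulate_fastq, simulate_pool

        design, clones = simulate_pool(4, 2, seed=5)
        truth = make_truth(design, clones, cells_per_clone=10, empty_fraction=0.0,
                           doublet_rate=1.0, layout=tenx_layout, seed=5)
        pairs = simulate_fastq(truth, fixed_reads_per_cell=40)
        table, _ = assign_cells(pairs, design, tenx_layout, tenx_thresholds)
        merged = table.merge(truth.cells, on="cell_id")
        doublets = merged[merged["is_doublet"]]
        assert (doublets["status"] == "multiple").mean() > 0.9

    def test_off_whitelist_reads_binned(self, tenx_layout, tenx_thresholds,
                                        small_design):
        pairs = [make_read_pair(tenx_layout, "G" * 16, f"{i:012d}".replace("1", "A")
                                .replace("0", "T"), "AAAACCCC", "ACGTAC")
                 for i in range(8)]
        table, report = assign_cells(pairs, small_design, tenx_layout,
                                     tenx_thresholds, whitelist=["C" * 16])
        assert report["reads"]["off_whitelist"] == 8
        assert table.empty
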