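import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from clonecatch.io import DesignEntry, DesignTable, ReadLayout, get_preset


@pytest.fixture
def small_design() -> DesignTable:
    """Four shRNAs with barcodes at pairwise Hamming >= 2 and hairpins."""
    return DesignTable(
        [
            DesignEntry("shA", "GENE1", "AAAACCCC", False, "A" * 21),
            DesignEntry("shB", "GENE1", "GGGGTTTT", False, "C" * 21),
            DesignEntry("shC", "GENE2", "ACGTACGT", False, "G" * 21),
            DesignEntry("SCR", "SCR", "TTTTAAAA", True, "T" * 21),
        ]
    )


@pytest.fixture
def tenx_layout() -> ReadLayout:
    return get_preset("tenx").layout


@pytest.fixture
def tenx_thresholds():
    return get_preset("tenx").thresholds


def make_read_pair(layout: ReadLayout, cell_id: str, umi: str, bc: str, uci: str,
                   anchor: str | None = None) -> tuple[str, str, str]:
    """Construct a synthetic read pair carrying the given fields."""
    anchor = anchor if anchor is not None else layout.anchor
    read1 = cell_id + umi
    if layout.field_order_after_anchor == "bc_then_uci":
        read2 = anchor + bc + uci
    else:
        read2 = anchor + uci + bc
    return read1, read2, f"pair:{cell_id}:{umi}"
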