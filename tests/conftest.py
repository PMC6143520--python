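import numpy as np
import pandas as pd
import pytest

from microbenet.taxa import RANKS, GroupDesign, RelAbundanceTable, TaxaCountTable


def make_lineage(rows: dict[str, tuple[str, ...]]) -> pd.DataFrame:
    """Build a lineage frame from taxon -> (possibly short) rank tuple."""
    full = {
        tid: tuple(list(slots) + [""] * (len(RANKS) - len(slots)))
        for tid, slots in rows.items()
    }
    return pd.DataFrame(
        [full[t] for t in rows], index=list(rows), columns=list(RANKS)
    )


def make_count_table(counts: dict[str, list[int]], lineages: dict[str, tuple[str, ...]],
                     sample_ids: list[str] | None = None) -> TaxaCountTable:
    frame = pd.DataFrame(counts)
    if sample_ids is not None:
        frame.index = sample_ids
    else:
        frame.index = [f"s{i + 1}" for i in range(len(frame))]
    return TaxaCountTable(counts=frame, lineage=make_lineage(lineages))


@pytest.fixture
def small_table() -> TaxaCountTable:
    """Three samples x four taxa spanning two phyla, one genus unresolved."""
    return make_count_table(
        counts={
            "t1": [10, 20, 5],
            "t2": [30, 10, 5],
            "t3": [40, 50, 70],
            "t4": [20, 20, 20],
        },
        lineages={
            "t1": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                   "Ruminococcaceae", "Faecalibacterium"),
            "t2": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                   "Streptococcaceae", "Streptococcus"),
            "t3": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
                   "Bacteroidaceae", "Bacteroides"),
            "t4": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                   "Clostridiaceae"),
        },
    )


@pytest.fixture
def small_design() -> GroupDesign:
    return GroupDesign(pd.Series({"s1": "case", "s2": "case", "s3": "control"}))


def make_rel_table(props: np.ndarray, taxon_labels: list[str], rank: str = "genus",
                   sample_ids: list[str] | None = None) -> RelAbundanceTable:
    """Relative table whose taxa are bare labels at ``rank``."""
    n = props.shape[0]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    frame = pd.DataFrame(props, index=sample_ids, columns=taxon_labels)
    idx = RANKS.index(rank)
    lineage = pd.DataFrame(
        [["Bacteria"] + [""] * (idx - 1) + [lab] + [""] * (len(RANKS) - idx - 1)
         for lab in taxon_labels],
        index=taxon_labels,
        columns=list(RANKS),
    )
    return RelAbundanceTable(props=frame, lineage=lineage, rank=rank)
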