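"""Short-chain fatty acid (SCFA) functional grouping of gut genera.

Genera are binned into four metabolic guilds -- butyrate producers,
lactate producers, mucin degraders, and other SCFA producers (propionate,
succinate, acetate) -- and each guild is summarised per sample as the sum
of its member genera's relative abundances.  Group-level case/control
comparison reuses the same rank-sum test as per-taxon differential
abundance, so its exactness guarantees carry over.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .diffabund import rank_sum_test
from .taxa import CASE, CONTROL, GroupDesign, RelAbundanceTable, TableValidationError

BUTYRATE = "butyrate"
LACTATE = "lactate"
MUCIN = "mucin"
OTHER_SCFA = "other_scfa"
GROUPS = (BUTYRATE, LACTATE, MUCIN, OTHER_SCFA)

# Established producer genera.  The "other SCFA" guild has no canonical
# genus list and starts empty: callers extend it explicitly rather than
# inheriting an invented membership.
_DEFAULT_MAP = {
    "Fusobacterium": BUTYRATE,
    "Eubacterium": BUTYRATE,
    "Anaerostipes": BUTYRATE,
    "Subdoligranulum": BUTYRATE,
    "Faecalibacterium": BUTYRATE,
    "Roseburia": BUTYRATE,
    "Lactobacillus": LACTATE,
    "Bifidobacterium": LACTATE,
    "Streptococcus": LACTATE,
    "Lactococcus": LACTATE,
    "Prevotella": MUCIN,
    "Akkermansia": MUCIN,
}


class FunctionalGroupError(ValueError):
    pass


def default_group_map() -> dict[str, str]:
    """Genus -> guild map for the four SCFA-related functional groups."""
    return dict(_DEFAULT_MAP)


def _validate_map(group_map: Mapping[str, str]) -> None:
    bad = {g for g in group_map.values() if g not in GROUPS}
    if bad:
        raise FunctionalGroupError(
            f"unknown functional groups {sorted(bad)}; expected one of {GROUPS}"
        )


def group_proportions(
    genus_table: RelAbundanceTable, group_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-sample summed relative abundance of each functional group.

    Requires a genus-level table (i.e. one produced by collapsing at the
    genus rank).  Genera absent from the map contribute to no group, so
    per-sample group sums are <= 1.  Membership is exact string match on
    the genus label -- no fuzzy matching.
    """
    if genus_table.rank != "genus":
        raise FunctionalGroupError(
            f"table must be collapsed at the genus rank (table rank: "
            f"{genus_table.rank!r})"
        )
    if group_map is None:
        group_map = default_group_map()
    _validate_map(group_map)
    out = pd.DataFrame(
        0.0, index=genus_table.sample_ids, columns=list(GROUPS)
    )
    for genus, group in group_map.items():
        if genus in genus_table.taxon_ids:
            out[group] += genus_table.props[genus]
    return out


def compare_groups(
    proportions: pd.DataFrame, design: GroupDesign
) -> pd.DataFrame:
    """Case/control rank-sum comparison of each functional group's
    per-sample proportion (columns: group, mean_case, mean_control, p)."""
    labels = design.for_samples(proportions.index)
    case_ids = labels.index[labels == CASE]
    control_ids = labels.index[labels == CONTROL]
    rows = []
    for group in proportions.columns:
        x = proportions.loc[case_ids, group].to_numpy()
        y = proportions.loc[control_ids, group].to_numpy()
        rows.append(
            {
                "group": group,
                "mean_case": float(x.mean()),
                "mean_control": float(y.mean()),
                "p_value": rank_sum_test(x, y),
            }
        )
    return pd.DataFrame(rows, columns=["group", "mean_case", "mean_control", "p_value"])


def read_group_map(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("genus", "group"):
        if col not in frame.columns:
            raise FunctionalGroupError(f"group map lacks column {col!r}")
    mapping = dict(zip(frame["genus"], frame["group"]))
    _validate_map(mapping)
    return mapping


def write_group_map(group_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(group_map.items()), columns=["genus", "group"]
    ).to_csv(path, sep="\t", index=False)
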