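"""Taxon count tables: I/O, relative abundance, rank collapsing, B/F ratio.

Tables are held as pandas DataFrames with samples on the rows and taxa on
the columns.  Each taxon carries a seven-rank Greengenes-style lineage
(kingdom through species); ranks that the classifier could not resolve are
stored as empty strings.  The on-disk dialect is the common QIIME "classic"
OTU table: one row per taxon, first header cell ``#OTU ID``, samples as
columns, and a trailing ``taxonomy`` column holding the ``"; "``-joined,
prefix-tagged lineage (``k__Bacteria; p__Firmicutes; ...``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

CASE = "case"
CONTROL = "control"
GROUP_LABELS = (CASE, CONTROL)


class TableValidationError(ValueError):
    """A count table, lineage, or design violated a structural invariant."""


# ---------------------------------------------------------------------------
# lineage helpers


def parse_lineage(text: str) -> tuple[str, ...]:
    """Parse a ``"; "``-separated, prefix-tagged lineage string.

    Returns a 7-tuple aligned with :data:`RANKS`; unresolved ranks are "".
    Tokens are matched by their prefix (``k__`` ... ``s__``), not position,
    so truncated lineages are accepted.
    """
    slots = [""] * len(RANKS)
    if text is None:
        return tuple(slots)
    text = text.strip()
    if not text or text.lower() in {"unassigned", "unclassified"}:
        return tuple(slots)
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        prefix = token[:3]
        if prefix not in RANK_PREFIXES:
            raise TableValidationError(
                f"malformed lineage token {token!r}: expected a rank prefix "
                f"like 'p__' (one of {', '.join(RANK_PREFIXES)})"
            )
        slots[RANK_PREFIXES.index(prefix)] = token[3:].strip()
    return tuple(slots)


def format_lineage(slots: Iterable[str]) -> str:
    return "; ".join(p + s for p, s in zip(RANK_PREFIXES, slots))


def collapse_label(slots: Iterable[str], rank: str) -> str:
    """Label of a taxon once collapsed at ``rank``.

    A taxon named at ``rank`` keeps that name; otherwise it is pooled under
    ``<deepest named ancestor>_unclass`` (e.g. a genus-less member of
    f__Clostridiaceae becomes ``Clostridiaceae_unclass``), or plain
    ``"unclass"`` when no ancestor is named at all.
    """
    if rank not in RANKS:
        raise TableValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    slots = list(slots)
    idx = RANKS.index(rank)
    if slots[idx]:
        return slots[idx]
    for j in range(idx - 1, -1, -1):
        if slots[j]:
            return f"{slots[j]}_unclass"
    return "unclass"


def _validate_axes(data: pd.DataFrame, lineage: pd.DataFrame) -> None:
    if data.index.has_duplicates:
        raise TableValidationError("duplicate sample ids")
    if data.columns.has_duplicates:
        raise TableValidationError("duplicate taxon ids")
    if list(lineage.columns) != list(RANKS):
        raise TableValidationError(f"lineage columns must be {RANKS}")
    if list(lineage.index) != list(data.columns):
        raise TableValidationError("lineage index must match the taxon axis")


# ---------------------------------------------------------------------------
# table types


@dataclasses.dataclass
class TaxaCountTable:
    """Samples x taxa integer counts plus a per-taxon rank lineage.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with taxon ids as columns;
        non-negative integers.
    lineage
        DataFrame indexed by taxon id with :data:`RANKS` as columns.
    rank
        Set when the table is the product of :func:`collapse_rank`.
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame
    rank: str | None = None

    def __post_init__(self) -> None:
        _validate_axes(self.counts, self.lineage)
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableValidationError("counts must be numeric")
        bad = np.argwhere((values < 0) | (values != np.floor(values)))
        if bad.size:
            i, j = bad[0]
            raise TableValidationError(
                f"count for sample {self.counts.index[i]!r}, taxon "
                f"{self.counts.columns[j]!r} is {values[i, j]!r}: counts must "
                "be non-negative integers"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def data(self) -> pd.DataFrame:
        return self.counts


@dataclasses.dataclass
class RelAbundanceTable:
    """Samples x taxa proportions; every row sums to 1."""

    props: pd.DataFrame
    lineage: pd.DataFrame
    rank: str | None = None

    _ROW_SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        _validate_axes(self.props, self.lineage)
        values = self.props.to_numpy(dtype=float)
        if (values < -1e-15).any() or (values > 1 + 1e-12).any():
            raise TableValidationError("proportions must lie in [0, 1]")
        sums = values.sum(axis=1)
        off = np.abs(sums - 1.0) > self._ROW_SUM_TOL
        if off.any():
            sid = self.props.index[int(np.argmax(off))]
            raise TableValidationError(
                f"sample {sid!r} proportions sum to {sums[np.argmax(off)]:.12g}, not 1"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.props.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.props.columns)

    @property
    def data(self) -> pd.DataFrame:
        return self.props


@dataclasses.dataclass
class GroupDesign:
    """Assignment of samples to the two comparison groups.

    ``labels`` maps sample id -> ``"case"`` or ``"control"``.
    """

    labels: pd.Series

    def __post_init__(self) -> None:
        if isinstance(self.labels, Mapping):
            self.labels = pd.Series(self.labels)
        if self.labels.index.has_duplicates:
            raise TableValidationError("duplicate sample ids in design")
        bad = set(self.labels) - set(GROUP_LABELS)
        if bad:
            raise TableValidationError(
                f"unknown group labels {sorted(bad)}; expected {GROUP_LABELS}"
            )
        self.labels = self.labels.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def case_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == CASE])

    @property
    def control_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == CONTROL])

    def for_samples(self, sample_ids: Iterable[str]) -> pd.Series:
        """Labels aligned to ``sample_ids``; every sample must be assigned."""
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.labels.index]
        if missing:
            raise TableValidationError(f"samples without a group label: {missing}")
        return self.labels.loc[sample_ids]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroupDesign":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("sample_id", "group"):
            if col not in frame.columns:
                raise TableValidationError(f"metadata file lacks column {col!r}")
        return cls(pd.Series(frame["group"].values, index=frame["sample_id"].values))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": self.labels.index, "group": self.labels.values}
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O


def read_taxa_table(path: str | Path, *, transposed: bool = False) -> TaxaCountTable:
    """Read a QIIME-classic OTU table (taxa as rows) from TSV.

    With ``transposed=True`` the file instead carries samples as rows
    (header ``#SampleID``) and a final row labelled ``taxonomy`` holding the
    per-taxon lineage strings.
    """
    frame = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    if transposed:
        first = frame.columns[0]
        if first != "#SampleID":
            raise TableValidationError(
                f"expected header '#SampleID' in first column, found {first!r}"
            )
        frame = frame.set_index(first)
        if "taxonomy" not in frame.index:
            raise TableValidationError("transposed table lacks a 'taxonomy' row")
        lineage_row = frame.loc["taxonomy"]
        counts = frame.drop(index="taxonomy")
        lineage = pd.DataFrame(
            [parse_lineage(lineage_row[t]) for t in counts.columns],
            index=counts.columns,
            columns=list(RANKS),
        )
        counts = _coerce_counts(counts)
        counts.index.name = None
        return TaxaCountTable(counts=counts, lineage=lineage)

    first = frame.columns[0]
    if first != "#OTU ID":
        raise TableValidationError(
            f"expected header '#OTU ID' in first column, found {first!r}"
        )
    if "taxonomy" not in frame.columns:
        raise TableValidationError("table lacks a 'taxonomy' column")
    frame = frame.set_index(first)
    lineage = pd.DataFrame(
        [parse_lineage(s) for s in frame["taxonomy"]],
        index=frame.index,
        columns=list(RANKS),
    )
    counts = _coerce_counts(frame.drop(columns="taxonomy").T)
    counts.index.name = None
    lineage.index.name = None
    return TaxaCountTable(counts=counts, lineage=lineage)


def _coerce_counts(frame: pd.DataFrame) -> pd.DataFrame:
    try:
        numeric = frame.astype(float)
    except ValueError as exc:
        raise TableValidationError(f"non-numeric count in table: {exc}") from exc
    return numeric


def write_taxa_table(
    table: TaxaCountTable, path: str | Path, *, transposed: bool = False
) -> None:
    """Write ``table`` in the dialect read by :func:`read_taxa_table`."""
    if transposed:
        out = table.counts.astype(str)
        out.loc["taxonomy"] = [
            format_lineage(table.lineage.loc[t]) for t in table.taxon_ids
        ]
        out.index.name = "#SampleID"
        out.to_csv(path, sep="\t")
        return
    out = table.counts.T.copy()
    out["taxonomy"] = [format_lineage(table.lineage.loc[t]) for t in table.taxon_ids]
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transforms


def to_relative(table: TaxaCountTable | RelAbundanceTable) -> RelAbundanceTable:
    """Normalise each sample (row) to proportions summing to 1.

    Idempotent on tables that are already relative.  A sample whose total
    is zero cannot be normalised and raises, naming the sample.
    """
    values = table.data.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        sid = table.data.index[int(np.argmax(totals <= 0))]
        raise TableValidationError(f"sample {sid!r} has zero total count")
    props = pd.DataFrame(
        values / totals[:, None], index=table.data.index, columns=table.data.columns
    )
    return RelAbundanceTable(props=props, lineage=table.lineage.copy(), rank=table.rank)


def collapse_rank(table, rank: str):
    """Sum taxa sharing the same label at ``rank``; pool unnamed taxa.

    Works on count and relative tables alike and returns the same type.
    Mass is conserved per sample.  Taxa unresolved at ``rank`` fall into
    ``<deepest named ancestor>_unclass`` buckets (see :func:`collapse_label`).
    """
    labels = [collapse_label(table.lineage.loc[t], rank) for t in table.taxon_ids]
    idx = RANKS.index(rank)
    # stable first-appearance ordering of collapsed labels
    order: dict[str, int] = {}
    for lab in labels:
        order.setdefault(lab, len(order))
    collapsed = table.data.T.groupby(labels, sort=False).sum().T
    collapsed = collapsed[sorted(collapsed.columns, key=order.__getitem__)]

    lineage_rows = {}
    for taxon, lab in zip(table.taxon_ids, labels):
        if lab in lineage_rows:
            continue
        slots = list(table.lineage.loc[taxon])[: idx + 1] + [""] * (len(RANKS) - idx - 1)
        slots[idx] = lab
        lineage_rows[lab] = slots
    lineage = pd.DataFrame(
        [lineage_rows[lab] for lab in collapsed.columns],
        index=collapsed.columns,
        columns=list(RANKS),
    )
    lineage.index.name = None
    if isinstance(table, TaxaCountTable):
        return TaxaCountTable(counts=collapsed, lineage=lineage, rank=rank)
    return RelAbundanceTable(props=collapsed, lineage=lineage, rank=rank)


class BFRatioResult(NamedTuple):
    """Per-sample Bacteroidetes/Firmicutes ratios plus excluded samples."""

    ratios: pd.Series
    excluded: list[str]


def bf_ratio(
    phylum_table: RelAbundanceTable, *, firmicutes_floor: float = 1e-6
) -> BFRatioResult:
    """Per-sample Bacteroidetes / Firmicutes proportion ratio.

    Samples whose Firmicutes proportion falls below ``firmicutes_floor`` have
    no meaningful ratio; they are excluded and reported separately rather
    than patched with a pseudocount (which would silently distort ranks in
    any downstream rank-based test).
    """
    for phylum in ("Bacteroidetes", "Firmicutes"):
        if phylum not in phylum_table.taxon_ids:
            raise TableValidationError(
                f"phylum table lacks {phylum!r}; collapse to 'phylum' rank first"
            )
    bact = phylum_table.props["Bacteroidetes"]
    firm = phylum_table.props["Firmicutes"]
    keep = firm >= firmicutes_floor
    ratios = (bact[keep] / firm[keep]).rename("bf_ratio")
    return BFRatioResult(ratios=ratios, excluded=list(firm.index[~keep]))
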