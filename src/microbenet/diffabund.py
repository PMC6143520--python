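"""Two-group per-taxon differential abundance testing.

The workhorse is an unpaired two-sided Wilcoxon rank-sum test.  When the
number of distinct group assignments C(n1+n2, n1) is small enough the test
is *exact*: the rank-sum statistic (midranks for ties) is enumerated over
every assignment and the two-sided p-value is twice the smaller tail
probability, capped at 1.  For larger designs the usual normal
approximation with tie-corrected variance and continuity correction is
used.  Per-rank p-values are adjusted by the Benjamini-Hochberg step-up
procedure into q-values.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb, sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hmdn import SignedProfile
from .taxa import CASE, CONTROL, GroupDesign, RelAbundanceTable, collapse_rank

EXACT_LIMIT = 200_000


class StatTestError(ValueError):
    """Invalid input to a statistical test."""


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_limit: int = EXACT_LIMIT,
    method: str = "auto",
    two_sided: str = "doubling",
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for samples ``x`` vs ``y``.

    ``method``: "exact" (full enumeration), "normal" (tie-corrected normal
    approximation with continuity correction), or "auto" (exact when
    C(n1+n2, n1) <= ``exact_limit``).

    ``two_sided``: how the exact two-sided p is formed -- "doubling"
    (2 * min(lower tail, upper tail), capped at 1; the default) or
    "deviation" (P(|W - E[W]| >= |w - E[W]|)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatTestError("both groups must be non-empty")
    if two_sided not in ("doubling", "deviation"):
        raise StatTestError(f"unknown two_sided mode {two_sided!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()

    if method == "auto":
        method = "exact" if comb(n, n1) <= exact_limit else "normal"
    if method == "exact":
        return _exact_rank_sum_p(ranks, n1, w_obs, two_sided)
    if method == "normal":
        return _normal_rank_sum_p(ranks, n1, w_obs)
    raise StatTestError(f"unknown method {method!r}")


def _exact_rank_sum_p(
    ranks: np.ndarray, n1: int, w_obs: float, two_sided: str
) -> float:
    n = ranks.size
    total = comb(n, n1)
    sums = np.fromiter(
        (sum(c) for c in combinations(ranks, n1)), dtype=float, count=total
    )
    eps = 1e-9
    if two_sided == "doubling":
        lower = int((sums <= w_obs + eps).sum())
        upper = int((sums >= w_obs - eps).sum())
        return min(1.0, 2.0 * min(lower, upper) / total)
    mean = n1 * (n + 1) / 2.0
    dev = np.abs(sums - mean)
    return float((dev >= abs(w_obs - mean) - eps).sum() / total)


def _normal_rank_sum_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    n = ranks.size
    n2 = n - n1
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # fully tied data carry no ordering information
        return 1.0
    diff = w_obs - mean
    z = (diff - 0.5 * np.sign(diff)) / sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def bh_adjust(
    p_values: Sequence[float], m: int | None = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1 and mapped back to
    the input order.  ``m`` defaults to the number of tests but may be set
    larger (e.g. when the family includes tests not passed in).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise StatTestError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise StatTestError(f"family size m={m} smaller than number of tests {p.size}")
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# per-taxon testing


@dataclasses.dataclass
class DiffAbundanceResult:
    """One taxon's two-group comparison (one table row)."""

    taxon: str
    rank: str
    mean_case: float
    mean_control: float
    p_value: float
    q_value: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.mean_case - self.mean_control))

    def __post_init__(self) -> None:
        if self.q_value < self.p_value - 1e-12:
            raise StatTestError("q-value cannot be smaller than its p-value")


def differential_abundance(
    table: RelAbundanceTable,
    design: GroupDesign,
    rank: str,
    *,
    prevalence_min: float = 0.1,
    family_size: int | None = None,
    method: str = "auto",
) -> list[DiffAbundanceResult]:
    """Per-taxon rank-sum tests at one taxonomic rank, BH-adjusted.

    The table is collapsed to ``rank``; taxa detected (nonzero) in fewer
    than ``prevalence_min`` of all samples are dropped before testing (an
    all-zero or near-all-zero taxon yields a degenerate, fully tied test).
    BH adjustment is applied within the rank, over the taxa actually
    tested, unless a larger ``family_size`` is given.
    """
    if not 0 <= prevalence_min <= 1:
        raise StatTestError("prevalence_min must lie in [0, 1]")
    collapsed = collapse_rank(table, rank)
    labels = design.for_samples(collapsed.sample_ids)
    case_ids = labels.index[labels == CASE]
    control_ids = labels.index[labels == CONTROL]
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise StatTestError(
            "each group needs at least 2 samples for a two-group test "
            f"(got {len(case_ids)} case, {len(control_ids)} control)"
        )
    props = collapsed.props
    prevalence = (props > 0).mean(axis=0)
    kept = [t for t in collapsed.taxon_ids if prevalence[t] >= prevalence_min]

    results: list[DiffAbundanceResult] = []
    p_values = []
    for taxon in kept:
        x = props.loc[case_ids, taxon].to_numpy()
        y = props.loc[control_ids, taxon].to_numpy()
        p_values.append(rank_sum_test(x, y, method=method))
    q_values = bh_adjust(p_values, m=family_size) if kept else np.array([])
    for taxon, p, q in zip(kept, p_values, q_values):
        results.append(
            DiffAbundanceResult(
                taxon=taxon,
                rank=rank,
                mean_case=float(props.loc[case_ids, taxon].mean()),
                mean_control=float(props.loc[control_ids, taxon].mean()),
                p_value=float(p),
                q_value=float(q),
            )
        )
    return results


def results_to_frame(results: Sequence[DiffAbundanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "rank": r.rank,
                "mean_case": r.mean_case,
                "mean_control": r.mean_control,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
            }
            for r in results
        ],
        columns=[
            "taxon",
            "rank",
            "mean_case",
            "mean_control",
            "p_value",
            "q_value",
            "direction",
        ],
    )


def write_results(results: Sequence[DiffAbundanceResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def extract_signed_profile(
    results: Sequence[DiffAbundanceResult],
    *,
    alpha: float = 0.05,
    disease: str = "ASD",
) -> SignedProfile:
    """Signed microbe profile from significant results (q < alpha).

    Taxa with a zero direction (exactly equal group means) are
    uninformative and skipped.  An empty profile is a legitimate outcome.
    """
    ranks = {r.rank for r in results}
    if len(ranks) > 1:
        raise StatTestError(
            f"results mix taxonomic ranks {sorted(ranks)}; profile needs one rank"
        )
    signs = {
        r.taxon: r.direction
        for r in results
        if r.q_value < alpha and r.direction != 0
    }
    return SignedProfile(
        disease=disease, signs=signs, rank=next(iter(ranks)) if ranks else None
    )
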