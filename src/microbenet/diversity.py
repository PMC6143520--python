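"""Alpha diversity, Bray-Curtis beta diversity, PCoA, and a PERMANOVA-style
permutation test for group separation."""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .taxa import CASE, CONTROL, GroupDesign, RelAbundanceTable, TableValidationError


class DiversityError(ValueError):
    """Invalid input to a diversity computation."""


def shannon(abundances: Sequence[float], base: float = 2.0) -> float:
    """Shannon entropy H = -sum p_i log_base(p_i) of a taxon profile.

    The vector is renormalised to proportions first, so raw counts are
    accepted.  Base 2 by default (the QIIME convention); pass
    ``base=np.e`` for nats.
    """
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise DiversityError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise DiversityError("cannot compute diversity of an all-zero profile")
    return float(stats.entropy(p / total, base=base))


def shannon_per_sample(table: RelAbundanceTable, base: float = 2.0) -> pd.Series:
    values = [shannon(row, base=base) for _, row in table.props.iterrows()]
    return pd.Series(values, index=table.sample_ids, name="shannon")


@dataclasses.dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample labels."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise DiversityError("distance matrix shape must match sample ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise DiversityError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0, atol=1e-12):
            raise DiversityError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis_matrix(table: RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities,
    BC(a, b) = sum_i |a_i - b_i| / sum_i (a_i + b_i)."""
    if len(table.sample_ids) < 2:
        raise DiversityError("need at least 2 samples for beta diversity")
    condensed = pdist(table.props.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(sample_ids=table.sample_ids, data=squareform(condensed))


@dataclasses.dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) output.

    ``coordinates`` has one column per retained (positive-eigenvalue) axis,
    ordered by descending eigenvalue and scaled by sqrt(eigenvalue).
    ``eigenvalues`` carries the full spectrum (negatives included, for
    diagnosing non-Euclidean input); ``proportion_explained`` is per
    retained axis, over the positive part of the spectrum.
    """

    sample_ids: list[str]
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal coordinates analysis (Gower's classical scaling).

    The doubly centred matrix -D^2/2 is eigendecomposed; coordinates are
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    Negative eigenvalues are reported unaltered and their axes dropped; if
    fewer than ``k`` positive eigenvalues exist the result is truncated
    with a warning.
    """
    if k < 1:
        raise DiversityError("k must be >= 1")
    n = len(dm.sample_ids)
    d2 = dm.data**2
    centering = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh((gram + gram.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-12, abs(eigval[0]) * 1e-12) if n else 1e-12
    n_positive = int((eigval > tol).sum())
    if k > n_positive:
        warnings.warn(
            f"requested {k} axes but only {n_positive} positive eigenvalues; "
            "truncating",
            stacklevel=2,
        )
        k = n_positive
    coords = eigvec[:, :k] * np.sqrt(eigval[:k]) if k else np.zeros((n, 0))
    positive_sum = eigval[:n_positive].sum() if n_positive else 1.0
    proportions = eigval[:k] / positive_sum if k else np.array([])
    return OrdinationResult(
        sample_ids=dm.sample_ids,
        coordinates=pd.DataFrame(
            coords, index=dm.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        eigenvalues=eigval,
        proportion_explained=proportions,
    )


class PermutationTestResult(NamedTuple):
    statistic: float
    p_value: float
    n_perm: int


def _pseudo_f(d2: np.ndarray, case_mask: np.ndarray) -> float:
    """Anderson's PERMANOVA pseudo-F for a two-group design from squared
    distances: among-group vs within-group sums of squares."""
    n = d2.shape[0]
    n1 = int(case_mask.sum())
    n2 = n - n1
    ss_total = d2.sum() / (2 * n)
    within_case = d2[np.ix_(case_mask, case_mask)].sum() / (2 * n1)
    within_ctrl = d2[np.ix_(~case_mask, ~case_mask)].sum() / (2 * n2)
    ss_within = within_case + within_ctrl
    if ss_within <= 0:
        return np.inf
    return (ss_total - ss_within) / (ss_within / (n - 2))


def permutation_group_test(
    dm: DistanceMatrix,
    design: GroupDesign,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Two-group PERMANOVA: pseudo-F tested by label permutation.

    Group labels are permuted ``n_perm`` times with fixed group sizes;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) (add-one smoothing, so the
    smallest attainable p is 1/(n_perm + 1)).
    """
    if n_perm < 99:
        raise DiversityError("n_perm must be >= 99")
    labels = design.for_samples(dm.sample_ids)
    case_mask = (labels == CASE).to_numpy()
    n1, n2 = int(case_mask.sum()), int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise DiversityError(
            f"each group needs >= 2 samples (got {n1} case, {n2} control)"
        )
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, case_mask)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    masks = rng.permuted(np.tile(case_mask, (n_perm, 1)), axis=1)
    # vectorised within-group sums across all permutations
    m = masks.astype(float)
    within_case = np.einsum("ij,jk,ik->i", m, d2, m) / (2 * n1)
    mo = 1.0 - m
    within_ctrl = np.einsum("ij,jk,ik->i", mo, d2, mo) / (2 * n2)
    ss_total = d2.sum() / (2 * (n1 + n2))
    ss_within = within_case + within_ctrl
    with np.errstate(divide="ignore"):
        f_perm = np.where(
            ss_within > 0,
            (ss_total - ss_within) * (n1 + n2 - 2) / ss_within,
            np.inf,
        )
    exceed = int((f_perm >= f_obs - 1e-12).sum())
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(statistic=float(f_obs), p_value=p, n_perm=n_perm)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise TableValidationError("distance matrix labels do not match")
    return DistanceMatrix(sample_ids=list(frame.index), data=frame.to_numpy())
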