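"""Signed microbe-based human disease network (HMDN).

Curated microbe-disease association records (disease, microbe, direction)
are condensed into one *signed profile* per disease: a map from microbe to
+1 (reported increased in that disease) or -1 (decreased).  Two diseases
are then compared by a signed cosine over their {-1, 0, +1} microbe
vectors,

    S(a, b) = sum_{m in Ma & Mb} sign_a(m) * sign_b(m) / sqrt(|Ma| * |Mb|),

which is symmetric, bounded in [-1, 1] (Cauchy-Schwarz), equal to +1 for
identical profiles and -1 for perfectly reversed ones, and 0 when the
profiles share no microbe.  Significance of a pairwise score is assessed by
a support-preserving permutation null: each profile's microbe set is
redrawn uniformly from a user-supplied universe keeping its size, and its
signs are reassigned as a random permutation of the observed sign multiset.

The resulting network has diseases as nodes and significant, signed,
weighted similarity edges; it is held as a :class:`networkx.Graph`.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INCREASE = "increase"
DECREASE = "decrease"
_DIRECTION_SIGNS = {INCREASE: +1, DECREASE: -1}


class AssociationError(ValueError):
    """Malformed association input or profile."""


def normalize_microbe_name(name: str) -> str:
    """Canonical microbe key: strip rank prefixes and whitespace, lowercase,
    and keep the genus token when a binomial (or longer phrase) is given.

    ``"g__Veillonella"``, ``"Veillonella"`` and ``"Veillonella parvula"``
    all normalise to ``"veillonella"``.
    """
    name = name.strip()
    for prefix in ("k__", "p__", "c__", "o__", "f__", "g__", "s__"):
        if name.startswith(prefix):
            name = name[len(prefix) :]
            break
    name = name.strip().lower()
    if not name:
        raise AssociationError("empty microbe name")
    return name.split()[0]


@dataclasses.dataclass(frozen=True)
class AssociationRecord:
    """One curated (disease, microbe, direction) assertion."""

    disease: str
    microbe: str
    direction: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTION_SIGNS:
            raise AssociationError(
                f"direction must be '{INCREASE}' or '{DECREASE}', "
                f"got {self.direction!r}"
            )
        if not self.disease.strip() or not self.microbe.strip():
            raise AssociationError("disease and microbe names must be non-empty")

    @property
    def sign(self) -> int:
        return _DIRECTION_SIGNS[self.direction]


@dataclasses.dataclass
class SignedProfile:
    """One disease's microbiome signature: microbe -> direction of change.

    ``signs`` maps normalised microbe keys to +1 / -1; zeros are never
    stored.  ``rank`` records the taxonomic context the signature was
    derived at (e.g. "genus"), when known.
    """

    disease: str
    signs: dict[str, int]
    rank: str | None = None

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for microbe, sign in self.signs.items():
            if sign not in (-1, 1):
                raise AssociationError(
                    f"profile sign for {microbe!r} must be +1 or -1, got {sign!r}"
                )
            cleaned[normalize_microbe_name(microbe)] = int(sign)
        self.signs = cleaned

    @property
    def microbes(self) -> set[str]:
        return set(self.signs)

    def __len__(self) -> int:
        return len(self.signs)


# ---------------------------------------------------------------------------
# I/O


def read_associations(path: str | Path) -> list[AssociationRecord]:
    """Read the association TSV (columns disease, microbe, direction,
    evidence); microbe names are normalised on the way in.  A bad direction
    token raises, naming the offending line."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("disease", "microbe", "direction"):
        if col not in frame.columns:
            raise AssociationError(f"association file lacks column {col!r}")
    records = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        direction = row.direction.strip().lower()
        if direction not in _DIRECTION_SIGNS:
            raise AssociationError(
                f"line {pos + 2}: unknown direction token {row.direction!r} "
                f"(expected '{INCREASE}' or '{DECREASE}')"
            )
        records.append(
            AssociationRecord(
                disease=row.disease.strip(),
                microbe=normalize_microbe_name(row.microbe),
                direction=direction,
                evidence=getattr(row, "evidence", ""),
            )
        )
    return records


def write_profile(profile: SignedProfile, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"disease": profile.disease, "microbe": m, "sign": s}
            for m, s in sorted(profile.signs.items())
        ],
        columns=["disease", "microbe", "sign"],
    ).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[SignedProfile]:
    """Read one or more signed profiles from a (disease, microbe, sign) TSV."""
    frame = pd.read_csv(path, sep="\t", dtype={"disease": str, "microbe": str, "sign": int})
    profiles = []
    for disease, chunk in frame.groupby("disease", sort=False):
        profiles.append(
            SignedProfile(
                disease=str(disease),
                signs={m: int(s) for m, s in zip(chunk["microbe"], chunk["sign"])},
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# profiles and similarity


def build_profiles(records: Iterable[AssociationRecord]) -> list[SignedProfile]:
    """Condense records into one profile per disease by majority vote.

    Multiple records for the same (disease, microbe) vote with their signs;
    an exact tie is uninformative, so the microbe is dropped from that
    disease's profile with a warning.
    """
    votes: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    order: list[str] = []
    for rec in records:
        if rec.disease not in votes:
            order.append(rec.disease)
        # accepts any record with disease/microbe/direction attributes
        votes[rec.disease][normalize_microbe_name(rec.microbe)] += _DIRECTION_SIGNS[
            rec.direction
        ]
    profiles = []
    for disease in order:
        signs = {}
        for microbe, total in votes[disease].items():
            if total == 0:
                logger.warning(
                    "disease %r: tied increase/decrease votes for %r; dropped",
                    disease,
                    microbe,
                )
                continue
            signs[microbe] = 1 if total > 0 else -1
        profiles.append(SignedProfile(disease=disease, signs=signs))
    return profiles


def microbe_similarity(a: SignedProfile, b: SignedProfile) -> float:
    """Signed cosine similarity of two disease profiles (see module docs)."""
    if len(a) == 0 or len(b) == 0:
        raise AssociationError("cannot score an empty profile")
    shared = a.microbes & b.microbes
    numerator = sum(a.signs[m] * b.signs[m] for m in shared)
    return numerator / math.sqrt(len(a) * len(b))


def shared_microbes(a: SignedProfile, b: SignedProfile) -> set[str]:
    return a.microbes & b.microbes


def similarity_pvalue(
    a: SignedProfile,
    b: SignedProfile,
    universe: Iterable[str],
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for ``|S(a, b)|``.

    Null draws keep each profile's support size and sign counts but redraw
    the supports uniformly from ``universe`` and shuffle the signs;
    p = (1 + #{|S_perm| >= |S_obs|}) / (1 + n_perm).  The computation is
    symmetric in (a, b): profiles are internally ordered by disease name.
    """
    if n_perm < 99:
        raise AssociationError("n_perm must be >= 99")
    universe = sorted({normalize_microbe_name(m) for m in universe})
    if a.disease > b.disease:  # symmetric seed policy
        a, b = b, a
    for prof in (a, b):
        extra = prof.microbes - set(universe)
        if extra:
            raise AssociationError(
                f"universe does not cover profile {prof.disease!r}: "
                f"missing {sorted(extra)[:5]}"
            )
    n_universe = len(universe)
    s_obs = abs(microbe_similarity(a, b))
    sa = np.fromiter(a.signs.values(), dtype=float, count=len(a))
    sb = np.fromiter(b.signs.values(), dtype=float, count=len(b))

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # vectorised support redraw: argsort of uniform noise gives independent
    # uniform subsets; signs are an independently permuted multiset
    def signed_matrix(signs: np.ndarray) -> np.ndarray:
        k = len(signs)
        picks = np.argsort(rng.random((n_perm, n_universe)), axis=1)[:, :k]
        shuffled = rng.permuted(np.tile(signs, (n_perm, 1)), axis=1)
        mat = np.zeros((n_perm, n_universe))
        np.put_along_axis(mat, picks, shuffled, axis=1)
        return mat

    va = signed_matrix(sa)
    vb = signed_matrix(sb)
    s_perm = np.abs((va * vb).sum(axis=1)) / math.sqrt(len(a) * len(b))
    exceed = int((s_perm >= s_obs - 1e-12).sum())
    return (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# network


def build_network(
    profiles: Sequence[SignedProfile],
    *,
    alpha: float = 0.05,
    min_shared: int = 1,
    n_perm: int = 999,
    seed: int = 0,
    universe: Iterable[str] | None = None,
    pinned: Iterable[str] = (),
    adjust: str = "none",
) -> nx.Graph:
    """Score every disease pair and keep significant signed edges.

    A pair enters the network when it shares at least ``min_shared``
    microbes, its score is nonzero, and its permutation p-value passes
    ``alpha`` (optionally after BH adjustment across all tested pairs with
    ``adjust="bh"``).  Nodes are diseases with at least one retained edge
    plus any ``pinned`` disease (kept even when isolated).  The permutation
    universe defaults to the union of all profile supports.

    Edge attributes: ``score``, ``shared``, ``p`` (and ``q`` under BH),
    ``sign`` ("positive"/"negative").
    """
    if len(profiles) < 2:
        raise AssociationError("need at least two profiles to build a network")
    if not 0 < alpha < 1:
        raise AssociationError("alpha must lie in (0, 1)")
    if adjust not in ("none", "bh"):
        raise AssociationError(f"unknown adjust mode {adjust!r}")
    by_name = {p.disease: p for p in profiles}
    if len(by_name) != len(profiles):
        raise AssociationError("duplicate disease names among profiles")
    if universe is None:
        universe = set().union(*(p.microbes for p in profiles))
    universe = sorted({normalize_microbe_name(m) for m in universe})

    names = sorted(by_name)
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    children = np.random.SeedSequence(seed).spawn(len(pairs))

    tested = []
    for (da, db), child in zip(pairs, children):
        a, b = by_name[da], by_name[db]
        if len(a) == 0 or len(b) == 0:
            continue
        shared = len(shared_microbes(a, b))
        if shared < max(1, min_shared):
            continue
        score = microbe_similarity(a, b)
        if score == 0:
            continue
        p = similarity_pvalue(
            a, b, universe, n_perm=n_perm, seed=int(child.generate_state(1)[0] % 2**31)
        )
        tested.append((da, db, score, shared, p))

    graph = nx.Graph(alpha=alpha, min_shared=min_shared, n_perm=n_perm)
    if adjust == "bh" and tested:
        from .diffabund import bh_adjust

        qs = bh_adjust([t[4] for t in tested])
        keep = [(t, q) for t, q in zip(tested, qs) if q < alpha]
    else:
        keep = [(t, None) for t in tested if t[4] < alpha]

    for (da, db, score, shared, p), q in keep:
        attrs = {
            "score": score,
            "shared": shared,
            "p": p,
            "sign": "positive" if score > 0 else "negative",
        }
        if q is not None:
            attrs["q"] = q
        graph.add_edge(da, db, **attrs)
    for name in pinned:
        graph.add_node(name)
    return graph


def disease_neighbors(graph: nx.Graph, disease: str) -> list[tuple[str, float]]:
    """Neighbors of ``disease`` ranked by |score| descending, sign kept."""
    if disease not in graph:
        raise AssociationError(f"disease {disease!r} is not a network node")
    ranked = sorted(
        ((nbr, data["score"]) for nbr, data in graph[disease].items()),
        key=lambda item: (-abs(item[1]), item[0]),
    )
    return ranked


_EDGE_COLUMNS = ["disease_a", "disease_b", "score", "shared", "p", "sign"]


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "tsv") -> None:
    """Write the network as an edge-list TSV or as GraphML (lossless)."""
    path = Path(path)
    if fmt == "tsv":
        rows = [
            {
                "disease_a": a,
                "disease_b": b,
                "score": data["score"],
                "shared": data["shared"],
                "p": data["p"],
                "sign": data["sign"],
            }
            for a, b, data in sorted(graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise AssociationError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str = "tsv") -> nx.Graph:
    path = Path(path)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t")
        graph = nx.Graph()
        for row in frame.itertuples(index=False):
            graph.add_edge(
                row.disease_a,
                row.disease_b,
                score=float(row.score),
                shared=int(row.shared),
                p=float(row.p),
                sign=str(row.sign),
            )
        return graph
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise AssociationError(f"unknown network format {fmt!r}")
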