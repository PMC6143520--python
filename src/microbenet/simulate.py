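"""Synthetic community and association data with known ground truth.

Two generators live here:

* :func:`simulate_counts` draws a samples x taxa count table from a
  Dirichlet-multinomial model with group-specific composition.  Case-group
  effects are planted multiplicatively: a taxon with baseline proportion
  ``p`` and fold change ``f`` has case proportion ``f*p / (1 + (f-1)*p)``
  after renormalisation (for a single perturbed taxon; in general the
  perturbed vector is renormalised jointly).  The Dirichlet layer adds the
  between-sample overdispersion typical of 16S gut profiles, which a plain
  multinomial would miss.

* :func:`simulate_associations` draws sparse signed (disease, microbe,
  direction) records in the style of curated microbe-disease association
  databases, with optional planted disease pairs of controlled sign
  consistency, so that network-recovery behaviour can be tested against a
  known answer.

Both are deterministic given their scenario seed: one ``SeedSequence``
derived from the scenario seed is split into per-sample (or per-stage)
child streams.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .taxa import (
    RANKS,
    CASE,
    CONTROL,
    GroupDesign,
    TaxaCountTable,
    collapse_label,
)

INCREASE = "increase"
DECREASE = "decrease"


class ScenarioError(ValueError):
    """A simulation scenario violated one of its invariants."""


# ---------------------------------------------------------------------------
# community scenario


@dataclasses.dataclass
class CommunityScenario:
    """Parameters of a two-group Dirichlet-multinomial community.

    Parameters
    ----------
    n_case, n_control
        Group sizes (>= 1 each).
    taxa
        Sequence of ``(taxon_id, lineage)`` with a 7-slot lineage tuple
        aligned to kingdom..species ("" for unresolved ranks).
    baseline_props
        Control-group expected composition; must sum to 1 (within 1e-12).
    fold_changes
        Map taxon_id -> positive multiplier applied in the case group
        before joint renormalisation.  Taxa absent from the map keep
        fold 1 (their realised proportion still shifts slightly through
        the renormalisation; only mapped taxa are counted as planted).
    dispersion
        Total Dirichlet concentration; larger means less between-sample
        variation (the model tends to a plain multinomial as it grows).
    library_size_law
        ``(mean, sigma)`` of a lognormal law for per-sample totals
        (sigma on the log scale); draws are rounded and floored at 1000.
    seed
        Root seed for all randomness.
    """

    n_case: int
    n_control: int
    taxa: Sequence[tuple[str, tuple[str, ...]]]
    baseline_props: np.ndarray
    fold_changes: dict[str, float] = dataclasses.field(default_factory=dict)
    dispersion: float = 200.0
    library_size_law: tuple[float, float] = (50_000.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_props = np.asarray(self.baseline_props, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ScenarioError("n_case and n_control must both be >= 1")
        ids = [t for t, _ in self.taxa]
        if len(set(ids)) != len(ids):
            raise ScenarioError("duplicate taxon ids in scenario")
        if len(self.baseline_props) != len(self.taxa):
            raise ScenarioError("baseline_props length must match taxa")
        if (self.baseline_props < 0).any():
            raise ScenarioError("baseline proportions must be non-negative")
        if abs(self.baseline_props.sum() - 1.0) > 1e-12:
            raise ScenarioError(
                f"baseline_props sum to {self.baseline_props.sum():.15g}, not 1"
            )
        unknown = set(self.fold_changes) - set(ids)
        if unknown:
            raise ScenarioError(f"fold changes for unknown taxa: {sorted(unknown)}")
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ScenarioError("all fold changes must be > 0")
        if self.dispersion <= 0:
            raise ScenarioError("dispersion must be > 0")
        mean, sigma = self.library_size_law
        if mean <= 0 or sigma < 0:
            raise ScenarioError("library size law needs mean > 0 and sigma >= 0")

    @property
    def taxon_ids(self) -> list[str]:
        return [t for t, _ in self.taxa]

    @property
    def control_props(self) -> np.ndarray:
        return self.baseline_props.copy()

    @property
    def case_props(self) -> np.ndarray:
        folds = np.array(
            [self.fold_changes.get(t, 1.0) for t in self.taxon_ids], dtype=float
        )
        weighted = self.baseline_props * folds
        return weighted / weighted.sum()

    def to_dict(self) -> dict:
        return {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "taxa": [[tid, list(lin)] for tid, lin in self.taxa],
            "baseline_props": [float(p) for p in self.baseline_props],
            "fold_changes": {k: float(v) for k, v in self.fold_changes.items()},
            "dispersion": float(self.dispersion),
            "library_size_law": [float(x) for x in self.library_size_law],
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CommunityScenario":
        return cls(
            n_case=payload["n_case"],
            n_control=payload["n_control"],
            taxa=[(tid, tuple(lin)) for tid, lin in payload["taxa"]],
            baseline_props=np.asarray(payload["baseline_props"], dtype=float),
            fold_changes=dict(payload["fold_changes"]),
            dispersion=payload["dispersion"],
            library_size_law=tuple(payload["library_size_law"]),
            seed=payload["seed"],
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def read_json(cls, path: str | Path) -> "CommunityScenario":
        return cls.from_dict(json.loads(Path(path).read_text()))


def simulate_counts(
    scenario: CommunityScenario,
) -> tuple[TaxaCountTable, GroupDesign, pd.DataFrame]:
    """Draw a count table, group design and planted-effect truth table.

    Per sample: library size ~ rounded lognormal (floor 1000), composition
    ~ Dirichlet(dispersion * group proportion vector), counts ~ multinomial.
    Taxa with zero group proportion receive zero counts exactly.

    The truth table lists each planted taxon (one row per entry of
    ``scenario.fold_changes``) with its genus-level collapsed label, fold
    and true direction ``sign(fold - 1)``.
    """
    scenario.validate()
    n_total = scenario.n_case + scenario.n_control
    sample_ids = [f"case_{i + 1:02d}" for i in range(scenario.n_case)] + [
        f"control_{i + 1:02d}" for i in range(scenario.n_control)
    ]
    labels = [CASE] * scenario.n_case + [CONTROL] * scenario.n_control
    group_props = {CASE: scenario.case_props, CONTROL: scenario.control_props}

    mean, sigma = scenario.library_size_law
    mu = math.log(mean) - 0.5 * sigma**2  # lognormal parameterised by its mean

    children = np.random.SeedSequence(scenario.seed).spawn(n_total)
    rows = np.zeros((n_total, len(scenario.taxa)), dtype=np.int64)
    for i, (child, label) in enumerate(zip(children, labels)):
        rng = np.random.default_rng(child)
        size = max(1000, int(round(rng.lognormal(mean=mu, sigma=sigma))))
        props = group_props[label]
        support = props > 0
        alpha = scenario.dispersion * props[support]
        theta = rng.dirichlet(alpha)
        rows[i, support] = rng.multinomial(size, theta)

    counts = pd.DataFrame(rows, index=sample_ids, columns=scenario.taxon_ids)
    lineage = pd.DataFrame(
        [list(lin) for _, lin in scenario.taxa],
        index=scenario.taxon_ids,
        columns=list(RANKS),
    )
    table = TaxaCountTable(counts=counts, lineage=lineage)
    design = GroupDesign(pd.Series(labels, index=sample_ids))

    lineage_by_id = dict(scenario.taxa)
    truth = pd.DataFrame(
        [
            {
                "taxon_id": tid,
                "label": collapse_label(lineage_by_id[tid], "genus"),
                "fold": fold,
                "direction": int(np.sign(fold - 1.0)),
            }
            for tid, fold in scenario.fold_changes.items()
        ],
        columns=["taxon_id", "label", "fold", "direction"],
    )
    return table, design, truth


# ---------------------------------------------------------------------------
# default ASD-vs-TD scenario

# Control-group gut composition used by the default scenario.  Phylum totals
# follow the rounded pattern of a Bacteroidetes ~0.3 / Firmicutes ~0.6 gut;
# genus-level values are plausible round numbers for a paediatric cohort.
# The rarest planted genera are kept in the fraction-of-a-percent range --
# taxa much below ~1e-3 are not resolvable at realistic sequencing depth
# and would make any recovery statement about them vacuous.
_DEFAULT_COMMUNITY: list[tuple[str, tuple[str, ...], float]] = [
    # taxon id, (kingdom, phylum, class, order, family, genus, species), control prop
    ("otu_bacteroides", ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", ""), 0.210),
    ("otu_prevotella", ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella", ""), 0.050),
    ("otu_parabacteroides", ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Parabacteroides", ""), 0.040),
    ("otu_faecalibacterium", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium", ""), 0.120),
    ("otu_lachnospiraceae", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "", ""), 0.100),
    ("otu_ruminococcus", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus", ""), 0.060),
    ("otu_blautia", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia", ""), 0.060),
    ("otu_oscillospira", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Oscillospira", ""), 0.050),
    ("otu_roseburia", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Roseburia", ""), 0.040),
    ("otu_eubacterium", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Eubacteriaceae", "Eubacterium", ""), 0.030),
    ("otu_clostridiaceae", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "", ""), 0.053),
    ("otu_veillonella", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Veillonellaceae", "Veillonella", ""), 0.027),
    ("otu_streptococcus", ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", ""), 0.025),
    ("otu_dialister", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Veillonellaceae", "Dialister", ""), 0.012),
    ("otu_lactobacillus", ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", ""), 0.010),
    ("otu_parvimonas", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Tissierellaceae", "Parvimonas", ""), 0.008),
    ("otu_bulleidia", ("Bacteria", "Firmicutes", "Erysipelotrichi", "Erysipelotrichales", "Erysipelotrichaceae", "Bulleidia", ""), 0.003),
    ("otu_peptoniphilus", ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Tissierellaceae", "Peptoniphilus", ""), 0.002),
    ("otu_escherichia", ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Escherichia", ""), 0.024),
    ("otu_sutterella", ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Alcaligenaceae", "Sutterella", ""), 0.010),
    ("otu_bifidobacterium", ("Bacteria", "Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", ""), 0.030),
    ("otu_actinomyces", ("Bacteria", "Actinobacteria", "Actinobacteria", "Actinomycetales", "Actinomycetaceae", "Actinomyces", ""), 0.004),
    ("otu_akkermansia", ("Bacteria", "Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae", "Akkermansia", ""), 0.012),
    ("otu_bacteria_unclass", ("Bacteria", "", "", "", "", "", ""), 0.020),
]

# genera significantly depleted in the case group (and the matching OTU ids)
DEPLETED_CASE_GENERA = (
    "Streptococcus",
    "Veillonella",
    "Escherichia",
    "Clostridiaceae_unclass",
    "Actinomyces",
    "Parvimonas",
    "Bulleidia",
    "Peptoniphilus",
)
_DEPLETED_OTUS = (
    "otu_streptococcus",
    "otu_veillonella",
    "otu_escherichia",
    "otu_clostridiaceae",
    "otu_actinomyces",
    "otu_parvimonas",
    "otu_bulleidia",
    "otu_peptoniphilus",
)
_ENRICHED_OTUS = ("otu_bacteroides", "otu_prevotella", "otu_parabacteroides")

_TRIO = [
    ("otu_odoribacter", ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Odoribacteraceae", "Odoribacter", ""), 0.004),
    ("otu_butyricimonas", ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Odoribacteraceae", "Butyricimonas", ""), 0.003),
]


def default_asd_scenario(
    *,
    seed: int = 0,
    effect_fold: float = 4.0,
    include_reported_increases: bool = False,
    null: bool = False,
) -> CommunityScenario:
    """Unbalanced 35-case vs 6-control gut community scenario.

    The case group is enriched in Bacteroidetes (fold ``effect_fold`` on its
    member genera, raising the Bacteroidetes/Firmicutes ratio) and depleted
    (fold ``1/effect_fold``) in the eight genera of
    :data:`DEPLETED_CASE_GENERA`.

    ``include_reported_increases=True`` additionally plants case-group
    increases for Sutterella, Odoribacter and Butyricimonas, a trio whose
    enrichment in cases is often described without a significance level;
    they are optional so that the default truth table contains only effects
    with a definite planted status.  ``null=True`` removes all planted
    effects (both groups share the baseline composition).
    """
    community = list(_DEFAULT_COMMUNITY)
    if include_reported_increases:
        community = community + _TRIO
    taxa = [(tid, lin) for tid, lin, _ in community]
    props = np.array([p for _, _, p in community], dtype=float)
    props = props / props.sum()

    fold_changes: dict[str, float] = {}
    if not null:
        for tid in _ENRICHED_OTUS:
            fold_changes[tid] = effect_fold
        for tid in _DEPLETED_OTUS:
            fold_changes[tid] = 1.0 / effect_fold
        if include_reported_increases:
            fold_changes["otu_sutterella"] = effect_fold
            fold_changes["otu_odoribacter"] = effect_fold
            fold_changes["otu_butyricimonas"] = effect_fold

    return CommunityScenario(
        n_case=35,
        n_control=6,
        taxa=taxa,
        baseline_props=props,
        fold_changes=fold_changes,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# association scenario


@dataclasses.dataclass
class AssociationScenario:
    """Parameters of a sparse signed microbe-disease association list.

    ``planted_pairs`` entries are ``(disease_a, disease_b, n_shared,
    consistency)``: the two diseases share exactly ``n_shared`` microbes,
    of which a fraction ``consistency`` carry the same sign in both
    profiles (1.0 = perfectly consistent, 0.0 = perfectly reversed).
    Background associations are sampled independently at rate ``density``
    over all remaining (disease, microbe) cells.
    """

    n_diseases: int
    n_microbes: int
    density: float
    planted_pairs: Sequence[tuple[str, str, int, float]] = ()
    seed: int = 0
    disease_names: Sequence[str] | None = None
    microbe_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.disease_names is not None:
            self.disease_names = list(self.disease_names)
            self.n_diseases = len(self.disease_names)
        if self.microbe_names is not None:
            self.microbe_names = list(self.microbe_names)
            self.n_microbes = len(self.microbe_names)
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.density <= 1:
            raise ScenarioError("density must lie in [0, 1]")
        if self.n_diseases < 0 or self.n_microbes < 0:
            raise ScenarioError("n_diseases and n_microbes must be >= 0")
        names = set(self.diseases)
        for da, db, n_shared, consistency in self.planted_pairs:
            if n_shared > self.n_microbes:
                raise ScenarioError(
                    f"planted pair ({da}, {db}) asks for {n_shared} shared "
                    f"microbes but only {self.n_microbes} exist"
                )
            if not 0 <= consistency <= 1:
                raise ScenarioError("consistency must lie in [0, 1]")
            if da not in names or db not in names:
                raise ScenarioError(f"planted pair names unknown disease: {da}, {db}")
            if da == db:
                raise ScenarioError("planted pair must name two distinct diseases")

    @property
    def diseases(self) -> list[str]:
        if self.disease_names is not None:
            return list(self.disease_names)
        return [f"disease_{i:02d}" for i in range(self.n_diseases)]

    @property
    def microbes(self) -> list[str]:
        if self.microbe_names is not None:
            return list(self.microbe_names)
        return [f"microbe_{i:03d}" for i in range(self.n_microbes)]


@dataclasses.dataclass(frozen=True)
class SimulatedAssociation:
    disease: str
    microbe: str
    direction: str
    evidence: str


def simulate_associations(
    scenario: AssociationScenario,
) -> tuple[list[SimulatedAssociation], pd.DataFrame]:
    """Draw association records and the planted-pair truth table.

    Planted pairs are laid down first (shared microbes drawn without
    replacement from those not yet used by either disease; the consistent
    subset has size ``round(consistency * n_shared)``); background cells are
    then filled independently at rate ``density``.  Records are returned in
    deterministic (disease, microbe) order.

    The truth table carries one row per planted pair with its expected
    similarity sign: +1 when consistency > 1/2, -1 when < 1/2, else 0.
    """
    scenario.validate()
    diseases = scenario.diseases
    microbes = scenario.microbes
    signs: dict[tuple[str, str], int] = {}

    ss = np.random.SeedSequence(scenario.seed).spawn(2)
    rng_planted = np.random.default_rng(ss[0])
    rng_background = np.random.default_rng(ss[1])

    truth_rows = []
    for da, db, n_shared, consistency in scenario.planted_pairs:
        used = {m for d, m in signs if d in (da, db)}
        free = [m for m in microbes if m not in used]
        if len(free) < n_shared:
            raise ScenarioError(
                f"not enough unused microbes to plant ({da}, {db}): "
                f"{len(free)} free, {n_shared} needed"
            )
        shared = list(rng_planted.choice(free, size=n_shared, replace=False))
        sign_a = rng_planted.choice([-1, 1], size=n_shared)
        n_consistent = int(round(consistency * n_shared))
        agree = np.zeros(n_shared, dtype=bool)
        agree[rng_planted.permutation(n_shared)[:n_consistent]] = True
        for m, sa, ok in zip(shared, sign_a, agree):
            signs[(da, m)] = int(sa)
            signs[(db, m)] = int(sa) if ok else -int(sa)
        truth_rows.append(
            {
                "disease_a": da,
                "disease_b": db,
                "n_shared": n_shared,
                "consistency": consistency,
                "expected_sign": int(np.sign(2 * consistency - 1)),
            }
        )

    for d in diseases:
        for m in microbes:
            if (d, m) in signs:
                continue
            if rng_background.random() < scenario.density:
                signs[(d, m)] = int(rng_background.choice([-1, 1]))

    records = [
        SimulatedAssociation(
            disease=d,
            microbe=m,
            direction=INCREASE if signs[(d, m)] > 0 else DECREASE,
            evidence=f"sim:{i:05d}",
        )
        for i, (d, m) in enumerate(
            sorted(signs, key=lambda dm: (diseases.index(dm[0]), microbes.index(dm[1])))
        )
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=["disease_a", "disease_b", "n_shared", "consistency", "expected_sign"],
    )
    return records, truth


def write_associations(
    records: Sequence[SimulatedAssociation], path: str | Path
) -> None:
    """Write records in the 4-column association TSV dialect."""
    pd.DataFrame(
        [
            {
                "disease": r.disease,
                "microbe": r.microbe,
                "direction": r.direction,
                "evidence": r.evidence,
            }
            for r in records
        ],
        columns=["disease", "microbe", "direction", "evidence"],
    ).to_csv(path, sep="\t", index=False)
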