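"""End-to-end orchestration: simulate (or load) -> differential abundance ->
diversity -> functional groups -> signed profile -> disease network.

Every stage writes plain-text outputs into a run directory, and the run
closes with a ``manifest.json`` recording package/library versions, the
full configuration, and a SHA-256 digest of every output file.  Given the
same configuration and seeds the manifest is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import networkx
import numpy
import pandas
import scipy

from . import __version__
from .diffabund import differential_abundance, extract_signed_profile, rank_sum_test, write_results
from .diversity import (
    bray_curtis_matrix,
    pcoa,
    permutation_group_test,
    shannon_per_sample,
    write_distance_matrix,
)
from .funcgroups import compare_groups, default_group_map, group_proportions
from .hmdn import build_network, build_profiles, disease_neighbors, read_associations, write_network, write_profile
from .simulate import (
    AssociationScenario,
    CommunityScenario,
    default_asd_scenario,
    simulate_associations,
    simulate_counts,
    write_associations,
)
from .taxa import CASE, CONTROL, GroupDesign, bf_ratio, collapse_rank, read_taxa_table, to_relative, write_taxa_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one reproducible end-to-end run.

    Either simulation scenarios or input paths may be supplied; paths win
    when both are present.  All randomness flows from the scenario seeds
    and ``n_perm`` seeds recorded here.
    """

    outdir: str | Path = "run"
    seed: int = 0
    ranks: tuple[str, ...] = ("phylum", "genus")
    alpha: float = 0.05
    prevalence_min: float = 0.1
    n_perm: int = 999
    min_shared: int = 1
    disease_name: str = "ASD"
    scenario: CommunityScenario | None = None
    assoc_scenario: AssociationScenario | None = None
    counts_path: str | Path | None = None
    metadata_path: str | Path | None = None
    associations_path: str | Path | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 <= self.prevalence_min <= 1:
            raise ConfigError("prevalence_min must lie in [0, 1]")
        if self.n_perm < 99:
            raise ConfigError("n_perm must be >= 99")
        for rank in self.ranks:
            if rank not in ("kingdom", "phylum", "class", "order", "family", "genus", "species"):
                raise ConfigError(f"unknown rank {rank!r}")
        for path in (self.counts_path, self.metadata_path, self.associations_path):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")
        if (self.counts_path is None) != (self.metadata_path is None):
            raise ConfigError("counts_path and metadata_path must be given together")

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "ranks": list(self.ranks),
            "alpha": self.alpha,
            "prevalence_min": self.prevalence_min,
            "n_perm": self.n_perm,
            "min_shared": self.min_shared,
            "disease_name": self.disease_name,
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "assoc_scenario": dataclasses.asdict(self.assoc_scenario)
            if self.assoc_scenario
            else None,
            "counts_path": str(self.counts_path) if self.counts_path else None,
            "metadata_path": str(self.metadata_path) if self.metadata_path else None,
            "associations_path": str(self.associations_path)
            if self.associations_path
            else None,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_assoc_scenario(seed: int, microbe_names: list[str]) -> AssociationScenario:
    """Background disease ensemble whose microbe universe includes the
    community's genera, so the focal disease profile can share microbes."""
    diseases = [f"disease_{i:02d}" for i in range(12)]
    return AssociationScenario(
        n_diseases=len(diseases),
        n_microbes=0,
        density=0.12,
        planted_pairs=[
            (diseases[0], diseases[1], 5, 1.0),
            (diseases[2], diseases[3], 5, 0.0),
        ],
        seed=seed,
        disease_names=diseases,
        microbe_names=microbe_names,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    A stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "setup"

    def emit(name: str) -> Path:
        path = outdir / name
        outputs.append(path)
        return path

    try:
        stage = "simulate"
        if config.counts_path is not None:
            table = read_taxa_table(config.counts_path)
            design = GroupDesign.read_tsv(config.metadata_path)
        else:
            scenario = config.scenario or default_asd_scenario(seed=config.seed)
            table, design, truth = simulate_counts(scenario)
            write_taxa_table(table, emit("counts.tsv"))
            design.write_tsv(emit("metadata.tsv"))
            truth.to_csv(emit("truth_taxa.tsv"), sep="\t", index=False)

        stage = "diffabund"
        rel = to_relative(table)
        results_by_rank = {}
        for rank in config.ranks:
            results = differential_abundance(
                rel, design, rank, prevalence_min=config.prevalence_min
            )
            results_by_rank[rank] = results
            write_results(results, emit(f"diffabund_{rank}.tsv"))
        phylum_rel = collapse_rank(rel, "phylum")
        ratios, excluded = bf_ratio(phylum_rel)
        ratios.rename_axis("sample_id").to_frame().to_csv(emit("bf_ratio.tsv"), sep="\t")
        labels = design.for_samples(list(ratios.index))
        bf_p = rank_sum_test(
            ratios[labels == CASE].to_numpy(), ratios[labels == CONTROL].to_numpy()
        )
        emit("bf_test.json").write_text(
            json.dumps(
                {
                    "p_value": bf_p,
                    "mean_case": float(ratios[labels == CASE].mean()),
                    "mean_control": float(ratios[labels == CONTROL].mean()),
                    "excluded_samples": excluded,
                },
                indent=2,
                sort_keys=True,
            )
        )

        stage = "diversity"
        shannon_per_sample(rel).rename_axis("sample_id").to_frame().to_csv(
            emit("shannon.tsv"), sep="\t"
        )
        dm = bray_curtis_matrix(rel)
        write_distance_matrix(dm, emit("braycurtis.tsv"))
        ordination = pcoa(dm, k=2)
        ordination.coordinates.rename_axis("sample_id").to_csv(emit("pcoa.tsv"), sep="\t")
        perm = permutation_group_test(dm, design, n_perm=config.n_perm, seed=config.seed)
        emit("permutation_test.json").write_text(
            json.dumps(
                {
                    "pseudo_F": perm.statistic,
                    "p_value": perm.p_value,
                    "n_perm": perm.n_perm,
                },
                indent=2,
                sort_keys=True,
            )
        )

        stage = "funcgroups"
        genus_rel = collapse_rank(rel, "genus")
        gp = group_proportions(genus_rel, default_group_map())
        gp.rename_axis("sample_id").to_csv(emit("func_group_proportions.tsv"), sep="\t")
        compare_groups(gp, design).to_csv(emit("func_group_tests.tsv"), sep="\t", index=False)

        stage = "profile"
        genus_results = results_by_rank.get("genus") or differential_abundance(
            rel, design, "genus", prevalence_min=config.prevalence_min
        )
        focal = extract_signed_profile(
            genus_results, alpha=config.alpha, disease=config.disease_name
        )
        write_profile(focal, emit("asd_profile.tsv"))

        stage = "hmdn"
        if config.associations_path is not None:
            records = read_associations(config.associations_path)
        else:
            genus_names = [
                g for g in genus_rel.taxon_ids if g and not g.endswith("_unclass")
            ]
            assoc_scenario = config.assoc_scenario or _default_assoc_scenario(
                config.seed, genus_names
            )
            sim_records, assoc_truth = simulate_associations(assoc_scenario)
            write_associations(sim_records, emit("associations.tsv"))
            assoc_truth.to_csv(emit("truth_pairs.tsv"), sep="\t", index=False)
            records = read_associations(outdir / "associations.tsv")
        profiles = build_profiles(records)
        if len(focal) > 0:
            profiles = [p for p in profiles if p.disease != focal.disease] + [focal]
        universe = set().union(*(p.microbes for p in profiles))
        network = build_network(
            profiles,
            alpha=config.alpha,
            min_shared=config.min_shared,
            n_perm=config.n_perm,
            seed=config.seed,
            universe=universe,
            pinned=(config.disease_name,),
        )
        write_network(network, emit("network_edges.tsv"), fmt="tsv")
        write_network(network, emit("network.graphml"), fmt="graphml")
        neighbors = disease_neighbors(network, config.disease_name)
        pandas.DataFrame(neighbors, columns=["disease", "score"]).to_csv(
            emit("asd_neighbors.tsv"), sep="\t", index=False
        )

        stage = "manifest"
        manifest = {
            "microbenet_version": __version__,
            "library_versions": {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
                "networkx": networkx.__version__,
            },
            "config": config.to_dict(),
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    except (PipelineError, ConfigError):
        raise
    except Exception as exc:  # partial outputs stay on disk for inspection
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return outdir
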