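import math

import networkx as nx
import numpy as np
import pytest

from microbenet.hmdn import (
    AssociationError,
    AssociationRecord,
    SignedProfile,
    build_network,
    build_profiles,
    disease_neighbors,
    microbe_similarity,
    normalize_microbe_name,
    read_associations,
    read_network,
    read_profiles,
    similarity_pvalue,
    write_network,
    write_profile,
)
from microbenet.simulate import AssociationScenario, simulate_associations, write_associations


def profile(name, signs):
    return SignedProfile(disease=name, signs=signs)


class TestNormalization:
    @pytest.mark.parametrize(
        "raw", ["g__Veillonella", "Veillonella", " veillonella ", "Veillonella parvula"]
    )
    def test_variants_share_one_key(self, raw):
        assert normalize_microbe_name(raw) == "veillonella"

    def test_empty_name_rejected(self):
        with pytest.raises(AssociationError):
            normalize_microbe_name("g__")


class TestReadAssociations:
    def test_valid_file(self, tmp_path):
        path = tmp_path / "assoc.tsv"
        path.write_text(
            "disease\tmicrobe\tdirection\tevidence\n"
            "asthma\tg__Veillonella\tincrease\tPMID:1\n"
            "asthma\tPrevotella\tdecrease\t\n"
        )
        records = read_associations(path)
        assert records[0].sign == 1
        assert records[1].sign == -1
        assert records[0].microbe == "veillonella"

    def test_bad_direction_names_line(self, tmp_path):
        path = tmp_path / "assoc.tsv"
        path.write_text(
            "disease\tmicrobe\tdirection\tevidence\n"
            "asthma\tVeillonella\tincrease\t\n"
            "asthma\tPrevotella\televated\t\n"
        )
        with pytest.raises(AssociationError, match="line 3"):
            read_associations(path)

    def test_simulated_records_round_trip(self, tmp_path):
        scenario = AssociationScenario(n_diseases=5, n_microbes=20, density=0.3, seed=1)
        records, _ = simulate_associations(scenario)
        path = tmp_path / "assoc.tsv"
        write_associations(records, path)
        back = read_associations(path)
        assert len(back) == len(records)
        assert {(r.disease, r.microbe) for r in back} == {
            (r.disease, r.microbe) for r in records
        }


class TestBuildProfiles:
    def test_single_record(self):
        profiles = build_profiles(
            [AssociationRecord("d", "m", "increase")]
        )
        assert profiles[0].signs == {"m": 1}

    def test_majority_vote(self):
        records = [
            AssociationRecord("d", "m", "increase"),
            AssociationRecord("d", "m", "increase"),
            AssociationRecord("d", "m", "decrease"),
        ]
        assert build_profiles(records)[0].signs == {"m": 1}

    def test_exact_tie_drops_microbe(self, caplog):
        records = [
            AssociationRecord("d", "m", "increase"),
            AssociationRecord("d", "m", "decrease"),
            AssociationRecord("d", "other", "decrease"),
        ]
        with caplog.at_level("WARNING"):
            profiles = build_profiles(records)
        assert profiles[0].signs == {"other": -1}
        assert "tied" in caplog.text


class TestSimilarity:
    def test_identical_profiles_score_one(self):
        a = profile("a", {"m1": 1, "m2": -1})
        b = profile("b", {"m1": 1, "m2": -1})
        assert microbe_similarity(a, b) == pytest.approx(1.0)

    def test_reversed_profiles_score_minus_one(self):
        a = profile("a", {"m1": 1, "m2": -1})
        b = profile("b", {"m1": -1, "m2": 1})
        assert microbe_similarity(a, b) == pytest.approx(-1.0)

    def test_disjoint_profiles_score_zero(self):
        a = profile("a", {"m1": 1})
        b = profile("b", {"m2": 1})
        assert microbe_similarity(a, b) == 0.0

    def test_hand_evaluated_mixed_case(self):
        a = profile("a", {"m1": 1, "m2": -1, "m3": 1})
        b = profile("b", {"m1": 1, "m2": 1})
        assert microbe_similarity(a, b) == pytest.approx((1 - 1) / math.sqrt(6))

    def test_reversed_shared_microbe_contributes_negative(self):
        # a microbe decreased in one disease but increased in another pulls
        # their similarity down
        asd = profile("ASD", {"veillonella": -1, "streptococcus": -1})
        t1d = profile("T1D", {"veillonella": 1})
        assert microbe_similarity(asd, t1d) == pytest.approx(-1 / math.sqrt(2))

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(0)
        microbes = [f"m{i}" for i in range(30)]
        for _ in range(100):
            a = profile("a", {m: int(s) for m, s in zip(
                rng.choice(microbes, size=rng.integers(1, 15), replace=False),
                rng.choice([-1, 1], size=14))})
            b = profile("b", {m: int(s) for m, s in zip(
                rng.choice(microbes, size=rng.integers(1, 15), replace=False),
                rng.choice([-1, 1], size=14))})
            s = microbe_similarity(a, b)
            assert abs(s) <= 1 + 1e-12
            assert s == pytest.approx(microbe_similarity(b, a))

    def test_empty_profile_rejected(self):
        with pytest.raises(AssociationError):
            microbe_similarity(profile("a", {}), profile("b", {"m": 1}))


class TestSimilarityPvalue:
    UNIVERSE = [f"m{i}" for i in range(50)]

    def test_minimum_attainable_p(self):
        a = profile("a", {f"m{i}": 1 for i in range(10)})
        b = profile("b", {f"m{i}": 1 for i in range(10)})
        p = similarity_pvalue(a, b, self.UNIVERSE, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_symmetric_in_profile_order(self):
        rng = np.random.default_rng(1)
        a = profile("alpha", {m: 1 for m in rng.choice(self.UNIVERSE, 8, replace=False)})
        b = profile("beta", {m: -1 for m in rng.choice(self.UNIVERSE, 6, replace=False)})
        pa = similarity_pvalue(a, b, self.UNIVERSE, n_perm=199, seed=5)
        pb = similarity_pvalue(b, a, self.UNIVERSE, n_perm=199, seed=5)
        assert pa == pb

    def test_universe_must_cover_profiles(self):
        a = profile("a", {"zzz": 1})
        b = profile("b", {"m0": 1})
        with pytest.raises(AssociationError, match="universe"):
            similarity_pvalue(a, b, self.UNIVERSE, n_perm=99)

    def test_adding_unshared_microbe_keeps_score(self):
        a = profile("a", {"m0": 1, "m1": -1})
        b = profile("b", {"m0": 1, "m2": 1})
        s_before = microbe_similarity(a, b)
        bigger = self.UNIVERSE + ["extra"]
        # score independent of the universe; p changes only through the null
        assert microbe_similarity(a, b) == s_before
        p = similarity_pvalue(a, b, bigger, n_perm=199, seed=2)
        assert 0 < p <= 1


class TestBuildNetwork:
    def test_no_shared_microbes_gives_edgeless_network(self):
        profiles = [
            profile("a", {"m1": 1}),
            profile("b", {"m2": 1}),
            profile("c", {"m3": -1}),
        ]
        net = build_network(profiles, n_perm=99, universe=[f"m{i}" for i in range(20)])
        assert net.number_of_edges() == 0

    def test_planted_pairs_recovered_with_correct_signs(self):
        scenario = AssociationScenario(
            n_diseases=8,
            n_microbes=60,
            density=0.05,
            planted_pairs=[
                ("disease_00", "disease_01", 5, 1.0),
                ("disease_02", "disease_03", 5, 0.0),
            ],
            seed=7,
        )
        records, truth = simulate_associations(scenario)
        net = build_network(build_profiles(records), n_perm=999, seed=7)
        assert net.has_edge("disease_00", "disease_01")
        assert net["disease_00"]["disease_01"]["sign"] == "positive"
        assert net.has_edge("disease_02", "disease_03")
        assert net["disease_02"]["disease_03"]["sign"] == "negative"

    def test_edge_sign_matches_score_sign_and_p_below_alpha(self):
        scenario = AssociationScenario(
            n_diseases=6, n_microbes=40, density=0.2, seed=3,
            planted_pairs=[("disease_00", "disease_01", 6, 1.0)],
        )
        records, _ = simulate_associations(scenario)
        net = build_network(build_profiles(records), alpha=0.05, n_perm=199, seed=1)
        for _, _, data in net.edges(data=True):
            assert data["p"] < 0.05
            expected = "positive" if data["score"] > 0 else "negative"
            assert data["sign"] == expected

    def test_pinned_disease_kept_when_isolated(self):
        profiles = [profile("a", {"m1": 1}), profile("b", {"m2": 1})]
        net = build_network(profiles, n_perm=99, pinned=("ASD",))
        assert "ASD" in net
        assert disease_neighbors(net, "ASD") == []


class TestNeighbors:
    def _star(self):
        net = nx.Graph()
        net.add_edge("ASD", "periodontitis", score=0.9, shared=4, p=0.001, sign="positive")
        net.add_edge("ASD", "type 1 diabetes", score=-0.4, shared=2, p=0.01, sign="negative")
        return net

    def test_ranked_by_absolute_score_with_sign_kept(self):
        ranked = disease_neighbors(self._star(), "ASD")
        assert ranked == [("periodontitis", 0.9), ("type 1 diabetes", -0.4)]

    def test_unknown_disease_rejected(self):
        with pytest.raises(AssociationError):
            disease_neighbors(self._star(), "missing")

    def test_consistent_and_reversed_profiles_rank_as_expected(self):
        # a disease sharing the focal profile's signs scores positive;
        # one with reversed signs scores negative
        focal = profile("ASD", {"veillonella": -1, "streptococcus": -1, "bacteroides": 1})
        periodontitis = profile(
            "periodontitis", {"veillonella": -1, "streptococcus": -1, "bacteroides": 1}
        )
        t1d = profile("type 1 diabetes", {"veillonella": 1, "streptococcus": 1})
        universe = [f"m{i}" for i in range(40)] + ["veillonella", "streptococcus", "bacteroides"]
        net = build_network(
            [focal, periodontitis, t1d], n_perm=999, seed=0, universe=universe
        )
        neighbors = dict(disease_neighbors(net, "ASD"))
        assert neighbors["periodontitis"] > 0
        assert neighbors["type 1 diabetes"] < 0


class TestNetworkIO:
    def _network(self):
        net = nx.Graph()
        net.add_edge("a", "b", score=0.5, shared=3, p=0.01, sign="positive")
        net.add_edge("b", "c", score=-0.25, shared=2, p=0.04, sign="negative")
        net.add_edge("a", "c", score=1.0, shared=4, p=0.001, sign="positive")
        return net

    def test_tsv_round_trip(self, tmp_path):
        net = self._network()
        path = tmp_path / "edges.tsv"
        write_network(net, path, fmt="tsv")
        header = path.read_text().splitlines()[0]
        assert header == "disease_a\tdisease_b\tscore\tshared\tp\tsign"
        back = read_network(path, fmt="tsv")
        assert set(back.edges) == set(net.edges)
        for a, b in net.edges:
            assert back[a][b]["score"] == pytest.approx(net[a][b]["score"])
            assert back[a][b]["sign"] == net[a][b]["sign"]

    def test_graphml_round_trip(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.graphml"
        write_network(net, path, fmt="graphml")
        back = read_network(path, fmt="graphml")
        assert set(back.edges) == set(net.edges)

    def test_empty_network_writes_header_only(self, tmp_path):
        path = tmp_path / "edges.tsv"
        write_network(nx.Graph(), path, fmt="tsv")
        assert path.read_text().strip() == "disease_a\tdisease_b\tscore\tshared\tp\tsign"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(AssociationError):
            write_network(nx.Graph(), tmp_path / "x", fmt="dot")

    def test_profile_round_trip(self, tmp_path):
        prof = profile("ASD", {"veillonella": -1, "bacteroides": 1})
        path = tmp_path / "profile.tsv"
        write_profile(prof, path)
        back = read_profiles(path)
        assert len(back) == 1
        assert back[0].disease == "ASD"
        assert back[0].signs == prof.signs
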