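"""Correlation screen, interaction rules, niche embedding, network IO."""

import numpy as np
import pandas as pd
import pytest

from adcomm.fba import ExchangeMatrix
from adcomm.interactions import (correlate_abundances, embed_niches,
                                 infer_competition, infer_mutualism,
                                 read_network, screen_pairs, write_network,
                                 InteractionEdge)
from adcomm.model import AnalysisConfig


def exchange_from(imports=None, exports=None) -> ExchangeMatrix:
    return ExchangeMatrix(imports=dict(imports or {}), exports=dict(exports or {}))


def corr_frames(pairs):
    """Build symmetric r/p frames from {(a, b): (r, p)}."""
    species = sorted({s for pair in pairs for s in pair})
    r = pd.DataFrame(np.eye(len(species)), index=species, columns=species)
    p = pd.DataFrame(np.zeros((len(species), len(species))), index=species,
                     columns=species)
    for (a, b), (rv, pv) in pairs.items():
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    return r, p


class TestCorrelateAbundances:
    def test_perfect_linear_dependence(self):
        ab = pd.DataFrame({"A": [0.1, 0.2, 0.3, 0.4],
                           "B": [0.2, 0.4, 0.6, 0.8]})
        r, p = correlate_abundances(ab)
        assert r.loc["A", "B"] == pytest.approx(1.0)
        assert p.loc["A", "B"] < 1e-6

    def test_perfect_anticorrelation(self):
        ab = pd.DataFrame({"A": [0.1, 0.2, 0.3], "B": [0.5, 0.4, 0.3]})
        r, _ = correlate_abundances(ab)
        assert r.loc["A", "B"] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(42)
        ab = pd.DataFrame(rng.random((30, 20)),
                          columns=[f"sp{i:02d}" for i in range(20)])
        r, p = correlate_abundances(ab)
        x = ab.to_numpy()
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc
        denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        expected = cov / denom
        assert np.max(np.abs(r.to_numpy() - expected)) < 1e-12
        # spot-check p against scipy's exact computation
        from scipy import stats

        r_sp, p_sp = stats.pearsonr(ab["sp00"], ab["sp01"])
        assert p.loc["sp00", "sp01"] == pytest.approx(p_sp, rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlate_abundances(pd.DataFrame({"A": [1.0, 2.0], "B": [2.0, 1.0]}))

    def test_zero_variance_species_excluded(self):
        ab = pd.DataFrame({"A": [0.1, 0.2, 0.3], "B": [0.5, 0.5, 0.5]})
        r, _ = correlate_abundances(ab)
        assert "B" not in r.columns


class TestScreenPairs:
    def test_r_below_065_excluded_despite_tiny_p(self):
        r, p = corr_frames({("A", "B"): (0.64, 1e-6)})
        pos, neg = screen_pairs(r, p)
        assert pos == [] and neg == []

    def test_p_above_threshold_excluded_despite_strong_r(self):
        r, p = corr_frames({("A", "B"): (0.9, 0.002)})
        pos, neg = screen_pairs(r, p)
        assert pos == [] and neg == []

    def test_boundary_r_exactly_065_kept(self):
        r, p = corr_frames({("A", "B"): (0.65, 1e-6)})
        pos, neg = screen_pairs(r, p)
        assert pos == [("A", "B")]

    def test_negative_pair_partitioned(self):
        r, p = corr_frames({("A", "B"): (-0.8, 1e-5)})
        pos, neg = screen_pairs(r, p)
        assert neg == [("A", "B")] and pos == []

    def test_ordering_invariance(self):
        pairs = {("A", "B"): (0.9, 1e-6), ("C", "D"): (-0.7, 1e-5)}
        r, p = corr_frames(pairs)
        shuffled = list(reversed(r.columns))
        pos1, neg1 = screen_pairs(r, p)
        pos2, neg2 = screen_pairs(r.loc[shuffled, shuffled], p.loc[shuffled, shuffled])
        assert set(pos1) == set(pos2) and set(neg1) == set(neg2)


class TestCompetitionRule:
    def test_shared_import_above_threshold_creates_edge(self):
        r, p = corr_frames({("A", "B"): (-0.8, 1e-5)})
        ex = {"s1": exchange_from(imports={("A", "glc"): 0.02, ("B", "glc"): 0.02})}
        edges = infer_competition([("A", "B")], ex, r, p)
        assert len(edges) == 1
        assert edges[0].compounds[0][0] == "glc"
        assert edges[0].r == pytest.approx(-0.8)

    def test_import_below_threshold_no_edge(self):
        r, p = corr_frames({("A", "B"): (-0.8, 1e-5)})
        ex = {"s1": exchange_from(imports={("A", "glc"): 0.009, ("B", "glc"): 0.009})}
        assert infer_competition([("A", "B")], ex, r, p) == []

    def test_threshold_is_strict(self):
        r, p = corr_frames({("A", "B"): (-0.8, 1e-5)})
        ex = {"s1": exchange_from(imports={("A", "glc"): 0.01, ("B", "glc"): 0.01})}
        assert infer_competition([("A", "B")], ex, r, p) == []

    def test_min_samples_aggregation(self):
        r, p = corr_frames({("A", "B"): (-0.8, 1e-5)})
        hit = exchange_from(imports={("A", "glc"): 0.02, ("B", "glc"): 0.02})
        miss = exchange_from(imports={("A", "glc"): 0.02})
        ex = {"s1": hit, "s2": miss, "s3": miss}
        assert len(infer_competition([("A", "B")], ex, r, p)) == 1
        strict = AnalysisConfig(min_samples=2)
        assert infer_competition([("A", "B")], ex, r, p, strict) == []

    def test_water_never_counts_as_shared_resource(self):
        r, p = corr_frames({("A", "B"): (-0.8, 1e-5)})
        ex = {"s1": exchange_from(imports={("A", "h2o"): 5.0, ("B", "h2o"): 5.0})}
        assert infer_competition([("A", "B")], ex, r, p) == []


class TestMutualismRule:
    def test_export_feeding_import_creates_edge(self):
        r, p = corr_frames({("A", "B"): (0.8, 1e-5)})
        ex = {"s1": exchange_from(exports={("A", "ac"): 0.5},
                                  imports={("B", "ac"): 0.3})}
        edges = infer_mutualism([("A", "B")], ex, r, p)
        assert len(edges) == 1
        cpd, fe, fi, direction = edges[0].compounds[0]
        assert (cpd, direction) == ("ac", "a->b")
        assert (fe, fi) == (0.5, 0.3)

    def test_positive_pair_without_flux_match_rejected(self):
        """A correlated pair with no export->import route stays a
        co-occurrence — this is how screened pairs outnumber edges."""
        r, p = corr_frames({("A", "B"): (0.9, 1e-6)})
        ex = {"s1": exchange_from(exports={("A", "ac"): 0.5},
                                  imports={("B", "glc"): 0.3})}
        assert infer_mutualism([("A", "B")], ex, r, p) == []

    def test_either_direction_counts(self):
        r, p = corr_frames({("A", "B"): (0.8, 1e-5)})
        ex = {"s1": exchange_from(exports={("B", "h2"): 0.4},
                                  imports={("A", "h2"): 0.2})}
        edges = infer_mutualism([("A", "B")], ex, r, p)
        assert edges[0].compounds[0][3] == "b->a"

    def test_edge_counts_bounded_by_screened_pairs(self):
        r, p = corr_frames({("A", "B"): (0.8, 1e-5), ("C", "D"): (0.9, 1e-6)})
        ex = {"s1": exchange_from(exports={("A", "ac"): 0.5},
                                  imports={("B", "ac"): 0.3})}
        pos = [("A", "B"), ("C", "D")]
        edges = infer_mutualism(pos, ex, r, p)
        assert len(edges) <= len(pos)


class TestNicheEmbedding:
    def _exchanges(self, n_samples=30, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for j in range(n_samples):
            imports = {}
            for i in range(6):  # guild 1: sugar eaters
                imports[(f"sug{i}", "glc")] = 1.0 + 0.1 * rng.random()
            for i in range(6):  # guild 2: acetate eaters
                imports[(f"acet{i}", "ac")] = 1.0 + 0.1 * rng.random()
            out[f"s{j:02d}"] = exchange_from(imports=imports)
        return out

    def test_fixed_seed_reproducible(self):
        ex = self._exchanges()
        config = AnalysisConfig(rng_seed=7, tsne_perplexity=10)
        m1 = embed_niches(ex, config)
        m2 = embed_niches(ex, config)
        assert m1.coordinates == m2.coordinates

    def test_guilds_separate(self):
        from sklearn.metrics import silhouette_score

        ex = self._exchanges()
        nm = embed_niches(ex, AnalysisConfig(rng_seed=7, tsne_perplexity=40))
        keys = sorted(nm.coordinates)
        X = np.array([nm.coordinates[k] for k in keys])
        labels = [k[0][:3] for k in keys]
        assert silhouette_score(X, labels) > 0.5

    def test_identical_import_vectors_land_together(self):
        ex = {f"s{j}": exchange_from(imports={("A", "glc"): 1.0, ("B", "glc"): 1.0,
                                              ("C", "ac"): 1.0})
              for j in range(5)}
        nm = embed_niches(ex, AnalysisConfig(rng_seed=1, tsne_perplexity=3))
        a = np.array([xy for (s, _), xy in sorted(nm.coordinates.items()) if s == "A"])
        b = np.array([xy for (s, _), xy in sorted(nm.coordinates.items()) if s == "B"])
        c = np.array([xy for (s, _), xy in sorted(nm.coordinates.items()) if s == "C"])
        ab = np.linalg.norm(a.mean(0) - b.mean(0))
        ac = np.linalg.norm(a.mean(0) - c.mean(0))
        assert ab < ac

    def test_too_few_points_suggests_lower_perplexity(self):
        ex = {"s1": exchange_from(imports={("A", "glc"): 1.0})}
        with pytest.raises(ValueError, match="perplexity"):
            embed_niches(ex, AnalysisConfig(tsne_perplexity=30))


class TestNetworkIO:
    EDGES = [
        InteractionEdge("A", "B", "mutualism", 0.8, 1e-5,
                        [("ac", 0.5, 0.3, "a->b")]),
        InteractionEdge("B", "C", "competition", -0.7, 1e-4,
                        [("glc", 0.2, 0.2, "shared")]),
        InteractionEdge("A", "C", "mutualism", 0.9, 1e-6,
                        [("h2", 1.0, 0.5, "a->b")]),
    ]

    @pytest.mark.parametrize("fmt,suffix", [("graphml", ".graphml"),
                                            ("edge-tsv", ".tsv")])
    def test_round_trip(self, tmp_path, fmt, suffix):
        path = tmp_path / f"net{suffix}"
        write_network(self.EDGES, path, fmt)
        back = read_network(path, fmt)
        original = {(e.species_a, e.species_b, e.type) for e in self.EDGES}
        assert {(e.species_a, e.species_b, e.type) for e in back} == original

    def test_empty_network_is_valid(self, tmp_path):
        path = tmp_path / "empty.graphml"
        write_network([], path, "graphml")
        assert read_network(path, "graphml") == []

    def test_node_count_equals_participating_species(self, tmp_path):
        import networkx as nx

        path = tmp_path / "net.graphml"
        write_network(self.EDGES, path, "graphml")
        g = nx.read_graphml(path)
        participating = {s for e in self.EDGES for s in (e.species_a, e.species_b)}
        assert set(g.nodes) == participating
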