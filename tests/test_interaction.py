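"""Interaction matrix, correlation layers, database votes and filtering."""

import numpy as np
import pandas as pd
import pytest

from mirtempo.data_ingest import TimeCourseDE, map_ids
from mirtempo.interaction import (
    InteractionError,
    InteractionMatrix,
    apply_db_flags,
    cluster_network_genes,
    filter_interactions,
    gene_trends,
    pair_correlations,
    pathway_mrnas,
)
from mirtempo.pathway_resources import Pathway, PathwaySet, TargetDB


def _de_from(trajs: dict, gene_types: dict, tps=("D1", "D2", "D3")):
    rows = []
    for g, vec in trajs.items():
        for tp, v in zip(tps, vec):
            rows.append({"gene": g, "gene_type": gene_types[g], "time_point": tp,
                         "log2fc": float(v), "padj": 0.01})
    return TimeCourseDE(pd.DataFrame(rows), tuple(tps))


def _matrix(corrs: dict, mirnas, mrnas):
    corr = pd.DataFrame(index=mirnas, columns=mrnas, dtype=float)
    for (m, g), c in corrs.items():
        corr.loc[m, g] = c
    return InteractionMatrix(corr=corr, method="pearson")


def _with_votes(mat, votes: dict):
    v = pd.DataFrame(0, index=mat.corr.index, columns=mat.corr.columns, dtype=int)
    for (m, g), n in votes.items():
        v.loc[m, g] = n
    return InteractionMatrix(corr=mat.corr, method=mat.method, flags={"targetscan": v.clip(0, 1)},
                             votes=v, selected=("targetscan",))


class TestPathwayMrnas:
    def _setup(self, tmp_path):
        trajs = {"Plau": (1, 2, 3), "Igf1": (0, 1, 0), "Gapdh": (2, 2, 1), "miR-a": (1, 0, 1)}
        types = {"Plau": "mRNA", "Igf1": "mRNA", "Gapdh": "mRNA", "miR-a": "miRNA"}
        de = _de_from(trajs, types)
        p = tmp_path / "map.tsv"
        with open(p, "w") as fh:
            fh.write("input_label\tentrez\tensembl\n")
            for i, g in enumerate(["Plau", "Igf1", "Gapdh", "miR-a"]):
                fh.write(f"{g}\t{100 + i}\tENS{i}\n")
        ids = map_ids(de, p)
        pathways = PathwaySet(
            (Pathway("WP1", "fibrosis", frozenset({"100", "101", "999"})),), "entrez"
        )
        return de, ids, pathways

    def test_intersection_sorted(self, tmp_path):
        de, ids, pathways = self._setup(tmp_path)
        assert pathway_mrnas("WP1", pathways, de, ids) == ["Igf1", "Plau"]

    def test_unknown_pathway_rejected(self, tmp_path):
        de, ids, pathways = self._setup(tmp_path)
        with pytest.raises(InteractionError, match="unknown pathway"):
            pathway_mrnas("WP404", pathways, de, ids)

    def test_empty_intersection_is_hard_error(self, tmp_path):
        de, ids, _ = self._setup(tmp_path)
        pathways = PathwaySet((Pathway("WP2", "x", frozenset({"777"})),), "entrez")
        with pytest.raises(InteractionError, match="another pathway"):
            pathway_mrnas("WP2", pathways, de, ids)


class TestPairCorrelations:
    types = {"m1": "miRNA", "g1": "mRNA", "g2": "mRNA"}

    def test_perfect_anticorrelation_pearson(self):
        de = _de_from({"m1": (1, 2, 3), "g1": (-1, -2, -3), "g2": (1, 1, 2)}, self.types)
        mat = pair_correlations(de, ["m1"], ["g1", "g2"])
        assert mat.corr.loc["m1", "g1"] == pytest.approx(-1.0)

    def test_kendall_tau_on_three_points(self):
        # pairs of (1,2,3) vs (3,1,2): 1 concordant, 2 discordant -> -1/3
        de = _de_from({"m1": (1, 2, 3), "g1": (3, 1, 2), "g2": (0, 1, 0)}, self.types)
        mat = pair_correlations(de, ["m1"], ["g1", "g2"], method="kendall")
        assert mat.corr.loc["m1", "g1"] == pytest.approx(-1 / 3)

    def test_spearman_monotone_is_one(self):
        de = _de_from(
            {"m1": (1, 2, 3, 4), "g1": (1, 4, 9, 16), "g2": (0, 1, 0, 1)},
            self.types, tps=("D1", "D2", "D3", "D4"),
        )
        mat = pair_correlations(de, ["m1"], ["g1", "g2"], method="spearman")
        assert mat.corr.loc["m1", "g1"] == pytest.approx(1.0)

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=6), rng.normal(size=6)
        de = _de_from({"m1": x, "g1": y, "g2": rng.normal(size=6)}, self.types,
                      tps=tuple(f"T{i}" for i in range(6)))
        sp = pair_correlations(de, ["m1"], ["g1", "g2"], method="spearman")
        from scipy.stats import rankdata, pearsonr

        assert sp.corr.loc["m1", "g1"] == pytest.approx(
            pearsonr(rankdata(x), rankdata(y))[0]
        )

    def test_all_methods_bounded(self):
        rng = np.random.default_rng(3)
        de = _de_from(
            {"m1": rng.normal(size=5), "g1": rng.normal(size=5), "g2": rng.normal(size=5)},
            self.types, tps=tuple(f"T{i}" for i in range(5)),
        )
        for method in ("pearson", "spearman", "kendall"):
            mat = pair_correlations(de, ["m1"], ["g1", "g2"], method=method)
            assert (mat.corr.abs() <= 1 + 1e-9).all().all()

    def test_zero_variance_marked_unavailable(self):
        de = _de_from({"m1": (1, 2, 3), "g1": (2, 2, 2), "g2": (1, 0, 1)}, self.types)
        mat = pair_correlations(de, ["m1"], ["g1", "g2"])
        assert pd.isna(mat.corr.loc["m1", "g1"])

    def test_fewer_than_three_time_points_is_error(self):
        de = _de_from({"m1": (1, 2), "g1": (2, 1), "g2": (0, 1)}, self.types, tps=("D1", "D2"))
        with pytest.raises(InteractionError, match="3 time points"):
            pair_correlations(de, ["m1"], ["g1"])


class TestApplyDbFlags:
    def _mat(self):
        return _matrix({("mA", "G1"): -0.9, ("mA", "G2"): -0.2}, ["mA"], ["G1", "G2"])

    def _dbs(self):
        return [
            TargetDB("targetscan", "predictive", frozenset({("mA", "G1")})),
            TargetDB("mirdb", "predictive", frozenset()),
            TargetDB("mirtarbase", "functional", frozenset({("mA", "G1")})),
        ]

    def test_flags_and_votes(self):
        mat = apply_db_flags(self._mat(), self._dbs())
        assert mat.votes.loc["mA", "G1"] == 2
        assert [mat.flags[n].loc["mA", "G1"] for n in ("targetscan", "mirdb", "mirtarbase")] == [1, 0, 1]

    def test_selection_restricts_votes(self):
        mat = apply_db_flags(self._mat(), self._dbs(), selected=["mirdb"])
        assert int(mat.votes.loc["mA", "G1"]) == 0
        assert mat.flags["targetscan"].loc["mA", "G1"] == 1  # flag still recorded

    def test_empty_database_all_zero(self):
        dbs = [TargetDB("mirdb", "predictive", frozenset())]
        mat = apply_db_flags(self._mat(), dbs)
        assert (mat.votes.to_numpy() == 0).all()

    def test_unloaded_selection_rejected(self):
        with pytest.raises(InteractionError):
            apply_db_flags(self._mat(), self._dbs(), selected=["starbase"])


def brute_force_filter(mat, max_corr, min_dbs):
    kept = set()
    for m in mat.mirnas:
        for g in mat.mrnas:
            c = mat.corr.loc[m, g]
            if pd.notna(c) and c <= max_corr and int(mat.votes.loc[m, g]) >= min_dbs:
                kept.add((m, g))
    return kept


class TestFilterInteractions:
    def _mat(self):
        mat = _matrix(
            {("mA", "G1"): -0.9, ("mA", "G2"): -0.4, ("mB", "G1"): -0.8,
             ("mB", "G2"): -0.5, ("mC", "G1"): 0.3, ("mC", "G2"): np.nan},
            ["mA", "mB", "mC"], ["G1", "G2"],
        )
        return _with_votes(mat, {("mA", "G1"): 2, ("mA", "G2"): 3, ("mB", "G1"): 0,
                                 ("mB", "G2"): 1, ("mC", "G1"): 1, ("mC", "G2"): 2})

    def test_defaults_keep_expected_single_edge_pattern(self):
        # (-0.9, votes 2) kept; (-0.4, votes 3) fails corr; (-0.8, votes 0) fails votes
        net = filter_interactions(self._mat())
        assert ("mA", "G1") in net.edge_set()
        assert ("mA", "G2") not in net.edge_set() and ("mB", "G1") not in net.edge_set()

    def test_boundary_corr_exactly_default_is_kept(self):
        net = filter_interactions(self._mat())
        assert ("mB", "G2") in net.edge_set()

    def test_vacuous_filter_keeps_all_available(self):
        net = filter_interactions(self._mat(), max_corr=1.0, min_dbs=0)
        assert net.edge_set() == {("mA", "G1"), ("mA", "G2"), ("mB", "G1"),
                                  ("mB", "G2"), ("mC", "G1")}

    def test_nan_corr_never_passes(self):
        net = filter_interactions(self._mat(), max_corr=1.0, min_dbs=0)
        assert ("mC", "G2") not in net.edge_set()

    def test_matches_brute_force_scan(self):
        mat = self._mat()
        for max_corr in (-0.9, -0.5, 0.0, 1.0):
            for min_dbs in (0, 1, 2, 3):
                net = filter_interactions(mat, max_corr, min_dbs)
                assert net.edge_set() == brute_force_filter(mat, max_corr, min_dbs)

    def test_anti_monotone_in_both_thresholds(self):
        mat = self._mat()
        base = filter_interactions(mat, -0.4, 1).edge_set()
        assert filter_interactions(mat, -0.6, 1).edge_set() <= base
        assert filter_interactions(mat, -0.4, 2).edge_set() <= base

    def test_network_is_bipartite(self):
        import networkx as nx

        net = filter_interactions(self._mat(), max_corr=1.0, min_dbs=0)
        assert nx.is_bipartite(net.graph)
        for u, v in net.graph.edges:
            assert net.graph.nodes[u]["type"] != net.graph.nodes[v]["type"]

    def test_unflagged_matrix_rejected(self):
        mat = _matrix({("mA", "G1"): -0.9}, ["mA"], ["G1"])
        with pytest.raises(InteractionError):
            filter_interactions(mat)


class TestGeneTrends:
    def _net(self):
        mat = _with_votes(_matrix({("mA", "G1"): -0.9}, ["mA"], ["G1"]),
                          {("mA", "G1"): 1})
        return filter_interactions(mat)

    def test_threshold_crossing_highlighted(self, tmp_path):
        de = _de_from({"G1": (0.2, 1.6, 0.4), "mA": (0.1, 0.2, 0.1)},
                      {"G1": "mRNA", "mA": "miRNA"})
        tab = gene_trends(de, self._net(), highlight_threshold=1.5, out=tmp_path / "t.png")
        assert bool(tab.set_index("gene").loc["G1", "highlighted"])
        assert not bool(tab.set_index("gene").loc["mA", "highlighted"])
        assert (tmp_path / "t.png").exists()

    def test_all_below_threshold_not_highlighted(self):
        de = _de_from({"G1": (0.2, 0.3, 0.4), "mA": (0.1, 0.2, 0.1)},
                      {"G1": "mRNA", "mA": "miRNA"})
        tab = gene_trends(de, self._net(), highlight_threshold=1.5)
        assert not tab["highlighted"].any()

    def test_non_finite_threshold_rejected(self):
        de = _de_from({"G1": (0.2, 0.3, 0.4), "mA": (0.1, 0.2, 0.1)},
                      {"G1": "mRNA", "mA": "miRNA"})
        with pytest.raises(InteractionError):
            gene_trends(de, self._net(), highlight_threshold=float("nan"))


class TestClusterNetworkGenes:
    def _net(self, pairs):
        corrs = {p: -0.9 for p in pairs}
        mirnas = sorted({m for m, _ in pairs})
        mrnas = sorted({g for _, g in pairs})
        mat = _with_votes(_matrix(corrs, mirnas, mrnas), {p: 1 for p in pairs})
        return filter_interactions(mat)

    def test_identical_trajectories_merge_first(self):
        de = _de_from(
            {"mA": (1, 2, 3), "G1": (5, 1, 5), "G2": (5, 1, 5)},
            {"mA": "miRNA", "G1": "mRNA", "G2": "mRNA"},
        )
        net = self._net([("mA", "G1"), ("mA", "G2")])
        res = cluster_network_genes(de, net, k=2)
        # the two identical mRNA trajectories share a cluster
        assert res["labels"]["G1"] == res["labels"]["G2"]
        assert res["linkage"][0, 2] == pytest.approx(0.0)

    def test_planted_two_shapes_recovered(self, tmp_path):
        rng = np.random.default_rng(4)
        trajs, types = {}, {}
        for i in range(3):
            trajs[f"up{i}"] = np.array([0, 1, 2, 3, 4]) + rng.normal(0, 0.05, 5)
            trajs[f"dn{i}"] = np.array([4, 3, 2, 1, 0]) + rng.normal(0, 0.05, 5)
            types[f"up{i}"] = types[f"dn{i}"] = "mRNA"
        trajs["mA"] = np.array([1, 0, 1, 0, 1.0])
        types["mA"] = "miRNA"
        de = _de_from(trajs, types, tps=tuple(f"T{i}" for i in range(5)))
        net = self._net([("mA", g) for g in trajs if g != "mA"])
        res = cluster_network_genes(de, net, k=3, out_prefix=str(tmp_path / "cl"))
        ups = {res["labels"][f"up{i}"] for i in range(3)}
        dns = {res["labels"][f"dn{i}"] for i in range(3)}
        assert len(ups) == 1 and len(dns) == 1 and ups != dns
        assert (tmp_path / "cl_heatmap.png").exists()

    def test_k_equal_genes_gives_singletons(self):
        de = _de_from(
            {"mA": (1, 2, 3), "G1": (5, 1, 5), "G2": (1, 5, 1)},
            {"mA": "miRNA", "G1": "mRNA", "G2": "mRNA"},
        )
        net = self._net([("mA", "G1"), ("mA", "G2")])
        res = cluster_network_genes(de, net, k=3)
        assert len(set(res["labels"].values())) == 3

    def test_k_above_genes_rejected(self):
        de = _de_from({"mA": (1, 2, 3), "G1": (5, 1, 5)}, {"mA": "miRNA", "G1": "mRNA"})
        net = self._net([("mA", "G1")])
        with pytest.raises(InteractionError):
            cluster_network_genes(de, net, k=5)
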