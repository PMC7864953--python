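"""Formation-kinetics engine: detection, Z-scoring, correlation network,
Louvain communities, toxicity association, Venn and export."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cdtox.kinetics_net import (
    KineticsMatrix,
    PeakTable,
    ProductNetwork,
    associate_toxicity,
    build_kinetics,
    community_toxicity,
    correlation_network,
    detect_products,
    export_network,
    louvain_communities,
    pearson_r_p,
    read_network,
    toxicity_vectors,
    venn_summary,
    zscore,
)

TPS = {"i0.5": 0.5, "i1": 1.0, "i4": 4.0, "i8": 8.0}


def _peak_table(rows):
    df = pd.DataFrame(rows, columns=["peak_id", "mz", "rt", "sample", "area"])
    return PeakTable(df, TPS, "control")


def _table_for(areas_by_product: dict, controls: dict):
    rows = []
    for pid, areas in areas_by_product.items():
        rows.append((pid, 200.0, 5.0, "control", controls[pid]))
        for s, a in zip(TPS, areas):
            rows.append((pid, 200.0, 5.0, s, a))
    return _peak_table(rows)


class TestDetectProducts:
    def test_threshold_is_strict_times_three(self):
        pt = _table_for({"just": [3.01, 3.01, 3.01, 3.01],
                         "under": [2.9, 2.9, 2.9, 2.9]},
                        {"just": 1.0, "under": 1.0})
        detected, flagged = detect_products(pt)
        assert all("just" in detected[s] for s in TPS)
        assert all("under" not in detected[s] for s in TPS)
        assert not flagged

    def test_zero_control_uses_noise_floor_and_flags(self):
        pt = _table_for({"p": [5.0, 5.0, 5.0, 5.0]}, {"p": 0.0})
        detected, flagged = detect_products(pt)
        # noise floor = 0.1 * min positive area = 0.5; 5 > 3*0.5
        assert all("p" in detected[s] for s in TPS)
        assert "p" in flagged


class TestBuildKinetics:
    def test_rows_are_z_scored(self):
        pt = _table_for({"p": [1.0, 2.0, 3.0, 4.0]}, {"p": 0.01})
        kin = build_kinetics(pt)
        row = kin.z.loc["p"].to_numpy()
        assert row.mean() == pytest.approx(0.0, abs=1e-9)
        assert row.std() == pytest.approx(1.0, abs=1e-9)

    def test_product_missing_at_one_timepoint_excluded(self):
        pt = _table_for({"full": [10, 10, 10, 11], "partial": [10, 1.0, 10, 10]},
                        {"full": 1.0, "partial": 1.0})
        kin = build_kinetics(pt)
        assert "full" in kin.z.index and "partial" not in kin.z.index

    def test_constant_row_dropped(self):
        pt = _table_for({"flat": [10, 10, 10, 10], "var": [5, 10, 20, 40]},
                        {"flat": 1.0, "var": 1.0})
        kin = build_kinetics(pt)
        assert kin.dropped_constant == ["flat"]
        assert list(kin.z.index) == ["var"]

    def test_zscore_idempotence(self):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        assert np.allclose(zscore(zscore(x)), zscore(x), atol=1e-9)


class TestCorrelationNetwork:
    def _kin(self, mat, ids):
        z = (mat - mat.mean(1, keepdims=True)) / mat.std(1, keepdims=True)
        return KineticsMatrix(
            z=pd.DataFrame(z, index=ids, columns=list(TPS)),
            areas=pd.DataFrame(mat, index=ids, columns=list(TPS)),
            timepoints=np.array(list(TPS.values())))

    def test_identical_rows_connected(self):
        kin = self._kin(np.array([[1.0, 2, 3, 4], [2.0, 4, 6, 8]]), ["a", "b"])
        net = correlation_network(kin)
        assert net.graph.has_edge("a", "b")
        assert net.graph["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_anticorrelated_rows_excluded_by_default(self):
        kin = self._kin(np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]]), ["a", "b"])
        assert correlation_network(kin).graph.number_of_edges() == 0
        net = correlation_network(kin, positive_only=False)
        assert net.graph.has_edge("a", "b")

    def test_edges_match_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        mat = 10.0 ** rng.normal(2, 1, (50, 4))
        ids = [f"p{i}" for i in range(50)]
        kin = self._kin(mat, ids)
        net = correlation_network(kin, p_threshold=0.01)
        oracle = set()
        for i, j in itertools.combinations(range(50), 2):
            r, p = stats.pearsonr(mat[i], mat[j])
            if p < 0.01 and r > 0:
                oracle.add(frozenset({ids[i], ids[j]}))
        got = {frozenset(e) for e in net.graph.edges}
        assert got == oracle

    def test_critical_r_at_four_timepoints(self):
        """With df=2, a p<0.001 edge needs |r| above the closed-form
        t-inversion critical value."""
        t_crit = stats.t.isf(0.0005, 2)
        r_crit = math.sqrt(t_crit**2 / (2 + t_crit**2))
        r, p = pearson_r_p(np.array([0.0, 1, 2, 3]), np.array([0.1, 0.9, 2.2, 2.9]))
        assert (p < 0.001) == (abs(r) > r_crit)
        assert r_crit == pytest.approx(0.9990, abs=5e-4)


class TestLouvain:
    def _clique_net(self, sizes):
        g = nx.Graph()
        label = 0
        for s in sizes:
            nodes = [f"c{label}_{i}" for i in range(s)]
            for u, v in itertools.combinations(nodes, 2):
                g.add_edge(u, v, weight=1.0)
            for n in nodes:
                g.add_node(n, kind="product")
            label += 1
        return ProductNetwork(g)

    def test_two_fifteen_cliques_two_reported(self):
        net = louvain_communities(self._clique_net([15, 15]), seed=0)
        assert len(net.reported) == 2

    def test_small_clique_not_reported(self):
        net = louvain_communities(self._clique_net([5]), seed=0)
        assert net.reported == []
        assert len(net.communities) == 5  # labeled but unreported

    def test_seeded_determinism(self):
        nets = [louvain_communities(self._clique_net([12, 14, 20]), seed=7)
                for _ in range(5)]
        parts = [tuple(sorted(n.communities.items())) for n in nets]
        assert len(set(parts)) == 1

    def test_modularity_beats_singletons(self):
        net = louvain_communities(self._clique_net([12, 12]), seed=0)
        g = net.graph
        comms = {}
        for n, lab in net.communities.items():
            comms.setdefault(lab, set()).add(n)
        q = nx.community.modularity(g, comms.values(), weight="weight")
        q0 = nx.community.modularity(g, [{n} for n in g.nodes], weight="weight")
        assert q >= q0

    def test_planted_partition_recovery(self, peak_study):
        """Louvain on the simulated peak table recovers planted communities
        (adjusted Rand index >= 0.9)."""
        pt, truth, _ = peak_study
        kin = build_kinetics(pt)
        net = louvain_communities(correlation_network(kin), seed=3)
        planted = truth.products[~truth.products["is_decoy"]]
        labels_true = planted["community"].to_numpy()
        labels_pred = np.array([net.communities.get(p, -1) for p in planted.index])
        assert _ari(labels_true, labels_pred) >= 0.9


def _ari(a, b):
    """Adjusted Rand index from the pair-counting contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    cats_a, inv_a = np.unique(a, return_inverse=True)
    cats_b, inv_b = np.unique(b, return_inverse=True)
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    for i, j in zip(inv_a, inv_b):
        table[i, j] += 1
    comb = lambda x: x * (x - 1) // 2
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(1)).sum()
    sum_b = comb(table.sum(0)).sum()
    total = comb(n)
    expected = sum_a * sum_b / total
    max_idx = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_idx - expected)


class TestToxicityAssociation:
    def _viability(self):
        rows = []
        for cell, inh in {"A": [10, 30, 70, 90], "B": [20, 60, 140, 180]}.items():
            for d, i in zip([0.5, 1, 4, 8], inh):
                rows.append((cell, d, 100.0, 100.0 - i))
        return pd.DataFrame(rows, columns=[
            "cell", "duration_days", "concentration", "viability_pct"])

    def test_vector_pipeline_arithmetic(self):
        tox = toxicity_vectors(self._viability(), concentration=100.0)
        v = tox["A"]
        assert v.inhibition.tolist() == [10, 30, 70, 90]
        expect = zscore(np.log10(np.array([10, 30, 70, 90.0])))
        assert np.allclose(v.z, expect)

    def test_proportional_profiles_have_identical_z(self):
        tox = toxicity_vectors(self._viability(), concentration=100.0)
        assert np.allclose(tox["A"].z, tox["B"].z, atol=1e-9)

    def test_inhibition_floor_applied(self):
        df = pd.DataFrame(
            [("A", d, 10.0, v) for d, v in zip([0.5, 1, 4, 8], [100, 100, 50, 10])],
            columns=["cell", "duration_days", "concentration", "viability_pct"])
        tox = toxicity_vectors(df, concentration=10.0)
        assert tox["A"].inhibition[0] == pytest.approx(0.1)

    def test_collinear_product_gets_edge_and_anticorrelated_does_not(self):
        tox = toxicity_vectors(self._viability(), concentration=100.0)
        tox = {"A": tox["A"]}
        prof = 10.0 ** (2 + tox["A"].z)
        areas = pd.DataFrame([prof, prof[::-1]], index=["with", "anti"],
                             columns=list(TPS))
        z = areas.apply(lambda r: zscore(r.to_numpy()), axis=1, result_type="expand")
        z.columns = list(TPS)
        kin = KineticsMatrix(z=z, areas=areas,
                             timepoints=np.array(list(TPS.values())))
        assoc = associate_toxicity(kin, tox, alpha=0.05)
        assert assoc["A"] == {"with"}

    def test_recall_and_false_rate_on_planted_data(self, peak_study):
        pt, truth, via = peak_study
        kin = build_kinetics(pt)
        tox = toxicity_vectors(via)
        assoc = associate_toxicity(kin, tox, alpha=0.05)
        prods = truth.products
        for cell in assoc:
            flag = prods[f"tox_{cell}"]
            n_pos = int(flag.sum())
            recall = sum(1 for p in prods.index[flag] if p in assoc[cell]) / n_pos
            negatives = prods.index[~flag & ~prods["is_decoy"]]
            fp_rate = sum(1 for p in assoc[cell] if p in set(negatives)) / len(negatives)
            assert recall >= 0.9
            assert fp_rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / len(negatives))


class TestCommunityToxicity:
    def test_collinear_community_attains_max_correlation(self, peak_study):
        pt, truth, via = peak_study
        kin = build_kinetics(pt)
        net = louvain_communities(correlation_network(kin), seed=3)
        tox = toxicity_vectors(via)
        mat = community_toxicity(kin, net, tox)
        # every cell's best community is one whose members are planted
        # collinear with that cell
        prods = truth.products
        for cell in mat.columns:
            best = mat[cell].idxmax()
            members = [p for p, lab in net.communities.items() if lab == best]
            frac_flagged = np.mean([prods.loc[p, f"tox_{cell}"] for p in members])
            assert frac_flagged > 0.9

    def test_single_community_yields_one_row(self):
        z = pd.DataFrame([[0.0, -1.0, 1.0, 0.0], [0.0, -1.0, 1.0, 0.0]],
                         index=["a", "b"], columns=list(TPS))
        kin = KineticsMatrix(z=z, areas=10.0 ** z, timepoints=np.array([0.5, 1, 4, 8]))
        net = ProductNetwork(nx.Graph())
        net.graph.add_nodes_from(["a", "b"], kind="product")
        net.communities = {"a": 1, "b": 1}
        net.reported = [1]
        from cdtox.kinetics_net import ToxVector
        tox = {"X": ToxVector("X", np.array([0.5, 1, 4, 8]),
                              np.ones(4), np.array([0.0, -1.0, 1.0, 0.0]))}
        mat = community_toxicity(kin, net, tox)
        assert mat.shape == (1, 1)
        assert mat.iloc[0, 0] == pytest.approx(1.0)


class TestVennSummary:
    def test_nested_sets(self):
        out = venn_summary({"A": {1, 2, 3}, "B": {2, 3}, "C": {3}})
        assert out["all"] == 1 and out["union"] == 3

    def test_disjoint_sets(self):
        out = venn_summary({"A": {1}, "B": {2}, "C": {3, 4}})
        assert out["all"] == 0 and out["union"] == 4

    def test_matches_membership_table_oracle(self):
        rng = np.random.default_rng(17)
        universe = list(range(200))
        sets = {k: set(rng.choice(universe, size=rng.integers(20, 120),
                                  replace=False)) for k in "ABC"}
        out = venn_summary(sets)
        # brute-force membership table
        regions = {k: 0 for k in out}
        for el in universe:
            m = tuple(k for k in "ABC" if el in sets[k])
            if not m:
                continue
            regions["union"] += 1
            if len(m) == 3:
                regions["all"] += 1
            elif len(m) == 1:
                regions[f"{m[0]} only"] += 1
            else:
                regions[f"{m[0]}&{m[1]}"] += 1
        assert out == regions
        # inclusion-exclusion identity
        singles = sum(len(sets[k]) for k in "ABC")
        pairs = sum(len(sets[a] & sets[b]) for a, b in itertools.combinations("ABC", 2))
        assert out["union"] == singles - pairs + len(sets["A"] & sets["B"] & sets["C"])


class TestExport:
    def _net(self):
        g = nx.Graph()
        g.add_node("p1", kind="product")
        g.add_node("p2", kind="product")
        g.add_node("HeLa", kind="cell")
        g.add_edge("p1", "p2", weight=0.999, p=0.0005)
        g.add_edge("p1", "HeLa", weight=0.96, p=0.04)
        return ProductNetwork(g, {"p1": 1, "p2": 1}, [])

    @pytest.mark.parametrize("ext", ["gexf", "graphml"])
    def test_round_trip(self, tmp_path, ext):
        net = self._net()
        path = str(tmp_path / f"net.{ext}")
        export_network(net, path)
        back = read_network(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {frozenset(e) for e in back.graph.edges} == \
            {frozenset(e) for e in net.graph.edges}
        assert back.graph.nodes["HeLa"]["kind"] == "cell"
        assert back.communities == {"p1": 1, "p2": 1}
        assert back.graph["p1"]["p2"]["weight"] == pytest.approx(0.999)

    def test_empty_network_is_valid_file(self, tmp_path):
        path = str(tmp_path / "empty.gexf")
        export_network(ProductNetwork(nx.Graph()), path)
        back = read_network(path)
        assert back.graph.number_of_nodes() == 0
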