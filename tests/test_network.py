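import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, t as t_dist

from raretaxa.classify import RarityClassification, classify_otus
from raretaxa.io import OtuTable, SampleMetadata, ENV_VARS, to_relative_abundance
from raretaxa.network import (
    build_network,
    correlation_edges,
    detect_modules,
    global_metrics,
    module_env_regression,
    node_metrics,
    powerlaw_r2,
    random_reference,
    tmm_cpm,
)


def _classification(otus, category="CRT"):
    return RarityClassification(
        pd.Series([category] * len(otus), index=otus),
        abundant_cut=0.01, rare_cut=0.0001)


def _brute_force_edges(counts: pd.DataFrame, r_thr=0.6, q_thr=0.01):
    """Independent edge oracle: exact average ranks, t-approximation p,
    textbook step-up BH over the upper triangle."""
    otus = list(counts.columns)
    n = counts.shape[0]
    rows = []
    for a, b in itertools.combinations(otus, 2):
        ra, rb = rankdata(counts[a]), rankdata(counts[b])
        rho = np.corrcoef(ra, rb)[0, 1]
        tt = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = 2 * t_dist.sf(abs(tt), n - 2)
        rows.append((a, b, rho, min(p, 1.0)))
    m = len(rows)
    order = np.argsort([r[3] for r in rows], kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_pos, idx in enumerate(reversed(order), 0):
        pass
    # step-up: q_(i) = min_{j>=i} p_(j) m / j
    sorted_p = [rows[i][3] for i in order]
    qs = np.minimum.accumulate(
        [min(1.0, p * m / (i + 1)) for i, p in enumerate(sorted_p)][::-1])[::-1]
    q[order] = qs
    return {(r[0], r[1]) for r, qv in zip(rows, q)
            if abs(r[2]) > r_thr and qv < q_thr}


class TestCorrelationEdges:
    def test_perfect_covariation_retained(self):
        counts = pd.DataFrame({
            "a": [1, 5, 9, 14, 20, 3, 7, 11, 16, 2],
            "c": [4, 9, 2, 1, 7, 20, 3, 6, 8, 5],
        })
        counts["b"] = counts["a"] * 2
        t = OtuTable(counts.astype(int))
        edges = correlation_edges(t, 0.6, 0.05)
        pairs = set(map(tuple, edges[["otu_a", "otu_b"]].to_numpy()))
        assert ("a", "b") in pairs
        got = edges.set_index(["otu_a", "otu_b"]).loc[("a", "b"), "rho"]
        assert got == pytest.approx(1.0)

    def test_moderate_rho_excluded_regardless_of_p(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=200)
        a = z + rng.normal(scale=1.6, size=200)   # rho ~ 0.5, p tiny
        counts = pd.DataFrame({"a": np.argsort(np.argsort(a)),
                               "z": np.argsort(np.argsort(z))})
        t = OtuTable(counts)
        rho = np.corrcoef(rankdata(a), rankdata(z))[0, 1]
        assert 0.3 < rho < 0.6
        edges = correlation_edges(t, 0.6, 0.5)
        assert len(edges) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(36, 4))
        mix = rng.normal(size=(4, 20))
        counts = np.round(50 + 10 * (base @ mix)
                          + rng.normal(scale=4, size=(36, 20))).astype(int)
        counts = np.clip(counts, 0, None)
        t = OtuTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(36)],
                                  columns=[f"o{i}" for i in range(20)]))
        edges = correlation_edges(t, 0.6, 0.01)
        got = set(map(tuple, edges[["otu_a", "otu_b"]].to_numpy()))
        assert got == _brute_force_edges(t.counts)
        assert len(got) > 0

    def test_constant_vector_excluded_with_warning(self):
        counts = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6], "b": [7] * 6,
                               "c": [2, 4, 6, 8, 10, 12]})
        with pytest.warns(UserWarning, match="constant"):
            edges = correlation_edges(OtuTable(counts), 0.6, 0.05)
        assert not edges[["otu_a", "otu_b"]].isin(["b"]).any().any()


class TestBuildNetwork:
    def test_empty_edge_list_gives_empty_graph(self):
        g = build_network(pd.DataFrame(columns=["otu_a", "otu_b", "rho", "q"]),
                          _classification([]))
        assert g.n_nodes == 0 and g.n_edges == 0
        assert len(g.block_counts) == 0

    def test_block_counts_conserve_edges_and_signs(self):
        edges = pd.DataFrame({
            "otu_a": ["a", "a", "b", "c"],
            "otu_b": ["b", "c", "d", "d"],
            "rho": [0.9, -0.8, 0.7, -0.95],
            "q": [0.001] * 4,
        })
        cls = RarityClassification(
            pd.Series({"a": "AAT", "b": "CRT", "c": "CRT", "d": "MT"}),
            0.01, 0.0001)
        g = build_network(edges, cls)
        bc = g.block_counts
        assert int(bc["positive"].sum() + bc["negative"].sum()) == 4
        assert int(bc["positive"].sum()) == 2


class TestNodeMetrics:
    def test_star_graph_closed_forms(self):
        edges = pd.DataFrame({
            "otu_a": ["hub"] * 4, "otu_b": list("abcd"),
            "rho": [0.9] * 4, "q": [0.001] * 4})
        g = build_network(edges, _classification(["hub", *"abcd"]))
        m = node_metrics(g)
        assert m.loc["hub", "degree"] == 4
        assert m.loc["hub", "betweenness"] == 6  # all C(4,2) leaf pairs
        assert m.loc["hub", "closeness"] == pytest.approx(1.0)

    def test_path_graph_middle_betweenness(self):
        edges = pd.DataFrame({"otu_a": ["a", "b"], "otu_b": ["b", "c"],
                              "rho": [0.9, 0.9], "q": [0.001, 0.001]})
        g = build_network(edges, _classification(list("abc")))
        assert node_metrics(g).loc["b", "betweenness"] == 1

    def test_matches_bfs_oracles_on_random_graph(self):
        rng = np.random.default_rng(2)
        gg = nx.gnm_random_graph(30, 60, seed=4)
        edges = pd.DataFrame(
            {"otu_a": [f"n{u}" for u, v in gg.edges],
             "otu_b": [f"n{v}" for u, v in gg.edges],
             "rho": [0.9] * gg.number_of_edges(),
             "q": [0.001] * gg.number_of_edges()})
        net = build_network(edges, _classification([f"n{i}" for i in range(30)]))
        m = node_metrics(net)
        g = net.graph
        for node in g.nodes:
            # degree
            assert m.loc[node, "degree"] == len(list(g.neighbors(node)))
            # closeness within component by BFS
            dists = nx.single_source_shortest_path_length(g, node)
            reach = {k: v for k, v in dists.items() if k != node}
            expected = (len(reach) / sum(reach.values())) if reach else 0.0
            assert m.loc[node, "closeness"] == pytest.approx(expected)
        # betweenness against a direct all-pairs path enumeration
        bf = dict.fromkeys(g.nodes, 0.0)
        for s, tt in itertools.combinations(g.nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(g, s, tt))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for mid in path[1:-1]:
                    bf[mid] += 1 / len(paths)
        for node in g.nodes:
            assert m.loc[node, "betweenness"] == pytest.approx(bf[node])
        # eigenvector: Av = lambda v on each component
        import numpy.linalg as la
        for comp in nx.connected_components(g):
            nodes = sorted(comp)
            if len(nodes) < 2:
                continue
            A = nx.to_numpy_array(g, nodelist=nodes)
            w, v = la.eigh(A)
            lead = np.abs(v[:, np.argmax(w)])
            lead /= np.linalg.norm(lead)
            got = m.loc[nodes, "eigenvector"].to_numpy()
            got = got / np.linalg.norm(got)
            assert np.allclose(got, lead, atol=1e-6)


class TestGlobalMetrics:
    def _net(self, edge_pairs):
        otus = sorted({n for e in edge_pairs for n in e})
        edges = pd.DataFrame({"otu_a": [a for a, b in edge_pairs],
                              "otu_b": [b for a, b in edge_pairs],
                              "rho": [0.9] * len(edge_pairs),
                              "q": [0.001] * len(edge_pairs)})
        return build_network(edges, _classification(otus))

    def test_triangle(self):
        g = self._net([("a", "b"), ("b", "c"), ("a", "c")])
        gm = global_metrics(g, seed=0)
        assert gm["acc"] == pytest.approx(1.0)
        assert gm["apl"] == pytest.approx(1.0)

    def test_tree_has_zero_clustering(self):
        g = self._net([("a", "b"), ("b", "c"), ("c", "d"), ("c", "e")])
        assert global_metrics(g, seed=0)["acc"] == pytest.approx(0.0)

    def test_apl_matches_bfs_average(self):
        rng = np.random.default_rng(5)
        gg = nx.gnm_random_graph(10, 20, seed=6)
        net = self._net([(f"n{u}", f"n{v}") for u, v in gg.edges])
        g = net.graph
        comp = max(nx.connected_components(g), key=len)
        tot, cnt = 0, 0
        for s, tt in itertools.combinations(sorted(comp), 2):
            tot += nx.shortest_path_length(g, s, tt)
            cnt += 1
        assert global_metrics(net, seed=0)["apl"] == pytest.approx(tot / cnt)


class TestRandomReference:
    def test_complete_graph_acc_is_one(self):
        res = random_reference(6, 15, n_random=5, seed=0)
        assert res.loc["acc", "mean"] == pytest.approx(1.0)
        assert res.loc["acc", "sd"] == pytest.approx(0.0)

    def test_reproducible_given_seed(self):
        a = random_reference(20, 40, n_random=10, seed=3)
        b = random_reference(20, 40, n_random=10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError):
            random_reference(4, 7)


class TestPowerlaw:
    def test_exact_power_law_r2_one(self):
        # frequencies 64, 16, 4, 1 at degrees 1, 2, 4, 8: log-log linear
        degs = [1] * 64 + [2] * 16 + [4] * 4 + [8]
        res = powerlaw_r2(degs)
        assert res["defined"]
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(-2.0)

    def test_regular_graph_undefined(self):
        res = powerlaw_r2([4] * 30)
        assert not res["defined"]

    def test_barabasi_albert_fits_well(self):
        g = nx.barabasi_albert_graph(500, 2, seed=7)
        res = powerlaw_r2([d for _, d in g.degree()])
        assert res["r_squared"] > 0.7


class TestModules:
    def _planted_graph(self, n_mod=4, size=12, p_in=0.5, p_out=0.01, seed=8):
        rng = np.random.default_rng(seed)
        nodes = [f"m{m}_n{i}" for m in range(n_mod) for i in range(size)]
        planted = {n: int(n[1]) for n in nodes}
        pairs = []
        for a, b in itertools.combinations(nodes, 2):
            p = p_in if planted[a] == planted[b] else p_out
            if rng.random() < p:
                pairs.append((a, b))
        edges = pd.DataFrame({"otu_a": [a for a, b in pairs],
                              "otu_b": [b for a, b in pairs],
                              "rho": [0.9] * len(pairs),
                              "q": [0.001] * len(pairs)})
        return build_network(edges, _classification(nodes)), planted

    @staticmethod
    def _rel(columns, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.dirichlet(np.ones(len(columns)), size=5)
        return pd.DataFrame(x, columns=columns)

    def test_two_cliques_recovered_exactly(self):
        cl1 = list(itertools.combinations(["a", "b", "c", "d"], 2))
        cl2 = list(itertools.combinations(["x", "y", "z", "w"], 2))
        edges = pd.DataFrame({"otu_a": [a for a, b in cl1 + cl2],
                              "otu_b": [b for a, b in cl1 + cl2],
                              "rho": [0.9] * 12, "q": [0.001] * 12})
        net = build_network(edges, _classification(list("abcdxyzw")))
        mods = detect_modules(net, self._rel(list("abcdxyzw")), seed=0)
        assert mods.membership.nunique() == 2
        assert len(set(mods.membership[list("abcd")])) == 1
        assert len(set(mods.membership[list("xyzw")])) == 1

    def test_planted_partition_recovered(self):
        net, planted = self._planted_graph()
        mods = detect_modules(net, self._rel(sorted(planted)), seed=1)
        agree = 0
        for mid in mods.membership.unique():
            members = mods.members(mid)
            counts = pd.Series([planted[n] for n in members]).value_counts()
            agree += int(counts.iloc[0])
        assert agree / len(planted) >= 0.9

    def test_observed_modularity_beats_random_reference(self):
        net, _ = self._planted_graph()
        gm = global_metrics(net, seed=2)
        rr = random_reference(net.n_nodes, net.n_edges, n_random=30, seed=2)
        assert gm["modularity"] > (rr.loc["modularity", "mean"]
                                   + 2 * rr.loc["modularity", "sd"])

    def test_ranking_matches_brute_force_mean_abundance(self):
        net, planted = self._planted_graph(n_mod=3, size=8, seed=9)
        rel = self._rel(sorted(planted), seed=3)
        mods = detect_modules(net, rel, seed=4)
        means = {mid: rel[mods.members(mid)].sum(axis=1).mean()
                 for mid in mods.mean_abundance.index}
        ranked = sorted(means, key=means.get, reverse=True)
        assert ranked == list(mods.mean_abundance.index)
        assert list(mods.mean_abundance.index) == sorted(mods.mean_abundance.index)


class TestTmm:
    def test_identical_libraries_unit_factors(self):
        counts = pd.DataFrame(np.tile([100, 50, 25, 10, 5], (3, 1)),
                              index=list("abc"), columns=[f"o{i}" for i in range(5)])
        cpm = tmm_cpm(OtuTable(counts))
        f = cpm.attrs["tmm_factors"]
        assert np.allclose(f, 1.0)
        assert cpm.iloc[0, 0] == pytest.approx(100 / 190 * 1e6)

    def test_pure_depth_scaling_leaves_cpm_equal(self):
        base = np.array([100, 50, 25, 10, 5, 40, 80, 12, 33, 7])
        counts = pd.DataFrame([base, base * 2], index=["a", "b"],
                              columns=[f"o{i}" for i in range(10)])
        cpm = tmm_cpm(OtuTable(counts))
        f = cpm.attrs["tmm_factors"]
        assert np.allclose(f, 1.0, atol=1e-9)
        assert np.allclose(cpm.loc["a"], cpm.loc["b"])

    def test_matches_step_by_step_hand_computation(self):
        # two samples, 10 OTUs, one doubled block; oracle below transcribes
        # the trimmed-mean-of-M definition term by term
        ya = np.array([100, 200, 300, 400, 500, 600, 700, 800, 900, 1000])
        yb = ya.copy()
        yb[:4] = yb[:4] * 4  # composition shift in a 4-OTU block
        counts = pd.DataFrame([ya, yb], index=["a", "b"],
                              columns=[f"o{i}" for i in range(10)])
        cpm = tmm_cpm(OtuTable(counts))
        f = cpm.attrs["tmm_factors"]

        na, nb = ya.sum(), yb.sum()
        # reference sample = closest upper quartile of positive count fractions
        uq = [np.quantile(ya / na, 0.75), np.quantile(yb / nb, 0.75)]
        ref = int(np.argmin(np.abs(np.array(uq) - np.mean(uq))))
        assert ref == 0
        m = np.log2((yb / nb) / (ya / na))
        a_val = 0.5 * np.log2((yb / nb) * (ya / na))
        w = (nb - yb) / (nb * yb) + (na - ya) / (na * ya)
        n_g = len(m)
        rank_m, rank_a = rankdata(m), rankdata(a_val)
        keep = ((rank_m >= np.floor(n_g * 0.3) + 1)
                & (rank_m <= n_g - np.floor(n_g * 0.3))
                & (rank_a >= np.floor(n_g * 0.05) + 1)
                & (rank_a <= n_g - np.floor(n_g * 0.05)))
        log_factor_b = np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep])
        raw = np.array([1.0, 2.0 ** log_factor_b])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.to_numpy(), expected, atol=1e-12)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame([[1, 2], [0, 0]], index=["a", "b"],
                              columns=["x", "y"])
        with pytest.raises(ValueError, match="b"):
            tmm_cpm(OtuTable(counts))

    def test_factors_geometric_mean_is_one(self, random_table):
        cpm = tmm_cpm(random_table)
        f = cpm.attrs["tmm_factors"].to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)


class TestModuleEnvRegression:
    def _setup(self, response_from_ph=True, seed=0):
        rng = np.random.default_rng(seed)
        n = 12
        ph = np.linspace(5.5, 8.5, n)
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "site_id": [f"t{i}" for i in range(n)],
            "latitude": np.linspace(35, 40, n),
            "longitude": np.linspace(100, 110, n),
            **{v: rng.uniform(1, 5, n) for v in ENV_VARS},
        }).assign(pH=ph))
        otus = [f"o{i}" for i in range(6)]
        if response_from_ph:
            signal = np.outer(100 + 40 * ph, np.ones(3))
        else:
            signal = rng.uniform(50, 400, size=(n, 3))
        counts = np.column_stack([signal, rng.uniform(50, 400, size=(n, 3))])
        counts = np.round(counts).astype(int)
        cpm = pd.DataFrame(counts.astype(float), columns=otus,
                           index=[f"s{i}" for i in range(n)])
        membership = pd.Series({o: 0 for o in otus})
        from raretaxa.network import ModuleSet
        mods = ModuleSet(membership=membership,
                         mean_abundance=pd.Series({0: 1.0}),
                         top_modules=[0],
                         category_composition=pd.DataFrame(),
                         family_composition=None)
        cls = RarityClassification(
            pd.Series({"o0": "AAT", "o1": "AAT", "o2": "CAT",
                       "o3": "CRT", "o4": "CRT", "o5": "ART"}), 0.01, 0.0001)
        return mods, cpm, cls, meta

    def test_constructed_ph_response_detected(self):
        mods, cpm, cls, meta = self._setup(response_from_ph=True)
        res = module_env_regression(mods, cpm, cls, meta, env_vars=("pH",))
        at = res[(res["aggregate"] == "AT") & (res["variable"] == "pH")]
        assert at["r"].iloc[0] == pytest.approx(1.0, abs=0.01)
        assert at["significant"].iloc[0]

    def test_accumulated_cpm_is_member_sum(self):
        mods, cpm, cls, meta = self._setup()
        at_members = ["o0", "o1", "o2"]
        expected = cpm[at_members].sum(axis=1)
        res = module_env_regression(mods, cpm, cls, meta, env_vars=("pH",))
        from scipy.stats import linregress
        fit = linregress(meta.env()["pH"], expected)
        at = res[(res["aggregate"] == "AT") & (res["variable"] == "pH")]
        assert at["slope"].iloc[0] == pytest.approx(fit.slope)

    def test_permuted_response_rarely_significant(self):
        hits = 0
        for seed in range(10):
            mods, cpm, cls, meta = self._setup(response_from_ph=False, seed=seed)
            res = module_env_regression(mods, cpm, cls, meta, env_vars=("pH",))
            at = res[(res["aggregate"] == "AT") & (res["variable"] == "pH")]
            hits += bool(at["significant"].iloc[0])
        assert hits <= 1
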