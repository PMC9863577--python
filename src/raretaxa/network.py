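"""Co-occurrence network inference, topology and module-environment links.

Edges are Spearman correlations between OTUs across samples that pass both a
magnitude threshold (|rho| > 0.6) and a BH-FDR threshold (q < 0.01) computed
over all upper-triangle OTU pairs of the prevalence-filtered table.  Module
detection uses Louvain; modules are ranked by the mean relative abundance of
their members, and the top modules' accumulated TMM-normalized CPM is
regressed on environmental variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .classify import RarityClassification
from .io import OtuTable, SampleMetadata


def correlation_edges(
    table: OtuTable,
    r_threshold: float = 0.6,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Spearman co-occurrence edge list from a prevalence-filtered table.

    rho uses average ranks for ties; p-values are the t-approximation; BH
    adjustment runs across all upper-triangle pairs; an edge is retained iff
    |rho| > r_threshold AND q < q_threshold.  Constant OTU vectors have
    undefined correlations and are excluded with a warning.
    """
    counts = table.counts
    constant = [o for o in counts.columns if counts[o].nunique() == 1]
    if constant:
        warnings.warn(f"excluding {len(constant)} constant OTU vector(s): {constant[:5]}")
        counts = counts.drop(columns=constant)
    otus = list(counts.columns)
    if len(otus) < 2:
        return pd.DataFrame(columns=["otu_a", "otu_b", "rho", "p", "q"])
    rho, p = spearmanr(counts.to_numpy(), axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu = np.triu_indices(len(otus), k=1)
    edges = pd.DataFrame({
        "otu_a": [otus[i] for i in iu[0]],
        "otu_b": [otus[j] for j in iu[1]],
        "rho": rho[iu],
        "p": p[iu],
    })
    _, q, _, _ = multipletests(edges["p"], method="fdr_bh")
    edges["q"] = q
    kept = edges[(edges["rho"].abs() > r_threshold) & (edges["q"] < q_threshold)]
    return kept.reset_index(drop=True)


@dataclass
class CooccurrenceNetwork:
    """Undirected signed network with per-node category labels."""

    graph: nx.Graph
    block_counts: pd.DataFrame  # per category-pair: positive/negative edges

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    edges: pd.DataFrame, classification: RarityClassification
) -> CooccurrenceNetwork:
    """Assemble the graph and count positive/negative edges per
    category-pair block (RT-RT, RT-AT, ...)."""
    g = nx.Graph()
    agg = classification.aggregate
    for row in edges.itertuples(index=False):
        sign = 1 if row.rho > 0 else -1
        g.add_edge(row.otu_a, row.otu_b, rho=float(row.rho), sign=sign,
                   q=float(row.q))
    for node in g.nodes:
        g.nodes[node]["category"] = str(agg.get(node, "NA"))
    blocks: dict[tuple, list[int]] = {}
    for u, v, d in g.edges(data=True):
        key = tuple(sorted((g.nodes[u]["category"], g.nodes[v]["category"])))
        pos_neg = blocks.setdefault(key, [0, 0])
        pos_neg[0 if d["sign"] > 0 else 1] += 1
    rows = [(a, b, pn[0], pn[1]) for (a, b), pn in sorted(blocks.items())]
    block_df = pd.DataFrame(rows, columns=["category_a", "category_b",
                                           "positive", "negative"])
    return CooccurrenceNetwork(graph=g, block_counts=block_df)


def _louvain(g: nx.Graph, seed: int, resolution: float = 1.0,
             weight=None) -> list[set]:
    """Louvain partition, deterministic across processes.

    networkx's implementation iterates over sets of (possibly string) nodes,
    whose order depends on the per-process hash seed; relabeling to sorted
    integers makes set iteration, and hence the partition, reproducible.
    """
    order = sorted(g.nodes)
    fwd = {n: i for i, n in enumerate(order)}
    h = nx.relabel_nodes(g, fwd, copy=True)
    parts = nx.community.louvain_communities(h, weight=weight, seed=seed,
                                             resolution=resolution)
    return [{order[i] for i in comm} for comm in parts]


def node_metrics(network: CooccurrenceNetwork) -> pd.DataFrame:
    """Degree, betweenness, closeness and eigenvector centrality per node.

    Betweenness is the unnormalized shortest-path count; closeness is
    computed within each connected component; eigenvector centrality is
    power iteration (tol 1e-10, max 10^4 iterations) per component.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=False)
    eig: dict = {}
    for comp in nx.connected_components(g):
        # concrete copy with sorted insertion: subgraph *views* iterate the
        # component set, whose order varies with the process hash seed, and
        # that perturbs the power iteration's summation order
        nodes = sorted(comp)
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from((u, v) for u in nodes for v in sorted(g.adj[u])
                           if u < v)
        if sub.number_of_edges() == 0:
            eig.update({n: 0.0 for n in comp})
            continue
        try:
            eig.update(nx.eigenvector_centrality(sub, max_iter=10_000, tol=1e-10))
        except nx.PowerIterationFailedConvergence as exc:
            raise RuntimeError(
                f"eigenvector centrality failed to converge on the component "
                f"containing {sorted(comp)[0]!r}"
            ) from exc
    nodes = list(g.nodes)
    return pd.DataFrame({
        "degree": [deg[n] for n in nodes],
        "betweenness": [btw[n] for n in nodes],
        "closeness": [clo[n] for n in nodes],
        "eigenvector": [eig[n] for n in nodes],
        "category": [g.nodes[n]["category"] for n in nodes],
    }, index=nodes)


def global_metrics(network: CooccurrenceNetwork, seed: int | None = None) -> dict:
    """Observed ACC, APL (largest component) and Louvain modularity."""
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    acc = nx.average_clustering(g)
    largest = max(nx.connected_components(g), key=len)
    sub = g.subgraph(largest)
    apl = nx.average_shortest_path_length(sub) if sub.number_of_nodes() > 1 else 0.0
    parts = _louvain(g, seed=seed if seed is not None else 0)
    mod = nx.community.modularity(g, parts)
    return {"acc": float(acc), "apl": float(apl), "modularity": float(mod)}


def random_reference(
    n_nodes: int, n_edges: int, n_random: int = 100, seed: int | None = None
) -> pd.DataFrame:
    """Erdos-Renyi G(n, m) reference ensemble statistics (mean and sd of
    ACC, APL over the largest component, and Louvain modularity)."""
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("more edges than the complete graph allows")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_random):
        s = int(rng.integers(0, 2**31 - 1))
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=s)
        acc = nx.average_clustering(g)
        largest = max(nx.connected_components(g), key=len)
        sub = g.subgraph(largest)
        apl = nx.average_shortest_path_length(sub) if sub.number_of_nodes() > 1 else 0.0
        parts = nx.community.louvain_communities(g, seed=s)  # integer nodes: stable
        rows.append((acc, apl, nx.community.modularity(g, parts)))
    df = pd.DataFrame(rows, columns=["acc", "apl", "modularity"])
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def powerlaw_r2(degree_sequence) -> dict:
    """Scale-free diagnostic: OLS of log10(frequency) on log10(degree).

    Integer degrees; zero-frequency bins and zero degrees are dropped before
    the log transform.  Requires >= 3 distinct positive degrees.
    """
    deg = np.asarray(degree_sequence, dtype=int)
    deg = deg[deg > 0]
    values, freq = np.unique(deg, return_counts=True)
    if len(values) < 3:
        return {"r_squared": float("nan"), "slope": float("nan"),
                "defined": False}
    fit = linregress(np.log10(values), np.log10(freq))
    return {"r_squared": float(fit.rvalue**2), "slope": float(fit.slope),
            "defined": True}


@dataclass
class ModuleSet:
    """Louvain partition with abundance ranking and composition tables."""

    membership: pd.Series           # node -> module id (0 = highest mean abundance)
    mean_abundance: pd.Series       # module id -> mean summed relative abundance
    top_modules: list[int]
    category_composition: pd.DataFrame
    family_composition: pd.DataFrame | None

    def members(self, module_id: int) -> list[str]:
        return list(self.membership.index[self.membership == module_id])


def _family(lineage: str) -> str:
    parts = [p.strip() for p in str(lineage).split(";")]
    return parts[4] if len(parts) > 4 else "unclassified"


def detect_modules(
    network: CooccurrenceNetwork,
    rel: pd.DataFrame,
    taxonomy: pd.Series | None = None,
    seed: int = 0,
    n_top: int = 4,
    resolution: float = 1.0,
) -> ModuleSet:
    """Louvain module detection on the unweighted graph.

    Modules are renumbered by decreasing mean abundance, defined as the mean
    over samples of the summed relative abundance of member OTUs; the top
    ``n_top`` are flagged as the major modules.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    parts = _louvain(g, seed=seed, resolution=resolution, weight=None)
    means = []
    for comm in parts:
        members = [n for n in sorted(comm) if n in rel.columns]
        means.append(rel[members].sum(axis=1).mean() if members else 0.0)
    order = np.argsort(np.asarray(means), kind="stable")[::-1]
    membership = {}
    for rank, k in enumerate(order):
        for node in sorted(parts[k]):
            membership[node] = rank
    membership = pd.Series(membership, name="module")
    mean_ab = pd.Series({rank: means[k] for rank, k in enumerate(order)},
                        name="mean_abundance").sort_index()
    top = list(range(min(n_top, len(parts))))

    cat_rows = []
    for mid in mean_ab.index:
        nodes = [n for n in membership.index if membership[n] == mid]
        cats = pd.Series([g.nodes[n]["category"] for n in nodes]).value_counts()
        for cat, c in cats.items():
            cat_rows.append((mid, cat, int(c)))
    cat_df = pd.DataFrame(cat_rows, columns=["module", "category", "n_otus"])

    fam_df = None
    if taxonomy is not None:
        fam_rows = []
        for mid in mean_ab.index:
            nodes = [n for n in membership.index if membership[n] == mid]
            fams = pd.Series([_family(taxonomy.get(n, "")) for n in nodes]).value_counts()
            for fam, c in fams.items():
                fam_rows.append((mid, fam, int(c)))
        fam_df = pd.DataFrame(fam_rows, columns=["module", "family", "n_otus"])
    return ModuleSet(membership=membership, mean_abundance=mean_ab,
                     top_modules=top, category_composition=cat_df,
                     family_composition=fam_df)


def tmm_cpm(table: OtuTable) -> pd.DataFrame:
    """TMM-normalized counts per million (samples x OTUs).

    Scaling factors follow the standard trimmed-mean-of-M-values scheme:
    the reference is the sample whose upper quartile of positive relative
    counts is closest to the mean upper quartile; per sample, log2 ratios
    (M) and average log2 abundances (A) over taxa positive in both are
    doubly trimmed (30% on M, 5% on A) and averaged with inverse
    asymptotic-variance weights; factors are rescaled to geometric mean 1.
    CPM = count / (library size x factor) x 1e6.
    """
    counts = table.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=1)
    if (lib == 0).any():
        zero = list(table.counts.index[lib == 0])
        raise ValueError(f"sample(s) with zero total counts: {zero}")

    def upper_quartile(y, n):
        pos = y[y > 0]
        return np.quantile(pos / n, 0.75) if len(pos) else 0.0

    uq = np.array([upper_quartile(counts[i], lib[i]) for i in range(len(lib))])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(len(lib))
    yr, nr = counts[ref], lib[ref]
    for i in range(len(lib)):
        if i == ref:
            continue
        yi, ni = counts[i], lib[i]
        both = (yi > 0) & (yr > 0)
        if not both.any():
            continue
        oi, orr = yi[both], yr[both]
        m = np.log2((oi / ni) / (orr / nr))
        a = 0.5 * np.log2((oi / ni) * (orr / nr))
        v = (ni - oi) / (ni * oi) + (nr - orr) / (nr * orr)
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, v = m[finite], a[finite], v[finite]
        n_m = len(m)
        if n_m == 0:
            continue
        lo_m, hi_m = np.floor(n_m * 0.3) + 1, n_m - np.floor(n_m * 0.3)
        lo_a, hi_a = np.floor(n_m * 0.05) + 1, n_m - np.floor(n_m * 0.05)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        factors[i] = 2 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    cpm = counts / (lib[:, None] * factors[:, None]) * 1e6
    out = pd.DataFrame(cpm, index=table.counts.index, columns=table.counts.columns)
    out.attrs["tmm_factors"] = pd.Series(factors, index=table.counts.index)
    return out


def module_env_regression(
    modules: ModuleSet,
    cpm: pd.DataFrame,
    classification: RarityClassification,
    metadata: SampleMetadata,
    env_vars: tuple[str, ...] = ("pH", "MAT"),
    aggregates: tuple[str, ...] = ("AT", "RT"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS of per-module accumulated CPM (within AT or RT) on environmental
    variables, for the top modules.

    The response for (module, aggregate) is the per-sample sum of CPM over
    the module's member OTUs belonging to that aggregate.  ``significant``
    distinguishes solid (p < alpha) from dashed (p >= alpha) relationships.
    """
    agg = classification.aggregate
    env = metadata.env().loc[cpm.index]
    rows = []
    for mid in modules.top_modules:
        members = modules.members(mid)
        for aggregate in aggregates:
            sel = [o for o in members if o in cpm.columns and agg.get(o) == aggregate]
            if not sel:
                rows.append((mid, aggregate, None, np.nan, np.nan, np.nan, False,
                             "no members in aggregate"))
                continue
            response = cpm[sel].sum(axis=1)
            for var in env_vars:
                x = env[var].to_numpy(dtype=float)
                if np.ptp(x) == 0 or response.std() == 0:
                    rows.append((mid, aggregate, var, np.nan, np.nan, np.nan,
                                 False, "degenerate"))
                    continue
                fit = linregress(x, response.to_numpy())
                r, _ = pearsonr(x, response.to_numpy())
                rows.append((mid, aggregate, var, float(fit.slope), float(r),
                             float(fit.pvalue), bool(fit.pvalue < alpha), ""))
    return pd.DataFrame(rows, columns=["module", "aggregate", "variable",
                                       "slope", "r", "p", "significant", "note"])


def export_graphml(network: CooccurrenceNetwork, modules: ModuleSet | None, path) -> None:
    """GraphML export with node attributes (category, module, degree) and
    edge attributes (rho, sign)."""
    g = network.graph.copy()
    deg = dict(g.degree())
    for n in g.nodes:
        g.nodes[n]["degree"] = int(deg[n])
        if modules is not None:
            g.nodes[n]["module"] = int(modules.membership.get(n, -1))
    nx.write_graphml(g, path)
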