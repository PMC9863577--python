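"""End-to-end orchestration: classify -> diversity -> biogeography ->
assembly -> network, from an OTU table + metadata (+ optional tree) to a
report directory of TSV tables and GraphML.

The run is pure dataflow: each stage reads the rarefied table and writes its
own artifacts; no stage mutates another's inputs.  All randomness derives
from one master seed through named per-stage streams, recorded in the run
manifest, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assembly, biogeography, classify, diversity, io, network

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one full analysis run."""

    otu_table: str
    metadata: str
    tree: str | None = None
    outdir: str = "raretaxa_out"
    rarefaction_depth: int | None = None  # None = min sample total
    abundant_cut: float = 0.01
    rare_cut: float = 0.0001
    prevalence_min_fraction: float = 0.2
    r_threshold: float = 0.6
    q_threshold: float = 0.01
    mantel_permutations: int = 999
    dbrda_permutations: int = 999
    nti_nulls: int = 199
    nst_nulls: int = 100
    n_random_graphs: int = 100
    louvain_resolution: float = 1.0
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (the output directory
        does not influence results and is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage_seed(master: int, name: str) -> int:
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# raretaxa {__version__} config={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(config: PipelineConfig) -> Path:
    """Run every stage; returns the report directory.

    A stage failure aborts with the stage named in the error; artifacts of
    completed stages are preserved.  The assembly stage is skipped with a
    logged notice when no tree is configured.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        table = io.read_otu_table(config.otu_table)
        metadata = io.read_metadata(config.metadata)
        table = io.OtuTable(table.counts.loc[metadata.sample_ids], table.taxonomy)
        tree = io.read_tree(config.tree) if config.tree else None

        stage = "rarefy"
        depth = config.rarefaction_depth or int(table.counts.sum(axis=1).min())
        table = io.rarefy(table, depth, seed=_stage_seed(config.seed, "rarefy"))
        metadata = io.SampleMetadata(
            metadata.data.loc[table.sample_ids].reset_index(drop=True))
        rel = io.to_relative_abundance(table)

        stage = "classify"
        cls = classify.classify_otus(rel, config.abundant_cut, config.rare_cut)
        _write(cls.to_frame(), out / "classification.tsv", config, index=False)
        _write(classify.summarize(cls), out / "classification_summary.tsv", config)
        subtables = {a: classify.subcommunity_table(table, cls, a)
                     for a in ("AT", "RT")}
        subtables = {a: t for a, t in subtables.items() if t.n_otus >= 2}

        stage = "diversity"
        alpha_frames, beta_rows, niche_frames = [], [], []
        dms = {}
        for name, sub in subtables.items():
            a = diversity.alpha_table(sub)
            a.insert(0, "subcommunity", name)
            alpha_frames.append(a)
            dm = diversity.bray_curtis(sub)
            dms[name] = dm
            for (i, j), d in zip(
                    zip(*np.triu_indices(len(dm.ids), k=1)), dm.condensed_form()):
                beta_rows.append((name, dm.ids[i], dm.ids[j], d))
            nb = diversity.levins_niche_breadth(
                io.to_relative_abundance(sub)).to_frame()
            nb.insert(0, "subcommunity", name)
            niche_frames.append(nb)
        _write(pd.concat(alpha_frames), out / "alpha_diversity.tsv", config)
        _write(pd.DataFrame(beta_rows, columns=["subcommunity", "sample_a",
                                                "sample_b", "bray_curtis"]),
               out / "beta_diversity.tsv", config, index=False)
        _write(pd.concat(niche_frames), out / "niche_breadth.tsv", config)
        if len(niche_frames) >= 2:
            comp = diversity.compare_groups(
                {n: f["levins_B"].to_numpy() for n, f in
                 zip(subtables, niche_frames)})
            _write(comp, out / "niche_breadth_tests.tsv", config, index=False)

        stage = "biogeography"
        geo_dm = biogeography.geographic_distance(metadata)
        env_raw = metadata.env()
        retained = biogeography.vif_screen(env_raw)
        env = biogeography.transform_env(env_raw[retained])
        env_dm = biogeography.environmental_distance(env)
        ddr_rows, mantel_rows, vpa_rows, select_rows = [], [], [], []
        geo_repr = pd.DataFrame(
            {"latitude": metadata.data["latitude"].to_numpy(dtype=float),
             "longitude": metadata.data["longitude"].to_numpy(dtype=float)},
            index=metadata.sample_ids)
        for name, dm in dms.items():
            for pname, pdm in (("geographic", geo_dm), ("environmental", env_dm)):
                f = biogeography.ddr_fit(dm, pdm)
                ddr_rows.append((name, pname, f.slope, f.intercept,
                                 f.r_squared, f.p_value, f.n_pairs))
            m_geo = biogeography.mantel(
                dm, geo_dm, n_perm=config.mantel_permutations,
                seed=_stage_seed(config.seed, f"mantel-geo-{name}"))
            m_env = biogeography.mantel(
                dm, env_dm, n_perm=config.mantel_permutations,
                seed=_stage_seed(config.seed, f"mantel-env-{name}"))
            pm = biogeography.partial_mantel(
                dm, env_dm, geo_dm, n_perm=config.mantel_permutations,
                seed=_stage_seed(config.seed, f"pmantel-{name}"))
            mantel_rows += [
                (name, "geographic", m_geo.r, m_geo.p_value, False),
                (name, "environmental", m_env.r, m_env.p_value, False),
                (name, "environmental|geo", pm.r, pm.p_value, True),
            ]
            sel = biogeography.dbrda_forward_select(
                dm, env, n_perm=config.dbrda_permutations,
                seed=_stage_seed(config.seed, f"dbrda-{name}"))
            for v in sel.selected:
                select_rows.append((name, v, sel.pseudo_f[v], sel.p_values[v]))
            vp = biogeography.variation_partition(dm, env[sel.selected], geo_repr)
            vpa_rows.append((name, vp.env_only, vp.geo_only, vp.shared, vp.residual))
        env_table = biogeography.mantel_env_table(
            dms, env_raw[retained], n_perm=config.mantel_permutations,
            seed=_stage_seed(config.seed, "mantel-table"))
        _write(pd.DataFrame(ddr_rows, columns=["subcommunity", "predictor", "slope",
                                               "intercept", "r_squared", "p",
                                               "n_pairs"]),
               out / "ddr_fits.tsv", config, index=False)
        _write(pd.DataFrame(mantel_rows, columns=["subcommunity", "predictor", "r",
                                                  "p", "partial"]),
               out / "mantel.tsv", config, index=False)
        _write(env_table, out / "mantel_env_table.tsv", config, index=False)
        _write(pd.DataFrame(select_rows, columns=["subcommunity", "variable",
                                                  "pseudo_F", "p"]),
               out / "dbrda_selection.tsv", config, index=False)
        _write(pd.DataFrame(vpa_rows, columns=["subcommunity", "env_only",
                                               "geo_only", "shared", "residual"]),
               out / "vpa.tsv", config, index=False)

        stage = "assembly"
        if tree is None:
            logger.warning("assembly stage skipped: no tree configured")
        else:
            nti_frames, nst_rows = [], []
            for name, sub in subtables.items():
                dist = assembly.patristic_matrix(tree, sub.otu_ids)
                res = assembly.nti(
                    sub, tree, n_null=config.nti_nulls, dist=dist,
                    seed=_stage_seed(config.seed, f"nti-{name}"))
                f = res.table.copy()
                f.insert(0, "subcommunity", name)
                nti_frames.append(f)
                for metric in ("bray", "jaccard"):
                    ns = assembly.nst(
                        sub, metric, n_null=config.nst_nulls,
                        seed=_stage_seed(config.seed, f"nst-{metric}-{name}"))
                    p = ns.pairs.copy()
                    p.insert(0, "metric", metric)
                    p.insert(0, "subcommunity", name)
                    nst_rows.append(p)
            _write(pd.concat(nti_frames), out / "nti.tsv", config)
            _write(pd.concat(nst_rows), out / "nst.tsv", config, index=False)

        stage = "network"
        filtered = io.prevalence_filter(table, config.prevalence_min_fraction)
        edges = network.correlation_edges(
            filtered, config.r_threshold, config.q_threshold)
        net = network.build_network(edges, cls)
        _write(net.block_counts, out / "network_block_counts.tsv", config,
               index=False)
        if net.n_nodes > 0:
            metrics = network.node_metrics(net)
            _write(metrics, out / "network_node_metrics.tsv", config)
            seed_net = _stage_seed(config.seed, "network")
            gm = network.global_metrics(net, seed=seed_net)
            rr = network.random_reference(
                net.n_nodes, net.n_edges, n_random=config.n_random_graphs,
                seed=seed_net)
            pw = network.powerlaw_r2([d for _, d in net.graph.degree()])
            topo = pd.DataFrame({
                "observed": [gm["acc"], gm["apl"], gm["modularity"]],
                "random_mean": rr["mean"].to_numpy(),
                "random_sd": rr["sd"].to_numpy(),
            }, index=["acc", "apl", "modularity"])
            topo.loc["powerlaw_r2"] = [pw["r_squared"], np.nan, np.nan]
            _write(topo, out / "network_topology.tsv", config)
            mods = network.detect_modules(
                net, rel, table.taxonomy, seed=seed_net,
                resolution=config.louvain_resolution)
            _write(mods.membership.to_frame(), out / "network_modules.tsv", config)
            _write(mods.category_composition,
                   out / "module_category_composition.tsv", config, index=False)
            if mods.family_composition is not None:
                _write(mods.family_composition,
                       out / "module_family_composition.tsv", config, index=False)
            cpm = network.tmm_cpm(table)
            reg = network.module_env_regression(mods, cpm, cls, metadata)
            _write(reg, out / "module_env_regression.tsv", config, index=False)
            network.export_graphml(net, mods, out / "network.graphml")

        stage = "manifest"
        manifest = {"version": __version__, "config": dataclasses.asdict(config),
                    "config_digest": config.digest(),
                    "rarefaction_depth_used": depth,
                    "vif_retained": retained,
                    "stage_seeds": {s: _stage_seed(config.seed, s)
                                    for s in ("rarefy", "network")}}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
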