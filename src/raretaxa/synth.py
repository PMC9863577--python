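"""Synthetic OTU tables, metadata and phylogenies with known structure.

The generator emulates a regional survey of rhizosphere soil communities:
a lognormal regional species pool (few dominant OTUs, long rare tail)
sampled at 12 sites x 3 replicates, with three latent processes whose
strengths are dials of the scenario:

* environmental filtering — Gaussian niche responses to MAT and pH with
  phylogenetically autocorrelated optima (Brownian motion on the tree), so
  strong filtering produces phylogenetically clustered, env-driven
  communities;
* dispersal limitation — each OTU has an origin site and its expected
  abundance decays exponentially with distance from it;
* planted co-occurrence modules — blocks of OTUs sharing a random
  site-preference profile, producing correlated abundances.

Samples are multinomial draws at a fixed depth, so every generated sample's
total equals the configured depth and no separate rarefaction is needed.
All latent quantities are returned as a ground-truth record.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import ENV_VARS, OtuTable, SampleMetadata

_FAMILIES = [
    "Nectriaceae", "Chaetomiaceae", "Mortierellaceae", "Micrococcaceae",
    "Sphingomonadaceae", "Geodermatophilaceae", "Bacillaceae",
    "Xanthobacteraceae", "Trichocomaceae", "Pleosporaceae",
    "Nocardioidaceae", "Gaiellaceae",
]

DISPERSAL_SCALE_KM = 150.0  # e-folding distance of the dispersal kernel
FILTER_RATE = 2.0  # niche-mismatch penalty per squared z-unit at strength 1


@dataclass
class ScenarioConfig:
    """Fully specified generation scenario.

    Strengths are in [0, 1]: 0 disables the process, 1 is the strongest
    regime the generator produces.
    """

    n_sites: int = 12
    replicates_per_site: int = 3
    n_otus: int = 2737
    depth: int = 43991
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    mat_range: tuple[float, float] = (2.0, 12.0)
    ph_range: tuple[float, float] = (6.5, 8.5)
    filtering_strength: float = 0.5
    dispersal_strength: float = 0.25
    n_modules: int = 0
    module_size: int = 25
    module_strength: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("filtering_strength", "dispersal_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.replicates_per_site


@dataclass
class GroundTruth:
    """Latent quantities behind one generated community."""

    pool_abundance: np.ndarray = field(repr=False)
    niche_optima_mat: np.ndarray = field(repr=False)
    niche_optima_ph: np.ndarray = field(repr=False)
    origin_site: np.ndarray = field(repr=False)
    module_of_otu: np.ndarray = field(repr=False)  # -1 = no planted module
    site_mat: np.ndarray = field(repr=False)
    site_ph: np.ndarray = field(repr=False)
    expected_site_composition: np.ndarray = field(repr=False)
    config: ScenarioConfig = None

    def to_json(self, path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_tree(n_otus: int, seed: int) -> dendropy.Tree:
    """Birth-death tree (birth 1.0, death 0.5) with ``n_otus`` extant tips,
    labeled OTU0001..; deterministic given the seed."""
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs for a tree")
    rng = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.5, num_extant_tips=n_otus,
        rng=rng, is_retain_extinct_tips=False,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{i + 1:04d}"
    return tree


def _brownian_tip_values(tree: dendropy.Tree, rng: np.random.Generator) -> dict[str, float]:
    """Brownian-motion trait simulated along branches; returns tip values."""
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            bl = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(0.0, np.sqrt(max(bl, 0.0)))
    return {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _haversine_km(lat, lon):
    lat, lon = np.radians(lat), np.radians(lon)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def generate_community(config: ScenarioConfig):
    """Generate (OtuTable, SampleMetadata, Phylogeny, GroundTruth).

    Regional pool abundances are lognormal; per-site expected composition is
    pool x niche-filter weight x dispersal kernel x module site preference,
    renormalized; each sample is one multinomial draw at ``config.depth``.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(6)
    tree_seed = int(seeds[0].generate_state(1)[0] % 2**31)
    rng_pool = np.random.default_rng(seeds[1])
    rng_env = np.random.default_rng(seeds[2])
    rng_traits = np.random.default_rng(seeds[3])
    rng_sample = np.random.default_rng(seeds[4])
    rng_tax = np.random.default_rng(seeds[5])

    n = config.n_otus
    tree = generate_tree(n, tree_seed)
    otu_ids = sorted(t.label for t in tree.taxon_namespace)

    pool = rng_pool.lognormal(config.lognormal_mu, config.lognormal_sigma, size=n)

    # sites on a ~1000 km x 1000 km box in northern China's coordinate range
    site_lat = rng_env.uniform(35.0, 44.0, size=config.n_sites)
    site_lon = rng_env.uniform(105.0, 117.0, size=config.n_sites)
    site_mat = rng_env.permutation(np.linspace(*config.mat_range, config.n_sites))
    site_ph = rng_env.permutation(np.linspace(*config.ph_range, config.n_sites))
    z_mat, z_ph = _zscore(site_mat), _zscore(site_ph)

    # phylogenetically autocorrelated niche optima, standardized to z-space
    opt_mat_raw = _brownian_tip_values(tree, rng_traits)
    opt_ph_raw = _brownian_tip_values(tree, rng_traits)
    opt_mat = _zscore(np.array([opt_mat_raw[o] for o in otu_ids])) * 1.2
    opt_ph = _zscore(np.array([opt_ph_raw[o] for o in otu_ids])) * 1.2

    lam = FILTER_RATE * config.filtering_strength
    mismatch = ((z_mat[:, None] - opt_mat[None, :]) ** 2
                + (z_ph[:, None] - opt_ph[None, :]) ** 2)
    filter_w = np.exp(-lam * mismatch)  # sites x otus

    origin = rng_traits.integers(0, config.n_sites, size=n)
    site_dist = _haversine_km(site_lat, site_lon)
    disp_w = np.exp(-config.dispersal_strength
                    * site_dist[:, origin] / DISPERSAL_SCALE_KM)

    module_of = np.full(n, -1)
    module_w = np.ones((config.n_sites, n))
    if config.n_modules > 0:
        # members drawn from mid-to-high abundance ranks so they survive
        # prevalence filtering; the top handful stay module-free
        ranks = np.argsort(pool)[::-1]
        eligible = ranks[5:max(6, int(0.5 * n))]
        needed = config.n_modules * config.module_size
        members = rng_traits.choice(eligible, size=min(needed, len(eligible)),
                                    replace=False)
        for m in range(config.n_modules):
            block = members[m * config.module_size:(m + 1) * config.module_size]
            module_of[block] = m
            pref = np.exp(config.module_strength
                          * rng_traits.normal(0.0, 1.0, size=config.n_sites))
            module_w[:, block] *= pref[:, None]

    expected = pool[None, :] * filter_w * disp_w * module_w
    expected = expected / expected.sum(axis=1, keepdims=True)

    sample_rows, sample_ids, meta_rows = [], [], []
    env_site = _site_environment(site_mat, site_ph, rng_env, config.n_sites)
    for s in range(config.n_sites):
        for r in range(config.replicates_per_site):
            sid = f"S{s + 1:02d}R{r + 1}"
            sample_ids.append(sid)
            sample_rows.append(rng_sample.multinomial(config.depth, expected[s]))
            meta_rows.append(
                {"sample_id": sid, "site_id": f"site{s + 1:02d}",
                 "latitude": site_lat[s], "longitude": site_lon[s],
                 **{v: env_site[v][s] for v in ENV_VARS}}
            )

    counts = pd.DataFrame(np.asarray(sample_rows, dtype=np.int64),
                          index=sample_ids, columns=otu_ids)
    taxonomy = pd.Series(
        [_lineage(rng_tax) for _ in otu_ids], index=otu_ids, name="taxonomy"
    )
    table = OtuTable(counts, taxonomy)
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    truth = GroundTruth(
        pool_abundance=pool, niche_optima_mat=opt_mat, niche_optima_ph=opt_ph,
        origin_site=origin, module_of_otu=module_of, site_mat=site_mat,
        site_ph=site_ph, expected_site_composition=expected, config=config,
    )
    return table, metadata, tree, truth


def _site_environment(site_mat, site_ph, rng, n_sites) -> dict[str, np.ndarray]:
    """Plausible soil/climate values per site; MAP tracks MAT loosely."""
    return {
        "pH": site_ph,
        "OM": rng.lognormal(np.log(15.0), 0.3, n_sites),        # g/kg
        "TN": rng.lognormal(np.log(1.0), 0.3, n_sites),          # g/kg
        "AP": rng.lognormal(np.log(10.0), 0.4, n_sites),         # mg/kg
        "AK": rng.lognormal(np.log(150.0), 0.3, n_sites),        # mg/kg
        "NH4": rng.lognormal(np.log(5.0), 0.4, n_sites),         # mg/kg
        "NO3": rng.lognormal(np.log(10.0), 0.4, n_sites),        # mg/kg
        "MAT": site_mat,                                          # degC
        "MAP": 250.0 + 20.0 * site_mat + rng.normal(0, 30, n_sites),  # mm
    }


def _lineage(rng: np.random.Generator) -> str:
    fam = _FAMILIES[int(rng.integers(0, len(_FAMILIES)))]
    return f"k__K;p__P{int(rng.integers(1, 7))};c__C;o__O;f__{fam};g__G"


def scenario_presets() -> dict[str, ScenarioConfig]:
    """Named seeded scenarios exercising one process each.

    The presets use a 300-OTU pool (enough for every rarity class to be
    populated while keeping null-model runtimes short) and isolate the
    latent processes: ``neutral`` disables all three, ``filtered`` turns
    environmental filtering to its maximum, ``dispersal_limited`` does the
    same for dispersal, and ``modular`` plants four co-occurrence modules.
    Depth scales with the pool size to hold the sequencing intensity near
    10 reads per pool OTU, the intensity rarefied field surveys of this
    kind operate at; oversampling a small pool would suppress the neutral
    sampling variance the stochastic scenarios rely on.
    """
    base = dict(n_otus=300, depth=3000, lognormal_sigma=2.0)
    return {
        "neutral": ScenarioConfig(**base, filtering_strength=0.0,
                                  dispersal_strength=0.0, n_modules=0, seed=101),
        "filtered": ScenarioConfig(**base, filtering_strength=1.0,
                                   dispersal_strength=0.0, n_modules=0, seed=202),
        "dispersal_limited": ScenarioConfig(**base, filtering_strength=0.0,
                                            dispersal_strength=1.0, n_modules=0,
                                            seed=303),
        "modular": ScenarioConfig(**base, filtering_strength=0.0,
                                  dispersal_strength=0.0, n_modules=4,
                                  module_size=25, module_strength=1.5, seed=404),
    }
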