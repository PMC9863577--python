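"""Null-model community-assembly statistics.

Two complementary views of determinism vs stochasticity:

* NTI (nearest taxon index): per-sample standardized effect size of the
  mean nearest-taxon phylogenetic distance (MNTD) against a tip-label
  shuffle null, sign-flipped so that phylogenetic clustering gives NTI > 0.
  NTI > +2 indicates deterministic clustering, < -2 overdispersion.
* NST (normalized stochasticity ratio): per-pair index in [0, 1] comparing
  observed community dissimilarity with its expectation under a null model
  that preserves per-sample richness and draws taxa by regional occupancy
  frequency with abundances proportional to regional relative abundances
  (the proportional-fixed, "PF", algorithm).  0.5 separates more
  deterministic (<0.5) from more stochastic (>0.5) assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .diversity import compare_groups
from .io import OtuTable


def patristic_matrix(tree: dendropy.Tree, otu_ids: list[str]) -> np.ndarray:
    """Tip-to-tip patristic distance matrix ordered by ``otu_ids``.

    Raises if any OTU is missing from the tree, listing the missing tips.
    """
    from skbio import TreeNode

    labels = {t.label for t in tree.taxon_namespace}
    missing = [o for o in otu_ids if o not in labels]
    if missing:
        raise ValueError(f"tree is missing {len(missing)} OTU tip(s): {missing[:10]}")
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    sk = TreeNode.read([newick])
    dm = sk.tip_tip_distances()
    return dm.filter(otu_ids).data


def _mntd_from_matrix(D: np.ndarray, present: np.ndarray,
                      weights: np.ndarray | None = None) -> float:
    sub = D[np.ix_(present, present)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if weights is None:
        return float(nearest.mean())
    w = weights / weights.sum()
    return float((nearest * w).sum())


def mntd(sample_counts, dist: np.ndarray, abundance_weighted: bool = False) -> float:
    """Mean nearest taxon distance of one sample.

    ``dist`` is the patristic matrix over the table's OTU order.  Undefined
    (NaN) for samples with fewer than 2 OTUs present.
    """
    arr = np.asarray(sample_counts, dtype=float)
    present = np.flatnonzero(arr > 0)
    if len(present) < 2:
        return float("nan")
    w = arr[present] if abundance_weighted else None
    return _mntd_from_matrix(dist, present, w)


@dataclass
class NtiResult:
    """Per-sample MNTD null-model comparison."""

    table: pd.DataFrame  # columns: mntd_obs, null_mean, null_sd, nti
    n_null: int
    null_model: str = "taxa_labels"

    @property
    def nti(self) -> pd.Series:
        return self.table["nti"]


def nti(
    table: OtuTable,
    tree: dendropy.Tree,
    n_null: int = 999,
    abundance_weighted: bool = False,
    seed: int | None = None,
    dist: np.ndarray | None = None,
) -> NtiResult:
    """Nearest taxon index per sample against a taxa-label shuffle null.

    The null shuffles tip labels among the OTUs of the analyzed table
    (equivalently, permutes the patristic matrix indices), recomputing MNTD
    for every sample at each of ``n_null`` shuffles.
    NTI = -(MNTD_obs - mean_null) / sd_null; samples where the null has zero
    spread (e.g. star phylogenies) are flagged as NaN.
    """
    if dist is None:
        dist = patristic_matrix(tree, table.otu_ids)
    counts = table.counts.to_numpy(dtype=float)
    n_otus = counts.shape[1]
    present_sets = [np.flatnonzero(row > 0) for row in counts]
    weights = [row[idx] if abundance_weighted else None
               for row, idx in zip(counts, present_sets)]

    obs = np.array([
        _mntd_from_matrix(dist, idx, w) if len(idx) >= 2 else np.nan
        for idx, w in zip(present_sets, weights)
    ])
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, len(present_sets)))
    for b in range(n_null):
        perm = rng.permutation(n_otus)
        for s, (idx, w) in enumerate(zip(present_sets, weights)):
            nulls[b, s] = (_mntd_from_matrix(dist, perm[idx], w)
                           if len(idx) >= 2 else np.nan)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nti_vals = -(obs - null_mean) / null_sd
    nti_vals = np.where(null_sd == 0, np.nan, nti_vals)
    out = pd.DataFrame(
        {"mntd_obs": obs, "null_mean": null_mean, "null_sd": null_sd, "nti": nti_vals},
        index=table.counts.index,
    )
    return NtiResult(table=out, n_null=n_null)


@dataclass
class NstResult:
    """Per-pair normalized stochasticity ratio and group summary."""

    pairs: pd.DataFrame  # sample_a, sample_b, observed, expected, nst
    metric: str
    n_null: int
    group_mean: float = field(init=False)
    group_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.group_mean = float(self.pairs["nst"].mean())
        self.group_sd = float(self.pairs["nst"].std(ddof=1))


def _pair_dissim(prop: np.ndarray, metric: str) -> np.ndarray:
    if metric == "bray":
        return pdist(prop, metric="braycurtis")
    return pdist(prop > 0, metric="jaccard")


def nst(
    table: OtuTable,
    metric: str = "bray",
    n_null: int = 1000,
    seed: int | None = None,
) -> NstResult:
    """Normalized stochasticity ratio for one sample group.

    Null communities (PF algorithm) keep each sample's observed richness,
    draw that many taxa without replacement with probability proportional to
    regional occupancy frequency, and give each drawn taxon an abundance
    proportional to its regional relative abundance.  For each sample pair,
    E_ij is the mean null dissimilarity; the per-pair NST is

        NST_ij = 1 - SS_ij,  SS_ij = (E-D)/E if D < E else (D-E)/(1-E)

    clamped to [0, 1], so agreement with the null (D = E) scores 1 (fully
    stochastic) and both deterministic extremes (identical communities, or
    fully divergent ones) score 0.
    """
    if metric not in ("bray", "jaccard"):
        raise ValueError(f"metric must be 'bray' or 'jaccard', got {metric!r}")
    counts = table.counts.to_numpy(dtype=float)
    n_samples = counts.shape[0]
    if n_samples < 3:
        raise ValueError("NST needs at least 3 samples in the group")
    totals = counts.sum(axis=1, keepdims=True)
    prop = counts / np.where(totals == 0, 1, totals)
    d_obs = _pair_dissim(prop, metric)

    occupancy = (counts > 0).mean(axis=0)
    regional = counts.sum(axis=0)
    regional = regional / regional.sum()
    pool = np.flatnonzero(occupancy > 0)
    p_draw = occupancy[pool] / occupancy[pool].sum()
    richness = (counts > 0).sum(axis=1)

    rng = np.random.default_rng(seed)
    e_sum = np.zeros_like(d_obs)
    null_prop = np.zeros_like(prop)
    for _ in range(n_null):
        null_prop[:] = 0.0
        for i in range(n_samples):
            k = min(richness[i], len(pool))
            if k == 0:
                continue
            chosen = rng.choice(pool, size=k, replace=False, p=p_draw)
            w = regional[chosen]
            if w.sum() == 0:
                w = np.ones(k)
            null_prop[i, chosen] = w / w.sum()
        e_sum += _pair_dissim(null_prop, metric)
    e_mean = e_sum / n_null

    with np.errstate(divide="ignore", invalid="ignore"):
        ss = np.where(d_obs < e_mean,
                      (e_mean - d_obs) / e_mean,
                      (d_obs - e_mean) / (1.0 - e_mean))
    ss = np.nan_to_num(ss, nan=0.0, posinf=1.0)
    nst_ij = np.clip(1.0 - ss, 0.0, 1.0)

    ids = table.sample_ids
    iu = np.triu_indices(n_samples, k=1)
    pairs = pd.DataFrame({
        "sample_a": [ids[i] for i in iu[0]],
        "sample_b": [ids[j] for j in iu[1]],
        "observed": d_obs,
        "expected": e_mean,
        "nst": nst_ij,
    })
    return NstResult(pairs=pairs, metric=metric, n_null=n_null)


def compare_assembly(results_by_subcommunity: dict) -> pd.DataFrame:
    """Mann-Whitney comparison of NTI or per-pair NST distributions across
    subcommunities, with BH-adjusted significance letters."""
    if len(results_by_subcommunity) < 2:
        raise ValueError("need at least 2 subcommunities to compare")
    values = {}
    for name, res in results_by_subcommunity.items():
        if isinstance(res, NtiResult):
            vals = res.nti.dropna().to_numpy()
        elif isinstance(res, NstResult):
            vals = res.pairs["nst"].to_numpy()
        else:
            vals = np.asarray(res, dtype=float)
        if len(vals) == 0:
            raise ValueError(f"subcommunity {name!r} has no values")
        values[name] = vals
    return compare_groups(values)
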