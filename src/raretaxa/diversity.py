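"""Alpha diversity, beta diversity, Levins niche breadth and nonparametric
group comparisons for abundant/rare subcommunities."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io import OtuTable


def richness(sample_counts) -> int:
    """Number of OTUs with count > 0 in one sample."""
    arr = np.asarray(sample_counts)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return int((arr > 0).sum())


def shannon(sample_counts) -> float:
    """Shannon diversity H = -sum p ln p, in nats (vegan convention)."""
    arr = np.asarray(sample_counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness and Shannon index."""
    return pd.DataFrame(
        {
            "richness": [richness(r) for r in table.counts.to_numpy()],
            "shannon": [shannon(r) if r.sum() > 0 else np.nan
                        for r in table.counts.to_numpy()],
        },
        index=table.counts.index,
    )


def _distance(table: OtuTable, metric: str) -> DistanceMatrix:
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    x = table.counts.to_numpy(dtype=float)
    empty = list(table.counts.index[x.sum(axis=1) == 0])
    if len(empty) >= 2:
        raise ValueError(
            f"dissimilarity undefined between all-zero samples: {empty}"
        )
    if metric == "braycurtis":
        d = pdist(x, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(x > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Abundance-based Bray-Curtis dissimilarities between samples:
    BC_ij = sum|x-y| / sum(x+y)."""
    return _distance(table, "braycurtis")


def jaccard(table: OtuTable) -> DistanceMatrix:
    """Presence/absence Jaccard dissimilarities: 1 - |A&B|/|A|B|."""
    return _distance(table, "jaccard")


def pairwise_dissimilarities(dm: DistanceMatrix) -> np.ndarray:
    """Condensed vector of all within-set pairwise dissimilarities — the
    values shown in beta-diversity box plots."""
    return dm.condensed_form()


def levins_niche_breadth(rel: pd.DataFrame) -> pd.Series:
    """Levins niche breadth B = 1 / sum_i q_i^2 per OTU, where q_i is the
    OTU's relative abundance in sample i divided by its total over samples.

    B ranges from 1 (found in a single sample: specialist) to n_samples
    (evenly spread: generalist).  Zero-total OTUs are skipped with a warning.
    """
    totals = rel.sum(axis=0)
    zero = list(totals.index[totals == 0])
    if zero:
        warnings.warn(f"niche breadth undefined for zero-total OTUs: {zero}")
    pos = rel.loc[:, totals > 0]
    q = pos / pos.sum(axis=0)
    b = 1.0 / (q**2).sum(axis=0)
    return b.rename("levins_B")


def _pairwise_mwu(values_by_group: dict) -> pd.DataFrame:
    names = list(values_by_group)
    rows = []
    for a, b in itertools.combinations(names, 2):
        x = np.asarray(values_by_group[a], dtype=float)
        y = np.asarray(values_by_group[b], dtype=float)
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
        u, p = mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append((a, b, float(u), float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p"])


def _compact_letters(names, sig_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Groups that are NOT significantly different share at least one letter;
    significantly different groups share none.
    """
    columns = [set(names)]
    for a, b in sig_pairs:
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop columns that are subsets of another
        columns = [
            c for i, c in enumerate(new_cols)
            if c and not any(c < d or (c == d and i > j)
                             for j, d in enumerate(new_cols))
        ]
    # order letters by the best (highest-mean) member for readable output
    letters = {n: "" for n in names}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for n in names:
            if n in col:
                letters[n] += letter
    return letters


def compare_groups(values_by_group: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between groups with BH
    adjustment and a compact letter display.

    Returns the pairwise table (U, raw p, BH-adjusted q, significance) with
    per-group letters attached as ``.attrs['letters']``.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in values_by_group.items():
        if len(np.asarray(vals)) == 0:
            raise ValueError(f"group {name!r} has no values")
    pairs = _pairwise_mwu(values_by_group)
    _, q, _, _ = multipletests(pairs["p"], method="fdr_bh")
    pairs["q"] = q
    pairs["significant"] = pairs["q"] < alpha
    sig = list(pairs.loc[pairs["significant"], ["group_a", "group_b"]].itertuples(index=False, name=None))
    pairs.attrs["letters"] = _compact_letters(list(values_by_group), sig)
    return pairs
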