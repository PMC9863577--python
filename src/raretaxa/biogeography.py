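"""Distance-decay, Mantel and constrained-ordination biogeography.

All routines operate on distance matrices over the same sample set.  The
distance-decay relationship (DDR) regresses community *similarity*
(1 - Bray-Curtis) on geographic or environmental distance, so dispersal
limitation and environmental filtering both appear as negative slopes.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress, rankdata
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from .io import SampleMetadata

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def geographic_distance(metadata: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distances between samples in km."""
    lat = np.radians(metadata.data["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata.data["longitude"].to_numpy(dtype=float))
    if np.isnan(lat).any() or np.isnan(lon).any():
        raise ValueError("missing coordinates")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ids=metadata.sample_ids)


def transform_env(env_raw: pd.DataFrame, log_exempt=("pH",)) -> pd.DataFrame:
    """log(x+1)-transform all variables except pH, then z-standardize.

    Returns the samples x variables matrix used for environmental distances
    and constrained ordination.
    """
    out = env_raw.astype(float).copy()
    for col in out.columns:
        if col not in log_exempt:
            out[col] = np.log1p(out[col])
    sd = out.std(ddof=1)
    if (sd == 0).any():
        const = list(sd.index[sd == 0])
        logger.warning("constant environmental variable(s) dropped: %s", const)
        out = out.drop(columns=const)
        sd = sd.drop(const)
    return (out - out.mean()) / sd


def environmental_distance(env: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance over (transformed, standardized) variables."""
    d = squareform(pdist(env.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(d, ids=list(env.index.astype(str)))


@dataclass
class DdrFit:
    """Linear distance-decay fit of similarity on distance."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int


def ddr_fit(community_dm: DistanceMatrix, predictor_dm: DistanceMatrix) -> DdrFit:
    """OLS of community similarity (1 - dissimilarity) on predictor distance
    over all unordered sample pairs.

    The parametric p-value treats pairs as independent, which they are not;
    a permutational check of the association should use :func:`mantel`.
    """
    if list(community_dm.ids) != list(predictor_dm.ids):
        predictor_dm = predictor_dm.filter(community_dm.ids)
    sim = 1.0 - community_dm.condensed_form()
    dist = predictor_dm.condensed_form()
    if len(sim) < 3:
        raise ValueError("need at least 3 sample pairs for a DDR fit")
    logger.info("DDR p-value is parametric OLS; pairs are non-independent")
    fit = linregress(dist, sim)
    return DdrFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), p_value=float(fit.pvalue),
        n_pairs=len(sim),
    )


@dataclass
class MantelResult:
    """Spearman Mantel (or partial Mantel) statistic and permutation p."""

    r: float
    p_value: float
    n_permutations: int
    partial: bool = False


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def _condensed(dm: DistanceMatrix, perm: np.ndarray | None = None) -> np.ndarray:
    data = dm.data
    if perm is not None:
        data = data[np.ix_(perm, perm)]
    return squareform(data, checks=False)


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Spearman Mantel test, one-sided 'greater' (vegan convention).

    p = (1 + #{permuted r >= observed r}) / (1 + n_perm) under simultaneous
    row/column permutation of ``dm_b``.
    """
    if dm_a.shape != dm_b.shape or list(dm_a.ids) != list(dm_b.ids):
        raise ValueError("distance matrices must share sample set and order")
    n = dm_a.shape[0]
    a = _condensed(dm_a)
    r_obs = _spearman(a, _condensed(dm_b))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _spearman(a, _condensed(dm_b, perm)) >= r_obs:
            hits += 1
    return MantelResult(r=r_obs, p_value=(1 + hits) / (1 + n_perm), n_permutations=n_perm)


def _partial_r(a, b, c) -> float:
    r_ab, r_ac, r_bc = _spearman(a, b), _spearman(a, c), _spearman(b, c)
    denom_sq = (1 - r_ac**2) * (1 - r_bc**2)
    if denom_sq <= 1e-14:
        # a matrix coincides with the control: nothing left to correlate
        return 0.0
    return (r_ab - r_ac * r_bc) / np.sqrt(denom_sq)


def partial_mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    dm_control: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel: Spearman correlation of A and B controlling C,
    permutation of B's rows/columns for significance (one-sided greater)."""
    for dm in (dm_b, dm_control):
        if dm.shape != dm_a.shape or list(dm.ids) != list(dm_a.ids):
            raise ValueError("distance matrices must share sample set and order")
    a, c = _condensed(dm_a), _condensed(dm_control)
    for name, v in (("dm_a", a), ("dm_b", _condensed(dm_b)), ("dm_control", c)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; partial Mantel undefined")
    n = dm_a.shape[0]
    r_obs = _partial_r(a, _condensed(dm_b), c)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _partial_r(a, _condensed(dm_b, perm), c) >= r_obs:
            hits += 1
    return MantelResult(
        r=r_obs, p_value=(1 + hits) / (1 + n_perm),
        n_permutations=n_perm, partial=True,
    )


def mantel_env_table(
    community_dms: dict[str, DistanceMatrix],
    env_raw: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel r (Spearman) of each community matrix against each single
    environmental variable's Euclidean distance — the variables x
    subcommunities table layout with significance stars."""
    env = transform_env(env_raw)
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(env.columns) * len(community_dms))
    k = 0
    for var in env.columns:
        dm_var = environmental_distance(env[[var]])
        for name, dm in community_dms.items():
            res = mantel(dm, dm_var, n_perm=n_perm,
                         seed=int(children[k].generate_state(1)[0] % 2**31))
            k += 1
            stars = ("***" if res.p_value < 0.001 else "**" if res.p_value < 0.01
                     else "*" if res.p_value < 0.05 else "")
            rows.append((var, name, res.r, res.p_value, stars))
    return pd.DataFrame(rows, columns=["variable", "community", "r", "p", "signif"])


def vif_screen(env_raw: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the variable with the largest variance inflation
    factor until all VIF <= threshold.

    VIF_j = 1/(1 - R2_j) from regressing variable j on the others (with
    intercept).  Perfect collinearity gives an infinite VIF; ties are broken
    by dropping the largest-index variable.
    """
    if env_raw.shape[1] < 2:
        return list(env_raw.columns)
    if env_raw.shape[0] <= env_raw.shape[1]:
        raise ValueError("need more samples than variables for VIF screening")
    cols = list(env_raw.columns)
    x_all = env_raw.to_numpy(dtype=float)

    def vifs(idx):
        out = []
        for j in idx:
            y = x_all[:, j]
            others = [k for k in idx if k != j]
            X = np.column_stack([np.ones(len(y))] + [x_all[:, k] for k in others])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            tss = ((y - y.mean()) ** 2).sum()
            r2 = 1.0 - resid @ resid / tss if tss > 0 else 1.0
            out.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
        return np.array(out)

    active = list(range(len(cols)))
    while len(active) > 1:
        v = vifs(active)
        if np.nanmax(v) <= threshold:
            break
        worst = np.max(v)
        # largest index among variables tied at the maximum
        drop_pos = max(i for i, val in enumerate(v) if val == worst)
        logger.info("VIF screen: dropping %s (VIF=%.2f)", cols[active[drop_pos]], v[drop_pos])
        active.pop(drop_pos)
    return [cols[i] for i in active]


def _pcoa_coords(community_dm: DistanceMatrix) -> np.ndarray:
    """Principal coordinates for positive eigenvalues, scaled by sqrt(eig)."""
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = pcoa(community_dm, method="eigh")
    eig = res.eigvals.to_numpy()
    neg = eig[eig < 0]
    if len(neg):
        logger.info("PCoA: discarding %d negative eigenvalues (total magnitude %.4g)",
                    len(neg), -neg.sum())
    keep = eig > max(1e-10, 1e-8 * abs(eig).max())
    return res.samples.to_numpy()[:, keep]


def _r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Proportion of Y's total variance explained by projection on X
    (with intercept) — the constrained proportion of a db-RDA."""
    Yc = Y - Y.mean(axis=0)
    X1 = np.column_stack([np.ones(len(Y)), X])
    beta, *_ = np.linalg.lstsq(X1, Yc, rcond=None)
    fit = X1 @ beta
    total = (Yc**2).sum()
    return float((fit**2).sum() / total) if total > 0 else 0.0


def _adj_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R2)(n-1)/(n-m-1)."""
    if n - m - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass
class ForwardSelection:
    """db-RDA forward-selection outcome."""

    selected: list[str]
    pseudo_f: dict[str, float]
    p_values: dict[str, float]
    adj_r2: float
    biplot_scores: pd.DataFrame | None


def dbrda_forward_select(
    community_dm: DistanceMatrix,
    env: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> ForwardSelection:
    """Forward selection of environmental variables for a distance-based RDA.

    The community matrix is embedded by PCoA (negative eigenvalues
    discarded); at each step the candidate giving the largest adjusted-R2
    gain is tested with a permutation pseudo-F test (permuting sample rows)
    and added if p <= alpha.  The null distribution is the *maximum* F over
    the remaining candidates, which corrects for best-of-k selection bias
    and keeps the per-step false-selection rate near alpha under pure noise.
    """
    Y = _pcoa_coords(community_dm)
    n = Y.shape[0]
    cols = list(env.columns)
    X_all = env.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    selected: list[int] = []
    fstats: dict[str, float] = {}
    pvals: dict[str, float] = {}
    while True:
        remaining = [j for j in range(len(cols)) if j not in selected]
        if not remaining:
            break
        m = len(selected) + 1

        def step_f(Ymat, j, base):
            r2_full = _r2(Ymat, X_all[:, selected + [j]])
            return ((r2_full - base) / 1) / ((1 - r2_full) / (n - m - 1)), r2_full

        base_r2 = _r2(Y, X_all[:, selected]) if selected else 0.0
        gains = []
        for j in remaining:
            f_j, r2_j = step_f(Y, j, base_r2)
            gains.append((_adj_r2(r2_j, n, m), f_j, j))
        adj_best, f_obs, j_best = max(gains)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Yp = Y[perm]
            r2_red = _r2(Yp, X_all[:, selected]) if selected else 0.0
            f_max = max(step_f(Yp, j, r2_red)[0] for j in remaining)
            if f_max >= f_obs:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        if p > alpha:
            break
        selected.append(j_best)
        fstats[cols[j_best]] = float(f_obs)
        pvals[cols[j_best]] = float(p)

    names = [cols[j] for j in selected]
    if selected:
        final_r2 = _r2(Y, X_all[:, selected])
        adj = _adj_r2(final_r2, n, len(selected))
        # biplot scores: correlation of each selected variable with the
        # first two fitted ordination axes
        X1 = np.column_stack([np.ones(n), X_all[:, selected]])
        beta, *_ = np.linalg.lstsq(X1, Y - Y.mean(axis=0), rcond=None)
        fit = X1 @ beta
        u, s, _ = np.linalg.svd(fit, full_matrices=False)
        axes = u[:, :2] * s[:2]
        scores = pd.DataFrame(
            [[np.corrcoef(X_all[:, j], axes[:, k])[0, 1] if axes[:, k].std() > 0 else 0.0
              for k in range(axes.shape[1])] for j in selected],
            index=names, columns=[f"CAP{k+1}" for k in range(axes.shape[1])],
        )
    else:
        adj = 0.0
        scores = None
    return ForwardSelection(selected=names, pseudo_f=fstats, p_values=pvals,
                            adj_r2=float(adj), biplot_scores=scores)


@dataclass
class VariationPartition:
    """Adjusted-R2 fractions of community variation."""

    env_only: float
    geo_only: float
    shared: float
    residual: float


def variation_partition(
    community_dm: DistanceMatrix,
    env_selected: pd.DataFrame,
    geo_repr: pd.DataFrame,
) -> VariationPartition:
    """Partition community variation into environmental, geographic, shared
    and residual adjusted-R2 fractions via db-RDA.

    ``geo_repr`` is the geographic predictor matrix (latitude and longitude
    columns by default upstream).  The shared fraction can be negative when
    the two predictor sets are suppressors of each other; fractions sum to 1.
    """
    Y = _pcoa_coords(community_dm)
    n = Y.shape[0]

    def adj(X: pd.DataFrame) -> float:
        if X.shape[1] == 0:
            return 0.0
        return _adj_r2(_r2(Y, X.to_numpy(dtype=float)), n, X.shape[1])

    both = pd.concat([env_selected, geo_repr], axis=1)
    r2_env, r2_geo, r2_both = adj(env_selected), adj(geo_repr), adj(both)
    if env_selected.shape[1] == 0:
        r2_both = r2_geo
    if geo_repr.shape[1] == 0:
        r2_both = r2_env
    env_only = r2_both - r2_geo
    geo_only = r2_both - r2_env
    shared = r2_env + r2_geo - r2_both
    return VariationPartition(
        env_only=float(env_only), geo_only=float(geo_only),
        shared=float(shared), residual=float(1.0 - r2_both),
    )
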