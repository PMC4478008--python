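"""Dissimilarity matrices and distance-based statistics.

Three layers of community dissimilarity are supported: Bray-Curtis on
sequence-group counts, normalized weighted UniFrac on the sequence table
plus the phylogeny, and Bray-Curtis on the trait pseudo-abundance matrix.
On top of these sit the spatial statistics: Mantel and partial Mantel
tests with a log10-log10 distance-decay slope and a randomization
(Manly-style) confidence interval, ANOSIM, multiple regression on
distance matrices (MRM), and bioenv-style environmental variable
selection. All permutation tests permute rows and columns of one matrix
simultaneously and use +1-smoothed p-values, p = (1 + #extreme) / (n_perm + 1),
from a seeded generator so results are reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr
from skbio.stats.distance import DistanceMatrix

from ._flat import FlatTree
from .exceptions import ValidationError
from .phylo_io import CommunityTable

log = logging.getLogger(__name__)

__all__ = ["bray_curtis", "weighted_unifrac", "jaccard_binary", "mantel",
           "anosim", "mrm", "bioenv", "prune_correlated_variables",
           "MantelResult", "AnosimResult", "MrmResult", "BioenvResult",
           "driver_analysis"]


# --------------------------------------------------------------------------- #
# dissimilarity layers
# --------------------------------------------------------------------------- #

def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples: sum|x-y| / sum(x+y)."""
    X = table.data.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 samples")
    if (X.sum(axis=1) <= 0).any():
        bad = [s for s, t in zip(table.samples, X.sum(axis=1)) if t <= 0]
        raise ValidationError(f"all-zero samples: {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.samples)


def weighted_unifrac(table: CommunityTable, tree,
                     normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac between samples on a rooted tree.

    Raw score: sum over branches b of l_b * |A_b - B_b| where A_b, B_b are
    the fractions of each sample's total counts descending from b. With
    ``normalized`` (default) the score is divided by
    sum_b l_b * (A_b + B_b) — the value two fully disjoint communities
    would attain — so entries lie in [0, 1].
    """
    flat = _as_flat(tree)
    missing = [u for u in table.units if u not in flat.tip_index]
    if missing:
        raise ValidationError(f"community units not in tree: {missing}")
    X = table.data.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError("all-zero samples")
    P = X / totals[:, None]

    n_samples = X.shape[0]
    mass = np.zeros((n_samples, flat.n))
    tip_pos = {flat.labels[t]: int(t) for t in flat.tip_ids}
    for j, unit in enumerate(table.units):
        mass[:, tip_pos[unit]] = P[:, j]
    parent = flat.parent
    for i in range(flat.n - 1):
        mass[:, parent[i]] += mass[:, i]

    weighted = mass * flat.length[None, :]
    raw = squareform(pdist(weighted, metric="cityblock"))
    if not normalized:
        return DistanceMatrix(raw, ids=table.samples)
    depth_mass = weighted.sum(axis=1)
    denom = depth_mass[:, None] + depth_mass[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2, ids=table.samples)


def jaccard_binary(table: pd.DataFrame) -> DistanceMatrix:
    """Jaccard dissimilarity on a presence/absence table (rows = samples)."""
    X = (table.to_numpy(dtype=float) > 0).astype(float)
    d = squareform(pdist(X, metric="jaccard"))
    return DistanceMatrix(d, ids=[str(i) for i in table.index])


# --------------------------------------------------------------------------- #
# Mantel tests and the distance-decay slope
# --------------------------------------------------------------------------- #

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    slope: float | None = None
    slope_ci: tuple[float, float] | None = None
    intercept: float | None = None
    n_pairs: int = 0
    partial: bool = False


def _aligned_condensed(*dms: DistanceMatrix) -> list[np.ndarray]:
    ids = list(dms[0].ids)
    for dm in dms[1:]:
        if set(dm.ids) != set(ids):
            raise ValidationError("distance matrices have different id sets")
    return [np.asarray(dm.filter(ids).condensed_form(), dtype=float)
            for dm in dms]


def _perm_condensed(square: np.ndarray, perm: np.ndarray,
                    iu: tuple) -> np.ndarray:
    return square[np.ix_(perm, perm)][iu]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na == 0 or nb == 0:
        raise ValidationError("zero variance in a distance triangle")
    return float((a @ b) / (na * nb))


def _residualize(v: np.ndarray, on: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(on), on])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def mantel(dx: DistanceMatrix, dy: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None, conditioning: DistanceMatrix | None = None,
           method: str = "pearson", loglog_slope: bool = False,
           loglog_zero_policy: str = "exclude",
           distance_floor: float = 0.01) -> MantelResult:
    """(Partial) Mantel test of association between two distance matrices.

    r is the Pearson (or Spearman) correlation of the lower-triangle
    entries; the p-value is one-sided (greater), from simultaneous
    row/column permutations of ``dy``. With ``conditioning`` set, both
    triangles are residualized on the third matrix (partial Mantel) and
    the permutation is applied to ``dy`` before residualizing. With
    ``loglog_slope`` the decay slope of log10(dy) on log10(dx) is also
    fitted; pairs with nonpositive values are excluded
    (``loglog_zero_policy='exclude'``) or floored at ``distance_floor``
    (``'floor'``, applied to dx only — meant for geographic distances with
    a sampling grain below the floor). The slope CI is a 95% residual-
    randomization interval driven by the same seeded stream as the test.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if method not in ("pearson", "spearman"):
        raise ValidationError("method must be 'pearson' or 'spearman'")
    mats = [dx, dy] + ([conditioning] if conditioning is not None else [])
    cond = _aligned_condensed(*mats)
    x, y = cond[0], cond[1]
    z = cond[2] if conditioning is not None else None
    n = len(dx.ids)
    iu = np.triu_indices(n, k=1)
    y_sq = squareform(y)
    rng = np.random.default_rng(seed)

    def corr(xv, yv):
        if method == "spearman":
            xv, yv = rankdata(xv), rankdata(yv)
        if z is not None:
            zz = rankdata(z) if method == "spearman" else z
            xv = _residualize(xv, zz)
            yv = _residualize(yv, zz)
        return _pearson(xv, yv)

    r_obs = corr(x, y)
    perms = [rng.permutation(n) for _ in range(n_perm)]
    n_ge = sum(corr(x, _perm_condensed(y_sq, p, iu)) >= r_obs for p in perms)
    p_val = (1 + n_ge) / (n_perm + 1)

    slope = slope_ci = intercept = None
    n_pairs = len(x)
    if loglog_slope:
        lx = x.copy()
        if loglog_zero_policy == "floor":
            lx = np.maximum(lx, distance_floor)
            keep = (lx > 0) & (y > 0)
        elif loglog_zero_policy == "exclude":
            keep = (lx > 0) & (y > 0)
        else:
            raise ValidationError("loglog_zero_policy must be 'exclude' or 'floor'")
        if keep.sum() < 3:
            raise ValidationError("too few positive pairs for the log-log fit")
        lx = np.log10(lx[keep])
        ly = np.log10(y[keep])
        n_pairs = int(keep.sum())
        X = np.column_stack([np.ones_like(lx), lx])
        beta, *_ = np.linalg.lstsq(X, ly, rcond=None)
        intercept, slope = float(beta[0]), float(beta[1])
        resid = ly - X @ beta
        rand_slopes = np.empty(n_perm)
        for i in range(n_perm):
            yr = X @ beta + rng.permutation(resid)
            b, *_ = np.linalg.lstsq(X, yr, rcond=None)
            rand_slopes[i] = b[1]
        lo_d, hi_d = np.quantile(rand_slopes - slope, [0.025, 0.975])
        slope_ci = (slope - hi_d + 0.0, slope - lo_d + 0.0)
        slope_ci = (float(min(slope_ci)), float(max(slope_ci)))
    return MantelResult(r=r_obs, p=p_val, n_perm=n_perm, slope=slope,
                        slope_ci=slope_ci, intercept=intercept,
                        n_pairs=n_pairs, partial=conditioning is not None)


# --------------------------------------------------------------------------- #
# ANOSIM
# --------------------------------------------------------------------------- #

@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int


def anosim(d: DistanceMatrix, groups, n_perm: int = 999,
           seed: int | None = None) -> AnosimResult:
    """Analysis of similarities: are between-group distances larger than within?

    R = (mean rank between - mean rank within) / (N(N-1)/4), ranks taken
    over all pairs; significance by permuting group labels.
    """
    labels = pd.Series(groups).astype(str)
    labels = labels.loc[list(d.ids)]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("need >= 2 groups")
    if (counts < 2).any():
        raise ValidationError(
            f"singleton groups: {counts[counts < 2].index.tolist()}")
    n = len(d.ids)
    condensed = np.asarray(d.condensed_form(), dtype=float)
    ranks = rankdata(condensed)
    codes = labels.to_numpy()
    iu = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0

    def stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = stat(codes)
    rng = np.random.default_rng(seed)
    n_ge = sum(stat(codes[rng.permutation(n)]) >= r_obs
               for _ in range(n_perm))
    return AnosimResult(R=float(r_obs), p=(1 + n_ge) / (n_perm + 1),
                        n_perm=n_perm)


# --------------------------------------------------------------------------- #
# multiple regression on distance matrices
# --------------------------------------------------------------------------- #

@dataclass
class MrmResult:
    coefficients: pd.Series         # incl. intercept
    p_values: pd.Series             # per predictor (permutation, two-sided)
    r_squared: float
    n_perm: int


def mrm(response: DistanceMatrix, predictors: dict[str, DistanceMatrix],
        n_perm: int = 999, seed: int | None = None) -> MrmResult:
    """OLS of the response triangle on predictor triangles, permutation p-values.

    The response matrix's rows/columns are permuted simultaneously and the
    regression refitted; per-coefficient p = (1 + #{|b_perm| >= |b_obs|}) /
    (n_perm + 1). Collinear predictor pairs (condition number > 1e10) are
    rejected with the offending pair named.
    """
    if not predictors:
        raise ValidationError("need >= 1 predictor")
    names = list(predictors)
    mats = _aligned_condensed(response, *[predictors[k] for k in names])
    y = mats[0]
    Xcols = mats[1:]
    X = np.column_stack([np.ones_like(y)] + Xcols)
    if np.linalg.cond(X) > 1e10:
        worst, pair = 0.0, (names[0], names[0])
        for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
            c = abs(np.corrcoef(Xcols[i], Xcols[j])[0, 1])
            if c > worst:
                worst, pair = c, (a, b)
        raise ValidationError(
            f"collinear predictors (|r|={worst:.4f}): {pair[0]} vs {pair[1]}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    n = len(response.ids)
    iu = np.triu_indices(n, k=1)
    y_sq = squareform(y)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _perm_condensed(y_sq, perm, iu)
        bp, *_ = np.linalg.lstsq(X, yp, rcond=None)
        exceed += np.abs(bp[1:]) >= np.abs(beta[1:])
    p = (1 + exceed) / (n_perm + 1)
    coef = pd.Series(beta, index=["intercept"] + names)
    return MrmResult(coefficients=coef,
                     p_values=pd.Series(p, index=names),
                     r_squared=r2, n_perm=n_perm)


# --------------------------------------------------------------------------- #
# environmental variable handling
# --------------------------------------------------------------------------- #

@dataclass
class BioenvResult:
    best_subset: tuple[str, ...]
    correlation: float
    table: pd.DataFrame


def _minmax_scale(env: pd.DataFrame) -> pd.DataFrame:
    scaled = {}
    for col in env.columns:
        v = env[col].to_numpy(dtype=float)
        span = v.max() - v.min()
        if span == 0:
            log.warning("dropping constant variable %r", col)
            continue
        scaled[col] = (v - v.min()) / span
    if not scaled:
        raise ValidationError("no non-constant environmental variables")
    return pd.DataFrame(scaled, index=env.index)


def bioenv(community_d: DistanceMatrix, env: pd.DataFrame,
           max_subset: int | None = None) -> BioenvResult:
    """Exhaustive search for the variable subset best matching community structure.

    Variables are min-max scaled to [0, 1] (constants dropped with a
    warning); for each subset of size <= ``max_subset`` the Euclidean
    distance over the scaled variables is rank-correlated (Spearman)
    with the community dissimilarities; the argmax subset is returned.
    """
    env = env.loc[list(community_d.ids)]
    scaled = _minmax_scale(env)
    names = list(scaled.columns)
    limit = len(names) if max_subset is None else min(max_subset, len(names))
    y = np.asarray(community_d.condensed_form(), dtype=float)
    rows = []
    best = (None, -np.inf)
    for size in range(1, limit + 1):
        for subset in itertools.combinations(names, size):
            d = pdist(scaled[list(subset)].to_numpy(), metric="euclidean")
            rho = spearmanr(d, y).statistic
            rows.append({"subset": subset, "size": size, "rho": rho})
            if rho > best[1]:
                best = (subset, rho)
    table = pd.DataFrame(rows).sort_values("rho", ascending=False,
                                           ignore_index=True)
    return BioenvResult(best_subset=tuple(best[0]),
                        correlation=float(best[1]), table=table)


def prune_correlated_variables(env: pd.DataFrame,
                               r2_threshold: float = 0.7) -> pd.DataFrame:
    """Drop the later of any variable pair with squared correlation >= threshold.

    A deterministic stand-in for variable-clustering pre-filters: variables
    are scanned in input order and a variable is dropped when its squared
    Pearson correlation with an already-kept variable reaches the
    threshold.
    """
    kept: list[str] = []
    for col in env.columns:
        v = env[col].to_numpy(dtype=float)
        if v.std() == 0:
            continue
        redundant = False
        for k in kept:
            r = np.corrcoef(v, env[k].to_numpy(dtype=float))[0, 1]
            if r * r >= r2_threshold:
                log.info("dropping %r (r^2=%.3f with %r)", col, r * r, k)
                redundant = True
                break
        if not redundant:
            kept.append(col)
    return env[kept]


# --------------------------------------------------------------------------- #
# driver analysis (decay + drivers for one or more layers)
# --------------------------------------------------------------------------- #

def driver_analysis(layers: dict[str, DistanceMatrix], metadata,
                    n_perm: int = 999, seed: int | None = None,
                    bonferroni: bool = True, max_subset: int | None = 3,
                    plant_metric: str = "jaccard") -> dict:
    """Distance-decay, ANOSIM, partial Mantel and MRM for each dissimilarity layer.

    Per layer: Mantel of community dissimilarity vs geographic distance
    with the log10-log10 slope; ANOSIM by continent; partial Mantel of
    geography conditioned on plant dissimilarity; MRM with geography,
    environment (bioenv-selected subset, Euclidean) and plant dissimilarity
    as predictors. Raw and Bonferroni-adjusted p-values are both reported;
    the correction is applied across the family of tests of one call.
    """
    ids = list(next(iter(layers.values())).ids)
    meta = metadata.subset(ids)
    geo = meta.geographic_distances()
    if plant_metric != "jaccard":
        raise ValidationError("only the jaccard plant metric is implemented")
    plants = meta.plants
    plant_d = jaccard_binary(plants) if plants.shape[1] else None
    env = prune_correlated_variables(meta.environment)

    results: dict = {"layers": {}, "n_perm": n_perm}
    p_entries = []
    rng = np.random.default_rng(seed)
    for name, dm in layers.items():
        dm = dm.filter(ids)
        layer_seed = int(rng.integers(2 ** 31))
        entry: dict = {}
        dec = mantel(geo, dm, n_perm=n_perm, seed=layer_seed,
                     loglog_slope=True, loglog_zero_policy="floor")
        entry["decay"] = {"r": dec.r, "p": dec.p, "slope": dec.slope,
                          "slope_ci": list(dec.slope_ci), "n_pairs": dec.n_pairs}
        p_entries.append((name, "decay", dec.p))
        ano = anosim(dm, meta.continent, n_perm=n_perm, seed=layer_seed + 1)
        entry["anosim"] = {"R": ano.R, "p": ano.p}
        p_entries.append((name, "anosim", ano.p))

        predictors: dict[str, DistanceMatrix] = {"geography": geo}
        if env.shape[1]:
            sel = bioenv(dm, env, max_subset=max_subset)
            env_d = DistanceMatrix(squareform(
                pdist(_minmax_scale(env[list(sel.best_subset)]).to_numpy(),
                      metric="euclidean")), ids=ids)
            predictors["environment"] = env_d
            entry["bioenv"] = {"subset": list(sel.best_subset),
                               "rho": sel.correlation}
        if plant_d is not None:
            predictors["plants"] = plant_d
            part = mantel(geo, dm, n_perm=n_perm, seed=layer_seed + 2,
                          conditioning=plant_d)
            entry["partial_mantel_geography_given_plants"] = {
                "r": part.r, "p": part.p}
            p_entries.append((name, "partial_mantel", part.p))
        reg = mrm(dm, predictors, n_perm=n_perm, seed=layer_seed + 3)
        entry["mrm"] = {"coefficients": reg.coefficients.to_dict(),
                        "p_values": reg.p_values.to_dict(),
                        "r_squared": reg.r_squared}
        for pname, pv in reg.p_values.items():
            p_entries.append((name, f"mrm_{pname}", pv))
        results["layers"][name] = entry

    if bonferroni:
        m = len(p_entries)
        adjusted = {}
        for layer, test, pv in p_entries:
            adjusted.setdefault(layer, {})[test] = min(1.0, pv * m)
        for layer, entry in results["layers"].items():
            entry["bonferroni_adjusted_p"] = adjusted.get(layer, {})
        results["n_tests"] = m
    return results


def _as_flat(tree) -> FlatTree:
    if isinstance(tree, FlatTree):
        return tree
    return FlatTree.from_dendropy(tree)
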