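"""Pairwise dissimilarities, ordination, group tests, SIMPER, Mantel, and VPA.

Sample x sample dissimilarities are carried as :class:`skbio.DistanceMatrix`
(which enforces symmetry and a zero diagonal).  Bray-Curtis uses scipy's
implementation and unweighted UniFrac scikit-bio's; PCoA, ANOSIM, Mantel,
SIMPER and variance partitioning are implemented here so that permutation
tests are explicitly seeded and eigenvalue/adjustment conventions are under
our control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .tables import CountTable, FracommError

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def bray_curtis_matrix(table: CountTable) -> DistanceMatrix:
    """BC(j,k) = 1 - 2 * sum_i min(x_ij, x_ik) / (sum_i x_ij + sum_i x_ik)."""
    sums = table.sample_sums()
    if (sums == 0).any():
        raise FracommError(
            f"zero-sum samples: {list(sums.index[sums == 0])}"
        )
    mat = table.counts.to_numpy(dtype=float).T  # samples x taxa
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(d, ids=list(table.samples))


def unweighted_unifrac_matrix(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Presence/absence UniFrac: unique branch length / union branch length."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(table.taxa) - tips)
    if missing:
        raise FracommError(f"taxa not in tree: {missing[:5]}")
    return beta_diversity(
        "unweighted_unifrac",
        table.counts.to_numpy().T,
        ids=list(table.samples),
        taxa=list(table.taxa),
        tree=tree,
    )


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def haversine_matrix(sample_meta: pd.DataFrame) -> DistanceMatrix:
    if not {"latitude", "longitude"} <= set(sample_meta.columns):
        raise FracommError("sample metadata lacks latitude/longitude")
    ids = list(sample_meta.index)
    lat = sample_meta["latitude"].to_numpy(dtype=float)
    lon = sample_meta["longitude"].to_numpy(dtype=float)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(d, ids=ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes (positive-eigenvalue axes only)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling of -1/2 J D^2 J.

    Negative eigenvalues are reported untouched (no Cailliez/Lingoes
    correction) and excluded from the coordinates and from
    ``proportion_explained``.
    """
    D = np.asarray(d.data, dtype=float)
    if not np.allclose(D, D.T, atol=1e-8):
        raise FracommError("distance matrix is not symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = scipy.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-12 * float(abs(evals).max())) if evals.size else 1e-12
    pos = evals > tol
    if pos.any():
        coords = evecs[:, pos] * np.sqrt(evals[pos])
        prop = evals[pos] / evals[pos].sum()
    else:  # degenerate input (e.g. all-zero distances)
        coords = np.zeros((n, 1))
        prop = np.array([])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int


def anosim(
    d: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int | str = 999,
    seed: int = 0,
) -> AnosimResult:
    """Clarke's ANOSIM with a label-permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4);
    p = (1 + #{perm R >= observed R}) / (1 + n_perm).  With
    ``n_perm="exact"`` every label permutation is enumerated and
    p = #{R_perm >= R_obs} / n! (the identity is included in the count).
    """
    ids = list(d.ids)
    labels = np.array([groups[i] for i in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise FracommError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        raise FracommError(f"singleton groups: {list(uniq[counts < 2])}")
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d.data[iu])
    denom = n * (n - 1) / 4.0

    def stat(lbl: np.ndarray) -> float:
        within = lbl[iu[0]] == lbl[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    obs = stat(labels)
    if n_perm == "exact":
        import itertools

        total = hits = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if stat(labels[list(perm)]) >= obs - 1e-12:
                hits += 1
        return AnosimResult(r=float(obs), p=hits / total, n_permutations=total)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) >= obs:
            hits += 1
    return AnosimResult(r=float(obs), p=(1 + hits) / (1 + n_perm), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------


@dataclass
class SimperResult:
    contributions: pd.DataFrame  # taxon, contribution, pct, cum_pct (sorted)
    mean_between_dissimilarity: float


def simper(table: CountTable, groups: Mapping[str, str] | pd.Series) -> SimperResult:
    """Decompose mean between-group Bray-Curtis into per-taxon contributions.

    Computed on per-sample relative abundances: for a sample pair (j,k), taxon
    i contributes |x_ij - x_ik| / sum_i (x_ij + x_ik); averaging over all
    between-group pairs, the contributions sum to the mean between-group
    Bray-Curtis dissimilarity exactly.
    """
    labels = pd.Series({s: groups[s] for s in table.samples})
    uniq = labels.unique()
    if len(uniq) != 2:
        raise FracommError("SIMPER supports exactly 2 groups")
    rel = table.relative_abundance()
    a_ids = labels.index[labels == uniq[0]]
    b_ids = labels.index[labels == uniq[1]]
    total = np.zeros(len(table.taxa))
    n_pairs = 0
    for sa in a_ids:
        xa = rel[sa].to_numpy()
        for sb in b_ids:
            xb = rel[sb].to_numpy()
            total += np.abs(xa - xb) / (xa + xb).sum()
            n_pairs += 1
    contrib = total / n_pairs
    df = pd.DataFrame({"taxon": table.taxa, "contribution": contrib})
    df = df.sort_values("contribution", ascending=False, kind="mergesort")
    mean_bc = float(contrib.sum())
    df["pct"] = 100.0 * df["contribution"] / mean_bc
    df["cum_pct"] = df["pct"].cumsum()
    return SimperResult(df.reset_index(drop=True), mean_bc)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int | str = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation over the strict upper triangles, one-sided (>= obs).

    One matrix's rows/columns are permuted jointly; Spearman by default.
    ``n_perm="exact"`` enumerates all n! relabelings (identity included),
    p = #{r_perm >= r_obs} / n!.
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise FracommError("distance matrices have different sample ids")
        d2 = d2.filter(d1.ids)
    if method not in ("spearman", "pearson"):
        raise FracommError(f"unknown method {method!r}")
    x = np.asarray(d1.data, dtype=float)
    y = np.asarray(d2.data, dtype=float)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        if method == "spearman":
            a, b = rankdata(a), rankdata(b)
        a = a - a.mean()
        b = b - b.mean()
        den = np.sqrt((a * a).sum() * (b * b).sum())
        if den == 0:
            raise FracommError("constant distance matrix in Mantel test")
        return float((a * b).sum() / den)

    obs = corr(x[iu], y[iu])
    if n_perm == "exact":
        import itertools

        total = hits = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            pi = np.array(perm)
            if corr(x[iu], y[pi][:, pi][iu]) >= obs - 1e-12:
                hits += 1
        return MantelResult(r=obs, p=hits / total, n_permutations=total, method=method)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(x[iu], y[perm][:, perm][iu]) >= obs:
            hits += 1
    return MantelResult(
        r=obs, p=(1 + hits) / (1 + n_perm), n_permutations=n_perm, method=method
    )


# ---------------------------------------------------------------------------
# Distance decay
# ---------------------------------------------------------------------------


@dataclass
class DistanceDecayResult:
    slope: float
    intercept: float
    mantel: MantelResult | None
    degenerate: bool


def distance_decay(
    table: CountTable, n_perm: int = 999, seed: int = 0
) -> DistanceDecayResult:
    """Regression of Bray-Curtis similarity (1 - BC) on geographic distance.

    Geographic distances are haversine kilometres from the sample metadata
    coordinates; also reports a Mantel test of the two distance matrices.
    """
    if len(table.samples) < 4:
        raise FracommError("distance decay needs at least 4 samples")
    geo = haversine_matrix(table.sample_meta)
    bc = bray_curtis_matrix(table)
    iu = np.triu_indices(len(table.samples), k=1)
    gd = geo.data[iu]
    sim = 1.0 - bc.data[iu]
    if np.allclose(gd, 0):
        return DistanceDecayResult(np.nan, np.nan, None, degenerate=True)
    slope, intercept = np.polyfit(gd, sim, 1)
    mt = mantel(bc, geo, method="spearman", n_perm=n_perm, seed=seed)
    return DistanceDecayResult(float(slope), float(intercept), mt, degenerate=False)


# ---------------------------------------------------------------------------
# Variance partitioning (VPA)
# ---------------------------------------------------------------------------


@dataclass
class VpaResult:
    fractions: dict[str, float]  # 7 unique/shared components + residual
    testable: dict[str, float]  # adjusted R^2 of each fitted subset


def _hellinger(counts: np.ndarray) -> np.ndarray:
    rel = counts / counts.sum(axis=0, keepdims=True)
    return np.sqrt(rel)


def _adjusted_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted RDA R^2 (Ezekiel) of community Y on predictor matrix X."""
    n = Y.shape[0]
    p = X.shape[1]
    if p > n - 1:
        raise FracommError(
            f"{p} predictors for {n} samples: reduce dimensionality first"
        )
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    sst = (Yc**2).sum()
    if sst == 0:
        raise FracommError("community matrix has no variance")
    r2 = (fitted**2).sum() / sst
    # rank-aware Ezekiel adjustment
    rank = np.linalg.matrix_rank(Xc)
    if n - rank - 1 <= 0:
        raise FracommError("not enough residual degrees of freedom")
    return float(1 - (1 - r2) * (n - 1) / (n - rank - 1))


def spatial_predictors(sample_meta: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Principal coordinates of the haversine distance matrix (top k axes)."""
    geo = haversine_matrix(sample_meta)
    ord_res = pcoa(geo)
    k = min(k, ord_res.coordinates.shape[1])
    out = ord_res.coordinates.iloc[:, :k]
    return out.rename(columns={c: f"Spa{i+1}" for i, c in enumerate(out.columns)})


def vpa(table: CountTable, env_sets: Mapping[str, pd.DataFrame]) -> VpaResult:
    """Three-set variance partitioning of the Hellinger-transformed community.

    ``env_sets`` maps set names (conventionally Env, Bio, Spa) to sample x
    predictor DataFrames.  Adjusted R^2 is computed for every subset of sets
    and the unique/shared fractions follow by inclusion-exclusion; fractions
    plus the residual sum to 1 exactly.  Individual fractions may be negative
    (a property of adjusted R^2).
    """
    names = list(env_sets)
    if len(names) != 3:
        raise FracommError("vpa expects exactly three explanatory sets")
    samples = list(table.samples)
    Y = _hellinger(table.counts.to_numpy(dtype=float)).T  # samples x taxa
    X = {}
    for name, df in env_sets.items():
        if set(samples) - set(df.index):
            raise FracommError(f"predictor set {name!r} is missing samples")
        mat = df.loc[samples].to_numpy(dtype=float)
        sd = mat.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise FracommError(f"constant predictor column in set {name!r}")
        X[name] = (mat - mat.mean(axis=0)) / sd

    def r2_of(subset: tuple[str, ...]) -> float:
        return _adjusted_r2(Y, np.hstack([X[s] for s in subset]))

    a, b, c = names
    R = {
        (a,): r2_of((a,)),
        (b,): r2_of((b,)),
        (c,): r2_of((c,)),
        (a, b): r2_of((a, b)),
        (a, c): r2_of((a, c)),
        (b, c): r2_of((b, c)),
        (a, b, c): r2_of((a, b, c)),
    }
    total = R[(a, b, c)]
    u = {
        a: total - R[(b, c)],
        b: total - R[(a, c)],
        c: total - R[(a, b)],
    }
    s_ab = R[(a, c)] + R[(b, c)] - total - R[(c,)]
    s_ac = R[(a, b)] + R[(b, c)] - total - R[(b,)]
    s_bc = R[(a, b)] + R[(a, c)] - total - R[(a,)]
    s_abc = R[(a,)] - u[a] - s_ab - s_ac
    fractions = {
        f"{a}": u[a],
        f"{b}": u[b],
        f"{c}": u[c],
        f"{a}&{b}": s_ab,
        f"{a}&{c}": s_ac,
        f"{b}&{c}": s_bc,
        f"{a}&{b}&{c}": s_abc,
        "residual": 1.0 - total,
    }
    testable = {"+".join(k): v for k, v in R.items()}
    return VpaResult(fractions=fractions, testable=testable)
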