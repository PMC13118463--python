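"""Ecological community-assembly inference.

Implements the phylogenetic null-model framework and the neutral community
model used to apportion assembly among deterministic and stochastic
processes:

* **βMNTD / βNTI** — abundance-weighted β-mean nearest taxon distance between
  sample pairs, compared against a null distribution obtained by shuffling
  tip labels across the whole phylogeny; βNTI is the z-score of the observed
  value against 999 (default) null replicates.
* **RC_Bray** — Bray-Curtis-based Raup-Crick: each null replicate assembles a
  community per sample that preserves the observed richness and read total,
  drawing taxa without replacement with probability proportional to their
  occurrence frequency and allocating reads proportional to regional relative
  abundance; RC rescales the rank of the observed dissimilarity to [-1, 1].
* **Process classification** — βNTI > 2 heterogeneous selection, βNTI < -2
  homogeneous selection, otherwise RC_Bray > 0.95 dispersal limitation,
  RC_Bray < -0.95 homogenizing dispersal, else undominated.
* **Sloan neutral community model** — fits the dispersal parameter of a
  neutral local community to the relationship between a taxon's mean relative
  abundance and its occurrence frequency across samples.

The NCM detection model.  A taxon with metacommunity frequency p has a
stationary local relative abundance ~ Beta(I*p, I*(1-p)), where I is the
fundamental dispersal number of the neutral process (I = m(N-1)/(1-m) for a
local community of N individuals with per-death immigration probability m).
The probability of detecting the taxon in a sample of N reads is

* ``detection="beta-binomial"`` (default): 1 - P(X = 0) under the exact
  beta-binomial count distribution, and
* ``detection="beta"``: 1 - BetaCDF(d; I*p, I*(1-p)) with detection limit
  d = 1/N, the continuous approximation used by the common sncm
  implementations (accurate for small I/N, biased for strong immigration).

The fitted parameter is I (reported as ``Nm``); the immigration rate is
obtained by inverting the Hubbell relation, m = Nm / (Nm + N - 1).  The
widely reported convention m = Nm / N is exposed as ``m_sloan``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist
from scipy.special import betainc, betaln
from skbio import TreeNode
from statsmodels.stats.proportion import proportion_confint

from .tables import CountTable, FracommError
from .util import log

# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------


def patristic_matrix(tree: TreeNode, taxa: Sequence[str]) -> np.ndarray:
    """Dense tip-to-tip distance matrix in the order of ``taxa``."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(taxa) - tips)
    if missing:
        raise FracommError(f"taxa not in tree: {missing[:5]}")
    dm = tree.tip_tip_distances(list(taxa))
    return np.asarray(dm.data, dtype=float)


# ---------------------------------------------------------------------------
# beta-MNTD and beta-NTI
# ---------------------------------------------------------------------------


def _bmntd_all_pairs(
    P: np.ndarray,  # taxa x samples relative abundances
    D: np.ndarray,  # taxa x taxa patristic distances
    supports: list[np.ndarray],
    perm: np.ndarray | None = None,
) -> np.ndarray:
    """βMNTD for every sample pair, optionally under a tip-label permutation.

    Shuffling tip labels is equivalent to remapping taxon indices through
    ``perm`` while keeping the distance matrix fixed, which avoids rebuilding
    anything per replicate.  For each sample b we precompute the distance
    from *every* taxon to its nearest member of b's (permuted) support, so a
    pair evaluation is just a weighted gather.
    """
    S = P.shape[1]
    idx = [perm[s] if perm is not None else s for s in supports]
    # nearest[:, b] = distance from each taxon row to sample b's support
    nearest = np.empty((D.shape[0], S))
    for b in range(S):
        nearest[:, b] = D[:, idx[b]].min(axis=1)
    out = np.zeros((S, S))
    weights = [P[supports[b], b] for b in range(S)]
    for a in range(S):
        for b in range(a + 1, S):
            term_a = weights[a] @ nearest[idx[a], b]
            term_b = weights[b] @ nearest[idx[b], a]
            out[a, b] = out[b, a] = 0.5 * (term_a + term_b)
    return out


def bmntd(table: CountTable, tree: TreeNode, pair: tuple[str, str]) -> float:
    """Abundance-weighted β-mean nearest taxon distance for one sample pair.

    βMNTD = 1/2 [ sum_i f_i(A) min_{j in B} d(i,j) + sum_j f_j(B) min_{i in A}
    d(j,i) ]; a taxon present in both samples contributes distance 0.
    """
    sa, sb = pair
    for s in (sa, sb):
        if s not in table.samples:
            raise FracommError(f"unknown sample {s!r}")
        if table.counts[s].sum() == 0:
            raise FracommError(f"sample {s!r} is empty")
    sub = CountTable(table.counts[[sa, sb]], table.sample_meta.loc[[sa, sb]])
    sub = sub.drop_empty_taxa()
    D = patristic_matrix(tree, list(sub.taxa))
    P = sub.relative_abundance().to_numpy()
    supports = [np.flatnonzero(P[:, j] > 0) for j in range(2)]
    return float(_bmntd_all_pairs(P, D, supports)[0, 1])


@dataclass
class BetaNtiResult:
    pairs: pd.DataFrame  # sample_a, sample_b, bmntd_obs, null_mean, null_sd, bnti
    n_null: int

    @property
    def bnti(self) -> pd.Series:
        return self.pairs["bnti"]


def bnti(
    table: CountTable, tree: TreeNode, n_null: int = 999, seed: int = 0
) -> BetaNtiResult:
    """βNTI for all sample pairs against a tip-label-shuffle null.

    The null randomizes taxon identities across the whole tree ("taxa labels"
    convention) and recomputes βMNTD; βNTI is (observed - null mean) / null
    SD.  Pairs whose null SD is zero are reported with βNTI = NaN rather than
    coerced to 0.
    """
    if n_null < 1:
        raise FracommError("n_null must be >= 1")
    work = table.drop_empty_taxa()
    taxa = list(work.taxa)
    D = patristic_matrix(tree, taxa)
    P = work.relative_abundance().to_numpy()
    S = P.shape[1]
    supports = [np.flatnonzero(P[:, j] > 0) for j in range(S)]
    for j, sup in enumerate(supports):
        if sup.size == 0:
            raise FracommError(f"sample {work.samples[j]!r} is empty")
    obs = _bmntd_all_pairs(P, D, supports)
    rng = np.random.default_rng(seed)
    T = len(taxa)
    null_sum = np.zeros((S, S))
    null_sq = np.zeros((S, S))
    for _ in range(n_null):
        perm = rng.permutation(T)
        nb = _bmntd_all_pairs(P, D, supports, perm)
        null_sum += nb
        null_sq += nb**2
    mean = null_sum / n_null
    var = null_sq / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    iu = np.triu_indices(S, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd[iu] > 0, (obs[iu] - mean[iu]) / sd[iu], np.nan)
    ids = list(work.samples)
    df = pd.DataFrame(
        {
            "sample_a": [ids[i] for i in iu[0]],
            "sample_b": [ids[j] for j in iu[1]],
            "bmntd_obs": obs[iu],
            "null_mean": mean[iu],
            "null_sd": sd[iu],
            "bnti": z,
        }
    )
    return BetaNtiResult(pairs=df, n_null=n_null)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)
# ---------------------------------------------------------------------------


@dataclass
class RaupCrickResult:
    pairs: pd.DataFrame  # sample_a, sample_b, bc_obs, rc
    n_null: int

    @property
    def rc(self) -> pd.Series:
        return self.pairs["rc"]


def _gumbel_topk(logw: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted sampling without replacement (Efraimidis-Spirakis keys)."""
    keys = logw + rng.gumbel(size=logw.size)
    return np.argpartition(-keys, k - 1)[:k]


def rc_bray(
    table: CountTable,
    n_null: int = 999,
    seed: int = 0,
    pool: CountTable | None = None,
) -> RaupCrickResult:
    """Abundance-based Raup-Crick on Bray-Curtis for all sample pairs.

    Null communities preserve each sample's observed richness and read total:
    taxa are drawn without replacement with probability proportional to their
    occurrence frequency, each drawn taxon is seeded with one read, and the
    remaining reads are allocated by a multinomial with probabilities
    proportional to regional relative abundance among the drawn taxa.
    Occurrence and regional abundance are estimated from ``pool`` when given
    (e.g. the full survey while analyzing a sample subset), otherwise from
    ``table`` itself.  One null community is assembled per sample per
    replicate (each pair's null distribution is unchanged relative to
    per-pair assembly).  RC = 2 * [ (#null < obs) + 0.5 * (#null = obs) ]
    / n_null - 1, so RC is bounded in [-1, 1] and centred at 0 under ties.
    """
    if n_null < 1:
        raise FracommError("n_null must be >= 1")
    work = table.drop_empty_taxa()
    if pool is None:
        ref = work
        counts = work.counts
    else:
        ref = pool.drop_empty_taxa()
        missing = sorted(set(work.taxa) - set(ref.taxa))
        if missing:
            raise FracommError(f"taxa absent from the pool table: {missing[:5]}")
        counts = work.counts.reindex(index=list(ref.taxa), fill_value=0)
    mat = counts.to_numpy()
    T, S = mat.shape
    ref_mat = ref.counts.to_numpy()
    occ = (ref_mat > 0).sum(axis=1).astype(float)
    regional = ref_mat.sum(axis=1).astype(float)
    regional /= regional.sum()
    log_occ = np.log(occ)  # occ >= 1 for every retained taxon
    richness = (mat > 0).sum(axis=0)
    depth = mat.sum(axis=0)
    rel_obs = (mat / depth).T  # samples x taxa
    iu = np.triu_indices(S, k=1)
    obs = _bc_condensed(rel_obs)
    rng = np.random.default_rng(seed)
    lt = np.zeros(obs.size)
    eq = np.zeros(obs.size)
    null_rel = np.empty((S, T))
    for _ in range(n_null):
        null_rel[:] = 0.0
        for s in range(S):
            k = int(richness[s])
            drawn = _gumbel_topk(log_occ, k, rng)
            p = regional[drawn]
            counts_s = 1 + rng.multinomial(int(depth[s]) - k, p / p.sum())
            null_rel[s, drawn] = counts_s / depth[s]
        nb = _bc_condensed(null_rel)
        lt += nb < obs - 1e-12
        eq += np.abs(nb - obs) <= 1e-12
    rc = 2.0 * (lt + 0.5 * eq) / n_null - 1.0
    ids = list(work.samples)
    df = pd.DataFrame(
        {
            "sample_a": [ids[i] for i in iu[0]],
            "sample_b": [ids[j] for j in iu[1]],
            "bc_obs": obs,
            "rc": rc,
        }
    )
    return RaupCrickResult(pairs=df, n_null=n_null)


def _bc_condensed(rel: np.ndarray) -> np.ndarray:
    return pdist(rel, metric="braycurtis")


def rc_null_table(table: CountTable, seed: int = 0) -> CountTable:
    """One draw from the null model that ``rc_bray`` uses, as a CountTable.

    Every sample keeps its observed richness and read total, but its taxa are
    re-drawn without replacement proportional to occurrence frequency, seeded
    with one read each, and the remaining reads re-allocated by a
    regional-abundance multinomial.  Running ``rc_bray(..., pool=table)`` on
    such tables is how the RC calibration (uniformity of RC on [-1, 1]) is
    checked.
    """
    work = table.drop_empty_taxa()
    mat = work.counts.to_numpy()
    T, S = mat.shape
    occ = (mat > 0).sum(axis=1).astype(float)
    regional = mat.sum(axis=1).astype(float)
    regional /= regional.sum()
    log_occ = np.log(occ)
    richness = (mat > 0).sum(axis=0)
    depth = mat.sum(axis=0)
    rng = np.random.default_rng(seed)
    out = np.zeros_like(mat)
    for s in range(S):
        k = int(richness[s])
        drawn = _gumbel_topk(log_occ, k, rng)
        p = regional[drawn]
        out[drawn, s] = 1 + rng.multinomial(int(depth[s]) - k, p / p.sum())
    counts = pd.DataFrame(out, index=work.taxa, columns=work.samples)
    return CountTable(counts, work.sample_meta.copy())


# ---------------------------------------------------------------------------
# Process classification
# ---------------------------------------------------------------------------

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class ProcessFractions:
    percentages: dict[str, float]
    n_pairs: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.n_pairs:
            assert abs(sum(self.percentages.values()) - 100.0) < 1e-6


def classify_pair(bnti_value: float, rc_value: float) -> str:
    if np.isnan(bnti_value):
        raise FracommError("cannot classify a pair with undefined bNTI")
    if bnti_value > 2:
        return "heterogeneous_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc_value > 0.95:
        return "dispersal_limitation"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def classify_processes(
    bnti_result: BetaNtiResult, rc_result: RaupCrickResult
) -> tuple[pd.DataFrame, ProcessFractions]:
    """Assign each sample pair to an assembly process and tally fractions.

    Pairs with undefined βNTI (degenerate null SD) are excluded from the
    fractions and counted in ``n_excluded``.
    """
    key = ["sample_a", "sample_b"]
    merged = bnti_result.pairs.merge(rc_result.pairs, on=key, how="inner")
    if len(merged) != len(bnti_result.pairs) or len(merged) != len(rc_result.pairs):
        raise FracommError("bNTI and RC results cover different sample pairs")
    ok = merged["bnti"].notna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.warning("excluding %d pairs with degenerate bNTI null", n_excluded)
    merged["process"] = [
        classify_pair(b, r) if not np.isnan(b) else "excluded"
        for b, r in zip(merged["bnti"], merged["rc"])
    ]
    kept = merged.loc[ok]
    counts = kept["process"].value_counts()
    n = len(kept)
    pct = {p: 100.0 * counts.get(p, 0) / n if n else 0.0 for p in PROCESSES}
    return merged, ProcessFractions(percentages=pct, n_pairs=n, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------


@dataclass
class NcmFit:
    Nm: float  # fundamental dispersal number I of the neutral process
    m: float  # immigration rate, Nm / (Nm + N - 1)
    m_sloan: float  # literature convention Nm / N
    r2: float
    m_ci: tuple[float, float]  # 95% bootstrap CI for m
    detection_limit: float
    mean_depth: float
    n_boot: int
    detection: str
    taxon_table: pd.DataFrame  # p, freq_obs, freq_pred, band


def _predicted_freq(
    Nm: float, p: np.ndarray, N: float, d: float, detection: str
) -> np.ndarray:
    a = Nm * p
    b = Nm * (1.0 - p)
    if detection == "beta":
        return 1.0 - betainc(a, b, d)
    if detection == "beta-binomial":
        # P(X >= 1) = 1 - B(a, b + N) / B(a, b)
        return 1.0 - np.exp(betaln(a, b + N) - betaln(a, b))
    raise FracommError(f"unknown detection model {detection!r}")


def predicted_occurrence(
    Nm: float,
    p: np.ndarray,
    mean_depth: float,
    detection: str = "beta-binomial",
    detection_limit: float | None = None,
) -> np.ndarray:
    """Model-predicted occurrence frequency for mean relative abundances p.

    See the module docstring for the two detection models; the detection
    limit defaults to 1/mean_depth (only used by ``detection="beta"``).
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise FracommError("mean relative abundances must lie in (0, 1)")
    if Nm <= 0 or mean_depth <= 0:
        raise FracommError("Nm and mean_depth must be positive")
    d = detection_limit if detection_limit is not None else 1.0 / mean_depth
    return _predicted_freq(Nm, p, mean_depth, d, detection)


def fit_occurrence_curve(
    p: np.ndarray,
    f: np.ndarray,
    mean_depth: float,
    detection: str = "beta-binomial",
    detection_limit: float | None = None,
) -> tuple[float, float]:
    """Least-squares Nm and R^2 for occurrence frequencies f at abundances p.

    This is the curve-level core of :func:`ncm_fit`, usable directly when
    (p, f) pairs come from somewhere other than a count table.
    """
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    if p.shape != f.shape or p.ndim != 1 or p.size < 3:
        raise FracommError("p and f must be matching 1-D arrays (>= 3 points)")
    N = float(mean_depth)
    d = detection_limit if detection_limit is not None else 1.0 / N
    sst = float(((f - f.mean()) ** 2).sum())
    if sst == 0:
        raise FracommError("occurrence frequencies are constant: no curvature")
    Nm = _fit_nm(p, f, N, d, detection, 1.0, 10.0 * N)
    pred = _predicted_freq(Nm, p, N, d, detection)
    r2 = 1.0 - float(((f - pred) ** 2).sum()) / sst
    return Nm, r2


def _fit_nm(
    p: np.ndarray,
    f: np.ndarray,
    N: float,
    d: float,
    detection: str,
    lo: float,
    hi: float,
    n_grid: int = 40,
) -> float:
    """Least-squares Nm by coarse log-grid search plus bounded refinement."""

    def sse(log_nm: float) -> float:
        pred = _predicted_freq(np.exp(log_nm), p, N, d, detection)
        return float(((f - pred) ** 2).sum())

    grid = np.linspace(np.log(lo), np.log(hi), n_grid)
    vals = [sse(g) for g in grid]
    k = int(np.argmin(vals))
    a = grid[max(0, k - 1)]
    b = grid[min(n_grid - 1, k + 1)]
    res = minimize_scalar(sse, bounds=(a, b), method="bounded")
    return float(np.exp(res.x))


def ncm_fit(
    table: CountTable,
    n_boot: int = 1000,
    seed: int = 0,
    detection: str = "beta-binomial",
    detection_limit: float | None = None,
) -> NcmFit:
    """Fit Sloan's neutral community model to abundance-occupancy data.

    For each taxon, the mean relative abundance p and the occurrence
    frequency f across samples are computed; the dispersal parameter Nm is
    fitted by least squares of f on the model-predicted detection frequency
    (see module docstring for the two detection models).  R^2 = 1 - SSE/SST
    with SST about the mean of f.  The 95% CI for m comes from ``n_boot``
    bootstrap resamples of taxa.  Each taxon is flagged ``above``/``below``/
    ``neutral`` relative to the 95% Wilson binomial prediction band around
    the fitted curve.
    """
    work = table.drop_empty_taxa()
    if len(work.taxa) < 10 or len(work.samples) < 5:
        raise FracommError("NCM fit needs >= 10 taxa and >= 5 samples")
    mat = work.counts.to_numpy()
    n_samples = mat.shape[1]
    N = float(mat.sum(axis=0).mean())
    rel = mat / mat.sum(axis=0)
    p = rel.mean(axis=1)
    f = (mat > 0).mean(axis=1)
    d = detection_limit if detection_limit is not None else 1.0 / N
    sst = float(((f - f.mean()) ** 2).sum())
    if sst == 0:
        raise FracommError(
            "occurrence frequencies are constant: neutral fit has no curvature "
            f"(n_taxa={len(p)}, n_samples={n_samples}, mean depth={N:.0f})"
        )
    lo, hi = 1.0, 10.0 * N
    Nm = _fit_nm(p, f, N, d, detection, lo, hi)
    pred = _predicted_freq(Nm, p, N, d, detection)
    r2 = 1.0 - float(((f - pred) ** 2).sum()) / sst

    def to_m(nm: float) -> float:
        return nm / (nm + N - 1.0)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    T = len(p)
    # bootstrap refits search a window around the point estimate (resampling
    # taxa perturbs Nm far less than the full prior range)
    b_lo = max(lo, Nm * np.exp(-2.0))
    b_hi = min(hi, Nm * np.exp(2.0))
    for i in range(n_boot):
        idx = rng.integers(0, T, T)
        boots[i] = to_m(
            _fit_nm(p[idx], f[idx], N, d, detection, b_lo, b_hi, n_grid=9)
        )
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))

    band_lo, band_hi = proportion_confint(
        np.round(pred * n_samples), n_samples, alpha=0.05, method="wilson"
    )
    band = np.where(f > band_hi, "above", np.where(f < band_lo, "below", "neutral"))
    taxon_table = pd.DataFrame(
        {
            "taxon": work.taxa,
            "p": p,
            "freq_obs": f,
            "freq_pred": pred,
            "band": band,
        }
    ).set_index("taxon")
    return NcmFit(
        Nm=Nm,
        m=to_m(Nm),
        m_sloan=Nm / N,
        r2=r2,
        m_ci=ci,
        detection_limit=d,
        mean_depth=N,
        n_boot=n_boot,
        detection=detection,
        taxon_table=taxon_table,
    )
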