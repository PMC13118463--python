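import numpy as np
import pandas as pd
import pytest
from conftest import (
    brute_bray_curtis,
    brute_mantel_r,
    brute_unifrac,
    exhaustive_anosim_p,
    exhaustive_mantel_p,
    make_table,
)
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from fracomm import (
    anosim,
    bray_curtis_matrix,
    distance_decay,
    haversine_km,
    mantel,
    pcoa,
    simper,
    spatial_predictors,
    unweighted_unifrac_matrix,
    vpa,
)
from fracomm.synthgen import TreeSimConfig, simulate_tree
from fracomm.tables import FracommError

# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def test_bray_curtis_hand_cases():
    t = make_table([[6, 2, 6], [2, 6, 2]])
    d = bray_curtis_matrix(t)
    assert d["S01", "S02"] == pytest.approx(0.5, abs=1e-12)  # (6,2) vs (2,6)
    assert d["S01", "S03"] == pytest.approx(0.0, abs=1e-12)  # identical
    t2 = make_table([[5, 0], [0, 9]])
    assert bray_curtis_matrix(t2)["S01", "S02"] == pytest.approx(1.0)  # disjoint


def test_bray_curtis_zero_sample_errors():
    with pytest.raises(FracommError, match="S02"):
        bray_curtis_matrix(make_table([[3, 0], [1, 0]]))


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------


def test_unifrac_identity_and_star_disjoint():
    # star-like rooted tree: zero-length internal edges, unit tip branches
    star = TreeNode.read(["((a:1,b:1):0,(c:1,d:1):0):0;"])
    t = make_table([[3, 5], [2, 1], [0, 0], [0, 0]], taxa=list("abcd"))
    d = unweighted_unifrac_matrix(t, star)
    assert d["S01", "S02"] == pytest.approx(0.0, abs=1e-12)
    t2 = make_table([[3, 0], [2, 0], [0, 1], [0, 9]], taxa=list("abcd"))
    assert unweighted_unifrac_matrix(t2, star)["S01", "S02"] == pytest.approx(1.0)


def test_unifrac_matches_brute_force():
    rng = np.random.default_rng(3)
    for i in range(20):
        tree = simulate_tree(TreeSimConfig(n_tips=10, seed=500 + i))
        tips = [t.name for t in tree.tips()]
        pres = rng.integers(0, 2, size=(10, 2))
        pres[rng.integers(0, 10), 0] = 1  # non-empty samples
        pres[rng.integers(0, 10), 1] = 1
        t = make_table(pres * (1 + rng.integers(0, 5, size=(10, 2))), taxa=tips)
        d = unweighted_unifrac_matrix(t, tree)
        a = {tips[k] for k in range(10) if t.counts.iloc[k, 0] > 0}
        b = {tips[k] for k in range(10) if t.counts.iloc[k, 1] > 0}
        assert d["S01", "S02"] == pytest.approx(brute_unifrac(tree, a, b), abs=1e-9)


def test_unifrac_missing_tip_errors(toy_tree):
    t = make_table([[1, 2], [3, 4]], taxa=["a", "zzz"])
    with pytest.raises(FracommError, match="zzz"):
        unweighted_unifrac_matrix(t, toy_tree)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def test_pcoa_collinear_points():
    x = np.array([0.0, 1.0, 2.0, 4.0])
    D = np.abs(x[:, None] - x[None, :])
    res = pcoa(DistanceMatrix(D, ids=list("abcd")))
    c1 = res.coordinates.iloc[:, 0].to_numpy()
    # reproduces the line up to reflection/translation
    rebuilt = np.abs(c1[:, None] - c1[None, :])
    assert np.allclose(rebuilt, D, atol=1e-6)
    assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)


def test_pcoa_all_zero_distances():
    res = pcoa(DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))
    assert np.allclose(res.coordinates.to_numpy(), 0.0)


def test_pcoa_euclidean_round_trip():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(6, 3))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    res = pcoa(DistanceMatrix(D, ids=[f"s{i}" for i in range(6)]))
    C = res.coordinates.to_numpy()
    D2 = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
    assert np.allclose(D2, D, atol=1e-6)


def test_pcoa_axes_ordered():
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(7, 4))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    res = pcoa(DistanceMatrix(D, ids=[f"s{i}" for i in range(7)]))
    assert (np.diff(res.eigenvalues) <= 1e-9).all()
    assert res.proportion_explained.sum() <= 1 + 1e-9


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def _dm_from_points(pts, ids):
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(D, ids=ids)


def test_anosim_perfect_separation():
    # two tight clusters far apart: every between distance > every within
    pts = np.vstack([np.random.default_rng(1).normal(0, 0.01, (3, 2)),
                     np.random.default_rng(2).normal(100, 0.01, (3, 2))])
    ids = [f"s{i}" for i in range(6)]
    d = _dm_from_points(pts, ids)
    groups = {i: ("g1" if k < 3 else "g2") for k, i in enumerate(ids)}
    res = anosim(d, groups, n_perm="exact", seed=0)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    # 3-vs-3 design: exactly the 3!*3!*2 partition-preserving label
    # permutations reach R = 1, so the exact p is 72/720 = 0.1
    assert res.p == pytest.approx(0.1, abs=1e-12)


def test_anosim_exact_matches_exhaustive_enumeration():
    rng = np.random.default_rng(4)
    ids = [f"s{i}" for i in range(6)]
    for trial in range(3):
        pts = rng.normal(size=(6, 2))
        d = _dm_from_points(pts, ids)
        labels = ["g1", "g1", "g1", "g2", "g2", "g2"]
        groups = dict(zip(ids, labels))
        res = anosim(d, groups, n_perm="exact")
        assert res.p == pytest.approx(
            exhaustive_anosim_p(d.data, labels), abs=1e-12
        )


def test_anosim_null_p_uniform():
    # 200 simulations with shuffled labels -> p uniform on its grid (KS screen)
    rng = np.random.default_rng(7)
    ids = [f"s{i}" for i in range(8)]
    pvals = []
    for sim in range(200):
        d = _dm_from_points(rng.normal(size=(8, 2)), ids)
        labels = rng.permutation(["g1"] * 4 + ["g2"] * 4)
        res = anosim(d, dict(zip(ids, labels)), n_perm=99, seed=int(rng.integers(2**31)))
        pvals.append(res.p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_anosim_singleton_group_errors():
    d = _dm_from_points(np.random.default_rng(0).normal(size=(4, 2)),
                        ["a", "b", "c", "d"])
    with pytest.raises(FracommError, match="singleton"):
        anosim(d, {"a": "g1", "b": "g1", "c": "g1", "d": "g2"})


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------


def test_simper_two_samples_sum_equals_pair_bc():
    t = make_table([[6, 2], [2, 6], [1, 1]], fractions=["pico", "nano"])
    res = simper(t, t.sample_meta["fraction"])
    rel = t.relative_abundance()
    bc = brute_bray_curtis(rel["S01"], rel["S02"])
    assert res.mean_between_dissimilarity == pytest.approx(bc, abs=1e-12)


def test_simper_hand_toy_2v2():
    # 3 taxa, groups {s1,s2} vs {s3,s4}; relative abundances by construction
    counts = np.array([[5, 4, 1, 0], [3, 4, 6, 5], [2, 2, 3, 5]])
    t = make_table(counts, fractions=["pico", "pico", "nano", "nano"])
    rel = counts / counts.sum(axis=0)
    expected = np.zeros(3)
    for a in (0, 1):
        for b in (2, 3):
            expected += np.abs(rel[:, a] - rel[:, b]) / (rel[:, a] + rel[:, b]).sum()
    expected /= 4
    res = simper(t, t.sample_meta["fraction"])
    got = res.contributions.set_index("taxon")["contribution"]
    for k, taxon in enumerate(t.taxa):
        assert got[taxon] == pytest.approx(expected[k], abs=1e-12)
    assert res.contributions["cum_pct"].iloc[-1] == pytest.approx(100.0, abs=1e-9)


def test_simper_absent_taxon_contributes_zero():
    t = make_table([[5, 1], [0, 0], [2, 6]], fractions=["pico", "nano"])
    res = simper(t, t.sample_meta["fraction"])
    got = res.contributions.set_index("taxon")["contribution"]
    assert got["T002"] == 0.0


def test_simper_rejects_three_groups():
    t = make_table([[1, 2, 3]], fractions=["pico", "nano", "pico"],
                   samples=["a", "b", "c"])
    with pytest.raises(FracommError):
        simper(t, pd.Series({"a": "x", "b": "y", "c": "z"}))


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def test_mantel_identity_and_monotone():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(6, 2))
    d1 = _dm_from_points(pts, [f"s{i}" for i in range(6)])
    res = mantel(d1, d1, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    d2 = DistanceMatrix(np.sqrt(d1.data), ids=list(d1.ids))
    res2 = mantel(d1, d2, method="spearman", n_perm=99, seed=0)
    assert res2.r == pytest.approx(1.0, abs=1e-12)


def test_mantel_exact_matches_exhaustive_120_perms():
    rng = np.random.default_rng(6)
    ids = [f"s{i}" for i in range(5)]
    for trial in range(3):
        d1 = _dm_from_points(rng.normal(size=(5, 2)), ids)
        d2 = _dm_from_points(rng.normal(size=(5, 2)), ids)
        for method in ("spearman", "pearson"):
            res = mantel(d1, d2, method=method, n_perm="exact")
            assert res.n_permutations == 120
            assert res.r == pytest.approx(
                brute_mantel_r(d1.data, d2.data, method), abs=1e-12
            )
            assert res.p == pytest.approx(
                exhaustive_mantel_p(d1.data, d2.data, method), abs=1e-12
            )


def test_mantel_label_mismatch_errors():
    d1 = DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ids=["a", "b"])
    d2 = DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ids=["a", "c"])
    with pytest.raises(FracommError):
        mantel(d1, d2)


# ---------------------------------------------------------------------------
# Haversine & distance decay
# ---------------------------------------------------------------------------


def test_haversine_closed_forms():
    assert haversine_km(10.0, 20.0, 10.0, 20.0) == 0.0
    antipodal = haversine_km(0.0, 0.0, 0.0, 180.0)
    assert antipodal == pytest.approx(np.pi * 6371.0, rel=1e-9)


def test_distance_decay_degenerate_geometry():
    t = make_table([[3, 1, 2, 4], [1, 2, 3, 1]],
                   lat=[5.0] * 4, lon=[100.0] * 4)
    res = distance_decay(t)
    assert res.degenerate
    assert np.isnan(res.slope)


def test_distance_decay_calibration():
    # spatially autocorrelated composition: Gaussian niches along the transect
    n, T = 14, 40
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(40_000 + seed)
        x = np.linspace(0, 1, n)
        peaks = rng.uniform(0, 1, T)
        comp = np.exp(-((peaks[:, None] - x[None, :]) ** 2) / 0.01)
        comp /= comp.sum(axis=0)
        counts = rng.multinomial(2000, comp[:, 0])[:, None]
        counts = np.column_stack(
            [rng.multinomial(2000, comp[:, j]) for j in range(n)]
        )
        t = make_table(counts, lat=[15.0] * n, lon=list(130 + 30 * x))
        res = distance_decay(t, n_perm=199, seed=seed)
        if res.slope < 0 and res.mantel.p < 0.05:
            hits += 1
    assert hits >= 90


# ---------------------------------------------------------------------------
# VPA
# ---------------------------------------------------------------------------


def _vpa_table(comp, n, depth=2_000_000):
    counts = np.round(comp * depth).astype(int)
    return make_table(counts)


def test_vpa_fractions_sum_to_one_exactly():
    rng = np.random.default_rng(0)
    n = 20
    t = make_table(rng.integers(1, 500, size=(15, n)))
    samples = list(t.samples)
    sets = {
        "Env": pd.DataFrame({"e": rng.normal(size=n)}, index=samples),
        "Bio": pd.DataFrame({"b": rng.normal(size=n)}, index=samples),
        "Spa": pd.DataFrame({"s": rng.normal(size=n)}, index=samples),
    }
    res = vpa(t, sets)
    assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_vpa_planted_env_only_signal():
    rng = np.random.default_rng(0)
    n, T = 30, 12
    e = rng.normal(size=n)
    b = rng.normal(size=T) * 0.4
    base = rng.uniform(1, 3, T)
    comp = np.exp(np.log(base)[:, None] + b[:, None] * e[None, :])
    comp /= comp.sum(axis=0)
    t = _vpa_table(comp, n)
    samples = list(t.samples)
    sets = {
        "Env": pd.DataFrame({"e": e}, index=samples),
        "Bio": pd.DataFrame({"b1": rng.normal(size=n)}, index=samples),
        "Spa": pd.DataFrame({"s1": rng.normal(size=n)}, index=samples),
    }
    res = vpa(t, sets)
    total = 1.0 - res.fractions["residual"]
    assert abs(res.fractions["Env"] - total) < 0.05
    assert abs(res.fractions["Bio"]) < 0.05
    assert abs(res.fractions["Spa"]) < 0.05


def test_vpa_orthogonal_predictors_no_shared_fractions():
    rng = np.random.default_rng(1)
    n, T = 30, 12
    M = rng.normal(size=(n, 3))
    Q, _ = np.linalg.qr(M - M.mean(axis=0))
    e, b, s = Q[:, 0], Q[:, 1], Q[:, 2]
    ce, cb, cs = (rng.normal(size=T) * 0.5 for _ in range(3))
    base = rng.uniform(1, 3, T)
    comp = np.exp(np.log(base)[:, None] + ce[:, None] * e + cb[:, None] * b
                  + cs[:, None] * s)
    comp /= comp.sum(axis=0)
    t = _vpa_table(comp, n)
    samples = list(t.samples)
    res = vpa(t, {
        "Env": pd.DataFrame({"e": e}, index=samples),
        "Bio": pd.DataFrame({"b": b}, index=samples),
        "Spa": pd.DataFrame({"s": s}, index=samples),
    })
    for key in ("Env&Bio", "Env&Spa", "Bio&Spa", "Env&Bio&Spa"):
        assert abs(res.fractions[key]) < 0.05


def test_vpa_too_many_predictors_errors():
    rng = np.random.default_rng(2)
    n = 6
    t = make_table(rng.integers(1, 100, size=(10, n)))
    samples = list(t.samples)
    wide = pd.DataFrame(rng.normal(size=(n, 7)),
                        index=samples, columns=[f"v{i}" for i in range(7)])
    one = pd.DataFrame({"x": rng.normal(size=n)}, index=samples)
    with pytest.raises(FracommError, match="reduce dimensionality"):
        vpa(t, {"Env": wide, "Bio": one, "Spa": one.rename(columns={"x": "y"})})


def test_vpa_constant_predictor_errors():
    rng = np.random.default_rng(3)
    n = 10
    t = make_table(rng.integers(1, 100, size=(8, n)))
    samples = list(t.samples)
    const = pd.DataFrame({"c": np.ones(n)}, index=samples)
    one = pd.DataFrame({"x": rng.normal(size=n)}, index=samples)
    with pytest.raises(FracommError, match="constant"):
        vpa(t, {"Env": const, "Bio": one, "Spa": one.rename(columns={"x": "y"})})


def test_spatial_predictors_shape():
    t = make_table(np.ones((3, 6), dtype=int),
                   lat=list(np.linspace(10, 20, 6)),
                   lon=list(np.linspace(130, 160, 6)))
    spa = spatial_predictors(t.sample_meta, k=3)
    assert list(spa.index) == list(t.samples)
    assert spa.shape[1] <= 3 and spa.shape[1] >= 1
    assert list(spa.columns) == [f"Spa{i+1}" for i in range(spa.shape[1])]
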