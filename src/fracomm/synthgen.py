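"""Synthetic two-fraction community datasets with a known assembly regime.

Generates everything the downstream analyses consume — a ZOTU count table for
pico and nano size fractions sampled at stations along a west-to-east
transect, a random phylogeny, station coordinates, and correlated
environmental covariates — from a single seed, under one of four assembly
regimes:

``neutral``
    Every sample is an independent stationary draw of a Hubbell-type local
    community: at each event one random individual dies and is replaced, with
    probability ``m`` by an immigrant drawn from the metacommunity and
    otherwise by the offspring of a random local individual.
``heterogeneous_selection``
    Taxa carry a Brownian trait evolved along the tree; stations fall into two
    groups with divergent environmental optima and each sample is drawn under
    a Gaussian trait filter, producing phylogenetically clustered turnover
    between the groups.
``homogeneous_selection``
    The same Gaussian filter with a single optimum shared by all stations.
``mixed``
    An even mixture of the neutral and heterogeneous-selection compositions.

The metacommunity is log-normal (heavy-tailed: a few dominant taxa and a long
rare tail), the two fractions draw from partially overlapping taxon pools, and
per-sample read depths are Poisson-distributed around ``depth_mean``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from skbio import TreeNode

from .tables import CountTable, FracommError
from .util import log, rng_from, write_tsv

# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeSimConfig:
    n_tips: int
    branch_rate: float = 1.0  # expected branch length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise FracommError("a tree needs at least 2 tips")
        if self.branch_rate <= 0:
            raise FracommError("branch_rate must be positive")


@dataclass(frozen=True)
class NeutralSimConfig:
    J: int  # local community size (individuals)
    m: float  # immigration probability per replacement (0 = closed community)
    generations: int  # number of single-replacement events
    metacommunity: tuple  # probability vector over taxa
    seed: int = 0
    init: str = "metacommunity"  # or "monodominant"

    def __post_init__(self) -> None:
        if self.J < 10:
            raise FracommError("local community size J must be >= 10")
        if not (0 <= self.m <= 1):
            raise FracommError("migration m must lie in [0, 1]")
        if self.generations < 1:
            raise FracommError("generations must be positive")
        if self.init not in ("metacommunity", "monodominant"):
            raise FracommError(f"unknown init {self.init!r}")
        p = np.asarray(self.metacommunity, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise FracommError("metacommunity must be a probability vector")


@dataclass(frozen=True)
class SelectionSimConfig:
    trait_sigma: float = 1.0  # Brownian rate on the tree
    filter_width: float = 1.0  # Gaussian filter SD in trait units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_sigma <= 0:
            raise FracommError("trait_sigma must be positive")
        if self.filter_width <= 0:
            raise FracommError("filter_width must be positive")


@dataclass(frozen=True)
class DatasetConfig:
    """Study design knobs for a full synthetic dataset.

    Defaults emulate the survey this package targets: 14 stations sampled for
    two size fractions, ~1,400 taxa of which ~80% are shared between the
    fraction pools, and read depths in the tens of thousands.
    """

    n_stations: int = 14
    fractions: tuple = ("pico", "nano")
    n_taxa: int = 1400
    depth_mean: int = 50_000
    shared_fraction_target: float = 0.8
    regime: str = "neutral"
    migration: float = 0.7  # per-death immigration probability (neutral/mixed)
    generations_per_individual: int = 10  # events = this x J
    trait_sigma: float = 1.0
    lognormal_sigma: float = 2.0  # heavy tail of the metacommunity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 3:
            raise FracommError("need at least 3 stations")
        if self.depth_mean < 100:
            raise FracommError("depth_mean must be >= 100")
        if not (0 < self.shared_fraction_target <= 1):
            raise FracommError("shared_fraction_target must lie in (0, 1]")
        if self.regime not in (
            "neutral",
            "heterogeneous_selection",
            "homogeneous_selection",
            "mixed",
        ):
            raise FracommError(f"unknown regime {self.regime!r}")


# ---------------------------------------------------------------------------
# Tree simulation (Yule topology, exponential branch lengths)
# ---------------------------------------------------------------------------


def simulate_tree(config: TreeSimConfig) -> TreeNode:
    """Yule pure-birth topology with i.i.d. exponential branch lengths.

    Tips are labelled ``Z0001..`` in birth order; the root branch has length
    zero.  Deterministic given the seed.
    """
    rng = rng_from(config.seed)
    root = TreeNode(name=None, length=0.0)
    a, b = TreeNode(), TreeNode()
    root.extend([a, b])
    tips = [a, b]
    while len(tips) < config.n_tips:
        k = int(rng.integers(len(tips)))
        parent = tips.pop(k)
        c1, c2 = TreeNode(), TreeNode()
        parent.extend([c1, c2])
        tips.extend([c1, c2])
    for i, tip in enumerate(root.tips()):
        tip.name = f"Z{i + 1:05d}"
    for node in root.postorder(include_self=False):
        node.length = float(rng.exponential(config.branch_rate))
    return root


def evolve_trait(tree: TreeNode, sigma: float, seed: int = 0) -> dict[str, float]:
    """Brownian motion along the tree: child = parent + N(0, sigma^2 * branch).

    Returns a tip-name -> trait mapping; the root trait is 0, so a tip's
    marginal variance is sigma^2 times its root-to-tip path length.
    """
    if sigma <= 0:
        raise FracommError("sigma must be positive")
    rng = rng_from(seed)
    values: dict[int, float] = {id(tree): 0.0}
    traits: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        bl = node.length or 0.0
        val = values[id(node.parent)] + rng.normal(0.0, sigma * np.sqrt(bl))
        values[id(node)] = val
        if node.is_tip():
            traits[node.name] = float(val)
    return traits


# ---------------------------------------------------------------------------
# Neutral (Hubbell/Moran) community simulation
# ---------------------------------------------------------------------------


@njit(cache=False)
def _moran_events(comm, deaths, coins, meta_draws, parents, m):  # pragma: no cover
    for t in range(deaths.size):
        i = deaths[t]
        if coins[t] < m:
            comm[i] = meta_draws[t]
        else:
            comm[i] = comm[parents[t]]


def simulate_neutral_counts(config: NeutralSimConfig) -> np.ndarray:
    """Census counts of the local community after ``generations`` events.

    The community starts as a multinomial draw from the metacommunity
    (``init="metacommunity"``; close to stationarity, so short runs suffice)
    or as J copies of the most abundant metacommunity taxon
    (``init="monodominant"``; useful for studying convergence), and is then
    run forward under single-replacement Moran dynamics with immigration
    probability ``m``; all randomness is pre-generated with numpy so results
    are bit-reproducible given the seed.
    """
    rng = rng_from(config.seed)
    p = np.asarray(config.metacommunity, dtype=float)
    cum = np.cumsum(p)
    J, n = config.J, config.generations
    if config.init == "monodominant":
        comm = np.full(J, int(np.argmax(p)), dtype=np.int64)
    else:
        comm = np.searchsorted(cum, rng.random(J)).astype(np.int64)
    deaths = rng.integers(0, J, n)
    coins = rng.random(n)
    meta_draws = np.searchsorted(cum, rng.random(n)).astype(np.int64)
    parents = rng.integers(0, J, n)
    _moran_events(comm, deaths, coins, meta_draws, parents, config.m)
    return np.bincount(comm, minlength=p.size)


def simulate_neutral_community(config: NeutralSimConfig) -> np.ndarray:
    """Relative abundances of the local community (see simulate_neutral_counts)."""
    counts = simulate_neutral_counts(config)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Environmental selection
# ---------------------------------------------------------------------------


def simulate_selected_community(
    metacommunity: pd.Series,
    traits: Mapping[str, float],
    env: float,
    config: SelectionSimConfig,
) -> pd.Series:
    """Deterministic environmental filtering of the metacommunity.

    Sampling weight of taxon i is metacommunity_i * exp(-(trait_i - env)^2 /
    (2 * filter_width^2)), renormalized.
    """
    taxa = [t for t in metacommunity.index if t in traits]
    if not taxa:
        raise FracommError("no overlap between metacommunity taxa and traits")
    meta = metacommunity.loc[taxa].to_numpy(dtype=float)
    tr = np.array([traits[t] for t in taxa])
    w = meta * np.exp(-((tr - env) ** 2) / (2.0 * config.filter_width**2))
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise FracommError("selection filter removed all probability mass")
    return pd.Series(w / total, index=taxa)


def sample_reads(composition: np.ndarray, depth: int, seed: int = 0) -> np.ndarray:
    """Multinomial sequencing draw; counts sum exactly to ``depth``."""
    if depth <= 0:
        raise FracommError("depth must be positive")
    p = np.asarray(composition, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise FracommError("composition must be a probability vector")
    rng = rng_from(seed)
    return rng.multinomial(depth, p / p.sum())


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    table: CountTable
    tree: TreeNode
    env: pd.DataFrame  # sample x variable
    env_groups: dict[str, str]  # variable -> {"Env", "Bio"}
    config: DatasetConfig
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.write(outdir / "counts.tsv", outdir / "metadata.tsv")
        write_tsv(self.env, outdir / "env.tsv", index_label="sample")
        self.tree.write(str(outdir / "tree.nwk"))
        manifest = {
            "config": asdict(self.config),
            "env_groups": self.env_groups,
            "n_taxa": int(len(self.table.taxa)),
            "n_samples": int(len(self.table.samples)),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _fraction_pools(
    taxa: Sequence[str], target: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Two equal-size taxon pools whose overlap / union ratio is ``target``."""
    n = len(taxa)
    n_shared = int(round(n * target))
    pool_size = (n + n_shared) // 2
    order = rng.permutation(n)
    shared = order[:n_shared]
    rest = order[n_shared:]
    n_uniq = pool_size - n_shared
    pools = {
        "pico": np.sort(np.concatenate([shared, rest[:n_uniq]])),
        "nano": np.sort(np.concatenate([shared, rest[n_uniq : 2 * n_uniq]])),
    }
    return pools


def generate_dataset(config: DatasetConfig) -> SyntheticDataset:
    """Build a complete synthetic study (counts, tree, coordinates, environment).

    One sample per station per size fraction; stations lie on a monotone
    west-to-east transect; environmental covariates follow the spatial
    gradient plus noise with a shared latent factor inducing collinearity.
    Fully reproducible given ``config.seed``.
    """
    rng = rng_from(config.seed, "dataset")

    tree = simulate_tree(TreeSimConfig(config.n_taxa, 1.0, rng_int(rng)))
    taxa = [t.name for t in tree.tips()]
    meta_ab = rng.lognormal(0.0, config.lognormal_sigma, config.n_taxa)
    meta_ab /= meta_ab.sum()
    metacommunity = pd.Series(meta_ab, index=taxa)

    pools = _fraction_pools(taxa, config.shared_fraction_target, rng)

    # -- stations, coordinates, environment ---------------------------------
    n = config.n_stations
    stations = [f"ST{i + 1:02d}" for i in range(n)]
    lon = np.linspace(130.0, 160.0, n) + rng.normal(0, 0.05, n)
    lon.sort()  # keep the transect monotone
    lat = 15.0 + rng.normal(0, 1.0, n)
    gradient = np.linspace(-1.0, 1.0, n)
    latent = rng.normal(0, 0.3, n)  # shared factor -> controlled collinearity

    traits = evolve_trait(tree, config.trait_sigma, rng_int(rng))
    trait_arr = np.array([traits[t] for t in taxa])
    t_mean, t_sd = trait_arr.mean(), trait_arr.std()

    regime = config.regime
    if regime == "heterogeneous_selection" or regime == "mixed":
        group = np.array([0] * (n // 2) + [1] * (n - n // 2))
        optima = np.where(group == 0, t_mean - 1.5 * t_sd, t_mean + 1.5 * t_sd)
        env_filter = optima + rng.normal(0, 0.05 * t_sd, n)
    elif regime == "homogeneous_selection":
        env_filter = np.full(n, t_mean) + rng.normal(0, 0.05 * t_sd, n)
    else:
        env_filter = gradient + rng.normal(0, 0.2, n)
    sel_cfg = SelectionSimConfig(
        trait_sigma=config.trait_sigma,
        filter_width=0.5 * t_sd if t_sd > 0 else 1.0,
        seed=rng_int(rng),
    )

    env_vars = {
        "temperature": 28.0 - 2.0 * gradient + latent + rng.normal(0, 0.3, n),
        "salinity": 34.5 + 0.4 * gradient + 0.5 * latent + rng.normal(0, 0.1, n),
        "no3_no2": np.exp(-0.5 * gradient + 0.5 * latent + rng.normal(0, 0.2, n)),
        "po4": np.exp(-0.4 * gradient + 0.5 * latent + rng.normal(0, 0.2, n)),
        "env_filter": env_filter,
    }
    bio_vars = {
        "bacteria": np.exp(0.3 * gradient + latent + rng.normal(0, 0.2, n)),
        "pnf_biomass": np.exp(0.2 * gradient + 0.8 * latent + rng.normal(0, 0.2, n)),
        "ciliate_biomass": np.exp(-0.2 * gradient + 0.5 * latent + rng.normal(0, 0.2, n)),
    }
    env_groups = {k: "Env" for k in env_vars} | {k: "Bio" for k in bio_vars}
    station_env = pd.DataFrame({**env_vars, **bio_vars}, index=stations)

    # -- per-sample communities ----------------------------------------------
    sample_ids, meta_rows, count_cols = [], [], []
    for f in config.fractions:
        pool_idx = pools[f]
        pool_taxa = [taxa[i] for i in pool_idx]
        meta_f = metacommunity.iloc[pool_idx]
        meta_f = meta_f / meta_f.sum()
        for s_i, st in enumerate(stations):
            sid = f"{st}_{f}"
            depth = max(100, int(rng.poisson(config.depth_mean)))
            if regime == "neutral":
                ncfg = NeutralSimConfig(
                    J=depth,
                    m=config.migration,
                    generations=config.generations_per_individual * depth,
                    metacommunity=tuple(meta_f.to_numpy()),
                    seed=rng_int(rng),
                )
                counts = simulate_neutral_counts(ncfg)
            elif regime in ("heterogeneous_selection", "homogeneous_selection"):
                comp = simulate_selected_community(
                    meta_f, traits, env_filter[s_i], sel_cfg
                ).to_numpy()
                counts = sample_reads(comp, depth, rng_int(rng))
            else:  # mixed: even blend of drifted-neutral and selected mass
                ncfg = NeutralSimConfig(
                    J=depth,
                    m=config.migration,
                    generations=config.generations_per_individual * depth,
                    metacommunity=tuple(meta_f.to_numpy()),
                    seed=rng_int(rng),
                )
                neutral = simulate_neutral_counts(ncfg) / depth
                selected = simulate_selected_community(
                    meta_f, traits, env_filter[s_i], sel_cfg
                ).to_numpy()
                comp = 0.5 * neutral + 0.5 * selected
                counts = sample_reads(comp / comp.sum(), depth, rng_int(rng))
            full = np.zeros(config.n_taxa, dtype=np.int64)
            full[pool_idx] = counts
            sample_ids.append(sid)
            count_cols.append(full)
            meta_rows.append(
                {
                    "sample": sid,
                    "fraction": f,
                    "station": st,
                    "latitude": lat[s_i],
                    "longitude": lon[s_i],
                }
            )

    counts_df = pd.DataFrame(
        np.column_stack(count_cols), index=taxa, columns=sample_ids
    )
    sample_meta = pd.DataFrame(meta_rows).set_index("sample")
    env = station_env.loc[sample_meta["station"]].set_index(sample_meta.index)

    # identifier spaces must line up by construction
    assert set(counts_df.index) == {t.name for t in tree.tips()}
    assert list(counts_df.columns) == list(sample_meta.index) == list(env.index)

    table = CountTable(counts_df, sample_meta).drop_empty_taxa()
    return SyntheticDataset(
        table=table,
        tree=tree,
        env=env,
        env_groups=env_groups,
        config=config,
        truth={"traits": traits, "env_filter": dict(zip(stations, env_filter))},
    )


def rng_int(rng: np.random.Generator) -> int:
    """Child seed below 2**31 drawn from a generator."""
    return int(rng.integers(0, 2**31 - 1))
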