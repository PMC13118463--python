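"""Config-driven orchestration of the full analysis sequence.

``run_pipeline`` executes, per size fraction where applicable: rarefaction ->
abundance classes -> alpha diversity (with pico-vs-nano Wilcoxon rank-sum
tests) -> Bray-Curtis / UniFrac / PCoA / ANOSIM -> SIMPER -> Mantel and
distance decay -> variance partitioning -> βNTI / RC_Bray / process fractions
-> neutral-model fit -> co-occurrence network, Zi-Pi roles and attack
simulation -> the shared/unique partition.  Every artifact is written as TSV
(fixed float format) plus a JSON manifest capturing the config and seeds, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import betadiv, netsci, tables
from .assembly import bnti, classify_processes, ncm_fit, rc_bray
from .synthgen import DatasetConfig, SyntheticDataset, generate_dataset
from .tables import (
    AbundanceClassConfig,
    CountTable,
    FRACTIONS,
    FracommError,
    alpha_diversity,
    classify_abundance,
    rarefy,
    read_tree,
    shared_unique_partition,
)
from .netsci import NetworkFilterConfig
from .util import derive_seed, log, setup_logging, write_tsv

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    outdir: str = "fracomm_run"
    seed: int = 0
    dataset: DatasetConfig | None = None  # synthesize ...
    inputs: dict[str, str] | None = None  # ... or load (counts/metadata/env/tree)
    env_groups: dict[str, str] = field(default_factory=dict)  # var -> Env/Bio
    rarefy_depth: int | str = "min"
    abundance: AbundanceClassConfig = field(default_factory=AbundanceClassConfig)
    network: NetworkFilterConfig = field(default_factory=NetworkFilterConfig)
    n_perm: int = 999
    n_null: int = 999
    n_boot: int = 1000
    attack_reps: int = 50
    spatial_axes: int = 3

    def __post_init__(self) -> None:
        if self.dataset is None and self.inputs is None:
            raise FracommError("config needs either a dataset block or input paths")
        if self.dataset is not None and self.inputs is not None:
            raise FracommError("config must not give both dataset and inputs")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            raw["seed"] = seed
        if "dataset" in raw and raw["dataset"] is not None:
            ds = dict(raw["dataset"])
            if "fractions" in ds:
                ds["fractions"] = tuple(ds["fractions"])
            raw["dataset"] = DatasetConfig(**ds)
        if "abundance" in raw:
            raw["abundance"] = AbundanceClassConfig(**raw["abundance"])
        if "network" in raw:
            raw["network"] = NetworkFilterConfig(**raw["network"])
        return cls(**raw)


@dataclass
class LoadedData:
    table: CountTable
    tree: Any
    env: pd.DataFrame
    env_groups: dict[str, str]


def load_data(config: PipelineConfig) -> LoadedData:
    if config.dataset is not None:
        ds_cfg = dataclasses.replace(
            config.dataset, seed=derive_seed(config.seed, "simulate")
        )
        ds = generate_dataset(ds_cfg)
        return LoadedData(ds.table, ds.tree, ds.env, ds.env_groups)
    paths = config.inputs or {}
    for key in ("counts", "metadata", "env", "tree"):
        if key not in paths:
            raise FracommError(f"inputs block is missing {key!r}")
    table = CountTable.read(paths["counts"], paths["metadata"])
    env = pd.read_csv(paths["env"], sep="\t", index_col=0)
    tree = read_tree(paths["tree"])
    groups = dict(config.env_groups) or {c: "Env" for c in env.columns}
    return LoadedData(table, tree, env, groups)


def _out(config: PipelineConfig, *parts: str) -> Path:
    p = Path(config.outdir).joinpath(*parts)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


def _dm_to_df(dm) -> pd.DataFrame:
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_rarefy(data: LoadedData, config: PipelineConfig) -> CountTable:
    rt = rarefy(data.table, config.rarefy_depth, seed=derive_seed(config.seed, "rarefy"))
    rt.write(_out(config, "rarefied_counts.tsv"), _out(config, "rarefied_metadata.tsv"))
    return rt


def stage_alpha(rt: CountTable, data: LoadedData, config: PipelineConfig) -> pd.DataFrame:
    alpha = alpha_diversity(rt, data.tree)
    alpha["fraction"] = rt.sample_meta["fraction"]
    tests = []
    for index in ("richness", "shannon", "faith_pd"):
        pico = alpha.loc[alpha["fraction"] == "pico", index]
        nano = alpha.loc[alpha["fraction"] == "nano", index]
        s, p = stats.ranksums(pico, nano)
        tests.append({"index": index, "statistic": s, "p_value": p})
    write_tsv(alpha, _out(config, "alpha_diversity.tsv"), index_label="sample")
    write_tsv(
        pd.DataFrame(tests).set_index("index"),
        _out(config, "alpha_wilcoxon.tsv"),
    )
    return alpha


def stage_beta(rt: CountTable, data: LoadedData, config: PipelineConfig) -> dict:
    bc = betadiv.bray_curtis_matrix(rt)
    uf = betadiv.unweighted_unifrac_matrix(rt, data.tree)
    res: dict[str, Any] = {"bray_curtis": bc, "unifrac": uf}
    groups = rt.sample_meta["fraction"]
    for name, dm in (("bray_curtis", bc), ("unifrac", uf)):
        write_tsv(_dm_to_df(dm), _out(config, f"dist_{name}.tsv"), index_label="sample")
        ordn = betadiv.pcoa(dm)
        write_tsv(
            ordn.coordinates, _out(config, f"pcoa_{name}.tsv"), index_label="sample"
        )
        an = betadiv.anosim(
            dm, groups, n_perm=config.n_perm, seed=derive_seed(config.seed, f"anosim/{name}")
        )
        res[f"anosim_{name}"] = an
        res[f"pcoa_{name}"] = ordn
    write_tsv(
        pd.DataFrame(
            [
                {"distance": n, "R": res[f"anosim_{n}"].r, "p": res[f"anosim_{n}"].p}
                for n in ("bray_curtis", "unifrac")
            ]
        ).set_index("distance"),
        _out(config, "anosim.tsv"),
    )
    return res


def stage_simper(rt: CountTable, config: PipelineConfig) -> betadiv.SimperResult:
    sim = betadiv.simper(rt, rt.sample_meta["fraction"])
    write_tsv(sim.contributions.set_index("taxon"), _out(config, "simper.tsv"))
    return sim


def stage_mantel(rt: CountTable, data: LoadedData, config: PipelineConfig) -> pd.DataFrame:
    """Mantel tests of community distance vs environment, plus distance decay."""
    from skbio import DistanceMatrix

    rows = []
    for f in FRACTIONS:
        sub = rt.subset_fraction(f)
        bc = betadiv.bray_curtis_matrix(sub)
        env = data.env.loc[list(sub.samples)]
        z = (env - env.mean()) / env.std(ddof=1)
        z = z.dropna(axis=1)  # drop constant variables
        env_d = DistanceMatrix(
            betadiv.squareform(betadiv.pdist(z.to_numpy())), ids=list(sub.samples)
        )
        mt = betadiv.mantel(
            bc, env_d, n_perm=config.n_perm, seed=derive_seed(config.seed, f"mantel/{f}")
        )
        dd = betadiv.distance_decay(
            sub, n_perm=config.n_perm, seed=derive_seed(config.seed, f"decay/{f}")
        )
        rows.append(
            {
                "fraction": f,
                "mantel_env_r": mt.r,
                "mantel_env_p": mt.p,
                "decay_slope": dd.slope,
                "decay_mantel_r": dd.mantel.r if dd.mantel else np.nan,
                "decay_mantel_p": dd.mantel.p if dd.mantel else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("fraction")
    write_tsv(df, _out(config, "mantel_decay.tsv"))
    return df


def _pca_reduce(df: pd.DataFrame, k: int) -> pd.DataFrame:
    """First k principal components of a standardized predictor block."""
    if df.shape[1] <= k:
        return df
    x = df.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=df.index, columns=[f"PC{i + 1}" for i in range(k)]
    )


def stage_vpa(rt: CountTable, data: LoadedData, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for f in FRACTIONS:
        sub = rt.subset_fraction(f)
        n = len(sub.samples)
        env = data.env.loc[list(sub.samples)]
        sets = {
            "Env": env[[c for c, g in data.env_groups.items() if g == "Env" and c in env]],
            "Bio": env[[c for c, g in data.env_groups.items() if g == "Bio" and c in env]],
            "Spa": betadiv.spatial_predictors(sub.sample_meta, k=config.spatial_axes),
        }
        if sets["Bio"].shape[1] == 0:
            log.warning("no Bio variables configured; skipping VPA for %s", f)
            continue
        # keep residual degrees of freedom for the full model
        k_max = max(1, (n - 2) // 3)
        sets = {name: _pca_reduce(df, k_max) for name, df in sets.items()}
        res = betadiv.vpa(sub, sets)
        for name, val in res.fractions.items():
            rows.append({"fraction": f, "component": name, "adj_r2": val})
    df = pd.DataFrame(rows)
    if len(df):
        write_tsv(df.set_index(["fraction", "component"]), _out(config, "vpa.tsv"))
    return df


def stage_assembly(
    rt: CountTable, data: LoadedData, config: PipelineConfig
) -> dict[str, Any]:
    out: dict[str, Any] = {}
    frac_rows = []
    for f in FRACTIONS:
        sub = rt.subset_fraction(f)
        b = bnti(sub, data.tree, n_null=config.n_null, seed=derive_seed(config.seed, f"bnti/{f}"))
        r = rc_bray(sub, n_null=config.n_null, seed=derive_seed(config.seed, f"rc/{f}"))
        pairs, fracs = classify_processes(b, r)
        write_tsv(
            pairs.set_index(["sample_a", "sample_b"]),
            _out(config, f"assembly_pairs_{f}.tsv"),
        )
        out[f] = {"bnti": b, "rc": r, "pairs": pairs, "fractions": fracs}
        for proc, pct in fracs.percentages.items():
            frac_rows.append({"fraction": f, "process": proc, "pct": pct})
    write_tsv(
        pd.DataFrame(frac_rows).set_index(["fraction", "process"]),
        _out(config, "process_fractions.tsv"),
    )
    return out


def stage_ncm(rt: CountTable, config: PipelineConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    rows = []
    for f in FRACTIONS:
        sub = rt.subset_fraction(f)
        fit = ncm_fit(sub, n_boot=config.n_boot, seed=derive_seed(config.seed, f"ncm/{f}"))
        out[f] = fit
        write_tsv(fit.taxon_table, _out(config, f"ncm_taxa_{f}.tsv"))
        rows.append(
            {
                "fraction": f,
                "Nm": fit.Nm,
                "m": fit.m,
                "m_sloan": fit.m_sloan,
                "r2": fit.r2,
                "m_ci_low": fit.m_ci[0],
                "m_ci_high": fit.m_ci[1],
            }
        )
    write_tsv(pd.DataFrame(rows).set_index("fraction"), _out(config, "ncm_fit.tsv"))
    return out


def stage_network(rt: CountTable, config: PipelineConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    node_tables = {}
    for f in FRACTIONS:
        sub = rt.subset_fraction(f)
        classes = classify_abundance(sub, config.abundance)
        filtered = netsci.filter_for_network(sub, config.network)
        edges = netsci.spearman_edges(filtered, config.network)
        rel = sub.taxon_sums() / sub.taxon_sums().sum()
        ann = pd.DataFrame({"abundance_class": classes, "rel_abundance": rel})
        g = netsci.build_network(edges, ann)
        write_tsv(edges, _out(config, f"network_edges_{f}.tsv"), index_label="edge")
        entry: dict[str, Any] = {"graph": g, "edges": edges, "classes": classes}
        if g.number_of_nodes() > 0:
            modules, q = netsci.detect_modules(g, seed=derive_seed(config.seed, f"louvain/{f}"))
            topo = netsci.global_topology(g, seed=derive_seed(config.seed, f"louvain/{f}"))
            nodes = netsci.node_topology(g)
            roles = netsci.zi_pi(g, modules)
            nodes = nodes.join(roles)
            nodes["abundance_class"] = classes.reindex(nodes.index)
            write_tsv(nodes, _out(config, f"network_nodes_{f}.tsv"))
            write_tsv(
                pd.DataFrame([topo], index=pd.Index([f], name="fraction")),
                _out(config, f"network_topology_{f}.tsv"),
            )
            entry.update(modules=modules, topology=topo, nodes=nodes, roles=roles)
            node_tables[f] = nodes
        out[f] = entry
    # node-level comparison between the two fraction networks
    if len(node_tables) == 2:
        rows = []
        for metric in ("betweenness", "closeness"):
            s, p = stats.ranksums(
                node_tables["pico"][metric], node_tables["nano"][metric]
            )
            rows.append({"metric": metric, "statistic": s, "p_value": p})
        write_tsv(
            pd.DataFrame(rows).set_index("metric"),
            _out(config, "network_node_wilcoxon.tsv"),
        )
    return out


def stage_attack(network_out: dict, config: PipelineConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f, entry in network_out.items():
        g = entry["graph"]
        if g.number_of_nodes() == 0 or "roles" not in entry:
            continue
        roles = entry["roles"]
        classes = entry["classes"]
        keystones = netsci.keystone_taxa(roles)
        cats = {
            c: [t for t in keystones if classes.get(t) == c] for c in ("AT", "IT", "RT")
        }
        cats = {c: v for c, v in cats.items() if v}
        if not cats:
            log.warning("no keystone taxa in %s network; attack skipped", f)
            continue
        res = netsci.attack_simulation(
            g, cats, n_reps=config.attack_reps, seed=derive_seed(config.seed, f"attack/{f}")
        )
        rows = []
        for cat, ar in res.items():
            for x, y in zip(ar.fraction_removed, ar.connectedness):
                rows.append(
                    {"category": cat, "fraction_removed": x, "connectedness": y}
                )
        write_tsv(
            pd.DataFrame(rows).set_index(["category", "fraction_removed"]),
            _out(config, f"attack_{f}.tsv"),
        )
        out[f] = res
    return out


def stage_partition(rt: CountTable, config: PipelineConfig) -> pd.DataFrame:
    classes = {
        f: classify_abundance(rt.subset_fraction(f), config.abundance)
        for f in FRACTIONS
    }
    part = shared_unique_partition(rt, classes)
    write_tsv(
        part.set_index(["fraction", "status", "class"]),
        _out(config, "shared_unique_partition.tsv"),
    )
    return part


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    if config.dataset is not None:
        d["dataset"] = asdict(config.dataset)
    return d


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the whole analysis; returns in-memory results and writes a report
    bundle plus a manifest under ``config.outdir``."""
    setup_logging(_out(config, "run.log"))
    results: dict[str, Any] = {}
    stage = "load"
    try:
        data = load_data(config)
        results["data"] = data
        if config.dataset is not None:
            SyntheticDataset(
                data.table, data.tree, data.env, data.env_groups,
                dataclasses.replace(config.dataset, seed=derive_seed(config.seed, "simulate")),
            ).write(_out(config, "dataset"))
        stage = "rarefy"
        rt = stage_rarefy(data, config)
        results["rarefied"] = rt
        stage = "alpha"
        results["alpha"] = stage_alpha(rt, data, config)
        stage = "beta"
        results["beta"] = stage_beta(rt, data, config)
        stage = "simper"
        results["simper"] = stage_simper(rt, config)
        stage = "mantel"
        results["mantel"] = stage_mantel(rt, data, config)
        stage = "vpa"
        results["vpa"] = stage_vpa(rt, data, config)
        stage = "assembly"
        results["assembly"] = stage_assembly(rt, data, config)
        stage = "ncm"
        results["ncm"] = stage_ncm(rt, config)
        stage = "network"
        results["network"] = stage_network(rt, config)
        stage = "attack"
        results["attack"] = stage_attack(results["network"], config)
        stage = "partition"
        results["partition"] = stage_partition(rt, config)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise FracommError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest = {
        "package": "fracomm",
        "version": __version__,
        "config": _config_dict(config),
    }
    _out(config, "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
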