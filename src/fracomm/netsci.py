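"""Co-occurrence network inference, topology, Zi-Pi roles, attack simulation.

A network is built per size fraction: taxa passing an abundance/prevalence
filter are correlated pairwise (Spearman, on per-sample relative abundances);
edges with |r| above the threshold and raw p below 0.05 form an undirected
graph.  Modules come from seeded Louvain optimization; nodes are classified
by the Guimerà-Amaral within-module degree z-score (Zi) and participation
coefficient (Pi), with non-peripheral nodes treated as keystone taxa.  The
attack simulation removes one node category at a time in random order and
tracks the relative size of the largest connected component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable, FracommError
from .util import log

# Guimerà-Amaral cut-offs for metabolic-network node roles
ZI_CUTOFF = 2.5
PI_CUTOFF = 0.62


@dataclass(frozen=True)
class NetworkFilterConfig:
    min_reads: int = 10  # total reads, boundary inclusive
    min_prevalence: float = 0.30  # fraction of samples, ceil & inclusive
    r_threshold: float = 0.6  # |r| must strictly exceed this
    p_threshold: float = 0.05  # raw p, no multiple-testing correction
    bh_correct: bool = False  # optional Benjamini-Hochberg on edge p-values

    def __post_init__(self) -> None:
        if not (0 < self.min_prevalence <= 1):
            raise FracommError("min_prevalence must lie in (0, 1]")
        if not (0 < self.r_threshold < 1):
            raise FracommError("r_threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Filtering and correlation
# ---------------------------------------------------------------------------


def filter_for_network(
    table: CountTable, config: NetworkFilterConfig = NetworkFilterConfig()
) -> CountTable:
    """Keep taxa with >= min_reads total reads present in >= min_prevalence
    of samples (sample count rounded up, boundary inclusive)."""
    n_samples = len(table.samples)
    need = math.ceil(config.min_prevalence * n_samples)
    totals = table.taxon_sums()
    prevalence = (table.counts > 0).sum(axis=1)
    keep = (totals >= config.min_reads) & (prevalence >= need)
    if not keep.any():
        raise FracommError(
            "no taxa pass the network filter; relax min_reads/min_prevalence"
        )
    return CountTable(table.counts.loc[keep], table.sample_meta)


def spearman_edges(
    table: CountTable, config: NetworkFilterConfig = NetworkFilterConfig()
) -> pd.DataFrame:
    """All pairwise Spearman correlations passing the compound threshold.

    Correlations are computed on per-sample relative abundances with
    average-rank ties; the p-value is the two-sided t approximation.  Edges
    require |r| > r_threshold (strict) and p < p_threshold (strict).
    Zero-variance taxa are excluded with a logged notice.
    """
    if len(table.samples) < 4:
        raise FracommError("need at least 4 samples for correlations")
    rel = table.relative_abundance()
    var = rel.var(axis=1)
    flat = list(var.index[var == 0])
    if flat:
        log.warning("excluding %d zero-variance taxa from correlations", len(flat))
        rel = rel.drop(index=flat)
    taxa = list(rel.index)
    if len(taxa) < 2:
        return pd.DataFrame(columns=["taxon_a", "taxon_b", "r", "p", "sign"])
    r, p = stats.spearmanr(rel.to_numpy().T)
    if np.ndim(r) == 0:  # scipy returns scalars for exactly two variables
        r = np.array([[1.0, float(r)], [float(r), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    iu = np.triu_indices(len(taxa), k=1)
    rr, pp = r[iu], p[iu]
    if config.bh_correct:
        pp = _benjamini_hochberg(pp)
    keep = (np.abs(rr) > config.r_threshold) & (pp < config.p_threshold)
    df = pd.DataFrame(
        {
            "taxon_a": [taxa[i] for i in iu[0][keep]],
            "taxon_b": [taxa[j] for j in iu[1][keep]],
            "r": rr[keep],
            "p": pp[keep],
        }
    )
    df["sign"] = np.where(df["r"] > 0, "positive", "negative")
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_network(
    edges: pd.DataFrame, node_annotations: pd.DataFrame | None = None
) -> nx.Graph:
    """Undirected simple graph from the retained edges.

    Taxa without any retained edge are excluded.  Duplicate edges are
    deduplicated with an assertion that their correlations agree.
    ``node_annotations`` (indexed by taxon; e.g. abundance class, relative
    abundance) is copied onto the nodes.
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b = row.taxon_a, row.taxon_b
        if a == b:
            raise FracommError(f"self-edge on {a!r}")
        if g.has_edge(a, b):
            assert np.isclose(g[a][b]["r"], row.r), "conflicting duplicate edge"
            continue
        g.add_edge(a, b, r=float(row.r), p=float(row.p), sign=row.sign)
    if node_annotations is not None:
        for node in g.nodes:
            if node in node_annotations.index:
                g.nodes[node].update(node_annotations.loc[node].to_dict())
    return g


def positive_edge_fraction(g: nx.Graph) -> float:
    if g.number_of_edges() == 0:
        raise FracommError("empty network")
    pos = sum(1 for *_, d in g.edges(data=True) if d.get("sign") == "positive")
    return pos / g.number_of_edges()


# ---------------------------------------------------------------------------
# Modules and topology
# ---------------------------------------------------------------------------


def detect_modules(g: nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Louvain modularity optimization (sign-ignored, unweighted), seeded.

    Returns a node -> module id mapping and the modularity Q of the final
    partition.  An edgeless graph puts every node in its own module, Q = 0.
    """
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(g.nodes)}, 0.0
    comms = nx.community.louvain_communities(g, weight=None, seed=seed)
    q = nx.community.modularity(g, comms, weight=None)
    modules = {}
    for i, comm in enumerate(comms):
        for n in comm:
            modules[n] = i
    return modules, float(q)


def global_topology(g: nx.Graph, seed: int = 0) -> dict[str, float]:
    """Whole-network summary statistics.

    Path-based metrics (diameter, average path length) are computed on the
    largest connected component; modularity comes from seeded Louvain.
    """
    if g.number_of_nodes() == 0:
        raise FracommError("empty network")
    n = g.number_of_nodes()
    e = g.number_of_edges()
    lcc_nodes = max(nx.connected_components(g), key=len)
    lcc = g.subgraph(lcc_nodes)
    _, q = detect_modules(g, seed=seed)
    return {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": 2.0 * e / n,
        "density": nx.density(g),
        "diameter_lcc": nx.diameter(lcc) if lcc.number_of_nodes() > 1 else 0,
        "average_path_length_lcc": (
            nx.average_shortest_path_length(lcc) if lcc.number_of_nodes() > 1 else 0.0
        ),
        "average_clustering": nx.average_clustering(g),
        "modularity": q,
        "lcc_fraction": len(lcc_nodes) / n,
    }


def node_topology(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree, normalized betweenness, and closeness centrality.

    Closeness uses the component-wise convention (no Wasserman-Faust
    rescaling across components).
    """
    if g.number_of_nodes() == 0:
        raise FracommError("empty network")
    betw = nx.betweenness_centrality(g, normalized=True)
    close = nx.closeness_centrality(g, wf_improved=False)
    return pd.DataFrame(
        {
            "degree": dict(g.degree()),
            "betweenness": betw,
            "closeness": close,
        }
    ).rename_axis("taxon")


# ---------------------------------------------------------------------------
# Zi-Pi node roles
# ---------------------------------------------------------------------------


def zi_pi(
    g: nx.Graph,
    modules: Mapping,
    zi_cutoff: float = ZI_CUTOFF,
    pi_cutoff: float = PI_CUTOFF,
) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardizes a node's within-module degree against the within-module
    degrees of its module (Zi = 0 when the module SD is zero); Pi = 1 -
    sum_s (k_is / k_i)^2.  Roles: network hub (Zi >= zi_cutoff and Pi >=
    pi_cutoff), module hub (Zi >= zi_cutoff only), connector (Pi >= pi_cutoff
    only), else peripheral.  Keystone taxa are the non-peripheral nodes.
    """
    nodes = list(g.nodes)
    k_within: dict = {}
    k_by_module: dict = {}
    for n in nodes:
        deg = g.degree(n)
        assert deg > 0, "degree-0 node in a co-occurrence graph"
        per_mod: dict = {}
        for nb in g.neighbors(n):
            per_mod[modules[nb]] = per_mod.get(modules[nb], 0) + 1
        k_by_module[n] = per_mod
        k_within[n] = per_mod.get(modules[n], 0)
    # module-wise mean/sd of within-module degree
    mod_members: dict = {}
    for n in nodes:
        mod_members.setdefault(modules[n], []).append(n)
    rows = []
    for n in nodes:
        members = mod_members[modules[n]]
        ks = np.array([k_within[m] for m in members], dtype=float)
        sd = ks.std()
        zi = (k_within[n] - ks.mean()) / sd if sd > 0 else 0.0
        deg = g.degree(n)
        pi = 1.0 - sum((k / deg) ** 2 for k in k_by_module[n].values())
        if zi >= zi_cutoff and pi >= pi_cutoff:
            role = "network hub"
        elif zi >= zi_cutoff:
            role = "module hub"
        elif pi >= pi_cutoff:
            role = "connector"
        else:
            role = "peripheral"
        rows.append(
            {"taxon": n, "module": modules[n], "Zi": zi, "Pi": pi, "role": role}
        )
    return pd.DataFrame(rows).set_index("taxon")


def keystone_taxa(roles: pd.DataFrame) -> list:
    return list(roles.index[roles["role"] != "peripheral"])


# ---------------------------------------------------------------------------
# Attack simulation
# ---------------------------------------------------------------------------


@dataclass
class AttackResult:
    category: str
    fraction_removed: np.ndarray  # of the whole network, including step 0
    connectedness: np.ndarray  # mean over orderings, |LCC| / original N
    auc: float
    n_reps: int


def _lcc_size(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    return len(max(nx.connected_components(g), key=len))


def robustness_curve(g: nx.Graph, order: Sequence) -> np.ndarray:
    """Connectedness (|LCC| / original N) after each removal in ``order``."""
    n0 = g.number_of_nodes()
    h = g.copy()
    curve = np.empty(len(order) + 1)
    curve[0] = _lcc_size(h) / n0
    for i, node in enumerate(order):
        h.remove_node(node)
        curve[i + 1] = _lcc_size(h) / n0
    return curve


def attack_simulation(
    g: nx.Graph,
    keystone_sets: Mapping[str, Iterable],
    n_reps: int = 100,
    seed: int = 0,
) -> dict[str, AttackResult]:
    """Random-order removal of each node category, averaged over orderings.

    For each category, its nodes are removed one at a time in ``n_reps``
    random orders; after each removal the relative size of the largest
    connected component is recorded.  The area under the mean curve (by the
    trapezoid rule over the fraction of network nodes removed) summarizes how
    quickly the network loses connectedness.  Empty categories are skipped
    with a warning.
    """
    rng = np.random.default_rng(seed)
    n0 = g.number_of_nodes()
    if n0 == 0:
        raise FracommError("empty network")
    results: dict[str, AttackResult] = {}
    for cat, nodes in keystone_sets.items():
        nodes = [n for n in nodes]
        missing = [n for n in nodes if n not in g]
        if missing:
            raise FracommError(f"attack category {cat!r} has unknown nodes")
        if not nodes:
            log.warning("attack category %r is empty; skipped", cat)
            continue
        curves = np.empty((n_reps, len(nodes) + 1))
        for r in range(n_reps):
            order = [nodes[i] for i in rng.permutation(len(nodes))]
            curves[r] = robustness_curve(g, order)
        mean_curve = curves.mean(axis=0)
        x = np.arange(len(nodes) + 1) / n0
        auc = float(np.trapezoid(mean_curve, x))
        results[cat] = AttackResult(
            category=cat,
            fraction_removed=x,
            connectedness=mean_curve,
            auc=auc,
            n_reps=n_reps,
        )
    return results
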