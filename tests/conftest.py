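"""Shared fixtures and independent brute-force oracles for the test suite.

The oracle functions here deliberately re-derive each quantity from its
definition (explicit loops, Floyd-Warshall, per-branch tallies, exhaustive
enumeration) rather than calling the library code under test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from fracomm import CountTable

# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------


def make_table(
    counts,
    taxa=None,
    samples=None,
    fractions=None,
    stations=None,
    lat=None,
    lon=None,
) -> CountTable:
    """CountTable from a 2-D array with auto-generated ids/metadata."""
    counts = np.asarray(counts)
    n_taxa, n_samples = counts.shape
    taxa = taxa or [f"T{i + 1:03d}" for i in range(n_taxa)]
    samples = samples or [f"S{j + 1:02d}" for j in range(n_samples)]
    fractions = fractions or ["pico"] * n_samples
    stations = stations or [f"ST{j + 1:02d}" for j in range(n_samples)]
    lat = lat if lat is not None else [15.0] * n_samples
    lon = lon if lon is not None else list(np.linspace(130.0, 160.0, n_samples))
    meta = pd.DataFrame(
        {
            "fraction": fractions,
            "station": stations,
            "latitude": lat,
            "longitude": lon,
        },
        index=pd.Index(samples, name="sample"),
    )
    return CountTable(pd.DataFrame(counts, index=taxa, columns=samples), meta)


def random_table(rng, n_taxa, n_samples, max_count=200, fractions=None) -> CountTable:
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    counts[rng.integers(0, n_taxa), :] += 1  # no all-zero samples
    return make_table(counts, fractions=fractions)


@pytest.fixture
def toy_tree() -> TreeNode:
    """((a:1,b:2):0.5,(c:3,d:1):0.25):0 — fixed branch lengths for hand math."""
    return TreeNode.read(["((a:1,b:2):0.5,(c:3,d:1):0.25):0;"])


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def brute_bray_curtis(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 1.0 - 2.0 * np.minimum(x, y).sum() / (x.sum() + y.sum())


def brute_faith_pd(tree: TreeNode, present: set[str]) -> float:
    """Union of root-to-tip edge sets (root-inclusive convention)."""
    edges: set[int] = set()
    total = 0.0
    for tip in tree.tips():
        if tip.name not in present:
            continue
        node = tip
        while node.parent is not None:
            if id(node) not in edges:
                edges.add(id(node))
                total += node.length or 0.0
            node = node.parent
    return total


def brute_unifrac(tree: TreeNode, set_a: set[str], set_b: set[str]) -> float:
    """Per-branch shared/unshared tally over all non-root branches."""
    unique = 0.0
    union = 0.0
    for node in tree.postorder(include_self=False):
        below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        in_a = bool(below & set_a)
        in_b = bool(below & set_b)
        length = node.length or 0.0
        if in_a or in_b:
            union += length
        if in_a != in_b:
            unique += length
    return unique / union if union > 0 else 0.0


def brute_bmntd(rel_a, rel_b, dist) -> float:
    """Direct double loop over the defining formula."""
    rel_a = np.asarray(rel_a, dtype=float)
    rel_b = np.asarray(rel_b, dtype=float)
    sup_a = np.flatnonzero(rel_a > 0)
    sup_b = np.flatnonzero(rel_b > 0)
    term_a = sum(rel_a[i] * min(dist[i, j] for j in sup_b) for i in sup_a)
    term_b = sum(rel_b[j] * min(dist[j, i] for i in sup_a) for j in sup_b)
    return 0.5 * (term_a + term_b)


def brute_ranks(x) -> np.ndarray:
    """Average ranks with ties, from first principles."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def brute_pearson(a, b) -> float:
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


def brute_spearman(x, y) -> float:
    return brute_pearson(brute_ranks(x), brute_ranks(y))


def brute_anosim_r(dm: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    n = dm.shape[0]
    dists, within = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(dm[i, j])
            within.append(labels[i] == labels[j])
    ranks = brute_ranks(dists)
    within = np.asarray(within)
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def brute_mantel_r(d1: np.ndarray, d2: np.ndarray, method="spearman") -> float:
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    a, b = d1[iu], d2[iu]
    if method == "spearman":
        return brute_spearman(a, b)
    return brute_pearson(a, b)


def exhaustive_anosim_p(dm: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    obs = brute_anosim_r(dm, labels)
    hits = total = 0
    for perm in itertools.permutations(range(len(labels))):
        total += 1
        if brute_anosim_r(dm, labels[list(perm)]) >= obs - 1e-12:
            hits += 1
    return hits / total


def exhaustive_mantel_p(d1: np.ndarray, d2: np.ndarray, method="spearman") -> float:
    n = d1.shape[0]
    obs = brute_mantel_r(d1, d2, method)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        pi = np.array(perm)
        if brute_mantel_r(d1, d2[pi][:, pi], method) >= obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Graph oracles (adjacency-matrix based, no networkx)
# ---------------------------------------------------------------------------


def graph_to_adjacency(g) -> tuple[list, np.ndarray]:
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=int)
    for a, b in g.edges:
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1
    return nodes, A


def floyd_warshall(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    return D


def brute_clustering(A: np.ndarray) -> float:
    """Mean local clustering coefficient via triangle counting."""
    n = A.shape[0]
    coeffs = []
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        k = len(nbrs)
        if k < 2:
            coeffs.append(0.0)
            continue
        links = sum(
            A[u, v] for a, u in enumerate(nbrs) for v in nbrs[a + 1 :]
        )
        coeffs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(coeffs))


def brute_betweenness(A: np.ndarray) -> np.ndarray:
    """Normalized betweenness from shortest-path counts (sigma DP)."""
    n = A.shape[0]
    D = floyd_warshall(A)
    # sigma[s, t] = number of shortest s-t paths, by BFS layers
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(D[s])
        for t in order:
            if t == s or not np.isfinite(D[s, t]):
                continue
            preds = [u for u in range(n) if A[u, t] and D[s, u] == D[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or not np.isfinite(D[s, t]):
                    continue
                if D[s, v] + D[v, t] == D[s, t] and sigma[s, t] > 0:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def brute_modularity(g, modules) -> float:
    m = g.number_of_edges()
    q = 0.0
    for a, b in g.edges:
        if modules[a] == modules[b]:
            q += 1.0 / m
    deg_by_mod: dict = {}
    for node in g.nodes:
        deg_by_mod[modules[node]] = deg_by_mod.get(modules[node], 0) + g.degree(node)
    for d in deg_by_mod.values():
        q -= (d / (2.0 * m)) ** 2
    return q
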