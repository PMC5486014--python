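"""Protein-interaction network construction, centralities and randomization.

Complexes are clique-expanded ("matrix model": every member interacts with
every other), merged with the binary pairs, and the result is cleaned to a
simple undirected graph with an audit of what was removed.  Centrality
conventions follow the source formulas literally: betweenness and stress
sum over *ordered* (s, t) pairs (twice the unordered convention on
undirected graphs; a flag restores the unordered value), radiality uses the
component diameter + 1 with an (n - 1) denominator and a component-size
prefactor, eigenvector centrality is the principal adjacency eigenvector by
power iteration, bridging multiplies the bridging coefficient by
betweenness, and the bottleneck score counts, over all BFS shortest-path
trees, the trees in which a node's subtree holds more than a quarter of the
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import NumericalError, ParameterError


@dataclass
class InteractionData:
    binary_pairs: list
    complexes: list
    nodes: list | None = None  # optional explicit node universe


@dataclass
class CleaningAudit:
    removed_multi_edges: int
    removed_self_loops: int
    removed_isolated_nodes: int


@dataclass
class Network:
    graph: nx.Graph
    audit: CleaningAudit

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(data: InteractionData) -> Network:
    """Clique-expand complexes, merge with binary pairs, clean, audit.

    Cleaning conserves counts: raw candidate edges = final edges +
    removed_multi_edges + removed_self_loops.
    """
    candidates: list[tuple] = [tuple(p) for p in data.binary_pairs]
    for cx in data.complexes:
        members = sorted(set(cx))
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                candidates.append((members[a_idx], members[b_idx]))

    self_loops = sum(1 for (a, b) in candidates if a == b)
    unique_edges = {frozenset((a, b)) for (a, b) in candidates if a != b}
    removed_multi = len(candidates) - self_loops - len(unique_edges)

    universe: set = set(data.nodes or ())
    for (a, b) in candidates:
        universe.update((a, b))
    for cx in data.complexes:
        universe.update(cx)

    g = nx.Graph()
    g.add_edges_from(tuple(sorted(e)) for e in unique_edges)
    isolated = universe - set(g.nodes)
    return Network(
        graph=g,
        audit=CleaningAudit(
            removed_multi_edges=removed_multi,
            removed_self_loops=self_loops,
            removed_isolated_nodes=len(isolated),
        ),
    )


def read_interactions(binary_path: str | Path, complex_path: str | Path | None = None) -> InteractionData:
    """Binary TSV (protein_a, protein_b) and complex TSV (complex_id, protein)."""
    bdf = pd.read_csv(binary_path, sep="\t", dtype=str)
    pairs = [(r[0], r[1]) for r in bdf.itertuples(index=False)]
    complexes = []
    if complex_path is not None:
        cdf = pd.read_csv(complex_path, sep="\t", dtype=str)
        for _, grp in cdf.groupby(cdf.columns[0], sort=True):
            complexes.append(sorted(grp[cdf.columns[1]]))
    return InteractionData(binary_pairs=pairs, complexes=complexes)


def write_edge_list(network: Network, path: str | Path, fmt: str = "tsv") -> None:
    edges = sorted(tuple(sorted(e)) for e in network.graph.edges)
    with open(path, "w") as fh:
        if fmt == "sif":
            for a, b in edges:
                fh.write(f"{a}\tpp\t{b}\n")
        else:
            fh.write("protein_a\tprotein_b\n")
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------


def degree(network: Network, v) -> int:
    if v not in network.graph:
        raise KeyError(f"node {v!r} not in network")
    return network.graph.degree[v]


def _bfs_sigma(adj: dict, s):
    """BFS from s: visit order, predecessor lists, path counts, distances."""
    dist = {s: 0}
    sigma = {s: 1}
    preds: dict = {s: []}
    order = [s]
    head = 0
    while head < len(order):
        v = order[head]
        head += 1
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                preds[w] = []
                order.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return order, preds, sigma, dist


def betweenness(network: Network, ordered_pairs: bool = True) -> dict:
    """Shortest-path betweenness, summed over ordered (s, t) pairs by default."""
    g = network.graph
    adj = {v: sorted(g.neighbors(v)) for v in g}
    bc = {v: 0.0 for v in g}
    for s in adj:
        order, preds, sigma, _ = _bfs_sigma(adj, s)
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    if not ordered_pairs:
        bc = {v: x / 2.0 for v, x in bc.items()}
    return bc


def stress(network: Network, ordered_pairs: bool = True) -> dict:
    """Number of shortest paths through each node (ordered (s, t) pairs)."""
    g = network.graph
    adj = {v: sorted(g.neighbors(v)) for v in g}
    st = {v: 0.0 for v in g}
    for s in adj:
        order, preds, sigma, _ = _bfs_sigma(adj, s)
        # phi[v] = number of shortest paths from v onward (any target) in the BFS DAG
        phi = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                phi[v] += 1.0 + phi[w]
        for w in order:
            if w != s:
                st[w] += sigma[w] * phi[w]
    if not ordered_pairs:
        st = {v: x / 2.0 for v, x in st.items()}
    return {v: x for v, x in st.items()}


def radiality(network: Network) -> dict:
    """Reach-like centrality: (diam + 1 - dist) averaged over the component.

    Computed per connected component with denominator (|C| - 1) and scaled
    by |C| / |V| so values remain comparable on disconnected graphs.
    Singleton components score 0.
    """
    g = network.graph
    n_total = g.number_of_nodes()
    rad = {}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        nc = len(comp)
        if nc == 1:
            rad[comp[0]] = 0.0
            continue
        sub = g.subgraph(comp)
        dists = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dists.values())
        scale = nc / n_total
        for v in comp:
            total = sum(diam + 1 - d for w, d in dists[v].items() if w != v)
            rad[v] = scale * total / (nc - 1)
    return rad


def eigenvector_centrality(network: Network, tol: float = 1e-10, max_iter: int = 10000) -> dict:
    """Principal adjacency eigenvector by (shifted) power iteration.

    Computed per connected component from the uniform start vector and
    normalised to unit Euclidean norm within the component; the A + I shift
    guarantees convergence on bipartite components without changing the
    eigenvector.  Raises ``NumericalError`` if max_iter is exhausted.
    """
    g = network.graph
    ev: dict = {}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        idx = {v: i for i, v in enumerate(comp)}
        n = len(comp)
        A = np.zeros((n, n))
        for a, b in g.subgraph(comp).edges:
            A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0
        x = np.full(n, 1.0 / np.sqrt(n))
        for _ in range(max_iter):
            x_new = A @ x + x
            norm = np.linalg.norm(x_new)
            if norm == 0:
                break
            x_new /= norm
            if np.max(np.abs(x_new - x)) < tol:
                x = x_new
                break
            x = x_new
        else:
            raise NumericalError(
                f"eigenvector centrality did not converge in {max_iter} iterations"
            )
        for v in comp:
            ev[v] = float(abs(x[idx[v]]))
    return ev


def bridging(network: Network, bc: dict | None = None) -> tuple[dict, dict]:
    """(bridging coefficient, bridging centrality = coeff x betweenness)."""
    g = network.graph
    if bc is None:
        bc = betweenness(network)
    bcoeff = {}
    for v in g:
        d = g.degree[v]
        if d == 0:
            bcoeff[v] = 0.0
            continue
        denom = sum(1.0 / g.degree[u] for u in g.neighbors(v))
        bcoeff[v] = (1.0 / d) / denom
    brg = {v: bcoeff[v] * bc[v] for v in g}
    return bcoeff, brg


def bottleneck_scores(network: Network) -> dict:
    """Roots-of-BFS-trees count: a node scores for each shortest-path tree in
    which its subtree exceeds a quarter of the component (strict).

    Parent ties are broken toward the lexicographically smallest predecessor
    so the tree, and hence the score, is deterministic.
    """
    g = network.graph
    scores = {v: 0 for v in g}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        sub = g.subgraph(comp)
        adj = {v: sorted(sub.neighbors(v)) for v in comp}
        quarter = len(comp) / 4.0
        for s in comp:
            order, preds, _, _ = _bfs_sigma(adj, s)
            parent = {w: min(preds[w]) for w in order if w != s}
            size = {w: 1 for w in order}
            for w in reversed(order):
                if w != s:
                    size[parent[w]] += size[w]
            for w in order:
                if w != s and size[w] > quarter:
                    scores[w] += 1
    return scores


@dataclass
class CentralityReport:
    """Per-node centrality table plus the conventions used to compute it."""

    table: pd.DataFrame  # columns: rad, bc, deg, stress, ev, bcoeff, brg, bottleneck
    metadata: dict

    def ranking(self, column: str) -> pd.Series:
        return self.table[column].sort_values(ascending=False)


def centrality_report(network: Network, ordered_pairs: bool = True) -> CentralityReport:
    g = network.graph
    bc = betweenness(network, ordered_pairs=ordered_pairs)
    bcoeff, brg = bridging(network, bc=bc)
    table = pd.DataFrame(
        {
            "rad": radiality(network),
            "bc": bc,
            "deg": {v: g.degree[v] for v in g},
            "stress": stress(network, ordered_pairs=ordered_pairs),
            "ev": eigenvector_centrality(network),
            "bcoeff": bcoeff,
            "brg": brg,
            "bottleneck": bottleneck_scores(network),
        }
    ).sort_index()
    metadata = {
        "pair_convention": "ordered" if ordered_pairs else "unordered",
        "radiality": "component diameter + 1, denominator |C|-1, prefactor |C|/|V|",
        "eigenvector": "power iteration with A+I shift, unit norm per component",
        "bottleneck": "BFS shortest-path trees, subtree > |C|/4, lexicographic parents",
    }
    return CentralityReport(table=table, metadata=metadata)


def rank_hubs(scores: dict | CentralityReport, method: str = "degree", top_k: int = 10) -> list[tuple[int, object, float]]:
    """Top nodes under competition ranking (ties share a rank; 1, 1, 3, ...)."""
    if isinstance(scores, CentralityReport):
        column = {"degree": "deg", "bottleneck": "bottleneck"}.get(method)
        if column is None:
            raise ParameterError(f"unknown hub method {method!r}")
        scores = scores.table[column].to_dict()
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = []
    for pos, (node, score) in enumerate(items):
        rank = pos + 1 if pos == 0 or score < ranked[pos - 1][2] else ranked[pos - 1][0]
        ranked.append((rank, node, score))
    return [r for r in ranked if r[0] <= top_k]


# ---------------------------------------------------------------------------
# Randomization null model
# ---------------------------------------------------------------------------


@dataclass
class RandomizationResult:
    ks_statistic: float
    p_value: float
    n_replicates: int
    model: tuple  # ("ER", n, m)
    seed: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def er_degree_sample(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Degree sequence of one uniform G(n, m) simple graph."""
    capacity = n * (n - 1) // 2
    if m > capacity:
        raise ParameterError(f"G({n}, {m}): more edges than a simple graph holds")
    idx = rng.choice(capacity, size=m, replace=False)
    i = np.floor((1.0 + np.sqrt(1.0 + 8.0 * idx)) / 2.0).astype(np.int64)
    i[i * (i - 1) // 2 > idx] -= 1
    j = idx - i * (i - 1) // 2
    return np.bincount(np.concatenate([i, j]), minlength=n)


def _ks_distance_counts(cdf_a: np.ndarray, cdf_b: np.ndarray) -> float:
    return float(np.max(np.abs(cdf_a - cdf_b)))


def randomize_and_test(
    network: Network,
    n_reps: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    p_method: str = "ensemble",
) -> RandomizationResult:
    """Compare the observed degree distribution with G(n, m) replicates.

    ``n_reps`` uniform G(n, m) graphs are generated with n = |nodes| and
    m = |edges|; the KS distance D is taken between the observed degree
    sequence and the pooled replicate degrees.  The default p-value is
    ensemble-calibrated: each replicate's KS distance to the pool of the
    remaining replicates forms the null distribution and
    p = (1 + #{D_r >= D_obs}) / (n_reps + 1), which stays valid for the
    discrete degree distribution.  ``p_method="asymptotic"`` returns
    scipy's two-sample KS p-value instead (conservative under ties).
    """
    g = network.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n < 2:
        raise ParameterError("randomization needs at least 2 nodes")
    rng = np.random.default_rng(seed)
    observed = np.array(sorted(d for _, d in g.degree), dtype=np.int64)

    reps = np.empty((n_reps, n), dtype=np.int64)
    for r in range(n_reps):
        reps[r] = er_degree_sample(n, m, rng)

    max_deg = int(max(reps.max(), observed.max()))
    support = max_deg + 1
    counts = np.zeros((n_reps, support), dtype=np.int64)
    for r in range(n_reps):
        counts[r] = np.bincount(reps[r], minlength=support)
    obs_counts = np.bincount(observed, minlength=support)

    cum = np.cumsum(counts, axis=1)            # per-replicate ECDF numerators
    total_cum = cum.sum(axis=0)                # pooled ECDF numerator
    obs_cdf = np.cumsum(obs_counts) / n
    pooled_cdf = total_cum / (n_reps * n)
    d_obs = _ks_distance_counts(obs_cdf, pooled_cdf)

    if p_method == "asymptotic":
        from scipy.stats import ks_2samp

        p = float(ks_2samp(observed, reps.ravel()).pvalue)
    elif p_method == "ensemble":
        loo_cdf = (total_cum[None, :] - cum) / ((n_reps - 1) * n)
        rep_cdf = cum / n
        d_null = np.max(np.abs(rep_cdf - loo_cdf), axis=1)
        p = (1.0 + int(np.sum(d_null >= d_obs))) / (n_reps + 1.0)
    else:
        raise ParameterError(f"unknown p_method {p_method!r}")

    return RandomizationResult(
        ks_statistic=d_obs,
        p_value=p,
        n_replicates=n_reps,
        model=("ER", n, m),
        seed=seed,
        alpha=alpha,
    )
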