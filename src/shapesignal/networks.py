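"""Bayesian-network dependency inference between morphology and TF localization.

Single-cell features are quantile-discretized and a directed acyclic graph is
learned per cell line × condition by greedy hill-climbing on the BDeu
(Bayesian-Dirichlet equivalent uniform) score with random restarts.  Edge
confidence is the fraction of bootstrap resamples (cells drawn with
replacement) in which the structure learner recovers the adjacency in either
orientation; an edge is reported oriented only when at least 70% of the
supporting resamples agree on its direction, mirroring how undirected lines
are displayed when the dependency direction cannot be determined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.special import gammaln

__all__ = [
    "discretize",
    "BDeuScorer",
    "hill_climb",
    "DependencyNetwork",
    "learn_network",
    "dependency_summary",
]


def discretize(
    table: pd.DataFrame, levels: int = 3, columns: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-feature quantile binning into ``levels`` states.

    Returns integer state codes (0..levels−1) and the bin edges per column.
    Constant columns collapse to a single state and are flagged with a
    warning.  Because binning is by quantile, any strictly monotone transform
    of a column yields identical states.
    """
    columns = columns or [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    if len(table) < levels:
        raise ValueError(f"need at least {levels} rows to form {levels} quantile bins")
    codes = {}
    edges: dict[str, np.ndarray] = {}
    qs = np.linspace(0, 1, levels + 1)
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        e = np.quantile(x, qs)
        inner = np.unique(e[1:-1])
        if x.min() == x.max():
            warnings.warn(f"column {col!r} is constant; single discrete state")
            codes[col] = np.zeros(len(x), dtype=np.int64)
            edges[col] = e
            continue
        codes[col] = np.searchsorted(inner, x, side="right").astype(np.int64)
        edges[col] = np.concatenate([[e[0]], inner, [e[-1]]])
    return pd.DataFrame(codes, index=table.index), edges


class BDeuScorer:
    """BDeu decomposable score over a discrete data matrix, with caching."""

    def __init__(self, X: np.ndarray, arities: np.ndarray, ess: float = 1.0):
        self.X = np.ascontiguousarray(X, dtype=np.int64)
        self.arities = np.asarray(arities, dtype=np.int64)
        self.ess = float(ess)
        self.n, self.p = self.X.shape
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, child: int, parents: tuple[int, ...]) -> float:
        """log BDeu marginal likelihood of ``child`` given a parent set."""
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        r = int(self.arities[child])
        q = int(np.prod(self.arities[list(parents)])) if parents else 1
        if parents:
            config = np.zeros(self.n, dtype=np.int64)
            mult = 1
            for pa in parents:
                config += self.X[:, pa] * mult
                mult *= int(self.arities[pa])
        else:
            config = np.zeros(self.n, dtype=np.int64)
        counts = np.bincount(config * r + self.X[:, child], minlength=q * r).reshape(q, r)
        nj = counts.sum(axis=1)
        seen = nj > 0
        a_jk = self.ess / (q * r)
        a_j = self.ess / q
        score = float(
            np.sum(gammaln(a_j) - gammaln(a_j + nj[seen]))
            + np.sum(gammaln(a_jk + counts[seen]) - gammaln(a_jk))
        )
        self._cache[key] = score
        return score

    def total(self, parent_sets: list[tuple[int, ...]]) -> float:
        return sum(self.local(j, pa) for j, pa in enumerate(parent_sets))


def _has_path(adj: list[set], src: int, dst: int) -> bool:
    """DFS reachability src -> dst over adjacency sets."""
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def _random_dag(rng: np.random.Generator, p: int, edge_prob: float = 0.2) -> list[set]:
    order = rng.permutation(p)
    children: list[set] = [set() for _ in range(p)]
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_prob:
                children[order[i]].add(int(order[j]))
    return children


def hill_climb(
    scorer: BDeuScorer,
    seed: int = 0,
    restarts: int = 5,
    max_iter: int = 200,
    forbidden_sources: frozenset[int] = frozenset(),
) -> tuple[np.ndarray, float]:
    """Greedy DAG search maximizing the BDeu score; best of random restarts.

    Moves are single-edge additions, deletions and reversals that preserve
    acyclicity; the first restart starts from the empty graph, later restarts
    from seeded random DAGs.  ``forbidden_sources`` blocks edges out of the
    listed nodes (e.g., to treat the TF ratio as a sink).  Returns the
    adjacency matrix (adj[i, j] = edge i→j) and its score; fully
    deterministic for a fixed seed.
    """
    p = scorer.p
    rng = np.random.default_rng(seed)
    best_adj, best_score = None, -np.inf
    for restart in range(max(restarts, 1)):
        children = [set() for _ in range(p)] if restart == 0 else _random_dag(rng, p)
        if forbidden_sources:
            for s in forbidden_sources:
                children[s].clear()
        parents = [set() for _ in range(p)]
        for u in range(p):
            for v in children[u]:
                parents[v].add(u)
        local = [scorer.local(j, tuple(sorted(parents[j]))) for j in range(p)]
        for _ in range(max_iter):
            best_delta, best_move = 1e-10, None
            for i in range(p):
                for j in range(p):
                    if i == j:
                        continue
                    if j in children[i]:
                        # delete i -> j
                        new_pa = tuple(sorted(parents[j] - {i}))
                        delta = scorer.local(j, new_pa) - local[j]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("del", i, j)
                        # reverse i -> j (becomes j -> i)
                        if j not in forbidden_sources:
                            children[i].discard(j)
                            ok = not _has_path(children, i, j)
                            children[i].add(j)
                            if ok:
                                d = (
                                    scorer.local(j, new_pa)
                                    - local[j]
                                    + scorer.local(i, tuple(sorted(parents[i] | {j})))
                                    - local[i]
                                )
                                if d > best_delta:
                                    best_delta, best_move = d, ("rev", i, j)
                    elif i not in children[j] and i not in forbidden_sources:
                        # add i -> j
                        if _has_path(children, j, i):
                            continue
                        delta = scorer.local(j, tuple(sorted(parents[j] | {i}))) - local[j]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("add", i, j)
            if best_move is None:
                break
            op, i, j = best_move
            if op == "add":
                children[i].add(j)
                parents[j].add(i)
            elif op == "del":
                children[i].discard(j)
                parents[j].discard(i)
            else:
                children[i].discard(j)
                parents[j].discard(i)
                children[j].add(i)
                parents[i].add(j)
            local[j] = scorer.local(j, tuple(sorted(parents[j])))
            local[i] = scorer.local(i, tuple(sorted(parents[i])))
        score = float(sum(local))
        if score > best_score + 1e-9:
            best_score = score
            best_adj = np.zeros((p, p), dtype=bool)
            for u in range(p):
                for v in children[u]:
                    best_adj[u, v] = True
    return best_adj, best_score


@dataclass
class EdgeRecord:
    a: str
    b: str
    oriented: bool            # True: a -> b; False: a -- b (a < b lexically)
    confidence: float


@dataclass
class DependencyNetwork:
    """Learned dependency network with bootstrap edge confidences."""

    nodes: list[str]
    edges: list[EdgeRecord]
    metadata: dict = field(default_factory=dict)

    def confident_edges(self, threshold: float = 0.6) -> list[EdgeRecord]:
        return [e for e in self.edges if e.confidence > threshold]

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"a": e.a, "b": e.b, "oriented": e.oriented, "confidence": e.confidence}
                for e in self.edges
            ]
        )

    def to_graphml(self, path) -> None:
        g = nx.DiGraph(**{k: str(v) for k, v in self.metadata.items()})
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.a, e.b, confidence=round(e.confidence, 6), oriented=e.oriented)
        nx.write_graphml(g, path)

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.a == e.b:
                raise ValueError("self edge")
            if not (0 <= e.confidence <= 1):
                raise ValueError("confidence outside [0, 1]")
            if e.oriented:
                g.add_edge(e.a, e.b)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("oriented edges contain a cycle")


def learn_network(
    discrete: pd.DataFrame,
    B: int = 100,
    seed: int = 0,
    restarts: int = 5,
    ess: float = 1.0,
    orientation_threshold: float = 0.7,
    min_rows: int = 100,
    tf_sink: str | None = None,
    metadata: dict | None = None,
) -> DependencyNetwork:
    """Learn a dependency network with bootstrap edge confidences.

    ``discrete`` is a cells × features matrix of integer state codes (see
    :func:`discretize`).  Per bootstrap resample a DAG is learned by
    :func:`hill_climb`; confidence of an adjacency is the fraction of
    resamples containing it in either orientation.  ``tf_sink`` optionally
    forbids edges out of that node (sensitivity analysis).
    """
    if len(discrete) < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {len(discrete)}")
    if discrete.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    names = list(discrete.columns)
    X = discrete.to_numpy(dtype=np.int64)
    arities = np.maximum(X.max(axis=0) + 1, 2)
    p = len(names)
    forbidden = frozenset({names.index(tf_sink)}) if tf_sink else frozenset()

    rng = np.random.default_rng(seed)
    adj_count = np.zeros((p, p), dtype=np.int64)     # upper-tri adjacency counts
    dir_count = np.zeros((p, p), dtype=np.int64)     # directed counts
    for b in range(B):
        idx = rng.integers(0, len(X), len(X))
        scorer = BDeuScorer(X[idx], arities, ess)
        adj, _ = hill_climb(
            scorer, seed=int(rng.integers(0, 2**31 - 1)), restarts=restarts,
            forbidden_sources=forbidden,
        )
        dir_count += adj
        und = adj | adj.T
        adj_count += np.triu(und, k=1)

    edges = []
    iu, ju = np.nonzero(np.triu(adj_count, k=1))
    order = np.argsort(-adj_count[iu, ju], kind="stable")
    oriented_graph = nx.DiGraph()
    oriented_graph.add_nodes_from(names)
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        support = adj_count[i, j]
        conf = support / B
        fwd, back = dir_count[i, j], dir_count[j, i]
        a, b_ = names[i], names[j]
        oriented = False
        if fwd / support >= orientation_threshold:
            src, dst, oriented = a, b_, True
        elif back / support >= orientation_threshold:
            src, dst, oriented = b_, a, True
        if oriented:
            oriented_graph.add_edge(src, dst)
            if not nx.is_directed_acyclic_graph(oriented_graph):
                oriented_graph.remove_edge(src, dst)  # conflict: fall back to undirected
                oriented = False
        if oriented:
            edges.append(EdgeRecord(src, dst, True, conf))
        else:
            edges.append(EdgeRecord(min(a, b_), max(a, b_), False, conf))
    edges.sort(key=lambda e: (-e.confidence, e.a, e.b))
    net = DependencyNetwork(
        nodes=names,
        edges=edges,
        metadata={
            "n_cells": len(discrete), "bootstrap": B, "seed": seed,
            "score": "bdeu", "ess": ess, **(metadata or {}),
        },
    )
    net.validate()
    return net


def dependency_summary(
    networks: list[DependencyNetwork],
    target: str = "log10_tf_ratio",
    threshold: float = 0.6,
    stratify_by: str = "treatment",
) -> pd.DataFrame:
    """Count, per feature, the networks with a confident edge to ``target``.

    An adjacency counts regardless of orientation when its confidence exceeds
    ``threshold``.  Rows are features, columns the strata found in the
    networks' metadata (plus a ``total``); permutation-invariant in the
    network order.
    """
    counts: dict[str, dict[str, int]] = {}
    strata = []
    for net in networks:
        if target not in net.nodes:
            warnings.warn(f"network {net.metadata} lacks target {target!r}; skipped")
            continue
        stratum = str(net.metadata.get(stratify_by, "all"))
        if stratum not in strata:
            strata.append(stratum)
        for e in net.confident_edges(threshold):
            if target in (e.a, e.b):
                other = e.b if e.a == target else e.a
                counts.setdefault(other, {}).setdefault(stratum, 0)
                counts[other][stratum] += 1
    features = sorted(counts)
    out = pd.DataFrame(
        [[counts[f].get(s, 0) for s in strata] for f in features],
        index=pd.Index(features, name="feature"),
        columns=strata,
    )
    out["total"] = out.sum(axis=1)
    return out.sort_values("total", ascending=False)
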