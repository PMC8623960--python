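"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive enumeration, grid
search, explicit path enumeration. None of it shares code with the
package's own algorithms.
"""

from itertools import combinations, permutations

import numpy as np


def grid_nnls(a: np.ndarray, upper: float = 1.5, rounds: int = 6, steps: int = 21):
    """Grid-search minimizer of ||A w - 1||² over w >= 0, refined around the
    incumbent; among near-optimal grid points the minimal-norm one wins
    (lexicographic objective, matching the minimal-norm NNLS contract)."""
    a = np.asarray(a, dtype=float)
    d = a.shape[0]
    b = np.ones(d)
    lo = np.zeros(d)
    hi = np.full(d, upper)
    best = None
    for _ in range(rounds):
        axes = [np.linspace(lo[i], hi[i], steps) for i in range(d)]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        resid = ((pts @ a.T - b) ** 2).sum(axis=1)
        tol = resid.min() + 1e-12
        near = pts[resid <= tol + 1e-9 * max(1.0, resid.min())]
        norms = (near**2).sum(axis=1)
        best = near[np.argmin(norms)]
        span = (hi - lo) / (steps - 1)
        lo = np.maximum(0.0, best - 2 * span)
        hi = best + 2 * span
    return best


def hypergeom_tail_enumerate(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) by enumerating all C(N, n) draws from a universe with M
    marked elements."""
    marked = set(range(M))
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= m:
            hits += 1
    return hits / total if total else 1.0


def bh_stepup(pvals):
    """Textbook BH step-up adjusted values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, p[i] * m / (rank_from_top + 1))
        adj[i] = running
    return adj


# ---------------------------------------------------------------- graphs


def all_shortest_paths(nodes, edges):
    """dict (s, t) -> (distance, list of node-tuples) by enumerating every
    simple path. Exponential; fine for <= 7 nodes."""
    adjacency = {v: set() for v in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    out = {}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            best_len = None
            best_paths = []
            inner = [v for v in nodes if v not in (s, t)]
            for r in range(len(inner) + 1):
                for mid in permutations(inner, r):
                    path = (s, *mid, t)
                    if all(path[i + 1] in adjacency[path[i]] for i in range(len(path) - 1)):
                        L = len(path) - 1
                        if best_len is None or L < best_len:
                            best_len, best_paths = L, [path]
                        elif L == best_len:
                            best_paths.append(path)
                if best_len is not None and best_len <= r:
                    break  # no shorter path can appear with more intermediates
            if best_len is not None:
                out[(s, t)] = (best_len, best_paths)
    return out


def brute_closeness(nodes, edges):
    sp = all_shortest_paths(nodes, edges)
    return {
        v: sum(1.0 / sp[(v, u)][0] for u in nodes if u != v and (v, u) in sp)
        for v in nodes
    }


def brute_stress(nodes, edges):
    sp = all_shortest_paths(nodes, edges)
    out = {v: 0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if (s, t) not in sp:
            continue
        for path in sp[(s, t)][1]:
            for v in path[1:-1]:
                out[v] += 1
    return out


def brute_mnc(nodes, edges):
    adjacency = {v: set() for v in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)

    def comp_sizes(sub):
        seen = set()
        sizes = []
        for start in sub:
            if start in seen:
                continue
            stack, size = [start], 0
            seen.add(start)
            while stack:
                x = stack.pop()
                size += 1
                for y in adjacency[x] & sub:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            sizes.append(size)
        return sizes

    return {
        v: max(comp_sizes(adjacency[v]), default=0) for v in nodes
    }


def exact_epc(nodes, edges, retention):
    """Exact expected reachable-set size by enumerating all 2^|E| edge
    subsets; retention is a list of per-edge keep probabilities."""
    nodes = list(nodes)
    out = {v: 0.0 for v in nodes}
    m = len(edges)
    for mask in range(1 << m):
        prob = 1.0
        kept = []
        for i in range(m):
            if mask >> i & 1:
                prob *= retention[i]
                kept.append(edges[i])
            else:
                prob *= 1.0 - retention[i]
        if prob == 0.0:
            continue
        adjacency = {v: set() for v in nodes}
        for u, v in kept:
            adjacency[u].add(v)
            adjacency[v].add(u)
        seen = set()
        for start in nodes:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                x = stack.pop()
                for y in adjacency[x]:
                    if y not in comp:
                        comp.add(y)
                        stack.append(y)
            seen |= comp
            for v in comp:
                out[v] += prob * (len(comp) - 1)
    return out


def random_graph(n_nodes: int, p: float, rng) -> tuple[list, list]:
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i, j in combinations(range(n_nodes), 2)
        if rng.random() < p
    ]
    return nodes, edges
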