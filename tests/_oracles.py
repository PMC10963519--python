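"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: path
betweenness is computed by exhaustive enumeration of all simple paths,
and helper statistics by direct loops.
"""

import numpy as np

TIE_RTOL = 1e-9


def enumerate_simple_paths(adj, s, t):
    """All simple paths s -> t over an adjacency-list dict."""
    paths = []

    def dfs(v, visited, path):
        if v == t:
            paths.append(list(path))
            return
        for u in adj.get(v, ()):
            if u not in visited:
                visited.add(u)
                path.append(u)
                dfs(u, visited, path)
                path.pop()
                visited.remove(u)

    dfs(s, {s}, [s])
    return paths


def brute_force_betweenness(weights):
    """Node and edge betweenness by exhaustive optimal-path enumeration.

    Optimal paths minimise the summed -log(weight); ties are taken at
    relative tolerance TIE_RTOL.  Normalisation: 2/((n-1)(n-2)) for nodes,
    2/(n(n-1)) for edges.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    adj = {
        i: [j for j in range(n) if w[i, j] > 0 and i != j] for i in range(n)
    }
    node_raw = np.zeros(n)
    edge_raw = {}
    for i in range(n):
        for j in range(n):
            if i < j and w[i, j] > 0:
                edge_raw[(i, j)] = 0.0
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_simple_paths(adj, s, t)
            if not paths:
                continue
            lengths = [
                sum(-np.log(w[a, b]) for a, b in zip(p[:-1], p[1:]))
                for p in paths
            ]
            best = min(lengths)
            tol = TIE_RTOL * max(1.0, abs(best))
            optimal = [p for p, l in zip(paths, lengths) if l <= best + tol]
            sigma = len(optimal)
            for p in optimal:
                for v in p[1:-1]:
                    node_raw[v] += 1.0 / sigma
                for a, b in zip(p[:-1], p[1:]):
                    key = (a, b) if a < b else (b, a)
                    edge_raw[key] += 1.0 / sigma
    node_norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    edge_norm = 2.0 / (n * (n - 1)) if n > 1 else 0.0
    return node_raw * node_norm, {k: v * edge_norm for k, v in edge_raw.items()}


def random_connected_weights(rng, n_nodes, p_edge=0.6, w_lo=0.1, w_hi=0.95):
    """Random symmetric weight matrix of a connected graph."""
    while True:
        w = np.zeros((n_nodes, n_nodes))
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < p_edge:
                    w[i, j] = w[j, i] = rng.uniform(w_lo, w_hi)
        # connectivity via BFS
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for u in range(n_nodes):
                if w[v, u] > 0 and u not in seen:
                    seen.add(u)
                    stack.append(u)
        if len(seen) == n_nodes:
            return w
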