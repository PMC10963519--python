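"""Correlation-weighted dynamical networks and communication centrality.

Nodes are residue representatives (one per included residue); an edge
exists between residues in persistent heavy-atom contact, and carries the
generalized correlation coefficient of the two nodes' displacement series:

    r_ij = sqrt(1 - exp(-2 I_ij / 3)),   I_ij = MI of the 3-D displacements,

estimated with the Kraskov-Stoegbauer-Grassberger k-nearest-neighbour
estimator.  For jointly Gaussian displacements with per-axis correlation
rho, I = -(3/2) ln(1 - rho^2) and r_ij = rho exactly, so r generalizes the
Pearson coefficient to nonlinear coupling while staying on the [0, 1]
scale.

An optimal communication path between two nodes maximizes the product of
edge correlations, i.e. minimizes the summed edge length -log(r_ij).
Betweenness counts, for every node (or edge), the fraction of optimal
paths passing through it, normalized by 2/((n-1)(n-2)) for nodes and
2/(n(n-1)) for edges so values lie in [0, 1].
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .system import MolecularSystem, NodeSelection, node_coordinates

log = logging.getLogger(__name__)

#: relative tolerance for treating two path lengths as tied
PATH_TIE_RTOL = 1e-9


# ---------------------------------------------------------------------------
# generalized correlation coefficient
# ---------------------------------------------------------------------------

def knn_mutual_information(x: np.ndarray, y: np.ndarray, k: int = 5) -> float:
    """KSG (algorithm 1) mutual information between two vector series.

    Uses the max-norm; neighbour counts in the marginal spaces are taken
    strictly inside the joint k-NN distance.
    """
    n = x.shape[0]
    z = np.hstack([x, y])
    dist, _ = cKDTree(z).query(z, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    # strictly-less-than count: shrink the radius by a relative hair
    radius = eps * (1.0 - 1e-12)
    nx = cKDTree(x).query_ball_point(x, r=radius, p=np.inf, return_length=True) - 1
    ny = cKDTree(y).query_ball_point(y, r=radius, p=np.inf, return_length=True) - 1
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


@lru_cache(maxsize=16)
def mi_null_floor(
    n_frames: int, k: int, n_null: int = 16, n_sigma: float = 4.0, seed: int = 20240101
) -> float:
    """Significance floor for the KSG estimate: mean + ``n_sigma`` std of
    the estimator on independent Gaussian series of the same length.

    The null spread of the estimator barely depends on the marginals, so
    one calibration per (n_frames, k) serves every edge of a network.
    """
    rng = np.random.default_rng(seed % (2**31))
    vals = [
        knn_mutual_information(
            rng.standard_normal((n_frames, 3)), rng.standard_normal((n_frames, 3)), k
        )
        for _ in range(n_null)
    ]
    v = np.asarray(vals)
    return float(v.mean() + n_sigma * v.std())


def generalized_correlation(
    series_i: np.ndarray,
    series_j: np.ndarray,
    k: int = 5,
    min_frames: int = 100,
    jitter_seed: int = 0,
    significance: bool = True,
) -> float:
    """Generalized correlation coefficient in [0, 1] between two per-frame
    3-vector displacement series.

    Zero-variance series (e.g. restrained residues) yield 0 with a
    warning.  A deterministic sub-tolerance jitter (seeded) breaks exact
    coordinate ties that would otherwise confuse the k-NN counts.  With
    ``significance`` on (default), mutual information below the
    independence null of the estimator (see :func:`mi_null_floor`) maps to
    exactly 0, so uncoupled residues do not acquire spurious small weights
    through the square-root transform.
    """
    x = np.asarray(series_i, dtype=float)
    y = np.asarray(series_j, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("series must both have shape (n_frames, 3)")
    if x.shape[0] < min_frames:
        raise ValueError(
            f"{x.shape[0]} frames < minimum {min_frames} for the MI estimator"
        )
    sx, sy = x.std(axis=0).max(), y.std(axis=0).max()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero-variance displacement series: correlation set to 0")
        return 0.0
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    rng = np.random.default_rng(jitter_seed)
    x = x + rng.standard_normal(x.shape) * (sx * 1e-10)
    y = y + rng.standard_normal(y.shape) * (sy * 1e-10)
    mi = max(knn_mutual_information(x, y, k=k), 0.0)
    if significance and mi <= mi_null_floor(x.shape[0], k):
        return 0.0
    r = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * mi / 3.0)))
    return float(min(r, 1.0))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class DynamicalNetwork:
    nodes: NodeSelection
    adjacency: np.ndarray  # (n, n) bool
    weights: np.ndarray  # (n, n) float in [0, 1], symmetric, 0 off-edges
    contact_fraction: np.ndarray  # (n, n) gating fractions
    contact_cutoff: float = 0.45
    contact_fraction_threshold: float = 0.75

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        ids = self.nodes.node_ids()
        for i, nid in enumerate(ids):
            row = self.nodes.labels.iloc[i]
            g.add_node(
                i, label=nid, chain=str(row["chain"]),
                resid=int(row["resid"]), resname=str(row["resname"]),
            )
        for i, j in self.edges():
            g.add_edge(
                i, j,
                weight=float(self.weights[i, j]),
                distance=float(-np.log(self.weights[i, j]))
                if self.weights[i, j] > 0 else float("inf"),
            )
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        g = self.to_networkx()
        for _, _, d in g.edges(data=True):
            d.pop("distance", None)  # inf not representable in GraphML
        nx.write_graphml(g, str(path))


def network_from_weights(
    weights: np.ndarray, chains: list[str] | None = None
) -> DynamicalNetwork:
    """Build a :class:`DynamicalNetwork` directly from a symmetric weight
    matrix (zero meaning no edge) — handy for analytic test graphs."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    adj = w > 0
    np.fill_diagonal(adj, False)
    labels = pd.DataFrame(
        {
            "chain": chains if chains is not None else ["A"] * n,
            "resid": np.arange(1, n + 1),
            "resname": ["GLY"] * n,
            "name": ["CA"] * n,
        }
    )
    nodes = NodeSelection(atom_indices=np.arange(n), labels=labels)
    return DynamicalNetwork(
        nodes=nodes, adjacency=adj, weights=np.where(adj, w, 0.0),
        contact_fraction=adj.astype(float),
    )


def residue_contact_fractions(
    system: MolecularSystem, nodes: NodeSelection, cutoff: float
) -> np.ndarray:
    """Fraction of frames in which each included residue pair is in
    heavy-atom contact (any atom of residue i within cutoff of any atom of
    residue j).  All atoms of the node residues participate, not just the
    representative atoms."""
    atoms = system.atoms
    heavy = atoms["element"].str.upper() != "H"
    key_of = {}
    for node_idx, row in nodes.labels.iterrows():
        key_of[(row["chain"], row["resid"])] = node_idx
    atom_node = np.full(len(atoms), -1, dtype=int)
    for ai, (chain, resid) in enumerate(zip(atoms["chain"], atoms["resid"])):
        atom_node[ai] = key_of.get((chain, resid), -1)
    use = np.nonzero((atom_node >= 0) & heavy.to_numpy())[0]
    owner = atom_node[use]

    n = len(nodes)
    counts = np.zeros((n, n))
    for f in range(system.n_frames):
        tree = cKDTree(system.coords[f, use, :])
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        a, b = owner[pairs[:, 0]], owner[pairs[:, 1]]
        mask = a != b
        if not mask.any():
            continue
        ij = np.unique(
            np.sort(np.stack([a[mask], b[mask]], axis=1), axis=1), axis=0
        )
        counts[ij[:, 0], ij[:, 1]] += 1
    counts = counts + counts.T
    return counts / system.n_frames


def build_network(
    system: MolecularSystem,
    nodes: NodeSelection,
    contact_cutoff: float = 0.45,
    contact_fraction: float = 0.75,
    knn_k: int = 5,
    seed: int = 0,
    min_frames: int = 100,
) -> DynamicalNetwork:
    """Contact-gated, correlation-weighted network over the node selection.

    An edge (i, j) exists iff the residues are in heavy-atom contact in at
    least ``contact_fraction`` of frames and are neither the same residue
    nor covalent (sequence-adjacent within a chain) neighbours; its weight
    is the generalized correlation of the node displacement series.
    """
    frac = residue_contact_fractions(system, nodes, contact_cutoff)
    n = len(nodes)
    adj = frac >= contact_fraction
    np.fill_diagonal(adj, False)

    chains = nodes.labels["chain"].to_numpy()
    resids = nodes.labels["resid"].to_numpy()
    for i in range(n):
        covalent = (chains == chains[i]) & (np.abs(resids - resids[i]) == 1)
        adj[i, covalent] = False

    if not adj.any():
        raise ValueError(
            "network has no edges; check contact cutoff "
            f"({contact_cutoff} nm) and gating fraction ({contact_fraction})"
        )

    series = node_coordinates(system, nodes)
    disp = series - series.mean(axis=0, keepdims=True)
    weights = np.zeros((n, n))
    for i, j in zip(*np.nonzero(np.triu(adj, k=1))):
        w = generalized_correlation(
            disp[:, i, :], disp[:, j, :], k=knn_k,
            min_frames=min_frames, jitter_seed=seed,
        )
        weights[i, j] = weights[j, i] = w
    return DynamicalNetwork(
        nodes=nodes, adjacency=adj, weights=weights, contact_fraction=frac,
        contact_cutoff=contact_cutoff, contact_fraction_threshold=contact_fraction,
    )


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------

@dataclass
class CentralityReport:
    n: int
    degree: pd.Series  # weighted degree per node id
    node_betweenness: pd.Series
    edge_betweenness: dict[tuple[int, int], float]
    node_norm: float
    edge_norm: float
    knee: float | None = None
    ranked_edges: pd.DataFrame | None = None


def degree_centrality(network: DynamicalNetwork) -> pd.Series:
    """Weighted degree dg_i = sum_j A_ij w_ij."""
    dg = (network.adjacency * network.weights).sum(axis=1)
    return pd.Series(dg, index=network.nodes.node_ids(), name="degree")


def _tied_shortest_paths(lengths: dict[int, list[tuple[int, float]]], n: int, s: int):
    """Dijkstra from ``s`` with tolerance-tied path counting.

    Returns (dist, sigma, order, preds): optimal-path counts sigma and the
    predecessor lists of the shortest-path DAG, where an edge (u, v) is a
    DAG edge when d(u) + l(u, v) equals d(v) within PATH_TIE_RTOL.
    """
    dist = np.full(n, np.inf)
    dist[s] = 0.0
    done = np.zeros(n, dtype=bool)
    heap = [(0.0, s)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v, l in lengths.get(u, ()):
            nd = d + l
            if nd < dist[v] * (1.0 - PATH_TIE_RTOL):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    order = [v for v in np.argsort(dist, kind="stable") if np.isfinite(dist[v])]
    sigma = np.zeros(n)
    sigma[s] = 1.0
    preds: list[list[int]] = [[] for _ in range(n)]
    for v in order:
        if v == s:
            continue
        tol = PATH_TIE_RTOL * max(1.0, dist[v])
        for u, l in lengths.get(v, ()):
            if np.isfinite(dist[u]) and abs(dist[u] + l - dist[v]) <= tol:
                preds[v].append(u)
                sigma[v] += sigma[u]
    return dist, sigma, order, preds


def betweenness_centrality(network: DynamicalNetwork) -> CentralityReport:
    """Node and edge betweenness over optimal (-log weight) paths.

    Path counting follows Brandes' accumulation on the shortest-path DAG,
    with float ties resolved at relative tolerance 1e-9 so equal-length
    path families are counted exactly.  Betweenness is accumulated per
    connected component and normalized by 2/((n-1)(n-2)) for nodes and
    2/(n(n-1)) for edges, n being the network's node count.
    """
    n = network.n_nodes
    lengths: dict[int, list[tuple[int, float]]] = {}
    dropped = 0
    for i, j in network.edges():
        w = network.weights[i, j]
        if w <= 0.0:
            dropped += 1
            continue
        l = -np.log(w)
        lengths.setdefault(i, []).append((j, l))
        lengths.setdefault(j, []).append((i, l))
    if dropped:
        log.warning("%d zero-weight edges excluded from path analysis", dropped)

    node_raw = np.zeros(n)
    edge_raw: dict[tuple[int, int], float] = {
        e: 0.0 for e in network.edges() if network.weights[e] > 0.0
    }
    for s in range(n):
        dist, sigma, order, preds = _tied_shortest_paths(lengths, n, s)
        delta = np.zeros(n)
        for v in reversed(order):
            for u in preds[v]:
                c = sigma[u] / sigma[v] * (1.0 + delta[v])
                delta[u] += c
                key = (u, v) if u < v else (v, u)
                edge_raw[key] += c
            if v != s:
                node_raw[v] += delta[v]

    # each unordered (s, t) pair was visited from both endpoints
    node_raw /= 2.0
    node_norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    edge_norm = 2.0 / (n * (n - 1)) if n > 1 else 0.0
    node_b = pd.Series(
        node_raw * node_norm, index=network.nodes.node_ids(), name="betweenness"
    )
    edge_b = {e: v / 2.0 * edge_norm for e, v in edge_raw.items()}
    return CentralityReport(
        n=n,
        degree=degree_centrality(network),
        node_betweenness=node_b,
        edge_betweenness=edge_b,
        node_norm=node_norm,
        edge_norm=edge_norm,
    )


# ---------------------------------------------------------------------------
# knee thresholding and top-edge reports
# ---------------------------------------------------------------------------

def knee_threshold(ranked_values: np.ndarray) -> float:
    """Knee of a descending ranked curve: the point with maximum
    perpendicular distance from the chord joining the first and last
    points.  An exactly linear curve has no knee; the last value is
    returned with a warning."""
    v = np.asarray(ranked_values, dtype=float)
    if v.size < 3:
        raise ValueError("knee detection needs at least 3 ranked values")
    if np.any(np.diff(v) > 1e-12):
        v = np.sort(v)[::-1]
    x = np.arange(v.size, dtype=float)
    x0, y0, x1, y1 = x[0], v[0], x[-1], v[-1]
    # |cross product| of (point - start) with the chord direction
    cross = np.abs((x - x0) * (y1 - y0) - (v - y0) * (x1 - x0))
    if cross.max() <= 1e-12 * max(1.0, abs(y0 - y1)):
        warnings.warn("ranked curve is linear; returning the last value as knee")
        return float(v[-1])
    return float(v[int(np.argmax(cross))])


def shared_knee_threshold(ranked_lists: list[np.ndarray]) -> float:
    """Across systems, the lowest per-system knee is the shared threshold."""
    return min(knee_threshold(v) for v in ranked_lists)


def top_edges(
    network: DynamicalNetwork,
    report: CentralityReport,
    threshold: float,
) -> pd.DataFrame:
    """Edges with betweenness strictly above the threshold, annotated with
    their chain interface (``chain_i|chain_j``, sorted) and whether they
    cross a chain-chain interface."""
    ids = network.nodes.node_ids()
    labels = network.nodes.labels
    rows = []
    for (i, j), b in sorted(
        report.edge_betweenness.items(), key=lambda kv: -kv[1]
    ):
        if b <= threshold:
            continue
        ci, cj = str(labels.iloc[i]["chain"]), str(labels.iloc[j]["chain"])
        rows.append(
            (
                ids[i], ids[j], ci, cj,
                float(network.weights[i, j]), float(b),
                ci != cj, "|".join(sorted([ci, cj])),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "node_i", "node_j", "chain_i", "chain_j",
            "weight", "betweenness", "cross_interface", "interface",
        ],
    )


def chain_centrality_summary(
    network: DynamicalNetwork, report: CentralityReport, threshold: float = 0.0
) -> pd.DataFrame:
    """Boxplot-ready per-chain distributions of node betweenness (above
    threshold) and weighted degree."""
    labels = network.nodes.labels
    rows = []
    for i, nid in enumerate(network.nodes.node_ids()):
        b = float(report.node_betweenness.iloc[i])
        if b < threshold:
            continue
        rows.append(
            (str(labels.iloc[i]["chain"]), nid, b, float(report.degree.iloc[i]))
        )
    return pd.DataFrame(rows, columns=["chain", "node", "betweenness", "degree"])
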