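"""Network-comparison toolkit: graph diffusion distance with classical MDS,
integrated value of influence (IVI) with PCA, and Hamming-profile Mantel
testing.

These three views answer complementary questions about a series of inferred
networks: how far apart their topologies are (GDD), which nodes drive them
(IVI), and whether two adjacency structures are correlated at all (Mantel on
Hamming profiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar

from .io import InferredNetwork


@dataclass
class NetworkSeries:
    """Ordered list of networks on a common node set with (group, time) labels."""

    networks: list[InferredNetwork]
    labels: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        taxa = self.networks[0].taxon_ids
        for net in self.networks[1:]:
            if net.taxon_ids != taxa:
                raise ValueError("all networks must share taxon_ids")
        if self.labels is None:
            self.labels = [(n.group_label, n.time_label) for n in self.networks]


@dataclass
class IVITable:
    """IVI scores (networks x nodes, in [0, 100]) plus the six raw measures."""

    scores: np.ndarray
    components: list[dict[str, np.ndarray]]


# ---------------------------------------------------------------------------
# graph diffusion distance


def _laplacian_eig(A: np.ndarray):
    L = np.diag(A.sum(axis=1)) - A
    vals, vecs = np.linalg.eigh(L)
    return vals, vecs


def _kernel(vals, vecs, tau):
    return (vecs * np.exp(-tau * vals)) @ vecs.T


def gdd(
    A1: np.ndarray,
    A2: np.ndarray,
    tau_grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Graph diffusion distance between two binary adjacencies.

    distance = max over diffusion time tau of ||exp(-tau L1) - exp(-tau L2)||_F
    with L = D - A the combinatorial Laplacian. The heat kernels come from one
    eigendecomposition per Laplacian; the search runs a log-spaced grid then a
    bounded golden-section refinement around the grid maximum.
    """
    A1 = np.asarray(A1, dtype=float)
    A2 = np.asarray(A2, dtype=float)
    if A1.shape != A2.shape:
        raise ValueError("adjacency dimension mismatch")
    if np.array_equal(A1, A2):
        return 0.0, 0.0
    e1 = _laplacian_eig(A1)
    e2 = _laplacian_eig(A2)
    if tau_grid is None:
        tau_grid = np.logspace(-3, 1, 100)

    def neg_obj(tau):
        diff = _kernel(*e1, tau) - _kernel(*e2, tau)
        return -np.linalg.norm(diff, "fro")

    vals = np.array([-neg_obj(t) for t in tau_grid])
    k = int(np.argmax(vals))
    lo = tau_grid[max(0, k - 1)]
    hi = tau_grid[min(len(tau_grid) - 1, k + 1)]
    if lo == hi:
        return float(vals[k]), float(tau_grid[k])
    res = minimize_scalar(neg_obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    best_tau, best = float(res.x), float(-res.fun)
    if vals[k] > best:
        best, best_tau = float(vals[k]), float(tau_grid[k])
    return best, best_tau


def gdd_matrix(series: NetworkSeries) -> np.ndarray:
    """Symmetric pairwise GDD matrix over an ordered series of networks."""
    nets = series.networks
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    m = len(nets)
    D = np.zeros((m, m))
    for a in range(m - 1):
        for b in range(a + 1, m):
            D[a, b] = D[b, a] = gdd(nets[a].adjacency, nets[b].adjacency)[0]
    return D


def classical_mds(distances: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson classical MDS: B = -1/2 J D^2 J; coordinates from the top-k
    positive eigenpairs (axes ordered by eigenvalue; negative eigenvalues are
    truncated)."""
    D = np.asarray(distances, dtype=float)
    m = D.shape[0]
    if not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distances must be symmetric with zero diagonal")
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.all(vals <= 1e-12):
        if np.allclose(D, 0):
            return np.zeros((m, k))
        raise ValueError("no positive eigenvalue: distances not embeddable")
    coords = np.zeros((m, k))
    for a in range(min(k, m)):
        if vals[a] > 1e-12:
            coords[:, a] = vecs[:, a] * np.sqrt(vals[a])
    return coords


# ---------------------------------------------------------------------------
# integrated value of influence


def _minmax_scale(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng == 0:
        return np.zeros_like(x, dtype=float)
    return 100.0 * (x - x.min()) / rng


def ivi_components(adjacency: np.ndarray) -> dict[str, np.ndarray]:
    """The six raw node-influence measures on a simple undirected graph.

    Local: degree centrality, ClusterRank. Semi-local: neighbourhood
    connectivity, local H-index. Global: betweenness centrality, collective
    influence (radius 2).
    """
    A = np.asarray(adjacency)
    if np.diag(A).any():
        raise ValueError("self-loops are not allowed")
    p = A.shape[0]
    g = nx.from_numpy_array(A)
    deg = A.sum(axis=1).astype(float)

    # ClusterRank: c_i = 10^(-cc_i) * sum_{j in N(i)} (deg_j + 1)
    cc = np.array([nx.clustering(g, i) for i in range(p)])
    cr = np.array(
        [10.0 ** (-cc[i]) * sum(deg[j] + 1 for j in g.neighbors(i)) for i in range(p)]
    )

    # neighbourhood connectivity: mean neighbour degree
    nc = np.array(
        [deg[list(g.neighbors(i))].mean() if deg[i] > 0 else 0.0 for i in range(p)]
    )

    # local H-index: LH_i = h_i + sum_{j in N(i)} h_j, h = h-index over
    # neighbour degrees
    h = np.array([_h_index(deg[list(g.neighbors(i))]) for i in range(p)])
    lh = np.array([h[i] + sum(h[j] for j in g.neighbors(i)) for i in range(p)])

    bc_map = nx.betweenness_centrality(g, normalized=True)
    bc = np.array([bc_map[i] for i in range(p)])

    # collective influence, radius 2: (deg_i - 1) * sum_{d(i,j)=2} (deg_j - 1)
    ci = np.zeros(p)
    lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
    for i in range(p):
        ball = [j for j, d in lengths.get(i, {}).items() if d == 2]
        ci[i] = max(deg[i] - 1, 0) * sum(deg[j] - 1 for j in ball)

    dc = deg / (p - 1) if p > 1 else deg
    return {
        "degree": dc,
        "clusterrank": cr,
        "neighborhood_connectivity": nc,
        "local_h_index": lh,
        "betweenness": bc,
        "collective_influence": ci,
    }


def _h_index(values: np.ndarray) -> int:
    vals = np.sort(np.asarray(values, dtype=float))[::-1]
    h = 0
    for k, v in enumerate(vals, start=1):
        if v >= k:
            h = k
    return h


def ivi(adjacency: np.ndarray, return_components: bool = False):
    """Integrated value of influence per node, scaled to [0, 100].

    Each of the six measures is min-max scaled to [0, 100] within the graph,
    then combined as hubness = DC + LH and spreading = (NC + CR) x (BC + CI);
    the product hubness x spreading is min-max rescaled to [0, 100]. Isolated
    nodes are pinned to 0.
    """
    comp = ivi_components(adjacency)
    scaled = {k: _minmax_scale(v) for k, v in comp.items()}
    hubness = scaled["degree"] + scaled["local_h_index"]
    spreading = (scaled["neighborhood_connectivity"] + scaled["clusterrank"]) * (
        scaled["betweenness"] + scaled["collective_influence"]
    )
    raw = hubness * spreading
    scores = _minmax_scale(raw)
    deg = np.asarray(adjacency).sum(axis=1)
    scores[deg == 0] = 0.0
    if return_components:
        return scores, comp
    return scores


def ivi_table(series: NetworkSeries) -> IVITable:
    rows, comps = [], []
    for net in series.networks:
        s, c = ivi(net.adjacency, return_components=True)
        rows.append(s)
        comps.append(c)
    return IVITable(scores=np.array(rows), components=comps)


def ivi_pca(table: IVITable, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the networks-by-nodes IVI score matrix: top-k coordinates and
    explained-variance fractions."""
    S = np.asarray(table.scores, dtype=float)
    if S.shape[0] < 2:
        raise ValueError("PCA needs at least 2 networks")
    Xc = S - S.mean(axis=0)
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    k_eff = min(k, svals.size)
    coords = np.zeros((S.shape[0], k))
    coords[:, :k_eff] = U[:, :k_eff] * svals[:k_eff]
    total = (svals**2).sum()
    frac = np.zeros(k)
    if total > 0:
        frac[:k_eff] = svals[:k_eff] ** 2 / total
    return coords, frac


# ---------------------------------------------------------------------------
# Hamming profiles and the Mantel test


def hamming_profile_distance(adjacency: np.ndarray) -> np.ndarray:
    """Node-by-node Hamming distances between rows of the adjacency: entry
    (a, b) counts the positions at which the two connection profiles differ."""
    A = np.asarray(adjacency)
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    # |row_a - row_b| summed over positions
    return np.abs(A[:, None, :] - A[None, :, :]).sum(axis=2).astype(float)


def mantel_test(
    D1: np.ndarray,
    D2: np.ndarray,
    n_perm: int = 999,
    seed=None,
) -> tuple[float, float]:
    """One-sided Mantel test of positive association between two node
    distance matrices.

    r is the Pearson correlation of the upper-triangle entries; p is
    (1 + #{r_perm >= r_obs}) / (n_perm + 1) under simultaneous row/column
    permutations of D2.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if D1.shape != D2.shape:
        raise ValueError("distance matrices must share a node set")
    iu = np.triu_indices(D1.shape[0], 1)
    x = D1[iu]
    if np.ptp(x) == 0 or np.ptp(D2[iu]) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, D2[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    m = D1.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(m)
        y = D2[np.ix_(perm, perm)][iu]
        if np.ptp(y) == 0:
            continue
        if np.corrcoef(x, y)[0, 1] >= r_obs - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (n_perm + 1)
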