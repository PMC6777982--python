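"""Communication measures on weighted, spatially embedded connectomes.

Streamline-count weights W are remapped to connection lengths

    L = -log10(W / (max(W) + 1))

so that stronger connections are shorter, and routing is evaluated under two
schemes: *shortest paths* (globally optimal, via Dijkstra) and *navigation*
(greedy geometric routing: from the current node, always hop to the
neighbour closest in Euclidean distance to the target; the walk fails when a
node repeats or the current node has no neighbours). Navigation yields three
per-pair quantities: the navigation path length Lambda^nav (sum of L along
the walk, inf on failure), the navigation distance D^nav (sum of Euclidean
hop distances) and the hop count.

Network efficiency is the mean inverse path length over ordered node pairs,
E = sum_{i != j} Lambda_ij^-1 / (N (N - 1)), with failed or disconnected
pairs contributing zero. Group analyses summarize efficiency as the
trapezoidal area under the curve (AUC) over proportional connection
densities 10%..50% in 5% steps, thresholding the raw weighted connectome at
each density before remapping and routing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import squareform, pdist

from .datatypes import Connectome, validate_regions

__all__ = [
    "DEFAULT_DENSITIES",
    "threshold_density",
    "weight_to_length",
    "shortest_paths",
    "navigate",
    "efficiency",
    "auc_over_densities",
    "euclidean_matrix",
    "region_to_lesion_distance",
    "CommProfile",
    "CommunicationModel",
    "CommunicationResults",
]

#: Proportional-threshold density grid used for AUC summaries.
DEFAULT_DENSITIES = tuple(np.round(np.arange(0.10, 0.501, 0.05), 2))


def threshold_density(conn: Connectome, density: float) -> Connectome:
    """Keep the ``ceil(density * N(N-1)/2)`` strongest undirected edges.

    Ties at the cutoff weight are resolved toward the lexicographically
    smaller (i, j) upper-triangle entry, making thresholding deterministic.
    If the graph has fewer edges than requested, all are kept.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = conn.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = conn.weights[iu, ju]
    present = np.flatnonzero(w > 0)
    k = int(np.ceil(density * n * (n - 1) / 2))
    keep = present
    if present.size > k:
        order = sorted(present, key=lambda e: (-w[e], iu[e], ju[e]))
        keep = np.array(order[:k])
    out = np.zeros_like(conn.weights)
    out[iu[keep], ju[keep]] = w[keep]
    out += out.T
    return Connectome(out, conn.coords.copy(), conn.region_ids.copy())


def weight_to_length(conn: Connectome, printed_form: bool = False) -> np.ndarray:
    """Monotonic remapping of connection weights into connection lengths.

    ``L_ij = -log10(W_ij / (max(W) + 1))`` for present edges, ``inf`` for
    absent edges (i != j) and 0 on the diagonal; strictly positive on edges
    and strictly decreasing in weight. ``printed_form=True`` instead applies
    ``-log10(W / max(W) + 1)`` — kept only for auditability, since it maps
    every edge to a negative length.
    """
    w = conn.weights
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("connectome has no positive weights")
    with np.errstate(divide="ignore"):
        if printed_form:
            L = -np.log10(w / wmax + 1.0)
        else:
            L = np.where(w > 0, -np.log10(w / (wmax + 1.0)), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def shortest_paths(L: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths Lambda^sp over a length matrix.

    Entries of ``inf`` in L are non-edges; disconnected pairs come back as
    ``inf``.
    """
    L = np.asarray(L, dtype=float)
    adj = np.where(np.isfinite(L), L, 0.0)
    np.fill_diagonal(adj, 0.0)
    mask = np.isfinite(L) & ~np.eye(L.shape[0], dtype=bool)
    # dijkstra treats explicit zeros as absent; offset avoids dropping
    # genuine zero-length edges (cannot occur under the log remapping, but
    # the routine should not silently rely on that)
    if np.any(adj[mask] == 0.0):
        adj = np.where(mask, adj + 1e-300, 0.0)
    sp = dijkstra(adj, directed=False)
    np.fill_diagonal(sp, 0.0)
    return sp


def navigate(L: np.ndarray, coords: np.ndarray):
    """Greedy spatial navigation between every ordered node pair.

    From the current node the walk moves to the neighbour (finite-L edge)
    closest in Euclidean distance to the target, ties broken toward the
    lower node index; it succeeds on reaching the target and fails when a
    node is revisited or the current node has no neighbours.

    Returns ``(lambda_nav, d_nav, hops, paths)``: path length (sum of L),
    Euclidean distance travelled, hop count (all ``inf`` on failure, 0 on
    the diagonal) and the dict of successful paths keyed by (source, target).
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (n, 3):
        raise ValueError("coords must be N x 3 and aligned with L")
    dist = euclidean_matrix(coords)
    neighbors = [np.flatnonzero(np.isfinite(L[u]) & (np.arange(n) != u)) for u in range(n)]
    # next_hop[u, j]: the neighbour of u closest to j (independent of source)
    next_hop = np.full((n, n), -1, dtype=int)
    for u in range(n):
        nb = neighbors[u]
        if nb.size == 0:
            continue
        next_hop[u] = nb[np.argmin(dist[nb], axis=0)]  # argmin takes lowest index on ties
    lam = np.full((n, n), np.inf)
    dnav = np.full((n, n), np.inf)
    hops = np.full((n, n), np.inf)
    np.fill_diagonal(lam, 0.0)
    np.fill_diagonal(dnav, 0.0)
    np.fill_diagonal(hops, 0.0)
    paths: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            u = i
            visited = {i}
            path = [i]
            lsum = 0.0
            dsum = 0.0
            while True:
                v = next_hop[u, j]
                if v < 0:
                    break  # stranded: no neighbours
                lsum += L[u, v]
                dsum += dist[u, v]
                path.append(int(v))
                if v == j:
                    lam[i, j] = lsum
                    dnav[i, j] = dsum
                    hops[i, j] = len(path) - 1
                    paths[(i, j)] = path
                    break
                if v in visited:
                    break  # revisit: failed navigation
                visited.add(v)
                u = v
    return lam, dnav, hops, paths


def efficiency(path_lengths: np.ndarray) -> float:
    """Network efficiency: mean of 1/Lambda over ordered pairs i != j.

    Failed or disconnected pairs (``inf``) contribute zero.
    """
    lam = np.asarray(path_lengths, dtype=float)
    n = lam.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(lam) & (lam > 0), 1.0 / np.where(lam > 0, lam, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def euclidean_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise straight-line distances in mm."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    return squareform(pdist(coords))


@dataclass
class CommProfile:
    """Communication measures of one connectome at one density."""

    density: float
    lambda_sp: np.ndarray
    lambda_nav: np.ndarray
    d_nav: np.ndarray
    hops_nav: np.ndarray
    e_sp: float
    e_nav: float


def _profile(conn: Connectome, density: float | None) -> CommProfile:
    g = conn if density is None else threshold_density(conn, density)
    L = weight_to_length(g)
    sp = shortest_paths(L)
    lam, dnav, hops, _ = navigate(L, g.coords)
    return CommProfile(
        density if density is not None else 1.0,
        sp,
        lam,
        dnav,
        hops,
        efficiency(sp),
        efficiency(lam),
    )


def auc_over_densities(
    conn: Connectome,
    densities=DEFAULT_DENSITIES,
    measure: str = "e_nav",
) -> float:
    """Trapezoidal AUC of an efficiency measure over a density grid.

    At each density the raw weighted connectome is proportionally
    thresholded, remapped to lengths and routed; ``measure`` selects
    shortest-path (``"e_sp"``) or navigation (``"e_nav"``) efficiency.
    """
    densities = np.asarray(densities, dtype=float)
    if densities.size < 2:
        raise ValueError("need at least 2 densities")
    if np.any(np.diff(densities) <= 0):
        raise ValueError("densities must be strictly increasing")
    if measure not in ("e_sp", "e_nav"):
        raise ValueError(f"unknown measure {measure!r}")
    vals = [getattr(_profile(conn, d), measure) for d in densities]
    return float(np.trapezoid(vals, densities))


def region_to_lesion_distance(regions: pd.DataFrame, subject) -> pd.Series:
    """Distance (mm) from each pair's ipsilesional region to the nearest lesion.

    Only the region in the lesioned hemisphere is considered; with multiple
    lesion centroids the minimum distance is taken. Indexed by pair id.
    """
    if not subject.lesion_centroids:
        raise ValueError("subject has no lesion centroids")
    if subject.lesion_side not in ("left", "right"):
        raise ValueError("subject lesion hemisphere is undefined")
    tab = validate_regions(regions)
    centroids = np.asarray(subject.lesion_centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != 3:
        raise ValueError("lesion centroids must be (x, y, z) coordinates")
    from .datatypes import homotopic_pairs

    out = {}
    for right_id, left_id in homotopic_pairs(tab):
        ipsi = right_id if subject.lesion_side == "right" else left_id
        com = tab.loc[ipsi, ["x", "y", "z"]].to_numpy(dtype=float)
        out[right_id] = float(np.linalg.norm(centroids - com, axis=1).min())
    return pd.Series(out, name="lesion_distance_mm").rename_axis("pair_id")


class CommunicationModel:
    """Shortest-path and navigation communication analysis of a connectome.

    ``fit`` evaluates both routing schemes at every density of the grid and
    summarizes each as an AUC; per-density matrices are retained on the
    results object.
    """

    def __init__(self, conn: Connectome, densities=DEFAULT_DENSITIES):
        self.conn = conn
        self.densities = tuple(float(d) for d in densities)
        if len(self.densities) < 2:
            raise ValueError("need at least 2 densities")

    def fit(self) -> "CommunicationResults":
        profiles = [_profile(self.conn, d) for d in self.densities]
        return CommunicationResults(self, profiles)


class CommunicationResults:
    """Per-density communication profiles plus AUC summaries."""

    def __init__(self, model: CommunicationModel, profiles: list[CommProfile]):
        self.model = model
        self.profiles = profiles
        dens = np.array([p.density for p in profiles])
        self.per_density = pd.DataFrame(
            {
                "density": dens,
                "e_sp": [p.e_sp for p in profiles],
                "e_nav": [p.e_nav for p in profiles],
            }
        )
        self.auc_e_sp = float(np.trapezoid(self.per_density["e_sp"], dens))
        self.auc_e_nav = float(np.trapezoid(self.per_density["e_nav"], dens))

    def pair_auc(self, i: int, j: int, measure: str = "lambda_nav") -> float:
        """AUC over densities of 1/measure_ij (0 where routing failed)."""
        dens = [p.density for p in self.profiles]
        vals = []
        for p in self.profiles:
            lam = getattr(p, measure)[i, j]
            vals.append(0.0 if not np.isfinite(lam) or lam <= 0 else 1.0 / lam)
        return float(np.trapezoid(vals, dens))

    def pair_mean(self, i: int, j: int, measure: str = "d_nav") -> float:
        """Mean over densities of measure_ij, ignoring failed densities.

        NaN if the pair fails at every density.
        """
        vals = [getattr(p, measure)[i, j] for p in self.profiles]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> str:
        lines = [
            "Connectome communication efficiency",
            f"  densities: {self.model.densities[0]:.2f}..{self.model.densities[-1]:.2f}"
            f" ({len(self.model.densities)} levels)",
            f"  AUC shortest-path efficiency: {self.auc_e_sp:.4f}",
            f"  AUC navigation efficiency:    {self.auc_e_nav:.4f}",
        ]
        return "\n".join(lines)
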