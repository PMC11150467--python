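"""Weighted graph measures on cleaned connectomes.

Six nodal measures (strength, betweenness centrality, clustering coefficient,
mean shortest path length, local efficiency, local assortativity) and four
whole-brain measures (mean clustering, mean local efficiency, characteristic
path length, global efficiency) plus the global assortativity coefficient.

Conventions
-----------
* Edge weight -> path length map: ``length = 1 / weight`` (the standard
  convention for streamline-weighted connectomes); absent edges have infinite
  length.  Shortest paths by Dijkstra's algorithm.
* Betweenness is the unnormalized Brandes count over weighted shortest paths,
  endpoints excluded, with fractional credit for tied geodesics.  Hub scoring
  uses within-subject ranks only, so any affine normalization is irrelevant.
* Weighted clustering follows the Zhang-Horvath generalization (variant
  ``"wang"``, the recommended one for weighted undirected brain graphs), with
  Onnela's geometric-mean form as the ``"onnela"`` fallback.  Triangle
  products use weights rescaled to [0, 1] by the maximum weight.
* Local efficiency (variant ``"wang"``) is an incident-weight-weighted mean of
  inverse shortest-path distances between a node's neighbors, computed on the
  neighbor-induced subgraph; ``"latora"`` is the plain global efficiency of
  that subgraph.  Both reduce to the textbook binary formula on 0/1 matrices.
* Local assortativity: the global coefficient is the edge-weighted Pearson
  correlation of endpoint strengths (each undirected edge contributing both
  orientations); each edge's contribution is split half to each endpoint, so
  the nodal values sum exactly to the global coefficient.
* Unreachable pairs contribute 0 to efficiencies and are excluded from
  path-length means.

Removed nodes carry NaN in every nodal vector and are excluded everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .connectome import Connectome

log = logging.getLogger(__name__)

NODAL_METRICS = (
    "strength",
    "betweenness",
    "clustering",
    "path_length",
    "local_efficiency",
    "assortativity",
)
GLOBAL_METRICS = (
    "clustering",
    "local_efficiency",
    "char_path_length",
    "global_efficiency",
    "assortativity",
)
#: the four whole-brain measures entering the group comparison
WHOLEBRAIN_TEST_METRICS = (
    "clustering",
    "local_efficiency",
    "char_path_length",
    "global_efficiency",
)
#: the four nodal measures entering the hubscore
HUB_METRICS = ("strength", "betweenness", "clustering", "path_length")


@dataclass
class NodalMetrics:
    subject_id: str
    labels: tuple[str, ...]
    values: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: bool = False


@dataclass
class GlobalMetrics:
    subject_id: str
    values: dict[str, float] = field(default_factory=dict)
    normalized: bool = False


# ---------------------------------------------------------------------------
# primitive operations (all defined on the retained submatrix)
# ---------------------------------------------------------------------------

def _retained_weights(c: Connectome) -> tuple[np.ndarray, np.ndarray]:
    ids = c.retained_ids
    return c.weights[np.ix_(ids, ids)], ids


def edge_lengths(w: np.ndarray) -> np.ndarray:
    """Length matrix 1/w with +inf for absent edges (and the diagonal)."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, np.inf)
    return lengths


def _shortest_path_matrix(w: np.ndarray) -> np.ndarray:
    """All-pairs Dijkstra distances; +inf for unreachable pairs."""
    ii, jj = np.nonzero(np.triu(w, 1))
    graph = csr_matrix((1.0 / w[ii, jj], (ii, jj)), shape=w.shape)
    return _dijkstra(graph, directed=False)


def nodal_strength(w: np.ndarray) -> np.ndarray:
    return w.sum(axis=1)


def path_length_stats(d: np.ndarray) -> tuple[np.ndarray, float, float, int]:
    """Nodal mean path length, characteristic path length, global efficiency
    and the number of reachable ordered pairs.

    Unreachable pairs are excluded from path-length means and contribute 0 to
    global efficiency.
    """
    m = d.shape[0]
    if m < 2:
        return np.zeros(m), 0.0, 0.0, 0
    off = ~np.eye(m, dtype=bool)
    finite = np.isfinite(d) & off
    n_reach = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        nodal_L = np.where(
            n_reach > 0, np.where(finite, d, 0.0).sum(axis=1) / np.maximum(n_reach, 1), np.nan
        )
    char_L = float(np.nanmean(nodal_L))
    inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    e_glob = float(inv.sum(axis=1).mean() / (m - 1))
    return nodal_L, char_L, e_glob, int(finite.sum())


def betweenness(w: np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness (Brandes), endpoints excluded."""
    ii, jj = np.nonzero(np.triu(w, 1))
    m = w.shape[0]
    g = ig.Graph(m, list(zip(ii.tolist(), jj.tolist())))
    if len(ii) == 0:
        return np.zeros(m)
    bc = g.betweenness(weights=(1.0 / w[ii, jj]).tolist())
    return np.asarray(bc, dtype=float)


def _hat(w: np.ndarray) -> np.ndarray:
    """Weights rescaled to [0, 1] by the maximum weight."""
    mx = w.max()
    return w / mx if mx > 0 else w


def clustering(w: np.ndarray, variant: str = "wang") -> np.ndarray:
    """Weighted clustering coefficient per node, in [0, 1].

    ``"wang"``: Zhang-Horvath ratio of the weighted triangle sum to the
    maximal possible one,
    ``C_i = sum_{j!=k} what_ij what_jk what_ki / (s_i^2 - sum_j what_ij^2)``.
    ``"onnela"``: mean geometric triangle intensity over connected triples.
    Nodes with degree < 2 get 0 by convention.
    """
    what = _hat(w)
    deg = (w > 0).sum(axis=1)
    if variant == "wang":
        num = np.diagonal(what @ what @ what)
        s = what.sum(axis=1)
        denom = s * s - (what * what).sum(axis=1)
    elif variant == "onnela":
        w3 = np.cbrt(what)
        num = np.diagonal(w3 @ w3 @ w3)
        denom = (deg * (deg - 1)).astype(float)
    else:
        raise ValueError(f"unknown clustering variant {variant!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where((deg >= 2) & (denom > 0), num / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def local_efficiency(w: np.ndarray, variant: str = "wang") -> np.ndarray:
    """Local efficiency per node (>= 0; degree < 2 gives 0 by convention).

    Distances between the neighbors j, k of node i are computed on the
    subgraph induced by the neighbors, with lengths ``1 / what``.
    ``"wang"`` weights each neighbor pair by its incident weights:
    ``E_i = sum_{j!=k} what_ij what_ik / d_jk  /  sum_{j!=k} what_ij what_ik``;
    ``"latora"`` is the unweighted mean of ``1 / d_jk``.
    """
    if variant not in ("wang", "latora"):
        raise ValueError(f"unknown local efficiency variant {variant!r}")
    what = _hat(w)
    m = w.shape[0]
    out = np.zeros(m)
    # neighbor subgraphs are padded into one (m, K, K) stack and solved with
    # a single vectorized Floyd-Warshall pass over all blocks at once
    neighborhoods = [np.flatnonzero(what[i] > 0) for i in range(m)]
    active = [i for i in range(m) if len(neighborhoods[i]) >= 2]
    if not active:
        return out
    K = max(len(neighborhoods[i]) for i in active)
    D = np.full((len(active), K, K), np.inf)
    for b, i in enumerate(active):
        nbrs = neighborhoods[i]
        k = len(nbrs)
        sub = what[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), np.inf)
        np.fill_diagonal(lengths, 0.0)
        D[b, :k, :k] = lengths
    for k in range(K):
        np.minimum(D, D[:, :, k : k + 1] + D[:, k : k + 1, :], out=D)
    for b, i in enumerate(active):
        nbrs = neighborhoods[i]
        k = len(nbrs)
        d = D[b, :k, :k]
        off = ~np.eye(k, dtype=bool)
        finite = np.isfinite(d) & off
        inv_d = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
        if variant == "latora":
            out[i] = inv_d.sum() / (k * (k - 1))
        else:
            wi = what[i, nbrs]
            pair_w = np.outer(wi, wi) * off
            out[i] = (pair_w * inv_d).sum() / pair_w.sum()
    return out


def assortativity(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Global strength assortativity and its nodal decomposition.

    The global coefficient r is the edge-weight-weighted Pearson correlation
    of endpoint strengths over directed edge orientations.  Each directed
    edge's standardized contribution is assigned to its source node, which
    splits every undirected edge half-and-half and makes the nodal values sum
    exactly to r.  Returns (nan, nan vector) when endpoint strengths carry no
    variance (e.g. regular equal-weight graphs).
    """
    s = w.sum(axis=1)
    w_tot = s.sum()  # = sum of w over directed orientations
    m = w.shape[0]
    if w_tot <= 0:
        return np.nan, np.full(m, np.nan)
    mu = (s * s).sum() / w_tot
    var = (s * s * s).sum() / w_tot - mu * mu
    if var <= 1e-15 * max(mu * mu, 1.0):
        log.warning("assortativity undefined: zero strength variance over edges")
        return np.nan, np.full(m, np.nan)
    ds = s - mu
    cov = ds @ w @ ds / w_tot
    r = cov / var
    local = ds * (w @ ds) / (w_tot * var)
    return float(r), local


# ---------------------------------------------------------------------------
# one-call computation
# ---------------------------------------------------------------------------

def compute_metrics(
    c: Connectome,
    metrics: tuple[str, ...] | None = None,
    clustering_variant: str = "wang",
    local_efficiency_variant: str = "wang",
) -> tuple[NodalMetrics, GlobalMetrics]:
    """Compute the requested nodal metrics (default: all six) and the
    whole-brain measures derivable from them, sharing one Dijkstra pass.

    Raises if a retained node is fully disconnected (strength 0) — such nodes
    should have been removed as floating.
    """
    metrics = tuple(metrics) if metrics is not None else NODAL_METRICS
    unknown = set(metrics) - set(NODAL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    w, ids = _retained_weights(c)
    strengths = nodal_strength(w)
    dead = np.flatnonzero(strengths == 0)
    if dead.size:
        names = [c.nodes.labels[ids[i]] for i in dead]
        raise ValueError(
            f"fully disconnected retained node(s) {names}; remove as floating first"
        )

    n = c.n_nodes
    nodal = NodalMetrics(c.subject_id, c.nodes.labels)
    glob = GlobalMetrics(c.subject_id)

    def put(name: str, vals: np.ndarray) -> None:
        full = np.full(n, np.nan)
        full[ids] = vals
        nodal.values[name] = full

    if "strength" in metrics:
        put("strength", strengths)
    if "path_length" in metrics:
        d = _shortest_path_matrix(w)
        nodal_L, char_L, e_glob, _ = path_length_stats(d)
        put("path_length", nodal_L)
        glob.values["char_path_length"] = char_L
        glob.values["global_efficiency"] = e_glob
    if "betweenness" in metrics:
        put("betweenness", betweenness(w))
    if "clustering" in metrics:
        vals = clustering(w, clustering_variant)
        put("clustering", vals)
        glob.values["clustering"] = float(vals.mean())
    if "local_efficiency" in metrics:
        vals = local_efficiency(w, local_efficiency_variant)
        put("local_efficiency", vals)
        glob.values["local_efficiency"] = float(vals.mean())
    if "assortativity" in metrics:
        r, local = assortativity(w)
        put("assortativity", local)
        glob.values["assortativity"] = r
    return nodal, glob
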