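"""Random-graph null ensembles and median normalization of graph measures.

For each subject, equivalent random graphs (same nodes, same weight
multiset) are generated by uniformly permuting the upper-triangle entries —
zeros included — across upper-triangle positions, mirroring for symmetry and
keeping the diagonal empty.  Permuted graphs in which any retained node ends
up with strength 0 ("floating" in the null sense) are rejected and redrawn.
Observed measures are then divided by the ensemble *median* of the same
measure at the same node (median rather than mean: robust to outliers).

Permuting across all pairs (not only existing edges) is the default because
the ensemble is meant to randomize topology given the weight distribution,
and floating-node rejections can only occur if zeros move; a restricted
``"existing_edges"`` scope is available for sensitivity checks.

Seeds: one master seed per run; the per-subject generator is derived with
``numpy.random.SeedSequence([master_seed, subject_index])`` so each subject is
reproducible in isolation and under parallel execution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .metrics import (
    GlobalMetrics,
    NODAL_METRICS,
    NodalMetrics,
    assortativity,
    betweenness,
    clustering,
    local_efficiency,
    nodal_strength,
    path_length_stats,
    _retained_weights,
    _shortest_path_matrix,
)

log = logging.getLogger(__name__)

DEFAULT_N_GRAPHS = 1000
#: null-medians smaller than this (in absolute value) make the ratio
#: ill-defined; the normalized value is set to missing instead
MEDIAN_FLOOR = 1e-12


@dataclass
class NullEnsemble:
    """Per-subject null-ensemble summary (medians, or full draws on request)."""

    subject_id: str
    n_graphs: int
    seed: int
    rejection_count: int
    nodal_medians: dict[str, np.ndarray] = field(default_factory=dict)
    global_medians: dict[str, float] = field(default_factory=dict)
    nodal_draws: dict[str, np.ndarray] | None = None  # (n_graphs, n_nodes)
    global_draws: dict[str, np.ndarray] | None = None


def subject_seed(master_seed: int, subject_index: int) -> np.random.Generator:
    """Counter-based per-subject RNG derivation from one master seed."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, subject_index]))


def permute_weights(
    w: np.ndarray, rng: np.random.Generator, scope: str = "all_pairs"
) -> np.ndarray:
    """One uniform permutation of the upper-triangle weight multiset.

    ``scope="all_pairs"`` permutes over every upper-triangle position (zeros
    move); ``"existing_edges"`` permutes weights only among currently nonzero
    positions (topology preserved).
    """
    m = w.shape[0]
    iu, ju = np.triu_indices(m, 1)
    vals = w[iu, ju]
    out = np.zeros_like(w)
    if scope == "all_pairs":
        perm = rng.permutation(vals)
        out[iu, ju] = perm
    elif scope == "existing_edges":
        nz = vals > 0
        perm = vals.copy()
        perm[nz] = rng.permutation(vals[nz])
        out[iu, ju] = perm
    else:
        raise ValueError(f"unknown permutation scope {scope!r}")
    out += out.T
    return out


def permute_graph(
    c: Connectome, rng: np.random.Generator, scope: str = "all_pairs"
) -> Connectome:
    """Permuted copy of a connectome (removed nodes stay empty)."""
    out = c.copy()
    ids = c.retained_ids
    sub = permute_weights(c.weights[np.ix_(ids, ids)], rng, scope)
    w = np.zeros_like(c.weights)
    w[np.ix_(ids, ids)] = sub
    out.weights = w
    return out


def _metrics_on(w, metrics, clustering_variant, local_efficiency_variant):
    """Nodal-value dict + global-value dict on a retained submatrix."""
    nodal: dict[str, np.ndarray] = {}
    glob: dict[str, float] = {}
    if "strength" in metrics:
        nodal["strength"] = nodal_strength(w)
    if "path_length" in metrics:
        d = _shortest_path_matrix(w)
        nodal_L, char_L, e_glob, _ = path_length_stats(d)
        nodal["path_length"] = nodal_L
        glob["char_path_length"] = char_L
        glob["global_efficiency"] = e_glob
    if "betweenness" in metrics:
        nodal["betweenness"] = betweenness(w)
    if "clustering" in metrics:
        vals = clustering(w, clustering_variant)
        nodal["clustering"] = vals
        glob["clustering"] = float(vals.mean())
    if "local_efficiency" in metrics:
        vals = local_efficiency(w, local_efficiency_variant)
        nodal["local_efficiency"] = vals
        glob["local_efficiency"] = float(vals.mean())
    if "assortativity" in metrics:
        r, local = assortativity(w)
        nodal["assortativity"] = local
        glob["assortativity"] = r
    return nodal, glob


def build_ensemble(
    c: Connectome,
    n_graphs: int = DEFAULT_N_GRAPHS,
    seed: int = 0,
    metrics: tuple[str, ...] | None = None,
    scope: str = "all_pairs",
    clustering_variant: str = "wang",
    local_efficiency_variant: str = "wang",
    store_draws: bool = False,
    rng: np.random.Generator | None = None,
) -> NullEnsemble:
    """Draw permutations until ``n_graphs`` accepted; summarize by medians.

    A permuted graph is rejected when any retained node has strength 0.
    Aborts with a diagnostic if the acceptance rate falls below 1% over
    ``10 * n_graphs`` attempts.
    """
    metrics = tuple(metrics) if metrics is not None else NODAL_METRICS
    if rng is None:
        rng = np.random.default_rng(seed)
    w, ids = _retained_weights(c)
    n_full = c.n_nodes

    nodal_acc: dict[str, list] = {m: [] for m in metrics}
    glob_acc: dict[str, list] = {}
    accepted = 0
    attempts = 0
    rejections = 0
    max_attempts = 10 * n_graphs
    while accepted < n_graphs:
        if attempts >= max_attempts and accepted < 0.01 * attempts:
            raise RuntimeError(
                f"{c.subject_id}: null-graph acceptance rate "
                f"{accepted}/{attempts} below 1%; graph too sparse for the "
                "all-pairs permutation null"
            )
        attempts += 1
        perm = permute_weights(w, rng, scope)
        if (perm.sum(axis=1) == 0).any():
            rejections += 1
            continue
        accepted += 1
        nodal, glob = _metrics_on(
            perm, metrics, clustering_variant, local_efficiency_variant
        )
        for k, v in nodal.items():
            nodal_acc[k].append(v)
        for k, v in glob.items():
            glob_acc.setdefault(k, []).append(v)

    ens = NullEnsemble(
        subject_id=c.subject_id,
        n_graphs=n_graphs,
        seed=seed,
        rejection_count=rejections,
    )
    for k, stack in nodal_acc.items():
        arr = np.asarray(stack)  # (n_graphs, m)
        med = np.full(n_full, np.nan)
        with warnings.catch_warnings():
            # all-NaN columns (e.g. undefined assortativity) yield NaN medians
            warnings.simplefilter("ignore", RuntimeWarning)
            med[ids] = np.nanmedian(arr, axis=0)
        ens.nodal_medians[k] = med
        if store_draws:
            ens.nodal_draws = ens.nodal_draws or {}
            full = np.full((n_graphs, n_full), np.nan)
            full[:, ids] = arr
            ens.nodal_draws[k] = full
    for k, stack in glob_acc.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ens.global_medians[k] = float(np.nanmedian(stack))
        if store_draws:
            ens.global_draws = ens.global_draws or {}
            ens.global_draws[k] = np.asarray(stack)
    return ens


def normalize_metrics(
    nodal: NodalMetrics, glob: GlobalMetrics, ensemble: NullEnsemble
) -> tuple[NodalMetrics, GlobalMetrics]:
    """Divide each raw measure by its null-ensemble median.

    Medians with absolute value below ``MEDIAN_FLOOR`` yield missing values
    (relevant for assortativity, whose null median can straddle zero).
    """
    out_n = NodalMetrics(nodal.subject_id, nodal.labels, normalized=True)
    for k, raw in nodal.values.items():
        med = ensemble.nodal_medians.get(k)
        if med is None:
            raise KeyError(f"ensemble lacks medians for nodal metric {k!r}")
        safe = np.abs(med) >= MEDIAN_FLOOR
        # a raw value exactly equal to its (near-zero) median is still "at
        # its null level": normalized value 1 by the identity rule
        identical = ~safe & (raw == med)
        bad = ~safe & ~identical & np.isfinite(raw)
        if bad.any():
            log.warning(
                "%s: near-zero null median for %s at %d node(s); set missing",
                nodal.subject_id, k, int(bad.sum()),
            )
        vals = np.where(safe, raw / np.where(safe, med, 1.0), np.nan)
        vals = np.where(identical, 1.0, vals)
        out_n.values[k] = vals
    out_g = GlobalMetrics(glob.subject_id, normalized=True)
    for k, raw in glob.values.items():
        med = ensemble.global_medians.get(k)
        if med is None:
            raise KeyError(f"ensemble lacks medians for global metric {k!r}")
        if abs(med) >= MEDIAN_FLOOR:
            out_g.values[k] = raw / med
        elif raw == med:
            out_g.values[k] = 1.0
        else:
            log.warning("%s: near-zero null median for global %s",
                        glob.subject_id, k)
            out_g.values[k] = np.nan
    return out_n, out_g
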