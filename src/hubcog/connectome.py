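"""Subject connectomes: containers, I/O and matrix-level cleaning.

A connectome is a weighted undirected graph over a fixed cohort-wide node set
(a 78-region DKT-style parcellation by default).  Edge weights are SIFT2-style
streamline counts; cleaning removes self-connections and "floating" nodes
(nodes receiving fewer than 1000 of 10 million streamlines), after which edge
weights are normalized by the sum of all edge weights.

Removed nodes are *retained* in the matrix as zero rows/columns plus a mask,
so every subject of a cohort keeps a common node index space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: reference tractogram size against which the floating-node threshold is defined
REFERENCE_STREAMLINE_TOTAL = 10_000_000
#: streamline threshold below which a node is considered floating (strict "<")
DEFAULT_MIN_STREAMLINES = 1000


@dataclass(frozen=True)
class NodeSet:
    """Ordered universe of parcellation nodes shared by a cohort."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("node labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def hemisphere(self, node_id: int) -> str:
        lab = self.labels[node_id]
        if lab.startswith("lh."):
            return "left"
        if lab.startswith("rh."):
            return "right"
        return "none"

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject demographics and clinical flags."""

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    education: int  # ordinal level (Verhage 1-7)
    sex: str = "F"
    putamen_involved: bool | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")


@dataclass
class Connectome:
    """One subject's weighted undirected connectome.

    ``weights`` is a symmetric non-negative square matrix with zero diagonal;
    ``removed`` maps node_id -> removal reason ("floating" or "user") and the
    corresponding rows/columns are all-zero.
    """

    subject_id: str
    group: str
    nodes: NodeSet
    weights: np.ndarray
    removed: dict[int, str] = field(default_factory=dict)
    streamline_total: float = REFERENCE_STREAMLINE_TOTAL
    normalized: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of nodes not removed."""
        mask = np.ones(self.n_nodes, dtype=bool)
        for i in self.removed:
            mask[i] = False
        return mask

    @property
    def retained_ids(self) -> np.ndarray:
        return np.flatnonzero(self.retained)

    def validate(self, rtol: float = 1e-8) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix is not square: shape {w.shape}")
        if w.shape[0] != self.n_nodes:
            raise ValueError(
                f"matrix size {w.shape[0]} does not match node count {self.n_nodes}"
            )
        if not np.allclose(w, w.T, rtol=rtol, atol=0.0):
            raise ValueError("weight matrix is asymmetric beyond tolerance")
        if (w < 0).any():
            raise ValueError("negative edge weights")
        for i in self.removed:
            if w[i].any():
                raise ValueError(f"removed node {i} has nonzero weights")

    def copy(self) -> "Connectome":
        return replace(self, weights=self.weights.copy(), removed=dict(self.removed))


# ---------------------------------------------------------------------------
# I/O (TSV dialect: square matrix with a header row of node labels)
# ---------------------------------------------------------------------------

def read_labels(labels_file: str | Path) -> NodeSet:
    """Read one node label per line."""
    labels = [
        ln.strip() for ln in Path(labels_file).read_text().splitlines() if ln.strip()
    ]
    return NodeSet(tuple(labels))


def read_connectome(
    matrix_file: str | Path,
    labels_file: str | Path | NodeSet,
    meta: SubjectMeta,
) -> Connectome:
    """Read a subject connectome from a delimited matrix + label file.

    Symmetry is *verified* (relative tolerance 1e-8), never repaired by
    averaging; nonzero diagonal entries are forced to zero with a warning.
    """
    nodes = labels_file if isinstance(labels_file, NodeSet) else read_labels(labels_file)
    matrix_file = Path(matrix_file)
    with open(matrix_file) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        w = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if tuple(header) != nodes.labels:
        raise ValueError(
            f"{matrix_file}: header labels do not match the cohort label file"
        )
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{matrix_file}: matrix is not square (shape {w.shape})")
    if w.shape[0] != len(nodes):
        raise ValueError(
            f"{matrix_file}: {w.shape[0]} rows for {len(nodes)} labels"
        )
    if (w < 0).any():
        raise ValueError(f"{matrix_file}: negative edge weights")
    if not np.allclose(w, w.T, rtol=1e-8, atol=0.0):
        raise ValueError(f"{matrix_file}: asymmetric beyond 1e-8 relative tolerance")
    if np.diagonal(w).any():
        log.warning("%s: nonzero diagonal forced to zero", matrix_file)
        np.fill_diagonal(w, 0.0)
    c = Connectome(
        subject_id=meta.subject_id, group=meta.group, nodes=nodes, weights=w
    )
    c.validate()
    return c


def write_connectome(c: Connectome, matrix_file: str | Path) -> None:
    """Write the matrix as TSV with a label header, 17 significant digits."""
    with open(matrix_file, "w") as fh:
        fh.write("\t".join(c.nodes.labels) + "\n")
        for row in c.weights:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def write_removed(c: Connectome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tlabel\treason\n")
        for i, reason in sorted(c.removed.items()):
            fh.write(f"{i}\t{c.nodes.labels[i]}\t{reason}\n")


def read_removed(path: str | Path) -> dict[int, str]:
    removed: dict[int, str] = {}
    lines = Path(path).read_text().splitlines()[1:]
    for ln in lines:
        if ln.strip():
            i, _label, reason = ln.split("\t")
            removed[int(i)] = reason
    return removed


# ---------------------------------------------------------------------------
# Cleaning operations
# ---------------------------------------------------------------------------

def remove_self_connections(c: Connectome) -> Connectome:
    """Zero the diagonal; off-diagonal weights are untouched."""
    out = c.copy()
    np.fill_diagonal(out.weights, 0.0)
    return out


def flag_floating_nodes(
    c: Connectome, min_streamlines: float = DEFAULT_MIN_STREAMLINES
) -> Connectome:
    """Flag nodes whose incident streamline count falls below threshold.

    The threshold (1000 of 10 million streamlines) is defined on raw counts and
    scales proportionally with ``streamline_total`` so that smaller synthetic
    tractograms behave consistently.  Flagged nodes are zeroed and recorded
    with reason ``"floating"``; the rule is a strict "<".
    """
    if c.normalized:
        raise ValueError(
            "floating-node threshold is defined on streamline counts; "
            "apply before edge-weight normalization"
        )
    out = c.copy()
    thr = min_streamlines * (c.streamline_total / REFERENCE_STREAMLINE_TOTAL)
    row_sums = out.weights.sum(axis=1)
    for i in np.flatnonzero((row_sums < thr) & out.retained):
        out.removed[int(i)] = "floating"
        out.weights[i, :] = 0.0
        out.weights[:, i] = 0.0
    return out


def normalize_edge_weights(c: Connectome, edge_sum: str = "upper") -> Connectome:
    """Divide all weights by the sum of all edge weights.

    ``edge_sum`` fixes the summation convention: ``"upper"`` counts each
    undirected edge once (upper triangle sums to 1, full matrix to 2);
    ``"full"`` counts mirrored entries twice (full matrix sums to 1).
    """
    if edge_sum not in ("upper", "full"):
        raise ValueError(f"edge_sum must be 'upper' or 'full', got {edge_sum!r}")
    out = c.copy()
    upper = np.triu(out.weights, 1).sum()
    if upper <= 0:
        raise ValueError("cannot normalize an all-zero connectome")
    total = upper if edge_sum == "upper" else 2.0 * upper
    out.weights = out.weights / total
    out.normalized = True
    return out


def binarize(c: Connectome, density: float) -> Connectome:
    """Threshold to a binary graph of the given edge density.

    Keeps the ``ceil(density * P)`` strongest off-diagonal pairs among the
    ``P = m(m-1)/2`` possible pairs of retained nodes at weight 1.  Pairs tied
    with the cutoff weight are included in label-lexicographic order (by the
    sorted pair of labels) until the target count is reached.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    out = c.copy()
    ids = c.retained_ids
    m = len(ids)
    n_pairs = m * (m - 1) // 2
    k = int(np.ceil(density * n_pairs))
    pairs = [
        (int(i), int(j)) for a, i in enumerate(ids) for j in ids[a + 1 :]
    ]
    labels = c.nodes.labels

    def sort_key(p):
        i, j = p
        return (-c.weights[i, j], tuple(sorted((labels[i], labels[j]))))

    keep = sorted(pairs, key=sort_key)[:k]
    w = np.zeros_like(out.weights)
    for i, j in keep:
        w[i, j] = w[j, i] = 1.0
    out.weights = w
    out.normalized = False
    return out
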