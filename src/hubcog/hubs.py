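"""Hubscore computation and group-level hub / non-hub classification.

Per subject, each retained node earns one point for each of four criteria:
highest 20% of nodal strength and betweenness centrality, lowest 20% of mean
shortest path length and clustering coefficient — yielding a hubscore of 0-4.
A node is a *group hub* when its hubscore is >= 2 in more than 80% of the
group's subjects; a *non-hub* is a node with hubscore 0 in every healthy
control.  By default the constituent metrics are the null-normalized ones
(the hubscore is rank-based within subject, so this matters only when
normalization reorders nodes).

Tie handling at the 20% cutoff: the cutoff is the m-th value (m = ceil(q*N))
in the criterion's favorable ordering and every node at-or-beyond the cutoff
scores the point (``tie_rule="inclusive"``, node-order invariant); the
``"strict_rank"`` alternative takes exactly the top m with ties broken by
node index.  Removed (floating) nodes receive no hubscore, are excluded from
the subject's N, and can therefore never become a hub or a non-hub.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import HUB_METRICS, NodalMetrics

log = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.20
DEFAULT_HUB_THRESHOLD = 0.80
#: criterion direction: True = highest values are favorable
_HIGHER_IS_HUBBY = {
    "strength": True,
    "betweenness": True,
    "path_length": False,
    "clustering": False,
}


def criterion_points(
    values: np.ndarray, higher: bool, q: float = DEFAULT_TOP_FRACTION,
    tie_rule: str = "inclusive",
) -> np.ndarray:
    """Boolean point vector for one criterion over one subject's nodes.

    NaN entries (removed nodes) never score and do not count toward N.
    """
    ok = np.isfinite(values)
    n_ret = int(ok.sum())
    m = math.ceil(q * n_ret)
    if n_ret < math.ceil(1.0 / q):
        raise ValueError(f"too few retained nodes ({n_ret}) for q={q}")
    pts = np.zeros(values.shape, dtype=bool)
    v = values[ok]
    order = np.argsort(-v if higher else v, kind="stable")
    if tie_rule == "inclusive":
        cutoff = v[order[m - 1]]
        pts[ok] = v >= cutoff if higher else v <= cutoff
    elif tie_rule == "strict_rank":
        sel = np.zeros(n_ret, dtype=bool)
        sel[order[:m]] = True
        pts[ok] = sel
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return pts


def subject_hubscore(
    nodal: NodalMetrics, q: float = DEFAULT_TOP_FRACTION,
    tie_rule: str = "inclusive",
) -> np.ndarray:
    """Per-node hubscore (0-4) for one subject; NaN at removed nodes."""
    missing = [m for m in HUB_METRICS if m not in nodal.values]
    if missing:
        raise KeyError(f"hubscore needs metrics {missing}")
    finite = np.isfinite(np.column_stack([nodal.values[m] for m in HUB_METRICS]))
    ok = finite.all(axis=1)
    score = np.zeros(len(nodal.labels))
    for metric in HUB_METRICS:
        vals = np.where(ok, nodal.values[metric], np.nan)
        score += criterion_points(vals, _HIGHER_IS_HUBBY[metric], q, tie_rule)
    score[~ok] = np.nan
    return score


@dataclass
class HubAssignment:
    """Hubscores per group plus the derived hub / non-hub node sets."""

    labels: tuple[str, ...]
    scores: dict[str, np.ndarray]  # group -> (n_subjects, n_nodes), NaN = removed
    hub_threshold: float = DEFAULT_HUB_THRESHOLD
    hub_fraction: dict[str, np.ndarray] = field(default_factory=dict)
    zero_fraction: dict[str, np.ndarray] = field(default_factory=dict)
    hubs: dict[str, np.ndarray] = field(default_factory=dict)  # group -> node ids
    nonhubs: np.ndarray | None = None  # control-defined

    def node_class(self, node_id: int) -> str:
        if node_id in self.hubs.get("control", ()):
            return "hub"
        if self.nonhubs is not None and node_id in self.nonhubs:
            return "nonhub"
        return "neither"


def group_hub_fractions(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(fraction with hubscore >= 2, fraction with hubscore == 0) per node,
    over the subjects in which the node was retained."""
    with np.errstate(invalid="ignore"):
        present = np.isfinite(scores)
        n = np.maximum(present.sum(axis=0), 1)
        hub_frac = np.where(present, scores >= 2, False).sum(axis=0) / n
        zero_frac = np.where(present, scores == 0, False).sum(axis=0) / n
    return hub_frac, zero_frac


def assign_hubs(
    scores: dict[str, np.ndarray],
    labels: tuple[str, ...],
    hub_threshold: float = DEFAULT_HUB_THRESHOLD,
    control_group: str = "control",
) -> HubAssignment:
    """Group hubs (hub_fraction strictly > threshold per group) and
    control-defined non-hubs (hubscore 0 in every control)."""
    asg = HubAssignment(labels=labels, scores=scores, hub_threshold=hub_threshold)
    for group, mat in scores.items():
        if mat.shape[0] == 0:
            raise ValueError(f"empty group {group!r}")
        hub_frac, zero_frac = group_hub_fractions(mat)
        asg.hub_fraction[group] = hub_frac
        asg.zero_fraction[group] = zero_frac
        asg.hubs[group] = np.flatnonzero(hub_frac > hub_threshold)
    if control_group in scores:
        zf = asg.zero_fraction[control_group]
        retained_everywhere = np.isfinite(scores[control_group]).any(axis=0)
        asg.nonhubs = np.flatnonzero((zf == 1.0) & retained_everywhere)
    return asg


def hub_frequency_tests(
    assignment: HubAssignment,
    nodes: np.ndarray | None = None,
    groups: tuple[str, str] = ("patient", "control"),
    bonferroni: int | None = None,
) -> pd.DataFrame:
    """Per-node 2x2 chi-square of group x (hubscore >= 2).

    Pearson chi-square without continuity correction; when any expected cell
    is < 1 the test switches to Fisher's exact with a logged warning.
    Default node family and Bonferroni divisor: the control-defined hubs.
    """
    g1, g2 = groups
    if nodes is None:
        nodes = assignment.hubs[g2]
    divisor = bonferroni if bonferroni is not None else max(len(nodes), 1)
    rows = []
    for node in nodes:
        table = np.zeros((2, 2))
        for gi, group in enumerate(groups):
            col = assignment.scores[group][:, node]
            col = col[np.isfinite(col)]
            table[gi] = [(col >= 2).sum(), (col < 2).sum()]
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        if table.sum(0).min() == 0 or table.sum(1).min() == 0:
            chi2, p, method = 0.0, 1.0, "degenerate"
        elif (expected < 1).any():
            log.warning(
                "node %s: expected cell < 1, using Fisher exact",
                assignment.labels[node],
            )
            _, p = stats.fisher_exact(table.astype(int))
            chi2, method = np.nan, "fisher"
        else:
            chi2 = float(((table - expected) ** 2 / expected).sum())
            p = float(stats.chi2.sf(chi2, 1))
            method = "chi2"
        rows.append(
            dict(
                node_id=int(node),
                node_label=assignment.labels[node],
                **{
                    f"hub_fraction_{g}": assignment.hub_fraction[g][node]
                    for g in groups
                },
                chi2=chi2,
                p=p,
                p_bonf=min(p * divisor, 1.0),
                method=method,
            )
        )
    return pd.DataFrame(rows)


def hub_report(assignment: HubAssignment) -> pd.DataFrame:
    """Tidy per-node, per-group table of fractions and labels."""
    rows = []
    for group, mat in assignment.scores.items():
        for node, label in enumerate(assignment.labels):
            rows.append(
                dict(
                    node_label=label,
                    group=group,
                    hub_fraction=assignment.hub_fraction[group][node],
                    zero_fraction=assignment.zero_fraction[group][node],
                    is_hub=node in assignment.hubs[group],
                    is_nonhub=(
                        assignment.nonhubs is not None and node in assignment.nonhubs
                    ),
                )
            )
    return pd.DataFrame(rows)
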