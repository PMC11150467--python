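"""Inferential battery on metric and cognitive tables.

Implements the group-comparison and brain-behaviour statistics of the
pipeline: Mann-Whitney U tests on whole-brain measures (Bonferroni over the
four measures), two mixed-design ANOVAs (group x node) on hub and non-hub
nodal measures with Mauchly sphericity check and Greenhouse-Geisser
correction, Pearson correlation grids between nodal measures and cognitive
domain w-scores with family-wise Bonferroni thresholds, and McNemar tests of
whether significant brain-behaviour correlations occur more often in hubs
than in non-hubs.

Bonferroni correction only (no FDR) throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# whole-brain group tests
# ---------------------------------------------------------------------------

def wholebrain_group_tests(
    values: pd.DataFrame, groups: pd.Series, bonferroni: int | None = None
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per whole-brain measure (columns of
    ``values``), patients vs controls; Bonferroni over the tested measures
    (divisor 4 for the default family)."""
    measures = list(values.columns)
    divisor = bonferroni if bonferroni is not None else len(measures)
    pat = groups == "patient"
    rows = []
    for m in measures:
        x = values.loc[pat, m].dropna().to_numpy()
        y = values.loc[~pat, m].dropna().to_numpy()
        method = "exact" if (len(x) <= 10 and len(y) <= 10
                             and len(np.unique(np.r_[x, y])) == len(x) + len(y)) \
            else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(dict(measure=m, U=float(res.statistic), p=float(res.pvalue),
                         p_bonf=min(float(res.pvalue) * divisor, 1.0)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-design ANOVA (one between factor, one within factor)
# ---------------------------------------------------------------------------

@dataclass
class MixedAnovaResult:
    """Classical univariate decomposition of a balanced group x node design.

    Between-subjects factor: group (2 levels); within-subjects factor: node
    (k levels).  Greenhouse-Geisser df scaling is applied to the within
    effects when Mauchly's test rejects sphericity at alpha = 0.05.
    """

    n_per_group: dict[str, int]
    k: int
    # between-group effect
    F_group: float = np.nan
    df_group: tuple[int, int] = (0, 0)
    p_group: float = np.nan
    eta_p2_group: float = np.nan
    # within effects
    F_node: float = np.nan
    df_node: tuple[int, int] = (0, 0)
    p_node: float = np.nan
    p_node_gg: float = np.nan
    eta_p2_node: float = np.nan
    F_interaction: float = np.nan
    df_interaction: tuple[int, int] = (0, 0)
    p_interaction: float = np.nan
    p_interaction_gg: float = np.nan
    eta_p2_interaction: float = np.nan
    # sphericity
    mauchly_W: float = np.nan
    mauchly_p: float = np.nan
    gg_epsilon: float = np.nan
    sphericity_violated: bool = False
    log_transformed: bool = False
    sums_of_squares: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(effect="group", F=self.F_group, df1=self.df_group[0],
                     df2=self.df_group[1], p=self.p_group, p_gg=self.p_group,
                     eta_p2=self.eta_p2_group),
                dict(effect="node", F=self.F_node, df1=self.df_node[0],
                     df2=self.df_node[1], p=self.p_node, p_gg=self.p_node_gg,
                     eta_p2=self.eta_p2_node),
                dict(effect="node_x_group", F=self.F_interaction,
                     df1=self.df_interaction[0], df2=self.df_interaction[1],
                     p=self.p_interaction, p_gg=self.p_interaction_gg,
                     eta_p2=self.eta_p2_interaction),
            ]
        )


def _gg_epsilon(S: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within covariance."""
    k = S.shape[0]
    if k == 2:
        return 1.0
    # eigenvalues of the double-centered covariance
    J = np.eye(k) - np.ones((k, k)) / k
    M = J @ S @ J
    lam = np.linalg.eigvalsh(M)
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)]
    return float(lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum()))


def _mauchly(S: np.ndarray, n_error: int) -> tuple[float, float]:
    """Mauchly's sphericity statistic W and its chi-square p-value."""
    k = S.shape[0]
    if k == 2:
        return 1.0, 1.0
    # orthonormal contrast
    C = np.linalg.qr(np.eye(k) - np.ones((k, k)) / k)[0][:, : k - 1].T
    T = C @ S @ C.T
    lam = np.linalg.eigvalsh(T)
    if (lam <= 0).any():
        return 0.0, 0.0
    d = k - 1
    W = float(np.prod(lam) / (lam.mean() ** d))
    f = d * (d + 2) / 2 - 1
    mult = n_error - (2 * d * d + d + 2) / (6.0 * d)
    chi2 = -mult * math.log(max(W, 1e-300))
    return W, float(sps.chi2.sf(chi2, f))


def _cell_normality_ok(y: np.ndarray, groups: np.ndarray, alpha=0.05) -> bool:
    """Shapiro-Wilk per group x node cell; False if any cell rejects."""
    for g in np.unique(groups):
        block = y[groups == g]
        for j in range(y.shape[1]):
            col = block[:, j]
            if len(col) >= 3 and np.ptp(col) > 0:
                if sps.shapiro(col).pvalue < alpha:
                    return False
    return True


def mixed_anova(
    values: np.ndarray,
    groups: np.ndarray | pd.Series,
    normality_check: bool = False,
    log_shift: bool = False,
) -> MixedAnovaResult:
    """Mixed-design ANOVA on a (subjects x nodes) matrix.

    ``normality_check=True`` log-transforms all values first when any
    group x node cell fails Shapiro-Wilk at alpha = 0.05.  ``log(x)`` errors
    on non-positive values; the documented fallback ``log(x - min + eps)``
    requires the explicit ``log_shift=True`` opt-in.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a subjects x nodes matrix with k >= 2 nodes")
    if np.isnan(y).any():
        raise ValueError("missing cells; the design must be balanced")
    logged = False
    if normality_check and not _cell_normality_ok(y, groups):
        if (y <= 0).any():
            if not log_shift:
                raise ValueError(
                    "non-positive values under log transform; "
                    "pass log_shift=True to use log(x - min + eps)"
                )
            y = np.log(y - y.min() + 1e-6)
        else:
            y = np.log(y)
        logged = True

    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups expected")
    n_g = {g: int((groups == g).sum()) for g in levels}
    N, k = y.shape

    gm = y.mean()
    subj_means = y.mean(axis=1)
    node_means = y.mean(axis=0)
    ss_total = ((y - gm) ** 2).sum()
    ss_subjects = k * ((subj_means - gm) ** 2).sum()
    ss_group = k * sum(
        n_g[g] * (subj_means[groups == g].mean() - gm) ** 2 for g in levels
    )
    ss_subj_within = ss_subjects - ss_group
    ss_within = ss_total - ss_subjects
    ss_node = N * ((node_means - gm) ** 2).sum()
    ss_inter = 0.0
    for g in levels:
        block = y[groups == g]
        cell = block.mean(axis=0)
        ss_inter += n_g[g] * (
            (cell - block.mean() - node_means + gm) ** 2
        ).sum()
    ss_err_within = ss_within - ss_node - ss_inter

    res = MixedAnovaResult(n_per_group=n_g, k=k, log_transformed=logged)
    res.sums_of_squares = dict(
        total=ss_total, subjects=ss_subjects, group=ss_group,
        subj_within=ss_subj_within, node=ss_node, interaction=ss_inter,
        error_within=ss_err_within,
    )

    df_g, df_sw = 1, N - 2
    res.df_group = (df_g, df_sw)
    res.F_group = (ss_group / df_g) / (ss_subj_within / df_sw)
    res.p_group = float(sps.f.sf(res.F_group, df_g, df_sw))
    res.eta_p2_group = ss_group / (ss_group + ss_subj_within)

    df_n, df_i, df_e = k - 1, k - 1, (N - 2) * (k - 1)
    ms_e = ss_err_within / df_e
    res.df_node = (df_n, df_e)
    res.F_node = (ss_node / df_n) / ms_e
    res.p_node = float(sps.f.sf(res.F_node, df_n, df_e))
    res.eta_p2_node = ss_node / (ss_node + ss_err_within)
    res.df_interaction = (df_i, df_e)
    res.F_interaction = (ss_inter / df_i) / ms_e
    res.p_interaction = float(sps.f.sf(res.F_interaction, df_i, df_e))
    res.eta_p2_interaction = ss_inter / (ss_inter + ss_err_within)

    # sphericity on the pooled within-group covariance
    centered = np.vstack([y[groups == g] - y[groups == g].mean(0) for g in levels])
    S = centered.T @ centered / (N - 2)
    res.mauchly_W, res.mauchly_p = _mauchly(S, N - 2)
    res.gg_epsilon = _gg_epsilon(S)
    res.sphericity_violated = bool(res.mauchly_p < 0.05)
    eps = res.gg_epsilon if res.sphericity_violated else 1.0
    res.p_node_gg = float(sps.f.sf(res.F_node, df_n * eps, df_e * eps))
    res.p_interaction_gg = float(sps.f.sf(res.F_interaction, df_i * eps, df_e * eps))
    return res


# ---------------------------------------------------------------------------
# correlation grid
# ---------------------------------------------------------------------------

def correlation_grid(
    nodal_values: dict[str, pd.DataFrame],
    domain_scores: pd.DataFrame,
    node_classes: dict[int, str],
    alpha: float = 0.05,
    alpha_divisor: int | None = None,
) -> pd.DataFrame:
    """Pearson r between each (metric, node) measure and each cognitive
    domain, pooled over participants.

    ``nodal_values[metric]`` is a subjects x nodes DataFrame (columns =
    node ids) aligned with ``domain_scores`` on the subject index.  The
    default Bonferroni divisor is #metrics x #domains x #classified nodes.
    """
    metrics = list(nodal_values)
    nodes = sorted(node_classes)
    domains = list(domain_scores.columns)
    if alpha_divisor is None:
        alpha_divisor = len(metrics) * len(domains) * len(nodes)
    thr = alpha / alpha_divisor
    rows = []
    for metric in metrics:
        vals = nodal_values[metric]
        for node in nodes:
            if node not in vals.columns:
                continue
            x_full = vals[node]
            for dom in domains:
                pair = pd.concat([x_full, domain_scores[dom]], axis=1).dropna()
                n = len(pair)
                if n < 3 or pair.iloc[:, 0].nunique() < 2:
                    r, p = np.nan, np.nan
                else:
                    r, p = sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                rows.append(dict(
                    metric=metric, node_id=node, node_class=node_classes[node],
                    domain=dom, r=r, p=p, n=n,
                    significant=bool(p < thr) if np.isfinite(p) else False,
                ))
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["alpha_divisor"] = alpha_divisor
    return out


# ---------------------------------------------------------------------------
# McNemar: correlations in hubs vs non-hubs
# ---------------------------------------------------------------------------

def mcnemar_test(b: int, c: int) -> tuple[float, float, str]:
    """McNemar on discordant counts: exact binomial when b + c < 25, else
    the chi-square (b - c)^2 / (b + c)."""
    n = b + c
    if n == 0:
        return np.nan, 1.0, "no discordant pairs"
    if n < 25:
        p = float(min(1.0, 2.0 * sps.binom.sf(max(b, c) - 1, n, 0.5)))
        return np.nan, p, "exact"
    chi2 = (b - c) ** 2 / n
    return float(chi2), float(sps.chi2.sf(chi2, 1)), "chi2"


def hub_vs_nonhub_frequency(
    grid: pd.DataFrame,
    pairing: str = "paired_nodes",
    alpha_divisor: int = 4,
) -> pd.DataFrame:
    """Per metric, test whether significant correlations occur more often in
    hubs than in non-hubs (McNemar on paired binary indicators).

    Pairing rules (the original analysis does not define the paired unit):

    * ``"paired_nodes"`` (default): for each domain, the j-th hub node (by
      node id) is paired with the j-th non-hub node, cycling through the
      smaller class; one binary pair per (domain, node of the larger class).
    * ``"majority"``: one pair per domain — (significant in > 50% of hub
      nodes, significant in > 50% of non-hub nodes).
    * ``"any_node"``: one pair per domain with the >=1-node indicator.
    """
    rows = []
    for metric, sub in grid.groupby("metric", sort=False):
        b = c = n_pairs = 0
        for _, dsub in sub.groupby("domain", sort=False):
            hub = dsub[dsub.node_class == "hub"].sort_values("node_id")
            non = dsub[dsub.node_class == "nonhub"].sort_values("node_id")
            if pairing == "paired_nodes":
                m = max(len(hub), len(non))
                if min(len(hub), len(non)) == 0:
                    continue
                hs = hub.significant.to_numpy()
                ns = non.significant.to_numpy()
                hs = hs[np.arange(m) % len(hs)]
                ns = ns[np.arange(m) % len(ns)]
                b += int((hs & ~ns).sum())
                c += int((~hs & ns).sum())
                n_pairs += m
            elif pairing in ("majority", "any_node"):
                if pairing == "majority":
                    hi = hub.significant.mean() > 0.5 if len(hub) else False
                    ni = non.significant.mean() > 0.5 if len(non) else False
                else:
                    hi = bool(hub.significant.any())
                    ni = bool(non.significant.any())
                b += int(hi and not ni)
                c += int(ni and not hi)
                n_pairs += 1
            else:
                raise ValueError(f"unknown pairing rule {pairing!r}")
        chi2, p, method = mcnemar_test(b, c)
        rows.append(dict(metric=metric, b=b, c=c, n_pairs=n_pairs, chi2=chi2,
                         p=p, p_bonf=min(p * alpha_divisor, 1.0), method=method,
                         pairing=pairing))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metadata subgroup filter
# ---------------------------------------------------------------------------

def subgroup_filter(cohort: pd.DataFrame, predicate) -> pd.DataFrame:
    """Filter a subject table on a metadata predicate (callable or pandas
    query string); errors on an empty result."""
    if callable(predicate):
        out = cohort[cohort.apply(predicate, axis=1)]
    else:
        out = cohort.query(predicate)
    if len(out) == 0:
        raise ValueError(f"subgroup filter {predicate!r} selected no subjects")
    return out
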