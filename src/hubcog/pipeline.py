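"""End-to-end analysis pipeline: clean -> metrics -> null-normalize -> hubs
-> w-scores -> statistics, with provenance and caching.

The pipeline consumes a cohort directory (TSV connectome matrices, a label
file, metadata and cognition CSVs) and writes tidy result CSVs plus a JSON
run manifest.  The expensive per-subject stage (graph metrics + null
ensemble) is cached on a content hash of the cleaned matrix and the relevant
configuration, so robustness variants (raw-metric hub scoring, binary
graphs, subgroups) reuse it where applicable.

Analysis conventions
--------------------
* Hub scoring and nodal/whole-brain comparisons use null-normalized values
  for the ratio-scale measures; *assortativity enters raw*: its null median
  straddles zero, which makes the ratio sign-unstable (see the nulls module).
* The mixed ANOVAs log-transform a measure when any group x node cell fails
  Shapiro-Wilk (log only applies to all-positive measures; assortativity is
  analyzed untransformed).
* The correlation grid takes the measures whose ANOVA group effect is
  Bonferroni-significant in both the hub and the non-hub family, log
  transformed where the ANOVA was, and correlates them with the six domain
  w-scores over the pooled sample.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cognition import (
    DEFAULT_BATTERY,
    DOMAINS,
    compute_wscores,
    domain_scores,
    fit_normative_model,
    group_domain_comparison,
    impairment_table,
)
from .connectome import (
    Connectome,
    SubjectMeta,
    binarize,
    flag_floating_nodes,
    normalize_edge_weights,
    read_connectome,
    read_labels,
)
from .hubs import assign_hubs, hub_frequency_tests, hub_report, subject_hubscore
from .metrics import (
    GlobalMetrics,
    NODAL_METRICS,
    NodalMetrics,
    WHOLEBRAIN_TEST_METRICS,
    compute_metrics,
)
from .nulls import build_ensemble, normalize_metrics, subject_seed
from .stats import (
    correlation_grid,
    hub_vs_nonhub_frequency,
    mixed_anova,
    subgroup_filter,
    wholebrain_group_tests,
)

log = logging.getLogger(__name__)

#: measures analyzed on the raw scale: assortativity straddles zero, and
#: betweenness has frequently-zero null medians (half the nodes of a permuted
#: graph carry no geodesic interior), which makes the ratio unstable.  For
#: the rank-based hubscore the betweenness choice is inconsequential.
RAW_SCALE_METRICS = ("assortativity", "betweenness")


@dataclass
class PipelineConfig:
    """All tunable analysis parameters (YAML-serializable)."""

    seed: int = 0
    min_streamlines: float = 1000.0
    edge_sum: str = "upper"            # normalization sum convention
    metrics: tuple[str, ...] = NODAL_METRICS
    clustering_variant: str = "wang"
    local_efficiency_variant: str = "wang"
    n_graphs: int = 1000
    permute_scope: str = "all_pairs"
    hub_on: str = "normalized"         # or "raw" (robustness variant)
    hub_q: float = 0.20
    hub_threshold: float = 0.80
    tie_rule: str = "inclusive"
    binary_density: float | None = None  # binarization robustness variant
    anova_bonferroni: int | None = None  # default: #metrics x 2 families
    wholebrain_bonferroni: int = 4
    domain_bonferroni: int = 6
    mcnemar_pairing: str = "paired_nodes"
    mcnemar_bonferroni: int = 4
    grid_alpha: float = 0.05
    subgroup: str | None = None        # pandas query on the metadata table

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "metrics" in data:
            data["metrics"] = tuple(data["metrics"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort loading
# ---------------------------------------------------------------------------

def load_cohort(cohort_dir: str | Path):
    """Read matrices, labels, metadata and cognition tables of a cohort."""
    cohort_dir = Path(cohort_dir)
    for required in ("labels.txt", "metadata.csv", "cognition.csv", "matrices"):
        if not (cohort_dir / required).exists():
            raise FileNotFoundError(f"cohort is missing {required}")
    nodes = read_labels(cohort_dir / "labels.txt")
    metadata = pd.read_csv(cohort_dir / "metadata.csv")
    cognition = pd.read_csv(cohort_dir / "cognition.csv")
    connectomes = []
    for row in metadata.itertuples():
        meta = SubjectMeta(
            subject_id=row.subject_id, group=row.group, age=row.age,
            education=int(row.education), sex=row.sex,
            putamen_involved=bool(row.putamen_involved)
            if not pd.isna(row.putamen_involved) else None,
        )
        path = cohort_dir / "matrices" / f"{row.subject_id}.tsv"
        c = read_connectome(path, nodes, meta)
        # tractogram size: taken from metadata when recorded, otherwise the
        # matrix is treated as self-describing (total = sum over edges)
        if "streamline_total" in metadata.columns:
            c.streamline_total = float(row.streamline_total)
        else:
            c.streamline_total = float(np.triu(c.weights, 1).sum())
        connectomes.append(c)
    return connectomes, metadata, cognition


# ---------------------------------------------------------------------------
# per-subject stage with caching
# ---------------------------------------------------------------------------

def clean_connectome(c: Connectome, config: PipelineConfig) -> Connectome:
    from .connectome import remove_self_connections

    c = remove_self_connections(c)
    c = flag_floating_nodes(c, config.min_streamlines)
    if config.binary_density is not None:
        c = binarize(c, config.binary_density)
        c.normalized = True  # binary weights need no sum normalization
        return c
    return normalize_edge_weights(c, config.edge_sum)


def _subject_cache_key(c: Connectome, config: PipelineConfig, sub_seed) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(c.weights).tobytes())
    h.update(json.dumps([
        sorted(c.removed.items()), list(config.metrics),
        config.clustering_variant, config.local_efficiency_variant,
        config.n_graphs, config.permute_scope, sub_seed,
    ]).encode())
    return h.hexdigest()[:24]


def subject_metrics(
    c: Connectome, config: PipelineConfig, subject_index: int,
    cache_dir: Path | None = None,
) -> dict:
    """Raw + normalized metrics for one cleaned connectome (cached)."""
    sub_seed = [config.seed, subject_index]
    key = None
    if cache_dir is not None:
        key = _subject_cache_key(c, config, sub_seed)
        cached = cache_dir / f"{key}.json"
        if cached.exists():
            return json.loads(cached.read_text())
    nodal, glob = compute_metrics(
        c, config.metrics, config.clustering_variant,
        config.local_efficiency_variant,
    )
    ens = build_ensemble(
        c, config.n_graphs, metrics=config.metrics,
        scope=config.permute_scope,
        clustering_variant=config.clustering_variant,
        local_efficiency_variant=config.local_efficiency_variant,
        rng=subject_seed(config.seed, subject_index), seed=config.seed,
    )
    norm_nodal, norm_glob = normalize_metrics(nodal, glob, ens)
    out = dict(
        subject_id=c.subject_id, group=c.group,
        removed={str(k): v for k, v in c.removed.items()},
        rejection_count=ens.rejection_count,
        nodal_raw={k: v.tolist() for k, v in nodal.values.items()},
        nodal_norm={k: v.tolist() for k, v in norm_nodal.values.items()},
        nodal_null_median={k: v.tolist() for k, v in ens.nodal_medians.items()},
        global_raw=glob.values,
        global_norm=norm_glob.values,
        global_null_median=ens.global_medians,
    )
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        (cache_dir / f"{key}.json").write_text(json.dumps(out))
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    cohort_dir: str | Path,
    results_dir: str | Path,
    config: PipelineConfig | None = None,
    use_cache: bool = True,
) -> Path:
    """Execute every stage on a cohort directory and write all outputs."""
    config = config or PipelineConfig()
    cohort_dir, results_dir = Path(cohort_dir), Path(results_dir)
    results_dir.mkdir(parents=True, exist_ok=True)
    cache_dir = results_dir / "cache" if use_cache else None
    manifest: dict = dict(
        package_version=__version__, config=config.to_dict(),
        config_hash=config.content_hash(), cohort_dir=str(cohort_dir),
        stages={},
    )
    t_all = time.time()

    # -- clean + per-subject metrics ------------------------------------
    t0 = time.time()
    connectomes, metadata, cognition = load_cohort(cohort_dir)
    if config.subgroup:
        keep_controls = metadata[metadata.group == "control"]
        kept_patients = subgroup_filter(
            metadata[metadata.group == "patient"], config.subgroup)
        metadata = pd.concat([kept_patients, keep_controls], ignore_index=True)
        keep = set(metadata.subject_id)
        connectomes = [c for c in connectomes if c.subject_id in keep]
        cognition = cognition[cognition.subject_id.isin(keep)]
    manifest["stages"]["load"] = round(time.time() - t0, 3)

    t0 = time.time()
    per_subject = []
    for idx, c in enumerate(connectomes):
        cleaned = clean_connectome(c, config)
        per_subject.append(subject_metrics(cleaned, config, idx, cache_dir))
    manifest["stages"]["metrics_and_nulls"] = round(time.time() - t0, 3)

    labels = connectomes[0].nodes.labels
    n_nodes = len(labels)
    _write_metric_table(per_subject, labels, results_dir / "metric_table.csv")

    # -- hubs ------------------------------------------------------------
    t0 = time.time()
    scores: dict[str, list] = {"patient": [], "control": []}
    order: dict[str, list] = {"patient": [], "control": []}
    for rec in per_subject:
        values = {}
        for k in rec["nodal_raw"]:
            layer = ("nodal_raw" if config.hub_on == "raw"
                     or k in RAW_SCALE_METRICS else "nodal_norm")
            values[k] = np.asarray(rec[layer][k])
        nm = NodalMetrics(rec["subject_id"], labels, values)
        s = subject_hubscore(nm, config.hub_q, config.tie_rule)
        scores[rec["group"]].append(s)
        order[rec["group"]].append(rec["subject_id"])
    score_mats = {g: np.vstack(v) for g, v in scores.items() if v}
    assignment = assign_hubs(score_mats, labels, config.hub_threshold)
    hub_report(assignment).to_csv(results_dir / "hub_report.csv", index=False)
    freq = hub_frequency_tests(assignment)
    freq.to_csv(results_dir / "hub_frequency_tests.csv", index=False)
    manifest["stages"]["hubs"] = round(time.time() - t0, 3)

    # -- cognition -------------------------------------------------------
    t0 = time.time()
    cog = cognition.merge(metadata, on="subject_id").set_index("subject_id")
    model = fit_normative_model(cog[cog.group == "control"])
    wsc = compute_wscores(cog, model)
    doms = domain_scores(wsc)
    impaired = impairment_table(wsc)
    cogtable = pd.concat(
        [cog[["group", "age", "education"]], wsc, doms,
         impaired.rename("impaired")], axis=1)
    cogtable.to_csv(results_dir / "cognitive_table.csv")
    domain_tests = group_domain_comparison(
        doms[cog.group == "patient"], doms[cog.group == "control"],
        config.domain_bonferroni)
    domain_tests.to_csv(results_dir / "domain_group_tests.csv", index=False)
    impairment_summary = (
        cogtable.groupby("group")["impaired"].agg(["mean", "sum", "count"])
        .rename(columns={"mean": "fraction"}))
    impairment_summary.to_csv(results_dir / "impairment_summary.csv")
    manifest["stages"]["wscores"] = round(time.time() - t0, 3)

    # -- whole-brain group tests ----------------------------------------
    t0 = time.time()
    gvals = pd.DataFrame([
        dict(subject_id=r["subject_id"], group=r["group"],
             **{m: (r["global_raw"] if m in RAW_SCALE_METRICS
                    else r["global_norm"]).get(m, np.nan)
                for m in r["global_norm"]})
        for r in per_subject
    ]).set_index("subject_id")
    wb_measures = [m for m in WHOLEBRAIN_TEST_METRICS if m in gvals.columns]
    wb = wholebrain_group_tests(gvals[wb_measures], gvals.group,
                                config.wholebrain_bonferroni)
    wb.to_csv(results_dir / "wholebrain_group_tests.csv", index=False)

    # -- mixed ANOVAs per nodal measure, hubs and non-hubs separately ----
    hub_ids = assignment.hubs.get("control", np.array([], int))
    nonhub_ids = (assignment.nonhubs
                  if assignment.nonhubs is not None else np.array([], int))
    nodal_frames = _nodal_frames(per_subject, n_nodes)
    groups_series = pd.Series(
        [r["group"] for r in per_subject],
        index=[r["subject_id"] for r in per_subject])
    anova_rows = []
    n_families = len(nodal_frames) * 2
    divisor = config.anova_bonferroni or n_families
    for metric, frame in nodal_frames.items():
        for family, ids in (("hubs", hub_ids), ("nonhubs", nonhub_ids)):
            if len(ids) < 2:
                continue
            sub = frame[list(ids)].dropna(axis=0)
            grp = groups_series.loc[sub.index].to_numpy()
            if len(sub) < 4 or len(np.unique(grp)) < 2:
                continue
            # the log option only applies to strictly positive measures;
            # sign-indefinite or zero-valued ones are analyzed untransformed
            vals = sub.to_numpy()
            check = metric not in RAW_SCALE_METRICS and (vals > 0).all()
            if metric not in RAW_SCALE_METRICS and not (vals > 0).all():
                log.info("%s/%s: non-positive values, analyzed untransformed",
                         metric, family)
            res = mixed_anova(vals, grp, normality_check=check,
                              log_shift=False)
            anova_rows.append(dict(
                metric=metric, family=family, n_nodes=len(ids),
                F=res.F_group, df1=res.df_group[0], df2=res.df_group[1],
                p=res.p_group, p_bonf=min(res.p_group * divisor, 1.0),
                eta_p2=res.eta_p2_group,
                F_node=res.F_node, p_node_gg=res.p_node_gg,
                F_interaction=res.F_interaction,
                p_interaction_gg=res.p_interaction_gg,
                mauchly_p=res.mauchly_p, gg_epsilon=res.gg_epsilon,
                log_transformed=res.log_transformed,
            ))
    anova = pd.DataFrame(anova_rows)
    anova.to_csv(results_dir / "mixed_anova.csv", index=False)
    manifest["stages"]["group_stats"] = round(time.time() - t0, 3)

    # -- correlation grid + McNemar -------------------------------------
    t0 = time.time()
    if len(anova):
        sig = anova[anova.p_bonf < 0.05]
        kept = sorted(set(sig[sig.family == "hubs"].metric)
                      & set(sig[sig.family == "nonhubs"].metric))
    else:
        kept = []
    node_classes = {int(i): "hub" for i in hub_ids}
    node_classes.update({int(i): "nonhub" for i in nonhub_ids})
    grid = pd.DataFrame()
    mcnemar = pd.DataFrame()
    if kept and node_classes:
        logged = {r.metric for r in anova.itertuples()
                  if r.log_transformed and r.metric in kept}
        grid_vals = {}
        for m in kept:
            frame = nodal_frames[m]
            grid_vals[m] = np.log(frame) if m in logged else frame
        grid = correlation_grid(grid_vals, doms, node_classes,
                                config.grid_alpha)
        grid["node_label"] = [labels[i] for i in grid.node_id]
        grid.to_csv(results_dir / "correlation_grid.csv", index=False)
        mcnemar = hub_vs_nonhub_frequency(
            grid, config.mcnemar_pairing, config.mcnemar_bonferroni)
        mcnemar.to_csv(results_dir / "hub_vs_nonhub_mcnemar.csv", index=False)
    manifest["stages"]["correlations"] = round(time.time() - t0, 3)
    manifest["grid_metrics"] = kept
    manifest["n_hubs"] = int(len(hub_ids))
    manifest["n_nonhubs"] = int(len(nonhub_ids))
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (results_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results_dir


def _nodal_frames(per_subject, n_nodes) -> dict[str, pd.DataFrame]:
    """subjects x node-id DataFrames per metric (analysis scale)."""
    frames = {}
    sids = [r["subject_id"] for r in per_subject]
    metric_names = per_subject[0]["nodal_norm"].keys()
    for m in metric_names:
        layer = "nodal_raw" if m in RAW_SCALE_METRICS else "nodal_norm"
        mat = np.vstack([r[layer][m] for r in per_subject])
        frames[m] = pd.DataFrame(mat, index=sids, columns=range(n_nodes))
    return frames


def _write_metric_table(per_subject, labels, path: Path) -> None:
    """Long-format metric table: one row per subject x node x metric."""
    rows = []
    for r in per_subject:
        for m, vals in r["nodal_raw"].items():
            norm = r["nodal_norm"][m]
            for i, lab in enumerate(labels):
                if np.isfinite(vals[i]):
                    rows.append((r["subject_id"], lab, m, vals[i], norm[i]))
        for m, v in r["global_raw"].items():
            rows.append((r["subject_id"], "WHOLE_BRAIN", m, v,
                         r["global_norm"].get(m, np.nan)))
    pd.DataFrame(rows, columns=["subject_id", "node_label", "metric",
                                "raw_value", "normalized_value"]
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(results_dir: str | Path) -> str:
    """Human-readable summary rendered from the result CSVs."""
    results_dir = Path(results_dir)
    if not (results_dir / "manifest.json").exists():
        raise FileNotFoundError(f"no manifest.json in {results_dir}")
    manifest = json.loads((results_dir / "manifest.json").read_text())
    lines = [
        "hubcog analysis report",
        "======================",
        f"config hash {manifest['config_hash']}  seed {manifest['config']['seed']}"
        f"  n_graphs {manifest['config']['n_graphs']}",
        "",
    ]

    def load(name):
        p = results_dir / name
        return pd.read_csv(p) if p.exists() else None

    wb = load("wholebrain_group_tests.csv")
    if wb is not None:
        lines.append("Whole-brain group comparisons (Mann-Whitney U, Bonferroni x4):")
        for r in wb.itertuples():
            lines.append(f"  {r.measure:18s} U={r.U:8.1f} p_bonf={r.p_bonf:.4g}")
        lines.append("")
    hubrep = load("hub_report.csv")
    if hubrep is not None:
        hubs = hubrep[(hubrep.group == "control") & hubrep.is_hub].node_label
        nonh = hubrep[(hubrep.group == "control") & hubrep.is_nonhub].node_label
        lines.append(f"Hubs in controls ({len(hubs)}): {', '.join(hubs)}")
        lines.append(f"Non-hubs in controls: {len(nonh)} nodes")
        lines.append("")
    freq = load("hub_frequency_tests.csv")
    if freq is not None and len(freq):
        lines.append("Hub-frequency chi-square (patients vs controls):")
        for r in freq.itertuples():
            star = " *" if r.p_bonf < 0.05 else ""
            lines.append(
                f"  {r.node_label:24s} {r.hub_fraction_patient:.2f} vs "
                f"{r.hub_fraction_control:.2f}  p_bonf={r.p_bonf:.4g}{star}")
        lines.append("")
    imp = load("impairment_summary.csv")
    if imp is not None:
        lines.append("Cognitive impairment (ICCTF):")
        for r in imp.itertuples():
            lines.append(f"  {r.group:8s} {100 * r.fraction:.0f}% "
                         f"({int(r.sum)}/{int(r.count)})")
        lines.append("")
    anova = load("mixed_anova.csv")
    if anova is not None and len(anova):
        lines.append("Mixed-design ANOVA, between-group effect per nodal measure:")
        for r in anova.itertuples():
            lines.append(
                f"  {r.metric:18s} {r.family:8s} F({r.df1},{r.df2})={r.F:8.3f} "
                f"p_bonf={r.p_bonf:.4g} eta_p2={r.eta_p2:.3f}"
                f"{'  [log]' if r.log_transformed else ''}")
        lines.append("")
    mcn = load("hub_vs_nonhub_mcnemar.csv")
    if mcn is not None and len(mcn):
        lines.append("Correlations in hubs vs non-hubs (McNemar):")
        for r in mcn.itertuples():
            star = " *" if r.p_bonf < 0.05 else ""
            lines.append(f"  {r.metric:18s} b={r.b} c={r.c} "
                         f"p_bonf={r.p_bonf:.4g}{star}")
        lines.append("")
    text = "\n".join(lines)
    (results_dir / "report.txt").write_text(text)
    return text
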