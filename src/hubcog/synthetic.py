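"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the analysis assumes, at the study's
scale: two demographically matched groups of 50 subjects, 78-node DKT-style
connectomes with 12 planted symmetric hub regions (including the bilateral
putamen), patient-specific network alterations, and a 17-test cognitive
battery whose attention and proxy-IQ scores are coupled to the subjects'
latent hub-coherence factor.

Network model
-------------
A cohort shares a fixed backbone: regular random graphs inside four
modules (hemisphere x anterior/posterior), sparse balanced between-module
bridges, a hub rich club, and a constant number of hub edges per background
node.  Node weight tiers — hubs (x ``kappa``), a high tier, a mid tier and a
weak "low tier" whose members also form local cliques — give every hubscore
criterion stable ranks, so the low tier ends up as the non-hub candidates.
Subject weights are the backbone base times log-normal edge noise.

Two alignment mechanisms act at *fixed node strengths* (a short Sinkhorn
pass restores row sums): the latent factor ``u ~ N(0,1)`` scales the
hub-hub edges (moving each subject's rich-club coherence, hence hub local
assortativity), and independent per-node jitter scales each background
node's hub edges (randomizing background assortativity so it carries no
shared factor).  Patients additionally get: putamen-like hub attenuation
``delta``, rich-club and between-module weakening, a rewired edge fraction,
and occasionally one near-disconnected node that cleaning must flag as
floating.  Matrices are written raw, on a streamline-count-like scale; the
pipeline's cleaning stage does the rest.

Cognition model
---------------
``raw = intercept + b_age*age + b_edu*edu + sigma * direction * perf`` with
``perf = load_g * g + gamma_t * z + noise``; ``g`` is a shared cognitive
factor (shifted down in patients), ``z`` the standardized latent network
factor (coupling only for attention / proxy-IQ tests), and timed tests flip
the sign so that worse performance means longer times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cognition import DEFAULT_BATTERY, TestSpec
from .connectome import (
    Connectome,
    NodeSet,
    SubjectMeta,
    write_connectome,
)

# ---------------------------------------------------------------------------
# node universe: 39 regions per hemisphere (31 DKT cortical + 8 subcortical)
# ---------------------------------------------------------------------------

_DKT_CORTICAL = (
    "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus", "entorhinal",
    "fusiform", "inferiorparietal", "inferiortemporal", "isthmuscingulate",
    "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal",
    "transversetemporal", "insula",
)
_SUBCORTICAL = (
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala",
    "accumbens", "ventraldc",
)


def default_node_set() -> NodeSet:
    labels = [f"{h}.{r}" for h in ("lh", "rh") for r in _DKT_CORTICAL + _SUBCORTICAL]
    return NodeSet(tuple(labels))


DEFAULT_PLANTED_HUBS = tuple(
    f"{h}.{r}" for h in ("lh", "rh")
    for r in ("putamen", "thalamus", "superiorparietal", "precuneus",
              "superiorfrontal", "insula")
)
DEFAULT_ATTENUATED = ("lh.putamen", "rh.putamen")

#: per-test normative parameters: intercept, b_age, b_edu, residual sigma
DEFAULT_TEST_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "hvlt_immediate": (28.0, -0.10, 0.8, 4.0),
    "hvlt_delayed": (10.0, -0.05, 0.3, 1.8),
    "hvlt_recognition": (10.5, -0.02, 0.15, 1.0),
    "tmt_b": (55.0, 0.55, -3.0, 14.0),
    "scwt_interference": (8.0, -0.08, 0.8, 6.0),
    "digit_span_backwards": (8.0, -0.03, 0.5, 2.0),
    "wais_sequencing": (8.5, -0.03, 0.5, 2.0),
    "symbol_substitution": (75.0, -0.45, 2.5, 10.0),
    "tmt_a": (25.0, 0.25, -1.2, 7.0),
    "scwt_colors": (60.0, 0.30, -2.0, 9.0),
    "scwt_words": (45.0, 0.20, -1.5, 6.0),
    "digit_span_forward": (9.0, -0.02, 0.4, 2.0),
    "pegboard_dominant": (62.0, 0.35, -1.0, 8.0),
    "pegboard_nondominant": (68.0, 0.40, -1.0, 9.0),
    "matrix_reasoning": (18.0, -0.12, 1.2, 4.0),
    "cowat_semantic": (45.0, -0.10, 2.0, 8.0),
    "cowat_phonemic": (38.0, -0.08, 2.2, 9.0),
}
#: Verhage education level distribution (levels 3-7, study demographics)
DEFAULT_EDUCATION_DIST = {3: 0.02, 4: 0.16, 5: 0.16, 6: 0.32, 7: 0.34}


@dataclass
class CohortConfig:
    """Generator parameters; the defaults are the study conditions."""

    n_per_group: int = 50
    planted_hub_labels: tuple[str, ...] = DEFAULT_PLANTED_HUBS
    attenuated_hub_labels: tuple[str, ...] = DEFAULT_ATTENUATED
    kappa: float = 3.0          # hub edge-weight multiplier
    delta: float = 0.4          # patient attenuation of putamen-like hubs
    patient_hub_attenuation: float = 0.5   # rich-club (hub-hub) weakening, patients
    n_modules: int = 4          # hemisphere x anterior/posterior communities
    module_within_factor: float = 2.0   # within-module edge boost
    patient_intermodule_attenuation: float = 0.85  # long-range weakening, patients
    backbone_degree: int = 12   # regular background graph within each module
    cross_module_edges: int = 2  # between-module bridges per background node
    hub_neighbors: int = 4      # hub edges per background node (constant)
    rich_club_density: float = 1.0  # fraction of hub-hub pairs connected
    clique_weight_boost: float = 1.0  # weight multiplier on low-tier clique edges
    n_low_tier: int = 30        # stably weak nodes (candidate non-hubs)
    low_tier_factor: float = 0.45
    n_high_tier: int = 12       # stably strong non-hub nodes ("neither" class)
    n_sparse: int = 0           # optional cross-wired low-clustering nodes
    high_tier_factor: float = 1.2
    weight_scale: float = 50.0  # median streamline count per edge
    edge_sigma: float = 0.4     # per-subject log-normal edge noise (log scale)
    tau: float = 0.7            # latent hub-connectivity loading on hub edges
    alignment_jitter: float = 0.7   # per-subject background assortativity noise
    rewire_fraction: float = 0.1    # patient rewiring noise
    floating_rate: float = 0.18     # P(patient has one floating node)
    age_mean: float = 42.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (21.0, 70.0)
    education_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_EDUCATION_DIST))
    putamen_involved_rate: float = 0.72
    test_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TEST_PARAMS))
    load_g: float = 0.95         # shared cognitive factor loading
    patient_g_shift: float = -1.3   # patient deficit on the shared factor
    gamma: float = 2.0          # network->attention/proxy-IQ coupling
    seed: int = 0

    def null(self) -> "CohortConfig":
        """Copy with every planted effect switched off (calibration runs)."""
        import dataclasses
        return dataclasses.replace(
            self, delta=1.0, tau=0.0, rewire_fraction=0.0,
            patient_hub_attenuation=1.0, patient_intermodule_attenuation=1.0, floating_rate=0.0,
            patient_g_shift=0.0, gamma=0.0,
        )


@dataclass
class SyntheticTruth:
    """Planted structure and per-subject latent draws (ground truth)."""

    planted_hub_ids: list
    attenuated_ids: list
    low_tier_ids: list
    node_factors: list
    subjects: dict  # subject_id -> {u, g, group, floating_node}
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# cohort-level structure
# ---------------------------------------------------------------------------

def _backbone(
    n: int, hub_ids: np.ndarray, low_ids: np.ndarray, sparse_ids: np.ndarray,
    modules: np.ndarray, degree: int, cross_edges: int, hub_neighbors: int,
    rich_club_density: float, rng: np.random.Generator,
) -> np.ndarray:
    """Backbone mask: modular regular graphs among non-hubs, sparse
    between-module bridges, a partial hub rich club, and exactly
    ``hub_neighbors`` hub edges per non-hub node.

    The constant hub-degree per background node is deliberate: it removes
    stable backbone-driven strength differences among background nodes, so
    that which of them flirts with the hub criteria varies from subject to
    subject instead of being a fixed false-hub set.  The modular structure
    makes between-module traffic depend on a small set of bridges, which
    gives the path-based whole-brain measures genuine position structure.
    """
    import networkx as nx
    mask = np.zeros((n, n), dtype=bool)
    non_hub = np.setdiff1d(np.arange(n), hub_ids)
    clustered = np.setdiff1d(non_hub, sparse_ids)
    # regular graph inside each module (sparse nodes excluded: they are
    # wired across modules below, giving them a stably low clustering
    # coefficient so the "lowest clustering" criterion lands on them and
    # never on the weak low-tier nodes)
    for mod in np.unique(modules):
        members = clustered[modules[clustered] == mod]
        k = len(members)
        d = min(degree, k - 1)
        if (d * k) % 2:
            d -= 1
        g = nx.random_regular_graph(d, k, seed=int(rng.integers(2**31)))
        for a, b in g.edges:
            i, j = members[a], members[b]
            mask[i, j] = mask[j, i] = True
    # sparse cross-module bridges: each round is a near-perfect matching of
    # background nodes across modules, so every node carries exactly
    # ``cross_edges`` bridges and no stable bridge-degree hierarchy arises
    for _ in range(cross_edges):
        for attempt in range(200):
            order = rng.permutation(clustered).tolist()
            pairs = []
            while len(order) > 1:
                i = order.pop()
                j_idx = next((a for a, j in enumerate(order)
                              if modules[j] != modules[i] and not mask[i, j]),
                             None)
                if j_idx is None:
                    break
                pairs.append((i, order.pop(j_idx)))
            else:
                for i, j in pairs:
                    mask[i, j] = mask[j, i] = True
                break
        else:
            raise RuntimeError("could not build balanced cross-module bridges")
    # sparse nodes: all their background edges go to other-module nodes,
    # dealt from a shuffled deck so receiver load stays near-uniform
    targets_all = clustered
    sparse_degree = max(degree - 2, 4)
    need = len(sparse_ids) * sparse_degree
    deck = np.tile(targets_all, int(np.ceil(need / max(len(targets_all), 1))))
    deck = rng.permutation(deck)
    pos = 0
    for i in sparse_ids:
        got = 0
        guard = 0
        while got < sparse_degree and guard < 10 * len(deck):
            j = deck[pos % len(deck)]
            pos += 1
            guard += 1
            if j != i and modules[j] != modules[i] and not mask[i, j]:
                mask[i, j] = mask[j, i] = True
                got += 1
        if got < sparse_degree:
            raise RuntimeError("could not wire sparse node")
    # hub rich club
    for a_i, i in enumerate(hub_ids):
        for j in hub_ids[a_i + 1:]:
            if rng.random() < rich_club_density:
                mask[i, j] = mask[j, i] = True
    # balanced hub assignment: deal hubs so each background node gets
    # `hub_neighbors` distinct hubs and hub loads stay equal up to rounding
    non_hub = np.setdiff1d(non_hub, sparse_ids)
    n_bg = len(non_hub)
    hands: list[set] = [set() for _ in range(n_bg)]
    for _ in range(hub_neighbors):
        deck = np.tile(hub_ids, int(np.ceil(n_bg / len(hub_ids))))[:n_bg]
        deck = rng.permutation(deck)
        for a in range(n_bg):
            if deck[a] in hands[a]:
                for b in rng.permutation(n_bg):
                    if deck[b] not in hands[a] and deck[a] not in hands[b]:
                        deck[a], deck[b] = deck[b], deck[a]
                        break
                else:
                    raise RuntimeError("could not deal distinct hub neighbors")
            hands[a].add(deck[a])
    for a, hand in enumerate(hands):
        for j in hand:
            mask[non_hub[a], j] = mask[j, non_hub[a]] = True
    return mask


@dataclass
class CohortStructure:
    nodes: NodeSet
    mask: np.ndarray
    factors: np.ndarray       # per-node tier factor (hub factor excluded)
    hub_ids: np.ndarray
    attenuated_ids: np.ndarray
    low_ids: np.ndarray
    modules: np.ndarray = None  # per-node community id
    clique_mask: np.ndarray = None  # low-tier mutual edges (weight-boosted)
    sparse_ids: np.ndarray = None   # cross-wired, stably low-clustering nodes


def build_structure(config: CohortConfig, rng: np.random.Generator) -> CohortStructure:
    nodes = default_node_set()
    n = len(nodes)
    hub_ids = np.array([nodes.index(l) for l in config.planted_hub_labels])
    att_ids = np.array([nodes.index(l) for l in config.attenuated_hub_labels])
    if not set(att_ids) <= set(hub_ids):
        raise ValueError("attenuated nodes must be planted hubs")
    # communities: hemisphere x anterior/posterior blocks of the label order
    half = n // 2
    modules = np.zeros(n, dtype=int)
    for i in range(n):
        hemi = i // half
        modules[i] = hemi * (config.n_modules // 2) + (
            (i % half) * (config.n_modules // 2) // half)
    non_hub = np.setdiff1d(np.arange(n), hub_ids)
    picked = rng.choice(
        non_hub, size=config.n_low_tier + config.n_high_tier + config.n_sparse,
        replace=False)
    low_ids = np.sort(picked[: config.n_low_tier])
    high_ids = picked[config.n_low_tier:config.n_low_tier + config.n_high_tier]
    sparse_ids = np.sort(picked[config.n_low_tier + config.n_high_tier:])
    mask = _backbone(n, hub_ids, low_ids, sparse_ids, modules,
                     config.backbone_degree, config.cross_module_edges,
                     config.hub_neighbors, config.rich_club_density, rng)
    # low-tier nodes are weak but cliquish: extra mutual edges at mid-tier
    # weight give them a high, stable clustering coefficient, so the
    # "lowest clustering" hub criterion never lands on them
    clique = np.zeros_like(mask)
    for mod in np.unique(modules):
        members = low_ids[modules[low_ids] == mod]
        for a_i, i in enumerate(members):
            for j in members[a_i + 1:]:
                if rng.random() < 0.8:
                    mask[i, j] = mask[j, i] = True
                    clique[i, j] = clique[j, i] = True
    factors = np.ones(n)
    factors[low_ids] = config.low_tier_factor
    factors[high_ids] = config.high_tier_factor
    return CohortStructure(nodes, mask, factors, hub_ids, att_ids,
                           np.sort(low_ids), modules, clique, sparse_ids)


# ---------------------------------------------------------------------------
# per-subject generation
# ---------------------------------------------------------------------------

def generate_connectome(
    structure: CohortStructure,
    config: CohortConfig,
    meta: SubjectMeta,
    u: float,
    rng: np.random.Generator,
    floating_node: int | None = None,
) -> Connectome:
    """Raw (uncleaned, unnormalized) streamline-count connectome."""
    n = len(structure.nodes)
    f = structure.factors
    is_hub = np.zeros(n, dtype=bool)
    is_hub[structure.hub_ids] = True
    hub_edge = is_hub[:, None] | is_hub[None, :]
    hubhub_edge = is_hub[:, None] & is_hub[None, :]
    att_edge = np.zeros((n, n), dtype=bool)
    if meta.group == "patient":
        att_edge[structure.attenuated_ids, :] = True
        att_edge[:, structure.attenuated_ids] = True
    # hub boost / attenuation applied once per incident edge, not per endpoint
    base = config.weight_scale * np.outer(f, f) / max(f.mean() ** 2, 1e-12)
    same_module = structure.modules[:, None] == structure.modules[None, :]
    base = np.where(same_module, base * config.module_within_factor, base)
    if structure.clique_mask is not None and config.clique_weight_boost != 1:
        base = np.where(structure.clique_mask,
                        base * config.clique_weight_boost, base)
    base = np.where(hub_edge, base * config.kappa, base)
    base = np.where(att_edge, base * config.delta, base)
    if meta.group == "patient":
        # patients lose rich-club coherence (hub-hub edges) and long-range
        # integration (between-module edges)
        base = np.where(hubhub_edge, base * config.patient_hub_attenuation,
                        base)
        base = np.where(~same_module,
                        base * config.patient_intermodule_attenuation, base)
    # Latent hub-coherence factor u scales the hub-hub (rich club) edges,
    # and each background node gets independent per-subject alignment jitter
    # on its few hub edges.  A short Sinkhorn pass then restores every
    # node's strength, so both manipulations move edge-weight *alignment*
    # (hence local assortativity) while strengths — and with them the hub /
    # non-hub ranks and the global normalizers — stay fixed.
    s0 = np.where(structure.mask, base, 0.0).sum(axis=1)
    base = np.where(hubhub_edge, base * np.exp(config.tau * u), base)
    if config.alignment_jitter > 0:
        eta = config.alignment_jitter * rng.standard_normal(n)
        eta[is_hub] = 0.0
        bg_hub = hub_edge & ~hubhub_edge
        base = np.where(bg_hub, base * np.exp(eta[:, None] + eta[None, :]),
                        base)
    for _ in range(6):
        s1 = np.where(structure.mask, base, 0.0).sum(axis=1)
        r = np.sqrt(s0 / np.maximum(s1, 1e-12))
        base = base * np.outer(r, r)
    noise = np.exp(config.edge_sigma * rng.standard_normal((n, n)))
    noise = np.triu(noise, 1)
    noise += noise.T
    w = np.where(structure.mask, base * noise, 0.0)

    if meta.group == "patient" and config.rewire_fraction > 0:
        w = _rewire(w, config.rewire_fraction, rng)
    if floating_node is not None:
        w[floating_node, :] *= 1e-4
        w[:, floating_node] *= 1e-4
    np.fill_diagonal(w, 0.0)
    total = float(np.triu(w, 1).sum())
    return Connectome(
        subject_id=meta.subject_id, group=meta.group, nodes=structure.nodes,
        weights=w, streamline_total=total,
    )


def _rewire(w: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Move a fraction of edges to random empty pairs, keeping their weights."""
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    present = np.flatnonzero(vals > 0)
    absent = np.flatnonzero(vals == 0)
    k = min(int(round(fraction * len(present))), len(absent))
    if k == 0:
        return w
    src = rng.choice(present, size=k, replace=False)
    dst = rng.choice(absent, size=k, replace=False)
    vals = vals.copy()
    vals[dst] = vals[src]
    vals[src] = 0.0
    out = np.zeros_like(w)
    out[iu, ju] = vals
    out += out.T
    return out


ATTENTION_IQ_DOMAINS = ("attention_processing_speed", "proxy_IQ")


def generate_cognition(
    config: CohortConfig,
    meta: SubjectMeta,
    z_network: float,
    g: float,
    rng: np.random.Generator,
    battery: tuple[TestSpec, ...] = DEFAULT_BATTERY,
) -> dict[str, float]:
    """Raw test scores for one subject given the latent factors."""
    scores = {}
    resid_load = np.sqrt(max(1.0 - config.load_g ** 2, 0.0))
    for t in battery:
        icpt, b_age, b_edu, sigma = config.test_params[t.test_id]
        gamma_t = config.gamma if t.domain in ATTENTION_IQ_DOMAINS else 0.0
        perf = (config.load_g * g + gamma_t * z_network
                + resid_load * rng.standard_normal())
        direction = -1.0 if t.inverted else 1.0
        scores[t.test_id] = (icpt + b_age * meta.age + b_edu * meta.education
                             + sigma * direction * perf)
    return scores


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

def _draw_meta(config: CohortConfig, rng: np.random.Generator):
    """Matched patient/control demographic pairs."""
    levels = np.array(sorted(config.education_dist))
    probs = np.array([config.education_dist[l] for l in levels], dtype=float)
    probs /= probs.sum()
    lo, hi = config.age_range
    metas = []
    for i in range(config.n_per_group):
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), lo, hi))
        edu = int(rng.choice(levels, p=probs))
        sex = "F" if i % 2 == 0 else "M"
        metas.append((
            SubjectMeta(f"pat{i:03d}", "patient", age, edu, sex,
                        putamen_involved=bool(rng.random() < config.putamen_involved_rate)),
            SubjectMeta(f"con{i:03d}", "control",
                        float(np.clip(age + rng.uniform(-3, 3), lo, hi)),
                        edu, sex),
        ))
    return metas


def generate_cohort_in_memory(
    config: CohortConfig,
) -> tuple[list[Connectome], pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate connectomes, metadata and cognition tables, plus the truth.

    All randomness derives from ``config.seed`` through per-subject
    ``SeedSequence([seed, stream])`` streams, so any subject can be
    regenerated in isolation.
    """
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    structure = build_structure(config, master)
    metas = _draw_meta(config, master)
    flat_metas = [m for pair in metas for m in pair]

    # latent factors per subject
    subjects = {}
    for idx, meta in enumerate(flat_metas):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1 + idx]))
        u = float(rng.standard_normal())
        g = float(rng.standard_normal()
                  + (config.patient_g_shift if meta.group == "patient" else 0.0))
        floating = None
        if meta.group == "patient" and rng.random() < config.floating_rate:
            candidates = np.setdiff1d(np.arange(len(structure.nodes)),
                                      structure.hub_ids)
            floating = int(rng.choice(candidates))
        subjects[meta.subject_id] = dict(u=u, g=g, group=meta.group,
                                         floating_node=floating, stream=1 + idx)

    # standardized network factor for the cognition coupling: u raises the
    # hub-hub / hub-background weight balance at fixed node strengths, i.e.
    # it moves hub local assortativity specifically
    u_all = np.array([subjects[m.subject_id]["u"] for m in flat_metas])
    z_raw = u_all
    z_std = (z_raw - z_raw.mean()) / max(z_raw.std(), 1e-12)

    connectomes, cog_rows, meta_rows = [], [], []
    for idx, meta in enumerate(flat_metas):
        info = subjects[meta.subject_id]
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1000 + info["stream"]]))
        c = generate_connectome(structure, config, meta, info["u"], rng,
                                floating_node=info["floating_node"])
        connectomes.append(c)
        scores = generate_cognition(config, meta, float(z_std[idx]),
                                    info["g"], rng)
        cog_rows.append(dict(subject_id=meta.subject_id, **scores))
        meta_rows.append(dict(
            subject_id=meta.subject_id, group=meta.group, age=meta.age,
            sex=meta.sex, education=meta.education,
            putamen_involved=meta.putamen_involved,
            streamline_total=c.streamline_total,
        ))
        subjects[meta.subject_id]["z"] = float(z_std[idx])

    truth = SyntheticTruth(
        planted_hub_ids=[int(i) for i in structure.hub_ids],
        attenuated_ids=[int(i) for i in structure.attenuated_ids],
        low_tier_ids=[int(i) for i in structure.low_ids],
        node_factors=[float(v) for v in structure.factors],
        subjects=subjects,
        seed=config.seed,
    )
    metadata = pd.DataFrame(meta_rows)
    cognition = pd.DataFrame(cog_rows)
    return connectomes, metadata, cognition, truth


def generate_cohort(config: CohortConfig, out_dir: str | Path):
    """Write a complete on-disk cohort: TSV matrices, labels, metadata CSV,
    cognition CSV and the ground-truth JSON."""
    out_dir = Path(out_dir)
    (out_dir / "matrices").mkdir(parents=True, exist_ok=True)
    connectomes, metadata, cognition, truth = generate_cohort_in_memory(config)
    nodes = connectomes[0].nodes
    (out_dir / "labels.txt").write_text("\n".join(nodes.labels) + "\n")
    for c in connectomes:
        write_connectome(c, out_dir / "matrices" / f"{c.subject_id}.tsv")
    metadata.to_csv(out_dir / "metadata.csv", index=False)
    cognition.to_csv(out_dir / "cognition.csv", index=False)
    truth.to_json(out_dir / "truth.json")
    return connectomes, metadata, cognition, truth
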