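# Methods

This note documents the scientific and numerical conventions implemented in
`hubcog`: what each stage computes, the choices made where the underlying
methodology is genuinely open, what the synthetic cohort generator does and
does not emulate, and the known limitations.

## Connectome cleaning

Input matrices are weighted, symmetric, non-negative, with zero diagonal;
symmetry is *verified* (relative tolerance 1e-8), never repaired by
averaging, and nonzero diagonals are zeroed with a warning.

* **Floating nodes.** A node receiving fewer than `min_streamlines = 1000`
  of a 10-million-streamline tractogram is removed (strict `<`). The
  threshold scales proportionally with the recorded tractogram size
  (`streamline_total`), so cohorts generated at other scales behave
  consistently. Removed nodes stay in the matrix as zero rows/columns plus a
  mask, keeping a common 78-node index space across subjects; they carry NaN
  in every nodal result and are excluded from all computations, including a
  subject's node count in the hubscore.
* **Edge-weight normalization.** Weights are divided by the sum of all edge
  weights. "Sum" counts each undirected edge once by default (`edge_sum:
  upper`; the upper triangle then sums to 1 and the full matrix to 2); the
  mirrored-count convention (`full`) is available. Metric ratios are
  unaffected by the choice; it is recorded for reproducibility.
* **Binarization** (robustness variant): the `ceil(density · P)` strongest
  pairs among the P retained-node pairs are kept at weight 1; pairs tied
  with the cutoff weight enter in label-lexicographic order until the target
  count is reached (deterministic).

## Graph measures

All measures operate on the retained submatrix. Path lengths use the
standard streamline-count convention `length = 1/weight` (absent edge =
infinite length); shortest paths are Dijkstra's. Unreachable pairs
contribute 0 to efficiencies and are excluded from path-length means. A
retained node with strength 0 is an error (it should have been removed as
floating).

* **Strength** `s_i = Σ_j w_ij`.
* **Nodal path length** `L_i` = mean Dijkstra distance to reachable nodes;
  **characteristic path length** λ = mean of `L_i`; **global efficiency** =
  mean inverse distance over ordered pairs.
* **Betweenness** is the unnormalized Brandes count over weighted shortest
  paths, endpoints excluded, fractional credit for tied geodesics (computed
  through igraph's C implementation; the test suite checks it against
  exhaustive simple-path enumeration). It is left unnormalized because the
  hubscore uses within-subject ranks only, for which any affine rescaling is
  irrelevant.
* **Weighted clustering**, default variant `wang`: the Zhang–Horvath
  generalization `C_i = Σ_{j≠k} ŵ_ij ŵ_jk ŵ_ki / (ŝ_i² − Σ_j ŵ_ij²)` with
  weights rescaled to [0, 1] by the maximum weight (`ŵ`); nodes with degree
  < 2 get 0. The Onnela geometric-mean form is available as `onnela`. Both
  reduce exactly to the binary triangle ratio on 0/1 matrices.
* **Local efficiency**, default variant `wang`: distances between the
  neighbors j, k of node i are computed on the subgraph induced by the
  neighbors (lengths 1/ŵ), and the inverse distances are averaged with
  weights `ŵ_ij ŵ_ik`; the unweighted mean (`latora`, the plain subgraph
  efficiency) is available. Both reduce to the binary formula.
  Implementation note: all neighbor subgraphs are padded into one array and
  solved with a single vectorized Floyd–Warshall pass.
* **Assortativity.** The global coefficient r is the edge-weight-weighted
  Pearson correlation of endpoint strengths over directed edge orientations.
  A *nodal* version is not standard; the implemented decomposition assigns
  each directed edge's standardized contribution to its source node,

      a_i = (s_i − μ) · Σ_j w_ij (s_j − μ) / (W_tot · σ²),

  which splits every undirected edge half-and-half and makes `Σ_i a_i = r`
  exactly (a tested identity). This definition is parameter-free and
  testable, but it is a declared stand-in: it is *global* in character
  (μ, σ², W_tot are whole-network quantities), so nodal values shift
  coherently when the overall weight organization changes. Graphs whose
  endpoint strengths carry no variance (e.g. regular equal-weight rings)
  return NaN with a warning.

## Null-model normalization

Per subject, `n_graphs = 1000` random graphs with the same nodes and the
same weight multiset are drawn by uniformly permuting the upper-triangle
entries — zeros included — and mirroring (scope `all_pairs`). Permuting over
all pairs, not only existing edges, is the default because the ensemble is
meant to randomize topology given the weight distribution, and the
floating-node rejection rule only has content if zeros can move; an
`existing_edges` scope is provided for sensitivity analyses. A draw in which
any retained node ends with strength 0 is rejected and redrawn; an
acceptance rate below 1% over 10·n attempts aborts with a diagnostic.

Observed measures are divided by the ensemble **median** (robust to
outliers) of the same measure at the same node. Two edge rules: when the
median's absolute value falls below 1e-12 the ratio is undefined and the
normalized value is set missing (logged) — unless the raw value equals the
median exactly, in which case the value is at its null level and the
normalized value is 1 (this makes normalization exact on degenerate graphs
such as the complete equal-weight graph, where every permutation is the
identity).

Two measures are **analyzed on the raw scale** throughout the downstream
statistics:

* *assortativity* — its null median straddles zero, making the ratio's sign
  unstable;
* *betweenness* — in permuted graphs roughly half the nodes lie on no
  geodesic interior, so the null median is frequently exactly zero and the
  ratio is undefined for a large, subject-varying set of nodes. For the
  rank-based hubscore this choice is inconsequential; for the ANOVAs it
  preserves the balanced node set.

Seeds: one master seed per run; per-subject generators derive from
`SeedSequence([master_seed, subject_index])`, so any subject is reproducible
in isolation and under parallel execution.

## Hub identification

Per subject and criterion, the cutoff is the m-th value (m = ceil(0.2 ·
N_retained)) in the favorable ordering — highest strength and betweenness,
lowest path length and clustering — and every node at-or-beyond the cutoff
scores the point (ties expand the set; this `inclusive` rule is invariant to
node ordering; a `strict_rank` rule is available). The hubscore is the sum
of the four indicators. Group hubs require hubscore ≥ 2 in strictly more
than 80% of the group's subjects (computed over the subjects in which the
node is retained); non-hubs require hubscore 0 in every control. Hub
frequency between groups is compared per node with a Pearson chi-square on
the 2×2 table of group × (hubscore ≥ 2), without continuity correction,
switching to Fisher's exact test when an expected cell is below 1;
Bonferroni is over the control-defined hubs by default.

## Cognitive scores

The default battery reproduces a standard 17-outcome neuropsychological
assessment grouped into six domains (memory 3, executive 4,
attention/processing speed 5, motor 2, proxy IQ 1, language 2). The
normative model is an ordinary-least-squares fit per test on age and
education (education as a single ordinal covariate, Verhage 1–7; categorical
coding available), fitted on controls only; the residual scale uses
denominator n − p. w-scores are `(observed − predicted) / residual SD` —
the z-analogue scale is chosen because the impairment cutoffs presuppose
unit variance — and the six time-scored outcomes (TMT A/B, SCWT colors and
words, both Grooved Pegboard hands) are multiplied by −1 so higher w is
always better. Domain scores average the available tests of the domain;
impairment is the ICCTF rule over all test-level w-scores (≥ 2 tests at w ≤
−1.5 or ≥ 1 at w ≤ −2.0, boundaries inclusive).

## Inferential battery

* **Mann–Whitney U**, two-sided, exact enumeration when both groups have
  n ≤ 10 and no ties, tie-corrected normal approximation otherwise. U is
  reported for the patient sample. Bonferroni: ×4 (whole-brain measures),
  ×6 (domains).
* **Mixed-design ANOVA** (group × node): classical univariate decomposition
  on the balanced subject × node matrix; between-group F = MS_group /
  MS_subjects-within-groups; partial η² = SS_effect/(SS_effect + SS_error)
  with each effect's own error term. Mauchly's test runs on the pooled
  within-group covariance; when it rejects at α = 0.05 the within-effect
  p-values are Greenhouse–Geisser corrected (ε from the double-centered
  covariance eigenvalues; ε = 1 exactly for two within levels). When any
  group × node cell fails Shapiro–Wilk at α = 0.05, the measure is
  log-transformed first; log applies only to strictly positive measures —
  sign-indefinite or zero-valued measures are analyzed untransformed, and
  the shifted log `log(x − min + ε)` requires an explicit opt-in. Subjects
  with a missing (floating) node in the analyzed node set are dropped from
  that family. The Bonferroni divisor defaults to the number of ANOVA
  families run (measures × 2 node classes).
* **Correlation grid**: Pearson r between each (measure, node) value and
  each domain w-score over the pooled sample. The pipeline's default grid
  takes the measures whose ANOVA group effect is Bonferroni-significant in
  both the hub and the non-hub family (log-transformed where the ANOVA
  was); the significance flag uses α/(measures × domains × classified
  nodes). Per-group correlations are available.
* **McNemar (hubs vs non-hubs)**: per measure, paired binary indicators of
  cell significance; exact binomial when discordant pairs b + c < 25, else
  χ² = (b−c)²/(b+c); Bonferroni ×4. The original paired unit is not
  documented anywhere, so three rules ship. The default `paired_nodes`
  pairs, per domain, the j-th hub node with the j-th non-hub node (by node
  id), cycling through the smaller class so that every node of the larger
  class is represented; `majority` and `any_node` collapse each class to a
  single per-domain indicator. The domain-level rules are so coarse (six
  pairs per measure) that the exact binomial cannot reach p_bonf < 0.05 even
  with complete discordance — a structural property worth knowing when
  interpreting them.
* **Subgroup analyses** re-run the full battery after filtering the patient
  metadata (e.g. patients without putamen involvement); controls are kept.

## Synthetic cohort generator

The generator's defaults are the study conditions: 50 patients and 50
controls matched pairwise on age (±3 years), sex and education; 78 DKT-style
nodes; 12 planted symmetric hubs (bilateral putamen, thalamus, superior
parietal, precuneus, superior frontal, insula); ~10⁵ total streamline-count
weight per subject.

**Backbone** (fixed per cohort — brains share gross wiring): regular random
graphs of degree 12 inside four modules (hemisphere × anterior/posterior),
two balanced cross-module bridges per background node, a complete hub rich
club, and exactly four hub edges per background node. The constant
hub-degree and bridge-degree are deliberate: stable backbone-driven strength
differences among background nodes would otherwise manufacture false hubs.
Weight tiers multiply the base weight: hubs ×3 (`kappa`), 12 high-tier nodes
×1.2, 30 low-tier nodes ×0.45; within-module edges ×2. Low-tier nodes also
form weak local cliques. The tiers give each hubscore criterion stable,
well-separated ranks: the low tier is never favorable on any criterion and
therefore yields the non-hub candidates.

**Subject variation**: independent log-normal edge noise (σ = 0.4 on the
log scale). Two alignment mechanisms act at *fixed node strengths* — after
applying them, a short Sinkhorn pass restores every node's row sum, so hub
and non-hub ranks and the global normalizers are untouched:

* the latent hub-coherence factor `u ~ N(0,1)` scales the hub-hub edges by
  `exp(0.7·u)`, moving each subject's rich-club weight share and with it the
  hubs' local assortativity;
* independent per-node jitter (σ = 0.7) scales each background node's hub
  edges jointly, randomizing background assortativity so that it carries no
  shared factor and cannot mimic the hub–cognition coupling.

**Patient effects**: putamen-like hub edges ×0.4 (`delta`; removes their
hub status), hub-hub edges ×0.5 (loss of rich-club coherence), between-
module edges ×0.85 (loss of long-range integration), 10% of background
edges rewired to random empty pairs, and with probability 0.18 one random
non-hub node attenuated to ~10⁻⁴ of its weight (a floating node for the
cleaning stage to catch). Together these reproduce the qualitative clinical
pattern: group differences in all four whole-brain measures, preserved
non-putamen hubs, and lost putamen hubs.

**Cognition**: per-test raw scores follow `intercept + b_age·age +
b_edu·education + σ·direction·perf` with plausible per-test parameters
(timed tests on a seconds scale, direction −1). `perf = 0.95·g + γ_t·z +
noise`, where `g` is a shared cognitive factor (patients shifted −1.3) and
`z` the standardized latent `u`, with γ = 2 for the attention and proxy-IQ
tests and 0 elsewhere. The coupling deliberately uses the generator's own
latent — not a re-computed graph measure — so recovery tests are
well-posed.

**What the generator does not emulate.** Real connectome weight
distributions and geometry (distance-dependent connectivity, consistent
inter-regional anatomy); lesion geometry; heterogeneous tumor locations;
realistic inter-test correlation structure beyond one shared factor.
Consequences visible in the defaults: the non-hub class is small (typically
6–12 nodes against ~30 in comparable clinical data), because with only 78
exchange-symmetric background nodes the strict "zero hubscore in every
control" rule is demanding; control impairment runs near 16–20% (clinical
normative samples show ~10%), because seventeen near-Gaussian outcomes with
one shared factor produce more multi-test coincidences than real batteries;
and the direction of some group effects (e.g. whether patients' normalized
clustering is higher or lower) follows from the chosen mechanism rather
than being tuned to match any particular cohort. Passing recovery tests
therefore demonstrates that the pipeline detects planted structure of
realistic effect size at the study's scale — not that real data would show
these exact patterns.

## Problem sizes used by the test suite

Simulation-based checks run at fixed seeds with reduced replicate counts:
graph-measure oracle equivalence on 200 random graphs of ≤ 6 nodes; binary
reduction on 100 fixtures; hubscore re-ranking on 50 fixtures; planted-hub
recovery on 3 default cohorts with 100-graph ensembles; the
hub-assortativity–cognition recovery on the same 3 cohorts; type-I
calibration of Mann–Whitney, mixed ANOVA, the α/1008 correlation grid and
McNemar at 200 replicates each (500 for the ANOVA unit test). The
acceptance script runs one full cohort at 100-graph ensembles.

## Known limitations

* The nodal assortativity decomposition is a stand-in for an unpublished
  definition; its global standardization makes nodal values sensitive to
  whole-network changes, which is why it is analyzed raw and why its null
  normalization is skipped.
* Betweenness null medians are frequently zero at realistic densities, so
  its null-normalized values are largely undefined; the pipeline analyzes
  betweenness raw (rank-equivalent for hub scoring).
* The mixed ANOVA uses the classical balanced decomposition; strongly
  unbalanced group sizes would need a mixed-effects model, which is out of
  scope.
* The McNemar pairing of unequal node classes has no canonical definition;
  all shipped rules are heuristics and reports state which was used.
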