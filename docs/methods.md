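# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, the assumptions they rest on, and what the synthetic
benchmarks do and do not establish.

## Differential statistics

Abundance tables are features × samples with a two-group design (control /
treated) and non-negative raw values; missing entries are allowed before
preprocessing. Preprocessing imputes each feature's missing entries with
that feature's minimum observed value — the standard conservative choice
for untargeted profiling, where missingness is usually censoring at the
detection limit — and then log-transforms. Fold changes are natural-log for
metabolites and log₂ for genes (the scale the reaction-weight conversion
expects); the transform base is an explicit parameter and is recorded in
the output metadata.

Per feature, Welch's two-sample *t*-test (unequal variances,
Welch–Satterthwaite degrees of freedom, two-sided) compares treated against
control. Two-sided p-values are the standard choice for profiling data
where either direction is of interest. The degenerate zero-variance case
with equal means returns (t = 0, p = 1) rather than NaN; zero variance with
unequal means is an error, since no finite test statistic exists.
Multiple-testing correction is Benjamini–Hochberg step-up (statsmodels),
with monotonicity enforced and q capped at 1. The pipeline's significance
filter defaults to q < 0.1; a raw p threshold is equally expressible by the
caller, but q < 0.1 is what every downstream stage uses by default.

Concordance between condition profiles uses Pearson correlation of log-FC
vectors over the feature intersection, either on all common features or
only on features significant in both conditions. Hierarchical clustering of
conditions uses distance 1 − r with average linkage (UPGMA); the
correlation-based distance matches the correlation-centric interpretation
of the profiles, and average linkage avoids the chaining of single linkage
on small condition sets. The tree is exported as Newick text.

## Gene-set activation (AFC / AAFC)

For per-gene log fold changes f and a gene set G, the AFC score is the
signed sum Σ_{g∈G∩measured} f_g and the AAFC score the absolute sum
Σ |f_g|. Genes absent from the table are skipped and counted; a set with no
measured member is reported with a null-result flag rather than dropped.

The null model draws size-matched random subsets from the observed
fold-change pool without replacement (with-replacement sampling is
available behind a flag). The p-value is upper-tail with add-one smoothing,
p = (1 + #{null ≥ actual})/(n_draws + 1), so ties count as extreme and p is
never 0; the z-score is the distance from the null mean in null standard
deviations (sample sd over the draws). Degenerate nulls (sd = 0) yield
z = 0 at the mean and a signed infinity otherwise. Defaults: 10,000 draws;
the seed is mandatory and echoed in every output row. Each set is scored
with a fresh generator seeded identically, so identically-defined sets get
identical (z, p) regardless of position.

Module activation filters the gene table to significant genes (q < 0.1)
and builds both the scores and the permutation pool from that filtered
table; an all-genes pool mode exists for sensitivity analysis. AFC pathway
scores use the same permutation machinery with signed scores over the
unfiltered fold-change table.

## TIMBR production scoring

The network is a stoichiometric matrix S (metabolites × reactions) with
flux bounds and GPR rules. Infinite bounds are replaced by a ±1e6 sentinel
only inside the LP layer; file I/O preserves "inf" tokens. All LPs are
solved with HiGHS through scipy.optimize.linprog with deterministic
settings; alternate optima are harmless because only the objective value
enters the score.

Per reaction, the GPR aggregates gene log₂ fold changes with AND = min
(a complex is limited by its least-changed subunit) and OR = max (the
best-expressed isozyme carries the reaction); missing genes contribute 0
(no measured change is neutral), as does an empty rule. Reaction fold
changes are clipped to [−L, L] (default L = 4) so one extreme transcript
cannot dominate the objective, then converted to weights
w_treated = 2^(−c/2), w_control = 2^(+c/2): up-regulated reactions are
cheap under treatment, expensive under control, and c = 0 gives weight 1.

The two conditions evaluate the GPR from their own perspective: treated
weights come from GPR(f), control weights from −GPR(−f). For single-gene
rules the two coincide; for AND/OR trees the min/max aggregation is not an
odd function, and the dual evaluation is what makes the intended symmetry
exact — negating every gene fold change swaps the two conditions' weight
vectors (and hence D_control and D_treatment) exactly.

For each scoreable (extracellular) metabolite, an irreversible demand sink
({met: −1}, bounds [0, ∞)) is added; v_max is the maximal demand flux at
steady state (S·v = 0). The demand LP then minimizes Σ w_r |v_r| subject to
steady state, the bounds, and demand ≥ f·v_max. Reversible reactions are
split into non-negative forward/backward parts so the absolute value is
linear; with strictly positive weights the optimum never carries both
directions. The enforced fraction defaults to f = 0.9: f = 1 pins the
demand exactly and leaves no routing freedom, so a strict-interior default
is used and f is a config knob.

The raw score is log₂(D_control) − log₂(D_treatment) (written that way so
negation is exact in floating point). Because network-wide constraints —
in particular MFA bounds that force flux through perturbed pathways in
both conditions — can shift every raw score by a shared offset, scores are
standardized across feasible metabolites by default (population sd; when
the spread is zero, e.g. all-zero fold changes, the raw value is kept so
the neutral case scores exactly 0). Classification uses strict thresholds:
score > 0.1 increased, < −0.1 decreased, otherwise unchanged; an exact tie
at ±0.1 is unchanged. Metabolites with v_max = 0 or an infeasible demand
LP are reported with feasible = false and no class.

Evaluation joins predictions to observed metabolite statistics on ids,
keeps observed-significant (q < 0.1), feasible metabolites, and counts a
prediction correct iff (increased ∧ log FC > 0) ∨ (decreased ∧ log FC < 0);
an "unchanged" call is never correct, and the breakdown of calls is
reported so other conventions can be recomputed. The shuffled-gene control
permutes the gene-id → fold-change assignment with a given seed and reruns
the entire scoring. The no-information reference implemented here is the
proportional-chance rate Σ_d P(observed = d)·P(predicted = d) with the
prediction shares pooled over the control runs.

## MFA flux constraints

MFA estimates arrive relative to an anchor (citrate synthase ≡ 100) and are
converted to absolute units (μmol·kg⁻¹·min⁻¹) by a single scale factor from
one anchor reaction with a known absolute flux; the anchor reaction and
value are explicit required inputs, and sds scale identically, so the
conversion is exactly linear. Constraints are v ± k·sd (default k = 2, a
conventional ~95% band; configurable), with the lower bound clipped to the
reaction's structural lower bound and incompatible bands rejected. Exchange
rates follow the constraint-based sign convention: uptake is a negative
exchange flux (−rate, 0), secretion positive (0, rate). Constraints apply
to a copy of the network; an inverse constraint set restores the original
bounds bit-for-bit. Condition-level averaging of per-animal fluxes is
upstream of this module; inputs are means and sds.

## Synthetic data generator

The generator emulates the structure, not the biology, of an acute
two-group toxicant study: n = 8 animals per group, hundreds of genes, tens
of metabolites, designed effects concentrated on network subsystems.

The toy network has n_pathways (default 6) linear routes from one shared
substrate (uptake capacity 10) to distinct extracellular products, each
route reactions_per_pathway (default 4) steps with a parallel isozyme
alternative at the middle step to exercise routing, a secretion exchange
per product so non-scored products can always leave, and GPR forms cycling
through single-gene, AND-pair and OR-pair rules over fresh gene ids.

Default designed perturbations: one flagship pathway up with δ = 2 (log₂
for genes, natural-log for its product) — the designed "active" module —
plus three satellite pathways at δ = 1 (one up, two down), so that the
significant-gene pool contains a range of effect sizes (the flagship module
must beat set-size-matched draws from that pool, which would be impossible
if every significant gene carried the same |FC|), and the direction
evaluation covers both signs. Noise sd is 0.25 on the log scale within
groups; gene baselines are log-normal (log₂-mean ~ N(5,1)), metabolite
baselines log-normal (ln-mean ~ N(3,1)). Metabolite effect directions are
imposed directly rather than simulated through kinetics: the claim under
test is concordance detection, not mechanistic simulation. Missing values
are inserted completely at random (default rate 0.05, metabolite table
only), matching the assumption of the minimum-value imputation rule;
150 background genes and 20 background metabolites carry no effect.

Flux tables are produced by picking a vertex of the network's flux polytope
with a random LP objective (each product's secretion ≥ 0.2 so the anchor is
active), rescaling so the anchor reads exactly 100, and attaching relative
sds drawn from 5–15% (floored at 0.5 relative units so near-zero fluxes get
non-degenerate bands). The reported vector is an exact steady state, so
k = 2 bands applied back to the generating network are always feasible.

Everything is bit-reproducible given (scenario, seed); all generators
derive child streams from the scenario seed.

What passing on this generator shows: the statistics, set scores, LPs and
classifications implement their definitions correctly and compose; designed
signals of realistic magnitude are recovered and label-shuffling destroys
them. What it does not show: performance on real data with correlated
noise, non-MCAR missingness, imperfect GPR annotation, or genome-scale
networks (thousands of reactions, compartmentalized tissues) — the toy
networks are orders of magnitude smaller, and metabolite changes are
imposed, not mechanistically propagated.

## Problem sizes and numerics

The test suite and the acceptance script run the default scenario
(6 pathways, ~200 genes, 26 metabolites, 16 samples), 100 random ≤8-reaction
networks for the LP oracle comparison, 200 modules × 1,000 draws for the
permutation-null calibration (the production default is 10,000 draws), and
20 shuffled-gene control seeds; these sizes make the whole suite run in
well under a minute while keeping Monte-Carlo error small relative to the
asserted bounds. LP feasibility tolerance is HiGHS defaults with a 1e-9
objective tolerance; the brute-force oracle uses an absolute feasibility
tolerance of 1e-7 scaled by solution magnitude; score comparisons against
the oracle are at 1e-6.

## Known limitations

- Production only: consumption scoring (the mirrored demand on the uptake
  side) is a listed extension, as are urine-side predictions.
- The GPR→weight transformation and the score normalization are this
  package's documented defaults; other TIMBR variants can be slotted in
  behind `condition_weights` / `production_scores`.
- Multi-tissue models are representable via compartment labels, but no
  topology checking beyond id resolution is done.
- The CLI's single-run config covers one treated-vs-control contrast;
  cross-condition concordance takes additional precomputed condition tables.
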