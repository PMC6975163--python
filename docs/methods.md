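# Methods

This note documents the models and procedures implemented in `gemcurate`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Gap-filling LP

Gap filling is a parsimonious-FBA-style linear program over the combined
system of the draft model (fluxes `v`, never penalized) and the universal
reaction bag (fluxes `y`, penalized): minimize the summed absolute flux
through penalized universal reactions subject to steady-state mass balance
`S·v + U·y = 0`, flux bounds, and a biomass floor. Choices:

- **Biomass floor** `v_biomass ≥ 0.05 hr⁻¹` (default). The floor represents
  a binary growth call rather than optimal growth. The strict inequality of
  the conceptual formulation (`> 0.05`) is implemented as `≥ 0.05`: an LP
  needs a closed feasible set, and at any optimum with a positive floor the
  two are equivalent.
- **|y| linearization.** Each universal flux is split into `y⁺, y⁻ ≥ 0`
  with `y = y⁺ − y⁻` and objective `Σ(y⁺ + y⁻)` over penalized reactions.
  At an optimum, penalized pairs are complementary (both positive would add
  cost); free reactions contribute nothing to the objective and are never
  reported as activated.
- **Activation cutoff** 1e-11: a penalized universal reaction is activated
  when its optimal |flux| exceeds this. The cutoff sits far above solver
  feasibility noise (1e-9 primal tolerance) relative to the biomass floor's
  flux scale (5e-2).
- **Universal bounds** default ±1000 mmol·gDW⁻¹·hr⁻¹ (configurable per
  reaction); the bag must have finite bounds so the split variables are
  bounded.
- **Solver.** All LPs go through `scipy.optimize.linprog` (HiGHS) with
  fixed tolerances (primal 1e-9, dual 1e-7) recorded here for
  reproducibility across solver builds. The LP backend is an implementation
  detail behind `solve_fba`/`gapfill_condition`; the contract is the
  optimum, not the solver. Tests cross-check optima against an independent
  solver (GLPK via cobrapy) on randomized networks.
- **Infeasibility** with the full bag raises an explicit error — some
  draft/medium combinations simply admit no gap-fill solution, and the
  pipeline reports them rather than guessing.

## Ensemble generation

One member = one random permutation of the growth conditions. Conditions
are gap-filled in order; each condition's activated reactions become
penalty-free for the member's later conditions (never re-penalized), and
the union of activated reactions over all conditions is the member's
recipe. Penalties reset for every member. Members with identical reaction
sets (media order ignored) are duplicates and removed; fewer than 3 unique
members raises a degenerate-ensemble error, since clustering two groups of
near-identical models is meaningless. Each retained member is verified to
reach the biomass floor in every input medium.

Randomness: one master seed; the member with index *i* draws its shuffle
from `default_rng([seed, i])`, so results are reproducible and independent
of execution order. Seed and per-member media orders are stored in the
ensemble metadata.

**Consensus absorption.** Reactions gap-filled in *every* unique member are
added to the ensemble's base model, and the feature matrix covers only
variable reactions (present in ≥1 member, absent in ≥1). This keeps the
feature matrix free of constant columns while `materialize_member` remains
lossless. During a member's construction, activated reactions stay in the
universal system with zero penalty; they are added to a model only when a
member is materialized.

## Ensemble simulations

Gene essentiality: per member, every gene is knocked out in turn; reactions
whose gene rule evaluates false get both bounds set to 0 (matrix shape
preserved for cheap repeated solves), biomass is maximized, and the gene is
called essential when the optimum is below 1e-6 hr⁻¹ (infeasible counts as
0). The call is insensitive to the threshold over 1e-10..1e-3 because
knockouts in these networks either block biomass entirely or leave a route
of normal magnitude; a test asserts this on the fixtures. The default
simulation medium is complete medium: every exchange open at 1000
mmol·gDW⁻¹·hr⁻¹ uptake.

The gene universe is the union over members. Universal (gap-filled)
reactions carry no gene rules — gap filling proposes biochemistry, not
annotation — so in practice the universe equals the draft's gene set; genes
absent from a member's rules are trivially nonessential for it.

Growth-rate statistics use plain FBA biomass maxima per member; their
subsampling statistic is the across-member variance within the draw. Single
knockouts only; double-gene interactions are out of scope.

## Subsampling curves

At each size (step, 2·step, …, full ensemble; default step 20), 1,000
member draws **with replacement** are made and the statistic — the count of
feature-matrix columns that vary within the draw, the count of
non-unanimous essentiality genes, or the growth-rate variance — is averaged
over draws. Both count statistics are monotone non-decreasing in
expectation with draw size and plateau at the ensemble totals; the curves
diagnose whether the ensemble is large enough to saturate the space of
alternative solutions.

## Clustering, classification, metrics

- **Collapsing.** Before clustering, gene columns of the essentiality
  matrix that are exactly identical across members are merged into one
  representative variable (duplicated columns would otherwise dominate the
  k-means geometry and produce one giant cluster), and constant columns are
  dropped — a zero-variance column cannot affect clustering, so the
  collapsing rule is extended to cover them. "Perfectly correlated" means
  exact column equality, not anti-correlation. An all-constant matrix is an
  error: there is no simulation uncertainty to analyze.
- **k-means** with k = 2 on the collapsed binary rows as reals: max 300
  iterations, tolerance 1e-4, Elkan's accelerated algorithm, k-means++
  initialization with 10 restarts and a fixed seed (the best-inertia
  restart is kept; the acceleration is an equal-optimum implementation
  detail, not part of the contract). k = 2 targets the two maximally
  different simulation regimes; finer cluster structure is future work.
- **PCoA** of pairwise Hamming distances (fraction of differing gene calls)
  for visualization, via scikit-bio; coordinates are scaled by
  √eigenvalue. Negative eigenvalues — impossible for exactly Euclidean
  inputs, but kept as a safety net — are truncated to zero and excluded
  from the explained-fraction normalization. All-identical members yield a
  degenerate all-zero result rather than an error.
- **Random forest** predicting cluster membership from the member ×
  variable-reaction matrix: 500 trees, Gini criterion, no depth limit,
  min 2 samples per split, min 1 per leaf, √(n features) candidates per
  split, bootstrap resampling, fixed seed. Out-of-bag accuracy is the
  headline fit statistic; a 70/30 holdout (`holdout_accuracy`) is available
  as an overfitting cross-check.
- **Fractional importance** = mean-decrease-in-impurity importances
  normalized to sum to 1. If no split ever used any feature (degenerate
  single-node trees), the mass is spread uniformly so the sum-to-1
  contract holds.
- **Cluster ratio** = 1 − min(f₁,f₂)/max(f₁,f₂) with f_c the presence
  frequency within cluster c. Anchors: 1 when cluster-exclusive, 0.5 when
  twice as abundant in one cluster, 0 when evenly spread. Reactions absent
  from both clusters are excluded (not variable). The metric is symmetric
  under label swap and invariant to member order.
- **Ranking.** Curation targets are sorted by fractional importance
  (descending), ties broken by cluster ratio (descending) then reaction id
  (ascending) for full determinism.

## Evaluation and meta-analysis

Precision = TP/(TP+FP) and recall = TP/(TP+FN) per member against an
experimental essentiality table, with experimental essential as the
positive class and the comparison restricted to genes present in both the
model and the table. A member predicting zero essential genes reports
precision as NaN (undefined) rather than 0, to avoid silently distorting
cluster comparisons; such members are excluded from the precision test
only. Cluster differences use the two-sided Mann–Whitney U test on
precision and on recall, Benjamini–Hochberg adjusted across the tests run
in one invocation.

Pan-species aggregation averages each reaction's metrics over only the
species in which it was gap filled and records that species count; an
optional filter drops reactions seen in fewer than a given number of
species (5 in the supplementary-style view). Subsystem analysis assigns a
reaction with multiple subsystem labels as one observation per subsystem,
keeps subsystems with ≥10 gap-filled reactions, and runs a Kruskal–Wallis
omnibus test followed by pairwise Dunn z-tests (rank-sum comparisons with
tie correction) under Bonferroni adjustment. Dunn's test is implemented
in-package and calibrated against seeded null and power simulations in the
test suite.

## Synthetic fixtures: what they emulate and what they do not

`make_toy_universe` builds linear-pathway scaffolds: each carbon source has
an exchange, a gene-gated transporter, and a missing conversion to a shared
precursor that sits in the universal bag; a 2:1 cross-feeding converter
into the first carbon is cheaper than the direct fix only once the first
pathway's fix is penalty-free, so media order genuinely changes the
selected reactions and ensembles are non-degenerate. "Split" carbons add a
universal bypass that skips a gene-gated draft step, so gap-fill choices
flip that gene's essentiality — the bimodality the analysis is built to
detect. Decoy universal reactions operate on disconnected metabolites and
can never carry flux. Ground-truth minimal gap-fill solutions are verified
at generation time by exhaustive subset enumeration whenever the universe
has ≤ 8 reactions.

`make_split_ensemble` constructs a 200-member ensemble directly: one real
bypass reaction whose presence deterministically flips two genes'
essentiality (the flip itself is computed by FBA knockouts, not assumed)
plus independent fair-coin decoy reactions. The member composition matrix
is sampled rather than produced by gap filling, because a deterministic LP
cannot sample hundreds of distinct alternate optima from a toy network;
the generator is labelled synthetic accordingly. Statistical-scale
behavior (cluster recovery, OOB accuracy, subsampling saturation) is
exercised on this fixture at 200 members with 20 decoys.

These fixtures validate the algorithmics, not the biochemistry: they have
no thermodynamic realism, trivial biomass equations, and far fewer genes
and reactions than genome-scale models. Passing tests demonstrates that
the machinery — LP formulation, ordering effects, dedup, clustering,
metrics — behaves as specified, not that any particular organism's
curation targets are correct. `make_synthetic_essentiality` emulates assay
noise by flipping a configurable fraction of simulated calls; real screens
have structured, not independent, noise.

## Problem sizes and defaults

Default operating point: 1,000 requested ensemble members, biomass floor
0.05 hr⁻¹, activation cutoff 1e-11, essentiality threshold 1e-6, complete-
medium limit 1,000, subsampling step 20 with 1,000 draws. The shipped test
and acceptance workloads run the same code paths at fixture scale (30–200
members, universes of ≤ 21 universal reactions, 3–5 media), chosen so the
exhaustive oracles (subset enumeration, all 2-partitions, truth tables)
remain tractable.

## Known limitations

- Gap filling minimizes summed flux, not reaction count; no MILP variant
  and no randomized penalty weights.
- Member diversity comes solely from media-order shuffling; with one medium
  the LP is deterministic and the ensemble degenerates by design.
- k is fixed at 2; iterative re-clustering and continuous-output variants
  (e.g. PCA + regression on growth rates) are not implemented.
- Flux variability analysis, flux sampling, dynamic FBA, and
  parallel-execution helpers are out of scope.
- SBML is read-only; the JSON dialect is the canonical format.
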