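# Methods

`panelbn` learns, stabilises and compares temporal Bayesian networks of
behaviour-change mechanisms from longitudinal intervention panels.  This
note records the model, the estimation procedures, the synthetic study
conditions, and the numerical and design choices a maintainer would want to
know about.

## Model class

The joint distribution over one subgroup's variables is a conditional
linear Gaussian (CLG) Bayesian network on a DAG *G*:

- discrete nodes (intervention arm, gender, education, impairment) carry a
  multinomial CPT over their discrete parents and may not have continuous
  parents;
- each continuous node *Y* (concept scores on 1–5 or 1–10 scales, the MVPA
  outcome, age in years) carries, for every configuration *j* of its
  discrete parents, a linear regression on its continuous parents
  `Y | pa(Y) ~ N(b0_j + b_j' X, sigma2_j)`.

Arcs are constrained by measurement tiers — static exogenous variables
first, then waves T0…T3 in order.  Any arc from a later tier into a
strictly earlier one is forbidden, so learned structures cannot run against
time.  Within a tier both orientations are searched.  The intervention arm
and the demographic covariates are fixed roots (no parents): the arm is
randomized and demographics are not caused by the psycho-social variables.
This exogeneity default is switchable (`TierConstraint.from_specs(...,
exogenous_roots=False)`).

## Scoring and search

Structures are scored by the decomposable BIC with the larger-is-better
convention, `sum_v [ ll_v - (k_v/2) ln n ]`, where a discrete family spends
`(levels-1) × (parent configurations)` parameters and a continuous family
`(continuous parents + 2)` per discrete configuration (intercept, slopes,
variance).  Family likelihoods are computed from per-configuration Gram
matrices of `[1 | continuous columns]`, cached per dataset, so a candidate
family costs one small linear solve.  Residual variances are ML estimates
floored at 1e-9 (guarding exactly collinear synthetic inputs); CPTs are raw
frequencies (pseudo-count 0, configurable).  A discrete configuration with
fewer rows than `continuous parents + 2` falls back to the pooled
(configuration-marginal) least-squares fit and is flagged; the BIC path
evaluates exactly the same fallback so that fitting and scoring share one
likelihood.

Search is a tabu-style hill climb over single-arc additions, deletions and
reversals (all tier-legal): the best move is applied even when it does not
improve, for at most `tabu_length` (default 10) consecutive non-improving
steps, with recently undone moves tabu unless they beat the best score
seen (aspiration); the best structure seen is returned.  Tie-breaks are
lexicographic by (move type, child, parent), so runs are reproducible.
Plain greedy ascent demonstrably stalls in Markov-equivalence basins on
small problems, which is why the escape phase exists.  For problems of up
to ~5 variables the recommended profile adds seeded iterated-local-search
restarts (`random_restarts=6`; each restart perturbs the incumbent by up to
three random arc toggles/reversals) — with that profile the climb attains
the exhaustively enumerated global optimum on all shipped random
instances.  The default for the full pipeline keeps 0 restarts: on tiered
20-plus-variable problems the bootstrap supplies the robustness and the
restart cost is better spent on replicates.

`exhaustive_search` (≤5 variables) maximises over topological orders with
per-node best parent subsets, which attains the enumeration optimum at a
fraction of the cost; `enumerate_legal_dags` provides the literal
enumeration for cross-checks.

## Missing data: structural EM

Panels assembled from several studies miss whole variables per study plus
scattered item-level cells.  Learning alternates:

- **E-step** — complete the missing cells under the current fitted network.
  Discrete nodes are completed in one topological sweep (most probable or
  drawn level given parents; the discrete variables are exogenous statics
  and are rarely missing).  Continuous nodes are completed *exactly*: given
  the discrete configuration the continuous block is jointly Gaussian
  (`x = c + Bx + e`, so `x ~ N((I-B)^{-1}c, (I-B)^{-1} D (I-B)^{-T})`), and
  each row's missing block is conditioned on **all** of its observed
  continuous values, children included.  Rows are grouped by
  (configuration, missingness pattern) to share the Schur-complement
  solves.  An earlier parents-only sweep was tried and rejected: ignoring
  children's evidence injected spurious arcs into a three-node chain
  oracle.
- **M-step** — hill climb on the completed data (warm-started from the
  previous structure), then ML parameter fitting.

The default completion is a **single draw** from the row-conditional
distribution rather than its expectation.  Conditional-mean completion
makes each imputed cell a deterministic function of the observed cells,
which biases completed-data partial correlations and can likewise
manufacture extra arcs on the chain oracle; stochastic completion
preserves the joint distribution and is what the chain-recovery test
exercises.  Expected-value completion remains available
(`completion_mode="expected_value"`).

Iteration stops when the completed-data BIC improves by less than `em_tol`
(1e-4) per row, or after `em_max_iter` (10) iterations, or as soon as an
iteration would lower the score (Monte-Carlo jitter): the best-so-far
network is returned and the reported score log is therefore non-decreasing
by construction.  Initial completion is column means/modes.

## Bootstrap averaging and stability

`B` Efron resamples (n rows with replacement) are each learned by
structural EM with counter-based per-replicate seeds
(`SeedSequence(master, spawn_key=(i,))`), so growing `B` never re-runs
earlier replicates and a failed replicate retries with a fresh derived
seed (at most 3 attempts).  The averaged model keeps every unordered pair
present in at least 60% of replicates (threshold configurable), orients it
by strict direction majority, and leaves an *exact* 50/50 split
undirected.  If majority orientations jointly close a directed cycle —
possible though not observed under the shipped conditions — the
lowest-confidence arc in each cycle is dropped and reported
(`dropped_for_cycles`); the repair can be disabled.

The bootstrap count is chosen from the structural Hamming distance (SHD)
between averaged models at consecutive grid points (default grid
100…150 in steps of 10): the smallest `B` whose SHD to the next grid point
is ≤ 0 (exact plateau, tolerance configurable) wins; without a plateau the
largest grid point is returned flagged.  SHD counts additions, deletions
and reorientations, with undirected↔directed transitions costing 1.

## Arc strength and pathway fragments

Retained edges are graded two ways:

- **Stability (thickness)** — presence confidence binned over [0.6, 1]
  with cuts at 0.7, 0.8, 0.9 → groups 1–4.
- **Strength (asterisks)** — jackknife bias-corrected mutual information on
  the complete cases of the two endpoints, allocated to terciles at the
  33%/67% quantiles *of the graded edge set* (per-fragment by default;
  ties at a cutpoint go to the lower group).

MI uses the model-consistent Gaussian forms: `-0.5 ln(1-r²)` for
continuous pairs, empirical cell frequencies for discrete pairs, and
pooled-minus-conditional Gaussian entropies for mixed pairs.  (The
estimator family differs from kernel-based MI; since the learner's model
class is Gaussian, the Gaussian MI is the internally consistent strength
measure.)  The jackknife correction is `n·θ̂ − (n−1)·mean(LOO)`, with
leave-one-out estimates computed by vectorised downdates.  The reported SE
adds, in quadrature, the null-scale variance `dof/(2n²)` (since `2n·MI` is
asymptotically χ²(dof) under independence, with dof 1 for
continuous–continuous, `(r−1)(c−1)` for discrete pairs and `2(levels−1)`
for mixed pairs): the plain jackknife variance collapses at the null
because the statistic is quadratic in the sample dependence, so without
the floor the SE is badly anti-conservative for independent pairs.  A
constant column yields MI 0 flagged degenerate.

A pathway fragment is the sub-network lying on any directed
intervention→outcome path: an edge (u,v) survives iff u is reachable from
the source and v reaches a target, undirected edges traversable both ways
(set `undirected_traversable=False` to exclude them entirely).  This
reachability rule equals brute-force simple-path enumeration on DAGs and is
verified against it.  A node's role for an outcome is *direct* (arc or
undirected edge straight into the outcome), *indirect* (in the fragment
without such an edge) or *absent*.  Fragment comparison reports shared
arcs, arcs unique to either subgroup, and per-node role transitions.

## Synthetic study conditions

Real pooled panels of this kind are not redistributable, so the generator
emulates their statistical structure from a known ground truth; its
defaults are the study conditions, not tuning knobs.

- **Full emulation** (`default_config`): 5,710 participants (the pooled
  subgroup tables sum to roughly this order), 52 variables — intervention
  (70% assigned, emulating a small waiting-list control arm), gender,
  age (years, truncated normal mean 63 / SD 8 on 50–90), 3-level
  education, impairment, plus 12 determinant concepts and the MVPA proxy
  at the waves each synthetic "study" measured them.  The ground-truth
  topology follows the staged determinant framework (premotivational →
  motivational → postmotivational → outcome, social concepts feeding the
  motivational stage), with autoregressive same-concept arcs across waves
  and intervention effects entering at T1/T2; coefficients are fixed,
  arbitrary defaults giving realistic effect sizes on the 1–5 scales.
  Concept scores are rendered as 4 ordinal items each (10-point scale for
  intention, 5-point otherwise; item = score + N(0, 0.3), rounded half-up,
  clipped), 5% of items missing at random, and re-aggregated as the mean
  of observed items allowing at most 25% missing (inclusive boundary).
  Whole-variable missingness follows the study-availability table with mix
  30/25/10/15/20% across five studies; studies 3 and 4 recruit only
  65-plus participants, which is what makes the five T3 variables
  measured solely by study 4 drop out of the under-65 subset.
  Demographics are 2% MCAR (the subgroup tables' footnote implies
  participants missing the moderator are dropped, which subsetting does).
- **Compact recovery truth** (`compact_config`): 20 variables in 4 tiers
  (5 statics; self-efficacy, intention, strategic planning, habit, MVPA at
  T1–T3), 30 arcs with coefficients 0.5–0.8 and unit residual SD, n=2000;
  recovery experiments add 20% MCAR to the wave variables.
- **Moderated truth** (`moderated_config`): 10 variables over T2/T3 with a
  single planted edit — the impairment level loses the direct
  intention@T2→MVPA@T2 arc but keeps the indirect route via habit, so the
  intention role flips direct→indirect; ~2,500 participants per level.

What the generator does *not* emulate: computer-tailored intervention
content, realistic (skewed) SQUASH minute distributions (any positive
continuous proxy suffices; an optional log-normal outcome transform
exists, while the learner stays Gaussian as the model class prescribes),
non-random attrition, and instrument differences between studies.  Passing
tests therefore show that the pipeline recovers the structures it assumes,
not that those assumptions hold in any real cohort.

## Numerical choices and degenerate inputs

- Score-improvement epsilon 1e-7; BIC cache keyed by (child, parent set).
- Singular Gram systems fall back to `lstsq`; negative round-off RSS is
  clamped at 0.
- Unseen discrete-parent configurations fall back to the child's marginal
  (discrete) or pooled (continuous) estimates at density evaluation.
- `average_network` treats presence within 1e-12 of the threshold as
  retained (exact 90/150 at 0.6 is kept).
- Direction ties must be exact count equality; near-ties stay directed.
- Problem sizes in the test and acceptance runs (n=1000–5710, B≤150,
  grids of six points) are the shipped experimental conditions chosen to
  make every property measurable on a single CPU.

## Known limitations

- The E-step conditions discrete completions on parents only; discrete
  evidence from children is ignored (discrete variables here are exogenous
  and almost always observed).
- Monte-Carlo EM stops at the first score decrease rather than averaging
  over completions; with heavy missingness this returns slightly
  conservative structures.
- Within-wave arcs whose orientation is not identified (no disambiguating
  v-structure) appear reversed or undirected in the averaged model; recall
  metrics count a reversal as a miss, and such pairs can hold confidence
  1.0 in the "wrong" direction — an equivalence-class property, not an
  averaging defect.
- Tercile cutpoints use the 33%/67% quantiles of whichever edge set is
  graded; grading the full model vs a fragment changes group assignment
  ("relative" allocation is per graded set, switchable by passing the edge
  subset).
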