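# Methods

## Problem

Keyhole approaches to deep brain targets (for example the retrocommissural
hippocampal formation in the mediobasal temporal region) differ in how much
eloquent tissue, vasculature and white-matter tract they traverse. Given a
parcellated 3D volume in which every voxel carries a clinician-rated penalty
in [0, 1] — 0 for structures that may be crossed freely, 1 for structures
whose violation is penalised — two questions arise:

1. how risky is a given hand-drawn straight corridor, and
2. what is the least-penalised (possibly nonlinear) corridor from a given
   scalp/cortex entry point to the target?

`qpath` answers the first by summing the penalty field over a voxelised
cylinder, and the second with a tabular Q-learning planner over the voxel
adjacency graph, cross-validated against an exact Dijkstra solver.

## Risk fields

A labelled volume (integer label map + label→segment-name map) and a risk
table (segment name → score in [0, 1]) produce a per-voxel penalty field by
lookup. Name matching is whitespace- and case-insensitive because clinical
tables are typographically irregular; a segment without a score is a hard
error unless the caller explicitly supplies a default, so unscored anatomy
cannot silently count as safe. A table listing one segment twice with
different scores is rejected at parse time with the segment named.

Risk fields from different modalities (parcellation, TOF-MRA vessels, DTI
tracts) are fused voxelwise. The default rule is the elementwise maximum —
where pre-aligned layers disagree, the most dangerous rating wins — with an
elementwise clipped sum available. Either rule keeps the fused field inside
[0, 1], preserving the score semantics. Fusion assumes the layers are
already registered; no resampling is performed.

## Corridor geometry

Hand-specified corridors are straight cylinders of fixed diameter (default
4 mm, a typical keyhole corridor calibre) between two physical points. A
voxel belongs to the corridor iff its centre lies within one radius of the
closed entry–target segment, measured in millimetres, so anisotropic
spacings are handled and the result is exactly testable against a
brute-force all-voxel distance check. The segment is closed, giving flat
end caps; the end treatment is a convention, not a claim. The corridor's
total risk is the arithmetic sum of per-voxel risk over the member set —
each voxel once, even if a corridor self-overlaps.

## The planner

Voxels are graph nodes; edges connect 26-neighbours by default (6-neighbour
mode available). The Q-table stores one value per ordered adjacent pair and
answers −1 for every non-adjacent pair ("no transition"); adjacent pairs are
initialised with uniform [0, 1) draws from the configured seed. Moving from
a voxel to a neighbour `v` costs

    R = step_cost + risk[v],

with `step_cost` defaulting to 0.01 so that across zero-risk plateaus
shorter corridors are strictly preferred (otherwise the optimum is
non-unique and arbitrarily long). Diagonal moves cost the same base step by
default — the penalty is risk-driven, not length-driven — with an option to
scale the base step by the physical step length. The temporal-difference
update is the penalty-minimising Bellman rule

    Q(s, a) ← Q(s, a) + α [ R + γ · min_{a'} Q(a, a') − Q(s, a) ],

i.e. the usual argmax form on negated rewards; values stay non-negative and
lower is better, matching the lowest-score-wins reading of the comparison
table. The target region is absorbing by default (`min` is 0 there).

Adjacent pairs are initialised with seeded uniform draws from
[0, `q_init_scale`), default scale 0.01. Keeping the random fill below the
smallest possible move cost makes every initial value an *underestimate* of
the true cost-to-go — an admissible heuristic in the shortest-path sense.
This is the load-bearing numerical choice: an unsampled transition can then
only attract the greedy policy (and be corrected on its first visit), never
hide a better corridor behind a random overestimate. With unscaled [0, 1)
initialisation, transitions near the target whose true cost-to-go is below
their initial value are avoided by the greedy policy and corrected only by
chance exploration; in validation this manifested as a few-percent rate of
corridors exactly one base-step longer than optimal, which vanishes under
admissible initialisation.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| α (learning rate) | 1.0 | the graph is deterministic, so α = 1 makes each update an exact asynchronous value-iteration step |
| γ (discount) | 1.0 | undiscounted total penalty is the quantity compared between corridors |
| ε schedule | 1.0 → 0.05, ×0.995/episode | early episodes are nearly pure random walks (coverage), late episodes refine the greedy corridor |
| episodes_max | 3,000 | hard cap; the stability stop almost always fires first |
| stable_episodes | 200 | stop once the greedy path is unchanged this long |
| step_cost | 0.01 | tie-break toward short corridors; small against any risk level |
| q_init_scale | 0.01 | admissible random initialisation (see above) |
| connectivity | 26 | surgical corridors are not axis-aligned |
| barrier_threshold | off | risky voxels are penalised, not forbidden; a threshold that removes voxels from the graph is available |

Two replay mechanisms accelerate propagation and are on by default:

- **backward replay** — at episode end the episode's transitions are
  re-updated in reverse order, so information obtained at the target
  propagates down the entire walk instead of one step per visit;
- **Dyna-style replay sweeps** — once per episode, a synchronous Bellman
  pass over *every transition visited so far* (vectorised as a segment-min
  over the CSR value array), keeping remembered transitions consistent with
  current downstream values instead of letting them go stale.

Both operate only on transitions the behaviour policy actually visited;
never-visited pairs keep their random initial values, and the planner
remains a sampling learner rather than a full-width dynamic-programming
solve. The exploratory arm of the ε-greedy policy draws uniformly over the
current node's neighbours by default; a least-visited-edge variant is
available.

Training stops when the greedy path (deterministic descent to the
minimum-Q successor, ties broken by lexicographic voxel order) is unchanged
for `stable_episodes` consecutive episodes, or at `episodes_max`. Path
extraction raises on a revisited node or dead end — the signature of an
undertrained table. The reported scores are the **Q-score** (sum of the
traversed transitions' Q-values; a node has no single value in a
connection-value table, so the transition reading is used) and the
**Qr score** (sum of per-voxel risk over the path, entry included).

With a fixed seed every run — table initialisation, exploration, and hence
the extracted path and scores — is bit-reproducible, reconciling random
initialisation with deterministic planning output.

### Exact oracle

`dijkstra_oracle` minimises the same Σ(step_cost + risk) objective on the
same graph with Dijkstra's algorithm (heap keyed by (cost, flat index), so
ties break lexicographically). It serves as the independent optimum in the
validation suite: on 50 seeded mixed-risk phantoms up to 15³ the trained
planner's corridor must attain the exact optimal cost in ≥95% of cases and
can never undercut it (any realised path cost is an upper bound on the
optimum). Equality of *cost* is asserted, not of path, to tolerate ties.
Any residual non-agreement under finite exploration takes the form of a
corridor one base-step (0.01) longer than optimal — a discovery failure,
not a scoring error.

## Synthetic phantoms

The generator emulates the product of atlas parcellation plus vessel/tract
masking at desk scale: Voronoi cells around seeded points become named
regions with clinician-style scores drawn from the levels seen in rating
tables {0.1, 0.3, 0.5, 0.6, 0.7, 1.0}; tubes (all voxels within a fixed
radius of a random polyline) stand in for vessels/tracts at score 1.0; an
optional low-risk channel (score ≤ 0.1) is carved from a boundary entry
voxel to an interior target centre, with the target ball its own label.
Default spacing is 0.8 mm isotropic, mirroring high-resolution T1 grids.
Identical specs produce bit-identical volumes.

What the phantom does **not** model: real anatomy and topology (gyral
geometry, ventricles, sulcal CSF), partial-volume effects, registration
error between modalities, and inter-rater variability in scores. Passing
tests therefore demonstrate the pipeline's correctness on label-complete
scored volumes, not clinical validity of any ranking.

Named toy fixtures ("free_line", "center_block", "wall_with_gap") are tiny
planning problems whose optimal costs are recomputed by the oracle at
construction time — changing the step cost or connectivity propagates into
the fixture instead of staling a stored constant. The forced values are
analytic: 4 steps × 0.01 on the free line; 0.03 for the three-step detour
around the risk-1 centre (the two-step diagonal costs 1.02).

## Comparison reports

`compare_approaches` scores each named approach independently — the hand
corridor's summed risk, and the planner's Q and Qr from that approach's
entry — and ranks ascending by Q-score (ties by name). A planner failure
marks the row failed and unranked but never drops it. Every report embeds
the planner config hash, seed and a checksum of the risk field, because a
ranking without that provenance cannot be re-derived.

## Numerical choices and degenerate inputs

- All tie-breaks (greedy descent, Dijkstra, argmin over neighbours) are by
  lexicographic voxel order, for reproducibility.
- Cylinder membership uses an inclusive boundary with a 1e-12 slack so
  voxel centres lying exactly on the radius are members.
- A zero-reward world with an absorbing target (zero risk, zero step cost,
  γ < 1) collapses all reachable Q-values to exactly 0; lexicographic
  descent then cycles. This degenerate configuration is documented rather
  than special-cased: with the default step_cost > 0 it cannot arise.
- Entry inside the target returns the single-node path with both scores 0
  without training.
- An unreachable target (sealed off by a barrier threshold) is detected by
  graph search up front and raised as an error.
- The learning-rate domain is (0, 1]: α = 0 would make training a no-op.

## Limitations

- Tabular state space: grids much beyond ~64³ make the Q-table and the
  episodic training impractical; the method is intended for cropped
  regions of interest or downsampled fields.
- The planner optimises a voxel-wise additive penalty; it knows nothing of
  instrument mechanics, corridor width (the planned path is one voxel
  wide), retraction, or approach angle.
- Scores are treated as exact; no uncertainty propagation from the
  clinician ratings.
- Straight-cylinder hand corridors only; curved hand-drawn corridors must
  be supplied as mask files.
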