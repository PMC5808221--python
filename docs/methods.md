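# Methods

## Model and assumptions

`tractolap` treats example-based tract segmentation as a streamline
correspondence problem. The operating assumptions are:

- Streamlines are polylines in world RAS+ millimetres. Point counts may vary
  per streamline; nothing in the correspondence path resamples them.
- Example tracts and the target tractogram are already affinely co-registered,
  but a *systematic residual displacement* of the homologous anatomy remains.
  This is the regime the method is designed for: a one-to-one assignment can
  follow a coherent displacement that defeats independent greedy matching.
- The MAM distance is an adequate dissimilarity for homology. It is symmetric,
  non-negative, zero on identical point sets and orientation-free (closest
  points ignore polyline direction), but it is **not** a metric — the triangle
  inequality can fail — so nothing downstream assumes metricity. The inner
  minimum is taken over the polyline's *points*, not its segments.

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| `n_prototypes` | 40 | dimensionality of the dissimilarity embedding |
| `subset_factor` | 25 | SFF random subset = `subset_factor × p` streamlines |
| `n_neighbors` | 500 | per-example-streamline k-NN union for sparsification |
| `mode` | `lap` | `lap` (one-to-one) or `nn` (greedy baseline) |
| `seed` | 0 | drives prototype selection; no global RNG state anywhere |
| `voxel_step_fraction` | 0.5 | resampling step for voxelization, × min voxel size |

Forty prototypes is the method's standard operating point for the embedding;
the SFF subset factor is our own choice (no established value exists): 25
gives a ~1000-streamline subset at p = 40, large enough for stable
farthest-first coverage and small enough to keep selection at seconds scale.
Prototypes are drawn from the **target** tractogram and reused to embed the
example tracts, so all embeddings share one coordinate frame. Farthest-first
ties break by ascending streamline index (a determinism choice, nothing
deeper).

The 500-neighbor union is generous at whole-brain scale (the candidate
superset stabilizes once it covers the true bundle — the test suite reproduces
this saturation on synthetic data); on tractograms smaller than 500 the count
is clamped to M with a warning and the reduced matrix is simply dense.

The k-NN index is exact by contract: results must equal exhaustive Euclidean
search (ties by ascending index). Approximate indexes are deliberately not
allowed — the test surface depends on exactness.

## The solver

The reduced cost matrix (rows = example streamlines, columns = neighbor-union
target streamlines, entries = exact MAM distances, +inf for unavailable
pairs) is solved with a rectangular Jonker–Volgenant shortest-augmenting-path
implementation. The contract is *exact optimality*, enforced in tests by
exhaustive enumeration on small matrices and cross-checked against an
independent library solver.

Tie-breaking is part of the contract: among equal-total-cost optima the
solver returns the assignment whose (row, column) pair list is
lexicographically smallest. This matters in practice — on the two-set worked
example the identity matching and a shift-by-one matching have exactly equal
total cost, and only the lexicographic rule makes "all five homologs
recovered" a deterministic outcome. The refinement exploits LP duality: the
duals produced by the augmenting-path solve are optimal (unmatched columns
keep a zero potential), so every cost-tied optimum uses only dual-tight
edges; the refinement walks rows in order and commits the smallest tight
column whose completion (checked by a sub-solve with a row-minima lower-bound
prune) still achieves the optimal total. Absolute tolerance for "tied" is
1e-9 scaled by the total.

The greedy baseline maps each example streamline to its embedding-space
nearest target streamline (duplicates allowed) and records the exact MAM cost
of each matched pair. An optional `mam_rerank` flag re-ranks a candidate list
by exact MAM before picking; it defaults off, mirroring the plain procedure
of taking the k-d tree's top hit. The sum of per-row minima is a lower bound
on the assignment total; tests assert it on every solved matrix.

## Merging multiple examples

Candidates are ranked by frequency (descending), accumulated selection cost
(ascending), then target index (ascending — our own third key; only the first
two are inherent to the scheme, and without the third the order of tied
streamlines would be arbitrary). Costs accumulate by *sum*, not mean; when
the greedy mode selects the same target streamline several times within one
example, those costs are also summed (the one-to-one mode cannot hit this
case). The final size k̂ is the median of the per-example segmentation sizes;
for an even number of examples we take the floor of the midpoint, the
conservative integer choice.

## Evaluation

Voxelization resamples each streamline at half the smallest voxel size
(keeping original vertices, so arc length is preserved and corners cannot be
skipped), maps points to voxel space by the inverse affine, and rounds
half-up to the nearest voxel center; out-of-grid points are dropped with a
counted warning. A refinement test checks that masks from the default step
are subsets of masks from a 10× finer step.

DSC on two empty masks raises instead of returning a sentinel: both 0 and 1
would mislead.

The ROC sweeps the threshold τ = 0…|ranking| over the ranked candidate list;
positives at τ are the voxels of the top-τ streamlines. **The voxel universe
for TN is the union of all ranked streamlines' voxels with the ground-truth
voxels, not the whole grid.** Against a whole-brain grid the enormous empty
background would pin FPR near zero and saturate every AUC at ~1; the chosen
universe makes FPR informative. Absolute AUC values are therefore only
comparable within this convention. AUC is the trapezoid area under the
(FPR, TPR) polyline closed with (0, 0) and (1, 1).

## Synthetic populations

The generator emulates exactly the structure the method assumes, with exact
ground truth real data cannot provide:

- a fixed cubic (Bézier) centerline ~65 mm long; the canonical bundle is a
  set of centerline copies offset within a 4 mm-radius disc in the local
  normal plane;
- each subject takes a nested prefix of the canonical bundle (size drawn from
  a clipped normal, mean 25, sd 5, min 3), adds per-point Gaussian jitter
  (0.3 mm), and applies a subject-level displacement **after** the nominal
  registration — either a uniform lateral shift of exactly
  `displacement_mm`, or a smooth low-frequency sinusoidal field with that
  peak amplitude;
- 100 distractor momentum random walks per subject, rejection-sampled to stay
  ≥ 3 bundle radii (plus displacement clearance) from the centerline and
  pushed further if their MAM distance to the bundle ever undercuts the
  intra-bundle spread, so bundle/distractor separation is guaranteed by
  construction;
- every subject records the canonical-id → streamline-index homolog map.

The default displacement is 3.2 mm = 2× the nominal bundle spacing
(`2·radius/√size ≈ 1.6 mm`): the regime where the one-to-one pipeline should
beat the greedy one, which is the package's central testable claim. The
default evaluation grid is 64³ voxels at 1.25 mm isotropic, centered on the
scene.

What the generator does **not** emulate: anatomically shaped bundles beyond
one parametric template, crossing/kissing bundle configurations, variable
streamline point counts within the bundle, tractography noise models, or
partial-volume effects. Passing tests on these populations therefore
demonstrate the machinery (correspondence, ranking, evaluation) under the
method's stated assumptions, not performance on real tractography.

Population experiments in the test suite use 16 subjects of ~128 streamlines
(25-streamline bundles, 100 distractors) averaged over 10 population seeds —
sizes chosen so the full stochastic suite completes in about a minute while
leaving the measured contrasts far from their decision thresholds.

## Numerical and degenerate-input choices

- Degenerate streamlines (< 2 points, non-finite, zero length) are dropped at
  tractogram construction with a logged count, not errored: real files
  contain junk.
- Resampling keeps original vertices; "step ≥ length" therefore returns the
  endpoints only for 2-point segments, and preserves interior vertices
  otherwise (arc-length preservation wins over point-count minimality).
- MAM equality checks in tests use 1e-9 mm absolute; solver optimality 1e-9
  relative; voxel rounding is half-up per axis (`floor(x + 0.5)`).
- Infeasible reduced matrices (a row with no available column, or fewer union
  columns than rows) raise errors naming the starved rows / suggesting a
  larger neighbor count, rather than silently padding.

## Known limitations

- Exact MAM on all (row, union-column) pairs dominates runtime; at
  whole-brain scale (M ~ 10⁵–10⁶) the embedding/k-d-tree sparsification is
  what keeps it tractable, but this package has only been profiled at desk
  scale (M ≤ a few thousand).
- The lexicographic refinement adds one sub-solve per tied row; adversarial
  matrices with massive tie structure (e.g., all-equal costs) cost more, but
  remain polynomial.
- Correspondence *accuracy* (hitting the exact homolog) degrades gracefully
  under large displacement even when the segmentation (the recovered set)
  stays correct: one-to-one matchings may legitimately shift pairings within
  a dense bundle. The homolog map makes this measurable; tests assert exact
  accuracy only below-spacing displacement.
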