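# tractolap

Example-based segmentation of white-matter tracts by streamline
correspondence.

Diffusion-MRI tractography reconstructs the brain's white matter as a
*tractogram*: a set of up to millions of 3-D polylines (*streamlines*).
Isolating an anatomically meaningful bundle — the corticospinal tract, the
arcuate fasciculus — from a new subject's tractogram is the *tract
segmentation* problem. `tractolap` solves it from examples: given the same
bundle already segmented in `N` other subjects, it finds the corresponding
streamlines in the new subject's tractogram. It is aimed at researchers who
have a handful of curated example bundles (from manual delineation or a
rule-based pipeline) and want to transfer them to new, affinely co-registered
subjects.

## Method

For one example bundle `t_A = {s_1^A, …, s_k^A}` and a target tractogram
`T_B = {s_1^B, …, s_M^B}` (k ≪ M), correspondence is cast as a rectangular
linear assignment problem (RLAP) on the symmetric minimum average mean (MAM)
streamline distance

    d_MAM(a, b) = ½ (D(a, b) + D(b, a)),   D(a, b) = mean_i min_j ‖x_i^a − x_j^b‖,

    P* = argmin_P Σ_ij c_ij p_ij,   c_ij = d_MAM(s_i^A, s_j^B),

with `P` a partial permutation matrix (each example streamline assigned to
exactly one target streamline, each target streamline used at most once). The
one-to-one constraint is the point: after imperfect affine registration,
homologous structures keep a systematic residual displacement, and a greedy
nearest-neighbor match collapses many example streamlines onto the near side
of the target bundle, while the assignment is forced to follow the shift.

The k×M cost matrix is never built in full. Streamlines are embedded in R^p
by their MAM distances to `p = 40` prototypes chosen with Subset Farthest
First from the target tractogram (the *dissimilarity representation*); a k-d
tree over the embedding returns, for each example streamline, its 500 nearest
target streamlines, and exact MAM costs are computed only on the union of
those neighborhoods. The reduced problem is solved exactly with a rectangular
Jonker–Volgenant (shortest-augmenting-path) solver; among cost-tied optima
the lexicographically smallest pair list is returned, so results are fully
deterministic.

With `N` examples, the per-example candidate sets are merged by ranking every
candidate streamline by (1) how many examples selected it, descending, then
(2) its accumulated selection cost, ascending ("cheaper match = more
reliable"), then (3) index. The final segmentation is the top `k̂` of the
ranking, where `k̂` is the median example-segmentation size.

Evaluation is voxel-level: tracts are rasterized onto a reference grid
("crossed-by" masks), compared with the Dice similarity coefficient
`DSC = 2|A∩B|/(|A|+|B|)`, and the ranking is swept threshold-by-threshold to
produce a ROC curve and its AUC. A synthetic multi-subject population
generator (curved bundle + distractors + per-subject displacement, with exact
homolog ground truth) makes the whole pipeline testable without any imaging
data.

## Worked example

`examples/01_two_bundle_correspondence.py` builds two sets of five parallel
homologous streamlines, 5 mm apart, with the target set displaced laterally
by 8 mm (1.6× the spacing), and runs both correspondence strategies:

```
two sets of 5 streamlines, spacing 5.0 mm, lateral shift 8.0 mm

greedy NN  : {0: 0, 1: 0, 2: 0, 3: 1, 4: 2} -> 3 distinct targets, 2 missed
assignment : {0: 0, 1: 1, 2: 2, 3: 3, 4: 4} -> 5/5 true homologs, total cost 40.0 mm

greedy total 17.0 mm <= assignment total 40.0 mm
```

The greedy rule maps three example streamlines onto the same near-side target
and misses two far-side targets entirely; the one-to-one assignment pays a
higher total distance (40 mm vs 17 mm — the greedy total is always a lower
bound) but recovers all five homologous pairs.

`examples/02_population_segmentation.py` runs the full multi-example pipeline
on a 16-subject synthetic population with a residual displacement of twice
the bundle spacing:

```
16 subjects; target tractogram M=128 (bundle 28 + 100 distractors), displacement 3.2 mm = 2 x spacing 1.6 mm
lap: k_hat= 26 candidates= 34 DSC=0.957 AUC=1.000
 nn: k_hat= 17 candidates= 28 DSC=0.804 AUC=1.000
```

Here DSC is voxel overlap with the planted bundle: the assignment pipeline
recovers it almost perfectly, the greedy baseline loses a fifth of it to
near-side pile-ups.

## Command line

```
tractolap segment  --target T.trk --examples ex1.trk --examples ex2.trk \
                   --mode lap --out seg.trk --ranking ranking.tsv --seed 0
tractolap evaluate --segmentation seg.trk --ground-truth gt.trk [--grid ref.nii.gz]
tractolap simulate --seed 5 --subjects 16 --out population/
```

`segment` prints a JSON run report (sizes, k̂, per-example costs, timing);
`evaluate` prints DSC (and AUC when a ranking table is supplied); `simulate`
writes a synthetic population as TRK files with JSON ground-truth sidecars.

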