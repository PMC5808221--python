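"""File round-trip and voxel-level evaluation artifacts.

Writes a small synthetic population to TRK, reloads it, segments through the
file-based path, and exports the ranking table and ROC curve the way the
command-line interface does. Everything on disk is standard: TRK streamlines,
NIfTI masks, TSV tables.
"""

import tempfile
from pathlib import Path

import tractolap as tl
from tractolap.evaluation import roc_table
from tractolap.io import read_streamlines, write_mask, write_streamlines
from tractolap.refinement import ranking_table

config = tl.PopulationConfig(n_subjects=4, n_distractors=40, seed=8)
population = tl.generate_population(config)
target, *example_subjects = population

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_streamlines(target.tractogram, tmp / "target.trk")
    reloaded = read_streamlines(tmp / "target.trk")
    print(f"TRK round-trip: {len(reloaded)} streamlines, "
          f"grid {reloaded.reference.shape} @ {reloaded.reference.voxel_size[0]:.2f} mm")

    examples = [
        s.tractogram.subset(s.true_tract.indices) for s in example_subjects
    ]
    result, _ = tl.segment_bundle(examples, reloaded, tl.RunConfig(seed=8))

    grid = reloaded.reference
    seg_mask = tl.voxelize(result.tract, grid)
    gt_mask = tl.voxelize(target.true_tract, grid)
    print(f"DSC vs planted bundle: {tl.dsc(seg_mask, gt_mask):.3f}")

    write_mask(seg_mask, tmp / "segmentation.nii.gz")
    (tmp / "ranking.tsv").write_text(ranking_table(result.ranking, result.k_hat))
    roc = tl.roc_analysis(result.ranking, reloaded, target.true_tract, grid)
    (tmp / "roc.tsv").write_text(roc_table(roc))
    print(f"wrote mask + ranking ({len(result.ranking)} rows) + "
          f"ROC ({len(roc.thresholds)} thresholds, AUC={roc.auc:.3f})")

# Equivalent shell usage:
#   tractolap simulate --seed 8 --subjects 4 --out pop/
#   tractolap segment --target pop/subject_00.trk --examples ... --out seg.trk
#   tractolap evaluate --segmentation seg.trk --ground-truth gt.trk
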