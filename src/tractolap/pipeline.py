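"""End-to-end multi-example segmentation pipeline.

Given N example tracts of one bundle and a target tractogram: select
prototypes from the target, embed everything, compute per-example
correspondences (one-to-one assignment or greedy nearest neighbor), then merge
the candidates with the frequency/cost ranking and median-size threshold.
"""

from __future__ import annotations

import logging
import time

from .config import RunConfig
from .core import Tract, Tractogram
from .correspondence import segment_from_single_example
from .embedding import NeighborIndex, embed, sff_select_prototypes
from .refinement import ExampleSegmentation, SegmentationResult, merge_examples

logger = logging.getLogger(__name__)

__all__ = ["segment_bundle"]


def segment_bundle(
    examples: list[Tract | list],
    target: Tractogram,
    config: RunConfig | None = None,
    label: str = "",
):
    """Segment the target's homolog of the bundle shown by ``examples``.

    Returns ``(result, per_example)`` where ``result`` is a
    :class:`~tractolap.refinement.SegmentationResult` and ``per_example`` is
    the list of :class:`~tractolap.refinement.ExampleSegmentation` (one per
    example, in input order) that fed the ranking.
    """
    if config is None:
        config = RunConfig()
    if len(examples) < 1:
        raise ValueError("need at least one example tract")

    t0 = time.perf_counter()
    p = min(config.n_prototypes, len(target))
    if p < config.n_prototypes:
        logger.warning(
            "n_prototypes=%d exceeds target size %d; clamped",
            config.n_prototypes,
            len(target),
        )
    prototypes = sff_select_prototypes(
        target, p, subset_factor=config.subset_factor, seed=config.seed
    )
    target_embedding = embed(target, prototypes)
    index = NeighborIndex(target_embedding)
    logger.info(
        "embedded target: M=%d, p=%d (%.2fs)",
        len(target),
        p,
        time.perf_counter() - t0,
    )

    per_example: list[ExampleSegmentation] = []
    for n, example in enumerate(examples):
        t1 = time.perf_counter()
        pairs, per_cost, total, _ = segment_from_single_example(
            example,
            target,
            mode=config.mode,
            n_neighbors=config.n_neighbors,
            mam_rerank=config.mam_rerank,
            prototypes=prototypes,
            target_embedding=target_embedding,
            index=index,
        )
        seg = ExampleSegmentation.from_pairs(pairs, per_cost)
        per_example.append(seg)
        logger.info(
            "example %d: k=%d -> %d candidates, total cost %.2f mm (%.2fs)",
            n,
            len(pairs),
            len(seg),
            total,
            time.perf_counter() - t1,
        )

    result = merge_examples(per_example, target, label=label)
    logger.info(
        "merged %d examples: union=%d, k_hat=%d",
        len(per_example),
        len(result.ranking),
        result.k_hat,
    )
    return result, per_example
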