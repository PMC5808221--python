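"""Synthetic tractography data with exact correspondence ground truth.

Two generators live here. ``fixture_figure1`` builds the classic didactic
scene for greedy-vs-assignment correspondence: two sets of five homologous
parallel streamlines whose lateral offset exceeds the inter-streamline
spacing, so the greedy nearest-neighbor rule collapses onto the near side
while a one-to-one assignment tracks the shift.

``generate_population`` emulates the structure the segmentation method
assumes in real data: a curved bundle shared across subjects (homologs drawn
from one canonical bundle), per-subject size variability, per-point jitter, a
per-subject systematic displacement standing in for residual misregistration
after affine alignment, and distractor streamlines kept well clear of the
bundle. Every subject records the canonical-id -> streamline-index homolog
map, giving exact correspondence ground truth that real data never has.

All randomness flows from explicit seeds; identical configurations produce
bit-identical populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpatialReference, Tract, Tractogram, mam_distance_matrix

__all__ = [
    "Figure1Fixture",
    "PopulationConfig",
    "SyntheticSubject",
    "fixture_figure1",
    "generate_subject",
    "generate_population",
    "default_grid",
]


def default_grid() -> SpatialReference:
    """64^3 grid at 1.25 mm isotropic, identity orientation, centered on the
    origin (voxel centers span about +-39.4 mm per axis)."""
    affine = np.diag([1.25, 1.25, 1.25, 1.0])
    affine[:3, 3] = -1.25 * (64 - 1) / 2.0
    return SpatialReference(affine=affine, shape=(64, 64, 64))


# ---------------------------------------------------------------------------
# Deterministic two-set fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Figure1Fixture:
    """Two homologous sets of parallel streamlines with a known lateral shift."""

    example_tractogram: Tractogram
    example_tract: Tract
    target_tractogram: Tractogram
    target_tract: Tract
    true_pairs: tuple[tuple[int, int], ...]
    spacing: float
    offset: float


def fixture_figure1(
    n_streamlines: int = 5,
    spacing: float = 5.0,
    offset_factor: float = 1.6,
    n_points: int = 21,
    length: float = 40.0,
) -> Figure1Fixture:
    """Deterministic parallel-bundle pair with homologs related by a shift.

    The example set holds ``n_streamlines`` straight streamlines along x,
    spaced ``spacing`` mm apart laterally; the target set is the same bundle
    translated laterally by ``offset_factor * spacing`` mm. With the default
    factor 1.6 the shift exceeds the spacing, the regime where greedy
    nearest-neighbor correspondence misses the far-side streamlines while the
    one-to-one assignment recovers every true pair. True pairs are identity by
    construction.
    """
    x = np.linspace(-length / 2.0, length / 2.0, n_points)
    offset = offset_factor * spacing
    blue, red = [], []
    for i in range(n_streamlines):
        pts = np.column_stack([x, np.full(n_points, i * spacing), np.zeros(n_points)])
        blue.append(pts)
        red.append(pts + np.array([0.0, offset, 0.0]))
    ex = Tractogram(blue, reference=default_grid())
    tg = Tractogram(red, reference=default_grid())
    return Figure1Fixture(
        example_tractogram=ex,
        example_tract=Tract(ex, tuple(range(n_streamlines)), label="example"),
        target_tractogram=tg,
        target_tract=Tract(tg, tuple(range(n_streamlines)), label="target"),
        true_pairs=tuple((i, i) for i in range(n_streamlines)),
        spacing=spacing,
        offset=offset,
    )


# ---------------------------------------------------------------------------
# Multi-subject populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationConfig:
    """Conditions for a synthetic multi-subject population.

    ``displacement_mm`` is the magnitude of the per-subject systematic
    displacement applied to the bundle after nominal registration; the default
    equals twice the nominal inter-streamline spacing
    (``2 * bundle_radius / sqrt(bundle_size_mean)``), the regime where a
    one-to-one assignment outperforms greedy matching. ``displacement_mode``
    is a uniform lateral shift or a smooth low-frequency field of the same
    peak amplitude.
    """

    n_subjects: int = 16
    bundle_size_mean: int = 25
    bundle_size_sd: float = 5.0
    n_distractors: int = 100
    bundle_radius: float = 4.0
    displacement_mm: float = 3.2
    displacement_mode: str = "uniform-shift"
    jitter_mm: float = 0.3
    n_points: int = 21
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.bundle_size_mean < 3:
            raise ValueError("bundle_size_mean must be >= 3")
        for name in ("bundle_size_sd", "displacement_mm", "jitter_mm", "bundle_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.displacement_mode not in ("uniform-shift", "smooth-field"):
            raise ValueError(f"unknown displacement_mode {self.displacement_mode!r}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def nominal_spacing(self) -> float:
        """Typical nearest-neighbor distance between bundle streamlines (mm)."""
        return 2.0 * self.bundle_radius / np.sqrt(self.bundle_size_mean)

    @property
    def canonical_size(self) -> int:
        return int(self.bundle_size_mean + np.ceil(4 * self.bundle_size_sd))


@dataclass
class SyntheticSubject:
    """One subject: tractogram, planted bundle, and exact homolog ground truth."""

    tractogram: Tractogram
    true_tract: Tract
    homolog_map: dict[int, int]  # canonical bundle id -> streamline index


def _centerline(n_points: int) -> np.ndarray:
    """Fixed cubic (Bezier) bundle template, ~65 mm long, centered near 0."""
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    p0 = np.array([-30.0, -10.0, -5.0])
    p1 = np.array([-10.0, 15.0, 0.0])
    p2 = np.array([10.0, 15.0, 0.0])
    p3 = np.array([30.0, -10.0, 5.0])
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t**2 * p2
        + t**3 * p3
    )


def _frames(center: np.ndarray):
    """Per-point orthonormal (normal, binormal) frame of a polyline."""
    tang = np.gradient(center, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    up = np.array([0.0, 0.0, 1.0])
    normal = up - (tang @ up)[:, None] * tang
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    binormal = np.cross(tang, normal)
    return normal, binormal


def _canonical_bundle(config: PopulationConfig) -> list[np.ndarray]:
    """The canonical bundle: centerline copies with fixed radial offsets."""
    rng = np.random.default_rng([config.seed, 0x0FF5E7])
    center = _centerline(config.n_points)
    normal, binormal = _frames(center)
    streamlines = []
    for _ in range(config.canonical_size):
        r = config.bundle_radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        a, b = r * np.cos(theta), r * np.sin(theta)
        streamlines.append(center + a * normal + b * binormal)
    return streamlines


def _displacement(config: PopulationConfig, rng, points: np.ndarray) -> np.ndarray:
    if config.displacement_mm == 0.0:
        return np.zeros(3)
    if config.displacement_mode == "uniform-shift":
        phi = rng.uniform(0.0, 2.0 * np.pi)
        return config.displacement_mm * np.array([0.0, np.cos(phi), np.sin(phi)])
    # smooth-field: low-frequency sinusoid per axis, peak magnitude bounded
    k = rng.uniform(0.8, 1.2) * 2.0 * np.pi / 70.0
    phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
    amp = config.displacement_mm / np.sqrt(3.0)
    arg = k * points[:, 0:1] + phase[None, :]
    return amp * np.sin(arg)


def _distractor(rng, n_points: int) -> np.ndarray:
    """Momentum random-walk streamline folded into the scene box."""
    start = rng.uniform(-30.0, 30.0, size=3)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [start]
    for _ in range(n_points - 1):
        d = d + 0.4 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + 3.0 * d)
    pts = np.array(pts)
    # reflect into [-38, 38] so the scene stays on the default grid
    box = 38.0
    pts = box - np.abs(np.mod(pts + box, 4 * box) - 2 * box)
    return pts


def generate_subject(config: PopulationConfig, subject_seed: int) -> SyntheticSubject:
    """One subject of the population, deterministic in (config.seed, subject_seed).

    The subject's bundle is a size-varying subset of the canonical bundle with
    per-point jitter and a subject-level displacement; distractors are kept at
    least three bundle radii (plus displacement clearance) away from the
    bundle, and pushed further if their MAM distance ever undercuts the
    intra-bundle spread.
    """
    rng = np.random.default_rng([config.seed, 1 + int(subject_seed)])
    canonical = _canonical_bundle(config)

    size = int(np.rint(rng.normal(config.bundle_size_mean, config.bundle_size_sd)))
    size = int(np.clip(size, 3, config.canonical_size))

    bundle = []
    for cid in range(size):
        pts = canonical[cid].copy()
        disp = _displacement(config, rng, pts)
        pts = pts + disp
        if config.jitter_mm > 0:
            pts = pts + rng.normal(0.0, config.jitter_mm, size=pts.shape)
        bundle.append(pts)

    clearance = 3.0 * config.bundle_radius + config.displacement_mm + 4.0
    center = _centerline(config.n_points)
    distractors = []
    for _ in range(config.n_distractors):
        for _attempt in range(200):
            cand = _distractor(rng, config.n_points)
            dmin = np.min(
                np.linalg.norm(cand[:, None, :] - center[None, :, :], axis=2)
            )
            if dmin >= clearance:
                distractors.append(cand)
                break
        else:  # push the last candidate radially away from the bundle
            shift = cand.mean(axis=0) - center.mean(axis=0)
            shift /= max(np.linalg.norm(shift), 1e-9)
            distractors.append(cand + shift * (clearance + 5.0))

    if distractors and bundle:
        intra = mam_distance_matrix(bundle, bundle)
        max_intra = float(intra.max())
        d2b = mam_distance_matrix(distractors, bundle).min(axis=1)
        for i in np.where(d2b <= max_intra + 1.0)[0]:
            shift = distractors[i].mean(axis=0) - center.mean(axis=0)
            shift /= max(np.linalg.norm(shift), 1e-9)
            distractors[i] = distractors[i] + shift * (max_intra + 5.0)

    streamlines = bundle + distractors
    order = rng.permutation(len(streamlines))
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(len(order))
    tractogram = Tractogram(
        [streamlines[i] for i in order], reference=default_grid()
    )
    homolog_map = {cid: int(inv_order[cid]) for cid in range(size)}
    true_tract = Tract(
        tractogram, tuple(sorted(homolog_map.values())), label="planted-bundle"
    )
    return SyntheticSubject(
        tractogram=tractogram, true_tract=true_tract, homolog_map=homolog_map
    )


def generate_population(config: PopulationConfig) -> list[SyntheticSubject]:
    """All subjects of the population; by convention subject 0 is the target
    and subjects 1..N-1 serve as examples."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]
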