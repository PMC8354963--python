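"""Synthetic frontal-sinus cohort generator.

No public mesh data accompany the study design this package replicates, so
the cohort is simulated. Each "subject" is a bilateral, multilobed implicit
shape: a union of Gaussian blobs on the right side, mirrored to the left
with per-lobe perturbations (real sinuses are markedly asymmetric), meshed
by marching cubes and rescaled anisotropically so that maximum breadth and
height hit per-subject targets drawn from the population distributions
(breadth 56.9 +/- 11.2 mm, height 32.0 +/- 7.0 mm; volume emerges from the
lobe geometry, calibrated near 8.9 cm^3).

A second "segmentation" of the same subject is simulated by
:func:`resegment`: correlated surface noise along vertex normals, mild
Laplacian smoothing, an inferior-border crop shift, and a pose jitter (two
segmentations of one CT scan are never exported in the same orientation,
which is what moves the axis-aligned size measurements). The noise scale is
calibrated so match superimpositions land near the 0.18 mm RMS regime,
while inter-subject shape variation keeps mismatch RMS well above the
0.96 mm identification threshold.

Everything is a pure function of its seed; the master seed of a cohort is
split into per-subject, per-stage child seeds so any single pair can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .mesh import validate_mesh
from .registration import RigidTransform, apply_transform

__all__ = [
    "SinusParams",
    "NoiseModel",
    "Cohort",
    "generate_sinus",
    "resegment",
    "make_cohort",
    "random_derangement",
]

# Nominal lobe-placement ranges (mm) chosen so the unscaled shape already has
# breadth ~55 and height ~33; the final anisotropic rescale is then gentle.
_LOBE_X = (6.0, 21.0)  # lateral offset of lobe centers from the midline
_LOBE_Y = (-3.0, 3.0)  # anterior-posterior spread
_LOBE_Z = (-9.0, 9.0)  # inferior-superior spread
_LOBE_RADIUS = (4.5, 8.0)  # Gaussian sigma per lobe
_ISO_LEVEL = 0.5
_DEPTH_FACTOR = 0.36  # y compression: sinuses are shallow antero-posteriorly;
# calibrated so the default cohort's mean volume sits near 8.9 cm^3


@dataclass
class SinusParams:
    """Shape parameters of one synthetic sinus.

    Lobe centers/radii describe the *right* side; the left side is the
    mirror image perturbed by ``left_right_asymmetry`` (relative jitter of
    centers and radii). Leave ``lobe_centers``/``lobe_radii`` as None to have
    them drawn from the generation seed.
    """

    n_lobes_per_side: int = 3
    lobe_centers: np.ndarray | None = None  # (n, 3) right-side centers, mm
    lobe_radii: np.ndarray | None = None  # (n,) Gaussian sigmas, mm
    lobe_weights: np.ndarray | None = None  # (n,) signed field weights
    lobe_scales: np.ndarray | None = None  # (n, 3) per-axis elongation of each lobe
    left_right_asymmetry: float = 0.18
    target_breadth: float = 56.9
    target_height: float = 32.0
    depth_factor: float = _DEPTH_FACTOR  # antero-posterior compression
    target_depth: float | None = None  # absolute antero-posterior extent, mm
    # (frontal-sinus depth is roughly size-independent; when set it overrides
    # the proportional depth_factor scaling)
    arc_radius_mm: float = 80.0  # frontal-bone curvature the lobes follow
    voxel_pitch: float = 1.0

    def __post_init__(self) -> None:
        if not (2 <= self.n_lobes_per_side <= 5):
            raise ValueError("n_lobes_per_side must be in 2..5")
        if self.target_breadth <= 0 or self.target_height <= 0 or self.voxel_pitch <= 0:
            raise ValueError("targets and voxel_pitch must be positive")
        if self.depth_factor <= 0 or self.arc_radius_mm <= 0:
            raise ValueError("depth_factor and arc_radius_mm must be positive")
        if self.lobe_radii is not None and np.any(np.asarray(self.lobe_radii) <= 0):
            raise ValueError("lobe radii must be positive")


@dataclass
class NoiseModel:
    """Repeated-segmentation noise for one independent segmentation pass.

    surface_noise_sd : mm, sd of the white vertex displacement along normals
        (subsequent smoothing leaves a correlated field of smaller amplitude).
    threshold_offset_sd : mm, sd of a single global inward/outward offset of
        the whole surface per segmentation — grey-level threshold variation
        between semi-automatic segmentation runs over- or under-segments the
        cavity as a whole.
    patch_noise_sd : mm, amplitude sd of a handful of smooth local patches
        (Gaussian bumps ~5-10 mm across, centered on the flat
        anterior/posterior tables) per segmentation: regions the
        region-growing step over- or under-fills. Off by default — like the
        global offset, net-volume noise couples the direction-swap RMS
        deltas to the volume deltas across matches (see docs/methods.md).
    crop_jitter_sd : mm, sd of a vertical shift of the inferior border (the
        sinus is cropped at its ostium, and where exactly differs between
        segmentation runs); applied as a smoothly weighted displacement of
        the lowermost surface, the dominant source of height variability.
    smoothing_iterations : Laplacian smoothing passes after displacement.
    remesh_fraction : vertex-count ratio of the second segmentation to the
        first (1 keeps the tessellation; 4^k applies k midpoint subdivisions).
    pose_rotation_deg / pose_translation_mm : maximum pose jitter per
        segmentation; removed again by registration, but it moves the
        axis-aligned size measurements the way re-positioned scans do.
    """

    surface_noise_sd: float = 0.21
    threshold_offset_sd: float = 0.0
    patch_noise_sd: float = 0.0
    crop_jitter_sd: float = 0.12
    smoothing_iterations: int = 1
    remesh_fraction: float = 1.0
    pose_rotation_deg: float = 14.0
    pose_translation_mm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("surface_noise_sd", "threshold_offset_sd", "patch_noise_sd",
                     "crop_jitter_sd", "smoothing_iterations", "remesh_fraction",
                     "pose_rotation_deg", "pose_translation_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _draw_lobes(
    params: SinusParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = params.n_lobes_per_side
    centers = np.column_stack(
        [
            rng.uniform(*_LOBE_X, size=n),
            rng.uniform(*_LOBE_Y, size=n),
            rng.uniform(*_LOBE_Z, size=n),
        ]
    )
    # one lobe anchored near the midline so the two sides approach the septum
    centers[0, 0] = rng.uniform(4.0, 8.0)
    centers[0, 2] = rng.uniform(-4.0, 4.0)
    # all lobes follow the frontal-bone arc: the posterior offset grows with
    # the square of the lateral position (sagitta of a circle of radius R)
    centers[:, 1] -= centers[:, 0] ** 2 / (2.0 * params.arc_radius_mm)
    radii = rng.uniform(*_LOBE_RADIUS, size=n)
    weights = np.ones(n)
    scales = rng.uniform(0.7, 1.4, size=(n, 3))  # elongated, not spherical, lobes

    # small signed satellite features hanging off the lobes: scalloped
    # lobulations and carved recesses, the fine structure that makes each
    # individual's sinus outline unique
    n_bumps = int(rng.integers(8, 14))
    parent = rng.integers(0, n, size=n_bumps)
    direction = rng.normal(size=(n_bumps, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    offsets = rng.uniform(0.6, 1.3, size=n_bumps)[:, None] * radii[parent][:, None] * direction
    bump_centers = centers[parent] + offsets
    bump_radii = rng.uniform(2.0, 3.5, size=n_bumps)
    bump_weights = rng.uniform(0.30, 0.60, size=n_bumps) * rng.choice([-1.0, 1.0], size=n_bumps)

    bump_scales = np.ones((n_bumps, 3))
    return (
        np.vstack([centers, bump_centers]),
        np.concatenate([radii, bump_radii]),
        np.concatenate([weights, bump_weights]),
        np.vstack([scales, bump_scales]),
    )


def _mirror_with_asymmetry(
    centers: np.ndarray, radii: np.ndarray, weights: np.ndarray,
    scales: np.ndarray, asym: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    left = centers.copy()
    left[:, 0] *= -1
    left += rng.normal(scale=asym * radii[:, None], size=left.shape)
    left_radii = radii * np.clip(1.0 + rng.normal(scale=asym, size=len(radii)), 0.5, 1.5)
    left_weights = weights * np.clip(1.0 + rng.normal(scale=asym, size=len(weights)), 0.3, 1.7)
    left_scales = scales * np.clip(1.0 + rng.normal(scale=asym, size=scales.shape), 0.6, 1.4)
    return left, left_radii, left_weights, left_scales


def _blob_field(grid: tuple[np.ndarray, np.ndarray, np.ndarray],
                centers: np.ndarray, radii: np.ndarray,
                weights: np.ndarray, scales: np.ndarray) -> np.ndarray:
    gx, gy, gz = grid
    out = np.zeros((len(gx), len(gy), len(gz)))
    X = gx[:, None, None]
    Y = gy[None, :, None]
    Z = gz[None, None, :]
    for c, s, w, sc in zip(centers, radii, weights, scales):
        out += w * np.exp(
            -(
                (X - c[0]) ** 2 / (sc[0] ** 2)
                + (Y - c[1]) ** 2 / (sc[1] ** 2)
                + (Z - c[2]) ** 2 / (sc[2] ** 2)
            )
            / (2.0 * s * s)
        )
    return out


def generate_sinus(params: SinusParams, seed: int) -> trimesh.Trimesh:
    """Build one watertight synthetic sinus mesh, deterministic per seed."""
    rng = np.random.default_rng(seed)
    if params.lobe_centers is None or params.lobe_radii is None:
        centers_r, radii_r, weights_r, scales_r = _draw_lobes(params, rng)
        params = replace(params, lobe_centers=centers_r, lobe_radii=radii_r,
                         lobe_weights=weights_r, lobe_scales=scales_r)
    else:
        centers_r = np.asarray(params.lobe_centers, dtype=float)
        radii_r = np.asarray(params.lobe_radii, dtype=float)
        weights_r = (np.ones(len(radii_r)) if params.lobe_weights is None
                     else np.asarray(params.lobe_weights, dtype=float))
        scales_r = (np.ones((len(radii_r), 3)) if params.lobe_scales is None
                    else np.asarray(params.lobe_scales, dtype=float))
    centers_l, radii_l, weights_l, scales_l = _mirror_with_asymmetry(
        centers_r, radii_r, weights_r, scales_r, params.left_right_asymmetry, rng
    )
    centers = np.vstack([centers_r, centers_l])
    radii = np.concatenate([radii_r, radii_l])
    weights = np.concatenate([weights_r, weights_l])
    scales = np.vstack([scales_r, scales_l])

    # grid covering every lobe out to 3.2 sigma, where the field is <2% of
    # the iso level: the isosurface cannot touch the boundary, so marching
    # cubes returns a closed surface
    margin = 3.2
    reach = margin * radii[:, None] * scales
    lo = (centers - reach).min(axis=0)
    hi = (centers + reach).max(axis=0)
    pitch = params.voxel_pitch
    axes = tuple(np.arange(lo[i] - pitch, hi[i] + 2 * pitch, pitch) for i in range(3))
    vol = _blob_field(axes, centers, radii, weights, scales)
    if vol.max() <= _ISO_LEVEL:
        raise ValueError("empty isosurface: lobes too small or too dispersed")
    verts, faces, _, _ = marching_cubes(vol, level=_ISO_LEVEL, spacing=(pitch, pitch, pitch))
    verts = verts + np.array([a[0] for a in axes])

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.fix_normals()

    # anisotropic rescale so breadth/height hit the subject's targets exactly;
    # the antero-posterior axis follows the mean factor, compressed to the
    # shallow depth typical of frontal sinuses
    ext = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    sx = params.target_breadth / ext[0]
    sz = params.target_height / ext[2]
    if params.target_depth is not None:
        sy = params.target_depth / ext[1]
    else:
        sy = params.depth_factor * np.sqrt(sx * sz)
    mesh.vertices = mesh.vertices * np.array([sx, sy, sz])
    mesh.vertices = mesh.vertices - mesh.vertices.mean(axis=0)
    return validate_mesh(mesh, require_watertight=True)


def _random_pose(rng: np.random.Generator, max_rot_deg: float, max_trans_mm: float) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_rot_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, max_trans_mm)
    return RigidTransform(R, t)


def resegment(mesh: trimesh.Trimesh, noise: NoiseModel, seed: int) -> trimesh.Trimesh:
    """Simulate an independent re-segmentation of the same anatomy.

    Optionally remeshes (midpoint subdivision for ratios above 1), displaces
    every vertex along its normal by white Gaussian noise, applies Laplacian
    smoothing, and jitters the pose. With a zero noise model the input is
    reproduced exactly.
    """
    if not mesh.is_watertight:
        raise ValueError("resegment requires a watertight input mesh")
    rng = np.random.default_rng(seed)
    out = mesh.copy()
    fraction = noise.remesh_fraction
    if fraction > 1.0:
        rounds = max(1, int(round(np.log(fraction) / np.log(4.0))))
        for _ in range(rounds):
            out = out.subdivide()
    elif fraction != 1.0 and fraction != 0.0:
        raise NotImplementedError(
            "remesh_fraction below 1 (decimation) is not supported; use 1 or powers of 4"
        )
    disp = np.zeros(len(out.vertices))
    if noise.surface_noise_sd > 0:
        disp += rng.normal(scale=noise.surface_noise_sd, size=len(out.vertices))
    if noise.threshold_offset_sd > 0:
        disp += rng.normal(scale=noise.threshold_offset_sd)
    if noise.patch_noise_sd > 0:
        verts = out.vertices.view(np.ndarray)
        n_patches = int(rng.integers(5, 10))
        # patches sit on the flat anterior/posterior tables, where the thin
        # bone lets region growing over- or under-fill; crease rims are spared
        normals = out.vertex_normals.view(np.ndarray)
        wall = np.flatnonzero(np.abs(normals[:, 1]) > 0.7)
        pool = wall if len(wall) >= n_patches else np.arange(len(verts))
        centers = verts[rng.choice(pool, size=n_patches)]
        for c in centers:
            radius = rng.uniform(5.0, 10.0)
            amp = rng.normal(scale=noise.patch_noise_sd)
            d2 = ((verts - c) ** 2).sum(axis=1)
            disp += amp * np.exp(-d2 / (2.0 * radius * radius))
    if np.any(disp != 0):
        out.vertices = out.vertices + disp[:, None] * out.vertex_normals
    if noise.crop_jitter_sd > 0:
        # shift the inferior border up/down with a weight decaying over the
        # lowermost few millimetres, leaving the rest of the surface alone
        z = out.vertices[:, 2]
        zmin = z.min()
        band = 8.0
        w = np.clip(1.0 - (z - zmin) / band, 0.0, 1.0) ** 2
        out.vertices = out.vertices + np.column_stack(
            [np.zeros_like(w), np.zeros_like(w), w * rng.normal(scale=noise.crop_jitter_sd)]
        )
    if noise.smoothing_iterations > 0:
        trimesh.smoothing.filter_laplacian(
            out,
            lamb=0.5,
            iterations=int(noise.smoothing_iterations),
            volume_constraint=True,
        )
    if noise.pose_rotation_deg > 0 or noise.pose_translation_mm > 0:
        pose = _random_pose(rng, noise.pose_rotation_deg, noise.pose_translation_mm)
        out = apply_transform(out, pose)
    if not out.is_watertight:
        import warnings

        warnings.warn("resegmented mesh lost watertightness (noise too large?)", stacklevel=2)
    return out


def random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random derangement of range(n) by rejection sampling."""
    if n < 2:
        raise ValueError("a derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


@dataclass
class Cohort:
    """A simulated study cohort: two segmentations per subject plus pairings."""

    sample1: list[trimesh.Trimesh]
    sample2: list[trimesh.Trimesh]
    match_pairs: list[tuple[int, int]]
    mismatch_pairs: list[tuple[int, int]]
    subject_seeds: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.uint32))

    @property
    def n_subjects(self) -> int:
        return len(self.sample1)


def make_cohort(
    n_subjects: int = 50,
    master_seed: int = 42,
    noise: NoiseModel | None = None,
    *,
    breadth_mean: float = 56.9,
    breadth_sd: float = 11.2,
    height_mean: float = 32.0,
    height_sd: float = 7.0,
    voxel_pitch: float = 1.0,
    base_params: SinusParams | None = None,
) -> Cohort:
    """Simulate the two-sample study cohort.

    sample1[i] and sample2[i] are two segmentations of subject i; match
    pairs are (i, i) and mismatch pairs follow a seeded random derangement,
    so no subject is ever paired with itself.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    noise = noise if noise is not None else NoiseModel()
    ss = np.random.SeedSequence(master_seed)
    subject_seeds = ss.generate_state(4 * n_subjects + 1) % (2**31)
    pairing_rng = np.random.default_rng(int(subject_seeds[-1]))

    template = base_params if base_params is not None else SinusParams()
    sample1: list[trimesh.Trimesh] = []
    sample2: list[trimesh.Trimesh] = []
    for i in range(n_subjects):
        s_draw, s_gen, s_seg1, s_seg2 = (int(s) for s in subject_seeds[4 * i : 4 * i + 4])
        draw_rng = np.random.default_rng(s_draw)
        tb = max(25.0, draw_rng.normal(breadth_mean, breadth_sd))
        th = max(12.0, draw_rng.normal(height_mean, height_sd))
        n_lobes = int(draw_rng.integers(2, 6))
        # individual antero-posterior depth and midline asymmetry:
        # size-matched subjects still differ in sagittal depth and lobe
        # layout, which is what keeps mismatch RMS away from the match range;
        # depth is drawn independently of breadth/height because sinus depth
        # does not scale with frontal size
        depth = float(np.clip(draw_rng.normal(10.6, 2.0), 6.5, 16.0))
        asym = float(draw_rng.uniform(0.10, 0.28))
        arc = float(np.clip(draw_rng.normal(80.0, 6.0), 62.0, 98.0))
        params = replace(
            template,
            n_lobes_per_side=n_lobes,
            lobe_centers=None,
            lobe_radii=None,
            left_right_asymmetry=asym,
            target_breadth=tb,
            target_height=th,
            target_depth=depth,
            arc_radius_mm=arc,
            voxel_pitch=voxel_pitch,
        )
        # both samples are independent re-segmentations of the same anatomy,
        # so the two segmentation processes are exchangeable — as they are
        # when one CT scan is segmented twice
        base = generate_sinus(params, s_gen)
        sample1.append(resegment(base, noise, s_seg1))
        sample2.append(resegment(base, noise, s_seg2))

    perm = random_derangement(n_subjects, pairing_rng)
    return Cohort(
        sample1=sample1,
        sample2=sample2,
        match_pairs=[(i, i) for i in range(n_subjects)],
        mismatch_pairs=[(i, int(perm[i])) for i in range(n_subjects)],
        subject_seeds=subject_seeds[:-1],
    )
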