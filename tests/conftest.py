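"""Shared fixtures: canonical solids and small synthetic sinus pairs."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from sinusid.synthetic import NoiseModel, SinusParams, generate_sinus, resegment


@pytest.fixture
def cube10():
    """Axis-aligned cube with 10 mm edges centered at the origin."""
    return trimesh.creation.box(extents=(10.0, 10.0, 10.0))


@pytest.fixture
def icosphere():
    """Subdivision-4 icosphere, radius chosen so the ball volume is 8 cm^3."""
    return trimesh.creation.icosphere(subdivisions=4, radius=12.407)


@pytest.fixture(scope="session")
def sinus_pair():
    """One synthetic sinus and its simulated re-segmentation (default noise)."""
    base = generate_sinus(SinusParams(), seed=11)
    seg1 = resegment(base, NoiseModel(), seed=21)
    seg2 = resegment(base, NoiseModel(), seed=22)
    return seg1, seg2


@pytest.fixture(scope="session")
def sinus_mismatch_pair():
    """Two sinuses from different synthetic subjects."""
    m1 = generate_sinus(SinusParams(), seed=31)
    m2 = generate_sinus(SinusParams(), seed=77)
    return m1, m2


def parity_voxel_volume_cm3(mesh: trimesh.Trimesh, pitch: float = 0.1) -> float:
    """Voxel-counting volume oracle by z-ray parity.

    For every (x, y) grid column, intersect the vertical ray with all
    triangles; voxel centers between consecutive crossing pairs are inside.
    Independent of both the divergence-theorem volume and the closest-point
    engine. Grid origin offsets are irrational fractions of the pitch so
    rays avoid edges and vertices.
    """
    tri = mesh.triangles.view(np.ndarray)
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    xs = np.arange(lo[0] + 0.5137 * pitch, hi[0], pitch)
    ys = np.arange(lo[1] + 0.5411 * pitch, hi[1], pitch)
    zs = np.arange(lo[2] + 0.5261 * pitch, hi[2], pitch)
    ny = len(ys)

    col_ids = []
    z_hits = []
    for a, b, c in tri:
        det = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
        if det == 0.0:  # vertical triangle: zero projected area, ray-tangent
            continue
        i0 = np.searchsorted(xs, min(a[0], b[0], c[0]))
        i1 = np.searchsorted(xs, max(a[0], b[0], c[0]))
        j0 = np.searchsorted(ys, min(a[1], b[1], c[1]))
        j1 = np.searchsorted(ys, max(a[1], b[1], c[1]))
        if i0 == i1 or j0 == j1:
            continue
        X, Y = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        v = ((X - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (Y - a[1])) / det
        w = ((b[0] - a[0]) * (Y - a[1]) - (X - a[0]) * (b[1] - a[1])) / det
        u = 1.0 - v - w
        inside = (u >= 0) & (v >= 0) & (w >= 0)
        if not inside.any():
            continue
        z = u * a[2] + v * b[2] + w * c[2]
        I, J = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        col_ids.append((I * ny + J)[inside])
        z_hits.append(z[inside])

    cols = np.concatenate(col_ids)
    hits = np.concatenate(z_hits)
    order = np.lexsort((hits, cols))
    cols = cols[order]
    hits = hits[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cols) > 0])
    ends = np.r_[starts[1:], len(cols)]
    inside_count = 0
    for s, e in zip(starts, ends):
        crossings = hits[s:e]
        for k in range(0, len(crossings) - 1, 2):
            inside_count += int(
                np.searchsorted(zs, crossings[k + 1]) - np.searchsorted(zs, crossings[k])
            )
    return inside_count * pitch**3 / 1000.0


def make_random_rigid(seed: int, max_angle=np.pi / 6, max_trans=20.0):
    """Random proper rigid transform (Rodrigues rotation + translation)."""
    from sinusid.registration import RigidTransform

    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, max_angle)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, rng.uniform(-max_trans, max_trans, size=3))


def random_blob_mesh(seed: int, n_sub: int = 2) -> trimesh.Trimesh:
    """Small random closed mesh (a few hundred faces) for oracle tests."""
    rng = np.random.default_rng(seed)
    mesh = trimesh.creation.icosphere(subdivisions=n_sub, radius=10.0)
    verts = mesh.vertices.view(np.ndarray).copy()
    # low-order harmonics keep the surface smooth and self-intersection free
    for _ in range(3):
        k = rng.normal(scale=0.15, size=3)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.5)
        verts += (
            amp
            * np.sin(verts @ k + phase)[:, None]
            * (verts / np.linalg.norm(verts, axis=1, keepdims=True))
        )
    out = trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
    return out
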