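"""Percent buried volume (%V_Bur), quadrant decomposition, and steric maps.

The buried volume of a ligand is the fraction of a probe sphere — radius
3.5 Å, centred 2.0 Å from the donor nitrogen along the (real or would-be)
metal–N axis — that falls inside the ligand's scaled van der Waals envelope.
It is evaluated on a cubic voxel grid of spacing ``mesh`` (0.1 Å by default)
aligned with the frame axes: a voxel belongs to the sphere iff its *centre*
is within the sphere radius of the origin, and is buried iff that centre also
lies within ``scale * r_vdw`` of any included atom.  No partial-volume
weighting is applied; the mesh-convergence tests bound the resulting error.

The equatorial (xy) plane splits the sphere into four quadrants named by the
signs of (x, y): NE (+,+), NW (−,+), SW (−,−), SE (+,−).  Voxel centres that
fall exactly on a quadrant boundary (possible only for meshes that do not
divide the sphere diameter evenly) are assigned to the positive side.  Total
%V_Bur is invariant to rotations about z; quadrant values are not, so the
x-axis convention of the frame matters for them.

A Monte-Carlo estimator over the same geometric predicate — but with an
entirely different sampling scheme — serves as an independent oracle, and
:func:`compute_steric_map` produces the topographic steric map: for every xy
grid column, the height (Å, relative to the frame origin) of the topmost
buried voxel, i.e. the ligand's surface as seen from the metal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .frame import SphereFrame, build_amine_frame
from .structure import RadiiTable, Structure

__all__ = [
    "BuriedVolumeResult",
    "StericMap",
    "compute_buried_volume",
    "monte_carlo_buried_volume",
    "compute_steric_map",
    "resolve_free_amine_frame",
]

QUADRANT_NAMES = ("NE", "NW", "SW", "SE")


@dataclass(frozen=True)
class BuriedVolumeResult:
    """Total and per-quadrant %V_Bur plus the voxel bookkeeping behind them."""

    total_pct: float
    quadrant_pct: tuple[float, float, float, float]  # NE, NW, SW, SE
    buried_voxels: int
    sphere_voxels: int
    mesh: float
    frame: SphereFrame
    included_atoms: tuple[int, ...]

    @property
    def low_pct(self) -> float:
        """%V_Bur of the least occupied quadrant."""
        return min(self.quadrant_pct)

    @property
    def high_pct(self) -> float:
        """%V_Bur of the most occupied quadrant."""
        return max(self.quadrant_pct)

    def as_dict(self) -> dict:
        d = {
            "total_pct": self.total_pct,
            "low_pct": self.low_pct,
            "high_pct": self.high_pct,
            "buried_voxels": self.buried_voxels,
            "sphere_voxels": self.sphere_voxels,
            "mesh": self.mesh,
            "radius": self.frame.radius,
            "offset": self.frame.offset,
            "included_atoms": list(self.included_atoms),
        }
        for name, q in zip(QUADRANT_NAMES, self.quadrant_pct):
            d[f"quadrant_{name}_pct"] = q
        return d


@dataclass(frozen=True)
class StericMap:
    """Topographic steric map over the equatorial disc of the probe sphere.

    ``z_top[i, j]`` is the height (Å, frame coordinates) of the highest buried
    voxel centre in the column at ``(x[i], y[j])``; columns with no buried
    voxel carry the sentinel ``-radius``.
    """

    x: np.ndarray
    y: np.ndarray
    z_top: np.ndarray
    mesh: float
    frame: SphereFrame
    column_buried_counts: np.ndarray = field(repr=False, default=None)

    @property
    def sentinel(self) -> float:
        return -self.frame.radius

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form (x, y, z_top) table, one row per grid column in the disc."""
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        inside = xx**2 + yy**2 <= self.frame.radius**2
        return pd.DataFrame(
            {"x": xx[inside], "y": yy[inside], "z_top": self.z_top[inside]}
        )

    def plot(self, ax=None, levels: int = 12):
        """Filled-contour rendering of the map (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        masked = np.ma.masked_where(
            self.x[:, None] ** 2 + self.y[None, :] ** 2 > self.frame.radius**2,
            self.z_top,
        )
        cs = ax.contourf(self.x, self.y, masked.T, levels=levels)
        ax.set_aspect("equal")
        ax.set_xlabel("x / Å")
        ax.set_ylabel("y / Å")
        return cs


def _grid_1d(radius: float, mesh: float) -> np.ndarray:
    """Voxel-centre coordinates along one axis: (k + 0.5) * mesh − radius."""
    n = int(math.ceil(2 * radius / mesh - 1e-9))
    return (np.arange(n) + 0.5) * mesh - radius


def _resolve_included(
    structure: Structure,
    include_indices: Sequence[int] | None,
    exclude_indices: Sequence[int],
) -> list[int]:
    excluded = set(exclude_indices)
    if include_indices is None:
        idx = [i for i in range(len(structure)) if i not in excluded]
    else:
        idx = [i for i in include_indices if i not in excluded]
    if not idx:
        raise ValueError("no atoms left to include in the buried-volume computation")
    return idx


def _burial_mask(
    centers: np.ndarray,
    structure: Structure,
    frame: SphereFrame,
    radii: RadiiTable,
    included: Sequence[int],
) -> np.ndarray:
    """Boolean mask over frame-coordinate ``centers`` inside any scaled atom sphere."""
    buried = np.zeros(len(centers), dtype=bool)
    R = frame.radius
    for i in included:
        atom = structure.atoms[i]
        r = radii.vdw_scaled(atom.element)
        p = frame.to_frame(atom.position)
        if np.linalg.norm(p) > R + r:
            continue  # cannot intersect the probe sphere
        d2 = ((centers - p) ** 2).sum(axis=1)
        buried |= d2 <= r * r
    return buried


def _voxelize(
    structure: Structure,
    frame: SphereFrame,
    radii: RadiiTable,
    mesh: float,
    included: Sequence[int],
):
    """Shared voxel pass: grid axes, sphere mask and burial mask (3D)."""
    if mesh <= 0:
        raise ValueError(f"mesh must be positive, got {mesh}")
    if mesh > frame.radius:
        raise ValueError(f"mesh {mesh} exceeds sphere radius {frame.radius}")
    ax = _grid_1d(frame.radius, mesh)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    sphere = (centers**2).sum(axis=1) <= frame.radius**2
    buried = np.zeros(len(centers), dtype=bool)
    buried[sphere] = _burial_mask(centers[sphere], structure, frame, radii, included)
    shape = (len(ax),) * 3
    return ax, sphere.reshape(shape), buried.reshape(shape)


def compute_buried_volume(
    structure: Structure,
    frame: SphereFrame,
    radii: RadiiTable | None = None,
    mesh: float = 0.1,
    include_indices: Sequence[int] | None = None,
    exclude_indices: Sequence[int] = (),
) -> BuriedVolumeResult:
    """Voxel-grid %V_Bur with quadrant decomposition.

    ``include_indices`` defaults to every atom of ``structure``; metal and
    other non-ligand atoms should be passed via ``exclude_indices`` (or the
    include list restricted to the ligand).
    """
    radii = radii or RadiiTable.default()
    included = _resolve_included(structure, include_indices, exclude_indices)
    ax, sphere, buried = _voxelize(structure, frame, radii, mesh, included)

    sphere_count = int(sphere.sum())
    buried_count = int(buried.sum())
    total_pct = 100.0 * buried_count / sphere_count

    # quadrants by sign of (x, y); exact zeros go to the positive side
    pos_x = ax >= 0
    pos_y = ax >= 0
    quads = []
    for qname in QUADRANT_NAMES:
        mx = pos_x if qname in ("NE", "SE") else ~pos_x
        my = pos_y if qname in ("NE", "NW") else ~pos_y
        sel = np.ix_(np.where(mx)[0], np.where(my)[0], np.arange(len(ax)))
        qs = int(sphere[sel].sum())
        qb = int(buried[sel].sum())
        quads.append(100.0 * qb / qs if qs else 0.0)

    return BuriedVolumeResult(
        total_pct=total_pct,
        quadrant_pct=tuple(quads),
        buried_voxels=buried_count,
        sphere_voxels=sphere_count,
        mesh=mesh,
        frame=frame,
        included_atoms=tuple(included),
    )


def monte_carlo_buried_volume(
    structure: Structure | None,
    frame: SphereFrame,
    radii: RadiiTable | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
    include_indices: Sequence[int] | None = None,
    exclude_indices: Sequence[int] = (),
) -> tuple[float, float]:
    """Monte-Carlo %V_Bur estimate with its standard error (both in %).

    Samples points uniformly in the probe sphere by drawing an isotropic
    direction and a radius proportional to the cube root of a uniform
    variate — a code path fully independent of the voxel grid.  ``structure``
    may be None (an empty sphere), returning exactly (0.0, 0.0).
    """
    if n_samples < 10_000:
        raise ValueError(f"n_samples must be >= 10000 for a usable SE, got {n_samples}")
    if structure is None:
        return 0.0, 0.0
    radii = radii or RadiiTable.default()
    included = _resolve_included(structure, include_indices, exclude_indices)

    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = frame.radius * np.cbrt(rng.uniform(size=n_samples))
    pts = v * r[:, None]

    hit = _burial_mask(pts, structure, frame, radii, included)
    p = hit.mean()
    se = math.sqrt(p * (1.0 - p) / n_samples)
    return 100.0 * p, 100.0 * se


def compute_steric_map(
    structure: Structure,
    frame: SphereFrame,
    radii: RadiiTable | None = None,
    mesh: float = 0.1,
    include_indices: Sequence[int] | None = None,
    exclude_indices: Sequence[int] = (),
) -> StericMap:
    """Topographic steric map over the same voxel grid as the %V_Bur scan.

    Summing :attr:`StericMap.column_buried_counts` reproduces the buried-voxel
    count of :func:`compute_buried_volume` exactly (identical voxelisation).
    """
    radii = radii or RadiiTable.default()
    included = _resolve_included(structure, include_indices, exclude_indices)
    ax, sphere, buried = _voxelize(structure, frame, radii, mesh, included)

    z_top = np.full((len(ax), len(ax)), -frame.radius, dtype=float)
    any_buried = buried.any(axis=2)
    # index of the topmost buried voxel per column (argmax on reversed z)
    top_idx = len(ax) - 1 - np.argmax(buried[:, :, ::-1], axis=2)
    z_top[any_buried] = ax[top_idx[any_buried]]
    counts = buried.sum(axis=2)
    return StericMap(
        x=ax, y=ax, z_top=z_top, mesh=mesh, frame=frame, column_buried_counts=counts
    )


def resolve_free_amine_frame(
    structure: Structure,
    n_index: int,
    radii: RadiiTable | None = None,
    mesh: float = 0.1,
    planar_tol: float = 1e-3,
    **frame_kwargs,
) -> SphereFrame:
    """Frame for a free amine, resolving the near-planar face ambiguity.

    For a clearly pyramidal nitrogen this is :func:`build_amine_frame`.  When
    the nitrogen is within ``planar_tol`` Å of its substituent plane the two
    faces are geometrically equivalent candidates; following the physical
    argument that a metal binds the less hindered face, both are evaluated and
    the one with the smaller total %V_Bur is returned.
    """
    import warnings as _warnings

    radii = radii or RadiiTable.default()
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        frame = build_amine_frame(
            structure, n_index, metal_index=None, radii=radii,
            planar_tol=planar_tol, **frame_kwargs,
        )
    ill_posed = any("face choice is arbitrary" in str(w.message) for w in caught)
    if not ill_posed:
        return frame
    other = frame.flipped()
    v1 = compute_buried_volume(structure, frame, radii, mesh=mesh).total_pct
    v2 = compute_buried_volume(structure, other, radii, mesh=mesh).total_pct
    return frame if v1 <= v2 else other
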