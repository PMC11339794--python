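"""Reference frames for buried-volume and steric-map computations.

Every steric computation in this package runs inside a :class:`SphereFrame`:
a right-handed orthonormal coordinate system whose origin sits where a metal
would bind — on the z axis, ``offset`` Å (2.0 by default) from the donor
nitrogen — and whose xy plane is parallel to the best plane through the three
nitrogen substituents.  The sphere of radius ``radius`` (3.5 Å by default)
around that origin is the region probed for buried volume.

For an amine–metal complex the z axis points from N toward the metal.  For a
free amine it is the substituent-plane normal pointing away from the
substituents, i.e. toward the side where a metal would coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .structure import RadiiTable, Structure, neighbors

__all__ = ["SphereFrame", "fit_plane", "build_amine_frame", "NearPlanarAmineWarning"]

_ORTHO_TOL = 1e-8


class NearPlanarAmineWarning(UserWarning):
    """The free-amine face choice is numerically ill-posed (nearly planar N)."""


@dataclass(frozen=True)
class SphereFrame:
    """Origin + right-handed orthonormal axes + sphere radius and N offset.

    ``origin`` lies at ``n_position + offset * z_axis``; all quantities in Å.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    radius: float = 3.5
    offset: float = 2.0

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        x, y, z = self.x_axis, self.y_axis, self.z_axis
        for name, v in (("x_axis", x), ("y_axis", y), ("z_axis", z)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} is not unit length: |{name}| = {np.linalg.norm(v)}")
        if max(abs(x @ y), abs(y @ z), abs(z @ x)) > 1e-6:
            raise ValueError("frame axes are not mutually orthogonal")
        if np.linalg.norm(np.cross(x, y) - z) > 1e-6:
            raise ValueError("frame axes are not right-handed (x × y must equal z)")
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are the frame axes (world -> frame)."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates to frame coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.rotation.T
        return out[0] if np.asarray(points).ndim == 1 else out

    def to_world(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation + self.origin
        return out[0] if np.asarray(points).ndim == 1 else out

    def flipped(self) -> "SphereFrame":
        """Frame mirrored through the substituent plane (z -> −z, y -> −y).

        Origin moves to the opposite side of the nitrogen; handedness is kept.
        """
        n_pos = self.origin - self.offset * self.z_axis
        return replace(
            self,
            origin=n_pos - self.offset * self.z_axis,
            z_axis=-self.z_axis,
            y_axis=-self.y_axis,
        )


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through ``points`` (>= 3, not collinear).

    Returns ``(normal, centroid)`` with a unit normal.  For exactly three
    points this is the exact plane; for more it minimises the sum of squared
    perpendicular distances (smallest principal axis of the centred points).
    The sign of the normal is arbitrary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError(f"need >= 3 points of dimension 3, got shape {pts.shape}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    # collinear (or coincident) points: two vanishing principal components
    scale = max(evals[-1], 1.0)
    if evals[1] <= 1e-12 * scale:
        raise ValueError("points are collinear or coincident; plane is undefined")
    normal = evecs[:, 0]
    return normal / np.linalg.norm(normal), centroid


def build_amine_frame(
    structure: Structure,
    n_index: int,
    metal_index: int | None = None,
    radii: RadiiTable | None = None,
    offset: float = 2.0,
    radius: float = 3.5,
    x_ref_index: int | None = None,
    neighbor_tolerance: float = 0.4,
    planar_tol: float = 1e-3,
) -> SphereFrame:
    """Build the steric reference frame for a trisubstituted nitrogen.

    The nitrogen at ``n_index`` must have exactly three bonded non-metal
    neighbours (``metal_index`` is excluded from the three; for an ammonium
    pass the acidic proton's index as ``metal_index`` so the frame points
    along the N–H+ axis).  The z axis is normal to the best plane of those
    three substituents, signed toward the metal when one is given and
    otherwise away from the substituent centroid.  The x axis is the unit
    projection of (first substituent − N) onto the plane perpendicular to z;
    ``x_ref_index`` overrides which substituent anchors it.

    When no metal is given and the nitrogen sits within ``planar_tol`` Å of
    the substituent plane, the face choice is ill-posed: a
    :class:`NearPlanarAmineWarning` is emitted and the +normal side is
    returned (see :func:`amsteric.buried.resolve_free_amine_frame` for the
    both-sides resolution that picks the less hindered face).
    """
    radii = radii or RadiiTable.default()
    nbrs = [
        j
        for j in neighbors(structure, n_index, radii, neighbor_tolerance)
        if j != metal_index
    ]
    if len(nbrs) != 3:
        raise ValueError(
            f"atom {n_index} ({structure.atoms[n_index].element}) has {len(nbrs)} "
            "eligible bonded neighbours; the frame needs exactly 3 (metal excluded)"
        )
    n_pos = structure.atoms[n_index].position
    sub_pos = structure.positions[nbrs]
    normal, centroid = fit_plane(sub_pos)

    if metal_index is not None:
        toward = structure.atoms[metal_index].position - n_pos
        if normal @ toward < 0:
            normal = -normal
    else:
        h = normal @ (n_pos - centroid)
        if abs(h) < planar_tol:
            warnings.warn(
                f"nitrogen {n_index} is within {planar_tol} Å of its substituent "
                "plane; the free-amine face choice is arbitrary (+normal side used)",
                NearPlanarAmineWarning,
                stacklevel=2,
            )
        elif h < 0:
            normal = -normal

    z = normal
    ref = x_ref_index if x_ref_index is not None else nbrs[0]
    v = structure.atoms[ref].position - n_pos
    x = v - (v @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-10:
        raise ValueError(
            f"x reference atom {ref} is collinear with the z axis; pick another"
        )
    x = x / nx
    y = np.cross(z, x)
    return SphereFrame(
        origin=n_pos + offset * z,
        x_axis=x,
        y_axis=y,
        z_axis=z,
        radius=radius,
        offset=offset,
    )
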