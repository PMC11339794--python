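"""Nitrogen pyramidalization: how far a 3-coordinate N deviates from planarity.

The default (and "ra-1989") strategy reports the perpendicular distance, in Å,
of the nitrogen from the plane through its three bonded substituents: exactly
0 for a planar nitrogen (e.g. pyridine), about 0.38 Å for ammonia and about
0.45 Å for an ideal sp3 trialkylamine — which is why 0.450 Å marks the
boundary between "pyramidal" and "flattened" amines in this package's
screening filters.  An "angle-defect" strategy (360° minus the sum of the
three substituent angles, in degrees) is available for comparison; it shares
the contract: zero for planar nitrogens, monotone in out-of-plane
displacement, invariant under rigid motions and substituent relabeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .frame import fit_plane
from .structure import RadiiTable, Structure, neighbors

__all__ = ["PyramidalizationResult", "pyramidalization", "STRATEGIES"]


def _oop_distance(n_pos: np.ndarray, sub_pos: np.ndarray) -> float:
    normal, centroid = fit_plane(sub_pos)
    return abs(float(normal @ (n_pos - centroid)))


def _angle_defect(n_pos: np.ndarray, sub_pos: np.ndarray) -> float:
    vecs = sub_pos - n_pos
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    pairs = [(0, 1), (1, 2), (2, 0)]
    total = sum(
        math.degrees(math.acos(float(np.clip(vecs[i] @ vecs[j], -1.0, 1.0))))
        for i, j in pairs
    )
    return max(0.0, 360.0 - total)


#: strategy label -> f(n_position, substituent_positions (3,3)) -> index
STRATEGIES: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "oop-distance": _oop_distance,
    # Height-based pyramidality in Å; see docs/methods.md for the basis of
    # identifying this with the index used in the hindered-amine literature.
    "ra-1989": _oop_distance,
    "angle-defect": _angle_defect,
}


@dataclass(frozen=True)
class PyramidalizationResult:
    """Pyramidalization index of one nitrogen (Å for the height strategies)."""

    index: float
    n_index: int
    substituent_indices: tuple[int, int, int]
    strategy: str


def pyramidalization(
    structure: Structure,
    n_index: int,
    strategy: str = "oop-distance",
    radii: RadiiTable | None = None,
    metal_index: int | None = None,
    neighbor_tolerance: float = 0.4,
) -> PyramidalizationResult:
    """Pyramidalization index of the nitrogen at ``n_index``.

    The nitrogen must have exactly three bonded neighbours once
    ``metal_index`` (a coordinated metal, or the acidic proton of an
    ammonium) is excluded.
    """
    try:
        func = STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; available: {sorted(STRATEGIES)}"
        ) from None
    radii = radii or RadiiTable.default()
    nbrs = [
        j
        for j in neighbors(structure, n_index, radii, neighbor_tolerance)
        if j != metal_index
    ]
    if len(nbrs) != 3:
        raise ValueError(
            f"atom {n_index} has {len(nbrs)} eligible bonded neighbours; "
            "pyramidalization needs exactly 3 (metal excluded)"
        )
    n_pos = structure.atoms[n_index].position
    sub_pos = structure.positions[nbrs]
    value = func(n_pos, sub_pos)
    if value < 1e-8:
        value = 0.0
    return PyramidalizationResult(
        index=value,
        n_index=n_index,
        substituent_indices=tuple(sorted(nbrs)),
        strategy=strategy,
    )
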