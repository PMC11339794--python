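"""Synthetic amine geometries and descriptor tables with known ground truth.

Two generators make every stage of the pipeline testable without any
external download:

* :func:`build_amine` constructs an idealized NR3 geometry of tunable bulk
  (substituent templates H, Me, Et, iPr, tBu, Ad) and tunable pyramidality
  (the nitrogen sits ``pyramid_height`` Å above the plane of its three
  substituent anchors, so the default pyramidalization index is known *by
  construction*).  Substituent internals use idealized sp3 geometry
  (109.47°, C–C 1.54 Å, C–H 1.09 Å); realism beyond steric bulk is not a
  goal.  The template series spans the buried-volume range of real amines,
  from ammonia-like (~15%) to extremely hindered (~70%).

* :func:`simulate_table` draws descriptor tables with a planted linear
  response model, Gaussian noise and missing cells, mirroring the structure
  (columns, value ranges, gaps) of the bundled reference table, and returns
  the generating truth alongside the records.

Both are fully deterministic given their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Atom, Structure

__all__ = [
    "AmineSpec",
    "TableSpec",
    "build_amine",
    "simulate_table",
    "sp3_height",
    "ideal_pyridine",
    "SUBSTITUENT_TEMPLATES",
]

SUBSTITUENT_TEMPLATES = ("H", "Me", "Et", "iPr", "tBu", "Ad")

_CC = 1.54
_CH = 1.09
_TET_COS = -1.0 / 3.0  # cos(109.47°)
_MIN_CLASH = 0.8


def sp3_height(bond: float, angle_deg: float) -> float:
    """Out-of-plane height of the apex X of an XY3 pyramid.

    ``bond`` is the X–Y distance and ``angle_deg`` the Y–X–Y angle; e.g.
    ammonia (N–H 1.012 Å, 106.7°) gives ≈ 0.381 Å.
    """
    half = math.radians(angle_deg) / 2.0
    circumradius = 2.0 * bond * math.sin(half) / math.sqrt(3.0)
    h2 = bond * bond - circumradius * circumradius
    if h2 < 0:
        raise ValueError(f"angle {angle_deg}° is wider than a planar XY3 allows")
    return math.sqrt(h2)


@dataclass(frozen=True)
class AmineSpec:
    """Recipe for one idealized NR3 geometry.

    ``pyramid_height`` is the N height above the substituent-anchor plane in
    Å (0 = planar); ``cn_bond`` the N–anchor distance (N–C for carbon
    substituents, N–H when the template is H).  ``azimuths`` rotate each
    substituent's internal geometry about its N–anchor axis (0° tilts the
    heavy branch toward the lone-pair side); the 15° default is a slight
    propeller gearing that avoids eclipsed inter-substituent contacts.
    """

    substituents: tuple[str, str, str] = ("Me", "Me", "Me")
    pyramid_height: float = 0.45
    cn_bond: float = 1.47
    seed: int = 0
    azimuths: tuple[float, float, float] = (15.0, 15.0, 15.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "substituents", tuple(self.substituents))
        if len(self.substituents) != 3:
            raise ValueError("exactly three substituents required")
        unknown = [s for s in self.substituents if s not in SUBSTITUENT_TEMPLATES]
        if unknown:
            raise ValueError(
                f"unknown substituent templates {unknown}; "
                f"available: {SUBSTITUENT_TEMPLATES}"
            )
        if self.pyramid_height < 0:
            raise ValueError("pyramid_height must be >= 0")
        if self.pyramid_height >= self.cn_bond:
            raise ValueError("pyramid_height must be smaller than cn_bond")


def _perp_basis(axis: np.ndarray, up: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (u, v) perpendicular to ``axis``, u along the projection of
    ``up`` (fallback to an arbitrary perpendicular when parallel)."""
    u = up - (up @ axis) * axis
    norm = np.linalg.norm(u)
    if norm < 1e-8:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(axis @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ axis) * axis
        norm = np.linalg.norm(u)
    u = u / norm
    v = np.cross(axis, u)
    return u, v


def _tetrahedral_dirs(back: np.ndarray, azimuth_deg: float, up: np.ndarray) -> np.ndarray:
    """Three unit vectors at 109.47° from ``back`` (the bond to the already
    placed neighbour), azimuth measured from the projection of ``up``."""
    u, v = _perp_basis(back, up)
    sin_t = math.sqrt(1.0 - _TET_COS * _TET_COS)
    dirs = []
    for k in range(3):
        phi = math.radians(azimuth_deg + 120.0 * k)
        d = _TET_COS * back + sin_t * (math.cos(phi) * u + math.sin(phi) * v)
        dirs.append(d / np.linalg.norm(d))
    return np.array(dirs)


def _methyl(center: np.ndarray, back: np.ndarray, az: float, up: np.ndarray) -> list[Atom]:
    return [Atom("H", center + _CH * d) for d in _tetrahedral_dirs(back, az, up)]


# heavy branches per template: (azimuth offset from the substituent azimuth,
# branch kind).  0° tilts the branch toward the lone-pair (+z) side.  The
# branch sets are nested (Et ⊂ iPr ⊂ tBu ⊂ Ad as point sets, since a carbon
# branch's sphere contains the hydrogen sphere it replaces), so the buried
# volume of the series is strictly increasing by construction wherever each
# added branch reaches the probe sphere.
_BRANCH_OFFSETS = {
    "Et": ((0.0, "methyl"),),
    "iPr": ((0.0, "methyl"), (120.0, "methyl")),
    "tBu": ((0.0, "methyl"), (120.0, "methyl"), (240.0, "methyl")),
    "Ad": ((0.0, "ethyl_arm"), (120.0, "methyl"), (240.0, "methyl")),
}


def _tet_dir(back: np.ndarray, azimuth_deg: float, up: np.ndarray) -> np.ndarray:
    return _tetrahedral_dirs(back, azimuth_deg, up)[0]


def _grow_substituent(
    label: str, anchor: np.ndarray, n_pos: np.ndarray, az: float, up: np.ndarray
) -> list[Atom]:
    """Atoms of one substituent (anchor atom first), idealized sp3 internals."""
    if label == "H":
        return [Atom("H", anchor)]
    back = n_pos - anchor
    back = back / np.linalg.norm(back)
    atoms = [Atom("C", anchor)]

    def branch(direction: np.ndarray, kind: str) -> None:
        c = anchor + _CC * direction
        atoms.append(Atom("C", c))
        b = -direction
        if kind == "methyl":
            atoms.extend(_methyl(c, b, 60.0, up))
        elif kind == "ethyl_arm":  # CH2 continuing into a terminal methyl
            sub = _tetrahedral_dirs(b, 60.0, up)
            c2 = c + _CC * sub[0]
            atoms.append(Atom("C", c2))
            atoms.extend(Atom("H", c + _CH * d) for d in sub[1:])
            atoms.extend(_methyl(c2, -sub[0] / np.linalg.norm(sub[0]), 0.0, up))

    if label == "Me":
        atoms.extend(Atom("H", anchor + _CH * d) for d in _tetrahedral_dirs(back, az, up))
        return atoms

    branches = _BRANCH_OFFSETS[label]
    for off, kind in branches:
        branch(_tet_dir(back, az + off, up), kind)
    # fill the remaining tetrahedral valences with hydrogens
    used = {off for off, _ in branches}
    for off in (0.0, 120.0, 240.0):
        if off not in used:
            atoms.append(Atom("H", anchor + _CH * _tet_dir(back, az + off, up)))
    return atoms


def build_amine(spec: AmineSpec) -> Structure:
    """Construct the idealized NR3 geometry described by ``spec``.

    The nitrogen sits at (0, 0, pyramid_height) with the three substituent
    anchors placed 3-fold-symmetrically in the z = 0 plane at N–anchor
    distance ``cn_bond``; +z is the lone-pair (metal-binding) side.  Raises
    when atoms of different substituents come within 0.8 Å (sterically
    impossible combination: use smaller templates, a longer cn_bond or a
    smaller pyramid_height).
    """
    h = spec.pyramid_height
    rho = math.sqrt(spec.cn_bond**2 - h * h)
    n_pos = np.array([0.0, 0.0, h])
    up = np.array([0.0, 0.0, 1.0])

    groups: list[list[Atom]] = []
    for k, (label, az) in enumerate(zip(spec.substituents, spec.azimuths)):
        theta = math.radians(120.0 * k)
        anchor = np.array([rho * math.cos(theta), rho * math.sin(theta), 0.0])
        groups.append(_grow_substituent(label, anchor, n_pos, az, up))

    # inter-substituent clash guard (0.8 Å)
    for a in range(3):
        for b in range(a + 1, 3):
            pa = np.array([at.position for at in groups[a]])
            pb = np.array([at.position for at in groups[b]])
            d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
            if d.min() < _MIN_CLASH:
                raise ValueError(
                    f"substituents {spec.substituents[a]!r} and "
                    f"{spec.substituents[b]!r} clash ({d.min():.2f} Å apart); "
                    "use smaller templates, a longer cn_bond, or less pyramid_height"
                )

    atoms = [Atom("N", n_pos)]
    for g in groups:
        atoms.extend(g)
    name = f"N({','.join(spec.substituents)})_h{h:.3f}"
    return Structure(name, atoms)


def ideal_pyridine() -> Structure:
    """Idealized planar pyridine (C2v) from standard ring parameters.

    Bond lengths N–C 1.338, C2–C3 1.394, C3–C4 1.392, C–H 1.08 Å; ring
    angles 116.9° (at N), 123.8°, 118.5°, 118.4°.  The nitrogen is at the
    origin with the ring extending along −y, so the lone pair points along
    +y and the ring lies in the z = 0 plane.
    """
    cnc, ncc, ccc = 116.9, 123.8, 118.5

    def rot(p: np.ndarray, deg: float) -> np.ndarray:
        a = math.radians(deg)
        return np.array(
            [math.cos(a) * p[0] - math.sin(a) * p[1],
             math.sin(a) * p[0] + math.cos(a) * p[1]]
        )

    n = np.zeros(2)
    # C2 at half the N angle off the −y axis (ring extends downward, +x side)
    c2 = 1.338 * rot(np.array([0.0, -1.0]), -cnc / 2.0)
    d_n = (n - c2) / np.linalg.norm(n - c2)
    cands = [c2 + 1.394 * rot(d_n, s * ncc) for s in (+1, -1)]
    c3 = min(cands, key=lambda p: p[1])  # continue downward around the ring
    d_c2 = (c2 - c3) / np.linalg.norm(c2 - c3)
    cands = [c3 + 1.392 * rot(d_c2, s * ccc) for s in (+1, -1)]
    c4 = min(cands, key=lambda p: abs(p[0]))  # closes on the symmetry axis
    c5, c6 = np.array([-c3[0], c3[1]]), np.array([-c2[0], c2[1]])

    ring = [("N", n), ("C", c2), ("C", c3), ("C", c4), ("C", c5), ("C", c6)]
    atoms = [Atom(el, np.array([p[0], p[1], 0.0])) for el, p in ring]
    for i in range(1, 6):  # a hydrogen on every carbon, along the outer bisector
        prev_p = ring[i - 1][1]
        next_p = ring[(i + 1) % 6][1]
        c = ring[i][1]
        bis = (prev_p - c) / np.linalg.norm(prev_p - c) + (next_p - c) / np.linalg.norm(next_p - c)
        out = -bis / np.linalg.norm(bis)
        hp = c + 1.08 * out
        atoms.append(Atom("H", np.array([hp[0], hp[1], 0.0])))
    return Structure("pyridine_ideal", atoms)


@dataclass(frozen=True)
class TableSpec:
    """Recipe for a synthetic descriptor table with a planted linear model.

    ``columns`` maps candidate names to uniform (low, high) sampling ranges;
    ``active`` maps a subset of those names to true coefficients.  The
    response is ``intercept + Σ coef·x + N(0, noise_sd)``, and cells (both
    candidates and response) are masked missing independently at
    ``missing_rate``, mirroring the gaps of real descriptor tables.
    Default ranges echo the bundled reference data (%V_Bur 15–70, Gibbs
    energies spanning roughly −30 to +10 kcal/mol including negatives, so
    the robustness code paths are exercised).
    """

    n_rows: int = 47
    columns: dict = field(
        default_factory=lambda: {
            "vbur_total": (15.0, 70.0),
            "vbur_low": (0.0, 25.0),
            "pyramidalization": (0.05, 0.55),
            "pka": (5.0, 12.0),
            "e_lumo": (-0.05, 0.15),
            "molecular_area": (150.0, 600.0),
            "mbo_nh": (0.70, 0.95),
        }
    )
    active: dict = field(default_factory=lambda: {"vbur_total": 0.3, "pka": -1.6})
    intercept: float = -5.0
    noise_sd: float = 2.0
    missing_rate: float = 0.0
    response: str = "dg"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        stray = set(self.active) - set(self.columns)
        if stray:
            raise ValueError(f"active variables {sorted(stray)} not among columns")
        if self.response in self.columns:
            raise ValueError("response name collides with a candidate column")


def simulate_table(spec: TableSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a descriptor table per ``spec``; returns ``(table, truth)``.

    ``truth`` carries the generating parameters (active coefficients,
    intercept, noise_sd, seed and the noiseless response) for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    data = {
        name: rng.uniform(lo, hi, size=spec.n_rows)
        for name, (lo, hi) in spec.columns.items()
    }
    signal = spec.intercept + sum(
        coef * data[name] for name, coef in spec.active.items()
    )
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_rows) if spec.noise_sd else 0.0
    data[spec.response] = signal + noise

    df = pd.DataFrame(data, index=[f"s{i+1}" for i in range(spec.n_rows)])
    df.index.name = "amine_id"
    if spec.missing_rate > 0:
        mask = rng.uniform(size=df.shape) < spec.missing_rate
        df = df.mask(mask)

    truth = {
        "active": dict(spec.active),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "response": spec.response,
        "signal": np.asarray(signal),
    }
    return df, truth
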