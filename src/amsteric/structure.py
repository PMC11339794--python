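"""Molecular structures, element radii tables, and bonded-neighbour detection.

This module is the geometry substrate for every steric descriptor in the
package.  A :class:`Structure` is an ordered list of atoms (element symbol +
Cartesian position in Å); atom indices are stable 0-based positions in that
list and are how every other module refers to atoms.

Radii conventions
-----------------
Van der Waals radii are the Bondi set, and buried-volume computations scale
them by 1.17 (the convention of the SambVca family of steric tools).  Covalent
radii (Cordero et al. single-bond values) are used only for bond perception:
two atoms are bonded when their distance does not exceed the sum of their
covalent radii plus a tolerance (0.4 Å by default).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "RadiiTable",
    "read_xyz",
    "write_xyz",
    "neighbors",
    "BONDI_VDW_RADII",
    "VDW_RADII",
    "COVALENT_RADII",
]

# Bondi (1964) van der Waals radii, Å.  Group-11/10 metals are Bondi's own
# values; the table is deliberately small — unknown elements are a hard error.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "Br": 1.85, "I": 1.98,
    "Ni": 1.63, "Cu": 1.40, "Zn": 1.39,
    "Pd": 1.63, "Ag": 1.72,
    "Pt": 1.75, "Au": 1.66,
}

# Default working set: Bondi, except hydrogen reduced to 1.09 Å — the value
# the buried-volume tools (SambVca and descendants) adopt from Rowland &
# Taylor because Bondi's 1.20 Å overestimates H in close contacts.  This is
# the convention that reproduces published %V_Bur values for small amines.
VDW_RADII: dict[str, float] = {**BONDI_VDW_RADII, "H": 1.09}

# Cordero et al. (2008) covalent radii, Å (sp3 value for carbon).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02,
    "Br": 1.20, "I": 1.39,
    "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Pd": 1.39, "Ag": 1.45,
    "Pt": 1.36, "Au": 1.36,
}

#: Default scaling applied to van der Waals radii in buried-volume work.
DEFAULT_VDW_SCALE = 1.17

#: Minimum allowed interatomic distance (degenerate-geometry guard), Å.
MIN_ATOM_SEPARATION = 0.3


class UnknownElementError(KeyError):
    """Raised when an element symbol has no entry in the radii table."""


class XYZParseError(ValueError):
    """Raised for malformed XYZ input; the message names the offending line."""


@dataclass(frozen=True)
class RadiiTable:
    """Element radii used throughout the package.

    Parameters
    ----------
    vdw:
        Van der Waals radii in Å (unscaled).
    covalent:
        Covalent radii in Å, used for bond perception.
    scale:
        Dimensionless multiplier applied to van der Waals radii by
        :meth:`vdw_scaled`; 1.17 by default.
    """

    vdw: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    covalent: dict[str, float] = field(default_factory=lambda: dict(COVALENT_RADII))
    scale: float = DEFAULT_VDW_SCALE

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"vdW scale must be positive, got {self.scale}")
        for name, table in (("vdw", self.vdw), ("covalent", self.covalent)):
            for el, r in table.items():
                if not r > 0:
                    raise ValueError(f"{name} radius of {el!r} must be positive, got {r}")

    def vdw_radius(self, element: str) -> float:
        """Unscaled van der Waals radius in Å."""
        try:
            return self.vdw[element]
        except KeyError:
            raise UnknownElementError(
                f"no van der Waals radius for element {element!r}"
            ) from None

    def vdw_scaled(self, element: str) -> float:
        """Van der Waals radius multiplied by :attr:`scale`, in Å."""
        return self.scale * self.vdw_radius(element)

    def covalent_radius(self, element: str) -> float:
        try:
            return self.covalent[element]
        except KeyError:
            raise UnknownElementError(
                f"no covalent radius for element {element!r}"
            ) from None

    def with_scale(self, scale: float) -> "RadiiTable":
        return replace(self, scale=scale)

    @classmethod
    def default(cls) -> "RadiiTable":
        """Working table: Bondi vdW radii with H = 1.09 Å, scale 1.17."""
        return cls()

    @classmethod
    def bondi(cls, scale: float = DEFAULT_VDW_SCALE) -> "RadiiTable":
        """Strict published Bondi vdW set (H = 1.20 Å)."""
        return cls(vdw=dict(BONDI_VDW_RADII), scale=scale)

    @classmethod
    def from_csv(cls, path: str | Path, scale: float = DEFAULT_VDW_SCALE) -> "RadiiTable":
        """Load an override table from a CSV of element,vdw_radius,covalent_radius."""
        vdw: dict[str, float] = {}
        cov: dict[str, float] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"element", "vdw_radius", "covalent_radius"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(f"radii CSV must have columns {sorted(required)}")
            for row in reader:
                el = row["element"].strip()
                vdw[el] = float(row["vdw_radius"])
                cov[el] = float(row["covalent_radius"])
        return cls(vdw=vdw, covalent=cov, scale=scale)


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol and Cartesian position in Å."""

    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite coordinate for {self.element}: {pos}")
        if self.element not in BONDI_VDW_RADII or self.element not in COVALENT_RADII:
            raise UnknownElementError(
                f"element {self.element!r} has no bundled radii; "
                "supply a custom RadiiTable and extend the element guard"
            )
        object.__setattr__(self, "position", pos)


class Structure:
    """An ordered collection of atoms with an optional total charge.

    Atom indices are stable 0-based positions.  Construction enforces two
    invariants: at least one atom, and no two atoms closer than 0.3 Å.
    """

    def __init__(self, name: str, atoms: Sequence[Atom], charge: int = 0):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        self.name = name
        self.atoms = atoms
        self.charge = int(charge)
        pos = self.positions
        if len(atoms) > 1:
            diff = pos[:, None, :] - pos[None, :, :]
            d = np.sqrt((diff ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            dmin = d.min()
            if dmin < MIN_ATOM_SEPARATION:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"atoms {i} ({atoms[i].element}) and {j} ({atoms[j].element}) "
                    f"are {dmin:.3f} Å apart (< {MIN_ATOM_SEPARATION} Å): degenerate geometry"
                )

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of Cartesian coordinates, Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"Structure({self.name!r}, {len(self)} atoms, charge={self.charge})"

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.atoms[i].position - self.atoms[j].position))

    def transformed(
        self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None
    ) -> "Structure":
        """Return a rigidly moved copy: x -> R @ x + t."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        atoms = [Atom(a.element, R @ a.position + t) for a in self.atoms]
        return Structure(self.name, atoms, self.charge)

    def subset(self, indices: Iterable[int], name: str | None = None) -> "Structure":
        idx = list(indices)
        return Structure(name or self.name, [self.atoms[i] for i in idx], self.charge)


def read_xyz(path: str | Path, name: str | None = None) -> Structure:
    """Read a standard XYZ file (count line, comment line, element x y z, Å).

    The comment line is used as the structure name when ``name`` is not given
    (falling back to the file stem for blank comments).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}: line 1: malformed atom count {lines[0]!r}") from None
    if count < 1:
        raise XYZParseError(f"{path}: line 1: atom count must be >= 1, got {count}")
    comment = lines[1].strip() if len(lines) > 1 else ""
    records = lines[2 : 2 + count]
    if len(records) < count:
        raise XYZParseError(
            f"{path}: expected {count} atom records, found {len(records)}"
        )
    atoms = []
    for k, line in enumerate(records):
        lineno = k + 3
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {lineno}: expected 'element x y z', got {line!r}")
        el = parts[0]
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(
                f"{path}: line {lineno}: non-numeric coordinate in {line!r}"
            ) from None
        try:
            atoms.append(Atom(el, np.array(xyz)))
        except UnknownElementError:
            raise XYZParseError(
                f"{path}: line {lineno}: unknown element symbol {el!r}"
            ) from None
    return Structure(name or comment or path.stem, atoms)


def write_xyz(structure: Structure, path: str | Path) -> None:
    """Write ``structure`` as a standard XYZ file (6-decimal coordinates)."""
    path = Path(path)
    lines = [str(len(structure)), structure.name]
    for a in structure.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    path.write_text("\n".join(lines) + "\n")


def neighbors(
    structure: Structure,
    index: int,
    radii: RadiiTable | None = None,
    tolerance: float = 0.4,
) -> list[int]:
    """Bonded neighbours of atom ``index``, sorted by distance (ascending).

    Atom ``j`` is bonded to ``i`` when ``dist(i, j) <= r_cov(i) + r_cov(j) +
    tolerance``.  The criterion is symmetric by construction.
    """
    if not 0 <= index < len(structure):
        raise IndexError(f"atom index {index} out of range for {len(structure)} atoms")
    radii = radii or RadiiTable.default()
    pos = structure.positions
    els = structure.elements
    ri = radii.covalent_radius(els[index])
    d = np.linalg.norm(pos - pos[index], axis=1)
    cut = np.array([ri + radii.covalent_radius(el) + tolerance for el in els])
    hits = [j for j in range(len(structure)) if j != index and d[j] <= cut[j]]
    # stable under rigid motions: near-equal distances (within 1e-6 Å) tie-break
    # on the atom index instead of on floating-point noise
    hits.sort(key=lambda j: (round(d[j], 6), j))
    return hits
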