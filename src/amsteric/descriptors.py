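"""Per-amine descriptor assembly.

A :class:`DescriptorRecord` is one amine's row in the screening table:
geometry-derived steric descriptors (buried volumes of the amine and its
ammonium, pyramidalization, bond distances, molecular surface area) together
with externally supplied quantum-chemical columns (orbital energies, Mayer
bond orders, NPA charges, pKa, chemical hardness) and the response Gibbs
energies.  QM columns are *inputs*, never computed here: they come from an
electronic-structure workflow outside the scope of this package.

Missing values are explicit (None / NaN), never encoded as 0 — the bundled
reference table has genuine gaps (complexes that could not be located) and
the screening module drops incomplete rows per evaluated variable subset.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .buried import compute_buried_volume, resolve_free_amine_frame
from .frame import build_amine_frame
from .pyramid import pyramidalization
from .structure import RadiiTable, Structure, neighbors, read_xyz

__all__ = [
    "DescriptorRecord",
    "longest_cn_bond",
    "molecular_area",
    "ligand_atoms",
    "assemble_table",
    "load_reference_table",
    "reference_table_checksum",
    "records_to_dataframe",
    "MANIFEST_ROLES",
]

MANIFEST_ROLES = ("amine", "ammonium", "au_complex", "pd0_complex", "pd2_complex")


@dataclass
class DescriptorRecord:
    """One amine's descriptor + response row; any numeric field may be None.

    Units: buried volumes in %, distances in Å, molecular area in Å²,
    e_lumo in hartree, eta in eV, Gibbs energies in kcal/mol; Mayer bond
    orders, pKa and NPA charges dimensionless (in e for NPA).
    """

    amine_id: str
    # geometry-derived, free amine
    vbur_total: float | None = None
    vbur_low: float | None = None
    vbur_high: float | None = None
    pyramidalization: float | None = None
    longest_cn: float | None = None
    molecular_area: float | None = None
    # geometry-derived, protonated form
    vbur_total_ammonium: float | None = None
    vbur_low_ammonium: float | None = None
    vbur_high_ammonium: float | None = None
    d_n_h: float | None = None
    # geometry-derived, metal complexes
    d_au_n: float | None = None
    pyramidalization_pd: float | None = None
    # externally supplied QM descriptors
    e_lumo: float | None = None
    mbo_nh: float | None = None
    mbo_au_n: float | None = None
    mbo_pd_n: float | None = None
    pka: float | None = None
    npa_n: float | None = None
    eta: float | None = None
    # responses
    dg_eq1: float | None = None
    dg_eq2: float | None = None
    dg_eq3: float | None = None
    dg_eq4: float | None = None
    dg_eq5: float | None = None
    ddg_eq2: float | None = None
    # unrecognised external columns are carried through untouched
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("vbur_total", "vbur_low", "vbur_high",
                     "vbur_total_ammonium", "vbur_low_ammonium", "vbur_high_ammonium"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        for name in ("d_n_h", "d_au_n", "longest_cn"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    def as_row(self) -> dict:
        row = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "extras"
        }
        row.update(self.extras)
        return row


def records_to_dataframe(records: Sequence[DescriptorRecord]) -> pd.DataFrame:
    """Tidy table, one row per amine, NaN for missing cells."""
    df = pd.DataFrame([r.as_row() for r in records])
    return df.set_index("amine_id")


def longest_cn_bond(
    structure: Structure,
    n_index: int,
    radii: RadiiTable | None = None,
    tolerance: float = 0.4,
) -> float:
    """Longest bonded N–C distance (Å) at the nitrogen ``n_index``."""
    radii = radii or RadiiTable.default()
    carbons = [
        j
        for j in neighbors(structure, n_index, radii, tolerance)
        if structure.atoms[j].element == "C"
    ]
    if not carbons:
        raise ValueError(f"atom {n_index} has no bonded carbon neighbour")
    return max(structure.distance(n_index, j) for j in carbons)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def molecular_area(
    structure: Structure,
    radii: RadiiTable | None = None,
    probe: float = 0.0,
    mesh: float = 0.1,
) -> float:
    """Scaled van der Waals surface area, Å² (Shrake–Rupley point sampling).

    Each atom's sphere (radius ``scale * r_vdw + probe``) is sampled on a
    golden-spiral lattice with roughly one point per ``mesh``² of surface;
    points inside any other atom's sphere are culled, and the exposed
    fraction times the sphere area is summed over atoms.  ``probe = 0``
    gives the bare van der Waals surface.
    """
    radii = radii or RadiiTable.default()
    pos = structure.positions
    rads = np.array([radii.vdw_scaled(el) + probe for el in structure.elements])
    total = 0.0
    for i in range(len(structure)):
        r = rads[i]
        n_pts = max(64, int(round(4.0 * math.pi * r * r / (mesh * mesh))))
        pts = pos[i] + r * _fibonacci_sphere(n_pts)
        exposed = np.ones(n_pts, dtype=bool)
        for j in range(len(structure)):
            if j == i:
                continue
            if np.linalg.norm(pos[j] - pos[i]) >= r + rads[j]:
                continue
            d2 = ((pts - pos[j]) ** 2).sum(axis=1)
            exposed &= d2 > rads[j] ** 2
            if not exposed.any():
                break
        total += 4.0 * math.pi * r * r * exposed.mean()
    return float(total)


def ligand_atoms(
    structure: Structure,
    n_index: int,
    metal_index: int,
    radii: RadiiTable | None = None,
    tolerance: float = 0.4,
) -> list[int]:
    """Atom indices of the amine ligand in a complex: the connected component
    of the donor nitrogen in the bond graph with the metal removed."""
    radii = radii or RadiiTable.default()
    seen = {n_index}
    stack = [n_index]
    while stack:
        i = stack.pop()
        for j in neighbors(structure, i, radii, tolerance):
            if j != metal_index and j not in seen:
                seen.add(j)
                stack.append(j)
    return sorted(seen)


def _num(value) -> float | None:
    if value is None:
        return None
    try:
        if pd.isna(value):
            return None
    except (TypeError, ValueError):
        pass
    return float(value)


def _read_manifest(manifest) -> pd.DataFrame:
    if isinstance(manifest, (str, Path)):
        df = pd.read_csv(manifest)
    else:
        df = pd.DataFrame(manifest).copy()
    required = {"amine_id", "role", "path", "n_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    if "metal_index" not in df.columns:
        df["metal_index"] = np.nan
    bad = ~df["role"].isin(MANIFEST_ROLES)
    if bad.any():
        raise ValueError(f"unknown manifest roles: {sorted(df.loc[bad, 'role'].unique())}")
    dup = df.duplicated(subset=["amine_id", "role"])
    if dup.any():
        pairs = df.loc[dup, ["amine_id", "role"]].itertuples(index=False)
        raise ValueError(f"duplicate manifest entries: {[tuple(p) for p in pairs]}")
    return df


def assemble_table(
    manifest,
    external: str | Path | pd.DataFrame | None = None,
    radii: RadiiTable | None = None,
    mesh: float = 0.1,
    offset: float = 2.0,
    radius: float = 3.5,
    area_probe: float = 0.0,
) -> tuple[list[DescriptorRecord], list[dict]]:
    """Build descriptor records from a geometry manifest plus an external CSV.

    The manifest (CSV path or DataFrame) has columns ``amine_id, role, path,
    n_index[, metal_index]`` where role is one of ``amine | ammonium |
    au_complex | pd0_complex | pd2_complex`` and atom indices are **1-based**
    (chemistry convention; converted internally).  For an ammonium,
    ``metal_index`` is the acidic proton.  The external table is keyed by
    ``amine_id``; its numeric columns are joined onto the records (known
    column names map to record fields, everything else lands in ``extras``).
    When a distance is available both from geometry and externally and the
    two differ by more than 0.01 Å a warning is emitted and geometry wins.

    Returns ``(records, provenance)`` where provenance lists the source of
    every filled cell.
    """
    radii = radii or RadiiTable.default()
    df = _read_manifest(manifest)
    known_fields = {f.name for f in fields(DescriptorRecord)} - {"amine_id", "extras"}

    rows: dict[str, dict] = {}
    provenance: list[dict] = []

    def put(amine_id: str, column: str, value, source: str) -> None:
        rows.setdefault(amine_id, {})[column] = value
        provenance.append({"amine_id": amine_id, "column": column, "source": source})

    for entry in df.itertuples(index=False):
        amine_id = str(entry.amine_id)
        struct = read_xyz(entry.path)
        n_idx = int(entry.n_index) - 1
        m_idx = None if pd.isna(entry.metal_index) else int(entry.metal_index) - 1
        src = str(entry.path)

        if entry.role == "amine":
            frame = resolve_free_amine_frame(
                struct, n_idx, radii, mesh=mesh, offset=offset, radius=radius
            )
            bv = compute_buried_volume(struct, frame, radii, mesh=mesh)
            put(amine_id, "vbur_total", bv.total_pct, src)
            put(amine_id, "vbur_low", bv.low_pct, src)
            put(amine_id, "vbur_high", bv.high_pct, src)
            pyr = pyramidalization(struct, n_idx, radii=radii)
            put(amine_id, "pyramidalization", pyr.index, src)
            put(amine_id, "molecular_area",
                molecular_area(struct, radii, probe=area_probe, mesh=mesh), src)
            try:
                put(amine_id, "longest_cn", longest_cn_bond(struct, n_idx, radii), src)
            except ValueError:
                pass  # no carbon substituent (e.g. ammonia): cell stays missing
        elif entry.role == "ammonium":
            if m_idx is None:
                raise ValueError(
                    f"ammonium entry {amine_id!r} needs metal_index = the acidic proton"
                )
            frame = build_amine_frame(
                struct, n_idx, metal_index=m_idx, radii=radii,
                offset=offset, radius=radius,
            )
            bv = compute_buried_volume(struct, frame, radii, mesh=mesh)
            put(amine_id, "vbur_total_ammonium", bv.total_pct, src)
            put(amine_id, "vbur_low_ammonium", bv.low_pct, src)
            put(amine_id, "vbur_high_ammonium", bv.high_pct, src)
            put(amine_id, "d_n_h", struct.distance(n_idx, m_idx), src)
        elif entry.role in ("au_complex", "pd0_complex", "pd2_complex"):
            if m_idx is None:
                raise ValueError(f"{entry.role} entry {amine_id!r} needs metal_index")
            if entry.role == "au_complex":
                put(amine_id, "d_au_n", struct.distance(n_idx, m_idx), src)
            else:
                pyr = pyramidalization(struct, n_idx, radii=radii, metal_index=m_idx)
                put(amine_id, "pyramidalization_pd", pyr.index, src)

    if external is not None:
        ext = (
            pd.read_csv(external)
            if isinstance(external, (str, Path))
            else pd.DataFrame(external).copy()
        )
        if "amine_id" not in ext.columns:
            raise ValueError("external table needs an amine_id column")
        if ext["amine_id"].astype(str).duplicated().any():
            raise ValueError("duplicate amine_id in external table")
        ext_src = str(external) if isinstance(external, (str, Path)) else "external"
        for rec in ext.to_dict("records"):
            amine_id = str(rec.pop("amine_id"))
            for col, raw in rec.items():
                try:
                    value = _num(raw)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell in external column {col!r} "
                        f"for amine {amine_id!r}: {raw!r}"
                    ) from None
                if value is None:
                    continue
                existing = rows.get(amine_id, {}).get(col)
                if existing is not None and col in ("d_au_n", "d_n_h"):
                    if abs(existing - value) > 0.01:
                        warnings.warn(
                            f"{col} for {amine_id}: geometry value {existing:.3f} Å "
                            f"differs from external {value:.3f} Å; keeping geometry",
                            stacklevel=2,
                        )
                    continue
                put(amine_id, col, value, f"external:{ext_src}")

    records = []
    for amine_id in sorted(rows, key=lambda s: (len(s), s)):
        cells = rows[amine_id]
        kwargs = {k: v for k, v in cells.items() if k in known_fields}
        extras = {k: v for k, v in cells.items() if k not in known_fields}
        records.append(DescriptorRecord(amine_id=amine_id, extras=extras, **kwargs))
    return records, provenance


def _reference_csv_bytes() -> bytes:
    return (resources.files("amsteric") / "data" / "amine_reference.csv").read_bytes()


def reference_table_checksum() -> str:
    """SHA-256 of the bundled reference CSV (transcription integrity guard)."""
    return hashlib.sha256(_reference_csv_bytes()).hexdigest()


def load_reference_table() -> list[DescriptorRecord]:
    """Bundled reference dataset: 47 amines (43 numbered + NH3, NMe3, NEt3, Py).

    Columns: Gibbs energies (kcal/mol) for protonation by a free proton
    (dg_eq1) and by acetic acid (dg_eq2), ligand exchange on AuCl(PMe3)
    (dg_eq3), Pd(PMe3)2 (dg_eq4) and PdCl2(PMe3) (dg_eq5), plus the amine's
    total %V_Bur.  Gaps are species whose complex could not be located; they
    are genuine missing values.
    """
    import io

    df = pd.read_csv(io.BytesIO(_reference_csv_bytes()), dtype={"amine_id": str})
    records = []
    for rec in df.to_dict("records"):
        amine_id = str(rec.pop("amine_id"))
        kwargs = {k: _num(v) for k, v in rec.items()}
        records.append(DescriptorRecord(amine_id=amine_id, **kwargs))
    return records
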