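# Methods

This note documents the models, conventions and numerical choices behind
`amsteric`, and what the synthetic-data tests do and do not establish about
real amines.

## Geometry substrate

Structures are ordered atom lists (element, Cartesian Å) read and written in
the plain XYZ dialect (count line, comment line, `element x y z` records).
Two guards are enforced at construction: every element must have bundled van
der Waals and covalent radii (unknown symbols are a hard error, never a
silent default), and no two atoms may sit closer than 0.3 Å (degenerate
geometries would otherwise silently corrupt every downstream descriptor).

Bond perception uses the covalent-radius-sum criterion
`d(i, j) ≤ r_cov(i) + r_cov(j) + t` with `t = 0.4 Å` (Cordero radii). For
well-optimized geometries any sane cutoff finds the three nitrogen
substituents; the tolerance is a parameter for pathological inputs.
Neighbour lists are sorted by distance with ties (within 1e-6 Å) broken by
atom index — without the stable tie-break the quadrant frame of a 3-fold
symmetric amine would depend on floating-point noise and rigid-motion
equivariance would fail.

## Buried volume

The buried volume of a ligand is evaluated inside a probe sphere of radius
R = 3.5 Å centred on the z axis of a dedicated frame, 2.0 Å from the donor
nitrogen — the average metal–N coordination distance, i.e. where a metal
sits or would sit. The frame's xy plane is parallel to the least-squares
plane of the three N substituents. For a complex, z points from N to the
metal (for an ammonium, to the acidic proton); for a free amine, z is the
plane normal on the side *away* from the substituents, which makes free-amine
and complex frames agree for undistorted complexes. For nearly planar
nitrogens (|N − plane| < 1e-3 Å) the face choice is ill-posed;
`resolve_free_amine_frame` evaluates both faces and keeps the one with the
smaller total %V_Bur, on the physical ground that a metal binds the less
hindered face. The x axis is the in-plane projection of the bond to the
lowest-index substituent; total %V_Bur is exactly invariant to this choice,
quadrant values are not, so an explicit reference-atom override exists.

The engine scans a cubic voxel grid of spacing `mesh` (default 0.1 Å)
aligned with the frame axes, voxel centres at `(k + 0.5)·mesh − R` per axis.
A voxel belongs to the sphere iff its centre lies within R of the origin and
is buried iff the centre also lies within `1.17 · r_vdw` of any included
atom — a pure centre test, no partial-volume weighting; the
mesh-convergence tests bound the resulting error (≤ 0.03 percentage points
for a centred atom at mesh 0.1, ≤ 0.3 on molecular fixtures). With the
default registration no voxel centre falls on a quadrant boundary; for
meshes that do not divide 2R evenly, centres with x = 0 or y = 0 go to the
positive side (documented tie-break). Each quadrant then holds exactly a
quarter of the sphere voxels, so the quadrant mean reproduces the total to
1e-9 by construction.

Radii are Bondi's van der Waals set scaled by 1.17, with one deliberate
exception: hydrogen uses 1.09 Å (the Rowland–Taylor value adopted throughout
the buried-volume tool lineage) rather than Bondi's 1.20 Å. The choice is
empirical: with H = 1.09 the idealized-ammonia buried volume lands at 15.25%
against the published 15.2% for DFT-optimized ammonia; with H = 1.20 it
overshoots by more than a point. The strict Bondi table remains available as
`RadiiTable.bondi()`. Hydrogens are *included* by default — small-amine
buried volumes are implausible from heavy atoms alone — with a
`--no-hydrogens` switch for comparison with older conventions. In complexes,
only the amine ligand (the connected component of N once the metal is
removed) is included; metal and co-ligands are excluded.

A Monte-Carlo estimator (uniform sampling in the sphere via isotropic
directions and cube-root radii — a code path sharing nothing with the voxel
grid but the burial predicate) provides an independent oracle with a
binomial standard error; voxel and Monte-Carlo agree within 3·SE at 10⁶
samples on randomly generated amines.

The topographic steric map reports, for every xy grid column, the height
(frame z, Å) of the topmost buried voxel centre — the ligand surface an
approaching metal sees — with a `−R` sentinel for unburied columns. It is
computed from the same voxelisation, so its column counts reproduce the
buried-voxel total exactly.

## Pyramidalization

The default index is the perpendicular distance (Å) of the nitrogen from the
exact plane of its three bonded substituents: 0 for planar nitrogens,
≈ 0.381 Å for ammonia (N–H 1.012 Å, 106.7°), ≈ 0.45 Å for an ideal sp³
trialkylamine — which is precisely why 0.450 Å works as the boundary between
the pyramidal regime (where pyramidality and buried volume track each other)
and the flattened regime. The strategy registry carries this height formula
under both `oop-distance` and `ra-1989`; the original literature formula
behind the latter label was not accessible during development, and the
height-based reading is the one consistent with both published anchors
(exactly zero for pyridine; a 0.450 threshold in Å-scale units). An
`angle-defect` strategy (360° − Σ of the three N angles, degrees) is
provided for cross-checks; all strategies share the contract: zero for
planar, monotone in out-of-plane displacement, rigid-motion and relabeling
invariant.

## Descriptor assembly

Geometry-derived columns (buried volumes of amine and ammonium forms,
pyramidalization — including the value of the N as bound in a Pd complex —
longest N–C bond, N–H⁺ and Au–N distances, molecular surface area) are
computed from a manifest of XYZ files; electronic columns (E(LUMO), Mayer
bond orders, pKa, NPA charge, chemical hardness η) and the response Gibbs
energies are *inputs* joined from an external CSV — they come from a
quantum-chemistry workflow that is out of scope here, and their units are
carried as metadata, never converted. Missing values are explicit NaN/None,
never 0. When a distance is available from both geometry and the external
table and the two disagree by > 0.01 Å, geometry wins with a warning. Every
filled cell is logged with its source (provenance list).

Molecular area is the scaled-vdW surface area by Shrake–Rupley-style point
sampling (golden-spiral lattice, ~1 point per mesh² of surface, probe 0 by
default); a single atom reproduces 4πr² to well under 1%. The probe radius
and scale are parameters because "molecular area" conventions differ between
workflows.

The bundled reference table (`load_reference_table`) transcribes a published
dataset of 47 amines — 43 numbered hindered amines plus NH₃, NMe₃, NEt₃ and
pyridine — with Gibbs energies (kcal/mol) for protonation by a free proton
and by acetic acid, and for ligand exchange on AuCl(PMe₃), Pd(PMe₃)₂ and
PdCl₂(PMe₃), plus each amine's total %V_Bur. Gaps are complexes that could
not be located and stay missing (41/36/16 located systems for the Au, Pd(0)
and Pd(II) columns). The transcription is protected by a SHA-256 checksum
and row-level spot checks.

## Best-subset screening

`fit_ols` is ordinary least squares with intercept (numpy least squares on
the augmented design). R² is defined as 1 − SS_res/SS_tot, which for OLS
with intercept equals the squared Pearson correlation of fitted vs observed
values — the equivalence is unit-tested against statsmodels rather than
assumed. A constant response is a defined degenerate case (R² = 0 via the
SS_tot = 0 guard). RMSE uses the population denominator n; the n − p − 1
variant is also emitted in ledgers since conventions differ. Rank-deficient
designs raise with the collinear column names.

`screen` enumerates *all* candidate subsets of size 1..max_vars (max 3),
applies the optional strict filter (canonically `pyramidalization > 0.450`)
and robustness transform first, and performs listwise deletion *per
evaluated subset* — each fit keeps every row complete for its own variables,
which maximises n per fit; the per-fit n is always reported so mismatches
with external system counts stay visible. Ranking is by R² descending with
deterministic tie-breaks (fewer variables, then lexicographic names). No
multiple-testing correction is applied — these are raw best-subset
statistics — but the number of subsets searched is part of every ledger so
selection effects can be judged. Robustness modes transform the response
only: clip negatives to zero (barrierless processes as zero barriers) or
drop those rows.

## Synthetic data

`build_amine` places N at (0, 0, h) over three substituent anchors arranged
3-fold in the z = 0 plane at the N–anchor distance, so the default
pyramidalization index equals h *exactly by construction*. Substituent
templates (H, Me, Et, iPr, tBu, Ad-like) use idealized sp³ internals
(109.47°, C–C 1.54 Å, C–H 1.09 Å); heavy branches are placed so the
template series is nested as point sets, which makes the buried volume of
Me → Et → iPr → tBu → Ad strictly increasing (29 → 49 → 49.4 → 51 → 70% at
the default geometry, spanning the range real amines cover). The default
15° azimuth is a slight propeller gearing avoiding eclipsed contacts;
inter-substituent contacts under 0.8 Å raise an error rather than emitting
an impossible geometry. The generator emulates steric bulk and pyramidality
only — no conformer ensembles, no force-field relaxation, no electronic
structure — so tests passing on synthetic geometries demonstrate the
correctness of the descriptor machinery, not the conformational realism of
any particular amine. That limitation is visible in the idealized reference
amines: rigid NH₃ and pyridine reproduce published buried volumes within
0.1 percentage points, while NMe₃ lands ~0.5 low and flexible NEt₃ several
points high of the DFT-conformer values.

`simulate_table` draws descriptor columns from uniform ranges mirroring the
reference table's spread (%V_Bur 15–70, pKa 5–12, responses spanning
negative values so the robustness paths are exercised), plants a linear
response with Gaussian noise, masks cells missing at a configurable rate,
and returns the generating truth for recovery tests. Everything is
deterministic under its seed.

## Problem sizes and defaults

Default parameters throughout: sphere radius 3.5 Å, offset 2.0 Å, mesh
0.1 Å, vdW scale 1.17, pyramidalization filter 0.450 Å. The test suite and
the acceptance script size their simulations for interactive runs: 10⁶
Monte-Carlo samples for oracle comparisons, 10 random amines per oracle
sweep, 100 seeded tables (n = 50, 8 candidates) for recovery rates, n = 200
for coefficient-recovery checks. The full suite runs in well under a minute
on one core.

## Known limitations

- Quadrant (Low/High) %V_Bur values depend on the x-axis convention; only
  the total is rotation-invariant about z. The reference-atom override is
  the mitigation when matching an external quadrant convention.
- The `ra-1989` pyramidalization strategy is the height formula as discussed
  above; if the original reference's functional form differs, a new strategy
  can be registered without touching the pipeline.
- Bidentate ligands, non-nitrogen donors and octant decompositions are out
  of scope; pyridine-type donors (two N substituents) are handled by
  supplying an explicit frame rather than `build_amine_frame`.
- The screening reports raw best-subset statistics; with tens of subsets
  searched, headline R² values are optimistic estimates of out-of-sample
  correlation.
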