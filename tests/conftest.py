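"""Shared fixtures: small reference geometries and random-amine helpers."""

from __future__ import annotations

import numpy as np
import pytest

from amsteric.frame import SphereFrame
from amsteric.structure import Atom, RadiiTable, Structure
from amsteric.synth import AmineSpec, build_amine, sp3_height

HEAVY_TEMPLATES = ("Me", "Et", "iPr", "tBu")


@pytest.fixture(scope="session")
def radii() -> RadiiTable:
    return RadiiTable.default()


@pytest.fixture
def origin_frame() -> SphereFrame:
    """Default-size probe sphere centred at the world origin, axes = world axes."""
    return SphereFrame(
        origin=np.zeros(3),
        x_axis=np.array([1.0, 0.0, 0.0]),
        y_axis=np.array([0.0, 1.0, 0.0]),
        z_axis=np.array([0.0, 0.0, 1.0]),
    )


@pytest.fixture
def single_carbon() -> Structure:
    return Structure("single_c", [Atom("C", np.zeros(3))])


@pytest.fixture
def ideal_ammonia() -> Structure:
    """Idealized NH3: N–H 1.012 Å, H–N–H 106.7°, apex along +z."""
    h = sp3_height(1.012, 106.7)
    return build_amine(AmineSpec(("H", "H", "H"), pyramid_height=h, cn_bond=1.012))


def random_amine(rng: np.random.Generator, height_range=(0.3, 0.5)) -> Structure:
    """Deterministic random NR3 geometry; redraws on sterically impossible
    template combinations (the generator raises for clashes)."""
    for _ in range(20):
        trio = tuple(str(t) for t in rng.choice(HEAVY_TEMPLATES, size=3))
        h = float(rng.uniform(*height_range))
        try:
            return build_amine(AmineSpec(trio, pyramid_height=h))
        except ValueError:
            continue
    raise RuntimeError("could not draw a clash-free amine in 20 attempts")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation from a QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
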