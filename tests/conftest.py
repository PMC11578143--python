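"""Shared fixtures: small synthetic phantoms with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import choroid3d as c3

#: default test spacing, µm/voxel: coarse but proportioned like a wide-field scan
SP = (12.0, 12.0, 4.0)
VOXEL_DIAG = float(np.linalg.norm(SP))


def ladder_spec(speckle_sigma: float = 0.0, seed: int = 7) -> c3.PhantomSpec:
    """Five straight tubes with diameters 100–300 µm in a 520 µm slab."""
    tubes = tuple(
        c3.straight_tube(300.0 + 600.0 * i, 360.0, float(d), 200.0, 2800.0)
        for i, d in enumerate((100, 150, 200, 250, 300))
    )
    return c3.PhantomSpec(
        grid_shape=(256, 256, 192),
        spacing=SP,
        inner_depth=100.0,
        choroid_thickness=520.0,
        vessels=tubes,
        speckle_sigma=speckle_sigma,
        seed=seed,
    )


def two_tube_spec(gap_um: float, r1: float = 75.0, r2: float = 50.0) -> c3.PhantomSpec:
    """Two parallel tubes with a designed edge-to-edge gap."""
    y1 = 400.0
    y2 = y1 + r1 + gap_um + r2
    vessels = (
        c3.straight_tube(y1, 360.0, 2 * r1, 200.0, 2000.0),
        c3.straight_tube(y2, 360.0, 2 * r2, 200.0, 2000.0),
    )
    ny = int((y2 + r2 + 400.0) / SP[0])
    return c3.PhantomSpec(
        grid_shape=(ny, 192, 192),
        spacing=SP,
        inner_depth=100.0,
        choroid_thickness=520.0,
        vessels=vessels,
    )


@pytest.fixture(scope="session")
def ladder_phantom():
    """Noiseless diameter-ladder phantom (volume, ground truth)."""
    return c3.generate_phantom(ladder_spec())


@pytest.fixture(scope="session")
def ladder_components(ladder_phantom):
    """Binarized and measured components of the noiseless ladder, sorted by y."""
    vol, gt = ladder_phantom
    vlv = c3.binarize_pipeline(vol, gt.choroid_mask)
    comps = c3.extract_components(vlv, SP)
    comps.sort(key=lambda c: int(c.path[:, 0].mean()))
    return vlv, comps


@pytest.fixture(scope="session")
def single_tube_phantom():
    """One 200 µm tube in a small slab, plus its labeled mask and components."""
    spec = c3.PhantomSpec(
        grid_shape=(64, 160, 192),
        spacing=SP,
        inner_depth=100.0,
        choroid_thickness=520.0,
        vessels=(c3.straight_tube(384.0, 360.0, 200.0, 200.0, 1700.0),),
    )
    vol, gt = c3.generate_phantom(spec)
    vlv = c3.label_components(gt.luminal_mask)
    comps = c3.extract_components(vlv, SP)
    return vol, gt, vlv, comps
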