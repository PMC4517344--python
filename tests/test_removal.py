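"""Staging platform, ultrasonic trough, and the access rectangle."""

import numpy as np
import pytest

from rdtsim.instrument import Fragment, place_fragment
from rdtsim.phantom import analytic_tube_phantom
from rdtsim.removal import (
    TroughSpec,
    access_rectangle,
    carve_staging_platform,
    carve_trough,
    trough_diameter,
    trough_z_span,
)
from rdtsim.thickness3d import min_rdt_3d, thickness_map
from rdtsim.volume import BACKGROUND, DENTIN, METAL, REMOVED


@pytest.mark.parametrize(
    "db, dc, expected",
    [
        (0.43, 0.40, 1.23),  # the conservative trough around the 3 mm segment
        (0.43, 0.0, 0.43),
        (0.55, 0.40, 1.35),
    ],
)
def test_trough_diameter(db, dc, expected):
    assert trough_diameter(db, dc) == pytest.approx(expected, abs=1e-12)


def test_trough_diameter_rejects_nonpositive():
    with pytest.raises(ValueError):
        trough_diameter(0.0, 0.4)
    with pytest.raises(ValueError):
        trough_diameter(0.43, -0.1)


def test_trough_spec_invariant():
    spec = TroughSpec.for_fragment(Fragment())
    assert spec.trough_diameter_mm == pytest.approx(0.43 + 2 * 0.40)


@pytest.mark.parametrize(
    "depth, expected_h",
    [(3.0, 4.5), (5.0, 6.5)],
)
def test_access_rectangle_dimensions(depth, expected_h):
    frag = Fragment(depth_below_orifice_mm=depth)
    spec = TroughSpec.for_fragment(frag)
    rect = access_rectangle(frag, spec)
    assert rect.width_mm == pytest.approx(1.23)
    assert rect.height_mm == pytest.approx(expected_h)


def test_access_rectangle_degenerate():
    frag = Fragment(depth_below_orifice_mm=0.0)
    spec = TroughSpec.for_fragment(frag, trough_depth_mm=0.0)
    rect = access_rectangle(frag, spec)
    assert rect.height_mm == 0.0


# ---------------------------------------------------------------------------
# carving


@pytest.fixture(scope="module")
def placed():
    tube = analytic_tube_phantom(500, 2000, 6000, 30)
    return place_fragment(tube, Fragment(depth_below_orifice_mm=2.0))


def test_platform_requires_fragment():
    tube = analytic_tube_phantom(500, 2000, 6000, 30)
    with pytest.raises(ValueError):
        carve_staging_platform(tube, Fragment())


def test_platform_is_idempotent(placed):
    frag = Fragment(depth_below_orifice_mm=2.0)
    once = carve_staging_platform(placed, frag)
    twice = carve_staging_platform(once, frag)
    assert np.array_equal(once.labels, twice.labels)


def test_platform_inside_wide_canal_removes_no_dentin():
    """A bur narrower than the canal only relabels existing canal space."""
    tube = analytic_tube_phantom(600, 2000, 6000, 30)  # canal diameter 1.2 mm
    frag = Fragment(depth_below_orifice_mm=2.0)
    placed = place_fragment(tube, frag)
    carved = carve_staging_platform(placed, frag, platform_diameter_mm=1.1)
    assert (carved.labels == DENTIN).sum() == (placed.labels == DENTIN).sum()
    assert (carved.labels == REMOVED).sum() > 0


def test_platform_opens_straight_corridor(placed):
    """Every axial ray inside the platform cylinder meets no dentin between
    the orifice and the fragment's coronal end."""
    frag = Fragment(depth_below_orifice_mm=2.0)
    carved = carve_staging_platform(placed, frag, platform_diameter_mm=1.1)
    xax = carved.world_axis(0)
    yax = carved.world_axis(1)
    in_disc = (xax[:, None] ** 2 + yax[None, :] ** 2) <= (550.0 - 30.0) ** 2
    k_frag = carved.z_index(6000.0 - 2000.0) + 1  # first slice above the fragment
    k_top = carved.z_index(6000.0)
    corridor = carved.labels[:, :, k_frag:k_top + 1][in_disc]
    assert not np.any(corridor == DENTIN)


def test_trough_min_rdt_matches_annulus_minus_cylinder(placed):
    """Centred trough D = 1.23 mm in a 2 mm-outer-radius tube leaves
    2.0 - 1.23/2 = 1.385 mm of wall."""
    frag = Fragment(depth_below_orifice_mm=2.0)
    spec = TroughSpec.for_fragment(frag)
    carved = carve_trough(carve_staging_platform(placed, frag), frag, spec)
    assert not carved.perforated
    roi = trough_z_span(carved, frag, spec)
    value, _ = min_rdt_3d(carved, roi=roi)
    assert value == pytest.approx(1385.0, abs=carved.voxel_size_um)


def test_trough_cross_section_diameter(placed):
    frag = Fragment(depth_below_orifice_mm=2.0)
    spec = TroughSpec.for_fragment(frag)
    carved = carve_trough(carve_staging_platform(placed, frag), frag, spec)
    k0, k1 = trough_z_span(carved, frag, spec)
    mid = (k0 + k1) // 2
    space = np.isin(carved.labels[:, :, mid], (REMOVED, METAL)) | (
        carved.labels[:, :, mid] == 2
    )
    cols = np.nonzero(space.any(axis=1))[0]
    width = (cols[-1] - cols[0] + 1) * carved.voxel_size_um
    assert width == pytest.approx(1230.0, abs=carved.voxel_size_um)


def test_zero_depth_trough_is_noop(placed):
    frag = Fragment(depth_below_orifice_mm=2.0)
    spec = TroughSpec.for_fragment(frag, trough_depth_mm=0.0)
    carved = carve_trough(placed, frag, spec)
    assert np.array_equal(carved.labels, placed.labels)


def test_carving_conserves_background_and_metal(placed):
    frag = Fragment(depth_below_orifice_mm=2.0)
    spec = TroughSpec.for_fragment(frag)
    carved = carve_trough(carve_staging_platform(placed, frag), frag, spec)
    for lab in (BACKGROUND, METAL):
        assert (carved.labels == lab).sum() == (placed.labels == lab).sum()


def test_carving_never_increases_min_rdt(placed):
    frag = Fragment(depth_below_orifice_mm=2.0)
    spec = TroughSpec.for_fragment(frag)
    roi = trough_z_span(placed, frag, spec)
    before = thickness_map(placed, roi=roi).min_value_um
    carved = carve_trough(carve_staging_platform(placed, frag), frag, spec)
    after = thickness_map(carved, roi=roi).min_value_um
    assert after <= before + 1e-9


def test_thin_root_trough_perforates():
    """A 1.23 mm trough through a 0.55 mm-radius root exits the root: the
    volume is flagged and the minimum RDT reads zero."""
    tube = analytic_tube_phantom(250, 550, 6000, 30)
    frag = Fragment(depth_below_orifice_mm=2.0)
    placed = place_fragment(tube, frag)
    spec = TroughSpec.for_fragment(frag)
    carved = carve_trough(carve_staging_platform(placed, frag), frag, spec)
    assert carved.perforated
    roi = trough_z_span(carved, frag, spec)
    value, _ = min_rdt_3d(carved, roi=roi)
    assert value == 0.0
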