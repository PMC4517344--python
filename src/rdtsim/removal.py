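"""Virtual removal of the broken fragment.

Clinically the fragment is freed in two stages: a Gates-Glidden bur cuts a
"staging platform" — a straight-line corridor from the orifice down to the
fragment's coronal end — and an ultrasonic tip then trephines a thin collar
of dentin ("trough") around the fragment, 1.5 mm deep along it.  The most
conservative trough diameter is ``D = Db + 2 Dc`` where ``Db`` is the
fragment's coronal diameter (0.43 mm for a size 25/.06 segment) and ``Dc``
the ultrasonic tip diameter (0.40 mm), giving D = 1.23 mm.

On a radiograph the space consumed by this access is summarised by a
rectangle of width ``D`` and height ``depth below orifice + trough depth``
(4.5 × 1.23 mm and 6.5 × 1.23 mm for the 3 and 5 mm depths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .instrument import MM, Fragment, _Polyline
from .volume import BACKGROUND, CANAL, DENTIN, METAL, REMOVED, ToothVolume

#: ISO nominal diameter of a Gates-Glidden #4 bur (mm); the platform cutter.
GG4_DIAMETER_MM = 1.1


def trough_diameter(Db_mm: float, Dc_mm: float) -> float:
    """Trough diameter ``D = Db + 2 Dc`` (mm)."""
    if Db_mm <= 0:
        raise ValueError("Db_mm must be positive")
    if Dc_mm < 0:
        raise ValueError("Dc_mm must be >= 0")
    return Db_mm + 2.0 * Dc_mm


@dataclass
class TroughSpec:
    """Cylindrical ultrasonic trough around the fragment."""

    ultrasonic_tip_diameter_mm: float = 0.40
    trough_diameter_mm: float = 1.23
    trough_depth_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.trough_depth_mm < 0:
            raise ValueError("trough_depth_mm must be >= 0")

    @classmethod
    def for_fragment(
        cls,
        fragment: Fragment,
        ultrasonic_tip_diameter_mm: float = 0.40,
        trough_depth_mm: float = 1.5,
    ) -> "TroughSpec":
        return cls(
            ultrasonic_tip_diameter_mm=ultrasonic_tip_diameter_mm,
            trough_diameter_mm=trough_diameter(
                fragment.coronal_diameter_mm, ultrasonic_tip_diameter_mm
            ),
            trough_depth_mm=trough_depth_mm,
        )


@dataclass
class RectangleSpec:
    """Straight-line-access rectangle overlaid on a projection.

    ``anchor`` is filled in at measurement time: the (x, z) projection-frame
    coordinate (μm) of the rectangle's centre-top point, centred on the
    projected canal axis with the top edge at orifice level.
    """

    width_mm: float
    height_mm: float
    anchor_um: tuple[float, float] | None = None


def access_rectangle(fragment: Fragment, spec: TroughSpec) -> RectangleSpec:
    """Rectangle summarising the access corridor on a radiograph.

    Width is the trough diameter D; height is the fragment depth below the
    orifice plus the trough depth (the printed 4.5/6.5 mm values are exactly
    depth + 1.5 mm).
    """
    return RectangleSpec(
        width_mm=spec.trough_diameter_mm,
        height_mm=fragment.depth_below_orifice_mm + spec.trough_depth_mm,
    )


def _require_fragment(volume: ToothVolume) -> None:
    if not np.any(volume.labels == METAL):
        raise ValueError("no fragment present in the volume")


def _carve_cylinder_slices(
    volume: ToothVolume,
    apex_point_um: np.ndarray,
    axis_unit: np.ndarray,
    radius_um: float,
    z_lo: float,
    z_hi: float,
) -> np.ndarray:
    """Boolean mask of voxels inside a (near-vertical) cylinder.

    The cylinder axis passes through ``apex_point_um`` with direction
    ``axis_unit``; each z slice in ``[z_lo, z_hi]`` gets a disc centred where
    the axis crosses it.
    """
    zax = volume.world_axis(2)
    sel = (zax >= z_lo - 1e-9) & (zax <= z_hi + 1e-9)
    t = np.where(axis_unit[2] != 0, (zax - apex_point_um[2]) / axis_unit[2], 0.0)
    cx = apex_point_um[0] + axis_unit[0] * t
    cy = apex_point_um[1] + axis_unit[1] * t
    xax = volume.world_axis(0)[:, None, None].astype(np.float32)
    yax = volume.world_axis(1)[None, :, None].astype(np.float32)
    d2 = (xax - cx[None, None, :].astype(np.float32)) ** 2 + (
        yax - cy[None, None, :].astype(np.float32)
    ) ** 2
    mask = d2 <= np.float32(radius_um**2)
    mask &= sel[None, None, :]
    return mask


def carve_staging_platform(
    volume: ToothVolume,
    fragment: Fragment,
    platform_diameter_mm: float = GG4_DIAMETER_MM,
) -> ToothVolume:
    """Cut the straight-line access corridor down to the fragment.

    Dentin and canal voxels inside a cylinder of the bur diameter, coaxial
    with the straight-line access direction (the canal tangent at the
    fragment's coronal end, extended coronally), from the orifice down to
    the fragment's coronal end, are relabelled ``removed``.  Metal and
    background are never touched.  Idempotent.
    """
    _require_fragment(volume)
    out = volume.copy()
    cl = _Polyline(volume.centerline_um)
    s0 = fragment.depth_below_orifice_mm * MM
    p0 = cl.point_at_s(s0)
    v = cl.tangent_at_s(s0)  # apical-pointing; corridor extends coronally
    z_orifice = float(volume.centerline_um[0, 2])
    mask = _carve_cylinder_slices(
        out, p0, v, platform_diameter_mm * MM / 2.0, z_lo=p0[2], z_hi=z_orifice
    )
    mask &= (out.labels == DENTIN) | (out.labels == CANAL)
    out.labels[mask] = REMOVED
    return out


def carve_trough(
    volume: ToothVolume, fragment: Fragment, spec: TroughSpec
) -> ToothVolume:
    """Trephine the collar of dentin around the fragment.

    A cylinder of diameter D, coaxial with the canal tangent at the
    fragment's coronal end, extends ``trough_depth`` apically from that end;
    dentin and canal voxels inside it (never metal) become ``removed``.

    If the trough exits the root the volume is flagged ``perforated`` rather
    than raising: the downstream minimum-RDT reads 0.
    """
    _require_fragment(volume)
    out = volume.copy()
    if spec.trough_depth_mm == 0:
        return out
    cl = _Polyline(volume.centerline_um)
    s0 = fragment.depth_below_orifice_mm * MM
    p0 = cl.point_at_s(s0)
    v = cl.tangent_at_s(s0)
    depth_um = spec.trough_depth_mm * MM
    z_bottom = p0[2] + v[2] * depth_um  # v points apically (v[2] < 0)
    mask = _carve_cylinder_slices(
        out, p0, v, spec.trough_diameter_mm * MM / 2.0, z_lo=z_bottom, z_hi=p0[2]
    )
    mask &= (out.labels == DENTIN) | (out.labels == CANAL)
    out.labels[mask] = REMOVED

    # perforation: the freshly removed space reaches exterior air
    from .thickness3d import exterior_mask  # local import avoids a cycle

    ext = exterior_mask(out)
    touched = ndimage.binary_dilation(
        mask, structure=ndimage.generate_binary_structure(3, 1)
    )
    if np.any(touched & ext):
        out.perforated = True
    return out


def trough_z_span(volume: ToothVolume, fragment: Fragment, spec: TroughSpec) -> tuple[int, int]:
    """Voxel z-index interval (half-open) of the trough: the danger zone ROI."""
    cl = _Polyline(volume.centerline_um)
    s0 = fragment.depth_below_orifice_mm * MM
    p0 = cl.point_at_s(s0)
    v = cl.tangent_at_s(s0)
    z_bottom = p0[2] + v[2] * spec.trough_depth_mm * MM
    k0 = volume.z_index(z_bottom)
    k1 = volume.z_index(p0[2])
    return (min(k0, k1), max(k0, k1) + 1)
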