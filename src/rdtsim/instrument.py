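"""Tapered endodontic-file geometry and virtual fragment placement.

A rotary file of nominal size 25 and 0.06 taper has a 0.25 mm tip diameter
that grows linearly by 0.06 mm per mm towards the shank.  The simulated
mishap is a 3 mm apical segment of such a file separated inside the
mesiobuccal canal, its coronal end 3 or 5 mm below the canal orifice; the
coronal diameter of the segment (``Db``) therefore equals
``tip + taper * length`` = 0.43 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CANAL, METAL, ToothVolume

MM = 1000.0  # μm per mm


class FragmentExceedsCanalError(ValueError):
    """Fragment placement runs past the apical end of the canal."""


def file_diameter(distance_from_tip_mm: float, tip_diameter_mm: float, taper: float) -> float:
    """Diameter (mm) of a tapered file at a distance from its tip.

    ``diameter = tip + taper * distance``; e.g. a size 25 / 0.06 file is
    0.43 mm across at 3 mm from the tip.
    """
    if distance_from_tip_mm < 0:
        raise ValueError("distance_from_tip_mm must be >= 0")
    return tip_diameter_mm + taper * distance_from_tip_mm


@dataclass
class Fragment:
    """A separated apical file segment lodged in the canal."""

    tip_diameter_mm: float = 0.25
    taper: float = 0.06
    length_mm: float = 3.0
    depth_below_orifice_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.length_mm < 0:
            raise ValueError("length_mm must be >= 0")
        if self.depth_below_orifice_mm < 0:
            raise ValueError("depth must be >= 0")

    @property
    def coronal_diameter_mm(self) -> float:
        """Db, the diameter at the fragment's coronal (broken) end."""
        return file_diameter(self.length_mm, self.tip_diameter_mm, self.taper)


def place_fragment(volume: ToothVolume, fragment: Fragment) -> ToothVolume:
    """Relabel the canal voxels occupied by the fragment as metal.

    The fragment is a truncated cone swept along the canal centreline from
    arc length ``depth`` (coronal end, diameter Db) to ``depth + length``
    (tip).  Depth is arc length from the orifice — the segment is assumed to
    conform to the canal curvature as a real NiTi segment does.  Only
    canal-space voxels are converted; dentin and background are never
    touched, so a fragment wider than the canal is clipped by the walls.
    """
    if volume.centerline_um is None:
        raise ValueError("volume has no canal centreline; cannot place a fragment")
    out = volume.copy()
    if fragment.length_mm == 0:
        return out
    cl = _Polyline(volume.centerline_um)
    s0 = fragment.depth_below_orifice_mm * MM
    s1 = s0 + fragment.length_mm * MM
    if s1 > cl.arc_length + volume.voxel_size_um:
        raise FragmentExceedsCanalError(
            f"fragment spans arc [{s0:.0f}, {s1:.0f}] um but canal arc length "
            f"is {cl.arc_length:.0f} um"
        )
    zax = out.world_axis(2)
    s_z = cl.s_of_z(zax)
    inside_z = (s_z >= s0) & (s_z <= s1)
    cx, cy = cl.xy_of_z(zax)
    # local radius: tip diameter grows linearly towards the coronal end
    dist_mm = np.clip(s1 - s_z, 0.0, None) / MM
    dia_um = (fragment.tip_diameter_mm + fragment.taper * dist_mm) * MM
    r_z = np.where(inside_z, dia_um / 2.0, 0.0)
    xax = out.world_axis(0)[:, None, None].astype(np.float32)
    yax = out.world_axis(1)[None, :, None].astype(np.float32)
    d2 = (xax - cx[None, None, :].astype(np.float32)) ** 2 + (
        yax - cy[None, None, :].astype(np.float32)
    ) ** 2
    cone = d2 <= (r_z[None, None, :].astype(np.float32)) ** 2
    cone &= r_z[None, None, :] > 0
    out.labels[cone & (out.labels == CANAL)] = METAL
    return out


class _Polyline:
    """Arc-length bookkeeping on a stored centreline polyline."""

    def __init__(self, points_um: np.ndarray):
        pts = np.asarray(points_um, dtype=float)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.points = pts
        self.s = np.concatenate([[0.0], np.cumsum(seg)])
        self.arc_length = float(self.s[-1])
        self._z_desc = pts[:, 2]

    def s_of_z(self, z_um):
        z = np.clip(z_um, self._z_desc[-1], self._z_desc[0])
        return np.interp(z, self._z_desc[::-1], self.s[::-1])

    def xy_of_z(self, z_um):
        z = np.clip(z_um, self._z_desc[-1], self._z_desc[0])
        x = np.interp(z, self._z_desc[::-1], self.points[::-1, 0])
        y = np.interp(z, self._z_desc[::-1], self.points[::-1, 1])
        return x, y

    def point_at_s(self, s_um) -> np.ndarray:
        s = np.clip(s_um, 0.0, self.arc_length)
        return np.asarray(
            [np.interp(s, self.s, self.points[:, i]) for i in range(3)]
        )

    def tangent_at_s(self, s_um) -> np.ndarray:
        s = float(np.clip(s_um, 0.0, self.arc_length))
        i = int(np.searchsorted(self.s, s))
        i = max(1, min(i, len(self.s) - 1))
        v = self.points[i] - self.points[i - 1]
        n = np.linalg.norm(v)
        if n == 0:
            return np.asarray([0.0, 0.0, -1.0])
        return v / n
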