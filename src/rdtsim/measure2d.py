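"""2D remaining-dentin-thickness measurement on simulated radiographs.

Mirrors the manual ImageJ workflow: the straight-line-access rectangle
(width = trough diameter D, height = fragment depth + trough depth) is
overlaid on the projection, centred on the projected canal axis with its
top edge at orifice level, and the RDT is read off as the minimum distance
from the rectangle's side to the external root edge on that side.

Distances default to horizontal (perpendicular to the projected long axis),
as a ruler measurement on a film; a point-to-nearest-edge variant is
available.  The measured side defaults to distal (+x in the image) — the
furcal danger zone where the MB root wall is thinnest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .projection import Projection2D
from .removal import RectangleSpec

MM = 1000.0


@dataclass
class RDTRecord:
    """One minimum-RDT reading."""

    value_um: float
    method: str  # "3D", "Pa" (paralleling) or "An" (angled/parallax)
    depth_group_mm: float
    phantom_id: str = ""
    angle_deg: float | None = None
    side: str = "distal"

    def __post_init__(self) -> None:
        if self.value_um < 0:
            raise ValueError("value_um must be >= 0")
        if self.method not in ("3D", "Pa", "An"):
            raise ValueError("method must be one of 3D, Pa, An")


def detect_root_edge(
    projection: Projection2D, threshold_fraction: float = 0.05
) -> np.ndarray:
    """Boundary pixels of the thresholded tooth silhouette.

    The silhouette is ``pixels >= threshold_fraction * max``; its edge is
    the silhouette minus its erosion.
    """
    pix = projection.pixels
    peak = float(pix.max(initial=0.0))
    if peak <= 0:
        raise ValueError("blank projection: no structure mass")
    mask = pix >= threshold_fraction * peak
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    return mask & ~interior


def min_rdt_2d(
    projection: Projection2D,
    rectangle: RectangleSpec,
    side: str = "distal",
    threshold_fraction: float = 0.05,
    mode: str = "horizontal",
    method: str = "Pa",
    depth_group_mm: float = 3.0,
    phantom_id: str = "",
) -> RDTRecord:
    """Minimum distance (μm) from a rectangle side to the root edge.

    The rectangle must be anchored (``rectangle.anchor_um`` = (x, z) of its
    centre-top in the projection frame).  For each image row over the
    rectangle's vertical extent the distance from the side to the silhouette
    edge on that side is taken; the minimum over rows is the 2D-RDT.  A
    rectangle side falling outside the root reads 0 — a radiographic
    perforation.
    """
    if rectangle.anchor_um is None:
        raise ValueError("rectangle is not anchored on the projection")
    if side not in ("distal", "mesial"):
        raise ValueError("side must be 'distal' or 'mesial'")
    if mode not in ("horizontal", "nearest"):
        raise ValueError("mode must be 'horizontal' or 'nearest'")

    pix = projection.pixels
    peak = float(pix.max(initial=0.0))
    if peak <= 0:
        raise ValueError("blank projection: no structure mass")
    mask = pix >= threshold_fraction * peak

    px = projection.pixel_size_um
    ax, az = rectangle.anchor_um
    half_w = rectangle.width_mm * MM / 2.0
    side_x = ax + half_w if side == "distal" else ax - half_w
    z_top = az
    z_bot = az - rectangle.height_mm * MM

    x0, z0 = projection.origin_xz_um
    j_lo = max(0, int(np.ceil((z_bot - z0) / px)))
    j_hi = min(pix.shape[1] - 1, int(np.floor((z_top - z0) / px)))
    if j_hi < j_lo:
        raise ValueError("rectangle lies outside the projection grid")

    xs = x0 + px * np.arange(pix.shape[0])
    if mode == "horizontal":
        dists = []
        for j in range(j_lo, j_hi + 1):
            cols = np.nonzero(mask[:, j])[0]
            if cols.size == 0:
                continue  # row beyond the root (e.g. above/below it)
            if side == "distal":
                d = xs[cols[-1]] - side_x
            else:
                d = side_x - xs[cols[0]]
            dists.append(d)
        if not dists:
            raise ValueError("no silhouette rows under the rectangle")
        value = max(0.0, min(dists))
    else:
        edge = detect_root_edge(projection, threshold_fraction)
        ei, ej = np.nonzero(edge)
        ex, ez = xs[ei], z0 + px * ej
        if side == "distal":
            keep = ex >= side_x
        else:
            keep = ex <= side_x
        ex, ez = ex[keep], ez[keep]
        if ex.size == 0:
            value = 0.0
        else:
            zq = np.clip(ez, z_bot, z_top)
            value = float(np.sqrt((ex - side_x) ** 2 + (ez - zq) ** 2).min())

    return RDTRecord(
        value_um=float(value),
        method=method,
        depth_group_mm=depth_group_mm,
        phantom_id=phantom_id,
        angle_deg=projection.angle_deg,
        side=side,
    )
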