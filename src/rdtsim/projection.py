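"""Simulated radiographs by parallel-beam ray casting.

A digitally reconstructed radiograph (DRR) is produced by rotating the
volume's attenuation field about the tooth long axis by a horizontal angle
θ and integrating along the fixed ray direction (grid axis 1).  θ = 0 is the
paralleling (buccolingual) view; positive angles move the palatal root
distally (+x in the image) out of the mesiobuccal ray path — the parallax
manoeuvre.  Parallel-beam (orthographic) geometry is used throughout, so
analytic chord-length oracles are exact and there is no magnification.

The parallax-angle search finds the smallest rotation at which the
silhouettes of two named structures (MB root, palatal root) no longer share
any image pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ToothVolume


class NoSeparationError(RuntimeError):
    """Silhouette overlap persists across the whole scanned angle range."""

    def __init__(self, message: str, result: "ParallaxResult"):
        super().__init__(message)
        self.result = result


@dataclass
class Projection2D:
    """A simulated radiograph.

    ``pixels[i, j]`` is the line-integral attenuation (dimensionless optical
    depth) at image column ``i`` (x′, the rotated in-plane axis) and row
    ``j`` (z, the long axis).  ``origin_xz_um`` is the (x′, z) world
    coordinate of pixel (0, 0); the x′ frame shares the world frame through
    the rotation pivot (the volume centre).
    """

    pixels: np.ndarray
    pixel_size_um: float
    angle_deg: float
    origin_xz_um: tuple[float, float] = (0.0, 0.0)
    geometry_tag: str = "parallel-beam"

    def pixel_index(self, x_um: float, z_um: float) -> tuple[int, int]:
        i = int(round((x_um - self.origin_xz_um[0]) / self.pixel_size_um))
        j = int(round((z_um - self.origin_xz_um[1]) / self.pixel_size_um))
        return i, j


def _pad_amounts(nx: int, ny: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Symmetric in-plane padding so no mass leaves the grid under rotation.

    Pad parity matches the original size so the rotation pivot (grid centre)
    stays at the same world point.
    """
    side = int(np.ceil(np.hypot(nx, ny))) + 2
    out = []
    for n in (nx, ny):
        s = side if (side - n) % 2 == 0 else side + 1
        p = (s - n) // 2
        out.append((p, p))
    return out[0], out[1]


def _rotation_matrices(angle_deg: float):
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    fwd = np.array([[c, s], [-s, c]])  # content motion: x' = x c + y s
    inv = fwd.T
    return fwd, inv


def _rotate_xy(arr: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Rotate array content about the in-plane grid centre (axes 0, 1)."""
    _, inv = _rotation_matrices(angle_deg)
    m = np.eye(3)
    m[:2, :2] = inv
    centre = (np.asarray(arr.shape, dtype=float) - 1) / 2.0
    offset = centre - m @ centre
    return ndimage.affine_transform(
        arr, m, offset=offset, order=order, mode="constant", cval=0.0, prefilter=False
    )


def render_drr(
    volume: ToothVolume,
    angle_deg: float,
    attenuation: dict[int, float] | None = None,
    pad: bool = True,
) -> Projection2D:
    """Render a parallel-beam radiograph at a horizontal angle.

    The per-label attenuation map (mm⁻¹) must cover every label present in
    the volume.  The attenuation field is rotated with trilinear
    interpolation and summed along grid axis 1, scaled by the voxel size so
    pixel values are path integrals ∫μ dl.
    """
    if attenuation is None:
        from .phantom import _default_attenuation

        attenuation = _default_attenuation()
    present = np.unique(volume.labels)
    missing = [int(l) for l in present if int(l) not in attenuation]
    if missing:
        raise KeyError(f"attenuation coefficient missing for labels {missing}")
    lut = np.zeros(int(present.max()) + 1, dtype=np.float32)
    for lab, mu in attenuation.items():
        if lab < len(lut):
            lut[lab] = mu
        if mu < 0:
            raise ValueError("attenuation coefficients must be >= 0")
    field = lut[volume.labels]

    origin_x = volume.origin_um[0]
    if pad:
        (px0, px1), (py0, py1) = _pad_amounts(*field.shape[:2])
        field = np.pad(field, ((px0, px1), (py0, py1), (0, 0)))
        origin_x -= px0 * volume.voxel_size_um
    if angle_deg != 0.0:
        field = _rotate_xy(field, angle_deg, order=1)
    pixels = field.sum(axis=1) * (volume.voxel_size_um / 1000.0)
    return Projection2D(
        pixels=pixels.astype(np.float64),
        pixel_size_um=volume.voxel_size_um,
        angle_deg=float(angle_deg),
        origin_xz_um=(float(origin_x), float(volume.origin_um[2])),
    )


def project_point(
    volume: ToothVolume, point_um, angle_deg: float
) -> tuple[float, float]:
    """(x′, z) projection-frame coordinate of a world point at angle θ."""
    fwd, _ = _rotation_matrices(angle_deg)
    c = volume.center_um()
    p = np.asarray(point_um, dtype=float)
    xy = fwd @ (p[:2] - c[:2]) + c[:2]
    return float(xy[0]), float(p[2])


def silhouette(projection: Projection2D, threshold: float = 0.0) -> np.ndarray:
    """Binary mask of image pixels carrying structure mass above a threshold
    (default: any mass)."""
    return projection.pixels > threshold


def structure_silhouette(
    volume: ToothVolume, structure: str | np.ndarray, angle_deg: float
) -> np.ndarray:
    """Silhouette of one labelled structure at angle θ.

    The binary mask is rotated with nearest-neighbour sampling (no
    partial-volume leakage) and collapsed along the ray axis.
    """
    mask = volume.structures[structure] if isinstance(structure, str) else structure
    m = mask.astype(np.float32)
    (px0, px1), (py0, py1) = _pad_amounts(*m.shape[:2])
    m = np.pad(m, ((px0, px1), (py0, py1), (0, 0)))
    if angle_deg != 0.0:
        m = _rotate_xy(m, angle_deg, order=0)
    return m.any(axis=1)


# ---------------------------------------------------------------------------
# parallax-angle search


@dataclass
class ParallaxResult:
    """Outcome of the silhouette-separation scan."""

    angle_deg: float  # smallest separating angle (signed by direction)
    angles_deg: np.ndarray  # scanned angles (signed)
    overlap_px: np.ndarray  # silhouette overlap area (pixels) per angle
    separated: bool
    min_overlap_angle_deg: float


class _SliceExtents:
    """Per-slice in-plane boundary coordinates of a structure, grouped by z."""

    def __init__(self, volume: ToothVolume, mask: np.ndarray):
        # in-plane boundary voxels are enough to bound each slice's extent
        interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 1), bool))
        i, j, k = np.nonzero(mask & ~interior)
        order = np.argsort(k, kind="stable")
        i, j, k = i[order], j[order], k[order]
        self.x = volume.world_axis(0)[i]
        self.y = volume.world_axis(1)[j]
        c = volume.center_um()
        self.x -= c[0]
        self.y -= c[1]
        self.z_rows, self.starts = np.unique(k, return_index=True)

    def intervals(self, cos_t: float, sin_t: float, margin: float):
        xp = self.x * cos_t + self.y * sin_t
        lo = np.minimum.reduceat(xp, self.starts) - margin
        hi = np.maximum.reduceat(xp, self.starts) + margin
        return lo, hi


def find_parallax_angle(
    volume: ToothVolume,
    structure_a: str = "mb_root",
    structure_b: str = "palatal_root",
    step_deg: float = 0.5,
    max_angle_deg: float = 90.0,
    direction: int = 1,
    overlap_threshold_px: float = 0.0,
) -> ParallaxResult:
    """Smallest horizontal angle freeing structure A from overlap with B.

    Angles ``0, step, 2·step, …`` (times ``direction`` = ±1) are scanned;
    at each, the projected silhouettes of the two structures are compared
    and the first angle with zero pixel overlap (or overlap below
    ``overlap_threshold_px``) is returned together with the full
    overlap-vs-angle profile.

    Overlap is decided on nearest-neighbour-rasterised silhouettes.  A fast
    per-slice interval bound on rotated boundary-voxel coordinates (the
    projection of a solid slice onto the image axis is an interval) first
    rules out clearly-overlapping angles, so the full masks are only
    rasterised near the separation angle.

    Raises
    ------
    NoSeparationError
        If overlap persists over the whole range; the exception carries the
        profile and the minimum-overlap angle.
    """
    mask_a = volume.structures[structure_a] if isinstance(structure_a, str) else structure_a
    mask_b = volume.structures[structure_b] if isinstance(structure_b, str) else structure_b
    if not np.any(mask_a) or not np.any(mask_b):
        raise ValueError("both structures must be nonempty")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")

    ext_a = _SliceExtents(volume, mask_a)
    ext_b = _SliceExtents(volume, mask_b)
    common, ia, ib = np.intersect1d(
        ext_a.z_rows, ext_b.z_rows, assume_unique=True, return_indices=True
    )
    vox = volume.voxel_size_um
    # image-pixel centres sit at origin + i*vox; offset relative to the pivot
    pix_off = volume.origin_um[0] - volume.center_um()[0]
    steps = np.arange(0.0, max_angle_deg + step_deg / 2.0, step_deg)
    angles = direction * steps
    overlaps = np.empty_like(steps)
    hit = None
    for idx, ang in enumerate(angles):
        th = np.deg2rad(ang)
        c, s = np.cos(th), np.sin(th)
        if common.size == 0:
            est = 0.0
        else:
            # lower bound: pixel centres strictly inside both slices'
            # boundary-voxel-centre extents are covered by both silhouettes
            lo_a, hi_a = ext_a.intervals(c, s, 0.0)
            lo_b, hi_b = ext_b.intervals(c, s, 0.0)
            lo = np.maximum(lo_a[ia], lo_b[ib])
            hi = np.minimum(hi_a[ia], hi_b[ib])
            i_lo = np.ceil((lo - pix_off) / vox)
            i_hi = np.floor((hi - pix_off) / vox)
            est = float(np.clip(i_hi - i_lo + 1, 0, None).sum())
        if est > overlap_threshold_px:
            overlaps[idx] = est  # certainly still overlapping
            continue
        sil_a = structure_silhouette(volume, mask_a, ang)
        sil_b = structure_silhouette(volume, mask_b, ang)
        overlaps[idx] = float((sil_a & sil_b).sum())
        if overlaps[idx] <= overlap_threshold_px:
            hit = idx
            break
    if hit is None:
        # exact profile for the failure report: the fallback angle (used as
        # the best-available view) should be the true minimum-overlap angle
        for idx, ang in enumerate(angles):
            sil_a = structure_silhouette(volume, mask_a, ang)
            sil_b = structure_silhouette(volume, mask_b, ang)
            overlaps[idx] = float((sil_a & sil_b).sum())
        best = int(np.argmin(overlaps))
        result = ParallaxResult(
            angle_deg=float(angles[best]),
            angles_deg=angles,
            overlap_px=overlaps,
            separated=False,
            min_overlap_angle_deg=float(angles[best]),
        )
        raise NoSeparationError(
            f"silhouette overlap persists up to {max_angle_deg} deg "
            f"(minimum {overlaps[best]:.1f} px at {angles[best]:.1f} deg)",
            result,
        )
    return ParallaxResult(
        angle_deg=float(angles[hit]),
        angles_deg=angles[: hit + 1],
        overlap_px=overlaps[: hit + 1],
        separated=True,
        min_overlap_angle_deg=float(angles[hit]),
    )
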