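"""Synthetic tooth phantoms.

Real maxillary-first-molar micro-CT data is not publicly available, so the
pipeline runs on parametric voxel phantoms that reproduce the anatomical
structure the analysis depends on:

* a mesiobuccal (MB) root whose curved canal is swept along a piecewise-cubic
  centreline, with tapering canal and outer-wall radius profiles;
* a furcal-side concavity — a spherical-cap indentation of the outer root
  surface facing the furcation — which thins the wall without changing the
  buccolingual (0°) silhouette, the mechanism by which paralleling
  radiographs overestimate the remaining dentin thickness;
* a palatal root displaced mainly along the 0° ray direction so that its
  projection overlaps the MB root on a paralleling view and separates only
  after a horizontal (parallax) rotation of roughly 20°.

All geometry is in world micrometres; the voxel grid is isotropic with the
tooth long axis on grid axis 2 (apex at low index, orifice/crown at high
index).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

from .volume import BACKGROUND, CANAL, DENTIN, METAL, ToothVolume


class PerforatedPhantomError(ValueError):
    """The requested concavity would breach the canal wall."""


class GridTooSmallError(ValueError):
    """Explicit grid bounds do not contain the requested geometry."""


# ---------------------------------------------------------------------------
# parameters


def _default_centerline() -> list[tuple[float, float, float]]:
    # Gentle palatal-ward curve typical of an MB canal, orifice -> apical end.
    return [
        (0.0, 0.0, 11500.0),
        (0.0, 150.0, 9000.0),
        (0.0, 600.0, 5500.0),
        (0.0, 1100.0, 1500.0),
    ]


def _default_attenuation() -> dict[int, float]:
    # Linear attenuation coefficients in mm^-1 (relative scale): dentin at
    # dental x-ray energies, NiTi metal an order of magnitude denser,
    # instrumented/empty space radiolucent.
    return {BACKGROUND: 0.0, DENTIN: 0.07, CANAL: 0.0, METAL: 1.5, 4: 0.0}


@dataclass
class PhantomParams:
    """Parameters of one synthetic tooth.

    Lengths are μm.  Radius profiles are ``(arc_length_um, radius_um)``
    breakpoints, linearly interpolated along the canal arc length measured
    from the orifice.  ``concavity_azimuth_deg`` is the direction the
    indentation faces in the axial plane (0° = distal/+x, 90° = palatal/+y);
    the default faces the furcation, between distal and palatal.
    """

    voxel_size_um: float = 30.0
    canal_centerline_um: list = field(default_factory=_default_centerline)
    canal_radius_profile_um: list = field(
        default_factory=lambda: [(0.0, 350.0), (5000.0, 280.0), (10000.0, 140.0)]
    )
    outer_radius_profile_um: list = field(
        default_factory=lambda: [(0.0, 1600.0), (6000.0, 1250.0), (10000.0, 700.0)]
    )
    concavity_depth_um: float = 300.0
    concavity_axial_extent_um: tuple = (2000.0, 7000.0)
    concavity_azimuth_deg: float = 40.0
    palatal_root_offset_um: tuple = (1200.0, 7000.0, 0.0)
    palatal_root_radius_um: float = 2000.0
    attenuation: dict = field(default_factory=_default_attenuation)
    orifice_position_um: tuple | None = None  # default: first centreline point
    apex_cap_um: float = 1000.0  # dentin below the canal's apical end
    crown_connector: bool = True  # furcation slab joining the two roots
    surface_noise_um: float = 0.0  # seeded outer-surface roughness (σ)
    grid_bounds_um: tuple | None = None  # ((xmin,xmax),(ymin,ymax),(zmin,zmax))

    def __post_init__(self) -> None:
        if self.orifice_position_um is None:
            self.orifice_position_um = tuple(self.canal_centerline_um[0])

    # -- profile helpers --------------------------------------------------

    def canal_radius(self, s_um):
        pts = np.asarray(self.canal_radius_profile_um, dtype=float)
        return np.interp(s_um, pts[:, 0], pts[:, 1])

    def outer_radius(self, s_um):
        pts = np.asarray(self.outer_radius_profile_um, dtype=float)
        return np.interp(s_um, pts[:, 0], pts[:, 1])

    def validate(self) -> None:
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        for prof, name in (
            (self.canal_radius_profile_um, "canal_radius_profile_um"),
            (self.outer_radius_profile_um, "outer_radius_profile_um"),
        ):
            arr = np.asarray(prof, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or np.any(arr[:, 1] <= 0):
                raise ValueError(f"{name} must be (arc, radius>0) pairs")
        if self.palatal_root_radius_um < 0:
            raise ValueError("palatal_root_radius_um must be >= 0")
        ctrl = np.asarray(self.canal_centerline_um, dtype=float)
        if ctrl.ndim != 2 or ctrl.shape[0] < 2 or ctrl.shape[1] != 3:
            raise ValueError("canal_centerline_um needs >= 2 3D points")
        if not np.all(np.diff(ctrl[:, 2]) < 0):
            raise ValueError("centreline z must decrease from orifice to apex")
        att = self.attenuation
        if att.get(BACKGROUND, 0.0) != 0.0:
            raise ValueError("attenuation[background] must be 0")
        if not (att.get(METAL, 0.0) > att.get(DENTIN, 0.0) > 0.0):
            raise ValueError("need attenuation[metal] > attenuation[dentin] > 0")
        if self.concavity_depth_um < 0:
            raise ValueError("concavity_depth_um must be >= 0")
        if self.concavity_depth_um > 0:
            s0, s1 = self.concavity_axial_extent_um
            if not s1 > s0 >= 0:
                raise ValueError("concavity_axial_extent_um must be increasing")
            s_mid = 0.5 * (s0 + s1)
            wall = self.outer_radius(s_mid) - self.canal_radius(s_mid)
            if self.concavity_depth_um >= wall - 2 * self.voxel_size_um:
                raise PerforatedPhantomError(
                    f"concavity depth {self.concavity_depth_um} um >= local wall "
                    f"thickness {wall:.0f} um"
                )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canal_centerline_um"] = [list(p) for p in self.canal_centerline_um]
        d["canal_radius_profile_um"] = [list(p) for p in self.canal_radius_profile_um]
        d["outer_radius_profile_um"] = [list(p) for p in self.outer_radius_profile_um]
        d["concavity_axial_extent_um"] = list(self.concavity_axial_extent_um)
        d["palatal_root_offset_um"] = list(self.palatal_root_offset_um)
        d["attenuation"] = {int(k): float(v) for k, v in self.attenuation.items()}
        if d["orifice_position_um"] is not None:
            d["orifice_position_um"] = list(d["orifice_position_um"])
        if d["grid_bounds_um"] is not None:
            d["grid_bounds_um"] = [list(b) for b in d["grid_bounds_um"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        d = dict(d)
        if "attenuation" in d:
            d["attenuation"] = {int(k): float(v) for k, v in d["attenuation"].items()}
        return cls(**d)


def default_params(voxel_size_um: float = 30.0) -> PhantomParams:
    """Study-condition default phantom at the given resolution."""
    return PhantomParams(voxel_size_um=voxel_size_um)


# ---------------------------------------------------------------------------
# centreline machinery


class _Centerline:
    """Piecewise-cubic canal centreline parameterised by height z.

    Arc length ``s`` runs from 0 at the orifice, increasing apically.
    """

    def __init__(self, control_points_um, step_um: float):
        ctrl = np.asarray(control_points_um, dtype=float)
        z_asc = ctrl[::-1, 2]
        self._fx = PchipInterpolator(z_asc, ctrl[::-1, 0])
        self._fy = PchipInterpolator(z_asc, ctrl[::-1, 1])
        self.z_top = float(ctrl[0, 2])
        self.z_bottom = float(ctrl[-1, 2])
        zf = np.arange(self.z_top, self.z_bottom, -step_um)
        zf = np.append(zf, self.z_bottom)
        dxdz = self._fx.derivative()(zf)
        dydz = self._fy.derivative()(zf)
        seg = np.sqrt(1.0 + dxdz**2 + dydz**2) * np.abs(np.diff(zf, prepend=zf[0]))
        self._zf = zf
        self._sf = np.cumsum(seg)
        self._sf[0] = 0.0
        self.arc_length = float(self._sf[-1])

    def xy(self, z_um):
        z = np.clip(z_um, self.z_bottom, self.z_top)
        return self._fx(z), self._fy(z)

    def s_of_z(self, z_um):
        z = np.clip(z_um, self.z_bottom, self.z_top)
        return np.interp(z, self._zf[::-1], self._sf[::-1])

    def z_of_s(self, s_um):
        s = np.clip(s_um, 0.0, self.arc_length)
        return np.interp(s, self._sf, self._zf)

    def point_at_s(self, s_um) -> np.ndarray:
        z = self.z_of_s(s_um)
        x, y = self.xy(z)
        return np.asarray([float(x), float(y), float(z)])

    def tangent_at_s(self, s_um) -> np.ndarray:
        """Unit tangent pointing apically (negative z component)."""
        z = float(self.z_of_s(s_um))
        dxdz = float(self._fx.derivative()(np.clip(z, self.z_bottom, self.z_top)))
        dydz = float(self._fy.derivative()(np.clip(z, self.z_bottom, self.z_top)))
        v = np.asarray([-dxdz, -dydz, -1.0])
        return v / np.linalg.norm(v)

    def polyline(self) -> np.ndarray:
        x, y = self.xy(self._zf)
        return np.column_stack([x, y, self._zf])


# ---------------------------------------------------------------------------
# generation


def _round_span(lo: float, hi: float, vox: float) -> np.ndarray:
    n = int(np.ceil((hi - lo) / vox)) + 1
    return lo + vox * np.arange(n)


def generate_phantom(params: PhantomParams, seed: int = 0) -> ToothVolume:
    """Rasterise one synthetic tooth.

    Deterministic for a fixed ``(params, seed)``; the seed only drives the
    optional outer-surface roughness (``surface_noise_um``, default 0).

    Raises
    ------
    PerforatedPhantomError
        If the concavity would reach the canal.
    GridTooSmallError
        If explicit ``grid_bounds_um`` do not contain the geometry.
    """
    params.validate()
    vox = params.voxel_size_um
    cl = _Centerline(params.canal_centerline_um, step_um=vox / 2.0)
    z_orifice = cl.z_top
    z_canal_end = cl.z_bottom
    z_root_end = z_canal_end - params.apex_cap_um

    # ---- grid extents ----------------------------------------------------
    s_dense = np.linspace(0.0, cl.arc_length, 256)
    r_out_max = float(np.max(params.outer_radius(s_dense)))
    cx_d, cy_d = cl.xy(cl.z_of_s(s_dense))
    xmin = float(np.min(cx_d)) - r_out_max
    xmax = float(np.max(cx_d)) + r_out_max
    ymin = float(np.min(cy_d)) - r_out_max
    ymax = float(np.max(cy_d)) + r_out_max
    pr = params.palatal_root_radius_um
    if pr > 0:
        pcx = params.canal_centerline_um[0][0] + params.palatal_root_offset_um[0]
        pcy = params.canal_centerline_um[0][1] + params.palatal_root_offset_um[1]
        xmin = min(xmin, pcx - pr)
        xmax = max(xmax, pcx + pr)
        ymin = min(ymin, pcy - pr)
        ymax = max(ymax, pcy + pr)
    margin = 4 * vox
    bounds = (
        (xmin - margin, xmax + margin),
        (ymin - margin, ymax + margin),
        (z_root_end - margin, z_orifice + margin),
    )
    if params.grid_bounds_um is not None:
        gb = params.grid_bounds_um
        for (need_lo, need_hi), (got_lo, got_hi) in zip(bounds, gb):
            if got_lo > need_lo + margin - vox or got_hi < need_hi - margin + vox:
                raise GridTooSmallError(
                    f"grid bounds {gb} do not contain geometry {bounds}"
                )
        bounds = tuple(tuple(b) for b in gb)

    xax = _round_span(bounds[0][0], bounds[0][1], vox)
    yax = _round_span(bounds[1][0], bounds[1][1], vox)
    zax = _round_span(bounds[2][0], bounds[2][1], vox)
    nx, ny, nz = len(xax), len(yax), len(zax)

    # ---- per-slice radii and centres ------------------------------------
    in_root = (zax <= z_orifice + 1e-9) & (zax >= z_root_end - 1e-9)
    in_canal = (zax <= z_orifice + 1e-9) & (zax >= z_canal_end - 1e-9)
    s_z = cl.s_of_z(zax)
    czx, czy = cl.xy(zax)
    r_out_z = np.where(in_root, params.outer_radius(s_z), 0.0)
    if params.apex_cap_um > 0:
        in_cap = in_root & (zax < z_canal_end)
        frac = np.clip((zax - z_root_end) / params.apex_cap_um, 0.0, 1.0)
        cap_shape = np.sqrt(np.clip(1.0 - (1.0 - frac) ** 2, 0.0, 1.0))
        # rounded apical tip: shrink the last-known outer radius to zero
        r_out_z = np.where(in_cap, params.outer_radius(cl.arc_length) * cap_shape, r_out_z)
    if params.surface_noise_um > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, params.surface_noise_um, size=nz)
        noise = ndimage.gaussian_filter1d(noise, sigma=3.0)
        r_out_z = np.where(in_root, np.maximum(r_out_z + noise, vox), r_out_z)
    r_can_z = np.where(in_canal, params.canal_radius(s_z), 0.0)

    X = xax[:, None, None].astype(np.float32)
    Y = yax[None, :, None].astype(np.float32)
    D2 = (X - czx[None, None, :].astype(np.float32)) ** 2 + (
        Y - czy[None, None, :].astype(np.float32)
    ) ** 2

    mb_inside = D2 <= (r_out_z[None, None, :].astype(np.float32)) ** 2
    mb_inside &= r_out_z[None, None, :] > 0
    canal_mask = D2 <= (r_can_z[None, None, :].astype(np.float32)) ** 2
    canal_mask &= (r_can_z[None, None, :] > 0) & mb_inside

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[mb_inside] = DENTIN
    labels[canal_mask] = CANAL

    pal_inside = np.zeros_like(mb_inside)
    if pr > 0:
        root_len = z_orifice - z_root_end
        taper = 1.0 - 0.55 * np.clip((z_orifice - zax) / root_len, 0.0, 1.0)
        r_p = np.where(in_root, pr * taper, 0.0)
        if params.apex_cap_um > 0:
            r_p = np.where(in_cap, r_p * cap_shape, r_p)
        P2 = (X - np.float32(pcx)) ** 2 + (Y - np.float32(pcy)) ** 2
        pal_inside = P2 <= (r_p[None, None, :].astype(np.float32)) ** 2
        pal_inside &= r_p[None, None, :] > 0
        labels[pal_inside & (labels == BACKGROUND)] = DENTIN

        if params.crown_connector:
            ox, oy = params.canal_centerline_um[0][:2]
            slab = (
                (xax[:, None, None] >= ox - 800.0)
                & (xax[:, None, None] <= pcx + 800.0)
                & (yax[None, :, None] >= oy + 700.0)
                & (yax[None, :, None] <= pcy)
                & (zax[None, None, :] >= z_orifice - 600.0)
                & (zax[None, None, :] <= z_orifice + 1e-9)
            )
            labels[slab & (labels == BACKGROUND)] = DENTIN

    # ---- furcal concavity (spherical-cap indentation) -------------------
    if params.concavity_depth_um > 0:
        s0, s1 = params.concavity_axial_extent_um
        d = params.concavity_depth_um
        h = 0.5 * (s1 - s0)
        r_s = (h**2 + d**2) / (2.0 * d)
        s_mid = 0.5 * (s0 + s1)
        centre = cl.point_at_s(s_mid)
        phi = np.deg2rad(params.concavity_azimuth_deg)
        u = np.asarray([np.cos(phi), np.sin(phi), 0.0])
        sph_c = centre + (params.outer_radius(s_mid) - d + r_s) * u
        Z = zax[None, None, :].astype(np.float32)
        dist2 = (
            (X - np.float32(sph_c[0])) ** 2
            + (Y - np.float32(sph_c[1])) ** 2
            + (Z - np.float32(sph_c[2])) ** 2
        )
        carve = (dist2 < np.float32(r_s**2)) & mb_inside & (labels == DENTIN)
        labels[carve] = BACKGROUND

    volume = ToothVolume(
        labels=labels,
        voxel_size_um=vox,
        origin_um=(float(xax[0]), float(yax[0]), float(zax[0])),
        structures={
            "mb_root": mb_inside & (labels != BACKGROUND),
            "palatal_root": pal_inside & (labels != BACKGROUND),
        },
        centerline_um=cl.polyline(),
    )

    # canal must remain enclosed by dentin except at the orifice
    if params.apex_cap_um > 0:
        bg_touch = ndimage.binary_dilation(
            labels == BACKGROUND, structure=ndimage.generate_binary_structure(3, 1)
        )
        leak = bg_touch & (labels == CANAL)
        z_ok = zax >= z_orifice - 2 * vox
        leak[:, :, z_ok] = False
        if np.any(leak):
            raise PerforatedPhantomError(
                "canal exposed to exterior away from the orifice "
                "(concavity or geometry breaches the wall)"
            )
    return volume


def analytic_tube_phantom(
    inner_radius_um: float,
    outer_radius_um: float,
    height_um: float,
    voxel_size_um: float,
) -> ToothVolume:
    """Straight hollow cylinder: the annulus oracle fixture.

    Canal label inside ``inner_radius_um``, dentin between the radii, open at
    both ends; wall thickness is ``outer - inner`` everywhere.
    """
    if not inner_radius_um < outer_radius_um:
        raise ValueError("inner radius must be < outer radius")
    params = PhantomParams(
        voxel_size_um=voxel_size_um,
        canal_centerline_um=[(0.0, 0.0, float(height_um)), (0.0, 0.0, 0.0)],
        canal_radius_profile_um=[(0.0, float(inner_radius_um))],
        outer_radius_profile_um=[(0.0, float(outer_radius_um))],
        concavity_depth_um=0.0,
        palatal_root_radius_um=0.0,
        apex_cap_um=0.0,
        crown_connector=False,
    )
    return generate_phantom(params, seed=0)


# ---------------------------------------------------------------------------
# population sampling

#: Relative spreads emulating inter-tooth variability in the study sample.
DEFAULT_VARIATION: dict[str, float] = {
    "outer_radius_profile_um": 0.05,
    "canal_radius_profile_um": 0.05,
    "concavity_depth_um": 0.25,
    "concavity_azimuth_deg": 0.15,
    "palatal_root_offset_um": 0.05,
    "canal_centerline_curvature": 0.20,
}

_MAX_RESAMPLE = 100


def sample_population(
    n: int,
    base: PhantomParams,
    variation: dict[str, float] | None = None,
    seed: int = 0,
) -> list[PhantomParams]:
    """Draw ``n`` phantom parameter sets around ``base``.

    Each varied field is scaled by an independent Gaussian factor
    ``1 + spread * N(0, 1)``; parameter sets violating the phantom invariants
    are redrawn (up to 100 attempts).  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    variation = DEFAULT_VARIATION if variation is None else variation
    known = set(DEFAULT_VARIATION) | {"palatal_root_radius_um"}
    unknown = set(variation) - known
    if unknown:
        raise ValueError(f"unknown variation fields: {sorted(unknown)}")
    if any(v < 0 for v in variation.values()):
        raise ValueError("spreads must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[PhantomParams] = []
    for _ in range(n):
        for _try in range(_MAX_RESAMPLE):
            cand = _perturb(base, variation, rng)
            try:
                cand.validate()
            except ValueError:
                continue
            out.append(cand)
            break
        else:
            raise RuntimeError("could not draw a valid parameter set in 100 tries")
    return out


def _scale_profile(profile, f: float):
    return [(float(s), float(r * f)) for s, r in profile]


def _perturb(base: PhantomParams, variation, rng) -> PhantomParams:
    cand = PhantomParams.from_dict(base.to_dict())
    for key in sorted(variation):
        spread = variation[key]
        if key in ("outer_radius_profile_um", "canal_radius_profile_um"):
            f = 1.0 + spread * rng.standard_normal()
            setattr(cand, key, _scale_profile(getattr(cand, key), f))
        elif key == "palatal_root_offset_um":
            fs = 1.0 + spread * rng.standard_normal(3)
            cand.palatal_root_offset_um = tuple(
                float(v * f) for v, f in zip(cand.palatal_root_offset_um, fs)
            )
        elif key == "canal_centerline_curvature":
            f = 1.0 + spread * rng.standard_normal()
            ctrl = np.asarray(cand.canal_centerline_um, dtype=float)
            dev = ctrl[:, :2] - ctrl[0, :2]
            ctrl[:, :2] = ctrl[0, :2] + f * dev
            cand.canal_centerline_um = [tuple(p) for p in ctrl]
        else:
            f = 1.0 + spread * rng.standard_normal()
            setattr(cand, key, float(getattr(cand, key) * f))
    cand.orifice_position_um = tuple(cand.canal_centerline_um[0])
    return cand
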