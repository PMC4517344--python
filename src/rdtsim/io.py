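"""Volume, projection and table I/O.

Volumes round-trip through MHD (+raw) or NIfTI with the voxel size in the
header; TIFF stacks are accepted read-only (they carry no voxel size, so it
must be supplied).  A JSON sidecar (``<file>.meta.json``) preserves the
canal centreline and the perforation flag, which the image headers cannot
hold.  Projections are written as 16-bit PNG/TIFF with a JSON sidecar
(angle, pixel size, intensity scale).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile
import yaml

from .projection import Projection2D
from .volume import ToothVolume

_VOLUME_SUFFIXES = (".mhd", ".nii", ".nii.gz")


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_volume(volume: ToothVolume, path) -> None:
    """Write labels + geometry as MHD or NIfTI (suffix decides the format).

    Header spacing/origin are stored in μm.  Structure masks are not
    serialised; the centreline and perforation flag go to the sidecar.
    """
    path = Path(path)
    name = path.name.lower()
    if not name.endswith(_VOLUME_SUFFIXES):
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.labels.transpose(2, 1, 0)))
    img.SetSpacing((volume.voxel_size_um,) * 3)
    img.SetOrigin(tuple(volume.origin_um))
    sitk.WriteImage(img, str(path))
    meta = {
        "voxel_size_um": volume.voxel_size_um,
        "origin_um": list(volume.origin_um),
        "perforated": volume.perforated,
        "centerline_um": None
        if volume.centerline_um is None
        else volume.centerline_um.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_volume(path, voxel_size_um: float | None = None) -> ToothVolume:
    """Read an MHD/NIfTI volume or a TIFF stack.

    TIFF stacks carry no geometry, so ``voxel_size_um`` is required for
    them (slices are taken as the long axis).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".tif", ".tiff")):
        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required for TIFF stacks")
        arr = tifffile.imread(str(path))
        labels = np.ascontiguousarray(np.asarray(arr).transpose(2, 1, 0))
        vol = ToothVolume(labels=labels, voxel_size_um=float(voxel_size_um))
    elif name.endswith(_VOLUME_SUFFIXES):
        img = sitk.ReadImage(str(path))
        labels = np.ascontiguousarray(sitk.GetArrayFromImage(img).transpose(2, 1, 0))
        spacing = img.GetSpacing()
        if max(spacing) - min(spacing) > 1e-9:
            raise ValueError("anisotropic headers are not supported")
        vol = ToothVolume(
            labels=labels.astype(np.uint8),
            voxel_size_um=float(spacing[0]),
            origin_um=tuple(img.GetOrigin()),
        )
    else:
        raise ValueError(f"unknown volume format: {path.name!r}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        vol.perforated = bool(meta.get("perforated", False))
        if meta.get("centerline_um") is not None:
            vol.centerline_um = np.asarray(meta["centerline_um"], dtype=float)
    return vol


def write_projection(projection: Projection2D, path) -> None:
    """16-bit image (PNG/TIFF) + JSON sidecar with the physical metadata.

    Image rows run coronal-to-apical (the conventional film orientation);
    pixel values are linearly rescaled to the full 16-bit range.
    """
    import imageio.v3 as iio

    path = Path(path)
    pix = projection.pixels
    peak = float(pix.max(initial=0.0))
    scale = 65535.0 / peak if peak > 0 else 1.0
    img = np.clip(pix * scale, 0, 65535).astype(np.uint16)
    iio.imwrite(str(path), img.T[::-1, :])
    meta = {
        "angle_deg": projection.angle_deg,
        "pixel_size_um": projection.pixel_size_um,
        "origin_xz_um": list(projection.origin_xz_um),
        "intensity_scale": scale,
        "geometry": projection.geometry_tag,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_projection(path) -> Projection2D:
    import imageio.v3 as iio

    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    img = iio.imread(str(path)).astype(np.float64)
    pixels = img[::-1, :].T / meta["intensity_scale"]
    return Projection2D(
        pixels=pixels,
        pixel_size_um=meta["pixel_size_um"],
        angle_deg=meta["angle_deg"],
        origin_xz_um=tuple(meta["origin_xz_um"]),
        geometry_tag=meta.get("geometry", "parallel-beam"),
    )


def write_table(df, path) -> None:
    df.to_csv(path, index=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
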