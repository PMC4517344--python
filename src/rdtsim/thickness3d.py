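"""3D remaining-dentin-thickness mapping — the gold standard measurement.

For every voxel on the prepared cavity wall (canal or removed space adjacent
to dentin) the wall thickness is the Euclidean distance to the nearest
exterior-air voxel, computed with a distance transform on the voxel grid.
"Exterior" means background connected to the grid boundary, so internal
spaces (the canal itself, enclosed voids) never terminate a distance ray.
The per-tooth 3D-RDT is the minimum of this map over an axial region of
interest, by default the axial span of the trough (the danger zone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BACKGROUND, CANAL, DENTIN, METAL, REMOVED, ToothVolume


@dataclass
class ThicknessMap:
    """Per-surface-voxel wall thickness of the cavity wall."""

    surface_voxels: np.ndarray  # (N, 3) voxel indices, C (lexicographic) order
    thickness_um: np.ndarray  # (N,)
    min_value_um: float
    min_location: tuple[int, int, int]
    perforated: bool = False


def exterior_mask(volume: ToothVolume) -> np.ndarray:
    """Background voxels connected to the grid boundary (exterior air)."""
    bg = volume.labels == BACKGROUND
    lab, n = ndimage.label(bg, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return np.zeros_like(bg)
    border = np.zeros_like(bg)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    ids = np.unique(lab[border & bg])
    ids = ids[ids > 0]
    return np.isin(lab, ids)


def distance_to_exterior_um(volume: ToothVolume) -> np.ndarray:
    """Euclidean distance (μm) from every voxel centre to the nearest
    exterior voxel centre, anisotropy-aware.

    Depends only on the outer root surface, so it can be computed once per
    phantom and reused across carving stages.
    """
    ext = exterior_mask(volume)
    return ndimage.distance_transform_edt(
        ~ext, sampling=[volume.voxel_size_um] * 3
    ).astype(np.float64)


def thickness_map(
    volume: ToothVolume,
    roi: tuple[int, int] | None = None,
    distance_um: np.ndarray | None = None,
) -> ThicknessMap:
    """Wall-thickness map of the cavity wall inside an axial ROI.

    Parameters
    ----------
    volume
        A (typically carved) tooth volume.
    roi
        Half-open z-index interval ``(k0, k1)``.  Defaults to the axial span
        of the trough — ``removed`` voxels at or below the fragment's
        coronal end — when carving has happened (the danger zone; the
        corridor's own coronal opening is not a wall), else the full grid.
    distance_um
        Optional precomputed :func:`distance_to_exterior_um` field.

    Raises
    ------
    ValueError
        If the ROI is empty or contains no cavity-wall voxels.
    """
    if roi is None:
        removed_z = np.any(volume.labels == REMOVED, axis=(0, 1))
        metal_z = np.nonzero(np.any(volume.labels == METAL, axis=(0, 1)))[0]
        if metal_z.size:  # trough only: removed space alongside the fragment
            removed_z[metal_z[-1] + 1 :] = False
        if np.any(removed_z):
            nz = np.nonzero(removed_z)[0]
            roi = (int(nz[0]), int(nz[-1]) + 1)
        else:
            roi = (0, volume.labels.shape[2])
    k0, k1 = roi
    if not (0 <= k0 < k1 <= volume.labels.shape[2]):
        raise ValueError(f"empty or out-of-grid roi {roi}")

    cavity = volume.cavity_mask()
    near_dentin = ndimage.binary_dilation(
        volume.labels == DENTIN, structure=ndimage.generate_binary_structure(3, 1)
    )
    surface = cavity & near_dentin
    surface[:, :, :k0] = False
    surface[:, :, k1:] = False
    idx = np.argwhere(surface)
    if idx.size == 0:
        raise ValueError("no cavity-wall voxels inside the roi")

    if distance_um is None:
        distance_um = distance_to_exterior_um(volume)
    vals = distance_um[surface]  # np.argwhere / boolean index share C order

    # perforation is diagnosed when the trough is carved (the access
    # corridor legitimately opens into exterior air at the orifice, so
    # exterior adjacency alone cannot distinguish a lateral breach)
    perforated = bool(volume.perforated)

    imin = int(np.argmin(vals))  # first minimum in index order breaks ties
    return ThicknessMap(
        surface_voxels=idx,
        thickness_um=vals,
        min_value_um=0.0 if perforated else float(vals[imin]),
        min_location=tuple(int(v) for v in idx[imin]),
        perforated=perforated,
    )


def min_rdt_3d(
    volume: ToothVolume,
    roi: tuple[int, int] | None = None,
    distance_um: np.ndarray | None = None,
) -> tuple[float, tuple[int, int, int]]:
    """Minimum 3D remaining dentin thickness (μm) and its voxel location.

    Returns 0 for a perforated preparation.
    """
    tmap = thickness_map(volume, roi=roi, distance_um=distance_um)
    return tmap.min_value_um, tmap.min_location


# ---------------------------------------------------------------------------
# exports


def thickness_to_csv(tmap: ThicknessMap, path) -> None:
    """Per-surface-voxel CSV: i, j, k, thickness_um."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "i": tmap.surface_voxels[:, 0],
            "j": tmap.surface_voxels[:, 1],
            "k": tmap.surface_voxels[:, 2],
            "thickness_um": tmap.thickness_um,
        }
    )
    df.to_csv(path, index=False)


def save_thickness_overlay(volume: ToothVolume, tmap: ThicknessMap, path) -> None:
    """Colour-coded thickness overlay on the tooth silhouette (PNG).

    Buccal (x–z) view: grey silhouette of the tooth, cavity-wall voxels
    coloured by their wall thickness (minimum over the viewing direction).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sil = (volume.labels != BACKGROUND).any(axis=1).astype(float)
    thick2d = np.full(sil.shape, np.nan)
    for (i, j, k), t in zip(tmap.surface_voxels, tmap.thickness_um):
        if np.isnan(thick2d[i, k]) or t < thick2d[i, k]:
            thick2d[i, k] = t
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(sil.T, origin="lower", cmap="gray", alpha=0.5)
    im = ax.imshow(thick2d.T, origin="lower", cmap="jet")
    fig.colorbar(im, ax=ax, label="wall thickness (um)")
    ax.set_xlabel("x (voxels)")
    ax.set_ylabel("z (voxels)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
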