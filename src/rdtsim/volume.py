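"""Labelled voxel volumes.

A :class:`ToothVolume` is the substrate of every stage of the simulation: a
3D integer label grid (background / dentin / canal space / metal fragment /
removed dentin) with a physical voxel size in micrometres.  The grid's third
axis is the tooth long axis; horizontal (parallax) rotations are about this
axis.  World coordinates are in μm, voxel indices are 0-based, and the world
position of voxel ``(i, j, k)`` is ``origin_um + voxel_size_um * (i, j, k)``
(voxel centres).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Label values.  Exactly one label per voxel.
BACKGROUND = 0
DENTIN = 1
CANAL = 2
METAL = 3
REMOVED = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    DENTIN: "dentin",
    CANAL: "canal",
    METAL: "metal",
    REMOVED: "removed",
}

#: Labels that form the prepared cavity (instrumented space inside the root).
CAVITY_LABELS = (CANAL, REMOVED)

LONG_AXIS = 2  # grid axis aligned with the tooth long axis


@dataclass
class ToothVolume:
    """A labelled voxel grid with physical geometry.

    Parameters
    ----------
    labels
        3D ``uint8`` array with values in {BACKGROUND, DENTIN, CANAL, METAL,
        REMOVED}; axis 2 is the tooth long axis (apex at low index, crown at
        high index).
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    origin_um
        World coordinate (μm) of the centre of voxel ``(0, 0, 0)``.
    structures
        Optional named boolean masks over the same grid (e.g. ``"mb_root"``,
        ``"palatal_root"``) used for silhouette/overlap analysis.
    centerline_um
        Optional ``(N, 3)`` polyline of canal-centreline points in world μm,
        ordered from the orifice (coronal) to the apical end; consumed by the
        fragment-placement and carving operations.
    perforated
        Set by carving operations when removal breaches the external root
        surface; a perforated volume reports a minimum wall thickness of 0.
    """

    labels: np.ndarray
    voxel_size_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    structures: dict[str, np.ndarray] = field(default_factory=dict)
    centerline_um: np.ndarray | None = None
    perforated: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.labels.dtype != np.uint8:
            self.labels = self.labels.astype(np.uint8)
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        self.origin_um = tuple(float(v) for v in self.origin_um)
        if self.centerline_um is not None:
            self.centerline_um = np.asarray(self.centerline_um, dtype=float)

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def world_axis(self, axis: int) -> np.ndarray:
        """Voxel-centre world coordinates (μm) along one grid axis."""
        n = self.labels.shape[axis]
        return self.origin_um[axis] + self.voxel_size_um * np.arange(n)

    def index_of(self, point_um) -> tuple[int, int, int]:
        """Nearest voxel index for a world point (μm)."""
        p = np.asarray(point_um, dtype=float)
        idx = np.round((p - np.asarray(self.origin_um)) / self.voxel_size_um)
        idx = np.clip(idx, 0, np.asarray(self.labels.shape) - 1).astype(int)
        return tuple(idx)

    def z_index(self, z_um: float) -> int:
        return self.index_of((self.origin_um[0], self.origin_um[1], z_um))[2]

    def center_um(self) -> np.ndarray:
        """World coordinate of the grid centre (rotation pivot)."""
        return np.asarray(self.origin_um) + self.voxel_size_um * (
            (np.asarray(self.labels.shape) - 1) / 2.0
        )

    # -- bookkeeping -------------------------------------------------------

    def label_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=5)
        return {LABEL_NAMES[i]: int(counts[i]) for i in range(5)}

    def copy(self) -> "ToothVolume":
        return ToothVolume(
            labels=self.labels.copy(),
            voxel_size_um=self.voxel_size_um,
            origin_um=self.origin_um,
            structures={k: v.copy() for k, v in self.structures.items()},
            centerline_um=None if self.centerline_um is None else self.centerline_um.copy(),
            perforated=self.perforated,
        )

    def cavity_mask(self) -> np.ndarray:
        return (self.labels == CANAL) | (self.labels == REMOVED)
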