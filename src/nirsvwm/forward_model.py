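"""Probe geometry, voxel grids, parametric channel sensitivity, and analysis masks.

Photon-transport Monte Carlo is out of scope here; channel sensitivity volumes
are generated by a smooth parametric "banana" kernel between each source and
detector, which preserves the geometric structure that the reconstruction and
mask logic depend on (localised, nonnegative, source-detector symmetric)
while remaining deterministic and cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ProbeGeometry",
    "VoxelGrid",
    "SensitivityProfile",
    "MaskVolume",
    "default_frontal_probe",
    "synth_sensitivity",
    "build_subject_mask",
    "build_group_mask",
    "intersect_age_masks",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """Source/detector layout in grid-frame millimetres.

    Optodes sit on the z = 0 surface plane of the voxel grid; +z points into
    the head. ``channels`` holds (source_index, detector_index) pairs.
    """

    sources: np.ndarray  # (n_sources, 3) mm
    detectors: np.ndarray  # (n_detectors, 3) mm
    channels: tuple  # ((si, di), ...)

    def __post_init__(self):
        src = np.asarray(self.sources, dtype=float)
        det = np.asarray(self.detectors, dtype=float)
        object.__setattr__(self, "sources", src)
        object.__setattr__(self, "detectors", det)
        object.__setattr__(self, "channels", tuple(tuple(c) for c in self.channels))
        if np.any(self.distances_cm <= 0):
            raise ValueError("source-detector distances must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def distances_cm(self) -> np.ndarray:
        """Source-detector separation per channel, in cm (positions are mm)."""
        d = np.array(
            [
                np.linalg.norm(self.sources[s] - self.detectors[dt])
                for s, dt in self.channels
            ]
        )
        return d / 10.0


@dataclass(frozen=True)
class VoxelGrid:
    """Abstract right-handed mm frame with 0-based voxel indices."""

    dims: tuple  # (nx, ny, nz)
    spacing: tuple = (2.0, 2.0, 2.0)  # mm
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def voxel_coords_mm(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-centre coordinates in mm, C order."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.dims[i])
            for i in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class SensitivityProfile:
    """Per-channel, per-wavelength voxel sensitivity volumes (Jacobian F).

    ``F`` has shape (n_channels, n_wavelengths, nx, ny, nz), nonnegative.
    """

    F: np.ndarray
    grid: VoxelGrid
    geometry: ProbeGeometry
    wavelengths: tuple = (690.0, 830.0)

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if np.any(self.F < 0) or not np.all(np.isfinite(self.F)):
            raise ValueError("sensitivity must be finite and nonnegative")
        if self.F.shape[2:] != self.grid.dims:
            raise ValueError("sensitivity volume does not match grid dims")

    def flat(self) -> np.ndarray:
        """(n_channels, n_wavelengths, n_voxels) view."""
        return self.F.reshape(self.F.shape[0], self.F.shape[1], -1)


@dataclass
class MaskVolume:
    """Boolean voxel volume with provenance (subject / age-group / intersection)."""

    data: np.ndarray
    grid: VoxelGrid
    provenance: str = "subject"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.dims:
            raise ValueError("mask does not match grid dims")

    @property
    def n_true(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """Flat (C-order) indices of voxels inside the mask."""
        return np.flatnonzero(self.data.ravel())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.grid.affine())

    def save(self, path):
        nib.save(self.to_nifti(), str(path))
        sidecar = Path(str(path)).with_suffix(".json")
        sidecar.write_text(json.dumps({"provenance": self.provenance}))


def default_frontal_probe(grid: VoxelGrid) -> ProbeGeometry:
    """A bilateral frontal probe: 4 sources, 6 detectors, 8 channels.

    Mirrors the study instrument's layout class (4 channels per frontal
    hemisphere) scaled to fit the given grid's x-y extent, optodes on z=0.
    """
    nx, ny, _ = grid.dims
    sx, sy, _ = grid.spacing
    ox, oy, _ = grid.origin
    w, h = (nx - 1) * sx, (ny - 1) * sy

    def pt(fx, fy):
        return [ox + fx * w, oy + fy * h, 0.0]

    # two sources + three detectors per hemisphere
    sources = np.array([pt(0.20, 0.35), pt(0.30, 0.65), pt(0.80, 0.35), pt(0.70, 0.65)])
    detectors = np.array(
        [
            pt(0.10, 0.55),
            pt(0.32, 0.30),
            pt(0.42, 0.60),
            pt(0.90, 0.55),
            pt(0.68, 0.30),
            pt(0.58, 0.60),
        ]
    )
    channels = ((0, 0), (0, 1), (1, 2), (1, 1), (2, 3), (2, 4), (3, 5), (3, 4))
    return ProbeGeometry(sources=sources, detectors=detectors, channels=channels)


def _arc_points(src: np.ndarray, det: np.ndarray, depth_scale: float, n: int = 65):
    """Sample points on the arc dipping ``depth_scale`` mm into the head."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    base = (1.0 - t) * src[None, :] + t * det[None, :]
    dip = np.zeros_like(base)
    dip[:, 2] = depth_scale * np.sin(np.pi * t[:, 0])
    return base + dip


def arc_midpoint(geometry: ProbeGeometry, channel: int,
                 depth_scale: float = 10.0) -> np.ndarray:
    """Deepest point (mm) of a channel's sensitivity arc — its peak location."""
    s, d = geometry.channels[channel]
    arc = _arc_points(geometry.sources[s], geometry.detectors[d], depth_scale)
    return arc[len(arc) // 2]


def synth_sensitivity(
    geometry: ProbeGeometry,
    grid: VoxelGrid,
    depth_scale: float = 10.0,
    width: float = 4.0,
    axial_scale: float | None = None,
    amplitude: float = 0.02,
    wavelengths: tuple = (690.0, 830.0),
    wavelength_gain: tuple = (1.0, 1.0),
) -> SensitivityProfile:
    """Parametric banana-shaped sensitivity for every channel and wavelength.

    For each channel the kernel is ``amplitude · exp(-dist_to_arc/width -
    dist_to_midpoint/axial_scale)`` where the arc joins source and detector,
    dipping ``depth_scale`` mm below the surface. The maximum sits at the arc
    midpoint; the construction is symmetric in source/detector exchange.
    ``amplitude`` sets the peak OD sensitivity (so thresholding the
    channel-summed profile at a small absolute OD value trims far voxels);
    ``wavelength_gain`` scales the profile per wavelength.
    """
    coords = grid.voxel_coords_mm()
    lo = np.array(grid.origin)
    hi = lo + (np.array(grid.dims) - 1) * np.array(grid.spacing)
    for s, d in geometry.channels:
        for p in (geometry.sources[s], geometry.detectors[d]):
            if np.any(p[:2] < lo[:2] - 1e-9) or np.any(p[:2] > hi[:2] + 1e-9):
                raise ValueError("channel optode outside grid bounds")

    if axial_scale is None:
        axial_scale = float(
            np.mean([np.linalg.norm(geometry.sources[s] - geometry.detectors[d])
                     for s, d in geometry.channels])
        )

    n_ch = geometry.n_channels
    F = np.empty((n_ch, len(wavelengths)) + grid.dims)
    for ci, (s, d) in enumerate(geometry.channels):
        arc = _arc_points(geometry.sources[s], geometry.detectors[d], depth_scale)
        mid = arc[len(arc) // 2]
        # min distance to sampled arc, and distance to its midpoint
        d2 = ((coords[:, None, :] - arc[None, :, :]) ** 2).sum(axis=2)
        dist_arc = np.sqrt(d2.min(axis=1))
        dist_mid = np.linalg.norm(coords - mid[None, :], axis=1)
        prof = amplitude * np.exp(-dist_arc / width - dist_mid / axial_scale)
        for wi, g in enumerate(wavelength_gain):
            F[ci, wi] = (g * prof).reshape(grid.dims)
    return SensitivityProfile(F=F, grid=grid, geometry=geometry,
                              wavelengths=tuple(wavelengths))


def build_subject_mask(profiles: SensitivityProfile,
                       od_threshold: float = 1e-4) -> MaskVolume:
    """Voxels whose channel-summed sensitivity exceeds ``od_threshold``."""
    total = profiles.F.sum(axis=(0, 1))
    return MaskVolume(data=total > od_threshold, grid=profiles.grid,
                      provenance="subject")


def build_group_mask(subject_masks: list, coverage: float = 0.75) -> MaskVolume:
    """Voxels covered by at least ``coverage`` fraction of subjects."""
    if not subject_masks:
        raise ValueError("no subject masks")
    grid = subject_masks[0].grid
    if any(m.grid.dims != grid.dims for m in subject_masks):
        raise ValueError("subject masks on different grids")
    stack = np.stack([m.data for m in subject_masks])
    frac = stack.mean(axis=0)
    return MaskVolume(data=frac >= coverage, grid=grid, provenance="age-group")


def intersect_age_masks(age_masks: list) -> MaskVolume:
    """Intersection across age-group masks; empty intersection is fatal."""
    if not age_masks:
        raise ValueError("no age masks")
    grid = age_masks[0].grid
    data = np.logical_and.reduce([m.data for m in age_masks])
    if not data.any():
        raise ValueError("intersection mask is empty; pipeline cannot proceed")
    return MaskVolume(data=data, grid=grid, provenance="intersection")
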