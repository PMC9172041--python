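"""Detector geometry, momentum-transfer maps, frame I/O, cropping and normalization.

The geometry model is a flat two-panel detector in the far field.  A pixel at
radial distance ``r`` (metres) from the beam axis sees scattering angle
``2theta = arctan(r / distance)`` and momentum transfer

    q = (4 pi / lambda) * sin(theta)        [nm^-1, lambda in nm]

Frames are stored as HDF5 containers with datasets ``/patterns`` (N x H x W),
``/mask`` (H x W, 1 = valid pixel), ``/ids`` (N strings) and, when present,
``/labels`` (N) and ``/true_size_nm`` (N); geometry parameters live as root
attributes.  The same layout is written by the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import yaml

from .errors import BoundsError, FormatError, InvalidParameterError

__all__ = [
    "DetectorGeometry",
    "DiffractionPattern",
    "NormalizationStats",
    "qmap",
    "qxy_map",
    "read_patterns",
    "write_patterns",
    "crop_patch",
    "default_crop_anchor",
    "normalize_patch",
    "compute_normalization_stats",
    "prepare_patches",
]

# Real-data standardization constants measured on the experiment's 20 000-frame
# training set; used as defaults only when stats cannot be computed from data.
REAL_DATA_MU = 0.342
REAL_DATA_SIGMA = 2.336

#: Patch size fed to the full-scale classifier (rows, cols).
DEFAULT_PATCH_SIZE = (192, 96)


@dataclass
class DetectorGeometry:
    """Far-field detector description.

    Parameters
    ----------
    distance : float
        Sample-detector distance in metres (default 0.130).
    pixel_size : float
        Pixel edge in metres (default 75e-6).
    wavelength : float
        Photon wavelength in nanometres (default 0.729, i.e. 1.7 keV).
    beam_center : tuple
        Beam position in fractional pixels, (row, col), 0-based.
    panel_mask : ndarray of bool
        True where the pixel is live.  Its shape defines the frame shape.
    """

    distance: float = 0.130
    pixel_size: float = 75e-6
    wavelength: float = 0.729
    beam_center: tuple[float, float] = (511.5, 511.5)
    panel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.pixel_size <= 0 or self.wavelength <= 0:
            raise InvalidParameterError(
                "distance, pixel_size and wavelength must all be positive"
            )
        if self.panel_mask is not None:
            self.panel_mask = np.asarray(self.panel_mask, dtype=bool)

    @property
    def frame_shape(self) -> tuple[int, int]:
        if self.panel_mask is None:
            raise InvalidParameterError("geometry has no panel mask / frame shape")
        return self.panel_mask.shape

    @classmethod
    def two_panel(
        cls,
        shape: tuple[int, int] = (1024, 1024),
        dead_lower: bool = True,
        **kwargs,
    ) -> "DetectorGeometry":
        """Geometry with one live and one dead panel (split along rows).

        Mirrors the experimental pnCCD configuration in which only the upper
        panel recorded signal.
        """
        mask = np.ones(shape, dtype=bool)
        half = shape[0] // 2
        if dead_lower:
            mask[half:, :] = False
        else:
            mask[:half, :] = False
        kwargs.setdefault("beam_center", ((shape[0] - 1) / 2, (shape[1] - 1) / 2))
        return cls(panel_mask=mask, **kwargs)

    def with_mask(self, mask: np.ndarray) -> "DetectorGeometry":
        return replace(self, panel_mask=np.asarray(mask, dtype=bool))

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "distance_m": float(self.distance),
            "pixel_um": float(self.pixel_size * 1e6),
            "wavelength_nm": float(self.wavelength),
            "center_xy": [float(self.beam_center[0]), float(self.beam_center[1])],
        }

    @classmethod
    def from_dict(cls, d: dict, panel_mask: np.ndarray | None = None) -> "DetectorGeometry":
        return cls(
            distance=float(d["distance_m"]),
            pixel_size=float(d["pixel_um"]) * 1e-6,
            wavelength=float(d["wavelength_nm"]),
            beam_center=tuple(d["center_xy"]),
            panel_mask=panel_mask,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


@dataclass
class DiffractionPattern:
    """One detector frame: photon counts, validity mask and an identifier."""

    intensity: np.ndarray
    mask: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensity.shape != self.mask.shape:
            raise InvalidParameterError(
                f"intensity shape {self.intensity.shape} != mask shape {self.mask.shape}"
            )
        if not np.all(np.isfinite(self.intensity[self.mask])):
            raise InvalidParameterError("non-finite intensity on valid pixels")


@dataclass
class NormalizationStats:
    """Standardization constants applied to every patch before the classifier.

    With ``log_scale`` the photon counts pass through ``log1p`` before
    standardization (mu/sigma are then statistics of the log counts); this
    compresses the orders-of-magnitude dynamic range of diffraction data.
    """

    mu: float = REAL_DATA_MU
    sigma: float = REAL_DATA_SIGMA
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive")


def qmap(geometry: DetectorGeometry, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel momentum-transfer magnitude in nm^-1.

    ``q = (4 pi / lambda) sin(theta)`` with ``2 theta = arctan(r / D)`` where
    ``r`` is the in-plane distance of the pixel centre from the beam centre.
    """
    if shape is None:
        shape = geometry.frame_shape
    rows = np.arange(shape[0], dtype=float) - geometry.beam_center[0]
    cols = np.arange(shape[1], dtype=float) - geometry.beam_center[1]
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    r_m = np.hypot(rr, cc) * geometry.pixel_size
    two_theta = np.arctan2(r_m, geometry.distance)
    return (4.0 * np.pi / geometry.wavelength) * np.sin(0.5 * two_theta)


def qxy_map(
    geometry: DetectorGeometry, shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane scattering-vector components (q_row, q_col) in nm^-1.

    Small-angle (flat Ewald sphere) components used for the relative phases of
    displaced scatterers: ``q_i = (2 pi / lambda) * x_i / D``.
    """
    if shape is None:
        shape = geometry.frame_shape
    scale = 2.0 * np.pi / (geometry.wavelength * geometry.distance)
    q_row = (np.arange(shape[0], dtype=float) - geometry.beam_center[0]) * geometry.pixel_size * scale
    q_col = (np.arange(shape[1], dtype=float) - geometry.beam_center[1]) * geometry.pixel_size * scale
    return np.meshgrid(q_row, q_col, indexing="ij")


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------

def write_patterns(
    patterns: Sequence[DiffractionPattern],
    path: str | Path,
    geometry: DetectorGeometry | None = None,
    labels: np.ndarray | None = None,
    true_sizes_nm: np.ndarray | None = None,
) -> None:
    """Write frames to the package HDF5 layout (lossless round trip)."""
    path = Path(path)
    n = len(patterns)
    with h5py.File(path, "w") as f:
        if n:
            stack = np.stack([p.intensity for p in patterns])
            mask = patterns[0].mask
        else:
            stack = np.zeros((0, 0, 0))
            mask = np.zeros((0, 0), dtype=bool)
        f.create_dataset("patterns", data=stack)
        f.create_dataset("mask", data=mask.astype(np.uint8))
        f.create_dataset(
            "ids",
            data=np.array([p.id for p in patterns], dtype=h5py.string_dtype()),
        )
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels, dtype=np.int8))
        if true_sizes_nm is not None:
            f.create_dataset("true_size_nm", data=np.asarray(true_sizes_nm, dtype=float))
        if geometry is not None:
            for k, v in geometry.to_dict().items():
                f.attrs[k] = v


def read_patterns(
    path: str | Path,
) -> tuple[list[DiffractionPattern], DetectorGeometry | None, dict]:
    """Read frames back; returns (patterns, geometry-or-None, extras).

    ``extras`` carries ``labels`` and ``true_size_nm`` arrays when stored.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for required in ("patterns", "mask"):
            if required not in f:
                raise FormatError(f"{path}: missing dataset '/{required}'")
        stack = f["patterns"][...]
        mask = f["mask"][...].astype(bool)
        if "ids" in f:
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][...]]
        else:
            ids = [str(i) for i in range(len(stack))]
        extras = {}
        if "labels" in f:
            extras["labels"] = f["labels"][...].astype(int)
        if "true_size_nm" in f:
            extras["true_size_nm"] = f["true_size_nm"][...]
        geometry = None
        if "distance_m" in f.attrs:
            geometry = DetectorGeometry.from_dict(
                {k: f.attrs[k] for k in ("distance_m", "pixel_um", "wavelength_nm", "center_xy")},
                panel_mask=mask if mask.size else None,
            )
    patterns = [
        DiffractionPattern(intensity=frame, mask=mask, id=pid)
        for frame, pid in zip(stack, ids)
    ]
    return patterns, geometry, extras


# ---------------------------------------------------------------------------
# Cropping and normalization
# ---------------------------------------------------------------------------

def crop_patch(
    pattern: DiffractionPattern,
    anchor: tuple[int, int],
    size: tuple[int, int] = DEFAULT_PATCH_SIZE,
) -> np.ndarray:
    """Extract a ``size`` window at ``anchor`` (top-left, row/col); masked pixels -> 0."""
    r0, c0 = int(anchor[0]), int(anchor[1])
    h, w = int(size[0]), int(size[1])
    H, W = pattern.intensity.shape
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise BoundsError(
            f"crop {size} at {anchor} exceeds frame bounds {pattern.intensity.shape}"
        )
    patch = pattern.intensity[r0 : r0 + h, c0 : c0 + w].astype(np.float32, copy=True)
    patch[~pattern.mask[r0 : r0 + h, c0 : c0 + w]] = 0.0
    return patch


def default_crop_anchor(
    geometry: DetectorGeometry, size: tuple[int, int] = DEFAULT_PATCH_SIZE
) -> tuple[int, int]:
    """Anchor of the live-panel window nearest the beam centre.

    The live region is taken as the bounding box of the valid pixels; the
    window is centred on the beam and clipped into that box, so for a
    half-dead detector it hugs the panel edge adjacent to the centre where
    the low-q signal is strongest.
    """
    mask = geometry.panel_mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise InvalidParameterError("panel mask has no valid pixels")
    h, w = size
    if rows.size < h or cols.size < w:
        raise BoundsError(f"live panel smaller than requested patch {size}")
    r = int(round(geometry.beam_center[0] - h / 2))
    c = int(round(geometry.beam_center[1] - w / 2))
    r = min(max(r, rows[0]), rows[-1] - h + 1)
    c = min(max(c, cols[0]), cols[-1] - w + 1)
    return r, c


def normalize_patch(patch: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Standardize a patch: ``(x - mu) / sigma`` elementwise (after the
    configured intensity transform)."""
    if stats.sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    x = np.asarray(patch, dtype=np.float32)
    if stats.log_scale:
        x = np.log1p(np.maximum(x, -0.999))
    return (x - stats.mu) / stats.sigma


def compute_normalization_stats(
    patterns: Sequence[DiffractionPattern] | np.ndarray,
    mask: np.ndarray | None = None,
    log_scale: bool = False,
) -> NormalizationStats:
    """Mean/std over valid pixels of the training frames (masked pixels excluded)."""
    if isinstance(patterns, np.ndarray):
        data = np.log1p(np.maximum(patterns, -0.999)) if log_scale else patterns
        valid = np.broadcast_to(mask.astype(bool), data.shape) if mask is not None else None
        values = data[valid] if valid is not None else data.ravel()
        mu = float(np.mean(values))
        sigma = float(np.std(values))
    else:
        # streaming accumulation over heterogeneous masks
        s = s2 = n = 0.0
        for p in patterns:
            v = p.intensity[p.mask]
            if log_scale:
                v = np.log1p(np.maximum(v, -0.999))
            s += float(v.sum())
            s2 += float(np.square(v, dtype=np.float64).sum())
            n += v.size
        mu = s / n
        sigma = float(np.sqrt(max(s2 / n - mu * mu, 0.0)))
    if sigma <= 0:
        raise InvalidParameterError("degenerate (constant) training data: sigma = 0")
    return NormalizationStats(mu=mu, sigma=sigma, log_scale=log_scale)


def prepare_patches(
    patterns: Sequence[DiffractionPattern],
    geometry: DetectorGeometry,
    stats: NormalizationStats | None = None,
    anchor: tuple[int, int] | None = None,
    size: tuple[int, int] = DEFAULT_PATCH_SIZE,
) -> np.ndarray:
    """Crop + zero-fill + (optionally) standardize every frame; returns (N, h, w) float32."""
    if anchor is None:
        anchor = default_crop_anchor(geometry, size)
    out = np.empty((len(patterns), size[0], size[1]), dtype=np.float32)
    for i, p in enumerate(patterns):
        out[i] = crop_patch(p, anchor, size)
    if stats is not None:
        out = normalize_patch(out, stats)
    return out
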