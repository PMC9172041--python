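"""Angular-averaged intensity (PSD) analytics: fringe contrast, sizing, filtering.

The PSD of a selection is the azimuthal average of frame intensity as a
function of momentum transfer q, averaged over all frames in the selection.
For quasi-spherical particles it shows concentric fringes whose visibility is
a proxy for the purity of a single-hit selection: multi-particle interference
and background fill the minima.  Contrast is quantified as the mean
difference between the first N (default 3) paired local maxima and minima of
the curve; following the logarithmic presentation of such curves, extrema are
detected and differenced on log10 of the max-normalized PSD by default.

Particle size is estimated per frame either by fitting the uniform-sphere
intensity (free radius, scale, flat background) to the frame's own PSD or
from the asymptotic fringe spacing of the sphere form factor,
``delta(qR) = pi`` i.e. ``diameter = 2 pi / delta q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .errors import (
    ContrastUndefinedError,
    DataError,
    InvalidParameterError,
    SizeUndeterminedError,
)
from .geomio import DetectorGeometry, DiffractionPattern, qmap
from .infer import Selection
from .simdata import sphere_intensity

__all__ = [
    "PSDCurve",
    "ContrastResult",
    "SizeEstimate",
    "compute_psd",
    "find_extrema",
    "psd_contrast",
    "estimate_size",
    "size_filter",
    "estimate_background",
]

DEFAULT_SIZE_RANGE = (55.0, 84.0)  # nm, nominal virus diameter band


@dataclass
class PSDCurve:
    """q-binned angular-averaged intensity with per-bin valid-pixel occupancy."""

    q_centers: np.ndarray
    intensity: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.q_centers = np.asarray(self.q_centers, float)
        self.intensity = np.asarray(self.intensity, float)
        self.occupancy = np.asarray(self.occupancy)
        if np.any(np.diff(self.q_centers) <= 0):
            raise InvalidParameterError("q_centers must be strictly increasing")

    @property
    def usable(self) -> np.ndarray:
        return self.occupancy > 0

    def normalized_log(self) -> tuple[np.ndarray, np.ndarray]:
        """(q, log10(I / max I)) restricted to occupied, positive bins."""
        ok = self.usable & (self.intensity > 0)
        q = self.q_centers[ok]
        y = self.intensity[ok]
        return q, np.log10(y / y.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q_nm_inv": self.q_centers, "intensity": self.intensity,
                             "occupancy": self.occupancy})


@dataclass
class ContrastResult:
    """Fringe-contrast outcome: paired extrema and the mean difference C."""

    maxima: list[tuple[float, float]]   # (q, value) on the analysis scale
    minima: list[tuple[float, float]]
    n_pairs: int
    contrast: float
    scale: str = "log"


@dataclass
class SizeEstimate:
    """Estimated particle diameter for one frame."""

    diameter: float           # nm
    fit_residual: float
    method: str               # "form-factor-fit" | "fringe-spacing"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError("diameter must be positive")


# ---------------------------------------------------------------------------
# PSD computation
# ---------------------------------------------------------------------------

def compute_psd(
    patterns: Sequence[DiffractionPattern],
    geometry: DetectorGeometry,
    q_bins: int | np.ndarray = 200,
) -> PSDCurve:
    """Azimuthal average over all valid pixels, averaged over the selection.

    ``q_bins`` is either a bin count (linear bins spanning the live-panel q
    range) or an explicit array of bin edges.
    """
    if len(patterns) == 0:
        raise DataError("cannot compute the PSD of an empty selection")
    q = qmap(geometry, patterns[0].intensity.shape)
    if np.isscalar(q_bins):
        live_q = q[geometry.panel_mask] if geometry.panel_mask is not None else q
        edges = np.linspace(live_q.min(), live_q.max(), int(q_bins) + 1)
    else:
        edges = np.asarray(q_bins, float)
    nbin = len(edges) - 1
    sums = np.zeros(nbin)
    occ = np.zeros(nbin, dtype=np.int64)
    for p in patterns:
        valid = p.mask
        which = np.digitize(q[valid], edges) - 1
        inside = (which >= 0) & (which < nbin)
        sums += np.bincount(which[inside], weights=p.intensity[valid][inside],
                            minlength=nbin)
        occ += np.bincount(which[inside], minlength=nbin)
    intensity = np.divide(sums, occ, out=np.zeros(nbin), where=occ > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PSDCurve(q_centers=centers, intensity=intensity, occupancy=occ)


def per_pattern_psd(pattern: DiffractionPattern, geometry: DetectorGeometry,
                    q_bins: int | np.ndarray = 200) -> PSDCurve:
    return compute_psd([pattern], geometry, q_bins)


# ---------------------------------------------------------------------------
# Extrema and contrast
# ---------------------------------------------------------------------------

def find_extrema(
    curve: PSDCurve,
    smoothing: int = 7,
    min_prominence: float = 0.02,
    scale: str = "log",
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Alternating local maxima/minima of the (smoothed) PSD curve.

    Works on log10 of the max-normalized curve by default (``scale='log'``)
    after a Savitzky-Golay smooth of window ``smoothing`` bins.
    ``min_prominence`` is a fraction of the curve's full range on the analysis
    scale.  Returns ``(maxima, minima)`` as (q, value) lists ordered by q; a
    monotone curve yields two empty lists.
    """
    if scale == "log":
        q, y = curve.normalized_log()
    else:
        ok = curve.usable
        q, y = curve.q_centers[ok], curve.intensity[ok]
    if len(q) < 5:
        raise DataError("need at least 5 usable PSD bins for extremum detection")
    if smoothing >= 3 and len(y) > smoothing:
        win = smoothing + 1 if smoothing % 2 == 0 else smoothing
        y = signal.savgol_filter(y, win, polyorder=2)
    prominence = min_prominence * (y.max() - y.min() + 1e-30)
    imax, _ = signal.find_peaks(y, prominence=prominence)
    imin, _ = signal.find_peaks(-y, prominence=prominence)
    # merge and enforce strict alternation, keeping the more extreme of a run
    tagged = sorted([(i, 1) for i in imax] + [(i, -1) for i in imin])
    kept: list[tuple[int, int]] = []
    for i, kind in tagged:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = (y[i] > y[prev]) if kind == 1 else (y[i] < y[prev])
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    maxima = [(float(q[i]), float(y[i])) for i, kind in kept if kind == 1]
    minima = [(float(q[i]), float(y[i])) for i, kind in kept if kind == -1]
    return maxima, minima


def psd_contrast(
    curve: PSDCurve,
    n_pairs: int = 3,
    smoothing: int = 7,
    min_prominence: float = 0.02,
    scale: str = "log",
) -> ContrastResult:
    """Mean difference between the first ``n_pairs`` paired maxima/minima.

    The i-th maximum is paired with the first minimum following it in q;
    ``C = mean(I_max,i - I_min,i)`` over the first ``n_pairs`` pairs on the
    analysis scale (log10 of the max-normalized curve by default).
    """
    maxima, minima = find_extrema(curve, smoothing, min_prominence, scale)
    pairs = []
    for qm, vm in maxima:
        following = [(qn, vn) for qn, vn in minima if qn > qm]
        if following:
            pairs.append(((qm, vm), following[0]))
        if len(pairs) == n_pairs:
            break
    if len(pairs) < n_pairs:
        raise ContrastUndefinedError(
            f"found {len(pairs)} max/min pairs, need {n_pairs}",
            n_pairs_found=len(pairs),
        )
    diffs = [vm - vn for (qm, vm), (qn, vn) in pairs]
    return ContrastResult(
        maxima=[p[0] for p in pairs], minima=[p[1] for p in pairs],
        n_pairs=n_pairs, contrast=float(np.mean(diffs)), scale=scale,
    )


# ---------------------------------------------------------------------------
# Particle sizing
# ---------------------------------------------------------------------------

def _fit_sphere_psd(q: np.ndarray, inten: np.ndarray,
                    radius_grid: np.ndarray) -> tuple[float, float]:
    """Grid + local-refine least squares of ``a * F^2(qR) + b``; returns (R, residual)."""

    def residual_for(radius: float) -> tuple[float, float, float]:
        basis = sphere_intensity(q, radius, 1.0)
        a_mat = np.stack([basis, np.ones_like(q)], axis=1)
        coef, res, *_ = np.linalg.lstsq(a_mat, inten, rcond=None)
        pred = a_mat @ coef
        return float(np.sum((pred - inten) ** 2)), coef[0], coef[1]

    losses = [residual_for(r)[0] for r in radius_grid]
    r_best = float(radius_grid[int(np.argmin(losses))])
    opt = optimize.minimize_scalar(
        lambda r: residual_for(r)[0],
        bracket=None,
        bounds=(max(r_best - 2.0, radius_grid[0]), min(r_best + 2.0, radius_grid[-1])),
        method="bounded",
    )
    r_ref = float(opt.x)
    loss, a, _b = residual_for(r_ref)
    if a <= 0:
        raise SizeUndeterminedError("sphere fit collapsed to zero amplitude")
    denom = float(np.sum((inten - inten.mean()) ** 2)) + 1e-30
    return r_ref, loss / denom


def estimate_size(
    pattern: DiffractionPattern | PSDCurve,
    geometry: DetectorGeometry | None = None,
    method: str = "form-factor-fit",
    q_bins: int | np.ndarray = 200,
    radius_grid: np.ndarray | None = None,
    q_min: float | None = None,
) -> SizeEstimate:
    """Estimate the particle diameter from one frame (or its PSD curve).

    ``form-factor-fit`` (default): least squares of the uniform-sphere
    intensity with free scale and flat background against the frame's PSD,
    radius searched on a grid then refined.  ``fringe-spacing``: diameter =
    2*pi / mean spacing of successive PSD minima.  The fit method falls back
    to fringe spacing when it fails.  Raises :class:`SizeUndeterminedError`
    when no usable estimate exists (callers drop such frames).
    """
    if isinstance(pattern, PSDCurve):
        curve = pattern
    else:
        if geometry is None:
            raise InvalidParameterError("geometry required when passing a raw pattern")
        curve = compute_psd([pattern], geometry, q_bins)
    ok = curve.usable & (curve.intensity >= 0)
    q, inten = curve.q_centers[ok], curve.intensity[ok]
    if q_min is not None:
        keep = q >= q_min
        q, inten = q[keep], inten[keep]
    if len(q) < 8 or inten.max() <= 0:
        raise SizeUndeterminedError("not enough usable PSD signal")
    if radius_grid is None:
        radius_grid = np.arange(10.0, 80.0, 0.5)

    if method == "form-factor-fit":
        try:
            radius, res = _fit_sphere_psd(q, inten, radius_grid)
            return SizeEstimate(diameter=2.0 * radius, fit_residual=res,
                                method="form-factor-fit")
        except SizeUndeterminedError:
            method = "fringe-spacing"

    if method != "fringe-spacing":
        raise InvalidParameterError(f"unknown sizing method '{method}'")
    _, minima = find_extrema(curve, scale="log")
    if len(minima) < 2:
        raise SizeUndeterminedError(
            f"only {len(minima)} fringe minima detected, need >= 2")
    qs = np.array([m[0] for m in minima])
    dq = float(np.mean(np.diff(qs)))
    if dq <= 0:
        raise SizeUndeterminedError("non-increasing fringe minima")
    return SizeEstimate(diameter=2.0 * np.pi / dq, fit_residual=float(np.std(np.diff(qs)) / dq),
                        method="fringe-spacing")


def size_filter(
    selection: Selection,
    sizes: Mapping[str, float | None],
    low: float = DEFAULT_SIZE_RANGE[0],
    high: float = DEFAULT_SIZE_RANGE[1],
    name: str | None = None,
) -> Selection:
    """Keep ids with ``low <= diameter <= high`` (inclusive).

    ``sizes`` maps id -> diameter in nm; ids mapped to None/NaN (size
    undetermined) or absent from the mapping are dropped.
    """
    if low > high:
        raise InvalidParameterError(f"invalid size range [{low}, {high}]")
    kept = set()
    for pid in selection.ids:
        d = sizes.get(pid)
        if d is None or (isinstance(d, float) and np.isnan(d)):
            continue
        if low <= d <= high:
            kept.add(pid)
    return Selection(name=name or f"{selection.name}+size", ids=frozenset(kept))


def estimate_background(
    source: PSDCurve | DiffractionPattern,
    q_high_region: tuple[float, float],
    geometry: DetectorGeometry | None = None,
    q_bins: int | np.ndarray = 200,
) -> float:
    """Mean intensity in a high-q window where particle signal is negligible."""
    if isinstance(source, DiffractionPattern):
        if geometry is None:
            raise InvalidParameterError("geometry required when passing a raw pattern")
        curve = compute_psd([source], geometry, q_bins)
    else:
        curve = source
    lo, hi = q_high_region
    if lo >= hi:
        raise InvalidParameterError("q_high_region must be an ordered interval")
    sel = curve.usable & (curve.q_centers >= lo) & (curve.q_centers <= hi)
    if not sel.any():
        raise InvalidParameterError("q_high_region contains no occupied bins")
    return float(np.average(curve.intensity[sel], weights=curve.occupancy[sel]))


def subtract_background(pattern: DiffractionPattern, level: float) -> DiffractionPattern:
    """Flat background subtraction, clamped at zero on valid pixels."""
    out = np.clip(pattern.intensity - level, 0.0, None)
    out[~pattern.mask] = 0.0
    return DiffractionPattern(intensity=out, mask=pattern.mask, id=pattern.id)
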