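"""Synthetic single-particle-imaging frames with experiment-like statistics.

The generator emulates the frame population of an XFEL single-particle run on a
quasi-spherical virus sample:

* **single hits** — far-field diffraction of one uniform sphere, concentric
  fringes with zeros at ``tan(qR) = qR``;
* **non-single hits** — either coherent sums of several displaced spheres
  (interference modulation crossing the fringes) or weak/empty frames that
  survived upstream hit finding;
* Poisson photon counting, shot-to-shot fluence jitter (log-normal), a flat
  background, and a half-dead two-panel detector mask;
* a heavily imbalanced class ratio (1 single per ~200 frames by default).

Sizes are drawn uniformly from the nominal virus band with a configurable
fraction of out-of-band contaminants so that downstream size filtering has
real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .geomio import DetectorGeometry, DiffractionPattern, qmap, qxy_map, write_patterns

__all__ = [
    "SimulationConfig",
    "LabeledDataset",
    "sphere_intensity",
    "sphere_amplitude",
    "simulate_pattern",
    "generate_dataset",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic frame generator.

    Defaults describe the emulated experiment: virus diameters 55-84 nm
    (radius 27.5-42 nm) with 20% contaminants outside that band, one single
    hit per ~200 frames, log-normal fluence jitter and a flat background.
    """

    particle_radius_range: tuple[float, float] = (27.5, 42.0)  # nm
    contaminant_fraction: float = 0.2
    single_fraction: float = 1.0 / 200.0
    fluence_jitter: float = 0.5        # sigma of log fluence
    mean_photon_scale: float = 20.0    # expected photons/pixel at q -> 0
    background_level: float = 0.05     # photons/pixel
    multi_particle_count_range: tuple[int, int] = (2, 4)
    displacement_range: tuple[float, float] = (100.0, 600.0)  # nm
    empty_fraction: float = 0.3        # of non-singles: weak/empty frames
    hit_threshold_photons: float = 500.0  # upstream hit-finding acceptance
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.particle_radius_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("particle_radius_range must be positive and ordered")
        if not (0.0 < self.single_fraction < 1.0):
            raise InvalidParameterError("single_fraction must lie strictly in (0, 1)")
        if self.multi_particle_count_range[0] < 2:
            raise InvalidParameterError("multi_particle_count_range minimum must be >= 2")
        if self.multi_particle_count_range[0] > self.multi_particle_count_range[1]:
            raise InvalidParameterError("multi_particle_count_range must be ordered")
        dlo, dhi = self.displacement_range
        if not (0 <= dlo <= dhi):
            raise InvalidParameterError("displacement_range must be non-negative and ordered")
        if not (0.0 <= self.empty_fraction < 1.0):
            raise InvalidParameterError("empty_fraction must lie in [0, 1)")


@dataclass
class LabeledDataset:
    """Frames with binary single/non-single labels and ground-truth diameters."""

    patterns: list[DiffractionPattern]
    labels: np.ndarray           # 1 = single hit, 0 = non-single
    true_sizes: np.ndarray       # diameter in nm; NaN for empty frames

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.true_sizes = np.asarray(self.true_sizes, dtype=float)
        if len(self.patterns) != len(self.labels):
            raise InvalidParameterError("labels and patterns must have the same length")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise InvalidParameterError("labels must be binary")

    def __len__(self) -> int:
        return len(self.patterns)

    def save(self, path: str | Path, geometry: DetectorGeometry | None = None) -> None:
        write_patterns(
            self.patterns, path, geometry=geometry,
            labels=self.labels, true_sizes_nm=self.true_sizes,
        )


def sphere_amplitude(q: np.ndarray | float, radius: float) -> np.ndarray | float:
    """Normalized scattering amplitude of a uniform sphere.

    ``F(qR) = 3 [sin(qR) - qR cos(qR)] / (qR)^3`` with ``F -> 1`` as ``qR -> 0``.
    Zeros sit at the roots of ``tan(x) = x`` (4.4934, 7.7253, ...).
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    x = np.asarray(q, dtype=float) * radius
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    small = np.abs(x) < 1e-4
    if np.any(small):
        # series: 1 - x^2/10 + O(x^4); continuous limit at q = 0
        f = np.where(small, 1.0 - x**2 / 10.0, f)
    return f if np.ndim(q) else float(f)


def sphere_intensity(q: np.ndarray | float, radius: float, i0: float) -> np.ndarray | float:
    """Sphere diffraction intensity ``i0 * F(qR)^2`` in photons."""
    if i0 < 0:
        raise InvalidParameterError("i0 must be non-negative")
    f = sphere_amplitude(q, radius)
    return i0 * np.square(f)


def _draw_radius(config: SimulationConfig, rng: np.random.Generator) -> float:
    lo, hi = config.particle_radius_range
    if rng.random() < config.contaminant_fraction:
        # contaminant: outside the nominal band on either side
        if rng.random() < 0.5:
            return float(rng.uniform(0.4 * lo, 0.95 * lo))
        return float(rng.uniform(1.05 * hi, 1.8 * hi))
    return float(rng.uniform(lo, hi))


def _noiseless_single(
    q: np.ndarray, radius: float, config: SimulationConfig, fluence: float
) -> np.ndarray:
    # scattering power scales with particle volume^2; reference at band centre
    r_ref = 0.5 * (config.particle_radius_range[0] + config.particle_radius_range[1])
    i0 = config.mean_photon_scale * fluence * (radius / r_ref) ** 6
    return sphere_intensity(q, radius, i0)


def _noiseless_multi(
    qmag: np.ndarray,
    q_row: np.ndarray,
    q_col: np.ndarray,
    radii: np.ndarray,
    displacements: np.ndarray,
    config: SimulationConfig,
    fluence: float,
) -> np.ndarray:
    r_ref = 0.5 * (config.particle_radius_range[0] + config.particle_radius_range[1])
    amp = np.zeros(qmag.shape, dtype=complex)
    for radius, (dr, dc) in zip(radii, displacements):
        a0 = np.sqrt(config.mean_photon_scale * fluence) * (radius / r_ref) ** 3
        phase = np.exp(1j * (q_row * dr + q_col * dc))
        amp += a0 * sphere_amplitude(qmag, radius) * phase
    return np.abs(amp) ** 2


def simulate_pattern(
    config: SimulationConfig,
    geometry: DetectorGeometry,
    is_single: bool,
    rng: np.random.Generator,
    pattern_id: str = "",
    poisson: bool = True,
) -> tuple[DiffractionPattern, float]:
    """Draw one frame of the requested class; returns (pattern, diameter_nm).

    Single hits are one sphere's fringe pattern; non-single hits are either a
    coherent sum of 2-4 displaced spheres or (with ``empty_fraction``
    probability) a weak/empty frame.  Particle-bearing frames are conditioned
    on upstream hit finding: parameter draws whose expected particle signal on
    the live panel falls below ``hit_threshold_photons`` are redrawn, since
    such frames would never have entered the hit set.  All branches add the
    flat background, apply Poisson noise per pixel (unless ``poisson=False``)
    and zero out masked pixels.  The returned size is the diameter of the
    (first) particle, NaN for empty frames.
    """
    qmag = qmap(geometry)
    live = geometry.panel_mask
    if is_single:
        for _ in range(100):
            fluence = float(np.exp(rng.normal(0.0, config.fluence_jitter)))
            radius = _draw_radius(config, rng)
            expect = _noiseless_single(qmag, radius, config, fluence)
            if expect[live].sum() >= config.hit_threshold_photons:
                break
        size = 2.0 * radius
    elif rng.random() < config.empty_fraction:
        # weak/empty frame: residual scatter well below a real hit
        expect = np.full(qmag.shape, 0.0)
        size = np.nan
    else:
        q_row, q_col = qxy_map(geometry)
        for _ in range(100):
            fluence = float(np.exp(rng.normal(0.0, config.fluence_jitter)))
            k = int(rng.integers(config.multi_particle_count_range[0],
                                 config.multi_particle_count_range[1] + 1))
            radii = np.array([_draw_radius(config, rng) for _ in range(k)])
            d_mag = rng.uniform(*config.displacement_range, size=k)
            d_ang = rng.uniform(0.0, 2.0 * np.pi, size=k)
            disp = np.stack([d_mag * np.cos(d_ang), d_mag * np.sin(d_ang)], axis=1)
            disp[0] = 0.0  # first particle defines the origin
            expect = _noiseless_multi(qmag, q_row, q_col, radii, disp, config, fluence)
            if expect[live].sum() >= config.hit_threshold_photons:
                break
        size = 2.0 * float(radii[0])
    expect = expect + config.background_level
    frame = rng.poisson(expect).astype(np.float32) if poisson else expect.astype(np.float32)
    frame[~geometry.panel_mask] = 0.0
    return DiffractionPattern(intensity=frame, mask=geometry.panel_mask, id=pattern_id), size


def draw_labels(config: SimulationConfig, n: int,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Bernoulli class draw for a frame stream: 1 with prob ``single_fraction``."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return (rng.random(n) < config.single_fraction).astype(int)


def generate_stream(
    config: SimulationConfig, geometry: DetectorGeometry, n: int
) -> LabeledDataset:
    """Generate ``n`` frames with classes drawn at the configured rate."""
    rng = np.random.default_rng(config.seed)
    labels = draw_labels(config, n, rng)
    patterns: list[DiffractionPattern] = []
    sizes = np.empty(n)
    for i, lab in enumerate(labels):
        p, s = simulate_pattern(config, geometry, bool(lab), rng, pattern_id=f"sim-{i:06d}")
        patterns.append(p)
        sizes[i] = s
    return LabeledDataset(patterns=patterns, labels=labels, true_sizes=sizes)


def generate_dataset(
    config: SimulationConfig,
    geometry: DetectorGeometry,
    n_single: int,
    n_nonsingle: int,
    shuffle: bool = True,
) -> LabeledDataset:
    """Generate exactly ``n_single`` + ``n_nonsingle`` labelled frames.

    Deterministic for a fixed ``config.seed``: the same call returns
    byte-identical frames.
    """
    if n_single < 0 or n_nonsingle < 0:
        raise InvalidParameterError("counts must be non-negative")
    rng = np.random.default_rng(config.seed)
    n = n_single + n_nonsingle
    labels = np.concatenate([np.ones(n_single, int), np.zeros(n_nonsingle, int)])
    if shuffle:
        labels = labels[rng.permutation(n)]
    patterns: list[DiffractionPattern] = []
    sizes = np.empty(n)
    for i, lab in enumerate(labels):
        p, s = simulate_pattern(config, geometry, bool(lab), rng, pattern_id=f"sim-{i:06d}")
        patterns.append(p)
        sizes[i] = s
    return LabeledDataset(patterns=patterns, labels=labels, true_sizes=sizes)
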