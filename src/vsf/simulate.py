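"""Synthetic corridor measurements and measurement-error experiments.

The cadaveric coordinate sets behind published corridor studies are rarely
released, so this module generates measurements with known ground truth:
conical corridors whose apex-to-extrema distances match the laboratory
regime (a fixed ~190 mm navigation probe read with ~5 mm standard deviation
of error along the probe axis), with optionally irregular and non-convex
base outlines.

It also reproduces the two error analyses that motivate height
normalization: the along-probe jitter experiment (normalized volumes are far
more stable than raw ones) and the probe-length extension experiment (for a
fixed cone shape, volume grows with the cube of the height, so a 5 mm /
2.7% height error at ~184 mm inflates the raw volume by 8.4%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .geometry import (
    average_plane,
    fit_plane_least_squares,
    parallel_plane_at_height,
    perpendicular_height,
    project_points_along_apex_rays,
)
from .metric import CorridorMeasurement, cone_volume
from .polygon import build_plane_basis, shoelace_area, to_plane_coords

__all__ = [
    "SimulationConfig",
    "ProbeLengthExperiment",
    "make_regular_cone",
    "make_irregular_corridor",
    "add_probe_noise",
    "probe_length_experiment",
    "regular_polygon_area",
]

#: Nominal navigation-probe length (mm) used across the laboratory series.
DEFAULT_PROBE_LENGTH = 190.0

#: Standard deviation (mm) of the apex-to-extremum distance error observed
#: across repeated measurements with the fixed-length probe.
DEFAULT_NOISE_SD_ALONG = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic corridor measurement.

    ``probe_length`` is the apex-to-extremum distance of the noise-free
    ring; ``base_radius`` sets the corridor aperture, and the cone height
    follows as ``sqrt(probe_length² − base_radius²)``.  ``base_irregularity``
    modulates the ring radii smoothly within ±that fraction; ``concavity``
    pulls one vertex inside the ring's convex hull to produce a notched,
    non-convex (but still simple) base.  ``rotation``/``translation`` pose
    the corridor in the world frame.
    """

    n_points: int = 8
    probe_length: float = DEFAULT_PROBE_LENGTH
    base_radius: float = 45.0
    noise_sd_along: float = DEFAULT_NOISE_SD_ALONG
    noise_sd_transverse: float = 0.0
    base_irregularity: float = 0.0
    concavity: bool = False
    rotation: tuple = None
    translation: tuple = None
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 3:
            raise ConfigError(f"n_points must be >= 3, got {self.n_points}")
        if not self.probe_length > 0:
            raise ConfigError(f"probe_length must be positive, got {self.probe_length}")
        if not 0 < self.base_radius < self.probe_length:
            raise ConfigError(
                "base_radius must lie in (0, probe_length); got "
                f"{self.base_radius} with probe_length {self.probe_length}"
            )
        if self.noise_sd_along < 0 or self.noise_sd_transverse < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if not 0 <= self.base_irregularity < 1:
            raise ConfigError(
                f"base_irregularity must lie in [0, 1), got {self.base_irregularity}"
            )

    @property
    def height(self) -> float:
        """Perpendicular cone height implied by probe length and base radius."""
        return math.sqrt(self.probe_length**2 - self.base_radius**2)


@dataclass(frozen=True)
class ProbeLengthExperiment:
    """Outcome of extending a fixed-shape cone's height by ``delta_h``."""

    volume_before: float
    volume_after: float
    height_before: float
    height_after: float
    pct_height_increase: float
    pct_volume_increase: float


def _pose_arrays(rotation, translation):
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    if rot.shape != (3, 3):
        raise ConfigError(f"rotation must be a 3x3 matrix, got shape {rot.shape}")
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
        raise ConfigError("rotation matrix must be orthogonal")
    tr = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    if tr.shape != (3,):
        raise ConfigError(f"translation must be a 3-vector, got shape {tr.shape}")
    return rot, tr


def _assemble(radii, height, rotation, translation, **meta) -> CorridorMeasurement:
    """Place a ring of per-vertex radii at ``height`` and pose it in the world."""
    n = len(radii)
    theta = 2 * np.pi * np.arange(n) / n
    local = np.column_stack(
        [radii * np.cos(theta), radii * np.sin(theta), np.full(n, height)]
    )
    rot, tr = _pose_arrays(rotation, translation)
    apex = tr.copy()
    extrema = local @ rot.T + tr
    return CorridorMeasurement(apex=apex, extrema=extrema, **meta)


def make_regular_cone(
    n: int,
    base_radius: float,
    height: float,
    rotation=None,
    translation=None,
    **meta,
) -> CorridorMeasurement:
    """Right cone with a regular n-gon base: the closed-form ground truth.

    The apex sits at the pose origin; the extrema are equally spaced on a
    circle of ``base_radius`` in the plane at perpendicular distance
    ``height``, numbered in protocol (perimeter) order.  Its normalized
    volume has the closed form ``(1/3) * (n/2) * r_norm² * sin(2π/n) * h_norm``
    with ``r_norm = base_radius * h_norm / height``.
    """
    if n < 3:
        raise ConfigError(f"n must be >= 3, got {n}")
    if not (base_radius > 0 and height > 0):
        raise ConfigError("base_radius and height must be positive")
    return _assemble(
        np.full(n, float(base_radius)), float(height), rotation, translation, **meta
    )


def regular_polygon_area(n: int, radius: float) -> float:
    """Area of a regular n-gon inscribed in a circle: ``(n/2) r² sin(2π/n)``."""
    return 0.5 * n * radius**2 * math.sin(2 * math.pi / n)


def make_irregular_corridor(cfg: SimulationConfig) -> CorridorMeasurement:
    """Noise-free corridor with a smoothly irregular, optionally notched base.

    Ring radii are modulated by a low-order Fourier perturbation (harmonics
    2 and 3) scaled so the modulation stays within ±``base_irregularity``;
    because the vertices keep their angular order around the apex axis, the
    base polygon is star-shaped and therefore always simple.  With
    ``concavity`` one randomly chosen vertex is pulled to 30% of its
    neighbors' mean radius, producing a reflex (notch) vertex inside the
    convex hull.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_points
    radii = np.full(n, cfg.base_radius)
    if cfg.base_irregularity > 0:
        theta = 2 * np.pi * np.arange(n) / n
        modulation = np.zeros(n)
        for k in (2, 3):
            a, b = rng.standard_normal(2)
            modulation += a * np.cos(k * theta) + b * np.sin(k * theta)
        peak = np.max(np.abs(modulation))
        if peak > 0:
            modulation *= cfg.base_irregularity / peak
        radii = cfg.base_radius * (1.0 + modulation)
    if cfg.concavity:
        notch = int(rng.integers(n))
        neighbor_mean = 0.5 * (radii[(notch - 1) % n] + radii[(notch + 1) % n])
        radii = radii.copy()
        radii[notch] = 0.3 * neighbor_mean
    return _assemble(
        radii,
        cfg.height,
        cfg.rotation,
        cfg.translation,
        measurement_id=f"sim-{cfg.seed}",
        specimen="synthetic",
    )


def add_probe_noise(
    m: CorridorMeasurement, cfg: SimulationConfig, seed: int | None = None
) -> CorridorMeasurement:
    """Apply Gaussian coordinate-capture error to the extrema.

    Each extremum is displaced by ``N(0, noise_sd_along)`` along its apex
    ray — the dominant error mode when reading a fixed-length probe — and by
    independent ``N(0, noise_sd_transverse)`` in the two perpendicular
    directions.  The apex is left untouched.  Deterministic for a fixed
    seed (``cfg.seed`` unless overridden).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rays = m.extrema - m.apex
    lengths = np.linalg.norm(rays, axis=1)
    units = rays / lengths[:, None]
    displaced = m.extrema + rng.normal(0.0, cfg.noise_sd_along, len(units))[:, None] * units
    if cfg.noise_sd_transverse > 0:
        for i, u in enumerate(units):
            helper = np.array([1.0, 0.0, 0.0])
            if abs(u @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(u, helper)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            displaced[i] += rng.normal(0.0, cfg.noise_sd_transverse) * e1
            displaced[i] += rng.normal(0.0, cfg.noise_sd_transverse) * e2
    return m.with_extrema(displaced)


def probe_length_experiment(
    m: CorridorMeasurement, delta_h: float = 5.0
) -> ProbeLengthExperiment:
    """Quantify how a probe-length error inflates the raw cone volume.

    The best-fit base plane is translated ``delta_h`` mm farther from the
    apex and the extrema are re-translated onto it along their apex rays —
    the same corridor as would have been measured with a longer probe.  For
    exactly conical data the volume ratio follows the similar-cone cube
    law ``(1 + delta_h / h)³``.
    """
    init = average_plane(m.extrema, apex=m.apex)
    best, _ = fit_plane_least_squares(m.extrema, init)
    h_before = perpendicular_height(best, m.apex)
    if not delta_h > -h_before:
        raise ValueError(
            f"delta_h must exceed -perpendicular height ({-h_before:.3f} mm)"
        )

    def _volume_at(plane, height):
        translated = project_points_along_apex_rays(m.extrema, m.apex, plane)
        basis = build_plane_basis(translated)
        area = shoelace_area(to_plane_coords(translated, basis))
        return cone_volume(area, height)

    volume_before = _volume_at(best, h_before)
    h_after = h_before + delta_h
    if delta_h == 0:
        volume_after = volume_before
    else:
        farther = parallel_plane_at_height(best, m.apex, h_after)
        volume_after = _volume_at(farther, h_after)
    return ProbeLengthExperiment(
        volume_before=volume_before,
        volume_after=volume_after,
        height_before=h_before,
        height_after=h_after,
        pct_height_increase=100.0 * delta_h / h_before,
        pct_volume_increase=100.0 * (volume_after / volume_before - 1.0),
    )
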