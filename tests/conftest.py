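"""Shared fixtures and geometric helpers for the test suite."""

import logging

import numpy as np
import pytest

from vsf import CorridorMeasurement


@pytest.fixture(autouse=True)
def _quiet_legacy_warnings(caplog):
    """Silence the (expected) non-coplanarity warnings of the legacy fan area."""
    caplog.set_level(logging.ERROR, logger="vsf.polygon")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_transform_measurement(
    m: CorridorMeasurement, rotation: np.ndarray, translation: np.ndarray
) -> CorridorMeasurement:
    """Apply the rigid motion ``p -> R p + t`` to apex and extrema."""
    return CorridorMeasurement(
        apex=rotation @ m.apex + translation,
        extrema=m.extrema @ rotation.T + translation,
        measurement_id=m.measurement_id,
        specimen=m.specimen,
        approach=m.approach,
        target=m.target,
        rater=m.rater,
        replicate=m.replicate,
    )


def star_polygon(rng: np.random.Generator, n: int = 8) -> np.ndarray:
    """Random simple 2D polygon: sorted angles with positive radii (star-shaped)."""
    angles = np.sort(rng.uniform(0.0, 2 * np.pi, n))
    while np.min(np.diff(angles)) < 1e-3:  # avoid near-duplicate vertices
        angles = np.sort(rng.uniform(0.0, 2 * np.pi, n))
    radii = rng.uniform(0.5, 3.0, n)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
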