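"""Per-measurement volume of surgical freedom and replicate aggregation.

The volume of surgical freedom (VSF) models a surgical access corridor as a
cone with an irregular base: the apex is the surgical target structure and
the base is the ring of instrument-extrema points captured with a
neuronavigation probe.  For one measurement the pipeline is:

1. fit the total-least-squares base plane to the extrema,
2. translate that plane to a fixed perpendicular distance ``h_norm`` from
   the apex (height normalization, default 10 mm),
3. translate each extremum onto the plane along its apex ray,
4. chart the translated ring in 2D and take the shoelace area,
5. volume = area x height / 3.

The normalized volume is probe-length independent: re-measuring the same
corridor with a longer instrument scales every extremum along its apex ray,
which leaves the normalized cross-section — and hence the normalized VSF —
unchanged.  The raw volume (to the best-fit plane at the measured height)
and the legacy Heron-fan "surgical freedom" area are reported alongside for
comparison with the older literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AmbiguousSideError, DegeneratePointError, EmptyGroupError, VSFError
from .geometry import (
    Plane,
    as_point,
    as_points,
    average_plane,
    fit_plane_least_squares,
    parallel_plane_at_height,
    perpendicular_height,
    project_points_along_apex_rays,
)
from .polygon import build_plane_basis, fan_triangulation_area, shoelace_area, to_plane_coords

__all__ = [
    "CorridorMeasurement",
    "VSFResult",
    "AggregateSummary",
    "DEFAULT_H_NORM",
    "DEFAULT_ANGLE_PAIRS",
    "cone_volume",
    "angle_of_attack",
    "compute_vsf",
    "legacy_surgical_freedom",
    "probe_lengths",
    "aggregate_measurements",
]

#: Default normalization height in mm (cross-section 10 mm from the target).
DEFAULT_H_NORM = 10.0

#: 1-based protocol indices of the angle-of-attack point pairs for the
#: 8-point protocol: points 1 & 5 span the craniocaudal maximal angle,
#: points 3 & 7 the mediolateral angle.
DEFAULT_ANGLE_PAIRS = ((1, 5), (3, 7))


@dataclass(frozen=True)
class CorridorMeasurement:
    """One corridor measurement: apex point plus the ordered extrema ring.

    ``extrema`` must be in protocol (perimeter) order — points are captured
    sequentially around the corridor boundary — because the base polygon is
    built directly from this order.
    """

    apex: np.ndarray
    extrema: np.ndarray
    measurement_id: str = ""
    specimen: str = ""
    approach: str = ""
    target: str = ""
    rater: str = ""
    replicate: int = 1

    def __post_init__(self):
        object.__setattr__(self, "apex", as_point(self.apex))
        object.__setattr__(self, "extrema", as_points(self.extrema))
        if len(self.extrema) < 3:
            raise ValueError(
                f"measurement {self.measurement_id!r}: need >= 3 extrema, "
                f"got {len(self.extrema)}"
            )
        dists = np.linalg.norm(self.extrema - self.apex, axis=1)
        if np.any(dists < 1e-9):
            raise ValueError(
                f"measurement {self.measurement_id!r}: an extremum coincides "
                "with the apex"
            )

    @property
    def n_points(self) -> int:
        return len(self.extrema)

    def with_extrema(self, extrema) -> "CorridorMeasurement":
        return replace(self, extrema=as_points(extrema))


@dataclass(frozen=True)
class VSFResult:
    """Every scalar derived from one corridor measurement.

    Volumes in mm³, areas in mm², lengths in mm, angles in degrees.
    ``raw_volume`` is the cone volume to the best-fit plane at the measured
    height; ``normalized_vsf`` is the volume re-cut at ``h_norm``.  Angles
    are NaN when the protocol point pairs do not exist (fewer extrema than
    the configured indices).
    """

    measurement_id: str
    specimen: str
    approach: str
    target: str
    rater: str
    replicate: int
    n_points: int
    raw_volume: float
    normalized_vsf: float
    base_area_raw: float
    base_area_norm: float
    perp_height: float
    h_norm: float
    craniocaudal_angle: float
    mediolateral_angle: float
    legacy_heron_area: float
    probe_length_mean: float
    probe_length_per_point: tuple = field(default=())

    SCALAR_FIELDS = (
        "raw_volume",
        "normalized_vsf",
        "base_area_raw",
        "base_area_norm",
        "perp_height",
        "h_norm",
        "craniocaudal_angle",
        "mediolateral_angle",
        "legacy_heron_area",
        "probe_length_mean",
    )

    def as_dict(self) -> dict:
        d = {
            "measurement_id": self.measurement_id,
            "specimen": self.specimen,
            "approach": self.approach,
            "target": self.target,
            "rater": self.rater,
            "replicate": self.replicate,
            "n_points": self.n_points,
        }
        for name in self.SCALAR_FIELDS:
            d[name] = getattr(self, name)
        d["probe_length_per_point"] = list(self.probe_length_per_point)
        return d


@dataclass(frozen=True)
class AggregateSummary:
    """Replicate summary for one approach x target group (mean and sample SD)."""

    approach: str
    target: str
    n: int
    normalized_vsf_mean: float
    normalized_vsf_sd: float
    craniocaudal_angle_mean: float
    craniocaudal_angle_sd: float
    mediolateral_angle_mean: float
    mediolateral_angle_sd: float

    def as_dict(self) -> dict:
        return {
            "approach": self.approach,
            "target": self.target,
            "n": self.n,
            "normalized_vsf_mean": self.normalized_vsf_mean,
            "normalized_vsf_sd": self.normalized_vsf_sd,
            "craniocaudal_angle_mean": self.craniocaudal_angle_mean,
            "craniocaudal_angle_sd": self.craniocaudal_angle_sd,
            "mediolateral_angle_mean": self.mediolateral_angle_mean,
            "mediolateral_angle_sd": self.mediolateral_angle_sd,
        }


def cone_volume(area: float, height: float) -> float:
    """Volume of a cone with base ``area`` (mm²) and perpendicular ``height`` (mm).

    ``V = area * height / 3`` holds for any planar base shape, regular or not.
    """
    if area < 0 or height < 0:
        raise ValueError(f"area and height must be non-negative, got ({area}, {height})")
    return area * height / 3.0


def angle_of_attack(apex, p_a, p_b) -> float:
    """Apex angle (degrees) between the directions to two extrema points.

    This is the full 3D angle at the apex between ``p_a - apex`` and
    ``p_b - apex`` — the instrument's maximal angular excursion between two
    opposing boundary points.
    """
    apex = as_point(apex)
    va = as_point(p_a) - apex
    vb = as_point(p_b) - apex
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        raise DegeneratePointError("an angle point coincides with the apex")
    cosang = np.clip(va @ vb / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def probe_lengths(m: CorridorMeasurement) -> tuple[np.ndarray, float]:
    """Apex-to-extremum Euclidean distances (mm) and their mean.

    The spread of these lengths around the nominal probe length is the
    measurement-error signature that height normalization suppresses.
    """
    dists = np.linalg.norm(m.extrema - m.apex, axis=1)
    return dists, float(dists.mean())


def legacy_surgical_freedom(m: CorridorMeasurement, anchor_index: int = 0) -> float:
    """Legacy surgical-freedom area (mm²): Heron fan over the raw extrema.

    Computed on the measured, generally non-coplanar 3D points, exactly as
    the historical method did — including its overestimation of the
    perpendicular cross-section.  ``anchor_index`` selects the fan vertex,
    since the historical triangle division was a per-study choice.
    """
    return fan_triangulation_area(m.extrema, anchor_index=anchor_index)


def _planar_area(extrema, apex, plane: Plane) -> float:
    """Shoelace area of the extrema after apex-ray translation onto ``plane``."""
    translated = project_points_along_apex_rays(extrema, apex, plane)
    basis = build_plane_basis(translated)
    return shoelace_area(to_plane_coords(translated, basis))


def compute_vsf(
    m: CorridorMeasurement,
    h_norm: float = DEFAULT_H_NORM,
    angle_pairs=DEFAULT_ANGLE_PAIRS,
    legacy_anchor: int = 0,
    strict: bool = False,
) -> VSFResult:
    """Run the full VSF pipeline on one measurement.

    Parameters
    ----------
    m
        The measurement (apex + ordered extrema ring).
    h_norm
        Normalization height in mm; the corridor cross-section is taken at
        this perpendicular distance from the apex.
    angle_pairs
        Two 1-based protocol index pairs, (craniocaudal, mediolateral).
        Angles are reported as NaN when an index exceeds the number of
        extrema (e.g. non-default protocols with fewer points).
    legacy_anchor
        Fan anchor for the legacy Heron area.
    strict
        Validate that the translated ring forms a simple polygon.
    """
    try:
        init = average_plane(m.extrema, apex=m.apex)
        best, _diag = fit_plane_least_squares(m.extrema, init)
        h = perpendicular_height(best, m.apex)
        if h < 1e-9:
            raise AmbiguousSideError(
                "best-fit plane passes through the apex; the corridor has no height"
            )

        base_area_raw = _planar_area(m.extrema, m.apex, best)
        raw_volume = cone_volume(base_area_raw, h)

        norm_plane = parallel_plane_at_height(best, m.apex, h_norm)
        translated = project_points_along_apex_rays(m.extrema, m.apex, norm_plane)
        basis = build_plane_basis(translated)
        coords2d = to_plane_coords(translated, basis)
        base_area_norm = shoelace_area(coords2d, strict=strict)
        normalized_vsf = cone_volume(base_area_norm, h_norm)

        cc_pair, ml_pair = angle_pairs
        cc = _angle_for_pair(m, cc_pair)
        ml = _angle_for_pair(m, ml_pair)

        legacy = legacy_surgical_freedom(m, anchor_index=legacy_anchor)
        per_point, mean_len = probe_lengths(m)
    except VSFError as exc:
        raise type(exc)(
            f"measurement {m.measurement_id!r}: {exc}"
        ) from exc

    return VSFResult(
        measurement_id=m.measurement_id,
        specimen=m.specimen,
        approach=m.approach,
        target=m.target,
        rater=m.rater,
        replicate=m.replicate,
        n_points=m.n_points,
        raw_volume=raw_volume,
        normalized_vsf=normalized_vsf,
        base_area_raw=base_area_raw,
        base_area_norm=base_area_norm,
        perp_height=h,
        h_norm=h_norm,
        craniocaudal_angle=cc,
        mediolateral_angle=ml,
        legacy_heron_area=legacy,
        probe_length_mean=mean_len,
        probe_length_per_point=tuple(float(x) for x in per_point),
    )


def _angle_for_pair(m: CorridorMeasurement, pair) -> float:
    i, j = pair
    if not (1 <= i <= m.n_points and 1 <= j <= m.n_points):
        return float("nan")
    return angle_of_attack(m.apex, m.extrema[i - 1], m.extrema[j - 1])


def aggregate_measurements(results) -> list[AggregateSummary]:
    """Group results by approach x target and summarize replicates.

    Uses the sample standard deviation (n−1 denominator), the replicate
    convention for repeated measurements; SD is 0 for singleton groups.
    """
    results = list(results)
    if not results:
        raise EmptyGroupError("no results to aggregate")
    frame = pd.DataFrame([r.as_dict() for r in results])
    summaries = []
    for (approach, target), grp in frame.groupby(["approach", "target"], sort=True):
        def _stats(col):
            vals = grp[col].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            return mean, sd

        vsf_m, vsf_s = _stats("normalized_vsf")
        cc_m, cc_s = _stats("craniocaudal_angle")
        ml_m, ml_s = _stats("mediolateral_angle")
        summaries.append(
            AggregateSummary(
                approach=approach,
                target=target,
                n=len(grp),
                normalized_vsf_mean=vsf_m,
                normalized_vsf_sd=vsf_s,
                craniocaudal_angle_mean=cc_m,
                craniocaudal_angle_sd=cc_s,
                mediolateral_angle_mean=ml_m,
                mediolateral_angle_sd=ml_s,
            )
        )
    return summaries
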