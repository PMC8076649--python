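"""Measurement-file and results-report serialization (CSV and JSON).

The measurement file is a long-format table, one row per captured point:

``measurement_id, specimen, approach, target, rater, replicate, role,
point_index, x_mm, y_mm, z_mm``

with ``role`` either ``apex`` (exactly one per measurement, blank
``point_index``) or ``extremum`` (``point_index`` consecutive from 1 in
protocol order).  Coordinates are millimeters in any fixed Cartesian frame;
every derived scalar is frame-invariant.  The JSON variant carries the same
content as one object per measurement.

Validation is aggregated: a malformed file reports *every* violation with
its row number, not just the first.
"""

from __future__ import annotations

import json
import math
import sys

import numpy as np
import pandas as pd

from .errors import ParseError, UnsupportedFormatError, ValidationError
from .metric import AggregateSummary, CorridorMeasurement, VSFResult

__all__ = [
    "MEASUREMENT_COLUMNS",
    "REPORT_UNITS",
    "read_measurements",
    "write_measurements",
    "write_report",
    "read_report",
    "write_aggregate",
]

MEASUREMENT_COLUMNS = [
    "measurement_id",
    "specimen",
    "approach",
    "target",
    "rater",
    "replicate",
    "role",
    "point_index",
    "x_mm",
    "y_mm",
    "z_mm",
]

#: Units of every scalar report column, appended to the column name so the
#: header itself documents them (e.g. ``normalized_vsf_mm3``).
REPORT_UNITS = {
    "raw_volume": "mm3",
    "normalized_vsf": "mm3",
    "base_area_raw": "mm2",
    "base_area_norm": "mm2",
    "perp_height": "mm",
    "h_norm": "mm",
    "craniocaudal_angle": "deg",
    "mediolateral_angle": "deg",
    "legacy_heron_area": "mm2",
    "probe_length_mean": "mm",
}

_META_COLUMNS = ["measurement_id", "specimen", "approach", "target", "rater", "replicate"]


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("csv", "json"):
            raise UnsupportedFormatError(f"unsupported table format {fmt!r}")
        return fmt
    suffix = str(path).rsplit(".", 1)[-1].lower()
    if suffix in ("csv", "json"):
        return suffix
    raise UnsupportedFormatError(
        f"cannot infer format of {path!r}; pass format='csv' or 'json'"
    )


def _finite(value) -> bool:
    try:
        return math.isfinite(float(value))
    except (TypeError, ValueError):
        return False


def read_measurements(path, fmt: str | None = None) -> list[CorridorMeasurement]:
    """Read and validate a measurement file.

    Raises
    ------
    ParseError
        If the file cannot be parsed at all (bad CSV/JSON, missing columns).
    ValidationError
        Listing every invariant violation (missing apex, non-consecutive
        point indices, non-finite coordinates, ...) with row context.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        return _read_measurements_csv(path)
    return _read_measurements_json(path)


def _read_measurements_csv(path) -> list[CorridorMeasurement]:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises a zoo of parser errors
        raise ParseError(f"could not parse CSV file {path!r}: {exc}") from exc
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path!r} is missing required columns: {missing}")

    problems: list[str] = []
    measurements: list[CorridorMeasurement] = []
    # +2: 1-based data rows after the header line.
    frame = frame.assign(_row=frame.index + 2)
    for mid, grp in frame.groupby("measurement_id", sort=False):
        if not str(mid).strip():
            problems.append("a row has an empty measurement_id")
            continue
        local: list[str] = []
        apex_rows = grp[grp["role"] == "apex"]
        extremum_rows = grp[grp["role"] == "extremum"]
        stray = grp[~grp["role"].isin(["apex", "extremum"])]
        for _, row in stray.iterrows():
            local.append(f"{mid}: row {row['_row']}: unknown role {row['role']!r}")
        if len(apex_rows) != 1:
            local.append(
                f"{mid}: expected exactly one apex row, found {len(apex_rows)}"
            )
        for _, row in grp.iterrows():
            for col in ("x_mm", "y_mm", "z_mm"):
                if not _finite(row[col]):
                    local.append(
                        f"{mid}: row {row['_row']}: {col}={row[col]!r} is not "
                        "a finite number"
                    )
        indices = []
        for _, row in extremum_rows.iterrows():
            try:
                indices.append(int(float(row["point_index"])))
            except (TypeError, ValueError):
                local.append(
                    f"{mid}: row {row['_row']}: extremum point_index "
                    f"{row['point_index']!r} is not an integer"
                )
        if len(indices) == len(extremum_rows) and sorted(indices) != list(
            range(1, len(indices) + 1)
        ):
            local.append(
                f"{mid}: extremum point_index values {sorted(indices)} are not "
                f"consecutive from 1"
            )
        if len(extremum_rows) < 3:
            local.append(
                f"{mid}: need at least 3 extremum rows, found {len(extremum_rows)}"
            )
        if local:
            problems.extend(local)
            continue
        apex_row = apex_rows.iloc[0]
        ordered = extremum_rows.assign(
            _idx=[int(float(v)) for v in extremum_rows["point_index"]]
        ).sort_values("_idx")
        try:
            measurements.append(
                CorridorMeasurement(
                    apex=[float(apex_row[c]) for c in ("x_mm", "y_mm", "z_mm")],
                    extrema=ordered[["x_mm", "y_mm", "z_mm"]].astype(float).to_numpy(),
                    measurement_id=str(mid),
                    specimen=str(apex_row["specimen"]),
                    approach=str(apex_row["approach"]),
                    target=str(apex_row["target"]),
                    rater=str(apex_row["rater"]),
                    replicate=int(float(apex_row["replicate"] or 1)),
                )
            )
        except ValueError as exc:
            problems.append(str(exc))
    if problems:
        raise ValidationError(problems)
    if not measurements:
        raise ValidationError([f"{path!r} contains no measurements"])
    return measurements


def _read_measurements_json(path) -> list[CorridorMeasurement]:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"could not parse JSON file {path!r}: {exc}") from exc
    records = payload.get("measurements") if isinstance(payload, dict) else payload
    if not isinstance(records, list):
        raise ParseError(
            f"{path!r}: expected a list of measurements or a "
            "{'measurements': [...]} object"
        )
    problems: list[str] = []
    measurements: list[CorridorMeasurement] = []
    for i, rec in enumerate(records):
        mid = rec.get("measurement_id", f"<record {i}>")
        apex = rec.get("apex")
        extrema = rec.get("extrema")
        if apex is None or extrema is None:
            problems.append(f"{mid}: missing 'apex' or 'extrema'")
            continue
        try:
            measurements.append(
                CorridorMeasurement(
                    apex=apex,
                    extrema=extrema,
                    measurement_id=str(rec.get("measurement_id", "")),
                    specimen=str(rec.get("specimen", "")),
                    approach=str(rec.get("approach", "")),
                    target=str(rec.get("target", "")),
                    rater=str(rec.get("rater", "")),
                    replicate=int(rec.get("replicate", 1)),
                )
            )
        except ValueError as exc:
            problems.append(f"{mid}: {exc}")
    if problems:
        raise ValidationError(problems)
    if not measurements:
        raise ValidationError([f"{path!r} contains no measurements"])
    return measurements


def write_measurements(measurements, path, fmt: str | None = None) -> None:
    """Write measurements in the long-format table (CSV) or JSON schema."""
    measurements = list(measurements)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        rows = []
        for m in measurements:
            meta = dict(
                measurement_id=m.measurement_id,
                specimen=m.specimen,
                approach=m.approach,
                target=m.target,
                rater=m.rater,
                replicate=m.replicate,
            )
            rows.append(
                {**meta, "role": "apex", "point_index": "",
                 "x_mm": m.apex[0], "y_mm": m.apex[1], "z_mm": m.apex[2]}
            )
            for k, p in enumerate(m.extrema, start=1):
                rows.append(
                    {**meta, "role": "extremum", "point_index": k,
                     "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
                )
        pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)
    else:
        records = [
            {
                "measurement_id": m.measurement_id,
                "specimen": m.specimen,
                "approach": m.approach,
                "target": m.target,
                "rater": m.rater,
                "replicate": m.replicate,
                "apex": list(m.apex),
                "extrema": m.extrema.tolist(),
            }
            for m in measurements
        ]
        with open(path, "w") as fh:
            json.dump({"measurements": records}, fh, indent=2)
            fh.write("\n")


def _report_column(name: str) -> str:
    unit = REPORT_UNITS.get(name)
    return f"{name}_{unit}" if unit else name


def report_frame(results) -> pd.DataFrame:
    """Per-measurement report as a DataFrame with unit-suffixed columns."""
    rows = []
    for r in results:
        row = {c: getattr(r, c) for c in _META_COLUMNS}
        row["n_points"] = r.n_points
        for name in VSFResult.SCALAR_FIELDS:
            row[_report_column(name)] = getattr(r, name)
        row["probe_length_per_point_mm"] = ";".join(
            format(v, ".6f") for v in r.probe_length_per_point
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(results, path, fmt: str | None = None) -> None:
    """Write one row per measurement with every derived scalar.

    Column order is deterministic; CSV stores 6 decimals, JSON full
    precision.  ``path`` may be ``"-"`` for stdout (CSV only).
    """
    results = list(results)
    if not results:
        raise ValidationError(["no results to write"])
    if path == "-":
        report_frame(results).to_csv(sys.stdout, index=False, float_format="%.6f")
        return
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        report_frame(results).to_csv(path, index=False, float_format="%.6f")
    else:
        with open(path, "w") as fh:
            json.dump({"results": [r.as_dict() for r in results]}, fh, indent=2)
            fh.write("\n")


def read_report(path, fmt: str | None = None) -> list[VSFResult]:
    """Read a per-measurement report back into :class:`VSFResult` objects."""
    fmt = _infer_format(path, fmt)
    results = []
    if fmt == "csv":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:
            raise ParseError(f"could not parse CSV report {path!r}: {exc}") from exc
        for _, row in frame.iterrows():
            per_point = row.get("probe_length_per_point_mm", "")
            per_point = (
                tuple(float(v) for v in str(per_point).split(";") if v)
                if isinstance(per_point, str) and per_point
                else ()
            )
            results.append(
                VSFResult(
                    **{c: row[c] for c in _META_COLUMNS},
                    n_points=int(row["n_points"]),
                    **{
                        name: float(row[_report_column(name)])
                        for name in VSFResult.SCALAR_FIELDS
                    },
                    probe_length_per_point=per_point,
                )
            )
    else:
        try:
            with open(path) as fh:
                payload = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ParseError(f"could not parse JSON report {path!r}: {exc}") from exc
        for rec in payload.get("results", []):
            rec = dict(rec)
            rec["probe_length_per_point"] = tuple(
                rec.get("probe_length_per_point", ())
            )
            results.append(VSFResult(**rec))
    if not results:
        raise ValidationError([f"{path!r} contains no results"])
    return results


def write_aggregate(summaries, path, fmt: str | None = None) -> None:
    """Write approach x target replicate summaries (means and sample SDs)."""
    summaries = list(summaries)
    if not summaries:
        raise ValidationError(["no summaries to write"])
    if path == "-":
        pd.DataFrame([s.as_dict() for s in summaries]).to_csv(
            sys.stdout, index=False, float_format="%.6f"
        )
        return
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        pd.DataFrame([s.as_dict() for s in summaries]).to_csv(
            path, index=False, float_format="%.6f"
        )
    else:
        with open(path, "w") as fh:
            json.dump({"aggregates": [s.as_dict() for s in summaries]}, fh, indent=2)
            fh.write("\n")
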