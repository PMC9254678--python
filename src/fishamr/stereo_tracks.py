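"""Distance-corrected lengths and swimming speeds from stereo-video tracks.

Stereo-video length measurements drift with distance from the nearest
camera, so a linear error model (error = intercept + slope * distance) is
fitted on calibration pairs and subtracted from every length and
displacement measurement.  Speeds are straight-line (chord) speeds of a
fish over consecutive 3-5 s windows; an individual's final length and field
speed are the means of its repeated measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import InputError

__all__ = [
    "ErrorModel",
    "fit_error_model",
    "apply_correction",
    "track_speed",
    "summarize_individual",
    "speeds_from_tracks",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrorModel:
    """Linear measurement-error model: error (cm) = intercept + slope * distance (m)."""

    intercept: float
    slope: float
    resid_sd: float = 0.0


def fit_error_model(calibration: pd.DataFrame) -> ErrorModel:
    """Least-squares fit of (measured - true) length on camera distance.

    ``calibration`` needs columns ``true_length_cm``, ``measured_length_cm``
    and ``distance_m`` with at least 3 rows spanning >= 2 distinct distances.
    """
    required = {"true_length_cm", "measured_length_cm", "distance_m"}
    missing = required - set(calibration.columns)
    if missing:
        raise InputError(f"calibration table missing columns {sorted(missing)}")
    if len(calibration) < 3:
        raise InputError("need >= 3 calibration measurements")
    dist = calibration["distance_m"].to_numpy(dtype=float)
    if np.any(dist < 0):
        raise InputError("camera distances must be non-negative")
    if np.unique(dist).size < 2:
        raise InputError("degenerate design: calibration spans a single distance")
    err = (
        calibration["measured_length_cm"] - calibration["true_length_cm"]
    ).to_numpy(dtype=float)
    res = stats.linregress(dist, err)
    fitted = res.intercept + res.slope * dist
    dof = max(len(err) - 2, 1)
    resid_sd = float(np.sqrt(np.sum((err - fitted) ** 2) / dof))
    return ErrorModel(float(res.intercept), float(res.slope), resid_sd)


def apply_correction(measurement, distance, model: ErrorModel):
    """Remove the fitted distance-dependent bias from a measurement (cm).

    Applied identically to fish lengths and to displacement distances.
    Accepts scalars or arrays.
    """
    corrected = (
        np.asarray(measurement, dtype=float)
        - model.intercept
        - model.slope * np.asarray(distance, dtype=float)
    )
    if np.any(corrected < 0):
        raise InputError("correction produced a negative length/distance")
    return float(corrected) if np.isscalar(measurement) else corrected


def track_speed(
    points: pd.DataFrame,
    model: ErrorModel | None = None,
    window: tuple[float, float] = (3.0, 5.0),
) -> np.ndarray:
    """Chord speeds (cm s-1) over consecutive track segments.

    ``points`` holds one individual's ordered 3D positions: columns ``time_s``,
    ``x_cm``, ``y_cm``, ``z_cm`` and optionally ``distance_m`` (to the nearest
    camera, used for the error correction).  Each consecutive pair of points
    gives one segment; segments whose duration falls outside ``window``
    seconds are dropped with a log entry.  The measured straight-line
    displacement of a segment is corrected with the segment's mean camera
    distance when ``model`` is given.
    """
    if len(points) < 2:
        raise InputError("need >= 2 track points")
    t = points["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InputError("track timestamps must be strictly increasing")
    xyz = points[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
    disp = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    dt = np.diff(t)
    if model is not None and "distance_m" in points.columns:
        d = points["distance_m"].to_numpy(dtype=float)
        seg_dist = 0.5 * (d[:-1] + d[1:])
        disp = np.asarray(disp) - model.intercept - model.slope * seg_dist
        if np.any(disp < 0):
            raise InputError("corrected displacement is negative")
    ok = (dt >= window[0]) & (dt <= window[1])
    if not np.all(ok):
        log.info("dropped %d segment(s) outside the %s s window", (~ok).sum(), window)
    return disp[ok] / dt[ok]


def summarize_individual(
    lengths,
    segment_speeds,
    individual_id: str = "",
    species_id: str = "",
    time_period: str = "",
) -> dict:
    """Final length and field speed of one fish: arithmetic means of the 3
    repeated length measurements and of the 3-5 segment speeds."""
    lengths = np.asarray(lengths, dtype=float)
    speeds = np.asarray(segment_speeds, dtype=float)
    if lengths.size != 3:
        raise InputError(f"expected 3 length replicates, got {lengths.size}")
    if not 3 <= speeds.size <= 5:
        raise InputError(f"expected 3-5 segment speeds, got {speeds.size}")
    if np.any(lengths <= 0) or np.any(speeds < 0):
        raise InputError("lengths must be positive and speeds non-negative")
    return {
        "individual_id": individual_id,
        "species_id": species_id,
        "length_cm": float(lengths.mean()),
        "v_field": float(speeds.mean()),
        "n_segments": int(speeds.size),
        "time_period": time_period,
    }


def speeds_from_tracks(
    tracks: pd.DataFrame,
    length_measurements: pd.DataFrame,
    model: ErrorModel | None = None,
    window: tuple[float, float] = (3.0, 5.0),
) -> pd.DataFrame:
    """Full track pipeline: per individual, correct the repeated length
    measurements, compute segment chord speeds, and average both.

    ``tracks``: columns individual_id, species_id, time_s, x_cm, y_cm, z_cm,
    distance_m.  ``length_measurements``: columns individual_id,
    measured_length_cm, distance_m (3 rows per individual).
    """
    rows = []
    for ind, pts in tracks.groupby("individual_id", sort=True):
        pts = pts.sort_values("time_s")
        speeds = track_speed(pts, model=model, window=window)
        lm = length_measurements[length_measurements["individual_id"] == ind]
        lengths = lm["measured_length_cm"].to_numpy(dtype=float)
        if model is not None:
            lengths = apply_correction(
                lengths, lm["distance_m"].to_numpy(dtype=float), model
            )
        species = pts["species_id"].iloc[0] if "species_id" in pts.columns else ""
        period = pts["time_period"].iloc[0] if "time_period" in pts.columns else ""
        rows.append(
            summarize_individual(lengths, speeds, ind, species, period)
        )
    return pd.DataFrame(rows)
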