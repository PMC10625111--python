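"""CSV/JSON readers and writers for the analysis file formats.

Formats (units are embedded in the column names):

* contour CSV: ``frame, angle_rad, radius_um`` (see
  :mod:`photomem.imaging_contour`)
* trace CSV: ``time_s``, either ``aspect`` or ``a_um``/``b_um``,
  ``illumination``, optional ``field_on``
* sweep CSV: ``frequency_hz, aspect_ratio`` plus a metadata JSON with
  ``radius_um``, ``lambda_in_uS_per_cm``, ``lambda_out_uS_per_cm``
* height-map CSV: plain numeric matrix (see
  :mod:`photomem.afm_thickness`)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .capacitance import FrequencySweep
from .constants import UM, US_PER_CM
from .electrodeform import AspectRatioTrace
from .imaging_contour import contours_to_frame, frame_to_contours


class FormatError(ValueError):
    """Malformed analysis input file."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


# -- contours ---------------------------------------------------------------

def read_contours(path):
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["frame", "angle_rad", "radius_um"], path)
    return frame_to_contours(df)


def write_contours(path, contours) -> None:
    contours_to_frame(contours).to_csv(path, index=False)


# -- traces -----------------------------------------------------------------

def read_trace(path) -> AspectRatioTrace:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["time_s", "illumination"], path)
    if "aspect" in df.columns:
        aspect = df["aspect"].to_numpy(float)
    elif {"a_um", "b_um"} <= set(df.columns):
        aspect = df["a_um"].to_numpy(float) / df["b_um"].to_numpy(float)
    else:
        raise FormatError(f"{path}: need either 'aspect' or 'a_um'/'b_um' columns")
    field_on = (
        df["field_on"].astype(bool).to_numpy() if "field_on" in df.columns else None
    )
    return AspectRatioTrace(
        times=df["time_s"].to_numpy(float),
        aspect=aspect,
        illumination=df["illumination"].astype(str).to_numpy(),
        field_on=field_on,
    )


def write_trace(path, trace: AspectRatioTrace) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "aspect": trace.aspect,
            "illumination": trace.illumination,
        }
    )
    if trace.field_on is not None:
        df["field_on"] = trace.field_on
    df.to_csv(path, index=False)


# -- sweeps -----------------------------------------------------------------

def read_sweep(path, metadata_path=None) -> FrequencySweep:
    """Read a sweep CSV plus its per-vesicle metadata JSON.

    ``metadata_path`` defaults to the CSV path with a ``.json`` suffix.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["frequency_hz", "aspect_ratio"], path)
    meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".json")
    if not meta_path.exists():
        raise FormatError(f"{path}: missing metadata JSON {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("radius_um", "lambda_in_uS_per_cm", "lambda_out_uS_per_cm"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing key {key!r}")
    return FrequencySweep(
        frequencies=df["frequency_hz"].to_numpy(float),
        aspect=df["aspect_ratio"].to_numpy(float),
        radius=float(meta["radius_um"]) * UM,
        lambda_in=float(meta["lambda_in_uS_per_cm"]) * US_PER_CM,
        lambda_out=float(meta["lambda_out_uS_per_cm"]) * US_PER_CM,
    )


def write_sweep(path, sweep: FrequencySweep, metadata_path=None) -> None:
    path = Path(path)
    pd.DataFrame(
        {"frequency_hz": sweep.frequencies, "aspect_ratio": sweep.aspect}
    ).to_csv(path, index=False)
    meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".json")
    meta_path.write_text(
        json.dumps(
            {
                "radius_um": sweep.radius / UM,
                "lambda_in_uS_per_cm": sweep.lambda_in / US_PER_CM,
                "lambda_out_uS_per_cm": sweep.lambda_out / US_PER_CM,
            },
            indent=2,
        )
    )


# -- tension-area -----------------------------------------------------------

def read_tension_area(path):
    """Tension-area CSV (area_nm2, tension_mN_per_m) -> TensionAreaPoint list."""
    from .mechanics import TensionAreaPoint

    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["area_nm2", "tension_mN_per_m"], path)
    return [
        TensionAreaPoint(area_per_lipid=a * 1e-18, tension=s * 1e-3)
        for a, s in zip(df["area_nm2"], df["tension_mN_per_m"])
    ]


def write_json_report(path, payload: dict) -> None:
    """Write a JSON report with deterministic key order."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n")
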