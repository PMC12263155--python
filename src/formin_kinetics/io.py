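"""CSV/JSON readers and writers for traces, events, and gels.

CSV dialect: comma-separated, UTF-8, header row required, '.' decimal.
Time is in seconds; formin concentrations in nM (actin in µM where it
appears).  JSON results use unit-suffixed keys (e.g. ``kd_nM``) to
prevent unit drift.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import AssemblyTrace, BundlingGel, FilamentTrace, PlantedEvent

__all__ = [
    "read_traces",
    "write_traces",
    "write_events_csv",
    "read_json",
    "write_json",
]

_SCHEMAS = {
    "assembly": ("trace_id", "formin_nM", "time_s", "signal_au"),
    "filament": ("filament_id", "time_s", "length_um"),
    "gel": ("lane", "formin_nM", "band", "intensity_au"),
}


def _require_columns(df: pd.DataFrame, schema: str, path):
    required = _SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing} for schema {schema!r} "
            f"(need {list(required)})"
        )


def _numeric(df: pd.DataFrame, cols, path):
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[converted.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value {df.loc[bad[0], c]!r} in column {c!r} "
                f"at row {int(bad[0]) + 2}"  # +2: header + 1-based
            )
        df[c] = converted
    return df


def read_traces(path, schema: str):
    """Read typed records from a CSV file.

    ``schema`` is one of ``assembly`` (-> list of AssemblyTrace, grouped
    by trace_id), ``filament`` (-> list of FilamentTrace) or ``gel``
    (-> list of BundlingGel, grouped by ``gel_id`` when present).
    Errors name the first offending row or column.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {list(_SCHEMAS)}")
    df = pd.read_csv(path)
    _require_columns(df, schema, path)

    if schema == "assembly":
        df = _numeric(df, ["formin_nM", "time_s", "signal_au"], path)
        traces = []
        for tid, grp in df.groupby("trace_id", sort=False):
            t = grp["time_s"].to_numpy()
            if t.size >= 2 and not np.all(np.diff(t) > 0):
                k = int(np.argmax(np.diff(t) <= 0))
                raise ValueError(
                    f"{path}: non-increasing time in trace {tid!r} near t={t[k]:g} s"
                )
            traces.append(
                AssemblyTrace(
                    trace_id=str(tid),
                    formin_nM=float(grp["formin_nM"].iloc[0]),
                    time_s=t,
                    signal_au=grp["signal_au"].to_numpy(),
                    baseline_au=float(grp["baseline_au"].iloc[0])
                    if "baseline_au" in grp
                    else None,
                    plateau_au=float(grp["plateau_au"].iloc[0])
                    if "plateau_au" in grp
                    else None,
                )
            )
        return traces

    if schema == "filament":
        cols = ["time_s", "length_um"] + (
            ["intensity_au"] if "intensity_au" in df.columns else []
        )
        df = _numeric(df, cols, path)
        traces = []
        for fid, grp in df.groupby("filament_id", sort=False):
            t = grp["time_s"].to_numpy()
            if t.size >= 2 and not np.all(np.diff(t) > 0):
                k = int(np.argmax(np.diff(t) <= 0))
                raise ValueError(
                    f"{path}: non-increasing time in filament {fid!r} near t={t[k]:g} s"
                )
            traces.append(
                FilamentTrace(
                    filament_id=str(fid),
                    time_s=t,
                    length_um=grp["length_um"].to_numpy(),
                    intensity_au=grp["intensity_au"].to_numpy()
                    if "intensity_au" in grp
                    else None,
                )
            )
        return traces

    # gel
    df = _numeric(df, ["formin_nM", "intensity_au"], path)
    bad_band = ~df["band"].isin(["pellet", "supernatant"])
    if bad_band.any():
        i = int(df.index[bad_band][0])
        raise ValueError(
            f"{path}: band must be 'pellet' or 'supernatant', got "
            f"{df.loc[i, 'band']!r} at row {i + 2}"
        )
    gels = []
    gel_groups = df.groupby("gel_id", sort=False) if "gel_id" in df.columns else [(0, df)]
    for _, gdf in gel_groups:
        lanes = []
        for lane, ldf in gdf.groupby("lane", sort=True):
            pel = ldf.loc[ldf["band"] == "pellet", "intensity_au"]
            sup = ldf.loc[ldf["band"] == "supernatant", "intensity_au"]
            if pel.empty or sup.empty:
                raise ValueError(
                    f"{path}: lane {lane!r} needs both pellet and supernatant bands"
                )
            lanes.append(
                (float(ldf["formin_nM"].iloc[0]), float(pel.iloc[0]), float(sup.iloc[0]))
            )
        gels.append(BundlingGel(lanes=lanes))
    return gels


def write_traces(records, path, schema: str):
    """Write traces or gels to CSV in the layout ``read_traces`` expects."""
    rows = []
    if schema == "assembly":
        for tr in records:
            for t, s in zip(tr.time_s, tr.signal_au):
                row = {
                    "trace_id": tr.trace_id,
                    "formin_nM": tr.formin_nM,
                    "time_s": t,
                    "signal_au": s,
                }
                if tr.baseline_au is not None:
                    row["baseline_au"] = tr.baseline_au
                if tr.plateau_au is not None:
                    row["plateau_au"] = tr.plateau_au
                rows.append(row)
    elif schema == "filament":
        for tr in records:
            for i, (t, ln) in enumerate(zip(tr.time_s, tr.length_um)):
                row = {"filament_id": tr.filament_id, "time_s": t, "length_um": ln}
                if tr.intensity_au is not None:
                    row["intensity_au"] = tr.intensity_au[i]
                rows.append(row)
    elif schema == "gel":
        for gi, gel in enumerate(records):
            for li, (dose, pel, sup) in enumerate(gel.lanes):
                rows.append(
                    {"gel_id": gi, "lane": li, "formin_nM": dose,
                     "band": "pellet", "intensity_au": pel}
                )
                rows.append(
                    {"gel_id": gi, "lane": li, "formin_nM": dose,
                     "band": "supernatant", "intensity_au": sup}
                )
    else:
        raise ValueError(f"unknown schema {schema!r}")
    pd.DataFrame(rows).to_csv(path, index=False)


def write_events_csv(events, path, truth: bool = False):
    """Write detected FormEvents (or planted ground truth) to CSV."""
    rows = []
    for ev in events:
        if truth:  # PlantedEvent
            rows.append(
                {
                    "t_pause_start_s": ev.t_pause_start,
                    "t_pause_end_s": ev.t_pause_end,
                    "t_burst_end_s": ev.t_burst_end,
                    "burst_rate_sub_per_s": ev.burst_rate,
                    "run_length_um": ev.run_length,
                }
            )
        else:
            rows.append(
                {
                    "filament_id": ev.filament_id,
                    "pause_duration_s": ev.pause_duration_s,
                    "burst_rate_sub_per_s": ev.burst_rate_sub_per_s,
                    "run_length_um": ev.run_length_um,
                    "burst_r2": ev.burst_r2,
                    "baseline_return": ev.baseline_return,
                    "censored": ev.censored,
                    "t_burst_start_s": ev.t_burst_start_s,
                    "t_burst_end_s": ev.t_burst_end_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(obj: dict, path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
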