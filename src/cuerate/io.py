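"""CSV / YAML / GeoJSON interchange for survey records.

All CSV is comma-separated UTF-8 with ISO-8601 timestamps and '.'
decimals.  Readers validate invariants row by row and report offending
row numbers rather than failing on the first bad value.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cue_rates import DailyAbundance, SightingRecord
from .detection import DetectionRecord
from .synthetic_data import CueEvent, WhaleTrack

SIGHTING_COLUMNS = [
    "timestamp",
    "bearing_deg",
    "range_m",
    "group_size",
    "direction",
    "beaufort",
    "visibility",
    "pod_id",
]


def read_sightings(path: str | Path) -> list[SightingRecord]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SightingRecord(
                time=pd.Timestamp(row.timestamp),
                bearing_deg=float(row.bearing_deg),
                range_m=float(row.range_m),
                group_size=int(row.group_size),
                direction=str(row.direction),
                beaufort=int(row.beaufort),
                visibility_code=int(row.visibility),
                pod_id=None if pd.isna(getattr(row, "pod_id", np.nan)) else int(row.pod_id),
            )
        )
    return records


def write_sightings(records: Sequence[SightingRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "timestamp": [r.time.isoformat() for r in records],
            "bearing_deg": [r.bearing_deg for r in records],
            "range_m": [r.range_m for r in records],
            "group_size": [r.group_size for r in records],
            "direction": [r.direction for r in records],
            "beaufort": [r.beaufort for r in records],
            "visibility": [r.visibility_code for r in records],
            "pod_id": [r.pod_id for r in records],
        }
    ).to_csv(path, index=False)


def read_abundance(path: str | Path) -> list[DailyAbundance]:
    df = pd.read_csv(path)
    return [
        DailyAbundance(
            day=int(r.day),
            median_whales=float(r.median),
            ci_low=float(r.ci_low),
            ci_high=float(r.ci_high),
        )
        for r in df.itertuples(index=False)
    ]


def write_tracks(tracks: Sequence[WhaleTrack], path: str | Path) -> None:
    pd.DataFrame(
        {
            "whale_id": [t.whale_id for t in tracks],
            "day": [t.day for t in tracks],
            "direction": [t.direction for t in tracks],
            "offshore_m": [t.offshore_m for t in tracks],
            "entry_time_s": [t.entry_time_s for t in tracks],
            "speed_mps": [t.speed_mps for t in tracks],
        }
    ).to_csv(path, index=False)


def write_cues(cues: Sequence[CueEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "whale_id": [c.whale_id for c in cues],
            "kind": [c.kind for c in cues],
            "time_s": [c.time_s for c in cues],
            "x_m": [c.x_m for c in cues],
            "y_m": [c.y_m for c in cues],
            "day": [c.day for c in cues],
            "direction": [c.direction for c in cues],
        }
    ).to_csv(path, index=False)


def write_detections(dets: Sequence[DetectionRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sensor": [d.sensor for d in dets],
            "time_s": [d.time_s for d in dets],
            "range_m": [d.range_m for d in dets],
            "pixel_row": [d.pixel[0] if d.pixel else np.nan for d in dets],
            "pixel_col": [d.pixel[1] if d.pixel else np.nan for d in dets],
            "direction": [d.direction for d in dets],
            "minute": [d.minute for d in dets],
        }
    ).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run/simulation config into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def points_to_geojson(
    positions: Iterable[tuple[float, float]], properties: Iterable[dict] | None = None
) -> dict:
    """GeoJSON FeatureCollection of (lat, lon) points."""
    positions = list(positions)
    props = list(properties) if properties is not None else [{} for _ in positions]
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": p,
            }
            for (lat, lon), p in zip(positions, props)
        ],
    }


def validate_sightings_csv(path: str | Path) -> list[str]:
    """Row-level schema and invariant checks for a sightings CSV.

    Returns a list of human-readable error strings (empty = clean).
    """
    errors: list[str] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - report any unreadable file
        return [f"unreadable file: {exc}"]
    missing = [c for c in SIGHTING_COLUMNS[:7] if c not in df.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
        return errors
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based plus header
        if not 0 <= float(row.bearing_deg) < 360:
            errors.append(f"row {rowno}: bearing {row.bearing_deg} outside [0, 360)")
        if float(row.range_m) <= 0:
            errors.append(f"row {rowno}: nonpositive range {row.range_m}")
        if int(row.group_size) < 1:
            errors.append(f"row {rowno}: group size {row.group_size} < 1")
        if str(row.direction) not in ("south", "north", "milling"):
            errors.append(f"row {rowno}: unknown direction {row.direction!r}")
        if not 0 <= int(row.beaufort) <= 9:
            errors.append(f"row {rowno}: Beaufort {row.beaufort} outside 0-9")
    return errors
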