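"""Reading and writing the pipeline's on-disk formats.

Tabular data are plain CSV with headers; frame point layers are GeoJSON
FeatureCollections of Point features carrying ``flight_id``,
``frame_index``, ``timestamp`` and (for synthetic truth) ``individual_id``
properties.  Synthetic frames use planar metre coordinates in a local
ground frame; real layers in lon/lat degrees can be projected with
:func:`lonlat_to_local` (equirectangular about the layer centroid, fine
for school extents far below a kilometre).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import FramePointSet

__all__ = [
    "read_units",
    "write_units",
    "write_frames",
    "read_frames",
    "lonlat_to_local",
]

UNIT_COLUMNS = [
    "photo_id", "flight_id", "observer_id", "height_m", "wind_ms",
    "cloud_class", "sun_class", "experienced", "n_definite", "n_possible",
    "est_pop",
]


def write_units(units: pd.DataFrame, path) -> None:
    cols = [c for c in UNIT_COLUMNS if c in units.columns]
    extra = [c for c in units.columns if c not in cols]
    units[cols + extra].to_csv(path, index=False, float_format="%.10g")


def read_units(path) -> pd.DataFrame:
    units = pd.read_csv(path)
    missing = set(UNIT_COLUMNS) - set(units.columns)
    if missing:
        raise ValueError(f"units table missing columns: {sorted(missing)}")
    return units


def write_frames(frames, path) -> None:
    """Write frame point sets as a GeoJSON FeatureCollection.

    ``frames`` is a list of FramePointSet or a dict flight_id -> list.
    """
    if isinstance(frames, dict):
        items = [(fid, fr) for fid, seq in sorted(frames.items())
                 for fr in seq]
    else:
        items = [(None, fr) for fr in frames]
    features = []
    for fid, fr in items:
        for j, (x, y) in enumerate(fr.points):
            props = {
                "frame_index": int(fr.frame_index),
                "timestamp": float(fr.timestamp),
            }
            if fid is not None:
                props["flight_id"] = int(fid)
            if fr.ids is not None:
                props["individual_id"] = int(fr.ids[j])
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point",
                                 "coordinates": [round(float(x), 6),
                                                 round(float(y), 6)]},
                    "properties": props,
                }
            )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def read_frames(path, flight_id: int | None = None,
                geographic: bool = False) -> list[FramePointSet]:
    """Read a GeoJSON point layer back into a frame sequence.

    Selects one flight when ``flight_id`` is given and the layer spans
    several.  ``geographic=True`` projects lon/lat coordinates to local
    planar metres first.
    """
    doc = json.loads(Path(path).read_text())
    rows = []
    for feat in doc.get("features", []):
        if feat.get("geometry", {}).get("type") != "Point":
            continue
        props = feat.get("properties", {})
        if flight_id is not None and props.get("flight_id") != flight_id:
            continue
        x, y = feat["geometry"]["coordinates"][:2]
        rows.append((props.get("frame_index", 0), props.get("timestamp", 0.0),
                     x, y, props.get("individual_id")))
    if not rows:
        raise ValueError(f"no point features found in {path}")
    df = pd.DataFrame(rows, columns=["frame", "ts", "x", "y", "iid"])
    if geographic:
        xy = lonlat_to_local(df[["x", "y"]].to_numpy())
        df[["x", "y"]] = xy
    frames = []
    for (fi, ts), grp in df.groupby(["frame", "ts"], sort=True):
        ids = (grp["iid"].to_numpy() if grp["iid"].notna().all() else None)
        frames.append(
            FramePointSet(frame_index=int(fi), timestamp=float(ts),
                          points=grp[["x", "y"]].to_numpy(),
                          ids=None if ids is None else ids.astype(int))
        )
    frames.sort(key=lambda f: f.timestamp)
    return frames


_M_PER_DEG_LAT = 110540.0
_M_PER_DEG_LON_EQ = 111320.0


def lonlat_to_local(lonlat: np.ndarray,
                    origin: tuple | None = None) -> np.ndarray:
    """Equirectangular projection to metres about ``origin`` (default centroid)."""
    ll = np.asarray(lonlat, float).reshape(-1, 2)
    if origin is None:
        origin = ll.mean(axis=0)
    lon0, lat0 = origin
    x = (ll[:, 0] - lon0) * _M_PER_DEG_LON_EQ * np.cos(np.radians(lat0))
    y = (ll[:, 1] - lat0) * _M_PER_DEG_LAT
    return np.column_stack([x, y])
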