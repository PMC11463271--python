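"""Readers and writers for the plain-text formats the pipeline consumes.

Track CSV: columns ``t`` then ``<keypoint>_x,<keypoint>_y`` per keypoint,
header mandatory, blank cells for missing samples.  An EthoVision-like export
dialect (semicolon separators, ``key;value`` metadata preamble before the
header row, ``X center``-style column names) is accepted through a reader
shim.  Field maps travel as long-form ``x,y,B_mT`` CSV; photometry as
``t,f465,f405``; events as a one-column CSV or a YAML list; epochs as a YAML
list of ``{label, start, end}``; images as multi-page TIFF with ground truth
in JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .behavior import Epoch, EpochSet, KeypointTrack
from .fieldmap import FieldGrid
from .photometry import PhotometrySession

__all__ = [
    "read_track_csv",
    "write_track_csv",
    "read_ethovision_csv",
    "read_field_grid_csv",
    "write_field_grid_csv",
    "read_photometry_csv",
    "write_photometry_csv",
    "read_events",
    "read_epochs_yaml",
    "write_epochs_yaml",
    "read_roi_csv",
    "read_pet_csv",
    "write_image_tiff",
    "read_image_tiff",
    "write_json",
]


# ---------------------------------------------------------------------------
# tracks


def read_track_csv(
    path, frame_rate: float, arena_size: tuple[float, float] = (26.5, 26.5)
) -> KeypointTrack:
    data = pd.read_csv(path)
    return KeypointTrack(data=data, frame_rate=frame_rate, arena_size=arena_size)


def write_track_csv(track: KeypointTrack, path) -> None:
    track.data.to_csv(path, index=False, na_rep="")


#: EthoVision-style column names mapped onto the canonical ones
_ETHOVISION_COLUMNS = {
    "trial time": "t",
    "x center": "center_x",
    "y center": "center_y",
    "x nose": "nose_x",
    "y nose": "nose_y",
    "x tail": "tail_x",
    "y tail": "tail_y",
}


def read_ethovision_csv(
    path, frame_rate: float, arena_size: tuple[float, float] = (26.5, 26.5)
) -> KeypointTrack:
    """Read a semicolon-separated export with a metadata preamble.

    Preamble lines (``key;value`` pairs) are skipped until the header row —
    the first line whose leading field is ``t`` or ``Trial time``.  Column
    names like ``X center`` are mapped to the canonical ``center_x`` form;
    ``-`` cells become missing.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        first = line.split(";")[0].strip().strip('"').lower()
        if first in ("t", "trial time"):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError("no header row found (expected 't' or 'Trial time')")
    data = pd.read_csv(path, sep=";", skiprows=header_idx, na_values=["-"])
    data.columns = [
        _ETHOVISION_COLUMNS.get(c.strip().strip('"').lower(), c.strip())
        for c in data.columns
    ]
    return KeypointTrack(data=data, frame_rate=frame_rate, arena_size=arena_size)


# ---------------------------------------------------------------------------
# field grids


def read_field_grid_csv(path) -> FieldGrid:
    """Long-form x,y,B_mT columns -> rectangular grid (rows may be in any
    order, but must tile a full rectangle)."""
    df = pd.read_csv(path)
    x = np.sort(df["x"].unique())
    y = np.sort(df["y"].unique())
    pivot = df.pivot_table(index="x", columns="y", values="B_mT")
    if pivot.isna().any().any():
        raise ValueError("field grid is not a complete rectangle")
    return FieldGrid(x=x, y=y, B=pivot.loc[x, y].to_numpy())


def write_field_grid_csv(grid: FieldGrid, path) -> None:
    xx, yy = np.meshgrid(grid.x, grid.y, indexing="ij")
    pd.DataFrame(
        {"x": xx.ravel(), "y": yy.ravel(), "B_mT": grid.B.ravel()}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# photometry


def read_photometry_csv(path, fs: float, events=None) -> PhotometrySession:
    df = pd.read_csv(path)
    return PhotometrySession(
        t=df["t"].to_numpy(float),
        f465=df["f465"].to_numpy(float),
        f405=df["f405"].to_numpy(float),
        fs=fs,
        events=np.asarray(events, dtype=float) if events is not None else None,
    )


def write_photometry_csv(session: PhotometrySession, path) -> None:
    pd.DataFrame(
        {"t": session.t, "f465": session.f465, "f405": session.f405}
    ).to_csv(path, index=False)


def read_events(path) -> np.ndarray:
    """TTL event times from a one-column CSV (header ``t``) or a YAML list."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        return np.asarray(yaml.safe_load(path.read_text()), dtype=float)
    df = pd.read_csv(path)
    return df[df.columns[0]].to_numpy(float)


# ---------------------------------------------------------------------------
# epochs


def read_epochs_yaml(path) -> EpochSet:
    items = yaml.safe_load(Path(path).read_text())
    return EpochSet(
        Epoch(str(e["label"]), float(e["start"]), float(e["end"])) for e in items
    )


def write_epochs_yaml(epochs: EpochSet, path) -> None:
    items = [
        {"label": e.label, "start": float(e.t_start), "end": float(e.t_end)}
        for e in epochs
    ]
    Path(path).write_text(yaml.safe_dump(items, sort_keys=False))


# ---------------------------------------------------------------------------
# ROI traces and PET tables


def read_roi_csv(path, baseline_window: tuple[float, float]):
    from .roi import RoiTraceSet

    return RoiTraceSet(data=pd.read_csv(path), baseline_window=baseline_window)


def read_pet_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# images and JSON sidecars


def write_image_tiff(image: np.ndarray, path) -> None:
    """Write a (C, H, W) stack as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(image), photometric="minisblack")


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n"
    )
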