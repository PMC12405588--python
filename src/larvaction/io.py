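"""Plain-text readers and writers for tracks, annotations and results.

The track table is long-form delimited text with one row per sample:
``larva_id, t, x1..x11, y1..y11`` (mm and seconds, head = point 1).
Stimulus metadata (onset and duration) lives in a small JSON sidecar next
to the table (``<table>.meta.json``) so the table itself stays a plain
rectangular file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import SpineTrack

logger = logging.getLogger(__name__)

__all__ = ["read_tracks", "write_tracks", "write_results", "track_columns"]


def track_columns() -> list[str]:
    return (["larva_id", "t"]
            + [f"x{i}" for i in range(1, 12)]
            + [f"y{i}" for i in range(1, 12)])


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_tracks(tracks: list[SpineTrack], path) -> Path:
    """Write tracks as one long-form CSV plus a JSON metadata sidecar."""
    path = Path(path)
    rows = []
    meta = {}
    for tr in tracks:
        n = tr.n_samples
        block = np.column_stack(
            [tr.times, tr.midline[:, :, 0], tr.midline[:, :, 1]]
        )
        df = pd.DataFrame(block, columns=track_columns()[1:])
        df.insert(0, "larva_id", tr.larva_id)
        rows.append(df)
        meta[tr.larva_id] = {
            "stimulus_onset": tr.stimulus_onset,
            "stimulus_duration": tr.stimulus_duration,
        }
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=track_columns())
    out.to_csv(path, index=False, float_format="%.9g")
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_tracks(path) -> list[SpineTrack]:
    """Read tracks from the long-form table; malformed rows are reported
    with their line numbers, non-monotone times reject the larva."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("empty track table %s", path)
        return []
    missing = set(track_columns()) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[track_columns()[1:]].isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValueError(f"{path}: malformed rows at lines {lines[:10]}")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    tracks = []
    for larva_id, g in df.groupby("larva_id", sort=False):
        t = g["t"].to_numpy(float)
        order = np.argsort(g.index.to_numpy())
        t = t[order]
        if np.any(np.diff(t) <= 0):
            first_bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
            line = int(g.index[order][first_bad + 1]) + 2
            raise ValueError(
                f"{path}: non-monotone times for larva {larva_id} at line {line}"
            )
        xs = g[[f"x{i}" for i in range(1, 12)]].to_numpy(float)[order]
        ys = g[[f"y{i}" for i in range(1, 12)]].to_numpy(float)[order]
        m = meta.get(str(larva_id), {})
        tracks.append(SpineTrack(
            larva_id=str(larva_id), times=t,
            midline=np.stack([xs, ys], axis=-1),
            stimulus_onset=float(m.get("stimulus_onset", 60.0)),
            stimulus_duration=float(m.get("stimulus_duration", 30.0)),
        ))
    return tracks


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(tables: dict[str, pd.DataFrame], summary: dict, outdir) -> Path:
    """Write tidy CSV tables plus a JSON summary (seeds, thresholds,
    p-values) into ``outdir``; existing files are overwritten."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.9g")
    (outdir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1))
    return outdir
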