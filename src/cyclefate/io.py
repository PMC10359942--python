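"""Serialization: long-format track CSV, lineage/truth/annotation/fate CSV,
multi-page TIFF stacks, config YAML and run manifests.

All times are written in hours with 4 decimal places and intensities with 6
significant digits, so identical cohorts serialize byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import SimConfig
from .simulate import ALL_CHANNELS, Cohort, ReporterTrack

TRACK_COLUMNS = ["cell_id", "parent_id", "time_h", "channel", "value"]
LINEAGE_COLUMNS = ["cell_id", "parent_id", "division_time_h"]


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def write_tracks_csv(tracks, path):
    """Write tracks as long-format CSV: cell_id,parent_id,time_h,channel,value."""
    rows = []
    for t in tracks:
        parent = t.parent_id or ""
        for ch in ALL_CHANNELS:
            if ch not in t.channels:
                continue
            vals = np.asarray(t.channels[ch], dtype=float)
            for time, v in zip(t.times, vals):
                rows.append((t.cell_id, parent, f"{time:.4f}", ch, f"{v:.6g}"))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_tracks_csv(path):
    """Read a long-format track CSV back into ReporterTrack objects."""
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str})
    _require_columns(df, TRACK_COLUMNS, f"track CSV {path}")
    bad = df["time_h"].isna() | df["value"].isna()
    if bad.any():
        # +2: header line and 1-based numbering
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise ValueError(f"track CSV {path}: malformed rows at lines {lines[:10]}")
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        parent = grp["parent_id"].iloc[0]
        parent = None if (pd.isna(parent) or parent == "") else str(parent)
        chans = {}
        times = None
        for ch, sub in grp.groupby("channel"):
            sub = sub.sort_values("time_h")
            chans[ch] = sub["value"].to_numpy(dtype=float)
            times = sub["time_h"].to_numpy(dtype=float)
        tracks.append(
            ReporterTrack(
                cell_id=str(cell_id),
                parent_id=parent,
                birth_time=float(times[0]),
                end_time=float(times[-1]),
                times=times,
                channels=chans,
            )
        )
    return tracks


def write_lineage_csv(lineage: pd.DataFrame, path):
    out = lineage.copy()
    out["division_time_h"] = out["division_time_h"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, index=False, lineterminator="\n")


def read_lineage_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str})
    _require_columns(df, LINEAGE_COLUMNS, f"lineage CSV {path}")
    df["division_time_h"] = df["division_time_h"].astype(float)
    counts = df.groupby("parent_id")["cell_id"].count()
    odd = counts[counts != 2]
    if len(odd):
        raise ValueError(
            f"lineage CSV {path}: mothers without exactly 2 daughters: "
            f"{list(odd.index)[:5]}"
        )
    return df


def write_truth_csv(truth: pd.DataFrame, path):
    truth.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def write_annotations_csv(annotations, frame_path, summary_path):
    """Per-frame labels and per-cell boundary/duration tables."""
    frames = pd.concat([a.to_frame() for a in annotations], ignore_index=True)
    frames["time_h"] = frames["time_h"].map(lambda v: f"{v:.4f}")
    frames.to_csv(frame_path, index=False, lineterminator="\n")
    rows = []
    for a in annotations:
        row = {"cell_id": a.cell_id}
        row.update({k: a.boundaries.get(k, np.nan) for k in
                    ("t_G1S", "t_SG2", "t_G2M", "t_div")})
        row.update({k: a.durations.get(k, np.nan) for k in
                    ("d_G1", "d_S", "d_G2", "d_M")})
        row.update({f"truncated_{p}": a.truncated.get(p, True)
                    for p in ("G1", "S", "G2", "M")})
        row["flags"] = ";".join(a.flags)
        rows.append(row)
    pd.DataFrame(rows).to_csv(summary_path, index=False, float_format="%.4f",
                              lineterminator="\n")


def write_fates_csv(calls, path):
    rows = [
        {
            "cell_id": c.cell_id,
            "binary": c.binary,
            "three_state": c.three_state,
            "longest_subthreshold_h": c.longest_subthreshold_h,
            "censored": c.censored,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f",
                              lineterminator="\n")


def read_fates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str})
    _require_columns(df, ["cell_id", "binary"], f"fate CSV {path}")
    return df


def write_cohort(cohort: Cohort, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tracks_csv(cohort.tracks, out / "tracks.csv")
    write_lineage_csv(cohort.lineage, out / "lineage.csv")
    write_truth_csv(cohort.truth, out / "truth.csv")
    save_config(cohort.config, out / "config.yaml")
    return out


def save_config(config: SimConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# TIFF


def write_stack_tiff(stacks: dict, path, channel_map_path=None):
    """Multi-page TIFF, one page per (frame, channel); channel order in a
    sidecar JSON map."""
    names = sorted(stacks)
    n_frames = len(next(iter(stacks.values())))
    pages = [
        np.asarray(stacks[c][f], dtype=np.float32)
        for f in range(n_frames)
        for c in names
    ]
    tifffile.imwrite(path, np.stack(pages))
    meta = {"channels": names, "n_frames": n_frames}
    if channel_map_path is not None:
        with open(channel_map_path, "w") as fh:
            json.dump(meta, fh, indent=1)
    return meta


def read_stack_tiff(path, channel_map_path):
    with open(channel_map_path) as fh:
        meta = json.load(fh)
    arr = tifffile.imread(path)
    names = meta["channels"]
    n_frames = meta["n_frames"]
    nc = len(names)
    stacks = {
        c: np.stack([arr[f * nc + i] for f in range(n_frames)])
        for i, c in enumerate(names)
    }
    return stacks


# ---------------------------------------------------------------------------
# manifest


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: SimConfig, seed: int, files, timestamps=True):
    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "seed": seed,
        "version": __version__,
        "files": {str(Path(f).name): file_digest(f) for f in files},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
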