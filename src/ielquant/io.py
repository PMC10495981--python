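"""File exchange: TIFF stacks with metadata sidecars, spot/track CSV tables.

Image stacks travel as multi-page TIFF in TCYX axis order together with a
YAML sidecar holding the physical calibration (pixel size, frame interval),
because TIFF tags alone are routinely lost by downstream tools.  Spot and
track tables are plain CSV so they can be inspected and re-imported
anywhere.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import Spot
from .tracking import Track

SPOT_COLUMNS = ["frame", "x_um", "y_um", "quality", "radius_um"]
TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "quality"]


def write_stack(path, stack: np.ndarray, pixel_size_um: float, frame_interval_s: float) -> None:
    """Write a (C, T, H, W) stack as a TCYX TIFF plus a YAML sidecar."""
    path = Path(path)
    tcyx = np.moveaxis(np.asarray(stack), 0, 1)  # (C,T,H,W) -> (T,C,H,W)
    tifffile.imwrite(
        path, tcyx.astype(np.float32),
        photometric="minisblack", planarconfig="separate",
        metadata={"axes": "TCYX"},
    )
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {
                "axes": "TCYX",
                "pixel_size_um": float(pixel_size_um),
                "frame_interval_s": float(frame_interval_s),
            },
            fh,
        )


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a TCYX TIFF written by :func:`write_stack`; returns the stack
    back in (C, T, H, W) order plus the sidecar metadata."""
    path = Path(path)
    tcyx = tifffile.imread(path)
    if tcyx.ndim == 3:  # single channel stored as TYX
        tcyx = tcyx[:, None]
    stack = np.moveaxis(tcyx, 1, 0)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
    return stack, meta


def spots_to_dataframe(spots: list[Spot]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.frame, s.x_um, s.y_um, s.quality, s.radius_um) for s in spots],
        columns=SPOT_COLUMNS,
    )


def dataframe_to_spots(df: pd.DataFrame) -> list[Spot]:
    return [
        Spot(frame=int(r.frame), x_um=float(r.x_um), y_um=float(r.y_um),
             quality=float(r.quality), radius_um=float(r.radius_um))
        for r in df.itertuples(index=False)
    ]


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        (t.track_id, s.frame, s.x_um, s.y_um, s.quality)
        for t in tracks
        for s in t.spots
    ]
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)


def dataframe_to_tracks(df: pd.DataFrame, radius_um: float = 3.5) -> list[Track]:
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        spots = [
            Spot(frame=int(r.frame), x_um=float(r.x_um), y_um=float(r.y_um),
                 quality=float(r.quality), radius_um=radius_um)
            for r in grp.itertuples(index=False)
        ]
        tracks.append(Track(track_id=int(tid), spots=spots))
    return tracks


def write_ground_truth_csv(path, true_positions_um: np.ndarray) -> None:
    """(n_cells, n_frames, 2) trajectories as long-format CSV."""
    n_cells, n_frames, _ = true_positions_um.shape
    rows = [
        (c, f, true_positions_um[c, f, 0], true_positions_um[c, f, 1])
        for c in range(n_cells)
        for f in range(n_frames)
    ]
    pd.DataFrame(rows, columns=["cell_id", "frame", "x_um", "y_um"]).to_csv(path, index=False)
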