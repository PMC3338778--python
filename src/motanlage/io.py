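"""Plain-text readers and writers for the pipeline's tabular formats.

Tracks:     CSV ``track_id,frame,t_min,x_um,y_um`` (frame 0-based).
Puncta:     CSV ``cell_id,x_um,y_um,area_um2`` with an optional sidecar
            CSV ``cell_id,cx,cy,axis_x,axis_y`` carrying centroid + axis.
Expression: TSV ``gene,genotype,replicate,value``.
Histogram:  CSV ``bin_left,bin_right,count``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .adhesion_quant import Punctum
from .cell_population import DnaHistogram
from .synthetic_data import AdhesionScene, TrackSet
from .track_metrics import Track, TrackStats

__all__ = [
    "write_tracks_csv",
    "read_tracks_csv",
    "write_track_stats_csv",
    "write_puncta_csv",
    "read_puncta_csv",
    "write_scene_sidecar_csv",
    "read_scene_sidecar_csv",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_histogram_csv",
    "read_histogram_csv",
]


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for frame, (x, y) in enumerate(tr.positions):
            rows.append((tr.track_id, frame, frame * tr.dt_min, x, y))
    pd.DataFrame(
        rows, columns=["track_id", "frame", "t_min", "x_um", "y_um"]
    ).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    required = {"track_id", "frame", "t_min", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns {sorted(missing)}")
    tracks = []
    for track_id, sub in df.groupby("track_id", sort=False):
        sub = sub.sort_values("frame")
        t = sub["t_min"].to_numpy(dtype=float)
        if len(t) > 1:
            dts = np.diff(t)
            if not np.allclose(dts, dts[0]):
                raise ValueError(f"track {track_id!r} is not uniformly sampled")
            dt = float(dts[0])
        else:
            dt = 1.0
        tracks.append(
            Track(
                track_id=str(track_id),
                positions=sub[["x_um", "y_um"]].to_numpy(dtype=float),
                dt_min=dt,
            )
        )
    return tracks


def write_track_stats_csv(
    stats: Sequence[TrackStats], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (
                s.track_id,
                s.T_um,
                s.D_um,
                s.dt_ratio,
                s.velocity_um_min,
                s.time_moving_min,
                s.time_paused_min,
                s.n_dir_changes,
            )
            for s in stats
        ],
        columns=[
            "track_id",
            "T_um",
            "D_um",
            "dt_ratio",
            "velocity_um_min",
            "time_moving_min",
            "time_paused_min",
            "n_dir_changes",
        ],
    ).to_csv(path, index=False)


def write_puncta_csv(
    scenes: Sequence[AdhesionScene], path: str | Path
) -> None:
    rows = [
        (sc.cell_id, pos[0], pos[1], area)
        for sc in scenes
        for pos, area in sc.puncta
    ]
    pd.DataFrame(
        rows, columns=["cell_id", "x_um", "y_um", "area_um2"]
    ).to_csv(path, index=False)


def read_puncta_csv(path: str | Path) -> dict[str, list[Punctum]]:
    df = pd.read_csv(path)
    required = {"cell_id", "x_um", "y_um", "area_um2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"puncta CSV missing columns {sorted(missing)}")
    out: dict[str, list[Punctum]] = {}
    for cell_id, sub in df.groupby("cell_id", sort=False):
        out[str(cell_id)] = [
            Punctum(position=np.array([r.x_um, r.y_um]), area_um2=r.area_um2)
            for r in sub.itertuples()
        ]
    return out


def write_scene_sidecar_csv(
    scenes: Sequence[AdhesionScene], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (
                sc.cell_id,
                sc.centroid[0],
                sc.centroid[1],
                sc.polarity_axis[0],
                sc.polarity_axis[1],
            )
            for sc in scenes
        ],
        columns=["cell_id", "cx", "cy", "axis_x", "axis_y"],
    ).to_csv(path, index=False)


def read_scene_sidecar_csv(
    path: str | Path,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    df = pd.read_csv(path)
    return {
        str(r.cell_id): (
            np.array([r.cx, r.cy]),
            np.array([r.axis_x, r.axis_y]),
        )
        for r in df.itertuples()
    }


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "genotype", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression TSV missing columns {sorted(missing)}")
    return df


def write_histogram_csv(hist: DnaHistogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_left": hist.bin_edges[:-1],
            "bin_right": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(path, index=False)


def read_histogram_csv(path: str | Path) -> DnaHistogram:
    df = pd.read_csv(path)
    required = {"bin_left", "bin_right", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"histogram CSV missing columns {sorted(missing)}")
    left = df["bin_left"].to_numpy(dtype=float)
    right = df["bin_right"].to_numpy(dtype=float)
    if not np.allclose(left[1:], right[:-1]):
        raise ValueError("histogram bins must be contiguous")
    edges = np.append(left, right[-1])
    return DnaHistogram(bin_edges=edges, counts=df["count"].to_numpy())
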