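"""Frame-to-frame linking of localizations into single-molecule tracks.

The linker follows the multiple-target-tracing recipe in its
distance-gated form: localizations in frame ``f`` are connected to open
tracks whose last localization lies within a search radius that grows as
the square root of the time gap (Brownian scaling), with gap closing for
short detection dropouts. Assignment is either greedy nearest-neighbor
(order-stable, the common choice in sparse single-molecule data) or
globally optimal per frame (Hungarian algorithm: maximum number of links
first, minimum total squared distance among those).

Every input localization ends up in exactly one track; localizations
that cannot be linked start new (possibly singleton) tracks, so the
decomposition is conservative and short spurious tracks are removed
afterwards by :func:`filter_min_steps`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import LocalizationTable

__all__ = ["LinkingParams", "Trajectory", "TrackSet", "link_localizations",
           "filter_min_steps"]

#: mobility ceiling used for the default search radius (um^2/s)
_D_MAX_DEFAULT = 0.3


def default_max_step_nm(frame_time_s: float = 0.032,
                        d_max: float = _D_MAX_DEFAULT) -> float:
    """3 sigma of the per-axis Brownian step at the mobility ceiling."""
    return 3.0 * math.sqrt(4.0 * d_max * 1e6 * frame_time_s)


@dataclass
class LinkingParams:
    """Parameters of the frame-to-frame linker.

    ``max_step_nm`` is the per-frame search radius (scaled by
    sqrt(gap+1) across detection gaps); ``max_gap`` the number of
    tolerated missed frames; ``assignment`` selects greedy or Hungarian
    per-frame assignment.
    """

    max_step_nm: float = field(default_factory=default_max_step_nm)
    max_gap: int = 1
    assignment: str = "greedy"

    def __post_init__(self) -> None:
        if self.max_step_nm <= 0:
            raise ValueError("max_step_nm must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.assignment not in ("greedy", "optimal"):
            raise ValueError(f"unknown assignment {self.assignment!r}")


class Trajectory:
    """Time-ordered localizations of one molecule.

    Attributes
    ----------
    track_id : int
    channel : str
    frames : ndarray of int, strictly increasing
    xy_nm : ndarray, shape (n, 2)
    intensity : ndarray
    source_rows : ndarray of int
        Row indices into the originating localization table.
    """

    __slots__ = ("track_id", "channel", "frames", "xy_nm", "intensity",
                 "source_rows")

    def __init__(self, track_id, channel, frames, xy_nm, intensity,
                 source_rows=None):
        self.track_id = int(track_id)
        self.channel = channel
        self.frames = np.asarray(frames, dtype=np.int64)
        self.xy_nm = np.asarray(xy_nm, dtype=float).reshape(-1, 2)
        self.intensity = np.asarray(intensity, dtype=float)
        self.source_rows = (np.asarray(source_rows, dtype=np.int64)
                            if source_rows is not None
                            else np.full(len(self.frames), -1, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        """Number of inter-localization links."""
        return max(len(self.frames) - 1, 0)

    @property
    def duration_s(self) -> float:
        raise AttributeError("duration requires a frame time; use "
                             "(frames[-1]-frames[0]) * frame_time_s")

    def step_lengths(self, consecutive_only: bool = True) -> np.ndarray:
        """Displacement lengths (nm) between linked localizations.

        With ``consecutive_only`` (default) steps spanning a detection
        gap are excluded, so every returned step covers exactly one
        frame interval.
        """
        if len(self.frames) < 2:
            return np.empty(0)
        d = np.linalg.norm(np.diff(self.xy_nm, axis=0), axis=1)
        if consecutive_only:
            d = d[np.diff(self.frames) == 1]
        return d


class TrackSet:
    """An ordered collection of :class:`Trajectory`."""

    def __init__(self, tracks: list[Trajectory], channel: str = "A"):
        self.tracks = list(tracks)
        self.channel = channel

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.tracks)

    def __getitem__(self, i) -> Trajectory:
        return self.tracks[i]

    @property
    def n_localizations(self) -> int:
        return sum(len(t) for t in self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        if not self.tracks:
            return pd.DataFrame(columns=["track_id", "frame", "x_nm", "y_nm",
                                         "intensity", "channel"])
        parts = []
        for t in self.tracks:
            parts.append(pd.DataFrame({
                "track_id": t.track_id, "frame": t.frames,
                "x_nm": t.xy_nm[:, 0], "y_nm": t.xy_nm[:, 1],
                "intensity": t.intensity, "channel": t.channel}))
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, channel: str = "A") -> "TrackSet":
        tracks = []
        for tid, g in df.groupby("track_id", sort=True):
            g = g.sort_values("frame")
            tracks.append(Trajectory(tid, channel, g["frame"].to_numpy(),
                                     g[["x_nm", "y_nm"]].to_numpy(),
                                     g["intensity"].to_numpy()))
        return cls(tracks, channel)


class _OpenTrack:
    __slots__ = ("frames", "xy", "inten", "rows", "last_xy", "last_frame")

    def __init__(self, frame, xy, inten, row):
        self.frames = [frame]
        self.xy = [xy]
        self.inten = [inten]
        self.rows = [row]
        self.last_xy = xy
        self.last_frame = frame

    def extend(self, frame, xy, inten, row):
        self.frames.append(frame)
        self.xy.append(xy)
        self.inten.append(inten)
        self.rows.append(row)
        self.last_xy = xy
        self.last_frame = frame


def _assign_greedy(cand: list[tuple[float, int, int]], n_tracks: int,
                   n_locs: int) -> list[tuple[int, int]]:
    # candidates: (distance, loc_index, track_index); ties -> smaller
    # distance, then lower localization index, then track order
    cand.sort()
    used_t = [False] * n_tracks
    used_l = [False] * n_locs
    links = []
    for dist, li, ti in cand:
        if used_t[ti] or used_l[li]:
            continue
        used_t[ti] = used_l[li] = True
        links.append((ti, li))
    return links


def _assign_optimal(dist2: np.ndarray, gate2: np.ndarray) -> list[tuple[int, int]]:
    """Maximum-cardinality, then minimum total squared distance assignment.

    ``dist2``: (n_tracks, n_locs) squared distances; ``gate2``: per-track
    squared gating radius. Implemented as a square augmented assignment
    problem where skipping a track or a localization costs ``B`` with
    ``2B`` exceeding any feasible link cost, so links are always
    preferred and, at fixed cardinality, total squared distance is
    minimized.
    """
    nt, nl = dist2.shape
    feasible = dist2 <= gate2[:, None]
    B = float(gate2.max()) + 1.0
    big = 1e6 * (B + 1.0)
    cost = np.full((nt + nl, nl + nt), 0.0)
    cost[:nt, :nl] = np.where(feasible, dist2, big)
    cost[:nt, nl:] = big
    cost[np.arange(nt), nl + np.arange(nt)] = B     # track skips
    cost[nt:, :nl] = big
    cost[nt + np.arange(nl), np.arange(nl)] = B     # localization starts new
    rows, cols = linear_sum_assignment(cost)
    links = []
    for r, c in zip(rows, cols):
        if r < nt and c < nl and feasible[r, c]:
            links.append((int(r), int(c)))
    return links


def link_localizations(table: LocalizationTable,
                       params: LinkingParams | None = None) -> TrackSet:
    """Link per-frame localizations into trajectories.

    Localizations are processed frame by frame; open tracks whose last
    localization is at most ``max_gap + 1`` frames old compete for the
    current frame's localizations within a search radius of
    ``max_step_nm * sqrt(f - last_frame)``. Unmatched localizations seed
    new tracks. Deterministic given the input order and parameters.

    An empty table yields an empty :class:`TrackSet`.
    """
    if params is None:
        params = LinkingParams()
    df = table.df
    if not len(df):
        return TrackSet([], table.channel)
    if not np.isfinite(df[["x_nm", "y_nm"]].to_numpy()).all():
        raise ValueError("non-finite coordinate in localization table")
    order = np.argsort(df["frame"].to_numpy(), kind="stable")
    frames_all = df["frame"].to_numpy()[order]
    xy_all = df[["x_nm", "y_nm"]].to_numpy()[order]
    inten_all = df["intensity"].to_numpy()[order]
    rows_all = df.index.to_numpy()[order]

    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    boundaries = np.flatnonzero(np.diff(frames_all)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(frames_all)]])

    for s, e in zip(starts, ends):
        f = int(frames_all[s])
        # retire tracks beyond gap reach
        still = []
        for tr in open_tracks:
            if f - tr.last_frame > params.max_gap + 1:
                closed.append(tr)
            else:
                still.append(tr)
        open_tracks = still

        locs_xy = xy_all[s:e]
        nl = e - s
        nt = len(open_tracks)
        links: list[tuple[int, int]] = []
        if nt and nl:
            last = np.array([tr.last_xy for tr in open_tracks])
            gaps = np.array([f - tr.last_frame for tr in open_tracks])
            gate = params.max_step_nm * np.sqrt(gaps.astype(float))
            diff = last[:, None, :] - locs_xy[None, :, :]
            dist2 = np.einsum("ijk,ijk->ij", diff, diff)
            if params.assignment == "optimal":
                links = _assign_optimal(dist2, gate**2)
            else:
                feas = dist2 <= (gate**2)[:, None]
                ti_idx, li_idx = np.nonzero(feas)
                cand = [(math.sqrt(dist2[ti, li]), int(li), int(ti))
                        for ti, li in zip(ti_idx, li_idx)]
                links = _assign_greedy(cand, nt, nl)

        linked_locs = set()
        for ti, li in links:
            open_tracks[ti].extend(f, locs_xy[li], inten_all[s + li],
                                   rows_all[s + li])
            linked_locs.add(li)
        for li in range(nl):
            if li not in linked_locs:
                open_tracks.append(_OpenTrack(f, locs_xy[li],
                                              inten_all[s + li],
                                              rows_all[s + li]))

    closed.extend(open_tracks)
    closed.sort(key=lambda tr: (tr.frames[0], tr.rows[0]))
    tracks = [Trajectory(i, table.channel, tr.frames, np.array(tr.xy),
                         tr.inten, tr.rows)
              for i, tr in enumerate(closed)]
    return TrackSet(tracks, table.channel)


def filter_min_steps(tracks: TrackSet, min_steps: int = 10) -> TrackSet:
    """Keep only trajectories with at least ``min_steps`` links.

    Ten steps at 32 ms/frame corresponds to ~320 ms of continuous
    observation, the standard cutoff separating genuine molecules from
    spurious short tracks.
    """
    if min_steps < 0:
        raise ValueError("min_steps must be >= 0")
    kept = [t for t in tracks if t.n_steps >= min_steps]
    return TrackSet(kept, tracks.channel)
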