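"""Dual-color co-localization / co-tracking quantification of dimerization.

The dimerization readout works on two registered single-channel
localization streams:

1. per frame, localizations detected in both channels within a 100 nm
   radius are paired one-to-one (minimum total distance);
2. the pair midpoints are handed to the single-channel linker to
   reconstruct co-locomotion trajectories ("co-trajectories");
3. co-trajectories shorter than 10 steps (~320 ms at 32 ms/frame) are
   discarded, which suppresses chance encounters of independently
   diffusing molecules;
4. the observed co-trajectory count AB is corrected for receptors
   stochastically double-labeled with the same fluorophore species::

       AB* = AB / (2 * (A/(A+B)) * (B/(A+B)))
       rel. co-locomotion = 2 * AB* / (A + B)

   where A and B are the single-channel trajectory counts. A dimer
   carries a visible two-color signature only when its two protomers
   drew different fluorophores, which happens with probability
   2*p*q / (p+q)^2 among labeled receptors; A/(A+B) estimates
   p/(p+q), so dividing AB by 2*p_hat*q_hat recovers the total dimer
   count and ``rel`` becomes the fraction of tracked molecules residing
   in dimers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import LocalizationTable
from .mobility import exclude_immobile
from .tracking import LinkingParams, TrackSet, filter_min_steps, \
    link_localizations

__all__ = ["CoTrajectory", "DimerizationResult", "CoTrackingParams",
           "pair_colocalizations", "build_cotrajectories",
           "correct_double_labeling", "quantify_dimerization"]

PAIR_COLUMNS = ["frame", "x_a", "y_a", "x_b", "y_b", "distance_nm",
                "idx_a", "idx_b"]


@dataclass
class CoTrajectory:
    """A reconstructed co-locomotion trajectory.

    ``entries`` holds one row per co-localized frame with both channels'
    coordinates and the pair distance; ``track_id_a``/``track_id_b`` are
    the constituent single-channel track ids where known (-1 otherwise).
    """

    co_id: int
    entries: pd.DataFrame
    track_id_a: int = -1
    track_id_b: int = -1

    @property
    def n_steps(self) -> int:
        return max(len(self.entries) - 1, 0)


@dataclass
class DimerizationResult:
    """Counts and corrected dimerization statistic of one measurement.

    ``ab_star`` is the double-labeling-corrected co-trajectory count and
    ``rel_colocomotion = 2*AB*/(A+B)`` the fraction of tracked molecules
    residing in dimers. Values above 1 are possible under sampling noise
    at extreme labeling imbalance and are reported as-is (with a
    warning), never clipped.
    """

    a: int
    b: int
    ab: int
    ab_star: float
    rel_colocomotion: float
    radius_nm: float = 100.0
    min_steps: int = 10
    intermediates: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (f"A={self.a} B={self.b} AB={self.ab} "
                f"AB*={self.ab_star:.2f} "
                f"rel. co-locomotion={self.rel_colocomotion:.4f} "
                f"(radius {self.radius_nm:.0f} nm, "
                f">={self.min_steps} steps)")


@dataclass
class CoTrackingParams:
    """Parameters of the full dimerization-quantification chain."""

    linking: LinkingParams = field(default_factory=LinkingParams)
    radius_nm: float = 100.0
    min_steps: int = 10
    exclude_immobile: bool = True
    immobile_eps_nm: float = 50.0
    immobile_min_pts: int = 5
    frame_time_s: float = 0.032

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be > 0")
        if self.min_steps < 0:
            raise ValueError("min_steps must be >= 0")


def _pair_frame(xy_a: np.ndarray, xy_b: np.ndarray,
                radius_nm: float) -> list[tuple[int, int, float]]:
    """One-to-one pairing of two point sets under a radius gate.

    Maximizes the number of pairs, then minimizes total distance —
    realised as an augmented linear assignment where leaving a point
    unpaired costs just over the gate radius.
    """
    na, nb = len(xy_a), len(xy_b)
    if na == 0 or nb == 0:
        return []
    diff = xy_a[:, None, :] - xy_b[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    feasible = dist <= radius_nm
    if not feasible.any():
        return []
    B = radius_nm + 1.0
    big = 1e6 * B
    cost = np.zeros((na + nb, nb + na))
    cost[:na, :nb] = np.where(feasible, dist, big)
    cost[:na, nb:] = big
    cost[np.arange(na), nb + np.arange(na)] = B
    cost[na:, :nb] = big
    cost[na + np.arange(nb), np.arange(nb)] = B
    rows, cols = linear_sum_assignment(cost)
    out = []
    for r, c in zip(rows, cols):
        if r < na and c < nb and feasible[r, c]:
            out.append((int(r), int(c), float(dist[r, c])))
    return out


def pair_colocalizations(table_a: LocalizationTable,
                         table_b: LocalizationTable,
                         radius_nm: float = 100.0) -> pd.DataFrame:
    """Per-frame one-to-one co-localization of two channels.

    A particle detected in both channels of a single frame within the
    distance threshold (default 100 nm radius) is regarded as
    co-localized. Each localization enters at most one pair; per frame
    the pairing maximizes the pair count and then minimizes the total
    distance.

    Returns a DataFrame with columns
    ``frame, x_a, y_a, x_b, y_b, distance_nm, idx_a, idx_b`` where
    ``idx_a``/``idx_b`` are positional row indices into the input
    tables.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be > 0")
    if not (table_a.registered and table_b.registered):
        warnings.warn("input tables are not flagged as registered; "
                      "co-localization assumes a common coordinate frame",
                      UserWarning, stacklevel=2)
    if not len(table_a) or not len(table_b):
        return pd.DataFrame(columns=PAIR_COLUMNS)
    dfa, dfb = table_a.df, table_b.df
    fa = dfa["frame"].to_numpy()
    fb = dfb["frame"].to_numpy()
    xya = dfa[["x_nm", "y_nm"]].to_numpy()
    xyb = dfb[["x_nm", "y_nm"]].to_numpy()
    rows = []
    for f in np.intersect1d(np.unique(fa), np.unique(fb)):
        ia = np.flatnonzero(fa == f)
        ib = np.flatnonzero(fb == f)
        for r, c, d in _pair_frame(xya[ia], xyb[ib], radius_nm):
            pa, pb = ia[r], ib[c]
            rows.append((int(f), xya[pa, 0], xya[pa, 1],
                         xyb[pb, 0], xyb[pb, 1], d, int(pa), int(pb)))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def build_cotrajectories(pairs: pd.DataFrame,
                         linking: LinkingParams | None = None,
                         min_steps: int = 10,
                         track_ids_a: np.ndarray | None = None,
                         track_ids_b: np.ndarray | None = None
                         ) -> list[CoTrajectory]:
    """Link per-frame co-localizations into co-trajectories.

    The single-channel linker is applied to the pair midpoints (a
    channel-symmetric representative coordinate); co-trajectories with
    fewer than ``min_steps`` links are discarded.

    ``track_ids_a``/``track_ids_b`` optionally map the pair's positional
    indices back to single-channel track ids.
    """
    if linking is None:
        linking = LinkingParams()
    if not len(pairs):
        return []
    mid = LocalizationTable.from_arrays(
        frame=pairs["frame"].to_numpy(),
        x_nm=0.5 * (pairs["x_a"].to_numpy() + pairs["x_b"].to_numpy()),
        y_nm=0.5 * (pairs["y_a"].to_numpy() + pairs["y_b"].to_numpy()),
        channel="A", registered=True)
    tracks = filter_min_steps(link_localizations(mid, linking), min_steps)
    out = []
    for co_id, t in enumerate(tracks):
        ent = pairs.iloc[t.source_rows].reset_index(drop=True)
        tid_a = tid_b = -1
        if track_ids_a is not None:
            ids = np.unique(track_ids_a[ent["idx_a"].to_numpy()])
            tid_a = int(ids[0]) if len(ids) == 1 else -1
        if track_ids_b is not None:
            ids = np.unique(track_ids_b[ent["idx_b"].to_numpy()])
            tid_b = int(ids[0]) if len(ids) == 1 else -1
        out.append(CoTrajectory(co_id, ent, tid_a, tid_b))
    return out


def correct_double_labeling(a: int, b: int, ab: int,
                            radius_nm: float = 100.0,
                            min_steps: int = 10) -> DimerizationResult:
    """Correct the observed co-trajectory count for stochastic labeling.

    Under independent two-color labeling only a ``2*p*q/(p+q)^2``
    fraction of labeled dimers is visible as a two-color pair; the
    single-channel counts estimate ``p_hat = A/(A+B)``, so::

        AB* = AB / (2 * p_hat * (1 - p_hat))
        rel. co-locomotion = 2 * AB* / (A + B)

    Raises
    ------
    ValueError
        If ``A + B == 0`` (undefined ratio) or one channel is empty
        while AB > 0 (inconsistent counts).
    """
    if a < 0 or b < 0 or ab < 0:
        raise ValueError("counts must be >= 0")
    if a + b == 0:
        raise ValueError("A + B = 0: labeling ratio undefined")
    if ab > min(a, b):
        raise ValueError("AB cannot exceed min(A, B)")
    if ab == 0:
        ab_star = 0.0
    else:
        if a == 0 or b == 0:
            raise ValueError("AB > 0 with an empty channel is inconsistent")
        p_hat = a / (a + b)
        ab_star = ab / (2.0 * p_hat * (1.0 - p_hat))
    rel = 2.0 * ab_star / (a + b)
    if rel > 1.0:
        warnings.warn(f"relative co-locomotion {rel:.3f} exceeds 1 "
                      "(sampling noise / labeling imbalance); reported "
                      "as-is", UserWarning, stacklevel=2)
    return DimerizationResult(int(a), int(b), int(ab), ab_star, rel,
                              radius_nm, min_steps)


def _trackset_to_table(tracks: TrackSet) -> tuple[LocalizationTable, np.ndarray]:
    df = tracks.to_dataframe()
    tids = df["track_id"].to_numpy() if len(df) else np.empty(0, dtype=int)
    table = LocalizationTable(
        df[["frame", "x_nm", "y_nm", "intensity", "channel"]].reset_index(
            drop=True),
        channel=tracks.channel, registered=True)
    return table, tids


def quantify_dimerization(table_a: LocalizationTable,
                          table_b: LocalizationTable,
                          params: CoTrackingParams | None = None
                          ) -> DimerizationResult:
    """Full dimerization quantification chain on two registered channels.

    Pipeline: track each channel independently -> exclude immobile
    tracks -> apply the minimum-steps filter -> co-localize the
    surviving localizations per frame -> reconstruct co-trajectories ->
    apply the double-labeling correction. All intermediate counts are
    recorded in ``result.intermediates``.
    """
    if params is None:
        params = CoTrackingParams()
    inter: dict = {}
    filtered = {}
    tables = {}
    tids = {}
    for tag, table in (("a", table_a), ("b", table_b)):
        tracks = link_localizations(table, params.linking)
        inter[f"n_tracks_{tag}_raw"] = len(tracks)
        if params.exclude_immobile:
            tracks, flags = exclude_immobile(tracks, params.immobile_eps_nm,
                                             params.immobile_min_pts)
            inter[f"n_immobile_{tag}"] = int(flags.sum())
        tracks = filter_min_steps(tracks, params.min_steps)
        inter[f"n_tracks_{tag}"] = len(tracks)
        filtered[tag] = tracks
        tables[tag], tids[tag] = _trackset_to_table(tracks)

    pairs = pair_colocalizations(tables["a"], tables["b"], params.radius_nm)
    inter["n_colocalizations"] = len(pairs)
    cotraj = build_cotrajectories(pairs, params.linking, params.min_steps,
                                  tids["a"], tids["b"])
    inter["n_cotrajectory_fragments"] = len(cotraj)

    # a co-trajectory is identified by its constituent single-channel track
    # pair; fragments of one pair (a brief >radius excursion splits the
    # midpoint track) are counted once
    seen: set = set()
    ab = 0
    for c in cotraj:
        key = (c.track_id_a, c.track_id_b)
        if c.track_id_a < 0 or c.track_id_b < 0 or key not in seen:
            ab += 1
            seen.add(key)
    inter["n_cotrajectories"] = ab

    a = len(filtered["a"])
    b = len(filtered["b"])
    if a + b == 0:
        result = DimerizationResult(0, 0, 0, 0.0, 0.0, params.radius_nm,
                                    params.min_steps)
    else:
        ab = min(ab, min(a, b))  # guard: degenerate fragmentation
        result = correct_double_labeling(a, b, ab, params.radius_nm,
                                         params.min_steps)
    result.intermediates = inter
    return result
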