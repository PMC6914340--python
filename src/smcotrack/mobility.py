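"""Mobility statistics of single-molecule tracks.

Four analyses live here:

* time-averaged mean squared displacement (MSD) curves and the diffusion
  constant from the slope of the MSD over lags 2-10, with an intercept
  absorbing the localization-error offset (4 sigma^2);
* a two-fraction mixture model of Brownian diffusion fitted to the
  step-length histogram by expectation-maximization — the standard way
  to resolve a slow (dimeric/confined) and a fast (monomeric) receptor
  population from pooled single-frame displacements;
* immobile-molecule detection with DBSCAN on each track's own
  localizations (surface-stuck particles collapse into one dense
  cluster) so they can be excluded from mobility and co-tracking;
* photobleaching step counting on single-emitter intensity traces by
  penalized least-squares change-point segmentation, the readout used to
  confirm dimer stoichiometry (two-step bleaching).

For a 2D Brownian walker with diffusion constant D observed at interval
dt, the per-frame step length r follows the Rayleigh-type law
``p(r) = r/(2 D dt) * exp(-r^2 / (4 D dt))`` and MSD(t) = 4 D t.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .tracking import TrackSet, Trajectory

__all__ = [
    "MSDCurve", "DiffusionEstimate", "StepLengthMixture",
    "StepLengthMixtureFit", "BleachStepResult",
    "compute_msd", "fit_diffusion_constant", "fit_step_length_mixture",
    "collect_step_lengths", "find_immobile", "count_bleach_steps",
    "UnidentifiableMixtureWarning",
]

NM2_PER_UM2 = 1e6


class UnidentifiableMixtureWarning(UserWarning):
    """Both mixture components collapsed to the same diffusion constant."""


@dataclass
class MSDCurve:
    """Ensemble time-averaged MSD: lag times (s), MSD (nm^2), pair counts."""

    lag_s: np.ndarray
    msd_nm2: np.ndarray
    counts: np.ndarray
    frame_time_s: float

    @property
    def lag_frames(self) -> np.ndarray:
        return np.rint(self.lag_s / self.frame_time_s).astype(int)


@dataclass
class DiffusionEstimate:
    """Diffusion constant from a weighted OLS line through the MSD.

    ``intercept_nm2`` absorbs the static localization-error offset
    (4 sigma_loc^2 for isotropic error of SD sigma_loc per axis).
    A negative fitted slope is flagged (``negative_slope``) and reported
    as D = 0 rather than silently clipped.
    """

    d_um2_s: float
    intercept_nm2: float
    lag_range: tuple[int, int]
    stderr_um2_s: float
    negative_slope: bool = False

    def summary(self) -> str:
        lines = [
            "Diffusion constant (MSD line fit)",
            f"  D         = {self.d_um2_s:.4g} um^2/s"
            f" (SE {self.stderr_um2_s:.2g})",
            f"  intercept = {self.intercept_nm2:.4g} nm^2",
            f"  lags used = {self.lag_range[0]}..{self.lag_range[1]} frames",
        ]
        if self.negative_slope:
            lines.append("  WARNING: fitted slope was negative")
        return "\n".join(lines)


def _track_msd(track: Trajectory, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum of squared displacements and pair count per lag for one track.

    Lags spanning a detection gap are excluded: a pair (i, i+m) counts
    for lag n only when the index difference m equals the frame
    difference n, i.e. all intermediate frames are present.
    """
    frames = track.frames
    xy = track.xy_nm
    ssd = np.zeros(max_lag)
    cnt = np.zeros(max_lag, dtype=np.int64)
    npts = len(frames)
    for m in range(1, min(max_lag, npts - 1) + 1):
        fd = frames[m:] - frames[:-m]
        ok = fd == m
        if not ok.any():
            continue
        d = xy[m:][ok] - xy[:-m][ok]
        ssd[m - 1] += float(np.sum(d * d))
        cnt[m - 1] += int(ok.sum())
    return ssd, cnt


def compute_msd(tracks: TrackSet | Trajectory, max_lag: int = 10,
                frame_time_s: float = 0.032) -> MSDCurve:
    """Ensemble time-averaged MSD over all tracks.

    Per-lag averages are pooled across tracks weighted by the number of
    displacement pairs each track contributes.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if isinstance(tracks, Trajectory):
        tracks = TrackSet([tracks], tracks.channel)
    ssd = np.zeros(max_lag)
    cnt = np.zeros(max_lag, dtype=np.int64)
    for t in tracks:
        if len(t) < 2:
            continue
        s, c = _track_msd(t, max_lag)
        ssd += s
        cnt += c
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = np.where(cnt > 0, ssd / np.maximum(cnt, 1), np.nan)
    lags = np.arange(1, max_lag + 1) * frame_time_s
    return MSDCurve(lags, msd, cnt, frame_time_s)


def fit_diffusion_constant(msd: MSDCurve,
                           lag_range: tuple[int, int] = (2, 10)
                           ) -> DiffusionEstimate:
    """Diffusion constant from the MSD slope over a lag range.

    Ordinary least squares of MSD against lag time over the stated lag
    window (inclusive, in frames); D = slope / 4 for 2D diffusion, and
    the intercept is reported (it carries the localization-error term).
    """
    lo, hi = lag_range
    sel = (msd.lag_frames >= lo) & (msd.lag_frames <= hi) & (msd.counts > 0)
    if sel.sum() < 2:
        raise ValueError("need at least 2 MSD points in the lag range")
    t = msd.lag_s[sel]
    y = msd.msd_nm2[sel]
    design = np.column_stack([t, np.ones_like(t)])
    coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = coef
    n = len(t)
    if n > 2:
        sigma2 = float(res[0]) / (n - 2) if res.size else 0.0
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se_slope = math.sqrt(max(cov[0, 0], 0.0))
    else:
        se_slope = float("nan")
    negative = slope < 0
    d = max(slope, 0.0) / 4.0 / NM2_PER_UM2
    return DiffusionEstimate(d, float(intercept), (lo, hi),
                             se_slope / 4.0 / NM2_PER_UM2, negative)


def collect_step_lengths(tracks: TrackSet) -> np.ndarray:
    """Pool single-frame displacement lengths (nm) from all tracks."""
    parts = [t.step_lengths(consecutive_only=True) for t in tracks]
    return np.concatenate(parts) if parts else np.empty(0)


@dataclass
class StepLengthMixtureFit:
    """Results of the two-fraction Brownian step-length mixture fit.

    Components are sorted so ``d1_um2_s >= d2_um2_s``; ``alpha`` is the
    weight of the fast component. ``loglik_path`` records the
    (monotonically non-decreasing) log-likelihood across EM iterations
    of the best restart.
    """

    alpha: float
    d1_um2_s: float
    d2_um2_s: float
    loglik: float
    converged: bool
    n_iter: int
    n_steps: int
    dt_s: float
    loglik_path: np.ndarray = field(repr=False, default=None)
    identifiable: bool = True

    @property
    def fractions(self) -> tuple[float, float]:
        return (self.alpha, 1.0 - self.alpha)

    def summary(self) -> str:
        lines = [
            "Two-fraction Brownian step-length mixture (EM)",
            f"  fast fraction alpha = {self.alpha:.3f}",
            f"  D_fast = {self.d1_um2_s:.4g} um^2/s",
            f"  D_slow = {self.d2_um2_s:.4g} um^2/s",
            f"  log-likelihood = {self.loglik:.2f}  "
            f"({self.n_iter} iterations, converged={self.converged})",
            f"  n steps = {self.n_steps}, dt = {self.dt_s} s",
        ]
        if not self.identifiable:
            lines.append("  WARNING: components coincide; alpha unidentifiable")
        return "\n".join(lines)


class StepLengthMixture:
    """Two-fraction mixture model of Brownian diffusion for step lengths.

    The model for a step length r (nm) at frame interval dt is::

        p(r) = alpha * r/(2 D1 dt) * exp(-r^2/(4 D1 dt))
             + (1-alpha) * r/(2 D2 dt) * exp(-r^2/(4 D2 dt))

    with D in nm^2/s internally (reported in um^2/s). Fitted by
    expectation-maximization with multiple seeded random restarts; the
    M-step is closed-form (weighted second moments).
    """

    def __init__(self, steps_nm: np.ndarray, dt_s: float,
                 n_components: int = 2):
        steps_nm = np.asarray(steps_nm, dtype=float)
        if dt_s <= 0:
            raise ValueError("dt must be > 0")
        if steps_nm.size and (steps_nm <= 0).any():
            raise ValueError("step lengths must be positive")
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if steps_nm.size < 50:
            warnings.warn("fewer than 50 steps; mixture fit will be noisy",
                          UserWarning, stacklevel=2)
        self.steps_nm = steps_nm
        self.dt_s = dt_s
        self.n_components = n_components

    def _loglik_and_resp(self, alpha, s1, s2):
        # s_k = 4 D_k dt (nm^2), the Rayleigh 'scale' of component k
        r2 = self.steps_nm**2
        with np.errstate(under="ignore"):
            la = (math.log(max(alpha, 1e-300))
                  + np.log(2.0 * self.steps_nm / s1) - r2 / s1)
            lb = (math.log(max(1.0 - alpha, 1e-300))
                  + np.log(2.0 * self.steps_nm / s2) - r2 / s2)
        m = np.maximum(la, lb)
        lse = m + np.log(np.exp(la - m) + np.exp(lb - m))
        gamma = np.exp(la - lse)
        return float(lse.sum()), gamma

    def fit(self, n_restarts: int = 5, tol: float = 1e-8,
            max_iter: int = 500, seed: int = 0) -> StepLengthMixtureFit:
        """Maximum-likelihood fit by EM (multi-start, seeded)."""
        r2 = self.steps_nm**2
        n = len(self.steps_nm)
        if n == 0:
            raise ValueError("no steps to fit")
        mean_r2 = float(r2.mean())

        if self.n_components == 1:
            s = mean_r2  # MLE: 4 D dt = <r^2>
            ll, _ = self._loglik_and_resp(1.0 - 1e-12, s, s)
            d = s / (4.0 * self.dt_s) / NM2_PER_UM2
            return StepLengthMixtureFit(1.0, d, d, ll, True, 0, n, self.dt_s,
                                        np.array([ll]))

        rng = np.random.default_rng(seed)
        best = None
        for restart in range(n_restarts):
            if restart == 0:
                # moment-flavored start: split at the median squared step
                lo = float(np.quantile(r2, 0.25))
                hi = float(np.quantile(r2, 0.75))
                alpha, s1, s2 = 0.5, max(hi, 1e-12), max(lo, 1e-12)
            else:
                alpha = rng.uniform(0.2, 0.8)
                f1, f2 = sorted(rng.uniform(0.1, 3.0, 2), reverse=True)
                s1, s2 = mean_r2 * f1, mean_r2 * f2
            path = []
            ll_prev = -np.inf
            converged = False
            for it in range(max_iter):
                ll, gamma = self._loglik_and_resp(alpha, s1, s2)
                # EM guarantees monotone log-likelihood (up to round-off)
                assert ll >= ll_prev - 1e-6 * max(1.0, abs(ll_prev)), \
                    "EM log-likelihood decreased"
                path.append(ll)
                if ll - ll_prev < tol * max(1.0, abs(ll)) and it > 0:
                    converged = True
                    break
                ll_prev = ll
                w1 = gamma.sum()
                w2 = n - w1
                alpha = w1 / n
                # M-step MLE of the scale 4*D*dt: weighted mean of r^2
                if w1 > 0:
                    s1 = max(float((gamma * r2).sum() / w1), 1e-12)
                if w2 > 0:
                    s2 = max(float(((1 - gamma) * r2).sum() / w2), 1e-12)
            ll, _ = self._loglik_and_resp(alpha, s1, s2)
            cand = (ll, alpha, s1, s2, converged, len(path), np.array(path))
            if best is None or ll > best[0]:
                best = cand

        ll, alpha, s1, s2, converged, n_iter, path = best
        d1 = s1 / (4.0 * self.dt_s) / NM2_PER_UM2
        d2 = s2 / (4.0 * self.dt_s) / NM2_PER_UM2
        if d1 < d2:
            d1, d2, alpha = d2, d1, 1.0 - alpha
        identifiable = True
        # closer than ~5% in D, the two Rayleigh components are practically
        # indistinguishable and alpha carries no information
        if abs(d1 - d2) <= 0.05 * max(d1, d2, 1e-12):
            identifiable = False
            warnings.warn("mixture components coincide (D1 ~= D2); the "
                          "fraction alpha is unidentifiable",
                          UnidentifiableMixtureWarning, stacklevel=2)
        return StepLengthMixtureFit(float(alpha), d1, d2, ll, converged,
                                    n_iter, n, self.dt_s, path, identifiable)


def fit_step_length_mixture(steps_nm: np.ndarray, dt_s: float,
                            n_components: int = 2, seed: int = 0,
                            **fit_kw) -> StepLengthMixtureFit:
    """Convenience wrapper: build a :class:`StepLengthMixture` and fit it."""
    return StepLengthMixture(steps_nm, dt_s, n_components).fit(seed=seed,
                                                               **fit_kw)


def find_immobile(tracks: TrackSet, eps_nm: float = 50.0,
                  min_pts: int = 5, cluster_fraction: float = 0.8
                  ) -> np.ndarray:
    """Flag immobile tracks by DBSCAN on each track's own localizations.

    A surface-stuck molecule's localizations pile up within the
    localization precision, forming one dense DBSCAN cluster, while a
    mobile molecule's points spread far beyond ``eps_nm``. A track is
    flagged immobile when at least ``cluster_fraction`` of its
    localizations fall in a single cluster. The default ``eps_nm`` is
    twice the typical localization error SD.

    Returns a boolean array aligned with ``tracks``.
    """
    if eps_nm <= 0:
        raise ValueError("eps_nm must be > 0")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    flags = np.zeros(len(tracks), dtype=bool)
    for i, t in enumerate(tracks):
        if len(t) < min_pts:
            # too short for density estimation; treat as immobile only if
            # it never moves beyond eps
            if len(t) >= 2:
                span = np.linalg.norm(t.xy_nm - t.xy_nm.mean(axis=0),
                                      axis=1).max()
                flags[i] = span <= eps_nm
            continue
        labels = DBSCAN(eps=eps_nm, min_samples=min_pts).fit_predict(t.xy_nm)
        core = labels[labels >= 0]
        if core.size == 0:
            continue
        largest = np.bincount(core).max()
        flags[i] = largest >= cluster_fraction * len(t)
    return flags


def exclude_immobile(tracks: TrackSet, eps_nm: float = 50.0,
                     min_pts: int = 5) -> tuple[TrackSet, np.ndarray]:
    """Drop immobile tracks; returns (mobile TrackSet, immobile flags)."""
    flags = find_immobile(tracks, eps_nm, min_pts)
    mobile = TrackSet([t for t, f in zip(tracks, flags) if not f],
                      tracks.channel)
    return mobile, flags


# ---------------------------------------------------------------------------
# bleaching-step counting

@dataclass
class BleachStepResult:
    """Change-point segmentation of an intensity trace.

    ``n_steps`` counts downward level changes (bleaching events);
    ``change_points`` are the first indices of each new segment.
    """

    n_steps: int
    change_points: list[int]
    segment_means: list[float]


def count_bleach_steps(trace: np.ndarray, penalty: float | None = None,
                       min_segment: int = 3) -> BleachStepResult:
    """Count photobleaching steps in a single-emitter intensity trace.

    The trace is segmented with a piecewise-constant least-squares model
    and a per-change-point penalty (optimal partitioning by dynamic
    programming). By default the penalty is BIC-style,
    ``3 * sigma^2 * log(n)``, with sigma estimated robustly from first
    differences. The number of downward level changes is the fluorophore
    count of the underlying emitter: a dimer carrying two same-color
    labels bleaches in two steps.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < 3:
        raise ValueError("trace must have length >= 3")
    if np.isnan(trace).all():
        raise ValueError("all-NaN trace")
    trace = np.nan_to_num(trace, nan=float(np.nanmedian(trace)))

    if penalty is None:
        diffs = np.diff(trace)
        mad = np.median(np.abs(diffs - np.median(diffs)))
        sigma = mad / (0.6744897501960817 * math.sqrt(2.0))
        penalty = max(3.0 * sigma * sigma * math.log(n), 1e-9)

    # prefix sums for O(1) segment SSE
    c1 = np.concatenate([[0.0], np.cumsum(trace)])
    c2 = np.concatenate([[0.0], np.cumsum(trace**2)])

    def sse(i: int, j: int) -> float:
        # segment trace[i:j]
        s = c1[j] - c1[i]
        q = c2[j] - c2[i]
        return q - s * s / (j - i)

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=np.int64)
    best[0] = -penalty
    for j in range(min_segment, n + 1):
        for i in range(0, j - min_segment + 1):
            if best[i] == np.inf:
                continue
            c = best[i] + sse(i, j) + penalty
            if c < best[j]:
                best[j] = c
                prev[j] = i
    # backtrack
    bounds = []
    j = n
    while j > 0:
        bounds.append(prev[j])
        j = prev[j]
    bounds = bounds[::-1]  # segment start indices, first is 0
    starts = [int(b) for b in bounds] + [n]
    means = [float(trace[starts[k]:starts[k + 1]].mean())
             for k in range(len(starts) - 1)]
    change_points = starts[1:-1]
    n_down = sum(1 for k in range(1, len(means)) if means[k] < means[k - 1])
    return BleachStepResult(n_down, change_points, means)
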