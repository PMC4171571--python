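"""Trajectory motility statistics for single-cell tracks.

Implements the random-motion analysis applied to the manually tracked
cells: frame-to-frame instant velocities and their time-binned
distributions, cumulative distance travelled, time-averaged mean-squared
displacement (MSD) per cell and per ensemble, effective diffusivity from a
straight-line MSD fit (D_eff = slope/4 in 2-D), a diffusivity timecourse
over 10-h windows, signed turning angles with a Kolmogorov–Smirnov
uniformity test for persistence, and the association between reporter
level and motion.

Conventions (documented because results depend on them): MSD uses
overlapping time-averaged pairs; the ensemble MSD weights cells equally;
velocity samples are timestamped at frame-pair midpoints; time bins are
half-open ``[lo, hi)``; turning angles are signed counter-clockwise in an
x-right/y-up frame with exact reversals mapped to +π; tracks with time
gaps are split into contiguous segments before any computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .synth import Track, TrackSet

__all__ = [
    "VelocitySeries",
    "MSDCurve",
    "DiffusivityEstimate",
    "TurningAngleResult",
    "AssociationReport",
    "PlateauFit",
    "InsufficientDataError",
    "EmptyResultError",
    "MissingChannelError",
    "instant_velocities",
    "bin_velocities_by_start",
    "cumulative_distance",
    "msd_curve",
    "ensemble_msd",
    "fit_effective_diffusivity",
    "diffusivity_timecourse",
    "turning_angles",
    "ks_uniformity_test",
    "expression_motility_association",
    "msd_plateau_onset",
]

DEFAULT_FIT_WINDOW = (0.0, 2.0)
DEFAULT_MIN_STEP_UM = 1.0
DEFAULT_BIN_EDGES = (0.0, 20.0, 40.0, 60.0)


class InsufficientDataError(ValueError):
    """Too few samples/lags for the requested statistic."""


class EmptyResultError(ValueError):
    """No track overlaps the requested interval."""


class MissingChannelError(KeyError):
    """The operation needs reporter intensities that the tracks lack."""


def _segments(track: Track) -> list[slice]:
    """Contiguous index ranges of a uniformly-sampled track.

    Tracks straight from the simulator are contiguous; externally loaded
    tables may contain gaps (multiples of dt), which split the track.
    """
    t = track.times
    if len(t) < 2:
        return [slice(0, len(t))]
    steps = np.diff(t)
    dt = np.min(steps)
    breaks = np.nonzero(steps > 1.5 * dt)[0]
    edges = [0, *(b + 1 for b in breaks), len(t)]
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class VelocitySeries:
    """Instant speeds (μm/h) timestamped at frame-pair midpoints."""

    cell_id: str
    t: np.ndarray
    v: np.ndarray
    ok: bool = True

    def __len__(self) -> int:
        return len(self.v)


def instant_velocities(track: Track) -> VelocitySeries:
    """Frame-to-frame speed: |Δr| / Δt per consecutive frame pair.

    Gaps produce no sample. A track with fewer than two frames yields an
    empty series flagged ``ok=False`` with a warning.
    """
    if track.n < 2:
        warnings.warn(f"track {track.cell_id}: fewer than 2 frames, "
                      "empty velocity series")
        return VelocitySeries(track.cell_id, np.empty(0), np.empty(0), ok=False)
    ts, vs = [], []
    for seg in _segments(track):
        t, x, y = track.times[seg], track.x[seg], track.y[seg]
        if len(t) < 2:
            continue
        dt = np.diff(t)
        v = np.hypot(np.diff(x), np.diff(y)) / dt
        ts.append((t[:-1] + t[1:]) / 2.0)
        vs.append(v)
    if not ts:
        return VelocitySeries(track.cell_id, np.empty(0), np.empty(0), ok=False)
    return VelocitySeries(track.cell_id, np.concatenate(ts), np.concatenate(vs))


@dataclass
class BinnedVelocities:
    label: str
    lo: float
    hi: float
    v: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.v.mean()) if self.v.size else float("nan")

    @property
    def n(self) -> int:
        return int(self.v.size)


def bin_velocities_by_start(series, bin_edges=DEFAULT_BIN_EDGES) -> list[BinnedVelocities]:
    """Assign velocity samples to half-open time bins ``[lo, hi)``.

    The default edges 0/20/40/60 h reproduce the three analysis windows
    used for the velocity build-up comparison.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    allt = np.concatenate([s.t for s in series]) if series else np.empty(0)
    allv = np.concatenate([s.v for s in series]) if series else np.empty(0)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (allt >= lo) & (allt < hi)
        out.append(BinnedVelocities(f"{lo:g}-{hi:g}", float(lo), float(hi), allv[m]))
    return out


def cumulative_distance(track: Track) -> np.ndarray:
    """Running sum of frame displacements (μm), starting at 0."""
    if track.n < 2:
        raise InsufficientDataError("cumulative distance needs >= 2 frames")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class MSDCurve:
    """Lag-indexed mean-squared displacement (μm²)."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    scope: str = "cell"
    interval_label: str = "all"


def _msd_segment(x: np.ndarray, y: np.ndarray, max_k: int):
    n = len(x)
    msd = np.zeros(max_k + 1)
    npairs = np.zeros(max_k + 1, dtype=int)
    npairs[0] = n
    for k in range(1, min(max_k, n - 1) + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        msd[k] = np.mean(dx * dx + dy * dy)
        npairs[k] = n - k
    return msd, npairs


def msd_curve(track: Track, max_lag: float) -> MSDCurve:
    """Time-averaged MSD over overlapping pairs, per lag multiple of dt.

    msd(k·dt) = mean_i |r(t_i + k·dt) − r(t_i)|². Gapped tracks contribute
    pairs only within contiguous segments.
    """
    dt = track.dt
    if max_lag < dt:
        raise ValueError(f"max_lag ({max_lag!r}) must be at least dt ({dt!r})")
    if max_lag > track.span + 1e-9:
        raise ValueError("max_lag exceeds the track span")
    max_k = int(np.floor(max_lag / dt + 1e-9))
    acc = np.zeros(max_k + 1)
    cnt = np.zeros(max_k + 1, dtype=int)
    for seg in _segments(track):
        x, y = track.x[seg], track.y[seg]
        if len(x) < 2:
            continue
        m, c = _msd_segment(x, y, max_k)
        acc += m * c
        cnt += c
    with np.errstate(invalid="ignore"):
        msd = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    msd[0] = 0.0
    return MSDCurve(np.arange(max_k + 1) * dt, msd, cnt, scope="cell")


def _clip_track(track: Track, lo: float, hi: float) -> Track | None:
    m = (track.times >= lo) & (track.times < hi)
    if m.sum() < 2:
        return None
    g = track.g[m] if track.g is not None else None
    return Track(track.cell_id, track.times[m], track.x[m], track.y[m], g=g,
                 censored_at=track.censored_at, truth=track.truth)


def ensemble_msd(tracks: TrackSet, interval: tuple[float, float] | None = None,
                 max_lag: float = 2.0, min_pairs: int = 6) -> MSDCurve:
    """Equal-weight average of per-cell MSD curves over an interval.

    Each cell's MSD is computed on its track portion inside the half-open
    interval, then averaged across cells with equal weight per cell; cells
    contributing fewer than ``min_pairs`` pairs at a lag are dropped at
    that lag. ``n_pairs`` reports the number of contributing cells.
    """
    lo, hi = interval if interval is not None else (-np.inf, np.inf)
    clipped = [c for c in (_clip_track(t, lo, hi) for t in tracks) if c is not None]
    if not clipped:
        raise EmptyResultError(f"no track overlaps interval [{lo}, {hi})")
    dt = clipped[0].dt
    max_k = int(np.floor(max_lag / dt + 1e-9))
    acc = np.zeros(max_k + 1)
    ncells = np.zeros(max_k + 1, dtype=int)
    for tr in clipped:
        lag_cap = min(max_lag, tr.span)
        if lag_cap < dt:
            continue
        c = msd_curve(tr, lag_cap)
        k = len(c.msd)
        use = c.n_pairs >= min_pairs
        use[0] = True
        acc[:k][use] += np.where(np.isnan(c.msd[use]), 0.0, c.msd[use])
        ncells[:k][use] += 1
    with np.errstate(invalid="ignore"):
        msd = np.where(ncells > 0, acc / np.maximum(ncells, 1), np.nan)
    msd[0] = 0.0
    label = "all" if interval is None else f"{lo:g}-{hi:g}"
    return MSDCurve(np.arange(max_k + 1) * dt, msd, ncells,
                    scope="ensemble", interval_label=label)


@dataclass
class DiffusivityEstimate:
    """Effective diffusivity from a straight-line MSD fit (2-D)."""

    d_eff: float
    fit_window: tuple[float, float]
    slope_se: float
    intercept: float = 0.0
    interval_label: str = "all"
    n_points: int = 0


def fit_effective_diffusivity(msd: MSDCurve,
                              fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW
                              ) -> DiffusivityEstimate:
    """OLS of MSD on lag over ``(τ_min, τ_max]``; D_eff = slope/4.

    The intercept is free; the slope standard error is reported (so the
    SE of D_eff is slope_se/4).
    """
    lo, hi = fit_window
    m = (msd.lags > lo) & (msd.lags <= hi) & np.isfinite(msd.msd)
    if m.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 lag points in window ({lo}, {hi}], got {int(m.sum())}")
    res = stats.linregress(msd.lags[m], msd.msd[m])
    return DiffusivityEstimate(d_eff=float(res.slope / 4.0),
                               fit_window=(float(lo), float(hi)),
                               slope_se=float(res.stderr),
                               intercept=float(res.intercept),
                               interval_label=msd.interval_label,
                               n_points=int(m.sum()))


def diffusivity_timecourse(tracks: TrackSet, window_len: float = 10.0,
                           fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
                           min_pairs: int = 6) -> list[DiffusivityEstimate]:
    """Effective diffusivity per consecutive experiment-time window.

    The experiment is partitioned into [0, w), [w, 2w), ...; each window
    gets an ensemble MSD of the clipped tracks and a straight-line fit.
    Windows without usable tracks yield a NaN entry rather than an error.
    """
    if window_len <= fit_window[1]:
        raise ValueError("window_len must exceed the fit window upper bound")
    total = max((t.times[-1] for t in tracks), default=0.0)
    out = []
    lo = 0.0
    while lo < total - 1e-9:
        hi = lo + window_len
        label = f"{lo:g}-{hi:g}"
        try:
            curve = ensemble_msd(tracks, (lo, hi), max_lag=fit_window[1],
                                 min_pairs=min_pairs)
            est = fit_effective_diffusivity(curve, fit_window)
            est.interval_label = label
        except (EmptyResultError, InsufficientDataError):
            est = DiffusivityEstimate(float("nan"), fit_window, float("nan"),
                                      interval_label=label)
        out.append(est)
        lo = hi
    return out


def turning_angles(track: Track, min_step: float = DEFAULT_MIN_STEP_UM) -> np.ndarray:
    """Signed angles between consecutive displacement vectors, in (−π, π].

    Angles are counter-clockwise positive in an x-right/y-up frame; exact
    reversals map to +π. Steps shorter than ``min_step`` are skipped and
    the angle chain restarts after a skip.
    """
    if track.n < 3:
        return np.empty(0)
    out = []
    for seg in _segments(track):
        x, y = track.x[seg], track.y[seg]
        if len(x) < 3:
            continue
        dx, dy = np.diff(x), np.diff(y)
        ok = np.hypot(dx, dy) >= min_step
        for i in range(len(dx) - 1):
            if ok[i] and ok[i + 1]:
                cross = dx[i] * dy[i + 1] - dy[i] * dx[i + 1]
                dot = dx[i] * dx[i + 1] + dy[i] * dy[i + 1]
                ang = float(np.arctan2(cross, dot))
                if ang <= -np.pi:
                    ang = np.pi
                out.append(ang)
    return np.asarray(out)


@dataclass
class TurningAngleResult:
    """KS uniformity test of pooled turning angles."""

    angles: np.ndarray
    ks_stat: float
    p_value: float
    n: int


def ks_uniformity_test(angles) -> TurningAngleResult:
    """One-sample KS test of the angles against Uniform(−π, π].

    Uses the asymptotic p-value; a persistent walk (angles peaked at 0)
    rejects decisively, an isotropic walk is calibrated at the nominal
    type-I level.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 8:
        raise InsufficientDataError(f"need >= 8 angles, got {a.size}")
    res = stats.kstest(a, stats.uniform(loc=-np.pi, scale=2 * np.pi).cdf,
                       method="asymp")
    return TurningAngleResult(a, float(res.statistic), float(res.pvalue),
                              int(a.size))


@dataclass
class AssociationReport:
    """Reporter-vs-motility association across a tracked population."""

    pearson_r: float
    pearson_p: float
    distance_ratio: float
    ratio_ci: tuple[float, float]
    n_cells: int
    n_samples: int
    split_value: float = float("nan")


def expression_motility_association(tracks: TrackSet, n_boot: int = 1000,
                                    seed: int = 0) -> AssociationReport:
    """Quantify whether higher-reporter cells move more.

    Reports (i) the Pearson correlation between per-sample reporter level
    (frame-pair mean) and instant speed pooled over all cells, and (ii)
    the ratio of mean final cumulative distance between cells whose peak
    reporter exceeds the population mean of peaks and those below, with a
    seeded bootstrap CI over cells.
    """
    with_g = [t for t in tracks if t.g is not None]
    if len(with_g) < 10:
        raise MissingChannelError(
            f"need reporter intensities on >= 10 tracks, got {len(with_g)}")
    gs, vs = [], []
    peaks, dists = [], []
    for t in with_g:
        ser = instant_velocities(t)
        if not ser.ok:
            continue
        # pair each speed sample with the mean reporter of its frame pair
        gmid = (t.g[:-1] + t.g[1:]) / 2.0
        gs.append(gmid[: len(ser.v)])
        vs.append(ser.v)
        peaks.append(float(t.g.max()))
        dists.append(float(cumulative_distance(t)[-1]))
    g = np.concatenate(gs)
    v = np.concatenate(vs)
    if np.std(g) == 0 or np.std(v) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(g, v)
    peaks = np.asarray(peaks)
    dists = np.asarray(dists)
    split = float(peaks.mean())
    hi = dists[peaks > split]
    lo = dists[peaks <= split]

    def ratio(h, l):
        if h.size == 0 or l.size == 0 or l.mean() == 0:
            return float("nan")
        return float(h.mean() / l.mean())

    point = ratio(hi, lo)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bh = rng.choice(hi, size=hi.size, replace=True) if hi.size else hi
        bl = rng.choice(lo, size=lo.size, replace=True) if lo.size else lo
        boots.append(ratio(bh, bl))
    boots = np.asarray(boots)
    boots = boots[np.isfinite(boots)]
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975))) \
        if boots.size else (float("nan"), float("nan"))
    return AssociationReport(float(r), float(p), point, ci,
                             n_cells=len(peaks), n_samples=int(v.size),
                             split_value=split)


@dataclass
class PlateauFit:
    """Saturating-exponential MSD fit and the plateau-onset time.

    The model is MSD(τ) = L·(1 − exp(−τ/τc)). The plateau onset is the
    intersection of the initial-slope line with the asymptote L, i.e.
    L / slope_init; when the data follow the model exactly this equals τc.
    """

    onset_time: float
    tau_c: float
    plateau: float
    slope_init: float


def msd_plateau_onset(msd: MSDCurve,
                      init_window: tuple[float, float] = (0.0, 0.5)) -> PlateauFit:
    """Locate the diffusive-to-confined transition of an MSD curve."""
    m = np.isfinite(msd.msd)
    lags, vals = msd.lags[m], msd.msd[m]
    if lags.size < 5:
        raise InsufficientDataError("need >= 5 finite MSD points")
    init = (lags >= init_window[0]) & (lags <= init_window[1])
    if init.sum() < 3:
        raise InsufficientDataError("need >= 3 points in the initial window")
    slope = float(stats.linregress(lags[init], vals[init]).slope)

    def model(tau, plateau, tau_c):
        return plateau * (1.0 - np.exp(-tau / tau_c))

    l0 = float(vals.max())
    above = vals > 0.632 * l0
    tc0 = float(lags[np.argmax(above)]) if above.any() else float(lags[-1] / 3)
    popt, _ = optimize.curve_fit(model, lags, vals, p0=(l0, max(tc0, 1e-3)),
                                 bounds=([0, 1e-6], [np.inf, np.inf]),
                                 maxfev=20000)
    plateau, tau_c = float(popt[0]), float(popt[1])
    onset = plateau / slope if slope > 0 else float("nan")
    return PlateauFit(onset_time=float(onset), tau_c=tau_c,
                      plateau=plateau, slope_init=slope)
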