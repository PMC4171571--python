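"""Synthetic data with the statistical structure the analysis assumes.

Four generators, one per data modality of the experimental study:

* :func:`simulate_trajectories` — confined persistent random walks with a
  per-cell EMT onset, an optional transient reporter pulse coupled to
  speed, and field-of-view censoring (live-imaging track tables);
* :func:`synthesize_image_series` — nuclear image stacks with correlated
  per-nucleus channel intensities (confocal quantitative-image-analysis
  fixtures);
* :func:`simulate_event_population` — replicate event-intensity tables
  (imaging/flow-cytometry-like data);
* :func:`simulate_qpcr_replicates` — per-cycle amplification curves from
  the MAK2 kinetic model plus Gaussian noise.

All randomness flows from a single integer seed. The master seed spawns
sub-streams through ``numpy.random.SeedSequence(entropy=seed,
spawn_key=(stream, index))`` where ``stream`` is a fixed per-generator code
and ``index`` counts cells / replicates; any subset of cells or replicates
is therefore reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .presets import ConditionPreset, ONSET_TRUNCATION_H

__all__ = [
    "Track",
    "TrackSet",
    "ImageScene",
    "ChannelModel",
    "concordance_channel_model",
    "PlacementError",
    "simulate_trajectories",
    "synthesize_image_series",
    "simulate_event_population",
    "simulate_qpcr_replicates",
    "write_tracks_csv",
    "read_tracks_csv",
]

# Sub-stream codes of the master seed (documented counter scheme).
_STREAM_TRACKS = 0
_STREAM_EVENTS = 1
_STREAM_QPCR = 2
_STREAM_IMAGES = 3

#: Frame interval of the live-imaging time grid: one frame every 10 min.
DEFAULT_DT_H = 1.0 / 6.0


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(stream, index))
    return np.random.default_rng(ss)


def _lognormal(rng, median: float, gsd: float, size=None):
    return rng.lognormal(mean=math.log(median), sigma=math.log(gsd), size=size)


def _truncnorm_low(rng, mean: float, sd: float, low: float, size=None):
    """Normal(mean, sd) truncated below at ``low`` by rejection."""
    scalar = size is None
    n = 1 if scalar else int(size)
    out = rng.normal(mean, sd, size=n)
    bad = out < low
    # Rejection terminates quickly for any truncation in the bulk; fall
    # back to clamping only in the pathological far-tail case.
    for _ in range(1000):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < low
    out = np.maximum(out, low)
    return float(out[0]) if scalar else out


def pulse_value(t, onset, dur, rise, peak):
    """Piecewise-linear reporter pulse: rise / plateau / fall.

    Zero before ``onset`` and after ``onset + dur``; linear rise over
    ``rise`` hours, plateau at ``peak``, linear fall over the final
    ``rise`` hours of the pulse. If the pulse is shorter than two rise
    times the ramps are shortened to ``dur/2`` (triangular pulse).
    """
    t = np.asarray(t, dtype=float)
    ramp = min(rise, dur / 2.0)
    rel = t - onset
    up = np.clip(rel / ramp, 0.0, 1.0) if ramp > 0 else (rel >= 0).astype(float)
    down = np.clip((dur - rel) / ramp, 0.0, 1.0) if ramp > 0 else (rel <= dur).astype(float)
    g = peak * np.minimum(up, down)
    g[(rel < 0) | (rel > dur)] = 0.0
    return np.maximum(g, 0.0)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """A single cell's sampled positions (μm) on a uniform time grid (h)."""

    cell_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    g: np.ndarray | None = None
    censored_at: float | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.g is not None:
            self.g = np.asarray(self.g, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.times)
        if n < 2:
            raise ValueError(f"track {self.cell_id}: needs >= 2 samples, got {n}")
        if len(self.x) != n or len(self.y) != n:
            raise ValueError(f"track {self.cell_id}: x/y length mismatch")
        steps = np.diff(self.times)
        if not (steps > 0).all():
            raise ValueError(f"track {self.cell_id}: times must strictly increase")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"track {self.cell_id}: time spacing must be constant")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError(f"track {self.cell_id}: non-finite positions")
        if self.g is not None:
            if len(self.g) != n:
                raise ValueError(f"track {self.cell_id}: g length mismatch")
            if (self.g < 0).any():
                raise ValueError(f"track {self.cell_id}: g must be >= 0")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class TrackSet:
    """A collection of tracks from one simulated or observed condition."""

    tracks: list[Track]
    condition: str = ""
    dt: float = DEFAULT_DT_H
    duration: float = 0.0
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cell_id, t_h, x_um, y_um[, g_afu]."""
        rows = []
        any_g = any(t.g is not None for t in self.tracks)
        for t in self.tracks:
            d = {"cell_id": t.cell_id, "t_h": t.times, "x_um": t.x, "y_um": t.y}
            if any_g:
                d["g_afu"] = t.g if t.g is not None else np.full(t.n, np.nan)
            rows.append(pd.DataFrame(d))
        if not rows:
            cols = ["cell_id", "t_h", "x_um", "y_um"] + (["g_afu"] if any_g else [])
            return pd.DataFrame(columns=cols)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str = "") -> "TrackSet":
        tracks = []
        for cid, sub in df.groupby("cell_id", sort=False):
            sub = sub.sort_values("t_h")
            g = sub["g_afu"].to_numpy() if "g_afu" in sub.columns else None
            if g is not None and np.isnan(g).all():
                g = None
            tracks.append(Track(str(cid), sub["t_h"].to_numpy(),
                                sub["x_um"].to_numpy(), sub["y_um"].to_numpy(), g=g))
        dt = tracks[0].dt if tracks else DEFAULT_DT_H
        dur = max((t.times[-1] for t in tracks), default=0.0)
        return cls(tracks, condition=condition, dt=dt, duration=float(dur))


def write_tracks_csv(tracks: TrackSet, path) -> None:
    tracks.to_frame().to_csv(path, index=False)


def read_tracks_csv(path, condition: str = "") -> TrackSet:
    return TrackSet.from_frame(pd.read_csv(path), condition=condition)


def simulate_trajectories(preset: ConditionPreset, n_cells: int,
                          duration: float, dt: float = DEFAULT_DT_H,
                          seed: int = 0) -> TrackSet:
    """Simulate confined persistent random walks with an EMT speed-up.

    Each cell carries a log-normal baseline speed, a truncated-normal EMT
    onset, and (with probability ``p_express``) one transient reporter
    pulse. The heading evolves by wrapped-normal increments; the speed is
    ``s_base · m_emt(t) · (1 + β·g(t)/g_peak)`` where ``m_emt`` ramps
    linearly from 1 to ``emt_speed_mult`` over ``mult_ramp`` hours after
    the EMT (and stays 1 when motility is blocked). Positions reflect at
    the active confinement disk (pre-EMT radius before the EMT, post-EMT
    radius after). Tracks are right-censored at the first frame where
    |x| or |y| exceeds ``fov_halfwidth``; cells censored before their
    second frame are dropped.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration!r}")
    if n_cells < 0:
        raise ValueError(f"n_cells must be >= 0, got {n_cells!r}")
    preset.validate()

    n_frames = int(round(duration / dt)) + 1
    times = np.arange(n_frames) * dt
    tracks: list[Track] = []
    for i in range(n_cells):
        rng = _rng(seed, _STREAM_TRACKS, i)
        # Per-cell traits, drawn in a fixed documented order.
        s_base = _lognormal(rng, preset.base_speed_median, preset.base_speed_gsd)
        emt_time = _truncnorm_low(rng, preset.emt_onset_mean, preset.emt_onset_sd, 0.0)
        expresses = rng.random() < preset.p_express
        onset = _truncnorm_low(rng, preset.expr_onset_mean, preset.expr_onset_sd,
                               ONSET_TRUNCATION_H)
        dur_pulse = _truncnorm_low(rng, preset.expr_dur_mean, preset.expr_dur_sd,
                                   min(preset.expr_rise, preset.expr_dur_mean / 4.0))
        peak = _lognormal(rng, preset.expr_peak_median, preset.expr_peak_gsd)
        theta = rng.uniform(-math.pi, math.pi)
        r0 = preset.confine_radius_pre * math.sqrt(rng.random())
        a0 = rng.uniform(-math.pi, math.pi)
        eta = rng.normal(0.0, preset.turn_sd, size=n_frames - 1)

        g = pulse_value(times, onset, dur_pulse, preset.expr_rise, peak) \
            if expresses else np.zeros(n_frames)
        if preset.motility_blocked:
            m_emt = np.ones(n_frames)
        else:
            ramp = np.clip((times - emt_time) / preset.mult_ramp, 0.0, 1.0)
            m_emt = 1.0 + (preset.emt_speed_mult - 1.0) * ramp
        coupling = 1.0 + preset.expr_speed_coupling * g / peak
        speed = s_base * m_emt * coupling

        x = np.empty(n_frames)
        y = np.empty(n_frames)
        x[0] = r0 * math.cos(a0)
        y[0] = r0 * math.sin(a0)
        post_active = (not preset.motility_blocked)
        for k in range(n_frames - 1):
            theta += eta[k]
            radius = (preset.confine_radius_post
                      if post_active and times[k] >= emt_time
                      else preset.confine_radius_pre)
            step = speed[k] * dt
            nx = x[k] + step * math.cos(theta)
            ny = y[k] + step * math.sin(theta)
            r = math.hypot(nx, ny)
            if r > radius:
                # Reflect position radially back inside and mirror the
                # heading about the tangent at the crossing direction.
                fold = max(2.0 * radius - r, 0.0) / r
                nxi, nyi = nx / r, ny / r
                nx, ny = nx * fold, ny * fold
                vx, vy = math.cos(theta), math.sin(theta)
                dot = vx * nxi + vy * nyi
                vx, vy = vx - 2.0 * dot * nxi, vy - 2.0 * dot * nyi
                theta = math.atan2(vy, vx)
            x[k + 1] = nx
            y[k + 1] = ny

        out = (np.abs(x) > preset.fov_halfwidth) | (np.abs(y) > preset.fov_halfwidth)
        censored_at = None
        last = n_frames
        if out.any():
            first_out = int(np.argmax(out))
            if first_out < 2:  # censored before a usable track exists
                continue
            last = first_out
            censored_at = float(times[first_out - 1])
        truth = {"emt_time": emt_time, "expresses": bool(expresses),
                 "s_base": s_base}
        if expresses:
            truth.update({"onset": onset, "pulse_duration": dur_pulse,
                          "peak": peak})
        tracks.append(Track(f"cell{i:04d}", times[:last], x[:last], y[:last],
                            g=g[:last], censored_at=censored_at, truth=truth))
    return TrackSet(tracks, condition=preset.name, dt=dt,
                    duration=duration, seed=seed)


# ---------------------------------------------------------------------------
# Image scenes
# ---------------------------------------------------------------------------

class PlacementError(RuntimeError):
    """Requested nucleus density is infeasible after bounded retries."""


@dataclass
class ChannelModel:
    """Joint distribution of per-nucleus mean intensities across channels.

    ``sample(n, rng)`` must return a DataFrame with one column per channel
    name (the first channel is the nuclear stain used for segmentation).
    """

    names: tuple[str, ...]

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:  # pragma: no cover
        raise NotImplementedError


@dataclass
class _ConcordanceModel(ChannelModel):
    """Nuclear stain + protein B + reporter G = B + ε, ε ~ N(0, σ_ε).

    With σ_ε = ``noise_ratio`` · sd(B), the population Pearson correlation
    between G and B is 1/√(1 + noise_ratio²); the default 0.822 gives
    r ≈ 0.773, the concordance measured between the knock-in reporter and
    the immunostained protein.
    """

    hoechst_mean: float = 120.0
    hoechst_gsd: float = 1.15
    protein_median: float = 150.0
    protein_gsd: float = 1.4
    noise_ratio: float = 0.822

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        mu, sig = math.log(self.protein_median), math.log(self.protein_gsd)
        b = rng.lognormal(mu, sig, size=n)
        mean_b = math.exp(mu + sig ** 2 / 2.0)
        sd_b = mean_b * math.sqrt(math.expm1(sig ** 2))
        gfp = b + rng.normal(0.0, self.noise_ratio * sd_b, size=n)
        gfp = np.maximum(gfp, 0.0)
        hoechst = _lognormal(rng, self.hoechst_mean, self.hoechst_gsd, size=n)
        return pd.DataFrame({self.names[0]: hoechst,
                             self.names[1]: b,
                             self.names[2]: gfp})


def concordance_channel_model(protein_median: float = 150.0,
                              protein_gsd: float = 1.4,
                              noise_ratio: float = 0.822) -> ChannelModel:
    """Channel model for the reporter-vs-immunostain concordance scene."""
    return _ConcordanceModel(names=("hoechst", "protein", "reporter"),
                             protein_median=protein_median,
                             protein_gsd=protein_gsd,
                             noise_ratio=noise_ratio)


@dataclass
class IndependentChannelModel(ChannelModel):
    """Independent log-normal channels (null model for correlation tests)."""

    medians: tuple[float, ...] = ()
    gsds: tuple[float, ...] = ()

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        cols = {}
        for name, med, gsd in zip(self.names, self.medians, self.gsds):
            cols[name] = _lognormal(rng, med, gsd, size=n)
        return pd.DataFrame(cols)


@dataclass
class ImageScene:
    """A T×C×H×W intensity stack with per-nucleus ground truth."""

    stack: np.ndarray
    channels: tuple[str, ...]
    pixel_size: float
    truth: pd.DataFrame

    def __post_init__(self):
        if self.stack.ndim != 4:
            raise ValueError("stack must be T x C x H x W")
        if self.stack.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if (self.stack < 0).any():
            raise ValueError("intensities must be >= 0")

    def channel(self, name: str, frame: int = 0) -> np.ndarray:
        return self.stack[frame, self.channels.index(name)]

    def write_tiff(self, path) -> None:
        """Multi-page TIFF (T-major then channel) + plain-text sidecar."""
        path = Path(path)
        t, c, h, w = self.stack.shape
        tifffile.imwrite(path, self.stack.reshape(t * c, h, w).astype(np.float32),
                         photometric="minisblack")
        meta = {"channels": list(self.channels), "pixel_size_um": self.pixel_size,
                "shape_tchw": [int(v) for v in self.stack.shape]}
        path.with_suffix(path.suffix + ".meta.yaml").write_text(
            yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def read_tiff(cls, path, truth: pd.DataFrame | None = None) -> "ImageScene":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
        pages = tifffile.imread(path)
        t, c, h, w = meta["shape_tchw"]
        stack = np.asarray(pages, dtype=float).reshape(t, c, h, w)
        if truth is None:
            truth = pd.DataFrame()
        return cls(stack, tuple(meta["channels"]), float(meta["pixel_size_um"]), truth)


def synthesize_image_series(n_nuclei: int,
                            channel_model: ChannelModel | None = None,
                            noise_sd: float = 2.0,
                            pixel_size: float = 0.65,
                            seed: int = 0,
                            *,
                            tile_shape: tuple[int, int] = (320, 320),
                            nuclei_per_tile: int = 50,
                            radius_range_px: tuple[float, float] = (8.0, 12.0),
                            background: float = 0.0,
                            max_tries_per_nucleus: int = 400) -> ImageScene:
    """Render non-overlapping nuclear disks with correlated channel means.

    Nuclei are placed on as many tiles (frames) as needed at up to
    ``nuclei_per_tile`` each, by rejection sampling of non-overlapping
    disks. Each nucleus's per-channel mean intensity is drawn from the
    channel model's joint distribution; pixels inside the disk take that
    mean, plus i.i.d. Gaussian noise (clipped at zero) everywhere.
    Ground truth (centroids, radii, true means) is recorded per nucleus.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if channel_model is None:
        channel_model = concordance_channel_model()
    rng = _rng(seed, _STREAM_IMAGES, 0)
    h, w = tile_shape
    n_tiles = max(1, math.ceil(n_nuclei / nuclei_per_tile)) if n_nuclei else 1
    channels = channel_model.names
    means = channel_model.sample(n_nuclei, rng) if n_nuclei else pd.DataFrame(
        columns=list(channels))

    stack = np.full((n_tiles, len(channels), h, w), background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    truth_rows = []
    placed = 0
    for tile in range(n_tiles):
        n_here = min(nuclei_per_tile, n_nuclei - placed)
        centers: list[tuple[float, float, float]] = []
        for j in range(n_here):
            r = rng.uniform(*radius_range_px)
            ok = False
            for _ in range(max_tries_per_nucleus):
                cx = rng.uniform(r + 1, w - r - 2)
                cy = rng.uniform(r + 1, h - r - 2)
                # gap wide enough that smoothing cannot bridge neighbours
                if all((cx - ox) ** 2 + (cy - oy) ** 2 > (r + orr + 8.0) ** 2
                       for ox, oy, orr in centers):
                    ok = True
                    break
            if not ok:
                raise PlacementError(
                    f"could not place nucleus {placed + j} on tile {tile} "
                    f"after {max_tries_per_nucleus} tries")
            centers.append((cx, cy, r))
            idx = placed + j
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
            row = {"frame": tile, "nucleus": idx, "cx_px": cx, "cy_px": cy,
                   "radius_px": r}
            for ci, ch in enumerate(channels):
                val = float(means.iloc[idx][ch])
                stack[tile, ci][disk] = val
                row[f"true_{ch}"] = val
            truth_rows.append(row)
        placed += n_here
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)
    truth = pd.DataFrame(
        truth_rows,
        columns=["frame", "nucleus", "cx_px", "cy_px", "radius_px"]
        + [f"true_{c}" for c in channels])
    return ImageScene(stack, tuple(channels), pixel_size, truth)


# ---------------------------------------------------------------------------
# Event populations (cytometry-like)
# ---------------------------------------------------------------------------

def simulate_event_population(preset: ConditionPreset,
                              timepoints: Sequence[float],
                              n_events: int = 10_000,
                              n_replicates: int = 3,
                              seed: int = 0) -> pd.DataFrame:
    """Replicate event-intensity tables sampled from the pulse model.

    At each timepoint every event is an independent cell: with probability
    ``p_express`` it carries the same piecewise-linear reporter pulse as
    the trajectory simulator, evaluated at the timepoint; all events add a
    log-normal autofluorescence background. A fixed fraction is flagged
    non-viable. Replicates use sub-seeds spawned from the master seed.
    """
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    preset.validate()
    frames = []
    for rep in range(n_replicates):
        rng = _rng(seed, _STREAM_EVENTS, rep)
        for tp in timepoints:
            expresses = rng.random(n_events) < preset.p_express
            onset = _truncnorm_low(rng, preset.expr_onset_mean,
                                   preset.expr_onset_sd, ONSET_TRUNCATION_H,
                                   size=n_events)
            dur = _truncnorm_low(rng, preset.expr_dur_mean, preset.expr_dur_sd,
                                 min(preset.expr_rise, preset.expr_dur_mean / 4.0),
                                 size=n_events)
            peak = _lognormal(rng, preset.expr_peak_median,
                              preset.expr_peak_gsd, size=n_events)
            ramp = np.minimum(preset.expr_rise, dur / 2.0)
            rel = tp - onset
            up = np.clip(rel / ramp, 0.0, 1.0)
            down = np.clip((dur - rel) / ramp, 0.0, 1.0)
            g = peak * np.minimum(up, down)
            g[(rel < 0) | (rel > dur) | ~expresses] = 0.0
            bg = _lognormal(rng, preset.bg_median, preset.bg_gsd, size=n_events)
            viable = rng.random(n_events) >= preset.nonviable_frac
            frames.append(pd.DataFrame({
                "condition": preset.name,
                "timepoint_h": float(tp),
                "replicate": rep,
                "intensity_afu": g + bg,
                "viable": viable,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# qPCR replicates
# ---------------------------------------------------------------------------

def simulate_qpcr_replicates(params, n_cycles: int, noise_sd: float = 0.0,
                             n_rep: int = 3, seed: int = 0):
    """MAK2 forward curves plus i.i.d. Gaussian fluorescence noise.

    The default of three replicates mirrors reactions run in triplicate.
    Returns a list of :class:`streaklab.qpcr.QPCRCurve`.
    """
    from .qpcr import mak2_forward  # local import to avoid a cycle

    if n_cycles < 5:
        raise ValueError("n_cycles must be >= 5")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    base = mak2_forward(params, n_cycles)
    curves = []
    for rep in range(n_rep):
        rng = _rng(seed, _STREAM_QPCR, rep)
        f = base.fluorescence + (rng.normal(0.0, noise_sd, size=n_cycles)
                                 if noise_sd > 0 else 0.0)
        curves.append(base.replace(fluorescence=np.asarray(f, dtype=float),
                                   replicate=rep))
    return curves
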