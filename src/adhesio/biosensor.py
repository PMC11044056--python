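"""Ratiometric biosensor analytics for focal-adhesion PKA activity.

The sensor is a paxillin-fused ratiometric A-kinase reporter: a
conformation-sensitive GFP whose intensity rises with PKA activity,
normalised by a fused mCherry that reports sensor abundance.  Per-FA activity
is therefore the ratio of summed numerator (GFP) to summed denominator
(mCherry) intensity over the FA footprint, per frame.

This module links per-frame FA segmentations into tracks, extracts raw and
boxcar-smoothed ratio time series, spatially registers each FA into a
vertical medial->distal frame to build sub-FA kymographs, scores the
position of peak activity (distal / central / medial third of the major
axis), classifies growth state from length kinetics (rates above +0.02
um/min sustained >= 5 min are Growing, below -0.02 Shrinking, between them
Stable), and summarises ratio statistics by growth state across a cohort.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import Movie, rolling_ball_background
from .morphometrics import FocalAdhesion

logger = logging.getLogger(__name__)

GROWTH_RATE_THRESHOLD_UM_PER_MIN = 0.02
MIN_SEGMENT_MIN = 5.0


@dataclass(frozen=True)
class TrackPoint:
    """One FA observation (or one bridged gap) within a track."""

    frame: int
    label: int | None  # segmentation label; None for an interpolated gap frame
    centroid_xy_um: tuple[float, float]
    orientation_rad: float
    major_um: float
    minor_um: float
    interpolated: bool = False

    @property
    def length_um(self) -> float:
        return self.major_um


@dataclass
class FATrack:
    track_id: int
    points: list[TrackPoint]

    @property
    def frames(self) -> list[int]:
        return [p.frame for p in self.points]

    @property
    def n_frames(self) -> int:
        return len(self.points)

    def lengths_um(self) -> np.ndarray:
        return np.array([p.length_um for p in self.points])


@dataclass(frozen=True)
class RatioSeries:
    track_id: int
    times_s: np.ndarray
    raw_ratio: np.ndarray
    smoothed_ratio: np.ndarray


@dataclass(frozen=True)
class Kymograph:
    """Ratio along the FA major axis (0 = medial end, 1 = distal end) x time."""

    track_id: int
    positions: np.ndarray
    times_s: np.ndarray
    matrix: np.ndarray  # (position, time)


@dataclass(frozen=True)
class GrowthSegment:
    t_start_min: float
    t_end_min: float
    rate_um_per_min: float
    state: str  # Growing / Stable / Shrinking


@dataclass(frozen=True)
class GrowthState:
    track_id: int
    segments: tuple[GrowthSegment, ...]


def track_fas(
    frame_fas: list[list[FocalAdhesion]],
    max_displacement_um_per_frame: float = 1.0,
) -> list[FATrack]:
    """Link per-frame FA lists into tracks by greedy nearest-centroid matching.

    Matches are accepted within ``max_displacement_um_per_frame`` (scaled by
    the frame gap); a track may skip one frame, which is bridged by linear
    interpolation of its geometry; unmatched detections start new tracks.
    Ambiguous crossings beyond the gate terminate tracks rather than swap
    identities.
    """
    if len(frame_fas) < 2:
        raise ValueError("need at least 2 frames of segmentations")
    tracks: list[FATrack] = []
    active: list[FATrack] = []
    next_id = 0
    for t, fas in enumerate(frame_fas):
        candidates = [tr for tr in active if t - tr.points[-1].frame <= 2]
        pairs = []
        for ti, tr in enumerate(candidates):
            last = tr.points[-1]
            gap = t - last.frame
            for di, fa in enumerate(fas):
                d = np.hypot(
                    fa.centroid_xy_um[0] - last.centroid_xy_um[0],
                    fa.centroid_xy_um[1] - last.centroid_xy_um[1],
                )
                if d <= max_displacement_um_per_frame * gap:
                    pairs.append((d, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for d, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = candidates[ti]
            fa = fas[di]
            last = tr.points[-1]
            point = TrackPoint(
                frame=t,
                label=fa.label,
                centroid_xy_um=fa.centroid_xy_um,
                orientation_rad=fa.orientation_rad,
                major_um=fa.major_um,
                minor_um=fa.minor_um,
            )
            if t - last.frame == 2:  # bridge the single missing frame
                tr.points.append(
                    TrackPoint(
                        frame=t - 1,
                        label=None,
                        centroid_xy_um=(
                            (last.centroid_xy_um[0] + fa.centroid_xy_um[0]) / 2,
                            (last.centroid_xy_um[1] + fa.centroid_xy_um[1]) / 2,
                        ),
                        orientation_rad=last.orientation_rad,
                        major_um=(last.major_um + fa.major_um) / 2,
                        minor_um=(last.minor_um + fa.minor_um) / 2,
                        interpolated=True,
                    )
                )
            tr.points.append(point)
        for di, fa in enumerate(fas):
            if di in used_d:
                continue
            tracks.append(
                FATrack(
                    track_id=next_id,
                    points=[
                        TrackPoint(
                            frame=t,
                            label=fa.label,
                            centroid_xy_um=fa.centroid_xy_um,
                            orientation_rad=fa.orientation_rad,
                            major_um=fa.major_um,
                            minor_um=fa.minor_um,
                        )
                    ],
                )
            )
            active.append(tracks[-1])
        active = [tr for tr in active if t - tr.points[-1].frame <= 1]
    return tracks


def _point_mask(point: TrackPoint, shape, pixel_size_um: float) -> np.ndarray:
    """Elliptical footprint of a track point, from its recorded geometry."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = point.centroid_xy_um
    cr, ccol = cy / pixel_size_um, cx / pixel_size_um
    th = point.orientation_rad
    dr = rr - cr
    dc = cc - ccol
    u = -dr * np.sin(th) + dc * np.cos(th)
    v = dr * np.cos(th) + dc * np.sin(th)
    a = max(point.major_um / 2 / pixel_size_um, 0.5)
    b = max(point.minor_um / 2 / pixel_size_um, 0.5)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def subtract_movie_background(movie: Movie, radius_px: float = 50.0) -> Movie:
    """Rolling-ball background subtraction, per channel per frame."""
    channels = {}
    for name, stack in movie.channels.items():
        out = np.empty_like(stack)
        for t in range(stack.shape[0]):
            out[t] = stack[t] - rolling_ball_background(stack[t], radius_px)
        channels[name] = out
    return Movie(channels, movie.pixel_size_um, movie.frame_interval_s)


def compute_ratio_series(
    movie: Movie,
    track: FATrack,
    label_stack: np.ndarray | None = None,
    numerator: str = "num",
    denominator: str = "den",
) -> RatioSeries:
    """Per-frame FA ratio: summed numerator over summed denominator intensity
    within the FA footprint, boxcar-smoothed (-/+1 time point).

    The footprint is taken from ``label_stack`` (a (t, y, x) label raster
    matching the track's per-frame labels) where available, else from the
    track point's elliptical geometry (always for interpolated gap frames).
    Frames whose denominator sum is zero are undefined (NaN).  Channels are
    assumed background-subtracted (see :func:`subtract_movie_background`).
    """
    num = movie.channels[numerator]
    den = movie.channels[denominator]
    times = []
    raw = []
    for p in track.points:
        if label_stack is not None and p.label is not None:
            mask = label_stack[p.frame] == p.label
        else:
            mask = _point_mask(p, num.shape[1:], movie.pixel_size_um)
        dsum = float(den[p.frame][mask].sum())
        nsum = float(num[p.frame][mask].sum())
        times.append(p.frame * movie.frame_interval_s)
        raw.append(nsum / dsum if dsum > 0 else np.nan)
    raw_arr = np.array(raw)
    return RatioSeries(
        track_id=track.track_id,
        times_s=np.array(times),
        raw_ratio=raw_arr,
        smoothed_ratio=boxcar_smooth(raw_arr),
    )


def boxcar_smooth(series) -> np.ndarray:
    """Boxcar average over {i-1, i, i+1}, window shrinking at the edges.

    NaN entries stay NaN and are excluded from their neighbours' windows.
    """
    x = np.asarray(series, dtype=float)
    out = np.full_like(x, np.nan)
    for i in range(x.size):
        if np.isnan(x[i]):
            continue
        window = x[max(i - 1, 0) : i + 2]
        out[i] = np.nanmean(window)
    return out


def register_fa_patch(
    movie: Movie,
    track: FATrack,
    cell_centroid_rc: tuple[float, float],
    numerator: str = "num",
    denominator: str = "den",
    margin_px: int = 3,
    min_aspect: float = 1.2,
):
    """Isolate, vertically align and register one FA across frames.

    Each frame is resampled on a patch grid centred on the FA centroid with
    the major axis vertical and the distal end (the axis endpoint farther
    from the cell centroid) at the top.  Near-circular frames
    (aspect < ``min_aspect``) reuse the previous frame's axis; a
    near-circular first frame is an error since the axis would be undefined.

    Returns ``(ratio_patches, den_patches)``: (t, h, w) stacks of the
    per-pixel ratio (NaN where the denominator vanishes) and of the sampled
    denominator (for footprint detection).
    """
    px = movie.pixel_size_um
    num = movie.channels[numerator]
    den = movie.channels[denominator]
    half = int(np.ceil(max(p.major_um for p in track.points) / 2 / px)) + margin_px
    size = 2 * half + 1
    ratio_patches = np.full((track.n_frames, size, size), np.nan)
    den_patches = np.zeros((track.n_frames, size, size))
    prev_u = None
    for k, p in enumerate(track.points):
        center = np.array([p.centroid_xy_um[1] / px, p.centroid_xy_um[0] / px])
        aspect = p.major_um / p.minor_um
        if aspect < min_aspect and prev_u is None:
            raise ValueError(
                "near-circular FA in first frame: major axis undefined"
            )
        if aspect >= min_aspect or prev_u is None:
            th = p.orientation_rad
            u = np.array([-np.sin(th), np.cos(th)])  # along major axis (row, col)
            tip_a = center + u * (p.major_um / 2 / px)
            tip_b = center - u * (p.major_um / 2 / px)
            if np.hypot(*(tip_b - cell_centroid_rc)) > np.hypot(
                *(tip_a - cell_centroid_rc)
            ):
                u = -u  # point u toward the distal end
            if prev_u is not None and np.dot(u, prev_u) < 0:
                u = -u  # keep axis direction continuous along the track
            prev_u = u
        u = prev_u
        w = np.array([u[1], -u[0]])
        ii, jj = np.mgrid[0:size, 0:size]
        offs_up = half - ii  # patch rows count downward; distal is up
        offs_right = jj - half
        src_r = center[0] + offs_up * u[0] + offs_right * w[0]
        src_c = center[1] + offs_up * u[1] + offs_right * w[1]
        coords = np.stack([src_r, src_c])
        n = ndimage.map_coordinates(num[p.frame], coords, order=1, cval=0.0)
        d = ndimage.map_coordinates(den[p.frame], coords, order=1, cval=0.0)
        den_patches[k] = d
        defined = d > 1e-9
        ratio_patches[k][defined] = n[defined] / d[defined]
    return ratio_patches, den_patches


def build_kymograph(
    ratio_patches: np.ndarray,
    den_patches: np.ndarray,
    times_s: np.ndarray,
    track_id: int = 0,
    line_width_px: int = 3,
    n_positions: int = 25,
    footprint_fraction: float = 0.2,
) -> Kymograph:
    """Linescan kymograph along the registered FA axis.

    Per frame, the FA extent is the run of rows whose central-line
    denominator exceeds ``footprint_fraction`` of that frame's maximum; the
    ratio is averaged across ``line_width_px`` central columns and resampled
    at ``n_positions`` normalized positions (0 = medial end, 1 = distal end).
    """
    if ratio_patches.shape[0] < 2:
        raise ValueError("need at least 2 aligned frames")
    nt, h, width = ratio_patches.shape
    c = width // 2
    w0 = max(c - line_width_px // 2, 0)
    w1 = min(c + line_width_px // 2 + 1, width)
    positions = np.linspace(0.0, 1.0, n_positions)
    matrix = np.full((n_positions, nt), np.nan)
    for t in range(nt):
        line_den = den_patches[t, :, w0:w1].mean(axis=1)
        thr = footprint_fraction * line_den.max()
        rows = np.flatnonzero(line_den > thr)
        if rows.size < 2:
            continue
        top, bottom = rows.min(), rows.max()  # top = distal end
        band = ratio_patches[t, :, w0:w1]
        counts = (~np.isnan(band)).sum(axis=1)
        sums = np.nansum(np.where(np.isnan(band), 0.0, band), axis=1)
        line_ratio = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        # position 0 (medial) at the bottom row, 1 (distal) at the top row
        sample_rows = bottom - positions * (bottom - top)
        matrix[:, t] = np.interp(sample_rows, np.arange(h), line_ratio)
    return Kymograph(
        track_id=track_id, positions=positions, times_s=np.asarray(times_s),
        matrix=matrix,
    )


def score_peak_location(kym: Kymograph) -> str:
    """Locate the global ratio maximum and map its axis position to a third:
    [0, 1/3) medial, [1/3, 2/3) central, [2/3, 1] distal.

    Ties across cells at the global maximum are broken by earliest time, then
    by larger (more distal) position; a tie spanning different thirds is
    logged.
    """
    m = kym.matrix
    if m.size == 0 or np.all(np.isnan(m)):
        raise ValueError("empty kymograph")
    peak = np.nanmax(m)
    tied = np.argwhere(m == peak)  # (position_idx, time_idx)
    thirds = {
        _third(kym.positions[i]) for i, _ in tied
    }
    if len(thirds) > 1:
        logger.info("kymograph %d: global-max tie across thirds %s", kym.track_id,
                    sorted(thirds))
    t_min = tied[:, 1].min()
    at_t = tied[tied[:, 1] == t_min]
    pos_idx = at_t[:, 0].max()
    return _third(kym.positions[pos_idx])


def _third(position: float) -> str:
    if position < 1.0 / 3.0:
        return "medial"
    if position < 2.0 / 3.0:
        return "central"
    return "distal"


def classify_rate(rate_um_per_min: float) -> str:
    if rate_um_per_min > GROWTH_RATE_THRESHOLD_UM_PER_MIN:
        return "Growing"
    if rate_um_per_min < -GROWTH_RATE_THRESHOLD_UM_PER_MIN:
        return "Shrinking"
    return "Stable"


def classify_growth_series(
    times_min: np.ndarray, lengths_um: np.ndarray, track_id: int = 0
) -> GrowthState:
    """Classify growth behaviour from a length time series.

    The length-change rate is the least-squares slope over a sliding 5-min
    window stepped one sample at a time; each window is Growing / Stable /
    Shrinking by the +/-0.02 um/min thresholds, and maximal runs of
    same-class windows become segments (so every segment spans >= 5 min, and
    a track transitioning between behaviours contributes one segment per
    behaviour).  Tracks shorter than 5 min yield no segments.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(lengths_um, dtype=float)
    ok = ~np.isnan(y)
    t, y = t[ok], y[ok]
    if t.size < 3 or t[-1] - t[0] < MIN_SEGMENT_MIN:
        return GrowthState(track_id=track_id, segments=())
    window_class: list[tuple[float, float, str]] = []
    for i in range(t.size):
        j = int(np.searchsorted(t, t[i] + MIN_SEGMENT_MIN))
        if j >= t.size and t[-1] - t[i] < MIN_SEGMENT_MIN - 1e-9:
            break
        j = min(j, t.size - 1)
        slope = stats.linregress(t[i : j + 1], y[i : j + 1]).slope
        window_class.append((t[i], t[j], classify_rate(slope)))
    segments = []
    run_start = 0
    for k in range(1, len(window_class) + 1):
        if k == len(window_class) or window_class[k][2] != window_class[run_start][2]:
            t0 = window_class[run_start][0]
            t1 = window_class[k - 1][1]
            sel = (t >= t0) & (t <= t1)
            rate = stats.linregress(t[sel], y[sel]).slope
            segments.append(
                GrowthSegment(
                    t_start_min=t0,
                    t_end_min=t1,
                    rate_um_per_min=float(rate),
                    state=window_class[run_start][2],
                )
            )
            run_start = k
    return GrowthState(track_id=track_id, segments=tuple(segments))


def classify_growth(track: FATrack, frame_interval_s: float) -> GrowthState:
    times_min = np.array([p.frame for p in track.points]) * frame_interval_s / 60.0
    return classify_growth_series(times_min, track.lengths_um(), track.track_id)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level activity-vs-dynamics summary.

    ``segments``: one row per growth segment with its state, rate and the
    min/mean/max smoothed ratio within the segment.  ``anova``: per statistic
    the one-way ANOVA F and p across states.  ``tukey``: per statistic the
    Tukey-HSD pairwise table.  ``correlations``: per (state, statistic) OLS
    of statistic versus |rate| with slope, r^2 and two-sided p.
    """

    segments: pd.DataFrame
    anova: dict
    tukey: dict
    correlations: pd.DataFrame


RATIO_STATS = ("min", "mean", "max")


def summarize_activity_by_state(
    series_and_states: list[tuple[RatioSeries, GrowthState]],
) -> CohortSummary:
    """Summarise ratio statistics per growth state across a cohort and test
    state differences (one-way ANOVA + Tukey HSD) and per-state correlation
    of each statistic with growth-rate magnitude (OLS r^2, two-sided p)."""
    rows = []
    for rs, gs in series_and_states:
        t_min = rs.times_s / 60.0
        for seg in gs.segments:
            sel = (t_min >= seg.t_start_min - 1e-9) & (t_min <= seg.t_end_min + 1e-9)
            vals = rs.smoothed_ratio[sel]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            rows.append(
                {
                    "track_id": rs.track_id,
                    "state": seg.state,
                    "rate_um_per_min": seg.rate_um_per_min,
                    "abs_rate": abs(seg.rate_um_per_min),
                    "min": float(vals.min()),
                    "mean": float(vals.mean()),
                    "max": float(vals.max()),
                }
            )
    segments = pd.DataFrame(rows)
    anova: dict = {}
    tukey: dict = {}
    correlations = []
    if not segments.empty:
        states = sorted(segments["state"].unique())
        for stat in RATIO_STATS:
            groups = [
                segments.loc[segments["state"] == s, stat].to_numpy() for s in states
            ]
            if len(groups) >= 2 and all(g.size >= 2 for g in groups):
                if np.ptp(np.concatenate(groups)) == 0:
                    anova[stat] = (0.0, 1.0)  # identical ratios: no state effect
                else:
                    f, p = stats.f_oneway(*groups)
                    anova[stat] = (float(f), float(p))
                if np.ptp(np.concatenate(groups)) == 0:
                    tukey[stat] = None  # post-hoc undefined at zero variance
                else:
                    from statsmodels.stats.multicomp import pairwise_tukeyhsd

                    tukey[stat] = pairwise_tukeyhsd(
                        segments[stat].to_numpy(), segments["state"].to_numpy()
                    )
            for s in states:
                sub = segments[segments["state"] == s]
                if len(sub) < 3:
                    continue
                res = stats.linregress(sub["abs_rate"], sub[stat])
                correlations.append(
                    {
                        "state": s,
                        "stat": stat,
                        "slope": float(res.slope),
                        "r_squared": float(res.rvalue**2),
                        "p_value": float(res.pvalue),
                        "n": len(sub),
                    }
                )
    return CohortSummary(
        segments=segments,
        anova=anova,
        tukey=tukey,
        correlations=pd.DataFrame(correlations),
    )
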