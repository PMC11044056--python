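"""Parameter-recovery benchmarks against synthetic ground truth.

Each function plants known structure with the generators in
:mod:`adhesio.synthetic`, runs the corresponding analysis stage, and returns
recovery metrics (recall, error, accuracy, scored fractions).  They are the
package's end-to-end validation surface: the test suite asserts on their
outputs and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
from scipy import stats

from . import biosensor as bsn
from . import colocalization as coloc
from . import morphometrics as morpho
from . import screen as scr
from . import synthetic as syn

# -- segmentation ---------------------------------------------------------


def match_fas(truth, found, max_dist_um: float = 1.0):
    """Greedy one-to-one matching of planted and segmented FAs by centroid."""
    pairs = []
    for ti, t in enumerate(truth):
        for fi, f in enumerate(found):
            d = np.hypot(
                f.centroid_xy_um[0] - t.centroid_xy_um[0],
                f.centroid_xy_um[1] - t.centroid_xy_um[1],
            )
            if d <= max_dist_um:
                pairs.append((d, ti, fi))
    pairs.sort()
    used_t, used_f, matches = set(), set(), []
    for d, ti, fi in pairs:
        if ti in used_t or fi in used_f:
            continue
        used_t.add(ti)
        used_f.add(fi)
        matches.append((truth[ti], found[fi]))
    return matches


def segmentation_recovery(
    n_scenes: int = 50,
    n_fas: int = 8,
    image_size: int = 192,
    seed: int = 0,
) -> dict:
    """Segment a sweep of synthetic scenes at the default noise spec and score
    FA recall, the median relative area error of matched FAs, and the maximum
    absolute r_rel error against the planted circular-cell geometry."""
    n_matched = n_true = 0
    area_errors: list[float] = []
    r_rel_errors: list[float] = []
    for i in range(n_scenes):
        spec = syn.random_scene_spec(
            n_fas=n_fas, image_size_px=(image_size, image_size), seed=seed + i
        )
        channels, truth = syn.generate_cell_image(spec)
        cell_mask = morpho.cell_mask_from_image(channels["cell"])
        _, fas = morpho.segment_fas(
            channels["fa"], morpho.SegmentationParams(), cell_mask=cell_mask
        )
        matches = match_fas(truth, fas)
        n_matched += len(matches)
        n_true += len(truth)
        for t, f in matches:
            area_errors.append(abs(f.area_um2 - t.area_um2) / t.area_um2)
            r_rel_errors.append(abs(f.r_rel - t.r_rel))
    return {
        "recall": n_matched / n_true,
        "median_area_error": float(np.median(area_errors)),
        "max_r_rel_error": float(np.max(r_rel_errors)),
        "n_fas": n_true,
    }


# -- KS oracle ------------------------------------------------------------


def brute_force_ks(sample1, sample2) -> float:
    """ECDF sup-difference by direct evaluation at every observed value."""
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    grid = np.unique(np.concatenate([s1, s2]))
    d = 0.0
    for x in grid:
        d = max(d, abs((s1 <= x).mean() - (s2 <= x).mean()))
    return d


def ks_oracle_deviation(max_size: int = 5, alphabet=(0.0, 1.0, 2.0)) -> dict:
    """Exhaustively compare ks_compare with the brute-force ECDF scan over all
    multiset pairs up to ``max_size`` from a small value alphabet."""
    multisets = [
        list(m)
        for n in range(1, max_size + 1)
        for m in combinations_with_replacement(alphabet, n)
    ]
    worst = 0.0
    n_pairs = 0
    for a in multisets:
        for b in multisets:
            n_pairs += 1
            d = morpho.ks_compare(a, b).ks_distance
            worst = max(worst, abs(d - brute_force_ks(a, b)))
    return {"max_abs_deviation": worst, "n_pairs": n_pairs}


# -- colocalization oracles ----------------------------------------------


def _naive_pearson(A, B):
    n = A.size
    ma = sum(A.ravel()) / n
    mb = sum(B.ravel()) / n
    num = va = vb = 0.0
    for a, b in zip(A.ravel(), B.ravel()):
        num += (a - ma) * (b - mb)
        va += (a - ma) ** 2
        vb += (b - mb) ** 2
    return num / np.sqrt(va * vb)


def _naive_icq(A, B):
    n = A.size
    ma = sum(A.ravel()) / n
    mb = sum(B.ravel()) / n
    pos = sum(1 for a, b in zip(A.ravel(), B.ravel()) if (a - ma) * (b - mb) > 0)
    return pos / n - 0.5


def _naive_manders(A, B, thrA, thrB):
    in_a = in_b = both = 0
    for a, b in zip(A.ravel(), B.ravel()):
        in_a += a > thrA
        in_b += b > thrB
        both += (a > thrA) and (b > thrB)
    return both / in_a, both / in_b


def coloc_oracle_deviation(n_rasters: int = 20, seed: int = 0) -> dict:
    """Compare the vectorised statistics with naive double-loop references on
    random 16x16 rasters; report the worst absolute deviation (exactness up to
    float associativity)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_rasters):
        A = rng.random((16, 16)) * 100
        B = rng.random((16, 16)) * 100
        thrA, thrB = float(np.median(A)), float(np.median(B))
        worst = max(worst, abs(coloc.pearson_cc(A, B) - _naive_pearson(A, B)))
        worst = max(worst, abs(coloc.li_icq(A, B) - _naive_icq(A, B)))
        m1, m2 = coloc.manders_overlap(A, B, thrA, thrB)
        nm1, nm2 = _naive_manders(A, B, thrA, thrB)
        worst = max(worst, abs(m1 - nm1), abs(m2 - nm2))
    return {"max_abs_deviation": worst, "n_rasters": n_rasters}


def coloc_range_violations(n_rasters: int = 200, seed: int = 0) -> dict:
    """Check the range and symmetry invariants on random rasters."""
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_rasters):
        A = rng.random((12, 12)) * rng.uniform(1, 1000)
        B = rng.random((12, 12)) * rng.uniform(1, 1000)
        cc = coloc.pearson_cc(A, B)
        icq = coloc.li_icq(A, B)
        m1, m2 = coloc.manders_overlap(A, B, float(np.median(A)), float(np.median(B)))
        if not (-1 <= cc <= 1 and -0.5 <= icq <= 0.5 and 0 <= m1 <= 1 and 0 <= m2 <= 1):
            violations += 1
        if abs(cc - coloc.pearson_cc(B, A)) > 1e-12:
            violations += 1
    return {"violations": violations, "n_rasters": n_rasters}


# -- growth classification ------------------------------------------------


def dominant_state(gs: bsn.GrowthState) -> str | None:
    if not gs.segments:
        return None
    seg = max(gs.segments, key=lambda s: s.t_end_min - s.t_start_min)
    return seg.state


def growth_classifier_accuracy(
    n_trajectories: int = 300,
    noise_sigma_um: float = 0.05,
    seed: int = 0,
) -> dict:
    """Classify simulated length trajectories and score agreement with the
    planted rate class, noise-free and at the given length noise."""
    rng = np.random.default_rng(seed)
    rates = rng.uniform(-0.06, 0.06, size=n_trajectories)
    agree_clean = agree_noisy = 0
    for i, rate in enumerate(rates):
        sub = int(rng.integers(2**31))
        t, l_clean, truth = syn.generate_length_trajectory(
            float(rate), duration_min=10.0, dt_min=1 / 3, noise_sigma_um=0.0, seed=sub
        )
        agree_clean += dominant_state(bsn.classify_growth_series(t, l_clean)) == truth
        t, l_noisy, _ = syn.generate_length_trajectory(
            float(rate), duration_min=10.0, dt_min=1 / 3,
            noise_sigma_um=noise_sigma_um, seed=sub,
        )
        agree_noisy += dominant_state(bsn.classify_growth_series(t, l_noisy)) == truth
    return {
        "accuracy_noise_free": agree_clean / n_trajectories,
        "accuracy_noisy": agree_noisy / n_trajectories,
        "n": n_trajectories,
    }


# -- biosensor cohorts ----------------------------------------------------


def _single_fa_movie_spec(pattern: str, seed: int, n_frames: int = 8) -> syn.MovieSpec:
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(0, 2 * np.pi))
    scene = syn.SceneSpec(
        image_size_px=(96, 96),
        pixel_size_um=0.16,
        cell_radius_um=6.5,
        fa_specs=(
            syn.FaSpec(
                r_rel=float(rng.uniform(0.5, 0.7)),
                angle_rad=angle,
                major_um=float(rng.uniform(2.0, 3.0)),
                minor_um=float(rng.uniform(0.7, 1.0)),
                orientation_rad=float(
                    (angle + rng.normal(0, 0.15) + np.pi / 2) % np.pi - np.pi / 2
                ),
                intensity=100.0,
            ),
        ),
        background_level=10.0,
        noise_sigma=2.0,
        psf_sigma_px=1.0,
        seed=seed,
    )
    return syn.MovieSpec(
        scene=scene, n_frames=n_frames, frame_interval_s=3.0,
        activity_patterns=(pattern,),
    )


def score_single_fa_movie(mspec: syn.MovieSpec) -> str | None:
    """Run the full biosensor chain on a one-FA movie and return the scored
    peak third (None if no usable track/kymograph)."""
    movie, _ = syn.generate_ratio_movie(mspec)
    movie = bsn.subtract_movie_background(movie)
    params = morpho.SegmentationParams()
    frame_fas, label_frames = [], []
    for t in range(movie.n_frames):
        labels, fas = morpho.segment_fas(movie.frame("den", t), params)
        frame_fas.append(fas)
        label_frames.append(labels)
    tracks = bsn.track_fas(frame_fas)
    if not tracks:
        return None
    track = max(tracks, key=lambda tr: tr.n_frames)
    if track.n_frames < 2:
        return None
    rs = bsn.compute_ratio_series(movie, track, np.stack(label_frames))
    try:
        patches, dens = bsn.register_fa_patch(
            movie, track, mspec.scene.cell_center_px
        )
        kym = bsn.build_kymograph(patches, dens, rs.times_s, track.track_id)
        return bsn.score_peak_location(kym)
    except ValueError:
        return None


def distal_cohort_recovery(
    n_fa: int = 300, frac_distal: float = 0.6, seed: int = 0
) -> dict:
    """Image a cohort of single-FA movies with a planted mixture of hot-spot
    locations (the remainder split between central and medial) and score the
    recovered distal fraction."""
    rng = np.random.default_rng(seed)
    n_distal = int(round(frac_distal * n_fa))
    rest = n_fa - n_distal
    patterns = (
        ["distal_hotspot"] * n_distal
        + ["central_hotspot"] * (rest // 2)
        + ["medial_hotspot"] * (rest - rest // 2)
    )
    counts = {"distal": 0, "central": 0, "medial": 0}
    n_scored = 0
    for i, pattern in enumerate(patterns):
        third = score_single_fa_movie(
            _single_fa_movie_spec(pattern, seed=int(rng.integers(2**31)))
        )
        if third is not None:
            counts[third] += 1
            n_scored += 1
    return {
        "planted_distal_fraction": n_distal / n_fa,
        "scored_distal_fraction": counts["distal"] / max(n_scored, 1),
        "counts": counts,
        "n_scored": n_scored,
    }


def inhibitor_step_recovery(ratio_drop: float = 0.5, seed: int = 0) -> dict:
    """Plant a reversible inhibitor step and recover the activity drop from
    the per-FA raw ratio series (during-step mean over pre-step mean)."""
    scene = syn.SceneSpec(
        image_size_px=(96, 96),
        pixel_size_um=0.16,
        cell_radius_um=6.5,
        fa_specs=(syn.FaSpec(0.6, 0.7, 2.5, 0.9, 0.7, 100.0),),
        background_level=10.0,
        noise_sigma=2.0,
        psf_sigma_px=1.0,
        seed=seed,
    )
    on, off = 8, 16
    mspec = syn.MovieSpec(
        scene=scene, n_frames=20, frame_interval_s=20.0,
        inhibitor_step=(on, off, ratio_drop),
    )
    movie, _ = syn.generate_ratio_movie(mspec)
    movie = bsn.subtract_movie_background(movie)
    params = morpho.SegmentationParams()
    frame_fas, label_frames = [], []
    for t in range(movie.n_frames):
        labels, fas = morpho.segment_fas(movie.frame("den", t), params)
        frame_fas.append(fas)
        label_frames.append(labels)
    track = max(bsn.track_fas(frame_fas), key=lambda tr: tr.n_frames)
    rs = bsn.compute_ratio_series(movie, track, np.stack(label_frames))
    in_step = (rs.times_s >= on * movie.frame_interval_s) & (
        rs.times_s < off * movie.frame_interval_s
    )
    pre = (rs.times_s < on * movie.frame_interval_s)
    measured = float(np.nanmean(rs.raw_ratio[in_step]) / np.nanmean(rs.raw_ratio[pre]))
    return {
        "planted_ratio_factor": 1.0 - ratio_drop,
        "measured_ratio_factor": measured,
    }


def _synthetic_cohort_series(
    n_per_state=(30, 30, 25),
    stable_offset: float = 0.2,
    max_ratio_rate_slope: float = 0.0,
    seed: int = 0,
):
    """Build (RatioSeries, GrowthState) pairs with planted state structure:
    growing / stable / shrinking groups sized per the cohort design, an
    optional ratio offset for stable FAs, and an optional linear dependence of
    ratio on growth-rate magnitude in growing FAs."""
    rng = np.random.default_rng(seed)
    pairs = []
    rate_ranges = {"Growing": (0.03, 0.08), "Stable": (-0.015, 0.015),
                   "Shrinking": (-0.08, -0.03)}
    track_id = 0
    for state, n in zip(("Growing", "Stable", "Shrinking"), n_per_state):
        for _ in range(n):
            rate = float(rng.uniform(*rate_ranges[state]))
            t_min, lengths, _ = syn.generate_length_trajectory(
                rate, duration_min=10.0, dt_min=1 / 3, noise_sigma_um=0.02,
                seed=int(rng.integers(2**31)),
            )
            base = 1.0 + 0.05 * rng.standard_normal()
            if state == "Stable":
                base += stable_offset
            if state == "Growing":
                base += max_ratio_rate_slope * abs(rate)
            raw = base + 0.03 * rng.standard_normal(t_min.size)
            rs = bsn.RatioSeries(
                track_id=track_id, times_s=t_min * 60.0, raw_ratio=raw,
                smoothed_ratio=bsn.boxcar_smooth(raw),
            )
            gs = bsn.classify_growth_series(t_min, lengths, track_id)
            pairs.append((rs, gs))
            track_id += 1
    return pairs


def state_offset_detection(
    stable_offset: float = 0.2, n_per_state=(30, 30, 25), seed: int = 0
) -> dict:
    """Plant a ratio offset in stable FAs and test whether the cohort summary
    detects the state difference (ANOVA p for the mean ratio) with the stable
    mean exceeding the growing and shrinking means."""
    pairs = _synthetic_cohort_series(
        n_per_state=n_per_state, stable_offset=stable_offset, seed=seed
    )
    summary = bsn.summarize_activity_by_state(pairs)
    means = summary.segments.groupby("state")["mean"].mean()
    stable = means.get("Stable", -np.inf)
    return {
        "anova_p_mean": summary.anova["mean"][1],
        "stable_exceeds_others": bool(
            stable > means.get("Growing", -np.inf)
            and stable > means.get("Shrinking", -np.inf)
        ),
        "group_means": means.to_dict(),
    }


def ratio_rate_correlation_recovery(slope: float = 5.0, seed: int = 0) -> dict:
    """Plant a linear dependence of ratio on growth-rate magnitude in growing
    FAs and recover the OLS slope sign and r^2 for the max ratio."""
    pairs = _synthetic_cohort_series(
        n_per_state=(30, 30, 25), stable_offset=0.0,
        max_ratio_rate_slope=slope, seed=seed,
    )
    summary = bsn.summarize_activity_by_state(pairs)
    corr = summary.correlations
    row = corr[(corr["state"] == "Growing") & (corr["stat"] == "mean")]
    if row.empty:
        return {"slope": np.nan, "r_squared": np.nan, "p_value": np.nan}
    return {
        "slope": float(row["slope"].iloc[0]),
        "r_squared": float(row["r_squared"].iloc[0]),
        "p_value": float(row["p_value"].iloc[0]),
    }


# -- substrate screen -----------------------------------------------------


def screen_recovery(
    n_proteins: int = 1000,
    n_planted_hits: int = 50,
    planted_fold: float = 8.0,
    noise_sigma: float = 0.3,
    threshold: float = 6.0,
    min_trials: int = 2,
    seed: int = 0,
) -> dict:
    """Plant enriched substrates in a quantitation table and score hit-calling
    recall and false-discovery proportion."""
    spec = syn.QuantTableSpec(
        n_proteins=n_proteins,
        n_planted_hits=n_planted_hits,
        planted_fold=planted_fold,
        lognormal_noise_sigma=noise_sigma,
        control_enriched_fraction=0.05,
        seed=seed,
    )
    table, hits, _ = syn.generate_quant_table(spec)
    enrich = scr.compute_enrichment(scr.filter_control_enriched(table))
    found = set(scr.call_hits(enrich, threshold, min_trials).accessions)
    recall = len(found & hits) / len(hits) if hits else 1.0
    fdp = len(found - hits) / len(found) if found else 0.0
    return {"recall": recall, "fdp": fdp, "n_hits_called": len(found)}


def hit_list_nesting(seed: int = 0) -> dict:
    """On a random noisy table, check that the >=6.0-fold hit set nests inside
    the >=1.5-fold set and that raising threshold/min_trials never adds hits."""
    table, _, _ = syn.generate_quant_table(
        syn.QuantTableSpec(
            n_proteins=400, n_planted_hits=40, planted_fold=4.0,
            lognormal_noise_sigma=0.6, missingness_rate=0.1, seed=seed,
        )
    )
    enrich = scr.compute_enrichment(scr.filter_control_enriched(table))
    low = set(scr.call_hits(enrich, 1.5, 2).accessions)
    high = set(scr.call_hits(enrich, 6.0, 2).accessions)
    strict_trials = set(scr.call_hits(enrich, 1.5, 3).accessions)
    return {
        "nested": high <= low,
        "monotone_in_threshold": high <= low,
        "monotone_in_min_trials": strict_trials <= low,
        "n_low": len(low),
        "n_high": len(high),
    }
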