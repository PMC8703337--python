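"""Reusable parameter-recovery experiments on synthetic scenes.

Each function here runs one self-contained study at desk scale —
segmentation recovery, end-to-end spectral conservation, the three-way
classifier comparison, band-importance recovery — and returns plain
dictionaries of measured quantities. They are the basis of both the
acceptance checks and the worked examples in the documentation.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from . import classify
from .calibration import calibrate, trim_bands
from .classify import (
    DatasetSplit,
    confusion_metrics,
    extract_subcubes,
    split_dataset,
    train_eval_seed_svm,
    train_pixel_svm,
    vote_seed_labels,
)
from .cnn import CNN3DClassifier, CNN3DConfig
from .extraction import mean_spectra
from .importance import rank_band_importance
from .segmentation import SegmentationParams, segment_scene
from .synthetic import (
    SceneSpec,
    default_wavelengths,
    generate_scene,
    match_seeds,
    planted_signal_curves,
)

logger = logging.getLogger(__name__)

#: Desk-scale segmentation parameters: seeds in the synthetic scenes span
#: roughly 120-400 px, so the minimum-size filter sits well below that.
DESK_SEG_PARAMS = SegmentationParams(min_pixels=50)

#: Matching radius (px) within which a recovered seed counts as the planted one.
MATCH_RADIUS_PX = 3.0


def segmentation_recovery(
    n_scenes: int = 20,
    base_seed: int = 0,
    overlap_fraction: float = 0.2,
    n_overlapping_pairs: int = 2,
) -> dict:
    """Seed-count and centre recovery over seeded scenes with overlaps.

    Each scene plants 12 seeds of which two pairs overlap by about
    ``overlap_fraction`` of the smaller seed; segmentation runs with
    ellipse fitting on. A scene counts as recovered when the seed count
    matches exactly; centre errors are Hungarian-matched distances.
    """
    successes = 0
    all_errors: list[float] = []
    counts = []
    for i in range(n_scenes):
        spec = SceneSpec(
            rng_seed=base_seed + i,
            overlap_fraction=overlap_fraction,
            n_overlapping_pairs=n_overlapping_pairs,
        )
        raw, _, truth = generate_scene(spec)
        mask = segment_scene(raw, replace(DESK_SEG_PARAMS, rng_seed=base_seed + i))
        counts.append(mask.n_seeds)
        if mask.n_seeds == truth.n_seeds:
            successes += 1
        all_errors.extend(d for _, _, d in match_seeds(truth, mask))
    errors = np.array(all_errors)
    return {
        "n_scenes": n_scenes,
        "recovery_rate": successes / n_scenes,
        "seed_counts": counts,
        "mean_center_error_px": float(errors.mean()),
        "max_center_error_px": float(errors.max()),
    }


def spectral_conservation(rng_seed: int = 0) -> dict:
    """Full pipeline on one scene; planted-vs-recovered group mean curves.

    Runs generate -> calibrate -> trim -> segment -> per-group pixel means
    and reports, per band and group, the deviation from the planted curve
    in units of the standard error of the recovered group mean. That SE
    has two independent parts: the pixel-noise scatter (empirical sd over
    the group's pixels / sqrt(n)) and the calibration-reference
    uncertainty, which is shared by every pixel in a sensor column and so
    is invisible to pixel scatter — it is propagated through the
    reflectance formula by the delta method, using the reference cubes'
    own line-to-line variance to estimate the profile standard errors.
    """
    spec = SceneSpec(rng_seed=rng_seed)
    raw, refs, truth = generate_scene(spec)
    cal = calibrate(raw, refs)
    cube, window = trim_bands(cal)
    mask = segment_scene(raw, replace(DESK_SEG_PARAMS, rng_seed=rng_seed))
    matches = [m for m in match_seeds(truth, mask) if m[2] <= MATCH_RADIUS_PX]

    keep = window.retained_indices
    planted = {0: truth.control_curve[keep], 1: truth.hs_curve[keep]}
    # reference-profile standard errors per (column, band), trimmed grid
    n_ref = refs.white.n_lines
    w_prof, d_prof = refs.profiles()
    se_w2 = refs.white.data[:, :, keep].astype(float).var(axis=0, ddof=1) / n_ref
    se_d2 = refs.dark.data[:, :, keep].astype(float).var(axis=0, ddof=1) / n_ref
    span = (w_prof - d_prof)[:, keep]

    max_abs_z = 0.0
    max_abs_dev = 0.0
    n_beyond_3se = 0
    n_comparisons = 0
    for g in (0, 1):
        seed_ids = [rec for t, rec, _ in matches if truth.group_labels[t - 1] == g]
        px = np.concatenate([np.column_stack(mask.pixels(k)) for k in seed_ids])
        vals = cube.data[px[:, 0], px[:, 1], :]
        n = vals.shape[0]
        mean = vals.mean(axis=0)
        var_pixel = vals.var(axis=0, ddof=1) / n
        # delta method: dIc/dIw = -R/(Iw-Id), dIc/dId = (R-1)/(Iw-Id);
        # reference errors are shared within a column, independent across columns
        cols, col_counts = np.unique(px[:, 1], return_counts=True)
        w_frac = (col_counts / n) ** 2
        var_ref = np.zeros(keep.size)
        r = mean  # reflectance level entering the sensitivities
        for c, w2 in zip(cols, w_frac):
            var_ref += w2 * (r**2 * se_w2[c] + (1 - r) ** 2 * se_d2[c]) / span[c] ** 2
        se = np.sqrt(var_pixel + var_ref)
        z = (mean - planted[g]) / se
        max_abs_z = max(max_abs_z, float(np.abs(z).max()))
        max_abs_dev = max(max_abs_dev, float(np.abs(mean - planted[g]).max()))
        n_beyond_3se += int(np.sum(np.abs(z) > 3.0))
        n_comparisons += z.size
    return {
        "n_matched_seeds": len(matches),
        "n_seeds": truth.n_seeds,
        "max_abs_z": max_abs_z,
        "max_abs_deviation": max_abs_dev,
        "n_beyond_3se": n_beyond_3se,
        "n_comparisons": n_comparisons,
        "n_bands": window.n_retained,
    }


def _build_classification_data(
    replicate_seed: int, n_scenes: int = 4
) -> tuple[np.ndarray, np.ndarray, classify.SubCubeSamples, np.ndarray]:
    """Generate scenes, run the pipeline, and pool seeds across scenes.

    Returns (seed mean spectra, seed group labels, pooled pixel samples,
    pixel->seed map) with globally renumbered seeds; recovered seeds take
    the group label of their matched planted seed, unmatched ones are
    dropped.
    """
    spectra_rows, groups = [], []
    patch_list, pixel_seed = [], []
    offset = 0
    for s in range(n_scenes):
        spec = SceneSpec(rng_seed=1000 * replicate_seed + s)
        raw, refs, truth = generate_scene(spec)
        cube, _ = trim_bands(calibrate(raw, refs))
        mask = segment_scene(raw, replace(DESK_SEG_PARAMS, rng_seed=s))
        matches = {rec: t for t, rec, d in match_seeds(truth, mask) if d <= MATCH_RADIUS_PX}
        keep = sorted(matches)
        if not keep:
            continue
        specs = mean_spectra(cube, mask, image_id=f"scene{s}")
        samples = extract_subcubes(cube, mask, patch_size=5)
        # map recovered seed -> global index; drop unmatched seeds' pixels
        local_to_global = {rec: offset + j for j, rec in enumerate(keep)}
        for rec in keep:
            spectra_rows.append(specs[rec - 1].reflectance)
            groups.append(truth.group_labels[matches[rec] - 1])
        sel = np.isin(samples.seed_ids + 1, keep)
        patch_list.append(samples.patches[sel])
        pixel_seed.extend(local_to_global[r + 1] for r in samples.seed_ids[sel])
        offset += len(keep)
    pooled = classify.SubCubeSamples(
        patches=np.concatenate(patch_list),
        centers=np.zeros((len(pixel_seed), 2), dtype=int),
        seed_ids=np.asarray(pixel_seed),
        patch_size=5,
    )
    return np.asarray(spectra_rows), np.asarray(groups), pooled, np.asarray(pixel_seed)


def _seed_accuracy_from_pixels(
    pixel_pred: np.ndarray, split: DatasetSplit, pixel_seed: np.ndarray, groups: np.ndarray
) -> float:
    votes = vote_seed_labels(pixel_pred, pixel_seed[split.pixel_test])
    seeds = np.array(sorted(votes))
    pred = np.array([votes[s] for s in seeds])
    return float(np.mean(pred == groups[seeds]))


def classification_comparison(replicate_seed: int = 0, cnn_epochs: int = 20) -> dict:
    """Train all three classifiers on one replicate of matched synthetic data.

    Returns seed-level accuracy for each model plus pixel-level metrics
    for the pixel models, all on the held-out test seeds.
    """
    spectra, groups, samples, pixel_seed = _build_classification_data(replicate_seed)
    split = split_dataset(groups, pixel_seed, rng_seed=replicate_seed)

    seed_report, _ = train_eval_seed_svm(spectra, groups, split)

    svm_pred = train_pixel_svm(samples, groups, split, rng_seed=replicate_seed)
    pixel_truth = groups[pixel_seed[split.pixel_test]]
    _, svm_pixel_report = confusion_metrics(pixel_truth, svm_pred)
    svm_seed_acc = _seed_accuracy_from_pixels(svm_pred, split, pixel_seed, groups)

    cnn = CNN3DClassifier(CNN3DConfig(rng_seed=replicate_seed, max_epochs=cnn_epochs))
    y = groups[pixel_seed]
    cnn.fit(
        samples.patches[split.pixel_train],
        y[split.pixel_train],
        samples.patches[split.pixel_val],
        y[split.pixel_val],
    )
    cnn_pred = cnn.predict(samples.patches[split.pixel_test])
    _, cnn_pixel_report = confusion_metrics(pixel_truth, cnn_pred)
    cnn_seed_acc = _seed_accuracy_from_pixels(cnn_pred, split, pixel_seed, groups)

    return {
        "n_seeds": int(groups.size),
        "n_test_seeds": int(split.seed_test.size),
        "seed_svm_accuracy": seed_report.accuracy,
        "pixel_svm_seed_accuracy": svm_seed_acc,
        "pixel_svm_pixel_accuracy": svm_pixel_report.accuracy,
        "cnn_seed_accuracy": cnn_seed_acc,
        "cnn_pixel_accuracy": cnn_pixel_report.accuracy,
    }


def importance_recovery(
    n_replicates: int = 10,
    base_seed: int = 0,
    signal_lo_nm: float = 1000.0,
    signal_hi_nm: float = 1600.0,
    top_n: int = 5,
) -> dict:
    """Band-importance recovery with the group signal confined to a window.

    Success in a replicate means every top-``top_n`` ranked wavelength
    falls inside [signal_lo_nm, signal_hi_nm].
    """
    wl = default_wavelengths()
    curves = planted_signal_curves(wl, signal_lo_nm, signal_hi_nm)
    successes = 0
    top_sets = []
    for i in range(n_replicates):
        spec = SceneSpec(rng_seed=base_seed + i, group_curves=curves)
        raw, refs, truth = generate_scene(spec)
        cube, window = trim_bands(calibrate(raw, refs))
        rows, cols = np.nonzero(truth.labels > 0)
        x = cube.data[rows, cols, :]
        y = truth.group_labels[truth.labels[rows, cols] - 1]
        ranking = rank_band_importance(x, y, cube.wavelengths_nm, rng_seed=base_seed + i)
        top = ranking.wavelengths_nm[ranking.rank_order[:top_n]]
        top_sets.append(top)
        if np.all((top >= signal_lo_nm) & (top <= signal_hi_nm)):
            successes += 1
    return {
        "n_replicates": n_replicates,
        "n_success": successes,
        "success_rate": successes / n_replicates,
        "top_wavelengths": [t.tolist() for t in top_sets],
    }


def table_split_bookkeeping(
    n_seeds_per_group: int = 100,
    group_pixel_totals: tuple[int, int] = (137_545, 137_096),
    group_test_pixel_totals: tuple[int, int] = (27_527, 26_865),
    rng_seed: int = 0,
) -> dict:
    """Two-level split bookkeeping at the published dataset scale.

    Plants 100 control + 100 HS seeds carrying the published per-group
    pixel totals (test seeds carry the published test-pixel totals), runs
    the stratified 80/20 seed split and the 95/5 pixel split, and reports
    the resulting partition sizes.
    """
    groups = np.repeat([0, 1], n_seeds_per_group)

    # the seed split does not depend on pixel counts, so resolve it first
    pre = split_dataset(groups, np.arange(groups.size), rng_seed=rng_seed)

    def spread(total: int, n: int) -> np.ndarray:
        base, extra = divmod(total, n)
        return np.full(n, base) + (np.arange(n) < extra)

    pixel_counts = np.zeros(groups.size, dtype=int)
    for g in (0, 1):
        test = np.intersect1d(pre.seed_test, np.nonzero(groups == g)[0])
        rest = np.setdiff1d(np.nonzero(groups == g)[0], test)
        pixel_counts[test] = spread(group_test_pixel_totals[g], test.size)
        pixel_counts[rest] = spread(group_pixel_totals[g] - group_test_pixel_totals[g], rest.size)

    pixel_seed_ids = np.repeat(np.arange(groups.size), pixel_counts)
    split = split_dataset(groups, pixel_seed_ids, rng_seed=rng_seed)
    pixel_groups = groups[pixel_seed_ids]
    return {
        "n_train_seeds": int(split.seed_train.size),
        "n_test_seeds": int(split.seed_test.size),
        "n_train_pixels": int(split.pixel_train.size),
        "n_val_pixels": int(split.pixel_val.size),
        "n_test_pixels": int(split.pixel_test.size),
        "n_train_pixels_control": int(np.sum(pixel_groups[split.pixel_train] == 0)),
        "n_train_pixels_hs": int(np.sum(pixel_groups[split.pixel_train] == 1)),
        "n_total_pixels": int(pixel_seed_ids.size),
    }
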