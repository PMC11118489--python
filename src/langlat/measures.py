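"""Individual-level neural measures: cross-validated response magnitude,
suprathreshold activation volume, laterality indices, and resting-state
inter-regional correlations.

The volume-based laterality index is LI = (LH - RH) / (LH + RH) over counts of
significant Language>Control voxels (one-tailed t threshold); the adaptive
bootstrap LI sweeps a grid of t thresholds, bootstraps the suprathreshold t
mass per hemisphere at each, and aggregates with threshold-proportional
weights, yielding a threshold-independent LI with a percentile confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ParcelAtlas
from .froi import CVFolds, FROISet, define_frois, make_cv_folds, split_run
from .glm import CONDITIONS, build_design, condition_psc, contrast, detect_outliers, fit_glm


@dataclass
class BootstrapConfig:
    """Adaptive-threshold bootstrap LI settings (LI-toolbox-style defaults)."""

    n_thresholds: int = 20
    n_boot: int = 100
    resample_frac: float = 0.25
    trim: float = 0.25  # total trimmed mass (split between tails)
    seed: int = 0


def _fit_runs(runs, run_indices, ar: float, highpass: float):
    subset = [runs[i] for i in run_indices]
    designs = []
    for run in subset:
        nvol = run.data.shape[-1]
        outl = detect_outliers(run) if run.motion_fd_mm is not None else ()
        designs.append(
            build_design(run.events, nvol, run.tr_seconds, highpass_seconds=highpass, outlier_indices=outl)
        )
    return fit_glm(subset, designs, ar_coefficient=ar)


def prepare_runs(runs) -> list:
    """Ensure at least two runs for cross-validation, splitting a single run
    at its temporal midpoint into two pseudo-runs when necessary."""
    if len(runs) == 1:
        return list(split_run(runs[0]))
    return list(runs)


def cv_response_magnitude(
    runs,
    atlas: ParcelAtlas,
    folds: CVFolds | None = None,
    top_fraction: float = 0.10,
    ar: float = 0.2,
    highpass: float = 128.0,
    conditions=CONDITIONS,
) -> pd.DataFrame:
    """Across-runs cross-validated fROI response magnitudes.

    For each fold, fROIs are defined on the define-runs' Language>Control t
    map and each condition's percent-signal-change effect (versus fixation) is
    averaged over those voxels in the held-out estimate runs; fold values are
    then averaged, giving one value per fROI x condition.
    """
    runs = prepare_runs(runs)
    if folds is None:
        folds = make_cv_folds(len(runs))
    rows = []
    for define_idx, estimate_idx in folds:
        fit_def = _fit_runs(runs, define_idx, ar, highpass)
        tmap = contrast(fit_def).tstat
        frois = define_frois(tmap, atlas, top_fraction, fold_id=define_idx)
        fit_est = _fit_runs(runs, estimate_idx, ar, highpass)
        for cond in conditions:
            psc_map = condition_psc(fit_est, cond).ravel()
            for label, vox in frois.voxels.items():
                if len(vox) == 0:
                    raise ValueError(f"empty fROI for parcel {label}")
                rows.append(
                    {
                        "fold": str(define_idx),
                        "froi": atlas.names[label],
                        "label": label,
                        "hemisphere": atlas.hemisphere_of(label),
                        "condition": cond,
                        "psc": float(np.nanmean(psc_map[vox])),
                    }
                )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["froi", "label", "hemisphere", "condition"], as_index=False)["psc"]
        .mean()
        .sort_values(["label", "condition"], ignore_index=True)
    )


def all_runs_contrast(runs, ar: float = 0.2, highpass: float = 128.0):
    """Language>Control contrast map from all runs combined (one GLM)."""
    runs = list(runs)
    fit = _fit_runs(runs, range(len(runs)), ar, highpass)
    return contrast(fit)


def count_supra_voxels(tmap: np.ndarray, atlas: ParcelAtlas, p_threshold: float, dof: int) -> dict[int, int]:
    """Count voxels per parcel exceeding the one-tailed t threshold at
    ``p_threshold`` (uncorrected) with ``dof`` degrees of freedom."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    if dof <= 0:
        raise ValueError("dof must be positive")
    tstar = stats.t.isf(p_threshold, dof)
    tflat = np.asarray(tmap).ravel()
    counts = {}
    for label in atlas.lh_labels + atlas.rh_labels:
        t = tflat[atlas.parcel_voxels(label)]
        counts[label] = int(np.sum(t > tstar))  # NaN never exceeds
    return counts


def volume_li(lh_count, rh_count) -> float:
    """Volume-based laterality index (LH - RH) / (LH + RH).

    Returns NaN (a flagged missing value, not 0) when both counts are zero.
    """
    lh, rh = float(lh_count), float(rh_count)
    if lh < 0 or rh < 0:
        raise ValueError("voxel counts must be non-negative")
    if lh + rh == 0:
        return float("nan")
    return (lh - rh) / (lh + rh)


def hemisphere_counts(counts: dict[int, int], atlas: ParcelAtlas) -> tuple[int, int]:
    lh = sum(counts[k] for k in atlas.lh_labels)
    rh = sum(counts[k] for k in atlas.rh_labels)
    return lh, rh


def magnitude_laterality(records: pd.DataFrame, atlas: ParcelAtlas) -> pd.DataFrame:
    """Per-fROI-pair Language>Control contrast difference LH - RH.

    ``records`` is the long measure table from :func:`cv_response_magnitude`
    (per condition); output has one row per homotopic parcel pair with the
    hemispheric contrast values and their difference.
    """
    contr = (
        records.pivot_table(index=["label", "froi", "hemisphere"], columns="condition", values="psc")
        .reset_index()
    )
    if not {"Language", "Control"} <= set(contr.columns):
        raise ValueError("records must contain both conditions")
    contr["contrast"] = contr["Language"] - contr["Control"]
    rows = []
    for lh_label in atlas.lh_labels:
        rh_label = atlas.homotope(lh_label)
        lh = contr[contr["label"] == lh_label]
        rh = contr[contr["label"] == rh_label]
        if lh.empty or rh.empty:
            raise ValueError(f"missing homotope for parcel {lh_label}")
        rows.append(
            {
                "label": lh_label,
                "froi_pair": atlas.names[lh_label][1:],
                "lh_contrast": float(lh["contrast"].iloc[0]),
                "rh_contrast": float(rh["contrast"].iloc[0]),
                "diff": float(lh["contrast"].iloc[0] - rh["contrast"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)


def _weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(np.interp(q / 100.0 * cw[-1], cw - 0.5 * w, v))


def bootstrap_li(
    tmap: np.ndarray,
    atlas: ParcelAtlas,
    config: BootstrapConfig | None = None,
) -> tuple[float, tuple[float, float]]:
    """Adaptive-threshold bootstrap laterality index with percentile CI.

    Thresholds run from 0 (exclusive weight) to just below the map maximum; at
    each threshold, ``n_boot`` resamples of size ``resample_frac * k`` are
    drawn per hemisphere from the suprathreshold t values inside the language
    parcels, LI is computed from the summed resampled t mass, a trimmed mean
    summarizes each threshold, and the final LI is the threshold-weighted mean
    (weights proportional to the threshold). The CI is the weighted 2.5/97.5
    percentile of the pooled resample distribution. Returns (nan, (nan, nan))
    if no hemisphere has suprathreshold voxels at any threshold.
    """
    config = config or BootstrapConfig()
    rng = np.random.default_rng(config.seed)
    tflat = np.asarray(tmap).ravel()
    lh = np.concatenate([tflat[atlas.parcel_voxels(k)] for k in atlas.lh_labels])
    rh = np.concatenate([tflat[atlas.parcel_voxels(k)] for k in atlas.rh_labels])
    lh = lh[np.isfinite(lh) & (lh > 0)]
    rh = rh[np.isfinite(rh) & (rh > 0)]
    if len(lh) == 0 and len(rh) == 0:
        return float("nan"), (float("nan"), float("nan"))
    tmax = max(lh.max(initial=0.0), rh.max(initial=0.0))
    thresholds = np.linspace(0.0, tmax, config.n_thresholds, endpoint=False)
    per_thr_mean, per_thr_w = [], []
    pooled_li, pooled_w = [], []
    for thr in thresholds:
        lv = lh[lh > thr]
        rv = rh[rh > thr]
        if len(lv) == 0 and len(rv) == 0:
            continue
        sums = []
        for vals in (lv, rv):
            if len(vals) == 0:
                sums.append(np.zeros(config.n_boot))
            else:
                m = max(1, int(round(config.resample_frac * len(vals))))
                draws = rng.choice(vals, size=(config.n_boot, m), replace=True)
                sums.append(draws.sum(axis=1))
        s_l, s_r = sums
        li_b = (s_l - s_r) / (s_l + s_r)
        per_thr_mean.append(stats.trim_mean(li_b, config.trim / 2.0))
        per_thr_w.append(thr)
        pooled_li.append(li_b)
        pooled_w.append(np.full(config.n_boot, thr))
    if not per_thr_mean or sum(per_thr_w) == 0:
        return float("nan"), (float("nan"), float("nan"))
    w = np.asarray(per_thr_w)
    li = float(np.dot(w, per_thr_mean) / w.sum())
    pool = np.concatenate(pooled_li)
    pw = np.concatenate(pooled_w)
    keep = pw > 0
    lo = _weighted_percentile(pool[keep], pw[keep], 2.5)
    hi = _weighted_percentile(pool[keep], pw[keep], 97.5)
    return float(np.clip(li, -1.0, 1.0)), (lo, hi)


def functional_correlations(
    cleaned_rest: np.ndarray,
    froi_set: FROISet,
    atlas: ParcelAtlas,
) -> pd.DataFrame:
    """Fisher-z inter-regional correlation matrix over the 10 fROIs.

    Voxel series are averaged within each fROI; Pearson correlations between
    fROI pairs are Fisher-transformed (z = atanh(r)). Pairs involving a
    constant series are recorded as missing. Returns a symmetric 10x10 frame
    indexed by fROI name with NaN on the diagonal.
    """
    nvol = cleaned_rest.shape[-1]
    flat = cleaned_rest.reshape(-1, nvol)
    labels = atlas.lh_labels + atlas.rh_labels
    series = np.stack([flat[froi_set.voxels[k]].mean(axis=0) for k in labels])
    sds = series.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(series)
    r[sds == 0, :] = np.nan
    r[:, sds == 0] = np.nan
    z = np.arctanh(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12))
    np.fill_diagonal(z, np.nan)
    names = [atlas.names[k] for k in labels]
    return pd.DataFrame(z, index=names, columns=names)


def connectivity_summary(zmat: pd.DataFrame, atlas: ParcelAtlas) -> dict[str, float]:
    """Mean Fisher z over the 10 LH-LH, 10 RH-RH, and 25 inter-hemispheric pairs."""
    n = len(atlas.lh_labels)
    z = zmat.to_numpy()
    iu = np.triu_indices(n, k=1)
    return {
        "lh_mean_z": float(np.nanmean(z[:n, :n][iu])),
        "rh_mean_z": float(np.nanmean(z[n:, n:][iu])),
        "inter_mean_z": float(np.nanmean(z[:n, n:])),
    }
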