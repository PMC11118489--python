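"""Group-constrained subject-specific fROI definition and CV fold construction.

Within each parcel, a subject's fROI is the top 10% of voxels ranked by the
Language>Control t statistic. To keep voxel selection independent of effect
estimation, runs are split into define/estimate folds: with two or more runs,
odd runs define and even runs estimate (and vice versa); a single run is split
at the block boundary nearest its temporal midpoint into two pseudo-runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .synth import LocalizerRun


class SplitError(ValueError):
    """Single run cannot be split into two valid pseudo-runs."""


@dataclass
class FROISet:
    """Selected voxel (flat C-order) indices per parcel label for one fold."""

    voxels: dict[int, np.ndarray]
    top_fraction: float = 0.10
    defining_fold: object = None

    def size(self, label: int) -> int:
        return len(self.voxels[label])


@dataclass
class CVFolds:
    """Disjoint (define_runs, estimate_runs) index pairs covering all runs."""

    folds: list[tuple[tuple[int, ...], tuple[int, ...]]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_cv_folds(n_runs: int) -> CVFolds:
    """Two-fold odd/even split over run indices.

    With >= 2 runs, fold 1 defines on even-indexed runs and estimates on
    odd-indexed runs, fold 2 the reverse. A single run must first be split
    with :func:`split_run` (the resulting two pseudo-runs then use this same
    pairing).
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    if n_runs == 1:
        raise SplitError("single run: split it into pseudo-runs with split_run() first")
    evens = tuple(range(0, n_runs, 2))
    odds = tuple(range(1, n_runs, 2))
    return CVFolds(folds=[(evens, odds), (odds, evens)])


def split_run(run: LocalizerRun) -> tuple[LocalizerRun, LocalizerRun]:
    """Split one run into two pseudo-runs at the block boundary nearest the
    temporal midpoint, shifting second-half onsets to the new origin."""
    events = run.events.sort_values("onset").reset_index(drop=True)
    nvol = run.data.shape[-1]
    tr = run.tr_seconds
    midpoint = nvol * tr / 2.0
    boundaries = events["onset"].to_numpy()[1:]  # cut before block i (i >= 1)
    if len(boundaries) == 0:
        raise SplitError("run has fewer than two blocks")
    cut_time = boundaries[np.argmin(np.abs(boundaries - midpoint))]
    first = events[events["onset"] < cut_time]
    second = events[events["onset"] >= cut_time].copy()
    for half in (first, second):
        counts = half["condition"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise SplitError("each half-run needs >= 2 blocks per condition")
    cut_vol = int(round(cut_time / tr))
    second["onset"] = second["onset"] - cut_vol * tr
    halves = []
    for ev, sl in ((first, slice(0, cut_vol)), (second, slice(cut_vol, nvol))):
        ev = ev.reset_index(drop=True)
        n_half = (sl.stop or nvol) - sl.start
        ev.attrs["tr_seconds"] = tr
        ev.attrs["total_seconds"] = n_half * tr
        halves.append(
            LocalizerRun(
                data=run.data[..., sl],
                tr_seconds=tr,
                events=ev,
                motion_fd_mm=None if run.motion_fd_mm is None else run.motion_fd_mm[sl],
                truth=run.truth,
            )
        )
    return halves[0], halves[1]


def define_frois(
    tmap: np.ndarray,
    atlas: ParcelAtlas,
    top_fraction: float = 0.10,
    fold_id=None,
    labels=None,
) -> FROISet:
    """Select the top ``top_fraction`` of voxels per parcel by t value.

    Voxels are ranked by t descending; the top ceil(fraction * parcel size)
    are selected. Ties at the cut (and anywhere) break by ascending flat voxel
    index; NaN t values rank last. A parcel whose t values are all missing is
    an error.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    tflat = np.asarray(tmap).ravel()
    if tflat.shape[0] != np.prod(atlas.grid_shape):
        raise ValueError("t map does not cover the atlas grid")
    out: dict[int, np.ndarray] = {}
    for label in labels if labels is not None else (atlas.lh_labels + atlas.rh_labels):
        vox = atlas.parcel_voxels(label)
        t = tflat[vox]
        if np.all(np.isnan(t)):
            raise ValueError(f"parcel {label} ({atlas.names.get(label, '?')}) has all-missing t values")
        k = math.ceil(top_fraction * len(vox))
        key = np.where(np.isnan(t), -np.inf, t)
        order = np.lexsort((vox, -key))
        out[label] = np.sort(vox[order[:k]])
    return FROISet(voxels=out, top_fraction=top_fraction, defining_fold=fold_id)
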