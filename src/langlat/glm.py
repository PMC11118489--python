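"""First-level GLM for block-design localizer runs and rest denoising.

Each condition is modelled as a boxcar convolved with the canonical
(double-gamma) HRF and peak-normalized to 1, so that with a baseline of 100
signal units the fitted condition betas read directly in percent signal change.
Temporal autocorrelation is handled by high-pass filtering (discrete-cosine
drift basis, 128 s cutoff) plus prewhitening with a fixed AR(1) model
(coefficient 0.2). Outlier volumes (framewise displacement > 0.9 mm or global
signal change > 5 SD above its mean) enter as indicator regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CONDITIONS = ("Language", "Control")
_UPSAMPLE_DT = 0.1  # s; internal grid for boxcar-HRF convolution


class DesignError(ValueError):
    """Design matrix assembly or rank problem."""


def canonical_hrf(time_grid_seconds: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response on a uniform time grid.

    Response gamma peaks near 5 s (shape 6, scale 1), undershoot near 15 s
    (shape 16, scale 1) with a 1:6 amplitude ratio; the kernel is scaled to
    unit peak and is zero for t < 0.
    """
    t = np.asarray(time_grid_seconds, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if t.size > 1:
        steps = np.diff(t)
        if np.ptp(steps) > 1e-9 * max(1.0, abs(steps[0])):
            raise ValueError("time grid must be uniform")
    h = stats.gamma.pdf(t, a=6, scale=1.0) - stats.gamma.pdf(t, a=16, scale=1.0) / 6.0
    h[t < 0] = 0.0
    peak = h.max()
    if peak <= 0:
        raise ValueError("time grid does not cover the HRF response peak")
    return h / peak


def condition_regressor(events, condition: str, n_volumes: int, tr: float) -> np.ndarray:
    """Boxcar ⊛ HRF regressor for one condition, peak-normalized to 1.

    The boxcar is built on a 0.1 s grid, convolved with the canonical HRF,
    sampled at volume acquisition times t = i * TR, and divided by the peak of
    the convolved response so the regressor's maximum is exactly 1. Returns an
    all-zero vector when the condition has no events.
    """
    dt = _UPSAMPLE_DT
    total = n_volumes * tr
    n_fine = int(np.ceil(total / dt)) + 1
    fine_t = np.arange(n_fine) * dt
    box = np.zeros(n_fine)
    sel = events[events["condition"] == condition]
    for onset, dur in zip(sel["onset"], sel["duration"]):
        box[(fine_t >= onset) & (fine_t < onset + dur)] = 1.0
    if not box.any():
        return np.zeros(n_volumes)
    kernel = canonical_hrf(np.arange(0, 32.0 + dt, dt))
    conv = np.convolve(box, kernel)[:n_fine] * dt
    vol_idx = np.clip(np.round(np.arange(n_volumes) * tr / dt).astype(int), 0, n_fine - 1)
    reg = conv[vol_idx]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg


def dct_drift_basis(n_volumes: int, tr: float, highpass_seconds: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift regressors spanning fluctuations slower than the cutoff.

    The number of columns is floor(2 * T_total / cutoff) with T_total = n * TR,
    i.e. all DCT components whose period exceeds the high-pass cutoff (the
    constant term is excluded; it is a separate design column).
    """
    t_total = n_volumes * tr
    n_basis = int(np.floor(2.0 * t_total / highpass_seconds))
    n_basis = min(n_basis, n_volumes - 1)
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes)) for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    """Named design matrix for one run."""

    matrix: np.ndarray  # volumes x regressors
    names: list[str]
    condition_names: tuple[str, ...]
    tr: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def _rank_check(matrix: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(matrix)
    if rank == matrix.shape[1]:
        return
    # name the offending columns by a greedy rank scan
    bad, kept = [], np.empty((matrix.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, matrix[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(name)
    raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def build_design(
    events,
    n_volumes: int,
    tr: float,
    highpass_seconds: float = 128.0,
    outlier_indices=(),
    include_derivatives: bool = True,
) -> DesignMatrix:
    """Assemble the run design: conditions, derivatives, drift, outliers, constant."""
    if events is not None and len(events):
        run_end = n_volumes * tr
        if (events["onset"] + events["duration"]).max() > run_end + 1e-6:
            raise DesignError("events extend beyond the run duration")
        present = [c for c in CONDITIONS if (events["condition"] == c).any()]
    else:
        present = []
    cols, names = [], []
    for cond in present:
        reg = condition_regressor(events, cond, n_volumes, tr)
        cols.append(reg)
        names.append(cond)
    if include_derivatives:
        for cond in present:
            d = np.gradient(cols[names.index(cond)], tr)
            cols.append(d)
            names.append(f"d{cond}")
    drift = dct_drift_basis(n_volumes, tr, highpass_seconds)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    for idx in sorted(set(int(i) for i in outlier_indices)):
        if not 0 <= idx < n_volumes:
            raise DesignError(f"outlier volume index {idx} outside run")
        ind = np.zeros(n_volumes)
        ind[idx] = 1.0
        cols.append(ind)
        names.append(f"outlier_{idx}")
    cols.append(np.ones(n_volumes))
    names.append("constant")
    matrix = np.column_stack(cols)
    _rank_check(matrix, names)
    return DesignMatrix(matrix=matrix, names=names, condition_names=tuple(present), tr=tr)


def detect_outliers(run, fd_mm: float = 0.9, global_sd: float = 5.0) -> np.ndarray:
    """Outlier volume indices: FD > ``fd_mm`` or global signal change more than
    ``global_sd`` standard deviations above its mean.

    Global signal change is the volume-to-volume difference of the spatial mean
    (absolute value); the first volume's change is zero by convention.
    """
    fd = np.asarray(run.motion_fd_mm, dtype=float)
    data = run.data
    nvol = data.shape[-1]
    if fd.shape[0] != nvol:
        raise ValueError("motion trace length does not match number of volumes")
    flagged = set(np.flatnonzero(fd > fd_mm).tolist())
    g = data.reshape(-1, nvol).mean(axis=0)
    dg = np.abs(np.diff(g, prepend=g[0]))
    sd = dg.std()
    if sd > 0:
        flagged |= set(np.flatnonzero(dg > dg.mean() + global_sd * sd).tolist())
    return np.array(sorted(flagged), dtype=int)


def exclude_participant(outlier_counts, volume_counts, threshold: float = 0.40) -> bool:
    """True iff pooled outlier volumes across runs exceed ``threshold`` strictly."""
    total_out = int(np.sum(outlier_counts))
    total_vol = int(np.sum(volume_counts))
    if total_vol <= 0:
        raise ValueError("no volumes provided")
    return total_out / total_vol > threshold


def _whiten(x: np.ndarray, a: float) -> np.ndarray:
    """Exact AR(1) whitening filter along axis 0."""
    out = x.astype(float, copy=True)
    out[1:] = x[1:] - a * x[:-1]
    out[0] = np.sqrt(1.0 - a * a) * x[0]
    return out


@dataclass
class GLMFit:
    """Per-voxel OLS fit of the prewhitened model."""

    beta: np.ndarray  # regressors x voxels
    sigma2: np.ndarray  # voxels
    dof: int
    names: list[str]
    xtx_inv: np.ndarray
    ar_coefficient: float
    shape: tuple[int, int, int]
    constant_voxels: np.ndarray  # bool, voxels with constant raw series
    mean_sq: np.ndarray = field(repr=False, default=None)  # mean whitened y^2, for variance floor


@dataclass
class ContrastMap:
    """Voxelwise effect (percent signal change) and t statistic."""

    effect: np.ndarray  # 3-D, PSC units
    tstat: np.ndarray  # 3-D; NaN where undefined
    dof: int


def _run_data(run) -> np.ndarray:
    if isinstance(run, np.ndarray):
        return run
    return run.data if hasattr(run, "data") else np.asarray(run)


def fit_glm(runs, designs, ar_coefficient: float = 0.2) -> GLMFit:
    """Prewhitened least-squares fit, single- or multi-run.

    Multi-run fits concatenate runs with shared condition/derivative columns
    and per-run drift, outlier, and constant columns (an SPM-style multi-session
    model), whitening each run independently. ``runs`` may be run objects with a
    ``.data`` attribute or bare 4-D arrays.
    """
    if not isinstance(runs, (list, tuple)):
        runs = [runs]
        designs = [designs]
    if len(runs) != len(designs):
        raise ValueError("one design per run required")
    shape = None
    shared = None
    y_blocks, shared_blocks, perrun_cols, perrun_names = [], [], [], []
    for r_i, (run, design) in enumerate(zip(runs, designs)):
        data = _run_data(run)
        if shape is None:
            shape = data.shape[:3]
        elif data.shape[:3] != shape:
            raise ValueError("runs must share a voxel grid")
        nvol = data.shape[-1]
        if design.n_volumes != nvol:
            raise DesignError("design rows must equal run volumes")
        deriv_names = {f"d{c}" for c in CONDITIONS}
        s_names = [n for n in design.names if n in CONDITIONS or n in deriv_names]
        if shared is None:
            shared = s_names
        elif s_names != shared:
            raise DesignError("runs disagree on condition columns")
        s_idx = [design.names.index(n) for n in s_names]
        p_idx = [j for j in range(len(design.names)) if j not in s_idx]
        y = _whiten(data.reshape(-1, nvol).T, ar_coefficient)
        xs = _whiten(design.matrix[:, s_idx], ar_coefficient) if s_idx else np.empty((nvol, 0))
        xp = _whiten(design.matrix[:, p_idx], ar_coefficient)
        y_blocks.append(y)
        shared_blocks.append(xs)
        perrun_cols.append(xp)
        perrun_names.append([f"{design.names[j]}_r{r_i}" for j in p_idx])
    n_total = sum(b.shape[0] for b in y_blocks)
    yw = np.concatenate(y_blocks, axis=0)
    x_shared = np.concatenate(shared_blocks, axis=0)
    n_perrun = sum(b.shape[1] for b in perrun_cols)
    x_perrun = np.zeros((n_total, n_perrun))
    row = col = 0
    for b in perrun_cols:
        x_perrun[row : row + b.shape[0], col : col + b.shape[1]] = b
        row += b.shape[0]
        col += b.shape[1]
    xw = np.concatenate([x_shared, x_perrun], axis=1)
    names = list(shared) + [n for group in perrun_names for n in group]
    rank = np.linalg.matrix_rank(xw)
    if rank < xw.shape[1]:
        _rank_check(xw, names)
    dof = n_total - rank
    beta, _, _, _ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof if dof > 0 else np.full(yw.shape[1], np.nan)
    raw = np.concatenate(
        [_run_data(r).reshape(-1, d.n_volumes).T for r, d in zip(runs, designs)],
        axis=0,
    )
    constant_voxels = np.ptp(raw, axis=0) == 0
    return GLMFit(
        beta=beta,
        sigma2=sigma2,
        dof=dof,
        names=names,
        xtx_inv=np.linalg.pinv(xw.T @ xw),
        ar_coefficient=ar_coefficient,
        shape=shape,
        constant_voxels=constant_voxels,
        mean_sq=np.mean(yw**2, axis=0),
    )


def _baseline(fit: GLMFit) -> np.ndarray:
    const_idx = [j for j, n in enumerate(fit.names) if n.startswith("constant")]
    return fit.beta[const_idx].mean(axis=0)


def contrast(fit: GLMFit, weights: dict[str, float] | None = None) -> ContrastMap:
    """Linear contrast of fitted betas with effect scaled to percent signal change.

    The effect is c'beta rescaled by 100 / baseline (baseline = mean of the
    per-run constant betas), so with a 100-unit baseline the effect equals the
    planted percent-signal-change amplitude. Voxels with a constant raw series
    report t as NaN; voxels with (numerically) zero residual variance get a
    tiny variance floor so t is large but never infinite.
    """
    if weights is None:
        weights = {"Language": 1.0, "Control": -1.0}
    c = np.zeros(len(fit.names))
    for name, w in weights.items():
        if name not in fit.names:
            raise ValueError(f"unknown regressor {name!r}; design has {fit.names}")
        c[fit.names.index(name)] = w
    effect = c @ fit.beta
    q = float(c @ fit.xtx_inv @ c)
    floor = np.finfo(float).eps * np.maximum(fit.mean_sq, 1.0)
    var = np.maximum(fit.sigma2, floor) * q
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(var)
    t[fit.constant_voxels] = np.nan
    base = _baseline(fit)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(np.abs(base) > 1e-6, 100.0 / base, np.nan)
    return ContrastMap(
        effect=(effect * scale).reshape(fit.shape),
        tstat=t.reshape(fit.shape),
        dof=fit.dof,
    )


def condition_psc(fit: GLMFit, condition: str) -> np.ndarray:
    """Percent-signal-change effect of one condition versus the fixation baseline."""
    return contrast(fit, {condition: 1.0}).effect


def bandpass_mask(n_volumes: int, tr: float, low_hz: float, high_hz: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    return (freqs >= low_hz) & (freqs <= high_hz)


def preprocess_rest(
    rest_run,
    atlas,
    band_hz: tuple[float, float] = (0.008, 0.09),
    n_nuisance_pcs: int = 5,
) -> np.ndarray:
    """Denoise a resting-state run: nuisance regression then band-pass filtering.

    Nuisance series are the leading principal components of out-of-parcel
    background voxels (a stand-in for white-matter/CSF signals on data without
    tissue segmentation) plus indicator columns for detected outlier volumes.
    The residual is band-pass filtered to 0.008–0.09 Hz with a frequency-domain
    mask, which also removes the mean.
    """
    data = rest_run.data
    nvol = data.shape[-1]
    if nvol <= 50:
        raise ValueError("rest run too short (need > 50 volumes)")
    mask = bandpass_mask(nvol, rest_run.tr_seconds, *band_hz)
    if not mask.any():
        raise ValueError(
            f"run of {nvol} volumes at TR {rest_run.tr_seconds}s has no frequency bins in {band_hz} Hz"
        )
    y = data.reshape(-1, nvol).T.astype(float)
    nuis = [np.ones(nvol)]
    bg = y[:, (atlas.labels == 0).ravel()]
    bg = bg - bg.mean(axis=0)
    if bg.size and bg.std() > 0:
        u, s, _ = np.linalg.svd(bg, full_matrices=False)
        k = min(n_nuisance_pcs, int((s > 1e-10 * s[0]).sum()))
        nuis.append(u[:, :k])
    for idx in detect_outliers(rest_run):
        ind = np.zeros(nvol)
        ind[idx] = 1.0
        nuis.append(ind)
    x = np.column_stack(nuis)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    f = np.fft.rfft(resid, axis=0)
    f[~mask] = 0.0
    cleaned = np.fft.irfft(f, n=nvol, axis=0)
    return cleaned.T.reshape(data.shape)
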