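"""Synthetic volumetric cohorts with planted lateralization, magnitude,
connectivity, and motion structure.

The generator emulates a developmental language-localizer study: four age
groups (early/middle/late childhood and adults), each subject contributing 1–4
block-design localizer runs (two conditions, Language vs Control) and a
resting-state run. Condition amplitudes are planted inside the five LH language
parcels with a smooth spatial profile peaking at a subject-specific jittered
location; right-hemisphere amplitudes are the mirrored LH condition differences
scaled by ``lateral_bias`` (1 = symmetric, <1 = left-lateralized). Resting runs
carry a planted inter-regional correlation structure. The baseline signal is
fixed at 100 units so planted amplitudes read directly in percent signal
change. Noise is temporally autocorrelated Gaussian AR(1) (coefficient
``noise_ar``, default 0.2), matching the covariance model the first-level GLM
whitens against.

Planted truth is retained on each run object for test code only; pipeline
stages never read it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas, build_atlas, mirror_index
from .glm import condition_regressor

GROUP_NAMES = ("early", "middle", "late", "adult")
AGE_RANGES = {"early": (4.0, 7.0), "middle": (7.0, 11.0), "late": (12.0, 15.0), "adult": (19.0, 45.0)}
BASELINE = 100.0
CORE_FRACTION = 0.15  # fraction of parcel voxels on the activation plateau
FWHM_VOXELS = 3.0


@dataclass
class GroupSpec:
    """Planted parameters for one age group.

    Amplitudes are in percent-signal-change units; ``lateral_bias`` scales the
    RH condition difference relative to the LH (1 = symmetric);
    ``connectivity_z`` is the planted mean within-hemisphere inter-regional
    Fisher z during rest.
    """

    name: str
    n_subjects: int
    psc_language: float = 1.0
    psc_control: float = 0.4
    lateral_bias: float = 0.9
    connectivity_z: float = 0.4
    n_runs: int = 2
    noise_sd: float = 1.0
    outlier_rate: float = 0.03
    noise_ar: float = 0.2

    def __post_init__(self) -> None:
        if self.name not in GROUP_NAMES:
            raise ValueError(f"group name must be one of {GROUP_NAMES}, got {self.name!r}")
        if self.n_subjects < 1:
            raise ValueError("group size must be >= 1")
        if not 0.0 <= self.lateral_bias <= 1.0:
            raise ValueError("lateral_bias must be in [0, 1]")
        if not 1 <= self.n_runs <= 4:
            raise ValueError("n_runs must be in [1, 4]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if not np.isfinite([self.psc_language, self.psc_control, self.connectivity_z]).all():
            raise ValueError("group amplitudes must be finite")


@dataclass
class CohortSpec:
    """Design of a synthetic cohort."""

    groups: list[GroupSpec]
    grid_shape: tuple[int, int, int] = (32, 36, 32)
    tr_seconds: float = 2.0
    seed: int = 0
    voxels_per_parcel: int = 80
    n_blocks_per_condition: int = 6
    block_seconds: float = 18.0
    fixation_seconds: float = 12.0
    n_rest_volumes: int = 160
    inter_hemi_scale: float = 0.8

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.grid_shape[0] % 2 != 0:
            raise ValueError("grid_shape first axis must be even (mid-sagittal mirror plane)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.groups:
            raise ValueError("at least one group required")


def default_cohort_spec(n_per_group: int = 10, seed: int = 0, **kwargs) -> CohortSpec:
    """The study conditions: four age groups with age-increasing response
    magnitude and connectivity and a common left-lateralized bias."""
    groups = [
        GroupSpec("early", n_per_group, psc_language=0.8, psc_control=0.30, connectivity_z=0.25),
        GroupSpec("middle", n_per_group, psc_language=1.0, psc_control=0.35, connectivity_z=0.35),
        GroupSpec("late", n_per_group, psc_language=1.2, psc_control=0.40, connectivity_z=0.45),
        GroupSpec("adult", n_per_group, psc_language=1.5, psc_control=0.50, connectivity_z=0.55),
    ]
    return CohortSpec(groups=groups, seed=seed, **kwargs)


@dataclass
class LocalizerRun:
    data: np.ndarray  # (x, y, z, t), baseline 100
    tr_seconds: float
    events: pd.DataFrame
    motion_fd_mm: np.ndarray = None
    truth: dict = field(default_factory=dict)  # test-only planted amplitudes


@dataclass
class RestRun:
    data: np.ndarray
    tr_seconds: float
    motion_fd_mm: np.ndarray = None
    truth_corr: np.ndarray = None  # test-only planted 10x10 correlation matrix


@dataclass
class SubjectData:
    subject_id: str
    group: str
    age: float
    localizer_runs: list[LocalizerRun]
    rest_run: RestRun | None = None


@dataclass
class Cohort:
    spec: CohortSpec
    atlas: ParcelAtlas
    subjects: list[SubjectData]


def make_block_design(
    n_blocks_per_condition: int,
    block_seconds: float = 18.0,
    fixation_seconds: float = 12.0,
    tr_seconds: float = 2.0,
) -> pd.DataFrame:
    """Deterministic alternating two-condition block design.

    Blocks alternate Language/Control with fixation padding at the start and
    end of the run. The returned frame carries ``attrs['total_seconds']`` and
    ``attrs['tr_seconds']``.
    """
    if not 2 <= n_blocks_per_condition <= 12:
        raise ValueError("n_blocks_per_condition must be in [2, 12]")
    if block_seconds <= 0 or fixation_seconds <= 0 or tr_seconds <= 0:
        raise ValueError("durations must be positive")
    order = ["Language", "Control"] * n_blocks_per_condition
    onsets = fixation_seconds + block_seconds * np.arange(len(order))
    events = pd.DataFrame(
        {"onset": onsets, "duration": block_seconds, "condition": order}
    )
    events.attrs["total_seconds"] = float(onsets[-1] + block_seconds + fixation_seconds)
    events.attrs["tr_seconds"] = float(tr_seconds)
    return events


def n_volumes_for(events: pd.DataFrame, tr_seconds: float) -> int:
    return int(round(events.attrs["total_seconds"] / tr_seconds))


def ar1_noise(rng: np.random.Generator, shape: tuple, sd: float, a: float) -> np.ndarray:
    """Stationary Gaussian AR(1) noise along the last axis."""
    if sd == 0:
        return np.zeros(shape)
    if a == 0:
        return rng.normal(0.0, sd, size=shape)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    out = np.empty(shape)
    out[..., 0] = rng.normal(0.0, sd, size=shape[:-1])
    eps = rng.normal(0.0, innov_sd, size=shape[:-1] + (shape[-1] - 1,))
    for t in range(1, shape[-1]):
        out[..., t] = a * out[..., t - 1] + eps[..., t - 1]
    return out


def _parcel_profile(atlas: ParcelAtlas, label: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth activation profile within one parcel: a plateau of ~15% of the
    parcel's voxels (value exactly 1) around a jittered centre voxel, with
    Gaussian falloff (FWHM ~3 voxels) outside the plateau. Returns a flat
    array aligned with the parcel's voxel list."""
    vox = np.argwhere(atlas.labels == label)
    n = len(vox)
    centre = vox[rng.integers(n)]
    d = np.sqrt(((vox - centre) ** 2).sum(axis=1))
    k_core = max(1, int(np.ceil(CORE_FRACTION * n)))
    d_core = np.partition(d, k_core - 1)[k_core - 1]
    sigma = FWHM_VOXELS / 2.3548
    excess = np.maximum(d - d_core, 0.0)
    return np.exp(-(excess**2) / (2.0 * sigma**2))


def planted_amplitudes(group: GroupSpec, atlas: ParcelAtlas, rng: np.random.Generator):
    """Per-voxel planted Language and Control amplitudes (PSC units).

    LH parcels carry ``psc_language``/``psc_control`` scaled by the spatial
    profile; RH homotopes carry the same Control amplitude but a condition
    difference scaled by ``lateral_bias`` at mirrored voxels.
    """
    amp_lang = np.zeros(atlas.grid_shape)
    amp_ctrl = np.zeros(atlas.grid_shape)
    nx = atlas.grid_shape[0]
    for label in atlas.lh_labels:
        vox = np.argwhere(atlas.labels == label)
        prof = _parcel_profile(atlas, label, rng)
        amp_lang[tuple(vox.T)] = group.psc_language * prof
        amp_ctrl[tuple(vox.T)] = group.psc_control * prof
        mvox = vox.copy()
        mvox[:, 0] = mirror_index(vox[:, 0], nx)
        diff = group.lateral_bias * (group.psc_language - group.psc_control) * prof
        amp_ctrl[tuple(mvox.T)] = group.psc_control * prof
        amp_lang[tuple(mvox.T)] = group.psc_control * prof + diff
    return amp_lang, amp_ctrl


def simulate_localizer_run(
    group: GroupSpec,
    atlas: ParcelAtlas,
    events: pd.DataFrame,
    subject_seed,
    amplitudes=None,
) -> LocalizerRun:
    """One block-design localizer run with planted amplitudes and AR(1) noise.

    ``subject_seed`` may be an int or a numpy Generator. Pass ``amplitudes``
    (from :func:`planted_amplitudes`) to share one spatial truth across runs of
    a subject; otherwise a fresh jitter is drawn.
    """
    rng = subject_seed if isinstance(subject_seed, np.random.Generator) else np.random.default_rng(subject_seed)
    tr = events.attrs["tr_seconds"]
    nvol = n_volumes_for(events, tr)
    if amplitudes is None:
        amplitudes = planted_amplitudes(group, atlas, rng)
    amp_lang, amp_ctrl = amplitudes
    x_lang = condition_regressor(events, "Language", nvol, tr)
    x_ctrl = condition_regressor(events, "Control", nvol, tr)
    signal = 1.0 + (
        amp_lang[..., None] / 100.0 * x_lang + amp_ctrl[..., None] / 100.0 * x_ctrl
    )
    data = BASELINE * signal + ar1_noise(rng, atlas.grid_shape + (nvol,), group.noise_sd, group.noise_ar)
    run = LocalizerRun(
        data=data,
        tr_seconds=tr,
        events=events,
        motion_fd_mm=np.full(nvol, 0.1),
        truth={
            "amp_language": amp_lang,
            "amp_control": amp_ctrl,
            "psc_language": group.psc_language,
            "psc_control": group.psc_control,
            "lateral_bias": group.lateral_bias,
        },
    )
    return run


def _planted_corr_matrix(group: GroupSpec, inter_hemi_scale: float) -> np.ndarray:
    r_within = np.tanh(group.connectivity_z)
    r_inter = inter_hemi_scale * r_within
    if abs(r_within) >= 1.0:
        raise ValueError("connectivity_z implies |r| >= 1")
    corr = np.full((10, 10), r_inter)
    for block in (slice(0, 5), slice(5, 10)):
        corr[block, block] = r_within
    np.fill_diagonal(corr, 1.0)
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("requested correlation matrix is not positive definite") from err
    return corr


def simulate_rest_run(
    group: GroupSpec,
    atlas: ParcelAtlas,
    n_volumes: int,
    subject_seed,
    inter_hemi_scale: float = 0.8,
    latent_sd: float = 1.0,
) -> RestRun:
    """Resting-state run with a planted 10-region correlation structure.

    Ten latent unit-variance series (one per parcel) are drawn from a
    multivariate normal whose correlation is ``tanh(connectivity_z)`` within
    each hemisphere and ``inter_hemi_scale`` times that between hemispheres;
    each is broadcast to its parcel's voxels on top of baseline plus AR(1)
    voxel noise.
    """
    if n_volumes < 50:
        raise ValueError("n_volumes must be >= 50")
    rng = subject_seed if isinstance(subject_seed, np.random.Generator) else np.random.default_rng(subject_seed)
    corr = _planted_corr_matrix(group, inter_hemi_scale)
    chol = np.linalg.cholesky(corr)
    latent = latent_sd * (chol @ rng.standard_normal((10, n_volumes)))
    data = BASELINE + ar1_noise(rng, atlas.grid_shape + (n_volumes,), group.noise_sd, group.noise_ar)
    for k, label in enumerate(atlas.lh_labels + atlas.rh_labels):
        data[atlas.labels == label] += latent[k]
    return RestRun(
        data=data,
        tr_seconds=2.0,
        motion_fd_mm=np.full(n_volumes, 0.1),
        truth_corr=corr,
    )


def simulate_motion(run, outlier_rate: float, seed) -> object:
    """Assign a framewise-displacement trace and inject outlier volumes.

    Baseline FD is well below the 0.9 mm flagging threshold; a
    Bernoulli(``outlier_rate``) subset of volumes gets FD > 0.9 mm and a
    global signal spike far above 5 SD of typical volume-to-volume change.
    Modifies ``run`` in place and returns it.
    """
    if not 0.0 <= outlier_rate <= 1.0:
        raise ValueError("outlier_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nvol = run.data.shape[-1]
    fd = np.abs(rng.normal(0.12, 0.06, size=nvol)).clip(0.0, 0.5)
    outliers = rng.random(nvol) < outlier_rate
    fd[outliers] = 1.0 + rng.exponential(0.3, size=int(outliers.sum()))
    run.motion_fd_mm = fd
    if outliers.any():
        run.data = run.data.copy()
        run.data[..., outliers] += 10.0 * max(1.0, float(np.std(run.data)))
    return run


def _subject_rng(cohort_seed: int, subject_index: int) -> np.random.Generator:
    """One RNG stream per subject, derived by hashing (cohort seed, index)."""
    return np.random.default_rng(np.random.SeedSequence(cohort_seed, spawn_key=(subject_index,)))


def make_cohort(spec: CohortSpec, include_rest: bool = True) -> Cohort:
    """Generate a full in-memory cohort: atlas plus per-subject runs."""
    atlas = build_atlas(spec.grid_shape, spec.voxels_per_parcel, seed=spec.seed)
    events = make_block_design(
        spec.n_blocks_per_condition, spec.block_seconds, spec.fixation_seconds, spec.tr_seconds
    )
    subjects = []
    index = 0
    for group in spec.groups:
        for _ in range(group.n_subjects):
            rng = _subject_rng(spec.seed, index)
            lo, hi = AGE_RANGES[group.name]
            age = float(rng.uniform(lo, hi))
            amps = planted_amplitudes(group, atlas, rng)
            runs = []
            for _run in range(group.n_runs):
                run = simulate_localizer_run(group, atlas, events, rng, amplitudes=amps)
                simulate_motion(run, group.outlier_rate, rng)
                runs.append(run)
            rest = None
            if include_rest:
                rest = simulate_rest_run(
                    group, atlas, spec.n_rest_volumes, rng, inter_hemi_scale=spec.inter_hemi_scale
                )
                rest.tr_seconds = spec.tr_seconds
                simulate_motion(rest, group.outlier_rate, rng)
            subjects.append(
                SubjectData(
                    subject_id=f"sub-{index:03d}",
                    group=group.name,
                    age=age,
                    localizer_runs=runs,
                    rest_run=rest,
                )
            )
            index += 1
    return Cohort(spec=spec, atlas=atlas, subjects=subjects)


def generate_cohort(spec: CohortSpec, out_dir, include_rest: bool = True) -> dict:
    """Write a cohort to disk (NIfTI runs, events TSVs, atlas, truth and
    manifest JSON) and return the manifest. Fully reproducible from (spec, seed)."""
    import nibabel as nib

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create cohort directory {out}: {err}") from err
    cohort = make_cohort(spec, include_rest=include_rest)
    affine = cohort.atlas.affine
    nib.save(nib.Nifti1Image(cohort.atlas.labels.astype(np.int16), affine), out / "atlas.nii.gz")
    manifest = {
        "spec": _spec_dict(spec),
        "atlas": "atlas.nii.gz",
        "parcel_names": {str(k): v for k, v in cohort.atlas.names.items()},
        "subjects": [],
    }
    truth_all = {}
    for subj in cohort.subjects:
        sdir = out / subj.subject_id
        sdir.mkdir(exist_ok=True)
        entry = {"subject_id": subj.subject_id, "group": subj.group, "age": subj.age, "runs": []}
        struth = {"group": subj.group, "age": subj.age, "runs": []}
        for i, run in enumerate(subj.localizer_runs):
            stem = f"loc_run-{i + 1}"
            nib.save(nib.Nifti1Image(run.data.astype(np.float32), affine), sdir / f"{stem}.nii.gz")
            run.events.to_csv(sdir / f"{stem}_events.tsv", sep="\t", index=False)
            np.savetxt(sdir / f"{stem}_fd.tsv", run.motion_fd_mm, fmt="%.6f")
            nib.save(
                nib.Nifti1Image(
                    np.stack([run.truth["amp_language"], run.truth["amp_control"]], axis=-1).astype(np.float32),
                    affine,
                ),
                sdir / f"{stem}_truth-amp.nii.gz",
            )
            entry["runs"].append(stem)
            struth["runs"].append(
                {k: run.truth[k] for k in ("psc_language", "psc_control", "lateral_bias")}
            )
        if subj.rest_run is not None:
            nib.save(nib.Nifti1Image(subj.rest_run.data.astype(np.float32), affine), sdir / "rest.nii.gz")
            np.savetxt(sdir / "rest_fd.tsv", subj.rest_run.motion_fd_mm, fmt="%.6f")
            entry["rest"] = "rest.nii.gz"
            struth["truth_corr"] = np.round(subj.rest_run.truth_corr, 10).tolist()
        manifest["subjects"].append(entry)
        truth_all[subj.subject_id] = struth
    (out / "truth.json").write_text(json.dumps(truth_all, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _spec_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["groups"] = [dataclasses.asdict(g) for g in spec.groups]
    d["grid_shape"] = list(spec.grid_shape)
    return d


def load_cohort(cohort_dir) -> Cohort:
    """Read a cohort written by :func:`generate_cohort` back into memory."""
    import nibabel as nib

    root = Path(cohort_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    sd = manifest["spec"]
    groups = [GroupSpec(**g) for g in sd.pop("groups")]
    spec = CohortSpec(groups=groups, **{k: v for k, v in sd.items() if k != "groups"})
    atlas_img = nib.load(root / manifest["atlas"])
    atlas = ParcelAtlas(
        labels=np.asarray(atlas_img.dataobj).astype(int),
        names={int(k): v for k, v in manifest["parcel_names"].items()},
        affine=atlas_img.affine,
    )
    truth_all = json.loads((root / "truth.json").read_text())
    subjects = []
    for entry in manifest["subjects"]:
        sdir = root / entry["subject_id"]
        runs = []
        for stem in entry["runs"]:
            events = pd.read_csv(sdir / f"{stem}_events.tsv", sep="\t")
            events.attrs["tr_seconds"] = spec.tr_seconds
            events.attrs["total_seconds"] = float(
                events["onset"].iloc[-1] + events["duration"].iloc[-1] + spec.fixation_seconds
            )
            amp = np.asarray(nib.load(sdir / f"{stem}_truth-amp.nii.gz").dataobj)
            runs.append(
                LocalizerRun(
                    data=np.asarray(nib.load(sdir / f"{stem}.nii.gz").dataobj, dtype=float),
                    tr_seconds=spec.tr_seconds,
                    events=events,
                    motion_fd_mm=np.loadtxt(sdir / f"{stem}_fd.tsv"),
                    truth={"amp_language": amp[..., 0], "amp_control": amp[..., 1]},
                )
            )
        rest = None
        if "rest" in entry:
            rest = RestRun(
                data=np.asarray(nib.load(sdir / entry["rest"]).dataobj, dtype=float),
                tr_seconds=spec.tr_seconds,
                motion_fd_mm=np.loadtxt(sdir / "rest_fd.tsv"),
                truth_corr=np.array(truth_all[entry["subject_id"]].get("truth_corr")),
            )
        subjects.append(
            SubjectData(
                subject_id=entry["subject_id"],
                group=entry["group"],
                age=entry["age"],
                localizer_runs=runs,
                rest_run=rest,
            )
        )
    return Cohort(spec=spec, atlas=atlas, subjects=subjects)
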