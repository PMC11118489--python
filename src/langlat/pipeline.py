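"""End-to-end orchestration: synthetic cohort -> first level -> exclusion ->
fROIs -> measures -> group statistics -> report tables.

All analysis thresholds live in :class:`PipelineConfig`, whose defaults are the
study parameters (top 10% fROI selection, volume threshold p < 0.001
one-tailed, FD > 0.9 mm and global-signal change > 5 SD outlier flags,
participant exclusion above 40% outlier volumes, 128 s high-pass, AR(0.2)
whitening, 0.008–0.09 Hz rest band-pass). Outputs are tidy CSVs shaped like
the study's four report tables plus figure-level per-group summaries and a
provenance log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm, group_stats, measures as meas
from .froi import define_frois
from .measures import BootstrapConfig
from .synth import Cohort, CohortSpec, GroupSpec, default_cohort_spec, load_cohort, make_cohort

log = logging.getLogger("langlat")


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with study-parameter defaults."""

    cohort_dir: str | None = None  # existing cohort; otherwise synthetic
    n_per_group: int = 8
    grid_shape: tuple[int, int, int] = (32, 36, 32)
    voxels_per_parcel: int = 80
    tr_seconds: float = 2.0
    n_rest_volumes: int = 160
    volume_p: float = 0.001
    top_fraction: float = 0.10
    fd_mm: float = 0.9
    global_sd: float = 5.0
    exclusion_fraction: float = 0.40
    highpass_s: float = 128.0
    ar: float = 0.2
    bandpass_hz: tuple[float, float] = (0.008, 0.09)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    include_rest: bool = True
    motion_covariate: bool = True
    seed: int = 0
    out_dir: str = "langlat_out"

    def __post_init__(self) -> None:
        if not 0 < self.volume_p < 1:
            raise ValueError("volume_p must be in (0, 1)")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.fd_mm <= 0 or self.global_sd <= 0:
            raise ValueError("outlier thresholds must be positive")
        if not 0 < self.exclusion_fraction < 1:
            raise ValueError("exclusion_fraction must be in (0, 1)")
        if self.highpass_s <= 0 or self.ar < 0 or self.ar >= 1:
            raise ValueError("invalid highpass_s or ar")
        lo, hi = self.bandpass_hz
        if not 0 <= lo < hi:
            raise ValueError("bandpass_hz must be an increasing non-negative pair")
        if self.volume_p not in (0.001, 0.01):
            warnings.warn(
                f"volume_p={self.volume_p} is outside the study's 0.001/0.01 choices", UserWarning, stacklevel=2
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["bandpass_hz"] = list(self.bandpass_hz)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "bootstrap" in raw and isinstance(raw["bootstrap"], dict):
            raw["bootstrap"] = BootstrapConfig(**raw["bootstrap"])
        for key in ("grid_shape", "bandpass_hz"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def validate_config(path) -> PipelineConfig:
    """Load and normalize a YAML or JSON config file (fail-closed on unknown keys)."""
    import yaml

    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as err:
        raise ValueError(f"malformed config {path}: {err}") from err
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    cfg = PipelineConfig.from_dict(raw)
    log.info("normalized config: %s", cfg.to_dict())
    return cfg


def _cohort_for(config: PipelineConfig) -> Cohort:
    if config.cohort_dir:
        return load_cohort(config.cohort_dir)
    spec = default_cohort_spec(
        n_per_group=config.n_per_group,
        seed=config.seed,
        grid_shape=config.grid_shape,
        voxels_per_parcel=config.voxels_per_parcel,
        tr_seconds=config.tr_seconds,
        n_rest_volumes=config.n_rest_volumes,
    )
    return make_cohort(spec, include_rest=config.include_rest)


def analyze_subject(subj, atlas, config: PipelineConfig) -> dict:
    """First-level through individual measures for one subject.

    Returns a dict with exclusion status, outlier counts, the cross-validated
    measure table, suprathreshold counts, laterality record, and (if rest data
    are present) the connectivity summary.
    """
    runs = subj.localizer_runs
    out_counts = [len(glm.detect_outliers(r, config.fd_mm, config.global_sd)) for r in runs]
    vol_counts = [r.data.shape[-1] for r in runs]
    excluded = glm.exclude_participant(out_counts, vol_counts, config.exclusion_fraction)
    result = {
        "subject": subj.subject_id,
        "group": subj.group,
        "age": subj.age,
        "n_outliers": int(sum(out_counts)),
        "n_volumes": int(sum(vol_counts)),
        "excluded": bool(excluded),
    }
    if excluded:
        return result
    cmap = meas.all_runs_contrast(runs, ar=config.ar, highpass=config.highpass_s)
    counts = meas.count_supra_voxels(cmap.tstat, atlas, config.volume_p, cmap.dof)
    lh, rh = meas.hemisphere_counts(counts, atlas)
    li = meas.volume_li(lh, rh)
    subj_no = int("".join(ch for ch in subj.subject_id if ch.isdigit()) or 0)
    boot_cfg = dataclasses.replace(config.bootstrap, seed=(config.seed * 100003 + subj_no) % 2**31)
    li_boot, li_ci = meas.bootstrap_li(cmap.tstat, atlas, boot_cfg)
    records = meas.cv_response_magnitude(
        runs, atlas, top_fraction=config.top_fraction, ar=config.ar, highpass=config.highpass_s
    )
    records.insert(0, "subject", subj.subject_id)
    records.insert(1, "group", subj.group)
    records.insert(2, "age", subj.age)
    maglat = meas.magnitude_laterality(records, atlas)
    maglat.insert(0, "subject", subj.subject_id)
    maglat.insert(1, "group", subj.group)
    result.update(
        {
            "counts": counts,
            "lh_count": lh,
            "rh_count": rh,
            "li_volume": li,
            "magnitude_diff": float(maglat["diff"].mean()),
            "li_bootstrap": li_boot,
            "li_bootstrap_ci": li_ci,
            "measures": records,
            "magnitude_laterality": maglat,
        }
    )
    if subj.rest_run is not None:
        cleaned = glm.preprocess_rest(subj.rest_run, atlas, band_hz=config.bandpass_hz)
        frois = define_frois(cmap.tstat, atlas, config.top_fraction, fold_id="all-runs")
        zmat = meas.functional_correlations(cleaned, frois, atlas)
        result["connectivity"] = zmat
        result.update(meas.connectivity_summary(zmat, atlas))
    return result


def _comparison_frame(comparisons, extra=None) -> pd.DataFrame:
    df = pd.DataFrame([c.as_dict() for c in comparisons])
    for key, val in (extra or {}).items():
        df[key] = val
    return df


def group_level(results: list[dict], atlas, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Fit every group-level model and assemble the four report tables."""
    kept = [r for r in results if not r["excluded"]]
    measures_df = pd.concat([r["measures"] for r in kept], ignore_index=True)
    laterality = pd.DataFrame(
        [
            {
                "subject": r["subject"],
                "group": r["group"],
                "age": r["age"],
                "lh_count": r["lh_count"],
                "rh_count": r["rh_count"],
                "li": r["li_volume"],
                "magnitude_diff": r["magnitude_diff"],
                "li_bootstrap": r["li_bootstrap"],
                "li_ci_low": r["li_bootstrap_ci"][0],
                "li_ci_high": r["li_bootstrap_ci"][1],
                "n_outliers": r["n_outliers"],
            }
            for r in kept
        ]
    )
    # Table 1: condition effect per group (network, frontal, temporal), LH
    t1 = []
    lh_meas = measures_df[measures_df["hemisphere"] == "LH"]
    for group, gdf in lh_meas.groupby("group"):
        for subset in (None, "frontal", "temporal"):
            eff = group_stats.fit_condition_model(gdf, subset=subset)
            t1.append({"group": group, "component": subset or "network", **eff.as_dict()})
    table1 = pd.DataFrame(t1)
    # Table 2: hemisphere effect per group on magnitude and volume
    contrast_by_hemi = (
        measures_df.pivot_table(
            index=["subject", "group", "hemisphere"], columns="condition", values="psc"
        )
        .reset_index()
        .assign(value=lambda d: d["Language"] - d["Control"])
    )
    volume_by_hemi = pd.DataFrame(
        [
            {"subject": r["subject"], "group": r["group"], "hemisphere": hemi, "value": cnt}
            for r in kept
            for hemi, cnt in (("LH", r["lh_count"]), ("RH", r["rh_count"]))
        ]
    )
    t2 = []
    for group in sorted(set(laterality["group"])):
        mags = contrast_by_hemi[contrast_by_hemi["group"] == group]
        vols = volume_by_hemi[volume_by_hemi["group"] == group]
        effs = group_stats.fit_hemisphere_models(mags, vols)
        for name, eff in effs.items():
            t2.append({"group": group, "measure": name, **eff.as_dict()})
    table2 = pd.DataFrame(t2)
    # Table 3: LI across groups + group x hemisphere interaction
    li_comp = group_stats.compare_li_across_groups(laterality)
    mag_long = contrast_by_hemi.rename(columns={"Language": "_l"})[
        ["subject", "group", "hemisphere", "value"]
    ].copy()
    per_froi = measures_df.pivot_table(
        index=["subject", "group", "hemisphere", "froi"], columns="condition", values="psc"
    ).reset_index()
    per_froi["value"] = per_froi["Language"] - per_froi["Control"]
    inter_comp, inter_structure = group_stats.fit_interaction_model(per_froi)
    table3 = pd.concat(
        [
            _comparison_frame(li_comp, {"analysis": "volume_li"}),
            _comparison_frame(inter_comp, {"analysis": "magnitude_interaction", "structure": inter_structure}),
        ],
        ignore_index=True,
    )
    # Table 4: LH magnitude and connectivity across groups (+ continuous age in children)
    lh_contrast = per_froi[per_froi["hemisphere"] == "LH"].copy()
    lh_contrast = lh_contrast.merge(laterality[["subject", "age"]], on="subject")
    mag_comp, mag_structure = group_stats.fit_magnitude_group_model(lh_contrast)
    parts = [_comparison_frame(mag_comp, {"analysis": "lh_magnitude", "structure": mag_structure})]
    child_contrast = lh_contrast[lh_contrast["group"] != group_stats.ADULT]
    age_eff = group_stats.fit_continuous_age_model(
        child_contrast.rename(columns={"value": "psc"}), response="psc"
    )
    age_df = pd.DataFrame([{"analysis": "lh_magnitude_age_slope", **age_eff.as_dict()}])
    conn_df = None
    if kept and "lh_mean_z" in kept[0]:
        conn_df = pd.DataFrame(
            [
                {
                    "subject": r["subject"],
                    "group": r["group"],
                    "age": r["age"],
                    "lh_mean_z": r["lh_mean_z"],
                    "rh_mean_z": r["rh_mean_z"],
                    "inter_mean_z": r["inter_mean_z"],
                }
                for r in kept
                if "lh_mean_z" in r
            ]
        )
        conn_comp = group_stats.compare_connectivity_across_groups(conn_df)
        parts.append(_comparison_frame(conn_comp, {"analysis": "lh_connectivity"}))
    table4 = pd.concat(parts, ignore_index=True)
    out = {
        "measures": measures_df,
        "laterality": laterality,
        "table1_condition_effects": table1,
        "table2_hemisphere_effects": table2,
        "table3_lateralization": table3,
        "table4_magnitude_connectivity": table4,
        "table4_age_slope": age_df,
        # figure-shaped per-group summaries
        "fig2_group_means": contrast_by_hemi.groupby(["group", "hemisphere"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index(),
        "fig3_li_by_group": laterality.groupby("group")[["li", "magnitude_diff", "li_bootstrap"]]
        .mean()
        .reset_index(),
    }
    if conn_df is not None:
        out["connectivity"] = conn_df
        out["fig4_connectivity_by_group"] = (
            conn_df.groupby("group")[["lh_mean_z", "rh_mean_z", "inter_mean_z"]].mean().reset_index()
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all outputs to ``config.out_dir``."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    cohort = _cohort_for(config)
    timings["generate_s"] = round(time.perf_counter() - t0, 3)
    results = []
    for subj in cohort.subjects:
        try:
            results.append(analyze_subject(subj, cohort.atlas, config))
        except Exception as err:
            raise RuntimeError(f"first-level stage failed for {subj.subject_id}: {err}") from err
        if results[-1]["excluded"]:
            log.info("excluded %s (%d/%d outlier volumes)", subj.subject_id, results[-1]["n_outliers"], results[-1]["n_volumes"])
    timings["first_level_s"] = round(time.perf_counter() - t0 - timings["generate_s"], 3)
    tables = group_level(results, cohort.atlas, config)
    timings["total_s"] = round(time.perf_counter() - t0, 3)
    stamp = {"stage": "langlat.run_pipeline", "config_hash": config.config_hash(), "seed": config.seed}
    for name, df in tables.items():
        df = df.copy()
        for key, val in stamp.items():
            df.attrs[key] = val
        header = f"# {json.dumps(stamp)}\n"
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    exclusions = pd.DataFrame(
        [{k: r[k] for k in ("subject", "group", "n_outliers", "n_volumes", "excluded")} for r in results]
    )
    exclusions.to_csv(out / "exclusions.csv", index=False)
    import scipy
    import statsmodels

    provenance = {
        **stamp,
        "config": config.to_dict(),
        "timings": timings,
        "n_subjects": len(results),
        "n_excluded": int(exclusions["excluded"].sum()),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    tables["exclusions"] = exclusions
    tables["provenance"] = provenance
    return tables
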