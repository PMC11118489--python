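"""Recompute the pipeline's headline quantities from scratch on a synthetic cohort.

Runs the full analysis (generation -> first level -> exclusion -> fROIs ->
measures -> group models) at a desk-scale problem size and reports the main
computed numbers: group mean laterality indices, child-vs-adult adjusted
p values, condition and hemisphere effects, percent more LH voxels, and mean
LH-network connectivity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .pipeline import PipelineConfig, run_pipeline

N_PER_GROUP = 6
GRID = (24, 28, 24)
VOXELS_PER_PARCEL = 60
N_REST = 120


def run_acceptance(seed: int, out_path) -> dict:
    cfg = PipelineConfig(
        n_per_group=N_PER_GROUP,
        grid_shape=GRID,
        voxels_per_parcel=VOXELS_PER_PARCEL,
        n_rest_volumes=N_REST,
        seed=int(seed) % 2**31,
        out_dir="scratch/acceptance_run",
    )
    tables = run_pipeline(cfg)
    lat = tables["laterality"]
    t1 = tables["table1_condition_effects"]
    t2 = tables["table2_hemisphere_effects"]
    t3 = tables["table3_lateralization"]
    t4 = tables["table4_magnitude_connectivity"]
    n_subj = int(tables["provenance"]["n_subjects"])

    adult = lat[lat["group"] == "adult"]
    li_rows = t3[t3["analysis"] == "volume_li"]
    mag_rows = t4[t4["analysis"] == "lh_magnitude"]
    pct_more_lh = 100.0 * (adult["lh_count"].sum() - adult["rh_count"].sum()) / adult["rh_count"].sum()

    def rec(value, n=n_subj):
        return {"value": float(np.round(value, 6)), "n": int(n)}

    values = {
        "adult_mean_volume_li": rec(adult["li"].mean(), len(adult)),
        "adult_mean_bootstrap_li": rec(adult["li_bootstrap"].mean(), len(adult)),
        "adult_pct_more_lh_voxels": rec(pct_more_lh, len(adult)),
        "adult_condition_effect_b": rec(
            t1[(t1["group"] == "adult") & (t1["component"] == "network")]["b"].iloc[0], len(adult)
        ),
        "adult_hemisphere_magnitude_b": rec(
            t2[(t2["group"] == "adult") & (t2["measure"] == "magnitude")]["b"].iloc[0], len(adult)
        ),
        "min_child_vs_adult_li_adjusted_p": rec(li_rows["p_adjusted"].min()),
        "max_child_vs_adult_li_adjusted_p": rec(li_rows["p_adjusted"].max()),
        "early_vs_adult_lh_magnitude_b": rec(
            mag_rows[mag_rows["contrast"] == "Early vs Adult"]["b"].iloc[0]
        ),
        "n_excluded": rec(tables["provenance"]["n_excluded"]),
    }
    if "connectivity" in tables:
        conn = tables["connectivity"]
        values["adult_mean_lh_connectivity_z"] = rec(
            conn[conn["group"] == "adult"]["lh_mean_z"].mean(), len(conn[conn["group"] == "adult"])
        )
        conn_rows = t4[t4["analysis"] == "lh_connectivity"]
        if len(conn_rows):
            values["early_vs_adult_connectivity_b"] = rec(
                conn_rows[conn_rows["contrast"] == "Early vs Adult"]["b"].iloc[0]
            )
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(values, indent=2, sort_keys=True))
    return values
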