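import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from langlat import glm
from langlat.synth import (
    CohortSpec,
    GroupSpec,
    ar1_noise,
    default_cohort_spec,
    generate_cohort,
    load_cohort,
    make_block_design,
    make_cohort,
    n_volumes_for,
    planted_amplitudes,
    simulate_localizer_run,
    simulate_motion,
    simulate_rest_run,
)


class TestBlockDesign:
    def test_six_blocks_per_condition(self):
        ev = make_block_design(6, 18.0, 12.0, 2.0)
        assert len(ev) == 12
        assert (np.diff(ev["onset"]) > 0).all()
        assert (ev["condition"].value_counts() == 6).all()
        assert ev.attrs["total_seconds"] == 2 * 12.0 + 12 * 18.0

    def test_two_blocks_gives_four_rows(self):
        assert len(make_block_design(2)) == 4

    @pytest.mark.parametrize("n", [0, 1, 13])
    def test_block_count_bounds(self, n):
        with pytest.raises(ValueError):
            make_block_design(n)

    def test_nonpositive_durations_rejected(self):
        with pytest.raises(ValueError):
            make_block_design(4, block_seconds=-1.0)

    def test_blocks_non_overlapping(self):
        ev = make_block_design(5, 15.0, 10.0)
        ends = ev["onset"] + ev["duration"]
        assert (ends.to_numpy()[:-1] <= ev["onset"].to_numpy()[1:] + 1e-12).all()


class TestGroupSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"name": "teen"},
            {"lateral_bias": 1.5},
            {"n_runs": 5},
            {"outlier_rate": -0.1},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        base = {"name": "adult", "n_subjects": 2}
        with pytest.raises(ValueError):
            GroupSpec(**{**base, **kwargs})

    def test_odd_grid_rejected(self):
        with pytest.raises(ValueError, match="even"):
            CohortSpec(groups=[GroupSpec("adult", 1)], grid_shape=(21, 24, 20))


class TestLocalizerTruth:
    def test_symmetric_truth_mirrors_exactly(self, small_atlas, events4):
        g = GroupSpec("adult", 1, psc_language=1.0, psc_control=0.4, lateral_bias=1.0, noise_sd=0.0)
        run = simulate_localizer_run(g, small_atlas, events4, 11)
        diff = run.truth["amp_language"] - run.truth["amp_control"]
        assert np.array_equal(diff[::-1, :, :], diff)

    def test_equal_conditions_give_zero_difference(self, small_atlas, events4):
        g = GroupSpec("adult", 1, psc_language=0.7, psc_control=0.7, noise_sd=0.0)
        run = simulate_localizer_run(g, small_atlas, events4, 11)
        assert np.all(run.truth["amp_language"] - run.truth["amp_control"] == 0)

    def test_lateral_bias_scales_mirrored_difference(self, small_atlas, events4):
        g = GroupSpec("adult", 1, psc_language=1.0, psc_control=0.2, lateral_bias=0.5, noise_sd=0.0)
        run = simulate_localizer_run(g, small_atlas, events4, 11)
        diff = run.truth["amp_language"] - run.truth["amp_control"]
        lh_mask = np.isin(small_atlas.labels, small_atlas.lh_labels)
        lh = diff[lh_mask]
        rh = diff[::-1, :, :][lh_mask]
        assert np.allclose(rh, 0.5 * lh)

    def test_baseline_is_100(self, small_atlas, events4):
        g = GroupSpec("adult", 1, noise_sd=0.0)
        run = simulate_localizer_run(g, small_atlas, events4, 11)
        background = small_atlas.labels == 0
        assert np.allclose(run.data[background], 100.0)

    def test_motion_trace_matches_volumes(self, small_atlas, events4):
        g = GroupSpec("adult", 1, noise_sd=0.5)
        run = simulate_localizer_run(g, small_atlas, events4, 11)
        assert len(run.motion_fd_mm) == run.data.shape[-1] == n_volumes_for(events4, 2.0)
        assert np.isfinite(run.data).all()


class TestAr1Noise:
    def test_lag1_autocorrelation_near_coefficient(self):
        rng = np.random.default_rng(0)
        x = ar1_noise(rng, (2000, 300), 1.0, 0.2)
        xc = x - x.mean(axis=1, keepdims=True)
        r1 = (xc[:, 1:] * xc[:, :-1]).sum(axis=1) / (xc**2).sum(axis=1)
        assert abs(r1.mean() - 0.2) < 0.02
        assert abs(x.std() - 1.0) < 0.02

    def test_zero_sd_is_silent(self):
        assert np.all(ar1_noise(np.random.default_rng(0), (4, 10), 0.0, 0.2) == 0)


class TestRestRun:
    def test_null_connectivity_near_zero(self, small_atlas):
        g = GroupSpec("adult", 1, connectivity_z=0.0, noise_sd=0.0)
        rest = simulate_rest_run(g, small_atlas, 300, 3)
        series = np.stack(
            [rest.data[small_atlas.labels == k].mean(axis=0) for k in range(1, 6)]
        )
        r = np.corrcoef(series)
        off = r[np.triu_indices(5, 1)]
        assert np.all(np.abs(off) < 3 / np.sqrt(300))

    def test_planted_r_recovered(self, small_atlas):
        g = GroupSpec("adult", 1, connectivity_z=np.arctanh(0.6), noise_sd=0.0)
        rest = simulate_rest_run(g, small_atlas, 300, 4)
        series = np.stack(
            [rest.data[small_atlas.labels == k].mean(axis=0) for k in range(1, 6)]
        )
        off = np.corrcoef(series)[np.triu_indices(5, 1)]
        assert abs(off.mean() - 0.6) < 0.1

    def test_truth_corr_symmetric_unit_diagonal(self, small_atlas):
        g = GroupSpec("adult", 1, connectivity_z=0.3)
        rest = simulate_rest_run(g, small_atlas, 80, 5)
        assert np.allclose(rest.truth_corr, rest.truth_corr.T)
        assert np.allclose(np.diag(rest.truth_corr), 1.0)

    def test_impossible_correlation_rejected(self, small_atlas):
        g = GroupSpec("adult", 1, connectivity_z=50.0)
        with pytest.raises(ValueError):
            simulate_rest_run(g, small_atlas, 80, 5)

    def test_too_few_volumes_rejected(self, small_atlas):
        with pytest.raises(ValueError):
            simulate_rest_run(GroupSpec("adult", 1), small_atlas, 30, 5)


class TestMotion:
    def test_zero_rate_keeps_fd_low(self, small_atlas, events4):
        g = GroupSpec("adult", 1, noise_sd=0.5)
        run = simulate_localizer_run(g, small_atlas, events4, 11)
        simulate_motion(run, 0.0, 7)
        assert np.all(run.motion_fd_mm < 0.9)

    def test_full_rate_flags_every_volume(self, small_atlas, events4):
        g = GroupSpec("adult", 1, noise_sd=0.5)
        run = simulate_localizer_run(g, small_atlas, events4, 11)
        simulate_motion(run, 1.0, 7)
        assert len(glm.detect_outliers(run)) == run.data.shape[-1]

    def test_flagged_fraction_matches_binomial_rate(self, tiny_atlas, events3):
        # mean flagged fraction over many seeds ~ Binomial(n, 0.1)/n
        g = GroupSpec("adult", 1, noise_sd=0.5)
        run = simulate_localizer_run(g, tiny_atlas, events3, 11)
        nvol = run.data.shape[-1]
        fracs = []
        for seed in range(200):
            r = dataclasses.replace(run, motion_fd_mm=None)
            simulate_motion(r, 0.1, seed)
            fracs.append(np.mean(r.motion_fd_mm > 0.9))
        se = np.sqrt(0.1 * 0.9 / nvol) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.1) < 3 * se


class TestCohortIO:
    def _tiny_spec(self, seed=0):
        groups = [GroupSpec(name, 1, n_runs=2, noise_sd=0.5) for name in ("early", "adult")]
        return CohortSpec(
            groups=groups,
            grid_shape=(20, 24, 20),
            voxels_per_parcel=50,
            n_blocks_per_condition=3,
            n_rest_volumes=60,
            seed=seed,
        )

    def test_truth_json_byte_identical_across_reruns(self, tmp_path):
        spec = self._tiny_spec()
        generate_cohort(spec, tmp_path / "a", include_rest=False)
        generate_cohort(spec, tmp_path / "b", include_rest=False)
        assert (tmp_path / "a" / "truth.json").read_bytes() == (tmp_path / "b" / "truth.json").read_bytes()

    def test_manifest_lists_all_subjects_with_groups(self, tmp_path):
        spec = dataclasses.replace(
            self._tiny_spec(),
            groups=[GroupSpec(n, 2, n_runs=1, noise_sd=0.5) for n in ("early", "middle", "late", "adult")],
        )
        manifest = generate_cohort(spec, tmp_path / "c", include_rest=False)
        assert len(manifest["subjects"]) == 8
        assert {s["group"] for s in manifest["subjects"]} == {"early", "middle", "late", "adult"}

    def test_roundtrip_preserves_data_within_write_precision(self, tmp_path):
        spec = self._tiny_spec(seed=4)
        cohort = make_cohort(spec, include_rest=True)
        generate_cohort(spec, tmp_path / "d", include_rest=True)
        loaded = load_cohort(tmp_path / "d")
        assert len(loaded.subjects) == len(cohort.subjects)
        orig = cohort.subjects[0].localizer_runs[0].data
        back = loaded.subjects[0].localizer_runs[0].data
        assert np.allclose(orig, back, atol=1e-4)  # float32 on disk
        assert np.array_equal(loaded.atlas.labels, cohort.atlas.labels)
        assert loaded.subjects[0].rest_run.truth_corr.shape == (10, 10)

    def test_in_memory_cohort_deterministic(self):
        spec = self._tiny_spec(seed=9)
        a = make_cohort(spec, include_rest=False)
        b = make_cohort(spec, include_rest=False)
        assert np.array_equal(
            a.subjects[1].localizer_runs[0].data, b.subjects[1].localizer_runs[0].data
        )
        assert a.subjects[1].age == b.subjects[1].age

    def test_default_spec_has_four_groups_and_age_trends(self):
        spec = default_cohort_spec(3, seed=1)
        names = [g.name for g in spec.groups]
        assert names == ["early", "middle", "late", "adult"]
        psc = [g.psc_language for g in spec.groups]
        assert psc == sorted(psc)
        cohort = make_cohort(dataclasses.replace(spec, grid_shape=(20, 24, 20), voxels_per_parcel=50,
                                                 n_blocks_per_condition=3, n_rest_volumes=60),
                             include_rest=False)
        ages = pd.DataFrame([{"g": s.group, "age": s.age} for s in cohort.subjects])
        assert ages.groupby("g")["age"].mean()["early"] < ages.groupby("g")["age"].mean()["adult"]
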