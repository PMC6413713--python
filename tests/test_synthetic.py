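"""Phantom construction, acquisition simulators, cohort generator."""

import numpy as np
import pandas as pd
import pytest

from neuroperf.datamodel import CVR_REGIONS, GROUPS, REGIONS
from neuroperf.synth import (
    AslTruth,
    CohortSpec,
    CvrTruth,
    PhantomSpec,
    make_phantom,
    rician,
    simulate_asl,
    simulate_cohort,
    simulate_cvr,
)


class TestPhantom:
    def test_default_has_seven_named_regions(self, default_phantom):
        anatomy, atlas = default_phantom
        assert set(atlas.names) == set(REGIONS)
        assert len(atlas.region_names) == 7
        assert anatomy.values.max() == 100.0 and anatomy.values.min() == 0.0

    def test_region_counts_equal_box_volumes(self):
        spec = PhantomSpec.small()
        _, atlas = make_phantom(spec)
        for region in spec.boxes:
            lab = atlas.label_of(region)
            assert (atlas.labels == lab).sum() == spec.region_voxel_count(region)

    def test_one_voxel_deep_grid_valid(self):
        boxes = {
            "cortex": ((0, 4), (0, 2), (0, 1)),
            "thalamus": ((0, 4), (3, 5), (0, 1)),
        }
        _, atlas = make_phantom(PhantomSpec(shape=(8, 8, 1), boxes=boxes))
        assert set(atlas.names) == {"cortex", "thalamus"}

    def test_overlapping_boxes_rejected(self):
        boxes = {
            "cortex": ((0, 4), (0, 4), (0, 2)),
            "thalamus": ((2, 6), (2, 6), (0, 2)),
        }
        with pytest.raises(ValueError, match="overlap"):
            make_phantom(PhantomSpec(shape=(8, 8, 2), boxes=boxes))

    def test_tiny_region_rejected(self):
        boxes = {"cortex": ((0, 2), (0, 2), (0, 1))}
        with pytest.raises(ValueError, match="smaller than 8"):
            make_phantom(PhantomSpec(shape=(8, 8, 1), boxes=boxes))


class TestSimulateAsl:
    def test_zero_cbf_gives_identical_series(self, small_phantom):
        _, atlas = small_phantom
        truth = AslTruth({r: 0.0 for r in REGIONS}, noise_sigma=0.0)
        acq = simulate_asl(truth, atlas, seed=0)
        for sel, glo in zip(acq.selective_series, acq.global_series):
            np.testing.assert_array_equal(sel.values, glo.values)

    def test_inverted_worked_example(self):
        # CBF 132.868 at T1_glob 1.70 implies selective T1 1.62
        truth = AslTruth({"cortex": 132.86829430327163}, t1_global_s=1.70)
        assert truth.t1_selective_s("cortex") == pytest.approx(1.62, abs=1e-9)

    def test_seeding_contract(self, small_phantom):
        _, atlas = small_phantom
        truth = AslTruth({r: 150.0 for r in REGIONS}, noise_sigma=2.0)
        a = simulate_asl(truth, atlas, seed=5)
        b = simulate_asl(truth, atlas, seed=5)
        c = simulate_asl(truth, atlas, seed=6)
        for va, vb in zip(a.selective_series, b.selective_series):
            np.testing.assert_array_equal(va.values, vb.values)
        assert not np.array_equal(
            a.selective_series[0].values, c.selective_series[0].values
        )

    def test_absurd_negative_cbf_rejected(self):
        truth = AslTruth({"cortex": -1e7}, t1_global_s=1.70)
        with pytest.raises(ValueError, match="cortex"):
            truth.t1_selective_s("cortex")

    def test_sparse_inversion_times_rejected(self, small_phantom):
        _, atlas = small_phantom
        truth = AslTruth({r: 150.0 for r in REGIONS})
        with pytest.raises(ValueError, match="inversion times"):
            simulate_asl(truth, atlas, inversion_times_s=np.array([1.0, 2.0, 3.0]))


class TestSimulateCvr:
    def test_no_reactivity_keeps_steady_state(self, small_phantom):
        _, atlas = small_phantom
        truth = CvrTruth(
            {r: 0.51083 for r in REGIONS},
            {r: 0.0 for r in REGIONS},
            {r: 0.0 for r in REGIONS},
            noise_sigma=0.0,
        )
        acq = simulate_cvr(truth, atlas, seed=0)
        inside = atlas.labels > 0
        s0 = acq.main_series[0].values[inside]
        for vol in acq.main_series[1:]:
            np.testing.assert_allclose(vol.values[inside], s0)

    def test_steady_state_level(self, small_phantom):
        # Spre 100, CBV0 0.51083 -> S0 = 60 exactly
        _, atlas = small_phantom
        truth = CvrTruth(
            {r: 0.51083 for r in REGIONS},
            {r: 0.061 for r in REGIONS},
            {r: 2.178 for r in REGIONS},
            noise_sigma=0.0,
        )
        acq = simulate_cvr(truth, atlas, seed=0)
        inside = atlas.labels > 0
        assert acq.pre_contrast[0].values[inside].mean() == pytest.approx(100.0)
        assert acq.main_series[0].values[inside].mean() == pytest.approx(60.0, abs=1e-3)

    def test_reinversion_of_noiseless_response(self, small_phantom):
        # dCBV%(40 min) = (0.061*40 + 2.178)^2 = 21.33
        _, atlas = small_phantom
        truth = CvrTruth(
            {r: 0.51083 for r in REGIONS},
            {r: 0.061 for r in REGIONS},
            {r: 2.178 for r in REGIONS},
            noise_sigma=0.0,
        )
        acq = simulate_cvr(truth, atlas, seed=0)
        inside = atlas.labels > 0
        rep_40min = 90  # (90 - 30) * 40 s = 40 min
        s = acq.main_series[rep_40min - 1].values[inside].mean()
        s0 = acq.main_series[0].values[inside].mean()
        spre = acq.pre_contrast[0].values[inside].mean()
        dcbv = 100.0 * np.log(s / s0) / np.log(s0 / spre)
        assert dcbv == pytest.approx((0.061 * 40 + 2.178) ** 2, rel=1e-9)

    def test_nonpositive_cbv0_rejected(self, small_phantom):
        _, atlas = small_phantom
        bad = CvrTruth(
            {r: (-0.1 if r == "thalamus" else 0.5) for r in REGIONS},
            {r: 0.05 for r in REGIONS},
            {r: 2.0 for r in REGIONS},
        )
        with pytest.raises(ValueError, match="thalamus"):
            simulate_cvr(bad, atlas)


class TestRicianNoise:
    def test_high_snr_bias_below_one_percent(self):
        rng = np.random.default_rng(0)
        signal = np.full(200_000, 40.0)  # SNR 20 at sigma 2
        mags = rician(signal, 2.0, rng)
        assert (mags.mean() - 40.0) / 40.0 < 0.01

    def test_zero_signal_noise_floor(self):
        # pure noise magnitude has mean sigma*sqrt(pi/2)
        rng = np.random.default_rng(1)
        mags = rician(np.zeros(200_000), 2.0, rng)
        assert mags.mean() == pytest.approx(2.0 * np.sqrt(np.pi / 2), rel=0.01)


class TestCohort:
    def test_zero_sd_gives_identical_truths(self):
        spec = CohortSpec(
            group_n={"NTL": 3, "arcAb": 3},
            cbf={g: {r: (150.0, 0.0) for r in REGIONS} for g in ("NTL", "arcAb")},
            cvr={
                g: {r: {"a": (0.05, 0.0), "b": (2.0, 0.0)} for r in CVR_REGIONS}
                for g in ("NTL", "arcAb")
            },
            cbv0=(0.5, 0.0),
            phantom=PhantomSpec.small(),
        )
        bundle = simulate_cohort(spec, seed=0, modalities=())
        per_subject = bundle.truth_cbf.groupby("subject_id")["value"].sum()
        assert per_subject.nunique() == 1

    def test_truth_tables_reproducible(self):
        spec = CohortSpec(phantom=PhantomSpec.small())
        a = simulate_cohort(spec, seed=11, modalities=())
        b = simulate_cohort(spec, seed=11, modalities=())
        pd.testing.assert_frame_equal(a.truth_cbf, b.truth_cbf)
        pd.testing.assert_frame_equal(a.truth_cvr, b.truth_cvr)

    def test_group_sizes_and_factors(self):
        spec = CohortSpec(phantom=PhantomSpec.small())
        bundle = simulate_cohort(spec, seed=0, modalities=())
        counts = pd.Series([s.record.group for s in bundle.subjects]).value_counts()
        assert counts["NTL"] == 8 and counts["NTL_noscapine"] == 9
        assert counts["arcAb"] == 9 and counts["arcAb_noscapine"] == 11

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            CohortSpec(group_n={"NTL": 1, "arcAb": 3})

    def test_truth_sample_means_near_spec_means(self):
        """CLT bound: per-group sample means within 2 SD/sqrt(n) of the spec
        means for all perfusion regions, averaged over 20 master seeds."""
        spec = CohortSpec(phantom=PhantomSpec.small())
        draws: dict[tuple[str, str], list[float]] = {}
        for seed in range(20):
            bundle = simulate_cohort(spec, seed=seed, modalities=())
            g = bundle.truth_cbf.groupby(["group", "region"])["value"].mean()
            for key, val in g.items():
                draws.setdefault(key, []).append(val)
        for (group, region), vals in draws.items():
            mean, sd = spec.cbf[group][region]
            n_eff = spec.group_n[group] * 20
            assert abs(np.mean(vals) - mean) < 2 * sd / np.sqrt(n_eff), (group, region)
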