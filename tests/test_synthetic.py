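"""Synthetic experiment generator: structure, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

import thromboquant as tq
from thromboquant.metrics import FLUOR_CHANNELS
from thromboquant.synthetic import (
    DesignError,
    GenerationError,
    field_targets,
    sample_ground_truth,
)

TINY = (128, 170)


def _blank_targets(**overrides):
    t = dict(
        platelet=0.0, agg_share=0.0, multi_share=0.0,
        PS=0.0, **{"P-selectin": 0.0}, fibrinogen=0.0, compactness=0.5,
    )
    t.update(overrides)
    return t


class TestDesign:
    def test_minimal_design_counts(self, control):
        with pytest.warns(UserWarning, match="donors"):
            design = tq.ExperimentDesign(
                donors=1, duplicate_runs_per_condition=1, microspots=("collagen-I",),
                shear_rates=(1000.0,), conditions=(control,),
                field_size=TINY, seed=1,
            )
        runs = tq.generate_experiment(design)
        assert len(runs) == 1
        roles = [f.role for f in runs[0].fields]
        assert roles.count("brightfield") == 2
        assert roles.count("fluorescence") == 3
        fluor = [f for f in runs[0].fields if f.role == "fluorescence"][0]
        assert set(fluor.images) == set(FLUOR_CHANNELS)

    def test_default_structure_run_count(self, control):
        # 3 donors × 2 runs × 3 microspots × 2 shears × C conditions
        design = tq.ExperimentDesign(
            conditions=(control,),
            images_per_run_brightfield=1, images_per_run_fluorescence=1,
            field_size=TINY, seed=2,
        )
        runs = tq.generate_experiment(design)
        assert len(runs) == 36
        keys = {r.metadata.key() for r in runs}
        assert len(keys) == 36

    def test_invalid_designs_rejected(self, control):
        with pytest.raises(DesignError):
            tq.ExperimentDesign(donors=0, conditions=(control,))
        with pytest.raises(DesignError):
            tq.ExperimentDesign(conditions=())
        with pytest.raises(DesignError):
            tq.ExperimentDesign(
                conditions=(tq.ConditionSpec("x", {999.0: {"seeding": 0.5}}),)
            )

    def test_negative_multiplier_rejected(self):
        cond = tq.ConditionSpec("bad", {1000.0: {"seeding": -1.0}})
        with pytest.raises(DesignError):
            cond.multiplier(1000.0, "seeding")


class TestDeterminism:
    def test_same_seed_same_truth_tables(self, tiny_design):
        def table(runs):
            return pd.DataFrame(
                [
                    dict(
                        key=r.metadata.key(), role=f.role, idx=f.index,
                        plat=f.truth.true_platelet_fraction,
                        agg=f.truth.true_aggregate_fraction,
                        **{ch: f.truth.true_channel_fraction[ch] for ch in FLUOR_CHANNELS},
                    )
                    for r in runs
                    for f in r.fields
                ]
            )

        t1 = table(tq.generate_experiment(tiny_design))
        t2 = table(tq.generate_experiment(tiny_design))
        pd.testing.assert_frame_equal(t1, t2)

    def test_same_seed_identical_pixels(self, tiny_design):
        r1 = tq.generate_experiment(tiny_design)
        r2 = tq.generate_experiment(tiny_design)
        a = r1[0].fields[0].images["brightfield"].pixels
        b = r2[0].fields[0].images["brightfield"].pixels
        np.testing.assert_array_equal(a, b)

    def test_render_seed_changes_noise_not_mask(self, small_truth):
        img1 = tq.render_brightfield(small_truth, seed=1)
        img2 = tq.render_brightfield(small_truth, seed=2)
        assert not np.array_equal(img1.pixels, img2.pixels)
        # the underlying truth (and hence noise-free render) is identical
        nf1 = tq.render_brightfield(small_truth, noise_sd=0.0, seed=1)
        nf2 = tq.render_brightfield(small_truth, noise_sd=0.0, seed=2)
        np.testing.assert_array_equal(nf1.pixels, nf2.pixels)


class TestGroundTruth:
    def test_blank_field(self):
        rng = np.random.default_rng(0)
        truth = sample_ground_truth(rng, _blank_targets(), TINY)
        assert truth.true_platelet_fraction == 0.0
        assert not truth.platelet_mask.any()
        img = tq.render_brightfield(truth, noise_sd=0.0, seed=0)
        assert np.ptp(img.pixels) <= 0.03 * 2 * 40000 + 1e-6  # illumination only

    def test_requested_coverage_realized_within_one_point(self):
        rng = np.random.default_rng(1)
        truth = sample_ground_truth(
            rng, _blank_targets(platelet=0.35, agg_share=0.4, multi_share=0.5), TINY
        )
        assert truth.true_platelet_fraction == pytest.approx(0.35, abs=0.01)
        assert truth.platelet_mask.mean() == pytest.approx(0.35, abs=0.01)

    def test_channel_fraction_realized_and_subset(self):
        rng = np.random.default_rng(2)
        truth = sample_ground_truth(
            rng, _blank_targets(platelet=0.30, PS=1.0 / 3.0), TINY
        )
        # requested: 1/3 of platelet area ≈ 10% of the field
        assert truth.true_channel_fraction["PS"] == pytest.approx(0.10, abs=0.01)
        assert not (truth.channel_masks["PS"] & ~truth.platelet_mask).any()

    def test_mask_hierarchy_invariants(self, small_truth):
        t = small_truth
        assert not (t.aggregate_mask & ~t.platelet_mask).any()
        assert not (t.multilayer_mask & ~t.aggregate_mask).any()
        assert 0 <= t.true_aggregate_fraction <= t.true_platelet_fraction
        for ch in FLUOR_CHANNELS:
            assert t.true_channel_fraction[ch] <= t.true_platelet_fraction

    def test_object_table_schema(self, small_truth):
        tab = small_truth.object_table
        assert {"equivalent_radius_um", "layer_count", "solidity"} <= set(tab.columns)
        assert tab["solidity"].between(0, 1).all()
        assert set(tab["layer_count"]) <= {1, 2}

    def test_impossible_coverage_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(GenerationError):
            sample_ground_truth(rng, _blank_targets(platelet=1.5), TINY)


class TestEffectModel:
    def test_seeding_multiplier_reduces_mean_coverage(self, control):
        halved = tq.ConditionSpec("halved", {1000.0: {"seeding": 0.5}})
        rng_c = np.random.default_rng(10)
        rng_t = np.random.default_rng(10)
        cov_c, cov_t = [], []
        for _ in range(20):
            tc = field_targets("collagen-I", 1000.0, control, 1.0, rng_c)
            tt = field_targets("collagen-I", 1000.0, halved, 1.0, rng_t)
            cov_c.append(sample_ground_truth(rng_c, tc, TINY).true_platelet_fraction)
            cov_t.append(sample_ground_truth(rng_t, tt, TINY).true_platelet_fraction)
        assert np.mean(cov_t) < np.mean(cov_c)

    def test_control_multipliers_are_unit(self, control):
        for group in ("seeding", "aggregate", "multilayer", "PS"):
            assert control.multiplier(1000.0, group) == 1.0

    def test_shear_specific_effect(self):
        cond = tq.ConditionSpec("hs", {1000.0: {"seeding": 0.6}})
        assert cond.multiplier(1000.0, "seeding") == 0.6
        assert cond.multiplier(150.0, "seeding") == 1.0
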