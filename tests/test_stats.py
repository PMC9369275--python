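"""Averaging hierarchy, 0–10 scaling, paired testing, subtraction heatmaps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from thromboquant.metrics import PARAMETERS
from thromboquant.stats import (
    TABLE_RANGES,
    average_images_to_run,
    average_runs_to_donor,
    cumulative_scaled,
    paired_t_test,
    scale_univariate,
    scaled_matrix,
    subtraction_heatmap,
)


def _image_row(donor="d1", condition="c", microspot="m1", shear=1000.0,
               run="r1", role="brightfield", idx=1, **params):
    row = dict(
        donor=donor, condition=condition, microspot=microspot,
        shear_rate=shear, run_id=run, image_role=role, image_index=idx,
        **{p: np.nan for p in PARAMETERS},
    )
    row.update(params)
    return row


def _donor_table(values_by_condition, donors=("d1", "d2", "d3"), **meta):
    """Donor summary with all parameters set to the same per-donor value."""
    rows = []
    for cond, vals in values_by_condition.items():
        for donor, v in zip(donors, vals):
            rows.append(
                dict(
                    donor=donor, condition=cond,
                    microspot=meta.get("microspot", "m1"),
                    shear_rate=meta.get("shear", 1000.0),
                    **{p: v for p in PARAMETERS},
                )
            )
    return pd.DataFrame(rows)


class TestAveraging:
    def test_brightfield_images_averaged(self):
        df = pd.DataFrame(
            [_image_row(idx=1, P1=30.0), _image_row(idx=2, P1=40.0)]
        )
        out = average_images_to_run(df)
        assert len(out) == 1
        assert out.loc[0, "P1"] == 35.0
        assert out.loc[0, "n_brightfield"] == 2

    def test_fractional_scores_after_averaging(self):
        df = pd.DataFrame(
            [_image_row(idx=1, P3=5.0), _image_row(idx=2, P3=4.0)]
        )
        assert average_images_to_run(df).loc[0, "P3"] == 4.5

    def test_single_image_identity(self):
        df = pd.DataFrame([_image_row(P1=17.5, P2=3.25)])
        out = average_images_to_run(df)
        assert out.loc[0, "P1"] == 17.5
        assert out.loc[0, "P2"] == 3.25

    def test_role_separation_and_missing_flagged(self):
        df = pd.DataFrame(
            [
                _image_row(role="brightfield", P1=30.0),
                _image_row(role="fluorescence", P6=5.0, P7=12.0, P8=8.0),
            ]
        )
        out = average_images_to_run(df)
        assert out.loc[0, "P6"] == 5.0
        assert np.isnan(
            average_images_to_run(
                pd.DataFrame([_image_row(role="brightfield", P1=30.0)])
            ).loc[0, "P6"]
        )

    def test_order_invariance(self):
        rows = [
            _image_row(idx=i, P1=v) for i, v in enumerate([12.0, 30.5, 44.0])
        ]
        a = average_images_to_run(pd.DataFrame(rows))
        b = average_images_to_run(pd.DataFrame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_runs_to_donor(self):
        per_run = pd.DataFrame(
            [
                dict(donor="d1", condition="c", microspot="m1", shear_rate=1000.0,
                     run_id=r, **{p: v for p in PARAMETERS})
                for r, v in [("r1", 35.0), ("r2", 45.0)]
            ]
        )
        out = average_runs_to_donor(per_run)
        assert len(out) == 1
        assert out.loc[0, "P1"] == 40.0
        assert out.loc[0, "n_runs"] == 2

    def test_three_runs_mean(self):
        per_run = pd.DataFrame(
            [
                dict(donor="d1", condition="c", microspot="m1", shear_rate=1000.0,
                     run_id=r, **{p: v for p in PARAMETERS})
                for r, v in [("r1", 10.0), ("r2", 20.0), ("r3", 60.0)]
            ]
        )
        assert average_runs_to_donor(per_run).loc[0, "P1"] == 30.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            average_images_to_run(pd.DataFrame(columns=["donor"]))


class TestScaling:
    def test_affine_map(self):
        scaled, frame = scale_univariate([2.0, 4.0, 6.0])
        np.testing.assert_allclose(scaled, [0.0, 5.0, 10.0])
        assert frame == (2.0, 6.0)

    def test_constant_vector_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            scaled, _ = scale_univariate([7.0, 7.0, 7.0])
        np.testing.assert_array_equal(scaled, [0.0, 0.0, 0.0])

    def test_fixed_frame_from_assay_ranges(self):
        scaled, frame = scale_univariate([35.85], mode="fixed", parameter="P1")
        assert frame == (0.0, 71.7)
        assert scaled[0] == pytest.approx(5.0)

    def test_fixed_mode_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            scaled, _ = scale_univariate([80.0], mode="fixed", parameter="P1")
        assert scaled[0] == 10.0

    def test_idempotence_on_scaled_vector(self):
        v = np.array([0.0, 3.3, 7.1, 10.0])
        scaled, _ = scale_univariate(v)
        np.testing.assert_allclose(scaled, v)

    def test_table_ranges_cover_all_parameters(self):
        assert set(TABLE_RANGES) == set(PARAMETERS)


class TestCumulative:
    def test_bounds_and_arithmetic(self):
        assert cumulative_scaled({p: 10.0 for p in PARAMETERS}) == 80.0
        assert cumulative_scaled({p: 0.0 for p in PARAMETERS}) == 0.0
        assert cumulative_scaled(
            {p: float(i + 1) for i, p in enumerate(PARAMETERS)}
        ) == 36.0

    def test_missing_parameter_named(self):
        row = {p: 1.0 for p in PARAMETERS if p != "P5"}
        with pytest.raises(ValueError, match="P5"):
            cumulative_scaled(row)


class TestPairedT:
    def test_closed_form_example(self):
        # differences (1, 2, 3): mean 2, sd 1 -> t = 2 / (1/sqrt(3))
        res = paired_t_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(3.4641016, abs=1e-6)
        assert res.degrees_of_freedom == 2
        assert res.p_value == pytest.approx(0.0742, abs=2e-4)
        assert res.mean_difference == 2.0

    def test_identical_vectors_convention(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(3, 12)
            a, b = rng.normal(size=(2, n))
            ours = paired_t_test(a, b)
            ref = sps.ttest_rel(b, a)
            assert ours.t_statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_agrees_with_signflip_permutation_oracle(self):
        """At moderate n the t p-value matches an exact sign-flip test."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, size=14)
            res = paired_t_test(np.zeros_like(d), d)
            signs = np.array(list(itertools.product([-1.0, 1.0], repeat=d.size)))
            perm_means = (signs * d).mean(axis=1)
            p_perm = np.mean(np.abs(perm_means) >= abs(d.mean()) - 1e-12)
            assert res.p_value == pytest.approx(p_perm, abs=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_t_test([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


class TestSubtractionHeatmap:
    def test_identical_condition_all_zero_nothing_significant(self):
        donor = _donor_table({"control": [10, 20, 30], "same": [10, 20, 30]})
        hm = subtraction_heatmap(donor, control="control")
        assert (hm["delta"] == 0.0).all()
        assert not hm["significant"].any()
        assert (hm["p_value"] == 1.0).all()

    def test_antisymmetry_under_fixed_frame(self):
        donor = _donor_table({"a": [30, 40, 50], "b": [20, 25, 30]})
        ab = subtraction_heatmap(donor, control="b", mode="fixed")
        ba = subtraction_heatmap(donor, control="a", mode="fixed")
        merged = ab.merge(
            ba, on=["microspot", "shear_rate", "parameter"], suffixes=("_ab", "_ba")
        )
        np.testing.assert_allclose(merged["delta_ab"], -merged["delta_ba"])

    def test_delta_sum_matches_cumulative_difference(self):
        donor = _donor_table({"control": [10, 20, 30], "rx": [8, 15, 22]})
        hm = subtraction_heatmap(donor, control="control")
        sm = scaled_matrix(donor)
        cum_rx = cumulative_scaled(sm.row("m1", 1000.0, "rx"))
        cum_ctrl = cumulative_scaled(sm.row("m1", 1000.0, "control"))
        assert hm["delta"].sum() == pytest.approx(cum_rx - cum_ctrl)

    def test_missing_control_rejected(self):
        donor = _donor_table({"a": [1, 2, 3]})
        with pytest.raises(ValueError, match="control"):
            subtraction_heatmap(donor, control="vehicle")

    def test_significance_threshold_bounds(self):
        donor = _donor_table({"control": [1, 2, 3], "a": [1, 2, 3]})
        with pytest.raises(ValueError):
            subtraction_heatmap(donor, control="control", alpha=1.5)

    def test_bh_adjustment_never_more_liberal(self):
        rng = np.random.default_rng(2)
        donor = _donor_table(
            {"control": rng.normal(20, 3, 3), "rx": rng.normal(15, 3, 3)}
        )
        raw = subtraction_heatmap(donor, control="control")
        adj = subtraction_heatmap(donor, control="control", adjust="bh")
        assert (adj["p_value"] >= raw["p_value"] - 1e-12).all()


class TestNullCalibration:
    def test_rejection_rate_under_null(self):
        """Paired t at donor level rejects ~5% under no condition effect."""
        rng = np.random.default_rng(3)
        rejections = 0
        n = 400
        for _ in range(n):
            donor_effect = rng.normal(0, 1, 3)
            a = donor_effect + rng.normal(0, 0.5, 3)
            b = donor_effect + rng.normal(0, 0.5, 3)
            rejections += paired_t_test(a, b).p_value < 0.05
        assert rejections / n == pytest.approx(0.05, abs=0.025)
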