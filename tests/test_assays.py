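"""Phagosome scoring indices: fusion, ROS, pH, degradation, export."""

import numpy as np
import pandas as pd
import pytest

from dcquant import assays, synthetic
from dcquant.datatypes import DomainError


def _fusion_df(rows):
    return pd.DataFrame(rows, columns=["object_id", "fret", "bead",
                                       "cell_ha_total", "is_external"])


class TestFusionIndex:
    def test_ratio_at_basal_scores_zero(self):
        df = _fusion_df([("ext", 10.0, 100.0, 2.0, True),
                         ("int", 5.0, 50.0, 2.0, False)])
        per, mean = assays.pl_fusion_index(df)
        assert mean == pytest.approx(0.0)

    def test_worked_arithmetic(self):
        # ratio 0.5, basal 0.1, HA total 2.0 -> (0.4/2)*10^4 = 2000
        df = _fusion_df([("ext", 10.0, 100.0, 2.0, True),
                         ("int", 50.0, 100.0, 2.0, False)])
        _, mean = assays.pl_fusion_index(df)
        assert mean == pytest.approx(2000.0)

    def test_unit_normalized_ratio_scores_scale_factor(self):
        # (ratio - basal)/HA = 1 must map to exactly 10,000
        df = _fusion_df([("ext", 50.0, 100.0, 1.0, True),
                         ("int", 150.0, 100.0, 1.0, False)])
        _, mean = assays.pl_fusion_index(df)
        assert mean == 10_000.0

    def test_invariant_to_uniform_channel_rescaling(self):
        df1 = _fusion_df([("ext", 10.0, 100.0, 2.0, True),
                         ("int", 50.0, 100.0, 2.0, False)])
        df2 = df1.assign(fret=df1["fret"] * 7.3, bead=df1["bead"] * 7.3)
        assert assays.pl_fusion_index(df1)[1] == pytest.approx(
            assays.pl_fusion_index(df2)[1]
        )

    def test_no_external_objects_errors(self):
        df = _fusion_df([("int", 5.0, 50.0, 2.0, False)])
        with pytest.raises(DomainError, match="external"):
            assays.pl_fusion_index(df)

    def test_zero_bead_excluded_with_warning(self):
        df = _fusion_df([("ext", 10.0, 100.0, 2.0, True),
                         ("bad", 5.0, 0.0, 2.0, False),
                         ("int", 50.0, 100.0, 2.0, False)])
        with pytest.warns(UserWarning, match="zero bead"):
            per, _ = assays.pl_fusion_index(df)
        assert list(per["object_id"]) == ["int"]

    def test_generator_round_trip(self):
        objs, _ = synthetic.gen_assay_objects(
            "fusion", {"planted_index": [500.0, 1500.0]}, seed=1
        )
        per, mean = assays.pl_fusion_index(objs)
        assert mean == pytest.approx(1000.0)


class TestRosIndex:
    def test_internal_at_external_mean_scores_zero(self):
        df = pd.DataFrame({"object_id": ["e", "i"], "oxyburst": [50.0, 100.0],
                           "alexa568": [100.0, 200.0], "is_external": [True, False]})
        _, mean = assays.phagosomal_ros_index(df)
        assert mean == pytest.approx(0.0)

    def test_worked_arithmetic(self):
        df = pd.DataFrame({"object_id": ["e", "i"], "oxyburst": [50.0, 200.0],
                           "alexa568": [100.0, 100.0], "is_external": [True, False]})
        _, mean = assays.phagosomal_ros_index(df)
        assert mean == pytest.approx(1.5)  # 2.0 - 0.5

    def test_all_external_errors(self):
        df = pd.DataFrame({"object_id": ["e"], "oxyburst": [50.0],
                           "alexa568": [100.0], "is_external": [True]})
        with pytest.raises(DomainError, match="internal"):
            assays.phagosomal_ros_index(df)


class TestIntracellularRos:
    def test_constant_trace_is_unity(self):
        t = np.arange(0, 90, 2.0)
        assert assays.intracellular_ros_summary(t, np.full(t.size, 7.0)) == 1.0

    def test_worked_arithmetic_and_inclusive_baseline(self):
        # 2-min cadence: baseline samples at t = 0, 2, 4, 6 (inclusive)
        t = np.array([0, 2, 4, 6, 8, 10], dtype=float)
        f = np.array([90, 100, 110, 100, 200, 250], dtype=float)
        assert assays.intracellular_ros_summary(t, f) == pytest.approx(2.5)

    def test_zero_baseline_errors(self):
        t = np.array([0, 2, 4, 6, 8], dtype=float)
        with pytest.raises(DomainError, match="baseline"):
            assays.intracellular_ros_summary(t, np.zeros(5))


class TestPhCalibration:
    def test_noiseless_round_trip_recovers_generator_params(self):
        stacks, _ = synthetic.gen_assay_objects(
            "ph_calibration",
            {"bottom": 0.3, "top": 2.2, "ph50": 6.2, "slope": 0.7},
            seed=2,
        )
        calib = assays.fit_ratio_ph_calibration(stacks)
        assert calib.bottom == pytest.approx(0.3, abs=1e-6)
        assert calib.top == pytest.approx(2.2, abs=1e-6)
        assert calib.ph50 == pytest.approx(6.2, abs=1e-6)
        assert calib.slope == pytest.approx(0.7, abs=1e-6)

    def test_buffer_means_round_trip_through_inverse(self):
        stacks, _ = synthetic.gen_assay_objects("ph_calibration", {}, seed=3)
        calib = assays.fit_ratio_ph_calibration(stacks)
        for ph, ratio in zip(calib.levels, calib.mean_ratios):
            assert assays.ratio_to_ph(ratio, calib) == pytest.approx(ph, abs=0.01)

    def test_replicate_order_does_not_matter(self):
        stacks, _ = synthetic.gen_assay_objects(
            "ph_calibration", {"noise_sd": 0.02}, seed=4
        )
        shuffled = stacks.sample(frac=1.0, random_state=0).reset_index(drop=True)
        c1 = assays.fit_ratio_ph_calibration(stacks)
        c2 = assays.fit_ratio_ph_calibration(shuffled)
        assert c1.ph50 == pytest.approx(c2.ph50, abs=1e-9)

    def test_nonmonotone_means_error_names_levels(self):
        stacks, _ = synthetic.gen_assay_objects("ph_calibration", {}, seed=5)
        stacks.loc[stacks["ph"] == 7.0, "ratio"] = 0.01  # break monotonicity
        with pytest.raises(DomainError, match="pH 6->7"):
            assays.fit_ratio_ph_calibration(stacks)

    def test_midpoint_ratio_maps_to_ph50(self):
        stacks, _ = synthetic.gen_assay_objects("ph_calibration", {}, seed=6)
        calib = assays.fit_ratio_ph_calibration(stacks)
        mid = (calib.bottom + calib.top) / 2.0
        assert assays.ratio_to_ph(mid, calib) == pytest.approx(calib.ph50, abs=1e-9)

    def test_out_of_range_ratio_refused(self):
        stacks, _ = synthetic.gen_assay_objects("ph_calibration", {}, seed=7)
        calib = assays.fit_ratio_ph_calibration(stacks)
        with pytest.raises(DomainError, match="outside calibrated range"):
            assays.ratio_to_ph(calib.mean_ratios.max() * 1.5, calib)


class TestDegradation:
    @pytest.mark.parametrize("mfi_frac, expected", [(1.0, 0.0), (0.0, 100.0),
                                                    (0.4, 60.0)])
    def test_percent_arithmetic(self, mfi_frac, expected):
        out = assays.ova_degradation_percent([30.0], [mfi_frac * 500.0], 500.0)
        assert out["degraded_percent"].iloc[0] == pytest.approx(expected)

    def test_bounded_and_antimonotone(self):
        mfi = np.array([800.0, 600.0, 400.0, 100.0, 0.0])
        out = assays.ova_degradation_percent(np.arange(5.0), mfi, 500.0)
        pct = out["degraded_percent"].to_numpy()
        assert np.all((pct >= 0) & (pct <= 100))
        assert np.all(np.diff(pct) >= 0)  # lower MFI -> more degradation

    def test_zero_reference_errors(self):
        with pytest.raises(DomainError, match="t0"):
            assays.ova_degradation_percent([0.0], [100.0], 0.0)


class TestCytosolExport:
    def test_planted_fraction_recovered(self):
        cells, _ = synthetic.gen_assay_objects(
            "export", {"n_treated": 100, "n_control": 100, "n_positive": 30}, seed=8
        )
        pct, _ = assays.cytosol_export_percent(cells, control_quantile=0.99)
        assert pct == pytest.approx(30.0)

    def test_all_below_control_max_scores_zero_at_quantile_one(self):
        rng = np.random.default_rng(0)
        ctrl = rng.uniform(0.5, 1.0, 50)
        treated = rng.uniform(0.0, 0.4, 50)
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(100)],
            "blue": np.concatenate([ctrl, treated]) * 100.0,
            "green": 100.0,
            "condition": ["probe_only_control"] * 50 + ["treated"] * 50,
        })
        pct, _ = assays.cytosol_export_percent(cells, control_quantile=1.0)
        assert pct == 0.0

    def test_small_control_population_errors(self):
        cells = pd.DataFrame({
            "cell_id": ["a", "b", "c"], "blue": [1.0, 2.0, 3.0],
            "green": [1.0, 1.0, 1.0],
            "condition": ["probe_only_control", "probe_only_control", "treated"],
        })
        with pytest.raises(DomainError, match=">= 20"):
            assays.cytosol_export_percent(cells)

    def test_degenerate_control_warns(self):
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(21)],
            "blue": [1.0] * 20 + [5.0],
            "green": [1.0] * 21,
            "condition": ["probe_only_control"] * 20 + ["treated"],
        })
        with pytest.warns(UserWarning, match="degenerate"):
            assays.cytosol_export_percent(cells)
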