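import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from explantquant import (
    EmptyBackgroundBandError,
    MissingColumnError,
    ProjectionFrame,
    QuantConfig,
    SyntheticNucleiConfig,
    ValidationError,
    angular_dispersion,
    bcat_counts_by_tier,
    call_positive,
    classify_domain,
    compute_ratio,
    filter_nuclei,
    generate_nuclei,
    measure_sample,
    percent_positive,
    quantify_sample,
    select_brightest,
    subtract_background,
    tier_profile,
)


def scored_table(ratios):
    return pd.DataFrame({"nucleus_id": np.arange(len(ratios)),
                         "ratio": np.asarray(ratios, dtype=float)})


class TestFilter:
    def test_toy_table_drop_accounting(self, toy_filter_tables, default_quant_config):
        """Of 8 nuclei — 2 EVL, 1 dividing, 1 below the 100 µm depth window,
        1 beyond 150 µm — exactly 3 survive and every drop is accounted."""
        tbl, proj = toy_filter_tables
        out = filter_nuclei(tbl, proj, default_quant_config)
        assert len(out) == 3
        drops = out.attrs["drops"]
        assert drops == {"evl": 2, "dividing": 1, "low_dapi": 0,
                         "z_window": 1, "distance": 1}
        assert len(tbl) == len(out) + sum(drops.values())

    def test_clean_table_passes_unchanged(self, toy_filter_tables, default_quant_config):
        tbl, proj = toy_filter_tables
        tbl = tbl.assign(is_evl=False, is_dividing=False, z_um=50.0)
        proj = proj.assign(dist_to_ref_um=40.0)
        out = filter_nuclei(tbl, proj, default_quant_config)
        assert len(out) == 8
        assert sum(out.attrs["drops"].values()) == 0

    def test_empty_table_passes_through(self, toy_filter_tables, default_quant_config):
        tbl, proj = toy_filter_tables
        out = filter_nuclei(tbl.iloc[0:0], proj.iloc[0:0], default_quant_config)
        assert len(out) == 0

    def test_missing_column_named_in_error(self, toy_filter_tables, default_quant_config):
        tbl, proj = toy_filter_tables
        with pytest.raises(MissingColumnError, match="is_evl"):
            filter_nuclei(tbl.drop(columns=["is_evl"]), proj, default_quant_config)


class TestBackgroundAndRatio:
    def test_band_mean_subtracted(self, default_quant_config):
        tbl = pd.DataFrame({
            "nucleus_id": range(4),
            "ch_signal_mean": [10.0, 20.0, 30.0, 25.0],
            "dist_to_ref_um": [130.0, 140.0, 125.0, 50.0],
        })
        out = subtract_background(tbl, default_quant_config)
        assert out.attrs["background"] == pytest.approx(20.0)
        assert out.loc[3, "signal_bgsub"] == pytest.approx(5.0)
        band = out["dist_to_ref_um"].between(120, 150)
        assert out.loc[band, "signal_bgsub"].mean() == pytest.approx(0.0)

    def test_constant_intensity_goes_to_zero(self, default_quant_config):
        tbl = pd.DataFrame({"nucleus_id": range(3), "ch_signal_mean": 7.0,
                            "dist_to_ref_um": [125.0, 135.0, 10.0]})
        out = subtract_background(tbl, default_quant_config)
        assert np.allclose(out["signal_bgsub"], 0.0)

    def test_empty_band_raises_unless_override(self, default_quant_config):
        tbl = pd.DataFrame({"nucleus_id": [0], "ch_signal_mean": [9.0],
                            "dist_to_ref_um": [10.0]})
        with pytest.raises(EmptyBackgroundBandError):
            subtract_background(tbl, default_quant_config)
        out = subtract_background(tbl, default_quant_config, background=4.0)
        assert out.loc[0, "signal_bgsub"] == pytest.approx(5.0)

    def test_ratio_and_nonpositive_drops(self):
        tbl = pd.DataFrame({
            "nucleus_id": range(3),
            "ch_signal_mean": [55.0, 48.0, 10.0],
            "signal_bgsub": [5.0, -2.0, 10.0],
            "ch_dapi_mean": [50.0, 50.0, 0.0],
        })
        out = compute_ratio(tbl)
        assert list(out["nucleus_id"]) == [0]
        assert out.loc[0, "ratio"] == pytest.approx(0.1)
        assert out.attrs["drops_ratio"] == {"nonpositive_dapi": 1,
                                            "nonpositive_signal": 1}

    def test_ratio_uncorrelated_with_depth(self):
        """Equal attenuation of both channels cancels in the DAPI ratio."""
        cfg = SyntheticNucleiConfig(seed=6, n_nuclei=500, intensity_noise_sd=0.0,
                                    depth_attenuation_per_um=2e-3)
        tbl, _ = generate_nuclei(cfg)
        ratio = tbl["ch_signal_mean"] / tbl["ch_dapi_mean"]
        resid = np.log(ratio) + tbl["true_dist_um"] / cfg.gradient_decay_length
        # after removing the gradient, the ratio carries no depth dependence
        assert np.ptp(resid) < 1e-9


class TestPositivity:
    def test_threshold_is_strict(self, default_quant_config):
        tbl = scored_table([0.10, 0.11])
        out = call_positive(tbl, default_quant_config)
        assert list(out["is_positive"]) == [False, True]

    def test_percent_positive(self):
        tbl = scored_table(np.linspace(0, 1, 20))
        tbl["is_positive"] = [False] * 15 + [True] * 5
        assert percent_positive(tbl) == pytest.approx(25.0)
        tbl["is_positive"] = False
        assert percent_positive(tbl) == 0.0
        with pytest.raises(ValidationError):
            percent_positive(tbl.iloc[0:0])

    def test_positive_count_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            tbl = scored_table(rng.uniform(-0.2, 0.6, size=30))
            counts = []
            for thr in np.linspace(-0.1, 0.5, 20):
                cfg = QuantConfig(ratio_threshold=thr)
                counts.append(int(call_positive(tbl, cfg)["is_positive"].sum()))
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBrightSelection:
    @pytest.mark.parametrize("n_pos,expected_k", [(10, 3), (7, 2), (1, 1), (2, 1)])
    def test_top_30_percent_count(self, n_pos, expected_k, default_quant_config):
        tbl = scored_table(np.linspace(0.2, 0.9, n_pos))
        tbl["is_positive"] = True
        bright = select_brightest(tbl, default_quant_config)
        assert len(bright) == expected_k
        assert bright["ratio"].min() >= tbl["ratio"].max() - 1e-12 or \
            bright["ratio"].min() == sorted(tbl["ratio"], reverse=True)[expected_k - 1]

    def test_no_positives_gives_empty_selection(self, default_quant_config):
        tbl = scored_table([0.05, 0.01])
        tbl["is_positive"] = False
        assert len(select_brightest(tbl, default_quant_config)) == 0

    def test_ties_broken_by_nucleus_id(self, default_quant_config):
        tbl = scored_table([0.5, 0.5, 0.5, 0.5])
        tbl["is_positive"] = True
        bright = select_brightest(tbl, default_quant_config)
        assert list(bright["nucleus_id"]) == [0]


class TestTierProfile:
    def test_per_tier_means_match_hand_binning(self):
        tbl = pd.DataFrame({
            "nucleus_id": range(12),
            "ratio": [0.4, 0.2, 0.3, 0.5, 0.25, 0.35, 0.45, 0.15, 0.2, 0.3, 0.25, 0.5],
            "tier": [0.1, 0.5, 0.9, 1.2, 1.5, 1.8, 2.1, 2.5, 0.3, 1.1, 2.9, 0.7],
        })
        per_nucleus, per_tier = tier_profile(tbl)
        assert per_nucleus["norm_intensity"].max() == pytest.approx(1.0)
        hand = tbl.assign(b=np.floor(tbl["tier"]).astype(int),
                          n=tbl["ratio"] / tbl["ratio"].max())
        for b, grp in hand.groupby("b"):
            row = per_tier[per_tier["tier_bin"] == b]
            assert row["mean_norm_intensity"].iloc[0] == pytest.approx(grp["n"].mean())

    def test_empty_subset_rejected(self):
        with pytest.raises(ValidationError):
            tier_profile(pd.DataFrame(columns=["nucleus_id", "ratio", "tier"]))


class TestDomainClassification:
    @pytest.mark.parametrize("n_bright,expected", [
        (0, "absent"), (10, "strongly_reduced"), (11, "strongly_reduced"),
        (12, "present"), (22, "present"),
    ])
    def test_explant_classes(self, n_bright, expected, default_quant_config):
        assert classify_domain(n_bright, "explant", default_quant_config) == expected

    def test_embryo_uses_its_own_control_mean(self, default_quant_config):
        assert classify_domain(40, "embryo", default_quant_config) == "strongly_reduced"
        assert classify_domain(41, "embryo", default_quant_config) == "present"

    def test_monotone_in_bright_count(self, default_quant_config):
        order = {"absent": 0, "strongly_reduced": 1, "present": 2}
        levels = [order[classify_domain(n, "explant", default_quant_config)]
                  for n in range(0, 40)]
        assert all(a <= b for a, b in zip(levels, levels[1:]))

    def test_unknown_sample_kind_rejected(self, default_quant_config):
        with pytest.raises(ValidationError):
            classify_domain(5, "organoid", default_quant_config)


class TestBetaCatenin:
    def test_counts_by_tier_example(self):
        counts = bcat_counts_by_tier([10.0, 30.0, 35.0], [20.0])
        assert counts.to_dict() == {0: 1, 1: 2}

    def test_all_at_reference_in_tier_zero(self):
        counts = bcat_counts_by_tier([0.0, 0.0], [15.0, 25.0])
        assert counts.to_dict() == {0: 2}

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 200, size=137)
        counts = bcat_counts_by_tier(d, rng.uniform(15, 25, size=10))
        assert counts.sum() == 137

    def test_empty_diameter_sample_rejected(self):
        with pytest.raises(ValidationError):
            bcat_counts_by_tier([10.0], [])


class TestAngularDispersion:
    @pytest.mark.parametrize("theta", [15.0, 45.0, 80.0])
    def test_symmetric_pair_closed_form(self, theta):
        t = np.radians(theta)
        pts = np.array([[1.0, 0.0],
                        [np.cos(t), np.sin(t)], [np.cos(t), -np.sin(t)]])
        stats = angular_dispersion(pts, (0.0, 0.0), [0])
        assert stats.circular_mean_deg == pytest.approx(0.0, abs=1e-9)
        assert stats.mean_resultant_length == pytest.approx(np.cos(t), abs=1e-9)

    def test_collinear_nuclei_have_no_dispersion(self):
        pts = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        stats = angular_dispersion(pts, (0.0, 0.0), [0])
        assert stats.mean_resultant_length == pytest.approx(1.0)

    def test_uniform_angles_have_near_zero_resultant(self):
        rng = np.random.default_rng(9)
        ang = rng.uniform(-np.pi, np.pi, size=5000)
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        pts = np.vstack([[2.0, 0.0], pts])
        stats = angular_dispersion(pts, (0.0, 0.0), [0])
        assert stats.mean_resultant_length < 0.05

    def test_coincident_positives_rejected(self):
        pts = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValidationError):
            angular_dispersion(pts, (0.0, 0.0), [0])


class TestChainInvariances:
    def test_rigid_motion_of_sample_leaves_scoring_unchanged(self, explant_sample,
                                                             default_quant_config):
        """Rotating and translating nuclei and references together (about the
        projection axis) leaves every scoring output unchanged."""
        cfg, tbl, refs, proj, _ = explant_sample
        res0, _ = quantify_sample(tbl, proj, default_quant_config, "explant")

        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([55.0, -30.0, 0.0])
        tbl2 = tbl.copy()
        tbl2[["x_um", "y_um", "z_um"]] = tbl[["x_um", "y_um", "z_um"]] @ rot.T + shift
        refs2 = type(refs)(label=refs.label, sample_kind=refs.sample_kind,
                           points=refs.points @ rot.T + shift,
                           recenter_point=refs.recenter_point @ rot.T + shift)
        frame = ProjectionFrame.from_axis((0.0, 0.0, 1.0))
        proj2, _ = measure_sample(tbl2, refs2, frame, cfg.cell_diameter)
        res2, _ = quantify_sample(tbl2, proj2, default_quant_config, "explant")

        assert res2.n_considered == res0.n_considered
        assert res2.n_positive == res0.n_positive
        assert sorted(res2.bright_ids) == sorted(res0.bright_ids)
        assert res2.classification == res0.classification

    def test_common_depth_attenuation_cancels_in_calls(self, default_quant_config):
        """With noise off and an explicit background, positivity calls are
        identical with and without depth attenuation of both channels."""
        base = dict(seed=13, n_nuclei=400, intensity_noise_sd=0.0)
        frame = ProjectionFrame.from_axis((0.0, 0.0, 1.0))
        calls = {}
        for a in (0.0, 3e-3):
            cfg = SyntheticNucleiConfig(depth_attenuation_per_um=a, **base)
            tbl, refs = generate_nuclei(cfg)
            proj, _ = measure_sample(tbl, refs, frame, cfg.cell_diameter)
            filt = filter_nuclei(tbl, proj, default_quant_config)
            bgsub = subtract_background(filt, default_quant_config, background=0.0)
            scored = call_positive(compute_ratio(bgsub), default_quant_config)
            calls[a] = set(scored.loc[scored["is_positive"], "nucleus_id"])
        assert calls[0.0] == calls[3e-3]

    def test_percent_positive_increases_with_amplitude(self, default_quant_config):
        frame = ProjectionFrame.from_axis((0.0, 0.0, 1.0))
        means = []
        for amp in (20.0, 100.0):
            pcts = []
            for seed in range(5):
                cfg = SyntheticNucleiConfig(seed=seed, n_nuclei=500,
                                            gradient_amplitude=amp)
                tbl, refs = generate_nuclei(cfg)
                proj, _ = measure_sample(tbl, refs, frame, cfg.cell_diameter)
                res, _ = quantify_sample(tbl, proj, default_quant_config, "explant")
                pcts.append(res.percent_positive)
            means.append(np.mean(pcts))
        assert means[1] > means[0]
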