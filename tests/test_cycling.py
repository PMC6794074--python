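"""ROI scoring, background subtraction, cycling ANOVA and damping amplitudes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circadam import (
    CyclingSimParams,
    background_correct,
    brightest_block_mean,
    damping_amplitudes,
    render_spot_image,
    simulate_timecourse,
    timecourse_summary,
    twoway_anova,
)


def exhaustive_block_mean(image, roi, k=3):
    """Independent sliding-window oracle: explicit loops over every block."""
    h, w = image.shape
    best = None
    for i in range(h - k + 1):
        for j in range(w - k + 1):
            if roi[i:i + k, j:j + k].all():
                m = image[i:i + k, j:j + k].mean()
                best = m if best is None else max(best, m)
    return best


class TestBrightestBlock:
    def test_constant_image(self):
        assert brightest_block_mean(np.full((8, 8), 3.5)) == 3.5

    def test_isolated_block(self):
        img = np.zeros((10, 10))
        img[4:7, 4:7] = 100.0
        assert brightest_block_mean(img) == 100.0

    def test_roi_restricts_search(self):
        img = np.zeros((10, 10))
        img[0:3, 0:3] = 50.0
        roi = np.zeros((10, 10), dtype=bool)
        roi[5:10, 5:10] = True
        assert brightest_block_mean(img, roi) == 0.0

    def test_roi_without_block_rejected(self):
        roi = np.zeros((6, 6), dtype=bool)
        roi[2, 2:5] = True
        with pytest.raises(ValueError, match="3x3"):
            brightest_block_mean(np.ones((6, 6)), roi)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spots = [
            (float(rng.uniform(2, 13)), float(rng.uniform(2, 13)),
             float(rng.uniform(10, 100)), float(rng.uniform(0.8, 2.5)))
            for _ in range(3)
        ]
        img, _ = render_spot_image(16, 16, spots, background_level=5.0,
                                   noise_sd=1.0, seed=seed % 2**16)
        roi = rng.random((16, 16)) > 0.2
        roi[4:9, 4:9] = True
        assert brightest_block_mean(img, roi) == exhaustive_block_mean(img, roi)


class TestBackgroundCorrect:
    def test_mean_of_three_subtracted(self):
        assert background_correct(100.0, [10, 10, 10]) == 90.0

    def test_negative_allowed(self):
        assert background_correct(5.0, [10, 10, 10]) == -5.0

    def test_hand_computed_mean(self):
        assert background_correct(50.0, [0, 30, 30]) == 30.0

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            background_correct(10.0, [1, 2])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.floats(0.1, 10.0), st.integers(0, 2**31 - 1))
    def test_linearity(self, a, seed):
        rng = np.random.default_rng(seed)
        raw = float(rng.uniform(0, 100))
        bg = rng.uniform(0, 50, 3)
        assert np.isclose(
            background_correct(a * raw, a * bg), a * background_correct(raw, bg)
        )


class TestTimecourseSummary:
    def test_single_brain_mean_is_value(self):
        df = pd.DataFrame(
            {"brain_id": ["a", "b"], "timepoint_h": [0.0, 6.0], "intensity": [10.0, 20.0]}
        )
        with pytest.warns(UserWarning, match="fewer than 5"):
            out = timecourse_summary(df)
        assert np.array_equal(out["mean"], [10.0, 20.0])
        assert out["sem"].isna().all()

    def test_hand_computed_sem(self):
        df = pd.DataFrame(
            {"brain_id": list("abc"), "timepoint_h": 0.0, "intensity": [10.0, 20.0, 30.0]}
        )
        with pytest.warns(UserWarning):
            out = timecourse_summary(df)
        assert np.isclose(out.loc[0, "mean"], 20.0)
        assert np.isclose(out.loc[0, "sem"], 5.7735, atol=1e-4)

    def test_noise_free_means_match_cosine(self):
        p = CyclingSimParams(amplitude=40.0, noise_sd=0.0, acrophase_h=6.0, seed=0)
        out = timecourse_summary(simulate_timecourse(p))
        expected = 100.0 + 40.0 * np.cos(
            2 * np.pi * (out["timepoint_h"] - 6.0) / 24.0
        )
        assert np.allclose(out["mean"], expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            timecourse_summary(pd.DataFrame(columns=["brain_id", "timepoint_h", "intensity"]))


def balanced_design(rng, effect=0.0, n=4):
    rows = []
    for g, shift in (("ctrl", 0.0), ("exp", effect)):
        for t in (0.0, 6.0, 12.0, 18.0):
            for _ in range(n):
                rows.append(
                    {"value": rng.normal(10.0 + shift * (t == 6.0), 1.0),
                     "genotype": g, "timepoint": t}
                )
    return pd.DataFrame(rows)


class TestTwowayAnova:
    def test_flat_data_all_effects_zero(self):
        df = balanced_design(np.random.default_rng(0))
        df["value"] = 5.0
        aov = twoway_anova(df)
        assert (aov.table["F"] == 0.0).all()
        assert (aov.table["p"] == 1.0).all()

    def test_balanced_2x2_matches_ss_oracle(self, rng):
        rows = []
        for g in ("a", "b"):
            for t in (0.0, 6.0):
                for _ in range(4):
                    rows.append({"value": rng.normal(0, 1), "genotype": g, "timepoint": t})
        df = pd.DataFrame(rows)
        aov = twoway_anova(df)
        # classical balanced sums-of-squares decomposition by hand
        grand = df["value"].mean()
        cell = df.groupby(["genotype", "timepoint"])["value"].mean()
        gm = df.groupby("genotype")["value"].mean()
        tm = df.groupby("timepoint")["value"].mean()
        ss_g = 8 * ((gm - grand) ** 2).sum()
        ss_t = 8 * ((tm - grand) ** 2).sum()
        ss_cells = 4 * ((cell - grand) ** 2).sum()
        ss_i = ss_cells - ss_g - ss_t
        ss_e = sum(
            ((d["value"] - cell[key]) ** 2).sum()
            for key, d in df.groupby(["genotype", "timepoint"])
        )
        mse = ss_e / 12
        assert np.isclose(aov.effect("genotype")["F"], (ss_g / 1) / mse)
        assert np.isclose(aov.effect("timepoint")["F"], (ss_t / 1) / mse)
        assert np.isclose(aov.effect("genotype:timepoint")["F"], (ss_i / 1) / mse)
        assert aov.residual_df == 12

    def test_empty_cell_named_in_error(self):
        df = balanced_design(np.random.default_rng(1))
        df = df[~((df["genotype"] == "exp") & (df["timepoint"] == 12.0))]
        with pytest.raises(ValueError, match="exp"):
            twoway_anova(df)

    def test_detects_injected_genotype_effect(self, rng):
        detected = 0
        for _ in range(20):
            df = balanced_design(rng, effect=4.0, n=5)
            aov = twoway_anova(df)
            if min(aov.p("genotype"), aov.p("genotype:timepoint")) < 0.05:
                detected += 1
        assert detected >= 16


class TestDampingAmplitudes:
    def test_constant_timecourse_zero_amplitude(self):
        df = pd.DataFrame(
            {"brain_id": list("abcdef"),
             "timepoint_h": [0, 0, 6, 6, 12, 12], "intensity": 9.0}
        )
        out = damping_amplitudes(df)
        assert (out["amplitude"] == 0.0).all()

    def test_hand_computed_amplitudes(self):
        # per-timepoint means {10, 30, 20, 15}; peak brains {28, 32} minus min mean 10
        rows = (
            [("a", 0.0, 10.0), ("b", 0.0, 10.0)]
            + [("c", 6.0, 28.0), ("d", 6.0, 32.0)]
            + [("e", 12.0, 20.0), ("f", 12.0, 20.0)]
            + [("g", 18.0, 15.0), ("h", 18.0, 15.0)]
        )
        df = pd.DataFrame(rows, columns=["brain_id", "timepoint_h", "intensity"])
        out = damping_amplitudes(df)
        assert sorted(out["amplitude"]) == [18.0, 22.0]
        assert (out["peak_timepoint_h"] == 6.0).all()

    def test_noise_free_cosine_matches_grid_range(self):
        p = CyclingSimParams(amplitude=50.0, noise_sd=0.0, acrophase_h=0.0, seed=0)
        out = damping_amplitudes(simulate_timecourse(p))
        grid = np.asarray(p.timepoints_h)
        cos = np.cos(2 * np.pi * grid / 24.0)
        expected = 50.0 * (cos.max() - cos.min())
        assert np.allclose(out["amplitude"], expected)

    def test_amplitude_monotone_in_truth_and_damping(self):
        def est(amplitude, damping):
            p = CyclingSimParams(
                amplitude=amplitude, damping_per_day=damping,
                noise_sd=0.5, seed=8,
            )
            return damping_amplitudes(simulate_timecourse(p, n_days=3))["amplitude"].mean()

        by_amp = [est(a, 0.0) for a in (10.0, 30.0, 60.0)]
        assert by_amp[0] < by_amp[1] < by_amp[2]
        by_damp = [est(50.0, d) for d in (0.0, 0.4, 0.8)]
        assert by_damp[0] > by_damp[1] > by_damp[2]

    def test_missing_peak_brains_rejected(self):
        df = pd.DataFrame(
            {"brain_id": ["a", "b"], "timepoint_h": [0.0, 6.0], "intensity": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            damping_amplitudes(df, peak_timepoint=12.0)


class TestImageRois:
    def test_tiff_roundtrip_and_labeled_mask_scoring(self, tmp_path):
        import tifffile

        from circadam.cycling import read_image, score_rois

        img, _ = render_spot_image(
            24, 24, [(6, 6, 80.0, 1.5), (17, 17, 40.0, 1.5)],
            background_level=10.0, seed=1,
        )
        path = tmp_path / "section.tif"
        tifffile.imwrite(path, img.astype(np.float32))
        loaded = read_image(path)
        assert loaded.shape == (24, 24)

        labels = np.zeros((24, 24), dtype=np.uint8)
        labels[2:11, 2:11] = 1
        labels[13:22, 13:22] = 2
        scores = score_rois(loaded, labels, backgrounds=[10.0, 10.0, 10.0])
        assert scores["1"] > scores["2"] > 0
        roi1 = labels == 1
        assert np.isclose(
            scores["1"], brightest_block_mean(loaded, roi1) - 10.0
        )

    def test_stack_rejected(self, tmp_path):
        import tifffile

        from circadam.cycling import read_image

        tifffile.imwrite(tmp_path / "stack.tif", np.zeros((3, 8, 8), np.float32))
        with pytest.raises(ValueError, match="2-D"):
            read_image(tmp_path / "stack.tif")
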