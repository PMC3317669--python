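"""Artifact screening, contralateral pooling, window extrema, PSC, ERP averages."""

import numpy as np
import pandas as pd
import pytest

from itfuse import (
    EpochArray,
    ElectrodePairMap,
    compute_erp,
    extract_bold_features,
    extract_eeg_features,
    make_trial_schedule,
    pool_contralateral,
    reject_amplitude_artifacts,
    simulate_eeg_epochs,
)
from itfuse.features import EEG_FMRI_WINDOWS, EEG_ONLY_WINDOWS, TimeWindowSet


def toy_epochs(data, channels=("O1", "O2"), t0=-100.0, dt=2.0):
    data = np.asarray(data, dtype=float)
    times = t0 + dt * np.arange(data.shape[2])
    return EpochArray(data, times, list(channels))


class TestArtifactRejection:
    def test_sample_beyond_range_rejects_trial(self):
        data = np.zeros((3, 2, 5))
        data[1, 0, 2] = 101.0
        data[2, 1, 4] = -100.5
        rejected = reject_amplitude_artifacts(toy_epochs(data))
        assert rejected.tolist() == [False, True, True]

    def test_boundary_inclusive(self):
        data = np.full((2, 2, 4), 100.0)
        data[1] = -100.0
        assert not reject_amplitude_artifacts(toy_epochs(data)).any()

    def test_bad_limits(self):
        with pytest.raises(ValueError):
            reject_amplitude_artifacts(toy_epochs(np.zeros((1, 2, 3))), 5.0, -5.0)


class TestContralateralPooling:
    def schedule(self, hemis):
        return pd.DataFrame(
            {"trial": np.arange(len(hemis)), "hemifield": hemis}
        )

    def test_left_hemifield_takes_right_electrode(self):
        data = np.zeros((1, 2, 4))
        data[0, 0] = 1.0  # O1
        data[0, 1] = 2.0  # O2
        pooled = pool_contralateral(
            toy_epochs(data), self.schedule(["left"]), ElectrodePairMap((("O1", "O2"),))
        )
        assert pooled.channels == ["O1/2"]
        assert np.all(pooled.data == 2.0)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((4, 2, 6))
        pairs = ElectrodePairMap((("O1", "O2"),))
        a = pool_contralateral(toy_epochs(data), self.schedule(["left", "right"] * 2), pairs)
        mirrored = data[:, ::-1, :]  # swap O1 <-> O2
        b = pool_contralateral(
            toy_epochs(mirrored), self.schedule(["right", "left"] * 2), pairs
        )
        assert np.array_equal(a.data, b.data)

    def test_eight_virtual_channels_for_default_pairs(self, eeg_only_config, quiet_effects):
        sched = make_trial_schedule(eeg_only_config, 0)
        epochs, _ = simulate_eeg_epochs(sched, quiet_effects, eeg_only_config)
        pooled = pool_contralateral(epochs, sched)
        assert len(pooled.channels) == 8
        assert pooled.channels[0] == "O1/2" and "TP7/8" in pooled.channels

    def test_unmapped_channel_raises(self):
        with pytest.raises(KeyError, match="PO3"):
            pool_contralateral(
                toy_epochs(np.zeros((1, 2, 3))),
                self.schedule(["left"]),
                ElectrodePairMap((("PO3", "PO4"),)),
            )

    def test_unknown_hemifield_raises(self):
        with pytest.raises(ValueError, match="hemifield"):
            pool_contralateral(
                toy_epochs(np.zeros((1, 2, 3))),
                self.schedule(["upper"]),
                ElectrodePairMap((("O1", "O2"),)),
            )


class TestWindowFeatures:
    def test_constant_epoch_gives_constant_features(self):
        data = np.full((2, 1, 301), 3.25)
        feats = extract_eeg_features(toy_epochs(data, channels=["O1"]), EEG_ONLY_WINDOWS)
        assert len(feats) == 2 * 1 * 5
        assert (feats["value"] == 3.25).all()

    @pytest.mark.parametrize(
        "windows,expected",
        [
            (EEG_ONLY_WINDOWS, [(-100, 58), (60, 120), (122, 154), (156, 370), (372, 500)]),
            (EEG_FMRI_WINDOWS, [(-100, 58), (60, 140), (142, 188), (190, 400), (402, 500)]),
        ],
    )
    def test_window_presets(self, windows, expected):
        assert [(lo, hi) for lo, hi, _ in windows] == expected
        assert [pol for _, _, pol in windows] == ["max", "max", "min", "max", "max"]

    def test_third_window_takes_minimum(self):
        data = np.zeros((1, 1, 301))
        t = -100 + 2 * np.arange(301)
        data[0, 0, (t >= 122) & (t <= 154)] = -7.5
        feats = extract_eeg_features(toy_epochs(data, channels=["O1"]), EEG_ONLY_WINDOWS)
        w3 = feats[feats.feature_id == "O1|w3"]["value"].iloc[0]
        assert w3 == -7.5

    def test_extrema_match_bruteforce(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((5, 2, 301))
        epochs = toy_epochs(data)
        feats = extract_eeg_features(epochs, EEG_ONLY_WINDOWS)
        t = epochs.times
        for k, (lo, hi, pol) in enumerate(EEG_ONLY_WINDOWS):
            mask = (t >= lo) & (t <= hi)
            ref = data[:, :, mask].min(2) if pol == "min" else data[:, :, mask].max(2)
            for j, ch in enumerate(epochs.channels):
                got = (
                    feats[feats.feature_id == f"{ch}|w{k+1}"]
                    .set_index("trial")["value"]
                    .to_numpy()
                )
                assert np.array_equal(got, ref[:, j])

    def test_window_outside_axis_raises(self):
        windows = TimeWindowSet(
            ((-100, 58, "max"), (60, 120, "max"), (122, 154, "min"),
             (156, 370, "max"), (372, 900, "max"))
        )
        with pytest.raises(ValueError, match="outside"):
            extract_eeg_features(toy_epochs(np.zeros((1, 2, 301))), windows)

    def test_window_set_validation(self):
        with pytest.raises(ValueError, match="third"):
            TimeWindowSet(((-100, 58, "min"), (60, 120, "max"), (122, 154, "max"),
                           (156, 370, "max"), (372, 500, "max")))
        with pytest.raises(ValueError, match="overlap"):
            TimeWindowSet(((-100, 60, "max"), (58, 120, "max"), (122, 154, "min")))


class TestBoldFeatures:
    def segments(self, series):
        series = np.asarray(series, dtype=float)[None, None, :]
        times = np.arange(-4, 12, 2.0)
        return EpochArray(series, times[: series.shape[2]], ["V1"], time_unit="s")

    def test_direct_formula(self):
        # baseline volumes 100, 100 -> peak 102 gives 2.0 % signal change
        seg = self.segments([100, 100, 100, 101, 102, 100.5, 100, 100])
        feats = extract_bold_features(seg)
        assert feats["value"].iloc[0] == pytest.approx(2.0)

    def test_flat_course_gives_zero(self):
        feats = extract_bold_features(self.segments([100.0] * 8))
        assert feats["value"].iloc[0] == 0.0

    def test_peak_outside_post_window_ignored(self):
        series = np.full(10, 100.0)
        series[3] = 101.0  # 2 s post-stimulus
        series[-1] = 110.0  # 14 s: outside the 10 s window
        seg = EpochArray(series[None, None, :], np.arange(-4, 16, 2.0), ["V1"],
                         time_unit="s")
        feats = extract_bold_features(seg, post_window_s=10.0)
        assert feats["value"].iloc[0] == pytest.approx(1.0)

    def test_zero_baseline_raises(self):
        with pytest.raises(ValueError, match="baseline"):
            extract_bold_features(self.segments([0, 0, 0, 2, 3, 1, 0, 0]))

    def test_needs_two_prestim_volumes(self):
        seg = EpochArray(np.ones((1, 1, 5)), np.arange(0, 10, 2.0), ["V1"], time_unit="s")
        with pytest.raises(ValueError, match="pre-stimulus"):
            extract_bold_features(seg)


class TestERP:
    def test_baseline_correction_zeroes_prestim_mean(self, eeg_only_config):
        sched = make_trial_schedule(eeg_only_config, 0)
        from itfuse import EffectSpec

        epochs, _ = simulate_eeg_epochs(sched, EffectSpec(), eeg_only_config)
        erp = compute_erp(epochs, sched, by=("informativeness",))
        for _, grp in erp.groupby("informativeness"):
            base = grp[(grp.time_ms >= -100) & (grp.time_ms <= 0)]["amplitude"]
            assert abs(base.mean()) < 1e-10

    def test_mean_of_identical_epochs_is_identity(self):
        wave = np.sin(np.linspace(0, 3, 301))
        wave -= wave[:51].mean()  # already baseline-zero
        data = np.tile(wave, (6, 1, 1))
        epochs = toy_epochs(data, channels=["O1"])
        sched = pd.DataFrame({"trial": np.arange(6), "informativeness": "high"})
        erp = compute_erp(epochs, sched, by=("informativeness",))
        assert np.allclose(erp["amplitude"].to_numpy(), wave, atol=1e-12)

    def test_p300_window_contrast_recovers_injected_effect(self, eeg_only_config):
        from itfuse import EffectSpec

        sched = make_trial_schedule(eeg_only_config, 0)
        eff = EffectSpec(p300_informativeness_delta=2.5, noise_sd_eeg=1.0)
        epochs, _ = simulate_eeg_epochs(sched, eff, eeg_only_config)
        pooled = pool_contralateral(epochs, sched)
        erp = compute_erp(pooled, sched, by=("informativeness",))
        t = erp["time_ms"]
        w4 = (t >= 156) & (t <= 370)
        low = erp[(erp.informativeness == "low") & w4]["amplitude"].mean()
        high = erp[(erp.informativeness == "high") & w4]["amplitude"].mean()
        assert low > high

    def test_empty_condition_cell_raises(self):
        epochs = toy_epochs(np.zeros((2, 2, 301)))
        sched = pd.DataFrame({"trial": [0, 1], "informativeness": ["high", "high"]})
        sched["informativeness"] = pd.Categorical(sched["informativeness"],
                                                  categories=["high", "low"])
        with pytest.raises(ValueError, match="no trials"):
            compute_erp(epochs, sched, by=("informativeness",))
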