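"""fNIRS chain: pruning, OD, motion PCA, MBLL, epochs and peak HbO2."""

from dataclasses import replace

import numpy as np
import pytest

from stopcancel import fnirs as fn
from stopcancel import synthgen as sg
from stopcancel.errors import ConfigurationError, ProcessingError
from stopcancel.fnirs import (
    Channel,
    Domain,
    FnirsEvent,
    HaemoSeries,
    Hemisphere,
    default_montage,
    detect_motion,
    epoch_and_average,
    expected_epoch_peak_gain,
    hemisphere_average,
    lowpass_haemo,
    od_to_concentration,
    pca_motion_correct,
    peak_hbo2,
    prune_channels,
    to_optical_density,
)

FS = 7.8125


def series_from(data, channels=None, domain=Domain.INTENSITY, events=()):
    data = np.asarray(data, float)
    if channels is None:
        channels = [Channel(i, i, 30.0, Hemisphere.LEFT, f"L{i}") for i in range(data.shape[0])]
    return HaemoSeries(channels=channels, data=data, fs=FS, events=list(events), domain=domain)


def clean_sim(amplitude=0.5, duration=200.0, events_at=(40.0, 90.0, 140.0), seed=0, **kw):
    params = sg.HaemoSimParams(
        amplitude_by_condition={"A": amplitude}, cardiac_amp_od=0, resp_amp_od=0,
        mayer_amp_od=0, white_noise_od=0, motion_spike_rate_per_min=0, **kw)
    events = [FnirsEvent(t, "A", "x") for t in events_at]
    return sg.simulate_fnirs(params, events, duration, np.random.default_rng(seed))


class TestPrune:
    def test_low_snr_removed(self, rng):
        data = np.full((2, 2, 400), 2.0)
        data[1] += 1.4 * rng.standard_normal((2, 400))  # SNR ~ 1.4
        data = np.clip(data, 0.2, None)
        pruned, removed = prune_channels(series_from(data))
        assert len(pruned.channels) == 1
        assert removed[0][0] == "L1" and "SNR" in removed[0][1]

    def test_wide_separation_removed(self):
        channels = [Channel(0, 0, 30.0, Hemisphere.LEFT, "ok"),
                    Channel(1, 1, 50.0, Hemisphere.LEFT, "far")]
        pruned, removed = prune_channels(series_from(np.full((2, 2, 100), 2.0), channels))
        assert [c.label for c in pruned.channels] == ["ok"]
        assert "separation" in removed[0][1]

    def test_out_of_range_intensity_removed(self):
        data = np.full((2, 2, 100), 2.0)
        data[1] = 0.5  # below dRange
        _, removed = prune_channels(series_from(data))
        assert "intensity" in removed[0][1]

    def test_clean_montage_untouched(self):
        series, _ = clean_sim()
        pruned, removed = prune_channels(series)
        assert removed == [] and len(pruned.channels) == len(series.channels)

    def test_all_removed_is_fatal(self):
        with pytest.raises(ProcessingError):
            prune_channels(series_from(np.full((1, 2, 100), 0.5)))


class TestOpticalDensity:
    def test_constant_intensity_zero_od(self):
        od = to_optical_density(series_from(np.full((1, 2, 100), 2.0)))
        assert np.allclose(od.data, 0.0)
        assert od.domain is Domain.OD

    def test_two_sample_closed_form(self):
        a, b = 2.0, 2.0 * np.e
        od = to_optical_density(series_from(np.array([[[a, b], [a, b]]])))
        mean = (a + b) / 2
        assert od.data[0, 0, 0] == pytest.approx(-np.log(a / mean))
        assert od.data[0, 0, 1] == pytest.approx(-np.log(b / mean))

    def test_uniform_scaling_invariant(self, rng):
        base = 2.0 + 0.1 * rng.standard_normal((2, 2, 300))
        od1 = to_optical_density(series_from(base))
        od2 = to_optical_density(series_from(base / 2.0))
        assert np.allclose(od1.data, od2.data)

    def test_nonpositive_intensity_names_channel(self):
        data = np.full((1, 2, 10), 2.0)
        data[0, 0, 3] = 0.0
        with pytest.raises(ProcessingError, match="L0"):
            to_optical_density(series_from(data))


class TestMotion:
    def test_clean_recording_unflagged(self):
        params = sg.HaemoSimParams(motion_spike_rate_per_min=0)
        series, _ = sg.simulate_fnirs(params, [FnirsEvent(30.0, "GO")], 120.0,
                                      np.random.default_rng(1))
        assert not detect_motion(to_optical_density(series)).any()

    def test_dilation_spans_tmask_each_side(self):
        data = np.zeros((1, 2, 400))
        data[:, :, 200] = 5.0  # isolated excursion in OD units
        od = series_from(2.0 * np.exp(-data))
        od = to_optical_density(od)
        mask = detect_motion(od, amp_thresh=1.0)
        run = np.flatnonzero(mask)
        assert run.size >= 2 * int(round(1.0 * FS))
        assert 200 in run

    def test_empty_mask_is_identity(self):
        series, _ = clean_sim()
        od = to_optical_density(series)
        corrected, report = pca_motion_correct(od, np.zeros(od.n_times, bool))
        assert report["iterations"] == 0
        assert np.array_equal(corrected.data, od.data)

    def test_rank_one_artifact_removed(self):
        series, _ = clean_sim()
        od = to_optical_density(series)
        clean = od.data.copy()
        t = od.times_s
        art = np.zeros(od.n_times)
        for t0 in (60.0, 120.0, 180.0):
            i0 = int(round(t0 * FS))
            art[i0:] += 0.4 * np.exp(-(t[i0:] - t[i0]) / 0.25)
        rng = np.random.default_rng(2)
        scales = 1 + 0.1 * rng.standard_normal(od.data.shape[0] * od.data.shape[1])
        od = replace(od, data=clean + (scales[:, None] * art[None, :]).reshape(od.data.shape))
        mask = detect_motion(od)
        assert mask.any()
        corrected, report = pca_motion_correct(od, mask)
        assert report["iterations"] <= 5
        resid = corrected.data - clean
        injected = (scales[:, None] * art[None, :]).reshape(od.data.shape)
        reduction = 1 - (resid[:, :, mask] ** 2).mean() / (injected[:, :, mask] ** 2).mean()
        assert reduction > 0.90

    def test_small_segment_skips_pca(self, caplog):
        data = np.zeros((30, 2, 300))
        data[:, :, 150] = 5.0
        od = series_from(2.0 * np.exp(-data),
                         channels=[Channel(i, i, 30.0, Hemisphere.LEFT, f"L{i}") for i in range(30)])
        od = to_optical_density(od)
        mask = np.zeros(300, bool)
        mask[148:153] = True  # 5 samples < 60 channel-wavelength variables
        _, report = pca_motion_correct(od, mask)
        assert report["warnings"]


class TestLowpass:
    def attenuation(self, f_hz):
        n = int(600 * FS)
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * f_hz * t)
        od = series_from(x[None, None, :].repeat(2, axis=1), domain=Domain.OD)
        y = lowpass_haemo(od).data[0, 0, int(50 * FS):-int(50 * FS)]
        return np.sqrt((y**2).mean()) / np.sqrt(0.5)

    def test_cardiac_band_attenuated(self):
        assert self.attenuation(1.0) < 0.2  # >80% amplitude reduction

    def test_slow_haemodynamics_preserved(self):
        assert self.attenuation(0.05) > 0.95

    def test_dc_preserved_exactly(self):
        od = series_from(np.full((1, 2, 500), 0.37), domain=Domain.OD)
        assert np.allclose(lowpass_haemo(od).data, 0.37, atol=1e-9)


class TestMBLL:
    def test_zero_od_zero_concentration(self):
        conc = od_to_concentration(series_from(np.zeros((1, 2, 50)), domain=Domain.OD))
        assert np.allclose(conc.data, 0.0)
        assert conc.domain is Domain.CONC

    def test_hbt_is_sum(self, rng):
        od = series_from(0.01 * rng.standard_normal((3, 2, 200)), domain=Domain.OD)
        conc = od_to_concentration(od)
        assert np.allclose(conc.data[:, 2], conc.data[:, 0] + conc.data[:, 1])

    def test_forward_inverse_roundtrip_exact(self):
        series, _ = clean_sim(amplitude=0.5)
        conc = od_to_concentration(to_optical_density(series))
        epochs, _ = epoch_and_average(conc)
        ep = epochs[("A", "x", series.channels[0].label)]
        gain, _ = expected_epoch_peak_gain()
        value, t_peak = peak_hbo2(ep)
        assert value / gain == pytest.approx(0.5, rel=1e-9)
        assert 4.0 <= t_peak <= 7.0

    def test_pure_hbo2_crosstalk_bounded(self):
        series, _ = clean_sim(amplitude=0.5, hbr_ratio=0.0)
        conc = od_to_concentration(to_optical_density(series))
        epochs, _ = epoch_and_average(conc)
        ep = epochs[("A", "x", series.channels[0].label)]
        gain, _ = expected_epoch_peak_gain()
        assert np.abs(ep.series[1]).max() < 0.05 * 0.5 * gain  # HbR ~ 0

    def test_singular_extinction_rejected(self):
        od = series_from(np.zeros((1, 2, 10)), domain=Domain.OD)
        with pytest.raises(ConfigurationError):
            od_to_concentration(od, extinction=np.ones((2, 2)))


class TestRegionsAndEpochs:
    def conc_of(self, series):
        return od_to_concentration(to_optical_density(series))

    def test_identical_channels_average_to_one(self):
        series, _ = clean_sim()
        conc = self.conc_of(series)
        regional, missing = hemisphere_average(conc)
        assert missing == []
        left = [i for i, c in enumerate(conc.channels) if c.hemisphere is Hemisphere.LEFT]
        assert np.allclose(regional.data[0], conc.data[left[0]])

    def test_midline_excluded(self):
        series, _ = clean_sim()
        conc = self.conc_of(series)
        perturbed = conc.data.copy()
        mid = [i for i, c in enumerate(conc.channels) if c.hemisphere is Hemisphere.MIDLINE]
        perturbed[mid] += 99.0
        regional_a, _ = hemisphere_average(conc)
        regional_b, _ = hemisphere_average(replace(conc, data=perturbed))
        assert np.allclose(regional_a.data, regional_b.data)

    def test_missing_hemisphere_flagged(self):
        series, _ = clean_sim()
        conc = self.conc_of(series)
        left_only = [i for i, c in enumerate(conc.channels) if c.hemisphere is not Hemisphere.RIGHT]
        sub = replace(conc, channels=[conc.channels[i] for i in left_only], data=conc.data[left_only])
        _, missing = hemisphere_average(sub)
        assert missing == ["RIGHT"]

    def test_baseline_zeroed(self):
        series, _ = clean_sim()
        epochs, _ = epoch_and_average(self.conc_of(series))
        ep = next(iter(epochs.values()))
        t = ep.times_s
        base = ep.series[:, (t >= 0) & (t <= 2)].mean(axis=1)
        assert np.allclose(base, 0.0, atol=1e-12)

    def test_identical_epochs_zero_ci(self):
        series, _ = clean_sim(events_at=(40.0, 90.0, 140.0))
        epochs, _ = epoch_and_average(self.conc_of(series))
        ep = next(iter(epochs.values()))
        assert ep.n_trials == 3
        assert np.allclose(ep.ci_hi - ep.ci_lo, 0.0, atol=1e-12)

    def test_single_event_group_mean_is_itself(self):
        series, _ = clean_sim(events_at=(40.0,))
        epochs, _ = epoch_and_average(self.conc_of(series))
        ep = next(iter(epochs.values()))
        assert ep.n_trials == 1
        assert np.allclose(ep.ci_hi, ep.series)

    def test_event_near_end_dropped(self):
        series, _ = clean_sim(events_at=(40.0, 195.0), duration=200.0)
        epochs, dropped = epoch_and_average(self.conc_of(series))
        assert len(dropped) == 1 and dropped[0].time_s == 195.0
        assert next(iter(epochs.values())).n_trials == 1

    def test_peak_at_boundary_for_monotone_decreasing(self):
        n = int(round(10 * FS)) + 1
        seriesarr = np.linspace(1.0, 0.0, n)[None, :].repeat(3, axis=0)
        ep = fn.HaemoEpoch(series=seriesarr, fs=FS, n_trials=1,
                           ci_lo=seriesarr, ci_hi=seriesarr)
        _, t_peak = peak_hbo2(ep)
        t = ep.times_s
        first_in_window = t[(t >= 4.0)][0]
        assert t_peak == pytest.approx(first_in_window)

    def test_constant_shift_moves_peak_by_constant(self):
        series, _ = clean_sim()
        epochs, _ = epoch_and_average(self.conc_of(series))
        ep = next(iter(epochs.values()))
        v0, _ = peak_hbo2(ep)
        shifted = replace(ep, series=ep.series + 0.123)
        v1, _ = peak_hbo2(shifted)
        assert v1 - v0 == pytest.approx(0.123)

    def test_amplitude_scaling_is_linear(self):
        gains = []
        for amp in (0.4, 0.8):
            series, _ = clean_sim(amplitude=amp)
            epochs, _ = epoch_and_average(self.conc_of(series))
            ep = epochs[("A", "x", series.channels[0].label)]
            gains.append(peak_hbo2(ep)[0])
        assert gains[1] == pytest.approx(2 * gains[0], rel=1e-12)


class TestSnirfRoundtrip:
    def test_write_read_roundtrip(self, tmp_path):
        series, _ = clean_sim(duration=100.0, events_at=(40.0,))
        path = tmp_path / "rec.snirf"
        fn.write_snirf(series, path)
        back = fn.read_snirf(path)
        assert np.allclose(back.data, series.data)
        assert back.fs == pytest.approx(series.fs, rel=1e-6)
        assert [c.label for c in back.channels] == [c.label for c in series.channels]
        assert back.events[0].condition == "A"
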