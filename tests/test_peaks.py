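"""Significance segments, peak windows, subject peak extraction, SNR."""
import numpy as np
import pytest

from oddmark.peaks import (PeakWindow, SignificanceProfile, compute_snr,
                           extract_peaks, select_peak_window,
                           timepoint_ttests)


def profile_from(time_ms, segments, alpha=0.001):
    return SignificanceProfile(time_ms=np.asarray(time_ms, float),
                               t_values=np.zeros(len(time_ms)),
                               p_values=np.ones(len(time_ms)),
                               alpha=alpha, min_run_ms=10.0,
                               segments=list(segments))


class TestTimepointTTests:
    def test_null_data_no_segments(self, rng):
        base = rng.normal(size=(6, 300))
        t = np.arange(300.0)
        prof = timepoint_ttests(base, base.copy(), t)
        assert prof.segments == []

    def test_run_length_rule(self, rng):
        """A 12 ms sub-alpha run survives; a 6 ms run is discarded (1 kHz)."""
        n_sub, n_t = 8, 400
        t = np.arange(n_t, dtype=float)
        std = rng.normal(scale=0.1, size=(n_sub, n_t))
        dev = std + rng.normal(scale=0.1, size=(n_sub, n_t))
        dev[:, 100:112] += 5.0  # 12 consecutive samples
        dev[:, 200:206] += 5.0  # 6 samples: too short
        prof = timepoint_ttests(std, dev, t, alpha=0.001, min_run_ms=10)
        assert len(prof.segments) == 1
        s, e = prof.segments[0]
        assert s == 100 and e == 111

    def test_matches_hand_computed_paired_t(self):
        """Five-subject toy at one timepoint against the textbook formula."""
        std = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        dev = np.array([[2.0], [2.5], [4.5], [4.0], [7.0]])
        d = (dev - std).ravel()
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        from scipy import stats as ss
        p_hand = 2 * ss.t.sf(abs(t_hand), 4)
        prof = timepoint_ttests(std, dev, np.array([0.0]), alpha=0.5,
                                min_run_ms=0.0)
        assert prof.t_values[0] == pytest.approx(t_hand, abs=1e-10)
        assert prof.p_values[0] == pytest.approx(p_hand, abs=1e-10)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            timepoint_ttests(np.zeros((2, 5)), np.zeros((2, 5)),
                             np.arange(5.0))

    def test_zero_variance_convention(self):
        std = np.zeros((4, 2))
        dev = np.zeros((4, 2))
        dev[:, 0] = 1.0  # identical nonzero difference: p -> 0
        prof = timepoint_ttests(std, dev, np.array([0.0, 1.0]),
                                min_run_ms=0.0)
        assert prof.p_values[0] == 0.0
        assert prof.p_values[1] == 1.0

    def test_alpha_monotonicity(self, rng):
        """Raising alpha never shortens any significant segment."""
        std = rng.normal(size=(6, 500))
        dev = std + 0.3 * rng.normal(size=(6, 500)) + 0.4
        t = np.arange(500.0)
        lo = timepoint_ttests(std, dev, t, alpha=0.001)
        hi = timepoint_ttests(std, dev, t, alpha=0.01)
        lo_mask = lo.segment_mask()
        hi_mask = hi.segment_mask()
        # every timepoint significant at the stricter level stays inside a
        # (possibly longer) run at the looser level unless its run was short
        assert (lo_mask & ~hi_mask).sum() == 0


class TestSelectWindow:
    def test_window_centers_on_extremum(self):
        t = np.arange(-100.0, 500.0)
        gd = -np.exp(-0.5 * ((t - 154) / 25) ** 2)
        prof = profile_from(t, [(120, 200)])
        win = select_peak_window(gd, prof, "MMN", condition="AV")
        assert win.center_ms == 154
        assert (win.start_ms, win.end_ms) == (104, 204)
        assert win.end_ms - win.start_ms == 100

    def test_edge_clipping_preserves_width(self):
        t = np.arange(-100.0, 551.0)
        gd = np.exp(-0.5 * ((t - 520) / 30) ** 2)
        prof = profile_from(t, [(480, 545)])
        win = select_peak_window(gd, prof, "P300",
                                 search_range_ms=(400, 545))
        assert (win.start_ms, win.end_ms) == (450, 550)
        assert win.center_ms == 520

    def test_trough_outside_range_ignored(self):
        """With a deeper trough outside 100-250 ms, the window still centers
        on the in-range trough (the 'second most negative' case)."""
        t = np.arange(-100.0, 500.0)
        gd = (-2.0 * np.exp(-0.5 * ((t - 320) / 20) ** 2)
              - 1.0 * np.exp(-0.5 * ((t - 150) / 20) ** 2))
        prof = profile_from(t, [(100, 400)])
        win = select_peak_window(gd, prof, "MMN")
        assert win.center_ms == 150

    def test_not_detected_returns_none(self):
        t = np.arange(-100.0, 500.0)
        prof = profile_from(t, [(300, 340)])
        assert select_peak_window(np.zeros_like(t), prof, "MMN") is None


class TestExtractPeaks:
    def test_analytic_sine_trough(self):
        t = np.arange(0.0, 400.0)
        diff = np.zeros_like(t)
        seg = (t >= 136) & (t <= 235)
        diff[seg] = -np.sin(np.pi * (t[seg] - 136) / 99)
        win = PeakWindow("MMN", "A", 136, 235, 185)
        pm = extract_peaks(diff, t, win, subject_id="S00")
        assert pm.latency_ms in (185, 186)
        assert pm.amplitude_uV == pytest.approx(-1.0, abs=1e-3)

    def test_all_zero_tie_goes_to_window_start(self):
        t = np.arange(0.0, 300.0)
        win = PeakWindow("P300", "A", 100, 200, 150)
        pm = extract_peaks(np.zeros_like(t), t, win)
        assert pm.latency_ms == 100
        assert pm.amplitude_uV == 0

    def test_window_outside_epoch_rejected(self):
        t = np.arange(0.0, 100.0)
        win = PeakWindow("MMN", "A", 50, 150, 100)
        with pytest.raises(ValueError, match="exceeds"):
            extract_peaks(np.zeros_like(t), t, win)

    def test_zero_noise_exact_recovery(self, small_montage):
        """Noiseless cohort: extraction recovers injected latency to the
        sample and amplitude at the best channel to 1e-9 uV."""
        from oddmark.paradigm import (NoiseModel, ParadigmConfig,
                                      SubjectSimConfig, simulate_condition)

        sim = SubjectSimConfig(montage=small_montage,
                               noise=NoiseModel(1.0, 0.0, 0.0),
                               latency_jitter_sd_ms=0.0,
                               amplitude_jitter_sd_uV=0.0)
        par = ParadigmConfig(n_trials_per_condition=20, block_size=5)
        ep, truth = simulate_condition(sim, par, 0, "A")
        best = small_montage.index(truth["MMN"]["best_channel"])
        diff = ep.difference_wave()[best]
        lat0 = truth["MMN"]["latency_ms"]
        win = PeakWindow("MMN", "A", lat0 - 50, lat0 + 50, lat0)
        pm = extract_peaks(diff, ep.time_ms, win)
        assert pm.latency_ms == pytest.approx(lat0, abs=0.5)
        comps = sim.components["A"]["deviant_extra"]
        expected = sum(c.topography[best] * c.waveform(pm.latency_ms)
                       for c in comps)
        assert pm.amplitude_uV == pytest.approx(expected, abs=1e-9)


class TestSnr:
    def test_noiseless_snr_is_100(self, small_montage):
        from oddmark.paradigm import (NoiseModel, ParadigmConfig,
                                      SubjectSimConfig, simulate_condition)

        sim = SubjectSimConfig(montage=small_montage,
                               noise=NoiseModel(1.0, 0.0, 0.0))
        par = ParadigmConfig(n_trials_per_condition=20, block_size=5)
        ep, _ = simulate_condition(sim, par, 0, "A")
        per_chan, mean = compute_snr(ep)
        # Gaussian component tails leak marginally into the baseline, so the
        # dispersion term is tiny rather than exactly zero
        assert np.all(per_chan > 99.5)
        assert mean == pytest.approx(100.0, abs=0.5)

    def test_hand_computed_formula(self, epochs_factory):
        data = np.zeros((2, 8, 300))
        t = np.arange(300) - 200.0
        wave = np.where(t > 0, np.sin(t / 10.0), 0.05 * np.sin(t))
        data[:, :, :] = wave
        ep = epochs_factory(data, tmin_ms=-200.0)
        per_chan, mean = compute_snr(ep, (-200.0, 0.0))
        erp = wave
        p2p = erp.max() - erp.min()
        sd = erp[(t >= -200) & (t <= 0)].std()
        assert mean == pytest.approx(100 * (p2p - sd) / p2p, abs=1e-9)

    def test_flat_channel_excluded(self, epochs_factory, rng):
        data = rng.normal(size=(3, 8, 100))
        data[:, 5, :] = 0.0
        ep = epochs_factory(data, tmin_ms=-50)
        with pytest.warns(RuntimeWarning, match="zero peak-to-peak"):
            per_chan, mean = compute_snr(ep, (-50.0, 0.0))
        assert np.isnan(per_chan[5])
        assert np.isfinite(mean)

    def test_epoch_dispersion_variant(self, epochs_factory, rng):
        data = rng.normal(size=(4, 8, 200))
        ep = epochs_factory(data, tmin_ms=-100)
        _, m_base = compute_snr(ep, (-100.0, 0.0), dispersion="avg_baseline")
        _, m_epoch = compute_snr(ep, dispersion="avg_epoch")
        assert np.isfinite(m_base) and np.isfinite(m_epoch)

    def test_single_trial_rejected(self, epochs_factory):
        ep = epochs_factory(np.zeros((1, 8, 50)))
        with pytest.raises(ValueError, match="2 trials"):
            compute_snr(ep)
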