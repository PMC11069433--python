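"""Filtering, baseline, rereferencing, rejection, equalization, interpolation."""
import numpy as np
import pytest

from oddmark.epochs import DEVIANT, STANDARD
from oddmark.preprocessing import (PreprocConfig, bandlimit, baseline_correct,
                                   equalize_counts, equalize_epochs,
                                   interpolate_channel, preprocess,
                                   regress_out, reject_amplitude, rereference)


class TestBandlimit:
    def test_passband_sinusoid_preserved(self, epochs_factory):
        """A 10 Hz sinusoid passes with <1% amplitude change and zero phase
        shift (judged away from the high-pass settling transient)."""
        fs, n = 1000.0, 200000
        t = np.arange(n) / fs
        sine = np.sin(2 * np.pi * 10 * t)
        data = sine[None, None, :].repeat(2, axis=1)
        from tests.conftest import make_epochs
        from oddmark.montage import SensorMontage

        mon = SensorMontage(["A1", "A2"], np.array([[0, 0, 1.0], [0, 1.0, 0]]))
        ep = make_epochs(mon, data, fs=fs, tmin_ms=0)
        out = bandlimit(ep, PreprocConfig())
        mid = slice(80000, 120000)
        ratio = np.ptp(out.data[0, 0, mid]) / np.ptp(data[0, 0, mid])
        assert ratio == pytest.approx(1.0, abs=0.01)
        # zero-phase: the input's peak sample is still at the maximum
        peak = 80000 + int(np.argmax(data[0, 0, mid]))
        assert out.data[0, 0, peak] == pytest.approx(out.data[0, 0, mid].max(),
                                                     abs=1e-3)

    def test_stopband_sinusoid_removed(self, epochs_factory):
        """100 Hz lies far above the 45 Hz cutoff: the forward-backward
        Butterworth leaves <1% of the input amplitude."""
        fs, n = 1000.0, 200000
        t = np.arange(n) / fs
        data = np.sin(2 * np.pi * 100 * t)[None, None, :].repeat(2, axis=1)
        from tests.conftest import make_epochs
        from oddmark.montage import SensorMontage

        mon = SensorMontage(["A1", "A2"], np.array([[0, 0, 1.0], [0, 1.0, 0]]))
        ep = make_epochs(mon, data, fs=fs, tmin_ms=0)
        out = bandlimit(ep, PreprocConfig())
        mid = slice(80000, 120000)
        assert np.abs(out.data[0, 0, mid]).max() < 0.01

    def test_dc_removed(self, epochs_factory):
        data = np.full((1, 8, 30000), 7.0)
        ep = epochs_factory(data, fs=1000.0, tmin_ms=0)
        out = bandlimit(ep, PreprocConfig())
        mid = slice(10000, 20000)
        assert np.abs(out.data[0, 0, mid]).max() < 0.07  # >=40 dB down

    def test_erp_bump_shape_preserved(self, epochs_factory):
        """The band limits leave a 30 ms Gaussian deflection essentially
        untouched (latency exactly, amplitude within 2%)."""
        fs, n = 1000.0, 1051
        t = np.arange(n) - 500.0
        bump = np.exp(-0.5 * ((t - 180) / 30.0) ** 2)
        data = np.tile(bump, (1, 8, 1))
        ep = epochs_factory(data, fs=fs, tmin_ms=-500)
        out = bandlimit(ep, PreprocConfig())
        assert np.argmax(out.data[0, 0]) == np.argmax(bump)
        # the short-epoch high-pass settling transient costs a few percent
        assert out.data[0, 0].max() == pytest.approx(1.0, abs=0.05)

    def test_lowpass_above_nyquist_rejected(self, epochs_factory):
        data = np.zeros((1, 8, 100))
        ep = epochs_factory(data, fs=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandlimit(ep, PreprocConfig(lowpass_hz=45.0))


class TestBaseline:
    def test_constant_trial_zeroed(self, epochs_factory):
        ep = epochs_factory(np.full((3, 8, 300), 5.0), tmin_ms=-200)
        out = baseline_correct(ep, (-200, 0))
        assert np.abs(out.data).max() < 1e-9

    def test_idempotent(self, epochs_factory, rng):
        ep = epochs_factory(rng.normal(size=(2, 8, 300)), tmin_ms=-200)
        once = baseline_correct(ep, (-150, 0))
        twice = baseline_correct(once, (-150, 0))
        assert np.abs(once.data - twice.data).max() < 1e-12

    def test_ramp_subtracts_hand_computed_mean(self, epochs_factory):
        """0->1 uV ramp over [-200, 0] at 1 kHz: the subtracted value is the
        arithmetic mean of the 201 baseline samples."""
        n = 400
        data = np.zeros((1, 8, n))
        tmin = -200.0
        time = tmin + np.arange(n)
        base = (time >= -200) & (time <= 0)
        ramp = np.linspace(0, 1, base.sum())
        data[0, :, base] = ramp[:, None]
        ep = epochs_factory(data, tmin_ms=tmin)
        out = baseline_correct(ep, (-200, 0))
        expected = data[0, 0] - ramp.mean()
        assert np.allclose(out.data[0, 0], expected, atol=1e-12)

    def test_empty_window_rejected(self, epochs_factory):
        ep = epochs_factory(np.zeros((1, 8, 100)), tmin_ms=-50)
        with pytest.raises(ValueError, match="no samples"):
            baseline_correct(ep, (-400, -300))


class TestRereference:
    def test_average_reference_zero_sum(self, epochs_factory, rng):
        ep = epochs_factory(rng.normal(size=(3, 8, 50)))
        out = rereference(ep, "average")
        assert np.abs(out.data.sum(axis=1)).max() < 1e-9

    def test_zero_mastoids_identity(self, epochs_factory, rng):
        data = rng.normal(size=(2, 8, 40))
        m1 = 6  # montage order: ..., M1, M2
        data[:, m1:, :] = 0.0
        ep = epochs_factory(data)
        out = rereference(ep, "linked_mastoids")
        assert np.allclose(out.data, data)

    def test_linked_mastoid_hand_arithmetic(self, epochs_factory):
        data = np.zeros((1, 8, 3))
        data[0, :, 0] = 10.0
        data[0, 6, 0] = 2.0  # M1
        data[0, 7, 0] = 4.0  # M2
        ep = epochs_factory(data)
        out = rereference(ep, "linked_mastoids")
        assert out.data[0, 0, 0] == pytest.approx(7.0)  # 10 - (2+4)/2
        assert out.data[0, 6, 0] == pytest.approx(-1.0)

    def test_missing_mastoid_named(self, montage64, rng):
        from tests.conftest import make_epochs
        from oddmark.montage import SensorMontage

        names = ["Fz", "Cz", "Pz"]
        pos = np.array([montage64.positions[montage64.index(n)] for n in names])
        ep = make_epochs(SensorMontage(names, pos),
                         rng.normal(size=(1, 3, 10)))
        with pytest.raises(ValueError, match="M1"):
            rereference(ep, "linked_mastoids")

    def test_baseline_rereference_commute(self, epochs_factory, rng):
        """On data whose baseline mean is already zero the two operations
        commute to numerical precision."""
        data = rng.normal(size=(2, 8, 300))
        ep = epochs_factory(data, tmin_ms=-200)
        ep = baseline_correct(ep, (-200, 0))
        a = rereference(baseline_correct(ep, (-200, 0)), "average")
        b = baseline_correct(rereference(ep, "average"), (-200, 0))
        assert np.abs(a.data - b.data).max() < 1e-9


class TestReject:
    def test_single_excursion_dropped(self, epochs_factory):
        data = np.zeros((3, 8, 50))
        data[1, 4, 10] = 101.0
        ep = epochs_factory(data)
        kept, report = reject_amplitude(ep, 100.0)
        assert kept.n_trials == 2
        assert report["dropped_trials"] == [1]
        assert report["offending_channels"][1] == ["Oz"]

    def test_threshold_is_strict(self, epochs_factory):
        data = np.full((4, 8, 20), 99.0)
        data[0] = 100.0  # exactly at threshold: kept
        data[1] = -100.0
        ep = epochs_factory(data)
        kept, report = reject_amplitude(ep, 100.0)
        assert kept.n_trials == 4 and report["n_dropped"] == 0

    def test_constructed_violations(self, epochs_factory, rng):
        data = rng.normal(scale=10, size=(10, 8, 30))
        np.clip(data, -99, 99, out=data)
        for t in (2, 5, 9):
            data[t, t % 8, 5] = -150.0
        ep = epochs_factory(data)
        kept, report = reject_amplitude(ep, 100.0)
        assert kept.n_trials == 7
        assert report["dropped_trials"] == [2, 5, 9]

    def test_all_rejected_is_explicit(self, epochs_factory):
        ep = epochs_factory(np.full((2, 8, 10), 500.0))
        with pytest.raises(ValueError, match="all 2 trials"):
            reject_amplitude(ep, 100.0)

    def test_default_synthetic_rejection_rate(self, small_montage):
        """Default noise stays well under the 6%-of-oddballs rejection bound."""
        from oddmark.paradigm import ParadigmConfig, SubjectSimConfig, \
            simulate_condition

        sim = SubjectSimConfig(montage=small_montage)
        par = ParadigmConfig(n_trials_per_condition=100, block_size=25)
        ep, _ = simulate_condition(sim, par, 0, "A")
        dev = ep.select(ep.category == DEVIANT)
        _, report = reject_amplitude(dev, 100.0)
        assert report["n_dropped"] / dev.n_trials <= 0.06


class TestEqualize:
    def test_matches_counts(self, epochs_factory, rng):
        data = rng.normal(size=(40, 8, 20))
        cat = np.array([STANDARD] * 33 + [DEVIANT] * 7, dtype=object)
        ep = epochs_factory(data, category=cat)
        std, dev = ep.split_categories()
        std_eq, dev_eq = equalize_counts(std, dev, seed=0)
        assert std_eq.n_trials == dev_eq.n_trials == 7

    def test_equal_counts_identity(self, epochs_factory, rng):
        data = rng.normal(size=(10, 8, 20))
        cat = np.array([STANDARD] * 5 + [DEVIANT] * 5, dtype=object)
        std, dev = epochs_factory(data, category=cat).split_categories()
        std_eq, _ = equalize_counts(std, dev, seed=3)
        assert np.array_equal(std_eq.data, std.data)

    def test_seed_controls_subset(self, epochs_factory, rng):
        data = rng.normal(size=(60, 8, 10))
        cat = np.array([STANDARD] * 50 + [DEVIANT] * 10, dtype=object)
        ep = epochs_factory(data, category=cat)
        a1, _ = equalize_epochs(ep, seed=1)
        a2, _ = equalize_epochs(ep, seed=1)
        b, _ = equalize_epochs(ep, seed=2)
        assert np.array_equal(a1.data, a2.data)
        assert not np.array_equal(a1.data, b.data)

    def test_more_deviants_than_standards_rejected(self, epochs_factory, rng):
        data = rng.normal(size=(10, 8, 10))
        cat = np.array([STANDARD] * 3 + [DEVIANT] * 7, dtype=object)
        std, dev = epochs_factory(data, category=cat).split_categories()
        with pytest.raises(ValueError, match="more deviants"):
            equalize_counts(std, dev)


class TestInterpolate:
    def test_consensus_neighbors(self, epochs_factory):
        data = np.zeros((2, 8, 30))
        w = np.sin(np.linspace(0, 3, 30))
        data[:, :, :] = w  # every channel identical
        data[:, 2, :] = 99.0  # corrupt Cz
        ep = epochs_factory(data)
        out = interpolate_channel(ep, "Cz", radius_deg=60)
        assert np.allclose(out.data[:, 2, :], w, atol=1e-12)
        assert np.allclose(out.data[:, 0, :], data[:, 0, :])

    def test_inverse_distance_weights_hand_computed(self, small_montage,
                                                    epochs_factory):
        data = np.zeros((1, 8, 5))
        for i in range(8):
            data[0, i, :] = float(i)
        ep = epochs_factory(data)
        ang = np.degrees(small_montage.angles_from("Cz"))
        neighbors = np.flatnonzero((ang > 0) & (ang <= 50))
        w = 1.0 / ang[neighbors]
        expected = (w / w.sum()) @ data[0, neighbors, 0]
        out = interpolate_channel(ep, "Cz", radius_deg=50)
        assert out.data[0, small_montage.index("Cz"), 0] == pytest.approx(
            expected, abs=1e-12)

    def test_no_neighbors_error(self, epochs_factory):
        ep = epochs_factory(np.zeros((1, 8, 5)))
        with pytest.raises(ValueError, match="neighbors"):
            interpolate_channel(ep, "Oz", radius_deg=1.0)


class TestChainAndCleaner:
    def test_full_chain_preserves_labels_and_time(self, epochs_factory, rng):
        data = rng.normal(scale=5, size=(30, 8, 400))
        cat = np.array([STANDARD] * 24 + [DEVIANT] * 6, dtype=object)
        ep = epochs_factory(data, category=cat, tmin_ms=-200)
        clean, report = preprocess(ep, PreprocConfig(
            baseline_window_ms=(-200, 0), epoch_window_ms=(-200, 199)))
        assert np.array_equal(clean.time_ms, ep.time_ms)
        assert (clean.category == DEVIANT).sum() == 6
        assert (clean.category == STANDARD).sum() == 6
        assert report["equalization"]["n_standard_after"] == 6

    def test_regression_cleaner_removes_reference(self, epochs_factory, rng):
        blink = np.zeros(200)
        blink[80:120] = np.hanning(40) * 50
        data = rng.normal(size=(3, 8, 200))
        coupling = np.linspace(0.1, 0.8, 8)
        data += coupling[None, :, None] * blink[None, None, :]
        ep = epochs_factory(data)
        out = regress_out(ep, blink)
        # residual correlation with the nuisance course is ~0
        bc = blink - blink.mean()
        corr = np.abs(np.einsum("ict,t->ic", out.data, bc))
        assert corr.max() < 1e-8 * np.abs(np.einsum("t,t->", bc, bc))
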