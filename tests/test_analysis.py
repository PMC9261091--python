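"""Spectral measures, ITC and estimation statistics against analytic oracles."""

import numpy as np
import pytest

from assrnet.analysis import (
    GroupEstimate,
    band_power,
    correlate,
    evoked_psd,
    group_table,
    itc,
    mean_difference,
    rayleigh_itc_null,
)

FS = 1000.0
T = np.arange(0, 1.0, 1 / FS)


def tone(freq, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * T + phase)


class TestEvokedPsd:
    def test_single_tone_power_proportional_to_half_amplitude_squared(self):
        # band integral follows A²/2 up to the fixed Hann main-lobe capture
        specs = {a: evoked_psd(np.tile(tone(40.0, a), (5, 1)), fs=FS)
                 for a in (1.0, 3.0)}
        assert (specs[3.0].power_4040 / specs[1.0].power_4040
                == pytest.approx(9.0, rel=1e-6))
        assert specs[3.0].power_4040 == pytest.approx(3.0**2 / 2, rel=0.25)
        assert specs[3.0].power_2040 < 0.01 * specs[3.0].power_4040

    def test_random_phase_tones_cancel_in_evoked_average(self, rng):
        # mean of n random unit phasors has expected squared modulus 1/n
        n = 50
        trials = np.vstack([tone(40.0, 1.0, rng.uniform(0, 2 * np.pi))
                            for _ in range(n)])
        spec = evoked_psd(trials, fs=FS)
        locked = evoked_psd(np.tile(tone(40.0), (n, 1)), fs=FS)
        assert spec.power_4040 < 0.1 * locked.power_4040

    def test_beat_skipping_surrogate_moves_power_to_20(self):
        # 40 Hz pulse train vs the same train with alternate pulses removed
        full = np.zeros_like(T)
        full[::25] = 1.0        # pulse every 25 ms
        skip = full.copy()
        skip[::50] = 0.0        # suppress every other pulse
        s_full = evoked_psd(np.tile(full, (3, 1)), fs=FS)
        s_skip = evoked_psd(np.tile(skip, (3, 1)), fs=FS)
        assert s_skip.power_2040 > 10 * s_full.power_2040
        assert s_skip.power_4040 < s_full.power_4040

    def test_requires_two_trials_and_long_window(self):
        with pytest.raises(ValueError):
            evoked_psd(tone(40.0)[None, :], fs=FS)
        with pytest.raises(ValueError):
            evoked_psd(np.ones((3, 100)), fs=FS)

    def test_band_power_integrates_psd(self):
        freqs = np.linspace(0, 100, 201)
        psd = np.ones_like(freqs)
        assert band_power(freqs, psd, 40.0, 2.0) == pytest.approx(4.0)


class TestITC:
    def test_identical_trials_give_unity(self):
        trials = np.tile(tone(40.0), (8, 1))
        out = itc(trials, fs=FS)
        assert out.itc_40 == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_matches_rayleigh_expectation(self, rng):
        # E[ITC] for n independent phases is sqrt(pi)/(2 sqrt(n))
        n = 20
        reps = 200
        vals = []
        for _ in range(reps):
            trials = rng.standard_normal((n, 500))
            vals.append(itc(trials, fs=FS).itc_40)
        expected = rayleigh_itc_null(n)
        assert np.mean(vals) == pytest.approx(expected, rel=0.10)

    def test_bounds_respected(self, rng):
        trials = rng.standard_normal((4, 600))
        out = itc(trials, fs=FS)
        assert 0.0 <= out.itc_40 <= 1.0

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValueError):
            itc(tone(40.0)[None, :], fs=FS)

    def test_phase_locked_beats_jittered(self, rng):
        locked = np.tile(tone(40.0), (10, 1))
        jittered = np.vstack([np.roll(tone(40.0), rng.integers(0, 12))
                              for _ in range(10)])
        assert itc(locked, fs=FS).itc_40 > itc(jittered, fs=FS).itc_40


class TestMeanDifference:
    def test_identical_groups_centre_on_zero(self, rng):
        x = rng.normal(10, 1, 20)
        est = mean_difference(x, x, n_boot=2000, seed=0)
        assert est.mean_difference == 0.0
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_known_shift_recovered_with_good_coverage(self, rng):
        # oracle: generator with a known -3 shift; the percentile bootstrap
        # CI must cover the true shift in the vast majority of replications
        hits = 0
        reps = 200
        for _ in range(reps):
            ctrl = rng.normal(10, 1, 20)
            cond = rng.normal(7, 1, 20)
            est = mean_difference(cond, ctrl, n_boot=1000, seed=1)
            hits += est.ci_low <= -3.0 <= est.ci_high
            assert est.mean_difference == pytest.approx(-3.0, abs=1.5)
        assert hits / reps >= 0.90

    def test_deterministic_given_seed(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        e1 = mean_difference(a, b, n_boot=1500, seed=42)
        e2 = mean_difference(a, b, n_boot=1500, seed=42)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_small_n_boot_warns_in_output(self, rng):
        est = mean_difference(rng.normal(0, 1, 5), rng.normal(0, 1, 5),
                              n_boot=100, seed=0)
        assert est.warning is not None

    def test_groups_below_two_rejected(self):
        with pytest.raises(ValueError):
            mean_difference([1.0], [1.0, 2.0])


class TestCorrelate:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = correlate(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula_on_fixture_table(self):
        x = np.array([1.2, 3.4, 2.2, 5.1, 4.4, 0.7])
        y = np.array([0.9, 2.8, 2.5, 4.0, 4.9, 1.1])
        r, _ = correlate(x, y)
        manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(manual, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2])


class TestGroupTable:
    def _table(self, rng):
        import pandas as pd

        rows = []
        for cond, mu in (("control", 10.0), ("Gmax", 8.0), ("IPSC", 5.0)):
            for s in range(6):
                rows.append({"condition": cond, "subject": s,
                             "power_4040": rng.normal(mu, 0.5),
                             "power_2040": rng.normal(1, 0.1),
                             "itc_40": 0.9})
        return pd.DataFrame(rows)

    def test_most_negative_condition_identified(self, rng):
        tab = self._table(rng)
        g = group_table(tab, n_boot=1500, seed=0)
        ipsc = g.loc[g.condition == "IPSC", "mean_difference"].item()
        assert ipsc == g.mean_difference.min()

    def test_reproducible_and_complete(self, rng):
        tab = self._table(rng)
        g1 = group_table(tab, n_boot=1000, seed=3)
        g2 = group_table(tab, n_boot=1000, seed=3)
        assert g1.equals(g2)
        assert set(g1.condition) == {"control", "Gmax", "IPSC"}

    def test_missing_control_rejected(self, rng):
        tab = self._table(rng)
        with pytest.raises(ValueError):
            group_table(tab[tab.condition != "control"])


def test_group_estimate_invariant():
    with pytest.raises(ValueError):
        GroupEstimate(mean_difference=1.0, ci_low=2.0, ci_high=3.0,
                      n_boot=1000, seed=0)
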