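import numpy as np
import pytest

import optoclock as oc
from optoclock.detuning import dominant_frequency, power_spectrum
from optoclock.model import OptoParams, RepressilatorParams


class TestPowerSpectrum:
    def test_pure_cosine_dominant_bin(self):
        dt = 0.1
        t = np.arange(0, 400, dt)
        freqs, power = power_spectrum(np.cos(2 * np.pi * t / 17.5), dt)
        nu = dominant_frequency(freqs, power)
        assert abs(nu - 1 / 17.5) <= freqs[1]

    def test_stronger_of_two_tones_wins(self):
        dt = 0.1
        t = np.arange(0, 400, dt)
        sig = 1.0 * np.cos(2 * np.pi * t / 10.0) + 0.3 * np.cos(2 * np.pi * t / 23.0)
        freqs, power = power_spectrum(sig, dt)
        # guard disabled: the tones are not harmonically related
        nu = dominant_frequency(freqs, power, subharmonic_guard=False)
        assert abs(nu - 0.1) <= freqs[1]

    def test_fundamental_preferred_over_strong_harmonic(self):
        dt = 0.1
        t = np.arange(0, 400, dt)
        sig = 0.8 * np.cos(2 * np.pi * t / 10.0) + 1.0 * np.cos(2 * np.pi * t / 5.0)
        freqs, power = power_spectrum(sig, dt)
        assert abs(dominant_frequency(freqs, power) - 0.1) <= freqs[1]

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.ones(8), 0.1)

    def test_free_run_spectrum_matches_peak_spacing_period(self, params, T0):
        traj = oc.simulate(params, oc.LightProtocol.constant("off"), t_end=350.0)
        freqs, power = power_spectrum(traj.y[traj.times > 30.0], 0.005)
        nu = dominant_frequency(freqs, power)
        assert abs(nu - 1 / T0) <= freqs[1]


class TestFrequencyRatio:
    def test_unforced_oscillator_keeps_natural_frequency(self, params, T0):
        tone = oc.frequency_ratio(params, f_over_nu0=1.6, beta_prime=0.0, nu0=1 / T0)
        res_bins = tone.resolution
        assert abs(tone.dominant_frequency - 1 / T0) <= res_bins
        assert tone.ratio == pytest.approx(1 / 1.6, abs=2 * res_bins * T0)

    def test_resonant_forcing_locks_one_to_one(self, params, T0):
        tone = oc.frequency_ratio(params, f_over_nu0=1.0, beta_prime=80.0, nu0=1 / T0)
        assert abs(tone.ratio - 1.0) <= tone.resolution / tone.forcing_frequency

    def test_ratio_is_invariant_under_time_rescaling(self, T0):
        # alpha, beta, pulse duration and forcing all scaled by 2
        fast = OptoParams(base=RepressilatorParams(alpha=1.5, beta=600.0))
        tone = oc.frequency_ratio(fast, f_over_nu0=2.0, beta_prime=80.0, tau=1.0,
                                  nu0=2 / T0, n_periods=40)
        assert abs(tone.ratio - 0.5) <= tone.resolution / tone.forcing_frequency

    def test_invalid_forcing_rejected(self, params, T0):
        with pytest.raises(ValueError):
            oc.frequency_ratio(params, f_over_nu0=-1.0, beta_prime=80.0, nu0=1 / T0)


@pytest.fixture(scope="module")
def surface(params):
    # 21 - 5 = 16 analysed forcing periods: an even count keeps f/2 on
    # the periodogram's frequency grid for the half-ratio tongue
    return oc.tongue_surface(
        params,
        f_grid=[0.5, 0.8, 1.0, 1.1, 1.2, 1.5, 2.0, 2.4],
        beta_prime_grid=[0.0, 10.0, 20.0, 40.0, 80.0],
        n_periods=21,
        discard_periods=5,
    )


class TestTongueSurface:
    def test_unforced_row_carries_no_plateau_labels(self, surface):
        j = list(surface.beta_primes).index(0.0)
        assert all(lbl == "unforced" for lbl in surface.labels[:, j])

    def test_principal_tongue_widens_with_amplitude(self, surface):
        counts = [(surface.labels[:, j] == "1").sum()
                  for j in range(1, len(surface.beta_primes))]
        assert counts == sorted(counts)
        assert counts[-1] >= 3  # 0.8..1.2 locked at beta' = 80

    def test_half_ratio_tongue_at_double_frequency(self, surface):
        i = list(surface.f_over_nu0).index(2.0)
        j = list(surface.beta_primes).index(80.0)
        assert surface.labels[i, j] == "1/2"
        assert surface.ratio[i, j] == pytest.approx(0.5, abs=0.02)

    def test_plateau_stable_under_half_step_refinement(self, surface, params, T0):
        """A point between grid nodes inside the principal tongue reports the
        same locking ratio as its neighbours."""
        tone = oc.frequency_ratio(params, 1.05, 80.0, nu0=1 / T0,
                                  n_periods=20, discard_periods=5)
        assert abs(tone.ratio - 1.0) <= 0.02

    def test_long_format_export(self, surface, tmp_path):
        import pandas as pd

        path = tmp_path / "surface.csv"
        surface.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["f_over_nu0", "beta_prime", "ratio", "label"]
        assert len(df) == 8 * 5


class TestAlternatePeaks:
    def test_identical_cells_share_parity_and_halve_frequency(self):
        spec = oc.EnsembleSpec(n_cells=4, alpha_sd=0.0, seed=1)
        alt = oc.alternate_peak_population(spec, f_over_nu0=2.0, beta_prime=80.0,
                                           n_periods=30)
        locked = alt.parities[alt.parities >= 0]
        assert len(locked) == 4
        assert len(set(locked.tolist())) == 1
        assert alt.dominant_population_frequency == pytest.approx(
            alt.forcing_frequency / 2, rel=0.05)

    def test_mixed_parities_average_to_forcing_frequency(self):
        """Cells locked on alternate pulses cancel pairwise; the population
        mean oscillates at the forcing frequency, not half of it."""
        spec = oc.EnsembleSpec(n_cells=30, seed=5, initial_condition_mode="random_phase")
        alt = oc.alternate_peak_population(spec, f_over_nu0=2.0, beta_prime=80.0)
        locked = alt.parities[alt.parities >= 0]
        assert {0, 1} <= set(locked.tolist())
        assert alt.n_unlocked == int((alt.parities < 0).sum())
        assert alt.dominant_population_frequency == pytest.approx(
            alt.forcing_frequency, rel=0.05)
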