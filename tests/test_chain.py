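"""Gate, transit carryover and SIM sampling forward model."""

import dataclasses

import numpy as np
import pytest

import conepulse as cp
from conepulse.chain import sample_continuous_events


def impulse_train(n=50_000, dt=4e-6, where=(1000,), amp=100.0):
    flux = np.zeros(n)
    cone = np.zeros(n, dtype=bool)
    for i in where:
        flux[i] = amp
        cone[i] = True
    return cp.EmissionTrain(flux, cone, dt)


class TestGate:
    def test_always_closed_zeroes_flux(self, short_train):
        gated = cp.apply_gate(short_train, cp.GateWaveform.always_closed())
        assert not gated.flux.any()

    def test_always_open_is_identity(self, short_train):
        gated = cp.apply_gate(
            short_train, cp.GateWaveform.always_open(short_train.duration)
        )
        np.testing.assert_array_equal(gated.flux, short_train.flux)

    def test_two_window_schedule_passes_only_inside_windows(self, short_train):
        gate = cp.GateWaveform(((0.0, 0.05), (0.1, 0.15)))
        gated = cp.apply_gate(short_train, gate)
        t = gated.times
        outside = ~(((t >= 0.0) & (t < 0.05)) | ((t >= 0.1) & (t < 0.15)))
        assert not gated.flux[outside].any()
        assert gated.flux[~outside].sum() > 0

    def test_cone_state_untouched_by_gate(self, short_train):
        gated = cp.apply_gate(short_train, cp.GateWaveform.always_closed())
        np.testing.assert_array_equal(gated.cone_state, short_train.cone_state)

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValueError):
            cp.GateWaveform(((0.0, 2.0), (1.0, 3.0)))


class TestTransitMixing:
    def test_zero_tau_is_pure_delay(self):
        train = impulse_train()
        params = cp.ChainParams(mixing_tau=0.0, transit_delay=1e-3)
        arrival = cp.transit_mixing(train, params)
        shift = round(1e-3 / train.dt)
        assert arrival[1000 + shift] == 100.0
        assert np.count_nonzero(arrival) == 1

    def test_impulse_response_is_normalized_exponential(self):
        train = impulse_train()
        params = cp.ChainParams(mixing_tau=5e-3, transit_delay=0.0)
        arrival = cp.transit_mixing(train, params)
        tail = arrival[1000:3000]
        # Log-linear decay with slope -dt/tau per sample.
        slopes = np.diff(np.log(tail))
        np.testing.assert_allclose(slopes, -train.dt / 5e-3, rtol=1e-6)
        # Unit-area kernel conserves the integrated flux.
        assert arrival.sum() == pytest.approx(train.flux.sum(), rel=1e-3)

    def test_modulation_attenuated_by_first_order_transfer_function(self):
        # A sinusoidal modulation at f through an exponential kernel of time
        # constant tau is attenuated by |1 / (1 + i 2 pi f tau)|.
        dt, f, tau = 4e-6, 1920.0, 5e-3
        n = 250_000
        t = dt * np.arange(n)
        flux = 1.0 + 0.5 * np.sin(2 * np.pi * f * t)
        train = cp.EmissionTrain(flux, np.ones(n, bool), dt)
        arrival = cp.transit_mixing(
            train, cp.ChainParams(mixing_tau=tau, transit_delay=0.0)
        )
        steady = arrival[n // 2 :]
        gain = (steady.max() - steady.min()) / 1.0  # peak-to-peak of input = 1
        expected = 1.0 / abs(1.0 + 2j * np.pi * f * tau)
        assert gain == pytest.approx(expected, rel=0.02)

    def test_conservation_never_creates_flux(self, short_train):
        arrival = cp.transit_mixing(short_train, cp.ChainParams())
        assert arrival.sum() <= short_train.flux.sum() * (1 + 1e-12)


class TestSimSampling:
    def test_30s_duration_gives_7500_events(self):
        starts = cp.ChainParams()
        flux = np.zeros(int(30.0 / 4e-6))
        ms = cp.sample_sim_events(flux, 4e-6, dataclasses.replace(
            starts, detector_noise_sd=0.0), 30.0, seed=0)
        assert len(ms) == 7500

    def test_constant_flux_gives_gain_times_c_times_dwell(self):
        params = cp.ChainParams(detector_noise_sd=0.0)
        c = 3.0
        flux = np.full(int(0.1 / 4e-6), c)
        ms = cp.sample_sim_events(flux, 4e-6, params, 0.1, seed=0)
        np.testing.assert_allclose(
            ms.intensity, params.gain * c * params.dwell, rtol=1e-6
        )

    def test_pulses_outside_dwell_windows_are_lost(self):
        # Construct pulses landing in the event's dead time (after 0.8 ms).
        params = cp.ChainParams(detector_noise_sd=0.0)
        dt = 4e-6
        n = int(0.1 / dt)
        flux = np.zeros(n)
        samples_per_event = round(params.event / dt)  # 1000
        in_dead_time = (np.arange(n) % samples_per_event) >= samples_per_event // 2
        flux[in_dead_time] = 50.0
        ms = cp.sample_sim_events(flux, dt, params, 0.1, seed=0)
        assert np.all(ms.intensity == 0.0)

    def test_doubling_gain_doubles_noiseless_intensities(self, short_train):
        params = cp.ChainParams(detector_noise_sd=0.0)
        arrival = cp.transit_mixing(short_train, params)
        a = cp.sample_sim_events(arrival, short_train.dt, params, 0.2, seed=0)
        b = cp.sample_sim_events(
            arrival, short_train.dt,
            dataclasses.replace(params, gain=2 * params.gain), 0.2, seed=0,
        )
        np.testing.assert_allclose(b.intensity, 2 * a.intensity)

    def test_continuous_sampler_has_no_duty_cycle_loss(self, short_train):
        params = cp.ChainParams(transit_delay=0.0, mixing_tau=0.0,
                                detector_noise_sd=0.0)
        ms = sample_continuous_events(
            short_train.flux, short_train.dt, params, 0.2
        )
        total = params.gain * short_train.flux.sum() * short_train.dt
        assert ms.intensity.sum() == pytest.approx(total, rel=1e-3)


class TestGatedExperiment:
    def test_no_spray_run_sits_at_noise_floor(self):
        preset = cp.make_preset(1.0)
        chain = cp.ChainParams()
        occ, ms = cp.run_gated_experiment(
            preset, chain, cp.GateWaveform.always_open(2.0), 2.0, seed=1
        )
        assert occ.percent.max() == 0.0
        # Clipped Gaussian noise: mean under sd, no event above ~5 sigma.
        assert ms.intensity.mean() < chain.detector_noise_sd
        assert ms.intensity.max() < 5 * chain.detector_noise_sd

    def test_burst_run_shows_sparse_high_events(self):
        preset = cp.make_preset(2.5)
        chain = cp.ChainParams(detector_noise_sd=0.0)
        occ, ms = cp.run_gated_experiment(
            preset, chain, cp.GateWaveform.always_open(2.0), 2.0, seed=1
        )
        nonzero = ms.intensity > 0.05 * ms.intensity.max()
        assert 0 < nonzero.mean() < 0.5

    def test_occupancy_and_events_share_the_4ms_grid(self, pulsating_preset):
        chain = cp.ChainParams()
        occ, ms = cp.run_gated_experiment(
            pulsating_preset, chain, cp.GateWaveform.always_open(1.0), 1.0, seed=1
        )
        assert len(occ) == len(ms) == 250
        np.testing.assert_allclose(occ.bin_times, ms.event_times)

    def test_duty_cycle_and_carryover_erase_correlation_monotonically(
        self, pulsating_preset
    ):
        # Ladder from an ideal chain to the default chain: |rho| must not
        # increase as blending and duty-cycle losses are piled on.
        gate = cp.GateWaveform.always_open(8.0)
        rhos = []
        ladder = [
            dict(mixing_tau=0.0, continuous=True),
            dict(mixing_tau=2e-3, continuous=False),
            dict(mixing_tau=8e-3, continuous=False),
        ]
        for spec_ in ladder:
            chain = cp.ChainParams(
                mixing_tau=spec_["mixing_tau"], detector_noise_sd=0.0
            )
            occ, ms = cp.run_gated_experiment(
                pulsating_preset, chain, gate, 8.0, seed=31,
                continuous_sampling=spec_["continuous"],
            )
            rhos.append(abs(cp.shift_scan(occ, ms).max_abs_rho))
        assert rhos[0] > rhos[1] > rhos[2]
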