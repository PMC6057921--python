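"""Generators: Poisson/exponential/binomial moment recovery, quantization."""

import numpy as np
import pytest

from tirfkin.dwell import detection_probability
from tirfkin.events import events_to_frame
from tirfkin.geometry import SiteMap
from tirfkin.synthetic import (
    KineticModel,
    MovieParams,
    SimScenario,
    TrueEvent,
    quantize_to_frames,
    render_movie,
    simulate_binding_events,
    simulate_debranching,
    simulate_dwell_sample,
    simulate_gel_standards,
    simulate_photobleach_traces,
)


@pytest.fixture
def one_filament_map():
    return SiteMap(
        filaments=[np.array([[5.0, 25.0], [45.0, 25.0]])],
        branches=np.array([[20.0, 25.0]]),
        extent_um=(50.0, 50.0),
    )


def scenario(site_map, rate, dwell, seed=0, duration=1000.0, dt=0.25):
    return SimScenario(
        seed=seed, duration_s=duration, frame_interval_s=dt, site_map=site_map,
        kinetics_per_class={"side": KineticModel(rate, dwell)},
    )


class TestSimulateBindingEvents:
    def test_zero_rate_gives_no_events(self, one_filament_map):
        assert simulate_binding_events(scenario(one_filament_map, 0.0, {"tau": 1.0})) == []

    def test_poisson_and_exponential_moments(self, one_filament_map):
        """One site, rate 0.5/s over 1000 s: count and mean dwell at 3 sigma."""
        evs = simulate_binding_events(scenario(one_filament_map, 0.5, {"tau": 2.0}, seed=1))
        n = len(evs)
        assert abs(n - 500) < 3 * np.sqrt(500)
        durs = np.array([e.duration for e in evs])
        assert abs(durs.mean() - 2.0) < 3 * 2.0 / np.sqrt(n)

    def test_seed_determinism_byte_identical(self, one_filament_map):
        sc = scenario(one_filament_map, 0.2, {"tau": 0.5}, seed=99)
        a = events_to_frame(quantize_to_frames(simulate_binding_events(sc), 0.25)).to_csv()
        b = events_to_frame(quantize_to_frames(simulate_binding_events(sc), 0.25)).to_csv()
        assert a == b

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticModel(-0.1, {"tau": 1.0})

    def test_malformed_dwell_rejected(self):
        with pytest.raises(ValueError):
            KineticModel(0.1, {"t_short": 3.0, "t_long": 1.0, "frac_long": 0.1})

    def test_labeled_fraction_thins_events(self, one_filament_map):
        sc_full = scenario(one_filament_map, 1.0, {"tau": 1.0}, seed=5)
        sc_half = SimScenario(
            seed=5, duration_s=1000.0, frame_interval_s=0.25, site_map=one_filament_map,
            kinetics_per_class={"side": KineticModel(1.0, {"tau": 1.0})},
            labeled_fraction=0.5,
        )
        n_full = len(simulate_binding_events(sc_full))
        n_half = len(simulate_binding_events(sc_half))
        assert abs(n_half - 0.5 * n_full) < 3 * np.sqrt(0.25 * n_full)


class TestQuantizeToFrames:
    def test_sub_frame_event_undetected(self):
        evs = [TrueEvent("s", "side", 0.10, 0.05)]
        assert quantize_to_frames(evs, 0.25) == []

    def test_three_frames_at_1s_is_3s(self):
        # spans acquisition instants 1, 2, 3 -> dwell 3 s
        evs = [TrueEvent("s", "side", 0.5, 3.0)]
        out = quantize_to_frames(evs, 1.0)
        assert len(out) == 1
        assert out[0].n_frames == 3
        assert out[0].dwell_s == pytest.approx(3.0)

    def test_detected_fraction_matches_closed_form(self):
        """P(detect) = (tau/dt)(1 - e^(-dt/tau)) under uniform start phase."""
        tau, dt, n = 0.46, 0.25, 40000
        rng = np.random.default_rng(17)
        evs = [
            TrueEvent("s", "side", float(10 + i * 2 * dt + rng.uniform(0, dt)), float(d))
            for i, d in enumerate(rng.exponential(tau, n))
        ]
        detected = len(quantize_to_frames(evs, dt, duration_s=10 + n * 2 * dt + 100))
        p = detection_probability(tau, dt)
        assert abs(detected / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_monotone_in_frame_interval_on_nested_grids(self):
        rng = np.random.default_rng(23)
        evs = [
            TrueEvent("s", "side", float(t), float(d))
            for t, d in zip(rng.uniform(0, 500, 3000), rng.exponential(0.3, 3000))
        ]
        counts = [len(quantize_to_frames(evs, dt)) for dt in (0.25, 0.5, 1.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_end_censoring_flag_and_drop(self):
        evs = [TrueEvent("s", "side", 8.6, 100.0)]
        out = quantize_to_frames(evs, 1.0, duration_s=10.0)
        assert out[0].censored and out[0].n_frames == 2  # instants 9, 10
        assert quantize_to_frames(evs, 1.0, duration_s=10.0, end_handling="drop") == []

    def test_min_frames_validation(self):
        with pytest.raises(ValueError):
            quantize_to_frames([], 0.25, min_frames=0)


class TestRenderMovie:
    def test_no_events_no_noise_is_flat(self, one_filament_map):
        mp = MovieParams(background_level=0.0)
        stack, truth = render_movie([], one_filament_map, mp, 5, 0.25)
        assert stack.sum() == 0.0 and truth.empty

    def test_single_spot_max_at_truth(self, one_filament_map):
        mp = MovieParams(pixel_size_um=0.27)
        ev = TrueEvent("s", "side", 0.0, 10.0, x_um=20 * 0.27, y_um=30 * 0.27)
        stack, _ = render_movie([ev], one_filament_map, mp, 3, 0.25)
        y, x = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert (x, y) == (20, 30)

    def test_poisson_noise_preserves_mean(self, one_filament_map):
        mp0 = MovieParams(photons_per_spot=500.0, background_level=2.0)
        mp1 = MovieParams(photons_per_spot=500.0, background_level=2.0, noise_model="poisson")
        ev = TrueEvent("s", "side", 0.0, 1000.0, x_um=30 * 0.27, y_um=30 * 0.27)
        clean, _ = render_movie([ev], one_filament_map, mp0, 100, 0.25, seed=0)
        noisy, _ = render_movie([ev], one_filament_map, mp1, 100, 0.25, seed=1)
        assert abs(noisy.sum() - clean.sum()) < 5 * np.sqrt(clean.sum())

    def test_out_of_bounds_rejected(self, one_filament_map):
        ev = TrueEvent("s", "side", 0.0, 1.0, x_um=1e4, y_um=0.0)
        with pytest.raises(ValueError):
            render_movie([ev], one_filament_map, MovieParams(), 5, 0.25)


class TestPhotobleachTraces:
    def test_monomers_only_noiseless(self):
        traces, truth = simulate_photobleach_traces(20, 0.0, 1.0, 0.05, 0.0, 100, seed=2)
        assert np.all(truth == 1)
        for tr in traces:
            drops = np.flatnonzero(np.diff(tr) < 0)
            assert drops.size == 1
            assert tr[-1] == 0.0 and tr[0] == 1.0

    def test_all_dimers(self):
        _, truth = simulate_photobleach_traces(50, 1.0, 1.0, 0.05, 0.1, 100, seed=3)
        assert np.all(truth == 2)

    def test_binomial_share(self):
        _, truth = simulate_photobleach_traces(1000, 0.2, 1.0, 0.05, 0.1, 100, seed=4)
        share = (truth == 2).mean()
        assert abs(share - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 1000)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_photobleach_traces(10, 0.2, 1.0, 0.05, -0.1, 100, seed=0)


class TestDebranching:
    def test_huge_window_never_censors(self):
        df = simulate_debranching(200, {"tau": 10.0}, 1e9, seed=0)
        assert df["censored"].sum() == 0

    def test_point_mass_beyond_window_all_censored(self):
        df = simulate_debranching(20, {"fixed": 10.0}, 5.0, seed=0)
        assert df["censored"].all()
        assert (df["lifetime_s"] == 5.0).all()

    def test_censored_fraction_closed_form(self):
        # exponential mean 100 s, window 900 s: P(censor) = e^-9
        df = simulate_debranching(100000, {"tau": 100.0}, 900.0, seed=1)
        p = np.exp(-9.0)
        assert abs(df["censored"].mean() - p) < 3 * np.sqrt(p / 100000) + 1e-4


class TestGelStandards:
    def test_noiseless_quadratic(self):
        df = simulate_gel_standards((2.0, 1.0), [1.0], [], 0.0, seed=0)
        assert df["raw_intensity"].iloc[0] == pytest.approx(3.0)

    def test_zero_concentration_exactly_zero(self):
        df = simulate_gel_standards((2.0, 1.0), [0.0, 1.0], [], 0.05, seed=0)
        assert df["raw_intensity"].iloc[0] == 0.0

    def test_noisy_mean_unbiased(self):
        df = simulate_gel_standards((2.0, 1.0), [1.0] * 100, [], 0.05, seed=5)
        vals = df["raw_intensity"].to_numpy()
        assert abs(vals.mean() - 3.0) < 3 * 3.0 * 0.05 / 10

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_gel_standards((2.0, 1.0), [-1.0], [], 0.0, seed=0)


class TestDwellSampleGenerator:
    def test_exact_detected_count(self):
        s = simulate_dwell_sample({"tau": 0.4}, 0.25, seed=0, n_detected=500)
        assert s.n == 500

    def test_determinism(self):
        a = simulate_dwell_sample({"tau": 0.4}, 0.25, seed=9, n_events=1000)
        b = simulate_dwell_sample({"tau": 0.4}, 0.25, seed=9, n_events=1000)
        assert np.array_equal(a.frame_counts, b.frame_counts)
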