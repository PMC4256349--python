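"""Time-domain processing chain: baseline, window, zero-fill, transform, picking."""

import numpy as np
import pytest

from oamspin import (
    PeldorTiming,
    PeldorTrace,
    PipelineConfig,
    PeldorSimSpec,
    analyze,
    apply_hamming,
    correct_baseline,
    cosine_transform,
    pick_peaks,
    simulate_peldor,
    zero_fill,
)
from oamspin.dipolar import distance_from_frequency, perpendicular_frequency
from oamspin.errors import ConfigurationError
from oamspin.peldor import read_trace, write_trace


def make_trace(v, timing=None):
    timing = timing or PeldorTiming(n_points=len(v))
    t = timing.dt * np.arange(len(v))
    return PeldorTrace(timing=timing, t=t, v=np.asarray(v, dtype=float))


class TestBaseline:
    def test_pure_polynomial_subtracts_to_zero(self):
        t = 8.0 * np.arange(148)
        v = 3.0 - 2e-3 * t + 5e-7 * t**2
        out = correct_baseline(make_trace(v), fit_start_fraction=0.0, order=2)
        assert np.max(np.abs(out.v)) < 1e-9 * np.ptp(v)

    def test_polynomial_plus_cosine_matches_normal_equations_oracle(self):
        """Subtracting the fitted quadratic leaves the cosine part up to the
        leakage that an independent normal-equations fit also shows."""
        t = 8.0 * np.arange(148)
        cos_part = 0.3 * np.cos(2 * np.pi * 2.1e-3 * (t - 200.0))
        v = (1.0 - 1e-4 * t + 2e-8 * t**2) + cos_part
        out = correct_baseline(make_trace(v), order=2)
        # oracle: explicit least-squares design matrix
        X = np.vander(t, 3, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ v)
        expected = v - X @ beta
        assert np.allclose(out.v, expected, atol=1e-9)

    def test_fit_region_mean_is_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(1.0, 0.1, 148)
        out = correct_baseline(make_trace(v), fit_start_fraction=0.3, order=2)
        t = out.t
        mask = t >= t[0] + 0.3 * (t[-1] - t[0])
        assert abs(np.mean(out.v[mask])) < 1e-9 * np.ptp(v)

    def test_underdetermined_region_raises(self):
        trace = make_trace([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        with pytest.raises(ConfigurationError):
            correct_baseline(trace, fit_start_fraction=0.9, order=2)


class TestHamming:
    def test_half_window_endpoints(self):
        """Descending half-window keeps the first point (x1.00) and scales the
        last by the Hamming endpoint value 0.54 - 0.46 = 0.08."""
        v = np.ones(148)
        out = apply_hamming(make_trace(v))
        assert out.v[0] == pytest.approx(1.0, abs=1e-12)
        assert out.v[-1] == pytest.approx(0.08, abs=1e-12)

    def test_all_ones_yields_window_itself(self):
        n = 64
        out = apply_hamming(make_trace(np.ones(n)))
        k = np.arange(n)
        expected = 0.54 + 0.46 * np.cos(np.pi * k / (n - 1))
        assert np.allclose(out.v, expected)

    def test_full_window_is_symmetric(self):
        out = apply_hamming(make_trace(np.ones(100)), full=True)
        assert np.allclose(out.v, out.v[::-1])
        assert out.v[0] == pytest.approx(0.08, abs=1e-12)


class TestZeroFill:
    def test_148_to_1024(self):
        trace = make_trace(np.arange(148, dtype=float))
        out = zero_fill(trace, 1024)
        assert len(out.v) == 1024
        assert np.array_equal(out.v[:148], trace.v)
        assert np.all(out.v[148:] == 0.0)
        assert np.allclose(np.diff(out.t), trace.timing.dt)

    def test_noop_when_equal_length(self):
        trace = make_trace(np.arange(100, dtype=float))
        out = zero_fill(trace, 100)
        assert np.array_equal(out.v, trace.v)

    def test_shrinking_raises(self):
        with pytest.raises(ConfigurationError):
            zero_fill(make_trace(np.ones(148)), 100)


class TestCosineTransform:
    def test_resolution_of_zero_filled_grid(self):
        trace = zero_fill(make_trace(np.ones(148)), 1024)
        spec = cosine_transform(trace)
        assert spec.resolution == pytest.approx(1e3 / (1024 * 8.0), rel=1e-12)
        assert spec.resolution == pytest.approx(0.1221, abs=1e-4)
        assert spec.nu[0] == 0.0
        assert np.allclose(np.diff(spec.nu), spec.resolution)

    def test_pure_cosine_peaks_at_its_frequency(self, exp_timing):
        t = exp_timing.dt * np.arange(exp_timing.n_points)
        v = np.cos(2 * np.pi * 2.1e-3 * (t - exp_timing.tau))
        trace = zero_fill(PeldorTrace(exp_timing, t, v), 1024)
        spec = cosine_transform(trace)
        # direct-summation oracle on the same grid
        oracle = np.array([
            np.sum(trace.v * np.cos(2 * np.pi * nu * 1e-3 * (trace.t - exp_timing.tau)))
            for nu in spec.nu
        ])
        assert np.allclose(spec.amp, oracle, atol=1e-9 * np.max(np.abs(oracle)))
        peak_nu = spec.nu[np.argmax(spec.amp)]
        assert abs(peak_nu - 2.1) <= spec.resolution

    def test_zero_trace_transforms_to_zero(self):
        spec = cosine_transform(make_trace(np.zeros(148)))
        assert np.all(spec.amp == 0.0)

    def test_linearity(self, rng):
        v1, v2 = rng.normal(size=148), rng.normal(size=148)
        s1 = cosine_transform(make_trace(v1)).amp
        s2 = cosine_transform(make_trace(v2)).amp
        s12 = cosine_transform(make_trace(2.0 * v1 - 0.5 * v2)).amp
        assert np.allclose(s12, 2.0 * s1 - 0.5 * s2, atol=1e-9 * np.max(np.abs(s1)))


class TestPeakPicking:
    def test_single_component_round_trip(self, exp_timing):
        spec_sim = PeldorSimSpec(components=((2.916, 1.0),), timing=exp_timing,
                                 perpendicular_only=True)
        rep = analyze(simulate_peldor(spec_sim), PipelineConfig(baseline_order=0))
        assert len(rep.assignments) == 1
        nu_true = float(perpendicular_frequency(2.916))
        assert abs(rep.assignments[0].nu_dd - nu_true) <= rep.spectrum.resolution

    def test_two_component_ordering(self, exp_timing):
        """Emulated resting-state data: 0.5 and 2.1 MHz components with the
        2.1 MHz peak the weaker of the two."""
        spec_sim = PeldorSimSpec(components=((4.703, 0.7), (2.916, 0.3)),
                                 timing=exp_timing, perpendicular_only=True)
        rep = analyze(simulate_peldor(spec_sim), PipelineConfig(baseline_order=0))
        assert len(rep.assignments) == 2
        first, second = rep.assignments
        assert first.rel_amplitude > second.rel_amplitude
        assert abs(first.nu_dd - 0.5) < 0.15
        assert abs(second.nu_dd - 2.1) < 0.3

    def test_flat_spectrum_yields_nothing(self):
        spec = cosine_transform(make_trace(np.zeros(64)))
        assert pick_peaks(spec) == []


class TestAnalyze:
    def test_single_distance_assignment(self, exp_timing):
        """A noise-free 2.916 nm trace is assigned 29 A by the full chain."""
        sim = PeldorSimSpec(components=((2.916, 1.0),), timing=exp_timing,
                            perpendicular_only=True)
        rep = analyze(simulate_peldor(sim), PipelineConfig(baseline_order=0))
        assert rep.assignments[0].r_A == 29

    def test_two_component_resting_state_emulation(self, exp_timing):
        """Two assignments near 47 and 29 A with the 47 A feature dominant."""
        sim = PeldorSimSpec(components=((4.703, 0.75), (2.916, 0.25)),
                            timing=exp_timing, perpendicular_only=True)
        rep = analyze(simulate_peldor(sim), PipelineConfig(baseline_order=0))
        assert len(rep.assignments) == 2
        big, small = rep.assignments
        assert big.rel_amplitude == 1.0
        assert abs(big.r_nm * 10 - 47.0) <= 2.0
        assert abs(small.r_nm * 10 - 29.2) <= 2.0

    def test_all_zero_trace_gives_no_assignments(self, exp_timing):
        t = exp_timing.dt * np.arange(exp_timing.n_points)
        rep = analyze(PeldorTrace(exp_timing, t, np.zeros_like(t)),
                      PipelineConfig(baseline_order=0))
        assert rep.assignments == []

    def test_bit_reproducible(self, exp_timing):
        sim = PeldorSimSpec(components=((4.2, 1.0),), noise_sd=0.02, seed=7,
                            timing=exp_timing)
        r1 = analyze(simulate_peldor(sim), PipelineConfig(baseline_order=0))
        r2 = analyze(simulate_peldor(sim), PipelineConfig(baseline_order=0))
        assert [a.nu_dd for a in r1.assignments] == [a.nu_dd for a in r2.assignments]
        assert np.array_equal(r1.spectrum.amp, r2.spectrum.amp)

    def test_stage_order_and_intermediates_retained(self, exp_timing):
        sim = PeldorSimSpec(components=((4.2, 1.0),), timing=exp_timing)
        rep = analyze(simulate_peldor(sim), PipelineConfig(baseline_order=0))
        assert list(rep.stages) == ["input", "baseline_corrected", "apodized", "zero_filled"]
        assert len(rep.stages["zero_filled"].v) == 1024

    def test_recovery_within_bin_bound_over_replicates(self, exp_timing):
        """Across the measured range, 2%-noise traces recover the distance to
        within max(1 A, the distance error of one resolution bin), 20 seeded
        replicates each (cosine modulation model)."""
        res = 1e3 / (1024 * 8.0)
        for r_nm in (2.0, 2.9, 3.5, 4.2, 4.7):
            nu = float(perpendicular_frequency(r_nm))
            tol = max(1.0, abs(float(distance_from_frequency(nu - res)) - r_nm) * 10.0)
            for seed in range(20):
                sim = PeldorSimSpec(components=((r_nm, 1.0),), noise_sd=0.02,
                                    seed=seed, timing=exp_timing,
                                    perpendicular_only=True)
                rep = analyze(simulate_peldor(sim), PipelineConfig(baseline_order=0))
                assert rep.assignments, (r_nm, seed)
                err = abs(rep.assignments[0].r_nm - r_nm) * 10.0
                assert err <= tol, (r_nm, seed, err, tol)

    def test_spectral_power_grows_with_amplitude(self, exp_timing):
        """Parseval-style sanity: scaling the modulation scales total power."""
        powers = []
        for depth in (0.1, 0.3, 0.6):
            sim = PeldorSimSpec(components=((3.0, 1.0),), mod_depth=depth,
                                timing=exp_timing)
            rep = analyze(simulate_peldor(sim), PipelineConfig(baseline_order=0))
            powers.append(float(np.sum(rep.spectrum.amp**2)))
        assert powers[0] < powers[1] < powers[2]


class TestTraceIO:
    def test_round_trip_csv_and_json(self, tmp_path, exp_timing):
        sim = PeldorSimSpec(components=((4.0, 1.0),), noise_sd=0.01, seed=3,
                            timing=exp_timing)
        trace = simulate_peldor(sim)
        write_trace(trace, tmp_path / "trace.csv", tmp_path / "timing.json")
        back = read_trace(tmp_path / "trace.csv", tmp_path / "timing.json")
        assert back.timing == exp_timing
        assert np.allclose(back.v, trace.v)
        assert np.allclose(back.t, trace.t)

    def test_yaml_sidecar(self, tmp_path, exp_timing):
        sim = PeldorSimSpec(components=((4.0, 1.0),), timing=exp_timing)
        trace = simulate_peldor(sim)
        write_trace(trace, tmp_path / "trace.tsv", tmp_path / "timing.yaml")
        back = read_trace(tmp_path / "trace.tsv", tmp_path / "timing.yaml")
        assert back.timing.tau == 200.0
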