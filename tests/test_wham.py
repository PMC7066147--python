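"""WHAM reconstruction, bias model, autocorrelation and diagnostics."""

import dataclasses

import numpy as np
import pytest

from groovestate.synthetic import (PotentialSpec, analytic_reference_pmf,
                                   default_double_well, sample_protocol,
                                   sample_window)
from groovestate.wham import (DegenerateSeriesError, UmbrellaSampling,
                              UmbrellaWindowSeries, WhamConfig,
                              WhamConvergenceError, autocorr_time,
                              bias_energy, conditional_dihedral_distribution,
                              make_windows, pmf_diagnostics, read_manifest,
                              read_window_file, well_sampled_mask, wham_pmf,
                              write_window_file, _bin_indices)
from groovestate.geometry import wrap_angle

KT300 = 0.0019872041 * 300.0


def _iid_biased_windows(potential, centers, k, n, seed, kt=KT300):
    """Bias-consistent iid sampler: exact draws from the biased Boltzmann
    distribution on a fine grid (independent of the Metropolis machinery)."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(-180.0, 180.0, 7200, endpoint=False) + 0.025
    out = []
    for c in centers:
        e = potential(grid) + bias_energy(grid, c, k)
        w = np.exp(-(e - e.min()) / kt)
        w /= w.sum()
        samples = rng.choice(grid, size=n, p=w)
        out.append(UmbrellaWindowSeries(center=c, force_constant=k,
                                        samples=samples))
    return out


class TestMakeWindows:
    def test_standard_protocol_has_17_windows(self):
        assert len(make_windows(-210, -50, 10)) == 17

    def test_degenerate_range(self):
        assert make_windows(0, 0, 10) == [0]

    def test_full_circle_layout(self):
        assert len(make_windows(-180, 180, 10)) == 37

    def test_non_divisible_range_rejected(self):
        with pytest.raises(ValueError):
            make_windows(0, 95, 10)


class TestBiasEnergy:
    def test_zero_at_center(self):
        assert bias_energy(42.0, 42.0, 0.015) == 0.0

    def test_quadratic_without_half_factor(self):
        assert bias_energy(10.0, 0.0, 0.015) == pytest.approx(1.5)

    def test_half_convention_switch(self):
        assert bias_energy(10.0, 0.0, 0.015, convention="half") == \
            pytest.approx(0.75)

    def test_periodic_wrap(self):
        assert bias_energy(150.0, -210.0, 0.015) == pytest.approx(0.0)

    def test_symmetry(self, rng):
        for _ in range(100):
            xi, c = rng.uniform(-400, 400, 2)
            assert bias_energy(xi, c, 0.02) == pytest.approx(
                bias_energy(c, xi, 0.02))


class TestWhamPmf:
    def test_flat_landscape_gives_flat_pmf(self):
        """Bias-consistent sampling of a flat potential reconstructs a profile
        whose variation is tiny compared with the benchmark barrier scale."""
        flat = PotentialSpec(terms=())
        windows = _iid_biased_windows(flat, make_windows(-180, 150, 30),
                                      k=0.005, n=20_000, seed=7)
        profile = wham_pmf(windows)
        diag = pmf_diagnostics(windows)
        assert profile.sampled.all()
        assert profile.barrier_height() < 0.25  # ~0.4 kT vs ~3 kcal/mol wells
        g = profile.free_energy - profile.free_energy.mean()
        ok = np.isfinite(diag.stderr) & (diag.stderr > 0)
        within = np.abs(g[ok]) <= 3.0 * diag.stderr[ok]
        assert within.mean() >= 0.95

    def test_double_well_benchmark_recovery(self, benchmark_windows,
                                            benchmark_pmf):
        potential, windows = benchmark_windows
        profile = benchmark_pmf
        reference = analytic_reference_pmf(potential, 300.0, profile.grid)
        mask = well_sampled_mask(windows)
        err = profile.free_energy[mask] - reference.free_energy[mask]
        assert np.nanmax(np.abs(err)) <= 0.2

    def test_single_window_reduces_to_boltzmann_inversion(self):
        flat = PotentialSpec(terms=((1, 1.0, 0.0),))
        window = sample_window(flat, 0.0, 1e-9, 50_000, step_size=90.0,
                               seed=4, burn_in=100)
        profile = wham_pmf([window])
        idx = _bin_indices(window.samples, 2.0, 180)
        hist = np.bincount(idx, minlength=180).astype(float)
        with np.errstate(divide="ignore"):
            direct = np.where(hist > 0, -KT300 * np.log(hist), np.nan)
        direct -= np.nanmin(direct)
        both = np.isfinite(direct) & profile.sampled
        # the residual k = 1e-9 bias leaves a deterministic discrepancy of
        # at most k * 180^2 ~ 3e-5 kcal/mol
        assert np.nanmax(np.abs(profile.free_energy[both] - direct[both])) \
            < 1e-4

    def test_period_shift_invariance(self):
        pot = default_double_well()
        windows = sample_protocol(pot, make_windows(-120, -40, 10),
                                  n_steps=4000, seed=11, burn_in=200)
        shifted = [dataclasses.replace(w, center=w.center + 360.0,
                                       samples=w.samples + 360.0)
                   for w in windows]
        p0, p1 = wham_pmf(windows), wham_pmf(shifted)
        assert np.allclose(p0.free_energy, p1.free_energy,
                           atol=1e-6, equal_nan=True)

    def test_window_order_invariance(self):
        pot = default_double_well()
        windows = sample_protocol(pot, make_windows(-120, -40, 10),
                                  n_steps=4000, seed=12, burn_in=200)
        p0 = wham_pmf(windows)
        p1 = wham_pmf(list(reversed(windows)))
        assert np.allclose(p0.free_energy, p1.free_energy,
                           atol=1e-6, equal_nan=True)

    def test_more_samples_never_worse_on_benchmark(self):
        pot = default_double_well()
        centers = make_windows(-210, -50, 10)
        reference = None
        errors = []
        for n in (4000, 8000):
            windows = sample_protocol(pot, centers, n_steps=n, seed=21,
                                      burn_in=500)
            profile = wham_pmf(windows)
            if reference is None:
                reference = analytic_reference_pmf(pot, 300.0, profile.grid)
            both = well_sampled_mask(windows) & profile.sampled
            errors.append(float(np.max(np.abs(
                profile.free_energy[both] - reference.free_energy[both]))))
        assert errors[1] <= errors[0]

    def test_nonconvergence_raises_with_residual(self):
        pot = default_double_well()
        windows = sample_protocol(pot, make_windows(-120, -40, 10),
                                  n_steps=2000, seed=13, burn_in=100)
        with pytest.raises(WhamConvergenceError) as exc:
            wham_pmf(windows, WhamConfig(tolerance=1e-14, max_iterations=3))
        assert np.isfinite(exc.value.residual)

    def test_disjoint_windows_warn(self):
        rng = np.random.default_rng(0)
        w1 = UmbrellaWindowSeries(0.0, 0.5, rng.normal(0, 2, 500))
        w2 = UmbrellaWindowSeries(120.0, 0.5, rng.normal(120, 2, 500))
        with pytest.warns(UserWarning, match="no occupied bins"):
            wham_pmf([w1, w2])


class TestAutocorrTime:
    def test_iid_noise_is_uncorrelated(self, rng):
        tau = autocorr_time(rng.normal(size=50_000))
        assert tau == pytest.approx(1.0, abs=0.2)

    def test_ar1_closed_form(self, rng):
        phi, n = 0.9, 100_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        # integrated time for AR(1): (1 + phi) / (1 - phi) = 19
        assert autocorr_time(x) == pytest.approx(19.0, abs=2.0)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            autocorr_time(np.full(100, 3.0))

    def test_sampling_interval_units(self, rng):
        x = rng.normal(size=20_000)
        series = UmbrellaWindowSeries(0.0, 1.0, x, sampling_interval=0.01)
        assert autocorr_time(series) == pytest.approx(
            0.01 * autocorr_time(x))


class TestDiagnostics:
    def test_identical_blocks_give_zero_stderr(self, rng):
        base = rng.uniform(-40, 40, 400)
        windows = [UmbrellaWindowSeries(0.0, 0.002, np.tile(base, 10))]
        diag = pmf_diagnostics(windows, n_blocks=10)
        assert np.nanmax(diag.stderr) == pytest.approx(0.0, abs=1e-12)

    def test_stderr_matches_direct_block_resampling(self):
        pot = default_double_well()
        windows = sample_protocol(pot, make_windows(-210, -50, 20),
                                  n_steps=5000, seed=17, burn_in=200)
        diag = pmf_diagnostics(windows, n_blocks=10)
        profiles = []
        for j in range(10):
            blocks = []
            for w in windows:
                n = w.samples.size
                blocks.append(w.restricted((j * n) // 10, ((j + 1) * n) // 10))
            profiles.append(wham_pmf(blocks).free_energy)
        g = np.stack(profiles)
        with np.errstate(invalid="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                expected = np.nanstd(g, axis=0, ddof=1) / np.sqrt(10)
        both = np.isfinite(diag.stderr) & np.isfinite(expected)
        assert np.allclose(diag.stderr[both], expected[both], rtol=1e-9)

    def test_full_fraction_equals_plain_wham(self):
        pot = default_double_well()
        windows = sample_protocol(pot, make_windows(-120, -40, 10),
                                  n_steps=3000, seed=19, burn_in=100)
        diag = pmf_diagnostics(windows, fractions=[1.0])
        full = wham_pmf(windows)
        assert np.allclose(diag.cumulative_profiles[0].free_energy,
                           full.free_energy, atol=1e-9, equal_nan=True)

    def test_too_few_samples_rejected(self):
        w = UmbrellaWindowSeries(0.0, 0.01, np.arange(5.0))
        with pytest.raises(ValueError):
            pmf_diagnostics([w], n_blocks=10)


class TestConditionalDistributions:
    def test_deterministic_coupling_gives_disjoint_support(self, rng):
        primary = rng.uniform(-180, 180, 20_000)
        secondary = wrap_angle(primary + 120.0)
        cond = conditional_dihedral_distribution(primary, secondary)
        a, b = cond.histograms
        assert np.sum((a > 0) & (b > 0)) == 0

    def test_independent_secondary_has_equal_conditionals(self, rng):
        primary = rng.uniform(-180, 180, 100_000)
        secondary = rng.uniform(-180, 180, 100_000)
        cond = conditional_dihedral_distribution(primary, secondary)
        assert cond.total_variation() <= 0.05

    def test_empty_regime_flagged(self):
        primary = np.full(1000, 180.0)   # all trans
        secondary = np.linspace(-170, 170, 1000)
        cond = conditional_dihedral_distribution(primary, secondary)
        assert cond.empty == (False, True)
        assert cond.histograms[1] is None

    def test_histograms_normalized(self, rng):
        primary = rng.uniform(-180, 180, 5000)
        secondary = rng.uniform(-180, 180, 5000)
        cond = conditional_dihedral_distribution(primary, secondary)
        for h in cond.histograms:
            assert h.sum() == pytest.approx(1.0)
        # counts are the regime memberships of the primary series
        from groovestate.geometry import classify_rotamer
        n_trans = sum(classify_rotamer(x) == "trans" for x in primary)
        n_gm = sum(classify_rotamer(x) == "gauche_minus" for x in primary)
        assert cond.counts == (n_trans, n_gm)


class TestModelInterface:
    def test_fit_summary_and_dataframe(self):
        pot = default_double_well()
        windows = sample_protocol(pot, make_windows(-210, -50, 20),
                                  n_steps=4000, seed=23, burn_in=200)
        result = UmbrellaSampling(windows).fit(n_blocks=5)
        text = result.summary()
        assert "barrier height" in text
        assert "windows:           9" in text
        df = result.to_dataframe()
        assert set(df.columns) == {"angle_deg", "free_energy_kcal_mol",
                                   "stderr_kcal_mol", "counts"}
        assert result.profile.stderr is not None

    def test_minima_near_both_wells(self, benchmark_windows):
        _, windows = benchmark_windows
        result = UmbrellaSampling(windows).fit(diagnostics=False)
        angles = sorted(angle for angle, _ in result.minima(2))
        assert any(abs(wrap_angle(a + 60)) < 15 for a in angles)
        assert any(abs(wrap_angle(a - 180)) < 15 for a in angles)


class TestWindowFiles:
    def test_window_file_round_trip(self, tmp_path, rng):
        series = UmbrellaWindowSeries(center=-130.0, force_constant=0.015,
                                      samples=rng.uniform(-150, -110, 200),
                                      sampling_interval=0.5)
        path = tmp_path / "w.dat"
        write_window_file(series, path)
        back = read_window_file(path)
        assert back.center == series.center
        assert back.force_constant == series.force_constant
        assert back.sampling_interval == series.sampling_interval
        assert np.allclose(back.samples, series.samples, atol=1e-5)

    def test_manifest_reading(self, tmp_path, rng):
        names = []
        for i, c in enumerate((-90.0, -60.0)):
            s = UmbrellaWindowSeries(c, 0.015, rng.uniform(c - 10, c + 10, 50))
            write_window_file(s, tmp_path / f"w{i}.dat")
            names.append(f"w{i}.dat")
        (tmp_path / "manifest.tsv").write_text("\n".join(names) + "\n")
        windows = read_manifest(tmp_path / "manifest.tsv")
        assert [w.center for w in windows] == [-90.0, -60.0]
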