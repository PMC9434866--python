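"""Synthetic spectra generator: band library, concentrations, forward model."""

import numpy as np
import pytest

from nircarb import (
    NoiseConfig,
    build_default_library,
    generate_dataset,
    sample_concentrations,
    wavelength_grid,
)
from nircarb.errors import InvalidDesignError, InvalidGridError
from nircarb.synthetic_data import (
    N_REPLICATES,
    design,
    default_tissue_designs,
    mixture_absorbance,
)


class TestComponentLibrary:
    def test_starch_band_positions(self, library):
        centers = {c for c, _, _ in library.bands["starch"]}
        assert {1480.0, 1640.0, 2020.0, 2123.0} == centers

    def test_water_band_position(self, library):
        assert library.bands["water"][0][0] == 1941.0

    def test_all_centers_within_grid_reach(self, grid, library):
        for name in library.component_names:
            for c, s, _ in library.bands[name]:
                assert grid[0] - 3 * s <= c <= grid[-1] + 3 * s
                assert c >= 1100  # sub-grid sugar region is clipped away

    def test_gaussian_peak_equals_amplitude(self, grid):
        # a single on-grid band evaluated at its center gives exactly amp
        from nircarb.synthetic_data import ComponentLibrary

        center, amp = 2020.0, 0.014  # 2020 nm lies on the 8 nm grid
        lib = ComponentLibrary(
            component_names=("starch",),
            bands={"starch": [(center, 16.0, amp)]},
            grid=grid,
        )
        idx = int(np.argmin(np.abs(grid - center)))
        assert grid[idx] == center
        assert lib.component_spectrum("starch")[idx] == amp

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(InvalidGridError):
            build_default_library(np.array([1100.0, 1090.0, 1200.0]))

    def test_sugars_spectrally_distinct(self, library):
        pure = {n: library.component_spectrum(n) for n in ("glucose", "fructose", "sucrose")}
        for a in pure:
            for b in pure:
                if a < b:
                    cos = pure[a] @ pure[b] / (
                        np.linalg.norm(pure[a]) * np.linalg.norm(pure[b])
                    )
                    assert cos < 0.999


class TestSampleConcentrations:
    def test_degenerate_sd_gives_exact_means(self):
        d = design("root", 11.05, 1.0, 1.5, 0.3, n_samples=5, rel_sd=0.0)
        table = sample_concentrations(d, 0)
        assert (table["starch"] == 11.05).all()

    def test_mean_within_three_standard_errors(self):
        d = design("trunk_phloem", 11.05, 1.03, 1.93, 0.63, n_samples=500)
        table = sample_concentrations(d, 123)
        se = d.sds["starch"] / np.sqrt(500)
        assert abs(table["starch"].mean() - 11.05) < 3 * se

    def test_nsc_is_computed_sum(self):
        d = design("root", 9.64, 0.25, 0.3, 0.01, n_samples=50)
        table = sample_concentrations(d, 5)
        np.testing.assert_allclose(
            table["nsc"],
            table[["glucose", "fructose", "sucrose", "starch"]].sum(axis=1),
            atol=1e-12,
        )

    def test_concentrations_nonnegative(self):
        d = design("root", 0.1, 0.05, 0.05, 0.01, n_samples=200, rel_sd=2.0)
        table = sample_concentrations(d, 9)
        assert (table[["glucose", "fructose", "sucrose", "starch"]] >= 0).all().all()

    def test_negative_sd_rejected(self):
        with pytest.raises(InvalidDesignError):
            design("root", 1, 1, 1, 1, rel_sd=-0.1)

    def test_sugar_correlation_honored(self):
        d = design("trunk_phloem", 11.05, 1.03, 1.93, 0.63, n_samples=400,
                   glucose_fructose_rho=0.9)
        table = sample_concentrations(d, 21)
        r = np.corrcoef(table["glucose"], table["fructose"])[0, 1]
        assert r > 0.8


class TestGenerateDataset:
    def test_empty_mixture_gives_unit_reflectance(self, library):
        d = design("root", 0, 0, 0, 0, n_samples=3, rel_sd=0.0,
                   water_mean=0.0, water_sd=0.0, matrix_mean=0.0, matrix_sd=0.0)
        spectra, _ = generate_dataset([d], library, NoiseConfig(seed=1).silent())
        np.testing.assert_allclose(spectra.reflectance, 1.0)

    def test_beer_lambert_doubling(self, library):
        kwargs = dict(n_samples=1, rel_sd=0.0, water_mean=2.0, water_sd=0.0,
                      matrix_mean=10.0, matrix_sd=0.0)
        silent = NoiseConfig(seed=1).silent()
        s1, _ = generate_dataset(
            [design("root", 5, 0.5, 0.5, 0.1, **kwargs)], library, silent)
        kwargs["water_mean"] = 4.0
        kwargs["matrix_mean"] = 20.0
        s2, _ = generate_dataset(
            [design("root", 10, 1.0, 1.0, 0.2, **kwargs)], library, silent)
        a1 = -np.log10(s1.reflectance[0])
        a2 = -np.log10(s2.reflectance[0])
        np.testing.assert_allclose(a2, 2 * a1, atol=1e-9)

    def test_same_seed_bit_identical(self, library):
        designs = [design("root", 9.64, 0.25, 0.3, 0.01, n_samples=5)]
        a, ca = generate_dataset(designs, library, NoiseConfig(seed=99))
        b, cb = generate_dataset(designs, library, NoiseConfig(seed=99))
        np.testing.assert_array_equal(a.reflectance, b.reflectance)
        assert ca.equals(cb)

    def test_three_replicates_per_sample(self, small_dataset):
        spectra, chem = small_dataset
        counts = spectra.replicate_counts()
        assert (counts == N_REPLICATES).all()
        assert spectra.n_samples == len(chem)

    def test_least_squares_recovers_concentrations(self, library):
        # zero-noise linearity oracle: regress absorbance on pure spectra
        d = design("root", 9.64, 0.5, 0.4, 0.2, n_samples=10)
        spectra, chem = generate_dataset([d], library, NoiseConfig(seed=3).silent())
        pure = library.pure_spectra()
        absorb = -np.log10(spectra.reflectance[::N_REPLICATES])
        recovered, *_ = np.linalg.lstsq(pure.T, absorb.T, rcond=None)
        truth = chem[list(library.component_names)].to_numpy().T
        np.testing.assert_allclose(recovered, truth, atol=1e-8)

    def test_replicate_averaging_reduces_noise_threefold(self, library):
        d = design("root", 9.64, 0, 0, 0, rel_sd=0.0, n_samples=400,
                   water_sd=0.0, matrix_sd=0.0)
        noise = NoiseConfig(
            replicate_noise_sd=0.002, baseline_offset_sd=0.0,
            baseline_slope_sd=0.0, multiplicative_scatter_sd=0.0,
            background_sd=0.0, seed=11,
        )
        spectra, _ = generate_dataset([d], library, noise)
        j = 80  # arbitrary interior channel
        per_rep = spectra.reflectance[:, j].reshape(-1, N_REPLICATES)
        var_single = per_rep.var(ddof=1)
        var_mean = per_rep.mean(axis=1).var(ddof=1)
        assert var_mean == pytest.approx(var_single / 3, rel=0.25)

    def test_duplicate_design_labels_rejected(self, library):
        d = design("root", 9.64, 0.25, 0.3, 0.01, n_samples=3)
        with pytest.raises(InvalidDesignError, match="duplicate"):
            generate_dataset([d, d], library, NoiseConfig(seed=0))


def test_default_designs_cover_six_tissues():
    designs = default_tissue_designs()
    assert len(designs) == 6
    # trace sucrose in root and needle tissue
    for tissue in ("root", "newly_needle", "one_yr_needle"):
        assert designs[tissue].means["sucrose"] <= 0.05


def test_mixture_absorbance_is_linear(library):
    a1 = mixture_absorbance(library, {"starch": 2.0})
    a2 = mixture_absorbance(library, {"starch": 4.0})
    np.testing.assert_allclose(a2, 2 * a1)
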