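import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memsense.errors import AnalysisError, InputError, StateDetectionError
from memsense.pmf import (
    FES2D,
    GAS_CONSTANT,
    PMF1D,
    boltzmann_invert,
    delta_delta_g,
    marginalize_cv2,
    read_fes,
    shift_min_zero,
    symmetrize,
)
from memsense.synthetic import gen_fes2d

T = 310.0
RT = GAS_CONSTANT * T


def _fes(values, cv1, cv2):
    return FES2D(cv1, cv2, values, T)


class TestMarginalization:
    CV1 = np.linspace(-2.0, 2.0, 41)
    CV2 = np.linspace(0.0, 180.0, 91)

    def test_cv2_independent_landscape_reduces_to_input(self):
        g = self.CV1**2
        fes = _fes(np.tile(g[:, None], (1, len(self.CV2))), self.CV1, self.CV2)
        pmf = shift_min_zero(marginalize_cv2(fes))
        np.testing.assert_allclose(pmf.G, g - g.min(), atol=1e-10)

    def test_harmonic_cv2_matches_gaussian_integral(self):
        """G(cv1,cv2) = g(cv1) + k/2 cv2'^2: the marginal offset equals the
        analytic Gaussian integral constant for every cv1 column."""
        k = 0.1  # kJ/mol/deg^2 -> harmonic width sqrt(RT/k) ~ 5 deg, well inside grid
        cv2 = np.linspace(-90.0, 90.0, 721)
        g = 3.0 * np.sin(self.CV1)
        vals = g[:, None] + 0.5 * k * cv2[None, :] ** 2
        C = float(cv2[-1] - cv2[0])
        pmf = marginalize_cv2(_fes(vals, self.CV1, cv2), C=C)
        offset = pmf.G - g
        analytic = -RT * np.log(np.sqrt(2 * np.pi * RT / k) / C)
        np.testing.assert_allclose(offset, analytic, atol=1e-6)

    def test_quadrature_converges_on_refined_grid(self):
        def build(n):
            cv2 = np.linspace(0.0, 180.0, n)
            vals = self.CV1[:, None] ** 2 + 0.001 * (cv2[None, :] - 90.0) ** 2
            return marginalize_cv2(_fes(vals, self.CV1, cv2), C=180.0)

        coarse, fine = build(181), build(1801)
        assert np.max(np.abs(coarse.G - fine.G)) < 1e-4

    def test_interior_unvisited_column_is_error(self):
        vals = np.zeros((len(self.CV1), len(self.CV2)))
        vals[5, 40] = np.nan
        with pytest.raises(AnalysisError, match="inside the domain"):
            marginalize_cv2(_fes(vals, self.CV1, self.CV2))

    def test_edge_unvisited_excluded_with_warning(self):
        vals = np.zeros((len(self.CV1), len(self.CV2)))
        vals[:, 0] = np.nan
        with pytest.warns(UserWarning, match="edges"):
            pmf = marginalize_cv2(_fes(vals, self.CV1, self.CV2))
        assert np.all(np.isfinite(pmf.G))

    def test_all_unvisited_column_names_cv1(self):
        vals = np.zeros((len(self.CV1), len(self.CV2)))
        vals[3, :] = np.nan
        with pytest.raises(AnalysisError, match=f"{self.CV1[3]:.4f}"):
            marginalize_cv2(_fes(vals, self.CV1, self.CV2))

    def test_huge_global_offset_is_harmless(self):
        """Log-sum-exp keeps landscapes offset by +1e6 kJ/mol exact."""
        fes0 = gen_fes2d(20.0, 60.0)
        fes1 = FES2D(fes0.cv1, fes0.cv2, fes0.values + 1e6, T)
        p0 = shift_min_zero(marginalize_cv2(fes0))
        p1 = shift_min_zero(marginalize_cv2(fes1))
        np.testing.assert_allclose(p0.G, p1.G, atol=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20)
    def test_log_sum_exp_bracket(self, seed):
        """Boltzmann averaging is bracketed by the column minimum plus
        entropic constants: the integral is at most range*exp(-beta*Gmin)
        and at least w_min*exp(-beta*Gmin)."""
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.0, 50.0, (11, 31))
        cv1 = np.linspace(-1, 1, 11)
        cv2 = np.linspace(0, 180, 31)
        C = 37.0
        pmf = marginalize_cv2(_fes(vals, cv1, cv2), C=C)
        gmin = vals.min(axis=1)
        span = cv2[-1] - cv2[0]
        w_min = (cv2[1] - cv2[0]) / 2.0  # smallest trapezoid weight
        assert np.all(pmf.G >= gmin - RT * np.log(span / C) - 1e-9)
        assert np.all(pmf.G <= gmin + RT * np.log(C / w_min) + 1e-9)


class TestSymmetrize:
    Z = np.linspace(-1.0, 1.0, 21)

    def test_symmetric_profile_unchanged(self):
        pmf = PMF1D(self.Z, self.Z**2, T)
        out = symmetrize(pmf)
        np.testing.assert_allclose(out.G, pmf.G)
        np.testing.assert_allclose(out.errors, 0.0, atol=1e-12)

    def test_antisymmetric_profile_averages_to_zero(self):
        out = symmetrize(PMF1D(self.Z, self.Z.copy(), T))
        np.testing.assert_allclose(out.G, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.errors, np.abs(self.Z))

    def test_programmed_leaflet_asymmetry_gives_half_error(self):
        fes = gen_fes2d(10.0, 50.0, asymmetry=1.0)
        pmf = symmetrize(marginalize_cv2(fes))
        assert np.nanmax(pmf.errors) == pytest.approx(0.5, abs=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        pmf = PMF1D(self.Z, rng.normal(size=21), T)
        once = symmetrize(pmf)
        twice = symmetrize(once)
        np.testing.assert_allclose(once.G, twice.G, atol=1e-12)

    def test_asymmetric_grid_requires_interpolation(self):
        z = np.linspace(-0.8, 1.0, 19)
        with pytest.raises(InputError):
            symmetrize(PMF1D(z, z**2, T))
        out = symmetrize(PMF1D(z, z**2, T), interpolate=True)
        np.testing.assert_allclose(out.G, out.G[::-1], atol=1e-12)


class TestShiftAndStates:
    def test_constant_profile_shifts_to_zero(self):
        z = np.linspace(-1, 1, 11)
        out = shift_min_zero(PMF1D(z, np.full(11, 7.3), T))
        np.testing.assert_allclose(out.G, 0.0)

    def test_shift_idempotent_and_ddg_invariant(self):
        fes = gen_fes2d(20.0, 60.0)
        pmf = symmetrize(marginalize_cv2(fes))
        once = shift_min_zero(pmf)
        twice = shift_min_zero(once)
        np.testing.assert_allclose(once.G, twice.G)
        assert delta_delta_g(pmf) == pytest.approx(delta_delta_g(once), abs=1e-12)

    def test_programmed_ddg_recovered(self):
        pmf = shift_min_zero(symmetrize(marginalize_cv2(gen_fes2d(20.0, 60.0))))
        assert delta_delta_g(pmf) == pytest.approx(20.0, abs=0.1)
        assert pmf.barrier == pytest.approx(60.0, abs=0.1)

    def test_table_scale_ddg_recovered(self):
        """A landscape programmed at the magnitude of a strongly adsorbed
        peptide (ΔΔG ~ 52.7 kJ/mol) is recovered the same way."""
        pmf = shift_min_zero(symmetrize(marginalize_cv2(gen_fes2d(52.7, 70.0))))
        assert delta_delta_g(pmf) == pytest.approx(52.7, abs=0.1)

    def test_ddg_invariant_to_normalization_constant(self):
        fes = gen_fes2d(15.0, 45.0)
        vals = [
            delta_delta_g(shift_min_zero(symmetrize(marginalize_cv2(fes, C=C))))
            for C in (1.0, 180.0, 1234.5)
        ]
        np.testing.assert_allclose(vals, vals[0], atol=1e-9)

    def test_symmetric_double_well_has_zero_ddg(self):
        pmf = shift_min_zero(symmetrize(marginalize_cv2(gen_fes2d(0.0, 30.0))))
        assert delta_delta_g(pmf) == pytest.approx(0.0, abs=1e-9)

    def test_monotonic_profile_raises_state_error(self):
        z = np.linspace(-2, 2, 41)
        with pytest.raises(StateDetectionError):
            delta_delta_g(PMF1D(z, z.copy(), T))


class TestBoltzmannInversion:
    def test_uniform_density_gives_flat_profile(self):
        z = np.linspace(-1, 1, 21)
        pmf = boltzmann_invert(np.ones(21), z, T)
        np.testing.assert_allclose(pmf.G, 0.0)

    def test_gaussian_density_gives_harmonic_profile(self):
        sigma = 0.5
        z = np.linspace(-1.5, 1.5, 301)
        rho = np.exp(-(z / sigma) ** 2 / 2.0)
        pmf = boltzmann_invert(rho, z, T)
        np.testing.assert_allclose(pmf.G, RT * z**2 / (2 * sigma**2), atol=1e-9)

    def test_round_trip_identity(self):
        z = np.linspace(-1, 1, 51)
        G = 5.0 * z**4 - 2.0 * z**2 + 3.0
        rho = np.exp(-G / RT)
        back = boltzmann_invert(rho, z, T)
        np.testing.assert_allclose(back.G, G - G.min(), atol=1e-9)

    def test_zero_bins_flagged_not_infinite(self):
        z = np.linspace(-1, 1, 5)
        pmf = boltzmann_invert(np.array([0.0, 1.0, 2.0, 1.0, 0.0]), z, T)
        assert np.isnan(pmf.G[0]) and np.isnan(pmf.G[-1])
        assert np.all(np.isfinite(pmf.G[1:-1]))

    def test_all_zero_density_rejected(self):
        with pytest.raises(InputError):
            boltzmann_invert(np.zeros(5), np.linspace(-1, 1, 5), T)


class TestFesIO:
    def test_text_round_trip(self, tmp_path):
        fes = gen_fes2d(12.0, 40.0, n_cv1=21, cv2_grid=np.linspace(0, 180, 19))
        path = tmp_path / "fes.dat"
        with open(path, "w") as fh:
            fh.write("# cv1 cv2 dG\n")
            for i, z in enumerate(fes.cv1):
                for j, a in enumerate(fes.cv2):
                    fh.write(f"{z:.6f} {a:.6f} {fes.values[i, j]:.8f}\n")
        back = read_fes(path, T)
        np.testing.assert_allclose(back.cv1, fes.cv1, atol=1e-6)
        np.testing.assert_allclose(back.values, fes.values, atol=1e-7)

    def test_pmf_csv_export_carries_state_annotations(self, tmp_path):
        pmf = shift_min_zero(symmetrize(marginalize_cv2(gen_fes2d(20.0, 60.0))))
        delta_delta_g(pmf)
        out = tmp_path / "pmf.csv"
        pmf.to_csv(out)
        text = out.read_text()
        assert "# state transmembrane" in text
        assert "# delta_delta_G_kJ_per_mol" in text
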