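"""Single-shell model: permittivities, CM factor, crossovers, window."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depsort import (
    EPS0,
    DielectricMaterial,
    FrequencyGrid,
    ShelledCell,
    clausius_mossotti,
    cm_spectrum,
    complex_permittivity,
    crossover_frequencies,
    effective_cell_permittivity,
    make_cell,
    make_medium,
    separation_window,
)


def oracle_cm(cell, medium, f):
    """Independently coded direct-arithmetic evaluation of the CM factor."""
    w = 2 * np.pi * f
    e_cyto = EPS0 * cell.cytoplasm.relative_permittivity - 1j * cell.cytoplasm.conductivity / w
    c_star = cell.cspec - 1j * cell.gspec / w
    e_p = (cell.radius * c_star * e_cyto) / (cell.radius * c_star + e_cyto)
    e_m = EPS0 * medium.relative_permittivity - 1j * medium.conductivity / w
    return (e_p - e_m) / (e_p + 2 * e_m)


class TestComplexPermittivity:
    def test_zero_conductivity_is_purely_real(self):
        mat = DielectricMaterial(78.0, 0.0)
        val = complex_permittivity(mat, 1e6)
        assert val == pytest.approx(78 * EPS0)
        assert val.imag == 0

    def test_high_frequency_limit_loses_conductivity_term(self):
        mat = DielectricMaterial(78.0, 0.01)
        val = complex_permittivity(mat, 1e15)
        assert val.real == pytest.approx(78 * EPS0)
        assert abs(val.imag) < 1e-5 * val.real

    def test_hand_computed_value(self):
        mat = DielectricMaterial(78.0, 0.01)
        expected = EPS0 * 78 - 1j * 0.01 / (2 * np.pi * 1e5)
        assert complex_permittivity(mat, 1e5) == pytest.approx(expected)

    @pytest.mark.parametrize("bad_f", [0.0, -10.0, np.nan])
    def test_nonpositive_frequency_rejected(self, bad_f):
        with pytest.raises(ValueError, match="frequency"):
            complex_permittivity(DielectricMaterial(78.0, 0.01), bad_f)

    def test_imaginary_part_never_positive(self, rng):
        mat = DielectricMaterial(60.0, 0.5)
        f = 10 ** rng.uniform(1, 9, 100)
        assert np.all(complex_permittivity(mat, f).imag <= 0)


class TestEffectiveCellPermittivity:
    def test_low_frequency_insulating_membrane_limit(self):
        cell = make_cell(20.0, gspec_s_m2=0.0)
        val = effective_cell_permittivity(cell, 1.0)
        assert val.real == pytest.approx(cell.radius * cell.cspec, rel=1e-3)
        assert abs(val.imag) / val.real < 1e-3

    def test_matches_independent_closed_form(self):
        cell = ShelledCell(8e-6, 0.02, 0.0, DielectricMaterial(60.0, 0.5))
        f = 1e6
        w = 2 * np.pi * f
        e_cyto = EPS0 * 60 - 1j * 0.5 / w
        expected = (8e-6 * 0.02 * e_cyto) / (8e-6 * 0.02 + e_cyto)
        assert effective_cell_permittivity(cell, f) == pytest.approx(expected, rel=1e-12)

    def test_membrane_transparent_at_high_frequency(self):
        cell = make_cell(20.0)
        e_cyto = complex_permittivity(cell.cytoplasm, 1e10)
        val = effective_cell_permittivity(cell, 1e10)
        assert abs(val - e_cyto) / abs(e_cyto) < 0.01


class TestClausiusMossotti:
    def test_index_matched_cell_gives_zero(self, medium):
        # a "cell" whose effective permittivity equals the medium's at f:
        # same dielectric on both sides with a huge transparent membrane
        cyto = DielectricMaterial(78.0, 0.01)
        cell = ShelledCell(8e-6, 50.0, 0.0, cyto)  # r*Cspec >> |eps|: shell invisible
        cm = clausius_mossotti(cell, DielectricMaterial(78.0, 0.01), 1e6)
        assert abs(cm) < 1e-5

    def test_low_frequency_limit_is_minus_half(self, medium):
        for cspec in (5.0, 20.0, 50.0):
            cm = clausius_mossotti(make_cell(cspec, gspec_s_m2=0.0), medium, 1.0)
            assert cm.real == pytest.approx(-0.5, abs=1e-3)

    def test_separation_frequency_with_opposed_signs_exists(self, gbm1, gbm2, medium):
        f = np.logspace(3, 8, 500)
        re1 = clausius_mossotti(gbm1, medium, f).real
        re2 = clausius_mossotti(gbm2, medium, f).real
        assert np.any((re1 > 0) & (re2 < 0))

    def test_oracle_equivalence_on_random_inputs(self, rng):
        """CM matches an independently coded evaluation to 1e-12 relative."""
        for _ in range(1000):
            cell = ShelledCell(
                radius=rng.uniform(2e-6, 20e-6),
                cspec=rng.uniform(2e-3, 50e-3),
                gspec=rng.uniform(0, 2000),
                cytoplasm=DielectricMaterial(rng.uniform(40, 90), rng.uniform(0.05, 2.0)),
            )
            medium = DielectricMaterial(rng.uniform(40, 90), rng.uniform(1e-4, 0.2))
            f = 10 ** rng.uniform(2, 9)
            got = clausius_mossotti(cell, medium, f)
            want = oracle_cm(cell, medium, f)
            assert got == pytest.approx(want, rel=1e-12)

    def test_re_cm_bounded_for_physical_inputs(self, rng):
        """-0.5 <= Re[CM] <= 1 over a large random physical parameter sweep."""
        n = 100_000
        freqs = 10 ** rng.uniform(2, 9, n)
        cspecs = rng.uniform(2e-3, 50e-3, n)
        radii = rng.uniform(2e-6, 20e-6, n)
        lo, hi = 0.0, 0.0
        for i in range(0, n, 10_000):
            sl = slice(i, i + 10_000)
            cell = ShelledCell(
                radius=float(radii[i]), cspec=float(cspecs[i]),
                gspec=float(rng.uniform(0, 2000)),
                cytoplasm=DielectricMaterial(60.0, 0.5),
            )
            med = DielectricMaterial(78.0, float(rng.uniform(1e-4, 0.1)))
            re = clausius_mossotti(cell, med, freqs[sl]).real
            lo, hi = min(lo, re.min()), max(hi, re.max())
        assert lo >= -0.5 - 1e-9
        assert hi <= 1.0 + 1e-9

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        cspec=st.floats(2.0, 60.0),
        gspec=st.floats(0.0, 3000.0),
        radius=st.floats(2.0, 20.0),
        sigma_m_us_cm=st.floats(10.0, 1000.0),
        log_f=st.floats(2.0, 9.0),
    )
    def test_re_cm_bounds_property(self, cspec, gspec, radius, sigma_m_us_cm, log_f):
        cell = make_cell(cspec, gspec, radius)
        med = make_medium(sigma_m_us_cm)
        re = clausius_mossotti(cell, med, 10.0**log_f).real
        assert -0.5 - 1e-9 <= re <= 1.0 + 1e-9


class TestCMSpectrum:
    def test_single_point_consistency(self, gbm1, medium):
        grid = FrequencyGrid(np.array([1e6]))
        spec = cm_spectrum(gbm1, medium, grid)
        assert spec.cm_values[0] == pytest.approx(clausius_mossotti(gbm1, medium, 1e6), rel=1e-14)

    def test_pointwise_equality_and_length(self, gbm1, medium, instrument_grid):
        spec = cm_spectrum(gbm1, medium, instrument_grid)
        assert len(spec.cm_values) == len(instrument_grid)
        for f, v in zip(instrument_grid.frequencies[::5], spec.cm_values[::5]):
            assert v == pytest.approx(clausius_mossotti(gbm1, medium, float(f)), rel=1e-14)

    def test_monotone_rise_through_low_frequency_dispersion(self, gbm1, medium):
        """No local maxima below the global maximum region on a dense grid."""
        grid = FrequencyGrid.log_spaced(1e4, 4.5e7, 400)
        re = cm_spectrum(gbm1, medium, grid).re_cm
        i_max = int(np.argmax(re))
        assert np.all(np.diff(re[: i_max + 1]) > 0)

    def test_reversed_grid_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            FrequencyGrid(np.array([1e6, 1e5, 1e4]))


class TestCrossoverFrequencies:
    def test_index_matched_cell_has_none(self):
        cyto = DielectricMaterial(78.0, 0.01)
        cell = ShelledCell(8e-6, 50.0, 0.0, cyto)
        band = FrequencyGrid.log_spaced(1e3, 1e8, 16)
        assert crossover_frequencies(cell, DielectricMaterial(78.0, 0.01), band) == []

    @pytest.mark.parametrize("cspec_mf", [5.0, 10.0, 20.0, 40.0])
    def test_analytic_low_conductance_limit(self, cspec_mf, medium, wide_band):
        """First crossover within 5% of sqrt(2)*sigma_m/(2 pi r Cspec)."""
        cell = make_cell(cspec_mf, gspec_s_m2=0.0)  # sigma_cyto = 0.5 >= 50 * 0.01
        roots = crossover_frequencies(cell, medium, wide_band)
        analytic = np.sqrt(2) * medium.conductivity / (2 * np.pi * cell.radius * cell.cspec)
        assert roots
        assert abs(roots[0] - analytic) / analytic < 0.05

    def test_crossover_decreases_with_cspec(self, medium, wide_band):
        firsts = [
            crossover_frequencies(make_cell(c), medium, wide_band)[0]
            for c in (5.0, 10.0, 15.0, 20.0, 25.0)
        ]
        assert all(a > b for a, b in zip(firsts, firsts[1:]))

    def test_gbm_archetype_ordering(self, gbm1, gbm2, medium, wide_band):
        f1 = crossover_frequencies(gbm1, medium, wide_band)[0]
        f2 = crossover_frequencies(gbm2, medium, wide_band)[0]
        assert f1 < f2

    def test_narrow_band_rejected(self, gbm1, medium):
        with pytest.raises(ValueError, match="decades"):
            crossover_frequencies(gbm1, medium, FrequencyGrid.log_spaced(1e5, 5e5, 8))


class TestSeparationWindow:
    def test_identical_cells_have_no_window(self, gbm1, medium, wide_band):
        assert separation_window(gbm1, gbm1, medium, wide_band) is None

    def test_gbm_presets_give_nonempty_window(self, gbm1, gbm2, medium, wide_band):
        w = separation_window(gbm1, gbm2, medium, wide_band)
        assert w is not None
        f_lo, f_hi = w
        assert f_lo < f_hi
        mid = 10 ** ((np.log10(f_lo) + np.log10(f_hi)) / 2)
        assert clausius_mossotti(gbm1, medium, mid).real > 0
        assert clausius_mossotti(gbm2, medium, mid).real < 0

    def test_window_endpoints_match_crossovers(self, gbm1, gbm2, medium, wide_band):
        f_lo, f_hi = separation_window(gbm1, gbm2, medium, wide_band)
        x1 = crossover_frequencies(gbm1, medium, wide_band)[0]
        x2 = crossover_frequencies(gbm2, medium, wide_band)[0]
        assert f_lo == pytest.approx(x1, rel=1e-4)
        assert f_hi == pytest.approx(x2, rel=1e-4)
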