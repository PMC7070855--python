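"""Lineshape simulation and line-metric measurements."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import cumulative_trapezoid

from eprbind.lineshape import (
    BiradicalModel,
    FieldGrid,
    LineshapeParameterError,
    RadicalSpecies,
    SatelliteSpec,
    line_metrics,
    simulate_biradical,
    simulate_spectrum,
)

GRID = FieldGrid(center_field=3480.0, span=120.0, n_points=4096)


def double_integral(spectrum):
    """Independent quadrature oracle: two cumulative trapezoid passes."""
    absorption = cumulative_trapezoid(spectrum.intensity, spectrum.field, initial=0.0)
    return np.trapezoid(absorption, spectrum.field)


class TestSimulateSpectrum:
    def test_degenerate_single_line_crosses_zero_at_center(self):
        sp = simulate_spectrum(RadicalSpecies(a_N=0.0, width_alpha=0.8), GRID)
        # derivative changes sign exactly at the absorption maximum
        idx = np.argmax(np.abs(np.diff(np.sign(sp.intensity))))
        crossing = sp.field[idx]
        assert abs(crossing - GRID.center_field) < 2 * GRID.step
        m = line_metrics(sp)
        assert not m.valid
        assert m.apparent_a_N is None
        assert m.ratio_I_minus_over_I_0 is None

    @pytest.mark.parametrize(
        "species",
        [
            RadicalSpecies(a_N=16.0, width_alpha=0.8),
            RadicalSpecies(a_N=16.0, width_alpha=0.8, width_beta=-0.2, width_gamma=0.3),
            RadicalSpecies(
                a_N=15.3,
                width_alpha=0.9,
                satellites=(SatelliteSpec(a_C=4.4, n_equivalent=4),),
            ),
            RadicalSpecies(a_N=14.0, width_alpha=1.5, lorentz_fraction=0.5),
        ],
        ids=["plain", "asymmetric", "satellites", "voigt"],
    )
    def test_unit_double_integral(self, species):
        sp = simulate_spectrum(species, GRID)
        assert double_integral(sp) == pytest.approx(1.0, abs=1e-3)

    def test_apparent_a_n_of_free_tempone_preset(self, tempone_preset):
        m = line_metrics(tempone_preset.spectrum_of("free", GRID))
        assert m.apparent_a_N == pytest.approx(16.0, abs=0.05)

    def test_apparent_a_n_of_bound_tempone_preset(self, tempone_preset):
        m = line_metrics(tempone_preset.spectrum_of("bound", GRID))
        assert m.apparent_a_N == pytest.approx(15.3, abs=0.05)

    def test_satellite_pair_positions_and_intensity(self):
        sat = SatelliteSpec(a_C=6.0, n_equivalent=4, abundance=0.0107)
        with_sat = simulate_spectrum(
            RadicalSpecies(a_N=16.0, width_alpha=0.5, satellites=(sat,)), GRID
        )
        without = simulate_spectrum(RadicalSpecies(a_N=16.0, width_alpha=0.5), GRID)
        diff = with_sat.intensity - (1 - sat.fraction) * without.intensity
        # residual structure is the satellites: peaks at +/- a_C/2 of each line
        absorption = cumulative_trapezoid(diff, with_sat.field, initial=0.0)
        center = GRID.center_field
        sat_field = center + sat.a_C / 2.0
        window = (with_sat.field > sat_field - 1) & (with_sat.field < sat_field + 1)
        assert absorption[window].max() > 0.8 * absorption.max()

    def test_narrow_grid_warns_and_flags(self):
        grid = FieldGrid(center_field=3480.0, span=40.0, n_points=512)
        with pytest.warns(UserWarning, match="span"):
            sp = simulate_spectrum(RadicalSpecies(a_N=16.0, width_alpha=0.8), grid)
        assert "grid_too_narrow" in sp.meta.get("warnings", [])

    def test_invalid_width_raises(self):
        with pytest.raises(LineshapeParameterError, match="not positive"):
            RadicalSpecies(a_N=16.0, width_alpha=0.1, width_beta=0.5, width_gamma=0.0)

    def test_antisymmetry_without_beta_or_satellites(self):
        sp = simulate_spectrum(
            RadicalSpecies(a_N=16.0, width_alpha=0.8, width_beta=0.0, width_gamma=0.1),
            GRID,
        )
        assert np.allclose(sp.intensity, -sp.intensity[::-1], atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.3, 2.0),
        beta=st.floats(-0.2, 0.2),
        gamma=st.floats(0.0, 0.5),
        a_n=st.floats(12.0, 17.0),
    )
    def test_integral_conserved_under_width_changes(self, alpha, beta, gamma, a_n):
        sp = simulate_spectrum(
            RadicalSpecies(
                a_N=a_n, width_alpha=alpha, width_beta=beta, width_gamma=gamma
            ),
            GRID,
        )
        assert double_integral(sp) == pytest.approx(1.0, abs=1e-3)


class TestSimulateBiradical:
    def test_identical_sites_reduce_to_monoradical(self):
        site = RadicalSpecies(a_N=16.0, width_alpha=0.8)
        composite = simulate_biradical(BiradicalModel(site, site), GRID)
        single = simulate_spectrum(site, GRID)
        np.testing.assert_allclose(composite.intensity, single.intensity, rtol=1e-12)

    def test_linearity_of_weighted_sum(self):
        s1 = RadicalSpecies(a_N=16.0, width_alpha=0.8)
        s2 = RadicalSpecies(a_N=15.5, width_alpha=1.2, width_gamma=0.2)
        composite = simulate_biradical(BiradicalModel(s1, s2, 0.3, 0.7), GRID)
        expected = (
            0.3 * simulate_spectrum(s1, GRID).intensity
            + 0.7 * simulate_spectrum(s2, GRID).intensity
        )
        np.testing.assert_allclose(composite.intensity, expected, rtol=1e-12)

    def test_weight_violation_raises(self):
        site = RadicalSpecies(a_N=16.0, width_alpha=0.8)
        with pytest.raises(LineshapeParameterError, match="sum to 1"):
            BiradicalModel(site, site, 0.6, 0.6)

    def test_shuttle_composite_a_n_decrease(self, btbk_preset):
        m_free = line_metrics(btbk_preset.spectrum_of("free", GRID))
        m_bound = line_metrics(btbk_preset.spectrum_of("bound", GRID))
        decrease = m_free.apparent_a_N_moment - m_bound.apparent_a_N_moment
        assert decrease == pytest.approx(0.17, abs=0.02)

    def test_first_moment_additivity(self):
        """Centroid of an equal-weight composite line sits midway between
        the component centroids when the component lines have equal width."""
        s1 = RadicalSpecies(a_N=16.0, width_alpha=1.0)
        s2 = RadicalSpecies(a_N=15.5, width_alpha=1.0)
        m1 = line_metrics(simulate_spectrum(s1, GRID))
        m2 = line_metrics(simulate_spectrum(s2, GRID))
        mc = line_metrics(simulate_biradical(BiradicalModel(s1, s2), GRID))
        expected = 0.5 * (m1.moment_centers + m2.moment_centers)
        np.testing.assert_allclose(mc.moment_centers, expected, atol=5e-3)


class TestLineMetrics:
    def test_lorentzian_peak_to_peak_width(self):
        """Derivative extrema of a Lorentzian sit at +/- HWHH/sqrt(3)."""
        w = 0.8  # full width at half height
        grid = FieldGrid(center_field=3480.0, span=120.0, n_points=8192)
        sp = simulate_spectrum(RadicalSpecies(a_N=16.0, width_alpha=w), grid)
        mask = np.abs(sp.field - grid.center_field) < 8.0
        peak_up = sp.field[mask][np.argmax(sp.intensity[mask])]
        peak_dn = sp.field[mask][np.argmin(sp.intensity[mask])]
        assert peak_dn - peak_up == pytest.approx(w / np.sqrt(3.0), abs=grid.step)

    def test_wahh_measurement(self):
        sp = simulate_spectrum(RadicalSpecies(a_N=16.0, width_alpha=0.8), GRID)
        m = line_metrics(sp)
        np.testing.assert_allclose(m.w_ahh, 0.8, atol=2 * GRID.step)

    def test_monotone_broadening_of_high_field_line(self):
        """Widening W(-1) alone lowers I- and the I-/I0 ratio."""
        ratios, amps = [], []
        for gamma in (0.05, 0.2, 0.5):
            sp = simulate_spectrum(
                RadicalSpecies(
                    a_N=16.0, width_alpha=0.8, width_beta=-gamma, width_gamma=gamma
                ),
                GRID,
            )  # W(+1) = alpha, W(-1) = alpha + 2*gamma
            m = line_metrics(sp)
            ratios.append(m.ratio_I_minus_over_I_0)
            amps.append(m.I_minus)
        assert amps[0] > amps[1] > amps[2]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_insufficient_lines_flagged_not_raised(self):
        sp = simulate_spectrum(RadicalSpecies(a_N=0.0, width_alpha=1.0), GRID)
        m = line_metrics(sp)
        assert m.valid is False
        assert m.n_lines_found < 3
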