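"""Global titration fitting: recovery, identifiability, model comparison."""

import numpy as np
import pytest

from eprbind.globalfit import (
    IdentifiabilityError,
    TitrationPoint,
    TitrationSeries,
    _population_matrix,
    compare_models,
    fit_titration,
    initial_guess,
    regression_coefficient,
)
from eprbind.lineshape import RadicalSpecies, Spectrum
from eprbind.speciation import BindingModel
from eprbind.synthetic import NoiseSpec, generate_epr_titration


class TestRegressionCoefficient:
    def test_perfect_and_anticorrelated(self):
        x = np.arange(10.0)
        assert regression_coefficient(x, x) == pytest.approx(1.0)
        assert regression_coefficient(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=10)
        d = rng.normal(size=10)
        num = np.sum((m - m.mean()) * (d - d.mean()))
        den = np.sqrt(np.sum((m - m.mean()) ** 2) * np.sum((d - d.mean()) ** 2))
        assert regression_coefficient(m, d) == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            regression_coefficient(np.ones(5), np.arange(5.0))


@pytest.fixture(scope="module")
def noiseless_fit(small_tempone_series, tempone_templates):
    return fit_titration(
        small_tempone_series, "one_to_one", templates=tempone_templates
    )


class TestFitTitration:
    def test_noiseless_recovery_within_0p1_percent(self, noiseless_fit, tempone_preset):
        assert noiseless_fit.model.K_a == pytest.approx(tempone_preset.K_a, rel=1e-3)

    def test_noiseless_spectral_parameters_recovered(self, noiseless_fit, tempone_preset):
        p = noiseless_fit.parameters
        assert p["free.a_N"] == pytest.approx(tempone_preset.free.a_N, abs=0.01)
        assert p["bound.a_N"] == pytest.approx(tempone_preset.bound.a_N, abs=0.01)
        assert p["free.W_0"] == pytest.approx(tempone_preset.free.width_alpha, rel=0.02)

    def test_noiseless_regression_coefficient(self, noiseless_fit):
        assert noiseless_fit.regression_coefficient >= 0.99999

    def test_refit_from_solution_is_fixed_point(
        self, small_tempone_series, noiseless_fit
    ):
        species = {
            k: v for k, v in noiseless_fit.species.items() if k in ("free", "bound")
        }
        again = fit_titration(
            small_tempone_series,
            "one_to_one",
            init=species,
            ka_inits=[noiseless_fit.model.K_a],
        )
        assert again.model.K_a == pytest.approx(noiseless_fit.model.K_a, rel=1e-8)
        for name, value in noiseless_fit.parameters.items():
            assert again.parameters[name] == pytest.approx(value, rel=1e-6, abs=1e-8)

    def test_all_zero_host_is_identifiability_error(self, tempone_preset, small_grid):
        series = generate_epr_titration(
            tempone_preset, schedule=[0.0, 0.0, 0.0], noise=NoiseSpec(), grid=small_grid
        )
        with pytest.raises(IdentifiabilityError, match="zero host"):
            fit_titration(series, "one_to_one")

    def test_too_few_points_rejected(self, tempone_preset, small_grid):
        with pytest.raises(IdentifiabilityError, match=">= 3 points"):
            generate_epr_titration(
                tempone_preset, schedule=[0.0, 1e-3], noise=NoiseSpec(), grid=small_grid
            )

    def test_series_without_zero_host_warns(self, tempone_preset, small_grid):
        with pytest.warns(UserWarning, match="zero-host"):
            generate_epr_titration(
                tempone_preset,
                schedule=[1e-4, 5e-4, 2e-3],
                noise=NoiseSpec(),
                grid=small_grid,
            )

    def test_two_stage_variant_close_to_joint(
        self, small_tempone_series, tempone_templates, noiseless_fit
    ):
        res = fit_titration(
            small_tempone_series,
            "one_to_one",
            templates=tempone_templates,
            strategy="two_stage",
        )
        assert res.model.K_a == pytest.approx(noiseless_fit.model.K_a, rel=0.05)


def _make_two_step_series(small_grid):
    """Synthetic series whose truth is the stepwise two-host model."""
    free = RadicalSpecies(label="free", a_N=16.0, width_alpha=0.8)
    bound1 = RadicalSpecies(label="bound1", a_N=15.3, width_alpha=0.9, width_gamma=0.2)
    bound2 = RadicalSpecies(label="bound2", a_N=14.9, width_alpha=1.1, width_gamma=0.3)
    model = BindingModel(kind="two_step_host", K1=8000.0, K2=1500.0)
    hosts = np.array([0.0, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0]) * 1e-3
    fields = small_grid.fields()
    dummy = [
        TitrationPoint(h, Spectrum(fields, np.zeros_like(fields))) for h in hosts
    ]
    series = TitrationSeries(guest_total=1e-4, points=dummy)
    clean = _population_matrix(
        model, {"free": free, "bound1": bound1, "bound2": bound2}, series
    )
    rng = np.random.default_rng(11)
    pts = []
    for h, row in zip(hosts, clean):
        noise = rng.normal(0, np.abs(row).max() / 200.0, row.size)
        pts.append(TitrationPoint(h, Spectrum(fields, row + noise)))
    return TitrationSeries(guest_total=1e-4, points=pts)


class TestCompareModels:
    def test_two_step_truth_ranks_at_least_as_well(self, small_grid):
        series = _make_two_step_series(small_grid)
        table = compare_models(series, ["one_to_one", "two_step_host"])
        r = {e["kind"]: e["regression_coefficient"] for e in table.entries}
        assert r["two_step_host"] >= r["one_to_one"]
        assert table.entries[0]["regression_coefficient"] >= table.entries[-1][
            "regression_coefficient"
        ]

    def test_one_to_one_truth_gains_little_from_extra_complex(
        self, tempone_preset, small_grid, tempone_templates
    ):
        schedule = np.array([0.0, 0.1, 0.3, 0.6, 1.0, 2.0, 3.5, 5.0, 7.5, 10.0]) * 1e-3
        series = generate_epr_titration(
            tempone_preset,
            schedule=schedule,
            noise=NoiseSpec(snr=50, seed=3),
            grid=small_grid,
        )
        table = compare_models(
            series, ["one_to_one", "two_step_host"], init=None,
            templates=tempone_templates,
        )
        r = {e["kind"]: e["regression_coefficient"] for e in table.entries}
        assert r["two_step_host"] - r["one_to_one"] <= 0.002

    def test_duplicate_kind_gives_identical_entries(
        self, small_tempone_series, tempone_templates
    ):
        table = compare_models(
            small_tempone_series,
            ["one_to_one", "one_to_one"],
            templates=tempone_templates,
        )
        a, b = table.entries
        assert a["constants"] == b["constants"]
        assert a["regression_coefficient"] == b["regression_coefficient"]

    def test_single_kind_rejected(self, small_tempone_series):
        with pytest.raises(ValueError, match="two model kinds"):
            compare_models(small_tempone_series, ["one_to_one"])


def test_initial_guess_reads_endpoints(small_tempone_series, tempone_preset):
    guess = initial_guess(small_tempone_series)
    assert guess["free"].a_N == pytest.approx(16.0, abs=0.1)
    assert guess["bound"].a_N == pytest.approx(15.3, abs=0.15)
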