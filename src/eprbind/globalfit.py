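"""Global ("2D": field x concentration) fitting of EPR titration series.

All spectra of a titration are fitted jointly: a small set of species
spectra, shared across the whole series, is mixed at each titration point
with weights dictated by the mass-action speciation at the candidate
binding constant(s) (slow exchange: the measured spectrum is the
population-weighted superposition of the component spectra).  Per-spectrum
instrument nuisances (amplitude scale, baseline offset and slope) are
solved by linear least squares inside every objective evaluation
(variable projection), so the nonlinear problem stays small: the binding
constant(s) on a log scale plus the spectral parameters of each species.

Model kinds
-----------
``one_to_one``
    free and bound monoradical species, weights from the 1:1 isotherm.
``two_step_host``
    free, HG and H2G species, weights from the stepwise two-host model.
``shuttle_1to1``
    free dinitroxide (both stations free, one fitted species) plus a bound
    population that is a 50/50 composite whose first station is pinned to
    the fitted free-species parameters and whose second (complexed)
    station is fitted — the two-station shuttle picture.
``shuttle_averaged``
    bound population is a single fitted species (both stations averaged);
    machinery identical to ``one_to_one``.

Spectral widths are optimized as the three line widths
(W(+1), W(0), W(-1)) with positive bounds, which keeps every iterate
physically valid, and are reported back as the fast-motion coefficients
(alpha, beta, gamma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .lineshape import (
    BiradicalModel,
    FieldGrid,
    RadicalSpecies,
    Spectrum,
    line_metrics,
    simulate_spectrum,
)
from .speciation import BindingModel, SpeciationError, solve_two_state, solve_two_step

__all__ = [
    "TitrationPoint",
    "TitrationSeries",
    "FitResult",
    "ModelComparison",
    "IdentifiabilityError",
    "FitError",
    "fit_titration",
    "regression_coefficient",
    "compare_models",
    "initial_guess",
]

LOG10_KA_BOUNDS = (0.0, 8.0)
KA_MULTISTART = np.logspace(2, 6, 5)  # 1e2 .. 1e6 M^-1
WIDTH_BOUNDS = (0.05, 10.0)
AN_BOUNDS = (5.0, 25.0)


class IdentifiabilityError(ValueError):
    """Raised when a titration design cannot identify the binding model."""


class FitError(RuntimeError):
    """Raised when the global fit fails to converge."""


@dataclass(frozen=True)
class TitrationPoint:
    host_total: float  # mol/L
    spectrum: Spectrum


@dataclass
class TitrationSeries:
    """An EPR titration: one guest concentration, many host concentrations."""

    guest_total: float  # mol/L, constant across the series
    points: list[TitrationPoint]
    meta: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise IdentifiabilityError(
                f"a titration series needs >= 3 points, got {len(self.points)}"
            )
        if not any(p.host_total == 0.0 for p in self.points):
            warnings.warn(
                "no zero-host point in the series; the free-species spectrum "
                "is only constrained indirectly",
                stacklevel=2,
            )
        ref = self.points[0].spectrum.field
        resampled = []
        for p in self.points:
            if p.spectrum.field.shape != ref.shape or not np.allclose(
                p.spectrum.field, ref
            ):
                resampled.append(TitrationPoint(p.host_total, p.spectrum.resample(ref)))
            else:
                resampled.append(p)
        self.points = resampled

    @property
    def field(self) -> np.ndarray:
        return self.points[0].spectrum.field

    @property
    def host_totals(self) -> np.ndarray:
        return np.array([p.host_total for p in self.points])

    @property
    def data_matrix(self) -> np.ndarray:
        return np.stack([p.spectrum.intensity for p in self.points])


@dataclass
class FitResult:
    """Outcome of a global titration fit."""

    model: BindingModel
    species: dict  # population label -> RadicalSpecies | BiradicalModel
    nuisance: np.ndarray  # (n_points, 3): scale, offset, slope
    regression_coefficient: float
    cost: float
    uncertainties: dict  # parameter name -> 1-sigma estimate
    diagnostics: dict
    parameters: dict  # flat name -> fitted value (optimizer domain mapped back)

    @property
    def K_a(self) -> Optional[float]:
        return self.model.K_a

    def fitted_matrix(self, series: TitrationSeries) -> np.ndarray:
        """Reconstruct the fitted model spectra including nuisances."""
        comps = _population_matrix(self.model, self.species, series)
        fields = series.field
        slope = _slope_column(fields)
        out = np.empty_like(comps)
        for i in range(comps.shape[0]):
            a, b, c = self.nuisance[i]
            out[i] = a * comps[i] + b + c * slope
        return out


@dataclass
class ModelComparison:
    """Ranking table of candidate binding models (no automatic selection)."""

    entries: list[dict]

    def __post_init__(self) -> None:
        self.entries = sorted(
            self.entries,
            key=lambda e: (
                -(e["regression_coefficient"] if e.get("error") is None else -np.inf)
            ),
        )


# ----------------------------------------------------------------------
# parameter vector layout


def _widths_of(sp: RadicalSpecies) -> tuple[float, float, float]:
    return (sp.width(1), sp.width(0), sp.width(-1))


def _species_from(template: RadicalSpecies, a_n: float, w: Sequence[float]) -> RadicalSpecies:
    w_p, w_0, w_m = w
    beta = (w_p - w_m) / 2.0
    gamma = (w_p + w_m) / 2.0 - w_0
    return replace(
        template, a_N=a_n, width_alpha=w_0, width_beta=beta, width_gamma=gamma
    )


def _clip(value: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return float(min(max(value, lo), hi))


class _Layout:
    """Maps the optimizer vector to binding constants and species."""

    def __init__(self, kind: str, init_species: dict):
        self.kind = kind
        self.templates = init_species
        self.names: list[str] = ["log10_Ka"] if kind != "two_step_host" else [
            "log10_K1",
            "log10_K2",
        ]
        # (label, whether a_N is fitted): the shuttle's uncomplexed station
        # keeps the free-species hyperfine coupling (nothing binds there)
        # but gets its own relaxation widths (slower tumbling of the whole
        # complex broadens that station too).
        blocks = {
            "one_to_one": [("free", True), ("bound", True)],
            "shuttle_averaged": [("free", True), ("bound", True)],
            "shuttle_1to1": [("free", True), ("site1", False), ("site2", True)],
            "two_step_host": [("free", True), ("bound1", True), ("bound2", True)],
        }[kind]
        self.blocks = blocks
        self.spec_labels = [lbl for lbl, _ in blocks]
        for lbl, fit_an in blocks:
            if fit_an:
                self.names.append(f"{lbl}.a_N")
            self.names += [f"{lbl}.W_p1", f"{lbl}.W_0", f"{lbl}.W_m1"]

    @property
    def n(self) -> int:
        return len(self.names)

    def pack(self, constants: Sequence[float], species: dict) -> np.ndarray:
        x = list(np.log10(np.maximum(constants, 10 ** LOG10_KA_BOUNDS[0])))
        x = [_clip(v, LOG10_KA_BOUNDS) for v in x]
        for lbl, fit_an in self.blocks:
            sp = species[lbl]
            if fit_an:
                x.append(_clip(sp.a_N, AN_BOUNDS))
            x += [_clip(w, WIDTH_BOUNDS) for w in _widths_of(sp)]
        return np.array(x)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        n_k = 2 if self.kind == "two_step_host" else 1
        lo = [LOG10_KA_BOUNDS[0]] * n_k
        hi = [LOG10_KA_BOUNDS[1]] * n_k
        for _, fit_an in self.blocks:
            if fit_an:
                lo.append(AN_BOUNDS[0])
                hi.append(AN_BOUNDS[1])
            lo += [WIDTH_BOUNDS[0]] * 3
            hi += [WIDTH_BOUNDS[1]] * 3
        return np.array(lo), np.array(hi)

    def unpack(self, x: np.ndarray) -> tuple[BindingModel, dict]:
        if self.kind == "two_step_host":
            model = BindingModel(kind="two_step_host", K1=10.0 ** x[0], K2=10.0 ** x[1])
            i = 2
        else:
            model = BindingModel(kind=self.kind, K_a=10.0 ** x[0])
            i = 1
        species = {}
        for lbl, fit_an in self.blocks:
            if fit_an:
                a_n = x[i]
                i += 1
            else:
                a_n = species["free"].a_N  # tied hyperfine coupling
            w_p, w_0, w_m = x[i : i + 3]
            species[lbl] = _species_from(self.templates[lbl], a_n, (w_p, w_0, w_m))
            i += 3
        return model, species


# ----------------------------------------------------------------------
# forward model


def _population_weights(model: BindingModel, guest_total: float, host_totals: np.ndarray):
    """Population weight columns per titration point, one row per species."""
    if model.kind == "two_step_host":
        rows = []
        for h in host_totals:
            r = solve_two_step(guest_total, h, model.K1, model.K2)
            g = max(guest_total, 1e-300)
            rows.append([r.free_guest / g, r.complex_1to1 / g, r.complex_2hosts / g])
        return np.array(rows).T
    fracs = np.array(
        [
            solve_two_state(guest_total, h, model.K_a).fraction_guest_bound
            for h in host_totals
        ]
    )
    return np.vstack([1.0 - fracs, fracs])


def _population_spectra(model_kind: str, species: dict, grid: FieldGrid) -> np.ndarray:
    """Unit-concentration spectra of each population, stacked as rows."""
    if model_kind == "shuttle_1to1":
        free = simulate_spectrum(species["free"], grid).intensity
        bound = simulate_biradical_intensity(species["site1"], species["site2"], grid)
        return np.vstack([free, bound])
    labels = {
        "one_to_one": ["free", "bound"],
        "shuttle_averaged": ["free", "bound"],
        "two_step_host": ["free", "bound1", "bound2"],
    }[model_kind]
    return np.vstack([simulate_spectrum(species[l], grid).intensity for l in labels])


def simulate_biradical_intensity(
    site1: RadicalSpecies, site2: RadicalSpecies, grid: FieldGrid
) -> np.ndarray:
    from .lineshape import simulate_biradical

    return simulate_biradical(BiradicalModel(site1, site2, 0.5, 0.5), grid).intensity


def _population_matrix(model: BindingModel, species: dict, series: TitrationSeries) -> np.ndarray:
    """Noise-free composite spectrum (before nuisances) at each point."""
    grid = _grid_from_field(series.field)
    spectra = _population_spectra(model.kind, species, grid)
    weights = _population_weights(model, series.guest_total, series.host_totals)
    return weights.T @ spectra


def _grid_from_field(fields: np.ndarray) -> FieldGrid:
    return FieldGrid(
        center_field=float((fields[0] + fields[-1]) / 2.0),
        span=float(fields[-1] - fields[0]),
        n_points=fields.size,
    )


def _slope_column(fields: np.ndarray) -> np.ndarray:
    center = (fields[0] + fields[-1]) / 2.0
    return (fields - center) / (fields[-1] - fields[0])


def _project_nuisance(
    composite: np.ndarray, data: np.ndarray, slope: np.ndarray, ones: np.ndarray
):
    """Per-spectrum linear solve for (scale, offset, slope); returns
    (residual matrix, nuisance array)."""
    n_pts = composite.shape[0]
    nuis = np.empty((n_pts, 3))
    resid = np.empty_like(data)
    for i in range(n_pts):
        X = np.column_stack((composite[i], ones, slope))
        # normal equations: 3x3, plenty accurate at these conditionings
        G = X.T @ X
        rhs = X.T @ data[i]
        try:
            coef = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(X, data[i], rcond=None)[0]
        nuis[i] = coef
        resid[i] = data[i] - X @ coef
    return resid, nuis


# ----------------------------------------------------------------------
# initial guesses


def initial_guess(
    series: TitrationSeries,
    model_kind: str = "one_to_one",
    templates: Optional[dict] = None,
) -> dict:
    """Data-driven starting species estimated from the series endpoints.

    The free species is read off the lowest-host spectrum and the
    bound-side template off the highest-host spectrum via
    :func:`line_metrics`; for the shuttle model the second-station aN is
    extrapolated from the 50/50 composite average
    (a_site2 = 2*a_apparent - a_free).

    ``templates`` optionally supplies, per population label, a
    :class:`RadicalSpecies` whose *structural* attributes (13C satellite
    set, Lorentzian fraction, g) are inherited; aN and the line widths are
    always estimated from the data.  Satellite couplings are molecular
    constants the analyst knows, not fitted quantities.
    """
    templates = templates or {}
    order = np.argsort(series.host_totals)
    first = series.points[order[0]].spectrum
    last = series.points[order[-1]].spectrum
    m0 = line_metrics(first)
    m1 = line_metrics(last)

    def build(label: str, metrics, fallback) -> RadicalSpecies:
        base = replace(templates.get(label, RadicalSpecies()), label=label)
        if not metrics.valid:
            return replace(
                fallback,
                label=label,
                satellites=base.satellites,
                lorentz_fraction=base.lorentz_fraction,
                g_iso=base.g_iso,
            )
        w = np.clip(metrics.w_ahh, *WIDTH_BOUNDS)
        return _species_from(base, float(metrics.apparent_a_N), (w[0], w[1], w[2]))

    default = RadicalSpecies(label="free")
    free = build("free", m0, default)
    bound = build("bound", m1, free)
    if model_kind == "shuttle_1to1":
        a2 = 2.0 * bound.a_N - free.a_N if m1.valid else free.a_N - 0.3
        site1 = replace(bound, label="site1", a_N=free.a_N)
        site2 = replace(bound, label="site2", a_N=_clip(a2, AN_BOUNDS))
        return {"free": free, "site1": site1, "site2": site2}
    if model_kind == "two_step_host":
        return {
            "free": free,
            "bound1": replace(bound, label="bound1"),
            "bound2": replace(bound, label="bound2"),
        }
    return {"free": free, "bound": bound}


# ----------------------------------------------------------------------
# fitting


def regression_coefficient(model_values, data_values) -> float:
    """Pearson correlation between fitted model and data (flattened)."""
    m = np.ravel(np.asarray(model_values, float))
    d = np.ravel(np.asarray(data_values, float))
    if m.size != d.size or m.size < 2:
        raise ValueError("model and data must have equal length >= 2")
    if np.ptp(d) == 0 or np.ptp(m) == 0:
        raise ValueError("regression coefficient undefined for constant input")
    return float(np.corrcoef(m, d)[0, 1])


def _check_design(series: TitrationSeries) -> None:
    hosts = series.host_totals
    if np.all(hosts == 0.0):
        raise IdentifiabilityError("all spectra are at zero host; Ka is unidentifiable")
    if np.unique(hosts).size < 2:
        raise IdentifiabilityError("need at least two distinct host concentrations")


def fit_titration(
    series: TitrationSeries,
    model_kind: str = "one_to_one",
    init: Optional[dict] = None,
    templates: Optional[dict] = None,
    ka_inits: Optional[Sequence[float]] = None,
    strategy: str = "joint",
    max_nfev_coarse: int = 400,
) -> FitResult:
    """Globally fit a titration series with the given binding model.

    Multi-start over log-spaced Ka initializations (the binding isotherm
    has local minima), coarse trust-region passes followed by a tight
    polish of the best start; ties below 1e-9 relative cost are resolved
    toward the smaller Ka.  ``strategy='two_stage'`` instead fits
    unconstrained per-spectrum bound fractions first and then the isotherm
    to those fractions (diagnostic variant).
    """
    _check_design(series)
    templates = (
        init if init is not None else initial_guess(series, model_kind, templates)
    )
    if strategy == "two_stage":
        return _fit_two_stage(series, model_kind, templates)
    if strategy != "joint":
        raise ValueError(f"unknown strategy {strategy!r}")

    layout = _Layout(model_kind, templates)
    data = series.data_matrix
    fields = series.field
    slope = _slope_column(fields)
    ones = np.ones_like(fields)

    def residual(x: np.ndarray) -> np.ndarray:
        model, species = layout.unpack(x)
        try:
            with warnings.catch_warnings():
                # transient iterates may push aN beyond the window heuristic
                warnings.simplefilter("ignore", UserWarning)
                comps = _population_matrix(model, species, series)
        except (SpeciationError, ValueError):
            return np.full(data.size, 1e6)
        resid, _ = _project_nuisance(comps, data, slope, ones)
        return resid.ravel()

    if ka_inits is None:
        ka_inits = KA_MULTISTART
    n_k = 2 if model_kind == "two_step_host" else 1

    starts = []
    for ka in ka_inits:
        constants = [ka] * n_k
        if model_kind == "two_step_host":
            constants[1] = max(ka / 10.0, 1.0)  # second binding usually weaker
        starts.append(layout.pack(constants, templates))

    lo, hi = layout.bounds()
    coarse = []
    for x0 in starts:
        sol = least_squares(
            residual,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            ftol=1e-8,
            xtol=1e-8,
            gtol=1e-8,
            max_nfev=max_nfev_coarse,
        )
        coarse.append(sol)

    costs = np.array([s.cost for s in coarse])
    best_cost = costs.min()
    # ties resolved toward smaller Ka (first parameter is log10 K)
    tied = [s for s in coarse if s.cost <= best_cost * (1.0 + 1e-9)]
    best = min(tied, key=lambda s: s.x[0])

    sol = least_squares(
        residual,
        best.x,
        bounds=(lo, hi),
        method="trf",
        x_scale="jac",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    if not sol.success and sol.status <= 0:
        raise FitError(f"global fit did not converge: {sol.message}")

    model, species = layout.unpack(sol.x)
    comps = _population_matrix(model, species, series)
    resid, nuis = _project_nuisance(comps, data, slope, ones)
    fitted = data - resid
    r = regression_coefficient(fitted, data)

    at_bound = bool(
        np.any(np.isclose(sol.x[:n_k], LOG10_KA_BOUNDS[0]))
        or np.any(np.isclose(sol.x[:n_k], LOG10_KA_BOUNDS[1]))
    )
    uncertainties = _linearized_uncertainties(sol, layout, data.size)
    species_out = dict(species)
    if model_kind == "shuttle_1to1":
        species_out["bound"] = BiradicalModel(
            species["site1"], species["site2"], 0.5, 0.5
        )
    result = FitResult(
        model=model,
        species=species_out,
        nuisance=nuis,
        regression_coefficient=r,
        cost=float(sol.cost),
        uncertainties=uncertainties,
        diagnostics={
            "success": bool(sol.success),
            "status": int(sol.status),
            "message": sol.message,
            "nfev": int(sol.nfev),
            "ka_at_bound": at_bound,
            "multistart_costs": costs.tolist(),
            "n_free_parameters": layout.n + 3 * len(series.points),
        },
        parameters={name: float(v) for name, v in zip(layout.names, sol.x)},
    )
    return result


def _linearized_uncertainties(sol, layout: _Layout, n_data: int) -> dict:
    """1-sigma estimates from the Jacobian at the solution."""
    try:
        J = sol.jac
        dof = max(n_data - layout.n, 1)
        s2 = 2.0 * sol.cost / dof
        cov = np.linalg.pinv(J.T @ J) * s2
        sig = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return {name: float(s) for name, s in zip(layout.names, sig)}
    except Exception:  # pragma: no cover - singular corner cases
        return {name: float("nan") for name in layout.names}


def _fit_two_stage(series: TitrationSeries, model_kind: str, templates: dict) -> FitResult:
    """Two-stage variant: free per-point fractions, then the isotherm.

    Stage 1 fits the shared species spectra together with an unconstrained
    bound fraction per spectrum; stage 2 least-squares fits Ka to those
    fractions.  Only 1:1-type kinds are supported.
    """
    if model_kind not in ("one_to_one", "shuttle_averaged"):
        raise ValueError("two_stage strategy supports 1:1-type models only")
    data = series.data_matrix
    fields = series.field
    grid = _grid_from_field(fields)
    slope = _slope_column(fields)
    ones = np.ones_like(fields)
    n_pts = len(series.points)

    def unpack(x):
        free = _species_from(templates["free"], x[0], x[1:4])
        bound = _species_from(templates["bound"], x[4], x[5:8])
        fracs = x[8:]
        return free, bound, fracs

    def residual(x):
        free, bound, fracs = unpack(x)
        try:
            sf = simulate_spectrum(free, grid).intensity
            sb = simulate_spectrum(bound, grid).intensity
        except ValueError:
            return np.full(data.size, 1e6)
        comps = np.outer(1.0 - fracs, sf) + np.outer(fracs, sb)
        resid, _ = _project_nuisance(comps, data, slope, ones)
        return resid.ravel()

    x0 = np.concatenate(
        [
            [templates["free"].a_N],
            _widths_of(templates["free"]),
            [templates["bound"].a_N],
            _widths_of(templates["bound"]),
            np.clip(series.host_totals / (series.host_totals.max() + 1e-30), 0, 1),
        ]
    )
    lo = np.concatenate(
        [[AN_BOUNDS[0]], [WIDTH_BOUNDS[0]] * 3, [AN_BOUNDS[0]], [WIDTH_BOUNDS[0]] * 3,
         np.zeros(n_pts)]
    )
    hi = np.concatenate(
        [[AN_BOUNDS[1]], [WIDTH_BOUNDS[1]] * 3, [AN_BOUNDS[1]], [WIDTH_BOUNDS[1]] * 3,
         np.ones(n_pts)]
    )
    sol = least_squares(residual, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
                        x_scale="jac", ftol=1e-10, xtol=1e-10, max_nfev=3000)
    free, bound, fracs = unpack(sol.x)

    # stage 2: fit Ka to the recovered fractions
    from scipy.optimize import least_squares as ls

    def iso_resid(logk):
        k = 10.0 ** logk[0]
        pred = np.array(
            [
                solve_two_state(series.guest_total, h, k).fraction_guest_bound
                for h in series.host_totals
            ]
        )
        return pred - fracs

    best = None
    for k0 in KA_MULTISTART:
        s = ls(iso_resid, [np.log10(k0)], bounds=([LOG10_KA_BOUNDS[0]], [LOG10_KA_BOUNDS[1]]))
        if best is None or s.cost < best.cost:
            best = s
    ka = 10.0 ** best.x[0]
    model = BindingModel(kind="one_to_one", K_a=ka)
    species = {"free": free, "bound": bound}
    comps = _population_matrix(model, species, series)
    resid, nuis = _project_nuisance(comps, data, slope, ones)
    r = regression_coefficient(data - resid, data)
    return FitResult(
        model=model,
        species=species,
        nuisance=nuis,
        regression_coefficient=r,
        cost=float(0.5 * np.sum(resid**2)),
        uncertainties={},
        diagnostics={
            "strategy": "two_stage",
            "stage1_cost": float(sol.cost),
            "fractions": fracs.tolist(),
        },
        parameters={"log10_Ka": float(np.log10(ka))},
    )


def compare_models(
    series: TitrationSeries,
    kinds: Sequence[str],
    init: Optional[dict] = None,
    **fit_kwargs,
) -> ModelComparison:
    """Fit each candidate binding model and rank by regression coefficient.

    No automatic selection is performed: the table reports constants, R and
    parameter counts and leaves the judgement to the user.  Fit failures
    are recorded per entry without aborting the comparison.
    """
    if len(kinds) < 2:
        raise ValueError("compare_models needs at least two model kinds")
    entries = []
    for kind in kinds:
        try:
            res = fit_titration(series, model_kind=kind, init=init, **fit_kwargs)
            constants = (
                {"K1": res.model.K1, "K2": res.model.K2}
                if kind == "two_step_host"
                else {"K_a": res.model.K_a}
            )
            entries.append(
                {
                    "kind": kind,
                    "constants": constants,
                    "regression_coefficient": res.regression_coefficient,
                    "n_free_parameters": res.diagnostics["n_free_parameters"],
                    "error": None,
                    "result": res,
                }
            )
        except Exception as exc:  # propagate per-entry, keep the table
            entries.append(
                {
                    "kind": kind,
                    "constants": {},
                    "regression_coefficient": float("nan"),
                    "n_free_parameters": None,
                    "error": str(exc),
                    "result": None,
                }
            )
    return ModelComparison(entries)
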