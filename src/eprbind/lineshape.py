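"""Fast-motion nitroxide EPR lineshapes and line metrics.

A nitroxide radical tumbling fast in solution shows three hyperfine lines
(coupling to the I = 1 nitrogen nucleus) whose widths follow the fast-motion
law W(mI) = alpha + beta*mI + gamma*mI**2, with W the full width at half
height of the absorption line in Gauss.  Naturally abundant 13C gives small
satellite pairs flanking each main line.  This module forward-simulates the
first-derivative (field-modulated CW) spectrum of mono- and biradical
species and measures line metrics (apparent aN, widths, amplitudes) back
from spectra.

Conventions (fixed here and documented in the methods note):

* low-field line is mI = +1, high-field is mI = -1; line positions are
  ``B_res - a_N*mI`` with ``B_res = center_field*(G_REF/g_iso)``, so a
  "broader high-field line" means W(-1) > W(0);
* the line profile is a Lorentzian derivative by default;
  ``lorentz_fraction < 1`` blends in a Gaussian derivative of equal
  half-width (pseudo-Voigt) for residual instrument broadening;
* a simulated spectrum is normalized so that its double integral
  (trapezoidal, over the simulated window) equals 1 — the standard EPR
  quantitation convention, i.e. unit spin concentration as measured on the
  recorded window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "G_REF",
    "SatelliteSpec",
    "RadicalSpecies",
    "BiradicalModel",
    "FieldGrid",
    "Spectrum",
    "LineMetrics",
    "LineshapeParameterError",
    "simulate_spectrum",
    "simulate_biradical",
    "line_metrics",
]

#: Reference g-factor used to convert g shifts into field shifts (typical
#: isotropic g of a nitroxide in water).
G_REF = 2.0059

_MI = (1, 0, -1)


class LineshapeParameterError(ValueError):
    """Raised for physically inadmissible lineshape parameters."""


@dataclass(frozen=True)
class SatelliteSpec:
    """One set of equivalent 13C nuclei producing a satellite pair.

    First-order treatment: at most one 13C per molecule per spec, so the
    pair carries a fraction ``n_equivalent*abundance`` of each main line's
    integral, half on each side at ``+/- a_C/2``.
    """

    a_C: float
    n_equivalent: int = 1
    abundance: float = 0.0107

    def __post_init__(self) -> None:
        if self.a_C < 0:
            raise LineshapeParameterError(f"a_C must be >= 0, got {self.a_C}")
        if self.n_equivalent < 1:
            raise LineshapeParameterError(
                f"n_equivalent must be >= 1, got {self.n_equivalent}"
            )
        if not 0.0 <= self.abundance <= 0.5:
            raise LineshapeParameterError(
                f"abundance must be in [0, 0.5], got {self.abundance}"
            )

    @property
    def fraction(self) -> float:
        """Total intensity fraction diverted into this satellite pair."""
        return self.n_equivalent * self.abundance


@dataclass(frozen=True)
class RadicalSpecies:
    """One magnetic environment of a nitroxide radical.

    Parameters
    ----------
    g_iso : isotropic electron g-factor (dimensionless).
    a_N : nitrogen hyperfine coupling constant, Gauss.
    width_alpha, width_beta, width_gamma : coefficients of the fast-motion
        width law ``W(mI) = alpha + beta*mI + gamma*mI**2`` (full width at
        half height of the absorption line, Gauss).
    satellites : 13C satellite specifications.
    lorentz_fraction : Lorentzian fraction of the pseudo-Voigt profile.
    """

    label: str = "nitroxide"
    g_iso: float = G_REF
    a_N: float = 16.0
    width_alpha: float = 0.8
    width_beta: float = 0.0
    width_gamma: float = 0.0
    satellites: tuple[SatelliteSpec, ...] = ()
    lorentz_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.a_N < 0:
            raise LineshapeParameterError(f"a_N must be >= 0, got {self.a_N}")
        if not 0.0 <= self.lorentz_fraction <= 1.0:
            raise LineshapeParameterError(
                f"lorentz_fraction must be in [0, 1], got {self.lorentz_fraction}"
            )
        for mi in _MI:
            if self.width(mi) <= 0:
                raise LineshapeParameterError(
                    f"W({mi:+d}) = {self.width(mi):.4g} G is not positive "
                    f"(alpha={self.width_alpha}, beta={self.width_beta}, "
                    f"gamma={self.width_gamma})"
                )
        total_sat = sum(s.fraction for s in self.satellites)
        if total_sat >= 1.0:
            raise LineshapeParameterError(
                f"total satellite fraction {total_sat:.3f} must be < 1"
            )
        object.__setattr__(self, "satellites", tuple(self.satellites))

    def width(self, mI: int) -> float:
        """Full width at half height of the absorption line for a given mI."""
        return self.width_alpha + self.width_beta * mI + self.width_gamma * mI**2


@dataclass(frozen=True)
class BiradicalModel:
    """Weighted pair of magnetically independent nitroxide sites.

    Models a dinitroxide whose two radicals are too far apart for spin
    exchange: the spectrum is the weighted superposition of the two site
    spectra.  The two-station shuttle composite is the 50/50 special case
    with one free-like and one complexed site.
    """

    site1: RadicalSpecies
    site2: RadicalSpecies
    weight1: float = 0.5
    weight2: float = 0.5

    def __post_init__(self) -> None:
        if self.weight1 < 0 or self.weight2 < 0:
            raise LineshapeParameterError("biradical site weights must be >= 0")
        if abs(self.weight1 + self.weight2 - 1.0) > 1e-9:
            raise LineshapeParameterError(
                f"biradical site weights must sum to 1, got "
                f"{self.weight1} + {self.weight2}"
            )


@dataclass(frozen=True)
class FieldGrid:
    """Uniform magnetic-field grid in Gauss (X-band defaults)."""

    center_field: float = 3480.0
    span: float = 120.0
    n_points: int = 4096

    def __post_init__(self) -> None:
        if self.n_points < 64:
            raise LineshapeParameterError(
                f"n_points must be >= 64, got {self.n_points}"
            )
        if self.span <= 0:
            raise LineshapeParameterError(f"span must be > 0, got {self.span}")

    def fields(self) -> np.ndarray:
        half = self.span / 2.0
        return np.linspace(
            self.center_field - half, self.center_field + half, self.n_points
        )

    @property
    def step(self) -> float:
        return self.span / (self.n_points - 1)


@dataclass
class Spectrum:
    """First-derivative CW EPR spectrum on an increasing field axis (Gauss)."""

    field: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.shape != self.intensity.shape or self.field.ndim != 1:
            raise ValueError("field and intensity must be equal-length 1-d arrays")
        if self.field.size and not np.all(np.diff(self.field) > 0):
            raise ValueError("field axis must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.field.size

    def absorption(self) -> np.ndarray:
        """Absorption lineshape reconstructed by cumulative integration."""
        return cumulative_trapezoid(self.intensity, self.field, initial=0.0)

    def resample(self, new_field: np.ndarray) -> "Spectrum":
        intensity = np.interp(new_field, self.field, self.intensity)
        return Spectrum(np.asarray(new_field, float), intensity, dict(self.meta))


@dataclass
class LineMetrics:
    """Per-line measurements of a three-line nitroxide spectrum.

    ``valid`` is False when fewer than three resolved lines were found; all
    quantities are then None rather than raising.  Line order is low field
    (mI = +1), center (mI = 0), high field (mI = -1).
    """

    valid: bool
    n_lines_found: int
    line_centers: Optional[np.ndarray] = None  # zero-crossing centers, G
    moment_centers: Optional[np.ndarray] = None  # centroid centers, G
    peak_to_peak_amplitudes: Optional[np.ndarray] = None  # (I+, I0, I-)
    w_ahh: Optional[np.ndarray] = None  # absorption FWHH per line, G
    apparent_a_N: Optional[float] = None
    apparent_a_N_moment: Optional[float] = None
    ratio_I_minus_over_I_0: Optional[float] = None

    @property
    def I_plus(self) -> Optional[float]:
        return None if not self.valid else float(self.peak_to_peak_amplitudes[0])

    @property
    def I_0(self) -> Optional[float]:
        return None if not self.valid else float(self.peak_to_peak_amplitudes[1])

    @property
    def I_minus(self) -> Optional[float]:
        return None if not self.valid else float(self.peak_to_peak_amplitudes[2])


# ----------------------------------------------------------------------
# forward simulation


def _derivative_profile(x: np.ndarray, hwhh: float, eta: float) -> np.ndarray:
    """Analytic first derivative of a unit-area pseudo-Voigt absorption.

    ``hwhh`` is the half width at half height shared by the Lorentzian and
    Gaussian components; ``eta`` is the Lorentzian fraction.
    """
    out = np.zeros_like(x)
    if eta > 0.0:
        g = hwhh
        out += eta * (-(2.0 * g / np.pi) * x / (x * x + g * g) ** 2)
    if eta < 1.0:
        sigma = hwhh / np.sqrt(2.0 * np.log(2.0))
        amp = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
        out += (1.0 - eta) * (-(x / sigma**2) * amp * np.exp(-0.5 * (x / sigma) ** 2))
    return out


def _components(species: RadicalSpecies, resonance: float):
    """Yield (position, weight, full_width) for every spectral component."""
    sat_total = sum(s.fraction for s in species.satellites)
    for mi in _MI:
        pos = resonance - species.a_N * mi
        w = species.width(mi)
        yield pos, (1.0 - sat_total) / 3.0, w
        for sat in species.satellites:
            half_int = sat.fraction / 2.0 / 3.0
            yield pos - sat.a_C / 2.0, half_int, w
            yield pos + sat.a_C / 2.0, half_int, w


def simulate_spectrum(species: RadicalSpecies, grid: FieldGrid = FieldGrid()) -> Spectrum:
    """Simulate the first-derivative spectrum of one species.

    The absorption is a sum over mI of equal-integral pseudo-Voigt lines at
    ``center_field*(G_REF/g_iso) - a_N*mI`` with full width at half height
    ``W(mI)``, each flanked by its 13C satellite pairs; the returned
    derivative is scaled to unit double integral over the grid window.
    """
    fields = grid.fields()
    resonance = grid.center_field * (G_REF / species.g_iso)
    intensity = np.zeros_like(fields)
    for pos, weight, w in _components(species, resonance):
        intensity += weight * _derivative_profile(
            fields - pos, w / 2.0, species.lorentz_fraction
        )

    meta: dict = {"label": species.label}
    if grid.span <= 4.0 * species.a_N:
        warnings.warn(
            f"field span {grid.span} G does not exceed 4*a_N = "
            f"{4 * species.a_N} G; outer lines may be clipped",
            stacklevel=2,
        )
        meta["warnings"] = ["grid_too_narrow"]

    spec = Spectrum(fields, intensity, meta)
    double_integral = np.trapezoid(spec.absorption(), fields)
    if double_integral > 0:
        spec.intensity = spec.intensity / double_integral
    return spec


def simulate_biradical(model: BiradicalModel, grid: FieldGrid = FieldGrid()) -> Spectrum:
    """Pointwise weighted superposition of the two site spectra.

    Both sites are simulated at unit double integral, so the composite also
    has unit double integral (one biradical = unit spin concentration per
    site, summed with the stated weights).
    """
    s1 = simulate_spectrum(model.site1, grid)
    s2 = simulate_spectrum(model.site2, grid)
    intensity = model.weight1 * s1.intensity + model.weight2 * s2.intensity
    meta = {"label": f"{model.site1.label}+{model.site2.label}"}
    for s in (s1, s2):
        if "warnings" in s.meta:
            meta.setdefault("warnings", []).extend(s.meta["warnings"])
    return Spectrum(s1.field, intensity, meta)


# ----------------------------------------------------------------------
# line metrics


def _select_maxima(
    absorption: np.ndarray,
    fields: np.ndarray,
    n_lines: int,
    min_separation: float,
) -> list[int]:
    """Indices of up to n_lines largest absorption maxima, kept apart.

    Plateau-tolerant: a symmetric line whose apex falls exactly between two
    equal samples still counts (the right-hand plateau sample is taken).
    """
    a = absorption
    interior = (a[1:-1] >= a[:-2]) & (a[1:-1] > a[2:])
    candidates = np.nonzero(interior)[0] + 1
    if candidates.size == 0:
        return []
    order = candidates[np.argsort(absorption[candidates])[::-1]]
    chosen: list[int] = []
    for idx in order:
        if all(abs(fields[idx] - fields[j]) >= min_separation for j in chosen):
            chosen.append(int(idx))
        if len(chosen) == n_lines:
            break
    return sorted(chosen)


def _zero_crossing(fields: np.ndarray, intensity: np.ndarray, near: float) -> float:
    """Down-going zero crossing of the derivative nearest ``near``.

    Linear interpolation between the bracketing samples; ties broken toward
    lower field (the first of equally near crossings wins).
    """
    sign = np.sign(intensity)
    idx = np.where((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    if idx.size == 0:
        idx = np.where(sign[:-1] * sign[1:] < 0)[0]
        if idx.size == 0:
            return np.nan
    crossings = fields[idx] - intensity[idx] * (fields[idx + 1] - fields[idx]) / (
        intensity[idx + 1] - intensity[idx]
    )
    return float(crossings[np.argmin(np.abs(crossings - near))])


def _half_height_width(fields: np.ndarray, absorption: np.ndarray, peak: int) -> float:
    """Full width at half height of one absorption line by interpolation."""
    half = absorption[peak] / 2.0
    left = np.nan
    for i in range(peak, 0, -1):
        if absorption[i - 1] <= half <= absorption[i]:
            left = np.interp(half, absorption[i - 1 : i + 1], fields[i - 1 : i + 1])
            break
    right = np.nan
    for i in range(peak, absorption.size - 1):
        if absorption[i + 1] <= half <= absorption[i]:
            right = fields[i] + (fields[i + 1] - fields[i]) * (
                (absorption[i] - half) / (absorption[i] - absorption[i + 1])
            )
            break
    return float(right - left)


def _moment_center(
    fields: np.ndarray,
    absorption: np.ndarray,
    peak: int,
    lo: int,
    hi: int,
    threshold: float = 0.02,
    n_iter: int = 4,
) -> float:
    """Truncation-robust first-moment center of one line region.

    Lorentzian tails make the raw moment over an asymmetric region biased
    by several tenths of a Gauss, so the centroid is computed on a
    symmetric window centered on the running centroid, after subtracting a
    local linear baseline anchored at the window edges.  The symmetric
    window cancels the truncation asymmetry of the line's own tails; the
    edge-anchored baseline removes the slowly varying tails of the
    neighbouring lines passing through the window.  Exact for a symmetric
    blend; residual bias for unequal-width two-component blends is O(mG).
    The window half-width is where the line falls below ``threshold`` of
    its maximum (the shorter side wins near a region boundary).
    """
    region_f = fields[lo:hi]
    region_a = absorption[lo:hi]
    peak_val = absorption[peak]
    cut = threshold * peak_val
    above = region_a >= cut
    # contiguous above-threshold block around the peak
    pk = peak - lo
    i0 = pk
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = pk
    while i1 < above.size - 1 and above[i1 + 1]:
        i1 += 1
    left = fields[peak] - region_f[i0]
    right = region_f[i1] - fields[peak]
    half_width = max(min(left, right), 3.0 * (region_f[1] - region_f[0]))
    center = fields[peak]
    for _ in range(n_iter):
        (idx,) = np.nonzero(np.abs(region_f - center) <= half_width)
        if idx.size < 5:
            return float(center)
        f = region_f[idx]
        a = region_a[idx]
        # edge-anchored linear baseline (3-sample averages at each end)
        a_lo = a[:3].mean()
        a_hi = a[-3:].mean()
        f_lo = f[:3].mean()
        f_hi = f[-3:].mean()
        baseline = a_lo + (a - a) if f_hi == f_lo else (
            a_lo + (f - f_lo) * (a_hi - a_lo) / (f_hi - f_lo)
        )
        w = np.clip(a - baseline, 0.0, None)
        m = np.trapezoid(w, f)
        if m <= 0:
            return float(center)
        center = np.trapezoid(w * f, f) / m
    return float(center)


def line_metrics(
    spectrum: Spectrum,
    n_lines: int = 3,
    min_separation: float = 4.0,
    moment_threshold: float = 0.02,
) -> LineMetrics:
    """Measure the three nitroxide lines of a first-derivative spectrum.

    The absorption is reconstructed by cumulative integration, the three
    largest maxima (at least ``min_separation`` Gauss apart) define the
    line regions split at the midpoints, and per line the zero-crossing
    center, a truncation-robust first-moment center, the peak-to-peak
    derivative amplitude, and the absorption width at half height are
    reported.  ``apparent_a_N`` is half the outer-line center separation.
    Fewer than three resolved lines yields ``valid=False`` (no exception).
    """
    fields = spectrum.field
    absorption = spectrum.absorption()
    peaks = _select_maxima(absorption, fields, n_lines, min_separation)
    if len(peaks) < n_lines:
        return LineMetrics(valid=False, n_lines_found=len(peaks))

    # region boundaries at midpoints between adjacent maxima
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append((a + b) // 2)
    bounds.append(fields.size)

    centers = np.empty(n_lines)
    moments = np.empty(n_lines)
    amps = np.empty(n_lines)
    widths = np.empty(n_lines)
    for k, pk in enumerate(peaks):
        lo, hi = bounds[k], bounds[k + 1]
        centers[k] = _zero_crossing(fields[lo:hi], spectrum.intensity[lo:hi], fields[pk])
        moments[k] = _moment_center(
            fields, absorption, pk, lo, hi, threshold=moment_threshold
        )
        seg = spectrum.intensity[lo:hi]
        amps[k] = float(seg.max() - seg.min())
        widths[k] = _half_height_width(fields, absorption, pk)

    a_n = float((centers[-1] - centers[0]) / 2.0)
    a_n_m = float((moments[-1] - moments[0]) / 2.0)
    ratio = float(amps[-1] / amps[1]) if amps[1] > 0 else np.nan
    return LineMetrics(
        valid=True,
        n_lines_found=n_lines,
        line_centers=centers,
        moment_centers=moments,
        peak_to_peak_amplitudes=amps,
        w_ahh=widths,
        apparent_a_N=a_n,
        apparent_a_N_moment=a_n_m,
        ratio_I_minus_over_I_0=ratio,
    )


def scale_widths(
    species: RadicalSpecies,
    alpha_factor: float = 1.0,
    beta_factor: float = 1.0,
    gamma_factor: float = 1.0,
    **overrides,
) -> RadicalSpecies:
    """Return a copy with the fast-motion width coefficients rescaled."""
    return replace(
        species,
        width_alpha=species.width_alpha * alpha_factor,
        width_beta=species.width_beta * beta_factor,
        width_gamma=species.width_gamma * gamma_factor,
        **overrides,
    )
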