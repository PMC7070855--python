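"""Mass-action speciation for host-guest binding equilibria.

Solves the equilibrium concentrations of guest G, host H and their
complexes for three binding models used throughout the pipeline:

* ``one_to_one``      H + G <-> HG, association constant Ka (M^-1);
* ``two_step_host``   H + G <-> HG (K1), HG + H <-> H2G (K2) — exploratory
  two-host stoichiometry with independent stepwise constants (no
  statistical-factor constraint imposed);
* ``shuttle_1to1``    identical speciation to one_to_one; the shuttle
  character of the complex (the host exchanging rapidly between the two
  stations of a dinitroxide guest) enters only through the spectral model.

Concentrations are mol/L internally; binding constants are M^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingModel",
    "SpeciationResult",
    "SpeciationError",
    "solve_two_state",
    "solve_two_step",
    "fraction_bound_from_integrals",
    "bound_fraction_curve",
]

ModelKind = Literal["one_to_one", "two_step_host", "shuttle_1to1", "shuttle_averaged"]


class SpeciationError(ValueError):
    """Raised for inadmissible speciation inputs."""


@dataclass(frozen=True)
class BindingModel:
    """Stoichiometry and association constant(s) of a binding model."""

    kind: ModelKind = "one_to_one"
    K_a: Optional[float] = None
    K1: Optional[float] = None
    K2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("K_a", "K1", "K2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise SpeciationError(f"{name} must be >= 0, got {v}")
        if self.kind == "two_step_host":
            if self.K1 is None or self.K2 is None:
                raise SpeciationError("two_step_host requires K1 and K2")
        elif self.K_a is None:
            raise SpeciationError(f"{self.kind} requires K_a")


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium concentrations (mol/L) and the bound guest fraction."""

    free_guest: float
    free_host: float
    complex_1to1: float
    complex_2hosts: float = 0.0

    @property
    def guest_total(self) -> float:
        return self.free_guest + self.complex_1to1 + self.complex_2hosts

    @property
    def host_total(self) -> float:
        return self.free_host + self.complex_1to1 + 2.0 * self.complex_2hosts

    @property
    def fraction_guest_bound(self) -> float:
        total = self.guest_total
        if total == 0.0:
            return 0.0
        return (self.complex_1to1 + self.complex_2hosts) / total


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0 or not np.isfinite(value):
            raise SpeciationError(f"{name} must be finite and >= 0, got {value}")


def solve_two_state(guest_total: float, host_total: float, K_a: float) -> SpeciationResult:
    """Solve the 1:1 equilibrium H + G <-> HG.

    The complex concentration is the physically admissible root of
    ``Ka*c**2 - (Ka*(G+H)+1)*c + Ka*G*H = 0``, computed in the
    cancellation-free form ``c = 2*Ka*G*H / (b + sqrt(disc))`` with
    ``disc = (Ka*(G-H))**2 + 2*Ka*(G+H) + 1`` and polished with one Newton
    step so that mass balances close to ~1e-15 relative.
    """
    _check_nonneg(guest_total=guest_total, host_total=host_total, K_a=K_a)
    g, h, k = guest_total, host_total, K_a
    if k == 0.0 or g == 0.0 or h == 0.0:
        return SpeciationResult(free_guest=g, free_host=h, complex_1to1=0.0)
    b = k * (g + h) + 1.0
    disc = (k * (g - h)) ** 2 + 2.0 * k * (g + h) + 1.0
    c = 2.0 * k * g * h / (b + np.sqrt(disc))
    # Newton polish on f(c) = k*(g-c)*(h-c) - c
    for _ in range(2):
        f = k * (g - c) * (h - c) - c
        fp = -k * ((g - c) + (h - c)) - 1.0
        step = f / fp
        c_new = min(c - step, min(g, h))
        if c_new == c:
            break
        c = c_new
    return SpeciationResult(free_guest=g - c, free_host=h - c, complex_1to1=c)


def solve_two_step(
    guest_total: float, host_total: float, K1: float, K2: float
) -> SpeciationResult:
    """Solve the stepwise two-host equilibrium H+G<->HG (K1), HG+H<->H2G (K2).

    Bracketed root-finding (Brent) on the free-host mass balance over
    ``[0, host_total]``, followed by a Newton polish.  ``K2 = 0`` reduces
    exactly to :func:`solve_two_state`.
    """
    _check_nonneg(guest_total=guest_total, host_total=host_total, K1=K1, K2=K2)
    g_tot, h_tot = guest_total, host_total
    if K2 == 0.0 or g_tot == 0.0 or h_tot == 0.0 or K1 == 0.0:
        base = solve_two_state(g_tot, h_tot, K1)
        if K1 == 0.0 and K2 > 0.0 and g_tot > 0.0 and h_tot > 0.0:
            # no first step means no second step either
            return SpeciationResult(g_tot, h_tot, 0.0, 0.0)
        return base

    def free_guest(h: float) -> float:
        return g_tot / (1.0 + K1 * h + K1 * K2 * h * h)

    def balance(h: float) -> float:
        g = free_guest(h)
        return h + g * (K1 * h + 2.0 * K1 * K2 * h * h) - h_tot

    h = brentq(balance, 0.0, h_tot, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    # Newton polish for the last bits of the host balance
    for _ in range(2):
        eps = max(h * 1e-8, 1e-300)
        d = (balance(h + eps) - balance(h - eps)) / (2.0 * eps)
        if d == 0.0:
            break
        h_new = h - balance(h) / d
        if not (0.0 <= h_new <= h_tot) or h_new == h:
            break
        h = h_new
    g = free_guest(h)
    c1 = K1 * g * h
    c2 = K1 * K2 * g * h * h
    return SpeciationResult(free_guest=g, free_host=h, complex_1to1=c1, complex_2hosts=c2)


def fraction_bound_from_integrals(intensity_free: float, intensity_bound: float) -> float:
    """Percent of guest bound from free/bound signal integrals.

    For slow-exchange spectra (EPR components or separate NMR signals) the
    integrals are proportional to concentrations, so the bound percentage
    is ``100*bound/(free+bound)``.
    """
    _check_nonneg(intensity_free=intensity_free, intensity_bound=intensity_bound)
    total = intensity_free + intensity_bound
    if total == 0.0:
        raise SpeciationError("free and bound integrals cannot both be zero")
    return 100.0 * intensity_bound / total


def bound_fraction_curve(
    K_a: float, guest_total: float, host_totals: Iterable[float]
) -> np.ndarray:
    """Bound guest fraction at each host total (elementwise 1:1 solve)."""
    return np.array(
        [
            solve_two_state(guest_total, h, K_a).fraction_guest_bound
            for h in host_totals
        ]
    )


def speciate(model: BindingModel, guest_total: float, host_total: float) -> SpeciationResult:
    """Dispatch to the solver matching ``model.kind``."""
    if model.kind == "two_step_host":
        return solve_two_step(guest_total, host_total, model.K1, model.K2)
    return solve_two_state(guest_total, host_total, model.K_a)


def write_speciation_table(
    path,
    model: BindingModel,
    guest_total: float,
    host_totals: Iterable[float],
) -> None:
    """Write a CSV speciation table (concentrations in mM)."""
    lines = ["host_total_mM,free_guest_mM,complex_mM,fraction_bound"]
    for h in host_totals:
        r = speciate(model, guest_total, h)
        bound = r.complex_1to1 + r.complex_2hosts
        lines.append(
            f"{h * 1e3:.6g},{r.free_guest * 1e3:.6g},{bound * 1e3:.6g},"
            f"{r.fraction_guest_bound:.6g}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
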