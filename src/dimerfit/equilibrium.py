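"""Mass-action equilibria for self-associating (monomer-dimer) receptors.

All concentrations are in µM. Totals are expressed in monomer equivalents,
i.e. ``total = [monomer] + 2·[dimer]``, and the homodimer dissociation
constant follows the convention

    K_D = [monomer]² / [dimer]    (units of concentration).

With that convention the free-monomer concentration has the closed form

    m = (−K_D + sqrt(K_D² + 8·K_D·T)) / 4,

implemented here in the algebraically equivalent, cancellation-free form
``m = 2T / (1 + sqrt(1 + 8T/K_D))`` so that K_D ≫ T does not lose precision
and the landmark identities f_dimer(T=K_D) = 1/2 and f_bound(T=K_D) = 1/3
hold exactly in floating point.

The module also solves the coupled homodimer + 1:1 heterodimer competition

    R + R <-> R2        (K_D,homo)
    R + P <-> RP        (K_D,het)

by monotone bisection on the free-receptor concentration; this is the
mass-action core behind the observation that a weak cis homodimer can
depress an apparent trans heterophilic affinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import NumericalError

__all__ = [
    "HomodimerEquilibrium",
    "SpeciesState",
    "CompetitionState",
    "free_monomer",
    "dimer_fraction",
    "fraction_bound_selfcompeting",
    "solve_species",
    "solve_competition",
    "oracle_mass_balance",
]

#: Floor used in relative comparisons to avoid 0/0 (µM).
EPS_CONC = 1e-15


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return value


def _check_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ValueError(f"{name} must be non-negative and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class HomodimerEquilibrium:
    """A self-associating species characterised by its homodimer K_D (µM)."""

    kd_homo: float

    def __post_init__(self) -> None:
        _check_positive("kd_homo", self.kd_homo)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium speciation of a monomer-dimer system.

    ``monomer + 2·dimer == total_monomer_equiv`` and
    ``monomer² == kd·dimer`` hold to relative 1e-9 in every state
    this module returns.
    """

    total_monomer_equiv: float  # µM, monomer equivalents
    monomer: float  # µM free monomer
    dimer: float  # µM dimer particles
    dimer_fraction: float  # 2·dimer / total, in [0, 1]


@dataclass(frozen=True)
class CompetitionState:
    """Coupled homodimer/heterodimer equilibrium concentrations (µM)."""

    total_receptor: float
    total_partner: float
    kd_homo: float
    kd_het: float
    free_receptor: float
    homodimer: float
    free_partner: float
    heterocomplex: float


def free_monomer(total: float, kd: float) -> float:
    """Free-monomer concentration of a self-dimerizing species.

    Parameters
    ----------
    total : float
        Total protein in monomer equivalents, µM.
    kd : float
        Homodimer dissociation constant [M]²/[D], µM.
    """
    total = _check_nonnegative("total", total)
    kd = _check_positive("kd", kd)
    if total == 0.0:
        return 0.0
    return 2.0 * total / (1.0 + math.sqrt(1.0 + 8.0 * total / kd))


def dimer_fraction(total: float, kd: float) -> float:
    """Fraction of monomer units incorporated into dimers, f = 2[D]/T."""
    total = _check_nonnegative("total", total)
    if total == 0.0:
        raise ValueError("dimer_fraction is undefined at total = 0")
    # f = 1 - m/T = 1 - 2/(1 + sqrt(1 + 8T/kd))
    kd = _check_positive("kd", kd)
    return 1.0 - 2.0 / (1.0 + math.sqrt(1.0 + 8.0 * total / kd))


def fraction_bound_selfcompeting(total: float, kd: float) -> float:
    """Surface-bound fraction when the analyte self-dimerizes in solution.

    Equals m/(kd + m) with m = :func:`free_monomer`, i.e. the 1:1 Langmuir
    occupancy evaluated at the free-monomer rather than the total
    concentration; this assumes the surface-binding K_D equals the solution
    homodimer K_D. Always ≤ the naive Langmuir T/(kd+T): self-competition
    can only depress binding.
    """
    m = free_monomer(total, kd)
    return m / (kd + m)


def solve_species(total: float, eq: HomodimerEquilibrium | float) -> SpeciesState:
    """Full monomer/dimer speciation at a given monomer-equivalent total."""
    kd = eq.kd_homo if isinstance(eq, HomodimerEquilibrium) else float(eq)
    total = _check_nonnegative("total", total)
    m = free_monomer(total, kd)
    d = (total - m) / 2.0
    f = 0.0 if total == 0.0 else 2.0 * d / total
    return SpeciesState(
        total_monomer_equiv=total, monomer=m, dimer=d, dimer_fraction=f
    )


def _competition_residual(
    r: float, total_receptor: float, total_partner: float, kd_homo: float, kd_het: float
) -> float:
    # receptor conservation with free partner eliminated analytically
    return r + 2.0 * r * r / kd_homo + r * total_partner / (kd_het + r) - total_receptor


def solve_competition(
    total_receptor: float,
    total_partner: float,
    kd_homo: float,
    kd_het: float,
    *,
    max_iter: int = 200,
) -> CompetitionState:
    """Solve the coupled homodimer + heterodimer competition equilibrium.

    Given totals (µM, receptor in monomer equivalents) and the two
    dissociation constants, finds the unique state satisfying

        free_receptor + 2·homodimer + heterocomplex = total_receptor
        free_partner + heterocomplex = total_partner
        free_receptor² = kd_homo · homodimer
        free_receptor · free_partner = kd_het · heterocomplex

    by bisection on the free-receptor concentration, on which the receptor
    conservation residual is strictly increasing.

    Raises
    ------
    NumericalError
        If bisection does not reduce the conservation residual below
        tolerance within ``max_iter`` iterations.
    """
    total_receptor = _check_nonnegative("total_receptor", total_receptor)
    total_partner = _check_nonnegative("total_partner", total_partner)
    kd_homo = _check_positive("kd_homo", kd_homo)
    kd_het = _check_positive("kd_het", kd_het)

    if total_receptor == 0.0:
        p = total_partner
        return CompetitionState(
            total_receptor, total_partner, kd_homo, kd_het, 0.0, 0.0, p, 0.0
        )

    lo, hi = 0.0, total_receptor
    r = total_receptor / 2.0
    g = _competition_residual(r, total_receptor, total_partner, kd_homo, kd_het)
    tol = 1e-12 * max(1.0, total_receptor, total_partner)
    for _ in range(max_iter):
        if abs(g) <= tol:
            break
        if g > 0.0:
            hi = r
        else:
            lo = r
        r_next = 0.5 * (lo + hi)
        if r_next == r:  # interval exhausted at machine precision
            break
        r = r_next
        g = _competition_residual(r, total_receptor, total_partner, kd_homo, kd_het)
    else:
        raise NumericalError(
            f"competition solver did not converge: residual {g:.3e} µM "
            f"after {max_iter} iterations"
        )
    if abs(g) > 1e-9 * max(1.0, total_receptor, total_partner):
        raise NumericalError(
            f"competition solver converged poorly: residual {g:.3e} µM"
        )

    homodimer = r * r / kd_homo
    free_partner = total_partner * kd_het / (kd_het + r)
    heterocomplex = r * free_partner / kd_het
    return CompetitionState(
        total_receptor=total_receptor,
        total_partner=total_partner,
        kd_homo=kd_homo,
        kd_het=kd_het,
        free_receptor=r,
        homodimer=homodimer,
        free_partner=free_partner,
        heterocomplex=heterocomplex,
    )


def oracle_mass_balance(total: float, kd: float, *, tol: float = 1e-14) -> float:
    """Brute-force free-monomer solution by bisection on the mass balance.

    Independent of the closed form in :func:`free_monomer`: bisects
    g(m) = m + 2m²/kd − total on [0, total]. Intended as a cross-check.
    """
    total = _check_nonnegative("total", total)
    kd = _check_positive("kd", kd)
    if total == 0.0:
        return 0.0

    def g(m: float) -> float:
        return m + 2.0 * m * m / kd - total

    lo, hi = 0.0, total
    # g(0) = -total < 0, g(total) = 2·total²/kd > 0: guaranteed bracket
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= tol * max(hi, EPS_CONC):
            break
    return 0.5 * (lo + hi)
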