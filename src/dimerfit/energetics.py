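"""Mutational energetics: K_D fold-changes and binding ΔΔG tables.

A mutation's effect on a binding equilibrium is summarised two ways:

* fold-change = K_D(mutant) / K_D(wild-type), > 1 meaning weaker binding;
* ΔΔG = R·T·ln(K_D,mut / K_D,wt) in kcal/mol, positive = destabilising.

Mutants whose binding could not be saturated are *censored*: their fitted
K_D is only a lower bound, so fold-change and ΔΔG are reported as lower
bounds and flagged, never as point estimates.

The temperature defaults to 298.15 K; R = 1.9872e-3 kcal·mol⁻¹·K⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DataError
from .spr import AffinityFit

__all__ = [
    "EnergeticsConfig",
    "PanelEntry",
    "PanelRow",
    "fold_change",
    "delta_delta_g",
    "build_panel",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)


@dataclass(frozen=True)
class EnergeticsConfig:
    """Temperature (K) and gas constant (kcal/mol/K) for ΔΔG conversion."""

    temperature: float = 298.15
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive, got {self.temperature!r}")
        if not (self.gas_constant > 0 and math.isfinite(self.gas_constant)):
            raise ValueError(f"gas_constant must be positive, got {self.gas_constant!r}")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class PanelEntry:
    """One fitted construct-partner affinity feeding a mutagenesis panel.

    ``censored=True`` marks a fit whose K_D is only a lower bound
    (binding not saturated / below detection at the top concentration).
    """

    construct: str
    partner: str
    fit: AffinityFit
    censored: bool = False


@dataclass(frozen=True)
class PanelRow:
    """Mutant-vs-wild-type comparison for one partner.

    For censored rows ``kd_mut`` is the detection bound and both
    ``fold_change`` and ``ddg`` are lower bounds.
    """

    construct: str
    partner: str
    kd_wt: float  # µM
    kd_mut: float  # µM (lower bound when censored)
    fold_change: float
    ddg: float  # kcal/mol, positive = destabilising
    censored: bool


def fold_change(kd_mut: float, kd_wt: float) -> float:
    """K_D ratio mutant/wild-type; > 1 means the mutant binds weaker."""
    if not (kd_mut > 0 and math.isfinite(kd_mut)):
        raise ValueError(f"kd_mut must be positive, got {kd_mut!r}")
    if not (kd_wt > 0 and math.isfinite(kd_wt)):
        raise ValueError(f"kd_wt must be positive, got {kd_wt!r}")
    return kd_mut / kd_wt


def delta_delta_g(
    kd_mut: float, kd_wt: float, cfg: EnergeticsConfig | None = None
) -> float:
    """Binding ΔΔG = R·T·ln(K_D,mut/K_D,wt) in kcal/mol.

    Antisymmetric in its arguments and zero when the affinities are equal.
    """
    cfg = cfg or EnergeticsConfig()
    return cfg.rt * math.log(fold_change(kd_mut, kd_wt))


def build_panel(
    entries: list[PanelEntry],
    cfg: EnergeticsConfig | None = None,
    wt_label: str = "WT",
) -> list[PanelRow]:
    """Join mutant fits to their same-partner wild-type references.

    Every non-wild-type entry must have a wild-type entry for the same
    partner, else :class:`DataError` names the orphan. Rows are sorted by
    construct then partner. Censoring on either side propagates to the row.
    """
    cfg = cfg or EnergeticsConfig()
    wt_by_partner: dict[str, PanelEntry] = {}
    for e in entries:
        if e.construct == wt_label:
            if e.partner in wt_by_partner:
                raise DataError(f"duplicate wild-type entry for partner {e.partner!r}")
            wt_by_partner[e.partner] = e

    rows: list[PanelRow] = []
    for e in entries:
        if e.construct == wt_label:
            continue
        wt = wt_by_partner.get(e.partner)
        if wt is None:
            raise DataError(
                f"mutant {e.construct!r} vs partner {e.partner!r} has no "
                f"wild-type ({wt_label!r}) reference for that partner"
            )
        kd_wt = wt.fit.kd_hat
        kd_mut = e.fit.kd_hat
        rows.append(
            PanelRow(
                construct=e.construct,
                partner=e.partner,
                kd_wt=kd_wt,
                kd_mut=kd_mut,
                fold_change=fold_change(kd_mut, kd_wt),
                ddg=delta_delta_g(kd_mut, kd_wt, cfg),
                censored=e.censored or wt.censored,
            )
        )
    rows.sort(key=lambda r: (r.construct, r.partner))
    return rows
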