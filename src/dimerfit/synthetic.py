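"""Seeded generators for synthetic SEC and SPR datasets.

These emulate the *designs* of the study this package supports — a
six-concentration dilution series over a mid-micromolar homodimer for SEC,
and multi-concentration equilibrium titrations of wild-type and mutant
construct pairs for SPR — with simple, explicit noise models, so that every
estimator in the package can be exercised end-to-end without instrument
data. They are emulated designs, not reconstructions of any measured run.

Noise models
------------
SPR responses: ``R = model(C)·(1 + ε_cv) + ε_add`` with independent
Gaussian ``ε_cv`` (coefficient of variation, default 2%) and ``ε_add``
(additive floor, default 0.5 RU) — a caricature of low-density surfaces
read near 100 RU.

SEC traces: each run is a Gaussian absorbance peak centered at the
model-predicted elution volume (height proportional to load) plus additive
baseline noise. Peak-position jitter therefore arises through the trace and
its peak detection, not by perturbing volumes directly, so the full
detection path is exercised.

All generators draw from ``numpy.random.default_rng(seed)``; a fixed
:class:`ScenarioSpec` reproduces its dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .equilibrium import dimer_fraction
from .errors import DataError
from .sec import SECCalibration, SECRun, predict_elution_volume
from .spr import TitrationSeries, predict_response

__all__ = [
    "ScenarioSpec",
    "gen_spr_titration",
    "gen_sec_dataset",
    "gen_mutant_panel",
    "SCENARIOS",
    "get_scenario",
    "list_scenarios",
]

#: default SEC calibration: chosen so f = 0.5 maps to exactly 12.0 mL
DEFAULT_CALIB = SECCalibration(v_dimer=11.0, v_monomer=13.2, column_volume=24.0)

#: chromatographic peak width (mL, Gaussian sigma) and trace grid step (mL)
PEAK_SIGMA = 0.25
TRACE_STEP = 0.01

#: absorbance per µM loaded (mAU/µM), sets trace peak heights
EXTINCTION = 2.0


def _threefold_design(center: float, n: int = 8) -> tuple[float, ...]:
    """n-point three-fold dilution series geometrically centered on ``center``."""
    exps = np.arange(n) - (n - 1) / 2.0
    return tuple(float(center * 3.0**e) for e in exps)


def _twofold_design(top: float = 100.0, n: int = 6) -> tuple[float, ...]:
    return tuple(float(top / 2.0**k) for k in range(n))


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to generate one synthetic dataset reproducibly."""

    name: str
    true_kd: float  # µM
    design: tuple[float, ...]  # analyte / load concentrations, µM
    model: str = "langmuir_1to1"  # SPR response model
    rmax: float = 100.0  # RU
    noise: tuple[float, float] = (0.02, 0.5)  # (cv, additive floor)
    calib: SECCalibration | None = None
    seed: int = 1
    true_kd_het: float | None = None
    fold_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.design or any(c <= 0 or not np.isfinite(c) for c in self.design):
            raise DataError("design concentrations must be positive and finite")
        if self.true_kd <= 0:
            raise DataError(f"true_kd must be positive, got {self.true_kd!r}")
        if any(f <= 0 for f in self.fold_map.values()):
            raise DataError("fold_map factors must be positive")


def gen_spr_titration(
    spec: ScenarioSpec, model: str | None = None, *, rng: np.random.Generator | None = None
) -> TitrationSeries:
    """Generate one noisy equilibrium titration from the scenario's truth."""
    model = model or spec.model
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    conc = np.asarray(sorted(spec.design), dtype=float)
    clean = np.asarray(predict_response(model, spec.true_kd, spec.rmax, conc))
    cv, floor = spec.noise
    resp = clean * (1.0 + cv * rng.standard_normal(len(conc)))
    resp = resp + floor * rng.standard_normal(len(conc))
    return TitrationSeries(
        ligand=spec.name,
        analyte=spec.name,
        concentrations=conc,
        responses=resp,
        channel="sim",
    )


def gen_sec_dataset(spec: ScenarioSpec) -> list[SECRun]:
    """Generate one SEC dilution series as full noisy chromatogram traces."""
    if spec.calib is None:
        raise DataError("SEC scenario requires a calibration")
    calib = spec.calib
    rng = np.random.default_rng(spec.seed)
    grid = np.arange(
        calib.v_dimer - 2.0, calib.v_monomer + 2.0 + TRACE_STEP / 2, TRACE_STEP
    )
    cv, floor = spec.noise
    runs: list[SECRun] = []
    for load in sorted(spec.design, reverse=True):
        f = dimer_fraction(load, spec.true_kd)
        center = predict_elution_volume(f, calib)
        height = EXTINCTION * load
        trace = height * np.exp(-0.5 * ((grid - center) / PEAK_SIGMA) ** 2)
        trace = trace + (cv * height + floor) * rng.standard_normal(len(grid))
        runs.append(SECRun(load_conc=load, trace=(grid.copy(), trace)))
    return runs


def gen_mutant_panel(
    spec: ScenarioSpec, fold_map: dict[str, float] | None = None, wt_label: str = "WT"
) -> dict[str, TitrationSeries]:
    """Wild-type plus mutants at stated K_D fold-factors, shared Rmax.

    Returns a mapping of construct label to titration, keyed ``wt_label``
    plus the fold_map keys. Each construct draws from a child stream of the
    scenario seed, so the panel is reproducible as a whole.
    """
    fold_map = fold_map if fold_map is not None else spec.fold_map
    if any(f <= 0 for f in fold_map.values()):
        raise DataError("fold_map factors must be positive")
    labels = [wt_label] + sorted(fold_map)
    streams = np.random.SeedSequence(spec.seed).spawn(len(labels))
    panel: dict[str, TitrationSeries] = {}
    for label, ss in zip(labels, streams):
        kd = spec.true_kd * (1.0 if label == wt_label else fold_map[label])
        sub = replace(spec, true_kd=kd, name=label)
        series = gen_spr_titration(sub, rng=np.random.default_rng(ss))
        panel[label] = TitrationSeries(
            ligand=label,
            analyte=spec.name,
            concentrations=series.concentrations,
            responses=series.responses,
            channel="sim",
        )
    return panel


# -- named built-in scenarios -----------------------------------------------
# Affinities follow the reported study values; concentration designs are
# emulated (two-fold SEC series 3.125-100 µM, three-fold SPR series spanning
# three decades around the true K_D, mutant panels capped at 100 µM).


def _dip_eta_sec(seed: int) -> ScenarioSpec:
    """Six-concentration SEC series over the DIP-eta homodimer (K_D 23 µM)."""
    return ScenarioSpec(
        name="dip_eta_sec",
        true_kd=23.0,
        design=_twofold_design(100.0, 6),
        noise=(0.01, 0.0),
        calib=DEFAULT_CALIB,
        seed=seed,
    )


def _dip_eta_spr_selfdimer(seed: int) -> ScenarioSpec:
    """Self-dimer-corrected SPR titration of DIP-eta (homodimer K_D 14 µM)."""
    return ScenarioSpec(
        name="dip_eta_spr_selfdimer",
        true_kd=14.0,
        design=_threefold_design(14.0),
        model="selfdimer_corrected",
        seed=seed,
    )


def _dpr6_dipa_langmuir(seed: int) -> ScenarioSpec:
    """Dpr6 vs DIP-alpha heterophilic titration (K_D 0.37 µM)."""
    return ScenarioSpec(
        name="dpr6_dipa_langmuir",
        true_kd=0.37,
        design=_threefold_design(0.37),
        seed=seed,
    )


def _dpr1_dipeta_langmuir(seed: int) -> ScenarioSpec:
    """Dpr1-captured Dpr1 vs DIP-eta titration (K_D 4.0 µM)."""
    return ScenarioSpec(
        name="dpr1_dipeta_langmuir",
        true_kd=4.0,
        design=_threefold_design(4.0),
        seed=seed,
    )


def _i83a_panel(seed: int) -> ScenarioSpec:
    """Wild-type (0.37 µM) plus a 700-fold-weakened mutant, top dose 100 µM."""
    return ScenarioSpec(
        name="i83a_panel",
        true_kd=0.37,
        design=tuple(100.0 / 3.0**k for k in range(8)),
        fold_map={"I83A": 700.0},
        seed=seed,
    )


SCENARIOS: dict[str, Callable[[int], ScenarioSpec]] = {
    "dip_eta_sec": _dip_eta_sec,
    "dip_eta_spr_selfdimer": _dip_eta_spr_selfdimer,
    "dpr6_dipa_langmuir": _dpr6_dipa_langmuir,
    "dpr1_dipeta_langmuir": _dpr1_dipeta_langmuir,
    "i83a_panel": _i83a_panel,
}


def get_scenario(name: str, seed: int = 1) -> ScenarioSpec:
    try:
        return SCENARIOS[name](seed)
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        ) from None


def list_scenarios() -> list[str]:
    return sorted(SCENARIOS)
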