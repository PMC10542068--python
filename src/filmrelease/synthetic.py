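"""Synthetic release-curve generation emulating the release-test design.

The generator reproduces the study design of a film-release experiment:
four scenarios (fatty 95%-ethanol and hydrophilic 10%-ethanol simulants,
each at 4 °C and 24 °C) with the reported diffusivities, volume ratios and
partition coefficients for rosemary-oleoresin release from a zein/gellan
film; sampling every 3 h for the first 24 h and every 24 h for three further
days; and multiplicative Gaussian measurement noise of assay-like magnitude.

Film thickness and the equilibrium concentration scale are not part of the
reported parameter set; the defaults (half-thickness 50 um, C_S,inf
100 mg GAE/kg) are typical of solvent-cast biopolymer films and of TPC
readouts, and the fits are invariant to the concentration scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .fitting import ReleaseCurve
from .release_model import (
    ModelKind,
    ReleaseGeometry,
    find_roots,
    fractional_release_erfc,
    fractional_release_series,
    select_model,
)

__all__ = [
    "Scenario",
    "REFERENCE_SCENARIOS",
    "study_sampling_schedule",
    "scenario_geometry",
    "generate_release_curve",
    "generate_study",
]

#: default half-thickness of the film, m (50 um)
DEFAULT_L = 5e-5
#: default equilibrium concentration scale, mg GAE / kg simulant
DEFAULT_C_S_INF = 100.0
#: default film volume used for bookkeeping geometries, m^3
DEFAULT_V_F = 2e-7


@dataclass(frozen=True)
class Scenario:
    """A named release-test condition with its generating parameters."""

    name: str
    simulant: str                  # "fatty" | "hydrophilic"
    temperature_C: float
    D_true: float                  # m^2/s
    alpha_true: float
    K_FS_true: float
    L: float = DEFAULT_L           # half-thickness, m
    C_S_inf: float = DEFAULT_C_S_INF
    noise_cv: float = 0.05
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.simulant not in ("fatty", "hydrophilic"):
            raise ValueError("simulant must be 'fatty' or 'hydrophilic'")
        for attr in ("D_true", "alpha_true", "K_FS_true", "L", "C_S_inf"):
            if getattr(self, attr) <= 0.0:
                raise ValueError(f"{attr} must be positive")
        if self.noise_cv < 0.0:
            raise ValueError("noise_cv must be >= 0")


#: the four reference conditions of the release test (D in m^2/s)
REFERENCE_SCENARIOS: dict[str, Scenario] = {
    "fatty_4C": Scenario("fatty_4C", "fatty", 4.0, 5.115e-14, 147e-4, 0.681),
    "fatty_24C": Scenario("fatty_24C", "fatty", 24.0, 21.140e-14, 181e-4, 0.552),
    "hydrophilic_4C": Scenario("hydrophilic_4C", "hydrophilic", 4.0, 0.802e-14, 7.34e-4, 13.630),
    "hydrophilic_24C": Scenario("hydrophilic_24C", "hydrophilic", 24.0, 5.949e-14, 9.19e-4, 10.880),
}


def study_sampling_schedule() -> np.ndarray:
    """Sampling times in seconds: every 3 h up to 24 h, then daily to 96 h."""
    hours = np.concatenate([np.arange(0, 25, 3), [48.0, 72.0, 96.0]])
    return hours * 3600.0


def scenario_geometry(scenario: Scenario, volume_film: float = DEFAULT_V_F) -> ReleaseGeometry:
    """Bookkeeping geometry consistent with a scenario's alpha and K_FS.

    Only the characteristic length matters for the kinetics; the simulant
    volume is back-computed so that ``V_S / (K_FS V_F)`` equals the
    scenario's alpha.
    """
    volume_simulant = scenario.alpha_true * scenario.K_FS_true * volume_film
    return ReleaseGeometry.from_characteristic_length(
        scenario.L, volume_film=volume_film, volume_simulant=volume_simulant
    )


def _forward_ratio(scenario: Scenario, times: np.ndarray) -> np.ndarray:
    geom = scenario_geometry(scenario)
    kind = select_model(scenario.alpha_true)
    if kind is ModelKind.SERIES:
        roots = find_roots(scenario.alpha_true)
        return fractional_release_series(
            times, scenario.D_true, geom, scenario.alpha_true, roots
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fractional_release_erfc(times, scenario.D_true, geom, scenario.alpha_true)


def generate_release_curve(
    scenario: Scenario,
    schedule: np.ndarray | None = None,
    seed: int = 0,
    replicate: int | None = None,
) -> ReleaseCurve:
    """Simulate one noisy release curve for a scenario.

    The forward model (series, or erfc when ``alpha < 0.01``) is evaluated at
    the schedule times, scaled by ``C_S_inf``, and perturbed by multiplicative
    Gaussian noise ``c * (1 + eps)`` with ``eps ~ N(0, noise_cv)``, truncated
    at zero.  Identical seeds give identical curves.
    """
    times = study_sampling_schedule() if schedule is None else np.asarray(schedule, float)
    conc = _forward_ratio(scenario, times) * scenario.C_S_inf
    if scenario.noise_cv > 0.0:
        rng = np.random.default_rng(seed)
        conc = conc * (1.0 + rng.normal(0.0, scenario.noise_cv, conc.size))
        conc = np.maximum(conc, 0.0)
    return ReleaseCurve(
        times=times,
        concentrations=conc,
        simulant_label=scenario.simulant,
        temperature_label=f"{scenario.temperature_C:g}C",
        C_S_inf=scenario.C_S_inf,
        replicate=replicate,
        name=scenario.name if replicate is None else f"{scenario.name}_r{replicate}",
    )


def generate_study(
    seed: int = 0,
    scenarios: dict[str, Scenario] | None = None,
    n_replicates: int | None = None,
    noise_cv: float | None = None,
    schedule: np.ndarray | None = None,
) -> list[ReleaseCurve]:
    """Simulate the full study: every scenario times its replicates.

    Each curve gets a distinct sub-seed derived deterministically from
    ``seed`` via a seed sequence, so the collection is reproducible while the
    replicates are statistically independent.
    """
    scenarios = REFERENCE_SCENARIOS if scenarios is None else scenarios
    names = sorted(scenarios)
    reps = [
        n_replicates if n_replicates is not None else scenarios[n].n_replicates
        for n in names
    ]
    children = np.random.SeedSequence(seed).spawn(int(np.sum(reps)))
    curves: list[ReleaseCurve] = []
    i = 0
    for name, n_rep in zip(names, reps):
        sc = scenarios[name]
        if noise_cv is not None:
            sc = replace(sc, noise_cv=noise_cv)
        for r in range(1, n_rep + 1):
            sub_seed = int(children[i].generate_state(1)[0] % (2**31))
            curves.append(generate_release_curve(sc, schedule, seed=sub_seed, replicate=r))
            i += 1
    return curves
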