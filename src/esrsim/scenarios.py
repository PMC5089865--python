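"""Named reference scenarios and a seeded random-scenario generator.

The reference parameterization for all shipped scenarios: 20% per-cycle
survival of susceptible phenotypes, 60% of resistant, 45% of deflected and
resistant-deflected (no cost of resistance); 0.5% initial resistance-allele
prevalence; 25% initial deflection-allele prevalence; three-cycle juvenile
development; 4% per-feed infection acquisition; 80% per-feed infectious
bite probability; three-cycle extrinsic incubation; 300 cycles of the
combined repellent + insecticide intervention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genetics import PhenotypeFitness
from .simulator import InfectionParams, LifeHistoryParams, Scenario

__all__ = [
    "NamedScenario",
    "baseline",
    "figure1",
    "figure2",
    "named_scenarios",
    "get_scenario",
    "random_scenario",
]


@dataclass(frozen=True)
class NamedScenario:
    """A scenario fixture with a human-readable provenance string."""

    name: str
    scenario: Scenario
    provenance: str

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must be non-empty")


def baseline() -> Scenario:
    """The reference combined-intervention scenario (see module docstring)."""
    return Scenario(
        fitness=PhenotypeFitness(F_S=0.20, F_R=0.60, F_D=0.45, F_RD=0.45),
        infection=InfectionParams(
            p_acquire_nondeflected=0.04,
            p_acquire_deflected=0.04,
            p_infectious_bite=0.8,
            incubation_cycles=3,
        ),
        life_history=LifeHistoryParams(
            development_cycles=3, recruits_per_cycle=1000.0, n_cycles=300
        ),
        init_R_freq=0.005,
        init_D_freq=0.25,
        intervention_mode="esr_plus_insecticide",
    )


def figure1(panel: str) -> Scenario:
    """Time-series scenarios: establishment (a), transient (b), failure (c).

    Panel ``a`` is the baseline; ``b`` lowers deflected survival (F_D and
    F_RD) to 40%; ``c`` additionally raises susceptible survival to 30%
    and starts from 5% resistance and 10% deflection alleles.
    """
    s = baseline()
    if panel == "a":
        return s
    if panel == "b":
        return replace(s, fitness=replace(s.fitness, F_D=0.40, F_RD=0.40))
    if panel == "c":
        return replace(
            s,
            fitness=replace(s.fitness, F_S=0.30, F_D=0.40, F_RD=0.40),
            init_R_freq=0.05,
            init_D_freq=0.10,
        )
    raise ValueError(f"unknown panel {panel!r}; expected one of a, b, c")


def figure2(panel: str) -> Scenario:
    """Grid-scan template scenarios, each one change away from the baseline.

    ``i`` baseline; ``ii`` 10% initial deflection alleles; ``iii`` 2%
    initial resistance alleles; ``iv`` 60% susceptible survival.
    """
    s = baseline()
    if panel == "i":
        return s
    if panel == "ii":
        return replace(s, init_D_freq=0.10)
    if panel == "iii":
        return replace(s, init_R_freq=0.02)
    if panel == "iv":
        return replace(s, fitness=replace(s.fitness, F_S=0.60))
    raise ValueError(f"unknown panel {panel!r}; expected one of i, ii, iii, iv")


def named_scenarios() -> list[NamedScenario]:
    """Every shipped fixture, with provenance."""
    base = (
        "reference parameterization: survivals 20/60/45/45%, "
        "initial alleles R=0.5%, D=25%, combined repellent+insecticide"
    )
    out = [NamedScenario("baseline", baseline(), base)]
    for p, note in (
        ("a", "time-series panel a: long-term establishment (= baseline)"),
        ("b", "time-series panel b: transient establishment (deflected survival 40%)"),
        ("c", "time-series panel c: failure (susceptible 30%, R0=5%, D0=10%)"),
    ):
        out.append(NamedScenario(f"figure1-{p}", figure1(p), note))
    for p, note in (
        ("i", "grid template i: baseline"),
        ("ii", "grid template ii: initial deflection alleles 10%"),
        ("iii", "grid template iii: initial resistance alleles 2%"),
        ("iv", "grid template iv: susceptible survival 60%"),
    ):
        out.append(NamedScenario(f"figure2-{p}", figure2(p), note))
    return out


def get_scenario(name: str) -> Scenario:
    for ns in named_scenarios():
        if ns.name == name:
            return ns.scenario
    known = ", ".join(ns.name for ns in named_scenarios())
    raise KeyError(f"unknown scenario {name!r}; known scenarios: {known}")


def random_scenario(seed: int, simplified: bool = False) -> Scenario:
    """A reproducible random but valid scenario for property tests.

    Survivals are drawn uniformly in [0.05, 0.95] (with F_RD tied to F_D,
    matching the shipped fixtures), allele frequencies uniformly in
    (0.01, 0.99).  With ``simplified=True`` the scenario uses one-cycle
    development and non-overlapping generations, the mode in which
    single-generation allele-frequency changes can be checked against the
    analytic spread conditions.
    """
    rng = np.random.default_rng(seed)
    f_s, f_r, f_d = rng.uniform(0.05, 0.95, size=3)
    lh = (
        LifeHistoryParams(
            development_cycles=1,
            recruits_per_cycle=1000.0,
            n_cycles=2,
            max_adult_cycles=1,
        )
        if simplified
        else LifeHistoryParams()
    )
    return Scenario(
        fitness=PhenotypeFitness(F_S=f_s, F_R=f_r, F_D=f_d, F_RD=f_d),
        life_history=lh,
        init_R_freq=float(rng.uniform(0.01, 0.99)),
        init_D_freq=float(rng.uniform(0.01, 0.99)),
        intervention_mode="esr_plus_insecticide",
    )
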