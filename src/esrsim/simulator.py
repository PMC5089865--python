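"""Deterministic feeding-cycle cohort dynamics for a malaria-vector population.

One model time unit is one gonotrophic (feeding) cycle.  Each cycle, every
adult female: survives with her phenotype's per-cycle probability, feeds
(possibly acquiring a *Plasmodium* infection, with incubating infections
advancing one cycle), gives an infectious bite if infectious, and lays a
clutch of eggs fathered by the sperm she stored at emergence.  Offspring
enter a fixed-length juvenile development queue; juvenile density
dependence holds the number of newly emerging adults per cycle constant,
so only the genotype composition of the delayed zygote pool matters.
Newly emerged females mate once, immediately, with males of their own
emergence cohort.

All dynamics are deterministic (expected-value recursions on real-valued
counts); there is no demographic stochasticity.

Infection bookkeeping: a female infected at the feed of cycle *t* becomes
infectious at the feed of cycle ``t + incubation_cycles`` inclusive, and
bites are credited to survivors of the current cycle's mortality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import (
    GAMETE_MATRIX,
    GENOTYPE_N_D,
    GENOTYPE_N_R,
    GENOTYPE_PHENOTYPE,
    GENOTYPES,
    PAIR_TO_GENOTYPE,
    PHENOTYPES,
    HaplotypeProportions,
    PhenotypeFitness,
    zygote_distribution,
)

__all__ = [
    "InfectionParams",
    "LifeHistoryParams",
    "Scenario",
    "PopulationState",
    "INTERVENTION_MODES",
    "initialize_population",
    "phenotype_survival",
    "step",
    "run",
    "relative_infectious_bites",
    "deflected_proportion",
    "TIMESERIES_COLUMNS",
]

logger = logging.getLogger(__name__)

INTERVENTION_MODES = ("none", "insecticide_only", "esr_plus_insecticide")

#: cohorts whose total count falls below this fraction of one cycle's
#: recruitment are dropped (per-cycle survival < 1 guarantees geometric decay)
_COHORT_PRUNE_FRACTION = 1e-12

#: behaviourally deflected phenotype indices (Deflected, ResistantDeflected)
_DEFLECTED_PHENOTYPES = np.array([False, False, True, True])


@dataclass(frozen=True)
class InfectionParams:
    """Per-feed *Plasmodium* transmission probabilities and incubation delay.

    ``p_acquire_nondeflected``: probability an uninfected, non-deflected
    female acquires an infection at a feed (default 4%).
    ``p_acquire_deflected``: the same for behaviourally deflected females
    (their feeds happen away from protected indoor hosts); the default
    assumes no transmission reduction.
    ``p_infectious_bite``: probability an infectious female's feed delivers
    an infectious bite to a human host (default 80%).
    ``incubation_cycles``: extrinsic incubation period in feeding cycles
    (default 3).
    """

    p_acquire_nondeflected: float = 0.04
    p_acquire_deflected: float = 0.04
    p_infectious_bite: float = 0.8
    incubation_cycles: int = 3

    def __post_init__(self) -> None:
        for name in ("p_acquire_nondeflected", "p_acquire_deflected", "p_infectious_bite"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.incubation_cycles < 0:
            raise ValueError("incubation_cycles must be >= 0")


@dataclass(frozen=True)
class LifeHistoryParams:
    """Development delay, recruitment and run length.

    ``development_cycles``: feeding cycles from egg laying to adult
    emergence (default 3).  ``recruits_per_cycle``: newly emerging adults
    per cycle, held constant by juvenile density dependence; only sets the
    population scale.  ``n_cycles``: simulation length.
    ``max_adult_cycles``: if set to 1, adults die after one reproductive
    cycle (non-overlapping generations) — a simplified mode used for
    analytic cross-checks, not part of the standard parameterization.
    """

    development_cycles: int = 3
    recruits_per_cycle: float = 1000.0
    n_cycles: int = 300
    max_adult_cycles: int | None = None

    def __post_init__(self) -> None:
        if self.development_cycles < 1:
            raise ValueError("development_cycles must be >= 1")
        if self.recruits_per_cycle <= 0:
            raise ValueError("recruits_per_cycle must be > 0")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.max_adult_cycles is not None and self.max_adult_cycles != 1:
            raise ValueError("max_adult_cycles supports only None or 1")


@dataclass(frozen=True)
class Scenario:
    """A complete parameterization of one simulation run.

    ``intervention_mode`` selects which survivals apply:

    * ``none`` — no treatment; every phenotype survives at the
      no-treatment rate ``U`` (identified with ``F_R`` under a zero cost
      of resistance) and nobody is behaviourally deflected;
    * ``insecticide_only`` — insecticide without the repellent: deflected
      phenotypes lose their protection (F_D -> F_S, F_RD -> F_R) and feed
      indoors like everyone else;
    * ``esr_plus_insecticide`` — the combined intervention: phenotype
      survivals apply as given and deflected phenotypes feed away from
      protected properties.
    """

    fitness: PhenotypeFitness
    infection: InfectionParams = field(default_factory=InfectionParams)
    life_history: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    init_R_freq: float = 0.0
    init_D_freq: float = 0.0
    intervention_mode: str = "esr_plus_insecticide"

    def __post_init__(self) -> None:
        if self.intervention_mode not in INTERVENTION_MODES:
            raise ValueError(
                f"intervention_mode must be one of {INTERVENTION_MODES}, "
                f"got {self.intervention_mode!r}"
            )
        for name in ("init_R_freq", "init_D_freq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def no_intervention_survival(self) -> float:
        """Pre-intervention per-cycle survival U.

        The resistant phenotype survives every feed untouched when its cost
        of resistance is zero, so its survival is the no-treatment rate.
        """
        return self.fitness.F_R


def phenotype_survival(s: Scenario, phenotype: int | None = None):
    """Per-cycle survival by phenotype index under the scenario's mode.

    Returns the length-4 vector (S, R, D, RD order), or a single value if
    ``phenotype`` is given.
    """
    f = s.fitness
    if s.intervention_mode == "none":
        u = s.no_intervention_survival
        v = np.array([u, u, u, u])
    elif s.intervention_mode == "insecticide_only":
        v = np.array([f.F_S, f.F_R, f.F_S, f.F_R])
    else:
        v = f.as_array()
    return v if phenotype is None else float(v[phenotype])


def _acquisition_by_phenotype(s: Scenario) -> np.ndarray:
    """Per-feed infection-acquisition probability by phenotype index.

    Deflected phenotypes use the deflected probability only when the
    repellent is actually deployed (``esr_plus_insecticide``); in the other
    modes every phenotype feeds on unprotected indoor hosts.
    """
    p_n = s.infection.p_acquire_nondeflected
    p_d = s.infection.p_acquire_deflected
    if s.intervention_mode == "esr_plus_insecticide":
        return np.where(_DEFLECTED_PHENOTYPES, p_d, p_n)
    return np.full(4, p_n)


@dataclass
class PopulationState:
    """Cohort-structured adult females plus the juvenile development queue.

    ``counts`` has shape (n_cohorts, 9, n_stages): real-valued female
    counts by emergence cohort, genotype and infection stage.  Stage 0 is
    uninfected; stages 1..incubation_cycles are incubating (stage 1 + k
    means k cycles since the infecting feed); the last stage is infectious.
    ``sperm`` has shape (n_cohorts, 4): the haplotype pool each cohort's
    females stored at emergence (the gamete pool of their own cohort's
    males).  ``juvenile_queue`` holds one unnormalized zygote genotype
    distribution per development cycle, oldest first.
    """

    counts: np.ndarray
    sperm: np.ndarray
    juvenile_queue: list[np.ndarray]
    cycle: int = 0
    last_infectious_bites: float = 0.0

    @property
    def n_stages(self) -> int:
        return self.counts.shape[2]

    @property
    def adult_count(self) -> float:
        return float(self.counts.sum())

    def genotype_counts(self) -> np.ndarray:
        """Total female count per genotype, summed over cohorts and stages."""
        return self.counts.sum(axis=(0, 2))

    def genotype_freqs(self) -> np.ndarray:
        n = self.genotype_counts()
        tot = n.sum()
        return n / tot if tot > 0 else np.full(9, np.nan)

    def allele_freqs(self) -> tuple[float, float]:
        """(R-allele, D-allele) frequencies among adults; NaN if empty."""
        n = self.genotype_counts()
        tot = n.sum()
        if tot <= 0:
            return float("nan"), float("nan")
        return (
            float(n @ GENOTYPE_N_R) / (2 * tot),
            float(n @ GENOTYPE_N_D) / (2 * tot),
        )

    def phenotype_proportions(self) -> np.ndarray:
        f = self.genotype_freqs()
        out = np.zeros(4)
        if np.any(np.isnan(f)):
            return np.full(4, np.nan)
        np.add.at(out, GENOTYPE_PHENOTYPE, f)
        return out


def initialize_population(s: Scenario) -> PopulationState:
    """Population at the moment the intervention is switched on.

    Genotype frequencies are at Hardy–Weinberg and linkage equilibrium for
    the initial allele frequencies.  The standing adult population is at
    its pre-intervention demographic equilibrium ``recruits / (1 - U)``
    (the age distribution is geometric under the no-treatment survival U,
    but age does not otherwise enter the model, so standing adults form a
    single aggregate cohort).  All adults start uninfected, and the
    juvenile queue is filled with the equilibrium zygote distribution.
    """
    lh = s.life_history
    h0 = HaplotypeProportions.from_allele_freqs(s.init_R_freq, s.init_D_freq)
    g0 = zygote_distribution(h0.as_array(), h0.as_array())
    n_stages = s.infection.incubation_cycles + 2
    if lh.max_adult_cycles == 1:
        standing = lh.recruits_per_cycle
    else:
        u = s.no_intervention_survival
        if u >= 1.0:
            raise ValueError(
                "no-treatment survival U must be < 1 for a finite standing population"
            )
        standing = lh.recruits_per_cycle / (1.0 - u)
    counts = np.zeros((1, 9, n_stages))
    counts[0, :, 0] = standing * g0
    sperm = h0.as_array()[None, :].copy()
    queue = [g0.copy() for _ in range(lh.development_cycles)]
    return PopulationState(counts=counts, sperm=sperm, juvenile_queue=queue, cycle=0)


def step(state: PopulationState, s: Scenario) -> PopulationState:
    """Advance the population by one feeding cycle, in place.

    Within-cycle event order: (1) per-phenotype survival; (2) the feed —
    incubating infections advance one cycle and surviving uninfected
    females acquire infection with their phenotype's probability; (3)
    infectious surviving feeders bite; (4) every surviving female
    contributes one egg-clutch unit (her gametes x her stored sperm) to the
    cycle's zygote pool, which joins the back of the juvenile queue; (5)
    the oldest queue entry emerges as ``recruits_per_cycle`` new adults,
    mated immediately within their cohort.

    Returns the same (mutated) state; ``state.last_infectious_bites``
    carries the cycle's infectious-bite count.
    """
    lh = s.life_history
    inc = s.infection.incubation_cycles
    counts = state.counts

    # (1) survival, by phenotype of each genotype
    surv = phenotype_survival(s)[GENOTYPE_PHENOTYPE]          # (9,)
    counts *= surv[None, :, None]

    # (2) the feed: advance incubation, then new acquisitions
    if inc > 0:
        counts[:, :, -1] += counts[:, :, inc]                  # last incubating -> infectious
        counts[:, :, 2 : inc + 1] = counts[:, :, 1:inc].copy()  # shift k -> k+1
        counts[:, :, 1] = 0.0
    p_acq = _acquisition_by_phenotype(s)[GENOTYPE_PHENOTYPE]   # (9,)
    newly = counts[:, :, 0] * p_acq[None, :]
    counts[:, :, 0] -= newly
    if inc > 0:
        counts[:, :, 1] += newly
    else:
        counts[:, :, -1] += newly

    # (3) infectious bites by surviving feeders
    bites = float(counts[:, :, -1].sum()) * s.infection.p_infectious_bite

    # (4) oviposition: zygote pool from each cohort's females x stored sperm
    totals = counts.sum(axis=2)                                # (C, 9)
    female_gametes = totals @ GAMETE_MATRIX.T                  # (C, 4) unnormalized
    zygotes = np.einsum("gij,ci,cj->g", PAIR_TO_GENOTYPE, female_gametes, state.sperm)
    state.juvenile_queue.append(zygotes)

    if lh.max_adult_cycles == 1:
        counts = state.counts = np.zeros((0, 9, state.n_stages))
        state.sperm = np.zeros((0, 4))

    # (5) emergence of the oldest juvenile cohort
    front = state.juvenile_queue.pop(0)
    mass = float(front.sum())
    if mass > 0.0:
        dist = front / mass
        new_counts = np.zeros((1, 9, state.n_stages))
        new_counts[0, :, 0] = lh.recruits_per_cycle * dist
        new_sperm = (GAMETE_MATRIX @ dist)[None, :]
        state.counts = np.concatenate([state.counts, new_counts])
        state.sperm = np.concatenate([state.sperm, new_sperm])

    # prune exhausted cohorts to bound the state size
    if state.counts.shape[0] > 0:
        keep = (
            state.counts.sum(axis=(1, 2))
            > _COHORT_PRUNE_FRACTION * lh.recruits_per_cycle
        )
        if not keep.all():
            state.counts = state.counts[keep]
            state.sperm = state.sperm[keep]

    state.cycle += 1
    state.last_infectious_bites = bites
    return state


#: fixed column order of the run() time series
TIMESERIES_COLUMNS = (
    ["cycle"]
    + ["geno_" + g.replace("/", "_") for g in GENOTYPES]
    + ["allele_R_freq", "allele_D_freq"]
    + ["phen_" + p.lower() for p in PHENOTYPES]
    + ["adult_count", "infectious_bites"]
)


def _record(state: PopulationState, bites: float) -> list[float]:
    r_freq, d_freq = state.allele_freqs()
    return (
        [float(state.cycle)]
        + list(state.genotype_freqs())
        + [r_freq, d_freq]
        + list(state.phenotype_proportions())
        + [state.adult_count, bites]
    )


def run(s: Scenario) -> pd.DataFrame:
    """Simulate ``n_cycles`` feeding cycles; return the per-cycle time series.

    Row ``cycle == 0`` is the initial state (before any intervention
    mortality); rows 1..n_cycles record the population after each cycle.
    Fully deterministic: identical inputs give identical output.
    """
    if s.intervention_mode == "esr_plus_insecticide":
        s.fitness.check_esr_relevant()
    state = initialize_population(s)
    rows = [_record(state, 0.0)]
    for _ in range(s.life_history.n_cycles):
        step(state, s)
        rows.append(_record(state, state.last_infectious_bites))
    ts = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
    ts["cycle"] = ts["cycle"].astype(int)
    logger.info(
        "run complete: mode=%s, %d cycles, final deflected proportion %.4f",
        s.intervention_mode,
        s.life_history.n_cycles,
        deflected_proportion(ts).iloc[-1],
    )
    return ts


def deflected_proportion(ts: pd.DataFrame) -> pd.Series:
    """Proportion of adults with a deflected phenotype (D plus RD carriers)."""
    return ts["phen_deflected"] + ts["phen_resistantdeflected"]


def relative_infectious_bites(
    ts: pd.DataFrame, baseline: pd.DataFrame
) -> pd.Series:
    """Per-cycle infectious bites as a proportion of a no-intervention run.

    Cycles before the baseline's infectious class is populated (the
    transient while the first infections incubate) are flagged as NaN.
    A zero baseline after that transient is an error.
    """
    if len(ts) != len(baseline):
        raise ValueError("time series lengths differ")
    b = baseline["infectious_bites"].to_numpy()
    x = ts["infectious_bites"].to_numpy()
    positive = np.nonzero(b > 0)[0]
    out = np.full(len(b), np.nan)
    if positive.size == 0:
        raise ValueError("baseline run produced no infectious bites")
    start = positive[0]
    if np.any(b[start:] <= 0):
        raise ValueError("baseline infectious bites hit zero after the transient")
    out[start:] = x[start:] / b[start:]
    return pd.Series(out, index=ts.index, name="relative_infectious_bites")
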