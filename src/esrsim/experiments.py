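"""Numerical experiments on the feeding-cycle model.

Covers: classifying whether a scenario establishes the repellent
(deflected phenotypes reaching a threshold proportion by a given cycle),
the one-time insecticide-swap "ratchet", grid scans over resistant x
deflected survival combinations, the minimum cost-of-resistance scan, the
blended-fitness variant for incomplete deflection, and the comparison of
infectious-bite trajectories across intervention variants.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genetics import PhenotypeFitness
from .simulator import (
    Scenario,
    deflected_proportion,
    relative_infectious_bites,
    run,
)

__all__ = [
    "EstablishmentCriterion",
    "GridResult",
    "classify_establishment",
    "ratchet_run",
    "grid_scan",
    "min_cor_scan",
    "blended_fitness",
    "figure4_experiment",
]

#: grid-cell classifications
DIRECT, RATCHET, FAIL = "direct", "ratchet", "fail"


@dataclass(frozen=True)
class EstablishmentCriterion:
    """Establishment = deflected phenotypes >= ``threshold`` at ``at_cycle``.

    Deflected phenotypes counts both deflected and resistant-deflected
    carriers (both are repelled).  Ties at exactly the threshold count as
    established ("at least").
    """

    threshold: float = 0.80
    at_cycle: int = 300

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        if self.at_cycle < 1:
            raise ValueError("at_cycle must be >= 1")


def _deflected_at(ts: pd.DataFrame, cycle: int) -> float:
    row = ts.index[ts["cycle"] == cycle]
    if len(row) == 0:
        raise ValueError(f"time series does not reach cycle {cycle}")
    return float(deflected_proportion(ts).loc[row[0]])


def classify_establishment(
    ts: pd.DataFrame, criterion: EstablishmentCriterion = EstablishmentCriterion()
) -> bool:
    """Whether a run's deflected-phenotype proportion meets the criterion."""
    value = _deflected_at(ts, criterion.at_cycle)
    return bool(value >= criterion.threshold)


def ratchet_run(
    s: Scenario,
    reset_R_freq: float = 0.005,
    criterion: EstablishmentCriterion = EstablishmentCriterion(),
    clock: str = "from-swap",
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Swap the partner insecticide once, at peak deflection prevalence.

    Runs the scenario, finds the maximum deflection-allele frequency
    achieved, then starts a fresh run re-initialized at that deflection
    prevalence with ``reset_R_freq`` resistance alleles (alleles to the new
    insecticide's resistance are rare) in linkage equilibrium, identical
    fitness parameters, and re-equilibrated cohorts.

    ``clock`` controls when the second run is classified: ``"from-swap"``
    (default) applies the criterion ``at_cycle`` cycles after the swap;
    ``"from-start"`` applies it ``at_cycle`` cycles after the *first*
    introduction, i.e. at cycle ``at_cycle - t_swap`` of the second run,
    where ``t_swap`` is the cycle at which deflection peaked.

    Returns ``(first_run, second_run, established)``.
    """
    if clock not in ("from-swap", "from-start"):
        raise ValueError(f"unknown ratchet clock {clock!r}")
    first = run(s)
    d_series = first["allele_D_freq"]
    max_d = float(d_series.max())
    t_swap = int(first.loc[d_series.idxmax(), "cycle"])
    second_scenario = replace(s, init_R_freq=reset_R_freq, init_D_freq=max_d)
    second = run(second_scenario)
    if clock == "from-swap":
        established = classify_establishment(second, criterion)
    else:
        eval_cycle = criterion.at_cycle - t_swap
        if eval_cycle < 1:
            established = False
        else:
            established = bool(
                _deflected_at(second, eval_cycle) >= criterion.threshold
            )
    return first, second, established


@dataclass(frozen=True)
class GridResult:
    """Result of a survival-combination scan.

    ``table`` is long format with one row per (resistant_survival,
    deflected_survival) cell; the value column is ``classification``
    (direct / ratchet / fail) for :func:`grid_scan` or ``min_cor`` (NaN
    where no tested cost establishes) for :func:`min_cor_scan`.
    """

    resistant_values: np.ndarray
    deflected_values: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        for ax in (self.resistant_values, self.deflected_values):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("grid axes must be strictly increasing")
        if len(self.table) != len(self.resistant_values) * len(self.deflected_values):
            raise ValueError("every grid cell must be populated")

    def pivot(self) -> pd.DataFrame:
        """Wide format: deflected survival as rows, resistant as columns."""
        value = self.table.columns[-1]
        return self.table.pivot(
            index="deflected_survival", columns="resistant_survival", values=value
        )


@contextmanager
def _quiet_scan():
    """Silence the ESR-relevance warning: scans visit F_D <= F_S on purpose."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="F_D <= F_S")
        yield


def _axis(rng, step: float) -> np.ndarray:
    lo, hi = rng
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("survival ranges must satisfy 0 <= lo <= hi <= 1")
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


def _cell_scenario(template: Scenario, f_r: float, f_d: float, fitness_transform):
    fit = replace(template.fitness, F_R=f_r, F_D=f_d, F_RD=f_d)
    if fitness_transform is not None:
        fit = fitness_transform(fit)
    return replace(template, fitness=fit)


def grid_scan(
    template: Scenario,
    resistant_range: tuple[float, float] = (0.30, 0.70),
    deflected_range: tuple[float, float] = (0.20, 0.60),
    step: float = 0.01,
    with_ratchet: bool = True,
    criterion: EstablishmentCriterion = EstablishmentCriterion(),
    fitness_transform=None,
    ratchet_clock: str = "from-swap",
) -> GridResult:
    """Classify every (resistant, deflected) survival combination.

    Each cell sets F_R and F_D (and F_RD = F_D, unless ``fitness_transform``
    overrides it, e.g. :func:`blended_fitness`) on the template, runs the
    model, and classifies: ``direct`` if the establishment criterion is met,
    else — when ``with_ratchet`` — ``ratchet`` if a single insecticide swap
    rescues establishment, else ``fail``.  Deterministic and independent of
    cell evaluation order.
    """
    r_vals = _axis(resistant_range, step)
    d_vals = _axis(deflected_range, step)
    rows = []
    with _quiet_scan():
        for f_d in d_vals:
            for f_r in r_vals:
                cell = _cell_scenario(
                    template, float(f_r), float(f_d), fitness_transform
                )
                if classify_establishment(run(cell), criterion):
                    label = DIRECT
                elif with_ratchet:
                    _, _, rescued = ratchet_run(
                        cell, criterion=criterion, clock=ratchet_clock
                    )
                    label = RATCHET if rescued else FAIL
                else:
                    label = FAIL
                rows.append((float(f_r), float(f_d), label))
    table = pd.DataFrame(
        rows, columns=["resistant_survival", "deflected_survival", "classification"]
    )
    return GridResult(r_vals, d_vals, table)


def min_cor_scan(
    template: Scenario,
    cor_values,
    resistant_range: tuple[float, float] = (0.30, 0.70),
    deflected_range: tuple[float, float] = (0.20, 0.60),
    step: float = 0.01,
    criterion: EstablishmentCriterion = EstablishmentCriterion(),
) -> GridResult:
    """Smallest cost of resistance (on F_RD) that rescues each cell.

    For each survival combination and each candidate cost ``c`` in
    ascending order, sets F_RD = F_D - c (resistant-deflected phenotypes
    pay the cost on top of the deflected survival) and reports the first
    ``c`` whose run establishes directly (no ratchet).  Cells where no
    tested cost establishes get NaN.  Costs exceeding F_D are skipped
    (they would imply negative survival).
    """
    cor_values = np.asarray(list(cor_values), dtype=float)
    if np.any(np.diff(cor_values) <= 0):
        raise ValueError("cor_values must be strictly ascending")
    if np.any((cor_values < 0) | (cor_values > 1)):
        raise ValueError("cor_values must lie in [0, 1]")
    r_vals = _axis(resistant_range, step)
    d_vals = _axis(deflected_range, step)
    rows = []
    with _quiet_scan():
        for f_d in d_vals:
            for f_r in r_vals:
                best = np.nan
                for cor in cor_values:
                    if cor > f_d:
                        break
                    fit = replace(
                        template.fitness,
                        F_R=float(f_r),
                        F_D=float(f_d),
                        F_RD=float(f_d - cor),
                    )
                    if classify_establishment(
                        run(replace(template, fitness=fit)), criterion
                    ):
                        best = float(cor)
                        break
                rows.append((float(f_r), float(f_d), best))
    table = pd.DataFrame(
        rows, columns=["resistant_survival", "deflected_survival", "min_cor"]
    )
    return GridResult(r_vals, d_vals, table)


def blended_fitness(f: PhenotypeFitness, w: float = 0.75) -> PhenotypeFitness:
    """Incomplete deflection: F_RD becomes w·F_D + (1-w)·F_R.

    Models resistant-deflected phenotypes that are deflected only a
    fraction ``w`` of the time (or a fraction ``w`` of insecticide-treated
    properties also carrying the repellent), so they enjoy a weighted blend
    of the deflected and resistant survivals.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError("blend weight w must lie in [0, 1]")
    return replace(f, F_RD=w * f.F_D + (1.0 - w) * f.F_R)


def figure4_experiment(
    template: Scenario,
    p_acquire_deflected_values=(0.04, 0.02, 0.01, 0.0),
) -> pd.DataFrame:
    """Relative infectious-bite trajectories across intervention variants.

    Runs a no-intervention baseline, an insecticide-only variant, and the
    combined repellent + insecticide variant at each per-feed infection
    probability for deflected mosquitoes.  Returns per-cycle infectious
    bites as a proportion of the no-intervention run (NaN during the
    baseline's incubation transient), one column per variant.
    """
    base_ts = run(replace(template, intervention_mode="none"))
    out = pd.DataFrame({"cycle": base_ts["cycle"]})
    ins_ts = run(replace(template, intervention_mode="insecticide_only"))
    out["insecticide_only"] = relative_infectious_bites(ins_ts, base_ts)
    for p in p_acquire_deflected_values:
        s = replace(
            template,
            intervention_mode="esr_plus_insecticide",
            infection=replace(template.infection, p_acquire_deflected=float(p)),
        )
        col = f"esr_p_acquire_deflected_{p:g}"
        out[col] = relative_infectious_bites(run(s), base_ts)
    return out
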