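"""Two-locus genotype/phenotype algebra for the evolved-spatial-repellent model.

The model tracks two unlinked, bi-allelic autosomal loci in a mosquito
population: a physiological insecticide-resistance locus (alleles ``r``/``R``)
and a behavioural deflection locus (alleles ``d``/``D``).  Both ``R`` and
``D`` are completely dominant.  This module provides:

* the four gamete haplotypes, nine unphased genotypes and four phenotypes,
  with the total genotype -> phenotype map;
* Mendelian gamete and zygote distributions under free recombination
  (recombination fraction 1/2) and random mating;
* the per-cycle survival algebra that derives the four phenotype survivals
  from a property-level treatment decomposition;
* the mean per-cycle survival of offspring classed by the allele they
  inherit at either locus, in closed form and as a brute-force enumeration
  over all sixteen ordered gamete pairings;
* the allele-spread predicates: whether the deflection (or resistance)
  allele is currently favoured by selection.

Haplotypes are indexed ``0=rd, 1=rD, 2=Rd, 3=RD`` (index = 2*has_R + has_D).
Genotypes are indexed ``3*n_R + n_D`` where ``n_R``/``n_D`` count copies of
the dominant allele, i.e. ``0=rr/dd ... 8=RR/DD``.  Phenotypes are indexed
``0=Susceptible, 1=Resistant, 2=Deflected, 3=ResistantDeflected``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HAPLOTYPES",
    "GENOTYPES",
    "PHENOTYPES",
    "GENOTYPE_PHENOTYPE",
    "GAMETE_MATRIX",
    "PAIR_TO_GENOTYPE",
    "NotApplicableError",
    "HaplotypeProportions",
    "PhenotypeFitness",
    "TreatmentModel",
    "OffspringFitnessSummary",
    "phenotype_of",
    "gamete_distribution",
    "pool_gametes",
    "zygote_distribution",
    "fitness_from_treatment",
    "mean_offspring_fitness_deflection",
    "mean_offspring_fitness_resistance",
    "brute_force_offspring_fitness",
    "deflection_spread_predicate",
    "resistance_spread_predicate",
]

_SUM_TOL = 1e-12

HAPLOTYPES: tuple[str, ...] = ("rd", "rD", "Rd", "RD")
GENOTYPES: tuple[str, ...] = (
    "rr/dd", "rr/Dd", "rr/DD",
    "Rr/dd", "Rr/Dd", "Rr/DD",
    "RR/dd", "RR/Dd", "RR/DD",
)
PHENOTYPES: tuple[str, ...] = (
    "Susceptible", "Resistant", "Deflected", "ResistantDeflected",
)

# copies of the dominant allele carried by each genotype, by locus
GENOTYPE_N_R = np.repeat(np.arange(3), 3)          # 0,0,0,1,1,1,2,2,2
GENOTYPE_N_D = np.tile(np.arange(3), 3)            # 0,1,2,0,1,2,0,1,2

#: genotype index -> phenotype index (R and D both completely dominant)
GENOTYPE_PHENOTYPE = ((GENOTYPE_N_R > 0) + 2 * (GENOTYPE_N_D > 0)).astype(int)

# haplotype allele indicators
_HAP_R = np.array([0, 0, 1, 1])
_HAP_D = np.array([0, 1, 0, 1])


def _build_gamete_matrix() -> np.ndarray:
    """4x9 matrix: column g is the gamete distribution of genotype g."""
    m = np.zeros((4, 9))
    for g in range(9):
        p_r = GENOTYPE_N_R[g] / 2.0
        p_d = GENOTYPE_N_D[g] / 2.0
        for h in range(4):
            pr = p_r if _HAP_R[h] else 1.0 - p_r
            pd = p_d if _HAP_D[h] else 1.0 - p_d
            m[h, g] = pr * pd
    return m


def _build_pair_tensor() -> np.ndarray:
    """(9,4,4) indicator: T[g,i,j]=1 iff gametes i and j unite into genotype g."""
    t = np.zeros((9, 4, 4))
    for i in range(4):
        for j in range(4):
            g = 3 * (_HAP_R[i] + _HAP_R[j]) + (_HAP_D[i] + _HAP_D[j])
            t[g, i, j] = 1.0
    return t


#: Mendelian gamete distributions under free recombination (r = 1/2).
GAMETE_MATRIX = _build_gamete_matrix()
#: collapse of ordered gamete pairs to unphased genotypes.
PAIR_TO_GENOTYPE = _build_pair_tensor()


class NotApplicableError(ValueError):
    """A spread predicate or mean offspring fitness is undefined.

    Raised when the focal allele is absent or fixed, so that the quantity
    has a zero denominator.  Callers must branch on this explicitly rather
    than treating the condition as "no spread".
    """


def _check_distribution(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < -_SUM_TOL):
        raise ValueError(f"{name} has negative entries")
    if abs(float(x.sum()) - 1.0) > 1e-9:
        raise ValueError(f"{name} does not sum to 1 (sum={x.sum()!r})")
    return x


@dataclass(frozen=True)
class HaplotypeProportions:
    """Frequencies of the four gamete haplotypes rd, rD, Rd, RD.

    These are the proportions, among alleles at either locus in the zygote
    pool, of each pairing with the allele at the other locus: ``rD`` is both
    "deflection allele paired with a susceptible allele" (deflection-locus
    view, written [Dr]) and "susceptible allele paired with a deflection
    allele" (resistance-locus view, written [rD]).
    """

    rd: float
    rD: float
    Rd: float
    RD: float

    def __post_init__(self) -> None:
        _check_distribution(self.as_array(), "haplotype proportions")

    def as_array(self) -> np.ndarray:
        return np.array([self.rd, self.rD, self.Rd, self.RD], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "HaplotypeProportions":
        x = np.asarray(x, dtype=float)
        return cls(rd=float(x[0]), rD=float(x[1]), Rd=float(x[2]), RD=float(x[3]))

    @classmethod
    def from_allele_freqs(cls, r_freq: float, d_freq: float) -> "HaplotypeProportions":
        """Linkage-equilibrium pool from the R- and D-allele frequencies."""
        if not (0.0 <= r_freq <= 1.0 and 0.0 <= d_freq <= 1.0):
            raise ValueError("allele frequencies must lie in [0, 1]")
        return cls(
            rd=(1 - r_freq) * (1 - d_freq),
            rD=(1 - r_freq) * d_freq,
            Rd=r_freq * (1 - d_freq),
            RD=r_freq * d_freq,
        )

    # marginal allele frequencies
    @property
    def freq_D(self) -> float:
        """[D-]: frequency of the deflection allele."""
        return self.rD + self.RD

    @property
    def freq_d(self) -> float:
        """[d-]: frequency of the non-deflection allele."""
        return self.rd + self.Rd

    @property
    def freq_R(self) -> float:
        """[-R]: frequency of the resistance allele."""
        return self.Rd + self.RD

    @property
    def freq_r(self) -> float:
        """[-r]: frequency of the susceptibility allele."""
        return self.rd + self.rD

    @property
    def linkage_disequilibrium(self) -> float:
        """D_LD = f(RD) - f(R)·f(D), the standard gametic disequilibrium."""
        return self.RD - self.freq_R * self.freq_D

    def to_json(self) -> dict[str, float]:
        return {"rd": self.rd, "rD": self.rD, "Rd": self.Rd, "RD": self.RD}

    @classmethod
    def from_json(cls, obj: dict[str, float]) -> "HaplotypeProportions":
        return cls(rd=obj["rd"], rD=obj["rD"], Rd=obj["Rd"], RD=obj["RD"])


@dataclass(frozen=True)
class PhenotypeFitness:
    """Per-feeding-cycle survival probability of each phenotype.

    ``F_S`` susceptible, ``F_R`` resistant, ``F_D`` deflected (non-resistant),
    ``F_RD`` resistant and deflected.
    """

    F_S: float
    F_R: float
    F_D: float
    F_RD: float

    def __post_init__(self) -> None:
        for name in ("F_S", "F_R", "F_D", "F_RD"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        """Survivals in phenotype index order (S, R, D, RD)."""
        return np.array([self.F_S, self.F_R, self.F_D, self.F_RD], dtype=float)

    def check_esr_relevant(self) -> None:
        """Warn if deflection is not fitter than susceptibility (F_D <= F_S)."""
        if self.F_D <= self.F_S:
            warnings.warn(
                "F_D <= F_S: deflection carries no fitness advantage over "
                "susceptibility, so a repellent cannot be evolved here",
                stacklevel=2,
            )

    def to_json(self) -> dict[str, float]:
        return {"F_S": self.F_S, "F_R": self.F_R, "F_D": self.F_D, "F_RD": self.F_RD}

    @classmethod
    def from_json(cls, obj: dict[str, float]) -> "PhenotypeFitness":
        return cls(F_S=obj["F_S"], F_R=obj["F_R"], F_D=obj["F_D"], F_RD=obj["F_RD"])


@dataclass(frozen=True)
class TreatmentModel:
    """Property-level decomposition of feeding-related survival.

    ``U`` is per-cycle survival with no treatment; ``I`` the survival
    reduction insecticide causes in susceptible mosquitoes; ``B`` the
    survival reduction caused by being deflected away from a protected
    building; ``Y1..Y4`` the proportions of properties that are untreated,
    insecticide-only, repellent-only, and insecticide+repellent; ``COR1``/
    ``COR2`` the cost-of-resistance survival reductions borne by resistant
    non-deflected and resistant deflected phenotypes.
    """

    U: float
    I: float
    B: float
    Y1: float
    Y2: float
    Y3: float
    Y4: float
    COR1: float = 0.0
    COR2: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.Y1 + self.Y2 + self.Y3 + self.Y4 - 1.0) > 1e-9:
            raise ValueError("property proportions Y1..Y4 must sum to 1")
        for name in ("Y1", "Y2", "Y3", "Y4"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")


def phenotype_of(genotype: int) -> int:
    """Phenotype index of a genotype index; R and D are completely dominant."""
    if not 0 <= genotype < 9:
        raise ValueError(f"invalid genotype index {genotype}")
    return int(GENOTYPE_PHENOTYPE[genotype])


def gamete_distribution(genotype: int) -> np.ndarray:
    """Haplotype distribution of gametes from one genotype.

    Loci re-assort independently (unlinked, recombination fraction 1/2), so
    the unphased double heterozygote emits all four haplotypes at 1/4 and
    phase never matters.
    """
    if not 0 <= genotype < 9:
        raise ValueError(f"invalid genotype index {genotype}")
    return GAMETE_MATRIX[:, genotype].copy()


def pool_gametes(genotype_freqs: np.ndarray) -> np.ndarray:
    """Gamete pool of a population: frequency-weighted mixture of gametes."""
    f = _check_distribution(np.asarray(genotype_freqs, float), "genotype frequencies")
    return GAMETE_MATRIX @ f


def zygote_distribution(
    female_gametes: np.ndarray, male_gametes: np.ndarray
) -> np.ndarray:
    """Unphased genotype distribution of zygotes under random gamete union."""
    f = _check_distribution(np.asarray(female_gametes, float), "female gametes")
    m = _check_distribution(np.asarray(male_gametes, float), "male gametes")
    return np.einsum("gij,i,j->g", PAIR_TO_GENOTYPE, f, m)


def fitness_from_treatment(t: TreatmentModel) -> PhenotypeFitness:
    """Average per-cycle survivals implied by the treatment decomposition.

    Susceptibles contact insecticide in every insecticide-treated property
    (F_S = U - I(Y2+Y4)); resistant non-deflected phenotypes survive
    everywhere bar their cost of resistance (F_R = U - COR1); deflected
    phenotypes are pushed away from every repellent-treated property
    (losing B there) and, lacking resistance, also die at insecticide-only
    properties (F_D = U - I·Y2 - B(Y3+Y4)); resistant deflected phenotypes
    only pay the deflection and resistance costs
    (F_RD = U - B(Y3+Y4) - COR2).
    """
    f_s = t.U - t.I * (t.Y2 + t.Y4)
    f_r = t.U - t.COR1
    f_d = t.U - t.I * t.Y2 - t.B * (t.Y3 + t.Y4)
    f_rd = t.U - t.B * (t.Y3 + t.Y4) - t.COR2
    for name, v in (("F_S", f_s), ("F_R", f_r), ("F_D", f_d), ("F_RD", f_rd)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"treatment model yields {name}={v} outside [0, 1]")
    return PhenotypeFitness(F_S=f_s, F_R=f_r, F_D=f_d, F_RD=f_rd)


@dataclass(frozen=True)
class OffspringFitnessSummary:
    """Mean per-cycle survival of offspring classed by the allele inherited."""

    Fbar_D: float
    Fbar_d: float
    Fbar_R: float
    Fbar_r: float


def mean_offspring_fitness_deflection(
    h: HaplotypeProportions, f: PhenotypeFitness
) -> tuple[float, float]:
    """Closed-form (F̄_D, F̄_d): mean survival of offspring inheriting D or d.

    Offspring are zygotes formed by random union of two draws from the
    haplotype pool ``h`` (the same pool is assumed for newly emerged
    females and the males they mate with); each zygote is weighted by the
    number of copies of the focal allele it inherits.

    F̄_D = F_S + ([Dr][-R] + [DR]) / [D-] · (F_RD - F_S)
               + [Dr][-r] / [D-] · (F_D - F_S)

    F̄_d = F_S + [dR](1 + [dr]/[d-]) · (F_R - F_S)
               + [dr][Dr]/[d-] · (F_D - F_S)
               + ([DR] + [dR][Dr]/[d-]) · (F_RD - F_S)

    where [Dr] ≡ f(rD), [dR] ≡ f(Rd) etc. (locus-view relabellings of the
    same haplotype frequencies).
    """
    dr, Dr, dR, DR = h.rd, h.rD, h.Rd, h.RD
    d_, D_ = h.freq_d, h.freq_D
    _r, _R = h.freq_r, h.freq_R
    if D_ <= 0.0:
        raise NotApplicableError("deflection allele absent: F̄_D undefined")
    if d_ <= 0.0:
        raise NotApplicableError("deflection allele fixed: F̄_d undefined")
    fs, fr, fd, frd = f.F_S, f.F_R, f.F_D, f.F_RD
    fbar_big = fs + (Dr * _R + DR) / D_ * (frd - fs) + Dr * _r / D_ * (fd - fs)
    fbar_small = (
        fs
        + dR * (1.0 + dr / d_) * (fr - fs)
        + dr * Dr / d_ * (fd - fs)
        + (DR + dR * Dr / d_) * (frd - fs)
    )
    return fbar_big, fbar_small


def _swap_loci(h: HaplotypeProportions, f: PhenotypeFitness):
    """Relabel so the resistance locus plays the deflection locus's role.

    Swapping locus roles maps haplotype xy -> yx (rD <-> Rd) and exchanges
    the single-trait phenotypes (F_R <-> F_D); both loci are dominant and
    unlinked, so every formula for the deflection locus applies verbatim to
    the resistance locus after this relabelling.
    """
    h2 = HaplotypeProportions(rd=h.rd, rD=h.Rd, Rd=h.rD, RD=h.RD)
    f2 = PhenotypeFitness(F_S=f.F_S, F_R=f.F_D, F_D=f.F_R, F_RD=f.F_RD)
    return h2, f2


def mean_offspring_fitness_resistance(
    h: HaplotypeProportions, f: PhenotypeFitness
) -> tuple[float, float]:
    """(F̄_R, F̄_r): mean survival of offspring inheriting R or r.

    Obtained from the deflection-locus closed form by the locus-role swap
    (see :func:`_swap_loci`); agrees with the brute-force enumeration.
    """
    try:
        return mean_offspring_fitness_deflection(*_swap_loci(h, f))
    except NotApplicableError:
        raise NotApplicableError(
            "resistance allele absent or fixed: F̄_R/F̄_r undefined"
        ) from None


def offspring_fitness_summary(
    h: HaplotypeProportions, f: PhenotypeFitness
) -> OffspringFitnessSummary:
    fD, fd = mean_offspring_fitness_deflection(h, f)
    fR, fr = mean_offspring_fitness_resistance(h, f)
    return OffspringFitnessSummary(Fbar_D=fD, Fbar_d=fd, Fbar_R=fR, Fbar_r=fr)


def brute_force_offspring_fitness(
    h: HaplotypeProportions, f: PhenotypeFitness, allele: str
) -> float:
    """Oracle for the mean offspring fitness by inherited allele.

    Enumerates all 16 ordered gamete pairings from the pool ``h``; each
    resulting zygote is weighted by (pairing probability x copies of the
    focal allele it carries) and the phenotype survivals are averaged under
    that weight.  Kept deliberately independent of the closed forms.
    """
    if allele not in ("D", "d", "R", "r"):
        raise ValueError(f"unknown allele {allele!r}")
    hv = h.as_array()
    fv = f.as_array()
    copies = {
        "D": _HAP_D,
        "d": 1 - _HAP_D,
        "R": _HAP_R,
        "r": 1 - _HAP_R,
    }[allele]
    num = 0.0
    den = 0.0
    for i in range(4):
        for j in range(4):
            p = hv[i] * hv[j]
            k = copies[i] + copies[j]
            if k == 0 or p == 0.0:
                continue
            g = 3 * (_HAP_R[i] + _HAP_R[j]) + (_HAP_D[i] + _HAP_D[j])
            w = fv[GENOTYPE_PHENOTYPE[g]]
            num += p * k * w
            den += p * k
    if den <= 0.0:
        raise NotApplicableError(f"allele {allele} absent from the pool")
    return num / den


def deflection_spread_predicate(
    h: HaplotypeProportions, f: PhenotypeFitness
) -> bool:
    """True iff selection currently increases the deflection-allele frequency.

    Implements the inequality

        [dr]²/[d-] (F_D - F_S)
            > [dR](1 + [dr]/[d-])(F_R - F_D)
              + ([DR](1 - 1/[D-]) + [Dr]([dR]/[d-] - [-R]/[D-]))(F_RD - F_D)

    which is algebraically identical to F̄_D > F̄_d.  Equality resolves to
    "no spread".  Undefined (raises :class:`NotApplicableError`) when the
    deflection allele is absent or fixed.
    """
    dr, Dr, dR, DR = h.rd, h.rD, h.Rd, h.RD
    d_, D_ = h.freq_d, h.freq_D
    _R = h.freq_R
    if not (0.0 < D_ < 1.0):
        raise NotApplicableError(
            "deflection allele absent or fixed: spread condition not applicable"
        )
    fs, fr, fd, frd = f.F_S, f.F_R, f.F_D, f.F_RD
    lhs = dr * dr / d_ * (fd - fs)
    rhs = dR * (1.0 + dr / d_) * (fr - fd) + (
        DR * (1.0 - 1.0 / D_) + Dr * (dR / d_ - _R / D_)
    ) * (frd - fd)
    return lhs > rhs


def resistance_spread_predicate(
    h: HaplotypeProportions, f: PhenotypeFitness
) -> bool:
    """True iff selection currently increases the resistance-allele frequency.

    Implements the inequality

        [rd](F_R - F_S) + [rD](F_R - F_D)
            + ([rD] + [RD][-d]/[R-] - [Rd][rD]/[r-])(F_RD - F_R)
            > [rd][rD]/[r-] (F_D - F_S)

    identical to F̄_R > F̄_r.  With deflection fixed it reduces to
    F_RD > F_D; with deflection absent, to F_R > F_S.
    """
    rd, rD, Rd, RD = h.rd, h.rD, h.Rd, h.RD
    r_, R_ = h.freq_r, h.freq_R
    _d, _D = h.freq_d, h.freq_D
    if not (0.0 < R_ < 1.0):
        raise NotApplicableError(
            "resistance allele absent or fixed: spread condition not applicable"
        )
    fs, fr, fd, frd = f.F_S, f.F_R, f.F_D, f.F_RD
    lhs = (
        rd * (fr - fs)
        + rD * (fr - fd)
        + (rD + RD * _d / R_ - Rd * rD / r_) * (frd - fr)
    )
    rhs = rd * rD / r_ * (fd - fs)
    return lhs > rhs
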