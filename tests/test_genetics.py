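"""Genotype/phenotype algebra, offspring-fitness equations and spread predicates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from esrsim import (
    GENOTYPES,
    HAPLOTYPES,
    PHENOTYPES,
    HaplotypeProportions,
    NotApplicableError,
    PhenotypeFitness,
    TreatmentModel,
    brute_force_offspring_fitness,
    deflection_spread_predicate,
    fitness_from_treatment,
    gamete_distribution,
    mean_offspring_fitness_deflection,
    mean_offspring_fitness_resistance,
    phenotype_of,
    pool_gametes,
    resistance_spread_predicate,
    zygote_distribution,
)
from conftest import random_fitness, random_pool

G = {name: i for i, name in enumerate(GENOTYPES)}
H = {name: i for i, name in enumerate(HAPLOTYPES)}
P = {name: i for i, name in enumerate(PHENOTYPES)}


# ---------------------------------------------------------------- phenotypes
@pytest.mark.parametrize(
    "genotype,phenotype",
    [
        ("rr/dd", "Susceptible"),
        ("Rr/dd", "Resistant"),
        ("RR/dd", "Resistant"),
        ("rr/Dd", "Deflected"),
        ("rr/DD", "Deflected"),
        ("Rr/Dd", "ResistantDeflected"),
        ("Rr/DD", "ResistantDeflected"),
        ("RR/Dd", "ResistantDeflected"),
        ("RR/DD", "ResistantDeflected"),
    ],
)
def test_phenotype_map_is_total_with_complete_dominance(genotype, phenotype):
    assert phenotype_of(G[genotype]) == P[phenotype]


# ------------------------------------------------------------------- gametes
@pytest.mark.parametrize(
    "genotype,expected",
    [
        ("Rr/Dd", {"rd": 0.25, "rD": 0.25, "Rd": 0.25, "RD": 0.25}),
        ("RR/dd", {"Rd": 1.0}),
        ("Rr/DD", {"rD": 0.5, "RD": 0.5}),
        ("rr/dd", {"rd": 1.0}),
    ],
)
def test_gamete_distribution_free_recombination(genotype, expected):
    dist = gamete_distribution(G[genotype])
    want = np.zeros(4)
    for hap, p in expected.items():
        want[H[hap]] = p
    np.testing.assert_allclose(dist, want, atol=1e-15)


def test_pool_gametes_mixes_by_frequency():
    freqs = np.zeros(9)
    freqs[G["rr/dd"]] = 0.75
    freqs[G["rr/Dd"]] = 0.25
    pool = pool_gametes(freqs)
    np.testing.assert_allclose(pool, [0.875, 0.125, 0.0, 0.0], atol=1e-15)


def test_pool_gametes_rejects_unnormalized_input():
    with pytest.raises(ValueError):
        pool_gametes(np.full(9, 0.2))


def test_zygote_cross_of_two_haplotypes():
    pool = np.array([0.5, 0.0, 0.0, 0.5])  # rd and RD
    z = zygote_distribution(pool, pool)
    want = np.zeros(9)
    want[G["rr/dd"]] = 0.25
    want[G["Rr/Dd"]] = 0.5
    want[G["RR/DD"]] = 0.25
    np.testing.assert_allclose(z, want, atol=1e-15)


def test_zygote_uniform_pools_factorize_across_loci():
    """Random union of uniform pools gives HWE at both loci, independently."""
    uniform = np.full(4, 0.25)
    z = zygote_distribution(uniform, uniform)
    hw = np.array([0.25, 0.5, 0.25])  # allele freq 1/2 at each locus
    np.testing.assert_allclose(z.reshape(3, 3), np.outer(hw, hw), atol=1e-15)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_zygote_distribution_normalized_for_any_pools(seed):
    rng = np.random.default_rng(seed)
    f, m = rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4))
    z = zygote_distribution(f, m)
    assert abs(z.sum() - 1.0) < 1e-12
    assert np.all(z >= 0)


# ------------------------------------------------------------ treatment model
def test_fitness_from_treatment_full_coverage_matches_reference_survivals():
    t = TreatmentModel(U=0.6, I=0.4, B=0.15, Y1=0, Y2=0, Y3=0, Y4=1)
    f = fitness_from_treatment(t)
    assert (f.F_S, f.F_R, f.F_D, f.F_RD) == pytest.approx((0.20, 0.60, 0.45, 0.45))


def test_fitness_from_treatment_no_intervention_gives_U_everywhere():
    t = TreatmentModel(U=0.7, I=0.0, B=0.0, Y1=0.25, Y2=0.25, Y3=0.25, Y4=0.25)
    f = fitness_from_treatment(t)
    assert f.as_array() == pytest.approx([0.7] * 4)


def test_fitness_from_treatment_susceptible_row():
    t = TreatmentModel(U=1.0, I=0.4, B=0.0, Y1=0.0, Y2=0.5, Y3=0.0, Y4=0.5)
    assert fitness_from_treatment(t).F_S == pytest.approx(0.6)


def test_treatment_model_rejects_bad_property_proportions():
    with pytest.raises(ValueError):
        TreatmentModel(U=0.6, I=0.1, B=0.1, Y1=0.5, Y2=0.5, Y3=0.5, Y4=0.5)


def test_fitness_from_treatment_rejects_out_of_range_survival():
    with pytest.raises(ValueError, match="F_S"):
        fitness_from_treatment(
            TreatmentModel(U=0.3, I=0.4, B=0.0, Y1=0, Y2=0, Y3=0, Y4=1)
        )


# ------------------------------------------------- offspring fitness equations
def test_closed_forms_match_brute_force_oracle_on_1000_random_inputs():
    """The analytic F̄ equations equal the 16-pairing enumeration to 1e-12."""
    rng = np.random.default_rng(8128)
    checked = 0
    while checked < 1000:
        h = random_pool(rng)
        f = random_fitness(rng)
        if not (0 < h.freq_D < 1 and 0 < h.freq_R < 1):
            continue
        fD, fd = mean_offspring_fitness_deflection(h, f)
        fR, fr = mean_offspring_fitness_resistance(h, f)
        assert fD == pytest.approx(brute_force_offspring_fitness(h, f, "D"), abs=1e-12)
        assert fd == pytest.approx(brute_force_offspring_fitness(h, f, "d"), abs=1e-12)
        assert fR == pytest.approx(brute_force_offspring_fitness(h, f, "R"), abs=1e-12)
        assert fr == pytest.approx(brute_force_offspring_fitness(h, f, "r"), abs=1e-12)
        lo, hi = f.as_array().min(), f.as_array().max()
        for v in (fD, fd, fR, fr):
            assert lo - 1e-12 <= v <= hi + 1e-12
        checked += 1


def test_equal_fitness_means_equal_offspring_fitness_and_no_spread():
    rng = np.random.default_rng(7)
    f = PhenotypeFitness(0.37, 0.37, 0.37, 0.37)
    for _ in range(20):
        h = random_pool(rng)
        fD, fd = mean_offspring_fitness_deflection(h, f)
        assert fD == pytest.approx(fd, abs=1e-12) == pytest.approx(0.37)
        assert not deflection_spread_predicate(h, f)
        assert not resistance_spread_predicate(h, f)


def test_offspring_fitness_without_resistance_has_closed_form(baseline_fitness):
    """With no R alleles: F̄_D = F_D and F̄_d = F_S + p(F_D - F_S), p = D freq."""
    p = 0.3
    h = HaplotypeProportions.from_allele_freqs(0.0, p)
    fD, fd = mean_offspring_fitness_deflection(h, baseline_fitness)
    f = baseline_fitness
    assert fD == pytest.approx(f.F_D, abs=1e-12)
    assert fd == pytest.approx(f.F_S + p * (f.F_D - f.F_S), abs=1e-12)


def test_reference_pool_favours_deflection(baseline_pool, baseline_fitness):
    fD, fd = mean_offspring_fitness_deflection(baseline_pool, baseline_fitness)
    assert fD > fd
    assert deflection_spread_predicate(baseline_pool, baseline_fitness)


def test_single_haplotype_oracle_cases(baseline_fitness):
    h = HaplotypeProportions(rd=0.0, rD=1.0, Rd=0.0, RD=0.0)
    assert brute_force_offspring_fitness(h, baseline_fitness, "D") == pytest.approx(
        baseline_fitness.F_D
    )
    h = HaplotypeProportions(rd=0.5, rD=0.0, Rd=0.5, RD=0.0)
    assert brute_force_offspring_fitness(h, baseline_fitness, "R") == pytest.approx(
        baseline_fitness.F_R
    )


def test_zero_marginal_is_signalled(baseline_fitness):
    fixed_D = HaplotypeProportions.from_allele_freqs(0.5, 1.0)
    with pytest.raises(NotApplicableError):
        mean_offspring_fitness_deflection(fixed_D, baseline_fitness)
    no_D = HaplotypeProportions.from_allele_freqs(0.5, 0.0)
    with pytest.raises(NotApplicableError):
        deflection_spread_predicate(no_D, baseline_fitness)
    no_R = HaplotypeProportions.from_allele_freqs(0.0, 0.5)
    with pytest.raises(NotApplicableError):
        resistance_spread_predicate(no_R, baseline_fitness)


# ----------------------------------------------------------- spread predicates
def test_predicates_equal_offspring_fitness_comparison():
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 300:
        h = random_pool(rng)
        f = random_fitness(rng)
        if not (0 < h.freq_D < 1 and 0 < h.freq_R < 1):
            continue
        fD, fd = mean_offspring_fitness_deflection(h, f)
        fR, fr = mean_offspring_fitness_resistance(h, f)
        assert deflection_spread_predicate(h, f) == (fD > fd)
        assert resistance_spread_predicate(h, f) == (fR > fr)
        checked += 1


def test_deflection_predicate_reduces_without_resistance(baseline_fitness):
    """No R alleles: deflection spreads iff F_D > F_S."""
    h = HaplotypeProportions.from_allele_freqs(0.0, 0.4)
    assert deflection_spread_predicate(h, baseline_fitness)
    worse = PhenotypeFitness(F_S=0.45, F_R=0.6, F_D=0.20, F_RD=0.20)
    assert not deflection_spread_predicate(h, worse)


def test_resistance_predicate_reduces_at_deflection_fixation():
    """D fixed: resistance spreads iff F_RD > F_D."""
    h = HaplotypeProportions.from_allele_freqs(0.3, 1.0)
    no_benefit = PhenotypeFitness(F_S=0.2, F_R=0.6, F_D=0.45, F_RD=0.45)
    assert not resistance_spread_predicate(h, no_benefit)
    benefit = PhenotypeFitness(F_S=0.2, F_R=0.6, F_D=0.45, F_RD=0.50)
    assert resistance_spread_predicate(h, benefit)


def test_resistance_predicate_reduces_without_deflection():
    """No D alleles: resistance spreads iff F_R > F_S."""
    h = HaplotypeProportions.from_allele_freqs(0.2, 0.0)
    f = PhenotypeFitness(F_S=0.2, F_R=0.6, F_D=0.45, F_RD=0.45)
    assert resistance_spread_predicate(h, f)
    flat = PhenotypeFitness(F_S=0.6, F_R=0.6, F_D=0.45, F_RD=0.45)
    assert not resistance_spread_predicate(h, flat)


# ------------------------------------------------------------- haplotype pools
def test_haplotype_proportions_marginals_and_views(baseline_pool):
    h = baseline_pool
    assert h.freq_d + h.freq_D == pytest.approx(1.0, abs=1e-12)
    assert h.freq_r + h.freq_R == pytest.approx(1.0, abs=1e-12)
    assert h.freq_D == pytest.approx(h.rD + h.RD, abs=1e-15)
    assert h.freq_R == pytest.approx(h.Rd + h.RD, abs=1e-15)
    assert h.linkage_disequilibrium == pytest.approx(0.0, abs=1e-15)


def test_haplotype_proportions_validation():
    with pytest.raises(ValueError):
        HaplotypeProportions(rd=0.5, rD=0.5, Rd=0.5, RD=0.5)


@pytest.mark.parametrize(
    "obj,cls",
    [
        (HaplotypeProportions.from_allele_freqs(0.1, 0.6), HaplotypeProportions),
        (PhenotypeFitness(0.2, 0.6, 0.45, 0.45), PhenotypeFitness),
    ],
)
def test_json_round_trip(obj, cls):
    assert cls.from_json(obj.to_json()) == obj
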