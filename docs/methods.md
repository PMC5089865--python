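# Methods

## Model structure

`esrsim` models the evolution of a mosquito population exposed to a
combined spatial-repellent + insecticide intervention. Time is discrete;
one unit is one gonotrophic (feeding) cycle. Two unlinked, bi-allelic,
autosomal loci are tracked: resistance (`r`/`R`) and deflection (`d`/`D`),
both with the intervention-relevant allele completely dominant. The four
phenotypes map to per-cycle survivals `F_S`, `F_R`, `F_D`, `F_RD`.

Assumptions, stated once:

1. single-locus dominant control of each trait;
2. loci re-assort freely (recombination fraction 1/2), so unphased
   genotypes suffice — cis and trans double heterozygotes emit identical
   gamete distributions, and the model stores nine genotype states;
3. deflected phenotypes never contact the partner insecticide while the
   repellent is deployed, so resistance confers no benefit on them;
4. mating is random; females mate exactly once, immediately at emergence,
   with males of their own emergence cohort, and store that sperm for life;
5. genotype does not affect juvenile survival;
6. juvenile density dependence fixes the number of adults emerging per
   cycle; only the genotype composition of the delayed zygote pool matters;
7. infection affects neither survival nor fecundity.

A consequence of assumption 4 worth stating explicitly: males mate before
experiencing any feeding-related mortality, so selection is transmitted
through females only, and the per-generation response to selection is half
what a both-sexes model would give. This is deliberate — male mosquitoes
do not blood-feed and are not exposed to indoor interventions.

## Genetics and the spread conditions

Gamete and zygote distributions are exact Mendelian linear maps (a 4×9
gamete matrix and a 9×4×4 pair-collapse tensor). The condition for the
deflection allele to increase is that the mean per-cycle survival of
offspring inheriting `D` exceeds that of offspring inheriting `d`, where
offspring are zygotes from random union of the current haplotype pool and
each zygote is weighted by the number of focal-allele copies it carries.
The module provides closed forms for `F̄_D`, `F̄_d` (and, by exchanging the
roles of the loci, `F̄_R`, `F̄_r`) plus an independent brute-force
enumeration over all 16 ordered gamete pairings; the two agree to 1e-12 on
randomized inputs, and the inequality-form predicates are algebraically
identical to the `F̄` comparisons (verified symbolically during
development). Degenerate pools (focal allele absent or fixed) raise
`NotApplicableError` rather than returning `False`: "cannot spread" and
"nothing to spread" are different answers. Ties resolve to "no spread".

## Treatment decomposition

`fitness_from_treatment` maps the property-level description (`U`, `I`,
`B`, coverage proportions `Y1..Y4`, costs of resistance) to the four
survivals: `F_S = U − I(Y2+Y4)`, `F_R = U − COR1`,
`F_D = U − I·Y2 − B(Y3+Y4)`, `F_RD = U − B(Y3+Y4) − COR2`. The shipped
scenarios use the full-coverage special case `Y4 = 1` (repellent always
deployed with the insecticide), which with `U=0.6, I=0.4, B=0.15`
reproduces the reference survivals 20/60/45/45%. Costs of resistance are
subtractive on per-cycle survival. `U` is identified with the resistant
survival at `COR1 = 0`, and doubles as the pre-intervention survival used
for the no-intervention mode and the initial standing-population size.

## Cohort dynamics

State: adult cohorts indexed by emergence cycle, each an array of
female counts by genotype × infection stage (uninfected, incubating
0..`incubation_cycles`−1, infectious), plus the cohort's stored-sperm
haplotype pool; and a juvenile queue of `development_cycles` zygote
distributions. Event order within a cycle, fixed by this package since
several orders are defensible:

1. per-phenotype survival;
2. the feed: incubating infections advance one cycle, then surviving
   uninfected females acquire infection (probability
   `p_acquire_deflected` for behaviourally deflected phenotypes under the
   combined intervention, `p_acquire_nondeflected` otherwise);
3. infectious surviving feeders emit `count × p_infectious_bite`
   infectious bites (bites are counted *after* the cycle's mortality; this
   choice is recorded in run metadata);
4. every surviving female contributes one clutch unit — her gamete
   distribution crossed with her stored sperm — to the zygote pool, which
   joins the back of the juvenile queue;
5. the front of the queue emerges as `recruits_per_cycle` adults with that
   genotype composition, mated immediately within the cohort (sperm pool =
   the cohort's own gamete pool).

A female infected at the feed of cycle *t* is infectious from the feed of
cycle *t* + `incubation_cycles` inclusive. Egg contribution happens every
cycle (each feeding cycle ends in oviposition). Initialization puts
genotypes at Hardy–Weinberg and linkage equilibrium for the given allele
prevalences, the standing adult population at its pre-intervention
equilibrium `recruits/(1−U)` (ages collapse into one aggregate cohort
because nothing in the model depends on adult age), everyone uninfected,
and the queue filled with the equilibrium zygote distribution.

Intervention modes: `none` (survival `U` for all, nobody deflected),
`insecticide_only` (deflected phenotypes lose protection: `F_D→F_S`,
`F_RD→F_R`), `esr_plus_insecticide` (survivals as given; deflected
phenotypes feed away from protected houses and use the deflected
acquisition probability). Reductions in onward transmission from
outdoor-feeding vectors are represented entirely through
`p_acquire_deflected`; proportional changes in the onward infectious-bite
probability would have an identical effect on the relative-bite metric.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `F_S, F_R, F_D, F_RD` | 0.20, 0.60, 0.45, 0.45 | per-cycle phenotype survivals |
| `init_R_freq, init_D_freq` | 0.005, 0.25 | initial allele prevalences |
| `development_cycles` | 3 | egg → emerging adult, in cycles |
| `incubation_cycles` | 3 | extrinsic incubation, in cycles |
| `p_acquire_nondeflected` | 0.04 | per-feed infection probability |
| `p_acquire_deflected` | 0.04 (0.04/0.02/0.01/0 scanned) | ditto, deflected feeds |
| `p_infectious_bite` | 0.8 | per-feed infectious-bite probability |
| `recruits_per_cycle` | 1000 | sets scale only; proportions and bite *ratios* are scale-free |
| `n_cycles` | 300 | run length |
| establishment threshold | 0.80 at cycle 300 | deflected + resistant-deflected phenotypes |

## Experiments

* **Establishment classification**: deflected-phenotype proportion
  (`Deflected` + `ResistantDeflected`) at cycle 300 ≥ 0.80; ties count as
  established.
* **Ratchet**: run once, find the maximum deflection-allele frequency,
  restart from that prevalence with 0.5% resistance alleles (linkage
  equilibrium, fresh cohorts) and classify the second run. By default the
  300-cycle establishment clock restarts at the swap (`from-swap`); a
  `from-start` clock, which deducts the pre-swap cycles, is available
  behind a flag and recorded in metadata.
* **Grid scans**: resistant survival 30–70% × deflected survival 20–60% in
  1% steps by default (extents configurable; the increments are the
  meaningful part), each cell `F_RD = F_D` unless a transform such as the
  blended-fitness variant (`F_RD = 0.75·F_D + 0.25·F_R`, for incomplete
  deflection) overrides it. Cells failing directly may be retried with the
  ratchet.
* **Minimum-cost-of-resistance scan**: smallest `COR2` (so
  `F_RD = F_D − COR2`) whose run establishes directly; NaN sentinel when
  none of the tested costs works; costs exceeding `F_D` are invalid and
  skipped.
* **Relative infectious bites**: per-cycle bites divided by a
  no-intervention run, for insecticide-only and the combined intervention
  at deflected acquisition probabilities 4, 2, 1 and 0%. Cycles before the
  baseline's first infectious mosquitoes (the incubation transient) are
  NaN-flagged rather than divided through.

## Numerical choices

Everything is double-precision linear algebra on expected counts; there is
no randomness anywhere in the dynamics (seeds appear only in the
property-test scenario generator). Distributions are validated to sum to 1
within 1e-12; neutral runs conserve allele frequencies to better than 1e-9
over 300 cycles. Cohorts whose total count falls below 1e-12 of one
cycle's recruitment are pruned (their mass decays geometrically, so this
truncation is far below the conservation tolerance and keeps a 300-cycle
run at ~60 live cohorts). An empty population is a valid zero-emission
steady state, not an error. CSV output uses 12 significant digits so
re-runs can be compared byte-for-byte.

## What the shipped scenarios do and do not show

The scenario fixtures are the study conditions themselves (they are the
model's inputs, not synthetic approximations of field data): deterministic,
closed, well-mixed populations with constant recruitment and two clean
dominant loci. Passing tests therefore demonstrate the internal logic of
the ESR argument — establishment regions, the ratchet, the
resistance-protection effect — not field performance. Real vector
populations add demographic stochasticity at low allele frequencies,
immigration of non-deflected genotypes, seasonality, polygenic or plastic
behaviour, and age-dependent mortality, all outside this model's scope.

## Known limitations

* Selection through females only (see above): terminal fixation of the
  deflection allele is slow because the susceptibility allele hides in
  heterozygotes — with no resistance and the reference fitness gap, the
  D allele reaches ≈0.95 by cycle 300 (the deflected *phenotype* ≈0.998)
  and approaches 1 on a 1/t trajectory thereafter. Statements about "near
  fixation" in finite time refer to the phenotype.
* Allele frequencies are reported over the standing adult population;
  during the first few cycles after intervention onset the pre-intervention
  juvenile queue dilutes the selected survivors, so adult-level frequencies
  can dip transiently even when selection favours the allele throughout.
* The infectious-bite output is proportional to EIR only under a constant
  human population; no human infection dynamics are modelled.
* One-time ratchet only; multi-swap strategies are not implemented.
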