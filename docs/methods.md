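# Methods

This note documents the model implemented in `batchspawn`, the choices
made where the design was genuinely open, and what the package's tests do
and do not establish.

## Model summary and assumptions

The simulator is an annual-step, individual-based model of a closed cod
population. Within a year, events run in a fixed order: (1) the density
ratio B/K is computed from start-of-year biomass; (2) all fish grow one
von Bertalanffy increment suppressed by the factor max(0, 1 − θB/K);
(3) maturation is evaluated (length ≥ 0.66·L∞, irreversible);
(4) every mature fish spawns as a dam, with one sire drawn uniformly per
dam from the mature pool, and recruits are created; (5) natural mortality
is applied as independent Bernoulli survivals; (6) if fishing is active,
each fish longer than 45 cm is captured with probability F·selectivity(L);
(7) ages increment and fish older than 25 are removed; (8) the annual
record is emitted. The order is a modelling decision — results are
order-sensitive — and is fixed and tested.

Key structural assumptions:

- **Hermaphroditic mating.** Sexes are not modelled; every mature
  individual produces eggs and can also sire. Each recruit credits both
  parents' lifetime ledgers, so in a stationary population the mean
  lifetime recruit count per individual is 2.
- **Independent environmental draws.** The forcing E is a per-batch,
  per-female independent Bernoulli. Batch survivals within and across
  females are independent. Consequently risk spreading reduces the
  *within-female* variance of seasonal output (Var_MBS = Var_SBS/n under
  an equal split at zero cost — a tested law) but leaves the
  population-level expectation of MBS at or slightly below SBS, because
  of the batch-quality costs.
- **Single regulation pathway.** Density dependence acts only on somatic
  growth. Because fecundity and the egg-to-recruit survival are fixed,
  the population can only dissipate its reproductive surplus by slowing
  growth and thereby delaying maturation; at equilibrium, maturation is
  reached around age 13–15 and the age distribution is bottom-heavy.
- Recruits enter at age 0 with length 0; the egg-to-recruit probability
  (applied once, at spawning) covers their first three years, which are
  exempt from the annual natural mortality.
- "Failed spawning season" means a female-season that produced zero
  recruits. The all-batches-died variant is also computable from the
  recorded batch tallies.
- Across-generational fitness assigns cohorts by birth year; only
  finalized cohorts (all members dead by the end of the run) enter the
  geometric mean, and a cohort with zero output forces the geometric mean
  to zero (no epsilon padding).

## Parameters

| Parameter | Default | Units | Source/choice |
|---|---|---|---|
| Loci / allele freq. | 10 / 0.5 | – | smallest architecture giving g ∈ [0, 20] |
| Expression noise s.d. | 3.5 | score | fixed; gives founder h² ≈ 0.29 |
| Score → cm map | 60 + 2·score | cm | calibration: mean unfished L∞ ≈ 80 cm |
| k–L∞ coupling | α = 0.3533, β = −0.65 | – | calibration, see below |
| Weight | 3.52e-6·L^3.19 | kg | empirical length–weight law |
| Fecundity | (0.48(W+0.37)^1.45+0.12)·10⁶ | eggs | empirical, in millions of eggs |
| Batch number | logistic(21.16, 55.0, 10.1) | – | empirical fit, fork length |
| Batch cost slope | 0.00523 | per batch | late-batch quality decline |
| Egg → recruit | 1.13e-6 | – | covers ages 0–2 |
| M immature / cost | 0.15 / +0.1 | yr⁻¹ | instantaneous rates |
| Maturation threshold | 0.66·L∞ | cm | individual-specific |
| Max age | 25 | yr | hard cap |
| Min size / selectivity | 45 cm; logit −12.5+0.25L | – | bottom-trawl curve |
| Stop fraction | 0.15 | – | moratorium trigger |
| K / θ | 4000 kg / 1 | – | calibration, see below |
| Founders / burn-in | 2000 / 5000 yr | – | study design |

## Calibration of the open constants

Two constants are not empirically pinned anywhere and had to be chosen:
the k–L∞ coefficients and the carrying capacity.

**k–L∞.** The coupling is log-log linear with negative slope. Two
requirements drove the calibration. First, *evolutionary stationarity*:
the selection balance between early maturation (favouring small L∞,
because maturation time grows with L∞) and fecundity (favouring large
L∞) should be approximately neutral near 80 cm, so that the unfished
mean phenotype is stable across millennial burn-ins instead of drifting
to dwarfism or gigantism. Second, *depletability*: the strength of the
compensatory response to fishing (density release → faster growth →
earlier maturation → more recruits) is governed by how far the
density-free maturation time sits below the demographically required
maturation delay; with fast growth (k(80) ≳ 0.1) compensation is so
strong that no fishing intensity in the studied range ever drives
biomass to the 15% moratorium threshold. The defaults β = −0.65 and
k(80 cm) = 0.0825 yr⁻¹ — a slow-growing, high-latitude growth regime —
satisfy both: mean L∞ stays near 78–81 cm over 3000-year burn-ins for
both strategies, and every scenario cell of the factorial reaches its
moratorium. Both coefficients are configurable.

**K and θ.** The model description fixes only the functional role
of K (denominator of the density ratio). Because the demographic balance
pins the equilibrium suppression factor, K acts almost purely as a scale
for equilibrium abundance. K = 4000 kg with θ = 1 puts the unfished
equilibrium near the 2000 founders at the mildest forcing (and smaller at
harsher forcing), keeping runs fast without changing dynamics. A pilot
self-calibration was considered and rejected as circular (the pilot
itself needs a K).

## What the generator emulates — and does not

The simulator *is* the data generator: all analyses consume its output.
It reproduces: a stable evolving trait with realistic heritability,
crowding-suppressed growth and late maturation, bet-hedged seasonal
reproduction with whole-batch environmental loss, size-selective removal
with a latched moratorium, and the full 36-cell factorial with
deterministic per-cell seed derivation.

It does not emulate: sexes or mate choice; correlated (population-wide)
environmental catastrophes — each female's batches face independent
draws, so strategy differences at the *population* level arise only
through costs and evolved size structure, not through shared-environment
risk; skipped spawning; sub-annual dynamics; spatial structure; or any
recruitment regulation beyond growth suppression. Passing tests therefore
establish the internal laws of this model, not the behaviour of real cod
stocks under correlated regime shifts.

Two emergent consequences deserve emphasis, because they shape any
comparison with observed stocks or with models that differ in these
respects. (i) With fixed fecundity and egg-to-recruit survival, the
stationary age distribution is pinned by the survivorship schedule; its
abundance-weighted mean age is ≈ 5–6 years regardless of parameters, and
realized individual fitness (recruits per mature adult) is ≈ 1 per year.
(ii) With independent environmental draws, the expected seasonal output
of a multiple-batch spawner is never above that of a single-batch
spawner; the strategy's advantage is confined to variance reduction at
the individual level.

## Numerical choices

- Population state is a struct-of-arrays (NumPy); scalar operations and
  the vectorised season share one code path, so the single-female
  contract and the population loop cannot diverge (tested by the
  MBS≡SBS degenerate equivalence at one batch and zero cost).
- Batch counts round half-up with a floor of one; egg splits are equal
  with the remainder on the first batches; phenotypes are truncated below
  at 1 cm; the 45 cm threshold is exclusive; the 15% trigger and the
  maturation threshold are inclusive.
- Seeds: a master seed plus the (strategy, E, F, replicate) tuple feed a
  `SeedSequence`, giving every cell an independent, individually
  reproducible stream; rerunning a cell standalone is bit-identical to
  the cell inside the full experiment.
- Extinction (zero abundance) terminates a run with a flagged record;
  metrics treat missing phases as missing values.
- Burn-in records are thinned (default every 50th year) to bound output.

## Problem sizes

The full study design (5000-year burn-ins, 50 replicates × 36 scenarios)
is hours of CPU. The package's own reduced scale — 800-year burn-ins and
5 replicates in `scripts/acceptance.py`, 500 years and 3 replicates in
the acceptance tests — was chosen so that burn-ins are long enough for
demographic equilibration and approximate evolutionary stationarity
(trait drift over 500–1000 years is ≈ 1 cm) while a full factorial
completes in minutes. Statistics that are maxima or medians over
scenarios are noticeably noisier at this replication than at the full
scale.

## Known limitations

- Mean L∞ wanders slowly (neutral drift around the calibrated balance
  point) on multi-millennial horizons; very long burn-ins can shift the
  pre-fishing trait by a few centimetres.
- Fitness recovery after the moratorium tends to overshoot its
  pre-fishing value in scenarios where biomass rebuilds quickly, because
  cohorts born into a depleted population realize above-replacement
  output; the recovery percentage is therefore sensitive to how much of
  the post window the rebuild occupies.
- At the harshest forcing (E = 0.30) equilibrium populations are small
  (hundreds of fish); combined with F = 0.3 the post-moratorium trough
  occasionally approaches demographic extinction, which is flagged
  rather than prevented.
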