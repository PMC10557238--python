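# Methods

## Overview

`semdrive` simulates the population dynamics of CRISPR homing gene
drives that carry a *self-eliminating mechanism* (SEM): a secondary,
small-molecule-inducible endonuclease engineered into the drive
construct that, once activated, cuts its own target site between direct
repeats so that single-strand annealing (SSA) excises the transgene and
leaves a cut-resistant wild-type allele. The model has three layers:
inheritance (gamete distributions and inheritance cubes), demography (a
stage-structured mosquito lifecycle expressed as a stochastic Petri
net), and simulation (exact, tau-leaping and mean-field samplers with
timed release and spray events), plus an analysis layer producing tidy
ensemble summaries.

## Inheritance model

### Alleles and state machine

The drive locus uses the alphabet W (susceptible wild-type), G (intact
construct), H (construct with activated excision endonuclease), V
(excised, cut-resistant wild-type), optionally S (construct whose
excision target was disrupted by NHEJ; excision-immune), and — depending
on flavor — R (in-frame drive-resistant) and B (out-of-frame broken).
The construct is resolved as a two-step state machine: G → H on
activation (still homing-active: the drive cassette is intact until
excision completes), and H → {V, W, S/H} on resolution in the next
round of gametogenesis. H and S home like G, since the homing cassette
is untouched by activation or by target-site NHEJ. This uses all four
plotted allele classes of the canonical scenario and makes H the
transient pulse visible during spraying.

### Gametogenesis

For each drive-locus allele in a parent, independently:

1. **Homing.** A W allele paired with an active drive allele (G, H or
   S) is cleaved with probability *p* (forced to 0 when the drive is
   inducible and the molecule absent). A cleaved allele is converted to
   G by homologous recombination with probability *q*; with probability
   1−*q* NHEJ yields R with probability ρ and B with 1−ρ (COMPLETE
   flavor), R (REDUCED), or the lethal token B (SIMPLIFIED). ρ defaults
   to 1/3 (one reading frame in three restores function); it is
   configurable.
2. **Meiosis.** One allele per locus is drawn uniformly; loci assort
   independently. Because each allele transforms independently, the
   per-locus gamete marginal is the average of the two transformed
   allele distributions.
3. **Excision** (skipped when the SEM is inducible and the molecule is
   absent, and — in trans designs — when the parent carries no copy of
   the element E). Each G in the gamete pool becomes H with probability
   *a*; each parental H resolves to V with probability *b·c*, W with
   *b·(1−c)*, and with probability 1−*b* the NHEJ branch yields S when
   SEM resistance is modelled, otherwise the allele stays H and
   re-resolves next generation (this keeps probability mass conserved
   without enlarging the alphabet; the documented alternative of
   routing that mass back to G is not used). Newly activated H does not
   resolve within the same gametogenesis.

The serialization — homing first, then activation of gametes, then
resolution of parental H — is one defensible ordering of the two
mechanisms; it is fixed so results are exactly reproducible, and the
Monte-Carlo oracle in the test suite implements the same ordering by
direct simulation.

### Designs, flavors, lethality

Five chromosomal arrangements are built: cis-acting autosomal,
cis-acting X-linked, and three trans arrangements (the excision element
E sits at its own locus and is inherited Mendelianly; excision of drive
alleles requires at least one parental copy of E and uses the same
(*a*, *b*, *c*)). X-linked loci are hemizygous in males (one allele
plus a Y placeholder token, which is never counted as an allele).
Offspring sex follows the sex-chromosome content for X-linked designs
and an even coin (configurable φ) otherwise.

In the SIMPLIFIED flavor, NHEJ at the drive locus "leads to an unviable
genotype": this is modelled with an explicit lethal allele B carried in
the cube's offspring axis with viability 0 (zygote-level death, applied
at the egg stage). Keeping the mass explicit means every cube row sums
to exactly 1 and conservation is testable; the lethality is applied by
thinning oviposition with the viability vector. Parent axes enumerate
only viable genotypes. Fitness/fecundity of G, H, S, R and B default to
neutral (multiplier 1); the viability vector is the hook for costs.

Genotype labels sort alleles alphabetically within each locus and join
loci in fixed order (drive locus first); male sex-linked genotypes end
in "Y". Enumeration order is deterministic and stable.

## Lifecycle model

Egg, larva and pupa stages have Erlang-distributed dwell times
(`n` sub-stages at rate `n/t` each). Defaults: β = 32 eggs/female/day,
t_E = 1, t_L = 14, t_P = 1 days with n = 2 sub-stages each, μ_E = μ_P
= 0, baseline larval mortality μ_L = 0.1/day with crowding factor
(1 + N_L/K), adult mortality μ_M = μ_F = 0.123/day (≈8-day lifespan),
mating rate ν = 1/day (near-instant), φ = 0.5. These are typical
warm-climate vector values that make a two-year horizon meaningful; all
are configurable.

Females mate once and store the mate's genotype; oviposition draws
offspring genotypes from the active inheritance cube row for the
(female, mate) pair, thinned by viability. Mate genotype is drawn
proportional to current adult male counts. Unmated females are a
short-lived transient (expected ~1 day at ν = 1 against an 8-day
lifespan) and carry no death transition; adult mortality acts on males
and mated females. The inducer molecule state is global and binary:
"daily spraying" is approximated as sustained induction over the
window, implemented as a molecule-on cube that replaces the off-cube at
oviposition for the duration of the window.

### Carrying capacity and equilibrium

At demographic equilibrium the replacement condition
φ·β·s_E·s_L·s_P = μ_F pins the larval through-survival s_L, hence the
equilibrium larval death rate d\* = r_L·(s_L^(−1/n_L) − 1) with
r_L = n_L/t_L — independent of K. Every compartment is then linear in
K, so the K holding a target adult census (unmated + mated females +
males) solves in closed form; no root-finding is needed, and doubling
the target doubles K exactly. A population below replacement
(R0 ≤ 1 at zero density) raises a parameter error reporting R0. The
"2000 mosquitoes" of the canonical scenario is interpreted as total
adults of both sexes at equilibrium, which is what the adult allele
proportions are computed over.

The returned equilibrium state is an exact fixed point of the
mean-field equations (verified to relative derivative < 1e-6 in the
tests) and is rounded to integers to initialize stochastic runs.

## Stochastic Petri net and samplers

Every transition is a competing Poisson process whose hazard is a rate
constant times the token count of its *first input place*, optionally
times a state factor (larval crowding, mate share). Categorical
outcomes are expanded into separate transitions (one oviposition
transition per mated-pair × viable offspring genotype; one mating
transition per female × male genotype), except adult emergence, which
is a single transition with a probabilistic female/male output split.
Mated-female places are catalytic inputs to oviposition (consumed and
returned), so egg-laying is never throttled by token capping.

**Sparsity-aware hazards.** Because all hazards are multiplicative in
the first input count, a transition whose first input place is empty is
disabled with hazard exactly zero; sparse mode skips the hazard
computation entirely and counts the skip, dense mode evaluates
everything. The two modes return identical vectors, and since all
randomness is a function of the hazard vector, same-seed trajectories
are bit-identical between modes. The runtime benefit is asserted as
skip counts, not wall-clock, since speedups are hardware-dependent.

**Samplers.**

* *Direct* (Gillespie): exponential waiting time at the summed rate,
  transition chosen proportional to rate. Exact; used for
  small-population validation (it reproduces the harmonic-sum mean
  extinction time of a pure-death chain and exponential inter-event
  times).
* *Tau-leaping*: each transition fires Poisson(hazard·dt) times per
  step. Firings are applied simultaneously through the net
  stoichiometry; if any count would go negative the step falls back to
  sequential processing in fixed transition order with per-place
  capping. At the default step and population scale the fallback
  essentially never triggers, so the documented capped semantics and
  the fast path coincide.
* *Mean-field*: classical RK4 on the expected flows with real-valued
  states, used for equilibria and verification.

**Time step.** The default tau-leap step is dt = 0.1 day (recording
daily). The equilibrium larval per-capita hazard is ≈1.6/day under the
default lifecycle rates (the crowding death rate that enforces ~0.8%
larval survival), so a 1-day leap would violate hazard·dt ≪ 1 and
distort stage throughput; dt = 0.1 keeps per-token event probabilities
≈0.16 and the tau-leap ensemble mean agrees with the mean-field
trajectory to well within Monte-Carlo error. The RK4 default is
dt = 0.25 day.

**Events and reproducibility.** Releases add tokens at exact times
(the preset releases intact-construct GG males — the molecule is absent
at release time, so released constructs are not yet activated; the
genotype is configurable). Spray windows are half-open [start, end).
Ensembles use one seed per repetition (base seed + repetition index).

## Canonical scenario

Cis-acting autosomal construct, simplified flavor, excision inducible:
p = 0.5, q = 1.0, a = 0.5, b = 1.0, c = 1.0; 2000-adult equilibrium;
four weekly releases of 100 GG males at days 91/98/105/112 ("~3
months"); molecule window [365, 547) ("~6 months" from the 1-year
mark); horizon 730 days; 100 repetitions by default (tests and the
acceptance script use 20 to stay inside their runtime budgets, which is
ample for ensemble-mean statements at this effect size).

## Analysis conventions

Allele accounting covers living adults only, each contributing its own
somatic genotype once: stored mate genotypes and aquatic stages are
excluded by default (both toggleable), matching what an adult field
survey would see; Y tokens are never counted. Proportions divide by
all counted alleles (the full alphabet) for the selected sex set, so
proportions over the full alphabet close to 1 exactly. "95% quantiles"
are the central empirical interval: 2.5%/97.5% order statistics with
linear interpolation; median, mean, min and max complete the statistic
set. Output is one row per (time, sex, feature, statistic).

## What the generator does and does not emulate

Synthetic scenarios capture overlapping generations, demographic
stochasticity, density-dependent larval regulation, mating structure
and inducible genetics in a single well-mixed node. They do not model
spatial structure or migration, seasonality or weather-driven rates,
maternal deposition of nuclease, fitness costs (available as hooks but
neutral by default), remating, or human–vector disease transmission.
Passing tests therefore demonstrate internal correctness and the
qualitative mechanism (sweep, induced elimination, wild-type
restoration), not field-level quantitative prediction.

## Numerical choices and degenerate inputs

* Cube rows conserve mass to < 1e-10 (achieved exactly up to float
  rounding); gamete distributions to 1e-12.
* Zero total hazard advances the clock to the horizon (absorbing
  states terminate cleanly).
* Tau-leap capping order is the fixed transition construction order;
  the reconciliation of a capped emergence count with its pre-drawn sex
  split favours the drawn female count within feasibility.
* Mean-field states are clipped at zero after each RK4 step (guards
  against −1e-16 undershoot; pure-transfer systems conserve mass to
  1e-12).
* The equilibrium solver raises on non-positive targets and on
  below-replacement parameters rather than returning a collapse state.

## Known limitations

* The molecule state is global and binary; pharmacokinetics of decay
  between daily sprays are not modelled.
* Whether partial excision products retain homing is not
  experimentally settled; the H-homes-like-G choice is documented
  above and isolated in one code path.
* The trans-acting element E is never itself driven.
* Single node only; the ensemble runner is embarrassingly parallel but
  scheduling is left to the caller.
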