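# semdrive

Stochastic simulation of **self-eliminating, small-molecule-inducible
CRISPR gene drives** in closed mosquito populations.

A homing gene drive converts heterozygotes toward drive homozygosity
and can sweep a vector population, but an autonomous transgene that
persists indefinitely is an ecological liability. A *self-eliminating
mechanism* (SEM) couples the drive to a second, chemically inducible
endonuclease whose target site sits inside the construct between
engineered direct repeats: applying the inducer activates the
endonuclease, the construct is excised by single-strand annealing, and
a *cut-resistant wild-type allele* (V) remains. The drive can therefore
be released, allowed to spread, and later removed by spraying — leaving
a population that is wild-type in phenotype and immune to re-invasion.

`semdrive` is a library (with a thin CLI) for exploring such designs:

* **Inheritance cubes** — offspring-genotype probability tensors
  P(offspring | mother, father) for five construct arrangements
  (cis/trans, autosomal/X-linked) × three model flavors (with/without
  resistance alleles), with and without the inducer molecule. Gametes
  follow the branching process: cleavage with probability *p*, homing
  repair with *q*, excision with *a*, SSA resolution with *b*, and
  cut-resistant outcome with *c*.
* **Lifecycle model** — egg/larva/pupa/adult stages with
  Erlang-distributed dwell times, density-dependent larval mortality
  μ_L(1 + N_L/K), once-mating females, and a closed-form solver for the
  larval density parameter K that holds a target adult census.
* **Samplers** — the lifecycle is a stochastic Petri net simulated as
  competing Poisson processes: Gillespie direct, tau-leaping and a
  mean-field ODE integrator, all with *first-order sparsity-aware*
  hazard evaluation (transitions rooted in an empty place are skipped,
  provably without changing the result).
* **Events and analysis** — timed adult releases and spray windows;
  long-format ensemble summaries (max, min, mean, median, central 95%
  empirical band) over alleles or genotypes, sex-specific, ready for
  ggplot2/seaborn.

## Worked example

```python
import semdrive as sd

spec  = sd.DesignSpec("CIS_AUTO", "SIMPLIFIED", inducible_sem=True)
drive = sd.DriveParams(p=0.5, q=1.0)   # cleavage 50%, HR 100%
sem   = sd.SemParams(a=0.5, b=1.0, c=1.0)

cube = sd.build_cube(spec, drive, sem, molecule_present=False)
print(dict(zip(cube.offspring_genotypes, cube.row("GW", "WW"))))
```

A drive-heterozygote mother × wild-type father yields

```
GW: 0.7500,  WW: 0.2500
```

— 75% drive transmission instead of the Mendelian 50%, the
super-Mendelian bias (extra p·q/2 = 0.25) that powers the sweep.

The full release-then-eliminate scenario
(`python examples/03_release_and_elimination.py`, a 5-repetition
ensemble of the bundled preset) prints:

```
ensemble-mean adult allele proportions (5 repetitions):
  day       W       G       H       V
    0   1.000   0.000   0.000   0.000
  100   0.944   0.056   0.000   0.000
  200   0.448   0.552   0.000   0.000
  364   0.004   0.996   0.000   0.000
  420   0.001   0.132   0.127   0.740
  500   0.001   0.007   0.006   0.986
  547   0.000   0.002   0.001   0.997
  730   0.000   0.000   0.003   0.997
```

Releases of 100 drive-homozygous males in weeks 14–17 drive G to
near-fixation by day 364; the inducer window (days 365–547) activates
the excision machinery (the transient H pulse) and converts the
construct to the cut-resistant wild-type V, which ends near 1 — the
drive is gone and the population restored.

Other examples: `01_inheritance_cube.py` (cube construction and
validation), `02_population_equilibrium.py` (carrying capacity and
equilibrium), `04_ensemble_summary.py` (tidy summary tables),
`05_sparse_sampling.py` (sparsity-aware hazards).

## Command line

```bash
semdrive preset sem-release --out scenario.json
semdrive build-cube --config scenario.json --out cube/
semdrive simulate --config scenario.json --reps 20 --seed 1 --out runs/
semdrive summarize --runs runs/ --features G,W,H,V --out summary.csv
```

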