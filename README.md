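# talekit

Tolerance adaptive laboratory evolution (TALE), end to end: simulate it,
control it, and analyze it.

Industrial pretreatment of lignocellulosic biomass with ionic liquids (ILs)
leaves residual IL in the sugar stream, and imidazolium ILs are toxic to the
*E. coli* chassis strains used for downstream fermentation. TALE addresses
this by serially passaging parallel batch cultures while a feedback
controller ratchets the stressor concentration upward as the population's
fitness recovers — strong selection without crashing the culture. The
campaign ends with isolate screening and whole-genome resequencing, where
*convergent* mutations (same gene hit independently, many times) point at
the causal tolerance loci.

`talekit` implements that whole loop as a tested Python package, aimed at
people who design or analyze automated evolution campaigns:

- **`talekit.simulate`** — a stochastic serial-passage population simulator:
  lineage-level bookkeeping with exponential batch growth under a
  dose-dependent stressor, Poisson mutation arrivals over cell divisions,
  binomial 1:100 bottlenecks, and frequency-weighted endpoint isolate
  sampling. It stands in for the wet-lab cultures and provides ground truth
  for the analysis stages.
- **`talekit.controller`** — the TALE feedback rule: pass at plate OD600
  0.3, escalate by a fixed step (default 0.75 % w/v) once the fitted growth
  rate is ≥ 0.15 h⁻¹ for a window of consecutive flasks, and on an
  over-stressed crash revert to the previous concentration with a halved
  step.
- **`talekit.growth`** — growth-curve kinetics: semi-log OLS rate fits with
  heteroscedasticity-robust standard errors, lag time, final OD,
  plate↔benchtop OD conversion (ratio 4.2), green-pixel calibration curves,
  and cumulative cell divisions (CCD).
- **`talekit.mutations`** — breseq-style mutation tables in, key mutations
  out: region canonicalization, hypermutator flagging and exclusion, and
  the recurrence rule (≥ 2 unique alleles in a region, or hits from ≥ 2
  independent populations), with "combined" vs "strain-specific"
  categories.
- **`talekit.screening`** — replicate %RSD statistics, genotype clustering
  (identical / Jaccard-similar), the best-clone decision rule, and
  per-condition endpoint aggregation.
- **`talekit.datasets`** — packaged worked-example fixtures: the endpoint
  table of a published 16-population campaign (two strains × two ILs) and
  its key-mutation catalogue.

## The model in brief

A lineage with tolerance *T* grows at concentration *C* at rate

    r(C) = r_max · max(0, 1 − (C/T)^h)

so growth ceases at *C* ≥ *T*. Beneficial mutations arrive as a Poisson
process with mean *μ_b* × (divisions) and multiply *T* by 1 + Exp(mean
`effect_mean` − 1); passaging transfers each lineage binomially at the
dilution ratio. Growth rates are estimated as the slope of ln OD vs time by
OLS in a fixed OD window, which is also what gates the controller's
escalations.

## Worked example

Evolve four independent populations under default conditions, sample three
endpoint isolates from each, and run the convergence analysis:

```python
from talekit.campaign import run_campaign

c = run_campaign(seed=11)
print("final concentrations (% w/v):", [round(f, 2) for f in c.final_concs])
print("increases per population:", [r.state.n_increases for r in c.runs])
print("crashes per population:  ", [r.state.n_crashes for r in c.runs])
for s in c.summaries:
    if s.category != "not-key":
        print(f"key region {s.region:10s} {s.category:15s} alleles={s.unique_alleles} "
              f"isolates={s.isolate_count} populations={len(s.populations)}")
```

prints

```
final concentrations (% w/v): [3.38, 5.25, 4.88, 5.62]
increases per population: [4, 10, 9, 11]
crashes per population:   [1, 1, 1, 1]
key region fhuA       strain-specific alleles=4 isolates=9 populations=3
key region mdtJ/tqsA  strain-specific alleles=4 isolates=9 populations=3
key region rpoC       strain-specific alleles=5 isolates=9 populations=3
key region yhdP       strain-specific alleles=3 isolates=9 populations=3
key region rho        strain-specific alleles=4 isolates=6 populations=2
```

Every population started at 1.5 % (w/v) and ended 2–4× higher after a
handful of controller escalations (each run also hit one over-stress crash
and recovered with a smaller step). All five causal regions seeded into the
simulator were recovered as key mutations, and none of the 45 neutral decoy
regions was falsely called.

The same loop is available from the shell:

```bash
talekit run-tale --seed 11 --out out/
# -> 4 increase(s), 1 crash(es), final concentration 3.38% (w/v)
talekit summarize-conditions --out conditions.tsv
```

`summarize-conditions` (on the packaged endpoint table by default) prints
per-condition means that match the published values, e.g. MG1655 on
[C4C1Im]Cl: mean end concentration 5.7 ± 0.6 % (w/v), and a minimum
fold-increase across the four conditions of 3.0 — the "threefold or
greater" tolerance gain.

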