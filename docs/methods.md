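# Methods

This note documents the models, parameter choices and numerical decisions
behind `talekit`, and what the synthetic benchmarks do and do not show.

## The evolution model

The simulator tracks a culture as a set of *lineages*: a lineage is the
clonal descendance of one mutational event, carrying an identifier, a
mutation set, a tolerance (the stressor concentration at which its growth
stops), and a cell count. Within a flask, growth is deterministic per
lineage; stochasticity enters through mutation arrivals and bottleneck
sampling. This keeps 10⁹–10¹⁰-cell cultures desk-scale while preserving the
population-genetic structure the downstream analyses assume (selective
sweeps, clonal interference between beneficial lineages, hitchhiking of
neutral alleles, drift at each 1:100 passage).

**Dose response.** A lineage with tolerance *T* grows at

r(C) = `r_max` · max(0, 1 − (C/T)^`hill`)

This is the simplest monotone family with the two properties the analyses
rely on: full growth at zero stress and growth ceasing at the tolerance
concentration. `hill` defaults to 1 (linear decline); higher values
sharpen the shoulder.

**Batch growth and passage.** Each flask starts from the transferred
inoculum and integrates Σᵢ nᵢ·exp(rᵢ t) until the culture reaches the
passage threshold (plate OD600 0.3) or the crash timeout (72 h) elapses.
The flask duration is found by scalar root-finding on the monotone total;
lineage sizes at passage are exact exponentials, so a mutation-free flask
is fully deterministic (a rate-ln 2 lineage exactly doubles in an hour).
The OD trace is sampled on a 0.5 h grid plus the passage instant. Cells
convert to OD via `cells_per_od` (cells·mL⁻¹ per benchtop OD unit) and the
4.2 benchtop:plate ratio.

**Mutation arrivals.** Over a flask, a lineage performs (end − start) cell
divisions (net new cells ≈ divisions; death is ignored). Beneficial and
neutral mutations arrive as Poisson processes with means `mu_b` × divisions
and `mu_n` × divisions. Each arrival founds a child lineage carrying one
new, globally unique allele in a region drawn uniformly from the causal or
neutral menu; mutation types are drawn SNP/DEL/INS/MOB at 50/25/15/10 %.
Arrival times follow the division-density within the flask (e^{rt} uniform
between 1 and the flask's growth factor), and the child then grows at its
own rate for the remainder of the flask. Beneficial arrivals multiply
tolerance by 1 + Exp(`effect_mean` − 1) — multiplicative, diminishing-return
steps with occasional large draws.

**Bottleneck.** Each lineage's transferred count is Binomial(n, dilution);
zero-count lineages are dropped. A crash re-uses the previous inoculum
(re-seeding from the last healthy flask).

**Isolate sampling.** Endpoint isolates are lineages drawn with probability
proportional to cell count — the analogue of picking random colonies from a
plated endpoint population. Each isolate's mutation table lists every
allele its lineage carries.

## Default parameters and their calibration

| parameter | default | units | rationale |
|---|---|---|---|
| `r_max` | 0.7 | h⁻¹ | typical *E. coli* glucose-minimal maximum |
| `ic50_wt` | 2.5 | % w/v | wild-type growth stops near 2.5 %; gives starting rates ≈ 0.2–0.3 h⁻¹ at the 1.5 % starting concentration, matching the worked-example endpoint table |
| `hill` | 1 | — | simplest monotone decline |
| `mu_b`, `mu_n` | 1e-10 | per division | effective rates of *callable* mutations, not genome-wide rates; see below |
| `effect_mean` | 1.1 | — | mean 10 % tolerance gain per beneficial mutation; see below |
| `cells_per_od` | 1e9 | cells·mL⁻¹·OD⁻¹ | order-of-magnitude *E. coli* convention; exposed as a knob because no measured calibration is available, so CCD magnitudes are order-of-magnitude context only |
| `volume_ml` | 15 | mL | working volume of a tube-scale ALE |
| menu | 5 causal / 45 neutral | — | enough causal signal for convergence plus a 9× excess of decoys for false-positive measurement |

`effect_mean` and the mutation rates were calibrated jointly against the
scale of the worked-example campaign (≈ 5 concentration increases and a
3–4× concentration gain over 60–90 flasks, with occasional over-stress
crashes). With large per-mutation effects (e.g. 1.3×) a single sweep
outruns the controller: escalations occur at the window-limited maximum
(every 3 flasks, 20+ per run) and endpoints reach > 10× the start, which
is not what tolerance evolution experiments look like. At `effect_mean` =
1.1 and `mu_b` = 1e-10 each escalation step requires roughly one to two
sweeps, giving 4–10 increases and ≈ 3–5× endpoint concentrations per
70-flask run — the empirically observed regime.

## The controller

Decisions use only observable quantities: the OD trace and fitted rates.

* **Passage** when the latest plate OD ≥ `passage_od` (0.3).
* **Escalate** by `step_pct` (0.75 % w/v) when the last `window_flasks`
  (3) fitted rates at the *current* concentration are all ≥
  `rate_threshold` (0.15 h⁻¹). The window resets on every concentration
  change, so with a zero threshold the controller escalates exactly every
  `window_flasks` flasks (the closed form used in tests). The new
  concentration applies to the next flask's medium, never mid-flask.
* **Crash** when the passage OD is not reached within `crash_timeout_h`
  (72 h): revert to the previous concentration, multiply the step by
  `step_reduction` (0.5), and re-approach. The escalation window length and
  the halving factor are design choices — the source experiments report
  only "a defined period of time" and "a smaller step change" — and both
  are configurable.

## Growth-curve numerics

* **Rate fits** are OLS on (time, ln OD) restricted to ODs in
  [`od_min`, `od_max`] (default [0.01, 0.3] plate units — exponential
  phase below the passage threshold). At least 3 usable points are
  required; non-positive readings in the window are excluded with a
  warning.
* **Standard errors** are heteroscedasticity-robust (HC3). Plate-reader
  noise is approximately constant on the OD scale, so after the log
  transform the residual variance shrinks as the culture grows; classical
  OLS standard errors understate the slope uncertainty in exactly the
  high-leverage early readings, while HC3 is accurate-to-conservative in
  the small samples a single batch curve provides. On exactly exponential
  data the fit is perfect and the reported SE is zero.
* **Lag** is where the fitted exponential crosses the first observed
  density (clamped at 0; undefined for non-growing fits). **Final OD** is
  the maximum of a 3-point running-median smoothed series, robust to
  single-read spikes.
* **CCD** counts net new cells as divisions: per flask,
  (OD_end − OD_start) × 4.2 × `cells_per_od` × volume; the campaign CCD is
  the running sum. Death and the subtracted inoculum are ignored.
* **Green-pixel calibration** is monotone piecewise-linear interpolation
  through the calibration knots, clamped (with a warning) outside the
  calibrated range.

## Mutation analysis decisions

* A *unique allele* is a distinct (position, description, type) triple
  within a canonical region. Intergenic names are canonicalized by sorting
  the flanking gene pair, so "tqsA/mdtJ" and "mdtJ/tqsA" group together.
  A deletion spanning several genes (e.g. a "pntA–tqsA" span) is kept as
  its own region label rather than expanded onto every overlapped gene:
  expansion would let one multi-gene deletion manufacture recurrence
  evidence in each overlapped gene, and the worked-example catalogue
  categorizes such spans as their own rows.
* A region is **key** iff it has ≥ 2 unique alleles or is hit in ≥ 2
  independent populations; isolates from one population share ancestry and
  never count as independent evidence. Key regions seen in ≥ 2 strains are
  **combined**, otherwise **strain-specific**.
* **Hypermutators** are flagged when an isolate's mutation count exceeds
  max(20, 4 × cohort median) — a configurable heuristic standing in for
  the by-inspection calls used in practice (e.g. a 267-mutation isolate
  against a 5 ± 4 cohort); flagged isolates are excluded before key-mutation
  analysis.

## Screening decisions

* %RSD = 100 × sample SD (n − 1) / mean; the reproducibility gate is
  ≤ 20 % on both rate and final OD. The (n − 1) convention is used
  throughout.
* Genotype clusters: exact-set equality → "identical"; single linkage on
  Jaccard ≥ 0.5 → "similar"; otherwise singleton. Labels derive from
  sorted member names, so clustering is order-independent.
* Best clone: within a reproducible cluster, rank by (mean rate desc, mean
  final OD desc, rate %RSD asc); if any member fails the %RSD gate, rank
  by (mean rate desc, mean final OD desc); ties break on the isolate
  label.
* Condition aggregation rounds displayed means/SDs half-away-from-zero at
  one decimal (via the shortest decimal representation, so a 6.05 mean
  prints 6.1); comparisons and fold-increases always use unrounded values.
  Rows may mix strains (for per-liquid flask averages) but never ionic
  liquids; fold increase is defined only when the rows share a starting
  concentration.

## What the synthetic benchmarks show — and what they do not

The end-to-end benchmark (20 seeded campaigns of 4 populations × 3
isolates, 5 causal / 45 neutral regions, ~70 flasks per population) checks
that (i) the controller reliably ratchets concentration upward under
selection, (ii) every causal region observed in two independent
populations is recovered as key, and (iii) neutral hitchhikers essentially
never produce more than one false key region. Problem sizes were chosen so
the full suite runs in well under a minute on one core.

These are *consistency* checks of the pipeline against a generator whose
assumptions it shares. Real campaigns differ in ways the simulator does
not emulate: no death phase or lag physiology, no media/temperature
effects, no clonal sequencing noise or variant-calling errors, labeled
alleles instead of sequences, no mutators arising spontaneously, and
mutation effects that are independent draws rather than epistatic. Passing
benchmarks therefore demonstrates the analysis logic, not wet-lab
performance; the packaged endpoint and key-mutation tables are the
empirical anchors.

## Known limitations

* The 2·SE coverage of the rate fit is intrinsically slightly below 95 %
  for 20-point curves (a t- rather than z-interval, plus residual
  heteroscedasticity); the calibration experiment in
  `scripts/acceptance.py` reports the measured coverage rather than
  asserting a nominal value.
* CCD magnitudes depend linearly on the unmeasured `cells_per_od` and are
  order-of-magnitude context only.
* The controller assumes OD is the only observable; it does not model
  sampling for glycerol stocks or contamination events.
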