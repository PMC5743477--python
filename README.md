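# localadapt

Three-tier statistical tests of local adaptation in reciprocal transplant
experiments, for restoration ecologists and evolutionary biologists asking
whether *local* seed sources really perform best.

A reciprocal transplant experiment grows plant ecotypes (seed origins,
named after their source region) in common gardens located in those same
regions; a plant is **sympatric** when its origin matches its garden region
and **allopatric** otherwise. Whether such data show "local adaptation"
depends heavily on how they are analyzed, and `localadapt` implements the
three standard readings side by side on one tidy table
(`species, garden, ecotype, replicate, biomass`):

1. **Local vs. foreign** — per garden × species cell: one-way model on
   ecotype, Tukey all-pairwise comparisons (studentized range,
   Tukey–Kramer under unequal n), and the strict classification
   *local is best* (local significantly beats **every** nonlocal ecotype)
   vs. *nonlocal is best* (**any** nonlocal significantly beats the local)
   vs. *no difference*.
2. **Sympatric vs. allopatric, per species** — linear mixed model
   `biomass ~ garden + sympatry + (1 | ecotype)`, effect size as the
   percentage difference of sympatric over allopatric plants
   (`100·β_symp/B̂`, with `B̂` the fitted allopatric mean over all
   garden × ecotype combinations).
3. **Sympatric vs. allopatric, across species** — biomass standardized to
   mean 0 / SD 1 within species, then
   `z ~ garden + sympatry + (1 | species:ecotype)`; the sympatry
   coefficient is the general effect in SD units.

Mixed-model inference is simulation-based Bayesian: from the (RE)ML fit,
10,000 posterior draws under a noninformative prior give 95% credible
intervals and the posterior probability `P(sympatric > allopatric)`
(> 0.95 ⇒ local adaptation, < 0.05 ⇒ maladaptation). A resampling check
refits the cross-species model on subsamples of single-species size to
confirm tier-3 conclusions are not a pure sample-size artifact.

A synthetic-data generator reproduces the benchmark multispecies design —
6 species × 4 gardens × 12 replicates, two species restricted to 3
regions: 22 species × garden cells, 984 plants — with a known log-scale
sympatry advantage δ, so power and calibration of all three tiers can be
studied without field data. See `docs/methods.md` for the models,
assumptions, and numerical choices.

## Worked example

Simulate a dataset with a 20% sympatric advantage (δ = ln 1.2) and analyze
it:

```python
import numpy as np
from localadapt import generate_dataset, study_design_config, write_dataset

ds = generate_dataset(study_design_config(np.log(1.2), seed=42))
write_dataset(ds, "demo.csv")
```

```sh
localadapt analyze --input demo.csv --out demo_out --n-permutations 1000 --seed 7
```

prints

```
tier 1: 22 cells classified: {'LOCAL_IS_BEST': 3, 'NO_DIFFERENCE': 15, 'NONLOCAL_IS_BEST': 4}
tier 2 [sp1]: effect +28.9% CI (11.5, 53.4) P(sym>allo) = 0.999 -> LOCAL_ADAPTATION
tier 2 [sp2]: effect +33.3% CI (14.1, 55.4) P(sym>allo) = 1.000 -> LOCAL_ADAPTATION
tier 2 [sp3]: effect +12.7% CI (-2.0, 30.1) P(sym>allo) = 0.950 -> INCONCLUSIVE
tier 2 [sp4]: effect +28.4% CI (11.4, 62.7) P(sym>allo) = 1.000 -> LOCAL_ADAPTATION
tier 2 [sp5]: effect +11.3% CI (-6.8, 31.8) P(sym>allo) = 0.891 -> INCONCLUSIVE
tier 2 [sp6]: effect +29.0% CI (10.3, 56.1) P(sym>allo) = 0.999 -> LOCAL_ADAPTATION
tier 3 [ALL]: effect +0.394 SD CI (0.269, 0.521) P(sym>allo) = 1.000 -> LOCAL_ADAPTATION
resampling (n = 192): sympatric advantage in 99.4% of 1000 permutations
```

Read bottom-up, this is the methodological point in one screen: the same
data that look mostly like "no difference" (15/22 cells) — and even yield
four *maladaptation* verdicts, because one intrinsically vigorous nonlocal
ecotype beats the local one somewhere — show a clear average sympatric
advantage once gardens and ecotype quality are modeled (4/6 species
individually, and decisively across species), and the advantage survives
when the cross-species model is cut down to single-species sample size.
Per-cell CSVs, effect-size tables, the resampling report, and a run log
with all stage seeds land in `demo_out/`.

The same pipeline runs from a YAML config (`localadapt simulate --config
cfg.yaml`), and `localadapt power --delta-grid 0,0.1,0.2 --n-sims 100`
tabulates the detection rates of the three tiers over a grid of true
effects — tier 3 ≥ tier 2 ≥ tier 1 throughout.

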