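# heightmort

**Does tree mortality really increase with height, or does the forest just
change composition as you look upward?**

During severe droughts, remote-sensing studies have reported that tall
trees die at twice the rate of short ones and concluded that tall trees
are intrinsically more vulnerable. `heightmort` implements the
ground-based counter-analysis for mixed forests: estimate drought-window
mortality separately for each taxonomic group × height-class cell, then
use direct standardization to ask whether the pooled height trend
survives once composition is held fixed. In a forest where low-mortality
angiosperms dominate the understory and high-mortality pines the canopy,
pooled mortality can rise with height even though mortality *falls* with
height within almost every group — a Simpson's-paradox reversal.

The package is aimed at forest ecologists and biostatisticians who work
with stem inventories of living and standing-dead trees, and at anyone
who wants a worked, tested example of direct standardization, Bayesian
data augmentation for uncertain event dates, and stratified-mortality
decomposition.

## The model in brief

For height class *i* and groups *t* = 1..x, pooled fractional mortality
is *M_i* = Σ<sub>t</sub> *m<sub>i,t</sub> p<sub>i,t</sub>* (equivalently
total deaths over total population), with Σ<sub>t</sub> *p<sub>i,t</sub>* = 1.
The analysis chain:

1. **Allometry** — each tree's 5-cm DBH class is mapped to a height class
   (5–15 m, 15–30 m, >30 m) by inverting a species-specific
   height–diameter curve, thresholds rounded to the nearest 5-cm class.
2. **Death dating** — gamma distributions of time-since-death, fitted per
   calibration-group × snag-retention-class from trees with known death
   years, give each standing dead tree its probability *q* of having died
   within the drought window (2014–2016) rather than earlier.
3. **Mortality MCMC** — per cell, a logistic model with a latent
   in-window indicator per snag (prior *q*) propagates death-date
   uncertainty into the posterior of *m<sub>i,t</sub>*; three chains ×
   20,000 iterations (5,000 burn-in), Gelman–Rubin convergence checks.
   Start-of-window populations are back-calculated as
   *n₂₀₁₃ = n₂₀₁₆/(1 − m)*, deaths as *d = n₂₀₁₃ − n₂₀₁₆*.
4. **Decomposition** — observed *M_i* versus two counterfactuals:
   constant composition (the whole-population reference) and constant
   focal-group mortality; plus automatic Simpson-reversal detection.

A fully tested synthetic-data module generates inventories, calibration
sets and ground truth with the statistical structure the analysis
assumes, so the entire chain runs and is testable without any data
download. See `docs/methods.md` for model details and limitations.

## Worked example

Run the full pipeline on the default synthetic survey (≈6,300 stems ≥5 m
in 89 plots, three taxonomic groups):

```bash
heightmort -v full --seed 1 --outdir out
```

This writes five CSV tables (`cell_mortality`, `pooled_mortality`,
`composition`, `standardized_mortality`, `diagnostics`) and prints:

```
Pooled 2014-2016 mortality by height class (posterior mean [95% CI]):
    5-15m: M = 0.160 [0.145, 0.175]
   15-30m: M = 0.177 [0.160, 0.196]
     >30m: M = 0.265 [0.232, 0.300]

Per-group mortality (posterior mean [95% CI], n2016):
   non-pinus conifer   5-15m: 0.261 [0.232, 0.290]  n2016=721
          angiosperm   5-15m: 0.089 [0.074, 0.104]  n2016=1454
               pinus  15-30m: 0.337 [0.276, 0.403]  n2016=152
   ...
          angiosperm    >30m: 0.002 [0.000, 0.018]  n2016=61

Counterfactual standardizations:
height_class  M_observed  M_constant_composition  M_constant_pinus_mortality
       5-15m       0.159                   0.189                       0.172
      15-30m       0.177                   0.160                       0.180
        >30m       0.264                   0.165                       0.218

Convergence: max R-hat = 1.0035 (OK)
```

Reading it: pooled mortality climbs from 0.16 to 0.26 (a ~1.7× rise with
height), yet within angiosperms and the non-pine conifers mortality
*falls* with height. Held at constant composition, the hypothetical
pooled mortality no longer rises (0.189 → 0.165): the height trend is a
composition artifact, driven by low-mortality angiosperms thinning out
and high-mortality pines gaining share with height. The
constant-pine-mortality column shows the secondary contribution of the
pines' own rising mortality. Every cell's R-hat is near 1, so the chains
agree.

Other entry points: `heightmort simulate` (inventory + calibration +
truth CSVs), `calibrate` (gamma death-dating fits), `fit`, `decompose`,
`report`; `--smoke` runs a reduced-MCMC end-to-end check in seconds.
Library use mirrors the CLI:

```python
from heightmort import SimConfig, generate_inventory, fit_mortality
```

To analyze real data, point the YAML config's `inventory:` and
`calibration:` paths at CSVs with the documented columns (tree_id,
species, group, dbh_class, status, retention_class; species,
retention_class, death_year, survey_year).

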