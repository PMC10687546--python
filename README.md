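# qwa — quantitative wood anatomy pipeline

`qwa` turns tracheid-level cell measurements (ROXAS-style CSV exports) and
monthly climate into the statistics dendroecologists use to ask whether
tree admixture changes how Scots pine builds its wood under climatic
stress: earlywood/latewood trait chronologies and their bootstrapped
monthly climate correlations, SPEI drought calendars, normalized
intra-annual trait profiles, Gini inequality of those profiles, and
before/during/after drought-legacy comparisons.  A first-class synthetic
data generator emulates the full study design (pure vs mixed stands,
planted droughts, planted group-specific drought effects) so every stage
is testable against known ground truth.

## The quantities at its core

Per tracheid with lumen area *A*, radial/tangential wall thickness and
wall area CWA:

- conduit diameter *d* = 2√(*A*/π); **mean hydraulic diameter**
  DH = Σ*d*⁵ / Σ*d*⁴ (conduits weighted by their hydraulic contribution);
- **cell wall thickness** CWT = (radial + tangential)/2;
- **anatomical density** AD = CWA / (CWA + *A*) ∈ [0, 1].

Each ring is split into 100 equal-width tangential sectors by relative
cell position; sectors are classed earlywood/latewood by Mork's index
*m* = 4·CWT_rad / lumen_diameter (latewood iff *m* ≥ 1, sector majority).
Annual per-tree medians are detrended by a cubic smoothing spline with a
50% frequency response at 30 years (ratio indices), prewhitened with an
AIC-selected AR model, and averaged across trees with the Tukey biweight
robust mean.  Chronologies are correlated with detrended monthly climate
(previous-year March … current October) by Pearson's *r* with
year-resampling bootstrap CIs.  Droughts are years whose 3-month SPEI —
the standard-normal quantile of the PWM-fitted log-logistic CDF of the
3-month climatic water balance *P* − PET — drops below −1.5 in any month
March–October.  Intra-annual profiles are min–max normalized per ring,
compared by Kolmogorov–Smirnov statistics, and their inequality summarized
by the Gini coefficient with percentile and BCa bootstrap intervals.

## Worked example

`examples/` contains one narrative script per capability.  Running
`python examples/05_drought_legacy_and_gini.py` generates a synthetic
study (9 + 9 trees, 62 years, six planted droughts, a 15% post-drought
earlywood-density elevation planted in the pure group only) and prints:

```
before-vs-after AD contrast (year-permutation KS):
group  mean_a  mean_b  d_stat  p_value  significant
 pure   0.401   0.426    0.35    0.003         True
mixed   0.398   0.403    0.13    0.317        False
```

The pure group's normalized AD profile is shifted upward the year after a
drought (mean 0.401 → 0.426, KS D = 0.35, permutation p = 0.003) while
the mixed group — generated without a legacy effect — shows none: the
pipeline recovers exactly the effect that was planted.  The script also
prints the drought/non-drought Gini table with BCa intervals.

The same analysis runs end to end from the shell:

```bash
qwa all --out run_output          # synthetic demo config
qwa simulate --seed 7 --out data/ # just write a synthetic dataset
qwa anatomy --cells data/cells.csv --rings data/ring_widths.csv --out out/
qwa climate --climate data/climate.csv --out out/
```

or from Python via `qwa.io.RunConfig` / `qwa.io.run_pipeline`, which
writes annual traits, sector profiles, SPEI, the drought calendar,
chronologies, correlation tables, legacy KS contrasts, the Gini table and
a JSON run report into the output directory.

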