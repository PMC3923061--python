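# strainscan

Linking gene expression to growth phenotype across a yeast strain cohort.

When 24 natural *Saccharomyces cerevisiae* and *S. paradoxus* strains are
grown on glucose, they all grow fast and alike (growth-rate std/mean ≈ 0.13);
on the non-natural sugar xylulose they grow slowly and diversely (std/mean ≈
0.29), which makes it possible to ask *which gene modules track growth rate
across strains*. Surprisingly, it is not the ribosomal-protein (RP) or
ribosome-biogenesis (Ribi) regulons — the canonical growth-rate reporters
across environments — but the Gcn4-controlled amino-acid biosynthesis (AA)
group whose induction anti-correlates with growth rate on xylulose
(Pearson c ≈ −0.79), echoing the behavior seen across deletion-mutant
compendia (c ≈ −0.36).

`strainscan` re-implements the complete computational chain behind that kind
of study, for anyone analyzing custom multi-probe two-color arrays together
with plate-reader growth curves:

* **`strainscan.simulate`** — a synthetic cohort generator with known ground
  truth: array design (3–4 probes per gene, each printed 3–4 times), strain
  phenotypes with per-carbon-source dispersion, a true expression matrix with
  configurable gene-group/phenotype couplings, probe-level intensities with a
  3′-positional bias, and three-phase OD growth curves.
* **`strainscan.normalize`** — the probe-to-gene normalization pipeline:
  median over replicate placements; per sample, the log-ratio `dy` of each
  probe to its gene's 3′-most probe (`P_last`) as a function of the distance
  `dx`; a Lowess fit of that dy-vs-dx trend, anchored to 0 at `dx = 0` and
  subtracted from all probes; per-gene probe medians; percentile (quantile)
  normalization across samples; and xylulose/glucose log2 ratios.
* **`strainscan.growth`** — log-linear growth fitting: the longest
  high-R² positive-slope window of ln(OD) vs time gives the specific growth
  rate and doubling time `ln 2 / μ`; `cohort_dispersion` gives std/mean.
* **`strainscan.groups`** — GMT gene sets, the ≥14-strains missingness
  filter, per-strain group mean profiles.
* **`strainscan.correlate`** — Pearson correlation with pairwise-complete
  deletion (two-sided t-test, α = 0.01), the systematic group-vs-phenotype
  scan, per-gene pathway classification by correlation sign (|c| > 0.3) and
  induction (|Δlog₂| > 0.2), profile similarity to reference conditions, and
  the RP-vs-AA bimodality quadrant rule.
* **`strainscan.pipeline` / `strainscan` CLI** — simulate → normalize →
  growth → correlate → report as one reproducible, seeded run emitting TSV
  and JSON artifacts.

## Worked example

Simulate a default-structure cohort (12 + 12 strains, two carbon sources,
AA-group coupling −0.79 to growth rate on xylulose) and run the full
pipeline:

```python
from strainscan import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(
    outdir="demo",
    cohort=CohortConfig(
        n_genes=400,
        group_sizes={"AA": 40, "RP": 25, "Ribi": 20, "PPP": 12, "GF": 10, "TCA": 10},
        seed=42,
    ),
)
run_pipeline(cfg)
```

or equivalently `strainscan all --config run.yaml --out demo`. The run writes
`probes.tsv`, `expr.tsv`, `logratio.tsv`, `growth_fits.tsv`,
`correlations.tsv`, `ppp_classes.tsv` and `summary.json`; the summary for the
run above reads

```json
{
  "growth_rate_dispersion": {
    "glucose": 0.15392418358809232,
    "xylulose": 0.2973890388507974
  },
  "top_anticorrelated_group": "AA"
}
```

with the leading scan row

```json
{
  "group": "AA",
  "phenotype": "growth_rate_xylulose",
  "r": -0.749736658,
  "p_value": 2.470461801e-05,
  "significant": true
}
```

Read: growth rates *estimated from the simulated OD curves* disperse ~2×
more on xylulose than on glucose, matching the generator's truth (0.13 vs
0.29 up to 24-strain sampling noise), and the systematic scan singles out the
amino-acid biosynthesis group as the one gene group significantly
anti-correlated with growth rate on xylulose — the configured coupling
(−0.79) recovered at r = −0.75 in this cohort.

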