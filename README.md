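# traitscan

Multi-trait subset scanning for GWAS summary statistics.

Given one genetic variant (or a weighted genetic score) and per-trait
association z-scores across dozens to thousands of traits, `traitscan`:

1. estimates the trait-level z-score correlation under the null (from a panel
   of null SNPs, from individual-level residuals, or supplied directly),
2. decorrelates the z-vector by ZCA-cor whitening (the symmetric inverse
   square root of the correlation matrix, which keeps each whitened score
   maximally correlated with its original),
3. finds the most anomalous trait subset with a **linear-time subset scan**
   under two score functions — **higher criticism** (HC, count of small
   p-values vs. its null expectation) and **truncated chi-squared** (TC, tail
   probability of the sum of squared scores above a threshold) — over a
   geometric grid of 200 thresholds from the Bonferroni level 0.05/p to 0.05,
4. calibrates the maximized statistics against Monte-Carlo null distributions
   (analytic, exact p-values for HC), and combines the two tests by the
   minimum p-value, with the selected subset taken from the winning test.

A PheWAS (per-trait Bonferroni) baseline, a genetic-score extension that
reconstructs score-level Wald statistics from per-SNP summary data plus a
reference panel, and a synthetic-data simulator for power/selection studies
are included.

## Python API

```python
import numpy as np
import traitscan as ts

# correlation from a null-SNP z panel
panel = ts.read_null_panel("null_panel.tsv")
R = ts.estimate_z_correlation(panel)
R = ts.repair_psd(R.R, trait_ids=R.trait_ids, source="null_snps")

# scan one variant
z = ts.read_z_wide("z.tsv")[0]            # or build a ZVector directly
res = ts.scan_and_test(z, R, B=10_000, seed=1)
print(res.p_hc, res.p_tc, res.p_combined, res.winner)
print([res.trait_ids[j] for j in res.s_combined])
```

The null distribution depends only on (p, grid, B, seed) and is cached and
reusable across variants (`ts.simulate_null`, `NullDistribution.to_json`).

## Command line

```bash
traitscan corr  --null-panel panel.tsv --out R.tsv [--pvals pv.tsv --threshold 0.05]
traitscan null  --p 754 --B 10000 --seed 1 --out null_p754.json
traitscan scan  --z z.tsv --cor R.tsv --null-cache null_p754.json --out result.json
traitscan score --weights w.tsv --ref panel.vcf --summary stats.tsv \
                --meta traits.tsv --cor R.tsv --out score.json
traitscan simulate --config scenario.yaml --out report.tsv
```

All file formats are plain text (TSV/JSON/VCF); every run writes a
`<out>.manifest.json` with resolved options, input digests and the seed, and
every subcommand is a pure function of (inputs, seed).

## Notes

- Priority ties are broken deterministically (ascending p\*, descending z\*²,
  then trait index); p-value ties between HC and TC award the combined subset
  to HC.
- The TC tail is evaluated from a seeded, cached Monte-Carlo table (binomial
  mixture over the number of threshold exceedances); a numeric-convolution
  evaluation is available as an independent cross-check. Only monotonicity in
  the subset sum matters for ranking — the outer Monte-Carlo null calibrates
  the statistic.
- `diag_cor` (correlation of each whitened score with its original) is always
  reported; traits below 0.7 are flagged for interpretability. Optional
  pruning of highly correlated traits is exposed (`--max-abs-cor` /
  `prune_correlated_traits`) but off by default.
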