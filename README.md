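# amyglia

Do Alzheimer's-disease GWAS risk genes converge on a single,
amyloid-responsive, microglia-dominated gene-expression module?  `amyglia`
implements the full analysis chain behind that question as a tested,
reusable Python package, exercisable end to end on synthetic data with
known ground truth:

- **2 × 2 interaction differential expression** on bulk RNA-seq from a
  two-strain mouse cohort (an amyloid and a tau model, each with
  age × genotype design): log2-CPM normalization, covariate
  residualization, per-gene OLS contrasts, Benjamini–Yekutieli adjustment,
  and signed log10-p rankings with cross-strain Spearman correlation.
- **Preranked risk-gene enrichment**: nested GWAS gene sets (thresholds on
  the association p-value P_mar) tested with the weighted
  Kolmogorov–Smirnov running-sum statistic, ES/NES and a gene-set
  resampling null.
- **Co-expression modules**: soft-power selection by scale-free fit,
  unsigned adjacency, topological overlap (TOM), average-linkage
  clustering with a static cut, module eigengenes, and Fisher/log-odds
  module enrichment.
- **Exact multi-set intersection test** (hypergeometric convolution in log
  space) for prioritizing genes at the meeting point of module membership,
  risk association and differential expression.
- **Baseline-anchored cell-type shift statistic**
  Z_is = (E_is − mean E_i(WT·4M)) / sd(E_i), averaged over marker sets,
  with a 10,000-draw resampling null and Bonferroni control.
- **Single-microglia state analysis**: QC (reads / mitochondrial fraction /
  doublet cap), log-normalization, signature module scores, homeostatic
  (HM) vs activated (ARM) state assignment, per-group state fractions, and
  ARM-vs-HM Wilcoxon differential expression.
- **Microgliosis-aware deconvolution**: predicted bulk expression
  P_g = M_g · (f_HM μ_HM + f_ARM⁺ μ_ARM⁺) from a marker-based microgliosis
  index M_g and single-cell state fractions/means, with an r² ≥ 0.67
  "explained by microglia" rule and a driver decomposition.

A synthetic-data module generates every input — negative-binomial bulk
counts for 8 groups (2 strains × 2 ages × 2 genotypes, n = 12), a GWAS
association table, GMT marker-set panels for 7 cell types, and 10x-style
single-cell UMI matrices with planted state mixtures — and records the
ground truth for parameter-recovery tests.  See `docs/methods.md` for the
models, defaults and design choices.

## Worked example

```python
from amyglia import pipeline

cfg = pipeline.load_config()          # defaults: 2,000 genes, n=12/group
cfg["seed"] = 1
report = pipeline.run_pipeline(cfg, outdir="amyglia_out")
s = report.summaries
print(s["bulk_de"]["APP"]["age_x_genotype"])
print(s["enrichment"])
print(s["intersection"]["APP"])
print(s["single_cell"]["fractions"]["APP_TG_10M"])
print(s["deconvolution"]["n_explained"], "/", s["deconvolution"]["n_genes"])
```

prints (seed 1):

```
{'n_sig': 240, 'n_up': 232, 'n_down': 8, 'n_total': 2000}
{'APP': {'any_significant': True, 'min_p_adj': 0.00293...},
 'TAU': {'any_significant': False, 'min_p_adj': 1.0}}
{'target_module': 'M1', 'n_prioritized': 111, 'p_upper': 5.47e-165}
{'ARM': 0.5631..., 'HM': 0.4368...}
57 / 59
```

Reading: in the amyloid strain, ~240 genes respond specifically in aged
transgenics (the planted 150-gene program plus responding microglial
markers); the GWAS risk sets enrich in the amyloid strain's interaction
ranking but not in the tau strain's; one co-expression module (`M1`)
captures the program and is significantly enriched for risk genes; the
three-way intersection of module × risk set × DE-significant genes is far
larger than chance (exact upper-tail p ≈ 5e-165); the recovered
activated-microglia fraction in aged amyloid transgenics is ~56%, matching
the planted mixture; and most prioritized genes are flagged as explained
by microglial expression once microgliosis and state shifts are accounted
for.  The same pipeline is scriptable from the shell:

```bash
amyglia run --set seed=1 --outdir amyglia_out
amyglia synthesize --set seed=1 --outdir inputs_only
amyglia report --outdir amyglia_out
```

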