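# glialseq

Bulk RNA-seq differential expression and glial phenotype scoring for
two-group designs.

`glialseq` is built for the analysis that follows quantification in a
small-n bulk RNA-seq comparison — for example, control versus treated
mouse brain tissue with five animals per group. Starting from a gene ×
sample counts matrix it runs:

1. **Expression filtering** — keep genes with raw CPM ≥ 1 in at least the
   smaller group's number of samples.
2. **TMM normalization** (trimmed mean of M-values): per-sample scaling
   factors robust to composition bias, rescaled to geometric mean 1.
3. **log₂-CPM transform** with a prior count:
   `log2((y + 0.5) / (L·f + 1) · 10⁶)`.
4. **Moderated differential expression.** Per gene, a two-group linear
   model gives the log₂ fold change β̂ (treatment − control) and residual
   variance s²_g on d_g = n − 2 df. Empirical Bayes shrinks each variance
   toward a global prior estimated by moment matching on
   `e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2)`, yielding prior df d₀ and prior
   variance s₀², the posterior `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`, and
   the moderated statistic `t_g = β̂/(s̃_g √(1/n₁ + 1/n₂))` on d₀ + d_g df.
   Benjamini–Hochberg adjusted p ≤ 0.05 defines significance, with
   |log₂FC| tiers at 0.5 and 0.25.
5. **Phenotype categorization** — intersect significant genes with
   cell-type marker lists (microglia, astrocyte, oligodendrocyte lineage)
   and assign phenotype categories (homeostatic vs neurodegenerative
   microglia; acute-injury / pan-injury / chronic-neurodegenerative
   reactive astrocytes; OPC/COP/NFOL/MFOL/MOL lineage stages), with a
   0.25 fold-change floor for the microglia scheme.
6. **Average z-score set statistic** — z-score each gene across all
   samples (n−1 sd), average z over a set's genes per sample, and compare
   groups with a pooled-variance two-tailed Student's t-test on
   n₁ + n₂ − 2 df. Sets with fewer than 4 usable genes are reported but
   not tested.
7. **Reports** — PCA (gene-centered), hierarchical clustering on
   1 − Pearson r with average linkage, volcano classification, figures
   and tidy TSVs.

A negative-binomial simulator (variance μ + φμ²; φ = 0 is Poisson) with
planted fold changes, library-size variation and optional composition
bias generates fully ground-truthed datasets, and the package ships the
published categorized glial gene tables it reproduces as worked-example
fixtures.

## Worked example

```python
import glialseq as g

cfg = g.SimConfig(n_genes=2000, dispersion=0.1, effect_log2fc=1.0,
                  frac_de_background=0.05, seed=7)
cm, design, truth, sets = g.simulate_experiment(
    cfg, [("homeo_like", 20, "down"), ("neuro_like", 20, "up"),
          ("null_set", 20, "null")])

res = g.DGEModel(cm, design).fit()
print(res.summary())
panel = g.SetScoreModel(res.expression, design, sets).fit()
print(panel.summary())
```

prints

```
Moderated two-group differential expression
===============================================
genes (post-filter):        2000
samples:                    10 (E vs C)
prior df (d0):              13.73
prior variance (s0^2):      0.2559
residual df per gene:       8
significant (adj p <= 0.05): 22
  ... and |log2FC| >= 0.5:  22
  ... and |log2FC| >= 0.25:  22

Average z-score set panel
===============================================
sets: 3 (3 tested, 0 skipped)

            n_genes  mean_control  mean_treatment      t   p_value direction note
set
homeo_like       20        0.6641         -0.6641 -8.643 2.492e-05      down
neuro_like       20       -0.6772          0.6772   12.9  1.23e-06        up
null_set         20      -0.05326        0.05326  0.688    0.5109        up
```

The empirical-Bayes fit borrowed 13.7 prior degrees of freedom across
genes (each gene alone has 8), 22 genes cleared the 5% FDR with
|log₂FC| ≥ 0.5, and the set panel recovered both planted directional
sets (p < 10⁻⁴, correct signs) while the null set stayed at p ≈ 0.5.

The same stages run from the shell:

```sh
glialseq simulate --seed 7 --outdir sim/
glialseq run --counts sim/counts.tsv --design sim/design.tsv \
    --markers sim/markers.gmt --outdir out/
glialseq fixtures --outdir fixtures/   # packaged worked-example tables
```

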