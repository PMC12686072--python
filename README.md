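# ehbmt — EMT-heterogeneity-based molecular typing of bulk transcriptomes

Epithelial–mesenchymal transition (EMT) is a plastic, heterogeneous program:
within one tumor cohort some samples are firmly epithelial, some firmly
mesenchymal, and many occupy a hybrid state that co-expresses markers of
both. `ehbmt` types bulk gene-expression cohorts (gastric cancer and
adjacent normal tissue being the motivating system) into three phenotype
clusters on the basis of a fixed EMT marker panel:

* **EPC** — epithelial phenotype cluster (epi-high),
* **HPC** — hybrid epithelial–mesenchymal phenotype cluster (epi-medium),
* **MPC** — mesenchymal phenotype cluster (epi-low),

and provides the downstream analyses that make the typing useful: clinical
covariate association (Pearson χ²), paired normal→tumor *traceability*
analysis (which subtype does a patient's tissue convert to during
carcinogenesis?), Kaplan–Meier / log-rank survival comparison, single-cell
E/M ratios, mIHC CDH1/VIM ratio subtyping and marker correlation-block
analysis. A synthetic-cohort simulator with the same statistical structure
makes every stage testable without any data download.

It is aimed at computational biologists who have a gene × sample expression
table (counts, FPKM or pre-normalized) plus sample metadata, and want
reproducible EMT subtype calls and the associated statistics.

## Method

Given expression matrix $X$ (genes × samples) and a marker panel of 22
epithelial and 16 mesenchymal genes:

1. **Normalize** — $\log_2(x+1)$ when the input looks like counts/FPKM
   (matrix max > 50), then per-gene z-scores across samples
   ($z_{gs} = (x_{gs}-\bar x_g)/s_g$, sample sd).
2. **Cluster** — agglomerative clustering of samples with complete linkage
   on the distance $d(i,j) = 1 - r_{ij}$, where $r_{ij}$ is the Pearson
   correlation of the two samples' panel z-score vectors; the dendrogram is
   cut into $k=3$ clusters.
3. **Score & label** — per sample, the epithelial score $E_s$ and
   mesenchymal score $M_s$ are the mean panel z-scores and
   $\Delta_s = E_s - M_s$; clusters ranked by mean $\Delta$ become
   EPC > HPC > MPC.
4. **Verify** — a rank-based per-sample enrichment score
   $(\overline{\mathrm{rank}}_S - \tfrac{G+1}{2}) / \tfrac{G-1}{2} \in [-1,1]$
   over the full transcriptome (epithelial set; stromal/mesenchymal set)
   tertiles the cohort on an axis independent of the clustering; each
   sample is flagged concordant/discordant, never re-labeled.

Paired cohorts additionally yield a 3×3 normal→tumor transition table and
conversion rates; survival uses the product-limit estimator and the
k-group log-rank test.

## Worked example

Simulate a paired cohort of 40 patients (80 samples), type it, and trace
the subtype transitions:

```python
from ehbmt import (SimulationParams, simulate_paired_cohort,
                   classify_cohort, conversion_rate)

params = SimulationParams(n_pairs=40)
expr, meta, truth = simulate_paired_cohort(params, seed=7)
res = classify_cohort(expr, meta=meta)
print(res.summary())
```

```
EMT-heterogeneity typing results
========================================
samples: 80    panel: emt-default v1.0
panel coverage: epithelial 100%, mesenchymal 100%

subtype   n      %    mean delta
EPC       30   37.5       1.309
HPC       24   30.0       0.177
MPC       26   32.5      -1.674

enrichment concordance: 65.0% overall EPC=40.0% HPC=100.0% MPC=61.5%
```

Thirty samples cluster as epithelial (mean epithelial-minus-mesenchymal
panel score +1.31), twenty-four as hybrid (≈0) and twenty-six as
mesenchymal (−1.67). Tracing subtype change within each patient:

```python
pairs, table = res.transition_analysis()
print(table)
print(conversion_rate(table, "EPC", {"HPC", "MPC"}), "%")
```

```
tumor   EPC  HPC  MPC
normal
EPC       5   12    7
HPC       0    3    3
MPC       1    3    6

79.2 %
```

Of 24 patients whose normal tissue is EPC, 19 convert to the hybrid or
mesenchymal subtype in the matched tumor (79.2%) — the hallmark pattern of
EMT progression during carcinogenesis.

The same pipeline is available from the shell:

```bash
ehbmt simulate --mode paired --n 40 --seed 7 --out sim/
ehbmt classify --expr sim/expression.tsv --meta sim/meta.tsv --out results/
ehbmt transitions --assignments results/assignments.tsv --meta sim/meta.tsv --out sankey.json
ehbmt survival --assignments results/assignments.tsv --meta sim/meta.tsv --endpoint os
```

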