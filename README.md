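# locop

Local gene co-expression discovery and its genetic dissection.

Nearby genes (TSSs < 1 Mb apart) are often expressed as a group across
individuals, and single regulatory variants can drive several of them at
once — with consequences that reach into GWAS trait pleiotropy. `locop`
implements the full analysis chain for this question on cross-individual
expression data:

1. **Discovery** — identify co-expressed gene pairs (COPs) by comparing each
   pair's Pearson correlation against a per-gene permutation null: the focal
   gene's values are shuffled R times and each shuffle keeps the *highest*
   |r| over the gene's cis set, so the test self-adjusts for the number of
   neighbours. Empirical "adjusted p-values" (1+k)/(R+1) are controlled by
   Benjamini–Hochberg on per-gene minima at FDR 1%, and a pair is called only
   when it passes from both genes' sides.
2. **Controls** — distance-matched non-COPs (≤100 bp discrepancy, adjusted
   p > 0.5) and correlation-matched trans-COPs, sampled without replacement.
3. **Molecular features** — 13 pair-level metrics (CTCF sites and inverted
   motifs between TSSs, Hi-C contacts of the TSS bins, enhancer sharing and
   totals, TF-binding in ±50 kb flanks, expression-level and CV similarity,
   GO-term sharing, an LD proxy, eQTL sharing and eGene counts) with a
   50-repetition 80/20 logistic-regression ROC-AUC harness.
4. **cis-eQTLs** — nominal and permutation passes of per-variant OLS on
   dosage, Beta-approximated or empirical gene-level adjusted p-values,
   eGene calling at FDR 5%, and lead-eQTL *sharing*: does the lead variant
   of one gene associate (p < 0.05, same effect sign) with its partner?
5. **Enrichment** — one-sided Fisher tests of COP functional relatedness,
   permutation-based eQTL–annotation enrichment (annotation neighborhoods
   reassigned among genes, preserving TSS-relative strand-oriented offsets),
   and shared-vs-other lead eQTL overlap comparisons.
6. **Pleiotropy** — trait-association counts at p < 5e-8, shared-vs-other
   odds ratios and Wilcoxon comparisons, and genomic inflation
   λ = median(χ²₁)/0.45494 with QQ coordinates.

A bundled synthetic-data generator (`locop.simdata`) produces gene catalogs,
expression with planted co-expression blocks, genotypes with planted shared
or unshared cis-eQTLs, annotation tracks with configurable depletion around
true pairs, enhancer links, Hi-C triplets and multi-trait GWAS summary
statistics — each with truth tables, so every stage is testable end to end
without any external download. It is intended for audiences working on
regulatory genomics pipelines who need a tested, reproducible reference
implementation of this analysis.

## Worked example

```python
import numpy as np
from locop import simdata, preprocess, copcall, controls, eqtl

cfg = simdata.SimConfig(
    n_individuals=300, n_genes=600, n_chromosomes=2,
    block_spec=[(2, 0.9)] * 200,      # 200 planted co-expressed pairs
    shared_fraction=0.5,              # half of them share a cis-eQTL
    variants_per_gene=10, seed=42,
)
ds = simdata.simulate_dataset(cfg)

expr, removed = preprocess.filter_genes(ds.expression, ds.catalog,
                                        preprocess.FilterRules())
expr = preprocess.inverse_normal_transform(expr)

disc = copcall.discover(expr, ds.catalog, R=200, fdr=0.01, seed=1)
cops = disc.cops()
print(f"tested pairs: {len(disc.pairs)}, COPs at FDR 1%: {len(cops)}")

matched = controls.match_noncops(disc, seed=2)
leads = eqtl.call_egenes(
    eqtl.map_cis_permute(expr, ds.genotypes, ds.catalog, R=200, seed=3))
sharing = eqtl.eqtl_sharing(cops, leads, expr, ds.genotypes)
print(f"eGenes: {int(leads.is_egene.sum())} / {len(leads)}")
print(f"COPs with a shared lead eQTL: {(sharing.sharing >= 1).mean():.1%}")
```

prints

```
tested pairs: 5895, COPs at FDR 1%: 202
eGenes: 242 / 600
COPs with a shared lead eQTL: 44.6%
```

All 200 planted pairs are among the 202 calls (sensitivity 1.000 at a
global adjusted-p threshold of 0.0050), and the 44.6% sharing rate reflects
the configured 50% shared fraction times the power of the eQTL pass —
unshared pairs cross-associate at roughly the nominal 5% rate.

The same pipeline is exposed as a thin CLI over plain-text formats
(TSV / BED / GTF / VCF):

```bash
locop simulate --config cfg.yaml --out sim/ --seed 42
locop preprocess --expr sim/expression.tsv --catalog sim/genes.bed --out pre/
locop discover --expr pre/expression.int.tsv --catalog sim/genes.bed \
               --perms 1000 --fdr 0.01 --seed 1 --out disc/
```

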