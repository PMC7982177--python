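# triagene

Three-stage integrative prioritization of disease risk genes from GWAS and
eQTL summary statistics.

Genome-wide association studies report trait-associated SNPs, but most hits
fall in non-coding regions and say little about *which gene* mediates the
risk. One productive hypothesis is regulatory: a risk SNP acts by changing a
gene's expression. `triagene` operationalizes this by matching each gene's
*expression signature* — its significant eQTL SNPs (eSNPs), cis or trans —
against the pattern of trait association in a GWAS, and then subjecting the
candidate genes to independent technical and biological replication before
prioritizing them. It is aimed at statistical geneticists who have GWAS
summary statistics and one or more eQTL association tables and want a
transparent, fully seeded re-implementation of this class of analysis,
validated end-to-end on synthetic data with planted signal.

## The analysis

**Stage 1 — discovery (Bayesian eSNP scoring).** For gene *g* with eSNPs
*s = 1..m*, each eSNP's GWAS p-value is converted to a z-score
*z = Φ⁻¹(1 − p/2)* and scored with an approximate Bayes factor

```
log10 BF(z) = ½ log10(1/(1+W)) + (z²/2) · W/(1+W) · log10 e
```

(*W* = prior variance of the standardized effect, default 0.1). The gene
score is

```
LBF(g) = Σ_s [ log10 BF(z_s) + log10( α_kind(s) / (1 − α_kind(s)) ) ]
```

with prior trait-association probabilities α_cis = 1.0×10⁻³ and
α_trans = 5.0×10⁻⁵. Weak GWAS signal contributes negatively, strong signal
positively, and a trait SNP that is not an eSNP contributes nothing.
Significance is a *simulated P*: the score is recomputed under `n_sim`
resamples of the gene's eSNP count of p-values from the whole GWAS pool
(cis/trans composition fixed) and the add-one tail proportion reported;
genes with simulated P ≤ .05 form Geneset #1.

**Stage 2 — replication.** The same scoring against an independent eQTL
table (Geneset #2), plus a gene-based association scan: SNPs within the gene
body ± 20 kb are aggregated into a mean-χ²₁ statistic whose null is drawn
from MVN(0, R) with R the SNP–SNP LD estimated from a reference dosage
panel (Geneset #3, empirical P ≤ .05). As a negative control the scan is
repeated on a GWAS of a *randomized* phenotype (Geneset #4).

**Stage 3 — prioritization.** The final candidates are
Geneset #1 ∩ #2 ∩ #3. Their reliability is checked by (i) an overlap
permutation (100,000 random draws of |Geneset #2| genes from the
replication background), (ii) a comparative analysis of replication rates
against the real versus null gene-based scans at cut points .05/.01/.001
with a paired Student t, (iii) hypergeometric pathway enrichment (set sizes
5–2000, BH-FDR) with Jaccard-distance classical MDS and k-medoids
clustering of the enriched sets, and (iv) expression-level validation:
pooled-variance t tests and case/control Pearson co-expression contrasts on
the final gene panel.

A first-class synthetic-data generator (`triagene.synthetic_data`) produces
every input with planted colocalized genes, so the whole pipeline is
testable against a known truth.

## Worked example

```python
from triagene import SyntheticConfig, PipelineConfig, simulate_study, run_pipeline

study = simulate_study(SyntheticConfig(seed=42))   # 5000 SNPs, 500 genes, 4 planted
paths = study.write("demo/inputs")
config = PipelineConfig(
    **{k: str(v) for k, v in paths.items() if k in (
        "gwas", "eqtl_discovery", "eqtl_replication", "annotation",
        "dosage", "gene_sets", "expression")},
    outdir="demo/out", seed=42)
report = run_pipeline(config)
print(report.to_markdown())
```

prints (abridged):

```
## Gene-set sizes
- geneset1_discovery: 8
- geneset2_replication: 12
- geneset3_gene_based_real: 22
- geneset4_gene_based_null: 27

## Final intersection (4 genes)
G0000, G0001, G0002, G0003

## Overlap permutation (discovery vs replication)
- N_observation: 4
- N_total: 131
- empirical_p_ge: 0.00026

## Comparative analysis (real vs null gene-based scan)
- paired t = 6.502, p = 0.001285 over 6 rate pairs

## Expression validation
- DGE genes at p<=0.05: 3
```

All four planted genes (`study.truth["genes"]` = G0000–G0003) survive the
three-stage triage; their discovery/replication overlap is far beyond chance
(permutation p ≈ 2.6×10⁻⁴, the floor plus ties at 100,000 trials);
replication rates against the real-trait scan dominate the null-trait scan;
and three of the four genes are differentially expressed at p ≤ .05 in the
19-sample expression arm. The same run is available from the shell via
`triagene simulate` and `triagene run`.

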