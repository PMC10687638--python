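# homeotrip

Expression divergence of retained homeolog **triplets** in polyploid RNA-seq.

Hexaploid species such as *Camelina sativa* retain many genes in three
syntenic copies (one per subgenome). Given a gene-level count matrix from a
two-condition experiment (control vs cold stress), a 3:1 syntelog map
(anchor gene → three homeologous copies), and gene lengths, `homeotrip`
answers three questions per triplet:

1. **Which copies are expressed, and does one dominate?** Under control
   conditions, copies are ranked by mean FPKM. A triplet is **Class 1** when
   the top copy is significantly higher than *both* others (p < 0.01 and
   FPKM fold change > 2), **Class 2** when the top two copies each dominate
   the third by the same rule, **Class 3** when all three copies are within
   1.5-fold, and *unclassified* otherwise.
2. **How do the copies respond to cold?** A gene is *cold-induced* when
   log2FC > 1 and p < 0.01 (up only). A triplet with 3 / 2 / 1 induced
   copies is **Type 1 / 2 / 3**. Within Type 1 triplets, copies are ranked
   by *inducibility* (FPKM fold change cold/control) and the triplet is
   flagged **divergent** when the rank-1 copy's inducibility is ≥ 2× the
   rank-3 copy's.
3. **Which genes are co-regulated, and what functions are enriched?**
   A Pearson r > 0.7 network on the top 20% most variable genes
   (log2(TPM+1)) with Leiden modules, and one-sided hypergeometric term
   enrichment with BH correction.

## The statistical core

Counts are modelled as negative binomial: for gene *g* in sample *s*,
`y_gs ~ NB(mu_gs, phi)` with mean `mu_gs = p_g * D_s` and variance
`mu + phi * mu^2` (`phi = 0` is the Poisson limit). `D_s` is the sample's
effective depth from TMM normalization. Differential expression uses the
classical two-group conditional exact test:

* samples are mapped to a common depth via the NB quantile function
  (mid-P CDF in, quantile out);
* a single common dispersion `phi` is estimated by maximizing the
  conditional log-likelihood given per-group totals;
* conditional on the total `T` of both groups, the two-sided p-value is the
  summed probability of all splits at most as probable as the observed one.

The same exact test compares two *different* genes of a triplet across the
same control samples after rescaling counts to per-kilobase pseudo-counts,
which removes gene-length bias.

A first-class synthetic-data generator plants presence categories,
dominance classes, induction types and inducibility spreads with recorded
truth, so every classifier can be scored for label recovery.

## Worked example

```python
import homeotrip as ht

cfg = ht.SimulationConfig(n_triplets=300, n_singletons=100, seed=42)
res = ht.run_pipeline(cfg, run_enrichment=False)
print(round(res.model.dispersion, 4))
print(res.report["presence_and_classes"]["class_counts"])
print(res.report["cold_response_types"])
```

prints (from `examples/simulate_and_classify.py`):

```
0.0986
{'class1': 40, 'class2': 46, 'class3': 80, 'unclassified': 134}
{'n_typed': 34, 'type_counts': {'type1': 7, 'type2': 14, 'type3': 13},
 'percent_type2_or_3': 79.0, 'percent_type1_divergent': 14.3, 'n_type1_divergent': 1}
```

The estimated common dispersion (0.0986) recovers the planted 0.1; 227 of
300 triplets express all three copies; among fully expressed triplets the
classifier finds 40 one-dominant, 46 two-dominant and 80 balanced triplets;
34 triplets have at least one cold-induced copy, and 79% of those show a
diverged cold response (Type 2 or 3). `res.recovery` scores each call
against the planted truth.

The `examples/` directory holds one short script per capability
(simulation + classification, the exact test, coexpression modules, term
enrichment), and the `homeotrip` console script exposes the same stages for
shell use (`homeotrip run-all --seed 5 --outdir out/`).

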