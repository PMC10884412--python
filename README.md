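# polyrekit

Inference toolkit for the polyploidization–rediploidization cycle in
plant genomes: detecting a whole-genome triplication (WGT) from synteny
and synonymous divergence, classifying the one/two/three-copy retention
groups it leaves behind, placing and dating the event phylogenetically,
testing expression divergence between retained duplicates, and measuring
how natural selection differs across retention classes.

It is written for molecular evolution researchers who want each stage of
that chain as a tested, scriptable Python library rather than a chain of
external binaries, and who want every estimator validated by parameter
recovery: the package ships a synthetic genome-evolution simulator that
generates all of its own inputs with known ground truth.

## What it computes

- **Synteny.** BLAST-style homology filtering (identity ≥ 30%, e-value
  < 1e−10, coverage ≥ 30% of both sequences), exact dynamic-programming
  chaining of collinear blocks (≥ 5 anchor genes), synteny-depth ratios
  (a triplicated descendant covers its pre-WGT relative at modal depth
  3), ploidy-ladder arithmetic (8 × 3 = 24), and lower-bound
  fusion/fission/inversion counts from karyotype segment maps.
- **Ks.** Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction,
  Gaussian-mixture peak detection on log Ks, block-median Ks filtering
  (medians in [0.2, 1.0], pairs ≤ 1.26), strict-clock WGT dating from a
  calibrated ortholog peak, and LTR-retrotransposon insertion ages from
  5′–3′ LTR divergence at 1.3 × 10⁻⁸ substitutions/site/year.
- **Retention groups.** Connected components of the Ks-filtered paralog
  graph as one/two/three-copy groups, outgroup-ortholog anchoring, and
  gene-list intersections.
- **Placement.** Gene-tree topology scenarios (shared WGT vs
  lineage-specific duplication), and MAPS-style per-node percentages of
  subtrees with duplications shared by a whole clade, compared against
  simulated null and positive gene-tree sets.
- **Expression.** The exact conditional (binomial) test for duplicate
  pairs with Bonferroni correction and three-replicate consistency,
  triplet pairwise testing, and per-tissue/cross-tissue DEGP summaries.
- **Selection.** Poisson-random-field folded SFS, a gamma DFE over
  deleterious N_e s fitted by maximum likelihood (four-fold sites fix
  the neutral mutation rate), |N_e s| bin proportions, the adaptive
  proportion of divergence α and rate ω_a with a 200-replicate by-gene
  bootstrap, the fixation index (Dn/Ds)/(Pn/Ps), log-ratio
  constraint/selection effects, and pairwise class contrasts.

`docs/methods.md` describes every model, default, and numerical choice.

## Worked example

Run the full simulate → analyze pipeline on a small synthetic genome:

```python
from polyrekit import pipeline, simgenome

config = simgenome.SimConfig(seed=71, n_anc_genes=400)
manifest = pipeline.run_end_to_end(config, "demo_run", {
    "n_families": 200, "n_maps_sims": 4, "n_genes_per_class": 60,
    "max_cds_pairs": None, "n_codons": 120, "n_bootstrap": 50,
})
print(open("demo_run/report.md").read())
```

The report this prints includes (numbers from this exact run):

```
- ancestor: 8 chromosomes, 400 genes; WGT x3
- descendants: 796 / 781 genes on 24 / 24 chromosomes
- expected post-WGT chromosome number: 24
- 504 pairs; detected peaks: mode=0.512 (w=1.00)
- true simulated WGT peak: 0.5
- detected: {1: 119, 2: 178, 3: 107, 'oversized': 0}
- truth ancestral-gene classes: {1: 112, 2: 180, 3: 108}
- observed shared-duplication percentage at wgt_clade: 20.0%
  (retention rate 0.2)
- verdict vs null/positive simulations: supports_wgd
- per-tissue DEGP fractions: t1=0.55, t2=0.55, t3=0.54, t4=0.53
- simulated truly diverged pair fraction: 0.61
```

Reading it: the simulator triplicated an 8-chromosome, 400-gene
ancestor and fractionated each lineage (796 of 1,200 gene copies
survive in lineage A). The synteny → Ks → graph chain recovers the Ks
peak the pairs were simulated at (0.512 vs 0.5) and the
one/two/three-copy retention classes within a few genes of the
simulator's ground truth (the difference comes from syntenic block
fragments that fall under the five-anchor minimum); the MAPS stage
recovers the simulated 20% WGD retention signal at the correct
species-tree node; and the exact conditional test recovers the
simulated fraction of expression-diverged duplicate pairs (0.53–0.55
detected vs 0.61 true).

The same stages are available as a CLI (`polyrekit simulate`,
`synteny`, `ks`, `retention`, `placement`, `dupexpr`, `selection`,
`run`) for file-based workflows on your own gene tables, homology hits,
CDS alignments, count matrices and SFS tables.

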