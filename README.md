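# graftflow

Mobile-mRNA detection and multi-omics integration for grafted plants.

When a scion (e.g. watermelon) is grafted onto a rootstock of another
species (e.g. pumpkin), some rootstock transcripts cross the graft union
and appear in scion tissues — so-called mobile mRNAs (mb-mRNAs), carried
over long distances through the phloem. Detecting them from RNA-seq of
scion tissue is a dual-genome classification problem: a read sampled in
the scion must be attributed to the scion genome or rescued, under a
strict identity rule, against the rootstock genome, while ortholog
homology between the two cucurbit genomes and sequencing error generate
false positives that must be subtracted using same-species (homograft)
control grafts.

`graftflow` implements this analysis end to end for researchers studying
graft-transmissible signals, at desk scale and fully offline:

- **`graftflow.simulate`** — a synthetic heterograft generator with known
  ground truth: scion/rootstock gene sets diverged to a controlled
  per-site identity, planted mobile transcripts whose abundance decreases
  with distance from the union (stem > pulp), homograft controls,
  FASTQ reads with substitution errors, and metabolite tables with
  controlled Spearman coupling to chosen transcripts.
- **`graftflow.classify`** — sliding-window quality trimming
  (Trimmomatic `SLIDINGWINDOW:4:15 MINLEN:75` semantics), k-mer-seeded
  banded alignment to the scion transcript set, rescue of unmapped reads
  against the rootstock set at ≥ 95 % identity, homograft subtraction,
  and per-sample read accounting (clean reads / mapped reads / mapped
  rate %).
- **`graftflow.quantify`** — FPKM, differential mb-mRNA calling at
  |log₂FC| ≥ 1 and Benjamini–Hochberg FDR ≤ 0.05 (exact binomial count
  test with library-size offset), hypergeometric term enrichment, and
  2^−ΔΔCt relative qPCR expression.
- **`graftflow.cluster`** — Mfuzz-style fuzzy c-means on z-scored
  log₂(FPKM + 1) profiles, as a scikit-learn estimator (`FuzzyCMeans`).
- **`graftflow.structure`** — RNA secondary structure under a simplified
  constant-energy model: Nussinov maximum-pairing folding, McCaskill-style
  base-pair probabilities and positional entropy, loop decomposition
  (hairpin / stack / bulge / internal / multibranch / external), and
  mountain-plot profiles (MFE / ensemble / centroid).
- **`graftflow.network`** — Spearman correlation networks across RNAs,
  mobile RNAs, and metabolites, with pathway subsetting and GraphML
  export.

## The core statistics

A read *r* is **scion-mapped** when its best scion hit satisfies
identity ≥ 0.90 over ≥ 0.90 of the read; otherwise it is aligned to the
rootstock set and **rescued** when identity = matches / alignment columns
≥ 0.95 over ≥ 0.80 of the read. A rootstock gene observed in *any*
homograft control (threshold 1 read) is removed; the survivors are the
mb-mRNA candidates. Per-sample accounting reports the mapped rate
100·mapped/clean, rounded half-away-from-zero to 2 decimals.

Differential calling conditions on the pooled count *n* of a gene across
groups A and B: the group-A count is Binomial(*n*, *p₀*) under the null
with *p₀* the group-A share of the total library size; two-sided exact
p-values (minimum-likelihood rule) are BH-adjusted, and a gene is called
at |log₂((FPKM̄_A+1)/(FPKM̄_B+1))| ≥ 1 and FDR ≤ 0.05.

For folding, each allowed pair (AU/GC/GU) contributes energy −1 (kT = 1),
hairpins enclose ≥ 3 unpaired bases; the partition function gives
P[i,j], per-base unpaired probability, and positional entropy
−Σ p ln p in nats.

## Worked example

```python
from graftflow import (SimulationConfig, simulate_experiment,
                       classify_experiment)

cfg = SimulationConfig(n_genes=60, gene_length_range=(300, 800),
                       n_mobile=8, reads_per_sample=10_000, seed=42)
exp = simulate_experiment(cfg)          # 12 samples, known ground truth
res = classify_experiment(exp)          # trim -> map -> rescue -> subtract

truth, called = exp.truth.mobile_gene_ids, set(res.mobile_genes)
tp = len(called & truth)
print(f"sensitivity {tp/len(truth):.2f}  precision {tp/len(called):.2f}")
print(res.accounting_frame().loc[
    ["hetero_stem_1", "hetero_pulp_1", "homo_stem_1"],
    ["clean_reads", "scion_mapped_rate", "rootstock_mapped",
     "rootstock_rate_of_clean"]])
```

prints

```
sensitivity 1.00  precision 1.00
               clean_reads  scion_mapped_rate  rootstock_mapped  rootstock_rate_of_clean
sample_id
hetero_stem_1        10000              98.11               189                     1.89
hetero_pulp_1        10000              99.67                33                     0.33
homo_stem_1          10000             100.00                 0                     0.00
```

All 8 planted mobile genes are recovered with no false positives. The
near-tissue (stem) sample carries ~1.9 % rootstock-origin reads versus
~0.3 % in the far tissue (pulp) — the distance dependence of RNA
mobility — and the homograft control yields zero rootstock candidates,
because ~85 % ortholog identity stays safely below the 95 % rescue rule.

The same stages are available from the shell:

```bash
graftflow simulate --config sim.yaml --outdir data --seed 1
graftflow classify --scion data/scion.fa --rootstock data/rootstock.fa \
    --samples data/samples.tsv --out results
graftflow fold --fasta candidates.fa --out folded
graftflow network --rna rna.tsv --mobile mb.tsv --metab met.tsv \
    --rho-min 0.9 --out net
```

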