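# triplextad

Long noncoding RNAs (lncRNAs) can anchor to duplex DNA as a third strand,
forming RNA:DNA:DNA triplexes at purine-rich target tracts via Hoogsteen
base pairing. `triplextad` implements a genome-wide analysis of such
**triplex-forming sites (TFSs)** relative to the units of 3D chromatin
organisation — **topologically associated domains (TADs)**, their boundaries
and loop anchors — for computational genomicists who want to run, test, or
extend this style of analysis on their own data or on fully synthetic study
systems with planted ground truth.

## What it computes

1. **Triplex site prediction.** Candidate triplex target sites (TTSs) are
   maximal polypurine tracts (purine fraction ≥ 0.9 over ≥ 20 bp windows, on
   either strand). The RNA third strand is matched to the purine strand
   through the three canonical binding codes — pyrimidine motif (parallel;
   U→A:T, C→G:C), purine motif (antiparallel; A→A:T, G→G:C), mixed motif
   (antiparallel; G→G:C, U→A:T) — reporting every containment-maximal
   ungapped match of length ≥ 20 with mismatch fraction ≤ 5 %. RNA-side
   footprints merge into **triplex-forming domains (TFDs)**; for multi-isoform
   genes the isoform with the most TFSs is kept.

2. **Permutation enrichment.** Observed base-pair coverage of TFSs with a
   region set is compared with the coverage of *n* = 1000 random
   re-placements of the same site-length multiset in the genome. The shuffle
   distribution is summarised by a fitted normal (checked with the
   Anderson–Darling test) and an upper-tail z/p is reported
   (`p < 1e-16` as a sentinel beyond floating precision).

3. **Positional statistics.** Five-bin positional profiles of TFSs across
   TADs with a two-sample Kolmogorov–Smirnov test against a random control;
   TAD-size vs size-normalised-coverage Pearson correlation; chi-square
   comparison of TFS→nearest-CTCF distance histograms (4 quantile bins)
   against uniformly re-placed CTCF sites.

4. **Functional annotation.** Promoter (TSS −1 kb/+100 bp), 5′UTR, 3′UTR,
   CDS exon, intron, intergenic labels by site midpoint under a
   promoter-first priority, and TFS density per 10 kb of merged element
   track.

5. **TAD classification.** *n* TADs vs *n* size-matched non-overlapping
   background regions, featurised by per-lncRNA TFS counts; random forest,
   elastic-net logistic regression, gradient boosting and RBF-SVM tuned by
   5-fold CV on a stratified 80 % split and scored on the held-out 20 %
   (accuracy, AUC, sensitivity, specificity, F1). Per-lncRNA importance is
   **target shuffling**: permute one feature column in the test set and
   measure the mean accuracy drop.

6. **Synthetic study systems.** A seeded generator produces multi-chromosome
   genomes with polypurine tracts planted inside TADs at a controlled
   enrichment factor, lncRNAs carrying 0–3 planted TFDs, cell-line-specific
   TPM block structure, boundary-enriched CTCF sites and gene models — with
   full ground truth for parameter-recovery testing.

## Worked example

```python
from triplextad import (SyntheticConfig, simulate, search_triplexes,
                        TriplexParams, tad_enrichment)

cfg = SyntheticConfig(seed=1)                    # 3 x 500 kb genome, 30 TADs
bundle = simulate(cfg)
sites = search_triplexes(bundle.lncrnas, bundle.genome, TriplexParams(),
                         bundle.gene_of)
print(f"{sites['lncrna_id'].nunique()} of {cfg.n_lncrnas} lncRNAs form "
      f"{len(sites)} triplex sites")

res = tad_enrichment(sites, bundle.tads, bundle.chrom_sizes,
                     n_shuffles=1000, rng=7)
print(f"TAD coverage: observed {res.observed_coverage} bp, "
      f"expected {res.expected_mean:.0f} ± {res.expected_sd:.0f} bp")
print(f"z = {res.z:.2f}, one-sided p {res.p_display} "
      f"(Anderson–Darling p = {res.ad_pvalue:.2f})")
```

prints

```
47 of 100 lncRNAs form 4477 triplex sites
TAD coverage: observed 5930 bp, expected 3162 ± 261 bp
z = 10.59, one-sided p < 1e-16 (Anderson–Darling p = 0.15)
```

About half the lncRNAs carry at least one triplex-forming domain (the
generator's default), each binding many genomic tracts. Because tracts were
planted inside TADs at three times the outside density, the observed TFS
coverage of TADs far exceeds the shuffle expectation — the expected-coverage
distribution is consistent with a normal (AD p = 0.15), and the observed
value sits 10.6 standard deviations above its mean.

The same stages are available from the shell:

```bash
triplextad simulate --seed 4 --outdir bundle
triplextad triplex --genome bundle/genome.fa --rna bundle/lncrnas.fa --out tfs.bed
triplextad enrich --tfs tfs.bed --regions bundle/tads.bed \
    --genome bundle/genome.fa --shuffles 1000 --seed 2
triplextad run-all --seed 7 --outdir results/
```

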