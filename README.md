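# cre-enrich

Are trait-associated regions of the genome enriched for open chromatin?
`cre-enrich` implements, as a tested and reusable pipeline, a
regulatory-genomics analysis built around that question: it constructs
linkage-disequilibrium (LD) blocks around genome-wide significant GWAS SNPs
from phased haplotype panels, draws GC- and annotation-matched background
region sets from a tiled genome, tests the enrichment of open-chromatin
(scATAC-seq) peaks inside the LD blocks with empirical permutation p-values,
and classifies the cross-species conservation of regulatory regions from
synteny-projection scores. The package is aimed at regulatory genomicists who
want each of these steps available as a library function, a shell command,
and a reproducible end-to-end run — with a synthetic-data generator so the
whole pipeline is testable without any external downloads.

## The statistics at the core

**LD blocks.** GWAS SNPs are filtered at genome-wide significance
(P < 5×10⁻⁸) and grouped by the superpopulation of the source study. For
each hit, the nearest panel variants up- and downstream act as proxies, and
the block spans from the most upstream to the most downstream panel variant
within a 500-kb window whose haplotype correlation with either proxy reaches
r² ≥ 0.8, where for allele frequencies *p*, *q* and haplotype frequency
*p*₁₁,

  r² = (p₁₁ − p q)² / [p(1−p) q(1−q)].

Overlapping blocks are merged, pooling population groups.

**Matched backgrounds and empirical p.** The genome is tiled into 500-bp
segments, each annotated with GC content and one class from
promoter > 5′UTR > 3′UTR > exon > intron > intergenic. N background sets
(default 1000) are drawn by stratified sampling without replacement so that
each set reproduces the peaks' joint (GC decile × annotation) histogram.
For a statistic T (peak–block overlap frequency, or overlapping peaks per Mb
of merged block length), the empirical p-value is

  p = #{i : T(background_i) ≥ T(observed)} / N,

with p = 0 reported alongside its resolution bound < 1/N.

**Conservation classes.** Regions project between species with a score in
[0, 1]; scores > 0.98 are directly conserved, > 0.84 indirectly conserved,
otherwise nonconserved. A differentially accessible region (DAR) is
*functionally conserved* when its conserved projection overlaps a DAR in the
other species, irrespective of cell type; tissue-level contrasts use the
conservation-rate ratio with a two-sided Fisher exact test.

## Worked example

The numbered scripts under `analysis/` run the default synthetic study and
narrate each stage. `python analysis/01_simulate_inputs.py` generates all
inputs under `results/run/`, then:

```sh
$ python analysis/02_build_ld_blocks.py
1687 of 2400 SNPs reach P < 5e-08
8 merged LD blocks covering 1557511 bp -> results/run/blocks.bed

$ python analysis/05_test_enrichment.py
        statistic   observed  null_mean   null_sd     fold  empirical_p p_bound  n_sets
overlap_frequency 629.000000 313.670000 15.427998 2.005292          0.0 < 0.001    1000
     peak_density 403.849475 201.391836  9.905547 2.005292          0.0 < 0.001    1000
```

629 of the 2000 simulated peaks touch an LD block, against a matched-null
mean of ~314 — a 2.0-fold enrichment no background set reaches (p < 0.001
at 1000 sets). The synthetic genome plants peaks at 5× density inside the
trait loci; the realized fold is lower because blocks built from edge SNPs
legitimately extend into flanking LD segments, diluting the planted signal.

```sh
$ python analysis/06_classify_conservation.py
       direction  n_dars  pct_direct  pct_indirect  pct_nonconserved  pct_functionally_conserved  identity_retention  ectoderm_mesenchyme_ratio     tissue_p
mouse_to_chicken    2000        14.5         42.05             43.45                        8.80            0.812500                   3.762482 4.919194e-19
chicken_to_mouse    2000        13.4         41.35             45.25                        1.35            0.740741                   6.810191 9.126034e-06
```

Roughly 14% of projections are directly and 42% indirectly conserved, yet
only 8.8% (mouse→chicken) and 1.4% (chicken→mouse) of DARs are functionally
conserved — and of those, ~81% keep their tissue identity, with ectodermal
DARs conserved at several times the mesenchymal rate.

The same pipeline runs on real inputs through the CLI
(`cre-enrich ld-blocks --snps snps.tsv --vcf panel.vcf ...`; see
`cre-enrich --help`), or end-to-end with `cre-enrich run-all --seed 1 --out
run/`, which also writes a `manifest.json` of config, seeds and output
digests.

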