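# Methods

This note documents the models and procedures implemented in `cre_enrich`,
the defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open (BED convention); VCF and
GFF3 positions are converted at the reader boundary (`pos − 1` for points).
Abutting half-open intervals do not overlap and are not merged. Overlap
counting merges the subject set and binary-searches each query, so counts
are invariant to how the subject set is fragmented; a peak overlapping two
blocks counts once.

## LD blocks

GWAS records are kept when `p_value < p_threshold` (strictly; default
5×10⁻⁸). Haplotype r² between two biallelic variants uses the standard
D²/[p(1−p)q(1−q)] form over phased haplotypes; a monomorphic variant has no
LD information and is treated as *not comparable* — it can never satisfy the
block threshold, and it does not abort the block.

For each significant SNP the nearest panel variants at or below and at or
above its position act as the downstream/upstream proxies (the SNP itself,
when present in the panel, is both). The block spans the outermost panel
variants within the search window whose r² with *either* proxy reaches
`r2_min` (default 0.8); the proxies are self-linked, so a block always
exists once proxies do. Decisions worth noting:

* **Window.** "A 500-kb window around the position" is read as centred:
  pos ± 250 kb, with `window` configurable. The total width, not the
  half-width, is the configured value.
* **No proxy in the window.** The SNP yields a degenerate 1-bp block with a
  warning (configurable to drop). Dropping hits silently would bias the
  block set toward well-covered regions.
* **Proxy distance ties** resolve downstream for the downstream proxy and
  upstream for the upstream proxy — deterministic and logged.
* **Groups.** Blocks are built per population group against that group's
  panel, then pooled for a single merge pass; merged blocks union their
  source-SNP provenance. Merging is strict-overlap, sorted by
  (chrom, start), idempotent, and conserves covered bases.

A practical property seen in both synthetic and real data: a significant
SNP near the edge of an LD segment can have one proxy in the adjacent
segment, so its block legitimately spans both segments. Blocks are
therefore not a partition of "true" LD segments, and aggregate enrichment
folds are diluted relative to the generative enrichment inside trait loci.

## Tiling, GC, annotation, strata

The genome is tiled into fixed-width (default 500 bp) half-open tiles; the
terminal partial tile is kept (its narrower width slightly increases GC
variance in the last stratum — accepted and noted here rather than special-
cased). GC is (G+C)/(A+C+G+T) case-insensitively; ambiguous bases count in
neither numerator nor denominator, and an all-ambiguous interval has
undefined GC and lands in an excluded sentinel stratum.

Annotation assigns exactly one class by any-overlap with fixed priority
promoter > utr5 > utr3 > exon > intron > intergenic. The promoter is a
strand-aware window TSS−2000/+200 bp — a common regulatory-genomics default,
configurable because reasonable definitions differ. UTRs are exonic sequence
outside the coding span; introns are the transcript span minus exons.
Majority-base assignment was considered and rejected as the default: for
500-bp tiles the two rules rarely disagree, and any-overlap is cheaper and
the more common convention for peak annotation.

Strata are (GC decile, annotation class); GC = 1.0 goes to the top bin. Ten
equal bins balance matching fidelity against stratum sparsity at desk scale;
the count is configurable.

## Matched background sampling

Each of N sets (default 1000) is drawn independently: within every stratum,
tiles are sampled uniformly without replacement to the foreground's count,
using a generator seeded from (master seed, set index) so any single set is
reproducible in isolation and results are independent of iteration order.
If a stratum is exhausted the sampler borrows, logging every substitution,
from: the nearest GC bin with the same annotation, then the same GC bin
with the priority-nearest annotation, then everything else by joint
distance. Set size always equals foreground size; a pool globally smaller
than the foreground is a hard error.

Two deliberate choices:

* **Foreground-overlapping tiles stay in the pool by default.** Excluding
  them ties the null to the observed peak configuration: whenever the
  observed peaks happen to fall inside the tested blocks, the matching
  in-block tiles vanish from the pool, the null statistic is deflated, and
  the test becomes anti-conservative (measured at roughly 13% rejections at
  α = 0.05 in the null calibration, versus 6% with the pool left intact).
  Exclusion remains available as an option.
* **Width mismatch.** Background units are fixed-width tiles while peaks
  may have variable width. With the default 501-bp fixed-width peaks the
  mismatch is negligible; for strongly variable peak widths the overlap
  probabilities of foreground and background differ at block edges, which
  is a known approximation of this matching scheme.

## Enrichment statistics

Observed and null values use identical code paths against the same merged
blocks. `overlap_frequency` counts peaks touching ≥1 bp of any block;
`peak_density` divides that count by merged block length in Mb (the
count-based density matches the per-peak counting style of the overlap
statistic; a base-pair density variant would weight long peaks more). The
empirical p is #{null ≥ observed}/N exactly — ties count toward p, there is
no add-one correction, and p = 0 is reported with the bound < 1/N. Both
tests are one-sided in the enrichment direction. The density test uses all
N background sets as its control distribution, the same machinery as the
overlap test: a single background set cannot form a null distribution of a
test statistic, so both statistics share the N-set null.

## Conservation classification

Classes partition [0, 1] with strict thresholds: score > 0.98 direct,
> 0.84 indirect, else nonconserved — a score exactly at a boundary falls in
the lower class. Functional conservation requires, in order: a conserved
class, projected target coordinates present, and ≥1 bp overlap with a
target-species DAR. A conserved projection without target coordinates
(anchor-interpolated) is therefore not functionally conserved, and a
nonconserved projection that happens to land on a DAR stays nonconserved.
DARs lacking a projection record count as nonconserved and are logged.
Identity retention is the fraction of functionally conserved DARs whose
best-overlapping target DAR (largest overlap, ties to the leftmost target)
shares the source tissue. The ectoderm/mesenchyme contrast is the ratio of
per-tissue conservation rates with a two-sided Fisher exact test on the
2×2 conserved × tissue table (the test choice is recorded in output
metadata; any exact 2×2 test would do at these counts). The two projection
directions are computed and reported separately — functional conservation
is not a symmetric relation.

## Synthetic data

All generators are pure functions of (config, seed); randomness flows from
one master seed through fixed numbered substreams, and text outputs are
byte-reproducible. Planted truths (significance counts, in-block flags,
class labels, tissue assignments) are returned and written to sidecar
tables for assertions.

* **Genome.** Per-1-kb GC drawn from Beta(41, 59) (mean 0.41, sd ≈ 0.05,
  mammal-like isochore scale); bases i.i.d. within a window given its GC.
  No dinucleotide structure — nothing downstream consumes it. Genes
  (default 10 per Mb) are placed uniformly without overlap with 3–6 exons
  and a coding span leaving both UTRs nonempty, so every annotation class
  is realizable.
* **Haplotype panel.** Each chromosome is partitioned into latent segments
  (exponential lengths, mean 50 kb). Per segment, a founder indicator is
  drawn per haplotype and each haplotype either carries the founder
  haplotype across the whole segment (probability ρ, default 0.95) or is an
  independent Bernoulli(½) recombinant. Expected within-segment r² is ≈ ρ²
  (≈ 0.90 at the default) and ≈ 0 across boundaries. A per-SNP copying
  variant was prototyped and rejected: it yields expected r² ≈ ρ⁴ ≈ 0.81,
  too close to the 0.8 block threshold for boundary recovery to be a sharp
  property (31% vs 100% recovery in an identical harness). The per-segment
  model is also the better cartoon of real haplotype mosaics.
* **GWAS.** 2400 hits, 1687 significant (drawn log-uniform below 5×10⁻⁸;
  the rest uniform above), with significant hits placed uniformly inside 8
  designated trait segments and groups rotating over EUR/AFR/EAS/SAS/AMR.
  Hits are intentionally *not* restricted to panel positions — proxies are
  the point of the block procedure. All population groups share the one
  simulated panel; per-group panels are supported by the block builder but
  are not the default desk-scale condition.
* **Peaks.** Fixed 501-bp width (the fixed-width scATAC peak convention),
  default 2000 peaks with enrichment factor λ = 5 inside the trait blocks:
  a peak is in-block with probability λf/(λf + 1 − f) for block fraction f,
  uniform within its compartment, clipped to chromosome ends.
* **Projections.** Class proportions default to (0.143, 0.411, 0.444) with
  scores uniform within each class band (boundary-exclusive, so planted
  labels round-trip exactly through the classifier). Conserved DARs hit a
  target-species DAR with per-tissue probabilities (0.29 ectoderm, 0.066
  mesenchyme; the reverse direction scaled by 2/9), chosen so the default
  run shows ≈9% (mouse→chicken) and ≈2% (chicken→mouse) functional
  conservation and a ≈4.4-fold ectoderm/mesenchyme rate ratio. Misses are
  placed in guaranteed DAR-free gaps of a gridded target genome, so planted
  conservation truth is exact. Identity retention defaults to 0.8.

What the generator does *not* emulate: coalescent genealogies and
recombination-rate variation, selection, empirical GC landscapes, peak-width
heterogeneity, and any spatial correlation between genes, GC and trait loci.
Passing tests therefore demonstrate the correctness and calibration of the
*procedures* under controlled LD and enrichment structure — not robustness
to every property of real genomes.

## Simulation-study conditions and numerical notes

The replicate experiments fix one genome (and its tiling, annotation and
strata) and re-simulate the stochastic layer per replicate. Study sizes:
type-I calibration uses λ = 1, a 4-Mb genome, 1000 peaks, blocks covering
5%, 200 replicates × 200 background sets; power/fold recovery uses λ = 5,
blocks 2%, 500 peaks, 200 sets, 100 replicates; block recovery uses ρ =
0.95, 200 haplotypes, 100 trials on 500-kb chromosomes; the conservation
contrast uses planted rates 0.44/0.10 at n = 500 per tissue over 100
replicates. In the calibration geometry, test blocks are deliberately
offset from the 500-bp tile grid: grid-aligned blocks would deny background
tiles the partial edge overlaps that arbitrarily placed peaks receive,
biasing the observed statistic high by about one tile per block edge.

Block-recovery error is measured against the outermost panel variants
inside the latent segment, not the latent breakpoints: with randomly placed
SNPs the nearest variant is already ~Exp(spacing) from the breakpoint, which
no r²-based method can see past.

Degenerate inputs: empty peak or block sets give zero counts (density
errors on zero block length); an empty background list is an error; r² of
vectors shorter than 2 is an error; a GWAS SNP with no panel variant in the
window produces the documented 1-bp block.

## Known limitations

* The LD model is a two-founder caricature; allele frequencies concentrate
  near 0.5, so frequency-dependent r² behaviour is unexplored.
* Stratified matching guarantees equality of the joint (GC bin, annotation)
  histogram, not of finer covariates (TSS distance, mappability).
* Empirical p-values are bounded below by 1/N; claims beyond that
  resolution require more background sets, not extrapolation.
* The projection algorithm itself is consumed, never computed: the package
  starts from a projection-score table and inherits its biases.
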