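# Methods

## Competition model and fitness definition

The simulator and the scorer share one model. Each barcoded mutant *i*
carries a relative fitness *w_i*, defined as doublings per population
doubling (neutral *w* = 1). Growth is deterministic and exponential
between sampling events:

```
p_i(g) = p_i(0) · 2^(g·w_i) / Σ_j p_j(0) · 2^(g·w_j)
```

where *g* is population doublings since T0. For a rare mutant in a
mostly neutral pool the denominator is ≈ 2^g, so the expected log2 fold
change of its frequency is Δ = g·(w − 1). This parameterization was
chosen because it makes the scorer's inversion exact in expectation:
gene effects planted as w = 1 + f*/g come back as fitness scores f ≈ f*,
and growth rates invert as μ = μ_pop·(1 + Δ/g), with μ_pop the nominal
population growth rate (1/h). The correction from a mutant's own
contribution to the population mean is neglected; at library scale
(each mutant ~1/60,000 of the pool) it is far below 1% relative error,
which the test suite verifies explicitly.

Sequencing is multinomial at fixed per-sample depth — the simplest noise
model consistent with the scorer's assumptions. A per-barcode
overdispersion (PCR jackpot) model is deliberately not included; the
consequence is that simulated counts are less dispersed than real BarSeq
data, so recovery benchmarks here bound the method's statistical (not
experimental) error. Starting frequencies get a log-normal spread
(σ = 0.5 by default) so T0 abundances vary as they do in a real
conjugation library.

### Feeding regimes

Continuous (chemostat) and batch regimes have no drift term: dilution in
a chemostat removes cells independently of genotype and the population
stays large. The pulsed (turbidostat-style) regime adds genetic drift:
each pulse replaces 6.2% of the culture volume with fresh medium (the
reactor geometry: 4 mL added to 65 mL), i.e. ~0.092 doublings of regrowth
per pulse, and the surviving pool is resampled multinomially at a
configurable effective population size (default 10⁷, a scaled-down stand-in
for the true reactor census, which is far larger). The true bottleneck
size during sampling events is not asserted; it is a parameter.

## Synthetic genomes and libraries

`make_genome` tiles non-overlapping genes with fixed intergenic gaps
over three replicons (55/35/10% of genes), default 6,600 genes — the
scale of the *C. necator* genome with its two chromosomes and
megaplasmid. Gene lengths are normal (mean 900 bp, sd 30%, floor
150 bp). Fixed gaps keep interval arithmetic exact for tests; real
genomes have variable gaps and overlapping features, which the
assignment code does not rely on either way.

`make_library` places insertions uniformly over the genome excluding
declared essential genes — essentiality is modeled as the *absence* of
viable mutants, matching the fact that strictly essential genes yield no
fitness score at all. A `per_gene` placement mode plants a fixed number
of barcodes per gene (default 5) plus a fraction of intergenic
insertions (default 10%), which is the configuration used for recovery
benchmarks. Insertions avoid a 50-bp margin at each replicon terminus:
replicons are circular in reality but linear strings here, and the
margin guarantees every junction read has a full-length genomic tail.

`plant_gene_effects` defines the benchmark's effect distribution:
f* ∈ {−3, −2, +1} on 10% of genes each, the rest neutral. Most genes in
a pooled screen are phenotypically neutral in any one condition (in this
kind of screen a few hundred of several thousand scored genes cross the
significance threshold), and a majority-neutral pool keeps the
per-condition median a valid neutral reference for centering.

## Barcode extraction and counting

Reads have fixed structure left-flank + N20 + right-flank (the standard
RB-TnSeq U1/U2 priming sites are the defaults). Matching is
substitution-only — the amplicon has fixed geometry, so indel alignment
buys nothing — with a configurable mismatch budget per flank and a short
right anchor (first 6 bp of the right flank). The leftmost acceptable
offset wins. Unknown barcodes are dropped by default because the library
is pre-mapped; optional distance-1 collapse attributes a barcode with a
single sequencing error to its unique known neighbor (ambiguous
neighbors are discarded). Raw read counts are used as-is; no UMI
deduplication is performed. Barcodes whose mean T0 count falls below 10
are removed before scoring — low-count T0 barcodes make log2 fold
changes unstable; the threshold is a declared default, not an inferred
value.

## Insertion mapping

The genomic tail after the right flank is located by exact substring
search against both strands of every replicon, via a sorted 2-bit-encoded
k-mer seed index (k = min(20, tail length)) with full-tail verification.
At bacterial genome scale and with ≥ 20-bp tails this is exhaustive and
fast; a full aligner would add dependencies without changing the answer
on exact data. Position convention: the insertion position is the first
genome base after the transposon junction, 0-based; a reverse-strand hit
places the insertion at the 3' end of the match.

A barcode is `unique` when all of its reads agree on one locus within a
±3-bp jitter window, or a ≥ 75% majority does; `ambiguous` when any
read's tail matches several loci or the reads disagree beyond that; and
`unmapped` otherwise. Ambiguous barcodes are excluded from gene
assignment entirely (never fractionally assigned) to avoid double
counting. Jitter window and majority threshold are declared defaults.

Gene assignment uses a central window (default 10–90% of gene length,
strand-aware): insertions in the terminal 10% of a gene often leave
function intact, following common RB-TnSeq practice. Unassigned barcodes
still contribute to frequency normalization.

## Gene fitness scores

Per condition and generation: barcode log2 fold changes (pseudocount 0.5
on counts before normalization — avoids −∞ for washed-out mutants at the
price of conservatively shrinking large |Δ|) are averaged per gene
within each replicate (unweighted; a count-weighted mean is a
configuration option), replicate means are averaged (≥ 1 replicate
required), and scores are centered by subtracting the per-condition
median over all scored genes. Centering anchors "neutral" to the bulk of
the distribution; whether the original pipeline centers or normalizes to
a reference set is not documented, so this is the package's own declared
choice. Cells with no barcodes are missing, never zero-filled.

Scoring defaults to the g = 8 samples; g = 16 columns are scored but
reported separately (selection has had longer to act there, so scores
are not commensurate across generations). Significance: |f| ≥ 2 in any
condition after at least eight generations, threshold inclusive.

## Clustering and enrichment

Hierarchical agglomerative clustering with Ward linkage on Euclidean
distances between raw fitness profiles (no row scaling — all values
share the log2 scale). Missing cells are imputed to 0 (missing means
"not scored"; neutral is the closest assumption) with the count logged.
The cluster number k maximizes mean silhouette width over k = 2–12
(range configurable, scan range is a declared default), ties broken
toward smaller k; identical rows are rejected as degenerate input.

Over-representation uses the hypergeometric upper tail
P(X ≥ overlap) with the scored-gene universe, on a plain (gene, pathway)
annotation table, so no pathway-database client is needed. Raw p-values
are the primary ranking (top-3 reporting mirrors common practice);
a Benjamini–Hochberg column is emitted alongside for convenience. A
t-SNE embedding helper exists for plotting only.

## Protein cost

Individual cost of a knockout = the proteome mass fraction ψ (% of total
protein mass) of its own product. Total cost sums ψ over the affected
set: the knocked-out gene, all downstream genes of its transcription
unit (transposon insertions are assumed fully polar; `polar=False`
models an in-frame deletion affecting only the gene itself), and —
iterated to a fixed point — all genes of every unit whose promoter
depends on a regulator already silenced. The dependency graph must be
acyclic, which is enforced at model construction; the hydrogenase system
is acyclic.

The packaged hox/hyp fixture encodes the megaplasmid hydrogenase
arrangement: MBH operon (hoxK…hoxV), accessory hyp operon
(hypA1…hypX), regulatory hoxABCJ unit, SH operon (hoxF…hoxI), with the
HoxA master regulator activating P_MBH and P_SH. The dependence of hoxA
expression on secondary promoters inside the hyp operon is encoded as
dependency edges from hypA1/hypB1 to the regulatory unit's promoter;
this edge is hypothesis-derived (it reproduces the observation that
primary hyp knockouts act like hoxA knockouts), not an independently
measured transcript. The fixture's mass fractions are **synthetic**
placeholders with the observed rank structure (SH operon ≫ hyp > MBH ≈
regulators); measured proteomics values can be dropped in as a TSV with
the same columns.

## Growth phenotypes

μ_max: a window of fixed 5-h time span slides over the OD series one
sample at a time (span-based windows tolerate missing samples; the
stride is one sample because the cost of full resolution is negligible),
a least-squares line is fitted to ln(OD) vs. time in each window, and
the maximum slope is returned. Natural log is used so the slope is μ
directly. OD series are assumed blank-corrected. Biomass yield =
DCW (mg) / (substrate (g/L) × volume (L) × 1000), gDCW per g substrate.

## Problem sizes and numerical choices

The recovery benchmark runs at 500 genes × 5 barcodes/gene (+10%
intergenic), depth 2×10⁶ reads/sample, 4 samples — about half a minute
end to end including read-level simulation and recounting. Unit tests
use smaller pools (100 genes, 500 barcodes) and depths of 10⁴–10⁶.
Monte-Carlo checks of the log-linearity of rare-mutant trajectories use
200–300 replicate draws and compare means within 3 standard errors plus
a small allowance (0.05) for the Jensen bias of log-of-counts at finite
depth. Enrichment p-values are validated against exact rational
(Fraction-based) tail sums to 10⁻¹⁰. Seeds are explicit arguments
everywhere; nothing reads global random state.

## Known limitations

- No PCR-chimera, index-hopping, or per-cycle quality error models; the
  substitution-error model is i.i.d. per base.
- Multi-insertion clones (one barcode, two loci in one cell) are not
  modeled and would surface as `ambiguous` barcodes.
- No moderated/shrinkage variance model for fitness scores; replicate SD
  is reported but not used for weighting.
- The protein-cost model treats transcription as on/off polarity; no
  partial polar effects or transcript-level quantification.
- Replicons are linear strings; insertions within 50 bp of a terminus
  are excluded by the generator rather than handled circularly.
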