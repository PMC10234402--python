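# Methods

## Gene-age assignment

Phylostratigraphy places each gene at the most inclusive taxonomic level
that contains a detectable homolog. The implementation consumes a
BLAST/DIAMOND-style tabular hit file, a subject→taxon map, and a lineage
table (taxon_id, semicolon-joined root-to-tip clade names). The focal
species' lineage defines the phylorank ladder; by default nine levels,
from cellular organisms (rank 1) to the focal species (rank 9). A subject
taxon's *divergence rank* is the length of the root-inclusive common
prefix of its lineage with the focal lineage, capped at the ladder
height; a gene's phylorank is the minimum divergence rank over its hits
with E ≤ `evalue_max` (default 1e-5), excluding self-hits in the focal
taxon. Genes with no qualifying non-focal hit are species-restricted and
take the top rank; ties resolve to the oldest rank by the min rule.

Lineage corrections are applied before rank computation: strain→species
renames (duplicates created by a rename merge into one entry), moves of a
named clade to an absolute 1-based level, and wholesale collapse of rank
names into their parent. All three are idempotent, so re-applying a
correction file is safe.

**Taxonomic representativeness.** For a gene assigned rank r, the
diagnostic taxa are the database taxa whose divergence rank equals r —
the level whose presence set the age. Representativeness is the
percentage of diagnostic taxa with at least one qualifying hit; genes
below 30% are flagged as possible contamination or horizontal transfer
and excluded from stratum profiles. The exact formula used by published
tooling is not restated anywhere accessible; the diagnostic-taxa ratio is
this package's documented approximation, and the threshold is exposed.

**Homology detection failure (HDF).** Apparent youth can be an alignment
artifact: scores decay with evolutionary distance until the search stops
reporting hits. Per gene, the best bitscore per non-focal taxon is
regressed as ln S = ln a − b·d on patristic distance d from the focal
taxon (ordinary least squares on the log scale; b floored at 0; residual
SD σ). The fitted model predicts detection at the nearest outgroup beyond
the assigned clade: P(detect) = P(N(ln a − b·d_out, σ) > ln θ), where the
detection threshold θ in bits comes from the Karlin–Altschul-style
mapping E = mn·2^(−S) with effective search space mn = 1e18, giving
θ = log2(mn / evalue_max) ≈ 76.4 bits at E ≤ 1e-5. If P(detect) ≥ 1 − α
(α = 0.05) and the outgroup nevertheless shows no homolog, absence is
informative and the age is high-confidence. Genes with fewer than three
usable taxa, or with all hits at a single distance, are untestable and
conservatively non-confident. The test applies between configurable
ranks (default 4–8, kingdom to genus on the nine-level ladder); older
assignments need no extrapolation and count as confident, the top
(species-restricted) rank is outside the testable range and counts as
non-confident.

Only relative consistency between the E-value filter and the bitscore
threshold matters for the analyses; mn is configurable and its default is
an order-of-magnitude figure for a large protein database search.

## Chromosomal landscapes

**Binning.** RPKM per fixed-width bin (default 200 bp) is
count / ((bin_len/1000)·(total_mapped/1e6)). Each read contributes
overlap_bp/read_length to every bin it overlaps, so bin counts sum
exactly to the number of reads and agree with a per-base counting oracle;
whole-read-per-bin counting would violate one or the other for
bin-spanning reads. Exact duplicate intervals are dropped by default,
mirroring common coverage-tool behavior.

**Smoothing.** Feature values are regressed on chromosome position with a
penalized cubic B-spline (P-spline): basis dimension 10, second-order
difference penalty on the coefficients, penalty weight selected by
generalized cross-validation over a 25-point log-spaced grid (1e-4 to
1e8). Linear trends span the penalty null space, so heavy smoothing
shrinks toward a line, and adding a constant to the data shifts the fit
by the same constant. This approximates the shrinkage cubic spline of
standard GAM software without promising coefficient-level equivalence;
accuracy is asserted by function recovery (noise-free sine recovered to
RMSE < 0.001 of amplitude at 500 points; RMSE to truth about 0.1σ under
Normal noise at 1,000 points). Chromosomes with fewer distinct positions
than basis functions fall back to an ordinary linear fit.

**Permutation test.** Gene ages are permuted genome-wide (default 1,000
times) with positions fixed, and the mean permuted age per gene is
recorded. Per chromosome, a paired t-test compares observed ages with
the permutation-mean ages at the same positions — asking whether the
chromosome's age composition departs from genome-wide reshuffling — and
p-values are Benjamini–Hochberg adjusted across chromosomes. Smoothed
observed and permutation-mean profiles are returned for plotting. The
pairing is deliberately on raw values: pairing the *smoothed* values
instead makes the t-test wildly anti-conservative (measured ~85%
rejections on null genomes, because smoothed residuals are correlated
along the chromosome), while calibrating that same statistic against its
permutation distribution destroys power (the t-statistic penalizes
exactly the spatial non-uniformity a planted young block creates).
Measured on synthetic genomes, the raw-value test holds type-I error
near 0.03 at α = 0.05 (400 null replicates, 200 permutations) with
power 1.0 on planted blocks of rank contrast ≥ 4 (20 replicates); the
mild conservatism comes from the permutation mean including each
chromosome's own genes.

**Young regions.** Bins exceeding the genome-wide 0.9 quantile of both
the smoothed age track and the smoothed small-RNA track are merged when
within 100 kb, and merged runs shorter than 200 kb are dropped. The raw
binned small-RNA signal is sparse (most bins zero), so the smoothed
track is thresholded; a quantile threshold that equals the track minimum
means the track is flat and no region is called. Output is sorted and
independent of input row order. The published two ~2 Mb loci were
identified visually; these thresholds are this package's own calibration
on synthetic data, and all four knobs are exposed.

**Per-gene correlation and methylation.** Age–expression association at
the single-gene scale uses Spearman rank correlation (Pearson optional);
constant input is reported as undefined rather than 0. The methylation
filter keeps CG rows with 5mC strictly above 80%, auto-detecting
fraction-scaled tables and dropping out-of-range rows with a warning.

## Poly(A) tails and the polyadenylation signal

A tail is the longest 3′-terminal segment with ≥ 90% A content, no
internal non-A run longer than 2 nt, length ≥ 10 nt, starting on an A;
up to 2 trailing non-A bases are clipped first. The thresholds are not
dictated by any published description; the 10 nt floor matches the
smallest tails observed in fungal spore transcripts and all three are
configurable. The detector is idempotent: removing a called tail leaves
no further callable tail.

Cleavage positions collapse into unique sites by single-linkage
clustering within 5 nt on the same reference and strand (radius 0
degenerates to distinct positions), reported at the modal position with
read support. Without a genome alignment, reads collapse by identical
50 nt upstream windows — adequate for signal tallying, not for genomic
site annotation.

The signal tally scans each 50 nt upstream window (RNA alphabet) for an
18-variant panel: the canonical AAUAAA, its single-base substitutions
observed in fungi, and three AAUGAA-type derivatives. If the canonical
hexamer occurs anywhere it is called; otherwise the variant occurring
nearest the cleavage end; otherwise NONE. One call per site makes counts
sum to the number of sites, and percentages are reported to one decimal.
Whether published tallies count multi-variant windows once or multiply
is unknown; the one-call rule is this package's documented choice.

## Assembly QC

N50/L50 sort piece lengths descending and take the first piece at which
the cumulative sum reaches half the total (NX/LX generalize to any x).
Contigs derive from scaffolds by splitting at runs of ≥ 10 N (the NCBI
gap convention; the threshold is a flag since contig statistics depend on
it), and splitting is exactly invertible. Telomere detection counts exact
tandem copies of TTAGGG: reads qualify with ≥ 8 copies of the unit or its
reverse complement anywhere; scaffold ends are classified from the
terminal 1 kb windows, expecting CCCTAA arrays at 5′ ends and TTAGGG at
3′ ends, so reverse-complementing a scaffold swaps its end states.
Mismatch-tolerant (HMM) telomere matching is deliberately out of scope;
on random sequence the exact-match rule produced zero false calls in 100
seeded 1 Mb sequences. Percentages in completeness reports use half-up
rounding at the printed precision, implemented in decimal arithmetic so
that e.g. 726/758 → 95.8% and 1,288,465/1,288,893 → 99.97% reproduce
exactly.

## Synthetic data: what it emulates, what it does not

The generator's defaults describe a scaled-down chromosome-scale fungal
genome with realistic densities: 4 chromosomes of 1.5 Mb (one gene per
5 kb, matching ~30k genes on a ~147 Mb genome), telomere arrays of 25
units per end, one 100 bp N gap, and one 500 kb young block per genome
(the real loci are ~2 Mb on ~5 Mb chromosomes; the proportion, not the
absolute size, is preserved). Background gene ages are Normal around
rank 1.5 (most genes ancient), young blocks Normal around rank 8, both
discretized and clipped to the ladder. Small-RNA locus weights are
gamma-distributed and 8-fold higher inside young blocks; long-RNA
coverage is 4-fold higher outside; 5mC is Beta-distributed with mean 80%
inside blocks and 20% outside. Homology bitscores decay as
400·exp(−0.4·d) with Normal(0, 5) noise along a ladder tree whose taxa
sit at patristic distances 0.5–4.0; hits falling below the 76.4-bit
detection threshold are not emitted — that omission *is* the simulated
homology-detection failure. Poly(A) reads plant the panel variants at
the fungal proportions (56.7% canonical, 22.8% no signal) 10–30 nt
before the cleavage point, with geometric tails of mean 42 nt floored at
10; windows are rejection-sampled so the planted call is unambiguous and
the last three window bases are non-A so the cleavage point is exactly
recoverable.

All randomness flows from one integer seed through per-stage generator
streams; identical configs give byte-identical files.

Deliberately not emulated: read error profiles, base composition bias,
repeat structure, Hi-C contacts, raw signal. Passing tests therefore
demonstrate correctness of the statistical machinery on data satisfying
the model's assumptions — not robustness to alignment artifacts,
sequencing error, or compositional heterogeneity of real genomes.

## Numerical choices and degenerate inputs

- GCV grid 1e-4..1e8 (25 points); decay-fit slopes within 1e-12 of zero
  snap to b = 0; paired differences with zero variance report p = 1.
- Permutation p-values use the t-distribution of the paired test; the
  smallest meaningful adjusted p is bounded by the number of chromosomes.
- Empty hit lists, missing diagnostic taxa, sub-minimal point counts and
  short upstream windows are logged and handled (youngest rank,
  exclusion, untestable, NONE respectively), never silent.
- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  converts at I/O boundaries; bedGraph/BED pass through unchanged.

## Known limitations

- The representativeness formula and the young-region thresholds are
  documented approximations of procedures whose exact definitions are
  not public; both are configurable rather than asserted.
- The HDF test extrapolates a two-parameter decay over modest distance
  ranges; on ladders where all of a gene's hit taxa are equidistant the
  gene is untestable by construction.
- Site collapsing without a reference treats identical upstream windows
  as one site; two genomic sites with identical upstream sequence would
  merge.
- Problem sizes in the test-suite simulations (replicate counts, bundle
  dimensions) are the package's chosen defaults for routine validation;
  all scale up by configuration.
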