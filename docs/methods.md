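# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `cnescan`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Upstream region extraction

Regions are anchored at (and exclude) the 5'-most annotated translation
start across a gene's transcripts — the most stable anchor available when
transcription start sites are unreliable — and read 5'→3' in gene
orientation (minus-strand regions are reverse-complemented). The default
span is 2000 bp, enough to cover most 5' UTR plus proximal promoter
sequence. A candidate region overlapping any *other* gene's span (either
strand; transcript-level spans are not consulted) is truncated to keep the
translation-start-proximal part; if another gene covers the base immediately
upstream of the translation start — in particular when the whole candidate
lies inside it — the gene is removed from the analysis. Internal coordinates
are 0-based half-open everywhere; GFF3 is converted on read.

## Window alignment

The scan computes the optimal *global* alignment score for every pair of
50 bp windows between two regions, scoring +1 per match, 0 per mismatch and
−0.5 per gap symbol, N mismatching everything (annotated repeats are masked
to N before alignment, realizing the repeat penalty). Global end-to-end
alignment of fixed-length windows is the natural reading of a fixed scheme
with one gap weight and avoids the shadowing of short strong alignments by
longer mediocre ones; a 1 bp step in both sequences gives the printed
(1951)² ≈ 3.8 M alignments per 2 kb comparison.

Under this scheme an alignment with x substitutions and g total gap symbols
scores `(|a|+|b|)/2 − (x + g)`, since it has `(|a|+|b|−g)/2` aligned pairs.
Maximizing the score is therefore equivalent to minimizing unit-cost edit
distance, and the all-pairs grid is computed with a Myers bit-parallel
edit-distance kernel (numba, one 64-bit word per ≤64 bp window), about 1 s
per 2 kb × 2 kb comparison on one core. The kernel is exact — scores are
integers for equal-length windows — and the test suite pins it cell-by-cell
to the direct quadratic dynamic program (`window_pair_score`), which also
handles arbitrary scoring schemes and unequal lengths.

## Scoring, bundling and calibration

Raw window scores are mapped to *intermediate scores* 100·raw/w, so the
upper bound U = 100 coincides with perfect conservation of a window.
Conservation scores use a logistic sigmoid between the bounds, with slope
k = 10/(U−L) at the midpoint and an affine rescaling to hit exactly 0 at L
and 1 at U; the curve is strictly increasing on (L, U) with value ½ at the
midpoint. The exact functional form is a package choice (only the endpoints
and sigmoid shape are dictated by the protocol); all detection decisions are
threshold crossings, so any midpoint-symmetric sigmoid gives identical call
sets at the same bounds.

Window pairs with intermediate score > L are bundled: central-species window
intervals `[offset, offset+50)` that overlap are merged transitively across
species; each merged interval collects, per species, the hull of that
species' overlapping windows as its support interval and the maximum
conservation score as `P_i`, combined as CCS = 1 − Π(1−P_i). `P_i` is taken
as the maximum over the merged support (not per pre-merge fragment), matching
the definition of P as the maximum conservation score for a potential
element in a species.

The detection threshold is the maximum CCS among candidates called on
pseudo-ortholog pairs (a uniform random derangement of the genes, sampled by
rejection), with the strict rule CCS > threshold, so the control set yields
zero detections *by construction*. Real non-orthologous sequence is the
right null here: it retains genomic composition and motif structure that
shuffled sequence destroys. Discovery is two-phase — candidates at
(L=80, U=94), coding filter, final scores at (L=87, U=100) — with the final
bounds acting only as a confidence scale for candidates already deemed
significant.

The coding filter takes the minimum e-value achieved by permuted candidate
sequences against a protein database as the threshold below which a true hit
marks unannotated coding sequence; with no permuted hits at all the
threshold is +∞ and any hit removes its candidate (logged prominently — this
limit indicates the permuted control was not actually searched).

## Synthetic cohorts

The generator is the package's study-condition definition, not a tuning
knob. Defaults: 2 kb ancestral regions at GC 0.40 (AT-rich intergenic
background), a central species plus four comparators on a star phylogeny,
background substitution rate 0.35 per site per branch with 1 % indels
(geometric lengths, mean 3) — deep divergence at which background windows
pair at ≈46 % identity, far below the L=80 bound — and planted 90 bp
elements at a fixed distance from the translation start evolved at their own
rate (default 0.02; the recovery analyses use 0.05). Elements are spliced in
after background evolution, so indels never land inside them and positional
truth is exact. One contig per gene (region + 300 bp synthetic gene body)
makes extraction recoverable byte-for-byte. Planted repeats are tandem
copies of a fixed 10-mer, annotated in BED for masking. Synthetic
transcripts cover a 5'-anchored fraction of each element, with the
element/body junction broken so no 20-mer spanning it can extend a match.

What the generator does *not* emulate: phylogenetic correlation between
comparators (star topology only), rate heterogeneity along the sequence,
selection, low-complexity and compositional structure of real intergenic
DNA, and real repeat families. Consequently pseudo-ortholog pairs on a clean
synthetic background essentially never produce candidates (background
identity between unrelated draws is ≈ GC²+AT² ≈ 33 %), the calibrated
threshold is typically 0, and the pseudo-CNE set is empty — on real genomes
chance similarity between AT-rich stretches makes this control populated, as
the original protocol's cutoff of 0.528 reflects. The characterization
drivers therefore compare CNEs against geometry-matched random control
regions (identical length and distance-to-TLS upstream of other genes),
which is also the protocol's control for composition and motif statistics.
Passing tests demonstrate correctness of the machinery under these
conditions, not performance on real genomes.

## Statistics

- **Rank-sum test**: exact enumeration of all C(n+m, n) group assignments
  with midrank ties for n+m ≤ 12 (two-sided p doubles the smaller tail,
  the `wilcox.test` convention); above that, the tie- and continuity-
  corrected normal approximation. At 12 < n+m ≤ 16 the approximation tracks
  the exact p to about a percent (worst around p ≈ 0.2); the suite asserts
  max |Δp| < 0.02, mean < 0.01.
- **Positional conservation**: Spearman rank correlation of distances to the
  translation start (central vs comparator), t-approximation p, exact
  permutation enumeration for n ≤ 10. Pearson can be substituted via
  `scipy.stats` by the caller; Spearman is the default because distances are
  heavy-tailed and the protocol's figure is rank-like.
- **Hypergeometric enrichment**: exact integer arithmetic (`math.comb`), so
  tail probabilities are meaningful at any magnitude.
- **Transcribed overlap**: exact both-strand 20-mer set matching (a
  deterministic replacement for a short-read mapper whose mismatch tolerance
  is configuration-dependent); an optional ≤1-mismatch budget exists but is
  off by default. A k-mer overlap percentage converts to a covered-length
  fraction as (matched + k − 1)/length when testing the "≥ ⅓ of the element
  transcribed" rule.
- **CpG O/E**: obs(CG)·len/(#C·#G) with len counting non-N positions;
  undefined (flagged, not zero) when the sequence lacks C or G.

## RNA structure

Folding goes through an engine contract. The default engine maximizes
Watson–Crick + GU pairs (Nussinov recursion, minimum hairpin loop 3,
energy −1 per pair); the consensus fold maximizes, over non-crossing column
pairings of the alignment, the summed fraction of rows that can pair at each
column pair (all-gap columns dropped with a coordinate map; zero-fraction
pairs are never used). Ties in energy prefer fewer pairs; the reported
structure comes from a deterministic canonical traceback (leftmost base
paired to its smallest admissible partner, unpaired preferred on full ties).
SCI = consensus energy / mean independent (de-gapped) row energy, undefined
and flagged when the denominator is zero. For this engine the consensus can
never beat the mean independent fold, so SCI ≤ 1; SCI > 1 (compensatory
mutations) is observable only with the thermodynamic engine
(RNAfold/RNAalifold via subprocess), whose numbers are never mixed with the
fallback's.

Significance uses column shuffles that preserve the conservation pattern:
columns are permuted only within classes of identical (gap pattern, number
of distinct non-gap residues). The empirical p-value uses the add-one rule
(1 + #{shuffled SCI ≥ true}) / (n_valid + 1) — never exactly zero — with the
Z score against the shuffled distribution reported alongside, since the
protocol is ambiguous about which produced its printed values. Default
n = 1000 shuffles; reports with fewer than 10 valid shuffled SCIs are
flagged unreliable.

## Motif statistics

PWM distance is the summed per-column Hellinger distance
h = √(½ Σ (√p−√q)²) over the best ungapped offset (overlap ≥ min(L_a, L_b,
5) columns, reverse complement considered). The sum — not the mean — is what
makes the published clustering threshold of 1.5 attainable: per-column h is
bounded by 1, so a mean could never exceed 1 and every library would
collapse into a single cluster. Clustering is complete-linkage
(deterministic; inputs sorted by id), cut at 1.5; each cluster is
represented by its lower-median-entropy member. Matrix GC is the
information-weighted mean of per-column G+C probability, weight 2 − column
entropy.

Scanning slides the PWM over both strands; a position is a hit when its
log-odds score against a uniform background reaches 0.8 of the maximum
attainable (probabilities clipped at 1e-9, so windows containing N never
hit but are still counted as scanned). Over-representation uses upper-tail
binomial p-values with the per-position hit probability pooled from the
control sets; a motif is "over" only when its p in the true set is strictly
below *every* control set's p, "under" when strictly above all — with 100
control sets a null motif is "over" with probability ≈ 1/101. The binomial
"strength of matches" weighting and the original linkage method are not
recoverable from the protocol text; both the score fraction and the linkage
are exposed as arguments.

## Problem sizes and determinism

The acceptance script runs discovery at the full study scale (2 kb regions,
10 genes, 4 comparators, ~80 grid computations, about a minute on one core);
the pytest suite uses 400–800 bp regions for the same machinery so the
default run stays fast. All randomness flows through `numpy.random.default_rng`
from explicit seeds; stage seeds are derived from the run seed, and repeated
runs are byte-identical. Window scores are stored as float64 (exact halves),
and score comparisons are exact; the L-bound comparison is performed on raw
scores (`raw > L·w/100`) to avoid rescaling rounding.

## Known limitations

- The star phylogeny ignores comparator relatedness; on real data, closely
  related comparators inflate CCS relative to independent evidence.
- Support intervals are hulls of significant windows; a CNE whose comparator
  support is split by a large insertion is reported as one wide support.
- CNE alignment blocks for SCI are built ungapped (support sequences trimmed
  to the central footprint), adequate for elements conserved without indels
  — as planted here — but a real pipeline would insert an MSA step before
  structure analysis.
- The fallback folding engine counts pairs rather than energies; its SCI and
  p-values are internally consistent but not comparable to thermodynamic
  values.
- `all_window_pairs` requires w ≤ 64 for the bit-parallel path; larger
  windows fall back to the direct DP, which is exact but slow.
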