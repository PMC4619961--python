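# Methods

## Scope and data model

The package analyses how a gene family expanded within and between related
genomes. Its inputs are per-species gene models (GFF3 with CDS features, or
a CDS FASTA keyed by gene/transcript id) and, optionally, an external
pairwise protein hit table in the 12-column tabular format. Coordinates are
1-based inclusive everywhere (the GFF3 convention); any half-open
arithmetic is internal and never serialized. When a gene has several
transcripts the longest CDS represents it — a convention, documented here
because isoform choice is rarely stated in family surveys. Ambiguous
nucleotides are tolerated in a CDS; codons containing them are excluded
from codon statistics.

## Motif scanning

The CCCH zinc-finger motif is C-X4-15-C-X4-6-C-X3-H. Because overlap
handling changes domain counts, the scanner's policy is fixed and simple:
scan left to right; at each start position report the match with the
smallest span (smallest x1, then x2); resume past the reported histidine,
so motifs never overlap. X (unknown residue) may occupy spacer positions
but never matches C or H. Family membership in real studies is usually
curated, so anchor selection accepts either a minimum domain count or an
explicit id list, which wins verbatim.

## Similarity evidence

At genome scale, similarity normally comes from an external search engine;
ingested hits are reduced to the best hit per directed pair (lowest
E-value, ties by bit score). For simulated or desk-scale data the package
computes similarity itself: exact global alignment under BLOSUM62 with
affine gap cost `11 + L`, and a surrogate expectation value in the
Karlin–Altschul form `E = K·m·n·exp(−λS)` with fixed constants λ = 0.267,
K = 0.041. These constants are a documented surrogate that lets one set of
thresholds (10⁻¹⁰ within species, 10⁻²⁰ between species) govern both
evidence sources; no claim is made that they reproduce any particular
search engine's E-values, and no result here depends on that.

Tandem duplicates are family members on one chromosome separated by at
most `max_intervening` (default 1) non-family genes; runs chain into
arrays, so three consecutive members yield two pairs, not three. The
default operationalizes "same or neighbouring intergenic regions" and is
configurable.

## Microsynteny blocks

Each anchor's region is the set of genes whose span overlaps the window
`[anchor_start − W, anchor_end + W]` (default W = 100 kb) by at least one
bp — whole spans, not midpoints, anchor always included, window clipped to
the chromosome. For a region pair, qualifying hits are reduced to one
E-value per unordered gene pair and accepted greedily in ascending E-value
order while both genes are unpaired (the literature rarely states how
many-to-many hits are resolved; greedy best-first is deterministic and
order-independent). A block requires at least 3 conserved pairs, counted
excluding the anchor–anchor pair itself (a `count_anchor` switch restores
the inclusive convention).

Orientation is the Kendall-type concordance of partner order: all
pairs-of-pairs concordant → `same`, all discordant → `opposite`, otherwise
`mixed`. The conserved-microsynteny flag requires ≥ 80 % (inclusive) of
pairs to be simultaneously order-concordant (agreeing with the block's
dominant direction against a majority of the other pairs) and
strand-concordant with that direction (same strands for parallel blocks,
flipped for inverted ones). Syntenic quality is
`2·pairs / (genes_a + genes_b)` in (0, 1], computed after collapsing each
tandem array to its left-most member on both sides; both the raw pair
count and the normalized quality are reported, since the two conventions
coexist in the literature.

Anchor pairs whose windows overlap on the same chromosome are skipped as
trivial self-synteny. The scan evaluates every unordered anchor pair within
and between species with the scope-appropriate threshold and emits blocks
in deterministic (species, chromosome, coordinate) order.

## Ka/Ks (NG86) and dating

Conserved pairs are aligned at the protein level; codon columns are taken
only from gapless aligned columns, dropping codons with ambiguous bases or
stops. Counting follows Nei–Gojobori (1986): per codon position, the
synonymous fraction of the three single-base changes with stop-creating
changes excluded from the denominator, so S + N = 3 per codon; site counts
are averaged between the two sequences. Multi-difference codons average
the per-step classification over all orderings of the single-step paths,
excluding paths through stop codons (equal path weights, as in the
original method). Proportions are corrected with Jukes–Cantor
`d = −¾ ln(1 − 4p/3)`; p ≥ ¾ yields an infinite, saturated estimate.
Estimates with Ks > 2.0 are flagged saturated and excluded from block
means but retained in per-pair output. Ka/Ks is undefined (serialized
"NA") when Ks is 0 or infinite — never coerced to a number.

Alternative counting families (maximum-likelihood codon models,
transition/transversion-weighted counts) are deliberately out of scope:
NG86 with JC correction is the single documented method, and the package
does not claim to reproduce Ks values computed with other estimators on
other data.

Block dating uses the synonymous clock `T = Ks/(2·rate)·10⁻⁶` mya with the
grass silent-site rate 6.5×10⁻⁹ substitutions/synonymous site/year as the
default (exposed as a parameter). The block mean and sample (n−1) standard
deviation are taken over non-saturated pairs; a single usable pair reports
s.d. 0 with a degenerate flag; a block with only saturated pairs is
undatable, not an error. Dates are reported to 4 decimals. Note that a
date recomputed from a 4-decimal rounded Ks can differ from a date
computed from the unrounded mean by up to 0.0038 mya — the half-ulp of Ks
propagated through the clock.

Sliding-window profiles use window 150 bp / step 9 bp by default; both
must be codon-sized (divisible by 3). Windows start at bp 1 and advance by
the step while they fit; an alignment shorter than one window yields a
single whole-length window flagged short.

## Phylogeny

Distances are Poisson-corrected amino-acid distances with pairwise
deletion: columns gapped or unknown in either row of the pair are dropped
from numerator and denominator; `d = −ln(1 − p)`; p = 1 is flagged
infinite and a replicate containing one is discarded during bootstrap.
Neighbor-joining follows Saitou–Nei with the standard Q criterion and
branch-length formulas; ties are broken by the lexicographically smallest
taxon-pair key so the tree is reproducible; negative branch-length
estimates are clamped to 0 and flagged. Bootstrap support resamples
alignment columns with replacement, rebuilds the tree per replicate, and
reports the percentage of replicates containing each internal bipartition
of the original tree; fixed seeds make it reproducible. Multiple alignment
is out of scope; the module accepts an existing alignment (simulated
families are indel-free and hence already aligned) and offers a
center-star merge of the exact pairwise aligner as a small-fixture
convenience, not a progressive-profile aligner.

## The simulator

The generator's defaults are the study conditions the analysis assumes:
three species splitting at 60 and 15 mya, two chromosomes of 40 genes,
mean gene length 400 codons (clipped below at 200 so that even the oldest
planted homologies remain detectable at the between-species threshold),
mean intergenic distance 10 kb (about 9 genes per 100 kb window — grass
gene density), synonymous rate 6.5×10⁻⁹ /site/year, dN/dS ω = 0.2
(typical purifying selection), and five planted segmental-duplication
groups of 8 genes centred on family anchors — one on the root branch
echoing a whole-genome-duplication-era event, the others lineage-specific
at 45, 30, 15 and 12 mya — plus an inversion inside one duplicated copy, a
tandem copy of one anchor, and a neutral translocation. Anchor genes carry
two planted CCCH motifs (their proteins avoid C/H elsewhere so the
ancestral count is exactly two; motifs may erode as sequences evolve,
which is realistic — recovery analyses therefore identify anchors from the
ground truth, as curated id lists do for real data).

Sequence evolution is a per-site Poisson event model classified NG86-style
rather than a full Markov codon-matrix simulator: synonymous events arrive
at rate `rate·t` per NG86 synonymous site (positions weighted by their
synonymous fraction over non-stop changes) and nonsynonymous events at ω
times that per nonsynonymous site; events interleave in random order,
multiple hits are allowed, and stop-creating changes never occur. This
matches the estimator's own site definitions, which is exactly what the
clock- and ω-recovery properties need, and is far easier to verify. Known
consequences: codon-state drift and back-substitution leave a small
(≈ 1–2 %) downward bias in recovered Ks at moderate divergence — well
inside the stochastic tolerances used — and stop-codon rejection slightly
biases composition at extreme divergences. There are no indels, no rate
heterogeneity across sites, and no demography; orthologous CDSs therefore
stay equal-length and column-alignable, which real data are not. Passing
recovery tests consequently demonstrates correctness of the statistics and
the detection logic under the stated generative model, not robustness to
alignment error or annotation noise.

Every copy event (speciation or duplication) creates new nodes in a gene
genealogy; the divergence time of two extant genes is the age of the event
at which their lineages separated, and their expected Ks is `2·rate·T`.
The ground truth derives from this genealogy the set of anchor-region
pairs a scan should call: flanking genes are matched one-to-one within
shared-ancestor groups under the same windows and same-chromosome-overlap
skip as the scanner, with the anchor–anchor pairing subtracted. When a
region holds extra copies of the anchor's lineage (a tandem array), the
scanner's greedy matching may legitimately pair the partner anchor with a
copy instead of the anchor itself, so the truth count is a lower bound and
recovery is compared on block identity, not exact pair counts.

With 20 % random gene loss (applied per terminal species, anchors exempt,
recorded in the truth), a block planted with 6 flanking pairs survives the
≥ 3-pair threshold with probability ≈ 0.94 per pair-survival arithmetic
(each pair survives with 0.8² = 0.64); aggregate recall over all truth
blocks with ≥ 6 pairs is measured against the pre-loss truth.

## Pipeline and determinism

The pipeline sequences anchors → tandem detection → synteny scan → per-pair
NG86 → block dating → sliding windows → NJ tree, writes a report bundle
(block TSV mirroring the dated-block table layout, per-pair and per-window
TSVs, Circos links, Newick, YAML run log echoing every parameter), and is
byte-deterministic for a fixed configuration and seed. All randomness
(simulator, bootstrap) flows from explicit integer seeds; the acceptance
script derives independent sub-seeds below 2³¹ from its single `--seed`.

Problem sizes used by the test suite and the acceptance script — the
standard three-species scenario (≈ 300 genes), 50 replicate pairs of 1,000
codons for clock recovery, 20 pairs at 60 mya, 1,000 bootstrap replicates
over 24 simulated family proteins — were chosen so the whole chain,
including two full synteny scans, completes in a few minutes on one CPU
while keeping Monte-Carlo standard errors a few percent of the quantities
checked.

## Known limitations

- The surrogate E-value is monotone in the alignment score but not
  calibrated against any search engine; thresholds applied to external
  hit tables and internal alignments are numerically identical but not
  statistically equivalent.
- NG86 with equal path weights ignores transition/transversion bias; on
  real data Ks from different estimators can differ substantially, which
  is why no cross-estimator numerical agreement is claimed.
- The 80 % conserved-microsynteny rule is an annotation, not a filter; its
  per-pair order-concordance vote is one of several defensible readings of
  "same order".
- Center-star alignment is adequate for near-equal-length families only.
- The clock assumes rate constancy; dates inherit the full uncertainty of
  that assumption plus the Ks sampling noise reported as the block s.d.
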