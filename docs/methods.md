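# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, the conditions the synthetic-data generator
emulates, and the limits of what passing tests demonstrate.

## Coordinates and alignment

All internal coordinates are 0-based half-open on the forward strand; GFF3's
1-based inclusive convention exists only at file boundaries.  Minus-strand
hits are stored in plus coordinates with a strand flag.

Pairwise global alignment uses match +1, mismatch −1, gap −2 (linear).
Identity is matching columns over alignment length.  For equal-length
sequences the gapless alignment is optimal under this scoring (replacing a
mismatch, −1, by an insertion–deletion pair, −4, can never help), so the
equal-length path is a vectorised Hamming comparison; this makes the
p-distance of the substitution-only synthetic data exact by construction.
Unequal lengths go through Biopython's PairwiseAligner.  Homology scanning
is exact k-mer seeding followed by ungapped maximal-segment evaluation per
diagonal (Kadane, +1/−1), which is the optimal local alignment for
substitution-only divergence; indel-bearing real data would need a banded
gapped extension, which the default pipeline deliberately does not attempt.

## MITE structure and annotation

A candidate is accepted as a MITE iff all of:

* length ≤ 800 bp (hard cap, also enforced on annotated copies);
* a terminal inverted repeat of length 10–30 bp with ≤ 1 mismatch between
  the 5′ terminus and the reverse complement of the 3′ terminus (the
  longest qualifying length is reported);
* an exact target-site duplication, the longest direct repeat across the
  element whose length is 3, 8, 9 or 10 bp.

Superfamily follows the TSD: TTA/TAA → PIF-Harbinger, 8 bp → hAT,
9–10 bp → Mutator, otherwise unknown.  These are the canonical diagnostic
TSDs of the three superfamilies; the TIR tolerance (≤ 1 mismatch, 10–30 bp)
is a conservative, testable stand-in for discovery heuristics whose internal
thresholds are unpublished.

Families are greedy centroid clusters at **80% identity** (inclusive),
elements processed by descending length with lexicographic tie-break, ids
`DTM/DTA/DTH + ordinal` by descending family size.  Genome-wide annotation
is seed-and-extend homology against family representatives (k = 12 seeds,
every 4th query k-mer looked up, ungapped diagonal evaluation), hits kept at
≥ 80% identity with higher-identity-wins overlap resolution; a hit is
full-length when it covers > 90% of its representative.  Hit boundaries are
snapped outward to the representative's termini when the extension stops
within 5 bp of them — an automated version of manual boundary curation.

The conserved-terminal scan for autonomous-partner candidates reports every
sub-interval starting `GGACTTG` and ending `CAGGTCC` (each ≤ 1 mismatch)
with an exact 9–10 bp TSD, on both strands, 100 bp – 20 kb long.

## Divergence dating

* p-distance: differing ungapped columns / total ungapped columns.
* Jukes–Cantor: k = −(3/4)·ln(1 − 4p/3), domain p < 0.75; implemented with
  `log1p` so k ≥ p holds down to subnormal p.
* Clock: T = k / 2r with r = 5.62 × 10⁻⁹ substitutions/site/year, i.e.
  twice a coding-region rate of 2.81 × 10⁻⁹ (both configurable via
  `DatingConfig`).

A family's amplification time is taken directly from its **mean pairwise**
divergence.  This is a deliberate reproduction of the field convention:
pairwise divergence between two copies of one burst is roughly twice the
copy-to-ancestor divergence, and no pair-vs-root correction is applied.

Modality of the pairwise-k distribution: histogram with 0.02 bins over
[0, 1.5], smoothed by a 3-bin moving average; peaks are local maxima at
≥ 5% of the pair count; unimodal iff exactly one peak.  The bin width,
window and floor make a visual classification reproducible; they are not
fitted quantities.

Neighbor joining is the standard agglomeration with a deterministic
lowest-index tie-break; trees are emitted as unrooted Newick with a
trifurcating root.  The star-shape score is internal branch length over
total branch length (negative NJ lengths clamped to 0 in the ratio);
single-burst families score near 0.

## P/A polymorphism

Flanks are 1 kb, taken immediately adjacent to the element so the TSD copy
stays inside the flank — this is what lets the empty allele (which retains
exactly one TSD) anchor cleanly.  A flank hit qualifies at aligned length
≥ 100 bp and identity ≥ 0.90 with a unique best score; this deterministic
rule replaces an engine-specific BLAST e-value threshold at equivalent
stringency for 1 kb queries.  A locus is allelic when both flanks map to
the same chromosome and strand with inner ends < 1 kb apart (inner ends,
not hit midpoints), and the anchored partner sequence maps back onto the
originating locus (reciprocality).  Presence requires an annotated copy of
the *same family* between the anchors.  Ambiguous or truncated loci are
unresolved and excluded from both numerator and denominator of

```
polymorphic ratio (%) = 100 · (absent_in_reference + absent_in_partner) / common_loci
```

Reciprocality (swapping the genomes exchanges the absence counts) is tested
directly.

## Genomic context

The genome is painted with region classes in increasing priority
intergenic < promoter < intron < gene body < UTR, so the partition conserves
genome length exactly and a UTR always wins; the promoter is the 1 kb
upstream of the TSS, strand-aware.  Relative abundance apportions element bp
across the classes it overlaps and normalises class density by the
genome-wide density (uniform insertion ⇒ 1 in expectation); a midpoint-count
variant serves the positional profiles.  TSS/TTS profiles bin element
midpoints in strand-oriented coordinates (default 5 kb span, 100 bp bins —
the published figure prints no axis parameters).  Chromosome tracks use
1 Mb windows with 100 kb steps, trailing partial windows dropped.

## Small RNA

Tags are unique sequences with counts.  Mapping is full-length, ungapped,
≤ 1 mismatch, both strands — a pigeonhole 9-mer index makes this exact and
deterministic; the same matcher produces the genome-mapped denominator.
The MITE-derived fraction is tag-level (each unique tag counts once), with
a count-weighted variant behind a flag; a multi-mapping tag counts once in
the fraction but each qualifying alignment contributes (count-weighted) to
the 100-bin relative-position histogram.  Representative copies for
positional statistics are members whose length differs from the family
seed by strictly less than 1% of the seed length.

## LTR retrotransposons

Candidates: direct repeat pairs ≥ 100 bp at ≥ 80% identity separated by a
1–15 kb internal region, found by exact 16-mer pairs grouped by separation
(substitution-only divergence preserves the diagonal) and chained, then
extended ungapped with an X-drop of 6.  Validation snaps boundaries to
TG…CA on both LTRs within ±15 bp, and requires an exact 4–6 bp TSD (longest
qualifying), a PBS (≥ 12 bp complementary to the 3′ end of any supplied
tRNA, ≤ 1 mismatch, within 20 bp downstream of the 5′ LTR) and a PPT
(≥ 10 bp window with ≥ 80% purines within 20 bp upstream of the 3′ LTR).
The X-drop/snap split matters: chance matches past the repeat boundary can
overrun it by ~10 bp, so extension is kept tight and the exact-TSD
requirement disambiguates the true boundary during snapping.  Overlap
resolution runs **after** validation so a spurious cross-element repeat
pair (5′ LTR of one copy paired with an LTR of a nearby copy) cannot shadow
the true elements it spans.

Families cluster on LTR sequence alone (completes contribute the 5′ LTR,
solos their whole sequence) at **75% identity**, so completes and solos
cluster together.  Solo-LTRs are homology hits to family LTR
representatives (identity ≥ 0.75, coverage ≥ 0.80) outside every complete
element, with exact 4–6 bp TSD flanks; the no-TSD rule deliberately drops
truncated-element leftovers.  Superfamily defaults to a flagged length
proxy (total length < 8 kb → Copia-like, ≥ 8 kb → Gypsy-like, boundary to
Gypsy) because domain-level classification is out of scope; an override
table (family id → superfamily) replaces the proxy when external domain
calls exist.

## Insertion/elimination dynamics

Element age is T = k/2r on the 5′/3′ LTR divergence (elements with p ≥ 0.75
are flagged undatable).  The age histogram (0.5 My bins, chosen to give
≥ 10 bins over a 0–10 My range) is fitted with y = a · 2^(b·x) by nonlinear
least squares from the initialisation (a₀ = 270, b₀ = −0.5), using scipy's
Levenberg–Marquardt (a damped Gauss–Newton); if the iteration fails, a
flagged log-linear regression on non-empty bins is the fallback.  The
base-2 parameterisation is kept so half-life = −1/b directly.

Per-family dynamics report S/C, mean insertion time (the mean over complete
members stands in for solo ages, which carry no internal clock), mean LTR
and internal lengths and their ratio; families with < 10 complete members
are flagged and excluded from correlations.  Spearman's rho is the Pearson
correlation of mid-ranks with a two-sided seeded permutation p-value
(10,000 permutations), cross-checked against scipy and a brute-force
mid-rank implementation in tests.

## The synthetic-data generator

`synthio` assembles genomes from an i.i.d. background at a stated GC
content (default 0.38), planted gene models (default 40 genes/Mb, fixed
3.2 kb exon/intron/UTR layout), and planted elements:

* **MITE copies** are the family seed with Binomial(L, d) substitutions at
  distinct sites, d per burst (defaults echo the observed family structure:
  an ancient burst near per-copy divergence 0.13, i.e. pairwise ≈ 0.26, and
  a recent near-zero burst), wrapped in an exact TSD of the superfamily's
  diagnostic length.
* **Complete LTR elements** draw ages from an exponential with a stated
  half-life (default 1.8 My); the 5′/3′ LTR pair distance is set from age
  via the inverse JC transform and T = k/2r, with mutation sites split
  between the two LTR copies.  A `solo_fraction` of copies become solo-LTRs
  instead, so S/C ≈ f/(1−f) in expectation.
* **Insertion semantics**: host `…[tsd]…` becomes `…[tsd][element][tsd]…`,
  so excision (P/A pairs) retains exactly one TSD and both alleles share
  their flanks — the structure reciprocal anchoring relies on.
* **Small RNA**: tags sliced from MITE copies with start positions
  over-weighted by a factor B in the terminal 10% bands (exclusive
  mixture; B = 1 is exactly uniform), lengths peaked at 24 nt, plus
  background tags from non-element sequence.

Mutations never touch the TIR termini, TG/CA dinucleotides, TSDs, PBS or
PPT; mutation counts are drawn over the full element length so the realized
divergence is an unbiased estimate of the planted value.  Substitutions
only, by default: p-distance then equals planted divergence and the JC
inversion used for planting is exact.  Planted loci are spaced ≥ 2.5 kb
apart, outside genes and away from chromosome ends.

What this does **not** emulate: indels and nested/fragmented insertions,
segmental duplication and repetitive flanks, GC/mutation-rate
heterogeneity, assembly gaps and errors, and realistic chromosome-scale
repeat landscapes.  Passing recovery tests therefore demonstrates the
correctness of the implemented rules under the stated element model, not
detector performance on real assemblies.

## Problem sizes and determinism

The test suite and acceptance script run on genomes of 0.3–0.7 Mb with tens
of planted copies per family, 2000-element dating simulations, and ~10⁴
small-RNA tags; these sizes give stable statistics for every check while
keeping a full run in the minutes range on one CPU.  Detector
recall/precision is measured at planted divergence ≤ 0.10 with exact
interval matching (IoU ≥ 0.9; ≥ 0.8 for solos).  The fitted half-life of a
single 2000-element dataset has ≈ 5% sampling SD, so estimator accuracy is
reported as the mean over three independent replicate datasets.  All
randomness flows from explicit integer seeds; fixed seeds reproduce outputs
bitwise.

## Known limitations

* Ungapped homology evaluation: divergent copies with indels would be
  truncated at the first indel; a gapped extension mode would be needed for
  real, indel-bearing data.
* The candidate scanner requires both LTRs on the same exact diagonal; an
  indel between LTR copies would split the pair.
* The superfamily length proxy misclassifies unusually long Copia or short
  Gypsy elements; it is flagged and overridable.
* Mean-pairwise dating inherits the convention's upward bias relative to
  copy-to-ancestor age; comparisons between families remain valid.
* The permutation p-value resolution is 1/(n_permutations + 1).
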