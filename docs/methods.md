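# Methods

## Coordinates, species and hit sets

All internal coordinates are 0-based, half-open; conversion to and from
1-based inclusive conventions (GFF3) happens only at the I/O boundary. A
*species* is a distinct read sequence; its *expression* is its read count in
one library, so dereplication conserves the library's total read count
exactly. A *hit* is a (reference, start, strand) triple; antisense means the
reverse complement of the species occurs at that forward-strand position. A
species that equals its own reverse complement produces both a sense and an
antisense hit at the same coordinate, counted as two locations — mapping is
symmetric under reverse complementation, and collapsing the pair would break
that symmetry. x is the number of distinct hits of a species in one
reference set; U/M tags (x = 1 / x > 1) are independent per reference set.

Exact matching is implemented as a hash index over every L-substring of the
references for the read lengths in use (21/22/24 nt by default). Windows
containing non-ACGT characters are not indexed, so N-containing reads and
N-masked reference regions can never match — the behaviour of zero-mismatch
alignment over the DNA alphabet. At the scales this package targets
(megabase references) the index is built in seconds; no compressed text
index is needed. SAM import accepts primary/secondary lines and XA-style
alternative-hit tags, keeping only ungapped, full-length, edit-distance-0
records, and is tested to agree with the internal mapper by round-trip.

## Weighting and per-locus metrics

Un-weighted counting values every location 1; weighted counting values each
location of a species 1/x. The denominator x always comes from a named
*denominator set*, which may differ from the set being tallied: weights sum
to exactly 1 per species only when tallied over the denominator set itself,
and genome-weighted tallies restricted to an annotated population are
deliberately smaller. Expression tallies multiply the weight by the species'
read count.

A hit belongs to a locus only if its full read span lies inside the locus
interval. Reads straddling an LTR/INT border therefore count for the full
element but for neither sub-locus; this avoids double counting at borders at
the cost of slightly undercounting boundary-spanning signal. The *species
count* of a locus counts each distinct species once; the *weighted species
density* instead sums 1/x over in-locus hits (each species contributes the
in-locus share of itself). Both are reported, since a weighted "number of
species" has no single canonical definition; output tables carry the scheme
label.

Window profiles split a locus into n contiguous windows (default 100) whose
sizes differ by at most 1 nt (boundary i at ⌊iL/n⌋). A hit is assigned to
the window containing its 5′-most coordinate in the locus — read start for
sense hits, read end − 1 for antisense hits — so each hit lands in exactly
one window and window totals × lengths reproduce locus totals exactly (a
tested conservation law).

## LTR divergence and insertion age

The two LTRs of an element are identical at insertion and diverge
independently afterwards, so divergence K between them estimates 2rT for
substitution rate r and age T: T = K/(2r), default
r = 1.3 × 10⁻⁸ substitutions/site/year (the rate conventionally applied to
grass LTR retrotransposons). LTR pairs are aligned globally with affine gap
costs (match +1, mismatch −1, open −4, extend −1; Needleman–Wunsch via
Biopython's pairwise aligner, validated against exhaustive enumeration for
short sequences). Gap and ambiguous columns are excluded from the site
count. K is the raw p-distance or a multiple-hit correction:

* JC69: K = −(3/4) ln(1 − 4p/3), undefined for p ≥ 3/4;
* K2P: K = −(1/2) ln(1 − 2P − Q) − (1/4) ln(1 − 2Q) for transition/
  transversion proportions P, Q, undefined when an argument is non-positive.

Saturated alignments report K (and T) as undefined rather than clamping —
silent clamping would bias family age profiles. The default correction is
K2P with JC69 and p available, and the choice is recorded in outputs, since
distance corrections differ negligibly in the low-divergence regime where
LTR dating is reliable but diverge beyond p ≈ 0.2.

## Contamination screening

The internal screen finds exact 20-mers shared between a host element and a
donor sequence (either strand), extends each seed ungapped in both
directions to its score maximum (+1/−1, X-drop 10), keeps extensions with
overall identity ≥ 0.8 and length ≥ 100 nt, and merges overlapping matches
per host/donor pair. This is a deliberately simple BLASTN stand-in with
length+identity thresholds instead of an E-value model; BLASTN tabular
output can be imported instead and filtered at E ≤ 10⁻²⁰ to reproduce an
external screening workflow. Any verbatim planted fragment at least as long
as max(min_match, seed) is guaranteed to be reported.

## Cross-talk, correlations, zoning

Cross-talk between families A and B is 100·s/(m_A + m_B − s) with m_A, m_B
the per-family mapped-species counts and s the shared count; the denominator
is the pair's non-redundant species total. Spearman correlations use
average ranks; p-values come from the t approximation
t = r√((n−2)/(1−r²)), with an exact permutation p for n ≤ 10 (the t
approximation is poor there). Constant inputs yield an undefined r reported
as missing.

The zoning diagnostic splits element totals into two groups at the
threshold maximising between-group variance of log expression (Otsu's
criterion in 1-D; the original observation was visual, so any reasonable
bimodality detector serves). The flag is raised when the upper/lower
group-median ratio is ≥ 1.5 with all species and falls below 1.5 after
removing the single species with the largest summed contribution, the split
being recomputed after removal. Elements with zero expression are excluded.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
any real genome's sequence composition:

* **Families and clocks.** Each family has an ancestral element
  (random sequence; LTR default 300–1000 nt, INT 900–4000 nt at desk
  scale). A copy draws an age T (uniform over 0–3 My by default, matching
  the age range over which such families are typically profiled); each of
  its two LTRs then mutates independently with per-site probability rT, so
  the expected LTR-pair p-distance is ≈ 2rT. Substitution-only: no indels,
  hence all copies stay positionally aligned to the ancestor and consensus
  building and truth coordinates need no MSA.
* **Hypervariable hotspot.** A palindrome-like LTR interval (default
  positions 100–300) carries, in addition to a ×5 clock factor, a per-copy
  variant written identically into both LTRs at insertion (per-site
  divergence 0.6 from the ancestor). The shared-at-insertion variant makes
  the hotspot hypervariable *across* copies — so consensus columns fall
  below the 0.6 majority threshold and are N-masked in exemplars — while
  leaving LTR-pair identity at insertion intact, i.e. without corrupting the
  age clock. A clock-rate elevation alone cannot produce N-masked columns at
  desk-scale ages, and would bias age estimates.
* **Exemplars.** Per-column majority consensus; a column with majority
  frequency < 0.6 becomes N. Runs of N arise in the hotspot, reproducing the
  masked unresolved regions of real exemplar databases.
* **Contamination.** With a configurable nesting rate, an element receives
  one fragment (log-normal length, median 189 nt) cut from a random copy of
  a *different* family and inserted at a random position of its INT domain,
  on either strand. Restricting insertion to INT keeps both LTRs and the
  sub-locus coordinate arithmetic intact; fragments are recorded in the
  truth table, and annotation intervals span the element including the
  fragment.
* **sRNA libraries.** Per element and read length L ∈ {21, 22, 24}, the
  number of species is Poisson with mean baseRate(L) · length ·
  exp(−decay · T) (defaults 0.01/0.01/0.02 species per nt and
  decay 5 × 10⁻⁷ y⁻¹, giving a ~3-fold decline across a 0–3 My age range —
  a visible but not degenerate silencing gradient). Start positions are
  drawn with hotspot starts over-weighted ×5; strands are equiprobable; each
  species is a perfect substring (or reverse complement) of its element.
  Expression is geometric with mean 5 — a heavy-tailed stand-in chosen so
  dominance analyses have outliers to find; no claim is made that it matches
  any real library's abundance distribution.

What the generator does *not* emulate: realistic nucleotide composition,
indels and solo-LTR formation, transposition bursts, sequencing error,
adapter artefacts, or fragmented/degraded copies. Passing tests therefore
demonstrate the correctness and directional behaviour of the algorithms
under a controlled model, not quantitative agreement with any real maize (or
other) dataset.

## Validation experiments and problem sizes

The bundled experiments run at sizes chosen to keep the full suite fast on a
laptop while leaving enough statistical resolution: the mapper oracle uses
1,000 species against 10 kb of reference (exhaustive quadratic scan as the
oracle); age recovery uses 500 elements with 1 kb LTRs in the
low-divergence regime 2rT ≤ 0.05, where the JC69-based estimator's mean
relative bias stays within 5%; direction-of-effect checks use two families
of 100 copies (n = 200 elements) over three independent seeds; the
clean-vs-contaminated cross-talk contrast uses 12 copies per family with
nesting rate 0.8. Age-recovery simulations use a uniform clock
(hotspot factors disabled) because the estimator is defined under the clock
model; the hotspot deliberately violates it and inflates apparent ages of
hotspot-bearing elements, which is itself visible in the default simulation.

## Known limitations

* Exact matching only; there is no mismatch tolerance, so sequencing errors
  in real data would reduce mapped fractions (real pipelines trim and
  quality-filter first, which is out of scope here).
* The weighted species density convention (sum of in-locus 1/x) is one of
  several defensible definitions; it is labelled in all outputs.
* The contamination screen has no E-value model and can over-merge tandem
  near-identical fragments.
* Cross-library pooling deduplicates species by sequence; per-library and
  pooled modes are both available but no normalisation across library sizes
  is attempted.
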