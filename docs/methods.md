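# Methods

This note records how each analysis in `plastotype` is defined, the
parameters that matter, the choices made where a definition was genuinely
open, and what the synthetic-data validation does and does not demonstrate.

## Circular-coordinate model

All analyses run on `CircularSequence`, an uppercase DNA string with
modular 1-based coordinates: position *L + k* resolves to *k*, intervals
may wrap the origin, and reports always use 1-based inclusive intervals.
IUPAC ambiguity codes (including N) are legal input but match nothing in
primer or enzyme-site scans — a conservative rule for assembled sequence,
where an ambiguous base should never *create* evidence.  Rotation and
strand changes are bookkeeping, not information: digestion spectra,
amplicon sizes and SSR counts are invariant under both, and the test suite
asserts this directly.

## Quadripartite structure

The inverted-repeat pair is defined as the longest pair of non-overlapping
intervals whose sequences are exact reverse complements, each at least
`min_len` (default 1000 bp — large enough to skip dispersed inverted
repeats, three orders of magnitude below a real plastome IR).  Detection
anchors 21-mers of the doubled sequence against its reverse complement,
groups anchors by diagonal, and reads maximal exact matches off the anchor
runs; ties are broken by the smaller start of the first interval, making
the result deterministic and rotation-invariant.  Exact matching is a
deliberate modelling choice: the IR copies of assembled plastomes are
perfect duplicates (polishing forces them to be), and a mismatch-tolerant
mode would trade determinism for nothing on this data.  Genomes without a
qualifying pair raise a structure-not-found error rather than returning a
partial answer.

The two arcs between the IR copies become LSC (longer) and SSC (shorter);
equal arcs are rejected as degenerate.  Canonicalisation rotates the LSC
to position 1 (the convention of deposited potato plastomes) and never
flips strands.  Junction positions (JLB, JSB, JSA, JLA) are reported as
the last base of the upstream segment; a feature "spans" a junction when
it covers both flanking bases, and otherwise the nearest features on both
sides are reported with distances.  `drop_one_ir` concatenates
LSC + SSC + IRa for redundancy-free downstream use (e.g. phylogenetics);
the result is linear, so the operation cannot be applied twice.

## In silico PCR

A primer site is any circular position where the primer (or its reverse
complement) matches with at most `max_mismatch` substitutions (default 0:
the NTCP markers are length polymorphisms, not priming polymorphisms).
Positions refer to the primer's 5' end.  An amplicon is any
opposing-orientation hit combination; its length is the circular distance
between the two 5' ends, inclusive — the product contains both primer
footprints, matching how marker product sizes are conventionally reported.
Both (forward +, reverse −) and (reverse +, forward −) orientations are
enumerated so product multisets are strand-symmetric.  Products are capped
at `max_product` (default 5 kb) to suppress genome-scale artefacts.
Marker profiling reports the unique product size per marker, the smallest
size flagged `multiple`, or `absent`.

No published marker primer sequences ship with the package — they belong
to the marker literature, not to this work — so marker typing of real
genomes requires a user-supplied panel TSV; all internal validation uses
the synthetic panel.

## In silico restriction digestion

Cut positions are every circular occurrence of the recognition site on
either strand (strands collapse for the five packaged palindromic
6-cutters), offset by the enzyme's cut offset.  Fragments are the circular
gaps between consecutive cuts; a genome without a site is one undigested
fragment, flagged.  Conservation — fragment lengths summing exactly to the
genome length — holds by construction and is asserted everywhere.  Offsets
default to 0 because fragment *lengths* on a circle are offset-invariant
and typing uses lengths only.

Spectrum comparison pairs lengths greedily in two stages: a strict
tolerance of max(5 bp, 0.5 %) absorbs gel-scale imprecision, then a relaxed
shift tolerance of max(100 bp, 5 %) pairs fragments that changed length by
a small indel (the 48 bp S-type shortening is the motivating case — it is
the same fragment, not a gain plus a loss).  Only lengths that fail both
stages are reported as gains or losses, which is what a fragment split by
a newly gained site produces.  Greedy closest-match pairing over
descending lengths keeps the diff deterministic.

## cpDNA typing

Typing combines two independent reads of the genome:

* **Marker route** — the product-size vector over the seven NTCP markers is
  matched exactly against the published reference patterns (one S row,
  three C rows reflecting accession-level size variation, and the pattern
  shared by C and A, which yields the ambiguous call "C/A").  Anything
  else, including absent or multi-product markers, is `inconclusive` —
  patterns outside the reference studies cannot be named by markers alone.
* **Sequence route** — diagnostic loci are located by two flanking 20-mer
  anchors (config data, not coordinates, so typing tolerates length
  variation elsewhere).  Site loci report whether the enzyme site exists
  between the anchors; deletion loci compare the inter-anchor distance
  against the recorded reference gap.  An anchor found zero or multiple
  times makes the locus `unresolvable`, never a guess.  The decision tree
  follows the type genealogy: cemA–petA BamHI site present → {S, C, A},
  refined by the 48 bp deletion (S) or the ccsA site (A), else C; site
  absent → 241 bp deletion (T), rps11 PvuII site (W2), else W.
  Contradictory states (e.g. the S diagnostic without the clade-defining
  site) yield `inconclusive` with the conflict in the evidence list.

Sequence-level diagnostics outrank spectrum heuristics because fragment
matching is tolerance-based; digests serve as corroborating evidence only
(`corroborate=True`).  The final call resolves marker × sequence:
agreement, refinement of "C/A", or substitution for an inconclusive side;
disagreement is `inconclusive` with both evidence trails.  W1 and W3 are
representable states with no packaged sequence rule, and are never emitted.

## MSA variant calling

The reference is the per-column majority: the symbol (gap included) with
frequency above 50 %.  Exact-half columns are undefined by that rule, so
they are flagged `tie` and carry the lexicographically smallest
most-frequent symbol — deterministic and explicit.  SNP sites are columns
with ≥2 distinct unambiguous bases; gap and N are missing data, never
alleles (rows carrying them at a column are simply ignored there — the
convention of standard MSA SNP callers).  Classification: if at least two
alleles occur in at least two rows each the site is parsimony-informative,
otherwise singleton; the allele count is appended (`singleton-2`,
`parsimony-informative-3`, …), and the four classes partition all sites.
Per-genome counts are differences from the consensus allele.

InDel events are counted per genome: each maximal run of columns where
exactly one of {row, consensus} is gapped is one event (insertion when the
consensus side is gapped).  Per-genome accounting is the headline number —
a deletion shared by two genomes is two events — with a deduplicated
union view available separately.  Alignment is delegated to MAFFT
(``--auto``) or to a precomputed aligned FASTA; alignment-engine choice can
shift indel decomposition in low-complexity regions, so exact variant
totals are only comparable under a fixed engine and options.  Annotation
projects feature and structure coordinates through the reference row's
gaps; intron features label `intron`, any genic feature labels `CDS`, the
rest is `intergenic`, and columns before the reference's first base are
`unplaced`.

## Repeat scanning

**SSRs** are perfect tandem runs of 1–6 bp units at the conventional
plastome-survey minima (10/5/4/3/3/3 copies).  A run is reported once, at
the primitive period of its motif (an ATAT… run is a dinucleotide repeat),
5'→3' on the given strand, with a canonical motif (lexicographic minimum
over rotations and strands) for strand-independent counting.  Runs crossing
the circular origin are found once.  Perfect-only is a known source of
count drift against surveys made with imperfect-repeat scanners.

**Tandem repeats** (period 7–100, total length ≥26 bp, identity ≥0.9) use a
deterministic lag-profile detector: self-match runs at each lag (runs
shorter than 4 discarded as chance matches, the isolated breaks left by a
substitution bridged), scored against the per-column consensus unit;
identity is the fraction of run positions agreeing with that unit.
Overlapping hits across periods keep the highest identity, then the
smallest period.  This intentionally replaces probabilistic
alignment-model detectors; implanted repeats are recovered exactly, but
literature counts produced by such detectors are not a target.

**Dispersed repeats** are maximal pairs ≥30 bp with Hamming distance ≤3 in
four orientations (forward, palindromic, reverse, complement).  Because a
mismatch budget can be split between the two ends in several ways,
"maximal" needs a canonical definition: on each alignment diagonal, report
every interval `[a, r(a)]` where `r(a)` is the budget-limited right end
and extending left would exceed the budget.  This set is complete,
deterministic, and — by pigeonhole — every qualifying pair contains an
exact seed of ⌊min_len/(mismatches+1)⌋ = 7 bases, so the seed-and-extend
scan finds exactly the same set as an exhaustive per-diagonal scan (the
test suite compares the two).  Overlapping copies are excluded (they are
tandem, not dispersed), and the genome-scale IR pair is excluded by
default (it would dominate every report) unless `include_ir_pair=True`.
The scan is linear in the given rotation.

## Synthetic data

The generator emulates the study system: a circular quadripartite genome
(toy ~20 kb with real proportions, or full scale with LSC 85,930 / IR
25,593 / SSC 18,376 bp for the S-type — the reference dimensions), ~62 % AT
background, an exact implanted IR pair with extension-blocking flank bases,
the five diagnostic loci wired to the type genealogy, seven marker
cassettes whose product sizes echo the published per-type profiles, and
implanted SSR/tandem/dispersed repeats with guard bases.  All anchor,
primer and payload constants come from a fixed internal stream, so the
emitted diagnostic and primer configs match every generated genome; all
other randomness flows from the user seed, and identical inputs reproduce
identical bytes.  Genomes of different types at the same seed share their
entire background and differ only at the diagnostic blocks — the same
single-event structure as the real types.

Panels derive several genomes from one ancestor with substitutions and
1–12 bp indels implanted at globally non-overlapping positions inside
background fillers (never in the IR, anchors, cassettes or loci), at
per-base rates defaulting to 2×10⁻⁴ and 5×10⁻⁵ — the order of magnitude of
the real panel's diversity (~750 SNPs and ~790 indels over 13 × 155 kb).
The truth includes an exactly constructed MSA, so caller validation is
independent of any aligner.

What passing tests show: every algorithm recovers planted truth exactly
under the stated definitions, at both scales.  What they do not show: the
generator has no gene content, codon structure, SSR length polymorphism
between genomes, IR boundary shifts, or alignment ambiguity — so agreement
with published counts on *real* panels additionally depends on assembly
quality, annotation and the alignment engine.  Reproducing the deposited
panel's numbers requires the accession sequences themselves (see the
README); the test exists and runs whenever they are present.

## Problem sizes

The default validation uses toy-scale genomes (~20 kb) for pipeline
round-trips, 500 bp–5 kb toys for brute-force oracle comparisons, 100
random 1.5–3.7 kb circles for digestion conservation, and one full-scale
(155 kb) genome per type for structure and typing; the whole suite runs in
well under a minute on one CPU, and `scripts/acceptance.py` in a few
seconds.  These sizes are the package's own validation design: each
property being checked is scale-free, and the full-scale runs confirm the
implementation at real plastome size.

## Known limitations

* Marker typing of real genomes needs user-supplied primer sequences, and
  sequence typing needs anchor configs derived from reference accessions;
  the packaged configs cover the synthetic system.
* IR detection is exact-match only; a plastome with diverged IR copies is
  reported non-quadripartite rather than approximately partitioned.
* Dispersed-repeat scanning is linear in the given rotation; a pair
  straddling the origin is found only after rotation (canonicalise first).
* Variant totals depend on the alignment; only the calling and annotation
  are defined here.
* The tandem-repeat detector's counts are not comparable to
  alignment-model detectors and are not presented as such.
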