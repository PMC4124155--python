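# Methods

This note records the models, rules and numerical choices implemented in
`rnannot`, including the decisions taken where a rule admitted more than
one reasonable reading, and what the synthetic fixtures do and do not
demonstrate about real data.

## The locus model

An RNA locus is a connected component of hit intervals under pairwise
overlap of at least 1 nt. Grouping is strand-agnostic: incompatible
annotations of the two strands of one position are exactly the conflicts
the framework must surface (the classic case is an Rfam snoRNA seed and
a miRBase hairpin annotating the same spot), so they must land in one
locus. Member strands are retained; the locus span takes a definite
strand only when all members agree. Internally all coordinates are
0-based half-open; GFF3/BED boundaries convert to their native
conventions at I/O time only.

The overlap requirement for locus formation is ≥ 1 nt. No minimum
overlap fraction is imposed; with typical structured-RNA lengths around
120 nt and tool hits tightly localized, fractional thresholds change
nothing on realistic inputs, and the 1-nt rule keeps the definition
order-free and transitive-closure exact.

## Confidence tiers and the Rfam filters

Three nested tiers (high ⊂ medium ⊂ low) are defined per tool; the
containment is over genomic extent — every high-tier locus lies inside
some medium-tier locus, which may be wider because weaker hits join it.

Boundary semantics are deliberate and tested: BLAST identity/coverage
thresholds and the tRNAscan-SE triple filter (HMM 10.0, 2'Str 5.0,
COVE 20) are inclusive (≥); the single-parser COVE filter is strictly
"above 55". The Infernal E-value cap for non-miRNA families is
min(gathering-score-implied E-value, 10⁻³): Rfam gathering scores are
tuned for sensitivity and can imply E-value cutoffs up to ~10⁶, so the
cap is what actually controls false positives when the models run
without BLAST pre-filtering. The BLAST anchor (same family's seed
sequences, any overlap ≥ 1 nt, strand-agnostic) pins a structure hit to
the right genomic neighbourhood; no overlap length is imposed because
the anchor's role is localization, not scoring. miRNA families, whose
plain hairpin structure matches promiscuously in mammalian genomes, are
excluded from the high tier outright and pass at medium/low only under
stricter Infernal E-values (10⁻⁹/10⁻⁶) with an anchor required at every
tier.

Within-database redundancy (databases are not redundancy-reduced) is
resolved before locus building: among overlapping hits of one database
and one RNA class the lowest E-value wins, with deterministic
tie-breaks (higher bit score, then lexicographic family name). Running
resolution first keeps the later cross-database conflict marking about
classification, not database redundancy.

Two demotion rules act on the assembled high tier: a tRNA locus never
seen by tRNAscan-SE drops to medium, and a miRNA locus whose only
evidence is BLAST similarity to a database entry without experimental
evidence — and which has no read support in the analysed small-RNA
data — drops to medium. The experimental-evidence bit is an input flag
in the family-metadata table; parsing database provenance records is
out of scope.

## Synteny, liftover and conservation

Chained pairwise alignments are reduced to gapless segments; the
alignments must be single-coverage on the annotated (target) genome and
the block builder raises on violations rather than guessing. Blocks
merge left-to-right greedily when target contig, query contig and
strand all match and the gap is < 5,000 nt — evaluated on **both**
genomes, because a target-side gap rule alone would tolerate arbitrary
query jumps inside one "block". Merged blocks shorter than 5,000 nt on
the target are discarded. Region merging relaxes the gap bound
(unlimited by default) and optionally the strand; region counts obey
strand-agnostic ≤ strand-aware ≤ block count on every input.

Conservation of a locus in another organism uses two separate
quantities: covered fraction (aligned locus positions / locus length)
and identity (matching non-N columns / aligned positions). Identity is
deliberately **not** diluted by unaligned positions; the coverage gate
(≥ 80%) decides whether identity is meaningful at all, then identity
≥ 80% (inclusive, like the coverage gate) calls the locus conserved.
Conservation depth counts conserved organisms, excluding the annotated
genome itself. Lineage specificity uses strict inequalities (> 60%
inside, < 30% outside, per the way such cutoffs are read off identity
histograms), treats organisms without any alignment at a locus as
satisfying the outside condition, and is only evaluated for loci with
≤ 5 genomic copies, no exact duplicate, and a position on an assembled
chromosome — repetitive and unplaced sequence makes the alignments
unreliable there.

Exact-duplicate detection compares extracted locus sequences
byte-for-byte (minus-strand loci reverse-complemented); every member of
a group of ≥ 2 is tagged, and all copies remain in downstream analyses
because their genomic contexts can legitimately differ.

## Genic context, clustering, marking

Coding-exon context requires ≥ 50% of the locus on coding exons; when
transcripts disagree about an exon, the coding reading wins. UTR labels
(5'/3' by CDS position on the transcript strand) are only assigned from
coding transcripts — a transcript without CDS defines no UTR. Flank
labels use ±10,000 nt; a locus is intergenic exactly when no gene
overlaps or flanks it. All labels from multiple nearby genes are kept,
plus a `multiple-genes` marker, since no principled precedence exists.

Clustering is single linkage on same-contig, same-strand loci with
end-to-start gap strictly < 10,000 nt (gap 0 for overlapping loci).
RNAz overlap marking needs ≥ 20 nt irrespective of strand (RNAz strand
prediction is unreliable enough that strandedness would lose true
overlaps); read support needs a single block of ≥ 10 reads overlapping
≥ 20 nt. Read-profile class transfer drops block groups shorter than
50 nt (too little profile shape) and transfers the best-scoring match's
class only at score ≥ 0.6.

## Promoter scanning

PWMs are log₂-odds matrices against a uniform 0.25 background with a
0.5 pseudocount, built from aligned equal-length training slices. Each
element carries an anchor: the expected distance of its start upstream
of the transcript start (PSEA −50, PSEB −25 for PolII; PSE −55 and the
TATA box near the 3' end of the slice, anchored −20, for PolIII), with
a ±10 nt scan window — anchors are biologically fixed but mapping of
transcript starts is not base-exact. Score thresholds are the empirical
99th percentile (α = 0.01) of best in-window scores over 1,000 random
background sequences; a uniform background sampler is the default, a
genome-trained dinucleotide sampler is available. N positions score the
column minimum (conservative). A PolII call may optionally accept
spatially inverted PSEA/PSEB (windows swapped) for the known exceptional
arrangement. A locus whose upstream 100 nt run off the contig edge is
left uncurated rather than guessed.

With two required elements per mode, the joint false-pass rate on
background is ≈ α² while each element's exceedance rate is ≈ α; the
calibration tests check the per-element rate against the binomial
interval and the joint rate against α.

## Curation rules

- cis-regulatory elements: curated with a sense-strand gene within
  1,000 nt (or overlapping); pseudogene with no gene within 10,000 nt;
  uncurated in between.
- rRNA: curated only inside a complete 28S/18S/5.8S cluster (single
  linkage at a 20,000-nt window — "closely together" quantified here as
  a configurable default); every other rRNA locus is a pseudogene.
- snoRNA: curated when its lifted coordinates overlap a curated
  reference snoRNA of the same family at identity strictly > 60%;
  remaining members of families with a curated member are pseudogenes;
  families without any curated member stay uncurated. An opt-in
  host-gene rule curates clusters whose family order (or its reversal)
  matches a reference host-gene arrangement.
- Expected PolII/PolIII transcripts: curated/pseudogene by the promoter
  call, uncurated when no upstream slice exists.
- A locus reaching both curated and pseudogene is treated as a rule-set
  bug and raises, rather than being silently overridden.

The read-based miRNA-prediction cleanup applies, in order: collapse of
identical (precursor, mature, star) triples across loci; resolution of
overlapping distinct precursors (keep both on identical star+mature,
discard both when star reads are absent); discarding the shorter of two
matures differing by a 2-nt extension; discarding precursors overlapping
high-tier non-miRNA annotation (already-marked conflict loci excepted);
demotion to medium for coding-exon context; and removal of predictions
flagged as arising from misplaced reads (an input flag — re-deriving it
would require the read mappings). The procedure logs every rule firing
and is idempotent. The collapse key includes mature and star sequences
so that the two-mature rule still sees its input; collapsing on the
precursor alone would destroy the evidence that rule inspects.

## Synthetic fixtures and what they show

The fixture generator emulates the statistical structure the pipeline
consumes: an i.i.d. background genome at configurable GC with planted N
runs; loci planted as random high-complexity motifs with hit evidence
constructed to sit exactly on the targeted side of each tier boundary;
deliberate conflict pairs, duplicate copies, clusters, promoter slices
(element consensus at canonical anchors for passes, a CG-alternating
slice for fails, so pass/fail truth is seed-independent); genes placed
to realize each genic-context label; and pairwise alignments built from
chunked chains with point mutations at a planted divergence,
inversions, and indels, with a per-base truth mask recording coverage
and identity exactly.

Passing tests on these fixtures demonstrates that the rules are
implemented exactly as stated (boundaries, orderings, invariances) and
that parameters are recovered when the model assumptions hold. They do
not demonstrate robustness to real-data pathologies: assembly errors,
repeat-driven multi-mapping, misannotated reference databases, or
alignment artefacts beyond simple inversions/indels. Fixture sizes
(genomes of ~0.5–1 Mb, ~35 planted loci, 55-locus recovery panels,
100-seed shuffle batches) were chosen as the smallest sizes at which
every behaviour is exercised and binomial checks have power.

## Shuffle null model

Each contig is cut into consecutive 120-nt windows (the typical
structured-RNA length scale; the final short window included) and each
window is shuffled by an Euler-path construction on its dinucleotide
multigraph: a random last-exit edge per vertex forming an arborescence
into the final nucleotide, remaining edges in random order, then one
Euler walk. This preserves the dinucleotide multiset and the first and
last nucleotide of every window exactly, hence global mono- and
di-nucleotide content, local GC bias and contig sizes. Windows
containing N are left unshuffled (logged) — shuffling across assembly
gaps would fabricate sequence. Windows of fewer than 2 nt are returned
unchanged.

## Determinism and degenerate inputs

All randomness flows through seeded NumPy generators; repeated runs are
byte-identical, and outputs are invariant under permutation of input
rows (sorting and documented tie-breaks throughout). Degenerate inputs
fail loudly: malformed tabular rows report their line number, unknown
Infernal families are skipped with a counted warning (never silently),
overlapping target alignments, empty hit sets for resolution, and
contradictory curation statuses raise.

## Known limitations

- The tabular dialects for BLAST/Infernal/tRNAscan-SE are single
  canonical layouts, round-trip-tested against the package's own
  emitters; real tool output varies by version and may need reshaping.
- Promoter thresholds are empirical quantiles; with two elements the
  effective stringency is quadratic in α and should be recalibrated if
  elements are added or windows widened.
- The alignment generator produces single-coverage chains by
  construction and cannot emulate paralogy-induced multi-coverage of
  the query genome; liftover onto paralogs is therefore untested.
- Identity-based conservation treats all columns equally; structured
  RNAs with compensatory substitutions can be conserved in structure
  while failing the 80% sequence-identity rule.
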