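"""Synteny blocks and regions, liftover, per-base identity and conservation.

Works on chained pairwise genome alignments reduced to gapless segments
(UCSC chain dialect).  The alignments are assumed single-coverage on the
target (annotated) genome — the netting/reciprocal-best cleaning that
guarantees this is done upstream and is out of scope here.

Coordinate conventions follow the chain format: query coordinates of a
minus-strand alignment are expressed on the reverse-complement strand of
the query contig; :func:`liftover` converts back to forward-strand
coordinates on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_model import Genome, GenomicInterval, reverse_complement

MIN_BLOCK_LEN = 5000
MAX_BLOCK_GAP = 5000
CONS_COVERED_MIN = 0.8
CONS_IDENTITY_MIN = 0.8
LINEAGE_INSIDE_MIN = 0.60
LINEAGE_OUTSIDE_MAX = 0.30
LINEAGE_MAX_COPIES = 5


@dataclass
class PairwiseAlignment:
    """One chained alignment: ordered gapless segments on one contig pair.

    ``segments`` are (target_start, query_start, length) triples with both
    coordinate series strictly increasing; for strand '-', query_start is
    in reverse-complement coordinates of the query contig (so forward
    coordinates decrease along the target).
    """

    target_contig: str
    query_contig: str
    strand: str
    segments: list[tuple[int, int, int]]
    organism: str = ""
    query_size: int = 0
    chain_id: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_t_end = prev_q_end = -1
        for t, q, ln in self.segments:
            if ln < 1:
                raise ValueError("segment length must be >= 1")
            if t < prev_t_end or q < prev_q_end:
                raise ValueError("segments must be non-overlapping and increasing")
            prev_t_end, prev_q_end = t + ln, q + ln

    @property
    def target_start(self) -> int:
        return self.segments[0][0]

    @property
    def target_end(self) -> int:
        t, _, ln = self.segments[-1]
        return t + ln

    @property
    def query_start(self) -> int:
        return self.segments[0][1]

    @property
    def query_end(self) -> int:
        _, q, ln = self.segments[-1]
        return q + ln

    @property
    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.target_contig, self.target_start, self.target_end)


@dataclass
class SyntenyBlock:
    """Run of merged alignments with consistent contigs and strand."""

    target: GenomicInterval
    query_contig: str
    strand: str
    member_ids: list[int] = field(default_factory=list)


@dataclass
class SyntenyRegion:
    target: GenomicInterval
    query_contig: str
    strand: str  # '.' when strand was ignored in the merge
    n_blocks: int = 1


@dataclass
class ConservationCall:
    locus_id: str
    organism: str
    covered_fraction: float
    identity_fraction: float | None
    conserved: bool


# ---------------------------------------------------------------------------
# Chain dialect I/O
# ---------------------------------------------------------------------------

def read_chain(path, organism: str = "") -> list[PairwiseAlignment]:
    """Read a UCSC chain file into gapless-segment alignments."""
    alignments: list[PairwiseAlignment] = []
    header = None
    segs: list[tuple[int, int, int]] = []
    t_pos = q_pos = 0

    def flush():
        nonlocal header, segs
        if header is not None:
            (t_name, q_name, q_strand, q_size, chain_id) = header
            alignments.append(
                PairwiseAlignment(
                    t_name, q_name, q_strand, segs, organism, q_size, chain_id
                )
            )
        header, segs = None, []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                flush()
                f = line.split()
                # chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
                t_name, t_start = f[2], int(f[5])
                q_name, q_size, q_strand, q_start = f[7], int(f[8]), f[9], int(f[10])
                header = (t_name, q_name, q_strand, q_size, int(f[12]))
                t_pos, q_pos = t_start, q_start
            else:
                f = line.split()
                size = int(f[0])
                segs.append((t_pos, q_pos, size))
                if len(f) == 3:
                    t_pos += size + int(f[1])
                    q_pos += size + int(f[2])
    flush()
    return alignments


def write_chain(alignments: Sequence[PairwiseAlignment], path) -> None:
    with open(path, "w") as fh:
        for i, aln in enumerate(alignments, 1):
            t_size = aln.target_end  # upper bound is sufficient for the dialect
            fh.write(
                f"chain 1000 {aln.target_contig} {t_size} + "
                f"{aln.target_start} {aln.target_end} {aln.query_contig} "
                f"{aln.query_size} {aln.strand} {aln.query_start} "
                f"{aln.query_end} {aln.chain_id or i}\n"
            )
            for (t, q, ln), nxt in zip(
                aln.segments, list(aln.segments[1:]) + [None]
            ):
                if nxt is None:
                    fh.write(f"{ln}\n\n")
                else:
                    dt = nxt[0] - (t + ln)
                    dq = nxt[1] - (q + ln)
                    fh.write(f"{ln}\t{dt}\t{dq}\n")


# ---------------------------------------------------------------------------
# Synteny blocks and regions
# ---------------------------------------------------------------------------

def build_synteny_blocks(
    alignments: Sequence[PairwiseAlignment],
    max_gap: int = MAX_BLOCK_GAP,
    min_len: int = MIN_BLOCK_LEN,
) -> list[SyntenyBlock]:
    """Greedy left-to-right merge of neighbouring alignments into blocks.

    Neighbours merge when target contig, query contig and strand all
    match and the gap is smaller than ``max_gap`` on both the target and
    the query; merged blocks shorter than ``min_len`` on the target are
    discarded.  Overlapping target alignments violate the single-coverage
    contract and raise.
    """
    alns = sorted(alignments, key=lambda a: (a.target_contig, a.target_start))
    for a, b in zip(alns, alns[1:]):
        if a.target_contig == b.target_contig and b.target_start < a.target_end:
            raise ValueError(
                f"overlapping alignments on {a.target_contig}: "
                f"{a.target_end} > {b.target_start} (not single-coverage)"
            )
    blocks: list[SyntenyBlock] = []
    cur: list[PairwiseAlignment] = []

    def flush():
        if not cur:
            return
        target = GenomicInterval(
            cur[0].target_contig, cur[0].target_start, cur[-1].target_end
        )
        if len(target) >= min_len:
            blocks.append(
                SyntenyBlock(
                    target,
                    cur[0].query_contig,
                    cur[0].strand,
                    [a.chain_id for a in cur],
                )
            )

    for aln in alns:
        if cur:
            prev = cur[-1]
            t_gap = aln.target_start - prev.target_end
            q_gap = aln.query_start - prev.query_end
            same = (
                aln.target_contig == prev.target_contig
                and aln.query_contig == prev.query_contig
                and aln.strand == prev.strand
            )
            if same and 0 <= t_gap < max_gap and 0 <= q_gap < max_gap:
                cur.append(aln)
                continue
        flush()
        cur = [aln]
    flush()
    return blocks


def merge_regions(
    blocks: Sequence[SyntenyBlock],
    respect_strand: bool = True,
    ignore_gaps: bool = True,
    max_gap: int = MAX_BLOCK_GAP,
) -> list[SyntenyRegion]:
    """Merge target-adjacent synteny blocks into regions.

    Adjacent blocks merge when their query contigs match and, if
    ``respect_strand``, their strands match too.  With ``ignore_gaps``
    the intervening target gap may be arbitrarily large (the paper-style
    region merge); otherwise gaps must stay below ``max_gap``.
    """
    bls = sorted(blocks, key=lambda b: (b.target.contig, b.target.start))
    regions: list[SyntenyRegion] = []
    for b in bls:
        if regions:
            r = regions[-1]
            gap = b.target.start - r.target.end
            ok = (
                b.target.contig == r.target.contig
                and b.query_contig == r.query_contig
                and (not respect_strand or b.strand == r.strand)
                and (ignore_gaps or gap < max_gap)
            )
            if ok:
                regions[-1] = SyntenyRegion(
                    GenomicInterval(
                        r.target.contig,
                        r.target.start,
                        max(r.target.end, b.target.end),
                    ),
                    r.query_contig,
                    r.strand if (respect_strand and b.strand == r.strand) else ".",
                    r.n_blocks + 1,
                )
                continue
        regions.append(
            SyntenyRegion(
                b.target,
                b.query_contig,
                b.strand if respect_strand else ".",
                1,
            )
        )
    return regions


def _union_intervals(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, spans in by_contig.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = [(s, e) for s, e in out]
    return merged


def coverage(
    intervals: Iterable[GenomicInterval],
    genome: Genome,
    assembled_only: bool = False,
) -> float:
    """Fraction of non-N target positions covered by the interval union."""
    merged = _union_intervals(intervals)
    covered = 0
    for contig, spans in merged.items():
        if contig not in genome:
            continue
        if assembled_only and not genome.assembled.get(contig, True):
            continue
        seq = genome.contigs[contig]
        for s, e in spans:
            sub = seq[s:e]
            covered += len(sub) - sub.count("N")
    total = genome.total_non_n(assembled_only=assembled_only)
    return covered / total if total else 0.0


# ---------------------------------------------------------------------------
# Liftover and conservation
# ---------------------------------------------------------------------------

def _overlapping_segments(interval: GenomicInterval, aln: PairwiseAlignment):
    """Yield (t_lo, t_hi, q_lo) clipped pieces of gapless segments."""
    if aln.target_contig != interval.contig:
        return
    for t, q, ln in aln.segments:
        lo = max(t, interval.start)
        hi = min(t + ln, interval.end)
        if lo < hi:
            yield lo, hi, q + (lo - t)


def liftover(
    interval: GenomicInterval, alignments: Sequence[PairwiseAlignment]
) -> list[GenomicInterval]:
    """Map a target interval through the alignments to query coordinates.

    Every target position inside a gapless segment maps to its query
    position; unaligned positions are unmapped.  Output intervals are on
    the forward strand of the query contigs, merged into maximal runs,
    sorted by (contig, start).
    """
    pieces: list[GenomicInterval] = []
    for aln in alignments:
        for lo, hi, q_lo in _overlapping_segments(interval, aln):
            ln = hi - lo
            if aln.strand == "+":
                start = q_lo
            else:
                start = aln.query_size - (q_lo + ln)
            pieces.append(
                GenomicInterval(aln.query_contig, start, start + ln, aln.strand)
            )
    merged = _union_intervals(pieces)
    out = []
    strand_by_contig = {p.contig: p.strand for p in pieces}
    for contig in sorted(merged):
        for s, e in merged[contig]:
            out.append(GenomicInterval(contig, s, e, strand_by_contig[contig]))
    return out


def locus_conservation(
    locus: GenomicInterval,
    alignments: Sequence[PairwiseAlignment],
    target_genome: Genome,
    query_genome: Genome,
    organism: str = "",
    locus_id: str = "",
    covered_min: float = CONS_COVERED_MIN,
    identity_min: float = CONS_IDENTITY_MIN,
) -> ConservationCall:
    """Per-base coverage and identity of a locus in one query organism.

    covered_fraction = aligned locus positions / locus length;
    identity_fraction = matching (case-insensitive, non-N) columns /
    aligned locus positions, or None with zero aligned positions.
    A locus is conserved when at least 80% of it is covered and the
    identity over the aligned part is at least 80% (both inclusive).
    """
    aligned = matches = 0
    for aln in alignments:
        if aln.target_contig != locus.contig:
            continue
        q_seq = query_genome.contigs.get(aln.query_contig)
        t_seq = target_genome.contigs[locus.contig]
        if q_seq is None:
            continue
        for lo, hi, q_lo in _overlapping_segments(locus, aln):
            ln = hi - lo
            t_sub = t_seq[lo:hi]
            if aln.strand == "+":
                q_sub = q_seq[q_lo : q_lo + ln]
            else:
                fwd_start = aln.query_size - (q_lo + ln)
                q_sub = reverse_complement(q_seq[fwd_start : fwd_start + ln])
            aligned += ln
            matches += sum(
                1
                for a, b in zip(t_sub.upper(), q_sub.upper())
                if a == b and a != "N"
            )
    covered = aligned / len(locus)
    identity = matches / aligned if aligned else None
    conserved = (
        covered >= covered_min and identity is not None and identity >= identity_min
    )
    return ConservationCall(locus_id, organism, covered, identity, conserved)


def conservation_depth(calls: Sequence[ConservationCall]) -> int:
    """Number of (other) organisms in which a locus is conserved.

    One call per organism; the annotated genome itself is not among the
    calls and is therefore excluded from the count.
    """
    orgs = [c.organism for c in calls]
    if len(set(orgs)) != len(orgs):
        raise ValueError("duplicate organism ids in conservation calls")
    return sum(1 for c in calls if c.conserved)


def lineage_specific(
    calls: dict[str, ConservationCall],
    inside_ids: Sequence[str],
    outside_ids: Sequence[str],
    copy_count: int = 1,
    is_exact_duplicate: bool = False,
    on_assembled_contig: bool = True,
    inside_min: float = LINEAGE_INSIDE_MIN,
    outside_max: float = LINEAGE_OUTSIDE_MAX,
    max_copies: int = LINEAGE_MAX_COPIES,
) -> bool:
    """Is a locus specific to the lineage defined by ``inside_ids``?

    Requires identity > 60% to every covered inside-lineage organism
    (strict), identity < 30% to every outside organism (unaligned
    organisms count as satisfying this), at most 5 genomic copies, no
    exact duplicate, and location on an assembled contig.
    """
    if copy_count > max_copies or is_exact_duplicate or not on_assembled_contig:
        return False
    covered_inside = [
        calls[o]
        for o in inside_ids
        if o in calls
        and calls[o].covered_fraction >= CONS_COVERED_MIN
        and calls[o].identity_fraction is not None
    ]
    if not covered_inside:
        return False
    if any(c.identity_fraction <= inside_min for c in covered_inside):
        return False
    for o in outside_ids:
        c = calls.get(o)
        if c is None or c.identity_fraction is None:
            continue  # unaligned outside organisms satisfy the < 30% condition
        if c.identity_fraction >= outside_max:
            return False
    return True


def find_exact_duplicates(
    loci: Sequence, genome: Genome
) -> list[list[int]]:
    """Group loci whose extracted sequences are byte-identical.

    Minus-strand loci are reverse-complemented before comparison.  Every
    member of a group of >= 2 is tagged ``duplicated``.  Returns groups
    of locus indices.
    """
    by_seq: dict[str, list[int]] = {}
    for i, locus in enumerate(loci):
        seq = genome.fetch(locus.span)
        by_seq.setdefault(seq, []).append(i)
    groups = [idxs for idxs in by_seq.values() if len(idxs) >= 2]
    for grp in groups:
        for i in grp:
            if hasattr(loci[i], "tags"):
                loci[i].tags.add("duplicated")
    groups.sort(key=lambda g: g[0])
    return groups


def in_synteny_block(
    interval: GenomicInterval, blocks: Sequence[SyntenyBlock]
) -> bool:
    from .genome_model import overlap_len

    return any(overlap_len(interval, b.target) >= 1 for b in blocks)


def conservation_table(
    loci: Sequence,
    calls_by_locus: dict[str, dict[str, ConservationCall]],
    blocks: Sequence[SyntenyBlock],
    reference_organism: str,
    depth_cuts: tuple[int, ...] = (1, 5, 15),
):
    """Per-class conservation summary: loci, syntenic, conserved-in-reference,
    both, and conserved in at least N other organisms for each cutoff."""
    import pandas as pd

    rows: dict[str, dict[str, int]] = {}
    for locus in loci:
        cls = locus.resolved_class
        row = rows.setdefault(
            cls,
            {
                "loci": 0,
                "syntenic": 0,
                "conserved": 0,
                "both": 0,
                **{f"N>={n}": 0 for n in depth_cuts},
            },
        )
        row["loci"] += 1
        calls = calls_by_locus.get(locus.locus_id, {})
        syntenic = in_synteny_block(locus.span, blocks)
        ref = calls.get(reference_organism)
        conserved_ref = bool(ref and ref.conserved)
        if syntenic:
            row["syntenic"] += 1
        if conserved_ref:
            row["conserved"] += 1
        if syntenic and conserved_ref:
            row["both"] += 1
        depth = sum(1 for c in calls.values() if c.conserved)
        for n in depth_cuts:
            if depth >= n:
                row[f"N>={n}"] += 1
    return (
        pd.DataFrame([{"rna_class": k, **v} for k, v in sorted(rows.items())])
        if rows
        else pd.DataFrame()
    )
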