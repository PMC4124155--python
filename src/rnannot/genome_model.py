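"""Core coordinate system: intervals, genomes, gene models and interval algebra.

All internal coordinates are 0-based half-open on the forward strand;
conversion to the 1-based closed convention happens only at GFF3/BED
I/O boundaries (see :mod:`rnannot.tool_io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a contig.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded).  Interval algebra
    (overlap, grouping) is strand-agnostic throughout; strand matters only
    for sequence extraction and the strand-aware operations that say so.
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in nt between two intervals; 0 if on different contigs.

    Strand is ignored.
    """
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def group_by_overlap(
    intervals: Sequence[GenomicInterval],
) -> list[list[int]]:
    """Partition interval indices into connected components under overlap.

    Two intervals belong to the same component iff they are connected by a
    chain of pairwise overlaps of >= 1 nt (strand-agnostic).  Components are
    ordered by (contig, min start); indices within a component are sorted.

    A sort-and-sweep is used: after sorting by (contig, start), a new
    component starts exactly when an interval begins at or after the running
    maximum end on the current contig.
    """
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].contig, intervals[i].start, intervals[i].end))
    components: list[list[int]] = []
    cur: list[int] = []
    cur_contig: str | None = None
    cur_end = -1
    for i in order:
        iv = intervals[i]
        if iv.contig != cur_contig or iv.start >= cur_end:
            if cur:
                components.append(sorted(cur))
            cur = [i]
            cur_contig = iv.contig
            cur_end = iv.end
        else:
            cur.append(i)
            cur_end = max(cur_end, iv.end)
    if cur:
        components.append(sorted(cur))
    return components


def hull(intervals: Iterable[GenomicInterval]) -> GenomicInterval:
    """Smallest interval containing all inputs (must share a contig)."""
    ivs = list(intervals)
    if not ivs:
        raise ValueError("hull of empty interval set")
    contigs = {iv.contig for iv in ivs}
    if len(contigs) > 1:
        raise ValueError(f"hull across contigs: {sorted(contigs)}")
    return GenomicInterval(
        ivs[0].contig, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Nucleotide sequences keyed by contig id, over {A,C,G,T,N}.

    ``assembled`` flags which contigs are assembled chromosomes (as
    opposed to unplaced scaffolds); analyses such as lineage specificity
    restrict themselves to assembled sequence.
    """

    contigs: dict[str, str]
    assembled: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name}")
        for name in self.contigs:
            self.assembled.setdefault(name, True)

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self._get(contig))

    def _get(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None

    def non_n_length(self, contig: str) -> int:
        """Number of non-N positions on a contig."""
        seq = self._get(contig)
        return len(seq) - seq.count("N")

    def total_non_n(self, assembled_only: bool = False) -> int:
        return sum(
            self.non_n_length(c)
            for c in self.contigs
            if not assembled_only or self.assembled.get(c, True)
        )

    def fetch(self, interval: GenomicInterval) -> str:
        """Extract the sequence of an interval; '-' strand reverse-complemented."""
        seq = self._get(interval.contig)
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} beyond contig end ({len(seq)})"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub


def non_n_length(genome: Genome, contig: str) -> int:
    return genome.non_n_length(contig)


def read_fasta(path) -> Genome:
    """Read a (multi-record) FASTA into a Genome.

    Sequences are upper-cased; characters outside {A,C,G,T,N} are mapped to
    N with a logged warning.  Contigs whose ids end in a recognised
    unplaced-scaffold suffix convention (``*_scaffold*`` or ``*_unplaced*``)
    are flagged unassembled; callers may override ``assembled`` afterwards.
    """
    contigs: dict[str, str] = {}
    assembled: dict[str, bool] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in "ACGTN" else "N" for c in seq)
        if cleaned != seq:
            n_bad = sum(1 for a, b in zip(seq, cleaned) if a != b)
            logger.warning(
                "contig %s: %d non-ACGTN characters mapped to N", rec.id, n_bad
            )
        contigs[rec.id] = cleaned
        low = rec.id.lower()
        assembled[rec.id] = not ("scaffold" in low or "unplaced" in low)
    return Genome(contigs, assembled)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        for c in self.cds:
            if not any(
                e.contig == c.contig and e.start <= c.start and c.end <= e.end
                for e in self.exons
            ):
                raise ValueError(
                    f"CDS {c} not contained in any exon of {self.transcript_id}"
                )

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_start(self) -> int:
        return self.cds[0].start

    @property
    def cds_end(self) -> int:
        return self.cds[-1].end


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[Transcript]

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, self.strand)
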