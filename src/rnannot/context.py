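"""Genomic context tagging: genic context, clustering, RNAz overlap and
read support.

All marking operations are pure annotations — they never change locus
membership or confidence tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genome_model import GeneModel, GenomicInterval, overlap_len
from .tool_io import ReadBlockGroup

GENIC_FLANK = 10_000
CLUSTER_MAX_DIST = 10_000
RNAZ_MIN_OVERLAP = 20
RNAZ_P_MIN = 0.9
READ_MIN_COUNT = 10
READ_MIN_OVERLAP = 20
BLOCK_GROUP_MIN_LEN = 50
DBA_MIN_SCORE = 0.6


@dataclass
class GenicContext:
    """Relation of a locus to the protein-coding gene annotation."""

    labels: set[str] = field(default_factory=set)
    #: (gene_id, signed distance in nt; 0 when overlapping, negative when
    #: the gene lies before the locus in genome coordinates)
    nearest_genes: list[tuple[str, int]] = field(default_factory=list)
    sense_relation: dict[str, str] = field(default_factory=dict)


@dataclass
class RnazLocus:
    """A structurally conserved locus predicted de novo (RNAz-style).

    The p-score is a prediction reliability score, not a p-value; loci
    are retained only at p-score >= the configured cutoff (default 0.9).
    """

    interval: GenomicInterval
    p_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_score <= 1.0):
            raise ValueError("p_score must be in [0, 1]")


def read_rnaz_bed(path, p_min: float = RNAZ_P_MIN) -> list[RnazLocus]:
    """BED6 with the p-score in the score column; sub-cutoff rows dropped."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            contig, start, end, _name, score, strand = line.split("\t")[:6]
            p = float(score)
            if p >= p_min:
                loci.append(
                    RnazLocus(GenomicInterval(contig, int(start), int(end), strand), p)
                )
    return loci


def write_rnaz_bed(loci: Sequence[RnazLocus], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(loci, 1):
            iv = r.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\trnaz{i}\t{r.p_score:.3f}\t{iv.strand}\n"
            )


def _signed_distance(locus: GenomicInterval, gene: GeneModel) -> int:
    if overlap_len(locus, gene.span) > 0:
        return 0
    if gene.start >= locus.end:
        return gene.start - locus.end
    return -(locus.start - gene.end)


def genic_context(
    locus: GenomicInterval,
    gene_models: Sequence[GeneModel],
    flank: int = GENIC_FLANK,
) -> GenicContext:
    """Assign genic-context labels to a locus.

    Per overlapping gene: ``coding-exon`` when at least 50% of the locus
    overlaps coding exons (exons carrying CDS in some transcript; the
    coding-exonic reading is preferred when transcripts disagree), else a
    UTR label when the locus overlaps non-coding exon sequence of a
    coding transcript (5' vs 3' by position relative to the CDS on the
    transcript's strand), else ``intronic``.  Genes within ``flank`` nt
    add upstream/downstream labels (relative to genome coordinates on
    the locus's strand).  A locus near no gene is ``intergenic``; labels
    from multiple genes are all kept, plus ``multiple-genes``.
    """
    ctx = GenicContext()
    contributing = 0
    for gene in gene_models:
        if gene.contig != locus.contig:
            continue
        dist = _signed_distance(locus, gene)
        if abs(dist) > flank:
            continue
        contributing += 1
        ctx.nearest_genes.append((gene.gene_id, dist))
        sense = (
            "sense"
            if locus.strand in (gene.strand, ".")
            else "antisense"
        )
        ctx.sense_relation[gene.gene_id] = sense
        if dist != 0:
            locus_strand = locus.strand if locus.strand in "+-" else "+"
            before = dist < 0  # gene lies before the locus in genome coords
            if locus_strand == "+":
                ctx.labels.add("upstream<=10k" if before else "downstream<=10k")
            else:
                ctx.labels.add("downstream<=10k" if before else "upstream<=10k")
            continue
        # Overlapping gene: classify against its exon structure.  An exon
        # is "coding" when it carries CDS in any transcript (the coding
        # reading is preferred when transcripts disagree).
        coding_exons: list[tuple[int, int]] = []
        noncoding_exons: list[tuple[GenomicInterval, "object"]] = []
        for t in gene.transcripts:
            for e in t.exons:
                if t.is_coding and any(overlap_len(e, c) > 0 for c in t.cds):
                    coding_exons.append((e.start, e.end))
                else:
                    noncoding_exons.append((e, t))
        # drop non-coding readings of exons that are coding elsewhere
        noncoding_exons = [
            (e, t)
            for e, t in noncoding_exons
            if not any(s < e.end and e.start < en for s, en in coding_exons)
        ]
        coding_overlap = 0
        if coding_exons:
            coding_exons.sort()
            merged_exons = [list(coding_exons[0])]
            for s, en in coding_exons[1:]:
                if s <= merged_exons[-1][1]:
                    merged_exons[-1][1] = max(merged_exons[-1][1], en)
                else:
                    merged_exons.append([s, en])
            coding_overlap = sum(
                max(0, min(locus.end, en) - max(locus.start, s))
                for s, en in merged_exons
            )
        utr_label: str | None = None
        for e, t in noncoding_exons:
            if overlap_len(locus, e) > 0 and t.is_coding:
                if e.end <= t.cds_start:
                    utr_label = "5'UTR" if t.strand == "+" else "3'UTR"
                elif e.start >= t.cds_end:
                    utr_label = "3'UTR" if t.strand == "+" else "5'UTR"
                if utr_label:
                    break
        exonic = coding_overlap > 0 or any(
            overlap_len(locus, e) > 0 for e, _ in noncoding_exons
        )
        if coding_overlap * 2 >= len(locus) and coding_overlap > 0:
            ctx.labels.add("coding-exon")
        elif utr_label is not None:
            ctx.labels.add(utr_label)
        elif not exonic:
            ctx.labels.add("intronic")
        else:
            # exonic but below the 50% coding rule with no UTR reading:
            # the coding-exonic context is still the preferred designation
            ctx.labels.add("coding-exon" if coding_overlap > 0 else "intronic")
    if contributing == 0:
        ctx.labels.add("intergenic")
    elif contributing > 1:
        ctx.labels.add("multiple-genes")
    ctx.nearest_genes.sort(key=lambda g: (abs(g[1]), g[0]))
    return ctx


def cluster_loci(
    loci: Sequence, max_dist: int = CLUSTER_MAX_DIST
) -> list[list[int]]:
    """Single-linkage clusters of loci on the same contig and strand.

    An edge joins two loci when their end-to-start gap (0 for
    overlapping loci) is strictly below ``max_dist``.  Singletons are
    clusters of size 1.  Returns index lists ordered by (contig, strand,
    first start).
    """
    def key(i):
        iv = loci[i].span if hasattr(loci[i], "span") else loci[i]
        return iv

    order = sorted(
        range(len(loci)),
        key=lambda i: (key(i).contig, key(i).strand, key(i).start, key(i).end),
    )
    clusters: list[list[int]] = []
    cur: list[int] = []
    cur_end = None
    cur_group = None
    for i in order:
        iv = key(i)
        group = (iv.contig, iv.strand)
        if cur and group == cur_group and iv.start - cur_end < max_dist:
            cur.append(i)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(cur)
            cur, cur_end, cur_group = [i], iv.end, group
    if cur:
        clusters.append(cur)
    return clusters


def cluster_class_composition(loci: Sequence, clusters: list[list[int]]):
    """Per-cluster class composition (e.g. to find clusters with >= 3 miRNAs)."""
    comp = []
    for cl in clusters:
        counts: dict[str, int] = {}
        for i in cl:
            cls = getattr(loci[i], "resolved_class", "other")
            counts[cls] = counts.get(cls, 0) + 1
        comp.append(counts)
    return comp


def mark_rnaz_overlap(
    locus: GenomicInterval,
    rnaz_loci: Sequence[RnazLocus],
    min_overlap: int = RNAZ_MIN_OVERLAP,
) -> bool:
    """True iff the locus overlaps any RNAz locus by >= 20 nt, strand ignored."""
    return any(
        overlap_len(locus, r.interval) >= min_overlap for r in rnaz_loci
    )


def mark_read_support(
    locus: GenomicInterval,
    block_groups: Sequence[ReadBlockGroup],
    min_reads: int = READ_MIN_COUNT,
    min_overlap: int = READ_MIN_OVERLAP,
) -> bool:
    """True iff some read block of >= 10 reads overlaps the locus by >= 20 nt."""
    for group in block_groups:
        for block, count in group.blocks:
            if count >= min_reads and overlap_len(locus, block) >= min_overlap:
                return True
    return False


def filter_block_groups(
    groups: Sequence[ReadBlockGroup],
    similarity: Sequence[Sequence[tuple[float, str]]] | None = None,
    min_len: int = BLOCK_GROUP_MIN_LEN,
    min_score: float = DBA_MIN_SCORE,
) -> list[tuple[ReadBlockGroup, str]]:
    """Length-filter block groups and transfer classes from profile matches.

    Groups shorter than 50 nt are dropped (their read profile carries too
    little shape to align).  For survivors the class of the best-scoring
    profile match is transferred when the alignment score is >= 0.6;
    otherwise the group is labelled ``unannotated``.
    """
    if similarity is not None and len(similarity) != len(groups):
        raise ValueError("similarity list must parallel groups")
    out = []
    for i, g in enumerate(groups):
        if g.length < min_len:
            continue
        label = "unannotated"
        if similarity is not None and similarity[i]:
            score, cls = max(similarity[i], key=lambda sc: (sc[0], sc[1]))
            if score >= min_score:
                label = cls
        out.append((g, label))
    return out


def classification_transfer_table(
    transferred: Sequence[tuple[ReadBlockGroup, str]],
    mirna_loci: Sequence[GenomicInterval],
    min_overlap: int = READ_MIN_OVERLAP,
):
    """Cross-table of transferred class vs overlap with miRNA-caller loci."""
    import pandas as pd

    rows: dict[tuple[str, bool], int] = {}
    for group, cls in transferred:
        hit = any(
            overlap_len(group.interval, m) >= min_overlap for m in mirna_loci
        )
        rows[(cls, hit)] = rows.get((cls, hit), 0) + 1
    return pd.DataFrame(
        [
            {"class": cls, "mirna_overlap": hit, "groups": n}
            for (cls, hit), n in sorted(rows.items())
        ]
    )
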