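"""Readers and writers for every external format the framework touches.

One canonical tabular dialect per tool is declared here (real tool outputs
drift between versions); each reader is the exact inverse of the matching
emitter used by the synthetic fixture generators, and round-trip tests
enforce that.  Downstream modules consume only the parsed domain types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_model import GeneModel, GenomicInterval, Transcript

logger = logging.getLogger(__name__)

TOOLS = (
    "blast",
    "infernal",
    "trnascan",
    "rnammer",
    "snostrip",
    "mirdeep",
    "rnaz",
    "blockbuster",
)

RNA_CLASSES = (
    "miRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "cisreg",
    "lncRNA-locus",
    "ribozyme",
    "other",
)


@dataclass
class ToolHit:
    """One hit from one search tool/database."""

    tool: str
    database: str
    family: str
    rna_class: str
    interval: GenomicInterval
    e_value: float | None = None
    bit_score: float = 0.0
    identity_pct: float | None = None
    query_coverage_pct: float | None = None
    tool_scores: dict[str, float] = field(default_factory=dict)
    # tRNAscan-SE: hit seen by both first-pass parsers
    both_first_pass_parsers: bool = False

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        if self.e_value is not None and self.e_value < 0:
            raise ValueError("E-value must be >= 0")
        has_blast_fields = (
            self.identity_pct is not None and self.query_coverage_pct is not None
        )
        if (self.tool == "blast") != has_blast_fields:
            raise ValueError(
                "identity_pct/query_coverage_pct present iff tool == blast"
            )


@dataclass
class FamilyMeta:
    """Per-family metadata (RNA class, gathering score, flags)."""

    family: str
    rna_class: str
    gathering_score: float
    ga_implied_evalue: float
    vertebrate_seed: bool
    is_mirna_family: bool
    experimental_evidence: bool = True
    expected_pol: str = "none"  # none | polII | polIII

    def __post_init__(self) -> None:
        if self.ga_implied_evalue <= 0:
            raise ValueError("ga_implied_evalue must be > 0")
        if self.expected_pol not in ("none", "polII", "polIII"):
            raise ValueError(f"bad expected_pol {self.expected_pol!r}")


@dataclass
class ReadBlockGroup:
    """Cluster of stacked small-RNA read blocks treated as one unit."""

    interval: GenomicInterval
    blocks: list[tuple[GenomicInterval, int]]

    def __post_init__(self) -> None:
        for iv, count in self.blocks:
            if count < 1:
                raise ValueError("block read_count must be >= 1")
            if iv.contig != self.interval.contig or not (
                self.interval.start <= iv.start and iv.end <= self.interval.end
            ):
                raise ValueError("block outside group interval")

    @property
    def length(self) -> int:
        return len(self.interval)


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = path, lineno


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# BLAST 12-column tabular (-m8 dialect)
# ---------------------------------------------------------------------------

def read_blast_tab(
    path,
    query_lengths: dict[str, int],
    query_meta: dict[str, tuple[str, str]] | None = None,
) -> list[ToolHit]:
    """Parse 12-column BLAST tabular output into ToolHits.

    Columns: query, subject, %identity, aln-len, mismatches, gaps, qstart,
    qend, sstart, send, E-value, bitscore; the subject is a genome contig
    and subject coordinates are 1-based closed.  ``sstart > send`` means a
    minus-strand hit.  Query coverage is aln-len / query-length * 100 using
    the supplied query-length table.

    ``query_meta`` optionally maps query id -> (database, rna_class); the
    query id itself is taken as the family name, with an optional
    ``db|family`` prefix convention overriding the database.
    """
    hits = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 12:
            raise ParseError(path, lineno, f"expected 12 columns, got {len(f)}")
        try:
            query, subject = f[0], f[1]
            identity = float(f[2])
            aln_len = int(f[3])
            sstart, send = int(f[8]), int(f[9])
            e_value = float(f[10])
            bit_score = float(f[11])
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        if sstart > send:
            strand, start, end = "-", send - 1, sstart
        else:
            strand, start, end = "+", sstart - 1, send
        database, rna_class = "unknown", "other"
        family = query
        if "|" in query:
            database, family = query.split("|", 1)
        if query_meta and query in query_meta:
            database, rna_class = query_meta[query]
        if family not in query_lengths and query not in query_lengths:
            raise ParseError(path, lineno, f"no query length for {query!r}")
        qlen = query_lengths.get(query, query_lengths.get(family))
        hits.append(
            ToolHit(
                tool="blast",
                database=database,
                family=family,
                rna_class=rna_class,
                interval=GenomicInterval(subject, start, end, strand),
                e_value=e_value,
                bit_score=bit_score,
                identity_pct=identity,
                query_coverage_pct=aln_len / qlen * 100.0,
            )
        )
    return hits


def write_blast_tab(hits: Sequence[ToolHit], query_lengths: dict[str, int], path) -> None:
    """Emit ToolHits in the 12-column dialect read_blast_tab expects."""
    with open(path, "w") as fh:
        for h in hits:
            if h.tool != "blast":
                raise ValueError("write_blast_tab accepts only BLAST hits")
            iv = h.interval
            qname = f"{h.database}|{h.family}"
            qlen = query_lengths[h.family]
            aln_len = round(h.query_coverage_pct * qlen / 100.0)
            if iv.strand == "-":
                sstart, send = iv.end, iv.start + 1
            else:
                sstart, send = iv.start + 1, iv.end
            fh.write(
                "\t".join(
                    [
                        qname,
                        iv.contig,
                        f"{h.identity_pct:.2f}",
                        str(aln_len),
                        "0",
                        "0",
                        "1",
                        str(aln_len),
                        str(sstart),
                        str(send),
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Infernal tabular dialect
# ---------------------------------------------------------------------------

def read_infernal_tab(
    path, meta: dict[str, FamilyMeta]
) -> tuple[list[ToolHit], int]:
    """Parse the Infernal tabular dialect; join rows to FamilyMeta by family.

    Columns: family, contig, start(1-based), end(closed), strand, bit score,
    E-value.  Rows whose family is absent from the metadata table are
    skipped with a logged warning; the skip count is returned alongside the
    parsed hits.
    """
    hits, skipped = [], 0
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 7:
            raise ParseError(path, lineno, f"expected 7 columns, got {len(f)}")
        family, contig, start_s, end_s, strand, score_s, e_s = f
        fam_meta = meta.get(family)
        if fam_meta is None:
            logger.warning("%s:%d: unknown family %s skipped", path, lineno, family)
            skipped += 1
            continue
        try:
            start, end = int(start_s) - 1, int(end_s)
            bit_score, e_value = float(score_s), float(e_s)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        hits.append(
            ToolHit(
                tool="infernal",
                database="rfam",
                family=family,
                rna_class=fam_meta.rna_class,
                interval=GenomicInterval(contig, start, end, strand),
                e_value=e_value,
                bit_score=bit_score,
            )
        )
    return hits, skipped


def write_infernal_tab(hits: Sequence[ToolHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if h.tool != "infernal":
                raise ValueError("write_infernal_tab accepts only Infernal hits")
            iv = h.interval
            fh.write(
                "\t".join(
                    [
                        h.family,
                        iv.contig,
                        str(iv.start + 1),
                        str(iv.end),
                        iv.strand,
                        f"{h.bit_score:.1f}",
                        f"{h.e_value:.3g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# tRNAscan-SE standard output
# ---------------------------------------------------------------------------

_TRNASCAN_HEADER = (
    "contig\ttRNA#\tbegin\tend\ttype\tanticodon\tintron_begin\tintron_end\t"
    "cove_score\thmm_score\tstr_score\tboth_parsers\n"
)


def read_trnascan(path) -> list[ToolHit]:
    """Parse tRNAscan-SE style output (with first-pass scores appended).

    Columns: contig, tRNA number, begin(1-based), end(closed), isotype,
    anticodon, intron begin, intron end, COVE score, HMM score, 2'Str
    score, both-first-pass-parsers flag.  begin > end means minus strand.
    """
    hits = []
    for lineno, line in _data_lines(path):
        if line.startswith("contig\t"):
            continue
        f = line.split("\t")
        if len(f) != 12:
            raise ParseError(path, lineno, f"expected 12 columns, got {len(f)}")
        try:
            contig = f[0]
            begin, end = int(f[2]), int(f[3])
            isotype, anticodon = f[4], f[5]
            cove, hmm, strsc = float(f[8]), float(f[9]), float(f[10])
            both = f[11] in ("1", "true", "True", "yes")
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        if begin > end:
            strand, start, stop = "-", end - 1, begin
        else:
            strand, start, stop = "+", begin - 1, end
        hits.append(
            ToolHit(
                tool="trnascan",
                database="trnascan",
                family=f"tRNA-{isotype}-{anticodon}",
                rna_class="tRNA",
                interval=GenomicInterval(contig, start, stop, strand),
                bit_score=cove,
                tool_scores={"COVE": cove, "HMM": hmm, "2'Str": strsc},
                both_first_pass_parsers=both,
            )
        )
    return hits


def write_trnascan(hits: Sequence[ToolHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRNASCAN_HEADER)
        for i, h in enumerate(hits, 1):
            if h.tool != "trnascan":
                raise ValueError("write_trnascan accepts only tRNAscan hits")
            str_score = h.tool_scores["2'Str"]
            iv = h.interval
            parts = h.family.split("-")
            isotype = parts[1] if len(parts) > 1 else "Xxx"
            anticodon = parts[2] if len(parts) > 2 else "NNN"
            if iv.strand == "-":
                begin, end = iv.end, iv.start + 1
            else:
                begin, end = iv.start + 1, iv.end
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        str(i),
                        str(begin),
                        str(end),
                        isotype,
                        anticodon,
                        "0",
                        "0",
                        f"{h.tool_scores['COVE']:.1f}",
                        f"{h.tool_scores['HMM']:.1f}",
                        f"{str_score:.1f}",
                        "1" if h.both_first_pass_parsers else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Generic GFF3 hits (RNAmmer / snoStrip / miRDeep / RNAz-style inputs)
# ---------------------------------------------------------------------------

def parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value
    return attrs


def format_gff3_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_generic_gff3_hits(path, tool: str, default_class: str = "other") -> list[ToolHit]:
    """Read GFF3 feature lines as hits from a class-specific or de novo tool.

    The feature type column carries the RNA class; attributes may carry
    Name (family), e_value and score.
    """
    hits = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 9:
            raise ParseError(path, lineno, f"expected 9 GFF3 columns, got {len(f)}")
        contig, _source, ftype, start_s, end_s, score_s, strand, _, attr_s = f
        attrs = parse_gff3_attributes(attr_s)
        rna_class = ftype if ftype in RNA_CLASSES else default_class
        try:
            start, end = int(start_s) - 1, int(end_s)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        score = 0.0 if score_s == "." else float(score_s)
        e_value = float(attrs["e_value"]) if "e_value" in attrs else None
        hits.append(
            ToolHit(
                tool=tool,
                database=attrs.get("database", tool),
                family=attrs.get("Name", ftype),
                rna_class=rna_class,
                interval=GenomicInterval(contig, start, end, strand),
                e_value=e_value,
                bit_score=score,
            )
        )
    return hits


def write_generic_gff3_hits(hits: Sequence[ToolHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            iv = h.interval
            attrs = {"Name": h.family, "database": h.database}
            if h.e_value is not None:
                attrs["e_value"] = f"{h.e_value:.3g}"
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        h.tool,
                        h.rna_class,
                        str(iv.start + 1),
                        str(iv.end),
                        f"{h.bit_score:.1f}",
                        iv.strand,
                        ".",
                        format_gff3_attributes(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FamilyMeta table (TSV)
# ---------------------------------------------------------------------------

_META_HEADER = (
    "family\trna_class\tgathering_score\tga_implied_evalue\tvertebrate_seed\t"
    "is_mirna_family\texperimental_evidence\texpected_pol\n"
)


def read_family_meta(path) -> dict[str, FamilyMeta]:
    meta = {}
    for lineno, line in _data_lines(path):
        if line.startswith("family\t"):
            continue
        f = line.split("\t")
        if len(f) != 8:
            raise ParseError(path, lineno, f"expected 8 columns, got {len(f)}")
        try:
            fm = FamilyMeta(
                family=f[0],
                rna_class=f[1],
                gathering_score=float(f[2]),
                ga_implied_evalue=float(f[3]),
                vertebrate_seed=f[4] == "1",
                is_mirna_family=f[5] == "1",
                experimental_evidence=f[6] == "1",
                expected_pol=f[7],
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        meta[fm.family] = fm
    return meta


def write_family_meta(meta: dict[str, FamilyMeta] | Iterable[FamilyMeta], path) -> None:
    rows = meta.values() if isinstance(meta, dict) else meta
    with open(path, "w") as fh:
        fh.write(_META_HEADER)
        for m in rows:
            fh.write(
                "\t".join(
                    [
                        m.family,
                        m.rna_class,
                        f"{m.gathering_score:g}",
                        f"{m.ga_implied_evalue:.3g}",
                        "1" if m.vertebrate_seed else "0",
                        "1" if m.is_mirna_family else "0",
                        "1" if m.experimental_evidence else "0",
                        m.expected_pol,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Read block groups (BED-like)
# ---------------------------------------------------------------------------

def read_block_groups(path) -> list[ReadBlockGroup]:
    """BED-like block-group file: group lines followed by their block lines.

    Group line:  contig  start  end  group  .      strand
    Block line:  contig  start  end  block  count  strand
    (0-based half-open, blockbuster-style nesting flattened to two levels)
    """
    groups: list[ReadBlockGroup] = []
    pending: tuple[GenomicInterval, list] | None = None
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 6:
            raise ParseError(path, lineno, f"expected 6 columns, got {len(f)}")
        contig, start_s, end_s, name, score_s, strand = f
        iv = GenomicInterval(contig, int(start_s), int(end_s), strand)
        if name.startswith("group"):
            if pending:
                groups.append(ReadBlockGroup(*pending))
            pending = (iv, [])
        else:
            if pending is None:
                raise ParseError(path, lineno, "block line before any group line")
            pending[1].append((iv, int(score_s)))
    if pending:
        groups.append(ReadBlockGroup(*pending))
    return groups


def write_block_groups(groups: Sequence[ReadBlockGroup], path) -> None:
    with open(path, "w") as fh:
        for gi, g in enumerate(groups, 1):
            iv = g.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\tgroup{gi}\t.\t{iv.strand}\n"
            )
            for bi, (b, count) in enumerate(g.blocks, 1):
                fh.write(
                    f"{b.contig}\t{b.start}\t{b.end}\tblock{gi}.{bi}\t{count}\t{b.strand}\n"
                )


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

def read_gene_models_gff3(path) -> list[GeneModel]:
    """Read coding gene models: gene / mRNA (Parent=gene) / exon, CDS (Parent=mRNA)."""
    genes: dict[str, list[str]] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # tx -> (gene, strand)
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    gene_order: list[str] = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 9:
            raise ParseError(path, lineno, f"expected 9 GFF3 columns, got {len(f)}")
        contig, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = f
        attrs = parse_gff3_attributes(attr_s)
        start, end = int(start_s) - 1, int(end_s)
        if ftype == "gene":
            gid = attrs["ID"]
            genes.setdefault(gid, [])
            gene_order.append(gid)
        elif ftype in ("mRNA", "transcript"):
            tid, gid = attrs["ID"], attrs["Parent"]
            genes.setdefault(gid, []).append(tid)
            tx_meta[tid] = (gid, strand)
        elif ftype == "exon":
            exons.setdefault(attrs["Parent"], []).append(
                GenomicInterval(contig, start, end, strand)
            )
        elif ftype == "CDS":
            cds.setdefault(attrs["Parent"], []).append(
                GenomicInterval(contig, start, end, strand)
            )
    models = []
    for gid in gene_order:
        txs = [
            Transcript(tid, tx_meta[tid][1], exons.get(tid, []), cds.get(tid, []))
            for tid in genes[gid]
        ]
        if txs:
            models.append(GeneModel(gid, txs))
    return models


def write_gene_models_gff3(models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                "\t".join(
                    [
                        g.contig, "rnannot", "gene",
                        str(g.start + 1), str(g.end), ".", g.strand, ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
            for t in g.transcripts:
                fh.write(
                    "\t".join(
                        [
                            g.contig, "rnannot", "mRNA",
                            str(t.start + 1), str(t.end), ".", t.strand, ".",
                            f"ID={t.transcript_id};Parent={g.gene_id}",
                        ]
                    )
                    + "\n"
                )
                for e in t.exons:
                    fh.write(
                        "\t".join(
                            [
                                e.contig, "rnannot", "exon",
                                str(e.start + 1), str(e.end), ".", t.strand, ".",
                                f"Parent={t.transcript_id}",
                            ]
                        )
                        + "\n"
                    )
                for c in t.cds:
                    fh.write(
                        "\t".join(
                            [
                                c.contig, "rnannot", "CDS",
                                str(c.start + 1), str(c.end), ".", t.strand, "0",
                                f"Parent={t.transcript_id}",
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Annotation GFF3 / BED6 output
# ---------------------------------------------------------------------------

_BED_SCORE = {"high": 1000, "medium": 500, "low": 100}


def write_annotation_gff3(loci, path) -> None:
    """Write finalized RNA loci as GFF3 (type = resolved class)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, locus in enumerate(loci, 1):
            iv = locus.span
            attrs = {
                "ID": locus.locus_id or f"locus{i}",
                "Name": locus.resolved_name,
                "confidence": locus.confidence,
                "conflict": "true" if locus.conflict else "false",
            }
            if locus.curation_status:
                attrs["curation"] = locus.curation_status
            if locus.tags:
                attrs["tags"] = ",".join(sorted(locus.tags))
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        "rnannot",
                        locus.resolved_class,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        format_gff3_attributes(attrs),
                    ]
                )
                + "\n"
            )


def read_annotation_gff3(path):
    """Read loci written by write_annotation_gff3 (inverse round trip)."""
    from .confidence_merge import RnaLocus

    loci = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 9:
            raise ParseError(path, lineno, f"expected 9 GFF3 columns, got {len(f)}")
        contig, _src, rna_class, start_s, end_s, _score, strand, _, attr_s = f
        attrs = parse_gff3_attributes(attr_s)
        iv = GenomicInterval(contig, int(start_s) - 1, int(end_s), strand)
        loci.append(
            RnaLocus(
                span=iv,
                members=[],
                resolved_name=attrs.get("Name", ""),
                resolved_class=rna_class,
                confidence=attrs.get("confidence", "low"),
                conflict=attrs.get("conflict") == "true",
                locus_id=attrs.get("ID", ""),
                curation_status=attrs.get("curation", ""),
                tags=set(attrs["tags"].split(",")) if attrs.get("tags") else set(),
            )
        )
    return loci


def write_bed6(loci, path) -> None:
    """BED6 track; score encodes the confidence tier (1000/500/100)."""
    with open(path, "w") as fh:
        for i, locus in enumerate(loci, 1):
            iv = locus.span
            name = locus.locus_id or f"locus{i}"
            score = _BED_SCORE[locus.confidence]
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n"
            )
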