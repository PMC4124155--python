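"""Class-specific curation rules: curated / pseudogene / uncurated ledger.

Pseudogenes are loci expected, but failing, to be PolII/PolIII
transcripts, ribosomal RNAs outside the complete rRNA cluster,
cis-regulatory elements without nearby gene context, and non-curated
members of snoRNA families with curated members.  Also implements the
miRNA-prediction cleanup rule set applied to read-based (miRDeep-style)
precursor predictions before they join the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genome_model import GenomicInterval, overlap_len
from .context import GenicContext
from .promoter import PromoterCall
from .synteny import ConservationCall

CISREG_CURATE_DIST = 1_000
CISREG_PSEUDO_DIST = 10_000
RRNA_CLUSTER_WINDOW = 20_000
SNORNA_MIN_IDENTITY = 0.60
MIRDEEP_MIN_READS = 10

STATUSES = ("curated", "pseudogene", "uncurated")


@dataclass
class CurationRecord:
    locus_id: str
    status: str
    rule: str = ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if self.status != "uncurated" and not self.rule:
            raise ValueError("rule required unless uncurated")


def curate_cisreg(
    locus,
    context: GenicContext,
    curate_dist: int = CISREG_CURATE_DIST,
    pseudo_dist: int = CISREG_PSEUDO_DIST,
) -> CurationRecord:
    """Cis-regulatory elements: curated with a sense gene within 1,000 nt
    (or overlapping); pseudogene with no gene within 10,000 nt; otherwise
    uncurated."""
    if locus.resolved_class != "cisreg":
        raise ValueError(f"curate_cisreg on class {locus.resolved_class!r}")
    sense_near = any(
        abs(dist) <= curate_dist
        and context.sense_relation.get(gene_id) == "sense"
        for gene_id, dist in context.nearest_genes
    )
    if sense_near:
        return CurationRecord(
            locus.locus_id, "curated", "cisreg-sense-context",
            "sense gene within 1,000 nt",
        )
    if not context.nearest_genes or all(
        abs(dist) > pseudo_dist for _g, dist in context.nearest_genes
    ):
        return CurationRecord(
            locus.locus_id, "pseudogene", "cisreg-no-gene-context",
            "no gene within 10,000 nt",
        )
    return CurationRecord(locus.locus_id, "uncurated")


def curate_rrna(
    rrna_loci: Sequence,
    subunits: dict[str, str],
    cluster_window: int = RRNA_CLUSTER_WINDOW,
    required: frozenset[str] = frozenset({"28S", "18S", "5.8S"}),
) -> list[CurationRecord]:
    """Ribosomal RNAs: members of a complete 28S/18S/5.8S cluster are
    curated; all other rRNA loci are pseudogenes.

    ``subunits`` maps locus_id -> subunit name.  A complete cluster is a
    set of loci on one contig, every pair within ``cluster_window`` nt,
    containing all three required subunits; membership is computed by
    single linkage at the window distance.
    """
    by_contig: dict[str, list] = {}
    for locus in rrna_loci:
        by_contig.setdefault(locus.span.contig, []).append(locus)
    curated_ids: set[str] = set()
    for contig_loci in by_contig.values():
        contig_loci.sort(key=lambda l: l.span.start)
        cluster: list = []
        def flush(cluster):
            names = {subunits.get(l.locus_id, "") for l in cluster}
            if required <= names:
                curated_ids.update(l.locus_id for l in cluster)
        for locus in contig_loci:
            if cluster and locus.span.start - cluster[-1].span.end <= cluster_window:
                cluster.append(locus)
            else:
                if cluster:
                    flush(cluster)
                cluster = [locus]
        if cluster:
            flush(cluster)
    records = []
    for locus in rrna_loci:
        if locus.locus_id in curated_ids:
            records.append(
                CurationRecord(
                    locus.locus_id, "curated", "rrna-full-cluster",
                    "member of complete 28S/18S/5.8S cluster",
                )
            )
        else:
            records.append(
                CurationRecord(
                    locus.locus_id, "pseudogene", "rrna-outside-cluster",
                    "rRNA outside the complete cluster",
                )
            )
    return records


def curate_snorna(
    snorna_loci: Sequence,
    families: dict[str, str],
    reference_curated: dict[str, list[GenomicInterval]],
    lifted: dict[str, list[GenomicInterval]],
    identities: dict[str, float | None],
    min_identity: float = SNORNA_MIN_IDENTITY,
) -> list[CurationRecord]:
    """snoRNAs: curated when the lifted coordinates overlap a reference
    curated snoRNA of the same family at sequence identity > 60%
    (strict); the remaining members of families with at least one
    curated member are pseudogenes; families with no curated member stay
    uncurated.

    ``families`` maps locus_id -> family; ``reference_curated`` maps
    family -> curated reference intervals (reference-genome coordinates);
    ``lifted`` maps locus_id -> liftover output; ``identities`` maps
    locus_id -> identity fraction to the reference organism (None when
    insufficient coverage).
    """
    status: dict[str, str] = {}
    curated_families: set[str] = set()
    for locus in snorna_loci:
        lid = locus.locus_id
        fam = families.get(lid, "")
        ident = identities.get(lid)
        refs = reference_curated.get(fam, [])
        hit = any(
            overlap_len(q, r) >= 1 for q in lifted.get(lid, []) for r in refs
        )
        if hit and ident is not None and ident > min_identity:
            status[lid] = "curated"
            curated_families.add(fam)
    records = []
    for locus in snorna_loci:
        lid = locus.locus_id
        fam = families.get(lid, "")
        if status.get(lid) == "curated":
            records.append(
                CurationRecord(
                    lid, "curated", "snorna-reference-match",
                    f"lifted match to curated {fam} above 60% identity",
                )
            )
        elif fam in curated_families:
            records.append(
                CurationRecord(
                    lid, "pseudogene", "snorna-noncurated-member",
                    f"family {fam} has a curated member elsewhere",
                )
            )
        else:
            records.append(CurationRecord(lid, "uncurated"))
    return records


def curate_host_gene_order(
    snorna_loci: Sequence,
    families: dict[str, str],
    reference_order: Sequence[str],
    max_dist: int = 10_000,
) -> list[str]:
    """Opt-in host-gene order rule: locus ids of a cluster whose family
    order along the genome equals the reference host-gene snoRNA order
    (the SNHG1/GAS5-style case).  Strand-reversed order also matches."""
    loci = sorted(snorna_loci, key=lambda l: (l.span.contig, l.span.start))
    curated: list[str] = []
    run: list = []
    for locus in loci:
        if run and (
            locus.span.contig != run[-1].span.contig
            or locus.span.start - run[-1].span.end > max_dist
        ):
            run = []
        run.append(locus)
        fams = [families.get(l.locus_id, "") for l in run[-len(reference_order):]]
        if len(fams) == len(reference_order) and (
            fams == list(reference_order) or fams == list(reference_order)[::-1]
        ):
            curated.extend(l.locus_id for l in run[-len(reference_order):])
    return curated


def curate_pol23(locus, promoter_call: PromoterCall | None) -> CurationRecord:
    """Expected PolII/PolIII transcripts: curated on a promoter pass,
    pseudogene on a fail, uncurated when no upstream slice was available
    (contig edge)."""
    if promoter_call is None:
        return CurationRecord(
            locus.locus_id, "uncurated", evidence="upstream sequence unavailable"
        )
    if promoter_call.passed:
        return CurationRecord(
            locus.locus_id, "curated", f"{promoter_call.mode}-promoter",
            "required promoter elements present",
        )
    return CurationRecord(
        locus.locus_id, "pseudogene", f"{promoter_call.mode}-promoter-fail",
        "expected promoter elements absent",
    )


# ---------------------------------------------------------------------------
# miRNA prediction cleanup
# ---------------------------------------------------------------------------

@dataclass
class MirnaPrediction:
    """One read-based miRNA precursor prediction."""

    name: str
    precursor_seq: str
    mature_seq: str
    star_seq: str | None
    loci: list[GenomicInterval]
    read_count: int
    misplaced: bool = False
    tier: str = "high"


@dataclass
class MirnaCleanupResult:
    kept: list[MirnaPrediction]
    audit_log: list[str] = field(default_factory=list)


def mirdeep_cleanup(
    predictions: Sequence[MirnaPrediction],
    annotation: Sequence,
    coding_exon_loci: set[str] | None = None,
    min_reads: int = MIRDEEP_MIN_READS,
) -> MirnaCleanupResult:
    """Apply the miRNA-prediction cleanup rules in order.

    1. collapse byte-identical precursor sequences across loci;
    2. overlapping distinct precursors: keep both when star and mature
       sequences are identical, discard both when star reads are absent;
    3. one precursor with two matures differing by a 2-nt extension:
       discard the shorter;
    4. discard precursors overlapping high-tier non-miRNA annotation
       (conflict-marked loci are kept);
    5. demote to medium precursors whose loci have coding-exon context;
    6. discard precursors flagged as arising from misplaced reads.

    ``coding_exon_loci`` holds the names of predictions with coding-exon
    genic context (rule 5).  Predictions with fewer than 10 reads are
    rejected at intake.  The audit log records every rule firing; the
    procedure is idempotent.
    """
    log: list[str] = []
    preds: list[MirnaPrediction] = []
    for p in predictions:
        if p.read_count < min_reads:
            raise ValueError(
                f"{p.name}: prediction with {p.read_count} reads (< {min_reads})"
            )
        preds.append(p)

    # 1. collapse identical precursors (same precursor, mature and star:
    # duplicated genomic sequence mapping one prediction to several loci)
    by_seq: dict[tuple, MirnaPrediction] = {}
    for p in preds:
        key = (p.precursor_seq, p.mature_seq, p.star_seq)
        if key in by_seq:
            keeper = by_seq[key]
            merged = {(iv.contig, iv.start, iv.end, iv.strand) for iv in keeper.loci}
            for iv in p.loci:
                if (iv.contig, iv.start, iv.end, iv.strand) not in merged:
                    keeper.loci.append(iv)
            keeper.read_count = max(keeper.read_count, p.read_count)
            log.append(f"collapse-identical: {p.name} -> {keeper.name}")
        else:
            by_seq[key] = MirnaPrediction(
                p.name, p.precursor_seq, p.mature_seq, p.star_seq,
                list(p.loci), p.read_count, p.misplaced, p.tier,
            )
    preds = list(by_seq.values())

    # 2. overlapping distinct precursors
    discard: set[str] = set()
    for i in range(len(preds)):
        for j in range(i + 1, len(preds)):
            a, b = preds[i], preds[j]
            if not any(
                overlap_len(x, y) >= 1 for x in a.loci for y in b.loci
            ):
                continue
            if (
                a.star_seq is not None
                and a.star_seq == b.star_seq
                and a.mature_seq == b.mature_seq
            ):
                log.append(f"overlap-resolved: {a.name}/{b.name} identical star+mature")
            elif a.star_seq is None or b.star_seq is None:
                discard.update((a.name, b.name))
                log.append(f"overlap-discard: {a.name}/{b.name} star reads missing")
    preds = [p for p in preds if p.name not in discard]

    # 3. two matures differing by a 2-nt extension of one precursor
    by_precursor: dict[str, list[MirnaPrediction]] = {}
    for p in preds:
        by_precursor.setdefault(p.precursor_seq, []).append(p)
    keep3: list[MirnaPrediction] = []
    for group in by_precursor.values():
        if len(group) == 2:
            short, long_ = sorted(group, key=lambda p: len(p.mature_seq))
            if (
                len(long_.mature_seq) - len(short.mature_seq) == 2
                and short.mature_seq in long_.mature_seq
            ):
                log.append(f"short-mature-discard: {short.name}")
                keep3.append(long_)
                continue
        keep3.extend(group)
    preds = keep3

    # 4. overlap with high-tier non-miRNA annotation
    kept4 = []
    for p in preds:
        clash = False
        for locus in annotation:
            if locus.confidence != "high" or locus.resolved_class == "miRNA":
                continue
            if any(overlap_len(iv, locus.span) >= 1 for iv in p.loci):
                if locus.conflict:
                    log.append(f"overlap-conflict-kept: {p.name} vs {locus.locus_id}")
                else:
                    clash = True
                    log.append(
                        f"annotation-discard: {p.name} overlaps "
                        f"{locus.resolved_class} {locus.locus_id}"
                    )
                    break
        if not clash:
            kept4.append(p)
    preds = kept4

    # 5. coding-exon context -> medium tier
    for p in preds:
        if coding_exon_loci and p.name in coding_exon_loci and p.tier == "high":
            p.tier = "medium"
            log.append(f"coding-context-demote: {p.name}")

    # 6. misplaced reads
    kept6 = []
    for p in preds:
        if p.misplaced:
            log.append(f"misplaced-discard: {p.name}")
        else:
            kept6.append(p)
    preds = kept6

    preds.sort(key=lambda p: p.name)
    return MirnaCleanupResult(preds, log)


# ---------------------------------------------------------------------------
# Final assembly
# ---------------------------------------------------------------------------

def assemble_curated_annotation(loci: Sequence, records: Sequence[CurationRecord]):
    """Merge per-rule curation records into the final per-class table.

    A locus may receive at most one non-uncurated status; a locus marked
    both curated and pseudogene is a rule-set bug and raises.  Returns
    (per-locus status dict, per-class summary DataFrame with columns
    high_confident / curated / pseudogene / remaining).
    """
    import pandas as pd

    status: dict[str, str] = {}
    for rec in records:
        prev = status.get(rec.locus_id)
        if prev in ("curated", "pseudogene") and rec.status in (
            "curated",
            "pseudogene",
        ) and prev != rec.status:
            raise ValueError(
                f"locus {rec.locus_id} marked both {prev} and {rec.status}"
            )
        if rec.status != "uncurated" or prev is None:
            status.setdefault(rec.locus_id, rec.status)
            if rec.status != "uncurated":
                status[rec.locus_id] = rec.status
    rows: dict[str, dict[str, int]] = {}
    for locus in loci:
        st = status.get(locus.locus_id, "uncurated")
        locus.curation_status = st
        row = rows.setdefault(
            locus.resolved_class,
            {"high_confident": 0, "curated": 0, "pseudogene": 0, "uncurated": 0},
        )
        row["high_confident"] += 1
        row[st] += 1
    table = pd.DataFrame(
        [{"rna_class": cls, **v} for cls, v in sorted(rows.items())]
    )
    if not table.empty:
        table["remaining"] = table["high_confident"] - table["pseudogene"]
    return status, table
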