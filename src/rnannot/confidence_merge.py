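"""Confidence-tiered integration of homology-search hits into RNA loci.

This is the annotation engine: per-tool confidence classification, the
four Infernal/Rfam filters, within-database conflict resolution, locus
building by overlap, conflict detection, tool-ranked naming, and the
built-in demotion rules.

An RNA *locus* is a set of overlapping RNA structure or sequence hits.
Three nested confidence tiers are produced (high, medium, low); on
identical inputs the high-tier annotation is a subset of the medium,
which is a subset of the low (tier monotonicity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genome_model import GenomicInterval, group_by_overlap, hull, overlap_len
from .tool_io import FamilyMeta, ToolHit

TIERS = ("high", "medium", "low")
_TIER_RANK = {"high": 0, "medium": 1, "low": 2}

#: Default tool ranking for naming: class-specific > blast > infernal > de novo.
DEFAULT_RANKING: dict[str, int] = {
    "trnascan": 0,
    "rnammer": 0,
    "snostrip": 0,
    "blast": 1,
    "infernal": 2,
    "mirdeep": 3,
    "rnaz": 3,
    "blockbuster": 3,
}


@dataclass
class ConfidencePolicy:
    """All per-tool thresholds defining the three confidence tiers.

    BLAST tiers require identity AND query coverage at or above the tier
    threshold (95/95 high, 92.5/92.5 medium, 90/90 low), after a global
    E <= 0.1 search cutoff.  Infernal non-miRNA hits must pass the
    family gathering score with an additional E-value cap of 1e-3 where
    the gathering-score-implied E-value is looser, plus a same-family
    BLAST anchor (E <= 1e-3 at high, 0.1 at medium, none at low).
    Rfam miRNA families are excluded from the high tier entirely and use
    stricter Infernal E-value cutoffs (1e-9 medium / 1e-6 low) with a
    BLAST anchor required at every tier.
    """

    blast_tiers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "high": (95.0, 95.0),
            "medium": (92.5, 92.5),
            "low": (90.0, 90.0),
        }
    )
    blast_global_e: float = 0.1
    infernal_e_cap: float = 1e-3
    infernal_anchor_e: dict[str, float | None] = field(
        default_factory=lambda: {"high": 1e-3, "medium": 0.1, "low": None}
    )
    mirna_infernal_e: dict[str, float | None] = field(
        default_factory=lambda: {"high": None, "medium": 1e-9, "low": 1e-6}
    )
    mirna_anchor_e: dict[str, float | None] = field(
        default_factory=lambda: {"high": None, "medium": 1e-3, "low": 0.1}
    )
    trnascan_hmm: float = 10.0
    trnascan_str: float = 5.0
    trnascan_cove: float = 20.0
    trnascan_single_parser_cove: float = 55.0


@dataclass
class RnaLocus:
    """A set of overlapping hits with a resolved name, class and tier."""

    span: GenomicInterval
    members: list[ToolHit]
    resolved_name: str = ""
    resolved_class: str = ""
    confidence: str = "low"
    conflict: bool = False
    conflict_detail: list[tuple[str, str]] = field(default_factory=list)
    tags: set[str] = field(default_factory=set)
    locus_id: str = ""
    curation_status: str = ""

    def __post_init__(self) -> None:
        if self.confidence not in TIERS:
            raise ValueError(f"bad confidence {self.confidence!r}")
        for m in self.members:
            if m.interval.contig != self.span.contig or not (
                self.span.start <= m.interval.start
                and m.interval.end <= self.span.end
            ):
                raise ValueError("member outside locus span")


def classify_blast_hit(hit: ToolHit, policy: ConfidencePolicy) -> str:
    """Highest tier whose identity AND coverage thresholds are both met.

    Returns ``reject`` below the low tier (90/90).  Thresholds are
    inclusive.
    """
    if hit.tool != "blast":
        raise ValueError("classify_blast_hit requires a BLAST hit")
    for tier in TIERS:
        min_id, min_cov = policy.blast_tiers[tier]
        if hit.identity_pct >= min_id and hit.query_coverage_pct >= min_cov:
            return tier
    return "reject"


def _evalue_key(hit: ToolHit) -> tuple[float, float, str]:
    e = hit.e_value if hit.e_value is not None else math.inf
    return (e, -hit.bit_score, hit.family)


def resolve_within_database(hits: list[ToolHit]) -> ToolHit:
    """Pick the single representative among overlapping same-database,
    same-class hits: lowest E-value, then higher bit score, then
    lexicographically smallest family name."""
    if not hits:
        raise ValueError("resolve_within_database on empty hit list")
    return min(hits, key=_evalue_key)


def resolve_blast_redundancy(hits: list[ToolHit]) -> list[ToolHit]:
    """Apply within-database resolution across a full BLAST hit set.

    Hits are partitioned by (database, rna_class); overlapping hits within
    each partition are reduced to the lowest-E representative.  Output
    order is deterministic (by contig, start).
    """
    by_group: dict[tuple[str, str], list[ToolHit]] = {}
    for h in hits:
        by_group.setdefault((h.database, h.rna_class), []).append(h)
    kept: list[ToolHit] = []
    for group_hits in by_group.values():
        comps = group_by_overlap([h.interval for h in group_hits])
        for comp in comps:
            kept.append(resolve_within_database([group_hits[i] for i in comp]))
    kept.sort(key=lambda h: (h.interval.contig, h.interval.start, h.family))
    return kept


def _has_anchor(
    hit: ToolHit, blast_by_family: dict[str, list[ToolHit]], max_e: float
) -> bool:
    """Same-family BLAST hit with E <= max_e overlapping by >= 1 nt."""
    for b in blast_by_family.get(hit.family, ()):
        if (
            b.e_value is not None
            and b.e_value <= max_e
            and overlap_len(hit.interval, b.interval) >= 1
        ):
            return True
    return False


def filter_infernal(
    infernal_hits: list[ToolHit],
    blast_hits: list[ToolHit],
    meta: dict[str, FamilyMeta],
    tier: str,
    policy: ConfidencePolicy | None = None,
) -> list[ToolHit]:
    """Apply the four Rfam/Infernal filters for one confidence tier.

    F1: keep only families with vertebrate seed sequences.
    F2: non-miRNA families: Infernal E <= min(gathering-score-implied E, 1e-3).
    F3: non-miRNA families: same-family BLAST anchor overlapping the hit,
        with E <= 1e-3 (high) / 0.1 (medium); no anchor required at low.
    F4: miRNA families: excluded from the high tier; at medium/low the
        Infernal E cutoff is 1e-9 / 1e-6 with an anchor at 1e-3 / 0.1.
    """
    policy = policy or ConfidencePolicy()
    blast_by_family: dict[str, list[ToolHit]] = {}
    for b in blast_hits:
        blast_by_family.setdefault(b.family, []).append(b)

    kept = []
    for h in infernal_hits:
        fam = meta.get(h.family)
        if fam is None or not fam.vertebrate_seed:
            continue
        if fam.is_mirna_family:
            e_cut = policy.mirna_infernal_e[tier]
            anchor_cut = policy.mirna_anchor_e[tier]
            if e_cut is None:  # high tier: miRNA families exempted
                continue
            if h.e_value is None or h.e_value > e_cut:
                continue
            if not _has_anchor(h, blast_by_family, anchor_cut):
                continue
        else:
            e_cut = min(fam.ga_implied_evalue, policy.infernal_e_cap)
            if h.e_value is None or h.e_value > e_cut:
                continue
            anchor_cut = policy.infernal_anchor_e[tier]
            if anchor_cut is not None and not _has_anchor(
                h, blast_by_family, anchor_cut
            ):
                continue
        kept.append(h)
    return kept


def filter_trnascan(
    hits: list[ToolHit], tier: str, policy: ConfidencePolicy | None = None
) -> list[ToolHit]:
    """tRNAscan-SE filtering.

    High/medium: keep when both first-pass parsers fired and HMM >= 10.0,
    2'Str >= 5.0 and COVE >= 20 (inclusive), otherwise only when
    COVE > 55 (strict).  Low: the unfiltered results.
    """
    policy = policy or ConfidencePolicy()
    if tier == "low":
        return list(hits)
    kept = []
    for h in hits:
        s = h.tool_scores
        if h.both_first_pass_parsers:
            ok = (
                s.get("HMM", -math.inf) >= policy.trnascan_hmm
                and s.get("2'Str", -math.inf) >= policy.trnascan_str
                and s.get("COVE", -math.inf) >= policy.trnascan_cove
            )
        else:
            ok = s.get("COVE", -math.inf) > policy.trnascan_single_parser_cove
        if ok:
            kept.append(h)
    return kept


def build_loci(hits: list[ToolHit], tier: str) -> list[RnaLocus]:
    """Group tier-filtered hits into loci by chained overlap (>= 1 nt,
    strand-agnostic); locus span is the hull of its members."""
    comps = group_by_overlap([h.interval for h in hits])
    loci = []
    for comp in comps:
        members = [hits[i] for i in comp]
        span_plus = hull(m.interval for m in members)
        strands = {m.interval.strand for m in members}
        strand = strands.pop() if len(strands) == 1 else "."
        span = GenomicInterval(span_plus.contig, span_plus.start, span_plus.end, strand)
        loci.append(RnaLocus(span=span, members=members, confidence=tier))
    return loci


def detect_conflicts(locus: RnaLocus) -> RnaLocus:
    """Mark cross-class and Rfam-family conflicts on a locus.

    A locus is conflicting when its members span two or more distinct RNA
    classes (e.g. annotated as both snoRNA and miRNA), or when two or
    more distinct Rfam families of the same class overlap among the
    Infernal members.  Same class but different names across tools is a
    naming issue, not a conflict.
    """
    detail: list[tuple[str, str]] = []
    classes = sorted({m.rna_class for m in locus.members})
    if len(classes) >= 2:
        seen = set()
        for m in sorted(locus.members, key=lambda m: (m.rna_class, m.tool)):
            if (m.rna_class, m.tool) not in seen:
                seen.add((m.rna_class, m.tool))
                detail.append((m.rna_class, m.tool))
    infernal_fams: dict[str, set[str]] = {}
    for m in locus.members:
        if m.tool == "infernal":
            infernal_fams.setdefault(m.rna_class, set()).add(m.family)
    for cls, fams in sorted(infernal_fams.items()):
        if len(fams) >= 2:
            for fam in sorted(fams):
                detail.append((fam, "infernal"))
    locus.conflict = bool(detail)
    locus.conflict_detail = detail
    return locus


def resolve_name(
    locus: RnaLocus, ranking: dict[str, int] | None = None
) -> tuple[str, str]:
    """Resolve the locus name and class by tool ranking.

    Class-specific methods are preferred over BLAST, which is preferred
    over Infernal/Rfam; de novo methods are a last resort.  Among members
    of equal rank the lowest E-value wins (ties broken by bit score and
    family name).  A conflicting locus gets class ``conflict`` and a name
    listing the member families.
    """
    if ranking is not None and not ranking:
        raise ValueError("empty tool ranking")
    ranking = ranking if ranking is not None else DEFAULT_RANKING
    if locus.conflict:
        name = ",".join(sorted({m.family for m in locus.members}))
        locus.resolved_name, locus.resolved_class = name, "conflict"
        return name, "conflict"
    best = min(
        locus.members,
        key=lambda m: (ranking.get(m.tool, max(ranking.values()) + 1),) + _evalue_key(m),
    )
    locus.resolved_name, locus.resolved_class = best.family, best.rna_class
    return best.family, best.rna_class


def demote(locus: RnaLocus, target_tier: str, reason: str) -> RnaLocus:
    """Lower a locus to a less confident tier, recording the reason."""
    if _TIER_RANK[target_tier] <= _TIER_RANK[locus.confidence]:
        raise ValueError(
            f"cannot demote from {locus.confidence} to {target_tier}"
        )
    locus.confidence = target_tier
    locus.tags.add(f"demoted:{reason}")
    return locus


def apply_demotion_rules(
    loci: list[RnaLocus], meta: dict[str, FamilyMeta] | None = None
) -> list[RnaLocus]:
    """Built-in demotion rules on the high tier.

    (a) a high-tier tRNA locus with no tRNAscan-SE member drops to medium;
    (b) a high-tier miRNA locus whose only evidence is BLAST to a miRBase
        entry without experimental evidence, and without read support in
        this study, drops to medium.
    """
    meta = meta or {}
    for locus in loci:
        if locus.confidence != "high":
            continue
        if locus.resolved_class == "tRNA" and not any(
            m.tool == "trnascan" for m in locus.members
        ):
            demote(locus, "medium", "no-tRNAscan")
        elif locus.resolved_class == "miRNA":
            blast_only = all(m.tool == "blast" for m in locus.members)
            no_evidence = all(
                not meta[m.family].experimental_evidence
                for m in locus.members
                if m.family in meta
            ) and any(m.family in meta for m in locus.members)
            if (
                blast_only
                and no_evidence
                and "read-supported" not in locus.tags
            ):
                demote(locus, "medium", "no-experimental-evidence")
    return loci


def annotate(
    blast_hits: list[ToolHit],
    infernal_hits: list[ToolHit],
    trnascan_hits: list[ToolHit],
    other_hits: list[ToolHit],
    meta: dict[str, FamilyMeta],
    tier: str,
    policy: ConfidencePolicy | None = None,
    ranking: dict[str, int] | None = None,
    apply_demotions: bool = True,
) -> list[RnaLocus]:
    """Run the full module-(i) annotation at one confidence tier.

    BLAST hits are tier-classified and reduced within each database and
    class; Infernal hits pass the four Rfam filters; tRNAscan-SE hits
    pass the score filter; class-specific tool hits (RNAmmer, snoStrip)
    are used as-is.  The surviving hits are grouped into loci, conflicts
    are marked, names resolved by tool ranking, and the built-in
    demotion rules applied.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}")
    policy = policy or ConfidencePolicy()
    rank = _TIER_RANK[tier]
    blast_kept = [
        h
        for h in blast_hits
        if (h.e_value is None or h.e_value <= policy.blast_global_e)
        and classify_blast_hit(h, policy) != "reject"
        and _TIER_RANK[classify_blast_hit(h, policy)] <= rank
    ]
    blast_kept = resolve_blast_redundancy(blast_kept)
    infernal_kept = filter_infernal(infernal_hits, blast_hits, meta, tier, policy)
    trnascan_kept = filter_trnascan(trnascan_hits, tier, policy)
    all_hits = blast_kept + infernal_kept + trnascan_kept + list(other_hits)
    all_hits.sort(
        key=lambda h: (h.interval.contig, h.interval.start, h.tool, h.family)
    )
    loci = build_loci(all_hits, tier)
    for i, locus in enumerate(loci, 1):
        detect_conflicts(locus)
        resolve_name(locus, ranking)
        locus.locus_id = f"RNA{i:05d}"
    if apply_demotions:
        apply_demotion_rules(loci, meta)
    return loci


def summarize_by_class(loci: list[RnaLocus]):
    """Per-class (class, family count, locus count) summary table."""
    import pandas as pd

    rows: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for locus in loci:
        rows.setdefault(locus.resolved_class, set()).add(locus.resolved_name)
        counts[locus.resolved_class] = counts.get(locus.resolved_class, 0) + 1
    return pd.DataFrame(
        [
            {"rna_class": cls, "families": len(fams), "loci": counts[cls]}
            for cls, fams in sorted(rows.items())
        ]
    )
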