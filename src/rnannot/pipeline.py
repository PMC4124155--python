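"""Pipeline orchestration: configuration, the three-stage run, and
verification against a planted-truth manifest.

Stages communicate through the domain types; every output is also
written to disk (GFF3/BED/TSV) together with a machine-readable run log
holding all thresholds and the seed, so a run can be reproduced from the
log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import confidence_merge, context, curation, promoter, synteny, tool_io
from .genome_model import Genome, GenomicInterval, overlap_len, read_fasta

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "seed", "tier", "genome", "blast", "infernal", "trnascan", "rnammer",
    "family_meta", "query_lengths", "gene_models", "block_groups", "rnaz",
    "pwm_training", "reference_snorna", "chains", "query_genomes",
    "reference_organism", "policy", "ranking", "inside_lineage",
    "outside_lineage",
}


@dataclass
class PipelineConfig:
    seed: int
    base_dir: Path
    tier: str = "high"
    paths: dict = field(default_factory=dict)
    chains: dict = field(default_factory=dict)
    query_genomes: dict = field(default_factory=dict)
    reference_organism: str = "human"
    policy_overrides: dict = field(default_factory=dict)
    ranking: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = path.parent
        paths = {
            k: raw[k]
            for k in (
                "genome", "blast", "infernal", "trnascan", "rnammer",
                "family_meta", "query_lengths", "gene_models",
                "block_groups", "rnaz", "pwm_training", "reference_snorna",
            )
            if k in raw
        }
        return cls(
            seed=int(raw.get("seed", 0)),
            base_dir=base,
            tier=raw.get("tier", "high"),
            paths=paths,
            chains=raw.get("chains", {}),
            query_genomes=raw.get("query_genomes", {}),
            reference_organism=raw.get("reference_organism", "human"),
            policy_overrides=raw.get("policy", {}),
            ranking=raw.get("ranking"),
        )

    def path(self, key: str) -> Path:
        return self.base_dir / self.paths[key]


@dataclass
class PipelineResult:
    loci_by_tier: dict[str, list]
    curation_status: dict[str, str]
    curation_table: object
    conservation_table: object
    contexts: dict[str, context.GenicContext]
    run_log: dict


def _read_query_lengths(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            fam, ln = line.rstrip("\n").split("\t")
            out[fam] = int(ln)
    return out


def _read_training(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            el, seq = line.rstrip("\n").split("\t")
            out.setdefault(el, []).append(seq)
    return out


def _read_reference_bed(path) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, family = line.split("\t")[:4]
            out.setdefault(family, []).append(
                GenomicInterval(contig, int(start), int(end))
            )
    return out


def upstream_slice(
    genome: Genome, span: GenomicInterval, length: int = promoter.SLICE_LEN
) -> str | None:
    """100-nt slice directly upstream of a locus on its strand, or None
    at a contig edge."""
    contig_len = genome.length(span.contig)
    if span.strand == "-":
        if span.end + length > contig_len:
            return None
        return genome.fetch(
            GenomicInterval(span.contig, span.end, span.end + length, "-")
        )
    if span.start - length < 0:
        return None
    return genome.fetch(
        GenomicInterval(span.contig, span.start - length, span.start, "+")
    )


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute annotate -> context/synteny -> promoter scan -> curate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(config.path("genome"))
    meta = tool_io.read_family_meta(config.path("family_meta"))
    qlens = _read_query_lengths(config.path("query_lengths"))
    blast_hits = tool_io.read_blast_tab(config.path("blast"), qlens)
    # database|family query naming carries the database; classes join via meta
    for h in blast_hits:
        if h.family in meta:
            h.rna_class = meta[h.family].rna_class
    infernal_hits, n_skipped = tool_io.read_infernal_tab(
        config.path("infernal"), meta
    )
    trnascan_hits = tool_io.read_trnascan(config.path("trnascan"))
    other_hits = tool_io.read_generic_gff3_hits(config.path("rnammer"), "rnammer")
    gene_models = tool_io.read_gene_models_gff3(config.path("gene_models"))
    block_groups = tool_io.read_block_groups(config.path("block_groups"))
    rnaz_loci = context.read_rnaz_bed(config.path("rnaz"))
    policy = confidence_merge.ConfidencePolicy(**config.policy_overrides)

    loci_by_tier: dict[str, list] = {}
    for tier in confidence_merge.TIERS:
        loci_by_tier[tier] = confidence_merge.annotate(
            blast_hits, infernal_hits, trnascan_hits, other_hits, meta, tier,
            policy, config.ranking, apply_demotions=False,
        )
    loci = loci_by_tier["high"]

    # context tagging before demotion (read support guards demotion rule b)
    for locus in loci:
        if context.mark_read_support(locus.span, block_groups):
            locus.tags.add("read-supported")
        if context.mark_rnaz_overlap(locus.span, rnaz_loci):
            locus.tags.add("rnaz-overlap")
    synteny.find_exact_duplicates(loci, genome)
    confidence_merge.apply_demotion_rules(loci, meta)

    clusters = context.cluster_loci(loci)
    for ci, cl in enumerate(clusters, 1):
        if len(cl) >= 2:
            for i in cl:
                loci[i].tags.add(f"cluster:{ci}")
    contexts = {
        locus.locus_id: context.genic_context(locus.span, gene_models)
        for locus in loci
    }

    # pairwise alignments and conservation
    alignments: dict[str, list[synteny.PairwiseAlignment]] = {}
    query_genomes: dict[str, Genome] = {}
    for org, rel in config.chains.items():
        alignments[org] = synteny.read_chain(config.base_dir / rel, org)
        query_genomes[org] = read_fasta(
            config.base_dir / config.query_genomes[org]
        )
    calls_by_locus: dict[str, dict[str, synteny.ConservationCall]] = {}
    for locus in loci:
        calls_by_locus[locus.locus_id] = {
            org: synteny.locus_conservation(
                locus.span, alignments[org], genome, query_genomes[org],
                org, locus.locus_id,
            )
            for org in alignments
        }
    blocks = (
        synteny.build_synteny_blocks(alignments[config.reference_organism])
        if config.reference_organism in alignments
        else []
    )
    cons_table = synteny.conservation_table(
        loci, calls_by_locus, blocks, config.reference_organism
    )

    # promoter scan
    training = _read_training(config.path("pwm_training"))
    anchors = {**promoter.POLII_ANCHORS, **promoter.POLIII_ANCHORS}
    pwms = {
        el: promoter.build_pwm(el, slices, anchor_offset=anchors.get(el))
        for el, slices in training.items()
    }
    thresholds = {
        el: promoter.score_threshold(pwm, None, seed=config.seed + i)
        for i, (el, pwm) in enumerate(sorted(pwms.items()))
    }
    promoter_calls: dict[str, promoter.PromoterCall | None] = {}
    for locus in loci:
        fam = meta.get(locus.resolved_name)
        if fam is None or fam.expected_pol == "none":
            continue
        sl = upstream_slice(genome, locus.span)
        if sl is None:
            promoter_calls[locus.locus_id] = None
            continue
        promoter_calls[locus.locus_id] = promoter.classify_promoter(
            sl, fam.expected_pol, pwms, thresholds, locus.locus_id
        )

    # curation
    records: list[curation.CurationRecord] = []
    for locus in loci:
        if locus.resolved_class == "cisreg":
            records.append(
                curation.curate_cisreg(locus, contexts[locus.locus_id])
            )
        if locus.locus_id in promoter_calls:
            records.append(
                curation.curate_pol23(locus, promoter_calls[locus.locus_id])
            )
    rrna_loci = [l for l in loci if l.resolved_class == "rRNA"]
    records.extend(
        curation.curate_rrna(
            rrna_loci, {l.locus_id: l.resolved_name for l in rrna_loci}
        )
    )
    snorna_loci = [l for l in loci if l.resolved_class == "snoRNA"]
    if "reference_snorna" in config.paths and config.reference_organism in alignments:
        ref = _read_reference_bed(config.path("reference_snorna"))
        ref_alns = alignments[config.reference_organism]
        lifted = {
            l.locus_id: synteny.liftover(l.span, ref_alns) for l in snorna_loci
        }
        idents = {
            l.locus_id: calls_by_locus[l.locus_id][
                config.reference_organism
            ].identity_fraction
            for l in snorna_loci
        }
        records.extend(
            curation.curate_snorna(
                snorna_loci,
                {l.locus_id: l.resolved_name for l in snorna_loci},
                ref, lifted, idents,
            )
        )
    status, table = curation.assemble_curated_annotation(loci, records)

    # outputs
    for tier, tier_loci in loci_by_tier.items():
        tool_io.write_annotation_gff3(tier_loci, outdir / f"annotation_{tier}.gff3")
    tool_io.write_bed6(loci, outdir / "annotation.bed")
    with open(outdir / "curation.tsv", "w") as fh:
        fh.write("locus\trna_class\tstatus\trule\n")
        by_id = {r.locus_id: r for r in records if r.status != "uncurated"}
        for locus in loci:
            rec = by_id.get(locus.locus_id)
            fh.write(
                f"{locus.locus_id}\t{locus.resolved_class}\t"
                f"{status.get(locus.locus_id, 'uncurated')}\t"
                f"{rec.rule if rec else '.'}\n"
            )
    confidence_merge.summarize_by_class(loci).to_csv(
        outdir / "class_summary.tsv", sep="\t", index=False
    )
    if table is not None and len(table):
        table.to_csv(outdir / "curated_summary.tsv", sep="\t", index=False)
    if cons_table is not None and len(cons_table):
        cons_table.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    run_log = {
        "seed": config.seed,
        "tier": config.tier,
        "policy": {
            "blast_tiers": {k: list(v) for k, v in policy.blast_tiers.items()},
            "blast_global_e": policy.blast_global_e,
            "infernal_e_cap": policy.infernal_e_cap,
            "trnascan": [policy.trnascan_hmm, policy.trnascan_str,
                         policy.trnascan_cove, policy.trnascan_single_parser_cove],
        },
        "thresholds": {k: float(v) for k, v in thresholds.items()},
        "counts": {
            tier: len(tier_loci) for tier, tier_loci in loci_by_tier.items()
        },
        "skipped_infernal_rows": n_skipped,
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh)
    return PipelineResult(
        loci_by_tier, status, table, cons_table, contexts, run_log
    )


# ---------------------------------------------------------------------------
# Truth verification
# ---------------------------------------------------------------------------

_TRACKED_TAGS = {
    "duplicated", "read-supported", "rnaz-overlap",
    "demoted:no-tRNAscan", "demoted:no-experimental-evidence",
}


def verify_against_truth(result: PipelineResult, truth_path) -> list[str]:
    """Compare a pipeline run against the planted-truth manifest.

    Returns a list of human-readable discrepancies (empty = exact
    recovery of tier, conflict, cluster, context and curation labels).
    """
    import csv

    problems: list[str] = []
    with open(truth_path) as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))

    def find(tier: str, row) -> list:
        iv = GenomicInterval(
            row["contig"], int(row["start"]), int(row["end"])
        )
        return [
            l
            for l in result.loci_by_tier[tier]
            if overlap_len(l.span, iv) >= 1
        ]

    matched_high_ids: set[str] = set()
    cluster_map: dict[str, set[str]] = {}
    for row in rows:
        label = f"{row['family']}@{row['contig']}:{row['start']}"
        tier = row["tier"]
        expect = {
            "high": (True, True, True),
            "medium-demoted": (True, True, True),
            "medium": (False, True, True),
            "low": (False, False, True),
            "none": (False, False, False),
        }[tier]
        for t, want in zip(("high", "medium", "low"), expect):
            present = bool(find(t, row))
            if present != want:
                problems.append(
                    f"{label}: {'present' if present else 'absent'} in {t} run, "
                    f"expected {'present' if want else 'absent'}"
                )
        if not expect[0]:
            continue
        hits = find("high", row)
        if not hits:
            continue
        locus = hits[0]
        matched_high_ids.add(locus.locus_id)
        want_conf = "medium" if tier == "medium-demoted" else "high"
        if locus.confidence != want_conf:
            problems.append(
                f"{label}: confidence {locus.confidence} != {want_conf}"
            )
        if locus.conflict != (row["conflict"] == "1"):
            problems.append(f"{label}: conflict flag mismatch")
        if locus.resolved_class != row["rna_class"]:
            problems.append(
                f"{label}: class {locus.resolved_class} != {row['rna_class']}"
            )
        # context
        ctx = result.contexts.get(locus.locus_id)
        want_ctx = row["context"]
        if want_ctx != "." and ctx is not None:
            if want_ctx == "intergenic":
                if ctx.labels != {"intergenic"}:
                    problems.append(f"{label}: context {ctx.labels} not intergenic")
            elif want_ctx not in ctx.labels:
                problems.append(
                    f"{label}: context {want_ctx} not in {ctx.labels}"
                )
        # curation
        got = result.curation_status.get(locus.locus_id, "uncurated")
        if got != row["curation"]:
            problems.append(
                f"{label}: curation {got} != {row['curation']}"
            )
        # tags
        want_tags = (
            set() if row["tags"] == "." else set(row["tags"].split(","))
        ) & _TRACKED_TAGS
        got_tags = locus.tags & _TRACKED_TAGS
        if got_tags != want_tags:
            problems.append(f"{label}: tags {got_tags} != {want_tags}")
        # clusters
        if row["cluster_id"] != ".":
            cluster_map.setdefault(row["cluster_id"], set()).add(locus.locus_id)
            if not any(t.startswith("cluster:") for t in locus.tags):
                problems.append(f"{label}: expected cluster membership")
        else:
            if any(t.startswith("cluster:") for t in locus.tags):
                problems.append(f"{label}: unexpected cluster membership")
    # planted cluster mates share one pipeline cluster
    id_to_cluster = {
        l.locus_id: next(
            (t for t in l.tags if t.startswith("cluster:")), None
        )
        for l in result.loci_by_tier["high"]
    }
    for cid, ids in cluster_map.items():
        got = {id_to_cluster.get(i) for i in ids}
        if len(got) != 1 or None in got:
            problems.append(f"planted cluster {cid} split across {got}")
    # spurious loci
    for locus in result.loci_by_tier["high"]:
        if locus.locus_id not in matched_high_ids:
            problems.append(
                f"spurious high-tier locus {locus.locus_id} "
                f"{locus.resolved_name}@{locus.span.contig}:{locus.span.start}"
            )
    return problems
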