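"""Synthetic-data generators and the shuffle null model.

Everything needed to build and test the framework with no downloads: a
background genome generator, a planter that inserts RNA loci with
tier-targeted hit evidence and emits every input file through the
:mod:`rnannot.tool_io` emitters, a pairwise-alignment generator with
known per-base divergence, and the windowed dinucleotide-preserving
shuffle used to gauge false-positive behaviour.

The planter's guarantee is exact: applying the annotation engine to the
emitted files recovers the planted tier, conflict, cluster, context and
curation labels recorded in the truth manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import synteny, tool_io
from .genome_model import Genome, GenomicInterval, write_fasta

logger = logging.getLogger(__name__)

SHUFFLE_WINDOW = 120
_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Background genome
# ---------------------------------------------------------------------------

def generate_genome(
    seed: int,
    n_contigs: int = 2,
    lengths: list[int] | None = None,
    gc: float = 0.42,
    n_run_rate: float = 0.0,
    names: list[str] | None = None,
) -> Genome:
    """Independent-nucleotide background genome at a given GC content.

    N runs are planted as a Poisson process along each contig
    (``n_run_rate`` expected runs per nt, geometric run lengths with
    mean 20).  Deterministic for a fixed seed.
    """
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    lengths = lengths or [100_000] * n_contigs
    names = names or [f"chr{i + 1}" for i in range(len(lengths))]
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs: dict[str, str] = {}
    for name, length in zip(names, lengths):
        if length < 1000:
            raise ValueError("contig lengths must be >= 1 kb")
        arr = _BASES[rng.choice(4, size=length, p=probs)].copy()
        if n_run_rate > 0:
            n_runs = rng.poisson(n_run_rate * length)
            for _ in range(n_runs):
                start = int(rng.integers(0, length))
                run = int(rng.geometric(0.05))
                arr[start : start + run] = b"N"
        contigs[name] = arr.tobytes().decode()
    return Genome(
        contigs,
        {n: not ("scaffold" in n or "unplaced" in n) for n in names},
    )


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Euler-path construction)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle_window(
    sequence: str, rng: np.random.Generator | int
) -> str:
    """Shuffle one window preserving its dinucleotide multiset exactly.

    The dinucleotide multigraph of the sequence is walked along a random
    Euler path constrained to start at the first and end at the last
    nucleotide (random last-exit-edge arborescence, then randomized edge
    order).  Windows containing N are returned unshuffled with a logged
    note; sequences shorter than 2 nt are returned unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if len(sequence) < 2:
        return sequence
    if "N" in sequence:
        logger.debug("window with N left unshuffled")
        return sequence
    if len(set(sequence)) == 1:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    last = sequence[-1]
    verts = sorted(set(sequence))
    non_last = [v for v in verts if v != last and edges.get(v)]
    # pick a random last-exit edge per vertex such that following the
    # last-exit pointers from any vertex reaches the final vertex
    while True:
        last_exit = {
            v: edges[v][int(rng.integers(len(edges[v])))] for v in non_last
        }
        ok = True
        for v in non_last:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_exit:
                    ok = False
                    break
                seen.add(cur)
                cur = last_exit[cur]
            if not ok:
                break
        if ok:
            break
    stacks: dict[str, list[str]] = {}
    for v in verts:
        out = list(edges.get(v, []))
        if v in last_exit:
            out.remove(last_exit[v])
        order = rng.permutation(len(out))
        shuffled = [out[i] for i in order]
        if v in last_exit:
            shuffled.append(last_exit[v])
        stacks[v] = shuffled
    walk = [sequence[0]]
    ptr = {v: 0 for v in verts}
    cur = sequence[0]
    total_edges = len(sequence) - 1
    for _ in range(total_edges):
        nxt = stacks[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def shuffle_genome(
    genome: Genome, window: int = SHUFFLE_WINDOW, seed: int = 0
) -> Genome:
    """Shuffle every contig in consecutive fixed-size windows.

    Each window (including a final short one) is shuffled independently
    and reassembled in order, so the shuffled genome keeps the exact
    mono- and di-nucleotide content, local GC bias and contig sizes of
    the original.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for name, seq in genome.contigs.items():
        parts = []
        for i in range(0, len(seq), window):
            parts.append(dinucleotide_shuffle_window(seq[i : i + window], rng))
        out[name] = "".join(parts)
    return Genome(out, dict(genome.assembled))


# ---------------------------------------------------------------------------
# Pairwise-alignment generator
# ---------------------------------------------------------------------------

@dataclass
class AlignmentTruth:
    """Generated query genome + chains + per-base truth for one organism.

    ``mask`` per target contig: -1 unaligned, 1 aligned match,
    0 aligned mismatch.
    """

    organism: str
    query_genome: Genome
    alignments: list[synteny.PairwiseAlignment]
    mask: dict[str, np.ndarray]

    def realized_identity(
        self, interval: GenomicInterval
    ) -> tuple[float, float | None]:
        """(covered_fraction, identity_fraction) from the truth mask."""
        m = self.mask[interval.contig][interval.start : interval.end]
        aligned = int((m >= 0).sum())
        if aligned == 0:
            return 0.0, None
        matches = int((m == 1).sum())
        return aligned / len(m), matches / aligned


def _mutate(seq: str, divergence: float, rng: np.random.Generator):
    """Point-mutate each base with probability ``divergence``; returns the
    mutated sequence and a boolean mutation mask."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mut = rng.random(len(arr)) < divergence
    non_n = arr != b"N"
    mut &= non_n
    if mut.any():
        idx = np.nonzero(mut)[0]
        base_idx = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=len(idx))
        arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode(), mut


def generate_pairwise_alignment(
    genome_a: Genome,
    seed: int,
    divergence: dict[str, float],
    rearrangement_rate: float = 0.0,
    gap_prob: float = 0.0,
    chunk_len: tuple[int, int] = (15_000, 30_000),
    interchunk_gap: tuple[int, int] = (0, 0),
) -> dict[str, AlignmentTruth]:
    """Derive one query genome + chain set per organism.

    The target is cut into chunks; each chunk becomes one chained
    alignment (single coverage of the target).  Chunks are inverted
    (strand '-') with probability ``rearrangement_rate``; plus-strand
    chunks may contain internal deletion/insertion gaps (probability
    ``gap_prob``); bases mutate independently at the organism's
    divergence rate.  The truth mask records, per target base, whether
    it is aligned and whether the aligned column matches.
    """
    from .genome_model import reverse_complement

    out: dict[str, AlignmentTruth] = {}
    for org_i, (org, d) in enumerate(sorted(divergence.items())):
        if not (0.0 <= d <= 1.0):
            raise ValueError(f"divergence for {org} must be in [0, 1]")
        rng = np.random.default_rng([seed, org_i])
        q_contigs: dict[str, str] = {}
        alns: list[synteny.PairwiseAlignment] = []
        masks: dict[str, np.ndarray] = {}
        chain_id = 1
        for contig, seq in genome_a.contigs.items():
            mask = np.full(len(seq), -1, dtype=np.int8)
            q_name = f"{org}_{contig}"
            q_parts: list[str] = []
            q_pos = 0
            # pending chains: (strand, [(t_start, q_fwd_start, len), ...])
            # for '-', q_fwd_start is the forward start of the chunk piece
            pending: list[tuple[str, list[tuple[int, int, int]]]] = []
            t = 0
            while t < len(seq):
                ln = int(rng.integers(chunk_len[0], chunk_len[1] + 1))
                t1 = min(t + ln, len(seq))
                if t1 - t < 2000:  # drop a tiny tail
                    break
                strand = "-" if rng.random() < rearrangement_rate else "+"
                if strand == "+":
                    segs: list[tuple[int, int, int]] = []
                    pos = t + 0
                    while pos < t1:
                        seg_len = t1 - pos
                        if gap_prob > 0 and rng.random() < gap_prob and seg_len > 2000:
                            seg_len = int(rng.integers(800, seg_len - 500))
                        seg_seq = seq[pos : pos + seg_len]
                        mut_seq, mut = _mutate(seg_seq, d, rng)
                        m = mask[pos : pos + seg_len]
                        m[:] = 1
                        m[mut] = 0
                        m[np.frombuffer(seg_seq.encode(), dtype="S1") == b"N"] = 0
                        segs.append((pos, q_pos, seg_len))
                        q_parts.append(mut_seq)
                        q_pos += seg_len
                        pos += seg_len
                        if pos < t1:
                            # alternate a target deletion or a query insertion
                            if rng.random() < 0.5:
                                pos = min(pos + int(rng.integers(100, 400)), t1)
                            else:
                                ins = int(rng.integers(100, 400))
                                q_parts.append(
                                    _BASES[rng.choice(4, size=ins)].tobytes().decode()
                                )
                                q_pos += ins
                    if segs:
                        pending.append(("+", segs))
                else:
                    chunk_seq = seq[t:t1]
                    mut_seq, mut = _mutate(chunk_seq, d, rng)
                    m = mask[t:t1]
                    m[:] = 1
                    m[mut] = 0
                    m[np.frombuffer(chunk_seq.encode(), dtype="S1") == b"N"] = 0
                    q_parts.append(reverse_complement(mut_seq))
                    pending.append(("-", [(t, q_pos, t1 - t)]))
                    q_pos += t1 - t
                t = t1 + int(rng.integers(interchunk_gap[0], interchunk_gap[1] + 1))
            q_seq = "".join(q_parts)
            q_contigs[q_name] = q_seq if q_seq else "A" * 1000
            masks[contig] = mask
            q_size = len(q_contigs[q_name])
            for strand, segs in pending:
                if strand == "-":
                    # single gapless piece: forward [q0, q0+L) reversed; the
                    # strand-space start is q_size - (q0 + L)
                    t0, q0, ln = segs[0]
                    segs = [(t0, q_size - (q0 + ln), ln)]
                alns.append(
                    synteny.PairwiseAlignment(
                        contig, q_name, strand, segs, org, q_size, chain_id
                    )
                )
                chain_id += 1
        out[org] = AlignmentTruth(
            org,
            Genome(q_contigs, {n: True for n in q_contigs}),
            alns,
            masks,
        )
    return out


# ---------------------------------------------------------------------------
# Annotation planting
# ---------------------------------------------------------------------------

@dataclass
class CatalogEntry:
    """One planted annotation (or decoy) in the fixture genome."""

    family: str
    rna_class: str
    tier: str  # high | medium | medium-demoted | low | none
    evidence: str  # blast | infernal | blast+infernal | trnascan | rnammer
    database: str = "rfam-seed"
    length: int = 120
    count: int = 1
    contig: str | None = None
    strand: str = "+"
    conflict_partner: tuple[str, str, str] | None = None  # family, class, db
    duplicate: bool = False  # copies share an identical sequence
    cluster_spacing: int | None = None  # copies < 10 kb apart, same strand
    promoter: str | None = None  # polIII-pass | polIII-fail | polII-pass | ...
    read_support: bool = False
    rnaz_overlap: int = 0  # planted RNAz overlap length (0 = none)
    experimental_evidence: bool = True
    expected_pol: str = "none"
    subunit: str | None = None  # rRNA subunit for the cluster rule
    near_gene: str | None = None  # sense-1k | mid | far | intronic | coding-exon
    trnascan_scores: tuple[float, float, float, bool] | None = None
    is_mirna_family: bool = False
    vertebrate_seed: bool = True
    infernal_e: float | None = None
    snorna_reference: str | None = None  # match | family-pseudo | none


@dataclass
class PlantedLocus:
    """Truth record for one planted locus."""

    interval: GenomicInterval
    family: str
    rna_class: str
    tier: str
    conflict: bool = False
    cluster_id: str = ""
    context: str = "intergenic"
    curation: str = "uncurated"
    tags: set[str] = field(default_factory=set)
    promoter: str | None = None
    snorna_reference: str | None = None
    entry: CatalogEntry | None = None


@dataclass
class PlantedTruth:
    genome: Genome
    loci: list[PlantedLocus]
    blast_hits: list[tool_io.ToolHit]
    infernal_hits: list[tool_io.ToolHit]
    trnascan_hits: list[tool_io.ToolHit]
    other_hits: list[tool_io.ToolHit]
    meta: dict[str, tool_io.FamilyMeta]
    query_lengths: dict[str, int]
    gene_models: list
    block_groups: list[tool_io.ReadBlockGroup]
    rnaz_loci: list
    pwm_training: dict[str, list[str]]
    motifs: list[str] = field(default_factory=list)


# promoter element consensus sequences used by the planter
PROMOTER_CONSENSUS = {
    "PSE": "TCACCCTAACTGTA",
    "TATA": "TATAAATA",
    "PSEA": "TTACCGTAACTTGA",
    "PSEB": "CTCACC",
}
_BLAST_PARAMS = {  # tier -> (identity, coverage)
    "high": (96.0, 97.0),
    "medium": (93.0, 94.0),
    "medium-demoted": (96.0, 97.0),
    "low": (90.5, 91.0),
}

FEATURE_SPACING = 12_000


def default_catalog() -> list[CatalogEntry]:
    """The standard planted scenario: one entry per behaviour the
    annotation engine, context tagging and curation rules must recover."""
    return [
        # sequence + structure homology, three tiers
        CatalogEntry("SNORD25", "snoRNA", "high", "blast+infernal",
                     database="snornabase", snorna_reference="match"),
        CatalogEntry("SNORD25", "snoRNA", "high", "blast+infernal",
                     database="snornabase", snorna_reference="family-pseudo"),
        CatalogEntry("SNORD99", "snoRNA", "high", "blast+infernal",
                     database="snornabase", snorna_reference="none"),
        CatalogEntry("U1", "snRNA", "medium", "blast", database="rfam-seed"),
        CatalogEntry("SRP_euk_arch", "other", "low", "blast"),
        # Rfam miRNA family: excluded from high, medium via strict E + anchor
        CatalogEntry("mir-599", "miRNA", "medium", "infernal",
                     is_mirna_family=True, infernal_e=1e-12),
        # decoys that must never annotate
        CatalogEntry("S_pombe_snR97", "snoRNA", "none", "infernal",
                     infernal_e=3.04e-2),
        CatalogEntry("Fungal_U3", "snoRNA", "none", "infernal",
                     vertebrate_seed=False, infernal_e=1e-20),
        # tRNAs: triple-score pass, single-parser pass, low-only, demotion
        CatalogEntry("tRNA-Ala-AGC", "tRNA", "high", "trnascan",
                     trnascan_scores=(60.1, 30.0, 20.0, True)),
        CatalogEntry("tRNA-Gly-GCC", "tRNA", "high", "trnascan",
                     trnascan_scores=(60.0, 0.0, 0.0, False)),
        CatalogEntry("tRNA-Met-CAT", "tRNA", "low", "trnascan",
                     trnascan_scores=(50.0, 4.0, 1.0, False)),
        CatalogEntry("tRNA-Leu-TAA", "tRNA", "medium-demoted", "blast",
                     database="trnadb"),
        # miRNAs: conflict pair, duplicates, cluster, evidence demotion
        CatalogEntry("SNORA81", "snoRNA", "high", "blast",
                     database="rfam-seed",
                     conflict_partner=("eca-mir-1248", "miRNA", "mirbase")),
        CatalogEntry("mir-196b", "miRNA", "high", "blast", database="mirbase",
                     count=2, duplicate=True, read_support=True),
        CatalogEntry("mir-17", "miRNA", "high", "blast", database="mirbase",
                     count=3, cluster_spacing=2_500, read_support=True),
        CatalogEntry("mir-9999", "miRNA", "medium-demoted", "blast",
                     database="mirbase", experimental_evidence=False),
        CatalogEntry("mir-2320", "miRNA", "high", "blast", database="mirbase",
                     read_support=True, rnaz_overlap=40),
        # rRNA cluster rule
        CatalogEntry("28S", "rRNA", "high", "rnammer", subunit="28S",
                     contig="chr1", cluster_spacing=3_000, length=500),
        CatalogEntry("18S", "rRNA", "high", "rnammer", subunit="18S",
                     contig="chr1", length=400),
        CatalogEntry("5.8S", "rRNA", "high", "rnammer", subunit="5.8S",
                     contig="chr1", length=150),
        CatalogEntry("18S", "rRNA", "high", "rnammer", subunit="18S",
                     contig="chr2", length=400),
        # PolIII promoter curation
        CatalogEntry("U6", "snRNA", "high", "blast+infernal",
                     expected_pol="polIII", promoter="polIII-pass"),
        CatalogEntry("U6", "snRNA", "high", "blast+infernal",
                     expected_pol="polIII", promoter="polIII-pass"),
        CatalogEntry("U6", "snRNA", "high", "blast+infernal",
                     expected_pol="polIII", promoter="polIII-fail"),
        CatalogEntry("U6atac", "snRNA", "high", "blast+infernal",
                     expected_pol="polIII", promoter="polIII-fail"),
        # genic context + cis-regulatory curation
        CatalogEntry("IRE", "cisreg", "high", "blast", near_gene="sense-1k"),
        CatalogEntry("SECIS-1", "cisreg", "high", "blast", near_gene="sense-1k"),
        CatalogEntry("GP_knot1", "cisreg", "high", "blast", near_gene="far"),
        CatalogEntry("GP_knot1", "cisreg", "high", "blast", near_gene="mid"),
        CatalogEntry("Histone3", "other", "high", "blast", near_gene="intronic"),
        CatalogEntry("Vault", "other", "high", "blast", near_gene="coding-exon",
                     length=100),
        CatalogEntry("RNaseP_nuc", "other", "high", "blast+infernal",
                     rnaz_overlap=19),
    ]


class _Allocator:
    """Deterministic position allocator with wide inter-feature spacing."""

    def __init__(self, genome: Genome, spacing: int = FEATURE_SPACING):
        self.cursors = {c: 6_000 for c in genome.contigs}
        self.limits = {c: len(s) - 6_000 for c, s in genome.contigs.items()}
        self.spacing = spacing
        self.order = [c for c in genome.contigs if genome.assembled.get(c, True)]
        self.rr = 0

    def place(self, length: int, contig: str | None = None, advance: int | None = None) -> tuple[str, int]:
        tried = 0
        while True:
            if contig is None:
                c = self.order[self.rr % len(self.order)]
                self.rr += 1
            else:
                c = contig
            pos = self.cursors[c]
            if pos + length < self.limits[c]:
                self.cursors[c] = pos + length + (
                    advance if advance is not None else self.spacing
                )
                return c, pos
            tried += 1
            if contig is not None or tried > len(self.order):
                raise ValueError("catalog overflow: planted loci do not fit")


def _tier_blast_hit(entry, iv, database=None, family=None, identity=None,
                    coverage=None, e_value=1e-30):
    tier = entry.tier if entry.tier in _BLAST_PARAMS else "high"
    ident, cov = _BLAST_PARAMS[tier]
    return tool_io.ToolHit(
        tool="blast",
        database=database or entry.database,
        family=family or entry.family,
        rna_class=entry.rna_class,
        interval=iv,
        e_value=e_value,
        bit_score=200.0,
        identity_pct=identity if identity is not None else ident,
        query_coverage_pct=coverage if coverage is not None else cov,
    )


def _make_training_slices(element: str, rng: np.random.Generator, n: int = 20):
    """Training slices: consensus with one random substitution in half."""
    consensus = PROMOTER_CONSENSUS[element]
    slices = []
    for i in range(n):
        s = list(consensus)
        if i % 2 == 1:
            j = int(rng.integers(len(s)))
            s[j] = "ACGT"[int(rng.integers(4))]
        slices.append("".join(s))
    return slices


# low-complexity CG background guaranteeing promoter failure for any seed
def _fail_slice(rng: np.random.Generator, length: int = 100) -> str:
    return "".join("CG"[int(b)] for b in rng.integers(0, 2, size=length))


def plant_annotations(
    genome: Genome, catalog: list[CatalogEntry], seed: int
) -> PlantedTruth:
    """Insert planted loci into the genome and build their hit evidence.

    Motif sequences are drawn from the seeded generator and written into
    the genome; hits are constructed so the annotation engine recovers
    exactly the targeted tier (and conflict/cluster/context/curation
    labels) for every entry.
    """
    rng = np.random.default_rng([seed, 7919])
    contigs = {c: bytearray(s.encode()) for c, s in genome.contigs.items()}
    alloc = _Allocator(genome)
    truth: list[PlantedLocus] = []
    blast: list[tool_io.ToolHit] = []
    infernal: list[tool_io.ToolHit] = []
    trnascan: list[tool_io.ToolHit] = []
    other: list[tool_io.ToolHit] = []
    meta: dict[str, tool_io.FamilyMeta] = {}
    qlens: dict[str, int] = {}
    genes: list = []
    block_groups: list[tool_io.ReadBlockGroup] = []
    rnaz_entries: list = []
    motifs: list[str] = []
    from .context import RnazLocus
    from .genome_model import GeneModel, Transcript

    def random_motif(length: int) -> str:
        return _BASES[rng.choice(4, size=length)].tobytes().decode()

    def write_motif(contig: str, pos: int, motif: str) -> None:
        contigs[contig][pos : pos + len(motif)] = motif.encode()

    def register_family(entry: CatalogEntry, family=None, rna_class=None,
                        database=None) -> None:
        fam = family or entry.family
        if fam in meta:
            return
        meta[fam] = tool_io.FamilyMeta(
            family=fam,
            rna_class=rna_class or entry.rna_class,
            gathering_score=30.0,
            ga_implied_evalue=10.0,
            vertebrate_seed=entry.vertebrate_seed,
            is_mirna_family=entry.is_mirna_family,
            experimental_evidence=entry.experimental_evidence,
            expected_pol=entry.expected_pol,
        )

    gene_counter = cluster_counter = 0
    for entry in catalog:
        register_family(entry)
        qlens.setdefault(entry.family, entry.length)
        shared_motif = random_motif(entry.length) if entry.duplicate else None
        cluster_id = ""
        if entry.cluster_spacing is not None and entry.count > 1:
            cluster_counter += 1
            cluster_id = f"cluster{cluster_counter}"
        entry_contig = entry.contig
        for copy in range(entry.count):
            advance = (
                entry.cluster_spacing
                if entry.cluster_spacing is not None and copy < entry.count - 1
                else None
            )
            if entry.near_gene in ("sense-1k", "mid"):
                # the planted gene extends into the spacing region; widen it
                # so the next feature stays outside the gene's 10-kb flank
                advance = FEATURE_SPACING + 10_000
            contig, pos = alloc.place(entry.length, entry_contig, advance)
            if entry.cluster_spacing is not None:
                entry_contig = contig  # keep cluster copies on one contig
            motif = shared_motif or random_motif(entry.length)
            write_motif(contig, pos, motif)
            motifs.append(motif)
            iv = GenomicInterval(contig, pos, pos + entry.length, entry.strand)
            locus = PlantedLocus(
                interval=iv,
                family=entry.family,
                rna_class=entry.rna_class,
                tier=entry.tier,
                promoter=entry.promoter,
                snorna_reference=entry.snorna_reference,
                cluster_id=cluster_id,
                entry=entry,
            )
            # --- hit evidence -------------------------------------------
            if "blast" in entry.evidence:
                blast.append(_tier_blast_hit(entry, iv))
            if "infernal" in entry.evidence:
                e = entry.infernal_e if entry.infernal_e is not None else 1e-6
                infernal.append(
                    tool_io.ToolHit(
                        tool="infernal", database="rfam", family=entry.family,
                        rna_class=entry.rna_class, interval=iv,
                        e_value=e, bit_score=80.0,
                    )
                )
                if entry.is_mirna_family and entry.tier == "medium":
                    # low-tier BLAST anchor: anchors the family without
                    # itself qualifying at high or medium
                    blast.append(
                        _tier_blast_hit(
                            entry, iv, identity=90.5, coverage=91.0,
                            e_value=1e-4,
                        )
                    )
                    qlens.setdefault(entry.family, entry.length)
            if entry.evidence == "trnascan":
                cove, hmm, strs, both = entry.trnascan_scores
                trnascan.append(
                    tool_io.ToolHit(
                        tool="trnascan", database="trnascan",
                        family=entry.family, rna_class="tRNA", interval=iv,
                        bit_score=cove,
                        tool_scores={"COVE": cove, "HMM": hmm, "2'Str": strs},
                        both_first_pass_parsers=both,
                    )
                )
            if entry.evidence == "rnammer":
                other.append(
                    tool_io.ToolHit(
                        tool="rnammer", database="rnammer",
                        family=entry.family, rna_class="rRNA", interval=iv,
                        bit_score=100.0,
                    )
                )
            # --- conflict partner ---------------------------------------
            if entry.conflict_partner:
                fam2, cls2, db2 = entry.conflict_partner
                partner = replace(
                    entry, family=fam2, rna_class=cls2, database=db2,
                    conflict_partner=None,
                )
                register_family(partner)
                qlens.setdefault(fam2, entry.length)
                blast.append(_tier_blast_hit(partner, iv))
                locus.conflict = True
                locus.family = ",".join(sorted([entry.family, fam2]))
                locus.rna_class = "conflict"
            # --- read support / RNAz ------------------------------------
            if entry.read_support:
                block = GenomicInterval(contig, pos + 10, pos + 40, entry.strand)
                block_groups.append(
                    tool_io.ReadBlockGroup(
                        GenomicInterval(contig, pos, pos + 60, entry.strand),
                        [(block, 12)],
                    )
                )
                locus.tags.add("read-supported")
            if entry.rnaz_overlap:
                rnaz_entries.append(
                    RnazLocus(
                        GenomicInterval(
                            contig,
                            pos + entry.length - entry.rnaz_overlap,
                            pos + entry.length - entry.rnaz_overlap + 60,
                            "-",
                        ),
                        0.95,
                    )
                )
                if entry.rnaz_overlap >= 20:
                    locus.tags.add("rnaz-overlap")
            if entry.duplicate and entry.count > 1:
                locus.tags.add("duplicated")
            # --- promoter slice -----------------------------------------
            if entry.promoter:
                mode, outcome = entry.promoter.split("-")
                if outcome == "pass":
                    slice_seq = list(random_motif(100))
                    if mode == "polIII":
                        pse = PROMOTER_CONSENSUS["PSE"]
                        tata = PROMOTER_CONSENSUS["TATA"]
                        slice_seq[45 : 45 + len(pse)] = pse
                        slice_seq[80 : 80 + len(tata)] = tata
                    else:
                        psea = PROMOTER_CONSENSUS["PSEA"]
                        pseb = PROMOTER_CONSENSUS["PSEB"]
                        slice_seq[50 : 50 + len(psea)] = psea
                        slice_seq[75 : 75 + len(pseb)] = pseb
                    write_motif(contig, pos - 100, "".join(slice_seq))
                else:
                    write_motif(contig, pos - 100, _fail_slice(rng))
                locus.curation = "curated" if outcome == "pass" else "pseudogene"
            # --- genic context / genes ----------------------------------
            if entry.near_gene:
                gene_counter += 1
                gid = f"gene{gene_counter}"
                tid = f"{gid}.t1"
                if entry.near_gene in ("sense-1k", "mid"):
                    dist = 800 if entry.near_gene == "sense-1k" else 5_000
                    g_start = iv.end + dist
                    exon = GenomicInterval(contig, g_start, g_start + 2_000, entry.strand)
                    cds = GenomicInterval(contig, g_start + 200, g_start + 1_800, entry.strand)
                    genes.append(GeneModel(gid, [Transcript(tid, entry.strand, [exon], [cds])]))
                    locus.context = "downstream<=10k" if entry.strand == "+" else "upstream<=10k"
                elif entry.near_gene == "intronic":
                    e1 = GenomicInterval(contig, pos - 1_800, pos - 1_500, "+")
                    e2 = GenomicInterval(contig, pos + 1_500, pos + 1_800, "+")
                    cds1 = GenomicInterval(contig, pos - 1_750, pos - 1_600, "+")
                    cds2 = GenomicInterval(contig, pos + 1_600, pos + 1_750, "+")
                    genes.append(
                        GeneModel(gid, [Transcript(tid, "+", [e1, e2], [cds1, cds2])])
                    )
                    locus.context = "intronic"
                elif entry.near_gene == "coding-exon":
                    exon = GenomicInterval(contig, pos - 200, pos + entry.length // 2, "+")
                    cds = GenomicInterval(contig, pos - 200, pos + entry.length // 2, "+")
                    genes.append(GeneModel(gid, [Transcript(tid, "+", [exon], [cds])]))
                    locus.context = "coding-exon"
                elif entry.near_gene == "far":
                    locus.context = "intergenic"
            if entry.near_gene in ("sense-1k", "mid", "far") and entry.rna_class == "cisreg":
                locus.curation = {
                    "sense-1k": "curated",
                    "mid": "uncurated",
                    "far": "pseudogene",
                }[entry.near_gene]
            # --- demotion truths ----------------------------------------
            if entry.tier == "medium-demoted":
                if entry.rna_class == "tRNA":
                    locus.tags.add("demoted:no-tRNAscan")
                else:
                    locus.tags.add("demoted:no-experimental-evidence")
            truth.append(locus)

    # rRNA cluster curation truth: complete 28S/18S/5.8S cluster on chr1
    rrna = [t for t in truth if t.rna_class == "rRNA"]
    by_contig: dict[str, list[str]] = {}
    for t in rrna:
        by_contig.setdefault(t.interval.contig, []).append(t.family)
    for t in rrna:
        members = set(by_contig[t.interval.contig])
        complete = {"28S", "18S", "5.8S"} <= members
        # completeness also requires proximity; the planter keeps same-contig
        # rRNAs within the cluster window by construction on chr1
        t.curation = "curated" if complete else "pseudogene"

    # snoRNA curation truth
    curated_fams = {
        t.family.split(",")[0]
        for t in truth
        if t.snorna_reference == "match"
    }
    for t in truth:
        if t.snorna_reference == "match":
            t.curation = "curated"
        elif t.snorna_reference == "family-pseudo" and t.family in curated_fams:
            t.curation = "pseudogene"
        elif t.snorna_reference == "none":
            t.curation = "uncurated"

    # extra unannotated read block group (too short for profile transfer)
    c0 = next(iter(contigs))
    block_groups.append(
        tool_io.ReadBlockGroup(
            GenomicInterval(c0, 1_000, 1_040, "+"),
            [(GenomicInterval(c0, 1_005, 1_035, "+"), 9)],
        )
    )

    pwm_training = {
        el: _make_training_slices(el, rng) for el in PROMOTER_CONSENSUS
    }
    new_genome = Genome(
        {c: b.decode() for c, b in contigs.items()}, dict(genome.assembled)
    )
    return PlantedTruth(
        genome=new_genome,
        loci=truth,
        blast_hits=blast,
        infernal_hits=infernal,
        trnascan_hits=trnascan,
        other_hits=other,
        meta=meta,
        query_lengths=qlens,
        gene_models=genes,
        block_groups=block_groups,
        rnaz_loci=rnaz_entries,
        pwm_training=pwm_training,
        motifs=motifs,
    )


# ---------------------------------------------------------------------------
# Bundle emission
# ---------------------------------------------------------------------------

BUNDLE_ORGANISMS = {"human": 0.05, "cow": 0.15, "outgroup": 0.45}
PROFILES = {
    "small": {"lengths": [300_000, 250_000, 40_000],
              "names": ["chr1", "chr2", "scaffold_1"]},
    "medium": {"lengths": [600_000, 500_000, 80_000],
               "names": ["chr1", "chr2", "scaffold_1"]},
}


def make_bundle(outdir, seed: int, profile: str = "small") -> dict:
    """Write a complete input bundle + truth manifest; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prof = PROFILES[profile]
    base = generate_genome(
        seed, lengths=prof["lengths"], names=prof["names"], gc=0.42,
        n_run_rate=2e-5,
    )
    planted = plant_annotations(base, default_catalog(), seed)
    genome = planted.genome

    # pairwise alignments: human gapless (used for snoRNA curation), others
    # with gaps and occasional inversions
    human = generate_pairwise_alignment(
        genome, seed + 1, {"human": BUNDLE_ORGANISMS["human"]},
    )["human"]
    others = generate_pairwise_alignment(
        genome, seed + 2,
        {o: d for o, d in BUNDLE_ORGANISMS.items() if o != "human"},
        rearrangement_rate=0.15, gap_prob=0.3,
    )
    organisms = {"human": human, **others}

    paths = {"dir": str(outdir)}
    write_fasta(genome, outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    tool_io.write_blast_tab(planted.blast_hits, planted.query_lengths, outdir / "blast.tsv")
    tool_io.write_infernal_tab(planted.infernal_hits, outdir / "infernal.tsv")
    tool_io.write_trnascan(planted.trnascan_hits, outdir / "trnascan.tsv")
    tool_io.write_generic_gff3_hits(planted.other_hits, outdir / "rnammer.gff3")
    tool_io.write_family_meta(planted.meta, outdir / "family_meta.tsv")
    tool_io.write_block_groups(planted.block_groups, outdir / "block_groups.bed")
    tool_io.write_gene_models_gff3(planted.gene_models, outdir / "genes.gff3")
    from .context import write_rnaz_bed

    write_rnaz_bed(planted.rnaz_loci, outdir / "rnaz.bed")
    with open(outdir / "query_lengths.tsv", "w") as fh:
        for fam, ln in sorted(planted.query_lengths.items()):
            fh.write(f"{fam}\t{ln}\n")
    with open(outdir / "pwm_training.tsv", "w") as fh:
        for el, slices in planted.pwm_training.items():
            for s in slices:
                fh.write(f"{el}\t{s}\n")
    for org, at in organisms.items():
        synteny.write_chain(at.alignments, outdir / f"{org}.chain")
        write_fasta(at.query_genome, outdir / f"query_{org}.fa")

    # reference curated snoRNA coordinates (human), via liftover of the
    # 'match' truth loci
    with open(outdir / "reference_snorna.bed", "w") as fh:
        for t in planted.loci:
            if t.snorna_reference == "match":
                for q in synteny.liftover(t.interval, human.alignments):
                    fh.write(
                        f"{q.contig}\t{q.start}\t{q.end}\t{t.family}\t0\t{q.strand}\n"
                    )

    # truth manifest
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "contig\tstart\tend\tstrand\tfamily\trna_class\ttier\tconflict\t"
            "cluster_id\tcontext\tcuration\ttags\n"
        )
        for t in planted.loci:
            iv = t.interval
            fh.write(
                "\t".join(
                    [
                        iv.contig, str(iv.start), str(iv.end), iv.strand,
                        t.family, t.rna_class, t.tier,
                        "1" if t.conflict else "0",
                        t.cluster_id or ".",
                        t.context,
                        t.curation,
                        ",".join(sorted(t.tags)) or ".",
                    ]
                )
                + "\n"
            )
    paths["truth"] = str(outdir / "truth.tsv")

    import yaml

    config = {
        "seed": seed,
        "tier": "high",
        "genome": "genome.fa",
        "blast": "blast.tsv",
        "infernal": "infernal.tsv",
        "trnascan": "trnascan.tsv",
        "rnammer": "rnammer.gff3",
        "family_meta": "family_meta.tsv",
        "query_lengths": "query_lengths.tsv",
        "gene_models": "genes.gff3",
        "block_groups": "block_groups.bed",
        "rnaz": "rnaz.bed",
        "pwm_training": "pwm_training.tsv",
        "reference_snorna": "reference_snorna.bed",
        "chains": {org: f"{org}.chain" for org in organisms},
        "query_genomes": {org: f"query_{org}.fa" for org in organisms},
        "reference_organism": "human",
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    paths["config"] = str(outdir / "config.yaml")
    paths["planted"] = planted
    paths["organisms"] = organisms
    return paths
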