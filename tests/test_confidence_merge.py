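import pytest

from rnannot.confidence_merge import (
    ConfidencePolicy,
    annotate,
    apply_demotion_rules,
    build_loci,
    classify_blast_hit,
    demote,
    detect_conflicts,
    filter_infernal,
    filter_trnascan,
    resolve_name,
    resolve_within_database,
)
from rnannot.genome_model import GenomicInterval
from rnannot.tool_io import FamilyMeta, ToolHit

from conftest import brute_force_components

POLICY = ConfidencePolicy()


def blast(family="fam", db="db", cls="snoRNA", start=100, end=200, strand="+",
          identity=96.0, coverage=97.0, e=1e-20, score=150.0, contig="c"):
    return ToolHit(
        tool="blast", database=db, family=family, rna_class=cls,
        interval=GenomicInterval(contig, start, end, strand),
        e_value=e, bit_score=score, identity_pct=identity,
        query_coverage_pct=coverage,
    )


def infernal(family="fam", cls="snoRNA", start=100, end=200, e=1e-6,
             contig="c", score=80.0):
    return ToolHit(
        tool="infernal", database="rfam", family=family, rna_class=cls,
        interval=GenomicInterval(contig, start, end, "+"),
        e_value=e, bit_score=score,
    )


def trna(cove, hmm, strs, both, start=100, end=172):
    return ToolHit(
        tool="trnascan", database="trnascan", family="tRNA-Ala-AGC",
        rna_class="tRNA", interval=GenomicInterval("c", start, end, "+"),
        bit_score=cove,
        tool_scores={"COVE": cove, "HMM": hmm, "2'Str": strs},
        both_first_pass_parsers=both,
    )


def meta(family="fam", cls="snoRNA", mirna=False, seed=True, ga_e=10.0,
         evidence=True):
    return FamilyMeta(family, cls, 30.0, ga_e, seed, mirna, evidence)


class TestBlastTiers:
    @pytest.mark.parametrize(
        "identity,coverage,tier",
        [
            (95.0, 95.0, "high"),  # inclusive boundary
            (94.9, 99.0, "medium"),
            (92.5, 92.5, "medium"),
            (90.0, 90.0, "low"),
            (96.0, 89.9, "reject"),  # coverage below the low tier
            (89.9, 99.0, "reject"),
        ],
    )
    def test_boundaries(self, identity, coverage, tier):
        hit = blast(identity=identity, coverage=coverage)
        assert classify_blast_hit(hit, POLICY) == tier

    def test_non_blast_hit_rejected(self):
        with pytest.raises(ValueError):
            classify_blast_hit(infernal(), POLICY)


class TestWithinDatabaseResolution:
    def test_lowest_evalue_wins(self):
        pig = blast("SNORA81", e=1e-30)
        bat = blast("SNORA81-bat", e=1e-20)
        assert resolve_within_database([bat, pig]) is pig

    def test_single_hit_identity(self):
        h = blast()
        assert resolve_within_database([h]) is h

    def test_deterministic_tie_break(self):
        a = blast("alpha", e=1e-10, score=100.0)
        b = blast("beta", e=1e-10, score=100.0)
        assert resolve_within_database([b, a]).family == "alpha"
        assert resolve_within_database([a, b]).family == "alpha"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            resolve_within_database([])


class TestInfernalFilters:
    META = {
        "fam": meta(),
        "mirfam": meta("mirfam", "miRNA", mirna=True),
        "nonvert": meta("nonvert", seed=False),
        "tight": meta("tight", ga_e=1e-6),
    }

    def test_anchored_non_mirna_kept_at_high(self):
        hits = [infernal(e=1e-4)]
        anchors = [blast("fam", e=1e-5)]
        assert filter_infernal(hits, anchors, self.META, "high") == hits

    def test_mirna_family_excluded_from_high_only(self):
        hits = [infernal("mirfam", "miRNA", e=1e-12)]
        anchors = [blast("mirfam", e=1e-5)]
        assert filter_infernal(hits, anchors, self.META, "high") == []
        assert filter_infernal(hits, anchors, self.META, "medium") == hits

    def test_loose_evalue_dropped_at_every_tier(self):
        # the E-value cap catches hits that sneak in under a loose
        # gathering-score-implied cutoff
        hits = [infernal(e=3.04e-2)]
        anchors = [blast("fam", e=1e-30)]
        for tier in ("high", "medium", "low"):
            assert filter_infernal(hits, anchors, self.META, tier) == []

    def test_vertebrate_seed_required(self):
        hits = [infernal("nonvert", e=1e-20)]
        assert filter_infernal(hits, [blast("nonvert")], self.META, "low") == []

    def test_gathering_score_cutoff_respected_when_tight(self):
        assert filter_infernal([infernal("tight", e=1e-5)],
                               [blast("tight")], self.META, "low") == []
        assert filter_infernal([infernal("tight", e=1e-7)],
                               [blast("tight")], self.META, "low") == [
            infernal("tight", e=1e-7)
        ]

    def test_anchor_not_required_at_low_for_non_mirna(self):
        hits = [infernal(e=1e-4)]
        assert filter_infernal(hits, [], self.META, "low") == hits
        assert filter_infernal(hits, [], self.META, "high") == []

    def test_mirna_evalue_ladder(self):
        anchors = [blast("mirfam", e=1e-2)]  # anchors only at the low cutoff
        h = [infernal("mirfam", "miRNA", e=1e-7)]
        assert filter_infernal(h, anchors, self.META, "medium") == []  # E and anchor fail
        assert filter_infernal(h, anchors, self.META, "low") == h


class TestTrnascanFilter:
    def test_triple_score_inclusive_boundary(self):
        h = trna(20.0, 10.0, 5.0, both=True)
        assert filter_trnascan([h], "high") == [h]

    def test_single_parser_cove_strict(self):
        at_55 = trna(55.0, 0, 0, both=False)
        above = trna(55.1, 0, 0, both=False)
        assert filter_trnascan([at_55], "high") == []
        assert filter_trnascan([above], "high") == [above]

    def test_low_tier_unfiltered(self):
        h = trna(1.0, 0, 0, both=False)
        assert filter_trnascan([h], "low") == [h]

    def test_triple_score_any_failure_drops(self):
        assert filter_trnascan([trna(19.9, 10, 5, both=True)], "medium") == []
        assert filter_trnascan([trna(20, 9.9, 5, both=True)], "medium") == []
        assert filter_trnascan([trna(20, 10, 4.9, both=True)], "medium") == []


class TestLoci:
    def test_overlapping_hits_form_one_locus(self):
        hits = [infernal(start=100, end=230), blast(start=150, end=220)]
        (locus,) = build_loci(hits, "high")
        assert len(locus.members) == 2
        assert (locus.span.start, locus.span.end) == (100, 230)

    def test_disjoint_hits_stay_separate(self):
        hits = [blast(start=0, end=50), blast(start=100, end=150)]
        assert len(build_loci(hits, "low")) == 2

    def test_matches_brute_force(self, rng):
        hits = []
        for _ in range(500):
            s = int(rng.integers(0, 20_000))
            hits.append(blast(start=s, end=s + int(rng.integers(1, 300)),
                              contig=str(rng.choice(["c1", "c2"]))))
        loci = build_loci(hits, "low")
        expected = brute_force_components([h.interval for h in hits])
        got = sorted(
            sorted(hits.index(m) for m in locus.members) for locus in loci
        )
        assert got == sorted(expected)


class TestConflicts:
    def test_cross_class_conflict(self):
        locus = build_loci(
            [blast("SNORA81", "rfam-seed", "snoRNA"),
             blast("eca-mir-1248", "mirbase", "miRNA")], "high",
        )[0]
        detect_conflicts(locus)
        assert locus.conflict
        assert ("miRNA", "blast") in locus.conflict_detail

    def test_same_class_different_tools_not_a_conflict(self):
        locus = build_loci(
            [blast("mir-127", "mirbase", "miRNA"),
             infernal("mir-127", "miRNA")], "high",
        )[0]
        detect_conflicts(locus)
        assert not locus.conflict

    def test_infernal_family_conflict_within_class(self):
        locus = build_loci(
            [infernal("SNORD1"), infernal("SNORD2")], "high"
        )[0]
        detect_conflicts(locus)
        assert locus.conflict
        fams = {f for f, tool in locus.conflict_detail if tool == "infernal"}
        assert fams == {"SNORD1", "SNORD2"}

    def test_flag_invariant_under_member_order(self):
        hits = [blast("a", cls="snoRNA"), blast("b", "db2", cls="miRNA")]
        l1 = build_loci(hits, "high")[0]
        l2 = build_loci(hits[::-1], "high")[0]
        assert detect_conflicts(l1).conflict == detect_conflicts(l2).conflict


class TestNaming:
    def test_class_specific_beats_blast(self):
        locus = build_loci(
            [trna(60, 30, 20, True), blast("tRNA-Xxx", "trnadb", "tRNA")],
            "high",
        )
        name, cls = resolve_name(detect_conflicts(locus[0]))
        assert name == "tRNA-Ala-AGC" and cls == "tRNA"

    def test_blast_beats_infernal(self):
        locus = build_loci(
            [infernal("RF-name"), blast("blast-name", cls="snoRNA")], "high"
        )[0]
        assert resolve_name(detect_conflicts(locus))[0] == "blast-name"

    def test_single_member(self):
        locus = build_loci([blast("only")], "high")[0]
        assert resolve_name(detect_conflicts(locus))[0] == "only"

    def test_empty_ranking_errors(self):
        locus = build_loci([blast()], "high")[0]
        with pytest.raises(ValueError):
            resolve_name(locus, ranking={})

    def test_conflict_locus_named_by_members(self):
        locus = build_loci(
            [blast("a", cls="snoRNA"), blast("b", "db2", cls="miRNA")], "high"
        )[0]
        detect_conflicts(locus)
        name, cls = resolve_name(locus)
        assert cls == "conflict" and name == "a,b"


class TestDemotion:
    def test_high_trna_without_trnascan_drops(self):
        locus = build_loci([blast("tRNA-Leu", "trnadb", "tRNA")], "high")[0]
        detect_conflicts(locus)
        resolve_name(locus)
        apply_demotion_rules([locus])
        assert locus.confidence == "medium"
        assert "demoted:no-tRNAscan" in locus.tags

    def test_mirna_without_evidence_or_reads_drops(self):
        m = {"mir-x": meta("mir-x", "miRNA", evidence=False)}
        locus = build_loci([blast("mir-x", "mirbase", "miRNA")], "high")[0]
        detect_conflicts(locus)
        resolve_name(locus)
        apply_demotion_rules([locus], m)
        assert locus.confidence == "medium"

    def test_read_support_guards_demotion(self):
        m = {"mir-x": meta("mir-x", "miRNA", evidence=False)}
        locus = build_loci([blast("mir-x", "mirbase", "miRNA")], "high")[0]
        detect_conflicts(locus)
        resolve_name(locus)
        locus.tags.add("read-supported")
        apply_demotion_rules([locus], m)
        assert locus.confidence == "high"

    def test_demote_direction_enforced(self):
        locus = build_loci([blast()], "low")[0]
        with pytest.raises(ValueError):
            demote(locus, "high", "nope")


class TestAnnotateProperties:
    def _inputs(self):
        m = {
            "fam": meta(),
            "mirfam": meta("mirfam", "miRNA", mirna=True),
            "tRNA-Ala-AGC": meta("tRNA-Ala-AGC", "tRNA"),
        }
        blast_hits = [
            blast(identity=96, coverage=97, start=100, end=220),
            blast("fam2", identity=93, coverage=94, start=1000, end=1100,
                  cls="snRNA"),
            blast("fam3", identity=90.5, coverage=91, start=2000, end=2100,
                  cls="other"),
        ]
        infernal_hits = [infernal(start=100, end=220, e=1e-5)]
        trna_hits = [trna(60, 30, 20, True, start=5000, end=5072)]
        return blast_hits, infernal_hits, trna_hits, m

    def test_tier_monotonicity(self):
        blast_hits, infernal_hits, trna_hits, m = self._inputs()
        results = {
            tier: annotate(blast_hits, infernal_hits, trna_hits, [], m, tier)
            for tier in ("high", "medium", "low")
        }
        def spans(tier):
            return [l.span for l in results[tier]]
        for small, big in (("high", "medium"), ("medium", "low")):
            for span in spans(small):
                assert any(
                    b.contig == span.contig and b.start <= span.start
                    and span.end <= b.end
                    for b in spans(big)
                ), f"{small} locus {span} not covered at {big}"

    def test_deterministic_under_input_permutation(self):
        blast_hits, infernal_hits, trna_hits, m = self._inputs()
        a = annotate(blast_hits, infernal_hits, trna_hits, [], m, "low")
        b = annotate(blast_hits[::-1], infernal_hits[::-1], trna_hits, [], m, "low")
        assert [(l.span, l.resolved_name, l.conflict) for l in a] == [
            (l.span, l.resolved_name, l.conflict) for l in b
        ]

    def test_anchored_high_tier_has_no_family_conflicts(self):
        # every Infernal family with its own BLAST anchor: no two families
        # survive on one locus at high tier
        m = {f"f{i}": meta(f"f{i}") for i in range(5)}
        infernal_hits = [
            infernal(f"f{i}", start=i * 1000, end=i * 1000 + 120, e=1e-5)
            for i in range(5)
        ]
        anchors = [
            blast(f"f{i}", start=i * 1000, end=i * 1000 + 120,
                  identity=96, coverage=97)
            for i in range(5)
        ]
        loci = annotate(anchors, infernal_hits, [], [], m, "high")
        assert all(not l.conflict for l in loci)
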