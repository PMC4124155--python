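import pytest

from rnannot.confidence_merge import RnaLocus
from rnannot.context import GenicContext
from rnannot.curation import (
    CurationRecord,
    MirnaPrediction,
    assemble_curated_annotation,
    curate_cisreg,
    curate_host_gene_order,
    curate_pol23,
    curate_rrna,
    curate_snorna,
    mirdeep_cleanup,
)
from rnannot.genome_model import GenomicInterval
from rnannot.promoter import PromoterCall


def locus(lid, cls="cisreg", start=1000, end=1100, contig="chr1",
          confidence="high", conflict=False):
    return RnaLocus(
        span=GenomicInterval(contig, start, end, "+"), members=[],
        resolved_name=lid, resolved_class=cls, confidence=confidence,
        conflict=conflict, locus_id=lid,
    )


def ctx(genes):
    c = GenicContext()
    for gid, dist, sense in genes:
        c.nearest_genes.append((gid, dist))
        c.sense_relation[gid] = sense
    return c


class TestCisreg:
    def test_sense_gene_within_1kb_curates(self):
        rec = curate_cisreg(locus("L1"), ctx([("g1", 800, "sense")]))
        assert rec.status == "curated"

    def test_no_gene_within_10kb_is_pseudogene(self):
        rec = curate_cisreg(locus("L1"), ctx([]))
        assert rec.status == "pseudogene"
        rec2 = curate_cisreg(locus("L1"), ctx([("g1", 12_000, "sense")]))
        assert rec2.status == "pseudogene"

    def test_mid_distance_uncurated(self):
        rec = curate_cisreg(locus("L1"), ctx([("g1", 5_000, "sense")]))
        assert rec.status == "uncurated"

    def test_antisense_gene_does_not_curate(self):
        rec = curate_cisreg(locus("L1"), ctx([("g1", 500, "antisense")]))
        assert rec.status == "uncurated"

    def test_wrong_class_errors(self):
        with pytest.raises(ValueError):
            curate_cisreg(locus("L1", cls="miRNA"), ctx([]))


class TestRrna:
    def test_complete_cluster_curated(self):
        loci = [
            locus("r1", "rRNA", 1000, 1500),
            locus("r2", "rRNA", 5000, 5400),
            locus("r3", "rRNA", 9000, 9150),
            locus("r4", "rRNA", 1000, 1400, contig="chr5"),
        ]
        subs = {"r1": "28S", "r2": "18S", "r3": "5.8S", "r4": "18S"}
        records = {r.locus_id: r.status for r in curate_rrna(loci, subs)}
        assert records == {
            "r1": "curated", "r2": "curated", "r3": "curated",
            "r4": "pseudogene",
        }

    def test_incomplete_cluster_is_pseudogene(self):
        loci = [locus("r1", "rRNA", 1000, 1400),
                locus("r2", "rRNA", 3000, 3150)]
        subs = {"r1": "18S", "r2": "5.8S"}
        assert all(
            r.status == "pseudogene" for r in curate_rrna(loci, subs)
        )

    def test_window_separates_clusters(self):
        loci = [
            locus("r1", "rRNA", 1000, 1500),
            locus("r2", "rRNA", 2000, 2400),
            locus("r3", "rRNA", 80_000, 80_150),  # 5.8S too far away
        ]
        subs = {"r1": "28S", "r2": "18S", "r3": "5.8S"}
        assert all(
            r.status == "pseudogene" for r in curate_rrna(loci, subs)
        )


class TestSnorna:
    def _inputs(self):
        loci = [locus("s1", "snoRNA"), locus("s2", "snoRNA", start=5000, end=5100),
                locus("s3", "snoRNA", start=9000, end=9100)]
        families = {"s1": "SNORD25", "s2": "SNORD25", "s3": "SNORD99"}
        ref = {"SNORD25": [GenomicInterval("h1", 100, 200)]}
        lifted = {
            "s1": [GenomicInterval("h1", 120, 220)],
            "s2": [GenomicInterval("h1", 9000, 9100)],
            "s3": [GenomicInterval("h1", 20_000, 20_100)],
        }
        idents = {"s1": 0.74, "s2": 0.95, "s3": 0.95}
        return loci, families, ref, lifted, idents

    def test_reference_match_curates_rest_pseudogene(self):
        loci, fams, ref, lifted, idents = self._inputs()
        records = {r.locus_id: r.status
                   for r in curate_snorna(loci, fams, ref, lifted, idents)}
        assert records == {
            "s1": "curated", "s2": "pseudogene", "s3": "uncurated"
        }

    def test_identity_cutoff_strict(self):
        loci, fams, ref, lifted, idents = self._inputs()
        idents["s1"] = 0.60  # exactly at the cutoff: not curated
        records = {r.locus_id: r.status
                   for r in curate_snorna(loci, fams, ref, lifted, idents)}
        assert records["s1"] == "uncurated"

    def test_host_gene_order_rule(self):
        fams_order = ["SNORD25", "SNORD26", "SNORD27"]
        loci = [
            locus(f"s{i}", "snoRNA", start=1000 + i * 3000,
                  end=1100 + i * 3000)
            for i in range(3)
        ]
        families = {f"s{i}": fams_order[i] for i in range(3)}
        assert curate_host_gene_order(loci, families, fams_order) == [
            "s0", "s1", "s2"
        ]
        # wrong order does not match
        families_bad = {"s0": "SNORD26", "s1": "SNORD25", "s2": "SNORD27"}
        assert curate_host_gene_order(loci, families_bad, fams_order) == []


class TestPol23:
    def test_pass_fail_unavailable(self):
        l = locus("u6", "snRNA")
        passed = PromoterCall("u6", "polIII", passed=True)
        failed = PromoterCall("u6", "polIII", passed=False)
        assert curate_pol23(l, passed).status == "curated"
        assert curate_pol23(l, failed).status == "pseudogene"
        assert curate_pol23(l, None).status == "uncurated"


def pred(name, precursor, mature="AACCGGTTAACCGGTTAACCGG", star="CCGG" * 5,
         loci=None, reads=25, misplaced=False):
    return MirnaPrediction(
        name, precursor, mature, star,
        loci or [GenomicInterval("chr1", 1000, 1080, "+")], reads, misplaced,
    )


class TestMirdeepCleanup:
    def test_identical_precursors_collapse(self):
        a = pred("pre-1", "ACGT" * 20)
        b = pred("pre-2", "ACGT" * 20,
                 loci=[GenomicInterval("chr2", 5000, 5080, "+")])
        result = mirdeep_cleanup([a, b], [])
        assert len(result.kept) == 1
        assert len(result.kept[0].loci) == 2

    def test_overlap_without_star_discards_both(self):
        a = pred("pre-1", "ACGT" * 20, star=None)
        b = pred("pre-2", "TGCA" * 20, star=None,
                 loci=[GenomicInterval("chr1", 1040, 1120, "+")])
        result = mirdeep_cleanup([a, b], [])
        assert result.kept == []

    def test_overlap_with_identical_star_and_mature_kept(self):
        a = pred("pre-1", "ACGT" * 20)
        b = pred("pre-2", "TGCA" * 20,
                 loci=[GenomicInterval("chr1", 1040, 1120, "+")])
        result = mirdeep_cleanup([a, b], [])
        assert {p.name for p in result.kept} == {"pre-1", "pre-2"}

    def test_short_mature_extension_discarded(self):
        long_m = "AACCGGTTAACCGGTTAACCGG"
        a = pred("pre-1", "ACGT" * 20, mature=long_m[:-2],
                 loci=[GenomicInterval("chr2", 100, 180, "+")])
        b = pred("pre-2", "ACGT" * 20, mature=long_m,
                 loci=[GenomicInterval("chr2", 100, 180, "+")])
        result = mirdeep_cleanup([a, b], [])
        assert [p.name for p in result.kept] == ["pre-2"]

    def test_high_tier_non_mirna_overlap_discards(self):
        sno = locus("S1", "snoRNA", 1000, 1100)
        result = mirdeep_cleanup([pred("pre-1", "ACGT" * 20)], [sno])
        assert result.kept == []

    def test_conflict_locus_overlap_kept(self):
        conf = locus("C1", "conflict", 1000, 1100, conflict=True)
        result = mirdeep_cleanup([pred("pre-1", "ACGT" * 20)], [conf])
        assert len(result.kept) == 1

    def test_coding_context_demotes(self):
        result = mirdeep_cleanup(
            [pred("pre-1", "ACGT" * 20)], [], coding_exon_loci={"pre-1"}
        )
        assert result.kept[0].tier == "medium"

    def test_misplaced_discarded(self):
        result = mirdeep_cleanup([pred("pre-1", "ACGT" * 20, misplaced=True)], [])
        assert result.kept == []

    def test_low_read_count_rejected_at_intake(self):
        with pytest.raises(ValueError):
            mirdeep_cleanup([pred("pre-1", "ACGT" * 20, reads=9)], [])

    def test_idempotent(self):
        preds = [
            pred("pre-1", "ACGT" * 20),
            pred("pre-2", "ACGT" * 20,
                 loci=[GenomicInterval("chr2", 5000, 5080, "+")]),
            pred("pre-3", "GGCC" * 20,
                 loci=[GenomicInterval("chr3", 100, 180, "+")]),
        ]
        once = mirdeep_cleanup(preds, [])
        twice = mirdeep_cleanup(once.kept, [])
        assert [(p.name, p.precursor_seq, len(p.loci), p.tier)
                for p in once.kept] == [
            (p.name, p.precursor_seq, len(p.loci), p.tier) for p in twice.kept
        ]

    def test_order_invariant(self):
        preds = [
            pred("pre-1", "ACGT" * 20),
            pred("pre-2", "GGCC" * 20,
                 loci=[GenomicInterval("chr3", 100, 180, "+")]),
        ]
        a = mirdeep_cleanup(preds, [])
        b = mirdeep_cleanup(preds[::-1], [])
        assert {p.name for p in a.kept} == {p.name for p in b.kept}


class TestAssemble:
    def test_partition_arithmetic(self):
        loci = [locus(f"c{i}") for i in range(10)]
        records = (
            [CurationRecord(f"c{i}", "curated", "cisreg-sense-context")
             for i in range(6)]
            + [CurationRecord(f"c{i}", "pseudogene", "cisreg-no-gene-context")
               for i in range(6, 9)]
            + [CurationRecord("c9", "uncurated")]
        )
        status, table = assemble_curated_annotation(loci, records)
        row = table[table.rna_class == "cisreg"].iloc[0]
        assert (row.curated, row.pseudogene, row.uncurated) == (6, 3, 1)
        assert row.curated + row.pseudogene + row.uncurated == row.high_confident
        assert row.remaining == row.high_confident - row.pseudogene

    def test_empty(self):
        status, table = assemble_curated_annotation([], [])
        assert status == {} and len(table) == 0

    def test_class_without_rule_stays_uncurated(self):
        loci = [locus("l1", "lncRNA-locus")]
        status, table = assemble_curated_annotation(loci, [])
        assert table.iloc[0].curated == 0 and table.iloc[0].pseudogene == 0
        assert loci[0].curation_status == "uncurated"

    def test_conflicting_statuses_error(self):
        loci = [locus("x")]
        records = [
            CurationRecord("x", "curated", "r1"),
            CurationRecord("x", "pseudogene", "r2"),
        ]
        with pytest.raises(ValueError, match="both"):
            assemble_curated_annotation(loci, records)
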