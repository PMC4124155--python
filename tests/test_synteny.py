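import numpy as np
import pytest

from rnannot.genome_model import Genome, GenomicInterval, reverse_complement
from rnannot.synteny import (
    ConservationCall,
    PairwiseAlignment,
    build_synteny_blocks,
    conservation_depth,
    coverage,
    find_exact_duplicates,
    lineage_specific,
    liftover,
    locus_conservation,
    merge_regions,
    read_chain,
    write_chain,
)


def aln(t0, q0, length, contig="chr1", q_contig="h1", strand="+", q_size=100_000,
        chain_id=1, segments=None):
    return PairwiseAlignment(
        contig, q_contig, strand, segments or [(t0, q0, length)], "human",
        q_size, chain_id,
    )


class TestBlocks:
    def test_hand_merge(self):
        a = aln(0, 0, 3000, chain_id=1)
        b = aln(4000, 4000, 3000, chain_id=2)  # gap 1000 on both sides
        (block,) = build_synteny_blocks([a, b])
        assert (block.target.start, block.target.end) == (0, 7000)
        assert block.member_ids == [1, 2]

    def test_gap_boundary_strict(self):
        # gap exactly 5,000 does not merge; both pieces are < 5,000 and drop
        a = aln(0, 0, 3000)
        b = aln(8000, 8000, 3000, chain_id=2)
        assert build_synteny_blocks([a, b]) == []

    def test_overlapping_alignments_rejected(self):
        with pytest.raises(ValueError, match="single-coverage"):
            build_synteny_blocks([aln(0, 0, 3000), aln(2000, 5000, 3000)])

    def test_strand_or_contig_change_breaks(self):
        a = aln(0, 0, 6000)
        b = aln(6500, 90_000, 6000, strand="-", chain_id=2)
        blocks = build_synteny_blocks([a, b])
        assert len(blocks) == 2

    def test_matches_sequential_merge_oracle(self, rng):
        for _ in range(30):
            alns, t = [], 0
            for i in range(int(rng.integers(5, 25))):
                t += int(rng.integers(100, 8000))
                ln = int(rng.integers(500, 8000))
                alns.append(
                    aln(t, t, ln, q_contig=str(rng.choice(["h1", "h2"])),
                        strand=str(rng.choice(["+", "-"])), chain_id=i + 1)
                )
                t += ln
            blocks = build_synteny_blocks(alns)
            # oracle: greedy scan over sorted alignments
            expected = []
            cur = [alns[0]]
            for prev, nxt in zip(alns, alns[1:]):
                same = (
                    prev.query_contig == nxt.query_contig
                    and prev.strand == nxt.strand
                    and 0 <= nxt.target_start - prev.target_end < 5000
                    and 0 <= nxt.query_start - prev.query_end < 5000
                )
                if same:
                    cur.append(nxt)
                else:
                    expected.append(cur)
                    cur = [nxt]
            expected.append(cur)
            expected = [
                (c[0].target_start, c[-1].target_end)
                for c in expected
                if c[-1].target_end - c[0].target_start >= 5000
            ]
            assert [(b.target.start, b.target.end) for b in blocks] == expected

    def test_block_invariants(self, rng):
        alns, t = [], 0
        for i in range(40):
            t += int(rng.integers(100, 6000))
            ln = int(rng.integers(1000, 9000))
            alns.append(aln(t, t, ln, chain_id=i + 1,
                            strand=str(rng.choice(["+", "-"]))))
            t += ln
        blocks = build_synteny_blocks(alns)
        for b in blocks:
            assert len(b.target) >= 5000
        for a, b in zip(blocks, blocks[1:]):
            assert a.target.end <= b.target.start  # disjoint on target


class TestRegions:
    def _blocks(self):
        return build_synteny_blocks(
            [aln(0, 0, 6000, chain_id=1),
             aln(20_000, 50_000, 6000, strand="-", chain_id=2),
             aln(40_000, 60_000, 6000, chain_id=3)]
        )

    def test_strand_aware_vs_agnostic(self):
        blocks = self._blocks()
        aware = merge_regions(blocks, respect_strand=True)
        agnostic = merge_regions(blocks, respect_strand=False)
        assert len(aware) == 3
        assert len(agnostic) == 1

    def test_single_block_identity(self):
        blocks = build_synteny_blocks([aln(0, 0, 7000)])
        regions = merge_regions(blocks)
        assert len(regions) == 1
        assert regions[0].target == blocks[0].target

    def test_count_monotonicity(self, rng):
        for _ in range(20):
            alns, t = [], 0
            for i in range(int(rng.integers(3, 20))):
                t += int(rng.integers(5001, 20_000))
                ln = int(rng.integers(5000, 9000))
                alns.append(aln(t, t, ln, chain_id=i + 1,
                                q_contig=str(rng.choice(["h1", "h2"])),
                                strand=str(rng.choice(["+", "-"]))))
                t += ln
            blocks = build_synteny_blocks(alns)
            aware = merge_regions(blocks, respect_strand=True)
            agnostic = merge_regions(blocks, respect_strand=False)
            assert len(agnostic) <= len(aware) <= len(blocks)


class TestCoverage:
    def test_half_covered(self):
        g = Genome({"chr1": "ACGT" * 1000})
        assert coverage([GenomicInterval("chr1", 0, 2000)], g) == 0.5

    def test_duplicate_intervals_union(self):
        g = Genome({"chr1": "ACGT" * 1000})
        iv = GenomicInterval("chr1", 0, 2000)
        assert coverage([iv, iv], g) == 0.5

    def test_non_n_denominator(self, rng):
        seq = list("ACGT" * 2500)
        for start in rng.integers(0, 9900, size=15):
            for i in range(int(start), int(start) + 40):
                seq[i] = "N"
        g = Genome({"chr1": "".join(seq)})
        ivs = [GenomicInterval("chr1", 0, 5000)]
        # bitmap oracle
        mask = np.zeros(10_000, bool)
        mask[0:5000] = True
        non_n = np.frombuffer("".join(seq).encode(), dtype="S1") != b"N"
        expected = (mask & non_n).sum() / non_n.sum()
        assert coverage(ivs, g) == pytest.approx(expected)


class TestLiftover:
    def test_inside_single_segment(self):
        a = aln(1000, 5000, 2000)
        (q,) = liftover(GenomicInterval("chr1", 1200, 1300), [a])
        assert (q.contig, q.start, q.end) == ("h1", 5200, 5300)
        assert len(q) == 100

    def test_spanning_gap_splits(self):
        a = aln(0, 0, 0, segments=[(1000, 5000, 500), (2000, 6000, 500)])
        out = liftover(GenomicInterval("chr1", 1400, 2100), [a])
        assert [(q.start, q.end) for q in out] == [(5400, 5500), (6000, 6100)]

    def test_unaligned_region_empty(self):
        assert liftover(GenomicInterval("chr1", 50_000, 50_100),
                        [aln(0, 0, 2000)]) == []

    def test_minus_strand_forward_coordinates(self):
        # strand-space query start 100 on a 10,000-nt query: forward
        # coordinates are q_size - (q_ss + len)
        a = aln(1000, 100, 500, strand="-", q_size=10_000)
        (q,) = liftover(GenomicInterval("chr1", 1000, 1500), [a])
        assert (q.start, q.end) == (10_000 - 600, 10_000 - 100)

    def test_per_position_oracle(self, rng):
        segments = []
        t, q = 0, 0
        for _ in range(8):
            t += int(rng.integers(0, 300))
            q += int(rng.integers(0, 300))
            ln = int(rng.integers(50, 400))
            segments.append((t, q, ln))
            t += ln
            q += ln
        a = aln(0, 0, 0, segments=segments)
        for _ in range(20):
            s = int(rng.integers(0, t))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(1, 500)))
            out = liftover(iv, [a])
            mapped = set()
            for ts, qs, ln in segments:
                for off in range(ln):
                    if iv.start <= ts + off < iv.end:
                        mapped.add(qs + off)
            got = set()
            for piece in out:
                got.update(range(piece.start, piece.end))
            assert got == mapped


class TestConservation:
    def _pair(self, length=100, n_mut=15, aligned=None):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        t = "".join(bases[i] for i in rng.integers(0, 4, 5000))
        q = list(t)
        mut_pos = rng.choice(np.arange(1000, 1000 + length), n_mut, replace=False)
        for p in mut_pos:
            q[p] = bases[(bases.index(q[p]) + 1) % 4]
        tg = Genome({"chr1": t})
        qg = Genome({"h1": "".join(q)})
        a = aln(0, 0, aligned if aligned else 5000)
        return tg, qg, a

    def test_column_count(self):
        tg, qg, a = self._pair()
        call = locus_conservation(
            GenomicInterval("chr1", 1000, 1100), [a], tg, qg, "human"
        )
        assert call.covered_fraction == 1.0
        assert call.identity_fraction == pytest.approx(0.85)
        assert call.conserved

    def test_coverage_gate(self):
        tg, qg, a = self._pair(n_mut=0, aligned=1070)
        call = locus_conservation(
            GenomicInterval("chr1", 1000, 1100), [a], tg, qg, "human"
        )
        assert call.covered_fraction == pytest.approx(0.70)
        assert not call.conserved

    def test_inclusive_80_80_boundary(self):
        t = "A" * 100
        q = "A" * 80 + "C" * 20
        tg = Genome({"chr1": t + "G" * 900})
        qg = Genome({"h1": q})
        a = aln(0, 0, 80, segments=[(0, 0, 80)])
        # covered exactly 0.8; all 80 aligned columns match
        call = locus_conservation(
            GenomicInterval("chr1", 0, 100), [a], tg, qg, "human"
        )
        assert call.covered_fraction == pytest.approx(0.80)
        assert call.conserved
        # identity exactly 0.8 on fully covered locus
        q2 = "A" * 80 + "C" * 20
        qg2 = Genome({"h1": q2})
        a2 = aln(0, 0, 100)
        call2 = locus_conservation(
            GenomicInterval("chr1", 0, 100), [a2], tg, qg2, "human"
        )
        assert call2.identity_fraction == pytest.approx(0.80)
        assert call2.conserved

    def test_minus_strand_alignment_compares_revcomp(self):
        t = "ACGTACGTAC" * 10
        q_fwd = reverse_complement(t)  # perfect match on '-'
        tg = Genome({"chr1": t})
        qg = Genome({"h1": q_fwd})
        a = aln(0, 0, 100, strand="-", q_size=100)
        call = locus_conservation(
            GenomicInterval("chr1", 10, 60), [a], tg, qg, "human"
        )
        assert call.identity_fraction == 1.0

    def test_brute_force_on_generated_fixture(self, rng):
        from rnannot.fixtures import generate_genome, generate_pairwise_alignment

        g = generate_genome(3, lengths=[60_000], names=["chr1"])
        truths = generate_pairwise_alignment(
            g, 4, {"human": 0.1}, gap_prob=0.3, rearrangement_rate=0.2
        )
        at = truths["human"]
        for _ in range(25):
            s = int(rng.integers(0, 59_000))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(50, 500)))
            call = locus_conservation(iv, at.alignments, g, at.query_genome)
            cov, ident = at.realized_identity(iv)
            assert call.covered_fraction == pytest.approx(cov)
            if ident is None:
                assert call.identity_fraction is None
            else:
                assert call.identity_fraction == pytest.approx(ident)


class TestDepthAndLineage:
    def _call(self, org, conserved=True, identity=0.9, covered=1.0):
        return ConservationCall("L1", org, covered, identity, conserved)

    def test_depth_counts_conserved(self):
        calls = [self._call("human"), self._call("cow"),
                 self._call("dog"), self._call("mouse", conserved=False)]
        assert conservation_depth(calls) == 3

    def test_no_calls(self):
        assert conservation_depth([]) == 0

    def test_duplicate_organism_errors(self):
        with pytest.raises(ValueError):
            conservation_depth([self._call("human"), self._call("human")])

    def test_lineage_specific_basic(self):
        calls = {
            "cow": self._call("cow", identity=0.70),
            "horse": self._call("horse", identity=0.65),
            "mouse": self._call("mouse", conserved=False, identity=0.20),
        }
        assert lineage_specific(calls, ["cow", "horse"], ["mouse", "chicken"])

    @pytest.mark.parametrize(
        "inside_ident,outside_ident,expected",
        [
            (0.55, 0.20, False),  # fails > 60% inside
            (0.60, 0.20, False),  # strict boundary
            (0.70, 0.31, False),  # fails < 30% outside
            (0.70, 0.30, False),  # strict boundary
            (0.70, 0.29, True),
        ],
    )
    def test_boundaries(self, inside_ident, outside_ident, expected):
        calls = {
            "cow": self._call("cow", identity=inside_ident),
            "mouse": self._call("mouse", conserved=False,
                                identity=outside_ident),
        }
        assert lineage_specific(calls, ["cow"], ["mouse"]) is expected

    def test_copy_and_duplicate_guards(self):
        calls = {"cow": self._call("cow", identity=0.7)}
        assert not lineage_specific(calls, ["cow"], [], copy_count=6)
        assert not lineage_specific(calls, ["cow"], [], is_exact_duplicate=True)
        assert not lineage_specific(calls, ["cow"], [],
                                    on_assembled_contig=False)


class TestDuplicates:
    def test_planted_triplicate(self):
        from rnannot.confidence_merge import RnaLocus

        motif = "ACGTTGCA" * 10
        seq = ("T" * 1000 + motif + "G" * 1000 + motif + "C" * 1000
               + motif + "A" * 1000)
        g = Genome({"chr1": seq})
        positions = [1000, 1000 + 80 + 1000, 1000 + 80 + 1000 + 80 + 1000]
        loci = [
            RnaLocus(span=GenomicInterval("chr1", p, p + 80, "+"), members=[],
                     confidence="high", locus_id=f"L{i}")
            for i, p in enumerate(positions)
        ]
        other = RnaLocus(
            span=GenomicInterval("chr1", 200, 280, "+"), members=[],
            confidence="high", locus_id="L9",
        )
        groups = find_exact_duplicates(loci + [other], g)
        assert groups == [[0, 1, 2]]
        assert all("duplicated" in l.tags for l in loci)
        assert "duplicated" not in other.tags


class TestChainIO:
    def test_round_trip(self, tmp_path, rng):
        alns = []
        t = 0
        for i in range(10):
            t += int(rng.integers(100, 5000))
            segs = []
            tt, qq = t, t + 17
            for _ in range(int(rng.integers(1, 4))):
                ln = int(rng.integers(100, 2000))
                segs.append((tt, qq, ln))
                tt += ln + int(rng.integers(1, 200))
                qq += ln + int(rng.integers(1, 200))
            alns.append(
                PairwiseAlignment("chr1", "h1", "+" if i % 2 else "-", segs,
                                  "human", 1_000_000, i + 1)
            )
            t = tt
        path = tmp_path / "a.chain"
        write_chain(alns, path)
        back = read_chain(path, "human")
        assert [(a.target_contig, a.strand, a.segments) for a in back] == [
            (a.target_contig, a.strand, a.segments) for a in alns
        ]
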