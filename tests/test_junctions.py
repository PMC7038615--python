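"""Junction-read collection, consensus building, and structure resolution,
including exact recovery of planted junction parameters."""

import pytest

from tdnascope.align import AlignmentRecord, SeedIndex, align_read
from tdnascope.detect import CandidateLocus
from tdnascope.junctions import (
    IntegrationRecord,
    JunctionConsensus,
    build_junction_consensus,
    collect_junction_reads,
    resolve_structure,
)
from tdnascope.simulate import (
    ANTISENSE,
    SENSE,
    IntegrationTruth,
    apply_integrations,
    make_cassette,
    make_host_genome,
    sanitize_integration,
)


def _rec(pos, cigar, seq, qname="r"):
    return AlignmentRecord(qname, "Chr01", pos, "+", cigar, seq=seq)


class TestCollect:
    def test_partition_by_clip_side(self):
        locus = CandidateLocus("Chr01", (4950, 5050), 5)
        reads = [
            _rec(4940, [("M", 60), ("S", 65)], "A" * 125, "left"),
            _rec(5000, [("S", 40), ("M", 85)], "C" * 125, "right"),
            _rec(4900, [("M", 125)], "G" * 125, "span"),
            _rec(4940, [("M", 60), ("S", 65)], "A" * 125, "dup"),  # duplicate
        ]
        left, right = collect_junction_reads(locus, reads)
        assert [r.qname for r in left] == ["left"]
        assert [r.qname for r in right] == ["right"]

    def test_small_clips_ignored(self):
        locus = CandidateLocus("Chr01", (4950, 5050), 5)
        reads = [_rec(4900, [("M", 120), ("S", 5)], "A" * 125)]
        left, right = collect_junction_reads(locus, reads)
        assert left == [] and right == []


class TestConsensus:
    def _clipped(self, n, clip="TTGACCGGTTACCAAGGT"):
        host = "ACGTAACCGGTTACGATCGA"
        return [
            _rec(5000 - len(host), [("M", len(host)), ("S", len(clip))], host + clip, f"r{i}")
            for i in range(n)
        ]

    def test_identical_reads_give_their_sequence(self):
        cons = build_junction_consensus(self._clipped(5), "left")
        assert cons is not None
        assert cons.clipped_seq == "TTGACCGGTTACCAAGGT"
        assert cons.host_breakpoint == 5000
        assert cons.n_reads == 5

    def test_single_read_unresolved(self):
        assert build_junction_consensus(self._clipped(1), "left") is None

    def test_majority_vote_tolerates_one_substitution(self):
        reads = self._clipped(4)
        seq = reads[0].seq
        reads[0].seq = seq[:25] + ("A" if seq[25] != "A" else "C") + seq[26:]
        cons = build_junction_consensus(reads, "left")
        assert cons.clipped_seq == "TTGACCGGTTACCAAGGT"

    def test_low_majority_near_breakpoint_unresolved(self):
        reads = self._clipped(4)
        for i in (0, 1):  # 2 of 4 disagree at clip column 2: majority 0.5 < 0.7
            seq = reads[i].seq
            j = 20 + 2
            reads[i].seq = seq[:j] + ("A" if seq[j] != "A" else "C") + seq[j + 1 :]
        assert build_junction_consensus(reads, "left") is None


@pytest.fixture(scope="module")
def planted():
    genome = make_host_genome(1, [20_000], 0.35, 41)
    cassette = make_cassette(42)
    return genome, cassette


def _resolve_planted(genome, cassette, truth, depth_reads=6):
    """Build junction consensi directly from error-free reads crossing the
    planted junctions, then resolve."""
    ref, edited_map = apply_integrations(genome, cassette, [truth])
    edited = edited_map["Chr01"]
    idx = SeedIndex(ref.chromosomes, 15)
    ds, de = truth.host_deletion
    insert_len = len(edited) - (len(ref.seq("Chr01")) - (de - ds))
    records = []
    for off in range(40, 40 + depth_reads * 7, 7):
        records += align_read(edited[ds - off : ds - off + 125], idx, qname=f"l{off}")
        right_end = ds + insert_len  # edited coordinate of the right junction
        records += align_read(edited[right_end + off - 125 : right_end + off], idx,
                              qname=f"r{off}")
    locus = CandidateLocus("Chr01", (ds - 200, de + 200), 5)
    lr, rr = collect_junction_reads(locus, [r for r in records if not r.is_secondary])
    left = build_junction_consensus(lr, "left")
    right = build_junction_consensus(rr, "right")
    return resolve_structure(left, right, ref, cassette, "Chr01"), ref


class TestResolve:
    def test_full_cassette_with_deletion_and_filler(self, planted):
        genome, cassette = planted
        truth = IntegrationTruth(
            "Chr01", (8000, 8035), filler_left="ACGT", filler_right="",
            cassette_segment=cassette.tdna_interval(),
        )
        genome2, truth = sanitize_integration(genome, cassette, truth)
        rec, _ = _resolve_planted(genome2, cassette, truth)
        assert rec.deletion_length == 35
        assert rec.filler_lengths == (4, 0)
        assert rec.completeness == "full"
        assert (rec.orientation_left, rec.orientation_right) == (SENSE, SENSE)

    def test_blunt_insertion(self, planted):
        genome, cassette = planted
        truth = IntegrationTruth(
            "Chr01", (9000, 9000), cassette_segment=cassette.tdna_interval()
        )
        genome2, truth = sanitize_integration(genome, cassette, truth)
        rec, _ = _resolve_planted(genome2, cassette, truth)
        assert rec.deletion_length == 0
        assert rec.filler_lengths == (0, 0)
        assert rec.completeness == "full"

    @pytest.mark.parametrize(
        "dlen,fl,fr,seg_kind,ol,or_,completeness",
        [
            (10, "", "ACGTACGTACG", "full", SENSE, SENSE, "full"),
            (8, "ACG", "ACGTACGTACGTACGTACGT", "half", SENSE, SENSE, "partial"),
            (3, "", "", "full", ANTISENSE, SENSE, "rearranged"),
            (12, "", "", "full", ANTISENSE, ANTISENSE, "full"),
        ],
    )
    def test_parameter_recovery_planted_events(
        self, planted, dlen, fl, fr, seg_kind, ol, or_, completeness
    ):
        """Deletion length, filler lengths, orientations and completeness are
        recovered exactly for planted events covered by clipped reads."""
        genome, cassette = planted
        tdna = cassette.tdna_interval()
        seg = tdna if seg_kind == "full" else (tdna[0], (tdna[0] + tdna[1]) // 2)
        truth = IntegrationTruth(
            "Chr01", (8000, 8000 + dlen), filler_left=fl, filler_right=fr,
            cassette_segment=seg, orientation_left=ol, orientation_right=or_,
        )
        genome2, truth = sanitize_integration(genome, cassette, truth)
        rec, _ = _resolve_planted(genome2, cassette, truth)
        assert rec.deletion_length == dlen
        assert rec.filler_lengths == (len(truth.filler_left), len(truth.filler_right))
        assert (rec.orientation_left, rec.orientation_right) == (ol, or_)
        assert rec.completeness == completeness

    def test_right_junction_only_partial(self, planted):
        """With only the right junction resolvable the event is partial and
        the left side stays unresolved (no deletion call possible)."""
        genome, cassette = planted
        right = JunctionConsensus(
            "right", 8000, cassette.sequence[150:230], 3
        )
        rec = resolve_structure(None, right, genome, cassette, "Chr01")
        assert rec.completeness == "partial"
        assert rec.orientation_left == "unresolved"
        assert rec.filler_left is None
        assert rec.host_deletion is None
        assert rec.cassette_breakpoint_right == 230

    def test_both_unresolved(self, planted):
        genome, cassette = planted
        rec = resolve_structure(None, None, genome, cassette, "Chr01")
        assert rec.completeness == "unresolved"
        assert rec.host_deletion is None

    def test_genic_annotation(self, planted):
        genome, cassette = planted
        truth = IntegrationTruth(
            "Chr01", (8000, 8010), cassette_segment=cassette.tdna_interval()
        )
        genome2, truth = sanitize_integration(genome, cassette, truth)
        ref, edited_map = apply_integrations(genome2, cassette, [truth])
        left = JunctionConsensus("left", 8000, edited_map["Chr01"][8000:8080], 3)
        right_seq = edited_map["Chr01"]
        ins_len = len(right_seq) - (len(ref.seq("Chr01")) - 10)
        right = JunctionConsensus("right", 8010, right_seq[8000 + ins_len - 80 : 8000 + ins_len], 3)
        in_gene = resolve_structure(left, right, ref, cassette, "Chr01",
                                    annotation=[("Chr01", 7000, 9000)])
        out_gene = resolve_structure(left, right, ref, cassette, "Chr01",
                                     annotation=[("Chr01", 1000, 2000)])
        no_ann = resolve_structure(left, right, ref, cassette, "Chr01")
        assert in_gene.genic == "yes"
        assert out_gene.genic == "no"
        assert no_ann.genic == "unknown"

    def test_deletion_invariant_to_read_order(self, planted):
        genome, cassette = planted
        truth = IntegrationTruth(
            "Chr01", (8000, 8020), cassette_segment=cassette.tdna_interval()
        )
        genome2, truth = sanitize_integration(genome, cassette, truth)
        ref, edited_map = apply_integrations(genome2, cassette, [truth])
        edited = edited_map["Chr01"]
        idx = SeedIndex(ref.chromosomes, 15)
        reads = [edited[8000 - off : 8000 - off + 125] for off in (40, 55, 70)]
        ins_len = len(edited) - (len(ref.seq("Chr01")) - 20)
        rend = 8000 + ins_len
        reads += [edited[rend + off - 125 : rend + off] for off in (40, 55, 70)]
        results = []
        for ordering in (reads, reads[::-1]):
            records = [align_read(s, idx, qname=f"x{i}")[0] for i, s in enumerate(ordering)]
            locus = CandidateLocus("Chr01", (7800, 8220), 5)
            lr, rr = collect_junction_reads(locus, records)
            rec = resolve_structure(
                build_junction_consensus(lr, "left"),
                build_junction_consensus(rr, "right"),
                ref, cassette, "Chr01",
            )
            results.append(rec.deletion_length)
        assert results[0] == results[1] == 20
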