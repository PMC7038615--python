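"""Junction reconstruction at candidate integration loci.

Reads that cross an integration junction align to the host with one soft-
clipped end; the clipped bases are insert-side sequence. Per side of a locus
the clipped reads are collapsed to a clip-anchored majority consensus, and
the two consensus sequences are decomposed against host and cassette to
recover the full integration structure: host deletion, filler DNA, cassette
breakpoints and orientations, and completeness.

Conventions: internally 0-based half-open; the left junction's host
breakpoint is the first host position no longer part of the left flank, the
right junction's is the first host position of the right flank, so the host
deletion is exactly ``[left_bp, right_bp)``. Cassette breakpoints are the
cassette coordinates of the junction-adjacent terminus. Breakpoint bases
shared by host and cassette (microhomology) are assigned to the host side
with leftmost placement, since single coordinates must be reported despite
the inherent ambiguity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import AlignmentRecord
from .detect import CandidateLocus
from .dna import revcomp
from .simulate import ANTISENSE, SENSE, CassetteModel, HostGenome

UNRESOLVED = "unresolved"


@dataclass
class JunctionConsensus:
    side: str  # 'left' or 'right'
    host_breakpoint: int
    clipped_seq: str  # insert-side bases, read left-to-right
    n_reads: int


@dataclass
class IntegrationRecord:
    """Resolved structure of one integration locus (one report row)."""

    chrom: str
    host_deletion: tuple[int, int] | None
    filler_left: str | None  # None = side unresolved, '' = blunt
    filler_right: str | None
    cassette_breakpoint_left: int | None
    cassette_breakpoint_right: int | None
    orientation_left: str = UNRESOLVED
    orientation_right: str = UNRESOLVED
    completeness: str = UNRESOLVED
    genic: str = "unknown"  # 'yes' | 'no' | 'unknown'
    support: dict = field(default_factory=dict)

    @property
    def deletion_length(self) -> int | None:
        if self.host_deletion is None:
            return None
        return self.host_deletion[1] - self.host_deletion[0]

    @property
    def filler_lengths(self) -> tuple[int | None, int | None]:
        return (
            None if self.filler_left is None else len(self.filler_left),
            None if self.filler_right is None else len(self.filler_right),
        )


def collect_junction_reads(
    locus: CandidateLocus,
    host_records: list[AlignmentRecord],
    min_clip: int = 10,
    pad: int = 50,
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Clipped reads at a locus, partitioned by junction side.

    Left-side reads carry a 3' soft clip with the clip boundary (their
    reference end) inside the locus interval; right-side reads mirror this
    with a 5' clip at their reference start. Duplicates (identical start,
    CIGAR and sequence) are collapsed.
    """
    lo = locus.interval[0] - pad
    hi = locus.interval[1] + pad
    left, right, seen = [], [], set()
    for rec in host_records:
        if not rec.is_mapped or rec.is_secondary or rec.ref_name != locus.chrom:
            continue
        key = (rec.pos, rec.cigar_string(), rec.seq)
        if key in seen:
            continue
        seen.add(key)
        if rec.clip_right() >= min_clip and lo <= rec.end <= hi:
            left.append(rec)
        if rec.clip_left() >= min_clip and lo <= rec.pos <= hi:
            right.append(rec)
    return left, right


def build_junction_consensus(
    clipped: list[AlignmentRecord],
    side: str,
    min_clip_reads: int = 2,
    majority: float = 0.7,
    check_window: int = 30,
) -> JunctionConsensus | None:
    """Clip-anchored majority-vote consensus of the insert-side bases.

    The host breakpoint is the modal clip boundary; reads with that boundary
    vote per column. Returns None (unresolved) when fewer than
    ``min_clip_reads`` agree on a boundary or the majority fraction drops
    below ``majority`` at any column within ``check_window`` bp of the
    breakpoint.
    """
    if len(clipped) < min_clip_reads:
        return None
    if side == "left":
        boundaries = [r.end for r in clipped]
    else:
        boundaries = [r.pos for r in clipped]
    boundary, _ = Counter(boundaries).most_common(1)[0]
    voters = [r for r, b in zip(clipped, boundaries) if b == boundary]
    if len(voters) < min_clip_reads:
        return None
    if side == "left":
        clips = [r.seq[len(r.seq) - r.clip_right() :] for r in voters]
    else:
        # right-side clips end at the boundary: right-align them
        clips = [r.seq[: r.clip_left()][::-1] for r in voters]
    length = max(len(c) for c in clips)
    cols = []
    for i in range(length):
        votes = Counter(c[i] for c in clips if i < len(c))
        base, n = votes.most_common(1)[0]
        frac = n / sum(votes.values())
        if i < check_window and frac < majority:
            return None
        cols.append(base)
    seq = "".join(cols)
    if side == "right":
        seq = seq[::-1]
    return JunctionConsensus(side, boundary, seq, len(voters))


def _longest_cassette_suffix(seq: str, fwd: str, rc: str) -> int:
    """Longest suffix of ``seq`` occurring in the cassette (either strand).
    Occurrence is monotone in suffix length, so binary search applies."""
    lo, hi = 0, len(seq)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        sub = seq[len(seq) - mid :]
        if sub in fwd or sub in rc:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _longest_cassette_prefix(seq: str, fwd: str, rc: str) -> int:
    lo, hi = 0, len(seq)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        sub = seq[:mid]
        if sub in fwd or sub in rc:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _anchor(
    cons: JunctionConsensus, cassette: CassetteModel, min_anchor: int
) -> tuple[str | None, int | None, int | None]:
    """Decompose a junction consensus into (filler_len, cassette breakpoint,
    orientation). Returns (None, None, None) when no adequate cassette anchor
    exists. Forward-strand matches win ties; among positions the leftmost is
    taken (deterministic)."""
    fwd = cassette.sequence
    rc = revcomp(fwd)
    n = len(fwd)
    if cons.side == "left":
        L = _longest_cassette_suffix(cons.clipped_seq, fwd, rc)
        if L < min_anchor:
            return None, None, None
        anchor = cons.clipped_seq[len(cons.clipped_seq) - L :]
        filler_len = len(cons.clipped_seq) - L
        p = fwd.find(anchor)
        if p >= 0:
            return cons.clipped_seq[:filler_len], p, SENSE
        p = rc.find(anchor)
        return cons.clipped_seq[:filler_len], n - p, ANTISENSE
    L = _longest_cassette_prefix(cons.clipped_seq, fwd, rc)
    if L < min_anchor:
        return None, None, None
    anchor = cons.clipped_seq[:L]
    filler = cons.clipped_seq[L:]
    p = fwd.find(anchor)
    if p >= 0:
        return filler, p + L, SENSE
    p = rc.find(anchor)
    return filler, n - (p + L), ANTISENSE


def resolve_structure(
    left: JunctionConsensus | None,
    right: JunctionConsensus | None,
    genome: HostGenome,
    cassette: CassetteModel,
    chrom: str,
    annotation: list[tuple[str, int, int]] | None = None,
    min_anchor: int = 12,
    border_tolerance: int = 5,
) -> IntegrationRecord:
    """Resolve the full integration structure from junction consensi.

    Completeness: ``full`` when both junctions share an orientation and the
    cassette breakpoints sit at the right-/left-border boundaries (within
    ``border_tolerance``), ``partial`` when they agree in orientation but
    span less, ``rearranged`` when the orientations differ, ``unresolved``
    when neither junction is resolved.
    """
    fl = fr = None
    bp_l = bp_r = None
    ori_l = ori_r = UNRESOLVED
    if left is not None:
        fl, bp_l, o = _anchor(left, cassette, min_anchor)
        if o is not None:
            ori_l = o
    if right is not None:
        fr, bp_r, o = _anchor(right, cassette, min_anchor)
        if o is not None:
            ori_r = o

    deletion = None
    if left is not None and right is not None:
        a, b = left.host_breakpoint, right.host_breakpoint
        if b < a:  # microhomology overlap: host-side, leftmost assignment
            b = a
        deletion = (a, b)

    resolved_l = ori_l != UNRESOLVED
    resolved_r = ori_r != UNRESOLVED
    if not resolved_l and not resolved_r:
        completeness = UNRESOLVED
        deletion = None
    elif resolved_l != resolved_r:
        completeness = "partial"
    elif ori_l != ori_r:
        completeness = "rearranged"
    else:
        t_start, t_end = cassette.tdna_interval()
        if ori_l == SENSE:
            lo, hi = bp_l, bp_r
        else:
            lo, hi = bp_r, bp_l
        if abs(lo - t_start) <= border_tolerance and abs(hi - t_end) <= border_tolerance:
            completeness = "full"
        else:
            completeness = "partial"

    genic = "unknown"
    if annotation is not None and deletion is not None:
        genic = "no"
        for c, a, b in annotation:
            if c == chrom and a < deletion[1] + 1 and deletion[0] - 1 < b:
                genic = "yes"
                break

    return IntegrationRecord(
        chrom=chrom,
        host_deletion=deletion,
        filler_left=fl,
        filler_right=fr,
        cassette_breakpoint_left=bp_l,
        cassette_breakpoint_right=bp_r,
        orientation_left=ori_l,
        orientation_right=ori_r,
        completeness=completeness,
        genic=genic,
        support={
            "left_reads": 0 if left is None else left.n_reads,
            "right_reads": 0 if right is None else right.n_reads,
        },
    )


def resolve_locus(
    locus: CandidateLocus,
    host_records: list[AlignmentRecord],
    genome: HostGenome,
    cassette: CassetteModel,
    annotation: list[tuple[str, int, int]] | None = None,
    min_clip: int = 10,
    min_clip_reads: int = 2,
) -> IntegrationRecord:
    """Convenience: collect clipped reads, build both consensi, resolve."""
    left_reads, right_reads = collect_junction_reads(locus, host_records, min_clip)
    left = build_junction_consensus(left_reads, "left", min_clip_reads)
    right = build_junction_consensus(right_reads, "right", min_clip_reads)
    rec = resolve_structure(left, right, genome, cassette, locus.chrom, annotation)
    rec.support["n_orphan_mates"] = locus.n_orphan_mates
    return rec
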