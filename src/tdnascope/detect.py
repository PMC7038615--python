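"""Transgene detection: partition read pairs against the cassette reference,
place orphan mates on the host genome, cluster placements into candidate
integration loci, and call cassette presence/absence from coverage.

The central trick mirrors the junction-read strategy used for T-DNA locus
discovery: a fragment that straddles an integration junction yields a pair in
which one mate aligns to the cassette and the other (the "orphan" mate) is
pure host sequence adjacent to the insertion; mapping orphans back to the
host and clustering their placements marks candidate loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignerParams, AlignmentRecord, SeedIndex, align_read, coverage
from .seqio import FastqRecord
from .simulate import CassetteModel

BOTH = "both_on_cassette"
ONE = "one_mate_on_cassette"
NEITHER = "neither"


@dataclass
class PairClass:
    pair_id: str
    category: str
    cassette_records: list[AlignmentRecord] = field(default_factory=list)
    orphan_mate: FastqRecord | None = None

    def __post_init__(self) -> None:
        assert (self.orphan_mate is not None) == (self.category == ONE)


@dataclass
class OrphanPlacement:
    pair_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: int
    #: 'left' if the orphan lies left of the putative insertion (maps '+',
    #: its cassette mate lies rightward), else 'right'
    side: str = "left"


@dataclass
class CandidateLocus:
    chrom: str
    interval: tuple[int, int]
    n_orphan_mates: int
    n_clipped_reads: int = 0
    side_evidence: dict = field(default_factory=dict)
    status: str = "candidate"

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.interval[0]}-{self.interval[1]}"


@dataclass
class PresenceCall:
    sample_id: str
    n_mapped_reads: int
    mean_coverage: float
    breadth: float
    verdict: str  # integrated | trace | absent


def classify_pairs(
    pairs: list[tuple[FastqRecord, FastqRecord]],
    cassette: CassetteModel,
    params: AlignerParams | None = None,
    cassette_index: SeedIndex | None = None,
) -> list[PairClass]:
    """Assign each pair a category by mapping both mates to the cassette
    reference (which includes its backbone flanks). Orphan mates are emitted
    verbatim for host placement."""
    if len(cassette) == 0:
        raise ValueError("empty cassette")
    params = params or AlignerParams()
    idx = cassette_index or SeedIndex([("cassette", cassette.sequence)], params.k)
    out = []
    for r1, r2 in pairs:
        recs1 = align_read(r1[1], idx, params, qname=r1[0], qual=r1[2])
        recs2 = align_read(r2[1], idx, params, qname=r2[0], qual=r2[2])
        m1, m2 = bool(recs1), bool(recs2)
        if m1 and m2:
            out.append(PairClass(r1[0], BOTH, [recs1[0], recs2[0]]))
        elif m1 or m2:
            cass = recs1[0] if m1 else recs2[0]
            orphan = r2 if m1 else r1
            out.append(PairClass(r1[0], ONE, [cass], orphan_mate=orphan))
        else:
            out.append(PairClass(r1[0], NEITHER))
    return out


def locate_orphans(
    pair_classes: list[PairClass],
    host_index: SeedIndex,
    params: AlignerParams | None = None,
) -> tuple[list[OrphanPlacement], int]:
    """Place orphan mates on the host genome in local (clipping-permissive)
    mode. Returns placements and the count of unplaceable orphans.

    Side inference: an orphan placed on the forward strand has its (cassette)
    mate to its right, so it is left-side evidence for the insertion; mirror
    for the reverse strand.
    """
    params = params or AlignerParams()
    placements = []
    unplaced = 0
    for pc in pair_classes:
        if pc.category != ONE:
            continue
        name, seq, qual = pc.orphan_mate
        recs = align_read(seq, host_index, params, qname=name, qual=qual)
        if not recs:
            unplaced += 1
            continue
        r = recs[0]
        placements.append(
            OrphanPlacement(
                pair_id=pc.pair_id,
                chrom=r.ref_name,
                start=r.pos,
                end=r.end,
                strand=r.strand,
                score=r.score,
                side="left" if r.strand == "+" else "right",
            )
        )
    return placements, unplaced


def cluster_orphans(
    placements: list[OrphanPlacement],
    frag_mean: float = 400.0,
    frag_sd: float = 60.0,
    min_support: int = 2,
) -> list[CandidateLocus]:
    """Single-linkage clustering of orphan placements into candidate loci.

    The linkage window is ``frag_mean + 3*frag_sd`` (an orphan can lie at
    most about a fragment length from the junction). Loci supported by fewer
    than ``min_support`` orphans are kept but marked rejected; output order
    is deterministic (chrom, start).
    """
    window = frag_mean + 3 * frag_sd
    placed = sorted(placements, key=lambda p: (p.chrom, p.start))
    loci: list[CandidateLocus] = []
    cluster: list[OrphanPlacement] = []

    def _flush():
        if not cluster:
            return
        n = len(cluster)
        sides = {
            "left": sum(p.side == "left" for p in cluster),
            "right": sum(p.side == "right" for p in cluster),
        }
        loci.append(
            CandidateLocus(
                chrom=cluster[0].chrom,
                interval=(min(p.start for p in cluster), max(p.end for p in cluster)),
                n_orphan_mates=n,
                side_evidence=sides,
                status="called" if n >= min_support else "rejected",
            )
        )

    for p in placed:
        if cluster and (p.chrom != cluster[-1].chrom or p.start - cluster[-1].start > window):
            _flush()
            cluster = []
        cluster.append(p)
    _flush()
    return loci


def cassette_presence(
    cassette_records: list[AlignmentRecord],
    cassette: CassetteModel,
    genome_mean_cov: float,
    sample_id: str = "sample",
    breadth_threshold: float = 0.5,
    depth_fraction: float = 0.2,
) -> PresenceCall:
    """Call transgene presence from read coverage over the cassette.

    Only unmasked cassette positions count: backbone flanks (not expected to
    transfer in border-to-border integration) and host-homologous components
    (e.g. a native-promoter segment that recruits reads from the host copy)
    are excluded from n_mapped_reads, mean coverage and breadth. Verdict:
    ``integrated`` if breadth >= 0.5 and mean >= 0.2 x genome coverage;
    ``trace`` if any unmasked reads mapped but thresholds not met (the
    handful-of-reads signature of library cross-contamination); else
    ``absent``.
    """
    if genome_mean_cov <= 0:
        raise ValueError("genome_mean_cov must be positive")
    intervals = cassette.unmasked_intervals()
    mask = np.zeros(len(cassette), dtype=bool)
    for a, b in intervals:
        mask[a:b] = True
    primary = [r for r in cassette_records if r.is_mapped and not r.is_secondary]
    cov = coverage(primary, "cassette", len(cassette))
    n_mapped = sum(1 for r in primary if mask[r.pos : r.end].any())
    unmasked_cov = cov[mask]
    mean_cov = float(unmasked_cov.mean()) if unmasked_cov.size else 0.0
    breadth = float((unmasked_cov >= 1).mean()) if unmasked_cov.size else 0.0
    if breadth >= breadth_threshold and mean_cov >= depth_fraction * genome_mean_cov:
        verdict = "integrated"
    elif n_mapped > 0:
        verdict = "trace"
    else:
        verdict = "absent"
    return PresenceCall(sample_id, n_mapped, mean_cov, breadth, verdict)
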