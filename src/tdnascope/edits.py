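"""CRISPR target-site scanning and indel allele quantification.

The scanner locates protospacer+NGG matches on both strands with up to a
given number of mismatches (catching paralogous off-targets, reported by
their mismatch distance from the PAM, PAM-proximal base = 1). The
quantifier assigns every window-spanning read an allele by its net indel
within the window, reports read counts and proportions, classifies alleles
(frameshift / in-frame), and flags transgene-integration-at-target (TGI)
events where an integration's deletion overlaps a target site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentRecord, SeedIndex
from .dna import encode, revcomp
from .simulate import HostGenome

WT = "WT"
TGI = "TGI"


@dataclass
class TargetSite:
    site_id: str
    chrom: str
    strand: str
    start: int  # forward-strand start of the protospacer interval
    protospacer: str  # as on the site strand (20 nt, PAM-adjacent at 3')
    pam: str
    cut: int  # forward-strand coordinate of the blunt cut (between-base)
    mismatches: list[int] = field(default_factory=list)  # distances from PAM

    def full_interval(self) -> tuple[int, int]:
        """Forward-strand interval of protospacer + PAM."""
        if self.strand == "+":
            return self.start, self.start + 23
        return self.start - 3, self.start + 20


@dataclass
class AlleleProfile:
    site_id: str
    alleles: list[tuple[str, int | None, int, float]]  # (descriptor, net, count, prop)
    n_reads: int
    no_coverage: bool = False

    def proportion(self, descriptor: str) -> float:
        for d, _, _, p in self.alleles:
            if d == descriptor:
                return p
        return 0.0

    def dominant_non_wt(self) -> tuple[str, int | None] | None:
        cands = [(c, d, n) for d, n, c, _ in self.alleles if d not in (WT, "other", TGI)]
        if not cands:
            return None
        c, d, n = max(cands, key=lambda x: (x[0], x[1]))
        return d, n


def _scan_strand(g: np.ndarray, proto: np.ndarray, max_mm: int) -> np.ndarray:
    """Positions i where g[i:i+20] matches proto with <= max_mm mismatches
    and g[i+21], g[i+22] are both G (NGG PAM)."""
    n = len(g) - 23 + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    mm = np.zeros(n, dtype=np.int16)
    for o in range(20):
        mm += g[o : o + n] != proto[o]
    pam = (g[21 : 21 + n] == 2) & (g[22 : 22 + n] == 2)
    return np.flatnonzero((mm <= max_mm) & pam)


def scan_target_sites(
    genome: HostGenome, protospacer: str, max_mm: int = 2, site_prefix: str = "site"
) -> list[TargetSite]:
    """Scan both strands of every chromosome for [protospacer<=max_mm mm][NGG].

    The cut is placed bluntly between bases 3 and 4 upstream of the PAM
    (SpCas9 model). Mismatch positions are distances from the PAM
    (PAM-proximal protospacer base = 1). Output order is deterministic:
    (chrom, forward start, strand).
    """
    if max_mm > 4:
        raise ValueError("max_mm must be <= 4")
    if len(protospacer) != 20 or any(b not in "ACGT" for b in protospacer):
        raise ValueError("protospacer must be 20 nt over ACGT")
    proto = encode(protospacer)
    hits: list[TargetSite] = []
    for chrom, seq in genome.chromosomes:
        g = encode(seq)
        for i in _scan_strand(g, proto, max_mm):
            i = int(i)
            obs = seq[i : i + 20]
            mism = [20 - k for k in range(20) if obs[k] != protospacer[k]]
            hits.append(
                TargetSite(
                    site_id="",
                    chrom=chrom,
                    strand="+",
                    start=i,
                    protospacer=obs,
                    pam=seq[i + 20 : i + 23],
                    cut=i + 17,
                    mismatches=sorted(mism),
                )
            )
        g_rc = encode(revcomp(seq))
        n = len(seq)
        for j in _scan_strand(g_rc, proto, max_mm):
            j = int(j)
            obs = revcomp(seq)[j : j + 20]
            mism = [20 - k for k in range(20) if obs[k] != protospacer[k]]
            fwd_start = n - (j + 20)  # forward coord of the protospacer interval
            hits.append(
                TargetSite(
                    site_id="",
                    chrom=chrom,
                    strand="-",
                    start=fwd_start,
                    protospacer=obs,
                    pam=revcomp(seq)[j + 20 : j + 23],
                    cut=fwd_start + 3,
                    mismatches=sorted(mism),
                )
            )
    hits.sort(key=lambda s: (s.chrom, s.start, s.strand))
    for i, s in enumerate(hits):
        s.site_id = f"{site_prefix}{i + 1}"
    return hits


def _net_indel_in_window(rec: AlignmentRecord, lo: int, hi: int) -> int:
    """Net inserted-minus-deleted bases whose reference anchor lies in
    [lo, hi), walked from the CIGAR."""
    pos = rec.pos
    net = 0
    for op, n in rec.cigar:
        if op == "M":
            pos += n
        elif op == "D":
            ov = min(pos + n, hi) - max(pos, lo)
            if ov > 0:
                net -= ov
            pos += n
        elif op == "I":
            if lo <= pos < hi:
                net += n
    return net


def descriptor_for_net(net: int) -> str:
    if net == 0:
        return WT
    return f"d{-net}bp" if net < 0 else f"+{net}bp"


def quantify_alleles(
    host_records: list[AlignmentRecord],
    site: TargetSite,
    window: int = 20,
    min_reads: int = 2,
    min_clip: int = 10,
    cassette_index: SeedIndex | None = None,
) -> AlleleProfile:
    """Allele profile at a target site from spanning reads.

    A read counts toward an indel/WT allele only if its aligned span covers
    the whole window (cut +/- ``window``), preventing length
    misclassification at the edges; substitution-only differences count as
    WT. Reads soft-clipped >= ``min_clip`` with the clip boundary inside the
    window are evidence of transgene integration at the site and are counted
    as a distinct TGI allele (if a cassette index is supplied, the clipped
    bases must place on the cassette). Alleles below ``min_reads`` are merged
    into 'other'; proportions are over all counted reads.
    """
    lo, hi = site.cut - window, site.cut + window
    counts: dict[str, int] = {}
    nets: dict[str, int | None] = {}
    for rec in host_records:
        if not rec.is_mapped or rec.is_secondary or rec.ref_name != site.chrom:
            continue
        clip_in_window = (rec.clip_right() >= min_clip and lo <= rec.end <= hi) or (
            rec.clip_left() >= min_clip and lo <= rec.pos <= hi
        )
        if clip_in_window:
            if cassette_index is not None:
                clipped = (
                    rec.seq[len(rec.seq) - rec.clip_right() :]
                    if rec.clip_right() >= min_clip and lo <= rec.end <= hi
                    else rec.seq[: rec.clip_left()]
                )
                k = cassette_index.k
                on_cassette = any(
                    cassette_index.lookup(clipped[i : i + k])
                    for i in range(0, max(1, len(clipped) - k + 1), k)
                )
                if not on_cassette:
                    continue
            counts[TGI] = counts.get(TGI, 0) + 1
            nets[TGI] = None
            continue
        # spanning: the aligned span covers the whole window (clip boundaries
        # then necessarily fall outside it)
        if rec.pos <= lo and rec.end >= hi:
            net = _net_indel_in_window(rec, lo, hi)
            d = descriptor_for_net(net)
            counts[d] = counts.get(d, 0) + 1
            nets[d] = net
    total = sum(counts.values())
    if total == 0:
        return AlleleProfile(site.site_id, [], 0, no_coverage=True)
    merged: dict[str, int] = {}
    for d, c in counts.items():
        if c < min_reads and d != WT:
            merged["other"] = merged.get("other", 0) + c
            nets["other"] = None
        else:
            merged[d] = c
    alleles = [
        (d, nets.get(d), c, c / total)
        for d, c in sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return AlleleProfile(site.site_id, alleles, total)


def classify_edit(descriptor: str, net: int | None = None) -> str:
    """wild_type / frameshift / in_frame / TGI from an allele descriptor."""
    if descriptor == TGI:
        return TGI
    if net is None:
        if descriptor == WT:
            return "wild_type"
        if descriptor.startswith("d") and descriptor.endswith("bp"):
            net = -int(descriptor[1:-2])
        elif descriptor.startswith("+") and descriptor.endswith("bp"):
            net = int(descriptor[1:-2])
        else:
            raise ValueError(f"cannot parse allele descriptor {descriptor!r}")
    if net == 0:
        return "wild_type"
    return "frameshift" if net % 3 != 0 else "in_frame"


def flag_TGI(
    sites: list[TargetSite],
    integrations,
    slop: int = 10,
) -> dict[str, bool]:
    """Per-site flag: does any integration's host deletion (padded by
    ``slop``) overlap the protospacer+PAM interval?"""
    flags = {}
    for site in sites:
        a, b = site.full_interval()
        hit = False
        for rec in integrations:
            if rec.host_deletion is None or rec.chrom != site.chrom:
                continue
            da, db = rec.host_deletion
            if da - slop < b and a < db + slop:
                hit = True
                break
        flags[site.site_id] = hit
    return flags
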