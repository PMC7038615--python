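"""Seed-and-extend local read aligner and SAM text I/O.

The aligner is a contract-level stand-in for a production short-read mapper,
adequate for low-divergence synthetic data: exact k-mer seeds are chained on
diagonals and extended with a banded affine-gap Smith-Waterman (numba-JIT
kernel). Unaligned read termini become soft clips; ties are broken
deterministically (lowest reference name, then coordinate, then forward
strand) and equal-best placements are emitted as secondary records.

Default scoring: match +1, mismatch -6 (the mismatch penalty used for the
short-read mapping this mirrors), gap open -5, gap extend -2, band 100.

SAM support is text-only (the 11 mandatory columns plus an ``AS`` score tag);
``parse_sam``/``write_sam`` round-trip bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .dna import encode, revcomp

CIGAR_OPS = "MIDS"  # 0=M 1=I 2=D 3=S

DEFAULT_SCORING = (1, 6, 5, 2)  # match, mismatch penalty, gap open, gap extend


@dataclass
class AlignmentRecord:
    """One read alignment (SAM semantics, 0-based internally)."""

    qname: str
    ref_name: str | None
    pos: int  # 0-based leftmost reference position (-1 if unmapped)
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    score: int = 0
    mapq: int = 60
    seq: str = "*"  # stored in alignment orientation, as in SAM
    qual: str = "*"
    is_secondary: bool = False
    is_paired: bool = False
    is_read1: bool = True
    is_proper: bool = False
    mate_ref: str | None = None
    mate_pos: int = -1
    mate_strand: str = "+"
    mate_unmapped: bool = False
    tlen: int = 0

    @property
    def is_mapped(self) -> bool:
        return self.ref_name is not None

    def read_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.pos + self.ref_span()

    def clip_left(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    def clip_right(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{n}{op}" for op, n in self.cigar)

    # -- SAM serialisation --------------------------------------------------

    def flag(self) -> int:
        f = 0
        if self.is_paired:
            f |= 0x1
            if self.is_proper:
                f |= 0x2
            if self.mate_unmapped:
                f |= 0x8
            if self.mate_strand == "-":
                f |= 0x20
            f |= 0x40 if self.is_read1 else 0x80
        if not self.is_mapped:
            f |= 0x4
        if self.strand == "-":
            f |= 0x10
        if self.is_secondary:
            f |= 0x100
        return f

    def to_sam(self) -> str:
        rname = self.ref_name if self.is_mapped else "*"
        if self.mate_ref is None:
            rnext = "*"
        elif self.mate_ref == self.ref_name and self.is_mapped:
            rnext = "="
        else:
            rnext = self.mate_ref
        fields = [
            self.qname,
            str(self.flag()),
            rname,
            str(self.pos + 1 if self.is_mapped else 0),
            str(self.mapq if self.is_mapped else 0),
            self.cigar_string() if self.is_mapped else "*",
            rnext,
            str(self.mate_pos + 1 if self.mate_pos >= 0 else 0),
            str(self.tlen),
            self.seq,
            self.qual,
        ]
        if self.is_mapped:
            fields.append(f"AS:i:{self.score}")
        return "\t".join(fields)

    @classmethod
    def from_sam(cls, line: str) -> "AlignmentRecord":
        f = line.rstrip("\n").split("\t")
        flag = int(f[1])
        mapped = not flag & 0x4
        cigar: list[tuple[str, int]] = []
        if f[5] != "*":
            num = ""
            for ch in f[5]:
                if ch.isdigit():
                    num += ch
                else:
                    cigar.append((ch, int(num)))
                    num = ""
        score = 0
        for tag in f[11:]:
            if tag.startswith("AS:i:"):
                score = int(tag[5:])
        mate_ref = None
        if f[6] != "*":
            mate_ref = f[2] if f[6] == "=" else f[6]
        return cls(
            qname=f[0],
            ref_name=f[2] if mapped else None,
            pos=int(f[3]) - 1,
            strand="-" if flag & 0x10 else "+",
            cigar=cigar,
            score=score,
            mapq=int(f[4]),
            seq=f[9],
            qual=f[10],
            is_secondary=bool(flag & 0x100),
            is_paired=bool(flag & 0x1),
            is_read1=not flag & 0x80,
            is_proper=bool(flag & 0x2),
            mate_ref=mate_ref,
            mate_pos=int(f[7]) - 1,
            mate_strand="-" if flag & 0x20 else "+",
            mate_unmapped=bool(flag & 0x8),
            tlen=int(f[8]),
        )


def sam_header(references: Sequence[tuple[str, int]]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in references:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    return "\n".join(lines) + "\n"


def write_sam(path, references: Sequence[tuple[str, int]], records: Iterable[AlignmentRecord]):
    with open(path, "wt") as fh:
        fh.write(sam_header(references))
        for rec in records:
            fh.write(rec.to_sam() + "\n")


def parse_sam(path) -> tuple[list[tuple[str, int]], list[AlignmentRecord]]:
    refs: list[tuple[str, int]] = []
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    d = dict(t.split(":", 1) for t in line.rstrip().split("\t")[1:])
                    refs.append((d["SN"], int(d["LN"])))
                continue
            records.append(AlignmentRecord.from_sam(line))
    return refs, records


# ---------------------------------------------------------------------------
# seed index
# ---------------------------------------------------------------------------


class SeedIndex:
    """Exact k-mer position index over a set of reference sequences.

    k-mers containing N are never indexed; a reference with more than
    ``max_n_fraction`` non-ACGT bases triggers a warning (via ``warnings``).
    """

    def __init__(self, references: Sequence[tuple[str, str]], k: int = 15):
        if not 11 <= k <= 31:
            raise ValueError("k must be in [11, 31]")
        self.k = k
        self.names = [n for n, _ in references]
        self.seqs = [s.upper() for _, s in references]
        self.lengths = [len(s) for s in self.seqs]
        self._index: dict[str, list[tuple[int, int]]] = {}
        for ri, seq in enumerate(self.seqs):
            n_frac = (len(seq) - sum(seq.count(b) for b in "ACGT")) / max(len(seq), 1)
            if n_frac > 0.1:
                import warnings

                warnings.warn(f"reference {self.names[ri]} is {n_frac:.0%} non-ACGT")
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((ri, i))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self._index.get(kmer, [])

    def n_positions(self) -> int:
        return sum(len(v) for v in self._index.values())

    def references(self) -> list[tuple[str, int]]:
        return list(zip(self.names, self.lengths))


# ---------------------------------------------------------------------------
# affine-gap local alignment kernel
# ---------------------------------------------------------------------------

NEG = -(10**8)


@njit(cache=True)
def _sw_kernel(read, ref, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    n, m = read.shape[0], ref.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i, j - 1] - gap_ext
            h = H[i, j - 1] - gap_open - gap_ext
            E[i, j] = e if e > h else h
            f = F[i - 1, j] - gap_ext
            h = H[i - 1, j] - gap_open - gap_ext
            F[i, j] = f if f > h else h
            s = match if read[i - 1] == ref[j - 1] else -mismatch
            v = H[i - 1, j - 1] + s
            if E[i, j] > v:
                v = E[i, j]
            if F[i, j] > v:
                v = F[i, j]
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best, bi, bj = v, i, j
    # traceback
    ops = np.empty(2 * (n + m), np.uint8)
    lens = np.empty(2 * (n + m), np.int32)
    k = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=E(D), 2=F(I)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            s = match if read[i - 1] == ref[j - 1] else -mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                if k > 0 and ops[k - 1] == 0:
                    lens[k - 1] += 1
                else:
                    ops[k] = 0
                    lens[k] = 1
                    k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:  # deletion from read view: consumes ref
            if k > 0 and ops[k - 1] == 2:
                lens[k - 1] += 1
            else:
                ops[k] = 2
                lens[k] = 1
                k += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_ext:
                state = 0
            j -= 1
        else:  # insertion: consumes read
            if k > 0 and ops[k - 1] == 1:
                lens[k - 1] += 1
            else:
                ops[k] = 1
                lens[k] = 1
                k += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_ext:
                state = 0
            i -= 1
    return best, i, bi, j, bj, ops[:k][::-1].copy(), lens[:k][::-1].copy()


def smith_waterman(
    read: str, ref: str, scoring: tuple[int, int, int, int] = DEFAULT_SCORING
) -> tuple[int, tuple[int, int], tuple[int, int], list[tuple[str, int]]]:
    """Full local affine-gap alignment of ``read`` against ``ref``.

    Returns (score, (read_start, read_end), (ref_start, ref_end), cigar)
    where the cigar covers only the aligned core (no clips). Score 0 means
    no positive-scoring local alignment exists.
    """
    match, mismatch, gap_open, gap_ext = scoring
    score, ri, re_, rj, rje, ops, lens = _sw_kernel(
        encode(read), encode(ref), match, mismatch, gap_open, gap_ext
    )
    cigar = [(CIGAR_OPS[o], int(l)) for o, l in zip(ops, lens)]
    return int(score), (int(ri), int(re_)), (int(rj), int(rje)), cigar


# ---------------------------------------------------------------------------
# read alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignerParams:
    k: int = 15
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING
    band: int = 100
    min_seeds: int = 2  # report if >= min_seeds chained seeds ...
    min_score: int = 40  # ... or extension score >= min_score
    max_candidates: int = 8


def _candidate_groups(index: SeedIndex, seq: str, params: AlignerParams):
    """Chain seed hits into per-reference diagonal groups."""
    k = index.k
    if len(seq) < k:
        return []
    qpos = list(range(0, len(seq) - k + 1, k))
    if qpos[-1] != len(seq) - k:
        qpos.append(len(seq) - k)
    hits: list[tuple[int, int, int]] = []  # (ref_idx, diag, qp)
    for qp in qpos:
        for ri, rp in index.lookup(seq[qp : qp + k]):
            hits.append((ri, rp - qp, qp))
    if not hits:
        return []
    hits.sort()
    groups = []
    cur_ref, cur_diag, nseeds, dmin, dmax = hits[0][0], hits[0][1], 1, hits[0][1], hits[0][1]
    for ri, d, _ in hits[1:]:
        if ri == cur_ref and d - cur_diag <= params.band:
            nseeds += 1
            dmax = d
            cur_diag = d
        else:
            groups.append((cur_ref, dmin, dmax, nseeds))
            cur_ref, cur_diag, nseeds, dmin, dmax = ri, d, 1, d, d
    groups.append((cur_ref, dmin, dmax, nseeds))
    groups.sort(key=lambda g: (-g[3], g[0], g[1]))
    return groups[: params.max_candidates]


def _exact_hits(index: SeedIndex, seq: str) -> list[tuple[int, int]]:
    """Full-length exact placements of ``seq`` (empty if none)."""
    k = index.k
    if len(seq) < k:
        return []
    out = []
    for ri, rp in index.lookup(seq[:k]):
        if index.seqs[ri][rp : rp + len(seq)] == seq:
            out.append((ri, rp))
    return out


def align_read(
    read_seq: str,
    index: SeedIndex,
    params: AlignerParams | None = None,
    qname: str = "read",
    qual: str | None = None,
) -> list[AlignmentRecord]:
    """Best local alignment(s) of a read against the index.

    The primary record comes first; equal-best placements follow flagged
    secondary. Returns [] when no placement passes the reporting threshold
    (at least ``min_seeds`` chained seeds or score >= ``min_score``).
    """
    params = params or AlignerParams()
    match = params.scoring[0]
    n = len(read_seq)
    results = []  # (score, ref_name, ref_start, strand, cigar, ref_end, nseeds)
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        exact = _exact_hits(index, seq)
        if exact:
            for ri, rp in exact:
                cigar = [("M", n)]
                results.append((n * match, index.names[ri], rp, strand, cigar, rp + n, 99))
            continue
        for ri, dmin, dmax, nseeds in _candidate_groups(index, seq, params):
            ref_seq = index.seqs[ri]
            lo = max(0, dmin - params.band)
            hi = min(len(ref_seq), dmax + n + params.band)
            score, (qs, qe), (rs, re_), core = smith_waterman(
                seq, ref_seq[lo:hi], params.scoring
            )
            if score <= 0:
                continue
            cigar: list[tuple[str, int]] = []
            if qs > 0:
                cigar.append(("S", qs))
            cigar.extend(core)
            if qe < n:
                cigar.append(("S", n - qe))
            results.append((score, index.names[ri], lo + rs, strand, cigar, lo + re_, nseeds))
    if not results:
        return []
    results.sort(key=lambda r: (-r[0], r[1], r[2], r[3]))
    best_score = results[0][0]
    # deduplicate identical placements from overlapping candidate windows
    seen = set()
    records = []
    for score, rname, rstart, strand, cigar, rend, nseeds in results:
        if score < best_score:
            break
        key = (rname, rstart, strand)
        if key in seen:
            continue
        seen.add(key)
        if nseeds < params.min_seeds and score < params.min_score:
            continue
        oriented_seq = read_seq if strand == "+" else revcomp(read_seq)
        oriented_qual = "*"
        if qual is not None:
            oriented_qual = qual if strand == "+" else qual[::-1]
        records.append(
            AlignmentRecord(
                qname=qname,
                ref_name=rname,
                pos=rstart,
                strand=strand,
                cigar=cigar,
                score=score,
                seq=oriented_seq,
                qual=oriented_qual,
                is_secondary=bool(records),
            )
        )
    return records


def align_pairs(
    pairs: Iterable[tuple[tuple[str, str, str], tuple[str, str, str]]],
    index: SeedIndex,
    frag_mean: float = 400.0,
    frag_sd: float = 60.0,
    params: AlignerParams | None = None,
) -> list[tuple[AlignmentRecord, AlignmentRecord]]:
    """Align read pairs and set mate/proper-pair fields.

    A pair is proper iff both mates map to the same reference in FR
    orientation with an implied fragment length within mean +/- 4 sd.
    Unmapped mates are encoded as placeholder records per SAM convention.
    """
    params = params or AlignerParams()
    out = []
    for (n1, s1, q1), (n2, s2, q2) in pairs:
        recs1 = align_read(s1, index, params, qname=n1, qual=q1)
        recs2 = align_read(s2, index, params, qname=n2, qual=q2)
        r1 = recs1[0] if recs1 else AlignmentRecord(n1, None, -1, "+", [], seq=s1, qual=q1)
        r2 = recs2[0] if recs2 else AlignmentRecord(n2, None, -1, "+", [], seq=s2, qual=q2)
        for r, m, first in ((r1, r2, True), (r2, r1, False)):
            r.is_paired = True
            r.is_read1 = first
            r.mate_ref = m.ref_name
            r.mate_pos = m.pos
            r.mate_strand = m.strand
            r.mate_unmapped = not m.is_mapped
        proper = False
        if r1.is_mapped and r2.is_mapped and r1.ref_name == r2.ref_name:
            left, right = (r1, r2) if r1.pos <= r2.pos else (r2, r1)
            if left.strand == "+" and right.strand == "-":
                frag = right.end - left.pos
                if abs(frag - frag_mean) <= 4 * frag_sd:
                    proper = True
                    left.tlen, right.tlen = frag, -frag
        r1.is_proper = r2.is_proper = proper
        out.append((r1, r2))
    return out


def coverage(records: Iterable[AlignmentRecord], ref_name: str, ref_len: int) -> np.ndarray:
    """Per-base reference-consuming coverage (M and D ops) from primary
    mapped records on ``ref_name``."""
    cov = np.zeros(ref_len, dtype=np.int32)
    for rec in records:
        if not rec.is_mapped or rec.is_secondary or rec.ref_name != ref_name:
            continue
        pos = rec.pos
        for op, n in rec.cigar:
            if op in "MD":
                cov[pos : pos + n] += 1
                pos += n
    return cov
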