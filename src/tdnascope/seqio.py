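"""FASTA/FASTQ reading and writing plus paired-read trimming.

FASTQ records are ``(id, sequence, quality)`` tuples; pairs are 2-tuples of
records. Files ending in ``.gz`` are opened transparently. Parsing goes
through Bio.SeqIO; writing is plain four-line FASTQ / wrapped FASTA so that
output is byte-reproducible.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

FastqRecord = tuple[str, str, str]


def _open(path, mode: str = "rt") -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    with _open(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[FastqRecord]:
    out = []
    with _open(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(path, records: Iterable[FastqRecord]) -> None:
    with _open(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq_pairs(path_r1, path_r2) -> list[tuple[FastqRecord, FastqRecord]]:
    r1, r2 = read_fastq(path_r1), read_fastq(path_r2)
    if len(r1) != len(r2):
        raise ValueError(f"R1 has {len(r1)} reads but R2 has {len(r2)}")
    return list(zip(r1, r2))


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------


@dataclass
class TrimCounts:
    pairs_in: int = 0
    adapter_trimmed: int = 0
    quality_trimmed: int = 0
    reads_dropped: int = 0
    pairs_out: int = 0
    orphaned_mates: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrimResult:
    pairs: list[tuple[FastqRecord, FastqRecord]] = field(default_factory=list)
    orphans: list[FastqRecord] = field(default_factory=list)
    counts: TrimCounts = field(default_factory=TrimCounts)


def _trim_adapter(seq: str, qual: str, adapter: str, min_overlap: int = 8) -> tuple[str, str, bool]:
    """Remove a 3' adapter: the read suffix must be an exact prefix of the
    adapter (or contain the whole adapter), with at least ``min_overlap``
    bases of overlap. The leftmost such occurrence wins."""
    n = len(seq)
    for p in range(0, n - min_overlap + 1):
        tail = seq[p:]
        la = min(len(tail), len(adapter))
        if tail[:la] == adapter[:la]:
            return seq[:p], qual[:p], True
    return seq, qual, False


def _trim_quality(seq: str, qual: str, min_q: int) -> tuple[str, str, bool]:
    """BWA/cutadapt-style 3' quality trimming: cut at the position that
    maximises the running sum of ``min_q - q`` accumulated from the 3' end."""
    best, s, cut = 0, 0, len(seq)
    for i in range(len(seq) - 1, -1, -1):
        s += min_q - (ord(qual[i]) - 33)
        if s > best:
            best, cut = s, i
    if cut == len(seq):
        return seq, qual, False
    return seq[:cut], qual[:cut], True


def trim_reads(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    adapter: str = "",
    min_len: int = 40,
    min_q: int = 20,
) -> TrimResult:
    """Adapter- and quality-trim read pairs.

    Reads shorter than ``min_len`` after trimming are dropped; a surviving
    mate of a dropped read becomes an orphan (single-end) record.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    res = TrimResult()
    for pair in pairs:
        res.counts.pairs_in += 1
        trimmed = []
        for name, seq, qual in pair:
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record {name!r}: seq/qual length differ")
            if adapter:
                seq, qual, hit = _trim_adapter(seq, qual, adapter)
                res.counts.adapter_trimmed += hit
            seq, qual, hit = _trim_quality(seq, qual, min_q)
            res.counts.quality_trimmed += hit
            trimmed.append((name, seq, qual))
        keep = [len(r[1]) >= min_len for r in trimmed]
        if all(keep):
            res.pairs.append((trimmed[0], trimmed[1]))
            res.counts.pairs_out += 1
        else:
            res.counts.reads_dropped += keep.count(False)
            for rec, k in zip(trimmed, keep):
                if k:
                    res.orphans.append(rec)
                    res.counts.orphaned_mates += 1
    return res
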