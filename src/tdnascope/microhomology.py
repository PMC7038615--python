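"""Microhomology scoring at integration junctions.

At a non-homologous end-joining junction, a short exact tract shared by the
cassette terminus and the host flank implicates microhomology-assisted
repair. Given the host flank around a breakpoint and the junction-adjacent
cassette terminus, the caller exhaustively searches exact common substrings
near both breakpoints and reports the best tract together with its offsets
and homopolymer content.

Coordinate conventions: ``host_flank`` is ``2w`` bp centred on the host
breakpoint (the breakpoint sits between positions ``w-1`` and ``w``);
``cassette_terminus`` is ``w`` bp of cassette with index 0 adjacent to the
junction. An offset is the gap in bp between a tract and its breakpoint
(0 when the tract touches or spans it).
"""

from __future__ import annotations

from dataclasses import dataclass

from .dna import revcomp


@dataclass
class MicrohomologyCall:
    junction_id: str
    tract: str
    length: int
    host_offset: int
    cassette_offset: int
    homopolymer_run: int
    strand: str = "+"

    @property
    def offset_delta(self) -> int:
        return abs(self.host_offset - self.cassette_offset)


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run (0 for an empty sequence)."""
    best = run = 0
    prev = None
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


def _host_offset(a: int, b: int, w: int) -> int:
    """Distance of host tract [a, b) from the breakpoint between w-1 and w."""
    if b <= w:
        return w - b
    if a >= w:
        return a - w
    return 0


def find_microhomology(
    host_flank: str,
    cassette_terminus: str,
    min_len: int = 2,
    window: int = 10,
    junction_id: str = "junction",
    terminus_at: str = "start",
) -> MicrohomologyCall:
    """Best exact common tract between host flank and cassette terminus.

    All common substrings of length >= ``min_len`` whose positions lie within
    ``window`` bp of the respective breakpoints are considered, on both
    cassette strands (junctions may be antisense); N never matches. The
    longest tract wins; ties break to the smallest offset delta, then the
    leftmost host offset, then the forward strand — fully deterministic.
    Returns a length-0 call when nothing qualifies.

    ``terminus_at`` says which end of ``cassette_terminus`` touches the
    junction ('start' for left junctions where the sequence runs into the
    cassette, 'end' for right junctions where it runs out of it).
    """
    if terminus_at not in ("start", "end"):
        raise ValueError("terminus_at must be 'start' or 'end'")
    w = len(host_flank) // 2
    empty = MicrohomologyCall(junction_id, "", 0, 0, 0, 0)
    if len(host_flank) < min_len or len(cassette_terminus) < min_len:
        return empty
    best: tuple | None = None  # (key, tract, host_off, cass_off, strand)
    for strand, cass in (("+", cassette_terminus), ("-", revcomp(cassette_terminus))):
        strand_rank = 0 if strand == "+" else 1
        # reverse-complementing flips which end of the string is junction-adjacent
        adj = terminus_at if strand == "+" else ("end" if terminus_at == "start" else "start")
        for L in range(min_len, min(len(host_flank), len(cass)) + 1):
            for ca in range(0, len(cass) - L + 1):
                c_off = ca if adj == "start" else len(cass) - (ca + L)
                if c_off > window:
                    continue
                sub = cass[ca : ca + L]
                if "N" in sub:
                    continue
                start = 0
                while True:
                    ha = host_flank.find(sub, start)
                    if ha < 0:
                        break
                    start = ha + 1
                    h_off = _host_offset(ha, ha + L, w)
                    if h_off > window:
                        continue
                    delta = abs(h_off - c_off)
                    key = (-L, delta, h_off, strand_rank, ca)
                    if best is None or key < best[0]:
                        best = (key, sub, h_off, c_off, strand)
    if best is None:
        return empty
    _, tract, h_off, c_off, strand = best
    return MicrohomologyCall(
        junction_id, tract, len(tract), h_off, c_off, max_homopolymer(tract), strand
    )


def summarize_homology(
    calls: list[MicrohomologyCall], bins: tuple[int, ...] = (0, 3, 9)
) -> dict:
    """Summary table over junction calls: cumulative counts of offset delta
    <= each bin, homopolymer >= 2 count, and tract-length distribution.
    Permutation-invariant over call order."""
    detected = [c for c in calls if c.length > 0]
    lengths = sorted(c.length for c in detected)
    return {
        "n_junctions": len(calls),
        "n_detected": len(detected),
        "delta_within": {b: sum(c.offset_delta <= b for c in detected) for b in bins},
        "n_homopolymer_ge2": sum(c.homopolymer_run >= 2 for c in detected),
        "length_distribution": {l: lengths.count(l) for l in sorted(set(lengths))},
    }
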