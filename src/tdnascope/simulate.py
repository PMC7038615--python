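"""Synthetic data generation: host genomes, transgene cassettes, planted
integration/edit events, and paired-end reads with machine-readable truth.

The generator emulates the data the analysis assumes: a multi-chromosome host
genome, a border-delimited transgene cassette with 100 bp vector-backbone
flanks, Agrobacterium-style integration events (host deletion, filler DNA,
junction microhomology, partial/rearranged cassettes), chimeric target-site
indels at set allele fractions, and 125 bp paired-end reads at ~20-fold
coverage with substitution sequencing error and optional trace library
cross-contamination.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical inputs give byte-identical output.
Coordinates are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .dna import BASES, mutate_base, random_seq, revcomp

SENSE = "sense"
ANTISENSE = "antisense"

#: roles a cassette component may take
COMPONENT_ROLES = (
    "backbone_flank",
    "right_border",
    "promoter",
    "nuclease",
    "guide_cassette",
    "marker",
    "left_border",
)

BACKBONE_FLANK_LEN = 100


class SimulationError(ValueError):
    """Invalid simulation input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HostGenome:
    """A synthetic multi-chromosome host reference (stand-in for a real
    plant assembly)."""

    chromosomes: list[tuple[str, str]]
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise SimulationError("chromosome names must be unique")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def seq(self, name: str) -> str:
        for n, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(name)

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def replace(self, name: str, seq: str) -> "HostGenome":
        chroms = [(n, seq if n == name else s) for n, s in self.chromosomes]
        return HostGenome(chroms, self.seed)


@dataclass
class CassetteComponent:
    label: str
    role: str
    sequence: str
    host_homologous: bool = False


@dataclass
class CassetteModel:
    """Ordered labeled transgene components: the 'transgene reference' is the
    concatenation of the component sequences, beginning and ending with a
    100 bp vector-backbone flank."""

    components: list[CassetteComponent]

    def __post_init__(self) -> None:
        roles = [c.role for c in self.components]
        if not roles or roles[0] != "backbone_flank" or roles[-1] != "backbone_flank":
            raise SimulationError("cassette must begin and end with backbone_flank")
        for end in (self.components[0], self.components[-1]):
            if len(end.sequence) != BACKBONE_FLANK_LEN:
                raise SimulationError("backbone flanks must be exactly 100 bp")
        if "right_border" in roles and "left_border" in roles:
            if roles.index("right_border") > roles.index("left_border"):
                raise SimulationError("right_border must precede left_border")
        for c in self.components:
            if c.role not in COMPONENT_ROLES:
                raise SimulationError(f"unknown component role {c.role!r}")

    @property
    def sequence(self) -> str:
        return "".join(c.sequence for c in self.components)

    def __len__(self) -> int:
        return len(self.sequence)

    def component_interval(self, label: str) -> tuple[int, int]:
        """0-based half-open interval of a labeled component on the cassette."""
        pos = 0
        for c in self.components:
            if c.label == label:
                return pos, pos + len(c.sequence)
            pos += len(c.sequence)
        raise KeyError(label)

    def role_interval(self, role: str) -> tuple[int, int]:
        pos = 0
        for c in self.components:
            if c.role == role:
                return pos, pos + len(c.sequence)
            pos += len(c.sequence)
        raise KeyError(role)

    def tdna_interval(self) -> tuple[int, int]:
        """Interval from the start of the right border to the end of the left
        border — the segment expected to transfer in full-cassette events."""
        rb = self.role_interval("right_border")
        lb = self.role_interval("left_border")
        return rb[0], lb[1]

    def unmasked_intervals(self) -> list[tuple[int, int]]:
        """Cassette intervals informative for presence calling: backbone
        flanks and host-homologous components (e.g. a native-promoter
        segment) are masked out."""
        out = []
        pos = 0
        for c in self.components:
            end = pos + len(c.sequence)
            if c.role != "backbone_flank" and not c.host_homologous:
                out.append((pos, end))
            pos = end
        return out


@dataclass
class IntegrationTruth:
    """Planted parameters of one transgene integration locus."""

    chrom: str
    host_deletion: tuple[int, int]  # 0-based half-open on the host reference
    filler_left: str = ""
    filler_right: str = ""
    cassette_segment: tuple[int, int] = (0, 0)
    orientation_left: str = SENSE
    orientation_right: str = SENSE
    microhomology_left: int = 0
    microhomology_right: int = 0
    completeness: str = "full"

    def __post_init__(self) -> None:
        s, e = self.host_deletion
        if e < s:
            raise SimulationError("host deletion interval reversed")
        for o in (self.orientation_left, self.orientation_right):
            if o not in (SENSE, ANTISENSE):
                raise SimulationError(f"bad orientation {o!r}")

    @property
    def deletion_length(self) -> int:
        return self.host_deletion[1] - self.host_deletion[0]


@dataclass
class EditTruth:
    """One planted indel allele at a CRISPR target site."""

    site_id: str
    net: int  # net length change: negative deletion, positive insertion
    inserted: str = ""
    allele_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise SimulationError("allele_fraction must be in [0, 1]")
        if self.net > 0 and len(self.inserted) != self.net:
            raise SimulationError("inserted sequence must match net length")


@dataclass
class TargetSpec:
    """A CRISPR target embedded in the host: ``sequence`` must occur exactly
    once on a haplotype; ``cut_offset`` is the blunt cut position within it."""

    site_id: str
    sequence: str
    cut_offset: int


@dataclass
class Haplotype:
    """One (possibly edited) copy of the genome contributing reads."""

    name: str
    chroms: list[tuple[str, str]]
    weight: float = 1.0

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chroms)


@dataclass
class SampleSpec:
    """A sequencing sample: a mixture of haplotypes plus planted truth."""

    sample_id: str
    generation: str
    haplotypes: list[Haplotype]
    integrations: list[tuple[IntegrationTruth, str]] = field(default_factory=list)
    edits: list[EditTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = sum(h.weight for h in self.haplotypes)
        if abs(w - 1.0) > 1e-9:
            raise SimulationError(f"haplotype weights sum to {w}, expected 1")


@dataclass
class ReadPairTruth:
    pair_id: str
    haplotype: str
    chrom: str
    start: int
    end: int
    strand: int  # 0: R1 on forward strand of the haplotype
    contaminant: bool = False


@dataclass
class SimulatedReads:
    pairs: list[tuple[str, str, str, str, str]]  # (id, r1, q1, r2, q2)
    truth: list[ReadPairTruth]

    def truth_json(self) -> str:
        return json.dumps([dataclasses.asdict(t) for t in self.truth], indent=0)


# ---------------------------------------------------------------------------
# genome and cassette construction
# ---------------------------------------------------------------------------


def make_host_genome(
    n_chrom: int, lengths: list[int], gc: float = 0.35, seed: int = 0
) -> HostGenome:
    """Generate a random host genome.

    Base composition is i.i.d. with expected GC fraction ``gc`` (soybean-like
    default 0.35), so observed GC converges to ``gc`` for long chromosomes.
    """
    if n_chrom < 1 or len(lengths) != n_chrom:
        raise SimulationError("lengths must list one length per chromosome")
    if any(l <= 0 for l in lengths):
        raise SimulationError("chromosome lengths must be positive")
    if not 0 < gc < 1:
        raise SimulationError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    chroms = [(f"Chr{i + 1:02d}", random_seq(rng, l, gc)) for i, l in enumerate(lengths)]
    return HostGenome(chroms, seed)


def make_cassette(
    seed: int = 0,
    promoter_from_host: str | None = None,
    sizes: dict[str, int] | None = None,
) -> CassetteModel:
    """Build a synthetic CRISPR/Cas9 expression cassette.

    Component order mirrors a typical binary-vector T-DNA: backbone flank,
    right border, promoter, Cas9 nuclease, gRNA cassette, selectable marker,
    left border, backbone flank. If ``promoter_from_host`` is given, that host
    subsequence is used as the promoter and flagged host-homologous (modelling
    a native-promoter construct whose promoter reads cannot distinguish
    transgene from genome).
    """
    rng = np.random.default_rng(seed)
    sz = {
        "right_border": 25,
        "promoter": 300,
        "nuclease": 1000,
        "guide_cassette": 250,
        "marker": 400,
        "left_border": 25,
    }
    if sizes:
        sz.update(sizes)
    promoter = promoter_from_host or random_seq(rng, sz["promoter"], 0.45)
    comps = [
        CassetteComponent("backbone5", "backbone_flank", random_seq(rng, BACKBONE_FLANK_LEN, 0.5)),
        CassetteComponent("RB", "right_border", random_seq(rng, sz["right_border"], 0.5)),
        CassetteComponent(
            "promoter", "promoter", promoter, host_homologous=promoter_from_host is not None
        ),
        CassetteComponent("cas9", "nuclease", random_seq(rng, sz["nuclease"], 0.45)),
        CassetteComponent("gRNA", "guide_cassette", random_seq(rng, sz["guide_cassette"], 0.45)),
        CassetteComponent("marker", "marker", random_seq(rng, sz["marker"], 0.45)),
        CassetteComponent("LB", "left_border", random_seq(rng, sz["left_border"], 0.5)),
        CassetteComponent("backbone3", "backbone_flank", random_seq(rng, BACKBONE_FLANK_LEN, 0.5)),
    ]
    return CassetteModel(comps)


# ---------------------------------------------------------------------------
# event planting
# ---------------------------------------------------------------------------


def oriented_insert(cassette: CassetteModel, truth: IntegrationTruth) -> str:
    """The cassette-derived part of the inserted sequence, oriented per truth.

    For rearranged events (discordant junction orientations) the segment is
    split at its midpoint and each half oriented per its junction, emulating
    multiple insertions/rearrangements at one locus.
    """
    s, e = truth.cassette_segment
    if not (0 <= s < e <= len(cassette)):
        raise SimulationError("cassette segment outside cassette")
    seq = cassette.sequence
    if truth.orientation_left == truth.orientation_right:
        seg = seq[s:e]
        return seg if truth.orientation_left == SENSE else revcomp(seg)
    mid = (s + e) // 2
    left = seq[s:mid] if truth.orientation_left == SENSE else revcomp(seq[s:mid])
    right = seq[mid:e] if truth.orientation_right == SENSE else revcomp(seq[mid:e])
    return left + right


def plant_integration(
    genome: HostGenome, cassette: CassetteModel, truth: IntegrationTruth
) -> tuple[HostGenome, str]:
    """Apply one integration event.

    Returns ``(reference, edited_chromosome)`` where ``reference`` is the host
    genome with any planted junction microhomology written into the flank
    (microhomology is by definition sequence shared between the host reference
    and the cassette terminus, so it must live in both), and
    ``edited_chromosome`` is the integrated haplotype sequence of
    ``truth.chrom``: left flank + filler + oriented cassette segment + filler
    + right flank, with the deleted interval removed.
    """
    ref, edited = apply_integrations(genome, cassette, [truth])
    return ref, edited[truth.chrom]


def _check_integration(genome: HostGenome, truth: IntegrationTruth) -> None:
    chrom_seq = genome.seq(truth.chrom)
    ds, de = truth.host_deletion
    if not (0 <= ds <= de <= len(chrom_seq)):
        raise SimulationError("deletion interval outside chromosome")
    for f in (truth.filler_left, truth.filler_right):
        if any(b not in BASES for b in f):
            raise SimulationError("filler must be over ACGT")


def _write_microhomology(chrom_seq: str, cassette: CassetteModel, t: IntegrationTruth) -> str:
    """Write the planted shared bases into the reference flank adjacent to
    each junction, so host flank and cassette terminus genuinely agree."""
    core = oriented_insert(cassette, t)
    ds, de = t.host_deletion
    ml, mr = t.microhomology_left, t.microhomology_right
    if ml > 0:
        if ml > ds or ml > len(core):
            raise SimulationError("left microhomology longer than flank/segment")
        chrom_seq = chrom_seq[: ds - ml] + core[:ml] + chrom_seq[ds:]
    if mr > 0:
        if de + mr > len(chrom_seq) or mr > len(core):
            raise SimulationError("right microhomology longer than flank/segment")
        chrom_seq = chrom_seq[:de] + core[-mr:] + chrom_seq[de + mr :]
    return chrom_seq


def apply_integrations(
    genome: HostGenome, cassette: CassetteModel, truths: list[IntegrationTruth]
) -> tuple[HostGenome, dict[str, str]]:
    """Apply integration events.

    Phase 1 writes any planted junction microhomology into the reference
    flanks (at reference coordinates, outside the deletions). Phase 2 builds
    edited chromosomes by applying inserts right-to-left so every truth's
    reference coordinates stay valid. Returns the (possibly adjusted)
    reference genome and a dict of edited chromosome sequences (chromosomes
    without events are omitted).
    """
    ref = genome
    for t in truths:
        _check_integration(ref, t)
        ref = ref.replace(t.chrom, _write_microhomology(ref.seq(t.chrom), cassette, t))
    edited: dict[str, str] = {}
    for chrom in sorted({t.chrom for t in truths}):
        cur = ref.seq(chrom)
        for t in sorted(
            (t for t in truths if t.chrom == chrom), key=lambda t: -t.host_deletion[0]
        ):
            ds, de = t.host_deletion
            insert = t.filler_left + oriented_insert(cassette, t) + t.filler_right
            cur = cur[:ds] + insert + cur[de:]
        edited[chrom] = cur
    return ref, edited


def plant_target_edit(haplotype: str, target: TargetSpec, edit: EditTruth) -> str:
    """Apply an indel at a CRISPR target on one haplotype sequence.

    The target ``sequence`` must occur exactly once. Deletions remove bases
    spanning the cut (``net//2`` left of it); insertions add ``edit.inserted``
    at the cut. A net of 0 is a no-op.
    """
    n = haplotype.count(target.sequence)
    if n != 1:
        raise SimulationError(f"target site occurs {n} times, expected exactly once")
    pos = haplotype.index(target.sequence) + target.cut_offset
    if edit.net == 0:
        return haplotype
    if edit.net < 0:
        k = -edit.net
        left = k // 2
        a, b = pos - left, pos - left + k
        if a < 0 or b > len(haplotype):
            raise SimulationError("deletion outside haplotype")
        return haplotype[:a] + haplotype[b:]
    return haplotype[:pos] + edit.inserted + haplotype[pos:]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

Q_GOOD = chr(30 + 33)  # Q30
Q_BAD = chr(15 + 33)  # Q15 on substituted bases, so trimming has work to do


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> int:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return int(round(x))
    return int(round(np.clip(mean, lo, hi)))


def _apply_errors(rng: np.random.Generator, seq: str, err_rate: float) -> tuple[str, str]:
    if err_rate <= 0:
        return seq, Q_GOOD * len(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < err_rate)
    if hits.size == 0:
        return seq, Q_GOOD * len(seq)
    bases = list(seq)
    qual = [Q_GOOD] * len(seq)
    for i in hits:
        bases[i] = mutate_base(rng, bases[i])
        qual[i] = Q_BAD
    return "".join(bases), "".join(qual)


def simulate_reads(
    sample: SampleSpec,
    depth: float = 20.0,
    read_len: int = 125,
    frag_mean: float = 400.0,
    frag_sd: float = 60.0,
    err_rate: float = 0.001,
    contamination: tuple[list[Haplotype], float] | None = None,
    seed: int = 0,
) -> SimulatedReads:
    """Simulate FR paired-end reads from a haplotype mixture.

    The number of pairs is ``round(depth * genome_length / (2 * read_len))``
    with genome length the weighted mean haplotype length. Fragment lengths
    are truncated-normal on ``[2*read_len, 3*frag_mean]``; errors are uniform
    substitutions at ``err_rate`` with Q15 quality (Q30 elsewhere).
    ``contamination`` draws whole pairs from a foreign haplotype set at the
    given fraction, emulating cross-contamination between barcoded libraries.
    """
    if depth <= 0:
        raise SimulationError("depth must be positive")
    if frag_mean < read_len:
        raise SimulationError("frag_mean must be at least read_len")
    rng = np.random.default_rng(seed)
    genome_len = sum(h.weight * h.total_length() for h in sample.haplotypes)
    n_pairs = int(round(depth * genome_len / (2 * read_len)))
    weights = np.array([h.weight for h in sample.haplotypes])
    weights = weights / weights.sum()
    contam_haps, contam_frac = (None, 0.0)
    if contamination is not None:
        contam_haps, contam_frac = contamination

    frag_lo, frag_hi = 2 * read_len, 3 * frag_mean
    pairs: list[tuple[str, str, str, str, str]] = []
    truth: list[ReadPairTruth] = []
    for i in range(n_pairs):
        contaminant = contam_haps is not None and rng.random() < contam_frac
        if contaminant:
            hap = contam_haps[int(rng.integers(len(contam_haps)))]
        else:
            hap = sample.haplotypes[int(rng.choice(len(sample.haplotypes), p=weights))]
        # chromosome proportional to length
        lens = np.array([len(s) for _, s in hap.chroms], dtype=float)
        ci = int(rng.choice(len(hap.chroms), p=lens / lens.sum()))
        cname, cseq = hap.chroms[ci]
        frag_len = _truncated_normal(rng, frag_mean, frag_sd, frag_lo, min(frag_hi, len(cseq)))
        start = int(rng.integers(0, len(cseq) - frag_len + 1))
        frag = cseq[start : start + frag_len]
        fwd = frag[:read_len]
        rev = revcomp(frag[-read_len:])
        strand = int(rng.integers(2))
        r1, r2 = (fwd, rev) if strand == 0 else (rev, fwd)
        r1, q1 = _apply_errors(rng, r1, err_rate)
        r2, q2 = _apply_errors(rng, r2, err_rate)
        pid = f"sim{i:06d}"
        pairs.append((pid, r1, q1, r2, q2))
        truth.append(
            ReadPairTruth(pid, hap.name, cname, start, start + frag_len, strand, contaminant)
        )
    return SimulatedReads(pairs, truth)


# ---------------------------------------------------------------------------
# junction identifiability
# ---------------------------------------------------------------------------


def junction_violations(
    ref_chrom: str, cassette: CassetteModel, truth: IntegrationTruth, anchor: int = 40
) -> list[str]:
    """String-level identifiability check of a planted junction, independent
    of the analysis pipeline.

    A junction's planted deletion/filler sizes are only recoverable when no
    coincidental base extends a host or cassette match across the breakpoint:

    - L1/R1: the first/last insert base must differ from the adjacent
      reference base, else the host anchor would absorb it;
    - L2/R2: a filler's junction-distal base must not extend the cassette
      match (checked by substring search against both cassette strands).

    ``ref_chrom`` must already carry any planted microhomology.
    """
    core = oriented_insert(cassette, truth)
    insert = truth.filler_left + core + truth.filler_right
    fwd = cassette.sequence
    rc = revcomp(fwd)
    ds, de = truth.host_deletion
    v = []
    if ds < len(ref_chrom) and insert and insert[0] == ref_chrom[ds]:
        v.append("L1")
    if de > 0 and insert and insert[-1] == ref_chrom[de - 1]:
        v.append("R1")
    if truth.filler_left:
        probe = truth.filler_left[-1] + core[: min(anchor, len(core))]
        if probe in fwd or probe in rc:
            v.append("L2")
    if truth.filler_right:
        probe = core[-min(anchor, len(core)) :] + truth.filler_right[0]
        if probe in fwd or probe in rc:
            v.append("R2")
    return v


def _mutable(pos: int, truth: IntegrationTruth, immutable: list[tuple[int, int]]) -> bool:
    ds, de = truth.host_deletion
    if ds - truth.microhomology_left <= pos < ds and truth.microhomology_left:
        return False
    if de <= pos < de + truth.microhomology_right and truth.microhomology_right:
        return False
    return not any(a <= pos < b for a, b in immutable)


def sanitize_integration(
    genome: HostGenome,
    cassette: CassetteModel,
    truth: IntegrationTruth,
    immutable: list[tuple[int, int]] | None = None,
    max_shift: int = 6,
) -> tuple[HostGenome, IntegrationTruth]:
    """Make a planted junction string-identifiable.

    Deterministically adjusts filler terminal bases, or deleted reference
    bases outside ``immutable`` intervals, so that ``junction_violations``
    is empty; as a last resort the deletion interval is shifted by up to
    ``max_shift`` bp. Raises if no placement works.
    """
    import dataclasses as _dc

    immutable = immutable or []
    fwd, rc = cassette.sequence, revcomp(cassette.sequence)
    core0 = oriented_insert(cassette, truth)

    for mag in range(max_shift + 1):
        for shift in ([0] if mag == 0 else [mag, -mag]):
            ds0, de0 = truth.host_deletion
            t = _dc.replace(truth, host_deletion=(ds0 + shift, de0 + shift))
            g = genome
            ok = False
            for _ in range(8):
                try:
                    ref2 = _write_microhomology(g.seq(t.chrom), cassette, t)
                except SimulationError:
                    break
                v = junction_violations(ref2, cassette, t)
                if not v:
                    ok = True
                    break
                ds, de = t.host_deletion
                core = core0
                insert = t.filler_left + core + t.filler_right
                fixed = False
                if "L1" in v:
                    if t.filler_left:
                        for b in BASES:
                            probe = b + core[:40] if len(t.filler_left) == 1 else None
                            if b != ref2[ds] and (
                                probe is None or (probe not in fwd and probe not in rc)
                            ):
                                t = _dc.replace(t, filler_left=b + t.filler_left[1:])
                                fixed = True
                                break
                    elif ds < de and _mutable(ds, t, immutable):
                        forbid = {insert[0]}
                        if de - 1 == ds:
                            forbid.add(insert[-1])
                        for b in BASES:
                            if b not in forbid:
                                s = g.seq(t.chrom)
                                g = g.replace(t.chrom, s[:ds] + b + s[ds + 1 :])
                                fixed = True
                                break
                    elif ds == de and _mutable(ds, t, immutable):
                        for b in BASES:
                            if b != insert[0]:
                                s = g.seq(t.chrom)
                                g = g.replace(t.chrom, s[:ds] + b + s[ds + 1 :])
                                fixed = True
                                break
                elif "R1" in v:
                    if t.filler_right:
                        for b in BASES:
                            probe = core[-40:] + b if len(t.filler_right) == 1 else None
                            if b != ref2[de - 1] and (
                                probe is None or (probe not in fwd and probe not in rc)
                            ):
                                t = _dc.replace(t, filler_right=t.filler_right[:-1] + b)
                                fixed = True
                                break
                    elif ds < de and _mutable(de - 1, t, immutable):
                        forbid = {insert[-1]}
                        if de - 1 == ds:
                            forbid.add(insert[0])
                        for b in BASES:
                            if b not in forbid:
                                s = g.seq(t.chrom)
                                g = g.replace(t.chrom, s[: de - 1] + b + s[de:])
                                fixed = True
                                break
                    elif ds == de and ds > 0 and _mutable(ds - 1, t, immutable):
                        for b in BASES:
                            if b != insert[-1]:
                                s = g.seq(t.chrom)
                                g = g.replace(t.chrom, s[: ds - 1] + b + s[ds:])
                                fixed = True
                                break
                elif "L2" in v:
                    for b in BASES:
                        probe = b + core[:40]
                        if (probe not in fwd and probe not in rc) and (
                            len(t.filler_left) > 1 or b != ref2[ds]
                        ):
                            t = _dc.replace(t, filler_left=t.filler_left[:-1] + b)
                            fixed = True
                            break
                elif "R2" in v:
                    for b in BASES:
                        probe = core[-40:] + b
                        if (probe not in fwd and probe not in rc) and (
                            len(t.filler_right) > 1 or b != ref2[de - 1]
                        ):
                            t = _dc.replace(t, filler_right=b + t.filler_right[1:])
                            fixed = True
                            break
                if not fixed:
                    break
            if ok:
                return g, t
    raise SimulationError("could not make junction identifiable")
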