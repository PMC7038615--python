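"""End-to-end per-sample and per-family orchestration plus report writers.

``run_sample`` chains the stages: trimming, pair classification against the
cassette, presence calling, orphan placement and clustering, junction
resolution, target-site allele quantification and TGI flagging.
``run_family`` genotypes a selfed parent and its progeny at the parent's
integration loci and classifies the family transmission outcome.

Report writers emit TSV/BED with a provenance header (tool version, seed,
config hash); human-readable coordinates are 1-based inclusive, internal
math stays 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from . import __version__
from .align import AlignerParams, AlignmentRecord, SeedIndex, align_pairs
from .detect import (
    CandidateLocus,
    PresenceCall,
    cassette_presence,
    classify_pairs,
    cluster_orphans,
    locate_orphans,
)
from .edits import AlleleProfile, TargetSite, flag_TGI, quantify_alleles, scan_target_sites
from .inheritance import (
    HEMIZYGOUS,
    HOMOZYGOUS,
    FamilyOutcome,
    LocusEvidence,
    SampleGenotype,
    classify_family,
    expected_segregation,
    genotype_sample,
    mendelian_test,
)
from .junctions import IntegrationRecord, collect_junction_reads, resolve_locus
from .microhomology import MicrohomologyCall, find_microhomology
from .seqio import FastqRecord, trim_reads
from .simulate import ANTISENSE, SENSE, CassetteModel, HostGenome


@dataclass
class PipelineParams:
    adapter: str = ""
    min_len: int = 40
    min_q: int = 20
    frag_mean: float = 400.0
    frag_sd: float = 60.0
    min_support: int = 2
    min_clip: int = 10
    min_clip_reads: int = 2
    allele_window: int = 20
    min_reads_per_allele: int = 2
    tgi_slop: int = 10
    max_mm: int = 2
    aligner: AlignerParams = field(default_factory=AlignerParams)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "aligner"}, sort_keys=True
        ) + json.dumps(self.aligner.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class SampleResult:
    sample_id: str
    generation: str
    presence: PresenceCall
    loci: list[CandidateLocus]
    integrations: list[IntegrationRecord]
    sites: list[TargetSite]
    profiles: list[AlleleProfile]
    tgi_flags: dict[str, bool]
    genotype: SampleGenotype
    host_records: list[AlignmentRecord]
    genome_mean_cov: float
    counts: dict


def _aligned_bases(records: list[AlignmentRecord]) -> int:
    return sum(
        sum(n for op, n in r.cigar if op == "M")
        for r in records
        if r.is_mapped and not r.is_secondary
    )


def _ref_spanning(
    records: list[AlignmentRecord], chrom: str, point: int, margin: int = 10
) -> int:
    """Reads whose aligned span covers [point-margin, point+margin) —
    evidence for a non-integrated allele at an insertion point. A read
    clipped at the junction (or into the cassette) stops there and cannot
    span, while a small target-site indel on the homolog without the
    insertion still counts."""
    lo, hi = point - margin, point + margin
    return sum(
        1
        for rec in records
        if rec.is_mapped
        and not rec.is_secondary
        and rec.ref_name == chrom
        and rec.pos <= lo
        and rec.end >= hi
    )


def locus_insertion_point(rec: IntegrationRecord, locus: CandidateLocus) -> int:
    if rec is not None and rec.host_deletion is not None:
        return (rec.host_deletion[0] + rec.host_deletion[1]) // 2
    return (locus.interval[0] + locus.interval[1]) // 2


def run_sample(
    sample_id: str,
    generation: str,
    pairs: list[tuple[FastqRecord, FastqRecord]],
    genome: HostGenome,
    cassette: CassetteModel,
    protospacers: list[str] | None = None,
    annotation: list[tuple[str, int, int]] | None = None,
    params: PipelineParams | None = None,
    host_index: SeedIndex | None = None,
    cassette_index: SeedIndex | None = None,
    genotype_loci: list[tuple[str, str, int]] | None = None,
) -> SampleResult:
    """Run the full per-sample analysis.

    ``genotype_loci`` — (locus_id, chrom, insertion point) triples at which
    to genotype this sample (e.g. the parent's loci when analysing progeny);
    defaults to the sample's own called loci.
    """
    params = params or PipelineParams()
    host_index = host_index or SeedIndex(genome.chromosomes, params.aligner.k)
    cassette_index = cassette_index or SeedIndex(
        [("cassette", cassette.sequence)], params.aligner.k
    )

    trim = trim_reads(pairs, params.adapter, params.min_len, params.min_q)
    pair_classes = classify_pairs(trim.pairs, cassette, params.aligner, cassette_index)
    cassette_records = [r for pc in pair_classes for r in pc.cassette_records]

    host_pairs = align_pairs(
        trim.pairs, host_index, params.frag_mean, params.frag_sd, params.aligner
    )
    host_records = [r for pr in host_pairs for r in pr if r.is_mapped]
    genome_mean_cov = _aligned_bases(host_records) / genome.total_length()

    presence = cassette_presence(
        cassette_records, cassette, max(genome_mean_cov, 1e-9), sample_id
    )

    placements, unplaced = locate_orphans(pair_classes, host_index, params.aligner)
    loci = cluster_orphans(placements, params.frag_mean, params.frag_sd, params.min_support)
    called = [l for l in loci if l.status == "called"]
    integrations = []
    for locus in called:
        rec = resolve_locus(
            locus,
            host_records,
            genome,
            cassette,
            annotation,
            params.min_clip,
            params.min_clip_reads,
        )
        left_reads, right_reads = collect_junction_reads(locus, host_records, params.min_clip)
        locus.n_clipped_reads = len(left_reads) + len(right_reads)
        integrations.append(rec)

    sites: list[TargetSite] = []
    for proto in protospacers or []:
        sites.extend(scan_target_sites(genome, proto, params.max_mm, site_prefix="site"))
    # re-id deterministically across protospacers
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    for i, s in enumerate(sites):
        s.site_id = f"site{i + 1}"
    profiles = [
        quantify_alleles(
            host_records,
            site,
            params.allele_window,
            params.min_reads_per_allele,
            params.min_clip,
            cassette_index,
        )
        for site in sites
    ]
    tgi = flag_TGI(sites, integrations, params.tgi_slop)

    if genotype_loci is None:
        genotype_loci = [
            (locus.locus_id, locus.chrom, locus_insertion_point(rec, locus))
            for locus, rec in zip(called, integrations)
        ]
    evidence = []
    for locus_id, chrom, point in genotype_loci:
        # junction support per side; the max keeps the hemizygous ratio near
        # 1:1 against spanning reads (summing sides would double-count the
        # integrated haplotype)
        left_n = right_n = 0
        for rec in host_records:
            if rec.is_secondary or rec.ref_name != chrom:
                continue
            if rec.clip_right() >= params.min_clip and abs(rec.end - point) <= 60:
                left_n += 1
            if rec.clip_left() >= params.min_clip and abs(rec.pos - point) <= 60:
                right_n += 1
        evidence.append(
            LocusEvidence(
                locus_id,
                chrom,
                point,
                n_junction_reads=max(left_n, right_n),
                n_ref_spanning=_ref_spanning(host_records, chrom, point),
            )
        )
    genotype = genotype_sample(presence, evidence, profiles, generation)
    genotype.sample_id = sample_id

    return SampleResult(
        sample_id=sample_id,
        generation=generation,
        presence=presence,
        loci=loci,
        integrations=integrations,
        sites=sites,
        profiles=profiles,
        tgi_flags=tgi,
        genotype=genotype,
        host_records=host_records,
        genome_mean_cov=genome_mean_cov,
        counts={
            "pairs_in": trim.counts.pairs_in,
            "pairs_after_trim": trim.counts.pairs_out,
            "orphans_placed": len(placements),
            "orphans_unplaced": unplaced,
            "loci_called": len(called),
        },
    )


@dataclass
class FamilyResult:
    outcome: FamilyOutcome
    parent: SampleResult
    progeny: list[SampleResult]
    segregation_tests: dict[str, float]


def run_family(
    family_id: str,
    parent: SampleResult,
    progeny: list[SampleResult],
) -> FamilyResult:
    """Classify transmission for a selfed family.

    Progeny are expected to have been genotyped at the parent's loci (pass
    ``genotype_loci`` from the parent's result into their ``run_sample``
    calls). Per hemizygous parental locus an exact binomial test compares
    the count of progeny that lost the locus with the Mendelian 1/4.
    """
    tgi_loci = tuple(
        locus.locus_id
        for locus, rec in zip(
            [l for l in parent.loci if l.status == "called"], parent.integrations
        )
        if any(
            parent.tgi_flags.get(s.site_id)
            and rec.host_deletion is not None
            and s.chrom == rec.chrom
            and rec.host_deletion[0] - 50 < s.cut < rec.host_deletion[1] + 50
            for s in parent.sites
        )
    )
    outcome = classify_family(
        parent.genotype, [p.genotype for p in progeny], tgi_loci, family_id
    )
    tests = {}
    for locus_id, (state, _) in parent.genotype.locus_states.items():
        if state not in (HEMIZYGOUS, HOMOZYGOUS):
            continue
        informative = [
            p.genotype.locus_states.get(locus_id, ("unresolved", 0.0))[0] for p in progeny
        ]
        informative = [s for s in informative if s != "unresolved"]
        if not informative:
            continue
        n_absent = sum(s == "absent" for s in informative)
        p_absent = 0.25 if state == HEMIZYGOUS else 0.0
        if state == HEMIZYGOUS:
            tests[locus_id] = mendelian_test(
                [n_absent, len(informative) - n_absent], [p_absent, 1 - p_absent]
            )
    return FamilyResult(outcome, parent, progeny, tests)


# ---------------------------------------------------------------------------
# microhomology over resolved junctions
# ---------------------------------------------------------------------------


def junction_microhomology(
    rec: IntegrationRecord,
    genome: HostGenome,
    cassette: CassetteModel,
    flank: int = 30,
    min_len: int = 2,
    window: int = 10,
) -> list[MicrohomologyCall]:
    """Microhomology calls for the resolved junctions of one integration."""
    calls = []
    if rec.host_deletion is None:
        return calls
    ref = genome.seq(rec.chrom)
    cas = cassette.sequence
    hl, hr = rec.host_deletion
    if rec.orientation_left in (SENSE, ANTISENSE) and rec.cassette_breakpoint_left is not None:
        bp = rec.cassette_breakpoint_left
        if rec.orientation_left == SENSE:
            term = cas[bp : bp + flank]
        else:
            term = cas[max(0, bp - flank) : bp][::-1].translate(
                str.maketrans("ACGT", "TGCA")
            )  # revcomp, junction-adjacent first
        calls.append(
            find_microhomology(
                ref[max(0, hl - flank) : hl + flank],
                term,
                min_len,
                window,
                junction_id=f"{rec.chrom}:{hl}:left",
                terminus_at="start",
            )
        )
    if rec.orientation_right in (SENSE, ANTISENSE) and rec.cassette_breakpoint_right is not None:
        bp = rec.cassette_breakpoint_right
        if rec.orientation_right == SENSE:
            term = cas[max(0, bp - flank) : bp]
        else:
            term = cas[bp : bp + flank][::-1].translate(str.maketrans("ACGT", "TGCA"))
        calls.append(
            find_microhomology(
                ref[max(0, hr - flank) : hr + flank],
                term,
                min_len,
                window,
                junction_id=f"{rec.chrom}:{hr}:right",
                terminus_at="end",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def _header(seed: int | None, params: PipelineParams | None) -> str:
    cfg = params.config_hash() if params else "na"
    return f"# tdnascope {__version__} seed={seed} config={cfg}\n"


def write_presence_tsv(path, results: list[SampleResult], seed=None, params=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, params))
        fh.write("sample\tn_mapped_reads\tmean_coverage\tbreadth\tverdict\n")
        for r in results:
            p = r.presence
            fh.write(
                f"{r.sample_id}\t{p.n_mapped_reads}\t{p.mean_coverage:.2f}"
                f"\t{p.breadth:.3f}\t{p.verdict}\n"
            )


def write_loci_bed(path, result: SampleResult, seed=None, params=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, params))
        for locus in result.loci:
            fh.write(
                f"{locus.chrom}\t{locus.interval[0]}\t{locus.interval[1]}"
                f"\t{locus.status}\t{locus.n_orphan_mates}\n"
            )


def format_deletion(rec: IntegrationRecord) -> str:
    if rec.deletion_length is None:
        return "unresolved"
    return f"d{rec.deletion_length}-bp"


def format_additions(rec: IntegrationRecord) -> str:
    fl, fr = rec.filler_lengths
    a = "unknown" if fl is None else f"{fl} bp"
    b = "unknown" if fr is None else f"{fr} bp"
    return f"{a}, {b}"


def write_integrations_tsv(path, results: list[SampleResult], seed=None, params=None) -> None:
    """Integration-event table: one row per resolved locus, with the host
    interval in 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write(_header(seed, params))
        fh.write(
            "sample\tposition\ttype\tgenic\tadditions\tcompleteness"
            "\torientation_left\torientation_right\n"
        )
        for r in results:
            for rec in r.integrations:
                if rec.host_deletion is not None:
                    a, b = rec.host_deletion
                    pos = f"{rec.chrom}: {a + 1:,}-{b:,}" if b > a else f"{rec.chrom}: {a + 1:,}"
                else:
                    pos = f"{rec.chrom}: unresolved"
                fh.write(
                    f"{r.sample_id}\t{pos}\t{format_deletion(rec)}\t{rec.genic}"
                    f"\t{format_additions(rec)}\t{rec.completeness}"
                    f"\t{rec.orientation_left}\t{rec.orientation_right}\n"
                )


def write_alleles_tsv(path, results: list[SampleResult], seed=None, params=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, params))
        fh.write("sample\tsite\tchrom\tcut\tallele\tnet\tcount\tproportion\tclass\n")
        for r in results:
            for site, prof in zip(r.sites, r.profiles):
                if prof.no_coverage:
                    fh.write(
                        f"{r.sample_id}\t{site.site_id}\t{site.chrom}\t{site.cut + 1}"
                        f"\tno_coverage\t\t0\t\t\n"
                    )
                    continue
                for d, net, count, prop in prof.alleles:
                    from .edits import classify_edit

                    cls = classify_edit(d, net) if d != "other" else "other"
                    fh.write(
                        f"{r.sample_id}\t{site.site_id}\t{site.chrom}\t{site.cut + 1}"
                        f"\t{d}\t{'' if net is None else net}\t{count}\t{prop:.3f}\t{cls}\n"
                    )


def write_microhomology_tsv(
    path, calls: list[MicrohomologyCall], seed=None, params=None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, params))
        fh.write(
            "junction\ttract\tlength\thost_offset\tcassette_offset"
            "\toffset_delta\thomopolymer_run\tstrand\n"
        )
        for c in calls:
            fh.write(
                f"{c.junction_id}\t{c.tract}\t{c.length}\t{c.host_offset}"
                f"\t{c.cassette_offset}\t{c.offset_delta}\t{c.homopolymer_run}\t{c.strand}\n"
            )


def write_family_json(path, fam: FamilyResult, seed=None, params=None) -> None:
    data = {
        "family": fam.outcome.family_id,
        "outcome": fam.outcome.outcome,
        "evidence": fam.outcome.evidence,
        "n_progeny": fam.outcome.n_progeny,
        "locus_transmission": fam.outcome.locus_transmission,
        "segregation_tests": fam.segregation_tests,
        "genotypes": {
            r.sample_id: {
                "generation": r.generation,
                "presence": r.presence.verdict,
                "loci": {k: v[0] for k, v in r.genotype.locus_states.items()},
            }
            for r in [fam.parent, *fam.progeny]
        },
        "provenance": _header(seed, params).strip("# \n"),
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
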