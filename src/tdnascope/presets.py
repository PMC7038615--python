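"""Named fixture presets emulating the four whole-plant-transformation
family scenarios the pipeline distinguishes, plus a wild-type control.

Each preset builds a seeded host genome, a cassette, planted integration and
edit events with the published junction parameters of its scenario (deletion
sizes, filler sizes, segment completeness, orientations), and sample specs
for a selfed parent plus progeny:

- ``fixture_536_2``  — single hemizygous full-cassette integration
  (35 bp host deletion, 4 bp/0 bp fillers) plus target-site indels; a
  progeny plant keeps the mutation homozygously but loses the transgene
  (clean Mendelian cosegregation).
- ``fixture_608_1``  — one integration (1 bp deletion, 9 bp filler, partial
  right-border segment) and chimeric somatic edits at two paralogous target
  sites (the paralog carries a 20% 4 bp-deletion allele); nothing reaches
  the progeny.
- ``fixture_608_3``  — four unlinked integrations (8/10/1/3 bp deletions,
  fillers 3+20/0+11/0+0/0+0 bp, one rearranged locus), two of them inside
  the paralogous CRISPR target sites (TGI); transgenes segregate into the
  progeny.
- ``fixture_553_6``  — mutations at the target site but no integrated
  transgene; trace cassette reads arise only from library
  cross-contamination; mutant alleles reach the progeny.

Geometry scales with ``host_len`` so the same scenarios serve both quick
tests and deeper fixtures. All placements are sanitized so the planted
junction parameters are the unique string-level interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import random_seq, revcomp
from .simulate import (
    ANTISENSE,
    SENSE,
    CassetteModel,
    EditTruth,
    Haplotype,
    HostGenome,
    IntegrationTruth,
    SampleSpec,
    TargetSpec,
    apply_integrations,
    make_cassette,
    make_host_genome,
    plant_target_edit,
    sanitize_integration,
    simulate_reads,
)

PAM = "AGG"
CUT_OFFSET = 17  # blunt cut between protospacer bases 17 and 18 (3 bp from PAM)


@dataclass
class FamilyFixture:
    family_id: str
    genome: HostGenome  # reference (sites injected, junctions sanitized)
    cassette: CassetteModel
    protospacers: list[str]
    targets: list[TargetSpec]
    samples: list[SampleSpec]  # parent first
    truths: dict[str, list[IntegrationTruth]]  # sample -> planted integrations
    annotation: list[tuple[str, int, int]] = field(default_factory=list)
    contamination: dict[str, tuple[list[Haplotype], float]] = field(default_factory=dict)
    expected_outcome: str = ""

    @property
    def parent(self) -> SampleSpec:
        return self.samples[0]

    @property
    def progeny(self) -> list[SampleSpec]:
        return self.samples[1:]


def _inject_site(
    genome: HostGenome, chrom: str, pos: int, protospacer: str, mismatch_from_pam: int = 0
) -> tuple[HostGenome, str]:
    """Overwrite the reference at ``pos`` with protospacer+PAM; optionally
    substitute one protospacer base at the given PAM distance (paralog
    model). Returns the genome and the site sequence as written."""
    site = protospacer
    if mismatch_from_pam:
        i = 20 - mismatch_from_pam
        repl = {"A": "G", "C": "T", "G": "A", "T": "C"}[site[i]]
        site = site[:i] + repl + site[i + 1 :]
    seq = genome.seq(chrom)
    new = seq[:pos] + site + PAM + seq[pos + 23 :]
    return genome.replace(chrom, new), site + PAM


def _diploid(
    sample_id: str,
    generation: str,
    hom0: list[tuple[str, str]],
    hom1: list[tuple[str, str]],
) -> SampleSpec:
    return SampleSpec(
        sample_id,
        generation,
        [Haplotype("hom0", hom0, 0.5), Haplotype("hom1", hom1, 0.5)],
    )


def _with_edit(
    chroms: list[tuple[str, str]], target: TargetSpec, edit: EditTruth
) -> list[tuple[str, str]]:
    out = []
    done = False
    for name, seq in chroms:
        if not done and target.sequence in seq:
            out.append((name, plant_target_edit(seq, target, edit)))
            done = True
        else:
            out.append((name, seq))
    if not done:
        raise ValueError(f"target {target.site_id} not found on any chromosome")
    return out


def _edited_chroms(
    genome: HostGenome, edited: dict[str, str]
) -> list[tuple[str, str]]:
    return [(n, edited.get(n, s)) for n, s in genome.chromosomes]


def fixture_536_2(seed: int = 0, host_len: int = 100_000) -> FamilyFixture:
    """Single-locus cosegregation scenario: hemizygous full cassette with a
    35 bp host deletion and a 4 bp filler on one side; a 2 bp-deletion and a
    1 bp-insertion allele at the target; progeny segregate the mutation away
    from the transgene."""
    rng = np.random.default_rng(seed)
    genome = make_host_genome(1, [host_len], 0.35, seed)
    cassette = make_cassette(seed + 1)
    chrom = genome.names[0]

    proto = random_seq(rng, 20, 0.5)
    site_pos = int(host_len * 0.72)
    genome, site_seq = _inject_site(genome, chrom, site_pos, proto)
    target = TargetSpec("t536", site_seq, CUT_OFFSET)

    ds = int(host_len * 0.30)
    truth = IntegrationTruth(
        chrom=chrom,
        host_deletion=(ds, ds + 35),
        filler_left=random_seq(rng, 4, 0.5),
        filler_right="",
        cassette_segment=cassette.tdna_interval(),
        orientation_left=SENSE,
        orientation_right=SENSE,
        microhomology_right=3,
        completeness="full",
    )
    genome, truth = sanitize_integration(
        genome, cassette, truth, immutable=[(site_pos, site_pos + 23)]
    )
    ref, edited = apply_integrations(genome, cassette, [truth])
    genome = ref

    wt = genome.chromosomes
    transgenic = _edited_chroms(genome, edited)
    d2 = EditTruth("t536", -2)
    ins1 = EditTruth("t536", +1, inserted="A")

    parent = _diploid(
        "WPT536-2",
        "T0/M0",
        _with_edit(wt, target, ins1),
        _with_edit(transgenic, target, d2),
    )
    prog_mut = SampleSpec(
        "WPT536-2-13-16",
        "M2",
        [Haplotype("d2hom", _with_edit(wt, target, d2), 1.0)],
    )
    prog_wt = SampleSpec(
        "WPT536-2-13-15", "M2", [Haplotype("wt", wt, 1.0)]
    )
    gene = (chrom, ds - 500, ds + 1500)  # the integration interrupts a gene model
    return FamilyFixture(
        family_id="WPT536-2",
        genome=genome,
        cassette=cassette,
        protospacers=[proto],
        targets=[target],
        samples=[parent, prog_mut, prog_wt],
        truths={"WPT536-2": [truth]},
        annotation=[gene],
        expected_outcome="cosegregating",
    )


def fixture_608_1(seed: int = 0, host_len: int = 100_000) -> FamilyFixture:
    """Failure-to-transmit scenario: one partial right-border integration
    (1 bp deletion, 9 bp filler on one side) plus chimeric somatic edits at
    an exact target and its 1-mismatch paralog (4 bp-deletion allele at 20%
    of reads); progeny are wild type."""
    rng = np.random.default_rng(seed)
    genome = make_host_genome(1, [host_len], 0.35, seed + 10)
    cassette = make_cassette(seed + 11)
    chrom = genome.names[0]

    proto = random_seq(rng, 20, 0.5)
    exact_pos = int(host_len * 0.55)
    genome, exact_seq = _inject_site(genome, chrom, exact_pos, proto)
    paralog_pos = int(host_len * 0.80)
    genome, paralog_seq = _inject_site(genome, chrom, paralog_pos, proto, mismatch_from_pam=16)
    t_exact = TargetSpec("t608", exact_seq, CUT_OFFSET)
    t_paralog = TargetSpec("t608p", paralog_seq, CUT_OFFSET)

    tdna = cassette.tdna_interval()
    ds = int(host_len * 0.25)
    truth = IntegrationTruth(
        chrom=chrom,
        host_deletion=(ds, ds + 1),
        filler_left="",
        filler_right=random_seq(rng, 9, 0.5),
        cassette_segment=(tdna[0], tdna[0] + 600),  # right border into the promoter
        orientation_left=SENSE,
        orientation_right=SENSE,
        completeness="partial",
    )
    immutable = [(exact_pos, exact_pos + 23), (paralog_pos, paralog_pos + 23)]
    genome, truth = sanitize_integration(genome, cassette, truth, immutable=immutable)
    ref, edited = apply_integrations(genome, cassette, [truth])
    genome = ref

    wt = genome.chromosomes
    transgenic = _edited_chroms(genome, edited)
    d4 = EditTruth("t608", -4)
    d4p = EditTruth("t608p", -4)
    edited_sector = _with_edit(_with_edit(wt, t_exact, d4), t_paralog, d4p)

    parent = SampleSpec(
        "WPT608-1",
        "T0/M0",
        [
            Haplotype("transgenic", transgenic, 0.5),
            Haplotype("wt", wt, 0.3),
            Haplotype("edited_sector", edited_sector, 0.2),
        ],
    )
    prog1 = SampleSpec("WPT608-1-1", "T1/M1", [Haplotype("wt", wt, 1.0)])
    prog2 = SampleSpec("WPT608-1-2", "T1/M1", [Haplotype("wt", wt, 1.0)])
    return FamilyFixture(
        family_id="WPT608-1",
        genome=genome,
        cassette=cassette,
        protospacers=[proto],
        targets=[t_exact, t_paralog],
        samples=[parent, prog1, prog2],
        truths={"WPT608-1": [truth]},
        expected_outcome="not_transmitted",
    )


def fixture_608_3(seed: int = 0, host_len: int = 24_000, n_chrom: int = 4) -> FamilyFixture:
    """Four-locus TGI scenario: integrations with 8, 10, 1 and 3 bp host
    deletions (fillers 3+20, 0+11, 0+0, 0+0 bp), one rearranged; the 10 bp
    and 1 bp deletions sit inside the paralogous CRISPR target sites, so the
    cassette itself repaired those cuts (TGI). Transgene loci segregate into
    the progeny. ``host_len`` is the per-chromosome length; with fewer than
    four chromosomes the loci share chromosomes but stay far apart."""
    rng = np.random.default_rng(seed)
    genome = make_host_genome(n_chrom, [host_len] * n_chrom, 0.35, seed + 20)
    cassette = make_cassette(seed + 21)
    names = genome.names

    c_a, c_b = names[0], names[1 % n_chrom]
    c_c, c_d = names[2 % n_chrom], names[3 % n_chrom]

    proto = random_seq(rng, 20, 0.5)
    exact_pos = int(host_len * 0.75)  # on c_c
    genome, exact_seq = _inject_site(genome, c_c, exact_pos, proto)
    paralog_pos = int(host_len * 0.35)  # on c_b
    genome, paralog_seq = _inject_site(genome, c_b, paralog_pos, proto, mismatch_from_pam=16)
    t_exact = TargetSpec("t16", exact_seq, CUT_OFFSET)
    t_paralog = TargetSpec("t09", paralog_seq, CUT_OFFSET)
    cut_exact = exact_pos + CUT_OFFSET
    cut_paralog = paralog_pos + CUT_OFFSET

    tdna = cassette.tdna_interval()
    half = (tdna[0] + tdna[1]) // 2
    t_chr06 = IntegrationTruth(
        chrom=c_a,
        host_deletion=(int(host_len * 0.30), int(host_len * 0.30) + 8),
        filler_left=random_seq(rng, 3, 0.5),
        filler_right=random_seq(rng, 20, 0.5),
        cassette_segment=(tdna[0], half),
        orientation_left=SENSE,
        orientation_right=SENSE,
        completeness="partial",
    )
    t_chr18 = IntegrationTruth(
        chrom=c_d,
        host_deletion=(int(host_len * 0.62), int(host_len * 0.62) + 3),
        cassette_segment=tdna,
        orientation_left=ANTISENSE,
        orientation_right=SENSE,
        microhomology_left=3,
        completeness="rearranged",
    )
    t_chr09 = IntegrationTruth(
        chrom=c_b,
        host_deletion=(cut_paralog - 5, cut_paralog + 5),
        filler_left="",
        filler_right=random_seq(rng, 11, 0.5),
        cassette_segment=tdna,
        orientation_left=SENSE,
        orientation_right=SENSE,
        completeness="full",
    )
    t_chr16 = IntegrationTruth(
        chrom=c_c,
        host_deletion=(cut_exact, cut_exact + 1),
        cassette_segment=tdna,
        orientation_left=SENSE,
        orientation_right=SENSE,
        completeness="full",
    )
    immutable = {
        c_c: [(exact_pos, exact_pos + 23)],
        c_b: [(paralog_pos, paralog_pos + 23)],
    }
    truths = []
    for t in (t_chr06, t_chr18, t_chr09, t_chr16):
        genome, t = sanitize_integration(
            genome, cassette, t, immutable=immutable.get(t.chrom, [])
        )
        truths.append(t)
    t_chr06, t_chr18, t_chr09, t_chr16 = truths

    ref, edited_all = apply_integrations(genome, cassette, truths)
    genome = ref
    wt = genome.chromosomes
    hom1 = _edited_chroms(genome, edited_all)  # all four integrations
    ins1 = EditTruth("t16", +1, inserted="T")
    ins1p = EditTruth("t09", +1, inserted="T")
    hom0 = _with_edit(wt, t_exact, ins1)  # +1 allele at the exact site

    parent = _diploid("WPT608-3", "T0/M0", hom0, hom1)

    # progeny 1: homozygous for the chr16-style TGI locus, hemizygous chr09
    _, ed16 = apply_integrations(genome, cassette, [t_chr16])
    _, ed16_09 = apply_integrations(genome, cassette, [t_chr16, t_chr09])
    p1_hom0 = _with_edit(_edited_chroms(genome, ed16), t_paralog, ins1p)
    p1_hom1 = _edited_chroms(genome, ed16_09)
    prog1 = _diploid("WPT608-3-2", "T1/M1", p1_hom0, p1_hom1)

    # progeny 2: hemizygous chr16 locus, +1 allele on the other homolog
    p2_hom0 = _with_edit(wt, t_exact, ins1)
    p2_hom1 = _edited_chroms(genome, ed16)
    prog2 = _diploid("WPT608-3-1", "T1/M1", p2_hom0, p2_hom1)

    return FamilyFixture(
        family_id="WPT608-3",
        genome=genome,
        cassette=cassette,
        protospacers=[proto],
        targets=[t_exact, t_paralog],
        samples=[parent, prog1, prog2],
        truths={"WPT608-3": truths},
        annotation=[
            (c_a, t_chr06.host_deletion[0] - 300, t_chr06.host_deletion[1] + 1200),
            (c_b, paralog_pos - 400, paralog_pos + 1200),
            (c_c, exact_pos - 400, exact_pos + 1200),
        ],
        expected_outcome="target_TGI_multilocus",
    )


def fixture_553_6(seed: int = 0, host_len: int = 100_000) -> FamilyFixture:
    """Mutation-without-integration scenario: the parent carries a chimeric
    7 bp-deletion allele but no integrated transgene; trace cassette reads
    come only from cross-contamination by a foreign transgenic library.
    Progeny carry novel 2 bp and 6 bp deletion alleles and no transgene."""
    rng = np.random.default_rng(seed)
    genome = make_host_genome(1, [host_len], 0.35, seed + 30)
    cassette = make_cassette(seed + 31)
    chrom = genome.names[0]

    proto = random_seq(rng, 20, 0.5)
    site_pos = int(host_len * 0.5)
    genome, site_seq = _inject_site(genome, chrom, site_pos, proto)
    target = TargetSpec("t553", site_seq, CUT_OFFSET)

    # foreign transgenic donor (the contaminating library)
    donor_truth = IntegrationTruth(
        chrom=chrom,
        host_deletion=(int(host_len * 0.22), int(host_len * 0.22) + 12),
        cassette_segment=cassette.tdna_interval(),
        orientation_left=SENSE,
        orientation_right=SENSE,
    )
    genome, donor_truth = sanitize_integration(
        genome, cassette, donor_truth, immutable=[(site_pos, site_pos + 23)]
    )
    ref, donor_edit = apply_integrations(genome, cassette, [donor_truth])
    genome = ref
    wt = genome.chromosomes
    donor = [Haplotype("donor", _edited_chroms(genome, donor_edit), 1.0)]

    # the T0 plant is chimeric for two distinct 7 bp-deletion alleles
    d7 = EditTruth("t553", -7)
    parent = SampleSpec(
        "WPT553-6",
        "T0/M0",
        [
            Haplotype("wt", wt, 0.5),
            Haplotype("d7a", _with_edit(wt, target, d7), 0.25),
            Haplotype("d7b", _with_edit(wt, target, d7), 0.25),
        ],
    )
    prog1 = _diploid(
        "WPT553-6-8", "T1/M1", wt, _with_edit(wt, target, EditTruth("t553", -2))
    )
    prog2 = _diploid(
        "WPT553-6-11", "T1/M1", wt, _with_edit(wt, target, EditTruth("t553", -6))
    )
    return FamilyFixture(
        family_id="WPT553-6",
        genome=genome,
        cassette=cassette,
        protospacers=[proto],
        targets=[target],
        samples=[parent, prog1, prog2],
        truths={},
        contamination={
            "WPT553-6": (donor, 0.012),
            "WPT553-6-8": (donor, 0.004),
            "WPT553-6-11": (donor, 0.004),
        },
        expected_outcome="mutation_without_integration",
    )


def fixture_wild_type(seed: int = 0, host_len: int = 50_000) -> FamilyFixture:
    """Non-transgenic control: no events, no contamination."""
    genome = make_host_genome(1, [host_len], 0.35, seed + 40)
    cassette = make_cassette(seed + 41)
    wt = SampleSpec("Bert-MN-01", "T0/M0", [Haplotype("wt", genome.chromosomes, 1.0)])
    return FamilyFixture(
        family_id="wild-type",
        genome=genome,
        cassette=cassette,
        protospacers=[],
        targets=[],
        samples=[wt],
        truths={},
        expected_outcome="",
    )


FAMILY_PRESETS = {
    "536-2": fixture_536_2,
    "608-1": fixture_608_1,
    "608-3": fixture_608_3,
    "553-6": fixture_553_6,
    "wild-type": fixture_wild_type,
}


def simulate_sample(
    fixture: FamilyFixture,
    sample: SampleSpec,
    depth: float = 20.0,
    err_rate: float = 0.001,
    seed: int = 0,
):
    """Simulate reads for one fixture sample (preset contamination applied)."""
    contam = fixture.contamination.get(sample.sample_id)
    return simulate_reads(
        sample,
        depth=depth,
        err_rate=err_rate,
        contamination=contam,
        seed=seed,
    )


def run_family_fixture(
    fixture: FamilyFixture,
    seed: int = 0,
    depth: float = 20.0,
    err_rate: float = 0.001,
    params=None,
):
    """Simulate every sample of a family fixture and run the full analysis:
    parent first, then progeny genotyped at the parent's called loci."""
    from .align import SeedIndex
    from .pipeline import PipelineParams, locus_insertion_point, run_family, run_sample

    params = params or PipelineParams()
    host_index = SeedIndex(fixture.genome.chromosomes, params.aligner.k)
    cassette_index = SeedIndex([("cassette", fixture.cassette.sequence)], params.aligner.k)

    def _run(sample, sub_seed, genotype_loci=None):
        sim = simulate_sample(fixture, sample, depth, err_rate, seed=sub_seed)
        pairs = [
            ((pid + "/1", r1, q1), (pid + "/2", r2, q2))
            for pid, r1, q1, r2, q2 in sim.pairs
        ]
        return run_sample(
            sample.sample_id,
            sample.generation,
            pairs,
            fixture.genome,
            fixture.cassette,
            protospacers=fixture.protospacers,
            annotation=fixture.annotation or None,
            params=params,
            host_index=host_index,
            cassette_index=cassette_index,
            genotype_loci=genotype_loci,
        )

    parent_res = _run(fixture.parent, seed * 1000 + 1)
    called = [l for l in parent_res.loci if l.status == "called"]
    loci = [
        (locus.locus_id, locus.chrom, locus_insertion_point(rec, locus))
        for locus, rec in zip(called, parent_res.integrations)
    ]
    prog_res = [
        _run(s, seed * 1000 + 2 + i, genotype_loci=loci)
        for i, s in enumerate(fixture.progeny)
    ]
    return run_family(fixture.family_id, parent_res, prog_res)


#: planted microhomology tracts (length 2-4, each containing a repeated-base
#: run) for the 11-junction microhomology fixture
MICROHOMOLOGY_TRACTS = (
    "AAT", "TTG", "GGC", "AATT", "CCA", "TTA", "GGGT", "CAA", "TTC", "GGA", "AAAT",
)


def microhomology_junction_fixture(seed: int = 0, flank: int = 30, window: int = 10):
    """Eleven junction fixtures with planted microhomology tracts.

    Each junction is a (host_flank, cassette_terminus, tract) triple where
    the tract sits immediately at both breakpoints and — by construction —
    is the best tract the caller can return: flanks are redrawn until no
    coincidental common substring beats the planted one.
    """
    from .microhomology import find_microhomology

    rng = np.random.default_rng(seed)
    bases = list("ACGT")
    out = []
    for tract in MICROHOMOLOGY_TRACTS:
        m = len(tract)
        for _ in range(200):
            host = "".join(rng.choice(bases, 2 * flank))
            cass = "".join(rng.choice(bases, flank))
            host = host[: flank - m] + tract + host[flank:]
            cass = tract + cass[m:]
            call = find_microhomology(host, cass, 2, window)
            if call.tract == tract and call.offset_delta == 0:
                out.append((host, cass, tract))
                break
        else:
            raise RuntimeError(f"could not build junction for tract {tract}")
    return out
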