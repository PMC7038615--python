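"""Synthetic-data generator: genome/cassette construction, event planting,
read simulation, and the generator's own contracts (determinism, origin
conservation, junction identifiability)."""

import numpy as np
import pytest
from scipy.stats import binomtest

from tdnascope.dna import gc_fraction, revcomp
from tdnascope.simulate import (
    EditTruth,
    Haplotype,
    IntegrationTruth,
    SampleSpec,
    SimulationError,
    TargetSpec,
    apply_integrations,
    junction_violations,
    make_cassette,
    make_host_genome,
    oriented_insert,
    plant_integration,
    plant_target_edit,
    sanitize_integration,
    simulate_reads,
)


class TestMakeHostGenome:
    def test_length_echo(self):
        g = make_host_genome(1, [100_000], 0.35, 7)
        assert len(g.chromosomes) == 1
        assert len(g.seq("Chr01")) == 100_000

    def test_seed_determinism(self):
        a = make_host_genome(2, [15_000, 12_000], 0.4, 3)
        b = make_host_genome(2, [15_000, 12_000], 0.4, 3)
        assert a.chromosomes == b.chromosomes

    def test_gc_content_converges(self):
        g = make_host_genome(2, [50_000, 50_000], 0.5, 1)
        gc = np.mean([gc_fraction(s) for _, s in g.chromosomes])
        assert 0.48 <= gc <= 0.52

    @pytest.mark.parametrize("bad", [(1, [0]), (1, [-5]), (2, [1000])])
    def test_invalid_lengths_rejected(self, bad):
        with pytest.raises(SimulationError):
            make_host_genome(bad[0], bad[1], 0.5, 0)


class TestCassette:
    def test_structure(self, cassette):
        assert len(cassette.components[0].sequence) == 100
        assert len(cassette.components[-1].sequence) == 100
        rb, lb = cassette.role_interval("right_border"), cassette.role_interval("left_border")
        assert rb[0] < lb[0]
        assert cassette.sequence == "".join(c.sequence for c in cassette.components)

    def test_host_homologous_promoter_masked(self, small_genome):
        promoter = small_genome.seq("Chr01")[1000:1300]
        cas = make_cassette(2, promoter_from_host=promoter)
        masked_total = sum(b - a for a, b in cas.unmasked_intervals())
        assert masked_total == len(cas) - 200 - 300  # flanks and promoter excluded


class TestPlantIntegration:
    def _truth(self, cassette, ds, **kw):
        kw.setdefault("cassette_segment", cassette.tdna_interval())
        return IntegrationTruth(chrom="Chr01", host_deletion=(ds, ds + kw.pop("dlen", 0)), **kw)

    def test_length_arithmetic_with_deletion_and_filler(self, small_genome, cassette):
        # 35 bp deletion, 4 bp filler on one side, full cassette segment
        t = self._truth(cassette, 5000, dlen=35, filler_left="ACGT")
        ref, edited = plant_integration(small_genome, cassette, t)
        seg = cassette.tdna_interval()
        assert len(edited) == 20_000 - 35 + 4 + (seg[1] - seg[0])

    def test_blunt_insertion_preserves_flanks(self, small_genome, cassette):
        t = self._truth(cassette, 7000)
        ref, edited = plant_integration(small_genome, cassette, t)
        orig = small_genome.seq("Chr01")
        assert edited[:7000] == orig[:7000]
        seg_len = cassette.tdna_interval()[1] - cassette.tdna_interval()[0]
        assert edited[7000 + seg_len :] == orig[7000:]

    def test_planted_microhomology_shared_bases(self, small_genome, cassette):
        t = self._truth(cassette, 6000, dlen=10, microhomology_left=4)
        ref, edited = plant_integration(small_genome, cassette, t)
        core = oriented_insert(cassette, t)
        assert ref.seq("Chr01")[5996:6000] == core[:4]
        assert edited[5996:6000] == core[:4]

    def test_antisense_insert_is_revcomp(self, small_genome, cassette):
        seg = cassette.tdna_interval()
        t = IntegrationTruth(
            "Chr01", (4000, 4000), cassette_segment=seg,
            orientation_left="antisense", orientation_right="antisense",
        )
        _, edited = plant_integration(small_genome, cassette, t)
        expected = revcomp(cassette.sequence[seg[0] : seg[1]])
        assert edited[4000 : 4000 + len(expected)] == expected

    def test_segment_outside_cassette_rejected(self, small_genome, cassette):
        t = IntegrationTruth("Chr01", (100, 100), cassette_segment=(0, len(cassette) + 1))
        with pytest.raises(SimulationError):
            plant_integration(small_genome, cassette, t)


class TestPlantTargetEdit:
    @pytest.fixture()
    def hap_and_target(self, small_genome):
        seq = small_genome.seq("Chr01")
        site = seq[9000:9023]
        return seq, TargetSpec("t1", site, 17)

    def test_deletion_shortens(self, hap_and_target):
        hap, target = hap_and_target
        out = plant_target_edit(hap, target, EditTruth("t1", -2))
        assert len(out) == len(hap) - 2

    def test_insertion_lengthens(self, hap_and_target):
        hap, target = hap_and_target
        out = plant_target_edit(hap, target, EditTruth("t1", +1, inserted="G"))
        assert len(out) == len(hap) + 1
        cut = 9000 + 17
        assert out[:cut] == hap[:cut] and out[cut] == "G" and out[cut + 1 :] == hap[cut:]

    def test_zero_net_is_noop(self, hap_and_target):
        hap, target = hap_and_target
        assert plant_target_edit(hap, target, EditTruth("t1", 0)) == hap

    def test_absent_site_rejected(self, hap_and_target):
        hap, target = hap_and_target
        bad = TargetSpec("t1", "A" * 30, 10)
        with pytest.raises(SimulationError):
            plant_target_edit(hap, bad, EditTruth("t1", -2))


class TestSimulateReads:
    def _sample(self, genome):
        return SampleSpec("s", "T0/M0", [Haplotype("wt", genome.chromosomes, 1.0)])

    def test_pair_count_formula(self):
        g = make_host_genome(1, [100_000], 0.35, 3)
        sim = simulate_reads(self._sample(g), depth=20, read_len=125, seed=1)
        assert len(sim.pairs) == 8000  # 20 * 100000 / (2 * 125)

    def test_error_free_reads_are_haplotype_substrings(self, small_genome):
        sim = simulate_reads(self._sample(small_genome), depth=2, err_rate=0.0, seed=2)
        seq = small_genome.seq("Chr01")
        for (pid, r1, _, r2, _), t in zip(sim.pairs, sim.truth):
            frag = seq[t.start : t.end]
            fwd, rev = frag[:125], revcomp(frag[-125:])
            assert (r1, r2) == ((fwd, rev) if t.strand == 0 else (rev, fwd))

    def test_byte_determinism(self, small_genome):
        a = simulate_reads(self._sample(small_genome), depth=1, seed=9)
        b = simulate_reads(self._sample(small_genome), depth=1, seed=9)
        assert a.pairs == b.pairs and a.truth_json() == b.truth_json()

    def test_chimeric_fraction_within_binomial_ci(self, small_genome):
        seq = small_genome.seq("Chr01")
        site = TargetSpec("t", seq[10_000:10_023], 17)
        mutant = plant_target_edit(seq, site, EditTruth("t", -4))
        sample = SampleSpec(
            "chimera",
            "T0/M0",
            [
                Haplotype("wt", [("Chr01", seq)], 0.8),
                Haplotype("d4", [("Chr01", mutant)], 0.2),
            ],
        )
        sim = simulate_reads(sample, depth=30, err_rate=0.0, seed=4)
        cut = 10_017
        n = k = 0
        for t in sim.truth:
            if t.start < cut - 130 or t.start > cut + 5:
                continue
            n += 1
            k += t.haplotype == "d4"
        ci = binomtest(k, n).proportion_ci(confidence_level=0.99, method="exact")
        assert ci.low <= 0.2 <= ci.high

    def test_contamination_recorded(self, small_genome):
        donor = [Haplotype("donor", small_genome.chromosomes, 1.0)]
        sim = simulate_reads(
            self._sample(small_genome), depth=5, seed=3, contamination=(donor, 0.05)
        )
        frac = np.mean([t.contaminant for t in sim.truth])
        assert 0.02 < frac < 0.09

    def test_bad_fragment_mean_rejected(self, small_genome):
        with pytest.raises(SimulationError):
            simulate_reads(self._sample(small_genome), frag_mean=100, read_len=125)


class TestJunctionIdentifiability:
    def test_sanitized_junctions_have_no_violations(self, cassette):
        for seed in range(5):
            g = make_host_genome(1, [15_000], 0.35, seed)
            rng = np.random.default_rng(seed)
            t = IntegrationTruth(
                "Chr01",
                (6000, 6010),
                filler_left="".join(rng.choice(list("ACGT"), 4)),
                filler_right="",
                cassette_segment=cassette.tdna_interval(),
                microhomology_right=3,
            )
            g2, t2 = sanitize_integration(g, cassette, t)
            ref, _ = apply_integrations(g2, cassette, [t2])
            assert junction_violations(ref.seq("Chr01"), cassette, t2) == []
            assert t2.deletion_length == 10 and len(t2.filler_left) == 4

    def test_fillers_recoverable_by_string_inspection(self, cassette):
        g = make_host_genome(1, [15_000], 0.35, 77)
        t = IntegrationTruth(
            "Chr01", (5000, 5020), filler_left="ACGT", filler_right="TTAAC",
            cassette_segment=cassette.tdna_interval(),
        )
        g, t = sanitize_integration(g, cassette, t)
        ref, edited_map = apply_integrations(g, cassette, [t])
        edited = edited_map["Chr01"]
        core = oriented_insert(cassette, t)
        ds, de = t.host_deletion
        insert = edited[ds : len(edited) - (len(ref.seq("Chr01")) - de)]
        assert insert == t.filler_left + core + t.filler_right
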