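"""Classify transgene/mutation transmission for the four family scenarios.

Runs each family preset end to end — simulate parent and progeny reads,
detect and genotype loci, quantify alleles — and classifies the family
outcome. Also shows the exact Mendelian test on the published-style count of
4 transgene-free plants out of 27 selfed progeny of a hemizygote.
"""

from tdnascope.inheritance import mendelian_test
from tdnascope.presets import FAMILY_PRESETS, run_family_fixture

scale = {
    "536-2": dict(host_len=12_000),
    "608-1": dict(host_len=12_000),
    "608-3": dict(host_len=10_000, n_chrom=2),
    "553-6": dict(host_len=12_000),
}
for name, kwargs in scale.items():
    fix = FAMILY_PRESETS[name](seed=4, **kwargs)
    fam = run_family_fixture(fix, seed=4, depth=20, err_rate=0.001)
    print(f"{fix.family_id}: {fam.outcome.outcome}")
    for sid, n in fam.outcome.locus_transmission.items():
        print(f"    locus {sid}: inherited by {n}/{fam.outcome.n_progeny} progeny")
    for lid, p in fam.segregation_tests.items():
        print(f"    segregation test at {lid}: p = {p:.3f}")

# A hemizygous locus should be lost by 1/4 of selfed progeny; observing 4
# transgene-free plants among 27 is entirely consistent with that:
p = mendelian_test([4, 23], [0.25, 0.75])
print(f"\nexact two-sided binomial test, 4/27 transgene-free vs 1/4: p = {p:.3f}")
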