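"""Per-plant genotyping and family-level transmission classification.

A plant is genotyped at each transgene locus from the ratio of
reference-spanning to junction-supporting reads, and at each target site
from its allele profile. Families (a selfed parent plus progeny) are then
classified into the transmission outcomes the segregation analysis
distinguishes: clean cosegregation of transgene and mutation, complete
failure to transmit, transgene integration at the target sites themselves,
and mutation transmission without any evidence of an integrated transgene.
An exact Mendelian segregation test (binomial or multinomial) supports
quantitative checks against selfing expectations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .detect import PresenceCall
from .edits import TGI, WT, AlleleProfile

ABSENT, HEMIZYGOUS, HOMOZYGOUS, UNRESOLVED = (
    "absent",
    "hemizygous",
    "homozygous",
    "unresolved",
)

GENERATIONS = ("T0/M0", "T0", "M0", "T1/M1", "T1", "M1", "T2/M2", "T2", "M2", "M3")


@dataclass
class LocusEvidence:
    """Read evidence for one transgene locus in one sample."""

    locus_id: str
    chrom: str
    position: int  # insertion point on the host reference
    n_junction_reads: int
    n_ref_spanning: int


@dataclass
class SampleGenotype:
    sample_id: str
    generation: str
    locus_states: dict[str, tuple[str, float]]  # locus_id -> (state, ref_fraction)
    profiles: dict[str, AlleleProfile]
    presence: PresenceCall | None = None
    warnings: list[str] = field(default_factory=list)

    def has_transgene(self) -> bool:
        if any(s in (HEMIZYGOUS, HOMOZYGOUS) for s, _ in self.locus_states.values()):
            return True
        return self.presence is not None and self.presence.verdict == "integrated"

    def has_mutation(self, min_proportion: float = 0.1) -> bool:
        for prof in self.profiles.values():
            for d, net, count, prop in prof.alleles:
                if d not in (WT, "other", TGI) and prop >= min_proportion:
                    return True
        return False

    def carries_locus(self, locus_id: str) -> bool:
        return self.locus_states.get(locus_id, (ABSENT, 1.0))[0] in (HEMIZYGOUS, HOMOZYGOUS)


@dataclass
class FamilyOutcome:
    family_id: str
    outcome: str
    evidence: list[str]
    locus_transmission: dict[str, int]  # locus_id -> n progeny carrying it
    n_progeny: int


def genotype_sample(
    presence: PresenceCall | None,
    loci_evidence: list[LocusEvidence],
    profiles: list[AlleleProfile],
    generation: str,
) -> SampleGenotype:
    """Call per-locus transgene state from junction vs reference reads.

    With ``f`` the reference-spanning fraction at a locus: f in [0.25, 0.75]
    is hemizygous, f <= 0.1 homozygous, f >= 0.9 absent provided nothing
    still supports the junction (or the sample-level presence verdict is
    trace/absent); anything else — including zero informative reads — is
    unresolved.
    """
    if generation not in GENERATIONS:
        raise ValueError(f"unknown generation label {generation!r}")
    states: dict[str, tuple[str, float]] = {}
    warnings = []
    for ev in loci_evidence:
        total = ev.n_junction_reads + ev.n_ref_spanning
        if total == 0:
            states[ev.locus_id] = (UNRESOLVED, float("nan"))
            warnings.append(f"{ev.locus_id}: no informative reads")
            continue
        f = ev.n_ref_spanning / total
        if 0.25 <= f <= 0.75:
            state = HEMIZYGOUS
        elif f <= 0.1:
            state = HOMOZYGOUS
        elif f >= 0.9 and (
            ev.n_junction_reads == 0
            or (presence is not None and presence.verdict in ("trace", "absent"))
        ):
            state = ABSENT
        else:
            state = UNRESOLVED
            warnings.append(f"{ev.locus_id}: ambiguous ref fraction {f:.2f}")
        states[ev.locus_id] = (state, f)
    sample_id = presence.sample_id if presence is not None else "sample"
    return SampleGenotype(
        sample_id=sample_id,
        generation=generation,
        locus_states=states,
        profiles={p.site_id: p for p in profiles},
        presence=presence,
        warnings=warnings,
    )


def expected_segregation(
    loci: list[tuple[str, str]], mating: str = "selfing"
) -> tuple[dict[str, dict[str, float]], dict[tuple[str, ...], float]]:
    """Selfing expectations for unlinked transgene loci.

    Per locus: a hemizygous parent gives 1/4 absent, 1/2 hemizygous, 1/4
    homozygous; a homozygous parent breeds true. Joint class probabilities
    multiply across loci (independent assortment). Returns (per-locus table,
    joint distribution over state tuples); both sum to 1.
    """
    if mating != "selfing":
        raise ValueError("only selfing is modelled")
    per_locus: dict[str, dict[str, float]] = {}
    for locus_id, zyg in loci:
        if zyg == HEMIZYGOUS:
            per_locus[locus_id] = {ABSENT: 0.25, HEMIZYGOUS: 0.5, HOMOZYGOUS: 0.25}
        elif zyg == HOMOZYGOUS:
            per_locus[locus_id] = {ABSENT: 0.0, HEMIZYGOUS: 0.0, HOMOZYGOUS: 1.0}
        else:
            raise ValueError(f"parental zygosity must be hemi/homozygous, got {zyg!r}")
    joint: dict[tuple[str, ...], float] = {}
    ids = [l for l, _ in loci]
    for combo in itertools.product((ABSENT, HEMIZYGOUS, HOMOZYGOUS), repeat=len(ids)):
        p = 1.0
        for lid, st in zip(ids, combo):
            p *= per_locus[lid][st]
        if p > 0:
            joint[combo] = p
    return per_locus, joint


def _log_multinomial_pmf(counts: tuple[int, ...], probs: np.ndarray) -> float:
    n = sum(counts)
    lp = math.lgamma(n + 1)
    for c, p in zip(counts, probs):
        if c > 0 and p == 0:
            return -math.inf
        lp -= math.lgamma(c + 1)
        if c > 0:
            lp += c * math.log(p)
    return lp


def mendelian_test(
    observed: list[int],
    expected: list[float],
    n: int | None = None,
    seed: int = 0,
    n_mc: int = 200_000,
    max_exact_n: int = 30,
) -> float:
    """Exact two-sided goodness-of-fit p-value under minimum-likelihood
    ordering: the p-value sums the probabilities of all outcomes no more
    likely than the observation.

    Two classes reduce to the exact binomial test. More classes are
    enumerated exhaustively for n <= ``max_exact_n`` and estimated by seeded
    Monte Carlo beyond that.
    """
    if len(observed) != len(expected):
        raise ValueError("observed and expected dimension mismatch")
    total = sum(observed)
    if n is None:
        n = total
    elif n != total:
        raise ValueError(f"sum(observed)={total} != n={n}")
    probs = np.asarray(expected, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("expected probabilities must sum to 1")
    eps = 1e-12
    if len(observed) == 2:
        from scipy.stats import binom

        k, p = observed[0], probs[0]
        pmf = binom.pmf(np.arange(n + 1), n, p)
        return float(pmf[pmf <= pmf[k] * (1 + eps)].sum())
    obs_lp = _log_multinomial_pmf(tuple(observed), probs)
    if n <= max_exact_n:
        k = len(observed)
        pval = 0.0
        for combo in itertools.combinations_with_replacement(range(k), n):
            counts = [0] * k
            for c in combo:
                counts[c] += 1
            lp = _log_multinomial_pmf(tuple(counts), probs)
            if lp <= obs_lp + eps:
                pval += math.exp(lp)
        return min(pval, 1.0)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=n_mc)
    lps = np.array([_log_multinomial_pmf(tuple(d), probs) for d in draws])
    return float((lps <= obs_lp + eps).mean())


COSEGREGATING = "cosegregating"
NOT_TRANSMITTED = "not_transmitted"
TARGET_TGI_MULTILOCUS = "target_TGI_multilocus"
MUTATION_WITHOUT_INTEGRATION = "mutation_without_integration"
OTHER = "other"


def classify_family(
    parent: SampleGenotype,
    progeny: list[SampleGenotype],
    tgi_loci: tuple[str, ...] = (),
    family_id: str = "family",
) -> FamilyOutcome:
    """Classify family-level transmission from parent and progeny genotypes.

    Decision rules, in order:

    1. cosegregating — the parent carries an integrated transgene and at
       least one progeny lost the transgene but kept a mutation (the
       Mendelian ideal: select the mutation away from the transgene).
    2. not_transmitted — the parent has mutations and/or an integration but
       no progeny shows either (a chimeric T0 whose transformed sector did
       not reach the germline).
    3. target_TGI_multilocus — a transgene locus sitting in a CRISPR target
       site segregates into the progeny.
    4. mutation_without_integration — the parent is mutation-positive with
       only trace/absent transgene evidence, and mutations reach progeny
       (transient-expression signature).
    5. other.

    The result is invariant to progeny order.
    """
    if not progeny:
        raise ValueError("at least one progeny required")
    transmission = {
        lid: sum(p.carries_locus(lid) for p in progeny) for lid in parent.locus_states
    }
    evidence: list[str] = []
    parent_tg = parent.has_transgene()
    parent_mut = parent.has_mutation()

    outcome = OTHER
    coseg = [
        p for p in progeny if not p.has_transgene() and p.has_mutation()
    ]
    if parent_tg and coseg:
        outcome = COSEGREGATING
        evidence.append(
            f"progeny without transgene but with mutation: "
            f"{sorted(p.sample_id for p in coseg)}"
        )
    elif (parent_tg or parent_mut) and not any(
        p.has_transgene() or p.has_mutation() for p in progeny
    ):
        outcome = NOT_TRANSMITTED
        evidence.append("no progeny carries transgene or mutation")
    elif any(
        lid in parent.locus_states
        and parent.carries_locus(lid)
        and transmission.get(lid, 0) > 0
        for lid in tgi_loci
    ):
        outcome = TARGET_TGI_MULTILOCUS
        evidence.append(f"TGI loci transmitted: {sorted(set(tgi_loci))}")
    elif (
        parent_mut
        and parent.presence is not None
        and parent.presence.verdict in ("trace", "absent")
        and any(p.has_mutation() for p in progeny)
    ):
        outcome = MUTATION_WITHOUT_INTEGRATION
        evidence.append(
            f"parent transgene evidence only {parent.presence.verdict}; "
            "mutations reached progeny"
        )
    return FamilyOutcome(family_id, outcome, evidence, transmission, len(progeny))
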