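"""Scan a genome for CRISPR target sites, including mismatched paralogs.

Embeds an exact protospacer+NGG site and a paralogous copy carrying one
substitution 16 bp from the PAM, then scans with up to two mismatches. The
scanner reports each mismatch by its distance from the PAM (PAM-proximal
base = 1) — the coordinate system used when describing off-target risk.
"""

from tdnascope.edits import scan_target_sites
from tdnascope.simulate import make_host_genome

PROTO = "GATTACAGGTCACTGCAATC"

genome = make_host_genome(1, [100_000], 0.35, seed=9)
seq = genome.seq("Chr01")
seq = seq[:20_000] + PROTO + "AGG" + seq[20_023:]          # exact site
i = 20 - 16                                                 # 16 bp from PAM
mut = PROTO[:i] + {"A": "G", "C": "T", "G": "A", "T": "C"}[PROTO[i]] + PROTO[i + 1:]
seq = seq[:60_000] + mut + "AGG" + seq[60_023:]             # paralog
genome = genome.replace("Chr01", seq)

for max_mm in (0, 1):
    sites = scan_target_sites(genome, PROTO, max_mm=max_mm)
    print(f"max_mm={max_mm}: {len(sites)} site(s)")
    for s in sites:
        mm = "perfect match" if not s.mismatches else \
            f"mismatch {s.mismatches} bp from PAM"
        print(f"  {s.chrom}:{s.start} ({s.strand})  cut at {s.cut}  {mm}")
# With max_mm=0 only the intended site appears; allowing one mismatch also
# reveals the paralogous site with its substitution 16 bp from the PAM.
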