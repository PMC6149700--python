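"""Scan a sequence for restriction sites and predict its digest fragments.

Builds a small substrate carrying one HindIII site (AAGCTT) and one BsrI
site (ACTGG, an outside cutter), locates every cut on both strands, and
prints the fragment sizes a complete linear digest would put on a gel.
"""

from rflpkit import NucleotideSequence, builtin_enzymes, digest_linear, find_sites

enzymes = builtin_enzymes()
substrate = NucleotideSequence(
    "demo", "GGGG" + "AAGCTT" + "ACGTACGTAC" + "ACTGG" + "TTTTTT"
)
print(f"substrate: {substrate.residues} ({len(substrate)} bp)\n")

for name in ("HindIII", "BsrI", "SphI"):
    sites = find_sites(substrate, enzymes[name])
    result = digest_linear(substrate, enzymes[name])
    where = ", ".join(
        f"{s.orientation} site at {s.site_start} cutting at {s.cut_pos}" for s in sites
    ) or "no sites"
    print(f"{name:8s} {where}")
    print(f"         fragments: {list(result.fragments)} bp "
          f"(sum {sum(result.fragments)} = substrate length)\n")

print("Each cut at coordinate c splits [0:c] from [c:L]; fragment sizes are")
print("what the bands on an agarose gel would read, largest first.")
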