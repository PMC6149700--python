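"""In-silico PCR with the six-species assay's plastid rbcL primer pair.

Constructs a template with 30 bp of flanking sequence around a known
insert, amplifies it with the published rbcL primers, and shows that the
product is exactly primer + insert + primer with coordinates on the
source record.
"""

import random

from rflpkit import NucleotideSequence, PrimerPair, extract_amplicon, reverse_complement

FWD = "GCGAACGTTACGAATCTGGAGT"    # rbcL forward, 22 nt
REV = "ATGCTACTGGTACAACTTTACGTA"  # rbcL reverse, 24 nt (5'->3' as synthesized)

rng = random.Random(5)
flank = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
insert = flank(500)
template = NucleotideSequence(
    "template", flank(30) + FWD + insert + reverse_complement(REV) + flank(30)
)

pair = PrimerPair(forward=FWD, reverse=REV)  # tolerates 2 mismatches, 3 bp exact 3' clamp
amp = extract_amplicon(template, pair)
print(f"template length : {len(template)} bp")
print(f"amplicon        : [{amp.start}, {amp.end}) on {amp.source_id}")
print(f"product size    : {amp.length} bp "
      f"(= {len(FWD)} + {len(insert)} + {len(REV)})")
print()
print("The product spans first base of the forward-primer site through the")
print("last base of the reverse-primer site; its bases come from the template.")
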