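"""In-silico PCR: primer binding-site search and amplicon extraction.

Primers are given 5'->3' as synthesized: the forward primer matches the
top strand directly, the reverse primer matches the bottom strand, so its
reverse complement is searched on the top strand.  Binding tolerates up
to ``max_mismatches`` substitutions except in the 3'-terminal
``three_prime_clamp`` bases, which must match exactly — polymerase
extension from a mismatched 3' end is what the clamp rule forbids.
No melting-temperature model is used; mismatch count only.

The amplicon spans from the first base of the forward-primer site to the
last base of the reverse-primer site, with primer-region bases taken from
the template (not overwritten by the primer sequence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .seq_core import NucleotideSequence, matches, reverse_complement

__all__ = [
    "PrimerPair",
    "PrimerHit",
    "Amplicon",
    "AmplificationError",
    "AmbiguousAmpliconError",
    "find_primer_sites",
    "extract_amplicon",
]

MIN_ANCHORED_OVERLAP = 12  # bases of a truncated primer site required flush with a record end


class AmplificationError(RuntimeError):
    """No consistent amplicon: a primer site is missing or misordered."""


class AmbiguousAmpliconError(RuntimeError):
    """More than one consistent (forward, reverse) primer pairing."""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair with binding tolerance settings.

    Defaults (2 mismatches, 3-base exact 3' clamp) mimic annealing of
    primers designed from cross-species conserved regions without
    inventing hybridisation thermodynamics.
    """

    forward: str
    reverse: str
    max_mismatches: int = 2
    three_prime_clamp: int = 3

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(p) <= 35:
                raise ValueError(f"{label} primer length {len(p)} outside 15-35 nt")
        if self.max_mismatches < 0 or self.max_mismatches >= min(
            len(self.forward), len(self.reverse)
        ):
            raise ValueError("max_mismatches must be >= 0 and < primer length")


@dataclass(frozen=True)
class PrimerHit:
    """One primer alignment on the top strand ([position, position+span))."""

    position: int
    orientation: Literal["forward", "reverse"]
    mismatch_count: int
    span: int  # matched length; < primer length only for anchored partial hits


def _count_mismatches(template: str, pattern: str, clamp_idx: set[int]) -> "int | None":
    """Mismatches of pattern vs template window; None if a clamp base mismatches."""
    mm = 0
    for j, (t, p) in enumerate(zip(template, pattern)):
        if not matches(t, p):
            if j in clamp_idx:
                return None
            mm += 1
    return mm


def find_primer_sites(
    s: NucleotideSequence,
    primer: str,
    max_mismatches: int = 2,
    clamp: int = 3,
    anchored: bool = False,
) -> list[PrimerHit]:
    """All top-strand binding sites of ``primer`` in both orientations.

    Forward orientation aligns the primer as given; reverse orientation
    aligns its reverse complement (the primer binding the top strand as
    template).  Ambiguity codes use subset semantics.  With ``anchored``,
    partial sites of >= 12 bases flush with a record end are also
    reported (the 3' clamp still applies), for reference records that
    begin or end inside a primer site.
    """
    primer = primer.upper()
    k = len(primer)
    res = s.residues
    L = len(res)
    rc = reverse_complement(primer)
    # 3'-terminal clamp positions within each oriented pattern: the primer's
    # 3' end is the right end in forward orientation, the left end of rc.
    fwd_clamp = {k - 1 - j for j in range(clamp)}
    rev_clamp = set(range(clamp))
    hits: list[PrimerHit] = []
    for p in range(L - k + 1):
        window = res[p : p + k]
        mm = _count_mismatches(window, primer, fwd_clamp)
        if mm is not None and mm <= max_mismatches:
            hits.append(PrimerHit(p, "forward", mm, k))
        mm = _count_mismatches(window, rc, rev_clamp)
        if mm is not None and mm <= max_mismatches:
            hits.append(PrimerHit(p, "reverse", mm, k))
    if anchored:
        hits.extend(_anchored_hits(res, primer, rc, max_mismatches, clamp))
    hits.sort(key=lambda h: (h.position, h.orientation))
    return hits


def _anchored_hits(
    res: str, primer: str, rc: str, max_mismatches: int, clamp: int
) -> list[PrimerHit]:
    """Truncated primer sites flush with the record ends.

    A record starting inside the forward-primer site retains a suffix of
    the primer at position 0; a record ending inside the reverse-primer
    site retains a prefix of the reverse complement at the right end.
    Both truncations keep the primer's 3' end, so the clamp is enforced.
    """
    k, L = len(primer), len(res)
    hits = []
    for q in range(MIN_ANCHORED_OVERLAP, k):
        if q > L:
            break
        # forward primer, 5' end truncated: suffix of length q at record start
        suffix = primer[k - q :]
        mm = _count_mismatches(res[:q], suffix, {q - 1 - j for j in range(clamp)})
        if mm is not None and mm <= max_mismatches:
            hits.append(PrimerHit(0, "forward", mm, q))
        # reverse primer truncated: prefix of rc (contains the 3' end) at record end
        mm = _count_mismatches(res[L - q :], rc[:q], set(range(clamp)))
        if mm is not None and mm <= max_mismatches:
            hits.append(PrimerHit(L - q, "reverse", mm, q))
    return hits


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product with its source coordinates.

    ``[start, end)`` on the template top strand; ``start`` is the first
    base of the forward-primer site, ``end`` one past the last base of
    the reverse-primer site.
    """

    source_id: str
    start: int
    end: int
    sequence: NucleotideSequence

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_amplicon(
    s: NucleotideSequence,
    p: PrimerPair,
    anchored: bool = False,
    take_outermost: bool = False,
) -> Amplicon:
    """Extract the unique amplicon delimited by the primer pair.

    Raises :class:`AmplificationError` naming the missing primer when no
    forward site, no reverse site, or no reverse site downstream of a
    forward site exists; raises :class:`AmbiguousAmpliconError` when
    several pairings are consistent, unless ``take_outermost`` selects
    the one with minimal start and maximal end.
    """
    fhits = find_primer_sites(s, p.forward, p.max_mismatches, p.three_prime_clamp, anchored)
    rhits = find_primer_sites(s, p.reverse, p.max_mismatches, p.three_prime_clamp, anchored)
    # A primer pair amplifies regardless of which template strand carries
    # the forward-primer sense: pair a plus-sense forward site with a
    # downstream minus-sense reverse site, or (mirrored template) a
    # plus-sense reverse site with a downstream minus-sense forward site.
    # Either way the product is reported as the top-strand slice.
    plus = [
        (f.position, r.position + r.span)
        for f in fhits if f.orientation == "forward"
        for r in rhits if r.orientation == "reverse"
        if r.position >= f.position + f.span
    ]
    minus = [
        (f.position, r.position + r.span)
        for f in rhits if f.orientation == "forward"
        for r in fhits if r.orientation == "reverse"
        if r.position >= f.position + f.span
    ]
    pairings = plus + minus
    if not pairings:
        if not any(h.orientation == "forward" for h in fhits) and not any(
            h.orientation == "reverse" for h in fhits
        ):
            raise AmplificationError(f"{s.id}: no forward-primer site found")
        if not any(h.orientation == "reverse" for h in rhits) and not any(
            h.orientation == "forward" for h in rhits
        ):
            raise AmplificationError(f"{s.id}: no reverse-primer site found")
        raise AmplificationError(
            f"{s.id}: no reverse-primer site downstream of a forward-primer site"
        )
    unique = sorted(set(pairings))
    if len(unique) > 1:
        if not take_outermost:
            raise AmbiguousAmpliconError(
                f"{s.id}: {len(unique)} consistent primer pairings; "
                "enable take_outermost to select the largest product"
            )
        start = min(a for a, _ in unique)
        end = max(b for _, b in unique)
    else:
        start, end = unique[0]
    product = NucleotideSequence(
        id=f"{s.id}:amplicon:{start}-{end}",
        residues=s.residues[start:end],
        species=s.species,
        description=f"in-silico PCR product from {s.id}",
    )
    return Amplicon(source_id=s.id, start=start, end=end, sequence=product)
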