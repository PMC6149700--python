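"""Both-strand degenerate restriction-site scanning and linear digests.

Coordinates are 0-based, half-open throughout.  A cut at coordinate ``c``
separates ``s[0:c]`` from ``s[c:L]``; fragment lengths are measured on
the top strand between top-strand cut coordinates (overhangs are not
length-adjusted), which is how gel band sizes are reported.

A reverse-orientation site is handled by scanning the reverse complement
of the substrate in forward orientation and mapping each cut coordinate
``c'`` back to top-strand coordinate ``L - c'`` — one code path and a
testable mirror invariant.  For palindromic enzymes each physical site is
reported once, in forward orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Literal

from .enzymes import RestrictionEnzyme
from .seq_core import NucleotideSequence, matches, reverse_complement

__all__ = ["CutSite", "DigestResult", "find_sites", "digest_linear", "digest_panel",
           "write_digest_report"]


@dataclass(frozen=True)
class CutSite:
    """One recognition-site match and the top-strand cut it produces."""

    enzyme_name: str
    site_start: int  # 0-based start of the matched region on the top strand
    orientation: Literal["forward", "reverse"]
    cut_pos: int  # cut falls between cut_pos-1 and cut_pos


def _scan_forward(residues: str, pattern: str) -> list[int]:
    """All 0-based offsets where pattern matches (subset semantics)."""
    n, m = len(residues), len(pattern)
    hits = []
    for i in range(n - m + 1):
        if all(matches(residues[i + j], pattern[j]) for j in range(m)):
            hits.append(i)
    return hits


def find_sites(s: NucleotideSequence, e: RestrictionEnzyme) -> list[CutSite]:
    """All recognition sites of ``e`` on both strands of ``s``.

    Overlapping sites are all reported.  Sites whose cut coordinate falls
    outside ``[0, L]`` (too close to an end for the enzyme's offset, as
    with outside cutters like BsrI) produce no entry.  Sorted by
    ``site_start`` then orientation.
    """
    L = len(s.residues)
    m = len(e.pattern)
    sites: list[CutSite] = []
    for start in _scan_forward(s.residues, e.pattern):
        cut = start + e.cut5
        if 0 <= cut <= L:
            sites.append(CutSite(e.name, start, "forward", cut))
    if not e.palindromic:
        rc = reverse_complement(s.residues)
        for start_rc in _scan_forward(rc, e.pattern):
            cut = L - (start_rc + e.cut5)
            if 0 <= cut <= L:
                sites.append(CutSite(e.name, L - start_rc - m, "reverse", cut))
    sites.sort(key=lambda c: (c.site_start, c.orientation))
    return sites


@dataclass(frozen=True)
class DigestResult:
    """Cut coordinates and fragment lengths for one enzyme on one substrate."""

    sequence_id: str
    enzyme_name: str
    cut_positions: tuple[int, ...]  # sorted, unique, top-strand
    fragments: tuple[int, ...]  # descending; sums to substrate length

    @property
    def n_cuts(self) -> int:
        return len(self.cut_positions)


def digest_linear(s: NucleotideSequence, e: RestrictionEnzyme) -> DigestResult:
    """Complete linear digest of ``s`` with ``e``.

    Duplicate cut coordinates from overlapping sites are collapsed, so
    the number of fragments is always ``n_cuts + 1`` and the fragment
    lengths sum to the substrate length.
    """
    L = len(s.residues)
    cuts = sorted({site.cut_pos for site in find_sites(s, e)})
    bounds = [0, *cuts, L]
    fragments = sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True)
    return DigestResult(
        sequence_id=s.id,
        enzyme_name=e.name,
        cut_positions=tuple(cuts),
        fragments=tuple(fragments),
    )


def digest_panel(
    seqs: list[NucleotideSequence], enzymes: list[RestrictionEnzyme]
) -> list[DigestResult]:
    """One :class:`DigestResult` per (sequence, enzyme) pair, in input order."""
    if not seqs or not enzymes:
        raise ValueError("digest_panel requires at least one sequence and one enzyme")
    return [digest_linear(s, e) for s in seqs for e in enzymes]


def write_digest_report(results: Iterable[DigestResult], stream: IO[str]) -> None:
    """TSV report: sequence_id, enzyme, n_cuts, fragments (comma-separated, descending)."""
    stream.write("sequence_id\tenzyme\tn_cuts\tfragments\n")
    for r in results:
        frags = ",".join(str(f) for f in r.fragments)
        stream.write(f"{r.sequence_id}\t{r.enzyme_name}\t{r.n_cuts}\t{frags}\n")
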