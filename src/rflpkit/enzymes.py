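"""Restriction enzyme definitions: recognition pattern plus cut geometry.

Cut geometry is stored as two offsets in the recognition-strand frame:
``cut5`` is where the strand reading the pattern 5'->3' is cut, ``cut3``
where the opposite strand is cut, both measured from the pattern start.
Outside cutters are normalised into the same frame, e.g. BsrI, written
ACTGG(1/-1) in REBASE, becomes cut5 = 5+1 = 6, cut3 = 5-1 = 4.  A site
lying too close to a substrate end for its offset simply produces no cut
there (it is not an error).

The packaged table ``enzymes_paper8.tsv`` holds the eight enzymes of the
six-species Pyropia identification panel: BglI, Tth111I, AvaII, BsrI,
BsaAI, HindIII, SacII and SphI.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable

from .seq_core import IUPAC_ALPHABET, reverse_complement

__all__ = [
    "RestrictionEnzyme",
    "EnzymeTableError",
    "load_enzyme_table",
    "write_enzyme_table",
    "builtin_enzymes",
    "BUILTIN_TABLE",
]

BUILTIN_TABLE = "enzymes_paper8.tsv"


class EnzymeTableError(ValueError):
    """Malformed enzyme definition or definition table."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: name, degenerate recognition pattern, cut offsets."""

    name: str
    pattern: str
    cut5: int
    cut3: int

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if len(pat) < 4:
            raise EnzymeTableError(f"{self.name}: pattern shorter than 4 nt: {pat!r}")
        bad = set(pat) - IUPAC_ALPHABET
        if bad:
            raise EnzymeTableError(
                f"{self.name}: non-IUPAC symbol(s) {sorted(bad)} in pattern {pat!r}"
            )

    @property
    def palindromic(self) -> bool:
        """True iff the recognition pattern equals its own reverse complement."""
        return self.pattern == reverse_complement(self.pattern)

    @property
    def overhang(self) -> int:
        """Length of the single-stranded overhang left by the cut (0 = blunt)."""
        return abs(self.cut5 - self.cut3)


def _parse_rows(rows: Iterable[list[str]], source: str) -> list[RestrictionEnzyme]:
    enzymes: list[RestrictionEnzyme] = []
    seen: set[str] = set()
    for lineno, row in rows:
        if len(row) != 4:
            raise EnzymeTableError(f"{source}:{lineno}: expected 4 columns, got {len(row)}")
        name, pattern, c5, c3 = (f.strip() for f in row)
        if name in seen:
            raise EnzymeTableError(f"{source}:{lineno}: duplicate enzyme name {name!r}")
        seen.add(name)
        try:
            cut5, cut3 = int(c5), int(c3)
        except ValueError:
            raise EnzymeTableError(
                f"{source}:{lineno}: malformed cut offsets {c5!r}/{c3!r}"
            ) from None
        enzymes.append(RestrictionEnzyme(name=name, pattern=pattern, cut5=cut5, cut3=cut3))
    return enzymes


def load_enzyme_table(source: "str | IO[str] | None" = None) -> list[RestrictionEnzyme]:
    """Load enzyme definitions from a TSV (``name pattern cut5 cut3``).

    ``source`` may be a path, an open text stream, or None for the
    packaged eight-enzyme panel.  Lines starting with ``#`` are comments.
    """
    if source is None:
        text = resources.files("rflpkit.data").joinpath(BUILTIN_TABLE).read_text()
        return _parse_table_text(text, BUILTIN_TABLE)
    if isinstance(source, str):
        with open(source) as fh:
            return _parse_table_text(fh.read(), source)
    return _parse_table_text(source.read(), getattr(source, "name", "<stream>"))


def _parse_table_text(text: str, source: str) -> list[RestrictionEnzyme]:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append((lineno, line.split("\t")))
    return _parse_rows(rows, source)


def write_enzyme_table(enzymes: Iterable[RestrictionEnzyme], stream: IO[str]) -> None:
    """Write enzymes as TSV; round-trips with :func:`load_enzyme_table`."""
    w = csv.writer(stream, delimiter="\t", lineterminator="\n")
    for e in enzymes:
        w.writerow([e.name, e.pattern, e.cut5, e.cut3])


def builtin_enzymes() -> dict[str, RestrictionEnzyme]:
    """The packaged eight-enzyme panel, keyed by name."""
    return {e.name: e for e in load_enzyme_table()}
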