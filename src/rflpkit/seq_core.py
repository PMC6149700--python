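"""IUPAC nucleotide alphabet, sequence records and FASTA I/O.

The 15-symbol IUPAC DNA alphabet is used throughout: concrete bases
A/C/G/T plus the eleven degeneracy codes (R=A/G, Y=C/T, S=C/G, W=A/T,
K=G/T, M=A/C, B=C/G/T, D=A/G/T, H=A/C/T, V=A/C/G, N=any).  Ambiguity
comparisons use *subset semantics*: a sequence symbol matches a pattern
symbol only if every base the sequence symbol could be satisfies the
pattern.  An ``N`` in a reference sequence therefore never creates a
spurious restriction site — conservative behaviour for assay design,
where a false diagnostic site is worse than a missed one.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_ALPHABET",
    "IUPAC_SETS",
    "AlphabetError",
    "FastaFormatError",
    "NucleotideSequence",
    "iupac_base_set",
    "matches",
    "reverse_complement",
    "parse_fasta",
    "write_fasta",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET: frozenset[str] = frozenset(IUPAC_SETS)

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# matches() is on the hot path of every scanner; precompute all 225 pairs.
_SUBSET: dict[tuple[str, str], bool] = {
    (a, b): IUPAC_SETS[a] <= IUPAC_SETS[b]
    for a in IUPAC_SETS
    for b in IUPAC_SETS
}


class AlphabetError(ValueError):
    """A character outside the IUPAC DNA alphabet was encountered."""


class FastaFormatError(ValueError):
    """Structurally invalid FASTA input (e.g. a header with no residues)."""


def iupac_base_set(symbol: str) -> frozenset[str]:
    """Return the set of concrete bases an IUPAC symbol stands for.

    >>> sorted(iupac_base_set("W"))
    ['A', 'T']
    """
    try:
        return IUPAC_SETS[symbol.upper()]
    except KeyError:
        raise AlphabetError(f"not an IUPAC nucleotide symbol: {symbol!r}") from None


def matches(seq_symbol: str, pattern_symbol: str) -> bool:
    """Subset-semantics symbol match.

    True iff ``base_set(seq_symbol) ⊆ base_set(pattern_symbol)``: an
    ambiguous sequence base matches only if every base it could be
    satisfies the pattern.  ``matches('N', 'G')`` is False.
    """
    try:
        return _SUBSET[(seq_symbol.upper(), pattern_symbol.upper())]
    except KeyError:
        bad = seq_symbol if seq_symbol.upper() not in IUPAC_SETS else pattern_symbol
        raise AlphabetError(f"not an IUPAC nucleotide symbol: {bad!r}") from None


def _validate_residues(residues: str, where: str = "") -> str:
    """Uppercase, convert U->T, strip alignment gaps, validate alphabet.

    Raises :class:`AlphabetError` naming the 0-based offending position
    in the *original* string.
    """
    up = residues.upper()
    if "-" in up:
        warnings.warn(
            f"stripping {up.count('-')} alignment gap(s){' in ' + where if where else ''}; "
            "digestion operates on ungapped sequences",
            stacklevel=3,
        )
    out = []
    for i, ch in enumerate(up):
        if ch == "-":
            continue
        if ch == "U":
            ch = "T"
        if ch not in IUPAC_SETS:
            loc = f" in {where}" if where else ""
            raise AlphabetError(f"invalid residue {ch!r} at position {i}{loc}")
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class NucleotideSequence:
    """A species-labelled IUPAC DNA record.

    ``residues`` are stored uppercase; ``U`` is converted to ``T`` and
    alignment gaps ``-`` are stripped (with a warning) at construction.
    """

    id: str
    residues: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _validate_residues(self.residues, self.id))
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(
            id=self.id,
            residues=reverse_complement(self.residues),
            species=self.species,
            description=self.description,
        )


def reverse_complement(s: "NucleotideSequence | str") -> "NucleotideSequence | str":
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, S/W/N fixed)."""
    if isinstance(s, NucleotideSequence):
        return s.reverse_complement()
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(s.upper().replace("U", "T")))
    except KeyError as e:
        raise AlphabetError(f"not an IUPAC nucleotide symbol: {e.args[0]!r}") from None


def _split_header(header: str) -> tuple[str, str, str]:
    """Split a FASTA description line into (id, species, free text).

    Header convention: ``>id species=<label> [description...]``.
    """
    tokens = header.split()
    seq_id = tokens[0] if tokens else ""
    species = ""
    rest: list[str] = []
    for tok in tokens[1:]:
        if tok.startswith("species="):
            species = tok[len("species="):]
        else:
            rest.append(tok)
    return seq_id, species, " ".join(rest)


def parse_fasta(stream: "IO[str] | str") -> list[NucleotideSequence]:
    """Parse multi-record FASTA into :class:`NucleotideSequence` records.

    Accepts an open text stream or a path.  The species label is taken
    from a ``species=<name>`` header token when present.  An empty file
    yields an empty list; a record with no residues is a
    :class:`FastaFormatError`; an invalid residue raises
    :class:`AlphabetError` naming the record and position.
    """
    close = False
    if isinstance(stream, str):
        stream = open(stream)
        close = True
    try:
        records = []
        for rec in SeqIO.parse(stream, "fasta"):
            seq_id, species, desc = _split_header(rec.description)
            raw = str(rec.seq)
            if not raw:
                raise FastaFormatError(f"record {seq_id!r} has no residues")
            records.append(
                NucleotideSequence(id=seq_id, residues=raw, species=species, description=desc)
            )
        return records
    finally:
        if close:
            stream.close()


def write_fasta(records: Iterable[NucleotideSequence], stream: "IO[str] | str") -> None:
    """Write records as 60-column wrapped FASTA (round-trips with parse_fasta)."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w")
        close = True
    try:
        out = []
        for r in records:
            header = r.id
            if r.species:
                header += f" species={r.species}"
            if r.description:
                header += f" {r.description}"
            out.append(SeqRecord(Seq(r.residues), id=header, description=""))
        SeqIO.write(out, stream, "fasta")
    finally:
        if close:
            stream.close()


def fasta_string(records: Iterable[NucleotideSequence]) -> str:
    """Render records to a FASTA string (convenience for CLI/stdout)."""
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()
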