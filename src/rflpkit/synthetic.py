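"""Deterministic synthetic species panels with planted diagnostic sites.

A panel emulates a set of per-species reference amplicon templates:
every species sequence is ``forward primer + random A/C/G/T core +
reverse-complemented reverse primer``, and selected enzyme recognition
sites are planted at chosen positions in chosen species only.  After
planting, a background sweep re-randomises any stretch of core that
accidentally spells a recognition site of *any* panel enzyme, so the
only cut-producing sites in the finished panel are the planted ones.
This gives tests and demonstrations a ground truth: the diagnostic
enzymes recovered downstream must be exactly the planted ones.

The default primer flanks are fixed 22/24-mers verified to contain no
recognition site of the packaged eight-enzyme panel in either
orientation (the published primer pair does not have this property: its
reverse primer carries a BsrI site and a BsaAI site straddles its
reverse complement, which in real amplicons simply adds small terminal
fragments shared by all species).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .enzymes import RestrictionEnzyme, load_enzyme_table
from .insilico_pcr import PrimerPair
from .seq_core import IUPAC_SETS, NucleotideSequence, reverse_complement
from .digestion import find_sites

__all__ = ["PanelSpec", "GenerationError", "generate_panel",
           "DEFAULT_FORWARD_PRIMER", "DEFAULT_REVERSE_PRIMER", "default_primer_pair"]

# Site-free flanks (checked against all eight packaged enzymes, both strands).
DEFAULT_FORWARD_PRIMER = "ATTGCGTTCGAAGTAGTTCGCT"
DEFAULT_REVERSE_PRIMER = "TGCTTGTTAGCCTTCTTGCGTGAT"

_MAX_SWEEPS = 200


class GenerationError(RuntimeError):
    """The cleanliness sweep could not remove an accidental site."""


def default_primer_pair() -> PrimerPair:
    return PrimerPair(forward=DEFAULT_FORWARD_PRIMER, reverse=DEFAULT_REVERSE_PRIMER)


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic species panel.

    ``planted`` lists (species index, enzyme name, position): a concrete
    instantiation of that enzyme's recognition pattern is written at
    that 0-based position in that species only.  Positions must lie in
    the inter-primer core and planted sites must not overlap each other.
    """

    n_species: int = 6
    seq_length: int = 1000
    seed: int = 0
    planted: tuple[tuple[int, str, int], ...] = ()
    primer_pair: PrimerPair = field(default_factory=default_primer_pair)
    enzymes: tuple[RestrictionEnzyme, ...] = field(
        default_factory=lambda: tuple(load_enzyme_table())
    )

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("panel needs at least 2 species")
        flank5 = len(self.primer_pair.forward)
        flank3 = len(self.primer_pair.reverse)
        if self.seq_length < flank5 + flank3 + 50:
            raise ValueError("seq_length too short for primer flanks plus a core")
        by_name = {e.name: e for e in self.enzymes}
        spans: dict[int, list[tuple[int, int]]] = {}
        for sp_idx, enz_name, pos in self.planted:
            if not 0 <= sp_idx < self.n_species:
                raise ValueError(f"planted species index {sp_idx} out of range")
            if enz_name not in by_name:
                raise ValueError(f"planted enzyme {enz_name!r} not in the panel table")
            m = len(by_name[enz_name].pattern)
            if pos < flank5 or pos + m > self.seq_length - flank3:
                raise ValueError(
                    f"planted site {enz_name} at {pos} overlaps a primer flank"
                )
            for a, b in spans.setdefault(sp_idx, []):
                if pos < b and a < pos + m:
                    raise ValueError(
                        f"planted sites overlap in species {sp_idx} at {pos}"
                    )
            spans[sp_idx].append((pos, pos + m))


def _instantiate(pattern: str, rng: random.Random) -> str:
    """A concrete A/C/G/T realisation of a degenerate pattern."""
    return "".join(rng.choice(sorted(IUPAC_SETS[sym])) for sym in pattern)


def generate_panel(spec: PanelSpec) -> list[NucleotideSequence]:
    """Generate the panel; deterministic for a fixed spec (seed included).

    Raises :class:`GenerationError` if an accidental recognition site
    cannot be randomised away within the retry budget (e.g. it lies
    entirely within a primer flank or a planted site).
    """
    rng = random.Random(spec.seed)
    fwd = spec.primer_pair.forward.upper()
    rev_rc = reverse_complement(spec.primer_pair.reverse.upper())
    L = spec.seq_length
    core_len = L - len(fwd) - len(rev_rc)
    by_name = {e.name: e for e in spec.enzymes}

    records: list[NucleotideSequence] = []
    for sp_idx in range(spec.n_species):
        seq = list(fwd + "".join(rng.choice("ACGT") for _ in range(core_len)) + rev_rc)
        protected = set(range(len(fwd))) | set(range(L - len(rev_rc), L))
        allowed: set[tuple[str, int]] = set()
        for p_idx, enz_name, pos in spec.planted:
            if p_idx != sp_idx:
                continue
            pat = by_name[enz_name].pattern
            seq[pos : pos + len(pat)] = _instantiate(pat, rng)
            protected |= set(range(pos, pos + len(pat)))
            allowed.add((enz_name, pos))
        _sweep_clean(seq, spec, allowed, protected, rng, sp_idx)
        species = f"species_{sp_idx}"
        records.append(
            NucleotideSequence(
                id=f"panel{spec.seed}_{species}",
                residues="".join(seq),
                species=species,
                description=f"synthetic panel seed={spec.seed}",
            )
        )
    return records


def _sweep_clean(
    seq: list[str],
    spec: PanelSpec,
    allowed: set[tuple[str, int]],
    protected: set[int],
    rng: random.Random,
    sp_idx: int,
) -> None:
    """Re-randomise accidental recognition sites until none remain."""
    for _ in range(_MAX_SWEEPS):
        record = NucleotideSequence(id="tmp", residues="".join(seq))
        offending: list[tuple[int, int]] = []
        for enz in spec.enzymes:
            m = len(enz.pattern)
            for site in find_sites(record, enz):
                if (enz.name, site.site_start) in allowed and site.orientation == "forward":
                    continue
                offending.append((site.site_start, site.site_start + m))
        if not offending:
            return
        for a, b in offending:
            mutable = [i for i in range(a, b) if i not in protected]
            if not mutable:
                raise GenerationError(
                    f"species {sp_idx}: accidental site at [{a},{b}) lies entirely "
                    "inside a primer flank or planted site"
                )
            for i in mutable:
                seq[i] = rng.choice("ACGT")
    raise GenerationError(
        f"species {sp_idx}: could not clean accidental sites within {_MAX_SWEEPS} sweeps"
    )
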