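"""Species-diagnostic enzyme calls from per-species digest profiles.

Fragment lists become *band patterns* through a simple gel model: a
fragment shorter than ``min_visible_bp`` runs off the gel, and fragments
closer together than the gel resolution co-migrate into one band
(single-linkage clustering with gap <= ``resolution_bp``, band reported
at the length of its largest member).  Two patterns are distinguishable
when their band lists cannot be matched one-to-one within resolution.

An enzyme is a unique identifier for a species when its band pattern in
that species differs from the pattern in every other species — an
*uncut* amplicon (single full-length band) is itself a valid, and often
the diagnostic, pattern.  The minimal enzyme set distinguishing all
species pairs is a set-cover problem, solved greedily by default with an
exhaustive option for small panels.

Defaults resolution_bp=20, min_visible_bp=80 reflect what a 1.5% agarose
gel discriminates: fragments of ~510 and ~495 bp co-migrate as one band
while a 119 bp fragment is still resolved and visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import IO, Iterable, Mapping, Sequence

from .digestion import DigestResult

__all__ = [
    "Band",
    "RFLPProfile",
    "DiagnosticReport",
    "band_pattern",
    "patterns_distinct",
    "build_profile",
    "diagnose",
    "exact_minimal_set",
    "load_profile_tsv",
    "write_profile_tsv",
    "load_table1_profile",
    "DEFAULT_RESOLUTION_BP",
    "DEFAULT_MIN_VISIBLE_BP",
    "TABLE1_PROFILES",
]

DEFAULT_RESOLUTION_BP = 20
DEFAULT_MIN_VISIBLE_BP = 80
TABLE1_PROFILES = "table1_profiles.tsv"

Band = tuple[int, int]  # (representative length = largest member, multiplicity)


def band_pattern(
    fragments: Sequence[int],
    resolution_bp: int = DEFAULT_RESOLUTION_BP,
    min_visible_bp: int = DEFAULT_MIN_VISIBLE_BP,
) -> tuple[Band, ...]:
    """Collapse a fragment-length multiset into visible gel bands.

    Returns bands as ``(representative_length, multiplicity)`` in
    descending length order; may be empty if every fragment ran off.
    """
    if not fragments:
        raise ValueError("fragment list must be nonempty")
    visible = sorted(f for f in fragments if f >= min_visible_bp)
    bands: list[Band] = []
    i = 0
    while i < len(visible):
        j = i
        while j + 1 < len(visible) and visible[j + 1] - visible[j] <= resolution_bp:
            j += 1
        bands.append((visible[j], j - i + 1))
        i = j + 1
    return tuple(sorted(bands, reverse=True))


def patterns_distinct(
    a: Sequence[Band], b: Sequence[Band], resolution_bp: int = DEFAULT_RESOLUTION_BP
) -> bool:
    """True iff two band patterns are distinguishable at gel resolution.

    Patterns are matchable when they have the same number of bands and,
    after sorting, every matched pair of representative lengths differs
    by at most ``resolution_bp`` (greedy matching on sorted lengths).
    """
    la = sorted(length for length, _ in a)
    lb = sorted(length for length, _ in b)
    if len(la) != len(lb):
        return True
    return any(abs(x - y) > resolution_bp for x, y in zip(la, lb))


@dataclass(frozen=True)
class RFLPProfile:
    """Band patterns for every (species, enzyme) cell of a panel."""

    species: tuple[str, ...]
    enzymes: tuple[str, ...]
    patterns: Mapping[tuple[str, str], tuple[int, ...]]  # raw fragment lengths
    resolution_bp: int = DEFAULT_RESOLUTION_BP
    min_visible_bp: int = DEFAULT_MIN_VISIBLE_BP

    def bands(self, species: str, enzyme: str) -> tuple[Band, ...]:
        return band_pattern(
            self.patterns[(species, enzyme)], self.resolution_bp, self.min_visible_bp
        )


def build_profile(
    digests: Iterable[DigestResult],
    species_map: Mapping[str, str],
    resolution_bp: int = DEFAULT_RESOLUTION_BP,
    min_visible_bp: int = DEFAULT_MIN_VISIBLE_BP,
) -> RFLPProfile:
    """Assemble an :class:`RFLPProfile` from a digest grid.

    ``species_map`` maps sequence ids to species labels.  Every
    (species, enzyme) cell must be present exactly once.
    """
    patterns: dict[tuple[str, str], tuple[int, ...]] = {}
    species: list[str] = []
    enzymes: list[str] = []
    for d in digests:
        sp = species_map.get(d.sequence_id, d.sequence_id)
        if sp not in species:
            species.append(sp)
        if d.enzyme_name not in enzymes:
            enzymes.append(d.enzyme_name)
        key = (sp, d.enzyme_name)
        if key in patterns:
            raise ValueError(f"duplicate profile cell for {key}")
        patterns[key] = tuple(d.fragments)
    for sp in species:
        for en in enzymes:
            if (sp, en) not in patterns:
                raise ValueError(f"missing digest for species {sp!r}, enzyme {en!r}")
    return RFLPProfile(
        species=tuple(species),
        enzymes=tuple(enzymes),
        patterns=patterns,
        resolution_bp=resolution_bp,
        min_visible_bp=min_visible_bp,
    )


@dataclass(frozen=True)
class DiagnosticReport:
    """Which enzymes separate which species, and a minimal discriminating set."""

    per_enzyme: Mapping[str, frozenset[frozenset[str]]]  # enzyme -> separated pairs
    unique_identifiers: Mapping[str, tuple[str, ...]]
    minimal_set: tuple[str, ...]
    fully_resolved: bool

    def summary(self) -> str:
        lines = ["Diagnostic report", "================="]
        for sp, enz in self.unique_identifiers.items():
            marker = ", ".join(enz) if enz else "(none)"
            lines.append(f"  {sp}: {marker}")
        lines.append(f"minimal enzyme set: {', '.join(self.minimal_set) or '(none)'}")
        lines.append(f"fully resolved: {'yes' if self.fully_resolved else 'no'}")
        return "\n".join(lines)


def _separated_pairs(profile: RFLPProfile, enzyme: str) -> frozenset[frozenset[str]]:
    bands = {sp: profile.bands(sp, enzyme) for sp in profile.species}
    return frozenset(
        frozenset((a, b))
        for a, b in combinations(profile.species, 2)
        if patterns_distinct(bands[a], bands[b], profile.resolution_bp)
    )


def diagnose(profile: RFLPProfile, exact: bool = False) -> DiagnosticReport:
    """Compute per-enzyme separation, unique identifiers and a minimal set.

    The minimal set is a greedy set cover over unordered species pairs
    (the enzyme covering most uncovered pairs is taken first, ties broken
    by lexicographic enzyme name); ``exact=True`` searches all enzyme
    subsets instead (feasible for panels of <= ~20 enzymes).
    """
    if len(profile.species) < 2:
        raise ValueError("diagnosis requires at least 2 species")
    per_enzyme = {e: _separated_pairs(profile, e) for e in profile.enzymes}
    all_pairs = frozenset(
        frozenset((a, b)) for a, b in combinations(profile.species, 2)
    )
    others = {sp: set(profile.species) - {sp} for sp in profile.species}
    unique_identifiers = {
        sp: tuple(
            e
            for e in profile.enzymes
            if all(frozenset((sp, o)) in per_enzyme[e] for o in others[sp])
        )
        for sp in profile.species
    }
    if exact:
        minimal = exact_minimal_set(profile, per_enzyme)
    else:
        minimal = _greedy_cover(profile.enzymes, per_enzyme, all_pairs)
    covered = frozenset().union(*(per_enzyme[e] for e in minimal)) if minimal else frozenset()
    return DiagnosticReport(
        per_enzyme=per_enzyme,
        unique_identifiers=unique_identifiers,
        minimal_set=tuple(minimal),
        fully_resolved=covered == all_pairs,
    )


def _greedy_cover(
    enzymes: Sequence[str],
    per_enzyme: Mapping[str, frozenset[frozenset[str]]],
    all_pairs: frozenset[frozenset[str]],
) -> list[str]:
    uncovered = set(all_pairs)
    chosen: list[str] = []
    while uncovered:
        best = max(
            sorted(e for e in enzymes if e not in chosen),
            key=lambda e: len(per_enzyme[e] & uncovered),
            default=None,
        )
        if best is None or not per_enzyme[best] & uncovered:
            break  # remaining pairs are inseparable by any enzyme
        chosen.append(best)
        uncovered -= per_enzyme[best]
    return chosen


def exact_minimal_set(
    profile: RFLPProfile,
    per_enzyme: "Mapping[str, frozenset[frozenset[str]]] | None" = None,
) -> list[str]:
    """Smallest enzyme subset separating all species pairs, by exhaustive search.

    Returns the lexicographically first subset of minimum size; falls
    back to the best-covering subset if no subset separates all pairs.
    """
    if per_enzyme is None:
        per_enzyme = {e: _separated_pairs(profile, e) for e in profile.enzymes}
    all_pairs = frozenset(
        frozenset((a, b)) for a, b in combinations(profile.species, 2)
    )
    names = sorted(profile.enzymes)
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            covered = frozenset().union(*(per_enzyme[e] for e in subset))
            if covered == all_pairs:
                return list(subset)
    return list(names)


# ---------------------------------------------------------------------------
# Profile TSV I/O and the packaged six-species reference profile
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: RFLPProfile, stream: IO[str]) -> None:
    """Species x enzyme matrix; cells are comma-separated fragment lengths."""
    stream.write("species\t" + "\t".join(profile.enzymes) + "\n")
    for sp in profile.species:
        cells = [
            ",".join(str(f) for f in profile.patterns[(sp, e)]) for e in profile.enzymes
        ]
        stream.write(sp + "\t" + "\t".join(cells) + "\n")


def load_profile_tsv(
    source: "str | IO[str]",
    resolution_bp: int = DEFAULT_RESOLUTION_BP,
    min_visible_bp: int = DEFAULT_MIN_VISIBLE_BP,
) -> RFLPProfile:
    """Load a species x enzyme fragment matrix written by :func:`write_profile_tsv`."""
    if isinstance(source, str):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    enzymes = tuple(header[1:])
    species: list[str] = []
    patterns: dict[tuple[str, str], tuple[int, ...]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        sp = fields[0]
        species.append(sp)
        if len(fields) != len(enzymes) + 1:
            raise ValueError(f"profile row for {sp!r} has {len(fields) - 1} cells, "
                             f"expected {len(enzymes)}")
        for e, cell in zip(enzymes, fields[1:]):
            patterns[(sp, e)] = tuple(int(x) for x in cell.split(",") if x)
    return RFLPProfile(
        species=tuple(species),
        enzymes=enzymes,
        patterns=patterns,
        resolution_bp=resolution_bp,
        min_visible_bp=min_visible_bp,
    )


def load_table1_profile(
    resolution_bp: int = DEFAULT_RESOLUTION_BP,
    min_visible_bp: int = DEFAULT_MIN_VISIBLE_BP,
) -> RFLPProfile:
    """The packaged six-species Pyropia reference profile.

    Transcribes the published fragment-size matrix: cells without a
    reported diagnostic cut are encoded as the uncut amplicon
    (single band of nominal length 1107 bp for the plastid rbcL column,
    1005 bp for the mitochondrial trnC-trnP columns), matching gel lanes
    where non-target species show the undigested product.
    """
    text = resources.files("rflpkit.data").joinpath(TABLE1_PROFILES).read_text()
    import io as _io

    return load_profile_tsv(_io.StringIO(text), resolution_bp, min_visible_bp)
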