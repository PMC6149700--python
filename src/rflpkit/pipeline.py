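"""End-to-end assay design: PCR -> digest -> profile -> diagnose -> gel."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .digestion import DigestResult, digest_panel
from .enzymes import RestrictionEnzyme
from .gel_render import GelConfig, GelLane, ladder_lane, render_gel_svg
from .insilico_pcr import Amplicon, AmplificationError, AmbiguousAmpliconError, PrimerPair, extract_amplicon
from .panel_diagnostics import (
    DEFAULT_MIN_VISIBLE_BP,
    DEFAULT_RESOLUTION_BP,
    DiagnosticReport,
    RFLPProfile,
    build_profile,
    diagnose,
)
from .seq_core import NucleotideSequence

__all__ = ["DesignResult", "run_design", "gel_lanes_from_profile"]


@dataclass(frozen=True)
class DesignResult:
    """Everything the design pipeline produced for one panel."""

    amplicons: Mapping[str, Amplicon]  # species -> amplicon
    failures: Mapping[str, str]  # species -> amplification error message
    digests: tuple[DigestResult, ...]
    profile: RFLPProfile
    report: DiagnosticReport
    gel_svg: str

    @property
    def ok(self) -> bool:
        """True iff every species amplified and the panel is fully resolved."""
        return not self.failures and self.report.fully_resolved


def gel_lanes_from_profile(profile: RFLPProfile) -> list[GelLane]:
    """One lane per (enzyme, species) cell, ladder first, grouped by enzyme."""
    lanes = [ladder_lane()]
    for enzyme in profile.enzymes:
        for sp in profile.species:
            bands = profile.bands(sp, enzyme)
            if bands:
                lanes.append(GelLane(label=f"{enzyme}:{sp}", bands=bands))
    return lanes


def run_design(
    seqs: Sequence[NucleotideSequence],
    primer_pair: PrimerPair,
    enzymes: Sequence[RestrictionEnzyme],
    resolution_bp: int = DEFAULT_RESOLUTION_BP,
    min_visible_bp: int = DEFAULT_MIN_VISIBLE_BP,
    anchored: bool = False,
    take_outermost: bool = False,
    exact_cover: bool = False,
    gel_config: GelConfig = GelConfig(),
) -> DesignResult:
    """Run the full assay-design pipeline on species-labelled references.

    Each input record must carry a species label (its ``species`` field,
    falling back to its id).  Species whose template fails to amplify
    are recorded in ``failures`` and excluded from the profile; the
    pipeline continues with the remaining species, which must number at
    least two.
    """
    labels = [s.species or s.id for s in seqs]
    if len(set(labels)) < 2:
        raise ValueError("run_design requires at least 2 species labels")
    amplicons: dict[str, Amplicon] = {}
    failures: dict[str, str] = {}
    for s, label in zip(seqs, labels):
        try:
            amplicons[label] = extract_amplicon(
                s, primer_pair, anchored=anchored, take_outermost=take_outermost
            )
        except (AmplificationError, AmbiguousAmpliconError) as e:
            failures[label] = str(e)
    if len(amplicons) < 2:
        raise AmplificationError(
            "fewer than 2 species amplified; cannot build a diagnostic profile "
            f"(failures: {failures})"
        )
    species_map = {a.sequence.id: label for label, a in amplicons.items()}
    digests = tuple(
        digest_panel([a.sequence for a in amplicons.values()], list(enzymes))
    )
    profile = build_profile(digests, species_map, resolution_bp, min_visible_bp)
    report = diagnose(profile, exact=exact_cover)
    svg = render_gel_svg(gel_lanes_from_profile(profile), gel_config)
    return DesignResult(
        amplicons=amplicons,
        failures=failures,
        digests=digests,
        profile=profile,
        report=report,
        gel_svg=svg,
    )
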