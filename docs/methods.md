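# Methods

## Sequence model and ambiguity semantics

Sequences are strings over the 15-symbol IUPAC DNA alphabet, stored
uppercase; `U` is converted to `T` and alignment gaps (`-`) are stripped
with a warning, since digestion operates on ungapped molecules. All
pattern matching — restriction sites and primers alike — uses *subset
semantics*: sequence symbol *x* matches pattern symbol *p* iff
bases(*x*) ⊆ bases(*p*). The asymmetry is deliberate: a degenerate
pattern (`GGWCC`) should match any sequence it can cut, but an ambiguous
*sequence* base (`N` in a reference record) must not be credited with a
site it may not have. For assay design a false diagnostic site is worse
than a missed one, so the conservative direction is the right default.

## Restriction enzymes and cut geometry

An enzyme is (name, recognition pattern, cut5, cut3). Both offsets are
measured from the pattern start in the frame of the strand that reads
the pattern 5′→3′: cut5 is the cut on that strand, cut3 on the opposite
strand. Outside cutters fold into the same frame — BsrI (`ACTGG`,
cutting one base beyond the site) is stored as cut5 = 6, cut3 = 4 — so
inside and outside cutters share one code path. |cut5 − cut3| is the
overhang (0 = blunt). A site lying too close to a substrate end for its
offset produces no cut rather than an error. The packaged table holds
the eight-enzyme *Pyropia* panel; patterns and offsets follow the
standard REBASE definitions and are cross-checked against biopython's
`Bio.Restriction` catalogue in the test suite.

## Site scanning and digestion

Coordinates are 0-based, half-open; a cut at coordinate *c* separates
`s[0:c]` from `s[c:L]`. Forward sites are direct pattern matches with
cut *c* = start + cut5. Reverse sites are found by scanning the
reverse complement in forward orientation and mapping each cut *c′* to
top-strand coordinate *L* − *c′* — one scanner, and the mapping is
itself a tested mirror invariant. Palindromic enzymes report each
physical site once (forward orientation).

One bookkeeping convention to be aware of: for non-palindromic enzymes
the reverse-site cut is recorded at the recognition-strand coordinate,
whereas the physical top-strand nick of a staggered cutter sits
overhang-many bases away. For BsrI (overhang 2) predicted fragments can
therefore differ from the top-strand nick positions by up to 2 bp —
immaterial at gel resolution, and the strand-symmetry test bounds the
deviation by exactly the overhang. Fragment lengths are measured on the
top strand between cut coordinates, without overhang adjustment, which
is how gel band sizes are read.

Digestion is complete (no partial-digest products) and linear (amplicons
are linear molecules; circular substrates are out of scope). Duplicate
cut coordinates from overlapping degenerate sites are collapsed, so
fragment count = cuts + 1 and fragment lengths always sum to the
substrate length — the conservation invariant enforced across ~1000
random digests in the acceptance sweep.

## In-silico PCR

Primer binding is a pure mismatch count under subset semantics: a site
is accepted with ≤ `max_mismatches` (default 2) substitutions and zero
mismatches in the 3′-terminal `three_prime_clamp` bases (default 3),
modelling the polymerase's inability to extend a mismatched 3′ end. No
melting-temperature or thermodynamic model is attempted; the defaults
mimic primers designed against cross-species conserved regions. The
amplicon runs from the first base of the forward-primer site to the last
base of the reverse-primer site, with all bases taken from the template.
Pairing is orientation-agnostic (a template presented on either strand
amplifies, and the product is reported as the top-strand slice), which
yields the mirror property: amplifying the reverse complement returns
the reverse-complemented amplicon. Multiple consistent pairings raise an
error by default — surfacing ambiguity is safer for assay design — with
an opt-in outermost-product policy. An optional *anchored* mode accepts
primer sites truncated flush with a record end (≥ 12 bases, clamp still
enforced), because public reference records of amplified regions often
begin or end inside a primer.

## Gel model and diagnostics

Fragments become bands by dropping everything below `min_visible_bp`
(default 80; small terminal fragments run off or stain too weakly) and
single-linkage clustering with gap ≤ `resolution_bp` (default 20 bp);
each band is reported at its largest member's length with a
multiplicity. The defaults describe a 1.5% agarose gel, which reads
~510 and ~495 bp as a single band yet still resolves a 119 bp fragment.
Two patterns are distinguishable iff their band-length lists cannot be
matched one-to-one within resolution after sorting. Multiplicity
(band intensity) is deliberately ignored in the comparison — intensity
is unreliable on real gels — and an uncut lane (single full-length band)
is a valid, often diagnostic, pattern.

An enzyme uniquely identifies a species when its pattern there differs
from every other species. The minimal discriminating set is a set cover
over the 15 unordered species pairs, solved greedily (most uncovered
pairs first, ties broken lexicographically by enzyme name, so results
are order-invariant); `exact=True` searches all subsets, feasible for
panels up to ~20 enzymes, and the greedy solution is compared against it
on every panel the tests and acceptance script construct. Raising
resolution can only merge bands, never split them, so separated pairs
are monotone non-increasing in `resolution_bp` (tested).

The packaged reference profile stores the published six-species fragment
matrix. Cells with no reported diagnostic cut are encoded as the uncut
amplicon (1107 bp for the plastid column, 1005 bp for the mitochondrial
columns), matching gel lanes where non-target species show the
undigested product. Published fragment tables typically list visible
bands only, so a row's fragments need not sum exactly to the nominal
amplicon length; the profile container therefore does not enforce the
sum, while digest-derived profiles satisfy it by construction and are
tested for it.

## Synthetic panels

The generator emulates a panel of per-species reference templates:
`forward primer + uniform-random A/C/G/T core + reverse-complemented
reverse primer`, with chosen enzyme sites (a concrete realisation of the
degenerate pattern) planted at chosen positions in chosen species. A
cleanliness sweep then rescans every species with every panel enzyme and
locally re-randomises any accidental site (bounded retries; a site that
cannot be removed because it lies wholly inside a primer or a planted
site is a generation error). One seeded stream drives everything, so a
panel is a pure function of its spec. The default primer flanks are
fixed 22/24-mers chosen to be free of all eight panel enzymes' sites in
both orientations; real primer pairs do not always have this property
(one widely used pair carries a BsrI site), which in practice only adds
small primer-proximal fragments shared by all species, but would blur
the planted-site ground truth the generator exists to provide.

What the generator does *not* emulate: within-species polymorphism,
indels, base-composition bias, sequencing errors, or heteroplasmy.
Passing the planted-panel tests therefore shows that the pipeline
recovers diagnostic sites exactly when they are the only signal; it does
not show robustness to intraspecific variation, which on real data must
be established by profiling multiple accessions per species.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: 1000 random
digests (30–400 bp) for conservation, 500 scanner-vs-oracle trials
(sequences ≤ 500 bp, degenerate patterns 4–12 nt, including negative and
beyond-pattern cut offsets), three seeded six-species 1 kb planted
panels through the full pipeline, and the packaged reference profile;
the whole suite completes in a few seconds. Determinism is part of the
contract: panels are seeded, greedy ties are lexicographic, SVG output
is byte-identical for identical input. Degenerate edge cases are pinned
by tests: empty digests return one full-length fragment, a cut at a
substrate boundary is kept (its zero-length complement is dropped by the
visibility threshold downstream), and an all-identical panel yields an
empty minimal set with `fully_resolved = False`.

## Limitations

No methylation sensitivity, star activity, isoschizomers, enzyme
kinetics or partial digestion; no primer design or Tm calculation; no
multiplex PCR; no densitometry or raster gel images. Diagnostics score
reference sequences only — field validation across multiple samples per
species is outside the model. The `fetch` subcommand requires network
access and is never exercised by the tests.
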