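"""Band modelling, pattern distinctness and diagnostic enzyme selection."""

import io
import itertools

import pytest

from rflpkit.digestion import DigestResult
from rflpkit.panel_diagnostics import (
    RFLPProfile,
    band_pattern,
    build_profile,
    diagnose,
    exact_minimal_set,
    load_profile_tsv,
    load_table1_profile,
    patterns_distinct,
    write_profile_tsv,
)


class TestBandPattern:
    def test_comigration_merges_close_fragments(self):
        # a 510/495 pair on 1.5% agarose shows as one heavier band
        assert band_pattern([510, 495], resolution_bp=20) == ((510, 2),)

    def test_well_separated_fragments_stay_apart(self):
        assert band_pattern([664, 333], resolution_bp=20) == ((664, 1), (333, 1))

    def test_single_fragment_single_band(self):
        assert band_pattern([1000]) == ((1000, 1),)

    def test_small_fragments_run_off(self):
        assert band_pattern([600, 50], min_visible_bp=80) == ((600, 1),)

    def test_single_linkage_chains(self):
        # 100-115-130: each step <= 20 so the chain is one band at its max
        assert band_pattern([100, 115, 130], resolution_bp=20) == ((130, 3),)

    def test_empty_fragment_list_rejected(self):
        with pytest.raises(ValueError):
            band_pattern([])


class TestPatternsDistinct:
    def test_cut_vs_uncut(self):
        cut = band_pattern([556, 551])   # merges to one band near 556
        uncut = band_pattern([1107])
        assert patterns_distinct(cut, uncut, 20)

    def test_identical_not_distinct(self):
        b = band_pattern([664, 333])
        assert not patterns_distinct(b, b, 20)

    def test_same_count_different_sizes(self):
        a = band_pattern([600, 401])
        b = band_pattern([844, 119])
        assert patterns_distinct(a, b, 20)

    def test_within_resolution_not_distinct(self):
        assert not patterns_distinct(band_pattern([500]), band_pattern([515]), 20)


def _digest(sid, enzyme, fragments):
    cuts = tuple(range(1, len(fragments)))  # placeholder coordinates
    return DigestResult(sid, enzyme, cuts, tuple(sorted(fragments, reverse=True)))


class TestBuildProfile:
    def test_grid_assembly(self):
        digests = [
            _digest(f"s{i}", e, [1000])
            for i in range(6)
            for e in ["E1", "E2"]
        ]
        profile = build_profile(digests, {f"s{i}": f"sp{i}" for i in range(6)})
        assert len(profile.species) == 6 and len(profile.enzymes) == 2
        assert profile.patterns[("sp0", "E1")] == (1000,)

    def test_missing_cell_named(self):
        digests = [_digest("s0", "E1", [500]), _digest("s1", "E1", [500]),
                   _digest("s0", "E2", [500])]
        with pytest.raises(ValueError, match="'sp1'.*'E2'"):
            build_profile(digests, {"s0": "sp0", "s1": "sp1"})


class TestDiagnose:
    def _profile(self, cells, resolution=20):
        species = sorted({sp for sp, _ in cells})
        enzymes = sorted({e for _, e in cells})
        return RFLPProfile(
            species=tuple(species), enzymes=tuple(enzymes),
            patterns=cells, resolution_bp=resolution,
        )

    def test_planted_unique_identifier(self):
        cells = {
            ("sp0", "E"): (600, 400), ("sp1", "E"): (1000,), ("sp2", "E"): (1000,),
            ("sp0", "F"): (1000,), ("sp1", "F"): (1000,), ("sp2", "F"): (1000,),
        }
        rep = diagnose(self._profile(cells))
        assert rep.unique_identifiers["sp0"] == ("E",)
        assert rep.unique_identifiers["sp1"] == ()
        assert not rep.fully_resolved  # sp1 vs sp2 inseparable

    def test_all_identical_panel(self):
        cells = {(sp, e): (900,) for sp in ("a", "b", "c") for e in ("E", "F")}
        rep = diagnose(self._profile(cells))
        assert all(not pairs for pairs in rep.per_enzyme.values())
        assert rep.minimal_set == () and not rep.fully_resolved

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(ValueError):
            diagnose(self._profile({("only", "E"): (500,)}))

    def test_order_invariance(self):
        cells = {
            ("a", "E"): (700, 300), ("b", "E"): (1000,), ("c", "E"): (500, 480),
            ("a", "F"): (1000,), ("b", "F"): (200, 800), ("c", "F"): (1000,),
        }
        rep1 = diagnose(self._profile(cells))
        shuffled = RFLPProfile(
            species=("c", "a", "b"), enzymes=("F", "E"),
            patterns=cells, resolution_bp=20,
        )
        rep2 = diagnose(shuffled)
        assert dict(rep1.per_enzyme) == dict(rep2.per_enzyme)
        assert set(rep1.minimal_set) == set(rep2.minimal_set)

    def test_resolution_monotonicity(self):
        cells = {
            ("a", "E"): (700,), ("b", "E"): (680,), ("c", "E"): (400,),
        }
        for lo, hi in [(5, 20), (20, 50), (50, 400)]:
            n_lo = len(diagnose(self._profile(cells, lo)).per_enzyme["E"])
            n_hi = len(diagnose(self._profile(cells, hi)).per_enzyme["E"])
            assert n_lo >= n_hi

    def test_greedy_cover_matches_exhaustive_size(self):
        """Brute-force oracle over all enzyme subsets on random panels."""
        import random

        rng = random.Random(11)
        for _ in range(15):
            n_sp, n_enz = 5, 6
            cells = {}
            for si in range(n_sp):
                for ei in range(n_enz):
                    # random fragment pattern from a small vocabulary
                    cells[(f"sp{si}", f"E{ei}")] = tuple(
                        rng.choice([(1000,), (600, 400), (700, 300), (900, 100)])
                    )
            profile = self._profile(cells)
            rep = diagnose(profile)
            # oracle: smallest subset separating all separable pairs
            all_pairs = {
                frozenset(p) for p in itertools.combinations(profile.species, 2)
            }
            separable = set().union(*rep.per_enzyme.values()) if rep.per_enzyme else set()
            best = None
            for size in range(0, n_enz + 1):
                for subset in itertools.combinations(profile.enzymes, size):
                    cov = set().union(*(rep.per_enzyme[e] for e in subset)) if subset else set()
                    if cov >= separable:
                        best = subset
                        break
                if best is not None:
                    break
            covered = (
                set().union(*(rep.per_enzyme[e] for e in rep.minimal_set))
                if rep.minimal_set else set()
            )
            # greedy is feasible (covers every separable pair) ...
            assert covered >= separable
            # ... and within the ln(n) guarantee; on panels this small, equal or +1
            assert len(best) <= len(rep.minimal_set) <= len(best) + 1
            assert rep.fully_resolved == (covered == all_pairs)


class TestReferenceProfile:
    def test_unique_identifiers_match_published_assignments(self):
        rep = diagnose(load_table1_profile())
        assert rep.unique_identifiers == {
            "P. yezoensis": ("BglI",),
            "P. seriata": ("Tth111I",),
            "P. dentata": ("AvaII",),
            "P. suborbiculata": ("BsrI",),
            "P. haitanensis": ("BsaAI",),
            "P. pseudolinearis": ("HindIII", "SacII", "SphI"),
        }
        assert rep.fully_resolved

    def test_greedy_minimal_set_matches_exhaustive(self):
        profile = load_table1_profile()
        rep = diagnose(profile)
        exact = exact_minimal_set(profile)
        assert len(rep.minimal_set) == len(exact) == 4

    def test_bsri_does_not_separate_seriata_from_dentata(self):
        rep = diagnose(load_table1_profile())
        assert frozenset({"P. seriata", "P. dentata"}) not in rep.per_enzyme["BsrI"]


def test_profile_tsv_round_trip():
    profile = load_table1_profile()
    buf = io.StringIO()
    write_profile_tsv(profile, buf)
    buf.seek(0)
    again = load_profile_tsv(buf)
    assert again.species == profile.species
    assert again.enzymes == profile.enzymes
    assert dict(again.patterns) == dict(profile.patterns)
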