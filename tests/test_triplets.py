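"""Residue bit strings, triplet enumeration, keys, index, and matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frasebot.structures import AtomRecord, Residue
from frasebot.triplets import (
    BITS_PER_RESIDUE,
    RESIDUE_BITS,
    ResidueTriplet,
    TripletIndex,
    UntypableResidueError,
    build_index,
    canonical_order,
    enumerate_triplets,
    load_index,
    match_target,
    residue_bits,
    save_index,
    triplet_key,
)

CODES = sorted(RESIDUE_BITS)


def _res(code, xyz, chain="A", seq=1):
    return Residue(code, chain, seq, [AtomRecord("C", np.asarray(xyz, float), name="CA")])


class TestResidueBits:
    def test_table_covers_20_codes_of_11_bits(self):
        assert len(RESIDUE_BITS) == 20
        assert all(len(bits) == BITS_PER_RESIDUE == 11 for bits in RESIDUE_BITS.values())
        assert all(set(b) <= {"0", "1"} for b in RESIDUE_BITS.values())

    def test_glycine_all_zero(self):
        assert residue_bits("GLY") == "0" * 11

    def test_tryptophan_volume_hbd_aromatic(self):
        bits = residue_bits("TRP")
        # layout: pos neg hba hbd ar hyd(3) vol(3)
        assert bits[8:11] == "111"  # all three volume bits set
        assert bits[3] == "1"  # H-bond donor
        assert bits[4] == "1"  # aromatic

    def test_phenylalanine_row(self):
        bits = residue_bits("PHE")
        assert bits[4] == "1" and bits[5:8] == "111" and bits[8:11] == "111"

    def test_charge_assignment_chemically_consistent(self):
        for code in ("ARG", "LYS", "HIS"):
            assert residue_bits(code)[0] == "1" and residue_bits(code)[1] == "0"
        for code in ("ASP", "GLU"):
            assert residue_bits(code)[0] == "0" and residue_bits(code)[1] == "1"

    def test_untypable_code_raises(self):
        with pytest.raises(UntypableResidueError):
            residue_bits("MSE")


class TestTripletKey:
    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(CODES), min_size=3, max_size=3))
    def test_permutation_invariance(self, codes):
        keys = {triplet_key(list(p)).canonical for p in itertools.permutations(codes)}
        assert len(keys) == 1

    def test_degenerate_identical_residues(self):
        key = triplet_key(("GLY", "GLY", "GLY"))
        assert len(key.fps) == 1
        assert key.canonical == "0" * 33

    def test_distinct_residues_give_six_strings(self):
        key = triplet_key(("ALA", "PHE", "TRP"))
        manual = {
            "".join(RESIDUE_BITS[c] for c in perm)
            for perm in itertools.permutations(("ALA", "PHE", "TRP"))
        }
        assert set(key.fps) == manual
        assert len(key.fps) == 6
        assert all(len(fp) == 33 for fp in key.fps)
        assert key.canonical == min(manual)

    def test_canonical_order_correspondence(self):
        t1 = ResidueTriplet(
            (_res("ALA", (0, 0, 0)), _res("PHE", (10, 0, 0)), _res("TRP", (5, 8.66, 0))),
            np.array([[0, 0, 0], [10, 0, 0], [5, 8.66, 0]], float),
        )
        t2 = ResidueTriplet(tuple(t1.residues[i] for i in (2, 0, 1)),
                            t1.ca_coords[[2, 0, 1]])
        o1, o2 = canonical_order(t1), canonical_order(t2)
        codes1 = [t1.residues[i].name for i in o1]
        codes2 = [t2.residues[i].name for i in o2]
        assert codes1 == codes2


class TestEnumerateTriplets:
    def test_constructed_equilateral(self):
        residues = [
            _res("ALA", (0, 0, 0), seq=1),
            _res("GLY", (10, 0, 0), seq=2),
            _res("SER", (5, 8.66, 0), seq=3),
        ]
        out = enumerate_triplets(residues)
        assert len(out) == 1
        assert all(8 <= e <= 12 for e in out[0].edges)

    def test_below_lower_bound_excluded(self):
        residues = [
            _res("ALA", (0, 0, 0), seq=1),
            _res("GLY", (7, 0, 0), seq=2),
            _res("SER", (3.5, 6.06, 0), seq=3),
        ]
        assert enumerate_triplets(residues) == []

    def test_bounds_inclusive(self):
        residues = [
            _res("ALA", (0, 0, 0), seq=1),
            _res("GLY", (8, 0, 0), seq=2),
            _res("SER", (0, 12, 0), seq=3),
        ]
        # edges: 8, 12, sqrt(64+144)=14.4 -> excluded; move third residue
        assert enumerate_triplets(residues) == []
        residues[2] = _res("SER", (4, 8, 0), seq=3)
        # edges: 8, sqrt(16+64)=8.94, sqrt(16+64)=8.94 -> included
        assert len(enumerate_triplets(residues)) == 1

    def test_matches_brute_force_on_lattice(self, rng):
        pts = rng.uniform(0, 18, size=(10, 3))
        residues = [_res(CODES[i % 20], pts[i], seq=i + 1) for i in range(10)]
        got = enumerate_triplets(residues)
        expected = 0
        for i, j, k in itertools.combinations(range(10), 3):
            d = [np.linalg.norm(pts[i] - pts[j]), np.linalg.norm(pts[j] - pts[k]),
                 np.linalg.norm(pts[i] - pts[k])]
            if all(8 <= x <= 12 for x in d):
                expected += 1
        assert len(got) == expected

    def test_nonstandard_and_ca_less_residues_skipped(self):
        residues = [
            _res("ALA", (0, 0, 0), seq=1),
            _res("GLY", (10, 0, 0), seq=2),
            Residue("MSE", "A", 3, [AtomRecord("C", (5.0, 8.66, 0.0), name="CA")]),
            Residue("SER", "A", 4, [AtomRecord("O", (5.0, -8.66, 0.0), name="OG")]),
        ]
        assert enumerate_triplets(residues) == []

    def test_fewer_than_three_residues(self):
        assert enumerate_triplets([_res("ALA", (0, 0, 0))]) == []


class TestIndexAndMatch:
    def test_fixture_frase_counts(self, frase_set_small):
        from frasebot.fixtures import brute_force_triplets

        index = build_index(frase_set_small)
        for fid, frase in enumerate(frase_set_small):
            assert index.counts[fid] == len(brute_force_triplets(frase.environment))

    def test_empty_db_empty_index(self):
        index = build_index([])
        assert len(index) == 0 and index.entries == {}

    def test_self_match(self, frase_set_small):
        index = build_index(frase_set_small)
        tts = enumerate_triplets(frase_set_small[0].environment)
        matches = match_target(tts, index)
        self_matches = [m for m in matches if m.frase_id == 0]
        # every target triplet matches at least its identical db counterpart
        assert len(self_matches) >= len(tts)
        matched_seqs = {
            frozenset(r.seq for r in m.db_triplet.residues) for m in self_matches
        }
        for tt in tts:
            assert frozenset(r.seq for r in tt.residues) in matched_seqs

    def test_no_match_for_absent_key(self, frase_set_small):
        index = build_index(frase_set_small)
        gly_triplet = [
            _res("GLY", (0, 0, 0), seq=1),
            _res("GLY", (10, 0, 0), seq=2),
            _res("GLY", (5, 8.66, 0), seq=3),
        ]
        tts = enumerate_triplets(gly_triplet)
        matches = match_target(tts, index)
        # all-zero key is absent from the fixture database
        if "0" * 33 not in index.entries:
            assert matches == []

    def test_match_equals_brute_force_all_pairs(self, frase_set_small):
        """Hashed canonical-key matching reproduces exhaustive comparison of
        the full 6-permutation fingerprint sets."""
        index = build_index(frase_set_small)
        db_triplets = {
            (fid, tid): tp for (fid, tid), tp in index.triplets.items()
        }
        target_tts = enumerate_triplets(frase_set_small[3].environment)
        got = {
            (id(m.target_triplet), m.frase_id, m.db_triplet_id)
            for m in match_target(target_tts, index)
        }
        expected = set()
        for tt in target_tts:
            tt_fps = {
                "".join(residue_bits(tt.residues[i].name) for i in perm)
                for perm in itertools.permutations(range(3))
            }
            for (fid, tid), dt in db_triplets.items():
                dt_fps = {
                    "".join(residue_bits(dt.residues[i].name) for i in perm)
                    for perm in itertools.permutations(range(3))
                }
                if tt_fps == dt_fps:
                    expected.add((id(tt), fid, tid))
        assert got == expected

    def test_save_load_round_trip(self, frase_set_small, tmp_path):
        index = build_index(frase_set_small)
        path = tmp_path / "idx.json"
        save_index(index, str(path))
        back = load_index(str(path))
        assert back.entries == index.entries
        assert back.counts == index.counts
        for key, tp in index.triplets.items():
            np.testing.assert_allclose(back.triplets[key].ca_coords, tp.ca_coords)
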