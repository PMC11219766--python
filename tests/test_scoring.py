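"""Interaction fingerprints, decoy generation, and the nativeness net."""

import math

import numpy as np
import pytest
from rdkit import Chem

from frasebot.extract import Fragment, Frase
from frasebot.fixtures import make_frase_set, make_separable_training_set, _random_rotation
from frasebot.scoring import (
    FINGERPRINT_DIM,
    LIGAND_TYPE_SMARTS,
    N_LIGAND_TYPES,
    N_PROTEIN_TYPES,
    PROTEIN_TYPES,
    DecoySpec,
    NativenessModel,
    TrainConfig,
    distance_weight,
    interaction_fingerprint,
    make_decoys,
    score_frase,
    split_ids,
    train_model,
    type_ligand_atoms,
    type_protein_atoms,
)
from frasebot.structures import AtomRecord, Residue

LNAMES = [n for n, _ in LIGAND_TYPE_SMARTS]


class TestVocabularies:
    def test_dimensions(self):
        assert N_LIGAND_TYPES == 29
        assert N_PROTEIN_TYPES == 13
        assert FINGERPRINT_DIM == 377

    def test_benzene_carbons(self):
        types = type_ligand_atoms(Chem.MolFromSmiles("c1ccccc1"))
        for t in types:
            assert {LNAMES[i] for i in t} == {"Aromatic", "Aromatic Carbon"}

    def test_fluorine_atom(self):
        types = type_ligand_atoms(Chem.MolFromSmiles("Fc1ccccc1"))
        f_types = {LNAMES[i] for i in types[0]}
        assert {"Halogen", "F", "Hetero"} <= f_types

    def test_carboxylate_oxygen(self):
        types = type_ligand_atoms(Chem.MolFromSmiles("CC(=O)[O-]"))
        mol = Chem.MolFromSmiles("CC(=O)[O-]")
        for atom, t in zip(mol.GetAtoms(), types):
            if atom.GetSymbol() == "O":
                names = {LNAMES[i] for i in t}
                assert "Carboxylate Oxygen" in names
                assert "Negative Ionizable" in names

    def test_asp_sidechain_protein_typing(self):
        res = Residue("ASP", "A", 1, [
            AtomRecord("O", (0, 0, 0), name="OD1"),
            AtomRecord("O", (1, 0, 0), name="OD2"),
        ])
        _, types = type_protein_atoms([res])
        for t in types:
            names = {PROTEIN_TYPES[i] for i in t}
            assert {"H-bond Acceptor", "Negative Ionizable", "Carboxylate Oxygen"} == names

    def test_untabulated_atom_has_empty_types(self):
        res = Residue("MET", "A", 1, [AtomRecord("S", (0, 0, 0), name="SD")])
        _, types = type_protein_atoms([res])
        assert types == [set()]


class TestDistanceWeight:
    @pytest.mark.parametrize(
        "d,expected",
        [(3.0, 1.0), (4.0, math.exp(-1.0)), (0.0, math.exp(-9.0)),
         (10.0, math.exp(-49.0)), (10.01, 0.0), (12.0, 0.0)],
    )
    def test_values(self, d, expected):
        assert distance_weight(d) == pytest.approx(expected, rel=1e-12)

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            distance_weight(-0.1)

    def test_vectorized(self):
        out = distance_weight(np.array([3.0, 11.0]))
        np.testing.assert_allclose(out, [1.0, 0.0])


def _one_pair_frase(d, resname="ALA", atom_name="CB"):
    """Single aliphatic ligand carbon at distance d from one CB carbon."""
    frag = Fragment(Chem.MolFromSmiles("C"), np.zeros((1, 3)))
    res = Residue(resname, "A", 1, [AtomRecord("C", (d, 0.0, 0.0), name=atom_name)])
    return Frase(frag, [res], 4.5)


class TestInteractionFingerprint:
    def test_single_pair_at_three_angstroms(self):
        fp = interaction_fingerprint(_one_pair_frase(3.0))
        m = LNAMES.index("Aliphatic Carbon")
        n = PROTEIN_TYPES.index("Aliphatic Carbon")
        assert fp[m * 13 + n] == pytest.approx(1.0)
        assert fp.sum() == pytest.approx(1.0)  # both atoms single-typed

    def test_pair_beyond_cap_is_zero(self):
        fp = interaction_fingerprint(_one_pair_frase(12.0))
        assert not fp.any()

    def test_length_and_nonnegativity(self, frase_set_small):
        fp = interaction_fingerprint(frase_set_small[0])
        assert fp.shape == (377,)
        assert (fp >= 0).all() and fp.any()

    def test_matches_brute_force_double_loop(self, frase_set_small):
        """Eq-by-eq literal double loop over atoms and type pairs."""
        from frasebot.structures import fragment_to_mol

        for frase in frase_set_small[:6]:
            fp = interaction_fingerprint(frase)
            lig_types = type_ligand_atoms(fragment_to_mol(frase.fragment))
            oracle = np.zeros(377)
            prot_atoms = [(a, r) for r in frase.environment for a in r.atoms]
            _, prot_types = type_protein_atoms(frase.environment)
            for i, lt in enumerate(lig_types):
                for j, (atom, _r) in enumerate(prot_atoms):
                    d = math.dist(frase.fragment.coords[i], atom.position)
                    w = math.exp(-((d - 3.0) ** 2)) if d <= 10.0 else 0.0
                    for m in lt:
                        for n in prot_types[j]:
                            oracle[m * 13 + n] += w
            np.testing.assert_allclose(fp, oracle, atol=1e-12)

    def test_invariant_under_rigid_motion(self, frase_set_small, rng):
        frase = frase_set_small[2]
        fp0 = interaction_fingerprint(frase)
        R = _random_rotation(rng)
        t = np.array([3.0, -7.0, 12.0])
        moved = Frase(
            frase.fragment.transformed(R, t),
            [r.transformed(R, t) for r in frase.environment],
            frase.env_radius,
        )
        fp1 = interaction_fingerprint(moved)
        np.testing.assert_allclose(fp0, fp1, atol=1e-9)

    def test_empty_environment_zero_vector(self):
        frag = Fragment(Chem.MolFromSmiles("C"), np.zeros((1, 3)))
        fp = interaction_fingerprint(Frase(frag, [], 4.5))
        assert fp.shape == (377,) and not fp.any()


class TestDecoys:
    def test_count_conservation(self, frase_set_small):
        decoys = make_decoys(frase_set_small, DecoySpec(2, 0))
        assert len(decoys) == 2 * len(frase_set_small)
        assert all(d.label == "decoy" for d in decoys)

    def test_environment_unchanged(self, frase_set_small):
        decoys = make_decoys(frase_set_small, DecoySpec(1, 0))
        for orig, dec in zip(frase_set_small, decoys):
            assert dec.environment is orig.environment

    def test_deterministic_for_fixed_seed(self, frase_set_small):
        d1 = make_decoys(frase_set_small, DecoySpec(2, 42))
        d2 = make_decoys(frase_set_small, DecoySpec(2, 42))
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.fragment.coords, b.fragment.coords)
            assert Chem.MolToSmiles(a.fragment.mol) == Chem.MolToSmiles(b.fragment.mol)

    def test_swapped_fragment_centroid_preserved(self, frase_set_small):
        decoys = make_decoys(frase_set_small, DecoySpec(1, 7))
        for orig, dec in zip(frase_set_small, decoys):
            np.testing.assert_allclose(
                dec.fragment.centroid(), orig.fragment.centroid(), atol=1e-8
            )

    def test_single_frase_raises(self, frase_set_small):
        with pytest.raises(ValueError):
            make_decoys(frase_set_small[:1], DecoySpec(2, 0))


class TestSplit:
    def test_disjoint_and_exhaustive(self):
        ids = list(range(1000))
        train, valid = split_ids(ids, 300, seed=1)
        assert len(train) == 300 and len(valid) == 700
        assert set(train) & set(valid) == set()
        assert set(train) | set(valid) == set(ids)


class TestNativenessModel:
    def test_separable_set_high_holdout_accuracy(self):
        tf, df, bayes = make_separable_training_set(300, effect=2.0, seed=0)
        assert bayes >= 0.95
        model = train_model(tf[:200], df[:400], TrainConfig(epochs=150, seed=0))
        acc = np.concatenate(
            [model.predict(tf[200:]) > 0.5, model.predict(df[400:]) <= 0.5]
        ).mean()
        assert acc >= 0.95

    def test_shuffled_labels_near_chance(self):
        tf, df, _ = make_separable_training_set(500, effect=2.0, seed=2, n_decoys=500)
        X = np.vstack([tf, df])
        y = np.concatenate([np.ones(500), np.zeros(500)])
        rng = np.random.default_rng(0)
        rng.shuffle(y)
        model = train_model(X[:700][y[:700] == 1], X[:700][y[:700] == 0],
                            TrainConfig(epochs=80, seed=0))
        acc = ((model.predict(X[700:]) > 0.5) == (y[700:] == 1)).mean()
        assert abs(acc - 0.5) <= 0.05

    def test_output_strictly_in_unit_interval(self, rng):
        model = NativenessModel(config=TrainConfig(seed=3))
        X = rng.normal(size=(40, 377)) * 100
        p = model.predict(X)
        assert np.all(p > 0) and np.all(p < 1)

    def test_single_class_raises(self):
        model = NativenessModel(10)
        with pytest.raises(ValueError):
            model.fit(np.zeros((5, 10)), np.zeros(5))

    def test_training_deterministic_for_seed(self):
        tf, df, _ = make_separable_training_set(60, effect=1.0, seed=5)
        m1 = train_model(tf, df, TrainConfig(epochs=20, seed=9))
        m2 = train_model(tf, df, TrainConfig(epochs=20, seed=9))
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_save_load_round_trip(self, tmp_path):
        tf, df, _ = make_separable_training_set(60, effect=1.0, seed=5)
        model = train_model(tf, df, TrainConfig(epochs=20, seed=9))
        path = tmp_path / "model.json"
        model.save(str(path))
        back = NativenessModel.load(str(path))
        X = tf[:10]
        np.testing.assert_array_equal(model.predict(X), back.predict(X))


@pytest.fixture(scope="module")
def trained():
    frases = make_frase_set(40, seed=3)
    decoys = make_decoys(frases, DecoySpec(2, 3))
    tfps = np.array([interaction_fingerprint(f) for f in frases])
    dfps = np.array([interaction_fingerprint(f) for f in decoys])
    model = train_model(tfps, dfps, TrainConfig(epochs=150, seed=0))
    return frases, decoys, model


class TestScoreFrase:
    def test_true_scores_above_decoy_scores(self, trained):
        frases, decoys, model = trained
        ts = np.mean([score_frase(model, f) for f in frases[:10]])
        ds = np.mean([score_frase(model, d) for d in decoys[:20]])
        assert ts > 0.5 > ds

    def test_score_invariant_under_rigid_motion(self, trained, rng):
        frases, _, model = trained
        frase = frases[0]
        R = _random_rotation(rng)
        t = np.array([1.0, 2.0, 3.0])
        moved = Frase(
            frase.fragment.transformed(R, t),
            [r.transformed(R, t) for r in frase.environment],
            frase.env_radius,
        )
        assert score_frase(model, moved) == pytest.approx(
            score_frase(model, frase), abs=1e-9
        )
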