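import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from pathsense.chemstruct import parse_and_normalize
from pathsense.errors import DiameterMismatchError
from pathsense.fixtures import random_molecule
from pathsense.oracle import brute_force_atomic_signature
from pathsense.signatures import (
    MolecularSignature,
    ReactionSignature,
    atomic_signature,
    molecular_signature,
    reaction_signature,
    signature_diameter_check,
)

DIAMETERS = (0, 2, 4, 6, 12)


class TestAtomicSignature:
    def test_lone_atom_is_root_only(self):
        water = parse_and_normalize("O")
        for diameter in DIAMETERS:
            assert atomic_signature(water, 0, diameter).canonical_string == "O"

    def test_ethanol_central_carbon_diameter_2(self):
        mol = parse_and_normalize("CCO")
        # central carbon: bonded to one C and one O
        central = next(
            i for i in range(mol.num_atoms)
            if len(mol.neighbors(i)) == 2
        )
        sig = atomic_signature(mol, central, 2).canonical_string
        assert sig == "C|C(0-)|O(0-)"

    def test_odd_diameter_rejected(self):
        mol = parse_and_normalize("CCO")
        with pytest.raises(ValueError):
            atomic_signature(mol, 0, 3)

    def test_out_of_range_atom_rejected(self):
        mol = parse_and_normalize("CCO")
        with pytest.raises(IndexError):
            atomic_signature(mol, 99, 2)

    def test_truncated_environments_never_collide_with_larger(self):
        # same local pattern, different environment size -> different strings
        ethanol = parse_and_normalize("CCO")
        propanol = parse_and_normalize("CCCO")
        eth_o = next(i for i in range(3) if ethanol.atom_label(i) == "O")
        prop_o = next(i for i in range(4) if propanol.atom_label(i) == "O")
        assert (atomic_signature(ethanol, eth_o, 12).canonical_string
                != atomic_signature(propanol, prop_o, 12).canonical_string)


class TestOracleEquivalence:
    FIXTURE_SMILES = [
        "O", "CCO", "CC=O", "CC(=O)O", "ON=O", "c1ccccc1", "C1CCCCC1",
        "Oc1ccccc1", "Cc1ccccc1", "Oc1ccccc1O", "Oc1ccc(O)cc1",
        "OC(=O)c1ccccc1", "CCOP(=S)(O)OCC", "Oc1ccc(cc1)[N+](=O)[O-]",
    ]

    @pytest.mark.parametrize("smiles", FIXTURE_SMILES)
    def test_matches_exhaustive_permutation_oracle(self, smiles):
        mol = parse_and_normalize(smiles)
        assert mol.num_atoms <= 12 or smiles in ("CCOP(=S)(O)OCC",)
        diameters = [0, 2, 4] + ([12] if mol.num_atoms <= 7 else [])
        for diameter in diameters:
            for idx in range(mol.num_atoms):
                fast = atomic_signature(mol, idx, diameter).canonical_string
                assert fast == brute_force_atomic_signature(mol, idx, diameter)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_oracle_on_random_molecules(self, seed):
        mol = parse_and_normalize(random_molecule(random.Random(seed), 3, 8))
        for diameter in (0, 2, 4):
            for idx in range(mol.num_atoms):
                assert (atomic_signature(mol, idx, diameter).canonical_string
                        == brute_force_atomic_signature(mol, idx, diameter))


class TestMolecularSignature:
    def test_ethanol_diameter_0(self):
        sig = molecular_signature(parse_and_normalize("CCO"), 0)
        assert sig.fragments == {"C": 2, "O": 1}

    def test_benzene_diameter_12_single_fragment(self):
        sig = molecular_signature(parse_and_normalize("c1ccccc1"), 12)
        assert len(sig.fragments) == 1
        assert sig.total() == 6

    def test_cocaine_total_is_22(self, cocaine_mol):
        for diameter in DIAMETERS:
            assert molecular_signature(cocaine_mol, diameter).total() == 22

    @pytest.mark.parametrize("smiles", ["CCO", "OC(=O)c1ccccc1", "CC(C)N", "O"])
    @pytest.mark.parametrize("diameter", DIAMETERS)
    def test_conservation(self, smiles, diameter):
        mol = parse_and_normalize(smiles)
        assert molecular_signature(mol, diameter).total() == mol.num_atoms

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_conservation_on_random_molecules(self, seed):
        mol = parse_and_normalize(random_molecule(random.Random(seed)))
        for diameter in (0, 2, 6):
            assert molecular_signature(mol, diameter).total() == mol.num_atoms

    def test_invariant_under_atom_permutation(self):
        rd = Chem.MolFromSmiles("CN1C2CCC1C(O)C2")
        rng = random.Random(3)
        reference = None
        for _ in range(4):
            order = list(range(rd.GetNumAtoms()))
            rng.shuffle(order)
            rendering = Chem.MolToSmiles(Chem.RenumberAtoms(rd, order), canonical=False)
            sig = molecular_signature(parse_and_normalize(rendering), 6)
            reference = reference or sig
            assert sig == reference

    def test_monotone_refinement(self):
        # equal fragments at d+2 imply equal fragments at d
        for smiles in ["Oc1ccc(O)cc1", "CCOP(=S)(O)OCC", "OC(=O)c1ccccc1"]:
            mol = parse_and_normalize(smiles)
            for d in (0, 2, 4, 6, 10):
                coarse = [atomic_signature(mol, i, d).canonical_string for i in range(mol.num_atoms)]
                fine = [atomic_signature(mol, i, d + 2).canonical_string for i in range(mol.num_atoms)]
                for i in range(mol.num_atoms):
                    for j in range(mol.num_atoms):
                        if fine[i] == fine[j]:
                            assert coarse[i] == coarse[j]

    def test_text_round_trip(self):
        sig = molecular_signature(parse_and_normalize("OC(=O)c1ccccc1"), 4)
        assert MolecularSignature.from_text(sig.to_text(), 4) == sig


class TestReactionSignature:
    def test_identity_reaction_is_empty(self):
        sig = molecular_signature(parse_and_normalize("CCO"), 12)
        assert reaction_signature([sig], [sig]).is_empty()

    def test_ethanol_to_acetaldehyde_diameter_0_empty(self):
        # both sides have atom-type counts C2 O1
        eth = molecular_signature(parse_and_normalize("CCO"), 0)
        ald = molecular_signature(parse_and_normalize("CC=O"), 0)
        assert Counter(eth.fragments) == Counter(ald.fragments)  # oracle
        assert reaction_signature([eth], [ald]).is_empty()

    def test_cocaine_hydrolysis_consumes_ester_fragments(self, cocaine_mol):
        diameter = 2
        cocaine = molecular_signature(cocaine_mol, diameter)
        water = molecular_signature(parse_and_normalize("O"), diameter)
        benzoate = molecular_signature(parse_and_normalize("OC(=O)c1ccccc1"), diameter)
        eme = molecular_signature(parse_and_normalize("COC(=O)C1C(O)CC2CCC1N2C"), diameter)
        sig = reaction_signature([cocaine, water], [benzoate, eme])
        negative = sig.negative_part()
        assert negative
        # every consumed fragment is present in cocaine or water
        available = Counter(cocaine.fragments) + Counter(water.fragments)
        for fragment, count in negative.items():
            assert available[fragment] >= count
        # the benzoyl-ester linkage of cocaine is among the consumed fragments
        assert any(frag in cocaine.fragments for frag in negative)

    def test_antisymmetry(self):
        a = molecular_signature(parse_and_normalize("CCO"), 4)
        b = molecular_signature(parse_and_normalize("CC=O"), 4)
        forward = reaction_signature([a], [b])
        backward = reaction_signature([b], [a])
        assert backward.deltas == {f: -d for f, d in forward.deltas.items()}
        assert forward.reversed() == backward

    def test_mixed_diameters_rejected(self):
        a = molecular_signature(parse_and_normalize("CCO"), 4)
        b = molecular_signature(parse_and_normalize("CC=O"), 6)
        with pytest.raises(DiameterMismatchError):
            reaction_signature([a], [b])

    def test_telescoping_over_two_step_chain(self):
        d = 8
        sig = lambda s: molecular_signature(parse_and_normalize(s), d)
        parathion = sig("CCOP(=S)(OCC)Oc1ccc(cc1)[N+](=O)[O-]")
        water = sig("O")
        np_ = sig("Oc1ccc(cc1)[N+](=O)[O-]")
        detp = sig("CCOP(=S)(O)OCC")
        hq = sig("Oc1ccc(O)cc1")
        nitrite = sig("ON=O")
        step1 = reaction_signature([parathion, water], [np_, detp])
        step2 = reaction_signature([np_, water], [hq, nitrite])
        net = reaction_signature([parathion, water, water], [detp, hq, nitrite])
        summed = Counter(step1.deltas)
        summed.update(step2.deltas)
        assert {f: c for f, c in summed.items() if c} == net.deltas


class TestDiameterCheck:
    def test_matching(self):
        sig = molecular_signature(parse_and_normalize("CCO"), 12)
        assert signature_diameter_check(sig, 12)

    def test_mismatched(self):
        sig = molecular_signature(parse_and_normalize("CCO"), 4)
        assert not signature_diameter_check(sig, 12)

    def test_default_config_diameter_is_12(self, default_config):
        assert default_config.diameter == 12
        sig = ReactionSignature({}, default_config.diameter)
        assert signature_diameter_check(sig, 12)
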