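import numpy as np
import pytest

from coevodock.errors import ConstructiveFailureError, InvalidModelError, ParameterError
from coevodock.msa import GAP
from coevodock.structure import structure_contacts
from coevodock.synthetic import (
    BOND_LENGTH,
    PlantedModel,
    make_synthetic_crosslinks,
    make_toy_complex,
    sample_potts_msa,
)
from coevodock.xlinks import count_within, map_distances


def empirical_mi(col_a, col_b, q):
    """Plug-in mutual information (nats) between two integer columns."""
    n = len(col_a)
    joint = np.zeros((q, q))
    for a, b in zip(col_a, col_b):
        joint[a, b] += 1
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / np.outer(pa, pb)[mask])))


class TestPlantedModel:
    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidModelError):
            PlantedModel(length_a=0, length_b=5)
        with pytest.raises(InvalidModelError):
            PlantedModel(length_a=5, length_b=5, alphabet_size=1)
        with pytest.raises(InvalidModelError):
            PlantedModel(length_a=5, length_b=5, planted_pairs=((7, 0, 1.0),))
        with pytest.raises(InvalidModelError):
            PlantedModel(length_a=5, length_b=5, planted_pairs=((0, 0, np.inf),))


class TestPottsSampler:
    def test_seeded_determinism(self):
        model = PlantedModel(length_a=6, length_b=6, alphabet_size=4, seed=11)
        fam1 = sample_potts_msa(model, 50)
        fam2 = sample_potts_msa(model, 50)
        assert fam1.msa_a.sequences == fam2.msa_a.sequences
        assert fam1.msa_b.sequences == fam2.msa_b.sequences
        assert fam1.msa_a.ids == fam2.msa_a.ids
        assert fam1.pairing == fam2.pairing

    def test_zero_coupling_mi_is_small(self):
        # q=2, n=2000, no couplings: empirical inter-domain MI ~ 0
        model = PlantedModel(length_a=8, length_b=8, alphabet_size=2, seed=3)
        fam = sample_potts_msa(model, 2000)
        states = fam.states
        mis = [
            empirical_mi(states[:, i], states[:, 8 + j], 2)
            for i in range(8)
            for j in range(8)
        ]
        assert max(abs(v) for v in mis) < 0.02

    def test_planted_pair_has_highest_mi(self):
        model = PlantedModel(
            length_a=6, length_b=6, alphabet_size=2, planted_pairs=((2, 4, 2.0),), seed=5
        )
        fam = sample_potts_msa(model, 5000)
        states = fam.states
        mi = np.array(
            [[empirical_mi(states[:, i], states[:, 6 + j], 2) for j in range(6)] for i in range(6)]
        )
        assert np.unravel_index(np.argmax(mi), mi.shape) == (2, 4)

    def test_uniform_marginals_without_fields(self):
        # zero couplings and fields: column frequencies uniform within 3 SE
        model = PlantedModel(length_a=5, length_b=5, alphabet_size=4, seed=9)
        fam = sample_potts_msa(model, 5000)
        states = fam.states
        n = states.shape[0]
        p = 1.0 / 4
        se = np.sqrt(p * (1 - p) / n)
        for col in range(10):
            freqs = np.bincount(states[:, col], minlength=4) / n
            assert np.abs(freqs - p).max() < 3 * se

    def test_gap_runs_inserted(self):
        # gap is alphabet state 0, so isolated gaps occur naturally (1/q of
        # columns); inserted runs show up as contiguous 4-column blocks
        model = PlantedModel(length_a=20, length_b=20, seed=2)
        fam = sample_potts_msa(model, 200, gap_run_fraction=0.5, gap_run_length_fraction=0.2)
        with_runs = sum(GAP * 4 in s for s in fam.msa_a.sequences)
        assert with_runs > 50  # about half the rows get a run
        clean = sample_potts_msa(model, 200)
        assert sum(GAP * 4 in s for s in clean.msa_a.sequences) < 5

    def test_ground_truth_pairing_is_a_permutation(self):
        model = PlantedModel(length_a=4, length_b=4, alphabet_size=3, seed=1)
        fam = sample_potts_msa(model, 30)
        assert sorted(fam.pairing.values()) == list(range(30))
        # species agree across the true pairing
        for ia, ib in fam.pairing.items():
            assert fam.msa_a.species[ia] == fam.msa_b.species[ib]

    def test_paralog_mode_copy_numbers(self):
        model = PlantedModel(length_a=10, length_b=10, seed=4)
        fam = sample_potts_msa(model, 0, n_paralogs_per_species=[1, 2, 3], paralog_mutations=5)
        assert len(fam.msa_a) == 6
        species = [fam.msa_a.species[i] for i in range(6)]
        assert sorted(set(species)) == ["sp00000", "sp00001", "sp00002"]

    def test_bad_arguments(self):
        model = PlantedModel(length_a=4, length_b=4, seed=0)
        with pytest.raises(ParameterError):
            sample_potts_msa(model, 0)
        with pytest.raises(ParameterError):
            sample_potts_msa(model, 10, n_paralogs_per_species=0)


class TestToyComplex:
    def test_single_pair_at_six_angstrom(self):
        toy = make_toy_complex([10, 10], [(("A", 3), ("B", 5))], target_distance=6.0, seed=1)
        (ka, kb), = toy.interface_pairs
        d = np.linalg.norm(toy.model.ca_coord(ka) - toy.model.ca_coord(kb))
        assert d == pytest.approx(6.0, abs=0.1)

    def test_single_chain_no_interface(self):
        toy = make_toy_complex([7], [])
        assert toy.model.chains == ["A"]
        assert len(toy.model.residues("A")) == 7

    @pytest.mark.parametrize("geometry", ["straight", "zigzag"])
    def test_bond_lengths_within_virtual_ca_range(self, geometry):
        toy = make_toy_complex(
            [12, 12], [(("A", i), ("B", i)) for i in (4, 6, 8)],
            target_distance=8.0, seed=0, geometry=geometry,
        )
        for chain in toy.model.chains:
            coords = toy.model.ca_coords(toy.model.residues(chain))
            bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            assert np.all((bonds >= 3.6) & (bonds <= 4.0))

    @pytest.mark.parametrize("geometry", ["straight", "zigzag"])
    def test_planted_pairs_are_contacts(self, geometry):
        pairs = [(("A", i), ("B", i)) for i in (3, 6, 9)]
        toy = make_toy_complex([12, 12], pairs, target_distance=8.0, seed=2, geometry=geometry)
        contacts = structure_contacts(toy.model, cutoff=8.5, inter_chain_only=True)
        for pair in pairs:
            assert pair in contacts

    def test_exactly_planted_pairs_at_tight_cutoff(self):
        # one pair per partner chain: each partner is rotated about its
        # paired bead, so in-register neighbours fall outside 6.5 A
        pairs = [(("A", 5), ("B", 4)), (("A", 15), ("C", 4)), (("A", 25), ("D", 4))]
        toy = make_toy_complex([30, 8, 8, 8], pairs, target_distance=6.0, seed=1)
        contacts = structure_contacts(toy.model, cutoff=6.5, inter_chain_only=True)
        assert set(contacts.pairs()) == {tuple(sorted(p)) for p in pairs}

    def test_mixed_offsets_unplaceable(self):
        with pytest.raises(ConstructiveFailureError):
            make_toy_complex([10, 10], [(("A", 2), ("B", 2)), (("A", 3), ("B", 7))])

    def test_target_below_bond_length_rejected(self):
        with pytest.raises(ParameterError):
            make_toy_complex([5, 5], [], target_distance=3.0)

    def test_pdb_roundtrip(self, tmp_path):
        from coevodock.structure import read_structure

        toy = make_toy_complex([6, 6], [(("A", 3), ("B", 3))], target_distance=8.0)
        path = tmp_path / "toy.pdb"
        toy.write_pdb(path)
        back = read_structure(path)
        for key in toy.model.residues():
            assert np.allclose(back.ca_coord(key), toy.model.ca_coord(key), atol=1e-3)


class TestSyntheticCrosslinks:
    @pytest.fixture()
    def toy(self):
        return make_toy_complex(
            [30, 30], [(("A", i), ("B", i)) for i in (10, 20)], target_distance=8.0, seed=3
        )

    def test_all_true_records_satisfied(self, toy):
        table = make_synthetic_crosslinks(toy, n_true=5, n_decoy=0, max_true_distance=35.0, seed=1)
        config = {"A": (["A"], 0), "B": (["B"], 0)}
        records = _records_from(table)
        mapped = map_distances(records, toy.model, config)
        count, fraction = count_within(mapped, 35.0)
        assert count == 5
        assert fraction == 1.0

    def test_decoys_on_distant_complex_unsatisfied(self):
        from coevodock.structure import StructureModel
        from coevodock.synthetic import ToyComplex

        # two chains 50 A apart: every inter-chain pair exceeds 35 A
        a = np.outer(np.arange(5), [3.8, 0, 0])
        b = a + np.array([0.0, 50.0, 0.0])
        model = StructureModel.from_beads({"A": a, "B": b})
        toy = ToyComplex(model=model, interface_pairs=[], contact_distance=35.0)
        table = make_synthetic_crosslinks(toy, n_true=0, n_decoy=3, max_true_distance=35.0, seed=2)
        mapped = map_distances(_records_from(table), model, {"A": (["A"], 0), "B": (["B"], 0)})
        count, _ = count_within(mapped, 35.0)
        assert count == 0

    def test_mixed_fixture_fraction_half(self, toy):
        table = make_synthetic_crosslinks(
            toy, n_true=10, n_decoy=10, max_true_distance=30.0, seed=4, decoy_min_distance=40.0
        )
        assert (table.loc[table.label == "true", "distance"] <= 30).all()
        assert (table.loc[table.label == "decoy", "distance"] > 40).all()
        mapped = map_distances(_records_from(table), toy.model, {"A": (["A"], 0), "B": (["B"], 0)})
        count, fraction = count_within(mapped, 35.0)
        assert count == 10
        assert fraction == pytest.approx(0.5)

    def test_infeasible_requests_rejected(self, toy):
        with pytest.raises(ParameterError):
            make_synthetic_crosslinks(toy, 0, 0)
        with pytest.raises(ConstructiveFailureError):
            make_synthetic_crosslinks(toy, n_true=10_000, n_decoy=0)

    def test_determinism(self, toy):
        t1 = make_synthetic_crosslinks(toy, 5, 5, seed=7)
        t2 = make_synthetic_crosslinks(toy, 5, 5, seed=7)
        assert t1.equals(t2)


def _records_from(table):
    from coevodock.xlinks import CrosslinkRecord

    return [
        CrosslinkRecord(r.Protein1, int(r.Residue1), r.Protein2, int(r.Residue2))
        for r in table.itertuples()
    ]
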