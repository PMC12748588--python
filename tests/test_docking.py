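import numpy as np
import pytest

from coevodock.benchmark import benchmark_complex, benchmark_topology
from coevodock.docking import (
    DockingRun,
    Trajectory,
    add_dca_restraints,
    apply_position_restraints,
    build_go_topology,
    compute_forces,
    docking_metrics,
    initialize_separation,
    run_langevin,
)
from coevodock.errors import ParameterError, PlacementError, UnstableRunError
from coevodock.structure import StructureModel
from coevodock.synthetic import make_toy_complex


def single_chain_model(n, geometry="zigzag", seed=0):
    return make_toy_complex([n], [], seed=seed, geometry=geometry).model


class TestTopology:
    def test_bonded_term_counts(self):
        top = build_go_topology(single_chain_model(10))
        assert len(top.bonds) == 9
        assert len(top.angles) == 8
        assert len(top.dihedrals) == 7

    def test_straight_chain_contacts_match_brute_force(self):
        model = single_chain_model(12, geometry="straight")
        top = build_go_topology(model, contact_cutoff=8.0)
        coords = model.ca_coords(model.residues())
        expected = {
            (i, j)
            for i in range(12)
            for j in range(i + 1, 12)
            if j - i > 3 and np.linalg.norm(coords[i] - coords[j]) <= 8.0
        }
        assert {tuple(p) for p in top.contacts} == expected
        assert expected == set()  # 3.8 A spacing puts |i-j|>3 pairs beyond 8 A

    def test_degenerate_angles_zeroed_on_straight_chains(self):
        straight = build_go_topology(single_chain_model(8, geometry="straight"))
        assert np.all(straight.angle_k == 0.0)
        assert np.all(straight.dihedral_k1 == 0.0)
        zigzag = build_go_topology(single_chain_model(8))
        assert np.all(zigzag.angle_k > 0.0)
        assert np.all(zigzag.dihedral_k1 > 0.0)

    def test_interacting_pairs_are_excluded(self):
        complex_ = benchmark_complex()
        top = benchmark_topology(complex_)
        top.validate()
        for i, j in np.vstack([top.bonds, top.contacts, top.dca_pairs]):
            assert top.exclusions[i, j] and top.exclusions[j, i]

    def test_contact_energy_minimum_at_native_distance(self):
        # a single 12-10 well: zero force and depth -eps at r = sigma
        import biotite.structure as struc
        from coevodock.docking import GoTopology

        coords = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        model = StructureModel.from_beads({"A": coords[:1], "B": coords[1:]})
        top = build_go_topology(model)
        top = add_dca_restraints(
            top, [(("A", 1), ("B", 1))], top_k=1, epsilon=1.0, target_distance=8.0
        )
        f, u = compute_forces(top, coords)
        assert np.abs(f).max() < 1e-6
        assert u == pytest.approx(-1.0)


class TestRestraints:
    @pytest.fixture()
    def two_chain_top(self):
        toy = make_toy_complex([16, 16], [], geometry="zigzag")
        return build_go_topology(toy.model)

    def candidates(self, n):
        return [(("A", i + 1), ("B", i + 1)) for i in range(n)]

    def test_top_k_of_many(self, two_chain_top):
        top = add_dca_restraints(two_chain_top, self.candidates(12), top_k=10)
        assert len(top.dca_pairs) == 10

    def test_zero_top_k_unchanged(self, two_chain_top):
        top = add_dca_restraints(two_chain_top, self.candidates(12), top_k=0)
        assert len(top.dca_pairs) == 0
        assert top is two_chain_top

    def test_subset_selector(self, two_chain_top):
        top = add_dca_restraints(
            two_chain_top, self.candidates(12), top_k=10, subset={1, 3, 5, 7, 9}
        )
        assert len(top.dca_pairs) == 5
        # rank-1 pair is (A1, B1) -> beads 0 and 16
        assert top.dca_pairs[0].tolist() == [0, 16]

    def test_missing_beads_dropped(self, two_chain_top):
        pairs = [(("A", 1), ("B", 99)), (("A", 2), ("B", 2))]
        top = add_dca_restraints(two_chain_top, pairs, top_k=2)
        assert len(top.dca_pairs) == 1

    def test_intra_chain_pairs_rejected(self, two_chain_top):
        top = add_dca_restraints(two_chain_top, [(("A", 1), ("A", 9))], top_k=1)
        assert len(top.dca_pairs) == 0


class TestPlacement:
    @pytest.fixture()
    def top(self):
        return benchmark_topology(benchmark_complex(), restrained=True)

    def test_com_separation_sixty(self, top):
        coords = initialize_separation(top, ["B"], distance=60.0, seed=3)
        lig = top.chain_mask(["B"])
        sep = np.linalg.norm(coords[lig].mean(axis=0) - coords[~lig].mean(axis=0))
        assert sep == pytest.approx(60.0, abs=1.0)
        d = np.linalg.norm(coords[lig][:, None] - coords[~lig][None, :], axis=2)
        assert d.min() >= 6.0

    def test_zero_distance_rejected(self, top):
        with pytest.raises(ParameterError):
            initialize_separation(top, ["B"], distance=0.0)

    def test_seeded_determinism(self, top):
        c1 = initialize_separation(top, ["B"], distance=40.0, seed=5)
        c2 = initialize_separation(top, ["B"], distance=40.0, seed=5)
        assert np.array_equal(c1, c2)

    def test_unsatisfiable_clearance(self, top):
        with pytest.raises(PlacementError):
            initialize_separation(top, ["B"], distance=1.0, seed=0)


class TestIntegrator:
    def test_frictionless_energy_conservation(self):
        model = StructureModel.from_beads({"A": np.array([[0.0, 0, 0], [3.8, 0, 0]])})
        top = build_go_topology(model)
        x0 = np.array([[0.0, 0, 0], [4.2, 0, 0]])  # stretched bond, E0 = 8 eps
        traj = run_langevin(
            top,
            x0,
            DockingRun(n_steps=100_000, seed=1, timestep=0.0005, friction=0.0, temperature=0.0, stride=100),
        )
        energy = traj.total_energy
        drift = np.abs(energy - energy[0]).max() / abs(energy[0])
        assert drift < 1e-3

    def test_zero_temperature_stays_at_native(self):
        complex_ = benchmark_complex()
        top = benchmark_topology(complex_)
        traj = run_langevin(
            top,
            top.coords0,
            DockingRun(n_steps=10_000, seed=0, timestep=0.002, friction=1.0, temperature=0.0, stride=1000),
        )
        rmsd = np.sqrt(np.mean(np.sum((traj.final_coords - top.coords0) ** 2, axis=1)))
        assert rmsd < 0.05

    def test_seeded_runs_bitwise_identical(self):
        top = benchmark_topology(benchmark_complex())
        params = DockingRun(n_steps=5000, seed=7, stride=100)
        t1 = run_langevin(top, top.coords0, params)
        t2 = run_langevin(top, top.coords0, params)
        assert np.array_equal(t1.potential, t2.potential)
        assert np.array_equal(t1.coords, t2.coords)

    def test_divergence_raises(self):
        model = StructureModel.from_beads({"A": np.array([[0.0, 0, 0], [3.8, 0, 0]])})
        top = build_go_topology(model)
        x0 = np.array([[0.0, 0, 0], [8.0, 0, 0]])  # violently stretched bond
        with pytest.raises(UnstableRunError):
            run_langevin(
                top, x0, DockingRun(n_steps=5000, seed=0, timestep=5.0, friction=0.0, temperature=0.0, stride=1)
            )

    def test_equipartition(self):
        model = single_chain_model(10)
        top = build_go_topology(model)
        traj = run_langevin(
            top,
            top.coords0,
            DockingRun(n_steps=200_000, seed=2, timestep=0.001, friction=1.0, temperature=0.5, stride=200),
        )
        n_dof = 3 * top.n_beads
        mean_ke = traj.kinetic[len(traj.kinetic) // 4 :].mean()  # discard equilibration
        assert mean_ke / n_dof == pytest.approx(0.25, rel=0.05)

    def test_force_gradient_consistency(self, rng):
        # forces must equal the negative numerical gradient of the potential
        coords = np.cumsum(rng.normal(size=(6, 3)), axis=0) * 2.5
        model = StructureModel.from_beads({"A": coords})
        top = build_go_topology(model, contact_cutoff=12.0)
        assert len(top.contacts) > 0 and np.all(top.angle_k > 0)
        x = coords + rng.normal(scale=0.3, size=coords.shape)
        f, _ = compute_forces(top, x)
        h = 1e-6
        for i in range(6):
            for c in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, c] += h
                xm[i, c] -= h
                grad = (compute_forces(top, xp)[1] - compute_forces(top, xm)[1]) / (2 * h)
                assert f[i, c] == pytest.approx(-grad, abs=5e-6)


class TestMetrics:
    def test_reference_trajectory_is_perfect(self):
        top = benchmark_topology(benchmark_complex(), restrained=True)
        traj = Trajectory(
            coords=np.repeat(top.coords0[None], 10, axis=0),
            potential=np.zeros(10),
            kinetic=np.zeros(10),
            stride=1,
            timestep=0.002,
        )
        m = docking_metrics(traj, top, ["B"])
        assert m.contact_fraction == 1.0
        assert m.ligand_rmsd < 1e-5

    def test_separated_ligand_scores_zero(self):
        top = benchmark_topology(benchmark_complex(), restrained=True)
        coords = initialize_separation(top, ["B"], distance=60.0, seed=1)
        traj = Trajectory(
            coords=np.repeat(coords[None], 10, axis=0),
            potential=np.zeros(10),
            kinetic=np.zeros(10),
            stride=1,
            timestep=0.002,
        )
        m = docking_metrics(traj, top, ["B"])
        assert m.contact_fraction == 0.0
        assert m.ligand_rmsd > 20


class TestDockingFunnel:
    def test_com_distance_decreases_across_quartiles(self):
        # short runs so the approach phase spans the whole trajectory
        from coevodock.benchmark import run_docking_benchmark

        results = [
            run_docking_benchmark(seed, restrained=True, n_steps=40_000)
            for seed in range(1, 6)
        ]
        quartile_medians = []
        for q in range(4):
            vals = []
            for res in results:
                com = res.com_distance
                chunk = com[q * len(com) // 4 : (q + 1) * len(com) // 4]
                vals.append(chunk.mean())
            quartile_medians.append(np.median(vals))
        assert all(a > b for a, b in zip(quartile_medians, quartile_medians[1:]))
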