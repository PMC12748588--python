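"""Fixed study conditions shared by the test suite and the results script.

Three benchmarks are defined here so their conditions live in one place:

* planted-coupling recovery — mean-field DCA on a Potts-sampled paired MSA
  (q = 21, two 30-column domains, ten planted inter-domain couplings of
  strength 1.5, 5000 sequences), scored as the precision of the top-10
  inter-domain DI pairs against the planted set;
* paralog-matching recovery — 50 species with mixed copy numbers (25
  single-copy anchors, 25 species with two paralogs, lineage divergence
  10 point mutations), scored as the fraction of ground-truth pairings
  recovered;
* restrained docking (below).

The toy restrained-docking benchmark:

Two 14-bead zig-zag chains (non-degenerate angles and dihedrals, so the
chains stay extended) form a native parallel interface of ten residue pairs
at 8 Å.  The receptor (chain A) is weakly tethered; the ligand (chain B)
starts at a 25 Å center-of-mass separation inside a 28 Å flat-bottom
spherical wall (the stand-in for the finite cell of any real simulation) and
must find the interface guided only by the ten DCA restraints.  Conditions:
reduced temperature 0.5, restraint depth 2 ε (4 k_BT, so the restraints
dominate thermal fluctuations), BAOAB with dt = 0.002 and friction 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .docking import (
    DockingMetrics,
    DockingRun,
    GoTopology,
    Trajectory,
    add_dca_restraints,
    apply_position_restraints,
    build_go_topology,
    docking_metrics,
    initialize_separation,
    run_langevin,
)
from .dca import run_dca
from .msa import paralog_match_concatenate
from .synthetic import PlantedModel, ToyComplex, make_toy_complex, sample_potts_msa

# planted-coupling recovery conditions
DCA_DOMAIN_LENGTH = 30
DCA_N_PLANTED = 10
DCA_STRENGTH = 1.5
DCA_N_SEQUENCES = 5000

# paralog-matching recovery conditions
PPM_COPY_NUMBERS = (1, 2) * 25  # 50 species, half single-copy anchors
PPM_MUTATIONS = 10

CHAIN_LENGTH = 14
INTERFACE_RESIDUES = tuple(range(3, 13))  # ten pairs (i, i)
INTERFACE_DISTANCE = 8.0
SEPARATION = 25.0
CONFINEMENT_RADIUS = 28.0
TEMPERATURE = 0.5
TIMESTEP = 0.002
FRICTION = 0.05
RESTRAINT_EPS = 2.0
N_STEPS = 500_000


def planted_recovery_benchmark(seed: int) -> float:
    """Precision of the top-10 inter-domain DI pairs against the planted set."""
    rng = np.random.default_rng(seed)
    ia = rng.choice(DCA_DOMAIN_LENGTH, size=DCA_N_PLANTED, replace=False)
    ib = rng.choice(DCA_DOMAIN_LENGTH, size=DCA_N_PLANTED, replace=False)
    planted = {(int(i) + 1, int(j) + 1) for i, j in zip(ia, ib)}
    model = PlantedModel(
        length_a=DCA_DOMAIN_LENGTH,
        length_b=DCA_DOMAIN_LENGTH,
        planted_pairs=tuple((int(i), int(j), DCA_STRENGTH) for i, j in zip(ia, ib)),
        seed=seed,
    )
    fam = sample_potts_msa(model, DCA_N_SEQUENCES)
    paired = paralog_match_concatenate(fam.msa_a, fam.msa_b)
    result = run_dca(paired, top_n=DCA_N_PLANTED)
    top = {(p.i, p.j) for p in result.pairs}
    return len(top & planted) / DCA_N_PLANTED


def ppm_recovery_benchmark(seed: int) -> float:
    """Fraction of ground-truth paralog pairings recovered by matching."""
    model = PlantedModel(length_a=30, length_b=30, seed=seed)
    fam = sample_potts_msa(
        model, 0, n_paralogs_per_species=PPM_COPY_NUMBERS, paralog_mutations=PPM_MUTATIONS
    )
    paired = paralog_match_concatenate(fam.msa_a, fam.msa_b)
    correct = sum(1 for ia, ib in paired.parent_indices if fam.pairing[ia] == ib)
    return correct / len(paired.parent_indices)


def benchmark_complex(seed: int = 0) -> ToyComplex:
    """The native two-chain toy complex with its ten-pair interface."""
    pairs = [(("A", i), ("B", i)) for i in INTERFACE_RESIDUES]
    return make_toy_complex(
        chain_lengths=[CHAIN_LENGTH, CHAIN_LENGTH],
        interface_pairs=pairs,
        target_distance=INTERFACE_DISTANCE,
        seed=seed,
        geometry="zigzag",
    )


def benchmark_topology(complex_: ToyComplex, restrained: bool = True) -> GoTopology:
    top = build_go_topology(complex_.model, contact_cutoff=8.0)
    if restrained:
        native = [
            (pair, float(np.linalg.norm(
                complex_.model.ca_coord(pair[0]) - complex_.model.ca_coord(pair[1])
            )))
            for pair in complex_.interface_pairs
        ]
        top = add_dca_restraints(
            top,
            [p for p, _ in native],
            top_k=len(native),
            epsilon=RESTRAINT_EPS,
            target_distance=INTERFACE_DISTANCE,
        )
    return apply_position_restraints(top, ["A"], k=0.02)


@dataclass
class BenchmarkResult:
    metrics: DockingMetrics
    trajectory: Trajectory
    topology: GoTopology
    com_distance: np.ndarray  # inter-body COM distance per snapshot


def run_docking_benchmark(
    seed: int,
    restrained: bool = True,
    n_steps: int = N_STEPS,
    separation: float = SEPARATION,
) -> BenchmarkResult:
    """One seeded docking run; returns interface-recovery metrics.

    When ``restrained=False`` the DCA restraints are omitted (negative
    control) but metrics are still scored against the ten native interface
    pairs.
    """
    complex_ = benchmark_complex(seed=0)  # the native structure is fixed
    top = benchmark_topology(complex_, restrained=restrained)
    coords = initialize_separation(top, ["B"], distance=separation, seed=seed)
    params = DockingRun(
        n_steps=n_steps,
        seed=seed,
        timestep=TIMESTEP,
        friction=FRICTION,
        temperature=TEMPERATURE,
        stride=1000,
        confinement_radius=CONFINEMENT_RADIUS,
    )
    traj = run_langevin(top, coords, params)
    score_top = top if restrained else _with_scoring_pairs(complex_, top)
    metrics = docking_metrics(traj, score_top, ["B"])
    lig = top.chain_mask(["B"])
    com = traj.coords[:, lig].mean(axis=1) - traj.coords[:, ~lig].mean(axis=1)
    return BenchmarkResult(
        metrics=metrics,
        trajectory=traj,
        topology=top,
        com_distance=np.linalg.norm(com, axis=1),
    )


def _with_scoring_pairs(complex_: ToyComplex, top: GoTopology) -> GoTopology:
    """Attach the native interface as zero-strength pairs for scoring only."""
    return add_dca_restraints(
        top,
        list(complex_.interface_pairs),
        top_k=len(complex_.interface_pairs),
        epsilon=0.0,
        target_distance=INTERFACE_DISTANCE,
    )
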