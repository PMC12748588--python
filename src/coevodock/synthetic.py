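"""Synthetic inputs for the whole pipeline.

Three generators stand in for the real-world inputs:

* paired alignments sampled from a pairwise Potts model with planted
  inter-domain couplings (Gibbs sampling, species-tagged headers, optional
  paralogs and gap runs),
* toy multi-chain Cα-bead complexes realizing a known interface,
* crosslink tables mixing distance-consistent "true" records with decoys.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConstructiveFailureError, InvalidModelError, ParameterError
from .msa import ALPHABET, GAP, Msa
from .structure import StructureModel, write_structure

BOND_LENGTH = 3.8  # virtual Calpha-Calpha bond, Angstrom


@dataclass(frozen=True)
class PlantedModel:
    """A two-domain Potts model with planted inter-domain couplings.

    ``planted_pairs`` holds ``(i, j, strength)`` with ``i`` 0-based in domain
    A, ``j`` 0-based in domain B; the coupling is diagonal (Potts-ferromagnetic):
    ``e(a, b) = strength * [a == b]``.  ``field_bias`` is an optional
    (L, q) array of single-site fields.
    """

    length_a: int
    length_b: int
    alphabet_size: int = 21
    planted_pairs: Tuple[Tuple[int, int, float], ...] = ()
    field_bias: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_a < 1 or self.length_b < 1:
            raise InvalidModelError("domain lengths must be positive")
        if self.alphabet_size < 2:
            raise InvalidModelError("alphabet size q must be at least 2")
        for i, j, s in self.planted_pairs:
            if not (0 <= i < self.length_a and 0 <= j < self.length_b):
                raise InvalidModelError(f"planted pair ({i}, {j}) out of domain bounds")
            if not np.isfinite(s):
                raise InvalidModelError("coupling strength must be finite")
        if self.field_bias is not None:
            fb = np.asarray(self.field_bias)
            if fb.shape != (self.length, self.alphabet_size):
                raise InvalidModelError("field_bias must have shape (L_A + L_B, q)")

    @property
    def length(self) -> int:
        return self.length_a + self.length_b


@njit(cache=True)
def _gibbs_records(
    length: int,
    q: int,
    h: np.ndarray,
    partner_idx: np.ndarray,
    partner_strength: np.ndarray,
    degree: np.ndarray,
    n_records: int,
    burn_in: int,
    thinning: int,
    seed: int,
) -> np.ndarray:
    np.random.seed(seed)
    state = np.empty(length, dtype=np.int8)
    for i in range(length):
        state[i] = np.random.randint(0, q)
    records = np.empty((n_records, length), dtype=np.int8)
    logits = np.empty(q)
    total_sweeps = burn_in + n_records * thinning
    rec = 0
    for sweep in range(total_sweeps):
        for i in range(length):
            for a in range(q):
                logits[a] = h[i, a]
            for k in range(degree[i]):
                other = partner_idx[i, k]
                logits[state[other]] += partner_strength[i, k]
            mx = logits[0]
            for a in range(1, q):
                if logits[a] > mx:
                    mx = logits[a]
            total = 0.0
            for a in range(q):
                logits[a] = np.exp(logits[a] - mx)
                total += logits[a]
            u = np.random.random() * total
            acc = 0.0
            choice = q - 1
            for a in range(q):
                acc += logits[a]
                if u <= acc:
                    choice = a
                    break
            state[i] = choice
        if sweep >= burn_in and (sweep - burn_in + 1) % thinning == 0:
            records[rec] = state
            rec += 1
            if rec == n_records:
                break
    return records


def _partner_arrays(model: PlantedModel):
    length = model.length
    partners: List[List[Tuple[int, float]]] = [[] for _ in range(length)]
    for i, j, s in model.planted_pairs:
        ja = model.length_a + j
        partners[i].append((ja, s))
        partners[ja].append((i, s))
    max_deg = max((len(p) for p in partners), default=0)
    max_deg = max(max_deg, 1)
    idx = np.zeros((length, max_deg), dtype=np.int64)
    strength = np.zeros((length, max_deg))
    degree = np.zeros(length, dtype=np.int64)
    for i, plist in enumerate(partners):
        degree[i] = len(plist)
        for k, (other, s) in enumerate(plist):
            idx[i, k] = other
            strength[i, k] = s
    return idx, strength, degree


def sample_potts_chain(
    model: PlantedModel,
    n_records: int,
    burn_in: int = 1000,
    thinning: int = 10,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Gibbs-sample ``n_records`` integer sequences from the Potts model.

    Sequential per-site sweeps; records are taken every ``thinning`` sweeps
    after ``burn_in`` sweeps.
    """
    if n_records < 1:
        raise ParameterError("n_records must be at least 1")
    h = (
        np.zeros((model.length, model.alphabet_size))
        if model.field_bias is None
        else np.asarray(model.field_bias, dtype=float)
    )
    idx, strength, degree = _partner_arrays(model)
    if seed is None:
        seed = model.seed
    return _gibbs_records(
        model.length,
        model.alphabet_size,
        h,
        idx,
        strength,
        degree,
        n_records,
        burn_in,
        thinning,
        int(seed) % (2**31),
    )


@dataclass
class SyntheticPairedFamilies:
    """Two species-tagged raw MSAs plus the ground-truth row pairing."""

    msa_a: Msa
    msa_b: Msa
    pairing: Dict[int, int]  # row in msa_a -> true partner row in msa_b
    model: PlantedModel
    states: np.ndarray = field(repr=False, default=None)  # (n, L) pre-shuffle


def _decode(states: np.ndarray, alphabet: str) -> List[str]:
    lut = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    return ["".join(map(chr, lut[row])) for row in states]


def _insert_gap_run(seq: str, run_length: int, rng: np.random.Generator) -> str:
    if run_length <= 0 or run_length >= len(seq):
        return seq
    start = int(rng.integers(0, len(seq) - run_length + 1))
    return seq[:start] + GAP * run_length + seq[start + run_length :]


def sample_potts_msa(
    model: PlantedModel,
    n_sequences: int,
    n_paralogs_per_species: Union[int, Sequence[int]] = 1,
    gap_run_fraction: float = 0.0,
    gap_run_length_fraction: float = 0.1,
    paralog_mutations: int = 10,
    burn_in: int = 1000,
    thinning: int = 10,
) -> SyntheticPairedFamilies:
    """Sample a species-tagged paired alignment from the planted Potts model.

    With one paralog per species (the default) each row is an independent
    Gibbs record and each species occurs once.  In paralog mode
    (``n_paralogs_per_species`` an integer > 1 or a per-species sequence of
    copy numbers, which overrides ``n_sequences``), each paralog slot has its
    own lineage ancestor (a distinct, widely spaced Gibbs record) and every
    species' copy is that ancestor with ``paralog_mutations`` random point
    mutations; a species carrying fewer copies than there are lineages is
    assigned a random subset of the lineage slots.  Paralog lineages are thus
    distinguishable across species, and single-copy species anchor the global
    lineage correspondence — the two properties paralog matching exploits.

    A ``gap_run_fraction`` of rows receives one contiguous gap run per domain
    of ``round(gap_run_length_fraction * L_domain)`` columns.  Rows of the B
    alignment are returned in shuffled order; the true pairing is returned.
    """
    if model.alphabet_size > len(ALPHABET):
        raise InvalidModelError(
            f"alphabet size {model.alphabet_size} exceeds the {len(ALPHABET)}-letter alphabet"
        )
    rng = np.random.default_rng(model.seed)
    q = model.alphabet_size

    if isinstance(n_paralogs_per_species, (int, np.integer)):
        if n_paralogs_per_species < 1:
            raise ParameterError("n_paralogs_per_species must be at least 1")
        if n_sequences < 1:
            raise ParameterError("n_sequences must be at least 1")
        if n_paralogs_per_species == 1:
            copy_numbers = None
        else:
            p = int(n_paralogs_per_species)
            n_species = n_sequences // p
            if n_species < 1:
                raise ParameterError("n_sequences must be at least n_paralogs_per_species")
            copy_numbers = [p] * n_species
    else:
        copy_numbers = [int(c) for c in n_paralogs_per_species]
        if not copy_numbers or min(copy_numbers) < 1:
            raise ParameterError("per-species copy numbers must be positive")

    if copy_numbers is None:
        states = sample_potts_chain(model, n_sequences, burn_in, thinning, seed=model.seed)
        species = [f"sp{i:05d}" for i in range(n_sequences)]
        paralog_slot = [0] * n_sequences
    else:
        n_lineages = max(copy_numbers)
        # widely spaced ancestors, one per paralog lineage
        ancestors = sample_potts_chain(model, n_lineages, burn_in, thinning * 50, seed=model.seed)
        rows, species, paralog_slot = [], [], []
        for s, count in enumerate(copy_numbers):
            slots = sorted(rng.choice(n_lineages, size=count, replace=False).tolist())
            for slot in slots:
                seq = ancestors[slot].copy()
                pos = rng.choice(model.length, size=min(paralog_mutations, model.length), replace=False)
                for c in pos:
                    old = seq[c]
                    new = int(rng.integers(0, q - 1))
                    seq[c] = new + 1 if new >= old else new
                rows.append(seq)
                species.append(f"sp{s:05d}")
                paralog_slot.append(slot)
        states = np.array(rows, dtype=np.int8)

    n = len(states)
    seqs = _decode(states, ALPHABET[:q])
    seq_a = [s[: model.length_a] for s in seqs]
    seq_b = [s[model.length_a :] for s in seqs]

    if gap_run_fraction > 0:
        run_a = int(round(gap_run_length_fraction * model.length_a))
        run_b = int(round(gap_run_length_fraction * model.length_b))
        for r in range(n):
            if rng.random() < gap_run_fraction:
                seq_a[r] = _insert_gap_run(seq_a[r], run_a, rng)
            if rng.random() < gap_run_fraction:
                seq_b[r] = _insert_gap_run(seq_b[r], run_b, rng)

    perm = rng.permutation(n)  # shuffle B rows; pairing maps A row -> B row
    inverse = np.argsort(perm)
    pairing = {a_row: int(inverse[a_row]) for a_row in range(n)}
    ids_a = [f"A{r:05d}_p{paralog_slot[r]}|OS={species[r]}" for r in range(n)]
    ids_b = [f"B{perm[r]:05d}_p{paralog_slot[perm[r]]}|OS={species[perm[r]]}" for r in range(n)]
    msa_a = Msa(ids=ids_a, sequences=seq_a, species=list(species))
    msa_b = Msa(
        ids=ids_b,
        sequences=[seq_b[perm[r]] for r in range(n)],
        species=[species[perm[r]] for r in range(n)],
    )
    return SyntheticPairedFamilies(msa_a=msa_a, msa_b=msa_b, pairing=pairing, model=model, states=states)


# --------------------------------------------------------------------- toys


InterfacePair = Tuple[Tuple[str, int], Tuple[str, int]]


@dataclass
class ToyComplex:
    """A multi-chain Cα-bead complex with a known, constructed interface."""

    model: StructureModel
    interface_pairs: List[InterfacePair]
    contact_distance: float
    provenance: Optional[PlantedModel] = None

    def write_pdb(self, path) -> None:
        write_structure(self.model, path)


def make_toy_complex(
    chain_lengths: Sequence[int],
    interface_pairs: Sequence[InterfacePair] = (),
    target_distance: float = 8.0,
    seed: int = 0,
    chain_ids: Optional[Sequence[str]] = None,
    geometry: str = "straight",
) -> ToyComplex:
    """Construct bead chains realizing the requested interface exactly.

    Chain 0 is laid along x with 3.8 Å bonds; each later chain is placed as a
    congruent translated copy of the (extended) template of one earlier
    partner chain, shifted perpendicular by ``target_distance``.  This
    realizes every interface pair at exactly the target distance but requires
    all pairs between two chains to share a single residue-index offset —
    incompatible pair sets raise :class:`ConstructiveFailureError`.  Residue
    numbers are 1-based.

    ``geometry='straight'`` gives collinear chains (simplest fixtures);
    ``geometry='zigzag'`` gives planar zig-zag chains whose bond angles and
    dihedrals are non-degenerate, which the docking engine needs for active
    angle/dihedral terms.  Zig-zag inter-chain shifts are out of the zig-zag
    plane so interface distances stay exact and no spurious short contacts
    appear.

    A straight chain carrying exactly one interface pair is rotated 45° about
    the paired bead, so only the planted pair sits at the target distance and
    neighbouring in-register pairs fall outside a cutoff of ~1.1x the target;
    chains carrying several pairs are placed in full register, where every
    same-offset bead pair sits at the target distance by construction.
    Chains cannot be constrained to a rotated chain.
    """
    if target_distance < BOND_LENGTH:
        raise ParameterError(f"target distance must be at least {BOND_LENGTH} Å")
    if chain_ids is None:
        chain_ids = [chr(ord("A") + k) for k in range(len(chain_lengths))]
    chain_ids = list(chain_ids)
    if len(chain_ids) != len(chain_lengths):
        raise ParameterError("chain_ids and chain_lengths must have equal length")
    rng = np.random.default_rng(seed)

    for (ca, ra), (cb, rb) in interface_pairs:
        for c, r in (((ca), (ra)), ((cb), (rb))):
            if c not in chain_ids:
                raise ParameterError(f"interface pair references unknown chain {c!r}")
            n = chain_lengths[chain_ids.index(c)]
            if not 1 <= r <= n:
                raise ConstructiveFailureError(f"interface residue {c}:{r} outside chain (1..{n})")

    if geometry not in ("straight", "zigzag"):
        raise ParameterError(f"unknown chain geometry: {geometry}")

    # template bead positions for a 1-based residue r: template(r-1) + origin;
    # zig-zag advances 2.2 A along x with a +-3.10 A alternation in y
    if geometry == "zigzag":
        axial = 2.2
        wobble = float(np.sqrt(BOND_LENGTH**2 - axial**2))

        def line(origin: np.ndarray, n: int, start: int = 0) -> np.ndarray:
            k = np.arange(start, start + n)
            out = np.zeros((n, 3))
            out[:, 0] = axial * k
            out[:, 1] = wobble * (k % 2)
            return origin + out

    else:

        def line(origin: np.ndarray, n: int, start: int = 0) -> np.ndarray:
            k = np.arange(start, start + n)
            return origin + BOND_LENGTH * np.outer(k, np.array([1.0, 0.0, 0.0]))

    placements: Dict[str, Tuple[np.ndarray, int]] = {}  # origin, template start index
    coords: Dict[str, np.ndarray] = {}
    rotated: set = set()
    placements[chain_ids[0]] = (np.zeros(3), 0)
    coords[chain_ids[0]] = line(np.zeros(3), chain_lengths[0])

    for c_idx, chain in enumerate(chain_ids[1:], start=1):
        n = chain_lengths[c_idx]
        constraints = []
        for (ca, ra), (cb, rb) in interface_pairs:
            if ca == chain and cb in placements:
                constraints.append((cb, rb, ra))
            elif cb == chain and ca in placements:
                constraints.append((ca, ra, rb))
        if not constraints:
            origin = np.array([0.0, 30.0 * c_idx, 0.0])
            coords[chain] = line(origin, n)
            placements[chain] = (origin, 0)
            continue
        partners = {c for c, _, _ in constraints}
        if len(partners) > 1:
            raise ConstructiveFailureError(
                f"chain {chain} is constrained to multiple chains {sorted(partners)}; "
                "not placeable by rigid translation"
            )
        partner = constraints[0][0]
        offsets = {r_self - r_partner for _, r_partner, r_self in constraints}
        if len(offsets) > 1:
            raise ConstructiveFailureError(
                f"interface pairs between {chain} and {partner} demand distinct index "
                f"offsets {sorted(offsets)}; more pairs than placeable by one rigid translation"
            )
        delta = offsets.pop()
        placed = np.vstack(list(coords.values()))
        if partner in rotated:
            raise ConstructiveFailureError(
                f"chain {chain} is constrained to rotated chain {partner}; not placeable"
            )
        origin_p, start_p = placements[partner]
        for attempt in range(100):
            if geometry == "straight" and len(constraints) == 1:
                # rotate about the single paired bead: only the planted pair
                # lies at the target distance
                _, r_partner, r_self = constraints[0]
                phi = rng.uniform(0, 2 * np.pi)
                v = np.array([0.0, np.cos(phi), np.sin(phi)])  # shift direction
                w = np.cross(v, np.array([1.0, 0.0, 0.0]))
                alpha = np.pi / 4 * (1.0 if rng.random() < 0.5 else -1.0)
                u = np.cos(alpha) * np.array([1.0, 0.0, 0.0]) + np.sin(alpha) * w
                pivot = coords[partner][r_partner - 1] + target_distance * v
                candidate = pivot + BOND_LENGTH * np.outer(np.arange(n) - (r_self - 1), u)
                origin, start = candidate[0], 0
                is_rotated = True
            elif geometry == "zigzag":
                start = (start_p + delta) % 2
                sign = 1.0 if (rng.random() < 0.5) else -1.0
                shift = target_distance * np.array([0.0, 0.0, sign])  # out of plane
                origin = origin_p - axial * (delta + start - start_p) * np.array([1.0, 0.0, 0.0]) + shift
                candidate = line(origin, n, start=start)
                is_rotated = False
            else:
                start = 0
                phi = rng.uniform(0, 2 * np.pi)
                shift = target_distance * np.array([0.0, np.cos(phi), np.sin(phi)])
                origin = origin_p - delta * BOND_LENGTH * np.array([1.0, 0.0, 0.0]) + shift
                candidate = line(origin, n)
                is_rotated = False
            dmin = np.min(
                np.linalg.norm(candidate[:, None, :] - placed[None, :, :], axis=2)
            )
            if dmin >= min(BOND_LENGTH, target_distance) - 1e-9:
                coords[chain] = candidate
                placements[chain] = (origin, start)
                if is_rotated:
                    rotated.add(chain)
                break
        else:
            raise ConstructiveFailureError(
                f"no clash-free placement found for chain {chain} after 100 attempts"
            )

    model = StructureModel.from_beads(coords)
    # verify the construction
    for (ca, ra), (cb, rb) in interface_pairs:
        d = float(np.linalg.norm(coords[ca][ra - 1] - coords[cb][rb - 1]))
        if abs(d - target_distance) > 0.1:
            raise ConstructiveFailureError(
                f"constructed pair {ca}:{ra}-{cb}:{rb} at {d:.2f} Å, wanted {target_distance} Å"
            )
    return ToyComplex(
        model=model,
        interface_pairs=[((ca, ra), (cb, rb)) for (ca, ra), (cb, rb) in interface_pairs],
        contact_distance=target_distance,
    )


# ---------------------------------------------------------------- crosslinks


def make_synthetic_crosslinks(
    complex_: ToyComplex,
    n_true: int,
    n_decoy: int,
    max_true_distance: float = 35.0,
    seed: int = 0,
    decoy_min_distance: Optional[float] = None,
) -> pd.DataFrame:
    """Sample a crosslink table of true (close) and decoy (distant) pairs.

    True records are drawn without replacement from inter-chain residue pairs
    with Cα–Cα distance ≤ ``max_true_distance``; decoys from pairs with
    distance > ``decoy_min_distance`` (default: the true cutoff).  Columns:
    Protein1, Residue1, Protein2, Residue2, label, distance — proteins are
    named by chain id; the label column is kept for evaluation and dropped by
    the plain-text writer.
    """
    if n_true + n_decoy < 1:
        raise ParameterError("at least one crosslink must be requested")
    if decoy_min_distance is None:
        decoy_min_distance = max_true_distance
    model = complex_.model
    rng = np.random.default_rng(seed)
    residues = [k for k in model.residues() if model.has_ca(k)]
    true_pool, decoy_pool = [], []
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            ka, kb = residues[a], residues[b]
            if ka[0] == kb[0]:
                continue
            d = float(np.linalg.norm(model.ca_coord(ka) - model.ca_coord(kb)))
            if d <= max_true_distance:
                true_pool.append((ka, kb, d))
            elif d > decoy_min_distance:
                decoy_pool.append((ka, kb, d))
    if n_true > 0 and not true_pool:
        raise ConstructiveFailureError(
            f"no inter-chain residue pair lies within {max_true_distance} Å"
        )
    if n_true > len(true_pool) or n_decoy > len(decoy_pool):
        raise ConstructiveFailureError(
            f"requested {n_true} true / {n_decoy} decoy records but only "
            f"{len(true_pool)} / {len(decoy_pool)} candidate pairs exist"
        )
    rows = []
    for pool, count, label in ((true_pool, n_true, "true"), (decoy_pool, n_decoy, "decoy")):
        if count == 0:
            continue
        picks = rng.choice(len(pool), size=count, replace=False)
        for p in picks:
            (c1, r1), (c2, r2), d = pool[int(p)]
            rows.append((c1, r1, c2, r2, label, d))
    df = pd.DataFrame(rows, columns=["Protein1", "Residue1", "Protein2", "Residue2", "label", "distance"])
    return df.sort_values(["Protein1", "Residue1", "Protein2", "Residue2"]).reset_index(drop=True)


def write_crosslink_table(table: pd.DataFrame, path) -> None:
    """Write the 4-column tab-separated crosslink table (labels dropped)."""
    table[["Protein1", "Residue1", "Protein2", "Residue2"]].to_csv(path, sep="\t", index=False)
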