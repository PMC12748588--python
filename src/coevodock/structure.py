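"""Coordinate models: PDB/mmCIF I/O, Cα geometry, contacts and SASA.

Thin wrapper around a :class:`biotite.structure.AtomArray`.  Author (PDB)
residue numbers are authoritative; sequence-position offsets are handled by
the callers (see :mod:`coevodock.xlinks`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io import pdbx
from scipy.spatial import cKDTree

from .errors import CapabilityError, LookupFailure, ParameterError, StructureFormatError

ResidueKey = Tuple[str, int]  # (chain id, author residue number)


class StructureModel:
    """Chains of residues with Cα (and optionally heavy-atom) coordinates."""

    def __init__(self, atoms: struc.AtomArray):
        if atoms.array_length() == 0:
            raise StructureFormatError("empty structure")
        if not np.all(np.isfinite(atoms.coord)):
            raise StructureFormatError("non-finite coordinates")
        self.atoms = atoms
        self._ca: Dict[ResidueKey, np.ndarray] = {}
        self._residues: List[ResidueKey] = []
        seen = set()
        for idx in range(atoms.array_length()):
            key = (str(atoms.chain_id[idx]), int(atoms.res_id[idx]))
            if key not in seen:
                seen.add(key)
                self._residues.append(key)
            if atoms.atom_name[idx] == "CA" and key not in self._ca:
                self._ca[key] = atoms.coord[idx]
        self.missing_ca: List[ResidueKey] = [k for k in self._residues if k not in self._ca]
        if self.missing_ca:
            warnings.warn(
                f"{len(self.missing_ca)} residues lack a CA atom and are excluded "
                "from distance operations",
                stacklevel=2,
            )

    # ------------------------------------------------------------------ info
    @property
    def chains(self) -> List[str]:
        out: List[str] = []
        for c, _ in self._residues:
            if c not in out:
                out.append(c)
        return out

    def residues(self, chain: Optional[str] = None) -> List[ResidueKey]:
        if chain is None:
            return list(self._residues)
        return [k for k in self._residues if k[0] == chain]

    @property
    def is_ca_only(self) -> bool:
        return bool(np.all(self.atoms.atom_name == "CA"))

    def has_ca(self, key: ResidueKey) -> bool:
        return (key[0], int(key[1])) in self._ca

    def ca_coord(self, key: ResidueKey) -> np.ndarray:
        k = (key[0], int(key[1]))
        if k not in self._ca:
            raise LookupFailure(f"no CA coordinate for residue {k}")
        return self._ca[k]

    def ca_coords(self, keys: Sequence[ResidueKey]) -> np.ndarray:
        return np.array([self.ca_coord(k) for k in keys])

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_beads(
        cls,
        chain_coords: Dict[str, np.ndarray],
        res_start: int = 1,
    ) -> "StructureModel":
        """Build a Cα-bead model from per-chain coordinate arrays."""
        n = sum(len(c) for c in chain_coords.values())
        atoms = struc.AtomArray(n)
        idx = 0
        for chain, coords in chain_coords.items():
            for k, xyz in enumerate(coords):
                atoms.coord[idx] = xyz
                atoms.chain_id[idx] = chain
                atoms.res_id[idx] = res_start + k
                atoms.res_name[idx] = "ALA"
                atoms.atom_name[idx] = "CA"
                atoms.element[idx] = "C"
                atoms.hetero[idx] = False
                idx += 1
        return cls(atoms)


def read_structure(path, fmt: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file (first model; highest-occupancy altlocs)."""
    path = Path(path)
    if fmt is None:
        fmt = "pdbx" if path.suffix.lower() in (".cif", ".mmcif", ".pdbx") else "pdb"
    try:
        if fmt == "pdb":
            atoms = PDBFile.read(str(path)).get_structure(model=1, altloc="occupancy")
        elif fmt in ("pdbx", "cif", "mmcif"):
            cif = pdbx.CIFFile.read(str(path))
            atoms = pdbx.get_structure(cif, model=1, altloc="occupancy")
        else:
            raise ParameterError(f"unsupported structure format: {fmt}")
    except ParameterError:
        raise
    except Exception as exc:  # biotite raises a mix of exception types
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    return StructureModel(atoms)


def write_structure(model: StructureModel, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    pdb.write(str(path))


def ca_distance(model: StructureModel, a: ResidueKey, b: ResidueKey) -> float:
    """Euclidean Cα–Cα distance in Å."""
    return float(np.linalg.norm(model.ca_coord(a) - model.ca_coord(b)))


@dataclass
class ContactMap:
    """Residue pairs within ``cutoff`` under ``metric`` (symmetric)."""

    distances: Dict[Tuple[ResidueKey, ResidueKey], float]
    cutoff: float
    metric: str

    @staticmethod
    def _key(a: ResidueKey, b: ResidueKey) -> Tuple[ResidueKey, ResidueKey]:
        return (a, b) if a <= b else (b, a)

    def __contains__(self, pair: Tuple[ResidueKey, ResidueKey]) -> bool:
        a, b = pair
        return self._key((a[0], int(a[1])), (b[0], int(b[1]))) in self.distances

    def __len__(self) -> int:
        return len(self.distances)

    def distance(self, a: ResidueKey, b: ResidueKey) -> float:
        return self.distances[self._key(a, b)]

    def pairs(self) -> List[Tuple[ResidueKey, ResidueKey]]:
        return sorted(self.distances)


def structure_contacts(
    model: StructureModel,
    cutoff: float = 8.0,
    metric: str = "ca",
    inter_chain_only: bool = False,
) -> ContactMap:
    """All residue pairs within ``cutoff`` Å.

    ``metric='ca'`` uses Cα–Cα distances; ``metric='heavy'`` the minimal
    heavy-atom distance (requires non-hydrogen atoms beyond Cα to be
    meaningful, but works on any atom set).
    """
    if metric not in ("ca", "heavy"):
        raise ParameterError(f"unknown contact metric: {metric}")
    if metric == "ca":
        keys = [k for k in model.residues() if model.has_ca(k)]
        coords = model.ca_coords(keys)
        atom_res = list(range(len(keys)))
    else:
        mask = model.atoms.element != "H"
        coords = model.atoms.coord[mask]
        chain_ids = model.atoms.chain_id[mask]
        res_ids = model.atoms.res_id[mask]
        keys_map: Dict[ResidueKey, int] = {}
        keys = []
        atom_res = []
        for c, r in zip(chain_ids, res_ids):
            key = (str(c), int(r))
            if key not in keys_map:
                keys_map[key] = len(keys)
                keys.append(key)
            atom_res.append(keys_map[key])
    tree = cKDTree(coords)
    found: Dict[Tuple[ResidueKey, ResidueKey], float] = {}
    for ia, ib in tree.query_pairs(cutoff):
        ra, rb = atom_res[ia], atom_res[ib]
        if ra == rb:
            continue
        ka, kb = keys[ra], keys[rb]
        if inter_chain_only and ka[0] == kb[0]:
            continue
        d = float(np.linalg.norm(coords[ia] - coords[ib]))
        pair = ContactMap._key(ka, kb)
        if pair not in found or d < found[pair]:
            found[pair] = d
    return ContactMap(distances=found, cutoff=cutoff, metric=metric)


def residue_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    point_number: int = 1000,
    vdw_radii="Single",
) -> Dict[ResidueKey, float]:
    """Per-residue Shrake–Rupley SASA (Å²), probe 1.4 Å.

    ``vdw_radii`` may be a named biotite radii set or an explicit per-atom
    radius array.  Cα-only bead models cannot be meaningfully SASA-filtered
    and raise :class:`CapabilityError`.
    """
    if model.is_ca_only:
        raise CapabilityError(
            "SASA requires heavy-atom coordinates; this model contains only CA beads"
        )
    if point_number < 960:
        raise ParameterError("at least 960 sphere points per atom are required")
    atom_sasa = struc.sasa(
        model.atoms,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii=vdw_radii,
    )
    out: Dict[ResidueKey, float] = {k: 0.0 for k in model.residues()}
    for idx in range(model.atoms.array_length()):
        if np.isnan(atom_sasa[idx]):
            continue
        key = (str(model.atoms.chain_id[idx]), int(model.atoms.res_id[idx]))
        out[key] += float(atom_sasa[idx])
    return out
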