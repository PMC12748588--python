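"""Crosslink mapping onto coordinate models and assembly comparison.

Crosslink tables are residue-pair exports (xiFDR dialect or a simplified
4-column form).  Records carry 1-based positions in the expressed construct
sequence; per-protein numbering offsets translate them to author residue
numbers (author = sequence position + offset).  Satisfaction uses a strict
Cα–Cα < cutoff criterion (35 Å by convention for BS3); multi-copy assemblies
resolve each record to the chain-copy pairing minimizing the distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ParameterError
from .structure import StructureModel, ca_distance

MAPPED = "mapped"
UNRESOLVED = "unresolved-residue"
UNMAPPED_PROTEIN = "unmapped-protein"


@dataclass(frozen=True)
class CrosslinkRecord:
    """One unique unordered residue-pair crosslink."""

    protein1: str
    residue1: int
    protein2: str
    residue2: int
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.residue1 < 1 or self.residue2 < 1:
            raise ParameterError("residue positions are 1-based and must be >= 1")

    @property
    def key(self) -> Tuple[Tuple[str, int], Tuple[str, int]]:
        a = (self.protein1, self.residue1)
        b = (self.protein2, self.residue2)
        return (a, b) if a <= b else (b, a)


@dataclass
class ChainMapping:
    """Where a protein lives in a model: chain copies and numbering offset."""

    chains: List[str]
    offset: int = 0


ChainConfig = Mapping[str, Union[ChainMapping, Tuple[Sequence[str], int]]]


def _as_mapping(value) -> ChainMapping:
    if isinstance(value, ChainMapping):
        return value
    chains, offset = value
    if isinstance(chains, str):
        chains = [chains]
    return ChainMapping(chains=list(chains), offset=int(offset))


@dataclass
class MappedCrosslink:
    """A record's mapping status and distance on one model."""

    record: CrosslinkRecord
    status: str
    distance: Optional[float] = None
    chain_pair: Optional[Tuple[str, str]] = None

    def __post_init__(self) -> None:
        if (self.status == MAPPED) != (self.distance is not None):
            raise ParameterError("distance must be present exactly when status is mapped")


def read_crosslinks(path, roster: Optional[Sequence[str]] = None, sep: Optional[str] = None) -> List[CrosslinkRecord]:
    """Read a delimited residue-pair table into deduplicated records.

    Accepts columns (Protein1, Residue1, Protein2, Residue2) or the xiFDR
    export dialect (Protein1, PepPos1, Protein2, PepPos2).  Unordered
    duplicates collapse into one record with the multiplicity retained.
    Records naming proteins outside ``roster`` are kept (they will map with
    unmapped-protein status), matching expanded-search outputs that include
    contaminants.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = {c.lower(): c for c in df.columns}

    def col(*names):
        for n in names:
            if n.lower() in cols:
                return cols[n.lower()]
        raise ParameterError(f"crosslink table lacks any of columns {names}; found {list(df.columns)}")

    p1, p2 = col("Protein1"), col("Protein2")
    r1 = col("Residue1", "PepPos1", "Position1")
    r2 = col("Residue2", "PepPos2", "Position2")
    counts: Dict[Tuple[Tuple[str, int], Tuple[str, int]], int] = {}
    for _, row in df.iterrows():
        rec = CrosslinkRecord(str(row[p1]), int(row[r1]), str(row[p2]), int(row[r2]))
        counts[rec.key] = counts.get(rec.key, 0) + 1
    records = [
        CrosslinkRecord(a[0], a[1], b[0], b[1], multiplicity=m)
        for (a, b), m in sorted(counts.items())
    ]
    return records


def map_distances(
    records: Sequence[CrosslinkRecord],
    model: StructureModel,
    chain_config: ChainConfig,
) -> List[MappedCrosslink]:
    """Map each record to the model and measure Cα–Cα distances.

    Author residue number = sequence position + the protein's offset.  When a
    protein maps to several chain copies, the copy pairing minimizing the
    distance is chosen and recorded.  Records touching residues absent from
    the model get status ``unresolved-residue``; unknown proteins get
    ``unmapped-protein``.
    """
    config = {p: _as_mapping(v) for p, v in chain_config.items()}
    out: List[MappedCrosslink] = []
    for rec in records:
        if rec.protein1 not in config or rec.protein2 not in config:
            out.append(MappedCrosslink(record=rec, status=UNMAPPED_PROTEIN))
            continue
        m1, m2 = config[rec.protein1], config[rec.protein2]
        res1 = rec.residue1 + m1.offset
        res2 = rec.residue2 + m2.offset
        best: Optional[Tuple[float, Tuple[str, str]]] = None
        for c1 in m1.chains:
            for c2 in m2.chains:
                k1, k2 = (c1, res1), (c2, res2)
                if k1 == k2:
                    continue  # same residue in the same copy: not a distance
                if not (model.has_ca(k1) and model.has_ca(k2)):
                    continue
                d = ca_distance(model, k1, k2)
                if best is None or d < best[0]:
                    best = (d, (c1, c2))
        if best is None:
            out.append(MappedCrosslink(record=rec, status=UNRESOLVED))
        else:
            out.append(
                MappedCrosslink(record=rec, status=MAPPED, distance=best[0], chain_pair=best[1])
            )
    return out


def count_within(mapped: Sequence[MappedCrosslink], cutoff: float = 35.0) -> Tuple[int, Optional[float]]:
    """Count mapped records with distance strictly below ``cutoff``.

    Returns (count, fraction of mapped records); the fraction is None when no
    record is mapped.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    dists = [m.distance for m in mapped if m.status == MAPPED]
    if not dists:
        return 0, None
    count = sum(1 for d in dists if d < cutoff)
    return count, count / len(dists)


@dataclass
class AssemblyComparison:
    """Per-record monomer vs dimer distances and summary counts."""

    table: pd.DataFrame = field(repr=False)
    n_records: int = 0
    n_mapped_monomer: int = 0
    n_mapped_dimer: int = 0
    n_mapped_both: int = 0
    n_shorter_in_dimer: int = 0


def compare_assemblies(
    records: Sequence[CrosslinkRecord],
    model_monomer: StructureModel,
    model_dimer: StructureModel,
    config_monomer: ChainConfig,
    config_dimer: ChainConfig,
) -> AssemblyComparison:
    """Compare crosslink satisfaction between two assembly models.

    For records mapped in both models, ``delta = d_dimer - d_monomer``;
    "shorter in dimer" means strictly negative delta.  Records unresolved in
    either model are excluded from the corresponding denominators.
    """
    mono = map_distances(records, model_monomer, config_monomer)
    dim = map_distances(records, model_dimer, config_dimer)
    rows = []
    for m, d in zip(mono, dim):
        delta = (
            d.distance - m.distance
            if m.status == MAPPED and d.status == MAPPED
            else np.nan
        )
        rows.append(
            {
                "protein1": m.record.protein1,
                "residue1": m.record.residue1,
                "protein2": m.record.protein2,
                "residue2": m.record.residue2,
                "status_monomer": m.status,
                "status_dimer": d.status,
                "d_monomer": m.distance,
                "d_dimer": d.distance,
                "delta": delta,
            }
        )
    table = pd.DataFrame(rows)
    both = table.dropna(subset=["delta"]) if len(table) else table
    return AssemblyComparison(
        table=table,
        n_records=len(records),
        n_mapped_monomer=sum(m.status == MAPPED for m in mono),
        n_mapped_dimer=sum(d.status == MAPPED for d in dim),
        n_mapped_both=len(both),
        n_shorter_in_dimer=int((both["delta"] < 0).sum()) if len(both) else 0,
    )
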