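"""Alignment I/O, gap-run filtering, species parsing and paralog matching.

Sequences are kept as upper-case strings over the 20 amino acids plus ``-``
for gaps.  Species annotations follow the UniProt header dialects: an
``OS=<species>`` field when present, otherwise the mnemonic suffix after the
last underscore of the identifier (``NED1_ARATH`` -> ``ARATH``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import linear_sum_assignment

from .errors import EmptyPairingError, MsaFormatError, ParameterError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = GAP + AMINO_ACIDS  # gap first; also the DCA state order

_OS_RE = re.compile(r"OS=(.+?)(?:\s+[A-Z]{2}=|$)")
_MNEMONIC_RE = re.compile(r"_([A-Z0-9]{2,10})$")


def parse_species(identifier: str, description: str = "") -> Optional[str]:
    """Extract a species tag from a UniProt-style header.

    Priority: explicit ``OS=`` field in the description, then the mnemonic
    suffix of the identifier.  Returns ``None`` when neither is present.
    """
    for text in (description, identifier):
        m = _OS_RE.search(text)
        if m:
            return m.group(1).strip()
    m = _MNEMONIC_RE.search(identifier.split()[0] if identifier else "")
    if m:
        return m.group(1)
    return None


@dataclass
class Msa:
    """A gapped alignment with per-row identifiers and species tags."""

    ids: List[str]
    sequences: List[str]
    species: List[Optional[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = [parse_species(i) for i in self.ids]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise MsaFormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if len(self.ids) != len(self.sequences) or len(self.species) != len(self.sequences):
            raise MsaFormatError("ids/species/sequences length mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return self.n_rows

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def subset(self, indices: Sequence[int]) -> "Msa":
        return Msa(
            ids=[self.ids[i] for i in indices],
            sequences=[self.sequences[i] for i in indices],
            species=[self.species[i] for i in indices],
        )

    def to_indices(self, alphabet: str = ALPHABET) -> np.ndarray:
        """Integer-encode the alignment (unknown letters -> gap state 0)."""
        lut = np.zeros(128, dtype=np.int8)
        for k, ch in enumerate(alphabet):
            lut[ord(ch)] = k
        mat = np.frombuffer("".join(self.sequences).encode("ascii"), dtype=np.uint8)
        return lut[mat].reshape(self.n_rows, self.length)


@dataclass
class PairedMsa:
    """Horizontally concatenated A+B alignment with per-row provenance.

    ``boundary`` is the number of columns belonging to domain A; columns
    ``0..boundary-1`` are A, ``boundary..`` are B.
    """

    sequences: List[str]
    boundary: int
    species: List[Optional[str]]
    parent_indices: List[Tuple[int, int]]
    ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"pair{k}" for k in range(len(self.sequences))]

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_indices(self, alphabet: str = ALPHABET) -> np.ndarray:
        return Msa(ids=self.ids, sequences=self.sequences, species=self.species).to_indices(alphabet)


def _clean_sequence(seq: str, context: str) -> str:
    seq = seq.upper().replace(".", GAP)
    bad = set(seq) - set(ALPHABET)
    if bad:
        warnings.warn(
            f"{context}: unknown residue letters {sorted(bad)} mapped to gap",
            stacklevel=3,
        )
        for ch in bad:
            seq = seq.replace(ch, GAP)
    return seq


def read_msa(path, fmt: str = "fasta") -> Msa:
    """Read a FASTA or Stockholm alignment into an :class:`Msa`.

    Ragged alignments raise :class:`MsaFormatError`; letters outside the
    20-amino-acid + gap alphabet are mapped to gap with a warning.
    """
    if fmt not in ("fasta", "stockholm"):
        raise ParameterError(f"unsupported alignment format: {fmt}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise MsaFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    ids, seqs, species = [], [], []
    for rec in aln:
        ids.append(rec.id)
        seqs.append(_clean_sequence(str(rec.seq), rec.id))
        species.append(parse_species(rec.id, rec.description or ""))
    return Msa(ids=ids, sequences=seqs, species=species)


def write_msa(msa: Msa, path, fmt: str = "fasta") -> None:
    records = []
    for i, seq in enumerate(msa.sequences):
        rid = msa.ids[i]
        desc = ""
        if msa.species[i] and "OS=" not in rid:
            desc = f"OS={msa.species[i]}"
        records.append(SeqRecord(Seq(seq), id=rid, description=desc))
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


def longest_gap_run(seq: str) -> int:
    """Length of the longest contiguous run of '-' (terminal runs included)."""
    best = cur = 0
    for ch in seq:
        if ch == GAP:
            cur += 1
            if cur > best:
                best = cur
        else:
            cur = 0
    return best


def filter_max_gap_run(msa: Msa, fraction: float) -> Msa:
    """Drop rows whose longest gap run exceeds ``ceil(fraction * L)``.

    The boundary is inclusive: a run of exactly ``ceil(f*L)`` columns is
    retained; strictly longer runs are removed.
    """
    if not 0 < fraction < 1:
        raise ParameterError("gap-run fraction must lie in (0, 1)")
    limit = int(np.ceil(fraction * msa.length))
    keep = [i for i, s in enumerate(msa.sequences) if longest_gap_run(s) <= limit]
    return msa.subset(keep)


def percent_identity(a: str, b: str) -> float:
    """Fraction of identical columns (gaps compared like letters)."""
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(np.mean(arr_a == arr_b))


def pair_paralogs_by_score(score: np.ndarray) -> List[Tuple[int, int]]:
    """Assign A-paralogs to B-paralogs maximizing total score.

    Exact (Hungarian) assignment when the matrix is at most 6x6; greedy
    otherwise.  Ties break toward the lowest (row, column) indices.
    """
    score = np.asarray(score, dtype=float)
    n_a, n_b = score.shape
    n_pairs = min(n_a, n_b)
    if max(n_a, n_b) <= 6:
        rows, cols = linear_sum_assignment(-score)
        return sorted(zip(rows.tolist(), cols.tolist()))[:n_pairs]
    pairs: List[Tuple[int, int]] = []
    work = score.copy()
    for _ in range(n_pairs):
        flat = int(np.argmax(work))  # argmax returns first = lowest index on ties
        r, c = divmod(flat, n_b)
        pairs.append((r, c))
        work[r, :] = -np.inf
        work[:, c] = -np.inf
    return sorted(pairs)


def _group_by_species(msa: Msa) -> Dict[str, List[int]]:
    groups: Dict[str, List[int]] = {}
    for i, sp in enumerate(msa.species):
        if sp is not None:
            groups.setdefault(sp, []).append(i)
    return groups


def paralog_match_concatenate(msa_a: Msa, msa_b: Msa) -> PairedMsa:
    """Progressively pair paralogs across species and concatenate A+B.

    Single-copy species (one sequence in each family) seed the paired set;
    multi-paralog species are then processed in order of increasing paralog
    count, scoring each candidate (a, b) pair by its best joint identity to
    any already-paired row: ``max_m pid(a, A_m) + pid(b, B_m)``.  Within a
    species the assignment maximizing total score is used (exact for up to
    6x6, greedy beyond).  Species present in only one family contribute no
    rows; each species contributes ``min(#A, #B)`` rows.
    """
    groups_a = _group_by_species(msa_a)
    groups_b = _group_by_species(msa_b)
    shared = sorted(set(groups_a) & set(groups_b))
    if not shared:
        raise EmptyPairingError("the two alignments share no species")

    paired: List[Tuple[int, int]] = []  # (row in A, row in B)
    paired_species: List[str] = []

    singles = [sp for sp in shared if len(groups_a[sp]) == 1 and len(groups_b[sp]) == 1]
    multis = [sp for sp in shared if sp not in singles]
    for sp in singles:
        paired.append((groups_a[sp][0], groups_b[sp][0]))
        paired_species.append(sp)

    multis.sort(key=lambda sp: (max(len(groups_a[sp]), len(groups_b[sp])), sp))
    for sp in multis:
        rows_a = groups_a[sp]
        rows_b = groups_b[sp]
        score = np.zeros((len(rows_a), len(rows_b)))
        if paired:
            pid_a = np.array(
                [[percent_identity(msa_a.sequences[a], msa_a.sequences[m]) for m, _ in paired] for a in rows_a]
            )
            pid_b = np.array(
                [[percent_identity(msa_b.sequences[b], msa_b.sequences[n]) for _, n in paired] for b in rows_b]
            )
            # best joint match to any single already-paired row
            score = (pid_a[:, None, :] + pid_b[None, :, :]).max(axis=2)
        assignment = pair_paralogs_by_score(score)
        for ra, rb in assignment:
            paired.append((rows_a[ra], rows_b[rb]))
            paired_species.append(sp)

    order = sorted(range(len(paired)), key=lambda k: (paired_species[k], paired[k][0]))
    sequences, species, parents, ids = [], [], [], []
    for k in order:
        ia, ib = paired[k]
        sequences.append(msa_a.sequences[ia] + msa_b.sequences[ib])
        species.append(paired_species[k])
        parents.append((ia, ib))
        ids.append(f"{msa_a.ids[ia]}+{msa_b.ids[ib]}")
    return PairedMsa(
        sequences=sequences,
        boundary=msa_a.length,
        species=species,
        parent_indices=parents,
        ids=ids,
    )


def species_cooccurrence(
    family_species: Mapping[str, Iterable[str]],
) -> Tuple[pd.DataFrame, int]:
    """Census of species presence across protein families.

    Returns an occurrence matrix (rows: union of species, columns: families,
    boolean) and the number of species present in *all* families.
    """
    if not family_species:
        raise ParameterError("at least one family is required")
    sets: Dict[str, Set[str]] = {f: set(s) for f, s in family_species.items()}
    all_species = sorted(set().union(*sets.values()))
    families = sorted(sets)
    matrix = pd.DataFrame(
        {fam: [sp in sets[fam] for sp in all_species] for fam in families},
        index=all_species,
    )
    core = set(all_species)
    for fam in families:
        core &= sets[fam]
    return matrix, len(core)
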