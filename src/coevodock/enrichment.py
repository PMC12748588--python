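"""Enrichment and surface filtering of ranked DI pairs.

Predicted inter-domain pairs are tested against a reference structure with a
right-tailed hypergeometric test (exact integer combinatorics, no normal
approximation), retained at p <= alpha (default 0.2, no multiple-testing
correction), and filtered by combined per-residue SASA strictly greater than
a threshold (default 100 Å²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from math import comb
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

from .dca import DiPair
from .errors import ParameterError
from .structure import ContactMap, ResidueKey, StructureModel, residue_sasa

logger = logging.getLogger(__name__)

PairMapper = Callable[[DiPair], Tuple[ResidueKey, ResidueKey]]


def default_pair_mapper(pair: DiPair) -> Tuple[ResidueKey, ResidueKey]:
    """Map a DiPair to residues (chain 'A', i) and (chain 'B', j)."""
    return ("A", pair.i), ("B", pair.j)


def hypergeom_right_tail(universe: int, successes: int, draws: int, observed: int) -> float:
    """Exact P(X >= observed) for X ~ Hypergeometric(N, K, n).

    Computed with integer binomial coefficients, so the only error is the
    final float rounding.  ``observed = 0`` gives exactly 1.
    """
    n_, k_, n, k = universe, successes, draws, observed
    if not (0 <= k_ <= n_ and 0 <= n <= n_):
        raise ParameterError("need 0 <= K <= N and 0 <= n <= N")
    if k < 0:
        k = 0
    total = comb(n_, n)
    tail = sum(comb(k_, x) * comb(n_ - k_, n - x) for x in range(k, min(n, k_) + 1))
    return float(Fraction(tail, total))


@dataclass
class EnrichmentResult:
    """Right-tailed hypergeometric enrichment of predicted contact pairs."""

    n_top: int  # predicted pairs tested (n)
    true_contacts: int  # contacts in the universe (K)
    universe: int  # all inter-domain residue pairs (N)
    hits: int  # true positives among the n_top (k)
    p_value: float

    @property
    def significance_class(self) -> Optional[str]:
        """Three-tier class: 'red' p<=0.05, 'blue' <=0.1, 'black' <=0.2."""
        return significance_class(self.p_value)


def significance_class(p: float) -> Optional[str]:
    if p <= 0.05:
        return "red"
    if p <= 0.1:
        return "blue"
    if p <= 0.2:
        return "black"
    return None


def hypergeometric_enrichment(
    top_pairs: Sequence[DiPair],
    contacts: ContactMap,
    universe_size: int,
    mapper: PairMapper = default_pair_mapper,
) -> EnrichmentResult:
    """Test the top-ranked DI pairs for contact enrichment.

    ``universe_size`` is the number of inter-domain residue pairs the
    predictions were drawn from; the contacts map must be restricted to that
    same universe.
    """
    n = len(top_pairs)
    big_k = len(contacts)
    if universe_size < n:
        raise ParameterError("universe must be at least as large as the tested pair set")
    if big_k > universe_size:
        raise ParameterError("more contacts than universe pairs")
    hits = sum(1 for p in top_pairs if mapper(p) in contacts)
    p_value = hypergeom_right_tail(universe_size, big_k, n, hits)
    return EnrichmentResult(
        n_top=n, true_contacts=big_k, universe=universe_size, hits=hits, p_value=p_value
    )


def retain_significant(
    results: Mapping[str, EnrichmentResult],
    alpha: float = 0.2,
) -> List[str]:
    """Keys of the pair sets with p <= alpha (inclusive, uncorrected)."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    return [name for name, res in results.items() if res.p_value <= alpha]


def pair_sasa_filter(
    di_pairs: Sequence[DiPair],
    model: StructureModel,
    threshold: float = 100.0,
    mapper: PairMapper = default_pair_mapper,
    top_k: Optional[int] = None,
    sasa: Optional[Dict[ResidueKey, float]] = None,
) -> List[DiPair]:
    """Keep pairs whose combined SASA is strictly greater than ``threshold``.

    Combined SASA is the sum over the pair's two residues computed in the
    context of the full complex.  Survivors are re-ranked by descending DI;
    ``top_k`` truncates the re-ranked list (the "top 10" selector).  Pairs
    mapping outside the model are dropped with a logged count.
    """
    if sasa is None:
        sasa = residue_sasa(model)
    survivors: List[DiPair] = []
    n_unmapped = 0
    for pair in di_pairs:
        key_a, key_b = mapper(pair)
        key_a = (key_a[0], int(key_a[1]))
        key_b = (key_b[0], int(key_b[1]))
        if key_a not in sasa or key_b not in sasa:
            n_unmapped += 1
            continue
        combined = sasa[key_a] + sasa[key_b]
        if combined > threshold:
            survivors.append(replace(pair, sasa_sum=combined))
    if n_unmapped:
        logger.warning("pair_sasa_filter: %d pairs not mapped to the model were dropped", n_unmapped)
    survivors.sort(key=lambda p: (-p.di, p.i, p.j))
    survivors = [replace(p, rank=r + 1) for r, p in enumerate(survivors)]
    if top_k is not None:
        survivors = survivors[:top_k]
    return survivors
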