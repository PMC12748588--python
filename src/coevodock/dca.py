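"""Mean-field direct coupling analysis (mfDCA) on paired alignments.

The inference chain is the classic one: identity-based sequence reweighting,
pseudocount-regularized single and pair frequencies, couplings from the
negative inverse of the connected-correlation matrix over q-1 states (gap is
the reference state), and Direct Information (DI) from the two-site model
whose auxiliary fields are fixed-point iterated to match the empirical
single-site marginals.  Inter-domain residue pairs are ranked by raw DI;
average-product correction is available but off by default.

All heavy loops are numba-compiled; alphabet encoding follows
``msa.ALPHABET`` (gap = state 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from .errors import ParameterError
from .msa import ALPHABET, PairedMsa

logger = logging.getLogger(__name__)


@dataclass
class CouplingStatistics:
    """Reweighted, pseudocount-regularized frequency statistics."""

    fi: np.ndarray  # (L, q)
    fij: np.ndarray  # (L, L, q, q); diagonal blocks delta_ab * fi
    weights: np.ndarray  # (M,)
    m_eff: float
    lam: float
    q: int

    def __post_init__(self) -> None:
        if not np.allclose(self.fi.sum(axis=1), 1.0, atol=1e-10):
            raise ParameterError("single-site frequencies must sum to 1 per site")

    @property
    def length(self) -> int:
        return self.fi.shape[0]


@dataclass
class CouplingModel:
    """Pairwise couplings e_ij(a,b); reference-state entries are zero."""

    couplings: np.ndarray  # (L, L, q, q), e[i,j,a,b] = e[j,i,b,a]
    reference_state: int = 0

    @property
    def length(self) -> int:
        return self.couplings.shape[0]


@dataclass
class DiPair:
    """An inter-domain residue pair with its Direct Information score.

    ``i`` is 1-based within domain A, ``j`` 1-based within domain B.
    """

    i: int
    j: int
    di: float
    rank: int
    p_value: Optional[float] = None
    sasa_sum: Optional[float] = None


@njit(cache=True)
def _neighbor_counts(x: np.ndarray, threshold: float) -> np.ndarray:
    m, length = x.shape
    counts = np.ones(m, dtype=np.int64)
    min_matches = threshold * length
    for a in range(m):
        for b in range(a + 1, m):
            same = 0
            for c in range(length):
                if x[a, c] == x[b, c]:
                    same += 1
            if same >= min_matches:
                counts[a] += 1
                counts[b] += 1
    return counts


def sequence_weights(x: np.ndarray, identity_threshold: float = 0.8) -> Tuple[np.ndarray, float]:
    """Standard DCA reweighting: w_m = 1 / #{m': identity >= threshold}.

    The sequence itself is always counted, so weights lie in (0, 1] and
    ``M_eff = sum(w)``.
    """
    if not 0 < identity_threshold <= 1:
        raise ParameterError("identity threshold must lie in (0, 1]")
    x = np.ascontiguousarray(x, dtype=np.int8)
    counts = _neighbor_counts(x, identity_threshold)
    w = 1.0 / counts
    return w, float(w.sum())


@njit(cache=True)
def _pair_counts(x: np.ndarray, w: np.ndarray, q: int) -> np.ndarray:
    m, length = x.shape
    fij = np.zeros((length, length, q, q))
    for r in range(m):
        for i in range(length):
            ai = x[r, i]
            for j in range(i + 1, length):
                fij[i, j, ai, x[r, j]] += w[r]
    return fij


def frequencies(
    x: np.ndarray,
    weights: Optional[np.ndarray] = None,
    lam: Optional[float] = None,
    q: int = 21,
) -> CouplingStatistics:
    """Pseudocount-regularized single and pair frequencies.

    ``f_i(a) = (lam/q + sum_m w_m [x_mi = a]) / (lam + M_eff)`` and the pair
    analogue with ``lam/q^2``.  ``lam`` defaults to ``M_eff`` (pseudocount
    weight 0.5, the field-standard mfDCA setting).  Diagonal blocks of
    ``f_ij`` are set to ``delta_ab f_i(a)`` for covariance construction.
    """
    x = np.ascontiguousarray(x, dtype=np.int8)
    m, length = x.shape
    if weights is None:
        weights = np.ones(m)
    m_eff = float(weights.sum())
    if lam is None:
        lam = m_eff
    if lam < 0:
        raise ParameterError("pseudocount must be non-negative")

    fi = np.zeros((length, q))
    for a in range(q):
        fi[:, a] = ((x == a) * weights[:, None]).sum(axis=0)
    fi = (lam / q + fi) / (lam + m_eff)

    fij = _pair_counts(x, weights, q)  # filled for i < j only
    fij = fij + np.transpose(fij, (1, 0, 3, 2))
    fij = (lam / q**2 + fij) / (lam + m_eff)
    idx = np.arange(length)
    fij[idx, idx] = 0.0
    for a in range(q):
        fij[idx, idx, a, a] = fi[:, a]
    return CouplingStatistics(fi=fi, fij=fij, weights=weights, m_eff=m_eff, lam=lam, q=q)


def mean_field_couplings(stats: CouplingStatistics) -> CouplingModel:
    """Couplings as the negative inverse of the connected correlation matrix.

    The matrix is built over the q-1 non-reference states per site
    (reference = gap = state 0) and is guaranteed invertible for lam > 0.
    """
    length, q = stats.fi.shape
    d = q - 1
    c = stats.fij[:, :, 1:, 1:] - stats.fi[:, None, 1:, None] * stats.fi[None, :, None, 1:]
    c = c.transpose(0, 2, 1, 3).reshape(length * d, length * d)
    try:
        inv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            "correlation matrix is singular; raise the pseudocount lam above 0"
        ) from exc
    e = np.zeros((length, length, q, q))
    e[:, :, 1:, 1:] = -inv.reshape(length, d, length, d).transpose(0, 2, 1, 3)
    idx = np.arange(length)
    e[idx, idx] = 0.0
    # enforce the symmetry e_ij(a,b) = e_ji(b,a) against round-off
    e = 0.5 * (e + np.transpose(e, (1, 0, 3, 2)))
    return CouplingModel(couplings=e)


def direct_information(
    model: CouplingModel,
    stats: CouplingStatistics,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> np.ndarray:
    """Direct Information matrix (nats), NaN for non-convergent pairs.

    For each pair the two-site distribution ``P(a,b) ~ exp(e_ij(a,b)) *
    h_i(a) * h_j(b)`` is computed with auxiliary fields iterated until both
    marginals match ``f_i`` and ``f_j`` within ``tol``; DI is the mutual
    information of that distribution against the product of marginals.
    """
    length, q = stats.fi.shape
    pairs = [(i, j) for i in range(length) for j in range(i + 1, length)]
    if not pairs:
        return np.zeros((length, length))
    pi = np.array([p[0] for p in pairs])
    pj = np.array([p[1] for p in pairs])
    w = np.exp(model.couplings[pi, pj])  # (P, q, q)
    fa = stats.fi[pi]  # (P, q)
    fb = stats.fi[pj]
    mu1 = np.full_like(fa, 1.0 / q)
    mu2 = np.full_like(fb, 1.0 / q)
    converged = np.zeros(len(pairs), dtype=bool)
    for _ in range(max_iter):
        mu1 = fa / np.einsum("pab,pb->pa", w, mu2)
        mu1 /= mu1.sum(axis=1, keepdims=True)
        mu2 = fb / np.einsum("pab,pa->pb", w, mu1)
        mu2 /= mu2.sum(axis=1, keepdims=True)
        p = mu1[:, :, None] * w * mu2[:, None, :]
        p /= p.sum(axis=(1, 2), keepdims=True)
        err_a = np.abs(p.sum(axis=2) - fa).max(axis=1)
        err_b = np.abs(p.sum(axis=1) - fb).max(axis=1)
        converged = np.maximum(err_a, err_b) < tol
        if converged.all():
            break

    prod = fa[:, :, None] * fb[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / prod), 0.0)
    di_flat = terms.sum(axis=(1, 2))
    di_flat = np.maximum(di_flat, 0.0)  # clip tiny negative round-off
    n_bad = int((~converged).sum())
    if n_bad:
        logger.warning("direct_information: %d pairs did not converge (DI=NaN)", n_bad)
        di_flat[~converged] = np.nan
    di = np.zeros((length, length))
    di[pi, pj] = di_flat
    di[pj, pi] = di_flat
    return di


def apply_apc(di: np.ndarray) -> np.ndarray:
    """Average-product correction: DI_ij - mean_i * mean_j / mean_all."""
    length = di.shape[0]
    off = ~np.eye(length, dtype=bool)
    row_mean = np.where(off, di, 0.0).sum(axis=1) / (length - 1)
    total = row_mean.mean()
    corr = di - np.outer(row_mean, row_mean) / total
    np.fill_diagonal(corr, 0.0)
    return corr


def rank_interdomain_pairs(
    di: np.ndarray,
    boundary: int,
    top_n: Optional[int] = None,
) -> List[DiPair]:
    """Rank inter-domain pairs (i in A, j in B) by descending DI.

    ``boundary`` is the number of A columns; ties break by ascending (i, j).
    Non-finite DI entries (non-converged pairs) are excluded and counted in
    the log.  Coordinates in the result are 1-based and domain-local.
    """
    length = di.shape[0]
    if not 1 <= boundary < length:
        raise ParameterError("boundary must lie within [1, L)")
    entries = []
    n_nan = 0
    for i in range(boundary):
        for j in range(boundary, length):
            v = di[i, j]
            if not math.isfinite(v):
                n_nan += 1
                continue
            entries.append((-v, i, j))
    if n_nan:
        logger.warning("rank_interdomain_pairs: %d non-finite DI pairs excluded", n_nan)
    entries.sort()
    if top_n is not None:
        entries = entries[:top_n]
    return [
        DiPair(i=i + 1, j=j - boundary + 1, di=-negv, rank=r + 1)
        for r, (negv, i, j) in enumerate(entries)
    ]


@dataclass
class DcaResult:
    """End-to-end mfDCA output for one paired alignment."""

    stats: CouplingStatistics
    model: CouplingModel
    di: np.ndarray
    pairs: List[DiPair] = field(default_factory=list)


def run_dca(
    paired: PairedMsa,
    identity_threshold: float = 0.8,
    lam: Optional[float] = None,
    q: int = len(ALPHABET),
    top_n: Optional[int] = None,
    apc: bool = False,
) -> DcaResult:
    """Convenience pipeline: weights -> frequencies -> couplings -> DI -> ranking."""
    x = paired.to_indices()
    w, _ = sequence_weights(x, identity_threshold)
    stats = frequencies(x, weights=w, lam=lam, q=q)
    model = mean_field_couplings(stats)
    di = direct_information(model, stats)
    ranking_matrix = apply_apc(di) if apc else di
    pairs = rank_interdomain_pairs(ranking_matrix, paired.boundary, top_n=top_n)
    return DcaResult(stats=stats, model=model, di=di, pairs=pairs)
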