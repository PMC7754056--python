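"""Step 1: identify Potential Modifiers (PMs) in healthy tissue.

A PM is a gene whose bottom-fraction expression samples significantly
overlap the bottom-fraction samples of the gene causal of disease (GCD),
under a Bonferroni-corrected hypergeometric upper-tail test at alpha = 0.01.
The rationale: genes whose loss co-occurs with GCD loss in *healthy* people
may be tolerated together, hinting at compensation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .exceptions import DomainError, EligibilityError, MissingGeneError, SampleSizeError
from .expression_io import ExpressionMatrix, GeneList

DEFAULT_FRACTION = 0.10
DEFAULT_ALPHA = 0.01


@dataclass
class LowMask:
    """The bottom-``fraction`` samples of one gene.

    Exactly ``k_low = floor(fraction * n_samples)`` samples are selected:
    those with the smallest values, ties at the boundary broken by matrix
    sample order (earlier columns first) for reproducibility.
    """

    sample_ids_selected: list[str]
    fraction: float
    k_low: int

    @property
    def selected_set(self) -> frozenset[str]:
        return frozenset(self.sample_ids_selected)


@dataclass
class PMRecord:
    """Per-gene Step-1 result.

    ``N`` eligible samples, ``K`` = |GCD low set|, ``n`` = |gene low set|,
    ``k`` their overlap; ``p_bonferroni = min(1, m * p_raw)`` over the ``m``
    eligible genes tested.
    """

    gene_id: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_bonferroni: float
    is_pm: bool


def low_expression_mask(
    values: Sequence[float],
    fraction: float = DEFAULT_FRACTION,
    sample_ids: Sequence[str] | None = None,
) -> LowMask:
    """Select the bottom-``fraction`` samples of one gene.

    ``k_low = floor(fraction * len(values))`` must be at least 1; ties at
    the cut are resolved in favour of earlier samples (stable sort).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    k_low = int(np.floor(fraction * n))
    if k_low < 1:
        raise SampleSizeError(
            f"cohort of {n} samples too small for fraction {fraction} (floor < 1)"
        )
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    order = np.argsort(values, kind="stable")
    selected = sorted(order[:k_low].tolist())
    return LowMask([sample_ids[i] for i in selected], float(fraction), k_low)


def _low_bool_matrix(values: np.ndarray, k_low: int) -> np.ndarray:
    """Boolean (genes x samples) low-set membership, stable tie-break per row."""
    order = np.argsort(values, axis=1, kind="stable")
    low = np.zeros(values.shape, dtype=bool)
    rows = np.repeat(np.arange(values.shape[0]), k_low)
    low[rows, order[:, :k_low].ravel()] = True
    return low


def _eligible_mask(values: np.ndarray, k_low: int) -> np.ndarray:
    """Eligibility screen for the low-set construction.

    A gene is eligible when it is non-constant and strictly fewer than
    ``n_samples - k_low`` of its samples are tied at the minimum, so the
    bottom set is not an arbitrary selection from a majority tie (the
    common failure mode is zero-inflated genes).
    """
    n = values.shape[1]
    non_constant = np.ptp(values, axis=1) > 0
    n_at_min = (values == values.min(axis=1, keepdims=True)).sum(axis=1)
    return non_constant & (n_at_min < n - k_low)


def eligible_genes(matrix: ExpressionMatrix, fraction: float = DEFAULT_FRACTION) -> GeneList:
    """Genes for which a bottom-fraction low set is meaningful."""
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise SampleSizeError("matrix is empty")
    k_low = int(np.floor(fraction * matrix.n_samples))
    if k_low < 1:
        raise SampleSizeError(
            f"cohort of {matrix.n_samples} samples too small for fraction {fraction}"
        )
    mask = _eligible_mask(matrix.values, k_low)
    return GeneList([g for g, ok in zip(matrix.gene_ids, mask) if ok])


def hypergeometric_upper_tail(N, K, n, k) -> float | np.ndarray:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts marked items in a draw of ``n`` from a population of ``N``
    containing ``K`` marked items. Computed in log space (log-gamma
    binomials combined with logsumexp) for numerical stability at large N.
    ``k`` may be an array; N, K, n are scalars.
    """
    N, K, n = int(N), int(K), int(n)
    k_arr = np.atleast_1d(np.asarray(k, dtype=int))
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"require 0 <= K={K} <= N={N} and 0 <= n={n} <= N")
    lo, hi = max(0, K + n - N), min(K, n)
    if np.any(k_arr < lo) or np.any(k_arr > hi):
        raise DomainError(f"k outside [{lo}, {hi}] for N={N}, K={K}, n={n}")
    j = np.arange(lo, hi + 1)
    log_pmf = (
        _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    )
    # suffix logsumexp: tail[i] = log sum_{j >= i} pmf
    tail = np.empty(j.size)
    running = -np.inf
    for i in range(j.size - 1, -1, -1):
        running = np.logaddexp(running, log_pmf[i])
        tail[i] = running
    p = np.exp(tail[k_arr - lo])
    p = np.minimum(p, 1.0)
    return float(p[0]) if np.isscalar(k) or np.asarray(k).ndim == 0 else p


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def run_step1(
    matrix: ExpressionMatrix,
    gcd_id: str,
    fraction: float = DEFAULT_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    gene_fraction: float | None = None,
) -> list[PMRecord]:
    """Screen every eligible gene for co-low overlap with the GCD.

    One record per eligible gene excluding the GCD itself; the Bonferroni
    family size ``m`` is the number of genes actually tested. Records are
    sorted by raw p-value ascending, ties by gene id. ``gene_fraction``
    lets the candidate-gene threshold differ from the GCD threshold
    (both default to ``fraction``).
    """
    if gcd_id not in matrix:
        raise MissingGeneError(f"GCD {gcd_id!r} absent from matrix")
    if gene_fraction is None:
        gene_fraction = fraction
    s = matrix.n_samples
    k_gcd = int(np.floor(fraction * s))
    k_gene = int(np.floor(gene_fraction * s))
    if min(k_gcd, k_gene) < 1:
        raise SampleSizeError(f"cohort of {s} samples too small for requested fractions")

    gcd_row = matrix.row(gcd_id)[None, :]
    if not _eligible_mask(gcd_row, k_gcd)[0]:
        raise EligibilityError(f"GCD {gcd_id!r} is ineligible (constant or zero-heavy)")
    gcd_low = _low_bool_matrix(gcd_row, k_gcd)[0]

    elig = _eligible_mask(matrix.values, k_gene)
    elig[matrix.gene_ids.index(gcd_id)] = False
    tested_idx = np.flatnonzero(elig)
    m = tested_idx.size
    if m == 0:
        return []

    low = _low_bool_matrix(matrix.values[tested_idx], k_gene)
    k_overlap = low.astype(np.int64) @ gcd_low.astype(np.int64)
    p_raw = hypergeometric_upper_tail(s, k_gcd, k_gene, k_overlap)
    p_bonf = np.minimum(1.0, m * p_raw)

    records = [
        PMRecord(
            gene_id=matrix.gene_ids[gi],
            N=s,
            K=k_gcd,
            n=k_gene,
            k=int(k_overlap[i]),
            p_raw=float(p_raw[i]),
            p_bonferroni=float(p_bonf[i]),
            is_pm=bool(p_bonf[i] < alpha),
        )
        for i, gi in enumerate(tested_idx)
    ]
    records.sort(key=lambda r: (r.p_raw, r.gene_id))
    return records


def pm_gene_list(records: Sequence[PMRecord]) -> GeneList:
    """Genes flagged ``is_pm``, in record order."""
    return GeneList([r.gene_id for r in records if r.is_pm])


def intersect_tissues(pm_sets: Sequence[Sequence[PMRecord]]) -> GeneList:
    """Genes flagged is_pm in every tissue, in lexicographic order.

    Used when a disease affects several tissues: Step 1 is run per tissue
    and the per-tissue PM lists are intersected before Step 2.
    """
    if not pm_sets:
        raise ValueError("need at least one tissue's PM records")
    sets = [frozenset(r.gene_id for r in recs if r.is_pm) for recs in pm_sets]
    common = frozenset.intersection(*sets)
    return GeneList(sorted(common))
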