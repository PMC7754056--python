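"""Candidate-locus scanning, shuffle robustness, and evaluation utilities.

Association and linkage studies report loci containing many genes; Step 1
applied to just the genes in a locus prioritises those whose low expression
co-occurs with low GCD expression in healthy tissue. Robustness is assessed
by shuffling the GCD's expression across samples, and prediction quality by
hypergeometric enrichment and sensitivity/specificity/PPV against curated
modifier lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import DomainError, EligibilityError, MissingGeneError, SampleSizeError
from .expression_io import ExpressionMatrix, GeneList
from .step1 import (
    DEFAULT_FRACTION,
    _eligible_mask,
    _low_bool_matrix,
    hypergeometric_upper_tail,
    low_expression_mask,
    run_step1,
)

logger = logging.getLogger(__name__)

DEFAULT_LOCUS_ALPHA = 0.05
DEFAULT_SHUFFLES = 10_000
STATUS_MISSING = "missing"
STATUS_TESTED = "tested"


@dataclass
class LocusGeneResult:
    gene_id: str
    position_index: int
    status: str
    p_raw: Optional[float]
    significant_local: Optional[bool]
    significant_global: Optional[bool]


@dataclass
class LocusScanResult:
    """Per-gene Step-1 p-values inside one locus, with two Bonferroni bars.

    ``m_local`` counts eligible genes in the locus, ``m_global`` eligible
    genes in the whole matrix; a globally significant gene is always
    locally significant.
    """

    records: list[LocusGeneResult]
    m_local: int
    m_global: int
    alpha: float


@dataclass
class EvaluationSummary:
    """Confusion counts of predicted vs reference modifiers over a universe.

    Ratios with zero denominators are reported as None (not-applicable),
    never silently as 0.
    """

    true_positive: int
    false_positive: int
    false_negative: int
    true_negative: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]


def locus_step1_scan(
    matrix: ExpressionMatrix,
    gcd_id: str,
    locus_genes: GeneList | Sequence[str],
    fraction: float = DEFAULT_FRACTION,
    alpha: float = DEFAULT_LOCUS_ALPHA,
) -> LocusScanResult:
    """Step-1 p-values for the genes of one candidate locus.

    Each tested gene is compared against two Bonferroni thresholds:
    alpha / m_local (over eligible locus genes) and alpha / m_global (over
    all eligible matrix genes). Genes absent from the matrix are reported
    with status ``missing``.
    """
    locus_ids = list(locus_genes)
    all_records = run_step1(matrix, gcd_id, fraction=fraction, alpha=alpha)
    by_gene = {r.gene_id: r for r in all_records}
    m_global = len(all_records)
    tested = [g for g in locus_ids if g in by_gene]
    if not tested:
        raise MissingGeneError("no locus gene is present and eligible in the matrix")
    m_local = len(tested)
    records = []
    for i, g in enumerate(locus_ids):
        rec = by_gene.get(g)
        if rec is None:
            records.append(LocusGeneResult(g, i, STATUS_MISSING, None, None, None))
        else:
            records.append(
                LocusGeneResult(
                    g, i, STATUS_TESTED, rec.p_raw,
                    rec.p_raw < alpha / m_local,
                    rec.p_raw < alpha / m_global,
                )
            )
    return LocusScanResult(records, m_local, m_global, alpha)


def shuffle_null_pvalue(
    matrix: ExpressionMatrix,
    gcd_id: str,
    gene_set: GeneList | Sequence[str],
    n_shuffles: int = DEFAULT_SHUFFLES,
    fraction: float = DEFAULT_FRACTION,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of GCD-expression shuffles yielding any Bonferroni hit.

    The GCD's expression vector is permuted across samples ``n_shuffles``
    times (equivalent to permuting its sample labels); for each permutation
    the Step-1 test is applied to every eligible gene of ``gene_set`` with
    Bonferroni family size equal to that eligible count. Returns the
    fraction of shuffles in which at least one gene passes; a value of 0
    should be read (and is reported by the CLI) as "< 1/n_shuffles".
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if gcd_id not in matrix:
        raise MissingGeneError(f"GCD {gcd_id!r} absent from matrix")
    s = matrix.n_samples
    k_low = int(np.floor(fraction * s))
    if k_low < 1:
        raise SampleSizeError(f"cohort of {s} samples too small for fraction {fraction}")

    gcd_row = matrix.row(gcd_id)[None, :]
    if not _eligible_mask(gcd_row, k_low)[0]:
        raise EligibilityError(f"GCD {gcd_id!r} is ineligible")
    base_mask = _low_bool_matrix(gcd_row, k_low)[0]

    gene_ids = [g for g in gene_set if g != gcd_id]
    idx = [matrix.gene_ids.index(g) for g in gene_ids if g in matrix]
    sub = matrix.values[np.array(idx, dtype=int)] if idx else np.empty((0, s))
    elig = _eligible_mask(sub, k_low) if idx else np.array([], dtype=bool)
    tested = sub[elig]
    m = int(tested.shape[0])
    if m == 0:
        raise EligibilityError("no eligible gene in gene_set")
    gene_low = _low_bool_matrix(tested, k_low)  # (m, s)

    # Every low set has exactly k_low members, so one tail table serves all
    # genes and all shuffles: p[k] = P(X >= k) with N=s, K=n=k_low.
    tail = hypergeometric_upper_tail(s, k_low, k_low, np.arange(0, k_low + 1))
    threshold = alpha / m

    rng = np.random.default_rng(seed)
    hits = 0
    batch = 512
    done = 0
    low_f = gene_low.astype(np.float32)
    while done < n_shuffles:
        b = min(batch, n_shuffles - done)
        keys = rng.random((b, s))
        perm_masks = np.take_along_axis(
            np.tile(base_mask, (b, 1)), np.argsort(keys, axis=1), axis=1
        )
        overlaps = low_f @ perm_masks.astype(np.float32).T  # (m, b)
        pvals = tail[overlaps.astype(int)]
        hits += int((pvals < threshold).any(axis=0).sum())
        done += b
    return hits / n_shuffles


def overlap_enrichment(
    predicted: GeneList | Sequence[str],
    reference: GeneList | Sequence[str],
    universe: GeneList | Sequence[str],
) -> float:
    """Hypergeometric upper-tail enrichment of predicted vs reference genes.

    N = |universe|, K = |reference|, n = |predicted|, k = |overlap|; the
    same tail routine as Step 1 (single implementation, two call sites).
    """
    pred, ref, uni = set(predicted), set(reference), set(universe)
    _require_subset(pred, uni, "predicted")
    _require_subset(ref, uni, "reference")
    N, K, n, k = len(uni), len(ref), len(pred), len(pred & ref)
    return float(hypergeometric_upper_tail(N, K, n, k))


def evaluate_predictions(
    predicted: GeneList | Sequence[str],
    reference: GeneList | Sequence[str],
    universe: GeneList | Sequence[str],
    measured_genes: Optional[GeneList | Sequence[str]] = None,
) -> EvaluationSummary:
    """Confusion counts and sensitivity/specificity/PPV over a gene universe.

    Reference genes absent from ``measured_genes`` (when given) are dropped
    from the positives with a logged note: a gene with no case-control
    measurement cannot possibly be predicted at Step 2.
    """
    pred, ref, uni = set(predicted), set(reference), set(universe)
    _require_subset(pred, uni, "predicted")
    _require_subset(ref, uni, "reference")
    if measured_genes is not None:
        measured = set(measured_genes)
        dropped = sorted(ref - measured)
        if dropped:
            logger.info(
                "dropping %d unmeasured reference gene(s) from positives: %s",
                len(dropped), dropped,
            )
            ref -= set(dropped)
            uni -= set(dropped)
            pred &= uni
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    tn = len(uni) - tp - fp - fn
    return EvaluationSummary(
        tp, fp, fn, tn,
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
        ppv=tp / (tp + fp) if tp + fp else None,
    )


def _require_subset(subset: set, universe: set, name: str) -> None:
    stray = subset - universe
    if stray:
        raise DomainError(f"{name} genes outside the universe: {sorted(stray)}")
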