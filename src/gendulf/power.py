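"""Resampling power and type-I-error estimation for the Step-2 test.

Both estimators need only the healthy cohort. For power, pseudo-cases and
pseudo-controls are both drawn from the GCD-low stratum S_GL: a true DPM is
*not* extra-low in cases, which is exactly what two same-stratum draws
emulate, so the fraction of replicates in which Step 2 accepts the PM is
the detection confidence at that arm size. For type-I error, pseudo-cases
come from S_GL and pseudo-controls from S_GH, reproducing the null
configuration, so every rejection is a false positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import SampleSizeError
from .expression_io import ExpressionMatrix, GeneList
from .step1 import DEFAULT_FRACTION, low_expression_mask
from .step2 import (
    DEFAULT_REPS,
    count_lower_pairs,
    empirical_dpm_pvalue,
    gene_substream_seed,
    sample_null_pair_counts,
)

logger = logging.getLogger(__name__)

DEFAULT_R = 10
DEFAULT_CONFIDENCE_THRESHOLD = 0.8
DEFAULT_TYPE1_REPLICATES = 100
DEFAULT_ALPHA = 0.05


@dataclass
class PowerEstimate:
    """Detection confidence of one PM at per-arm size N over R replicates."""

    gene_id: str
    N: int
    R: int
    accepted_count: int
    confidence: float


@dataclass
class Type1Estimate:
    """Null rejection rate of one PM at per-arm size N."""

    gene_id: str
    N: int
    replicates: int
    rejection_rate: float


def _gcd_low_mask(healthy: ExpressionMatrix, gcd_id: str, fraction: float) -> np.ndarray:
    mask_obj = low_expression_mask(healthy.row(gcd_id), fraction, healthy.sample_ids)
    mask = np.zeros(healthy.n_samples, dtype=bool)
    mask[healthy.sample_indices(mask_obj.sample_ids_selected)] = True
    return mask


def dpm_detection_confidence(
    healthy: ExpressionMatrix,
    gcd_id: str,
    pm_id: str,
    N: int,
    R: int = DEFAULT_R,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    fraction: float = DEFAULT_FRACTION,
    alpha: float = DEFAULT_ALPHA,
) -> PowerEstimate:
    """Fraction of R pseudo-studies (both arms from S_GL) that Step 2 accepts.

    When 2N fits in the stratum the two pseudo-arms are drawn jointly
    without replacement (disjoint); otherwise they are independent draws
    and a warning is logged. The null distribution is resampled in full on
    every replicate.
    """
    gcd_low = _gcd_low_mask(healthy, gcd_id, fraction)
    low_idx = np.flatnonzero(gcd_low)
    if N > low_idx.size:
        raise SampleSizeError(f"N={N} exceeds GCD-low stratum size {low_idx.size}")
    pm_values = healthy.row(pm_id)
    base_seed = gene_substream_seed(seed, f"power:{pm_id}:{N}")
    rng = np.random.default_rng(base_seed)
    accepted = 0
    for r in range(R):
        if 2 * N <= low_idx.size:
            both = rng.choice(low_idx, size=2 * N, replace=False)
            arm1, arm2 = both[:N], both[N:]
        else:
            logger.warning(
                "2N=%d exceeds GCD-low stratum (%d); pseudo-arms may overlap",
                2 * N, low_idx.size,
            )
            arm1 = rng.choice(low_idx, size=N, replace=False)
            arm2 = rng.choice(low_idx, size=N, replace=False)
        observed = count_lower_pairs(pm_values[arm1], pm_values[arm2])
        null = sample_null_pair_counts(
            pm_values, gcd_low, N, N, reps, seed=gene_substream_seed(base_seed, f"null:{r}")
        )
        if empirical_dpm_pvalue(observed, null) < alpha:
            accepted += 1
    return PowerEstimate(pm_id, N, R, accepted, accepted / R)


def minimal_case_control_size(
    healthy: ExpressionMatrix,
    gcd_id: str,
    pm_list: GeneList | Sequence[str],
    n_grid: Sequence[int],
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    R: int = DEFAULT_R,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    fraction: float = DEFAULT_FRACTION,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[int | None, dict[int, float]]:
    """Smallest per-arm N on the grid with mean PM confidence >= threshold.

    Returns ``(minimal_N_or_None, {N: mean_confidence})``. The search is
    grid-based because confidence is Monte-Carlo noisy and not strictly
    monotone.
    """
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    pm_ids = list(pm_list)
    gcd_low = _gcd_low_mask(healthy, gcd_id, fraction)
    if max(n_grid) > int(gcd_low.sum()):
        raise SampleSizeError(
            f"grid maximum {max(n_grid)} exceeds GCD-low stratum size {int(gcd_low.sum())}"
        )
    means: dict[int, float] = {}
    minimal: int | None = None
    for N in sorted(n_grid):
        confs = [
            dpm_detection_confidence(
                healthy, gcd_id, pm, N, R=R, reps=reps, seed=seed,
                fraction=fraction, alpha=alpha,
            ).confidence
            for pm in pm_ids
        ]
        means[N] = float(np.mean(confs))
        if minimal is None and means[N] >= threshold:
            minimal = N
    return minimal, means


def type1_error_summary(
    healthy: ExpressionMatrix,
    gcd_id: str,
    pm_list: GeneList | Sequence[str],
    N: int,
    replicates: int = DEFAULT_TYPE1_REPLICATES,
    alpha: float = DEFAULT_ALPHA,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    fraction: float = DEFAULT_FRACTION,
) -> tuple[list[Type1Estimate], float]:
    """Per-PM null rejection rate and the share of PMs with rate < alpha.

    Pseudo-cases come from S_GL and pseudo-controls from S_GH: the PM's
    healthy co-low pattern holds, H0 is true, and any rejection is a
    type-I error. ``fraction_controlled`` is the fraction of PMs whose
    estimated rejection rate stays below alpha.
    """
    gcd_low = _gcd_low_mask(healthy, gcd_id, fraction)
    low_idx = np.flatnonzero(gcd_low)
    high_idx = np.flatnonzero(~gcd_low)
    if N > low_idx.size or N > high_idx.size:
        raise SampleSizeError(
            f"N={N} exceeds a stratum (low {low_idx.size}, not-low {high_idx.size})"
        )
    estimates: list[Type1Estimate] = []
    for pm in pm_list:
        pm_values = healthy.row(pm)
        base_seed = gene_substream_seed(seed, f"type1:{pm}:{N}")
        rng = np.random.default_rng(base_seed)
        rejections = 0
        for r in range(replicates):
            arm_case = rng.choice(low_idx, size=N, replace=False)
            arm_ctrl = rng.choice(high_idx, size=N, replace=False)
            observed = count_lower_pairs(pm_values[arm_case], pm_values[arm_ctrl])
            null = sample_null_pair_counts(
                pm_values, gcd_low, N, N, reps,
                seed=gene_substream_seed(base_seed, f"null:{r}"),
            )
            if empirical_dpm_pvalue(observed, null) < alpha:
                rejections += 1
        estimates.append(Type1Estimate(pm, N, replicates, rejections / replicates))
    fraction_controlled = float(np.mean([e.rejection_rate < alpha for e in estimates]))
    return estimates, fraction_controlled
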