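"""Step 2: filter PMs to Disease-associated PMs (DPMs).

The null hypothesis is that a PM's expression is always low when the GCD is
low, whatever the tissue: the PM should then be as far below controls in the
disease study as it is below the GCD-not-low samples in the healthy cohort.
The test statistic is a pair count — the number of (case, control) value
pairs with case < control — compared against the same statistic on 10,000
pseudo-studies resampled (without replacement) from the healthy cohort's
GCD-low stratum (S_GL) versus its complement (S_GH). Because only
within-dataset ranks enter, the two datasets may live on different
measurement scales.

The empirical p-value is T / reps where T counts null replicates whose pair
count P_i does not exceed the observed disease pair count; a small p means
the disease drop is consistently *weaker* than the healthy-cohort drop, so
H0 is rejected and the PM is kept as a DPM (candidate compensatory
modifier).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import SampleSizeError
from .expression_io import CaseControlStudy, ExpressionMatrix, GeneList
from .step1 import DEFAULT_FRACTION, low_expression_mask

DEFAULT_REPS = 10_000
DEFAULT_ALPHA = 0.05

STATUS_DPM = "dpm"
STATUS_REJECTED = "rejected"
STATUS_NOT_MEASURED = "not_measured"


@dataclass
class DPMRecord:
    """Per-gene Step-2 result.

    ``T`` counts null replicates with pair count <= the observed disease
    pair count; ``p_empirical = T / reps`` exactly, with no add-one
    smoothing, so p = 0 is attainable.
    """

    gene_id: str
    disease_pair_count: int
    max_pairs: int
    T: int
    reps: int
    p_empirical: float
    status: str


@dataclass
class NullPairCounts:
    """Pair statistics of resampled healthy pseudo-studies."""

    counts: np.ndarray  # shape (reps,), ints in [0, max_pairs]
    rng_seed: int

    @property
    def reps(self) -> int:
        return int(self.counts.size)


def count_lower_pairs(group_a: Sequence[float], group_b: Sequence[float]) -> int:
    """Number of ordered pairs (a, b) with a strictly below b; ties count 0."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return int((a[:, None] < b[None, :]).sum())


def sample_null_pair_counts(
    pm_values_gtex: np.ndarray,
    gcd_low_mask: np.ndarray,
    n_cases: int,
    n_controls: int,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> NullPairCounts:
    """Resample the pair statistic from the healthy cohort.

    Each replicate draws ``n_cases`` samples without replacement from the
    GCD-low stratum and ``n_controls`` from its complement, then counts
    pairs (low draw < not-low draw) on the PM's values. The sequence is a
    deterministic function of ``seed``.

    Parameters
    ----------
    pm_values_gtex : per-sample PM expression, healthy cohort order
    gcd_low_mask : boolean per-sample indicator of the GCD-low stratum
    """
    pm_values_gtex = np.asarray(pm_values_gtex, dtype=float)
    gcd_low_mask = np.asarray(gcd_low_mask, dtype=bool)
    low_vals = pm_values_gtex[gcd_low_mask]
    high_vals = pm_values_gtex[~gcd_low_mask]
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if low_vals.size < n_cases:
        raise SampleSizeError(
            f"GCD-low stratum has {low_vals.size} samples; need {n_cases}"
        )
    if high_vals.size < n_controls:
        raise SampleSizeError(
            f"GCD-not-low stratum has {high_vals.size} samples; need {n_controls}"
        )
    rng = np.random.default_rng(seed)
    sel_low = _draw_without_replacement(rng, reps, low_vals.size, n_cases)
    sel_high = _draw_without_replacement(rng, reps, high_vals.size, n_controls)
    a = low_vals[sel_low]   # (reps, n_cases)
    b = high_vals[sel_high]  # (reps, n_controls)
    counts = (a[:, :, None] < b[:, None, :]).sum(axis=(1, 2))
    return NullPairCounts(counts.astype(int), int(seed))


def _draw_without_replacement(rng: np.random.Generator, reps: int, pool: int, k: int) -> np.ndarray:
    """(reps, k) index draws without replacement, vectorised via random keys."""
    keys = rng.random((reps, pool))
    return np.argpartition(keys, k - 1, axis=1)[:, :k] if k < pool else np.tile(
        np.arange(pool), (reps, 1)
    )


def empirical_dpm_pvalue(disease_pair_count: int, null_counts: NullPairCounts) -> float:
    """T / reps, where T counts null pair statistics <= the observed one."""
    T = int((int(disease_pair_count) >= null_counts.counts).sum())
    return T / null_counts.reps


def gene_substream_seed(master_seed: int, gene_id: str) -> int:
    """Deterministic, platform-independent per-gene seed.

    Derived by hashing the gene id together with the master seed so that
    gene order and parallel execution cannot change results.
    """
    digest = hashlib.sha256(f"{master_seed}:{gene_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


def run_step2(
    pm_genes: GeneList | Sequence[str],
    healthy: ExpressionMatrix,
    gcd_id: str,
    study: CaseControlStudy,
    fraction: float = DEFAULT_FRACTION,
    reps: int = DEFAULT_REPS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> list[DPMRecord]:
    """Apply the empirical permutation test to every PM.

    PMs absent from the case-control matrix get status ``not_measured``.
    Per-gene random substreams are derived from the master seed and the
    gene id, so output is bit-identical across runs and platforms.
    """
    n_cases = len(study.case_sample_ids)
    n_controls = len(study.control_sample_ids)
    gcd_mask_obj = low_expression_mask(healthy.row(gcd_id), fraction, healthy.sample_ids)
    gcd_low = np.zeros(healthy.n_samples, dtype=bool)
    gcd_low[healthy.sample_indices(gcd_mask_obj.sample_ids_selected)] = True
    n_low, n_high = int(gcd_low.sum()), int((~gcd_low).sum())
    if n_low < n_cases:
        raise SampleSizeError(
            f"GCD-low stratum ({n_low} samples) smaller than case arm ({n_cases})"
        )
    if n_high < n_controls:
        raise SampleSizeError(
            f"GCD-not-low stratum ({n_high} samples) smaller than control arm ({n_controls})"
        )

    max_pairs = n_cases * n_controls
    records: list[DPMRecord] = []
    for gene in pm_genes:
        if gene not in study.matrix:
            records.append(
                DPMRecord(gene, 0, max_pairs, 0, reps, float("nan"), STATUS_NOT_MEASURED)
            )
            continue
        observed = count_lower_pairs(study.case_values(gene), study.control_values(gene))
        null = sample_null_pair_counts(
            healthy.row(gene), gcd_low, n_cases, n_controls, reps,
            seed=gene_substream_seed(seed, gene),
        )
        p = empirical_dpm_pvalue(observed, null)
        status = STATUS_DPM if p < alpha else STATUS_REJECTED
        records.append(
            DPMRecord(gene, observed, max_pairs, int(round(p * reps)), reps, p, status)
        )
    return records


def dpm_gene_list(records: Sequence[DPMRecord]) -> GeneList:
    """Genes with status ``dpm``, in record order."""
    return GeneList([r.gene_id for r in records if r.status == STATUS_DPM])
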