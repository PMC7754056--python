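"""Step 3: rank DPMs by association with a compensatory isoform ratio.

Some diseases have a known endogenous rescue route: a paralog whose
full-length (functional) isoform can substitute for the lost gene product,
with the full-length/truncated ratio marking how strongly that route is
engaged (the motivating instance is SMN2 exon-7 inclusion in spinal
muscular atrophy). This step asks, per DPM, whether *low* DPM expression in
healthy tissue associates with a *high* (> 1) full-length/truncated ratio,
via a one-sided rank-sum test, and ranks DPMs by that p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from .exceptions import DegeneratePartitionError, FormatError, ValueRangeError
from .expression_io import ExpressionMatrix
from .step2 import DPMRecord, STATUS_DPM

#: combined group size up to which the exact enumeration test is used
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class IsoformPair:
    """Per-sample abundances of a full-length and a truncated isoform."""

    sample_ids: list[str]
    fl_values: np.ndarray
    trunc_values: np.ndarray

    def __post_init__(self) -> None:
        self.fl_values = np.asarray(self.fl_values, dtype=float)
        self.trunc_values = np.asarray(self.trunc_values, dtype=float)
        n = len(self.sample_ids)
        if self.fl_values.shape != (n,) or self.trunc_values.shape != (n,):
            raise FormatError("isoform value arrays must align with sample_ids")
        for arr, name in ((self.fl_values, "full-length"), (self.trunc_values, "truncated")):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueRangeError(f"{name} isoform values must be finite and >= 0")


@dataclass
class RatioGroups:
    """Partition of samples by full-length vs truncated abundance.

    ``high``: FL strictly above truncated (ratio > 1, defined even when the
    truncated value is 0); ``low``: FL strictly below; samples with FL equal
    to truncated (including both zero) are excluded.
    """

    high_ratio_samples: list[str]
    low_ratio_samples: list[str]
    excluded_samples: list[str]


@dataclass
class Step3Result:
    gene_id: str
    p_ranksum: float
    rank: int


def read_isoforms(path: str | Path) -> IsoformPair:
    """Read a 3-column TSV: sample_id, full-length value, truncated value."""
    samples, fl, trunc = [], [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{line_no}: expected 3 columns")
            if line_no == 1:
                try:
                    float(parts[1])
                except ValueError:
                    continue  # header
            samples.append(parts[0])
            fl.append(float(parts[1]))
            trunc.append(float(parts[2]))
    return IsoformPair(samples, np.array(fl), np.array(trunc))


def ratio_groups(pair: IsoformPair) -> RatioGroups:
    """Split samples into high-ratio (FL > truncated) and low-ratio groups."""
    high = [s for s, f, t in zip(pair.sample_ids, pair.fl_values, pair.trunc_values) if f > t]
    low = [s for s, f, t in zip(pair.sample_ids, pair.fl_values, pair.trunc_values) if f < t]
    excluded = [s for s, f, t in zip(pair.sample_ids, pair.fl_values, pair.trunc_values) if f == t]
    if not high or not low:
        raise DegeneratePartitionError(
            f"degenerate ratio partition: {len(high)} high / {len(low)} low samples"
        )
    return RatioGroups(high, low, excluded)


def rank_sum_one_sided(
    values_high_group: Sequence[float], values_low_group: Sequence[float]
) -> float:
    """One-sided rank-sum p-value: is the high-ratio group's expression
    stochastically smaller than the low-ratio group's?

    Exact enumeration over all group labelings (ties handled by midranks,
    observed tables included — no mid-p) when the combined size is at most
    ``EXACT_ENUMERATION_LIMIT``; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(values_high_group, dtype=float)
    y = np.asarray(values_low_group, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= EXACT_ENUMERATION_LIMIT:
        return _exact_ranksum_p(x, y)
    res = mannwhitneyu(x, y, alternative="less", method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """P(rank sum of the first group <= observed) by full enumeration."""
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    n = x.size
    observed = ranks[:n].sum()
    total = 0
    at_most = 0
    for combo in itertools.combinations(range(combined.size), n):
        total += 1
        if sum(ranks[i] for i in combo) <= observed + 1e-9:
            at_most += 1
    return at_most / total


def run_step3(
    dpms: Sequence[DPMRecord],
    healthy: ExpressionMatrix,
    pair: IsoformPair,
) -> list[Step3Result]:
    """Rank DPMs by association of low expression with a high isoform ratio.

    Only records with status ``dpm`` are tested. Results are sorted by
    p-value ascending, ties broken by gene id; the top-ranked gene is the
    headline modifier candidate.
    """
    groups = ratio_groups(pair)
    hi_idx = healthy.sample_indices(groups.high_ratio_samples)
    lo_idx = healthy.sample_indices(groups.low_ratio_samples)
    results = []
    for rec in dpms:
        if rec.status != STATUS_DPM:
            continue
        row = healthy.row(rec.gene_id)
        p = rank_sum_one_sided(row[hi_idx], row[lo_idx])
        results.append((rec.gene_id, p))
    results.sort(key=lambda t: (t[1], t[0]))
    return [Step3Result(g, p, i + 1) for i, (g, p) in enumerate(results)]
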