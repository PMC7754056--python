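"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the shapes the pipeline consumes: a large healthy
cohort with heavy-tailed non-negative expression (log-normal marginals), a
small case-control study on a different measurement scale, planted
modifiers whose low expression co-occurs with low GCD expression in healthy
samples but which are *not* downregulated in cases, and decoy genes that
track the GCD in both settings. Co-occurrence is induced by a bivariate
Gaussian copula on the latent scale, the minimal model that produces
lower-tail dependence without dictating global linear correlation.

Gene label semantics
--------------------
``gcd``                    the gene causal of disease (exactly one)
``planted_pm_true_dpm``    co-low with the GCD in health, unaffected in cases
``step3_modifier``         a true DPM that additionally drives the isoform ratio
``planted_pm_decoy``       co-low in health AND downregulated in cases
``coregulated_decoy``      like a planted decoy, bookkept separately
``background``             independent of everything
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, ndtri

from .exceptions import SpecificationError
from .expression_io import CaseControlStudy, ExpressionMatrix
from .step3 import IsoformPair

LABEL_GCD = "gcd"
LABEL_TRUE_DPM = "planted_pm_true_dpm"
LABEL_STEP3 = "step3_modifier"
LABEL_PM_DECOY = "planted_pm_decoy"
LABEL_COREG_DECOY = "coregulated_decoy"
LABEL_BACKGROUND = "background"

GCD_ID = "GCD"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic study.

    Defaults are the desk-scale study conditions: a 400-sample, 1,000-gene
    healthy cohort with 50 planted PMs coupled to the GCD at latent
    correlation 0.9, of which 20 are true DPMs (5 of those also drive the
    isoform ratio), plus 20 co-regulated decoys; a 7+7 case-control study
    whose cases carry GCD expression below the healthy 2nd percentile and
    whose decoys drop to 0.3x in cases.
    """

    n_samples: int = 400
    n_genes: int = 1000
    n_planted_pm: int = 50
    n_decoy_coregulated: int = 20
    n_true_dpm: int = 20
    n_step3_modifiers: int = 5
    coupling_rho: float = 0.9
    marginal_log_mean: float = 1.0
    marginal_log_sd: float = 0.5
    case_gcd_quantile: float = 0.02
    decoy_case_effect: float = 0.3
    noise_sd: float = 0.15
    platform_scale: float = 100.0
    isoform_link_weight: float = 6.0
    n_cases: int = 7
    n_controls: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_pm + self.n_decoy_coregulated >= self.n_genes:
            raise SpecificationError("planted + decoy genes must be fewer than n_genes")
        if not 0 <= self.n_true_dpm <= self.n_planted_pm:
            raise SpecificationError("n_true_dpm must be within [0, n_planted_pm]")
        if not 0 <= self.n_step3_modifiers <= self.n_true_dpm:
            raise SpecificationError("n_step3_modifiers must be within [0, n_true_dpm]")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise SpecificationError("coupling_rho must be in [0, 1]")
        if not 0.0 < self.case_gcd_quantile < 1.0:
            raise SpecificationError("case_gcd_quantile must be in (0, 1)")
        if not 0.0 < self.decoy_case_effect <= 1.0:
            raise SpecificationError("decoy_case_effect must be in (0, 1]")
        if min(self.n_samples, self.n_genes, self.n_cases, self.n_controls) < 1:
            raise SpecificationError("sample and gene counts must be positive")
        if self.platform_scale <= 0:
            raise SpecificationError("platform_scale must be positive")


@dataclass
class SyntheticTruth:
    """Ground-truth gene labels emitted alongside a simulated cohort."""

    labels: dict[str, str]
    spec: CohortSpec

    def genes_with(self, *wanted: str) -> list[str]:
        return [g for g, lab in self.labels.items() if lab in wanted]

    @property
    def gcd_id(self) -> str:
        (g,) = self.genes_with(LABEL_GCD)
        return g

    @property
    def planted_pm_ids(self) -> list[str]:
        return self.genes_with(LABEL_TRUE_DPM, LABEL_STEP3, LABEL_PM_DECOY)

    @property
    def true_dpm_ids(self) -> list[str]:
        return self.genes_with(LABEL_TRUE_DPM, LABEL_STEP3)

    @property
    def decoy_ids(self) -> list[str]:
        return self.genes_with(LABEL_PM_DECOY, LABEL_COREG_DECOY)

    @property
    def step3_modifier_ids(self) -> list[str]:
        return self.genes_with(LABEL_STEP3)

    @property
    def background_ids(self) -> list[str]:
        return self.genes_with(LABEL_BACKGROUND)


def _gene_names(spec: CohortSpec) -> tuple[list[str], dict[str, str]]:
    """Gene ids and their truth labels, in matrix row order."""
    labels: dict[str, str] = {GCD_ID: LABEL_GCD}
    names = [GCD_ID]
    counters = {
        LABEL_STEP3: spec.n_step3_modifiers,
        LABEL_TRUE_DPM: spec.n_true_dpm - spec.n_step3_modifiers,
        LABEL_PM_DECOY: spec.n_planted_pm - spec.n_true_dpm,
        LABEL_COREG_DECOY: spec.n_decoy_coregulated,
    }
    prefixes = {
        LABEL_STEP3: "S3MOD",
        LABEL_TRUE_DPM: "TDPM",
        LABEL_PM_DECOY: "PMDEC",
        LABEL_COREG_DECOY: "CODEC",
    }
    for label, count in counters.items():
        for i in range(count):
            g = f"{prefixes[label]}{i:04d}"
            names.append(g)
            labels[g] = label
    n_background = spec.n_genes - len(names)
    for i in range(n_background):
        g = f"BG{i:04d}"
        names.append(g)
        labels[g] = LABEL_BACKGROUND
    return names, labels


def simulate_healthy(spec: CohortSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate the healthy cohort.

    GCD and background genes are independent log-normals. Every planted PM
    and decoy shares a Gaussian copula with the GCD's latent variable at
    correlation ``coupling_rho``, so their bottom-decile co-occurrence
    exceeds the independence baseline; decoys are generated identically to
    planted PMs and differ only in the case-control stage. Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    names, labels = _gene_names(spec)
    truth = SyntheticTruth(labels, spec)
    s = spec.n_samples
    z = np.empty((spec.n_genes, s))
    z_gcd = rng.standard_normal(s)
    rho = spec.coupling_rho
    coupled = {LABEL_TRUE_DPM, LABEL_STEP3, LABEL_PM_DECOY, LABEL_COREG_DECOY}
    for i, g in enumerate(names):
        lab = labels[g]
        if lab == LABEL_GCD:
            z[i] = z_gcd
        elif lab in coupled:
            z[i] = rho * z_gcd + np.sqrt(1.0 - rho**2) * rng.standard_normal(s)
        else:
            z[i] = rng.standard_normal(s)
    values = np.exp(spec.marginal_log_mean + spec.marginal_log_sd * z)
    sample_ids = [f"H{i:04d}" for i in range(s)]
    return ExpressionMatrix(names, sample_ids, values), truth


def simulate_case_control(spec: CohortSpec, truth: SyntheticTruth) -> CaseControlStudy:
    """Simulate the case-control study implied by the truth labels.

    Cases carry GCD expression below the ``case_gcd_quantile`` of the
    healthy marginal; true DPMs follow their unconditional healthy marginal
    in both arms (not downregulated in disease); decoys are multiplied by
    ``decoy_case_effect`` in cases (they track the GCD); background is
    unchanged. The whole matrix is then moved to a different measurement
    platform: one global positive scale factor plus multiplicative
    log-normal noise of width ``noise_sd``.
    """
    if truth.spec != spec:
        raise SpecificationError("truth was generated under a different spec")
    rng = np.random.default_rng([spec.seed, 1])
    names = [truth.gcd_id] + truth.true_dpm_ids + truth.decoy_ids + truth.background_ids
    # keep healthy matrix row order for readability
    order = {g: i for i, g in enumerate(truth.labels)}
    names.sort(key=order.__getitem__)
    n_case, n_ctrl = spec.n_cases, spec.n_controls
    n_tot = n_case + n_ctrl
    mu, sd = spec.marginal_log_mean, spec.marginal_log_sd
    decoys = set(truth.decoy_ids)

    values = np.empty((len(names), n_tot))
    for i, g in enumerate(names):
        if truth.labels[g] == LABEL_GCD:
            u = rng.uniform(0.0, spec.case_gcd_quantile, size=n_case)
            cases = np.exp(mu + sd * ndtri(u))
            ctrls = np.exp(mu + sd * rng.standard_normal(n_ctrl))
        else:
            cases = np.exp(mu + sd * rng.standard_normal(n_case))
            ctrls = np.exp(mu + sd * rng.standard_normal(n_ctrl))
            if g in decoys:
                cases = cases * spec.decoy_case_effect
        values[i, :n_case] = cases
        values[i, n_case:] = ctrls
    noise = np.exp(spec.noise_sd * rng.standard_normal(values.shape))
    values = values * noise * spec.platform_scale
    case_ids = [f"CASE{i:02d}" for i in range(n_case)]
    ctrl_ids = [f"CTRL{i:02d}" for i in range(n_ctrl)]
    matrix = ExpressionMatrix(names, case_ids + ctrl_ids, values)
    return CaseControlStudy(matrix, case_ids, ctrl_ids)


def simulate_isoforms(
    spec: CohortSpec, truth: SyntheticTruth, healthy: ExpressionMatrix
) -> IsoformPair:
    """Simulate a full-length / truncated isoform pair over healthy samples.

    Per sample, the probability that the full-length isoform exceeds the
    truncated one rises as the planted step-3 modifiers' expression falls:
    a logistic link on the mean negated z-score of the modifiers, with
    weight ``isoform_link_weight``. Non-modifier genes have no effect.
    """
    if truth.spec != spec:
        raise SpecificationError("truth was generated under a different spec")
    mods = truth.step3_modifier_ids
    if not mods:
        raise SpecificationError("truth contains no step3_modifier gene")
    rng = np.random.default_rng([spec.seed, 2])
    rows = np.stack([np.log(healthy.row(g) + 1e-12) for g in mods])
    zs = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, keepdims=True)
    score = -zs.mean(axis=0)
    p_high = expit(spec.isoform_link_weight * score)
    high = rng.random(healthy.n_samples) < p_high
    a = np.exp(spec.marginal_log_mean + spec.marginal_log_sd * rng.standard_normal(healthy.n_samples))
    b = np.exp(spec.marginal_log_mean + spec.marginal_log_sd * rng.standard_normal(healthy.n_samples))
    hi, lo = np.maximum(a, b), np.minimum(a, b)
    fl = np.where(high, hi, lo)
    trunc = np.where(high, lo, hi)
    return IsoformPair(list(healthy.sample_ids), fl, trunc)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the per-gene truth labels as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\n")
        for g, lab in truth.labels.items():
            fh.write(f"{g}\t{lab}\n")
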