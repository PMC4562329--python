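"""Polygenic risk scoring and cognitive-ability moderation analysis for Type 2 diabetes.

This module implements, end to end, an analysis pipeline asking whether a
continuous moderator (childhood cognitive ability) alters how Type 2 diabetes
(T2D) polygenic risk manifests in later life:

1. **Synthetic cohort generation** — Hardy–Weinberg genotypes, GWAS-style
   summary statistics with estimation noise, and phenotypes (HbA1c in
   mmol/mol and a liability-threshold binary diabetes status) generated from
   a linear predictor ``b_s·S + b_m·M + b_i·S·M`` where ``S`` is the
   standardized true polygenic score and ``M`` the moderator.
2. **PRS engine** — allele harmonization between summary statistics and a
   genotype matrix (direct match / allele swap / strand complement /
   ambiguous exclusion), weighted-sum scoring with missing-dosage policies,
   and a family of p-value-thresholded score variants.
3. **Interaction analysis** — descriptive prevalences, linear (HbA1c) and
   logistic (diabetes) main-effect and score×moderator interaction models
   with standardized coefficients and odds ratios per SD, median-split
   stratified effect sizes, and sensitivity refits (sample exclusion or
   covariate addition).
4. **IO & pipeline** — TSV/CSV/VCF readers and writers, a YAML run
   configuration, and a deterministic multi-stage pipeline with a manifest.

Sections appear in the order the method runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "GenotypeMatrix",
    "RiskScoreSet",
    "HarmonizationReport",
    "TermEstimate",
    "ModelFit",
    "StratifiedResult",
    "SensitivityResult",
    "ModerationResult",
    "RunConfig",
    "ValidationError",
    "EmptyOverlapError",
    "DegenerateScoreError",
    "SeparationError",
    "PipelineError",
    "simulate_genotypes",
    "simulate_summary_stats",
    "simulate_cohort",
    "calibrate_stratified_effects",
    "validate_summary_stats",
    "harmonize",
    "compute_score",
    "threshold_scores",
    "standardize",
    "describe_prevalence",
    "fit_linear",
    "fit_logistic",
    "fit_moderation",
    "median_split_analysis",
    "sensitivity_refit",
    "plot_interaction",
    "read_summary_stats",
    "write_summary_stats",
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_scores",
    "write_scores",
    "write_harmonization_report",
    "write_cohort",
    "run_pipeline",
    "DEFAULT_THRESHOLDS",
]

# --------------------------------------------------------------------------
# configuration constants & logging
# --------------------------------------------------------------------------

logger = logging.getLogger("prsmod")

#: p-value inclusion grid: one primary (all SNPs) plus seven increasingly
#: stringent score variants.
DEFAULT_THRESHOLDS: tuple[float, ...] = (1.0, 0.5, 0.1, 0.05, 0.01, 1e-3, 1e-4, 5e-8)

#: HbA1c diagnostic cutoff, mmol/mol (IFCC); 48 mmol/mol == 6.5% DCCT.
DEFAULT_HBA1C_CUTOFF = 48.0

NUCLEOTIDES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: A/T and C/G pairs are their own reverse complements: strand orientation
#: cannot be resolved from allele labels alone.
AMBIGUOUS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})

_TINY_P = float(np.nextafter(0, 1))  # p-values are clamped into (0, 1]
_HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)  # E[|Z|] = E[Z | Z>0] for Z~N(0,1)


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class EmptyOverlapError(ValidationError):
    """Harmonization retained zero SNPs."""


class DegenerateScoreError(ValidationError):
    """A score vector has zero variance and cannot be standardized."""


class SeparationError(RuntimeError):
    """Logistic fit shows complete or quasi-complete separation."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


def _clamp_p(p):
    """Clamp p-values into (0, 1]; underflow to 0 becomes the smallest float."""
    return np.clip(np.asarray(p, dtype=float), _TINY_P, 1.0)


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Per-sample risk-allele dosages at a set of biallelic SNPs.

    ``dosages`` is an ``(n_samples, n_snps)`` float array with values in
    {0, 1, 2} counting copies of ``counted_allele``; missing genotypes are
    ``NaN``.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.counted_allele = np.asarray(self.counted_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match dosage rows")
        for name, arr in (
            ("snp_ids", self.snp_ids),
            ("counted_allele", self.counted_allele),
            ("other_allele", self.other_allele),
        ):
            if len(arr) != m:
                raise ValidationError(f"{name} length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in genotype matrix")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("duplicate SNP ids in genotype matrix")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, snp_indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(snp_indices)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[idx],
            counted_allele=self.counted_allele[idx],
            other_allele=self.other_allele[idx],
            dosages=self.dosages[:, idx].copy(),
        )


@dataclass
class RiskScoreSet:
    """Per-sample polygenic scores at each p-value inclusion threshold.

    ``raw`` and ``z`` are ``(n_samples, n_thresholds)``; ``z`` columns have
    mean 0 and sample SD 1 (n−1 denominator) except for columns flagged in
    ``degenerate`` (no SNP retained, or zero score variance), which are NaN.
    """

    sample_ids: np.ndarray
    thresholds: np.ndarray
    raw: np.ndarray
    z: np.ndarray
    n_snps_per_threshold: np.ndarray
    degenerate: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"sample_id": self.sample_ids}
        for k, t in enumerate(self.thresholds):
            cols[f"raw_{t:g}"] = self.raw[:, k]
            cols[f"z_{t:g}"] = self.z[:, k]
        return pd.DataFrame(cols)


@dataclass
class HarmonizationReport:
    """Machine-readable accounting of per-SNP harmonization dispositions.

    The five count fields partition the summary-statistics SNP set:
    ``n_strand_complemented`` includes strand+swap SNPs; ``n_unmatched``
    includes both absent-from-genotypes and allele-incompatible SNPs.
    """

    n_matched: int
    n_allele_flipped: int
    n_strand_complemented: int
    n_ambiguous_excluded: int
    n_unmatched: int
    table: pd.DataFrame
    n_genotype_only: int = 0

    @property
    def n_input(self) -> int:
        return (
            self.n_matched
            + self.n_allele_flipped
            + self.n_strand_complemented
            + self.n_ambiguous_excluded
            + self.n_unmatched
        )

    def summary(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "n_allele_flipped": self.n_allele_flipped,
            "n_strand_complemented": self.n_strand_complemented,
            "n_ambiguous_excluded": self.n_ambiguous_excluded,
            "n_unmatched": self.n_unmatched,
            "n_genotype_only": self.n_genotype_only,
        }


@dataclass
class TermEstimate:
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ModelFit:
    """One fitted regression model.

    For ``family == "linear"`` the coefficients are standardized βs (outcome
    and continuous predictors z-scored before fitting); for logistic models
    the continuous predictors are z-scored and ``odds_ratios_per_sd`` maps
    each to ``(OR, ci_low, ci_high)``.
    """

    outcome_name: str
    family: str
    terms: dict[str, TermEstimate]
    standardized_betas: dict[str, float]
    odds_ratios_per_sd: dict[str, tuple[float, float, float]]
    n_used: int
    converged: bool

    def term(self, name: str) -> TermEstimate:
        return self.terms[name]

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "family": self.family,
            "n_used": self.n_used,
            "converged": self.converged,
            "terms": {k: dataclasses.asdict(v) for k, v in self.terms.items()},
            "standardized_betas": self.standardized_betas,
            "odds_ratios_per_sd": {
                k: list(v) for k, v in self.odds_ratios_per_sd.items()
            },
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, t in self.terms.items():
            row = {
                "term": name,
                "estimate": t.estimate,
                "std_error": t.std_error,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p_value": t.p_value,
            }
            if name in self.standardized_betas:
                row["standardized_beta"] = self.standardized_betas[name]
            if name in self.odds_ratios_per_sd:
                orr, lo, hi = self.odds_ratios_per_sd[name]
                row["or_per_sd"] = orr
                row["or_ci_low"] = lo
                row["or_ci_high"] = hi
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class StratifiedResult:
    """Median-split moderation analysis: per-stratum fits and effect sizes."""

    split_variable: str
    split_value: float
    low_group: ModelFit
    high_group: ModelFit
    effect_r_low: float
    effect_r_high: float
    n_low: int
    n_high: int

    def to_dict(self) -> dict:
        return {
            "split_variable": self.split_variable,
            "split_value": self.split_value,
            "effect_r_low": self.effect_r_low,
            "effect_r_high": self.effect_r_high,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "low_group": self.low_group.to_dict(),
            "high_group": self.high_group.to_dict(),
        }


@dataclass
class SensitivityResult:
    baseline: ModelFit
    sensitivity: ModelFit
    delta_score: float
    delta_interaction: float | None

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "sensitivity": self.sensitivity.to_dict(),
            "delta_score": self.delta_score,
            "delta_interaction": self.delta_interaction,
        }


@dataclass
class ModerationResult:
    """score×moderator interaction fits across the threshold grid."""

    fits: dict[float, ModelFit]
    summary: pd.DataFrame


# --------------------------------------------------------------------------
# synthetic data: genotypes, summary statistics, cohort
# --------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Generative settings for a synthetic cohort.

    Defaults emulate the study conditions the pipeline targets: 940
    relatively healthy older adults, 8.8% diabetes prevalence, a polygenic
    score aggregating many small effects, and a score→HbA1c slope that is
    stronger below the moderator's median than above it.

    ``noise_sd=None`` completes the continuous-outcome variance to 1 given
    the three betas, so the betas are standardized-scale estimands.
    """

    n_samples: int = 940
    n_snps: int = 2000
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    effect_sd: float = 0.05
    frac_null_snps: float = 0.9
    beta_score_main: float = 0.16
    beta_moderator_main: float = -0.13
    beta_interaction: float = -0.08
    noise_sd: float | None = None
    disease_liability_threshold: float = 0.912
    seed: int = 0
    # secondary knobs
    frac_ambiguous: float = 0.1
    frac_swapped: float = 0.2
    frac_strand_flipped: float = 0.1
    gwas_n: float | None = 150_000.0
    moderator_score_corr: float = 0.0
    hba1c_mean: float = 38.0
    hba1c_sd: float = 6.0
    frac_insulin_among_cases: float = 11.0 / 83.0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("allele_freq_range must satisfy 0 < lo <= hi < 1")
        if not 0 <= self.frac_null_snps <= 1:
            raise ValidationError("frac_null_snps must be in [0, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 < self.disease_liability_threshold < 1:
            raise ValidationError("disease_liability_threshold must be in (0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        if not -1 < self.moderator_score_corr < 1:
            raise ValidationError("moderator_score_corr must be in (-1, 1)")

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        explained = (
            self.beta_score_main**2
            + self.beta_moderator_main**2
            + self.beta_interaction**2
        )
        if explained >= 1.0:
            raise ValidationError(
                "betas explain >= 100% variance; pass noise_sd explicitly"
            )
        return math.sqrt(1.0 - explained)


@dataclass
class SimulatedCohort:
    """Ground-truth-carrying synthetic cohort for parameter-recovery tests."""

    genotypes: GenotypeMatrix
    summary_stats: pd.DataFrame
    phenotypes: pd.DataFrame
    true_effects: np.ndarray
    true_betas: dict[str, float]
    true_score: np.ndarray


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage substream seeds derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) % (2**31) for s in state]


def _draw_allele_pairs(
    n_snps: int, frac_ambiguous: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    ordered = [
        (a, b) for a in NUCLEOTIDES for b in NUCLEOTIDES if a != b
    ]  # 12 ordered pairs
    ambiguous = [p for p in ordered if frozenset(p) in AMBIGUOUS_PAIRS]
    unambiguous = [p for p in ordered if frozenset(p) not in AMBIGUOUS_PAIRS]
    is_amb = rng.random(n_snps) < frac_ambiguous
    counted = np.empty(n_snps, dtype=object)
    other = np.empty(n_snps, dtype=object)
    amb_idx = rng.integers(0, len(ambiguous), size=n_snps)
    una_idx = rng.integers(0, len(unambiguous), size=n_snps)
    for j in range(n_snps):
        counted[j], other[j] = (
            ambiguous[amb_idx[j]] if is_amb[j] else unambiguous[una_idx[j]]
        )
    return counted, other


def simulate_genotypes(
    n_samples: int,
    allele_freqs: Sequence[float],
    seed: int,
    *,
    frac_ambiguous: float = 0.0,
    snp_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Draw Hardy–Weinberg genotypes: dosage_ij ~ Binomial(2, freq_j), iid.

    Frequencies of exactly 0 or 1 are allowed for degenerate edge cases.
    No missingness is generated.
    """
    freqs = np.asarray(allele_freqs, dtype=float)
    bad = ~np.isfinite(freqs) | (freqs < 0) | (freqs > 1)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"allele frequency at SNP index {j} is invalid: {freqs[j]!r}"
        )
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    m = len(freqs)
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, freqs, size=(n_samples, m)).astype(float)
    counted, other = _draw_allele_pairs(m, frac_ambiguous, rng)
    if snp_ids is None:
        snp_ids = [f"rs{j + 1:06d}" for j in range(m)]
    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        snp_ids=np.array(list(snp_ids), dtype=object),
        counted_allele=counted,
        other_allele=other,
        dosages=dosages,
    )


def simulate_summary_stats(
    genotypes: GenotypeMatrix,
    effect_sd: float,
    frac_null_snps: float,
    seed: int,
    *,
    gwas_n: float | None = 150_000.0,
    frac_swapped: float = 0.0,
    frac_strand_flipped: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Emulate external meta-analytic summary statistics for the cohort's SNPs.

    True per-SNP effects (log-OR per counted-allele copy) are drawn
    ``N(0, effect_sd^2)`` with an exact ``frac_null_snps`` fraction set to 0.
    Reported effects add estimation noise with the GWAS-scale standard error
    ``se_j = 1 / sqrt(2 f_j (1 - f_j) gwas_n)`` and reported p-values are the
    two-sided normal tail of ``beta_hat/se`` — so p-value thresholding
    enriches for truly non-null SNPs, and under the global null p-values are
    Uniform(0, 1). ``gwas_n=None`` disables estimation noise (reported
    effect = true effect; p = 1 where the effect is 0).

    A ``frac_swapped`` fraction reports the genotype *other* allele as
    effect allele (sign and EAF adjusted) and a ``frac_strand_flipped``
    fraction reports complementary-strand labels, to exercise harmonization.
    Returned ``true_effects`` always refer to the genotype counted allele.
    """
    if effect_sd < 0:
        raise ValidationError("effect_sd must be >= 0")
    if not 0 <= frac_null_snps <= 1:
        raise ValidationError("frac_null_snps must be in [0, 1]")
    m = genotypes.n_snps
    rng = np.random.default_rng(seed)
    true = (
        rng.normal(0.0, effect_sd, size=m) if effect_sd > 0 else np.zeros(m)
    )
    n_null = int(round(frac_null_snps * m))
    if n_null:
        null_idx = rng.choice(m, size=n_null, replace=False)
        true[null_idx] = 0.0

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(genotypes.dosages, axis=0) / 2.0
    freq = np.where(np.isfinite(freq), freq, 0.5)
    freq_c = np.clip(freq, 0.01, 0.99)

    if gwas_n is None:
        se = np.zeros(m)
        beta_hat = true.copy()
        p = np.where(beta_hat == 0.0, 1.0, _TINY_P)
    else:
        se = 1.0 / np.sqrt(2.0 * freq_c * (1.0 - freq_c) * float(gwas_n))
        beta_hat = true + rng.normal(0.0, 1.0, size=m) * se
        p = 2.0 * sps.norm.sf(np.abs(beta_hat) / se)
    p = _clamp_p(p)

    ea = genotypes.counted_allele.copy()
    oa = genotypes.other_allele.copy()
    eaf = freq.copy()
    swapped = rng.random(m) < frac_swapped
    flipped = rng.random(m) < frac_strand_flipped
    ea[swapped], oa[swapped] = oa[swapped], ea[swapped].copy()
    beta_hat = np.where(swapped, -beta_hat, beta_hat)
    eaf = np.where(swapped, 1.0 - eaf, eaf)
    comp = np.vectorize(COMPLEMENT.get)
    if flipped.any():
        ea[flipped] = comp(ea[flipped].astype(str))
        oa[flipped] = comp(oa[flipped].astype(str))

    stats = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "effect_allele": ea,
            "other_allele": oa,
            "effect_size": beta_hat,
            "p_value": p,
            "eaf": eaf,
        }
    )
    return stats, true


def calibrate_stratified_effects(
    r_low: float, r_high: float, beta_moderator: float = -0.13
) -> tuple[float, float, float]:
    """Solve for ``(beta_score_main, beta_interaction, noise_sd)`` hitting
    target score–outcome Pearson correlations below/above the moderator
    median.

    Under the generative model with S ⟂ M, both standard normal, and total
    outcome variance 1, the within-stratum correlation is::

        r_g = (b_s + b_i m_g) / sqrt(1 - b_m^2 (2/pi) + 2 b_s b_i m_g)

    with ``m_g = ∓ sqrt(2/pi)`` the truncated-normal stratum mean of M.
    """
    mu = _HALF_NORMAL_MEAN
    a = 1.0 - beta_moderator**2 * (2.0 / math.pi)

    def equations(x):
        bs, bi = x
        return [
            (bs - mu * bi) / math.sqrt(a - 2.0 * mu * bs * bi) - r_low,
            (bs + mu * bi) / math.sqrt(a + 2.0 * mu * bs * bi) - r_high,
        ]

    x0 = [(r_low + r_high) / 2.0, -(r_low - r_high) / (2.0 * mu)]
    sol, info, ier, msg = optimize.fsolve(equations, x0, full_output=True)
    if ier != 1 or max(abs(v) for v in equations(sol)) > 1e-10:
        raise ValidationError(f"stratified-effect calibration failed: {msg}")
    bs, bi = float(sol[0]), float(sol[1])
    explained = bs**2 + bi**2 + beta_moderator**2
    if explained >= 1.0:
        raise ValidationError("calibration targets imply > 100% explained variance")
    return bs, bi, math.sqrt(1.0 - explained)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort: genotypes, summary stats, and phenotypes.

    The continuous outcome follows ``y = b_s S + b_m M + b_i S·M + e`` with
    ``S`` the standardized true-effect polygenic score and ``M`` a standard
    normal moderator (independent of genotype unless
    ``moderator_score_corr`` is set), then is affinely mapped to the HbA1c
    scale (default mean 38, SD 6 mmol/mol). The binary outcome thresholds a
    second, independently noised liability with the same linear predictor at
    its empirical ``disease_liability_threshold`` quantile, so the realized
    prevalence matches the target (0.912 → 8.8% cases).

    Randomness is governed by ``config.seed`` through four documented
    substreams (allele frequencies, genotypes, summary statistics,
    phenotypes), so identical configs give bit-identical cohorts.
    """
    config.validate()
    s_freq, s_geno, s_stats, s_pheno = _stage_seeds(config.seed, 4)
    lo, hi = config.allele_freq_range
    freqs = np.random.default_rng(s_freq).uniform(lo, hi, size=config.n_snps)
    genotypes = simulate_genotypes(
        config.n_samples, freqs, s_geno, frac_ambiguous=config.frac_ambiguous
    )
    stats, true_effects = simulate_summary_stats(
        genotypes,
        config.effect_sd,
        config.frac_null_snps,
        s_stats,
        gwas_n=config.gwas_n,
        frac_swapped=config.frac_swapped,
        frac_strand_flipped=config.frac_strand_flipped,
    )

    rng = np.random.default_rng(s_pheno)
    n = config.n_samples
    raw_score = genotypes.dosages @ true_effects
    sd = float(np.std(raw_score, ddof=1))
    if sd > 0:
        score = (raw_score - raw_score.mean()) / sd
    else:
        score = np.zeros(n)
    moderator = rng.standard_normal(n)
    rho = config.moderator_score_corr
    if rho != 0.0 and sd > 0:
        moderator = rho * score + math.sqrt(1.0 - rho**2) * moderator

    noise_sd = config.resolved_noise_sd()
    linpred = (
        config.beta_score_main * score
        + config.beta_moderator_main * moderator
        + config.beta_interaction * score * moderator
    )
    y = linpred + rng.normal(0.0, noise_sd, size=n)
    ysd = float(np.std(y, ddof=1))
    if ysd > 0:
        hba1c = config.hba1c_mean + config.hba1c_sd * (y - y.mean()) / ysd
    else:
        hba1c = np.full(n, config.hba1c_mean)

    liability = linpred + rng.normal(0.0, noise_sd, size=n)
    threshold = float(np.quantile(liability, config.disease_liability_threshold))
    diabetes = (liability > threshold).astype(int)

    insulin = np.zeros(n, dtype=int)
    cases = np.flatnonzero(diabetes == 1)
    if cases.size:
        insulin[cases] = (
            rng.random(cases.size) < config.frac_insulin_among_cases
        ).astype(int)

    phenotypes = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "hba1c": hba1c,
            "diabetes": diabetes,
            "moderator": moderator,
            "age": rng.normal(69.55, 0.85, size=n),
            "sex": rng.integers(0, 2, size=n),
            "bmi": rng.normal(27.5, 4.4, size=n),
            "insulin_therapy": insulin,
        }
    )
    true_betas = {
        "score": config.beta_score_main,
        "moderator": config.beta_moderator_main,
        "interaction": config.beta_interaction,
    }
    return SimulatedCohort(
        genotypes=genotypes,
        summary_stats=stats,
        phenotypes=phenotypes,
        true_effects=true_effects,
        true_betas=true_betas,
        true_score=score,
    )


# --------------------------------------------------------------------------
# PRS engine: harmonization, scoring, thresholding, standardization
# --------------------------------------------------------------------------

_STATS_COLUMNS = ("snp_id", "effect_allele", "other_allele", "effect_size", "p_value")


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Validate canonical summary-statistics columns; returns a clean copy."""
    missing = [c for c in _STATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValidationError(
            f"summary statistics missing columns {missing}; found {list(stats.columns)}"
        )
    out = stats.reset_index(drop=True).copy()
    if out["snp_id"].duplicated().any():
        dup = out.loc[out["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValidationError(f"duplicate SNP id in summary statistics: {dup!r}")
    p = out["p_value"].to_numpy(dtype=float)
    if not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any():
        bad = int(np.flatnonzero(~np.isfinite(p) | (p <= 0) | (p > 1))[0])
        raise ValidationError(
            f"p_value must be in (0, 1]; offending SNP {out['snp_id'].iloc[bad]!r}"
        )
    same = out["effect_allele"].astype(str) == out["other_allele"].astype(str)
    if same.any():
        raise ValidationError(
            f"effect and other allele identical for SNP "
            f"{out.loc[same, 'snp_id'].iloc[0]!r}"
        )
    return out


def harmonize(
    stats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    drop_ambiguous: bool = True,
) -> tuple[pd.DataFrame, GenotypeMatrix, HarmonizationReport]:
    """Align summary statistics with genotypes so every retained SNP's
    effect allele equals the counted genotype allele.

    Resolution order per SNP: direct allele match; allele swap (dosage
    recoded ``d → 2−d``); strand complement then match or swap. A/T and C/G
    SNPs are excluded when ``drop_ambiguous`` (default) because their strand
    cannot be resolved from labels. SNPs absent from the genotypes or with
    incompatible alleles are dropped and counted as unmatched.
    """
    stats = validate_summary_stats(stats)
    geno_index = {s: j for j, s in enumerate(genotypes.snp_ids)}

    dispositions: list[str] = []
    kept: list[tuple[int, int, bool]] = []  # (stats row, geno col, flip)
    for i, row in enumerate(stats.itertuples(index=False)):
        snp = row.snp_id
        j = geno_index.get(snp)
        if j is None:
            dispositions.append("unmatched_absent")
            continue
        ea, oa = str(row.effect_allele), str(row.other_allele)
        if drop_ambiguous and frozenset((ea, oa)) in AMBIGUOUS_PAIRS:
            dispositions.append("ambiguous_excluded")
            continue
        ca = str(genotypes.counted_allele[j])
        og = str(genotypes.other_allele[j])
        cea, coa = COMPLEMENT.get(ea), COMPLEMENT.get(oa)
        if (ea, oa) == (ca, og):
            dispositions.append("matched")
            kept.append((i, j, False))
        elif (ea, oa) == (og, ca):
            dispositions.append("allele_flipped")
            kept.append((i, j, True))
        elif (cea, coa) == (ca, og):
            dispositions.append("strand_complemented")
            kept.append((i, j, False))
        elif (cea, coa) == (og, ca):
            dispositions.append("strand_complemented_flipped")
            kept.append((i, j, True))
        else:
            dispositions.append("unmatched_alleles")

    table = pd.DataFrame(
        {"snp_id": stats["snp_id"], "disposition": dispositions}
    )
    counts = table["disposition"].value_counts()
    report = HarmonizationReport(
        n_matched=int(counts.get("matched", 0)),
        n_allele_flipped=int(counts.get("allele_flipped", 0)),
        n_strand_complemented=int(
            counts.get("strand_complemented", 0)
            + counts.get("strand_complemented_flipped", 0)
        ),
        n_ambiguous_excluded=int(counts.get("ambiguous_excluded", 0)),
        n_unmatched=int(
            counts.get("unmatched_absent", 0) + counts.get("unmatched_alleles", 0)
        ),
        table=table,
        n_genotype_only=genotypes.n_snps - len({s for s in stats["snp_id"]} & geno_index.keys()),
    )
    logger.info("harmonization dispositions: %s", report.summary())
    if not kept:
        raise EmptyOverlapError(
            "no SNP retained after harmonization (empty overlap)"
        )

    kept.sort(key=lambda t: t[1])  # genotype column order
    stat_rows = [i for i, _, _ in kept]
    geno_cols = np.array([j for _, j, _ in kept])
    flips = np.array([f for _, _, f in kept])

    aligned_stats = stats.iloc[stat_rows].reset_index(drop=True)
    sub = genotypes.subset(geno_cols)
    dos = sub.dosages
    dos[:, flips] = 2.0 - dos[:, flips]
    aligned_genos = GenotypeMatrix(
        sample_ids=sub.sample_ids,
        snp_ids=sub.snp_ids,
        counted_allele=aligned_stats["effect_allele"].to_numpy(dtype=object),
        other_allele=aligned_stats["other_allele"].to_numpy(dtype=object),
        dosages=dos,
    )
    return aligned_stats, aligned_genos, report


def compute_score(
    genotypes: GenotypeMatrix,
    weights: Sequence[float],
    missing_policy: str = "mean_impute",
) -> np.ndarray:
    """Weighted risk-allele sum: ``score_i = Σ_j w_j · d_ij``.

    Missing dosages are handled per policy: ``mean_impute`` replaces a
    missing dosage by that SNP's sample mean; ``omit_and_rescale`` drops the
    term and rescales the sample's sum by (total SNPs / observed SNPs).
    Accumulation is per-SNP sequential, so the result is bit-identical to a
    per-sample left-to-right loop-and-sum.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (genotypes.n_snps,):
        raise ValidationError("weights length does not match SNP count")
    if missing_policy not in ("mean_impute", "omit_and_rescale"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    d = genotypes.dosages
    miss = np.isnan(d)
    n = genotypes.n_samples
    scores = np.zeros(n)
    if missing_policy == "mean_impute":
        if miss.any():
            n_obs = (~miss).sum(axis=0)
            if (n_obs == 0).any():
                snp = genotypes.snp_ids[int(np.flatnonzero(n_obs == 0)[0])]
                raise ValidationError(
                    f"SNP {snp!r} has all dosages missing; cannot mean-impute"
                )
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(d, axis=0)
            d = np.where(miss, col_mean, d)
        for j in range(d.shape[1]):
            scores += w[j] * d[:, j]
    else:  # omit_and_rescale
        d0 = np.where(miss, 0.0, d)
        for j in range(d0.shape[1]):
            scores += w[j] * d0[:, j]
        n_obs = (~miss).sum(axis=1)
        zero = n_obs == 0
        if zero.any():
            logger.warning(
                "%d sample(s) have no observed dosages; scores set to NaN",
                int(zero.sum()),
            )
        with np.errstate(divide="ignore"):
            factor = np.where(zero, np.nan, genotypes.n_snps / n_obs)
        scores = scores * factor
    return scores


def standardize(scores: Sequence[float]) -> np.ndarray:
    """z-score a vector: mean 0, sample SD 1 (n−1 denominator)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValidationError("standardize requires at least 2 values")
    sd = float(np.std(x, ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise DegenerateScoreError("zero or non-finite variance; cannot standardize")
    return (x - x.mean()) / sd


def threshold_scores(
    aligned_stats: pd.DataFrame,
    aligned_genotypes: GenotypeMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    missing_policy: str = "mean_impute",
) -> RiskScoreSet:
    """Family of p-value-thresholded polygenic scores.

    For each threshold ``t`` (sorted descending; 1.0 reproduces the full-set
    score exactly) the score uses only SNPs with ``p_value <= t``. Columns
    that retain no SNP, or whose score has zero variance, are flagged
    degenerate (z column NaN) rather than silently zero-filled.
    """
    thr = np.asarray(list(thresholds), dtype=float)
    if thr.size < 1:
        raise ValidationError("at least one threshold required")
    if (np.diff(thr) >= 0).any():
        raise ValidationError("thresholds must be sorted strictly descending")
    if not np.array_equal(
        np.asarray(aligned_stats["snp_id"]), aligned_genotypes.snp_ids
    ):
        raise ValidationError("stats and genotypes are not aligned (run harmonize)")

    p = aligned_stats["p_value"].to_numpy(dtype=float)
    w = aligned_stats["effect_size"].to_numpy(dtype=float)
    n = aligned_genotypes.n_samples
    k = thr.size
    raw = np.zeros((n, k))
    z = np.full((n, k), np.nan)
    n_snps = np.zeros(k, dtype=int)
    degenerate = np.zeros(k, dtype=bool)
    for i, t in enumerate(thr):
        idx = np.flatnonzero(p <= t)
        n_snps[i] = idx.size
        if idx.size == 0:
            degenerate[i] = True
            logger.warning("threshold %g retains zero SNPs; column degenerate", t)
            continue
        raw[:, i] = compute_score(
            aligned_genotypes.subset(idx), w[idx], missing_policy
        )
        try:
            z[:, i] = standardize(raw[:, i])
        except DegenerateScoreError:
            degenerate[i] = True
            logger.warning("threshold %g score has zero variance", t)
        logger.info("threshold %g: %d SNPs retained", t, idx.size)
    return RiskScoreSet(
        sample_ids=aligned_genotypes.sample_ids,
        thresholds=thr,
        raw=raw,
        z=z,
        n_snps_per_threshold=n_snps,
        degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# interaction analysis: descriptives, model fits, moderation, sensitivity
# --------------------------------------------------------------------------


def describe_prevalence(
    phenotypes: pd.DataFrame, hba1c_cutoff: float = DEFAULT_HBA1C_CUTOFF
) -> dict:
    """Counts and percentages of self-reported diabetes and of HbA1c at or
    above the diagnostic cutoff (inclusive ≥). Percentages are reported
    rounded to 1 decimal alongside full precision."""
    h = phenotypes["hba1c"].to_numpy(dtype=float)
    if np.isnan(h).all():
        raise ValidationError("all HbA1c values missing")
    n = len(phenotypes)
    if "diabetes" in phenotypes.columns:
        dia = phenotypes["diabetes"].to_numpy(dtype=float)
        n_diabetes = int(np.nansum(dia == 1))
    else:
        n_diabetes = 0
    n_above = int(np.nansum(h >= hba1c_cutoff))
    pct_dia = 100.0 * n_diabetes / n
    pct_above = 100.0 * n_above / n
    return {
        "n": n,
        "n_diabetes": n_diabetes,
        "pct_diabetes": round(pct_dia, 1),
        "pct_diabetes_exact": pct_dia,
        "n_above_cutoff": n_above,
        "pct_above_cutoff": round(pct_above, 1),
        "pct_above_cutoff_exact": pct_above,
        "hba1c_cutoff": float(hba1c_cutoff),
    }


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[~np.isnan(x)])
    return vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()


def _assemble_design(
    phenotypes: pd.DataFrame,
    score: Sequence[float],
    outcome: str,
    include_moderator: bool,
    include_interaction: bool,
    covariates: Sequence[str],
    standardize_vars: bool,
) -> tuple[np.ndarray, pd.DataFrame, int]:
    """Listwise-complete model frame with z-scored continuous predictors.

    Returns (outcome vector, predictor frame without intercept, n_used).
    The interaction column is the product of the z-scored components.
    """
    if outcome not in phenotypes.columns:
        raise ValidationError(f"outcome column {outcome!r} not in phenotype table")
    score = np.asarray(score, dtype=float)
    if score.shape != (len(phenotypes),):
        raise ValidationError("score length does not match phenotype table")
    frame = pd.DataFrame({outcome: phenotypes[outcome].to_numpy(dtype=float)})
    frame["score"] = score
    need_mod = include_moderator or include_interaction
    if need_mod:
        if "moderator" not in phenotypes.columns:
            raise ValidationError("phenotype table has no 'moderator' column")
        frame["moderator"] = phenotypes["moderator"].to_numpy(dtype=float)
    for c in covariates:
        if c not in phenotypes.columns:
            raise ValidationError(f"covariate {c!r} not in phenotype table")
        frame[c] = phenotypes[c].to_numpy(dtype=float)
    frame = frame.dropna()
    n_used = len(frame)
    if n_used < 10:
        raise ValidationError(f"only {n_used} complete cases; need at least 10")

    pred_cols = [c for c in frame.columns if c != outcome]
    for c in pred_cols:
        if frame[c].nunique() < 2:
            raise ValidationError(f"predictor {c!r} is constant")
    if standardize_vars:
        for c in pred_cols:
            x = frame[c].to_numpy()
            if not _is_binary(x):
                frame[c] = standardize(x)
    if include_interaction:
        frame["score_x_moderator"] = (
            frame["score"].to_numpy() * frame["moderator"].to_numpy()
        )
        pred_cols.append("score_x_moderator")
    y = frame[outcome].to_numpy()
    return y, frame[pred_cols], n_used


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify columns linearly dependent on the preceding ones
        bad = []
        for j in range(1, mat.shape[1]):
            if np.linalg.matrix_rank(mat[:, : j + 1]) == np.linalg.matrix_rank(
                mat[:, :j]
            ):
                bad.append(X.columns[j - 1])
        raise ValidationError(f"rank-deficient design; collinear terms: {bad}")


def _terms_from_results(
    params, bse, conf, pvals, names
) -> dict[str, TermEstimate]:
    terms = {}
    for i, name in enumerate(names):
        terms[name] = TermEstimate(
            estimate=float(params[i]),
            std_error=float(bse[i]),
            ci_low=float(conf[i, 0]),
            ci_high=float(conf[i, 1]),
            p_value=float(_clamp_p(pvals[i])) if np.isfinite(pvals[i]) else 1.0,
        )
    return terms


def fit_linear(
    phenotypes: pd.DataFrame,
    score: Sequence[float],
    *,
    outcome: str = "hba1c",
    include_moderator: bool = False,
    include_interaction: bool = False,
    covariates: Sequence[str] = (),
    standardize_vars: bool = True,
) -> ModelFit:
    """OLS regression of a continuous outcome on the polygenic score and,
    optionally, the moderator and their interaction.

    With ``standardize_vars`` (default), the outcome and continuous
    predictors are z-scored before fitting and the interaction term is built
    from the z-scored components, so coefficients are standardized βs. Wald
    95% CIs and two-sided p-values use the t reference. Listwise deletion.
    """
    y, X, n_used = _assemble_design(
        phenotypes, score, outcome, include_moderator, include_interaction,
        covariates, standardize_vars,
    )
    if standardize_vars:
        y = standardize(y)
    _check_rank(X)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    names = ["const"] + list(X.columns)
    res = sm.OLS(y, design).fit()
    conf = np.asarray(res.conf_int())
    terms = _terms_from_results(res.params, res.bse, conf, res.pvalues, names)
    std_betas = (
        {n: t.estimate for n, t in terms.items() if n != "const"}
        if standardize_vars
        else _posthoc_std_betas(terms, X, y)
    )
    return ModelFit(
        outcome_name=outcome,
        family="linear",
        terms=terms,
        standardized_betas=std_betas,
        odds_ratios_per_sd={},
        n_used=n_used,
        converged=True,
    )


def _posthoc_std_betas(terms, X, y) -> dict[str, float]:
    ysd = float(np.std(y, ddof=1))
    out = {}
    for name, t in terms.items():
        if name == "const":
            continue
        xsd = float(np.std(X[name].to_numpy(dtype=float), ddof=1))
        out[name] = t.estimate * xsd / ysd if ysd > 0 else float("nan")
    return out


_SEPARATION_COEF = 15.0  # |log-odds| per SD beyond this ⇒ quasi-separation


def fit_logistic(
    phenotypes: pd.DataFrame,
    score: Sequence[float],
    *,
    outcome: str = "diabetes",
    include_moderator: bool = False,
    include_interaction: bool = False,
    covariates: Sequence[str] = (),
    standardize_vars: bool = True,
) -> ModelFit:
    """Maximum-likelihood logistic regression (IRLS, tol 1e-10, ≤ 100
    iterations) of a binary outcome on the score and optional moderation
    terms.

    Continuous predictors are z-scored, so ``exp(coef)`` is the odds ratio
    per SD; Wald 95% CIs are formed on the log-odds scale and exponentiated.
    Complete or quasi-complete separation raises :class:`SeparationError`.
    """
    y, X, n_used = _assemble_design(
        phenotypes, score, outcome, include_moderator, include_interaction,
        covariates, standardize_vars,
    )
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValidationError(f"outcome {outcome!r} must be binary 0/1")
    if classes.size < 2:
        raise ValidationError(f"outcome {outcome!r} has a single class")
    n_events = int((y == 1).sum())
    if n_events < 10:
        raise ValidationError(f"only {n_events} events; need at least 10")
    _check_rank(X)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    names = ["const"] + list(X.columns)
    model = sm.GLM(y, design, family=sm.families.Binomial())
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PerfectSeparationWarning)
        res = model.fit(maxiter=100, tol=1e-10)
    separated = any(
        issubclass(w.category, PerfectSeparationWarning) for w in caught
    )
    converged = bool(getattr(res, "converged", True))
    coefs = np.asarray(res.params)
    if separated or not converged or np.abs(coefs[1:]).max(initial=0.0) > _SEPARATION_COEF:
        raise SeparationError(
            "logistic fit indicates complete or quasi-complete separation "
            f"(converged={converged}, max|coef|={np.abs(coefs).max():.2f})"
        )
    conf = np.asarray(res.conf_int())
    terms = _terms_from_results(res.params, res.bse, conf, res.pvalues, names)
    ors = {}
    for i, name in enumerate(names):
        if name == "const":
            continue
        ors[name] = (
            math.exp(coefs[i]),
            math.exp(conf[i, 0]),
            math.exp(conf[i, 1]),
        )
    return ModelFit(
        outcome_name=outcome,
        family="logistic",
        terms=terms,
        standardized_betas={},
        odds_ratios_per_sd=ors,
        n_used=n_used,
        converged=converged,
    )


def _align_score_matrix(
    phenotypes: pd.DataFrame, scores: RiskScoreSet
) -> np.ndarray:
    """Reorder score rows to phenotype sample order; error on missing ids."""
    pos = {s: i for i, s in enumerate(scores.sample_ids)}
    try:
        idx = np.array([pos[s] for s in phenotypes["sample_id"]])
    except KeyError as e:
        raise ValidationError(f"sample {e.args[0]!r} has no score") from None
    return idx


def fit_moderation(
    phenotypes: pd.DataFrame,
    scores: RiskScoreSet,
    *,
    outcome: str = "hba1c",
    covariates: Sequence[str] = (),
) -> ModerationResult:
    """Fit ``outcome ~ score + moderator + score×moderator (+ covariates)``
    for every threshold column of the score set.

    The family is linear for continuous outcomes and logistic for binary.
    Degenerate score columns are skipped with a warning; the summary table
    of interaction estimates and p-values across thresholds supports the
    robustness reading across score variants.
    """
    idx = _align_score_matrix(phenotypes, scores)
    out_vals = phenotypes[outcome].to_numpy(dtype=float)
    binary = _is_binary(out_vals)
    fits: dict[float, ModelFit] = {}
    rows = []
    for k, t in enumerate(scores.thresholds):
        if scores.degenerate[k]:
            logger.warning("skipping degenerate score column at threshold %g", t)
            continue
        col = scores.z[idx, k]
        try:
            fitter = fit_logistic if binary else fit_linear
            fit = fitter(
                phenotypes,
                col,
                outcome=outcome,
                include_moderator=True,
                include_interaction=True,
                covariates=covariates,
            )
        except (ValidationError, SeparationError) as e:
            logger.warning("threshold %g fit skipped: %s", t, e)
            continue
        fits[float(t)] = fit
        inter = fit.term("score_x_moderator")
        row = {
            "threshold": float(t),
            "n_snps": int(scores.n_snps_per_threshold[k]),
            "interaction_estimate": inter.estimate,
            "interaction_se": inter.std_error,
            "interaction_p": inter.p_value,
            "n_used": fit.n_used,
        }
        if binary:
            row["interaction_or_per_sd"] = fit.odds_ratios_per_sd[
                "score_x_moderator"
            ][0]
        rows.append(row)
    return ModerationResult(fits=fits, summary=pd.DataFrame(rows))


def median_split_analysis(
    phenotypes: pd.DataFrame,
    score: Sequence[float],
    *,
    outcome: str = "hba1c",
    tie_rule: str = "low",
) -> StratifiedResult:
    """Split the sample at the moderator median and estimate the
    score–outcome association within each stratum.

    Samples with moderator ≤ median form the low group under the default
    ``tie_rule="low"`` (``"high"`` sends ties up instead). For a continuous
    outcome the stratum effect r is the standardized simple-regression β,
    identical to the Pearson correlation; for a binary outcome the stratum
    fit is a logistic OR per SD and effect r is the point-biserial
    correlation.
    """
    if tie_rule not in ("low", "high"):
        raise ValidationError(f"unknown tie_rule {tie_rule!r}")
    if "moderator" not in phenotypes.columns:
        raise ValidationError("phenotype table has no 'moderator' column")
    mod = phenotypes["moderator"].to_numpy(dtype=float)
    score = np.asarray(score, dtype=float)
    out_vals = phenotypes[outcome].to_numpy(dtype=float)
    complete = ~(np.isnan(mod) | np.isnan(score) | np.isnan(out_vals))
    if np.unique(mod[complete]).size < 2:
        raise ValidationError("moderator is constant; cannot median-split")
    med = float(np.median(mod[complete]))
    if tie_rule == "low":
        low_mask = complete & (mod <= med)
        high_mask = complete & (mod > med)
    else:
        low_mask = complete & (mod < med)
        high_mask = complete & (mod >= med)

    binary = _is_binary(out_vals[complete])

    def stratum_fit(mask: np.ndarray) -> tuple[ModelFit, float, int]:
        sub = phenotypes.loc[mask].reset_index(drop=True)
        s = score[mask]
        if mask.sum() < 10:
            raise ValidationError(
                f"stratum has {int(mask.sum())} complete cases; need at least 10"
            )
        if binary:
            fit = fit_logistic(sub, s, outcome=outcome)
            r = float(np.corrcoef(s, sub[outcome].to_numpy(dtype=float))[0, 1])
        else:
            fit = fit_linear(sub, s, outcome=outcome)
            r = fit.standardized_betas["score"]
        return fit, r, int(mask.sum())

    low_fit, r_low, n_low = stratum_fit(low_mask)
    high_fit, r_high, n_high = stratum_fit(high_mask)
    return StratifiedResult(
        split_variable="moderator",
        split_value=med,
        low_group=low_fit,
        high_group=high_fit,
        effect_r_low=r_low,
        effect_r_high=r_high,
        n_low=n_low,
        n_high=n_high,
    )


def sensitivity_refit(
    phenotypes: pd.DataFrame,
    score: Sequence[float],
    *,
    outcome: str = "hba1c",
    exclude_flag: str | None = None,
    add_covariate: str | None = None,
    include_moderator: bool = True,
    include_interaction: bool = True,
    covariates: Sequence[str] = (),
) -> SensitivityResult:
    """Refit a model excluding flagged samples (e.g. insulin therapy,
    screening out potential Type 1 diabetes) and/or adding a covariate
    (e.g. BMI); returns the paired fits and the change in the score and
    interaction coefficients."""
    if exclude_flag is None and add_covariate is None:
        raise ValidationError("specify exclude_flag and/or add_covariate")
    for col in (exclude_flag, add_covariate):
        if col is not None and col not in phenotypes.columns:
            raise ValidationError(f"column {col!r} not in phenotype table")
    score = np.asarray(score, dtype=float)
    out_vals = phenotypes[outcome].to_numpy(dtype=float)
    binary = _is_binary(out_vals[~np.isnan(out_vals)])
    fitter = fit_logistic if binary else fit_linear

    def fit(pheno, s, covs):
        return fitter(
            pheno,
            s,
            outcome=outcome,
            include_moderator=include_moderator,
            include_interaction=include_interaction,
            covariates=covs,
        )

    baseline = fit(phenotypes, score, tuple(covariates))
    sens_pheno, sens_score = phenotypes, score
    if exclude_flag is not None:
        flag = phenotypes[exclude_flag].to_numpy(dtype=float)
        keep = ~(flag == 1)
        sens_pheno = phenotypes.loc[keep].reset_index(drop=True)
        sens_score = score[keep]
    sens_covs = tuple(covariates) + (
        (add_covariate,) if add_covariate is not None else ()
    )
    sensitivity = fit(sens_pheno, sens_score, sens_covs)

    delta_score = sensitivity.term("score").estimate - baseline.term("score").estimate
    delta_inter = None
    if include_interaction:
        delta_inter = (
            sensitivity.term("score_x_moderator").estimate
            - baseline.term("score_x_moderator").estimate
        )
    return SensitivityResult(
        baseline=baseline,
        sensitivity=sensitivity,
        delta_score=delta_score,
        delta_interaction=delta_inter,
    )


def plot_interaction(
    phenotypes: pd.DataFrame,
    score: Sequence[float],
    path: str | Path,
    *,
    outcome: str = "hba1c",
    tie_rule: str = "low",
) -> None:
    """Scatter of outcome vs score with per-stratum regression lines
    (below/above the moderator median)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = median_split_analysis(
        phenotypes, score, outcome=outcome, tie_rule=tie_rule
    )
    mod = phenotypes["moderator"].to_numpy(dtype=float)
    s = np.asarray(score, dtype=float)
    y = phenotypes[outcome].to_numpy(dtype=float)
    low = mod <= res.split_value if tie_rule == "low" else mod < res.split_value
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for mask, label, color in (
        (low, f"below median (r={res.effect_r_low:.2f})", "#c44e52"),
        (~low, f"above median (r={res.effect_r_high:.2f})", "#4c72b0"),
    ):
        ok = mask & ~(np.isnan(s) | np.isnan(y))
        ax.scatter(s[ok], y[ok], s=8, alpha=0.35, color=color, label=label)
        if ok.sum() >= 2:
            b, a = np.polyfit(s[ok], y[ok], 1)
            xs = np.linspace(np.nanmin(s[ok]), np.nanmax(s[ok]), 50)
            ax.plot(xs, a + b * xs, color=color, lw=2)
    ax.set_xlabel("polygenic score (SD units)")
    ax.set_ylabel(outcome)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# --------------------------------------------------------------------------
# IO: readers, writers, run configuration
# --------------------------------------------------------------------------

_SS_DEFAULT_MAP = {
    "snp": "snp_id",
    "ea": "effect_allele",
    "oa": "other_allele",
    "beta": "effect_size",
    "p": "p_value",
    "eaf": "eaf",
}
_MISSING_TOKENS = {"", ".", "na", "nan"}


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a summary-statistics table (header SNP/EA/OA/BETA/P[/EAF],
    case-insensitive; override with ``column_map`` from file header name to
    canonical name). Rows with unparseable effect sizes or out-of-domain
    p-values are rejected with their line numbers."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if column_map is None:
        column_map = _SS_DEFAULT_MAP
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in column_map:
            rename[col] = column_map[key]
        elif col in column_map:
            rename[col] = column_map[col]
    df = df.rename(columns=rename)
    required = ["snp_id", "effect_allele", "other_allele", "effect_size", "p_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: missing required columns {missing}; "
            f"found headers {list(pd.read_csv(path, sep=sep, nrows=0).columns)}"
        )
    for col in ("effect_size", "p_value", "eaf"):
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad][:5]]
            raise ValidationError(
                f"{path.name}: unparseable {col} at line(s) {lines}"
            )
        # convert via strtod (exact round-trip); to_numeric's parser is not
        df[col] = df[col].astype(float)
    p = df["p_value"].to_numpy(dtype=float)
    bad = ~np.isfinite(p) | (p <= 0) | (p > 1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:5]]
        raise ValidationError(
            f"{path.name}: p-value outside (0, 1] at line(s) {lines}"
        )
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValidationError(f"{path.name}: duplicate SNP id {dup!r}")
    keep = [c for c in (*required, "eaf") if c in df.columns]
    return validate_summary_stats(df[keep])


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    out = stats.rename(
        columns={
            "snp_id": "SNP",
            "effect_allele": "EA",
            "other_allele": "OA",
            "effect_size": "BETA",
            "p_value": "P",
            "eaf": "EAF",
        }
    )
    # %.17g guarantees binary64 round-trip through text
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _parse_tsv_snp_header(token: str) -> tuple[str, str, str]:
    parts = token.split(":")
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    return token, "N", "N"


def read_genotypes(path: str | Path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT-derived ALT dosage; biallelic SNVs
    only) or a dosage TSV (samples × SNPs, values 0/1/2/NA, SNP headers
    optionally ``id:counted:other``)."""
    path = Path(path)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValidationError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{path.name}: duplicate sample ids in VCF header")
    snp_ids, counted, other, cols = [], [], [], []
    for var in vcf:
        where = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValidationError(f"{path.name}: multi-allelic record at {where}")
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            raise ValidationError(f"{path.name}: non-SNV record at {where}")
        dos = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1]]  # last entry is the phased flag
            if len(alleles) != 2:
                raise ValidationError(
                    f"{path.name}: non-diploid genotype at {where}, sample {samples[i]}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                dos[i] = np.nan
            else:
                dos[i] = alleles[0] + alleles[1]  # ALT-allele count, phase ignored
        snp_ids.append(var.ID if var.ID not in (None, ".") else where)
        counted.append(alt)
        other.append(ref)
        cols.append(dos)
    if not cols:
        raise ValidationError(f"{path.name}: VCF contains no records")
    return GenotypeMatrix(
        sample_ids=np.array(samples, dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        counted_allele=np.array(counted, dtype=object),
        other_allele=np.array(other, dtype=object),
        dosages=np.column_stack(cols),
    )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValidationError(f"{path.name}: first column must be 'sample_id'")
    sample_ids = df["sample_id"].to_numpy(dtype=object)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path.name}: duplicate sample ids")
    snp_ids, counted, other = [], [], []
    for tok in df.columns[1:]:
        sid, ca, oa = _parse_tsv_snp_header(tok)
        snp_ids.append(sid)
        counted.append(ca)
        other.append(oa)
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    dos = np.empty(raw.shape, dtype=float)
    for (i, j), v in np.ndenumerate(raw):
        s = str(v).strip().lower() if v is not None else ""
        if s in _MISSING_TOKENS:
            dos[i, j] = np.nan
        elif s in ("0", "1", "2", "0.0", "1.0", "2.0"):
            dos[i, j] = float(s)
        else:
            raise ValidationError(
                f"{path.name}: invalid dosage {v!r} at row {i + 2}, column {df.columns[j + 1]!r}"
            )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=np.array(snp_ids, dtype=object),
        counted_allele=np.array(counted, dtype=object),
        other_allele=np.array(other, dtype=object),
        dosages=dos,
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write unphased GT records, one biallelic SNV per SNP; REF is the
    other allele, ALT the counted allele, so ALT dosage round-trips."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=prsmod\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.sample_ids)
            + "\n"
        )
        for j in range(genotypes.n_snps):
            gts = [
                _GT_CODE.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"1\t{j + 1}\t{genotypes.snp_ids[j]}\t{genotypes.other_allele[j]}\t"
                f"{genotypes.counted_allele[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    header = ["sample_id"] + [
        f"{genotypes.snp_ids[j]}:{genotypes.counted_allele[j]}:{genotypes.other_allele[j]}"
        for j in range(genotypes.n_snps)
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i in range(genotypes.n_samples):
            cells = [str(genotypes.sample_ids[i])]
            for d in genotypes.dosages[i]:
                cells.append("NA" if np.isnan(d) else str(int(d)))
            fh.write("\t".join(cells) + "\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path.name}: phenotype CSV needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path.name}: duplicate sample id {dup!r}")
    for col in df.columns:
        if col == "sample_id":
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "diabetes" in df.columns:
        d = df["diabetes"].to_numpy(dtype=float)
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0))
        if not ok.all():
            raise ValidationError(f"{path.name}: diabetes must be 0/1/missing")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, index=False)


def write_scores(scores: RiskScoreSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#thresholds=" + ",".join(f"{t:g}" for t in scores.thresholds) + "\n")
        fh.write(
            "#n_snps=" + ",".join(str(int(c)) for c in scores.n_snps_per_threshold) + "\n"
        )
        fh.write(
            "#degenerate=" + ",".join("1" if d else "0" for d in scores.degenerate) + "\n"
        )
        scores.to_frame().to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_scores(path: str | Path) -> RiskScoreSet:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
            pos = fh.tell()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    for key in ("thresholds", "n_snps", "degenerate"):
        if key not in meta:
            raise ValidationError(f"{path.name}: missing '#{key}=' header line")
    thresholds = np.array([float(t) for t in meta["thresholds"].split(",")])
    n_snps = np.array([int(c) for c in meta["n_snps"].split(",")])
    degenerate = np.array([c == "1" for c in meta["degenerate"].split(",")])
    raw = np.column_stack([df[f"raw_{t:g}"].to_numpy(dtype=float) for t in thresholds])
    z = np.column_stack([df[f"z_{t:g}"].to_numpy(dtype=float) for t in thresholds])
    return RiskScoreSet(
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        thresholds=thresholds,
        raw=raw,
        z=z,
        n_snps_per_threshold=n_snps,
        degenerate=degenerate,
    )


def write_harmonization_report(
    report: HarmonizationReport, tsv_path: str | Path, json_path: str | Path
) -> None:
    report.table.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort's inputs in the formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary_stats": out / "summary_stats.tsv",
        "genotypes_vcf": out / "genotypes.vcf",
        "genotypes_tsv": out / "dosages.tsv",
        "phenotypes": out / "phenotypes.csv",
        "true_effects": out / "true_effects.tsv",
    }
    write_summary_stats(cohort.summary_stats, paths["summary_stats"])
    write_genotypes_vcf(cohort.genotypes, paths["genotypes_vcf"])
    write_genotypes_tsv(cohort.genotypes, paths["genotypes_tsv"])
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    pd.DataFrame(
        {"snp_id": cohort.genotypes.snp_ids, "true_effect": cohort.true_effects}
    ).to_csv(paths["true_effects"], sep="\t", index=False)
    return paths


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration for one end-to-end pipeline run."""

    summary_stats_path: str
    genotypes_path: str
    phenotypes_path: str
    output_dir: str
    genotype_format: str = "vcf"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    missing_policy: str = "mean_impute"
    drop_ambiguous: bool = True
    tie_rule: str = "low"
    covariates: tuple[str, ...] = ()
    hba1c_cutoff: float = DEFAULT_HBA1C_CUTOFF
    exclude_flag: str | None = "insulin_therapy"
    sensitivity_covariate: str | None = "bmi"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in data:
            data["thresholds"] = tuple(float(t) for t in data["thresholds"])
        if "covariates" in data:
            data["covariates"] = tuple(data["covariates"])
        return cls(**data)

    def validate(self) -> None:
        for name in ("summary_stats_path", "genotypes_path", "phenotypes_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"{name} does not exist: {p}")
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.size < 1:
            raise ValidationError("threshold grid is empty")
        if (np.diff(thr) >= 0).any():
            raise ValidationError("threshold grid must be sorted strictly descending")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run harmonize → threshold scores → descriptives → main-effect fits →
    moderation → median split → sensitivity, writing every artifact plus a
    manifest (input hashes, seed, config echo, version) to the output
    directory. Reruns with the same config produce byte-identical outputs.
    """
    from . import __version__

    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {
            "summary_stats": _sha256(config.summary_stats_path),
            "genotypes": _sha256(config.genotypes_path),
            "phenotypes": _sha256(config.phenotypes_path),
        },
        "complete": False,
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:
                manifest["failed_stage"] = name
                _write_manifest(out, manifest)
                raise PipelineError(f"[{name}] {e}") from e

        return deco

    results: dict = {}

    @stage("read_inputs")
    def _inputs():
        stats = read_summary_stats(config.summary_stats_path)
        genos = read_genotypes(config.genotypes_path, config.genotype_format)
        pheno = read_phenotypes(config.phenotypes_path)
        return stats, genos, pheno

    stats, genos, pheno = _inputs

    @stage("harmonize")
    def _harm():
        aligned_stats, aligned_genos, report = harmonize(
            stats, genos, drop_ambiguous=config.drop_ambiguous
        )
        write_harmonization_report(
            report, out / "harmonization.tsv", out / "harmonization.json"
        )
        return aligned_stats, aligned_genos, report

    aligned_stats, aligned_genos, report = _harm
    results["harmonization"] = report.summary()

    @stage("threshold_scores")
    def _scores():
        rss = threshold_scores(
            aligned_stats, aligned_genos, config.thresholds, config.missing_policy
        )
        write_scores(rss, out / "scores.tsv")
        return rss

    rss = _scores
    results["n_snps_per_threshold"] = [int(c) for c in rss.n_snps_per_threshold]

    # phenotype rows must have scores; order alignment happens inside fits
    idx = _align_score_matrix(pheno, rss)
    primary = rss.z[idx, 0]

    @stage("describe_prevalence")
    def _prev():
        prev = describe_prevalence(pheno, config.hba1c_cutoff)
        (out / "prevalence.json").write_text(
            json.dumps(prev, indent=2, sort_keys=True) + "\n"
        )
        return prev

    results["prevalence"] = _prev

    has_diabetes = "diabetes" in pheno.columns and pheno["diabetes"].notna().any()

    @stage("main_effects")
    def _mains():
        fits = {}
        fits["hba1c_main"] = fit_linear(
            pheno, primary, include_moderator=True, covariates=config.covariates
        )
        if has_diabetes:
            fits["diabetes_main"] = fit_logistic(
                pheno, primary, include_moderator=True, covariates=config.covariates
            )
        return fits

    mains = _mains

    @stage("moderation")
    def _moder():
        moder = {"hba1c": fit_moderation(pheno, rss, outcome="hba1c",
                                         covariates=config.covariates)}
        if has_diabetes:
            moder["diabetes"] = fit_moderation(
                pheno, rss, outcome="diabetes", covariates=config.covariates
            )
        for name, m in moder.items():
            m.summary.to_csv(out / f"moderation_{name}.tsv", sep="\t", index=False)
        return moder

    moderation = _moder

    @stage("median_split")
    def _split():
        return median_split_analysis(
            pheno, primary, outcome="hba1c", tie_rule=config.tie_rule
        )

    stratified = _split

    sensitivity = None
    if config.exclude_flag and config.exclude_flag in pheno.columns:

        @stage("sensitivity_exclusion")
        def _sens_ex():
            return sensitivity_refit(
                pheno, primary, outcome="hba1c",
                exclude_flag=config.exclude_flag, covariates=config.covariates,
            )

        sensitivity = {"exclusion": _sens_ex}
    if config.sensitivity_covariate and config.sensitivity_covariate in pheno.columns:

        @stage("sensitivity_covariate")
        def _sens_cov():
            return sensitivity_refit(
                pheno, primary, outcome="hba1c",
                add_covariate=config.sensitivity_covariate,
                covariates=config.covariates,
            )

        sensitivity = sensitivity or {}
        sensitivity["covariate"] = _sens_cov

    @stage("write_results")
    def _write():
        bundle = {
            "prevalence": results["prevalence"],
            "harmonization": results["harmonization"],
            "n_snps_per_threshold": results["n_snps_per_threshold"],
            "main_effects": {k: f.to_dict() for k, f in mains.items()},
            "moderation_summary": {
                k: m.summary.to_dict(orient="records") for k, m in moderation.items()
            },
            "median_split": stratified.to_dict(),
        }
        if sensitivity:
            bundle["sensitivity"] = {k: s.to_dict() for k, s in sensitivity.items()}
        (out / "results.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True) + "\n"
        )
        for k, f in mains.items():
            f.to_frame().to_csv(out / f"model_{k}.tsv", sep="\t", index=False)
        return bundle

    bundle = _write
    manifest["complete"] = True
    _write_manifest(out, manifest)
    results.update(
        {
            "main_effects": mains,
            "moderation": moderation,
            "median_split": stratified,
            "sensitivity": sensitivity,
            "bundle": bundle,
            "output_dir": str(out),
        }
    )
    return results


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
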