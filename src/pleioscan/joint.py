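"""Joint multi-trait association scanning with the O'Brien combined statistic.

Given per-trait signed Z statistics for M SNPs, the between-trait covariance
of the test statistics is estimated from all SNPs (under the global null the
Z vector is multivariate normal with unit variances and covariance equal to
the phenotypic overlap-induced correlation).  Each SNP's Z vector is then
collapsed to a single combined statistic

    gls   : T = (1' S^-1 z) / sqrt(1' S^-1 1)      (O'Brien's GLS weighting)
    equal : T = (1' z)      / sqrt(1' S 1)

both standard normal under the null.  A SNP is declared pleiotropic for a
trait subset when the joint p-value is at least one order of magnitude
smaller than every member trait's univariate p AND every univariate p is
nominally significant (< 0.05); genome-wide-significant pleiotropy
additionally requires the joint p below the GWS threshold (5e-8).

Diagnostics: the genomic-control inflation factor (lambda) and QQ tables.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, NumericalError
from .sumstats import log10p_to_p, z_to_log10p

__all__ = [
    "ZMatrix",
    "TestCovariance",
    "estimate_covariance",
    "obrien_statistic",
    "joint_scan",
    "classify_pleiotropy",
    "classify_pleiotropy_log10",
    "genomic_lambda",
    "qq_table",
    "NOT_PLEIOTROPIC",
    "PLEIOTROPIC",
    "GWS_PLEIOTROPIC",
    "APOE_REGION_GRCH37",
]

NOT_PLEIOTROPIC = "not_pleiotropic"
PLEIOTROPIC = "pleiotropic"
GWS_PLEIOTROPIC = "gws_pleiotropic"

#: default exclusion window for the APOE region (build GRCh37), chr19 44.4-46.5 Mb
APOE_REGION_GRCH37 = ("19", 44_400_000, 46_500_000)

#: median of the 1-df chi-square distribution
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

_EIG_FLOOR = 1e-8


@dataclasses.dataclass
class ZMatrix:
    """M x K matrix of signed per-trait Z statistics with SNP coordinates."""

    values: np.ndarray  # (M, K) float
    snps: pd.DataFrame  # columns snp_id, chrom, pos (alleles optional)
    traits: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("Z matrix must be two-dimensional")
        if self.values.shape[1] != len(self.traits):
            raise InputError("trait labels do not match Z matrix width")
        if len(self.snps) != self.values.shape[0]:
            raise InputError("SNP index length does not match Z matrix height")
        if not np.isfinite(self.values).all():
            raise InputError("Z matrix contains missing or non-finite entries")
        if self.values.shape[0] < self.values.shape[1]:
            raise InputError("need at least as many SNPs as traits")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, traits: Sequence[str]) -> "ZMatrix":
        idx = [self._trait_index(t) for t in traits]
        return ZMatrix(self.values[:, idx], self.snps, list(traits))

    def _trait_index(self, label: str) -> int:
        try:
            return self.traits.index(label)
        except ValueError:
            raise ConfigurationError(
                f"trait {label!r} not in Z matrix (has {self.traits})"
            ) from None


@dataclasses.dataclass
class TestCovariance:
    """K x K covariance of the per-trait test statistics under the null."""

    sigma: np.ndarray
    traits: list[str]
    mode: str
    m_used: int
    diag_inflation: float = 0.0

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-12):
            raise NumericalError("covariance matrix is not symmetric")
        if np.any(np.diag(self.sigma) <= 0):
            raise NumericalError("covariance matrix has non-positive diagonal entries")

    def restrict(self, traits: Sequence[str]) -> "TestCovariance":
        idx = []
        for t in traits:
            if t not in self.traits:
                raise ConfigurationError(f"trait {t!r} not in covariance ({self.traits})")
            idx.append(self.traits.index(t))
        return TestCovariance(
            self.sigma[np.ix_(idx, idx)], list(traits), self.mode, self.m_used,
            self.diag_inflation,
        )

    def correlation(self) -> np.ndarray:
        d = 1.0 / np.sqrt(np.diag(self.sigma))
        return self.sigma * np.outer(d, d)


def _regularize(sigma: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimal diagonal inflation making the matrix positive definite."""
    w = np.linalg.eigvalsh(sigma)
    lam_min = float(w[0])
    floor = _EIG_FLOOR * max(1.0, float(np.max(np.diag(sigma))))
    if lam_min >= floor:
        return sigma, 0.0
    add = floor - lam_min
    return sigma + add * np.eye(sigma.shape[0]), add


def estimate_covariance(
    Z: ZMatrix, mode: str = "all_snps", z_cap: float = 2.0
) -> TestCovariance:
    """Sample covariance of the per-trait Z statistics across SNPs.

    ``mode="all_snps"`` (default) uses every row, mirroring the
    approximation of the null covariance by the genome-wide sample
    covariance of the test statistics.  ``mode="truncated"`` restricts to
    rows where every ``|z| < z_cap`` as a robustness option that limits the
    influence of true signals.  The result is regularized by minimal
    diagonal inflation if not positive definite.

    Raises
    ------
    InputError
        If fewer than ``10 * K`` rows are available in the chosen mode.
    """
    M, K = Z.shape
    if mode == "all_snps":
        rows = Z.values
    elif mode == "truncated":
        rows = Z.values[(np.abs(Z.values) < z_cap).all(axis=1)]
    else:
        raise ConfigurationError(f"unknown covariance mode {mode!r}")
    if rows.shape[0] <= 10 * K:
        raise InputError(
            f"covariance estimation needs more than {10 * K} rows, got {rows.shape[0]}"
        )
    sigma = np.cov(rows, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    sigma, add = _regularize(sigma)
    return TestCovariance(sigma, list(Z.traits), mode, rows.shape[0], add)


def _obrien_weights(sigma: np.ndarray, weights: str) -> tuple[np.ndarray, float]:
    """Per-trait weights w and the normalizer sqrt(denominator)."""
    K = sigma.shape[0]
    ones = np.ones(K)
    if weights == "gls":
        try:
            w = np.linalg.solve(sigma, ones)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"covariance matrix singular for K={K}: {exc}") from exc
        denom = float(ones @ w)
        if denom <= 0:
            raise NumericalError("GLS normalizer is non-positive; covariance not PD")
        return w, math.sqrt(denom)
    if weights == "equal":
        denom = float(ones @ sigma @ ones)
        if denom <= 0:
            raise NumericalError("equal-weight normalizer is non-positive")
        return ones, math.sqrt(denom)
    raise ConfigurationError(f"unknown weighting {weights!r} (use 'gls' or 'equal')")


def obrien_statistic(z_vec, Sigma: TestCovariance | np.ndarray, weights: str = "gls") -> float:
    """Combined test statistic for one SNP; standard normal under the null.

    For K = 1 both weightings reduce to the univariate Z.
    """
    sigma = Sigma.sigma if isinstance(Sigma, TestCovariance) else np.atleast_2d(np.asarray(Sigma, float))
    z = np.asarray(z_vec, dtype=float).ravel()
    if z.shape[0] != sigma.shape[0]:
        raise InputError(f"z has length {z.shape[0]} but Sigma is {sigma.shape[0]}x{sigma.shape[1]}")
    w, norm = _obrien_weights(sigma, weights)
    return float(w @ z) / norm


def joint_scan(
    Z: ZMatrix,
    Sigma: TestCovariance,
    traits: Sequence[str] | None = None,
    weights: str = "gls",
    gws: float = 5e-8,
    magnitude_factor: float = 10.0,
    nominal: float = 0.05,
) -> pd.DataFrame:
    """Genome-wide joint scan of a trait subset; one row per SNP.

    Columns: SNP coordinates, per-trait ``z``/``log10p``/``p``, ``T_joint``,
    ``log10p_joint``, ``p_joint``, and the pleiotropy ``pleio_class``.
    Deterministic given its inputs.
    """
    traits = list(traits) if traits is not None else list(Z.traits)
    if not 1 <= len(traits) <= len(Z.traits):
        raise ConfigurationError(f"trait subset size must be in [1, {len(Z.traits)}]")
    if len(set(traits)) != len(traits):
        raise ConfigurationError(f"trait subset has duplicates: {traits}")
    Zs = Z.subset(traits)
    Sig = Sigma.restrict(traits)
    w, norm = _obrien_weights(Sig.sigma, weights)
    T = (Zs.values @ w) / norm

    out = Zs.snps.copy().reset_index(drop=True)
    log10p_univ = np.empty_like(Zs.values)
    for j, t in enumerate(traits):
        out[f"z_{t}"] = Zs.values[:, j]
        log10p_univ[:, j] = z_to_log10p(Zs.values[:, j])
        out[f"log10p_{t}"] = log10p_univ[:, j]
        out[f"p_{t}"] = log10p_to_p(log10p_univ[:, j])
    out["T_joint"] = T
    log10p_joint = z_to_log10p(T)
    out["log10p_joint"] = log10p_joint
    out["p_joint"] = log10p_to_p(log10p_joint)
    out["pleio_class"] = classify_pleiotropy_log10(
        log10p_joint, log10p_univ, gws=gws, magnitude_factor=magnitude_factor,
        nominal=nominal,
    )
    return out


def classify_pleiotropy(
    p_joint: float,
    p_univ: Sequence[float],
    gws: float = 5e-8,
    magnitude_factor: float = 10.0,
    nominal: float = 0.05,
) -> str:
    """Pleiotropy declaration rule for one SNP and one trait subset.

    ``pleiotropic`` iff the joint p is at least ``magnitude_factor`` times
    smaller than every member trait's univariate p (non-strict:
    ``p_joint <= p_univ / factor``) AND every univariate p < ``nominal``;
    ``gws_pleiotropic`` iff additionally ``p_joint < gws``.
    """
    p_univ = np.asarray(p_univ, dtype=float)
    if not (0 < p_joint <= 1) or not ((p_univ > 0) & (p_univ <= 1)).all():
        raise InputError("p-values must lie in (0, 1]")
    pleio = bool((p_joint <= p_univ / magnitude_factor).all() and (p_univ < nominal).all())
    if not pleio:
        return NOT_PLEIOTROPIC
    return GWS_PLEIOTROPIC if p_joint < gws else PLEIOTROPIC


def classify_pleiotropy_log10(
    log10p_joint: np.ndarray,
    log10p_univ: np.ndarray,
    gws: float = 5e-8,
    magnitude_factor: float = 10.0,
    nominal: float = 0.05,
) -> np.ndarray:
    """Vectorized declaration rule operating in log10 space (underflow-safe)."""
    lj = np.asarray(log10p_joint, dtype=float).reshape(-1, 1)
    lu = np.atleast_2d(np.asarray(log10p_univ, dtype=float))
    shift = math.log10(magnitude_factor)
    pleio = (lj <= lu - shift).all(axis=1) & (lu < math.log10(nominal)).all(axis=1)
    gws_hit = pleio & (lj.ravel() < math.log10(gws))
    out = np.full(lj.shape[0], NOT_PLEIOTROPIC, dtype=object)
    out[pleio] = PLEIOTROPIC
    out[gws_hit] = GWS_PLEIOTROPIC
    return out


def genomic_lambda(
    p_values,
    chrom=None,
    pos=None,
    exclude_region: tuple[str, int, int] | None = None,
) -> float:
    """Genomic-control inflation factor.

    lambda = median of the 1-df chi-square quantiles of the observed
    p-values divided by the null chi-square median (~0.4549).  An optional
    (chrom, start, end) region — e.g. the APOE region — is excluded first;
    this requires ``chrom``/``pos`` arrays parallel to ``p_values``.

    Raises
    ------
    InputError
        If the (post-exclusion) p-value vector is empty.
    """
    p = np.asarray(p_values, dtype=float)
    if exclude_region is not None:
        if chrom is None or pos is None:
            raise ConfigurationError("exclude_region requires chrom and pos arrays")
        c, start, end = exclude_region
        chrom = np.asarray(chrom).astype(str)
        pos = np.asarray(pos)
        inside = (chrom == str(c)) & (pos >= start) & (pos <= end)
        p = p[~inside]
    if p.size == 0:
        raise InputError("no p-values left for lambda estimation")
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    chi2_obs = stats.chi2.isf(p, df=1)
    return float(np.median(chi2_obs) / CHI2_1_MEDIAN)


def qq_table(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p sorted ascending; expected quantile for rank i (1-based) is
    i/(n+1).  Output columns ``expected_neglog10p``, ``observed_neglog10p``,
    both monotone, length n (ties kept).
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise InputError("empty p-value vector")
    n = p.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    return pd.DataFrame(
        {
            "expected_neglog10p": -np.log10(expected),
            "observed_neglog10p": -np.log10(p),
        }
    )
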