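"""Two-sample MR causal-effect estimators.

Given a harmonized set of J instruments with exposure effects gamma_j
(SE sigma_gamma_j) and outcome effects Gamma_j (SE sigma_Gamma_j), the
per-SNP Wald ratio is ``beta_j = Gamma_j / gamma_j`` with first-order
standard error ``se_j = sigma_Gamma_j / |gamma_j|``. The suite combines
these ratios four ways:

* **IVW** — the inverse-variance-weighted mean of the Wald ratios;
  fixed-effects SE, or multiplicative random-effects SE (inflated by the
  residual dispersion, floored at 1) when between-SNP heterogeneity is
  plausible. The ``auto`` rule uses fixed effects for 3 or fewer SNPs and
  random effects for 4 or more.
* **IVW with correlated instruments** — generalized weighted least squares
  of Gamma on gamma through the origin with covariance
  ``Omega_jk = sigma_Gamma_j sigma_Gamma_k rho_jk`` built from the signed
  LD matrix rho, so correlated SNPs are not double-counted.
* **Weighted median** — the weight-interpolated 50th percentile of the
  ordered Wald ratios; consistent when valid instruments carry more than
  half of the total weight. SE by parametric bootstrap.
* **MR-Egger** — weighted regression of Gamma on gamma with a free
  intercept after orienting every SNP to gamma_j >= 0; the intercept
  estimates average directional pleiotropy and its p-value tests for it
  (valid under the InSIDE assumption), while the slope remains a causal
  estimate even when all instruments are invalid.

P-values use the normal reference for IVW and the weighted median, and the
t reference with J - 2 degrees of freedom for MR-Egger; confidence
intervals follow the same reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .exceptions import (
    EmptyInstrumentSetError,
    EstimationError,
    InfeasibleEstimatorError,
)
from .summary import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal-effect estimate.

    ``beta`` is in outcome units per unit exposure (e.g. SD of BMD per unit
    ln hsCRP). ``intercept*`` fields are populated only for MR-Egger, where
    the intercept measures average directional pleiotropy per instrument.
    """

    method: str  # "IVW" | "WM" | "MR-Egger"
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    effects_model: str | None = None  # "fixed" | "random" (IVW only)
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise EstimationError(f"{self.method}: SE must be positive, got {self.se}")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise EstimationError(f"{self.method}: CI does not bracket the estimate")
        minimum = 3 if self.method in ("WM", "MR-Egger") else 1
        if self.n_snps < minimum:
            raise InfeasibleEstimatorError(
                f"{self.method} needs at least {minimum} SNPs, got {self.n_snps}"
            )


def wald_ratio(
    gamma: float, se_gamma: float, Gamma: float, se_Gamma: float
) -> tuple[float, float]:
    """Per-SNP causal estimate ``Gamma/gamma`` with first-order SE ``se_Gamma/|gamma|``.

    This is the leading term of the delta-method expansion of the ratio,
    ignoring the uncertainty in the (strong) instrument's exposure effect.
    """
    if gamma == 0:
        raise EstimationError("wald_ratio: exposure effect gamma is zero")
    return Gamma / gamma, se_Gamma / abs(gamma)


def _ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    if np.any(h.gamma == 0):
        zero = [rs for rs, g in zip(h.rsids, h.gamma) if g == 0]
        raise EstimationError(f"zero exposure effect for SNP(s) {zero}")
    return h.Gamma / h.gamma, h.se_Gamma / np.abs(h.gamma)


def ivw(h: HarmonizedSet, effects_model: str = "auto") -> MrEstimate:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    ``effects_model`` is ``fixed``, ``random`` (multiplicative, inflation
    floored at 1) or ``auto`` (fixed for J <= 3, random for J >= 4). For a
    single SNP this reduces to the Wald ratio. Use :func:`ivw_correlated`
    when an LD matrix is attached.
    """
    if h.ld is not None:
        raise EstimationError(
            "HarmonizedSet has an LD matrix attached; use ivw_correlated"
        )
    J = h.n_snps
    if J == 0:
        raise EmptyInstrumentSetError("IVW: no SNPs")
    if effects_model not in ("fixed", "random", "auto"):
        raise EstimationError(f"unknown effects_model {effects_model!r}")
    if effects_model == "auto":
        effects_model = "fixed" if J <= 3 else "random"
    ratios, ses = _ratios(h)
    w = ses**-2
    theta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    se = se_fixed
    if effects_model == "random" and J > 1:
        phi2 = float(np.sum(w * (ratios - theta) ** 2) / (J - 1))
        se = se_fixed * max(1.0, np.sqrt(phi2))
    pvalue = float(2 * stats.norm.sf(abs(theta) / se))
    return MrEstimate(
        method="IVW",
        beta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pvalue=pvalue,
        n_snps=J,
        effects_model=effects_model,
    )


def _solve_spd(omega: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve omega @ x = b for symmetric positive-definite omega by Cholesky,
    adding a 1e-10 ridge when the matrix is near-singular (logged)."""
    if np.linalg.cond(omega) > 1e12:
        logger.warning(
            "correlated-instrument covariance is near-singular "
            "(condition number > 1e12); adding 1e-10 ridge"
        )
        omega = omega + 1e-10 * np.eye(len(omega))
    try:
        cho = linalg.cho_factor(omega, lower=True)
    except linalg.LinAlgError as exc:
        raise EstimationError(
            f"instrument covariance not positive definite: {exc}"
        ) from None
    return linalg.cho_solve(cho, b)


def ivw_correlated(h: HarmonizedSet) -> MrEstimate:
    """IVW for correlated instruments via generalized weighted least squares.

    Regresses Gamma on gamma through the origin with residual covariance
    ``Omega = diag(se_Gamma) @ rho @ diag(se_Gamma)``:
    ``theta = (gamma' Omega^-1 gamma)^-1 gamma' Omega^-1 Gamma`` with
    ``SE = (gamma' Omega^-1 gamma)^-1/2``. With an identity LD matrix this
    is exactly fixed-effects IVW. Solved by Cholesky factorization, never an
    explicit inverse.
    """
    if h.ld is None:
        raise EstimationError("ivw_correlated requires an LD matrix on the set")
    J = h.n_snps
    if J == 0:
        raise EmptyInstrumentSetError("IVW: no SNPs")
    omega = np.outer(h.se_Gamma, h.se_Gamma) * h.ld.r
    oi_gamma = _solve_spd(omega, h.gamma)
    oi_Gamma = _solve_spd(omega, h.Gamma)
    gtg = float(h.gamma @ oi_gamma)
    if gtg <= 0:
        raise EstimationError("degenerate GLS normal equations")
    theta = float(h.gamma @ oi_Gamma) / gtg
    se = gtg**-0.5
    pvalue = float(2 * stats.norm.sf(abs(theta) / se))
    return MrEstimate(
        method="IVW",
        beta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pvalue=pvalue,
        n_snps=J,
        effects_model="fixed",
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated 50th percentile of the ordered ratios.

    With the ratios sorted ascending and weights normalized to sum 1, the
    cumulative weight at each ratio's midpoint is
    ``s_j = sum_{k<=j} w_k - w_j / 2``; the estimate interpolates linearly
    between the ratios bracketing s = 0.5. Equal weights reproduce the
    interpolated simple median.
    """
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, b))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 2000, seed: int | None = None
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when SNPs carrying at least half of the inverse-variance
    weight are valid instruments. The SE is the standard deviation of the
    estimate over ``n_boot`` replicates that redraw gamma_j and Gamma_j from
    normal distributions centred at the observed effects with the reported
    SEs. ``seed`` is required for reproducibility. Correlated instruments
    are not supported: attach no LD matrix.
    """
    if h.ld is not None:
        raise InfeasibleEstimatorError(
            "weighted median does not support correlated instruments; "
            "detach the LD matrix or prune to independent SNPs"
        )
    J = h.n_snps
    if J < 3:
        raise InfeasibleEstimatorError(
            f"weighted median is only feasible with more than two SNPs, got {J}"
        )
    if seed is None:
        raise EstimationError("weighted_median requires an explicit seed")
    if n_boot < 2:
        raise EstimationError(f"n_boot must be at least 2, got {n_boot}")
    ratios, ses = _ratios(h)
    theta = _weighted_median(ratios, ses**-2.0)

    rng = np.random.default_rng(seed)
    g_star = rng.normal(h.gamma, h.se_gamma, size=(n_boot, J))
    G_star = rng.normal(h.Gamma, h.se_Gamma, size=(n_boot, J))
    g_star[g_star == 0] = np.finfo(float).tiny  # zero crossings are measure-zero
    r_star = G_star / g_star
    w_star = (np.abs(g_star) / h.se_Gamma) ** 2
    boot = np.array(
        [_weighted_median(r_star[b], w_star[b]) for b in range(n_boot)]
    )
    se = float(np.std(boot, ddof=1))
    if se == 0:
        raise EstimationError("bootstrap SE degenerate (zero)")
    pvalue = float(2 * stats.norm.sf(abs(theta) / se))
    return MrEstimate(
        method="WM",
        beta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pvalue=pvalue,
        n_snps=J,
    )


def mr_egger(h: HarmonizedSet) -> MrEstimate:
    """MR-Egger regression: slope = causal estimate, intercept = average
    directional pleiotropy.

    Each SNP is first oriented so its exposure effect is non-negative
    (flipping both gamma_j and Gamma_j when gamma_j < 0), which the
    intercept's interpretation requires. The regression
    ``Gamma_j = b0 + theta * gamma_j`` is weighted by ``se_Gamma_j^-2``
    (or by the full LD-derived covariance when an LD matrix is attached),
    with multiplicative residual scaling floored at 1 and t(J - 2)
    reference for p-values and CIs.
    """
    J = h.n_snps
    if J < 3:
        raise InfeasibleEstimatorError(
            f"MR-Egger is only feasible with more than two SNPs, got {J}"
        )
    sign = np.where(h.gamma < 0, -1.0, 1.0)
    g = h.gamma * sign
    G = h.Gamma * sign
    if np.ptp(g) < 1e-12:
        raise EstimationError(
            "MR-Egger: all exposure effects equal after orientation (collinear)"
        )
    X = np.column_stack([np.ones(J), g])
    if h.ld is not None:
        # experimental: GLS with the LD-derived covariance, sign-adjusted for
        # the per-SNP orientation flips
        omega = np.outer(h.se_Gamma, h.se_Gamma) * h.ld.r * np.outer(sign, sign)
        oi_X = np.column_stack([_solve_spd(omega, X[:, k]) for k in range(2)])
        xtx = X.T @ oi_X
        coef = np.linalg.solve(xtx, oi_X.T @ G)
        resid = G - X @ coef
        sigma2 = float(resid @ _solve_spd(omega, resid)) / (J - 2)
    else:
        w = h.se_Gamma**-2.0
        xtx = (X * w[:, None]).T @ X
        coef = np.linalg.solve(xtx, (X * w[:, None]).T @ G)
        resid = G - X @ coef
        sigma2 = float(np.sum(w * resid**2)) / (J - 2)
    cov = np.linalg.inv(xtx) * max(1.0, sigma2)
    b0, theta = float(coef[0]), float(coef[1])
    se_b0, se_theta = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    tq = float(stats.t.ppf(0.975, J - 2))
    p_theta = float(2 * stats.t.sf(abs(theta) / se_theta, J - 2))
    p_b0 = float(2 * stats.t.sf(abs(b0) / se_b0, J - 2))
    return MrEstimate(
        method="MR-Egger",
        beta=theta,
        se=se_theta,
        ci_low=theta - tq * se_theta,
        ci_high=theta + tq * se_theta,
        pvalue=p_theta,
        n_snps=J,
        intercept=b0,
        intercept_se=se_b0,
        intercept_pvalue=p_b0,
    )
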