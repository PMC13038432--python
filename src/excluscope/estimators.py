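"""Two-sample MR estimators.

All estimators operate on a harmonized :class:`~excluscope.types.InstrumentSet`.
The per-SNP building block is the Wald ratio b_j = beta_out_j / beta_exp_j with
first-order delta SE (outcome uncertainty only, the standard two-sample
convention). The inverse-variance-weighted (IVW) meta-analysis of the ratios,
with weights w_j = beta_exp_j^2 / se_out_j^2, is the primary estimator;
MR-Egger regression (directional-pleiotropy intercept), the weighted median
and the simple/weighted mode serve as sensitivity analyses, and Cochran's Q
quantifies heterogeneity across instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import InstrumentSet, MREstimate


class InsufficientInstrumentsError(ValueError):
    pass


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float
) -> MREstimate:
    """Single-instrument causal-effect ratio.

    beta = beta_out / beta_exp; se = se_out / |beta_exp| (first-order delta,
    exposure uncertainty ignored); two-sided normal p.
    """
    if beta_exp == 0:
        raise ZeroDivisionError("wald ratio undefined: exposure beta is 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald", beta, se, _two_sided_normal_p(beta / se))


def _ratios_and_weights(iset: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    bx = np.asarray(iset.beta_exp, float)
    by = np.asarray(iset.beta_out, float)
    sy = np.asarray(iset.se_out, float)
    if np.any(bx == 0):
        raise ZeroDivisionError("exposure beta of 0 in instrument set")
    return by / bx, bx**2 / sy**2


def ivw(iset: InstrumentSet, random_effects: bool = False) -> MREstimate:
    """Fixed-effects inverse-variance-weighted estimate.

    With ``random_effects=True`` the SE is inflated multiplicatively by
    sqrt(Q/(n-1)) when the heterogeneity ratio exceeds 1.
    """
    if len(iset) < 1:
        raise InsufficientInstrumentsError("IVW needs >= 1 instrument")
    if len(iset) == 1:
        est = wald_ratio(iset.beta_exp[0], iset.se_exp[0],
                         iset.beta_out[0], iset.se_out[0])
        return MREstimate("ivw", est.beta, est.se, est.pval)
    b, w = _ratios_and_weights(iset)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    if random_effects and len(iset) >= 2:
        q = float(np.sum(w * (b - beta) ** 2))
        phi = q / (len(iset) - 1)
        if phi > 1.0:
            se *= math.sqrt(phi)
    return MREstimate("ivw", beta, se, _two_sided_normal_p(beta / se))


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def mr_egger(iset: InstrumentSet) -> EggerResult:
    """MR-Egger weighted regression with directional-pleiotropy intercept.

    Exposure betas are oriented non-negative first (outcome effects re-signed
    with them), then beta_out is regressed on beta_exp with intercept under
    weights 1/se_out^2. Slope p uses the normal reference; the intercept test
    is two-sided t with n-2 degrees of freedom.
    """
    n = len(iset)
    if n < 3:
        raise InsufficientInstrumentsError("insufficient instruments for Egger")
    bx = np.asarray(iset.beta_exp, float)
    by = np.asarray(iset.beta_out, float)
    sy = np.asarray(iset.se_out, float)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    # weighted normal equations: (X' W X) theta = X' W y
    xtwx = X.T @ (w[:, None] * X)
    theta = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ theta
    dof = n - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov = sigma2 * np.linalg.inv(xtwx)
    icpt, slope = float(theta[0]), float(theta[1])
    icpt_se, slope_se = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
    icpt_p = float(min(1.0, 2.0 * stats.t.sf(abs(icpt / icpt_se), dof))) if icpt_se > 0 else 1.0
    slope_p = _two_sided_normal_p(slope / slope_se) if slope_se > 0 else 1.0
    return EggerResult(
        slope=MREstimate("egger_slope", slope, slope_se, slope_p),
        intercept=icpt,
        intercept_se=icpt_se,
        intercept_pval=icpt_p,
    )


def _interpolated_weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b)
    b, w = b[order], w[order]
    w = w / w.sum()
    # cumulative weight at the centre of each observation's mass
    cum = np.cumsum(w) - 0.5 * w
    below = cum < 0.5
    if not np.any(below):
        return float(b[0])
    if np.all(below):
        return float(b[-1])
    j = int(np.max(np.nonzero(below)[0]))
    return float(
        b[j] + (b[j + 1] - b[j]) * (0.5 - cum[j]) / (cum[j + 1] - cum[j])
    )


def weighted_median(
    iset: InstrumentSet, boot_reps: int = 200, seed: int = 0
) -> MREstimate:
    """Weighted median of Wald ratios, interpolated at cumulative weight 0.5.

    The SE comes from a seeded parametric bootstrap: each replicate redraws
    every ratio from N(b_j, se_j) and recomputes the weighted median.
    """
    if len(iset) < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    b, w = _ratios_and_weights(iset)
    beta = _interpolated_weighted_median(b, w)

    bx = np.asarray(iset.beta_exp, float)
    ratio_se = np.asarray(iset.se_out, float) / np.abs(bx)
    rng = np.random.default_rng(seed)
    boots = np.empty(boot_reps)
    for r in range(boot_reps):
        boots[r] = _interpolated_weighted_median(
            b + ratio_se * rng.standard_normal(b.size), w
        )
    se = float(np.std(boots, ddof=1))
    p = _two_sided_normal_p(beta / se) if se > 0 else 1.0
    return MREstimate("weighted_median", beta, se, p)


def _silverman_bandwidth(b: np.ndarray) -> float:
    n = b.size
    s = float(np.std(b, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(b, [75, 25])))
    candidates = [v for v in (s, iqr / 1.349) if v > 0]
    spread = min(candidates) if candidates else 1.0
    return 0.9 * spread * n ** (-1 / 5)


def _kde_mode(b: np.ndarray, w: np.ndarray, bw: float, grid_size: int = 512) -> float:
    lo, hi = b.min() - 3 * bw, b.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - b[:, None]) / bw) ** 2), axis=0
    )
    return float(grid[np.argmax(dens)])


def mode_estimates(
    iset: InstrumentSet, bandwidth_mult: float = 1.0
) -> tuple[MREstimate, MREstimate]:
    """Simple-mode and weighted-mode estimates (diagnostic; no p-value).

    The mode of a Gaussian-kernel density of the Wald ratios, evaluated on a
    512-point grid spanning the ratio range padded by 3 bandwidths; the
    bandwidth is ``bandwidth_mult`` times a modified Silverman rule.
    """
    if len(iset) < 3:
        raise InsufficientInstrumentsError("mode estimators need >= 3 instruments")
    b, w = _ratios_and_weights(iset)
    if np.allclose(b, b[0]):
        c = float(b[0])
        return (
            MREstimate("simple_mode", c, float("nan"), float("nan")),
            MREstimate("weighted_mode", c, float("nan"), float("nan")),
        )
    bw = bandwidth_mult * _silverman_bandwidth(b)
    simple = _kde_mode(b, np.ones_like(b), bw)
    weighted = _kde_mode(b, w / w.sum(), bw)
    return (
        MREstimate("simple_mode", simple, float("nan"), float("nan")),
        MREstimate("weighted_mode", weighted, float("nan"), float("nan")),
    )


def cochran_q(iset: InstrumentSet, beta_ivw: float) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic and chi-square(n-1) p-value."""
    n = len(iset)
    if n < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    b, w = _ratios_and_weights(iset)
    q = float(np.sum(w * (b - beta_ivw) ** 2))
    return q, float(stats.chi2.sf(q, n - 1))


def all_estimates(iset: InstrumentSet, seed: int = 0) -> dict[str, MREstimate]:
    """Run the five estimators on one instrument set (>=3 instruments)."""
    est = {"ivw": ivw(iset)}
    egger = mr_egger(iset)
    est["egger_slope"] = egger.slope
    est["weighted_median"] = weighted_median(iset, seed=seed)
    simple, weighted = mode_estimates(iset)
    est["simple_mode"] = simple
    est["weighted_mode"] = weighted
    return est
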