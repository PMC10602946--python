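"""Two-sample MR causal-effect estimators and instrument-level sensitivity
analyses.

All estimators consume a harmonized instrument set: aligned pairs of exposure
effects beta_j (SD units of the exposure) and outcome effects Gamma_j
(log-odds), with the outcome standard errors se_j providing the weights.
The causal effect theta is reported as a log OR per SD of exposure together
with its OR, 95% CI and two-sided p-value.

Implemented methods:

* Wald ratio (single instrument), Gamma_j / beta_j with first-order SE.
* Inverse-variance weighted (IVW): weighted regression of Gamma on beta
  through the origin, with multiplicative random effects — the SE is
  inflated by sqrt(phi), phi = max(1, Q/df), never deflated below the
  fixed-effect SE.
* IVW for correlated instruments: generalized least squares with
  Omega_ij = se_i * se_j * rho_ij built from a signed LD correlation matrix.
* MR-Egger: the same regression with a free intercept after orienting all
  exposure effects positive; the intercept estimates the average directional
  pleiotropy and its test is reported alongside the slope.
* Simple and weighted median, and the weighted mode of the kernel-smoothed
  ratio density, with parametric-bootstrap standard errors.

Heterogeneity among the per-instrument ratios is summarized by Cochran's Q
(chi-square with J-1 df under homogeneity) and I^2 = max(0, (Q-df)/Q)*100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .harmonize import HarmonizedInstrument, kept

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q heterogeneity summary for a set of instrument estimates."""

    q: float
    df: int
    p_q: float
    i2: float

    @classmethod
    def from_q(cls, q: float, df: int) -> "HeterogeneityStats":
        p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
        return cls(q=float(q), df=df, p_q=p, i2=i2)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate: log OR per SD of exposure, with uncertainty."""

    method: str
    n_variants: int
    beta: float
    se: float
    pvalue: float
    scale_phi: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    heterogeneity: HeterogeneityStats | None = None

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z975 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z975 * self.se))

    def __post_init__(self) -> None:
        if (self.method == "egger") != (self.intercept is not None):
            raise ValueError("intercept fields are present exactly for the egger method")


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _arrays(instruments: list[HarmonizedInstrument]):
    ins = kept(instruments)
    b = np.array([h.beta_exp for h in ins], dtype=float)
    g = np.array([h.beta_out for h in ins], dtype=float)
    s = np.array([h.se_out for h in ins], dtype=float)
    return ins, b, g, s


def wald_ratio(instrument: HarmonizedInstrument) -> MREstimate:
    """Single-instrument causal estimate Gamma/beta with first-order SE."""
    if instrument.status != "kept":
        raise ValueError(f"{instrument.rsid}: not a kept instrument")
    if instrument.beta_exp == 0:
        raise ZeroDivisionError(f"{instrument.rsid}: exposure effect is zero")
    beta = instrument.beta_out / instrument.beta_exp
    se = instrument.se_out / abs(instrument.beta_exp)
    return MREstimate(method="wald", n_variants=1, beta=float(beta), se=float(se),
                      pvalue=_normal_p(beta, se))


def ivw(instruments: list[HarmonizedInstrument]) -> MREstimate:
    """Multiplicative random-effects inverse-variance weighted estimate.

    Weighted regression of outcome on exposure effects through the origin
    with weights 1/se_out^2; the fixed-effect SE is inflated by
    sqrt(max(1, Q/df)).
    """
    ins, b, g, s = _arrays(instruments)
    if len(ins) < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs >=2 instruments, got {len(ins)}; use wald_ratio")
    w = 1.0 / s ** 2
    denom = float(np.sum(w * b * b))
    beta = float(np.sum(w * b * g)) / denom
    se0 = 1.0 / np.sqrt(denom)
    q = float(np.sum(w * (g - beta * b) ** 2))
    df = len(ins) - 1
    phi = max(1.0, q / df)
    se = se0 * np.sqrt(phi)
    return MREstimate(method="ivw", n_variants=len(ins), beta=beta, se=float(se),
                      pvalue=_normal_p(beta, se), scale_phi=phi,
                      heterogeneity=HeterogeneityStats.from_q(q, df))


def ivw_correlated(instruments: list[HarmonizedInstrument],
                   correlation: np.ndarray) -> MREstimate:
    """IVW generalized to correlated instruments via GLS.

    ``correlation`` is the signed LD correlation matrix in instrument order;
    Omega_ij = se_i * se_j * rho_ij.  With the identity matrix this reduces
    exactly to :func:`ivw`.
    """
    ins, b, g, s = _arrays(instruments)
    rho = np.asarray(correlation, dtype=float)
    if rho.shape != (len(ins), len(ins)):
        raise ValueError(f"correlation matrix shape {rho.shape} != ({len(ins)},{len(ins)})")
    if not np.allclose(rho, rho.T, atol=1e-10) or not np.allclose(np.diag(rho), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric with unit diagonal")
    eigmin = float(np.linalg.eigvalsh(rho).min())
    if eigmin <= 0:
        raise np.linalg.LinAlgError(
            f"correlation matrix not positive definite (smallest eigenvalue {eigmin:.3e})")
    omega = np.outer(s, s) * rho
    oinv_b = np.linalg.solve(omega, b)
    oinv_g = np.linalg.solve(omega, g)
    denom = float(b @ oinv_b)
    beta = float(b @ oinv_g) / denom
    se0 = 1.0 / np.sqrt(denom)
    resid = g - beta * b
    q = float(resid @ np.linalg.solve(omega, resid))
    df = len(ins) - 1
    phi = max(1.0, q / df) if df > 0 else 1.0
    se = se0 * np.sqrt(phi)
    return MREstimate(method="ivw_correlated", n_variants=len(ins), beta=beta,
                      se=float(se), pvalue=_normal_p(beta, se), scale_phi=phi,
                      heterogeneity=HeterogeneityStats.from_q(q, df))


def egger(instruments: list[HarmonizedInstrument],
          p_reference: str = "normal") -> MREstimate:
    """MR-Egger regression: pleiotropy-robust slope plus intercept test.

    Exposure effects are oriented non-negative (negating both members of a
    pair where beta_exp < 0), then Gamma_j = b0 + theta * beta_j is fitted by
    weighted least squares with weights 1/se_out^2.  Both SEs carry the
    multiplicative random-effects factor sqrt(max(1, Q/(J-2))).
    ``p_reference`` selects a normal or t (J-2 df) reference for the p-values.
    """
    ins, b, g, s = _arrays(instruments)
    j = len(ins)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >=3 instruments, got {j}")
    sign = np.where(b < 0, -1.0, 1.0)
    b, g = b * sign, g * sign
    if np.ptp(b) == 0:
        raise np.linalg.LinAlgError("no spread in oriented exposure effects")
    w = 1.0 / s ** 2
    X = np.column_stack([np.ones(j), b])
    xtwx = X.T * w @ X
    coef = np.linalg.solve(xtwx, X.T * w @ g)
    b0, beta = float(coef[0]), float(coef[1])
    resid = g - X @ coef
    q = float(np.sum(w * resid ** 2))
    df = j - 2
    phi = max(1.0, q / df)
    cov = np.linalg.inv(xtwx) * phi
    se_b0, se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    if p_reference == "t":
        pfun = lambda est, sd: float(2.0 * stats.t.sf(abs(est) / sd, df))
    elif p_reference == "normal":
        pfun = lambda est, sd: _normal_p(est, sd)
    else:
        raise ValueError("p_reference must be 'normal' or 't'")
    return MREstimate(method="egger", n_variants=j, beta=beta, se=se,
                      pvalue=pfun(beta, se), scale_phi=phi,
                      intercept=b0, intercept_se=se_b0, intercept_p=pfun(b0, se_b0),
                      heterogeneity=HeterogeneityStats.from_q(q, df))


# ---------------------------------------------------------------------------
# Median and mode estimators


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative midpoints."""
    order = np.argsort(theta, kind="mergesort")
    th, w = theta[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(th[0])
    if 0.5 >= s[-1]:
        return float(th[-1])
    return float(np.interp(0.5, s, th))


def _ratio_weights(b: np.ndarray, s: np.ndarray, weighted: bool) -> np.ndarray:
    return b ** 2 / s ** 2 if weighted else np.ones_like(b)


def _bootstrap_se(point_fn, b, g, se_b, se_g, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bb = rng.normal(b, se_b)
        gg = rng.normal(g, se_g)
        est[i] = point_fn(bb, gg)
    return float(np.std(est, ddof=1))


def median_estimator(instruments: list[HarmonizedInstrument], weighted: bool = True,
                     n_boot: int = 10_000, seed: int = 0) -> MREstimate:
    """Simple or weighted median of the per-instrument Wald ratios.

    Weighted median weights are the first-order inverse ratio variances
    beta_j^2 / se_out_j^2.  The SE is the standard deviation of the point
    estimate over ``n_boot`` parametric-bootstrap resamples in which both
    effect vectors are redrawn from normals centred at the observed values.
    """
    ins, b, g, s = _arrays(instruments)
    if len(ins) < 3:
        raise InsufficientInstrumentsError(f"median needs >=3 instruments, got {len(ins)}")
    se_b = np.array([h.se_exp for h in ins], dtype=float)

    def point(bb, gg):
        return _weighted_median(gg / bb, _ratio_weights(bb, s, weighted))

    beta = point(b, g)
    se = _bootstrap_se(point, b, g, se_b, s, n_boot, seed)
    return MREstimate(method="weighted_median" if weighted else "simple_median",
                      n_variants=len(ins), beta=beta, se=se, pvalue=_normal_p(beta, se))


def _kde_argmax(theta: np.ndarray, weights: np.ndarray, bandwidth_factor: float,
                refine: bool = True, n_grid: int = 512) -> float:
    w = weights / weights.sum()
    sd = float(np.std(theta, ddof=1)) if theta.size > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = bandwidth_factor * 0.9 * spread * theta.size ** (-0.2)
    if h <= 0:
        return float(theta[0])
    lo, hi = theta.mean() - 4.0 * sd, theta.mean() + 4.0 * sd
    grid = np.linspace(lo, hi, n_grid)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2)).sum(axis=1)
    i = int(np.argmax(dens))
    if not refine:
        return float(grid[i])
    a, bnd = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda x: -(w * np.exp(-0.5 * ((x - theta) / h) ** 2)).sum(),
        bounds=(a, bnd), method="bounded",
        options={"xatol": 1e-10})
    return float(res.x)


def mode_estimator(instruments: list[HarmonizedInstrument], bandwidth_factor: float = 1.0,
                   n_boot: int = 10_000, seed: int = 0) -> MREstimate:
    """Weighted mode of the kernel-smoothed density of the Wald ratios.

    A Gaussian kernel with the modified Silverman bandwidth
    h = phi_bw * 0.9 * min(sd, IQR/1.349) * J^(-1/5) smooths the ratio
    estimates (weights beta_j^2/se_out_j^2); the point estimate is the
    density argmax (grid search then bounded refinement).  Degenerate input
    (all ratios equal) returns the common ratio with a warning.  SE by
    parametric bootstrap as in :func:`median_estimator` (grid argmax only,
    for speed).
    """
    ins, b, g, s = _arrays(instruments)
    if len(ins) < 3:
        raise InsufficientInstrumentsError(f"mode needs >=3 instruments, got {len(ins)}")
    se_b = np.array([h.se_exp for h in ins], dtype=float)
    theta = g / b
    if np.ptp(theta) == 0:
        logger.warning("all ratio estimates identical; mode is degenerate")
    beta = _kde_argmax(theta, _ratio_weights(b, s, True), bandwidth_factor)

    def point(bb, gg):
        return _kde_argmax(gg / bb, _ratio_weights(bb, s, True),
                           bandwidth_factor, refine=False, n_grid=256)

    se = _bootstrap_se(point, b, g, se_b, s, n_boot, seed)
    return MREstimate(method="weighted_mode", n_variants=len(ins), beta=beta,
                      se=se, pvalue=_normal_p(beta, se))


# ---------------------------------------------------------------------------
# Scans


def single_variant_scan(instruments: list[HarmonizedInstrument]) -> list[tuple[str, MREstimate]]:
    """Wald ratio for every kept instrument, input order preserved."""
    out = []
    for h in kept(instruments):
        if h.beta_exp == 0:
            logger.warning("skipping %s: zero exposure effect", h.rsid)
            continue
        out.append((h.rsid, wald_ratio(h)))
    return out


def leave_one_out(instruments: list[HarmonizedInstrument], base_method=ivw,
                  exclude: tuple[str, ...] = ()) -> list[tuple[str, MREstimate]]:
    """Re-estimate after dropping each instrument (or an explicit set) in turn.

    With ``exclude`` empty: one estimate per dropped variant, each on the
    remaining J-1.  With ``exclude`` given: a single estimate labelled by the
    joined excluded rsids, computed on the instruments that remain.
    """
    ins = kept(instruments)
    if exclude:
        remaining = [h for h in ins if h.rsid not in exclude]
        return [("-".join(exclude), base_method(remaining))]
    if len(ins) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >=3 instruments")
    return [(drop.rsid, base_method([h for h in ins if h.rsid != drop.rsid]))
            for drop in ins]


def funnel_data(instruments: list[HarmonizedInstrument]):
    """Plot-ready funnel table: per-instrument Wald estimate vs its precision."""
    import pandas as pd
    rows = []
    for rsid, est in single_variant_scan(instruments):
        rows.append({"rsid": rsid, "wald_beta": est.beta, "precision": 1.0 / est.se})
    return pd.DataFrame(rows)
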