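"""Two-sample Mendelian-randomization estimators.

All estimators operate on an :class:`~bilimr.instruments.InstrumentSet` of
harmonized per-variant effects (bx, sx) on the exposure (SD units) and
(by, sy) on the outcome (log odds ratio) and return the causal log odds
ratio per 1-SD of exposure:

* Wald ratio (single variant), first-order delta-method SE by default;
* inverse-variance weighted with multiplicative random effects (weighted
  regression through the origin, SE inflated by sqrt(max(1, Q/(k−1))));
* likelihood-based (profile likelihood over the bivariate-normal
  measurement model bx_j ~ N(ξ_j, sx_j²), by_j ~ N(θξ_j, sy_j²), with
  zero exposure–outcome correlation for non-overlapping samples);
* MR-Egger weighted regression with an unconstrained intercept (the
  intercept tests directional pleiotropy; t-distribution with k−2 df);
* weighted median of the Wald ratios (parametric-bootstrap SE);
* simple mode-based estimate (normal-kernel density argmax over the Wald
  ratios with a modified-Silverman bandwidth; parametric-bootstrap SE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm, t as t_dist

from .instruments import HarmonizedInstrument, InstrumentSet

__all__ = [
    "MREstimate",
    "MRConvergenceError",
    "wald_ratio",
    "ivw_mre",
    "likelihood_based",
    "egger",
    "weighted_median",
    "mode_based",
    "leave_out",
]

Z95 = 1.959964  # fixed normal quantile for 95% intervals (bit-reproducible)


class MRConvergenceError(RuntimeError):
    """Raised when an iterative estimator fails to converge."""


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-OR-per-1-SD scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    extras: dict = field(default_factory=dict)
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.or_ = float(np.exp(self.beta))
        self.ci_low = float(np.exp(self.beta - Z95 * self.se))
        self.ci_high = float(np.exp(self.beta + Z95 * self.se))

    def as_dict(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "or": self.or_, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pval, "n_snps": self.n_snps, "extras": self.extras,
        }


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2 * norm.sf(abs(beta) / se))


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-variant causal estimate by/bx with delta-method SE."""
    if inst.bx == 0:
        raise ValueError(f"{inst.snp_id}: undefined ratio (bx = 0)")
    beta = inst.by / inst.bx
    if second_order:
        se = np.sqrt(inst.sy**2 / inst.bx**2 + inst.by**2 * inst.sx**2 / inst.bx**4)
    else:
        se = inst.sy / abs(inst.bx)
    return MREstimate("wald_ratio", float(beta), float(se), _norm_p(beta, se), 1,
                      extras={"snp": inst.snp_id})


def ivw_mre(inst_set: InstrumentSet) -> MREstimate:
    """Inverse-variance weighted estimate with multiplicative random effects."""
    k = inst_set.k
    if k < 2:
        raise ValueError(f"IVW requires k >= 2 instruments, got {k}")
    bx, _, by, sy = inst_set.arrays()
    w = 1.0 / sy**2
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    se_fixed = np.sqrt(1.0 / np.sum(w * bx**2))
    scale = np.sqrt(max(1.0, q / (k - 1)))
    se = se_fixed * scale
    return MREstimate("ivw_mre", float(beta), float(se), _norm_p(beta, se), k,
                      extras={"Q": q, "df": k - 1, "scale": float(scale),
                              "se_fixed": float(se_fixed)})


def _ivw_fixed_beta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    w = 1.0 / sy**2
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def likelihood_based(inst_set: InstrumentSet) -> MREstimate:
    """Profile-likelihood causal estimate under the measurement model.

    For fixed θ, the per-variant means ξ_j maximize out analytically,
    leaving the profile log-likelihood
    −½ Σ (by_j − θ·bx_j)² / (sy_j² + θ²·sx_j²); the SE comes from its
    numerical curvature at the maximum.
    """
    k = inst_set.k
    if k < 1:
        raise ValueError("likelihood-based MR requires k >= 1 instruments")
    bx, sx, by, sy = inst_set.arrays()

    def nll(theta: float) -> float:
        return 0.5 * float(np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)))

    theta0 = _ivw_fixed_beta(bx, by, sy)
    try:
        res = optimize.minimize_scalar(
            nll, bracket=(theta0 - 0.5, theta0 + 0.5),
            method="brent", options={"maxiter": 500, "xtol": 1e-12},
        )
    except ValueError:
        res = optimize.minimize_scalar(
            nll, bounds=(theta0 - 20.0, theta0 + 20.0),
            method="bounded", options={"maxiter": 500, "xatol": 1e-12},
        )
    if not np.isfinite(res.x):
        raise MRConvergenceError(f"likelihood-based MR failed: {res}")
    theta = float(res.x)
    h = 1e-5 * max(1.0, abs(theta))
    curv = (nll(theta + h) - 2 * nll(theta) + nll(theta - h)) / h**2
    if not np.isfinite(curv) or curv <= 0:
        raise MRConvergenceError(
            f"likelihood-based MR: non-positive curvature {curv} at theta={theta}")
    se = float(1.0 / np.sqrt(curv))
    return MREstimate("likelihood_based", theta, se, _norm_p(theta, se), k,
                      extras={"nll": float(res.fun), "iterations": int(res.nit)})


def egger(inst_set: InstrumentSet) -> MREstimate:
    """MR-Egger weighted regression of by on bx with an intercept.

    Instruments are oriented to bx ≥ 0 before fitting; weights are 1/sy².
    Inference uses the weighted-least-squares residual variance and a
    t-distribution with k−2 degrees of freedom for both slope and
    intercept; the intercept p-value is the directional-pleiotropy test.
    """
    k = inst_set.k
    if k < 3:
        raise ValueError(f"MR-Egger requires k >= 3 instruments, got {k}")
    bx, _, by, sy = inst_set.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    w = 1.0 / sy**2

    X = np.column_stack([np.ones(k), x])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ y)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(xtwx) * sigma2
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    def t_p(val: float, se: float) -> float:
        if se == 0:
            return 0.0 if val != 0 else 1.0
        return float(2 * t_dist.sf(abs(val) / se, k - 2))

    p_slope = t_p(slope, se_slope)
    p_int = t_p(intercept, se_int)
    return MREstimate("egger", slope, se_slope, p_slope, k,
                      extras={"intercept": intercept, "intercept_se": se_int,
                              "intercept_p": p_int, "sigma2": sigma2, "df": k - 2})


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= cum[0]:
        return float(v[0])
    if 0.5 >= cum[-1]:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def _ratio_arrays(inst_set: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    bx, _, by, sy = inst_set.arrays()
    if np.any(bx == 0):
        raise ValueError("Wald ratios undefined: some bx = 0")
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    return ratios, se_ratio


def weighted_median(inst_set: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the per-variant Wald ratios.

    Weights are the inverse variances of the ratios (first-order); the
    estimate is consistent when valid instruments carry at least half the
    weight.  SE by parametric bootstrap with an explicit seed.
    """
    k = inst_set.k
    if k < 3:
        raise ValueError(f"weighted median requires k >= 3 instruments, got {k}")
    ratios, se_ratio = _ratio_arrays(inst_set)
    weights = 1.0 / se_ratio**2
    beta = _weighted_median(ratios, weights)
    boots = _bootstrap_ratio_statistic(
        inst_set, n_boot, seed,
        lambda r, s: _weighted_median(r, 1.0 / s**2),
    )
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", beta, se, _norm_p(beta, se), k,
                      extras={"n_boot": n_boot, "seed": seed})


def _mode_estimate(ratios: np.ndarray, bandwidth_factor: float, grid_size: int = 2048) -> float:
    r = np.asarray(ratios, float)
    if np.ptp(r) == 0:
        return float(r[0])
    s = np.std(r, ddof=1)
    mad = np.median(np.abs(r - np.median(r))) * 1.4826
    sig = min(s, mad) if mad > 0 else s
    h = bandwidth_factor * 0.9 * sig * len(r) ** (-0.2)
    if h <= 0:
        return float(np.median(r))
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_based(
    inst_set: InstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Simple mode-based estimate: argmax of a normal-kernel density over
    the Wald ratios, bandwidth = bandwidth_factor × modified-Silverman rule.
    SE by parametric bootstrap with an explicit seed."""
    k = inst_set.k
    if k < 3:
        raise ValueError(f"mode-based estimate requires k >= 3 instruments, got {k}")
    ratios, _ = _ratio_arrays(inst_set)
    beta = _mode_estimate(ratios, bandwidth_factor)
    boots = _bootstrap_ratio_statistic(
        inst_set, n_boot, seed,
        lambda r, s: _mode_estimate(r, bandwidth_factor),
    )
    se = float(np.std(boots, ddof=1))
    return MREstimate("mode_based", beta, se, _norm_p(beta, se), k,
                      extras={"bandwidth_factor": bandwidth_factor,
                              "n_boot": n_boot, "seed": seed})


def _bootstrap_ratio_statistic(inst_set, n_boot, seed, stat) -> np.ndarray:
    """Parametric bootstrap of a statistic of (ratios, ratio SEs)."""
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = inst_set.arrays()
    k = len(bx)
    out = np.empty(n_boot)
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    for b in range(n_boot):
        xb = bxs[b]
        xb = np.where(xb == 0, 1e-300, xb)
        r = bys[b] / xb
        s = sy / np.abs(xb)
        out[b] = stat(r, s)
    return out


def leave_out(inst_set: InstrumentSet, snp_id: str) -> InstrumentSet:
    """Return the instrument set without one variant (diagnostics
    recomputed)."""
    ids = inst_set.ids()
    if snp_id not in ids:
        raise KeyError(f"snp {snp_id!r} not in instrument set")
    return InstrumentSet(
        [i for i in inst_set.instruments if i.snp_id != snp_id],
        inst_set.exposure_n,
    )
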