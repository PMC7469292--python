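"""MR-PRESSO: pleiotropy residual sum and outlier test.

A simulation-based test for horizontal pleiotropy in two-sample MR.  The
observed statistic is the inverse-variance-weighted residual sum of
squares of each variant against the leave-one-out IVW fit.  A parametric
null distribution is obtained by redrawing (bx, by) from their standard
errors under the leave-one-out fitted model.  Three outputs:

* ``global_p`` — empirical tail probability of the observed RSS
  (heterogeneity between variant effects, evidence of pleiotropy);
* per-variant outlier p-values (Bonferroni-adjusted) and the flagged set;
* ``distortion_p`` — whether removing the flagged outliers significantly
  shifts the causal estimate, against random same-size removals.

Empirical p-values use the (r+1)/(n+1) estimator and are therefore never
exactly zero; all randomness is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instruments import InstrumentSet
from .mr import MREstimate, ivw_mre

__all__ = ["PressoResult", "run_presso"]


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    per_snp_outlier_p: dict[str, float]
    outliers: list[str]
    distortion_coef: float | None
    distortion_p: float | None
    estimate_all: MREstimate
    estimate_no_outliers: MREstimate
    n_sim: int
    seed: int


def _loo_theta(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW (fixed-effect) slope for every variant."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def _weighted_loo_residuals(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    theta = _loo_theta(bx, by, w)
    return w * (by - theta * bx) ** 2


def run_presso(
    inst_set: InstrumentSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Run the global, outlier, and distortion tests.

    Requires at least 4 instruments and 100 simulations.  Outliers are
    variants whose Bonferroni-adjusted per-variant p-value falls below
    ``outlier_alpha``; when none are flagged the distortion test is
    reported as not applicable (``None``).
    """
    k = inst_set.k
    if k < 4:
        raise ValueError(f"MR-PRESSO requires k >= 4 instruments, got {k}")
    if n_sim < 100:
        raise ValueError(f"n_sim must be >= 100, got {n_sim}")

    rng = np.random.default_rng(seed)
    bx, sx, by, sy = inst_set.arrays()
    ids = inst_set.ids()
    w = 1.0 / sy**2

    obs_res = _weighted_loo_residuals(bx, by, w)
    global_rss = float(np.sum(obs_res))

    # Null simulations are generated under one homogeneous slope — the
    # median of the leave-one-out estimates, which is robust to outliers.
    # Using per-variant leave-one-out means instead would inject their
    # spread into the null and make the global test conservative when
    # instrument strengths are highly asymmetric.
    theta_null = float(np.median(_loo_theta(bx, by, w)))
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_null * bx, sy, size=(n_sim, k))

    # vectorized leave-one-out residuals across simulations
    s_xy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    th = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim**2)
    sim_res = w * (by_sim - th * bx_sim) ** 2
    sim_rss = sim_res.sum(axis=1)

    global_p = float((np.sum(sim_rss >= global_rss) + 1) / (n_sim + 1))

    per_p_raw = (np.sum(sim_res >= obs_res[None, :], axis=0) + 1) / (n_sim + 1)
    per_p_adj = np.minimum(1.0, per_p_raw * k)
    per_snp_outlier_p = {i: float(p) for i, p in zip(ids, per_p_adj)}
    outlier_mask = per_p_adj < outlier_alpha
    outliers = [i for i, o in zip(ids, outlier_mask) if o]

    estimate_all = ivw_mre(inst_set)
    if outliers and k - len(outliers) >= 2:
        keep = [i for i in ids if i not in outliers]
        estimate_no = ivw_mre(inst_set.subset(keep))
        denom = abs(estimate_no.beta) if estimate_no.beta != 0 else np.finfo(float).tiny
        d_obs = 100.0 * (estimate_all.beta - estimate_no.beta) / denom
        # null distortion: remove random same-size subsets of the non-outliers
        inlier_idx = np.flatnonzero(~outlier_mask)
        n_out = len(outliers)
        if len(inlier_idx) - n_out < 2:
            return PressoResult(
                global_rss=global_rss, global_p=global_p,
                per_snp_outlier_p=per_snp_outlier_p, outliers=outliers,
                distortion_coef=float(d_obs), distortion_p=None,
                estimate_all=estimate_all, estimate_no_outliers=estimate_no,
                n_sim=n_sim, seed=seed,
            )
        d_null = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(inlier_idx, size=n_out, replace=False)
            mask = np.zeros(k, dtype=bool)
            mask[inlier_idx] = True
            mask[drop] = False
            th_b = float(np.sum(w[mask] * bx[mask] * by[mask])
                         / np.sum(w[mask] * bx[mask] ** 2))
            d_null[b] = 100.0 * (th_b - estimate_no.beta) / denom
        distortion_p = float((np.sum(np.abs(d_null) >= abs(d_obs)) + 1) / (n_sim + 1))
        distortion_coef = float(d_obs)
    else:
        estimate_no = estimate_all
        distortion_p = None
        distortion_coef = None

    return PressoResult(
        global_rss=global_rss,
        global_p=global_p,
        per_snp_outlier_p=per_snp_outlier_p,
        outliers=outliers,
        distortion_coef=distortion_coef,
        distortion_p=distortion_p,
        estimate_all=estimate_all,
        estimate_no_outliers=estimate_no,
        n_sim=n_sim,
        seed=seed,
    )
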