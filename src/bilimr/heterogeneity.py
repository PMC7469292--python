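"""Between-estimate heterogeneity statistics (Cochran Q, I²).

Used for the between-sex comparison of causal and serological estimates:
a fixed-effect inverse-variance pooling of the two log odds ratios,
Cochran's Q with 1 degree of freedom, the I² share of variance attributed
to heterogeneity (truncated at 0), and a chi-square p-value.  A helper
reconstructs the log-scale standard error from a printed odds ratio and
its 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

__all__ = ["HetResult", "se_from_ci", "cochran_q", "sex_heterogeneity"]

Z95 = 1.959964


@dataclass
class HetResult:
    q: float
    df: int
    i2: float
    pval: float

    def as_dict(self) -> dict:
        return {"q": self.q, "df": self.df, "i2": self.i2, "pval": self.pval}


def se_from_ci(or_: float, ci_low: float, ci_high: float) -> float:
    """Log-OR standard error from a symmetric (log-scale) 95% interval."""
    if not (0 < ci_low <= or_ <= ci_high):
        raise ValueError(
            f"require 0 < ci_low <= or <= ci_high, got ({or_}, {ci_low}, {ci_high})")
    return float((np.log(ci_high) - np.log(ci_low)) / (2 * Z95))


def cochran_q(betas: Sequence[float], ses: Sequence[float]) -> HetResult:
    """Fixed-effect Cochran Q and I² across k estimates (df = k−1)."""
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    if len(b) < 2:
        raise ValueError("need at least two estimates")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all standard errors must be finite and positive")
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(b) - 1
    i2 = 100.0 * max(0.0, (q - df) / q) if q > 0 else 0.0
    return HetResult(q=q, df=df, i2=float(i2), pval=float(chi2.sf(q, df)))


def _beta_se(est) -> tuple[float, float]:
    if isinstance(est, tuple) and len(est) == 2:
        return float(est[0]), float(est[1])
    beta = getattr(est, "beta", None)
    se = getattr(est, "se", None)
    if beta is None or se is None:
        raise ValueError(f"estimate {est!r} carries no beta/se")
    return float(beta), float(se)


def sex_heterogeneity(est_m, est_f) -> HetResult:
    """Fixed-effect heterogeneity between the male and female estimates.

    Accepts any pair of objects exposing ``beta`` and ``se`` on the log-OR
    scale (MR estimates, conditional-logistic results) or plain
    ``(beta, se)`` tuples; df is 1.
    """
    bm, sm = _beta_se(est_m)
    bf, sf = _beta_se(est_f)
    return cochran_q([bm, bf], [sm, sf])
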