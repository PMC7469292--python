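"""Matched case-control (serological) analysis.

Conditional logistic regression for 1:1 matched sets via the exact
pair-difference reduction: conditioning on one case per pair, the
likelihood is a no-intercept binomial likelihood on within-pair covariate
differences (case minus control), maximized here by Newton iterations
with step-halving.  On top of it:

* restricted-cubic-spline dose-response with a Wald nonlinearity test
  (three knots at the 10th/50th/90th percentiles, one nonlinear term);
* effect-modification (interaction) tests with stratum-specific estimates;
* cancer sub-site heterogeneity via a competing-risks stratified
  conditional likelihood (the exposure coefficient is indexed by the
  case's sub-site; overlapping colon lesions count toward all-colon only);
* liver-function exclusions by the BTR index (branched-chain amino acids /
  tyrosine) and Fischer's ratio (BCAA / (tyrosine + phenylalanine));
* validation of the lead genotype as an exposure instrument by ordinary
  least squares of log-exposure on allele dose in controls.

Exposure is analyzed as log-transformed and standardized per 1-SD;
standardization moments default to sex-specific because all models are
sex-stratified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, inv, solve
from scipy.special import expit
from scipy.stats import chi2, linregress, norm

__all__ = [
    "ClogitResult",
    "SplineSpec",
    "LiverIndices",
    "SeparationError",
    "standardize_log_exposure",
    "clogit_fit",
    "spline_nonlinearity",
    "interaction_test",
    "subsite_heterogeneity",
    "liver_exclusion",
    "liver_indices",
    "genotype_exposure_check",
    "restricted_cubic_spline",
]

Z95 = 1.959964

CATEGORICAL = {"education", "smoking", "physical_activity", "ht_use", "menopause",
               "center", "fasting", "sex", "subsite"}


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a conditional fit."""

    def __init__(self, covariate: str):
        super().__init__(f"complete separation detected for covariate {covariate!r}")
        self.covariate = covariate


@dataclass
class ClogitResult:
    """Result of a conditional logistic fit (1:1 pair-difference form)."""

    params: dict[str, float]
    bse: dict[str, float]
    exposure_term: str
    or_per_sd: float
    ci_low: float
    ci_high: float
    pval: float
    n_pairs_used: int
    converged: bool
    n_iter: int
    loglike: float
    cov: np.ndarray
    names: list[str]

    @property
    def beta(self) -> float:
        """Log odds ratio of the exposure term (for pooling/heterogeneity)."""
        return self.params[self.exposure_term]

    @property
    def se(self) -> float:
        return self.bse[self.exposure_term]

    def as_dict(self) -> dict:
        return {
            "or_per_sd": self.or_per_sd, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "pval": self.pval, "beta": self.beta,
            "se": self.se, "n_pairs_used": self.n_pairs_used,
            "converged": self.converged,
        }


@dataclass
class SplineSpec:
    """Three-knot restricted cubic spline placement."""

    knots: tuple[float, float, float]
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0)

    def __post_init__(self) -> None:
        k = tuple(self.knots)
        if not (k[0] < k[1] < k[2]):
            raise ValueError(f"knots must be strictly increasing, got {k}")
        self.knots = k


@dataclass
class LiverIndices:
    btr: float
    fischer: float


def standardize_log_exposure(
    pairs: pd.DataFrame, sd_scope: str = "sex_specific"
) -> pd.DataFrame:
    """Return a copy with ``z_log_exposure`` (z-scored log exposure).

    Moments (sample SD, ddof=1) are computed over all members in scope —
    pooled or per sex.  Non-positive exposures and zero spread raise.
    """
    if sd_scope not in ("pooled", "sex_specific"):
        raise ValueError(f"sd_scope must be 'pooled' or 'sex_specific', got {sd_scope!r}")
    bad = pairs[pairs["exposure"] <= 0]
    if len(bad):
        pid = bad.iloc[0]["pair_id"]
        raise ValueError(f"non-positive exposure in pair {pid}")
    out = pairs.copy()
    logx = np.log(out["exposure"].to_numpy(float))
    out["_logx"] = logx
    groups = [("all", out.index)] if sd_scope == "pooled" else \
        [(s, idx) for s, idx in out.groupby("sex").groups.items()]
    z = np.empty(len(out))
    for label, idx in groups:
        vals = out.loc[idx, "_logx"].to_numpy(float)
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"constant exposure in scope {label!r}: zero SD")
        z[out.index.get_indexer(idx)] = (vals - vals.mean()) / sd
    out["z_log_exposure"] = z
    return out.drop(columns="_logx")


# ---------------------------------------------------------------------------
# pair-difference design and Newton fitter

def _member_design(
    df: pd.DataFrame,
    exposure_cols: Sequence[str],
    covariates: Sequence[str],
    missing_policy: str = "category",
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in exposure_cols:
        cols.append(df[c].to_numpy(float))
        names.append(c)
    for c in covariates:
        if c in CATEGORICAL or df[c].dtype == object:
            vals = df[c].astype(object).where(~pd.isna(df[c]), "missing").astype(str)
            if missing_policy != "category":
                raise ValueError(f"unsupported missing_policy {missing_policy!r}")
            levels = sorted(vals.unique())
            for lev in levels[1:]:  # first level is the reference
                cols.append((vals == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
        else:
            v = df[c].to_numpy(float)
            if np.any(np.isnan(v)):
                raise ValueError(f"continuous covariate {c!r} has missing values")
            cols.append(v)
            names.append(c)
    return np.column_stack(cols) if cols else np.empty((len(df), 0)), names


def _pair_differences(
    pairs: pd.DataFrame,
    exposure_cols: Sequence[str],
    covariates: Sequence[str],
    missing_policy: str = "category",
) -> tuple[np.ndarray, list[str]]:
    df = pairs.sort_values(["pair_id", "is_case"], ascending=[True, False])
    counts = df.groupby("pair_id").agg(n=("is_case", "size"), ncase=("is_case", "sum"))
    if not ((counts["n"] == 2).all() and (counts["ncase"] == 1).all()):
        raise ValueError("each pair must have exactly one case and one control")
    X, names = _member_design(df, exposure_cols, covariates, missing_policy)
    case = X[df["is_case"].to_numpy(bool)]
    ctrl = X[~df["is_case"].to_numpy(bool)]
    return case - ctrl, names


def _newton_pair_logit(
    D: np.ndarray, names: Sequence[str], max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Maximize sum log sigmoid(D beta) (the 1:1 conditional likelihood)."""
    n, p = D.shape
    beta = np.zeros(p)

    def ll(b: np.ndarray) -> float:
        eta = D @ b
        # log sigmoid, numerically stable
        return float(-np.sum(np.logaddexp(0.0, -eta)))

    cur = ll(beta)
    converged = False
    it = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        from scipy.linalg import LinAlgWarning
        warnings.simplefilter("ignore", category=LinAlgWarning)
        for it in range(1, max_iter + 1):
            eta = D @ beta
            mu = expit(eta)
            grad = D.T @ (1.0 - mu)
            wdiag = mu * (1.0 - mu)
            H = (D * wdiag[:, None]).T @ D
            try:
                step = solve(H, grad, assume_a="pos")
            except (LinAlgError, np.linalg.LinAlgError) as exc:
                raise ValueError(
                    "singular information matrix (collinear covariates "
                    f"among {list(names)})") from exc
            alpha = 1.0
            for _ in range(40):
                new = beta + alpha * step
                new_ll = ll(new)
                if new_ll >= cur - 1e-14:
                    break
                alpha *= 0.5
            beta = beta + alpha * step
            prev, cur = cur, ll(beta)
            if np.max(np.abs(beta)) > 15:
                j = int(np.argmax(np.abs(beta)))
                raise SeparationError(names[j])
            if np.max(np.abs(alpha * step)) < 1e-9 and abs(cur - prev) < tol:
                converged = True
                break
    cov = inv((D * (expit(D @ beta) * (1 - expit(D @ beta)))[:, None]).T @ D)
    return beta, cov, cur, it, converged


def _fit_diffs(
    D: np.ndarray, names: list[str], exposure_term: str,
    drop_separated: bool = False,
) -> ClogitResult:
    informative = np.any(D != 0, axis=1)
    n_used = int(informative.sum())
    if n_used == 0:
        raise ValueError("zero informative pairs: all within-pair differences are 0")
    Dn = D[informative]
    nonzero_cols = np.any(Dn != 0, axis=0)
    if exposure_term in names and not nonzero_cols[names.index(exposure_term)]:
        raise ValueError(f"exposure term {exposure_term!r} has no within-pair variation")
    kept_names = [n for n, keep in zip(names, nonzero_cols) if keep]
    Dk = Dn[:, nonzero_cols]
    while True:
        try:
            beta, cov, loglike, n_iter, converged = _newton_pair_logit(Dk, kept_names)
            break
        except SeparationError as exc:
            # In sparse strata a rare dummy level can separate; collapsing it
            # into the reference keeps the conditional MLE finite.
            if not drop_separated or exc.covariate == exposure_term:
                raise
            warnings.warn(f"collapsing separated covariate column {exc.covariate!r}")
            j = kept_names.index(exc.covariate)
            kept_names = kept_names[:j] + kept_names[j + 1:]
            Dk = np.delete(Dk, j, axis=1)
    params = dict(zip(kept_names, map(float, beta)))
    bse = dict(zip(kept_names, map(float, np.sqrt(np.diag(cov)))))
    for n in names:  # absorbed (pair-constant) columns
        params.setdefault(n, 0.0)
        bse.setdefault(n, float("nan"))
    b, s = params[exposure_term], bse[exposure_term]
    return ClogitResult(
        params=params, bse=bse, exposure_term=exposure_term,
        or_per_sd=float(np.exp(b)),
        ci_low=float(np.exp(b - Z95 * s)), ci_high=float(np.exp(b + Z95 * s)),
        pval=float(2 * norm.sf(abs(b) / s)) if s > 0 else 1.0,
        n_pairs_used=n_used, converged=converged, n_iter=n_iter,
        loglike=loglike, cov=cov, names=kept_names,
    )


def clogit_fit(
    pairs: pd.DataFrame,
    covariates: Sequence[str] = (),
    exposure_col: str = "z_log_exposure",
    missing_policy: str = "category",
    drop_separated: bool = False,
) -> ClogitResult:
    """Fit the 1:1 conditional logistic model.

    The crude model uses no covariates (matching factors are absorbed by
    the pairing); the multivariable model lists the adjustment covariates,
    continuous ones entered linearly and categorical ones dummy-coded with
    missing values as their own level.
    """
    D, names = _pair_differences(pairs, [exposure_col], covariates, missing_policy)
    return _fit_diffs(D, names, exposure_col, drop_separated=drop_separated)


# ---------------------------------------------------------------------------
# restricted cubic splines

def restricted_cubic_spline(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Nonlinear basis term of a 3-knot restricted cubic spline.

    Zero at and below the first knot, linear beyond the last; scaled by
    (k3−k1)² so its coefficient is on the scale of the linear term.
    """
    k1, k2, k3 = knots
    if not (k1 < k2 < k3):
        raise ValueError(f"knots must be strictly increasing, got {knots}")
    x = np.asarray(x, float)

    def cube(v):
        return np.clip(v, 0.0, None) ** 3

    return (cube(x - k1) - cube(x - k2) * (k3 - k1) / (k3 - k2)
            + cube(x - k3) * (k2 - k1) / (k3 - k2)) / (k3 - k1) ** 2


def spline_nonlinearity(
    pairs: pd.DataFrame,
    spec: SplineSpec | None = None,
    covariates: Sequence[str] = (),
    scale: str = "raw",
    n_grid: int = 100,
) -> tuple[pd.DataFrame, float, ClogitResult]:
    """Spline dose-response and Wald test of the nonlinear term.

    Fits the conditional model with a linear and one restricted-cubic
    nonlinear term of the exposure (raw scale by default, ``scale='log'``
    for log-exposure); returns the predicted log-OR curve relative to the
    first (10th-percentile) knot, the nonlinearity p-value, and the fit.
    """
    if scale not in ("raw", "log"):
        raise ValueError(f"scale must be 'raw' or 'log', got {scale!r}")
    work = pairs.copy()
    x = work["exposure"].to_numpy(float)
    if scale == "log":
        if np.any(x <= 0):
            raise ValueError("non-positive exposure on log scale")
        x = np.log(x)
    if spec is None:
        spec = SplineSpec(tuple(np.percentile(x, [10, 50, 90])))
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct exposure values")
    work["_sx"] = x
    work["_spl"] = restricted_cubic_spline(x, spec.knots)
    D, names = _pair_differences(work, ["_sx", "_spl"], covariates)
    res = _fit_diffs(D, names, "_sx")
    b1, b2 = res.params["_sx"], res.params["_spl"]
    se2 = res.bse["_spl"]
    p_nonlinear = float(2 * norm.sf(abs(b2) / se2)) if se2 > 0 else 1.0

    ref = spec.knots[0]
    grid = np.linspace(x.min(), x.max(), n_grid)
    curve = pd.DataFrame({
        "exposure": grid,
        "log_or": b1 * (grid - ref)
        + b2 * (restricted_cubic_spline(grid, spec.knots)
                - restricted_cubic_spline(np.array([ref]), spec.knots)[0]),
    })
    return curve, p_nonlinear, res


# ---------------------------------------------------------------------------
# effect modification and sub-site heterogeneity

@dataclass
class StratifiedResult:
    strata: dict[str, ClogitResult]
    q: float
    df: int
    p_heterogeneity: float


def _case_level(pairs: pd.DataFrame, column: str) -> pd.Series:
    """Per-pair value of ``column`` taken from the case member."""
    cases = pairs[pairs["is_case"]]
    return cases.set_index("pair_id")[column]


def _wald_equality(betas: np.ndarray, ses: np.ndarray) -> tuple[float, int, float]:
    """Inverse-variance Wald test that all coefficients are equal."""
    w = 1.0 / ses**2
    pooled = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = len(betas) - 1
    return q, df, float(chi2.sf(q, df))


def interaction_test(
    pairs: pd.DataFrame,
    modifier: str,
    cutpoint: str = "median",
    covariates: Sequence[str] = (),
    exposure_col: str = "z_log_exposure",
) -> StratifiedResult:
    """Multiplicative effect modification of the exposure association.

    Continuous modifiers are dichotomized at the pooled median by default
    (``cutpoint='median'``); categorical modifiers (or
    ``cutpoint='categories'``) use their observed levels, missing as its
    own level.  The pair's stratum is the case member's value.  Returns
    stratum-specific conditional-logistic estimates and a Wald
    heterogeneity p-value for equality of the stratum exposure
    coefficients.
    """
    if modifier not in pairs.columns:
        raise ValueError(f"modifier {modifier!r} not in cohort columns")
    col = pairs[modifier]
    is_continuous = pd.api.types.is_numeric_dtype(col) and modifier not in CATEGORICAL
    if is_continuous and cutpoint == "median":
        med = float(col.median())
        stratum_member = np.where(col.to_numpy(float) < med, "low", "high")
    else:
        stratum_member = col.astype(object).where(~pd.isna(col), "missing").astype(str)
    work = pairs.copy()
    work["_stratum"] = stratum_member
    case_stratum = _case_level(work, "_stratum")
    if case_stratum.nunique() < 2:
        raise ValueError(f"modifier {modifier!r} is constant across case strata")

    strata: dict[str, ClogitResult] = {}
    betas, ses = [], []
    for lev in sorted(case_stratum.unique()):
        sub_ids = case_stratum.index[case_stratum == lev]
        sub = work[work["pair_id"].isin(sub_ids)]
        try:
            res = clogit_fit(sub, covariates=covariates, exposure_col=exposure_col,
                             drop_separated=True)
        except (ValueError, SeparationError) as exc:
            warnings.warn(f"stratum {lev!r} skipped: {exc}")
            continue
        strata[str(lev)] = res
        betas.append(res.beta)
        ses.append(res.se)
    if len(strata) < 2:
        raise ValueError("fewer than two informative strata")
    q, df, p = _wald_equality(np.array(betas), np.array(ses))
    return StratifiedResult(strata=strata, q=q, df=df, p_heterogeneity=p)


_SITE_GROUPS = {
    "colon-vs-rectum": {
        "proximal": "colon", "distal": "colon",
        "overlapping-colon": "colon", "rectum": "rectum",
    },
    # overlapping lesions count toward all-colon only, so they are excluded
    # from the proximal-vs-distal comparison
    "proximal-vs-distal": {"proximal": "proximal", "distal": "distal"},
}


def subsite_heterogeneity(
    pairs: pd.DataFrame,
    grouping: str = "colon-vs-rectum",
    covariates: Sequence[str] = (),
    exposure_col: str = "z_log_exposure",
) -> StratifiedResult:
    """Sub-site-specific associations and their heterogeneity.

    A competing-risks stratified conditional likelihood: each case is
    compared with its matched control and the exposure coefficient is
    indexed by the case's sub-site, which for 1:1 sets factorizes into
    independent per-site conditional fits; heterogeneity is a Wald test of
    coefficient equality.
    """
    if grouping not in _SITE_GROUPS:
        raise ValueError(f"grouping must be one of {sorted(_SITE_GROUPS)}, got {grouping!r}")
    site_map = _SITE_GROUPS[grouping]
    case_site = _case_level(pairs, "subsite").map(site_map)
    case_site = case_site.dropna()

    strata: dict[str, ClogitResult] = {}
    betas, ses = [], []
    for site in sorted(set(site_map.values())):
        sub_ids = case_site.index[case_site == site]
        if len(sub_ids) == 0:
            warnings.warn(f"sub-site {site!r} has no pairs; excluded")
            continue
        sub = pairs[pairs["pair_id"].isin(sub_ids)]
        strata[site] = clogit_fit(sub, covariates=covariates, exposure_col=exposure_col,
                                  drop_separated=True)
        betas.append(strata[site].beta)
        ses.append(strata[site].se)
    if len(strata) < 2:
        raise ValueError("need at least two sub-sites with informative pairs")
    q, df, p = _wald_equality(np.array(betas), np.array(ses))
    return StratifiedResult(strata=strata, q=q, df=df, p_heterogeneity=p)


# ---------------------------------------------------------------------------
# sensitivity filters and instrument validation

def liver_indices(bcaa: float, tyrosine: float, phenylalanine: float) -> LiverIndices:
    """BTR index (BCAA/Tyr) and Fischer's ratio (BCAA/(Tyr+Phe))."""
    if tyrosine == 0 or tyrosine + phenylalanine == 0:
        raise ValueError("zero denominator in liver index")
    return LiverIndices(btr=bcaa / tyrosine, fischer=bcaa / (tyrosine + phenylalanine))


def liver_exclusion(
    pairs: pd.DataFrame, btr_min: float = 4.4, fischer_min: float = 1.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude pairs with suspected hepatic impairment.

    A pair is dropped when either member's BTR index or Fischer's ratio
    falls below the corresponding threshold.  Returns the filtered cohort
    and an exclusion log (pair, member role, indices, reason).
    """
    tyr = pairs["tyrosine"].to_numpy(float)
    phe = pairs["phenylalanine"].to_numpy(float)
    bad = (tyr == 0) | (tyr + phe == 0)
    if np.any(bad):
        pid = pairs.loc[np.flatnonzero(bad)[0], "pair_id"]
        raise ValueError(f"zero liver-index denominator in pair {pid}")
    btr = pairs["bcaa"].to_numpy(float) / tyr
    fischer = pairs["bcaa"].to_numpy(float) / (tyr + phe)
    low = (btr < btr_min) | (fischer < fischer_min)
    log_rows = pairs.loc[low, ["pair_id", "is_case"]].copy()
    log_rows["btr"] = btr[low]
    log_rows["fischer"] = fischer[low]
    log_rows["reason"] = np.where(btr[low] < btr_min, "btr", "fischer")
    dropped_pairs = set(log_rows["pair_id"])
    filtered = pairs[~pairs["pair_id"].isin(dropped_pairs)].copy()
    return filtered, log_rows.reset_index(drop=True)


@dataclass
class GenotypeExposureResult:
    slope: float
    r2: float
    pval: float
    n: int


def genotype_exposure_check(controls: pd.DataFrame) -> GenotypeExposureResult:
    """OLS of measured log-exposure on lead-variant allele dose in controls."""
    sub = controls.dropna(subset=["lead_genotype", "exposure"])
    if len(sub) < 3:
        raise ValueError(f"need >= 3 controls with genotype and exposure, got {len(sub)}")
    g = sub["lead_genotype"].to_numpy(float)
    if np.ptp(g) == 0:
        raise ValueError("constant genotype: regression undefined")
    y = np.log(sub["exposure"].to_numpy(float))
    fit = linregress(g, y)
    return GenotypeExposureResult(
        slope=float(fit.slope), r2=float(fit.rvalue**2),
        pval=float(fit.pvalue), n=len(sub),
    )
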