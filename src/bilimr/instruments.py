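"""Instrument diagnostics, QC filtering, and exposure/outcome harmonization.

The genetic instrument for the exposure is a set of independent variants.
This module computes per-variant variance explained (2·MAF(1−MAF)·β² for a
standardized trait), the instrument-strength F-statistic
F = ((n−k−1)/k)·(R²/(1−R²)), applies the consortium QC filters (call rate,
Hardy-Weinberg equilibrium in controls, minor allele frequency), and aligns
exposure and outcome associations to a common effect allele.  Palindromic
(A/T, C/G) variants are either dropped or replaced by a supplied
high-LD proxy; allele-frequency-based strand rescue is deliberately not
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SNPAssociation",
    "HarmonizedInstrument",
    "InstrumentSet",
    "variance_explained",
    "f_statistic",
    "qc_filter",
    "harmonize",
    "mr_power_binary",
    "associations_from_frame",
    "report_to_frame",
]

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class SNPAssociation:
    """One variant's summary association with a trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float = 1.0
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    call_rate: float | None = None
    hwe_p: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (0 < self.eaf < 1):
            raise ValueError(f"{self.snp_id}: eaf must be in (0,1), got {self.eaf}")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _AMBIGUOUS


@dataclass
class HarmonizedInstrument:
    """Exposure/outcome effects aligned to a common effect allele."""

    snp_id: str
    bx: float
    sx: float
    by: float
    sy: float
    eaf: float
    aligned_allele: str
    other_allele: str
    provenance: str = "direct"

    def __post_init__(self) -> None:
        if not (self.sx > 0 and self.sy > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be > 0")


@dataclass
class InstrumentSet:
    """An analysis-ready instrument set with strength diagnostics."""

    instruments: list[HarmonizedInstrument]
    exposure_n: int
    r2_total: float = field(init=False)
    f_statistic: float = field(init=False)

    def __post_init__(self) -> None:
        self.r2_total = float(
            sum(variance_explained(i.bx, i.eaf) for i in self.instruments)
        )
        k = len(self.instruments)
        if k >= 1 and self.exposure_n > k + 1 and 0 <= self.r2_total < 1:
            self.f_statistic = f_statistic(self.r2_total, self.exposure_n, k)
        else:
            self.f_statistic = float("nan")

    @property
    def k(self) -> int:
        return len(self.instruments)

    def ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        bx = np.array([i.bx for i in self.instruments])
        sx = np.array([i.sx for i in self.instruments])
        by = np.array([i.by for i in self.instruments])
        sy = np.array([i.sy for i in self.instruments])
        return bx, sx, by, sy

    def subset(self, ids: Iterable[str]) -> "InstrumentSet":
        keep = set(ids)
        return InstrumentSet(
            [i for i in self.instruments if i.snp_id in keep], self.exposure_n
        )


def variance_explained(beta_sd: float, maf: float) -> float:
    """Phenotypic variance explained by one variant: 2·maf·(1−maf)·β²."""
    if not (0 < maf < 1):
        raise ValueError(f"maf must be in (0,1), got {maf}")
    return 2.0 * maf * (1.0 - maf) * beta_sd**2


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument F-statistic, F = ((n−k−1)/k)·(R²/(1−R²))."""
    if not (0 <= r2 < 1):
        raise ValueError(f"r2 must be in [0,1), got {r2}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ValueError(f"need n > k+1, got n={n}, k={k}")
    return ((n - k - 1) / k) * (r2 / (1.0 - r2))


def qc_filter(
    snps: Sequence[SNPAssociation],
    call_rate_min: float = 0.98,
    hwe_p_min: float = 1e-4,
    maf_min: float = 0.01,
) -> tuple[list[SNPAssociation], list[tuple[SNPAssociation, str]]]:
    """Partition variants into (kept, removed-with-reason).

    A variant is removed iff its call rate is below ``call_rate_min``, its
    Hardy-Weinberg p-value is below ``hwe_p_min``, or its minor allele
    frequency is at or below ``maf_min``; only the first failing reason is
    recorded.  Missing optional fields pass the corresponding check.
    """
    for name, val in (("call_rate_min", call_rate_min),
                      ("hwe_p_min", hwe_p_min), ("maf_min", maf_min)):
        if not (0 < val < 1):
            raise ValueError(f"{name} must be in (0,1), got {val}")
    kept: list[SNPAssociation] = []
    removed: list[tuple[SNPAssociation, str]] = []
    for s in snps:
        if s.call_rate is not None and s.call_rate < call_rate_min:
            removed.append((s, "call_rate"))
        elif s.hwe_p is not None and s.hwe_p < hwe_p_min:
            removed.append((s, "hwe"))
        elif min(s.eaf, 1 - s.eaf) <= maf_min:
            removed.append((s, "maf"))
        else:
            kept.append(s)
    return kept, removed


def harmonize(
    exposure: Sequence[SNPAssociation],
    outcome: Sequence[SNPAssociation],
    ambiguous_policy: str = "drop",
    proxy_map: Mapping[str, tuple[str, float]] | None = None,
) -> tuple[InstrumentSet, list[tuple[str, str, str]]]:
    """Align exposure and outcome associations to a common effect allele.

    Returns the harmonized :class:`InstrumentSet` (oriented so every
    exposure effect is non-negative, i.e. to the exposure-increasing
    allele) and a report of ``(snp_id, provenance, reason)`` rows.

    Palindromic variants are dropped under ``ambiguous_policy='drop'`` or
    substituted by ``proxy_map[snp_id] = (proxy_id, ld_r2)`` when
    ``ld_r2 > 0.8`` under ``'proxy'``.
    """
    if ambiguous_policy not in ("drop", "proxy"):
        raise ValueError(f"ambiguous_policy must be 'drop' or 'proxy', got {ambiguous_policy!r}")
    if ambiguous_policy == "proxy" and proxy_map is None:
        raise ValueError("ambiguous_policy='proxy' requires a proxy_map")

    exp_by_id = {s.snp_id: s for s in exposure}
    out_by_id = {s.snp_id: s for s in outcome}
    if len(exp_by_id) != len(exposure) or len(out_by_id) != len(outcome):
        raise ValueError("snp ids must be unique within each table")

    instruments: list[HarmonizedInstrument] = []
    report: list[tuple[str, str, str]] = []

    for s in exposure:
        original_id = s.snp_id
        provenance = "direct"
        if s.is_palindromic:
            if ambiguous_policy == "drop":
                report.append((original_id, "dropped", "ambiguous_strand"))
                continue
            entry = proxy_map.get(original_id)
            if entry is None:
                report.append((original_id, "dropped", "no_proxy"))
                continue
            proxy_id, ld_r2 = entry
            proxy_exp = exp_by_id.get(proxy_id)
            if ld_r2 <= 0.8 or proxy_exp is None or proxy_id not in out_by_id \
                    or proxy_exp.is_palindromic:
                report.append((original_id, "dropped", "no_valid_proxy"))
                continue
            s = proxy_exp
            provenance = "proxy-substituted"

        out = out_by_id.get(s.snp_id)
        if out is None:
            report.append((original_id, "dropped", "missing_in_outcome"))
            continue

        if (out.effect_allele, out.other_allele) == (s.effect_allele, s.other_allele):
            by = out.beta
        elif (out.effect_allele, out.other_allele) == (s.other_allele, s.effect_allele):
            by = -out.beta
            if provenance == "direct":
                provenance = "allele-flipped"
        else:
            report.append((original_id, "dropped", "allele_mismatch"))
            continue

        bx, eaf = s.beta, s.eaf
        allele, other = s.effect_allele, s.other_allele
        if bx < 0:  # orient to the exposure-increasing allele
            bx, by, eaf = -bx, -by, 1 - eaf
            allele, other = other, allele

        instruments.append(HarmonizedInstrument(
            snp_id=original_id, bx=bx, sx=s.se, by=by, sy=out.se,
            eaf=eaf, aligned_allele=allele, other_allele=other,
            provenance=provenance,
        ))
        report.append((original_id, provenance, ""))

    exposure_n = max((s.n for s in exposure if s.n is not None), default=0)
    return InstrumentSet(instruments, exposure_n), report


def mr_power_binary(
    n_cases: int,
    n_controls: int,
    r2: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Approximate power of a two-sample MR test with a binary outcome.

    Uses the normal approximation
    power = Φ(√(N·R²·φ(1−φ))·|ln OR| − z_{1−α/2}) with N the total sample
    size and φ the case fraction.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    if not (0 < r2 < 1):
        raise ValueError(f"r2 must be in (0,1), got {r2}")
    if or_alt <= 0:
        raise ValueError(f"or_alt must be > 0, got {or_alt}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    n_total = n_cases + n_controls
    phi = n_cases / n_total
    ncp = np.sqrt(n_total * r2 * phi * (1 - phi)) * abs(np.log(or_alt))
    return float(norm.cdf(ncp - norm.ppf(1 - alpha / 2)))


# ---------------------------------------------------------------------------
# frame conversion helpers for the summary-statistics TSV dialect

def associations_from_frame(df: pd.DataFrame) -> list[SNPAssociation]:
    """Build :class:`SNPAssociation` records from a summary-statistics table."""
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(SNPAssociation(
            snp_id=str(d["snp"]),
            effect_allele=str(d["effect_allele"]),
            other_allele=str(d["other_allele"]),
            eaf=float(d["eaf"]),
            beta=float(d["beta"]),
            se=float(d["se"]),
            pval=float(d.get("pval", 1.0)),
            n=int(d["n"]) if d.get("n") is not None and not pd.isna(d.get("n")) else None,
            n_cases=int(d["n_cases"]) if not pd.isna(d.get("n_cases", np.nan)) else None,
            n_controls=int(d["n_controls"]) if not pd.isna(d.get("n_controls", np.nan)) else None,
            call_rate=float(d["call_rate"]) if not pd.isna(d.get("call_rate", np.nan)) else None,
            hwe_p=float(d["hwe_p"]) if not pd.isna(d.get("hwe_p", np.nan)) else None,
        ))
    return out


def set_to_exposure_associations(inst_set: InstrumentSet) -> list[SNPAssociation]:
    """Re-express a harmonized set as exposure-side associations."""
    return [
        SNPAssociation(
            snp_id=i.snp_id, effect_allele=i.aligned_allele,
            other_allele=i.other_allele, eaf=i.eaf, beta=i.bx, se=i.sx,
            n=inst_set.exposure_n or None,
        )
        for i in inst_set.instruments
    ]


def set_to_outcome_associations(inst_set: InstrumentSet) -> list[SNPAssociation]:
    """Re-express a harmonized set as outcome-side associations."""
    return [
        SNPAssociation(
            snp_id=i.snp_id, effect_allele=i.aligned_allele,
            other_allele=i.other_allele, eaf=i.eaf, beta=i.by, se=i.sy,
        )
        for i in inst_set.instruments
    ]


def report_to_frame(report: list[tuple[str, str, str]]) -> pd.DataFrame:
    return pd.DataFrame(report, columns=["snp", "provenance", "reason"])
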