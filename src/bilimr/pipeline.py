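"""End-to-end orchestration of the two-arm (serological + MR) analysis.

``run_full_analysis`` runs, per sex: the matched case-control models
(crude and multivariable conditional logistic, spline nonlinearity,
sub-site heterogeneity), the single-lead-variant Wald MR, and the
multi-variant MR suite on the remaining instruments (likelihood-based,
IVW multiplicative random effects, MR-Egger, weighted median, mode-based,
MR-PRESSO), then the between-sex heterogeneity rows, and returns one
machine-readable report.  All randomness is derived from a single seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .heterogeneity import sex_heterogeneity
from .instruments import associations_from_frame, harmonize
from .mr import egger, ivw_mre, leave_out, likelihood_based, mode_based, \
    wald_ratio, weighted_median
from .presso import run_presso
from .serology import clogit_fit, spline_nonlinearity, standardize_log_exposure, \
    subsite_heterogeneity
from .simulate import CohortConfig, GwasConfig, gen_matched_cohort, gen_two_sample_gwas

logger = logging.getLogger("bilimr")

SCHEMA_VERSION = "1.0"

ADJUSTMENT_COVARIATES = {
    "men": ["education", "bmi", "height", "smoking", "physical_activity",
            "alcohol", "fiber", "red_meat", "processed_meat", "dairy", "energy"],
    "women": ["education", "bmi", "height", "smoking", "physical_activity",
              "alcohol", "fiber", "red_meat", "processed_meat", "dairy",
              "energy", "ht_use"],
}

# Planted truths for simulate mode: the study's sex-specific serological
# conditional log-ORs and the lead-variant vs remaining-instrument causal
# log-ORs per 1-SD of bilirubin.
DEFAULT_PLANTED = {
    "men": {"serology": float(np.log(1.19)), "mr_lead": float(np.log(1.07)),
            "mr_other": float(np.log(0.89))},
    "women": {"serology": float(np.log(0.86)), "mr_lead": float(np.log(1.01)),
              "mr_other": float(np.log(1.00))},
}

OUTCOME_COUNTS = {"men": (28_207, 22_204), "women": (24_568, 23_736)}


@dataclass
class RunConfig:
    """Configuration of a full simulate-mode or files-mode run."""

    mode: str = "simulate"
    seed: int = 0
    output_dir: str | None = None
    make_plots: bool = False
    n_boot: int = 500
    presso_n_sim: int = 1000
    planted: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_PLANTED)))
    cohort_paths: dict = field(default_factory=dict)   # sex -> cohort CSV
    exposure_paths: dict = field(default_factory=dict)  # sex -> exposure TSV
    outcome_paths: dict = field(default_factory=dict)   # sex -> outcome TSV

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.mode == "files":
            for d in (self.cohort_paths, self.exposure_paths, self.outcome_paths):
                if set(d) != {"men", "women"}:
                    raise ValueError("files mode needs men/women paths for cohort, "
                                     "exposure, and outcome tables")


def _stage_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _est_dict(est) -> dict:
    return est.as_dict()


def run_full_analysis(config: RunConfig) -> dict:
    """Run both analysis arms for both sexes and return the report dict."""
    config.validate()
    seeds = _stage_seeds(config.seed, 8)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "software": {"name": "bilimr", "version": __version__},
        "seed": config.seed,
        "mode": config.mode,
    }
    sex_rows = {}
    for i, sex in enumerate(("men", "women")):
        logger.info("analysis arm: %s", sex)
        sex_rows[sex] = _run_one_sex(config, sex, seeds[4 * i: 4 * i + 4])
        report[sex] = sex_rows[sex]

    def _pair(path_keys):
        m = sex_rows["men"]
        f = sex_rows["women"]
        for k in path_keys:
            m, f = m[k], f[k]
        return (m["beta"], m["se"]), (f["beta"], f["se"])

    het = {}
    for label, keys in [
        ("serology_multivariable", ("serology", "multivariable")),
        ("mr_wald_lead", ("mr", "wald_lead")),
        ("mr_likelihood_other", ("mr", "suite", "likelihood_based")),
    ]:
        em, ef = _pair(keys)
        het[label] = sex_heterogeneity(em, ef).as_dict()
    report["sex_heterogeneity"] = het

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n")
        if config.make_plots:
            for sex in ("men", "women"):
                _scatter_plot(sex_rows[sex]["_plot_data"], sex,
                              out / f"scatter_{sex}.png")
    for sex in ("men", "women"):
        report[sex].pop("_plot_data", None)
    return report


def _run_one_sex(config: RunConfig, sex: str, seeds: list[int]) -> dict:
    from .simulate import read_cohort_csv, read_gwas_tsv

    planted = config.planted[sex]
    if config.mode == "simulate":
        cohort = gen_matched_cohort(CohortConfig.for_sex(
            sex, causal_logor_per_sd=planted["serology"], seed=seeds[0]))
        cases, controls = OUTCOME_COUNTS[sex]
        exp_tab, out_tab = gen_two_sample_gwas(GwasConfig(
            causal_logor_per_sd=planted["mr_other"],
            lead_causal_logor_per_sd=planted["mr_lead"],
            outcome_cases=cases, outcome_controls=controls, seed=seeds[1]))
    else:
        cohort = read_cohort_csv(config.cohort_paths[sex])
        exp_tab = read_gwas_tsv(config.exposure_paths[sex])
        out_tab = read_gwas_tsv(config.outcome_paths[sex])

    # serological arm
    std = standardize_log_exposure(cohort, sd_scope="sex_specific")
    crude = clogit_fit(std)
    covars = [c for c in ADJUSTMENT_COVARIATES[sex] if c in std.columns]
    multi = clogit_fit(std, covariates=covars)
    _, p_nonlin, _ = spline_nonlinearity(std)
    subsite = subsite_heterogeneity(std)

    serology = {
        "crude": crude.as_dict(),
        "multivariable": multi.as_dict(),
        "p_nonlinearity": p_nonlin,
        "subsites": {
            "p_heterogeneity": subsite.p_heterogeneity,
            "sites": {k: v.as_dict() for k, v in subsite.strata.items()},
        },
    }

    # MR arm
    inst_set, _ = harmonize(
        associations_from_frame(exp_tab), associations_from_frame(out_tab))
    lead_id = max(inst_set.instruments, key=lambda i: i.bx**2 * i.eaf * (1 - i.eaf)).snp_id
    lead = next(i for i in inst_set.instruments if i.snp_id == lead_id)
    others = leave_out(inst_set, lead_id)

    suite = {
        "likelihood_based": likelihood_based(others),
        "ivw_mre": ivw_mre(others),
        "egger": egger(others),
        "weighted_median": weighted_median(others, n_boot=config.n_boot, seed=seeds[2]),
        "mode_based": mode_based(others, n_boot=config.n_boot, seed=seeds[2] + 1),
    }
    presso = run_presso(others, n_sim=config.presso_n_sim, seed=seeds[3])

    mr = {
        "instrument": {
            "k": inst_set.k, "r2_total": inst_set.r2_total,
            "f_statistic": inst_set.f_statistic, "lead_snp": lead_id,
            "r2_others": others.r2_total, "f_others": others.f_statistic,
        },
        "wald_lead": wald_ratio(lead).as_dict(),
        "suite": {name: est.as_dict() for name, est in suite.items()},
        "presso": {
            "global_rss": presso.global_rss, "global_p": presso.global_p,
            "outliers": presso.outliers, "distortion_p": presso.distortion_p,
        },
    }
    return {
        "serology": serology,
        "mr": mr,
        "_plot_data": {
            "bx": [i.bx for i in others.instruments],
            "by": [i.by for i in others.instruments],
            "sx": [i.sx for i in others.instruments],
            "sy": [i.sy for i in others.instruments],
            "slope": suite["likelihood_based"].beta,
            "slope_ci": (suite["likelihood_based"].beta
                         - 1.959964 * suite["likelihood_based"].se,
                         suite["likelihood_based"].beta
                         + 1.959964 * suite["likelihood_based"].se),
        },
    }


def _scatter_plot(data: dict, sex: str, path) -> None:
    """Per-variant exposure vs outcome effects with the fitted MR line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bx = np.asarray(data["bx"])
    by = np.asarray(data["by"])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(bx, by, xerr=data["sx"], yerr=data["sy"], fmt="o", ms=3,
                color="0.3", ecolor="0.7", lw=0.8)
    xs = np.linspace(0, bx.max() * 1.05, 50)
    ax.plot(xs, data["slope"] * xs, "b--", label="likelihood-based MR")
    lo, hi = data["slope_ci"]
    ax.plot(xs, lo * xs, "b:", lw=0.8)
    ax.plot(xs, hi * xs, "b:", lw=0.8)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.set_xlabel("per-allele effect on bilirubin (SD)")
    ax.set_ylabel("per-allele effect on CRC risk (log OR)")
    ax.set_title(f"Instrument effects, {sex}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
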