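"""Side-by-side method comparison and the Monte-Carlo simulation harness.

``compare_methods`` produces a table with one row per (outcome, method) —
pooled Cohen's d, its SE, the 95% CI, BIC where applicable — in the fixed
order two-stage pooling, pooled regression, mixed model.  ``run_simulation``
repeats generate-and-analyze cycles over scenario configurations and
summarizes bias, empirical and model-based SEs, CI coverage and width,
BIC preference and the meta-vs-mega estimate discrepancy, each with its
Monte-Carlo standard error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    AnalysisSubset,
    CovariateSpec,
    FitResult,
    IPDDataset,
    NoEstimableCohortsError,
    validate_for_analysis,
)
from .one_stage import (
    RANDOM_INTERCEPT,
    RANDOM_INTERCEPT_SLOPE,
    MixedModelSpec,
    fit_lmm,
    fit_mega_lr,
    lmm_to_fitresult,
    select_random_structure,
)
from .synthetic import AgeModel, ScenarioConfig, default_enigma_structure, generate_cohorts
from .two_stage import run_meta

logger = logging.getLogger(__name__)

#: fixed presentation order of the analysis methods
METHOD_ORDER = ("meta_re", "mega_lr", "mega_lmm_ri", "mega_lmm_ris")

DEFAULT_ALPHA = 0.001


@dataclass
class ReportRow:
    outcome: str
    group: str
    result: FitResult
    significant: bool | None = None


@dataclass
class ComparisonReport:
    """Rows of method results per outcome, plus the significance threshold."""

    rows: list[ReportRow] = field(default_factory=list)
    alpha: float | None = None

    def for_method(self, method: str) -> list[ReportRow]:
        return [r for r in self.rows if r.result.method == method]


def _run_method(method: str, subset: AnalysisSubset) -> FitResult:
    if method == "meta_re":
        return run_meta(subset)[0]
    if method == "mega_lr":
        return fit_mega_lr(subset)
    if method == "mega_lmm_ri":
        fit = fit_lmm(subset, MixedModelSpec(random=RANDOM_INTERCEPT))
        return lmm_to_fitresult(fit, subset.n1, subset.n2)
    if method == "mega_lmm_ris":
        fit = fit_lmm(subset, MixedModelSpec(random=RANDOM_INTERCEPT_SLOPE))
        return lmm_to_fitresult(fit, subset.n1, subset.n2)
    if method == "mega_lmm_auto":
        return select_random_structure(subset)[0]
    raise ValueError(f"unknown method {method!r}")


def compare_methods(
    ds: IPDDataset,
    roi: str,
    group: str = "all",
    methods: tuple[str, ...] = ("meta_re", "mega_lr", "mega_lmm_ri"),
    min_cohort_n: int = 10,
    alpha: float | None = None,
) -> ComparisonReport:
    """Run the requested methods on one ROI and assemble a report.

    The analysis-ready subset is built once per ROI; all methods see the
    identical complete-case rows, with the two-stage arm restricted to its
    eligible cohorts.  A hard failure of one method is recorded as a
    non-converged row rather than aborting the report.
    """
    spec = CovariateSpec.for_measure(ds.measure_type(roi))
    sub_ds = ds.subset(group) if group != "all" else ds
    subset = validate_for_analysis(sub_ds, roi, spec, min_cohort_n=min_cohort_n)
    ordered = [m for m in METHOD_ORDER + ("mega_lmm_auto",) if m in methods]
    report = ComparisonReport()
    for method in ordered:
        try:
            result = _run_method(method, subset)
        except Exception as e:  # recorded, not fatal
            logger.warning("method %s failed on %s: %s", method, roi, e)
            result = FitResult(method=method, converged=False, note=str(e))
        report.rows.append(ReportRow(outcome=roi, group=group, result=result))
    if alpha is not None:
        apply_threshold(report, alpha)
    return report


def apply_threshold(report: ComparisonReport, alpha: float = DEFAULT_ALPHA) -> ComparisonReport:
    """Flag rows with p strictly below the significance threshold.

    The default threshold of 0.001 is a fixed reporting cut-off; no further
    multiplicity adjustment is applied.
    """
    if not report.rows:
        raise ValueError("report is empty")
    report.alpha = alpha
    for row in report.rows:
        p = row.result.p
        row.significant = None if p is None else bool(p < alpha)
    return report


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

_THICKNESS_BASE = dict(
    beta_dx=-0.02,
    sigma_e=0.15,
    grand_mean=2.5,
    covariate_effects={"age": -0.005, "sex": 0.01, "icv": 0.0},
    age_model=AgeModel(p_pediatric=0.0),
)


def scenario_presets() -> dict[str, ScenarioConfig]:
    """Named simulation scenarios spanning the regimes of interest.

    * ``equivalence`` — constant diagnosis effect and residual variance
      across cohorts (the classical regime in which two-stage pooling and
      pooled regression coincide): K = 10 large cohorts of 200 + 200.
    * ``intercept-heterogeneity`` — the 38-cohort default structure with
      unequal cohort sizes and cohort-intercept SD of 0.3 x residual SD.
    * ``slope-heterogeneity`` — cohort-varying diagnosis effects
      (slope SD = 0.5 x residual SD), K = 30 cohorts of 50 + 50.
    * ``heteroscedastic`` — residual SD varying threefold across cohorts.
    * ``small-cohorts`` — many small cohorts (15 + 15), where per-cohort
      estimation is noisy and fixed-effects pooling is fragile.
    """
    enigma = default_enigma_structure(n_rois=1)
    presets = {
        "equivalence": ScenarioConfig(
            cohort_sizes=tuple([(200, 200)] * 10),
            sigma_u=0.05,
            sigma_slope=0.0,
            **_THICKNESS_BASE,
        ),
        "intercept-heterogeneity": enigma.with_(
            sigma_u=0.3 * 0.15, sigma_slope=0.0
        ),
        "slope-heterogeneity": ScenarioConfig(
            cohort_sizes=tuple([(50, 50)] * 30),
            sigma_u=0.05,
            sigma_slope=0.5 * 0.15,
            **_THICKNESS_BASE,
        ),
        "heteroscedastic": ScenarioConfig(
            cohort_sizes=tuple([(50, 50)] * 10),
            sigma_u=0.05,
            sigma_slope=0.0,
            **{**_THICKNESS_BASE, "sigma_e": tuple(np.linspace(0.08, 0.24, 10))},
        ),
        "small-cohorts": ScenarioConfig(
            cohort_sizes=tuple([(15, 15)] * 38),
            sigma_u=0.05,
            sigma_slope=0.0,
            **_THICKNESS_BASE,
        ),
    }
    return presets


# ---------------------------------------------------------------------------
# Monte-Carlo study
# ---------------------------------------------------------------------------


@dataclass
class SimulationSummary:
    """Replicate-level records and per-method / pairwise summaries.

    ``replicates`` is a long table with one row per scenario x replicate x
    method; ``per_method`` aggregates bias, empirical SD, mean model SE,
    coverage and CI width (each with a Monte-Carlo SE); ``pairwise`` holds
    the cross-method comparisons (SE ordering, BIC preference, meta-mega
    discrepancy).
    """

    replicates: pd.DataFrame
    per_method: pd.DataFrame
    pairwise: pd.DataFrame
    reps: int
    seed: int


def _mc_se_mean(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


def _mc_se_prop(p: float, n: int) -> float:
    return float(math.sqrt(p * (1 - p) / n)) if n > 0 else float("nan")


def run_simulation(
    scenarios: dict[str, ScenarioConfig],
    reps: int,
    seed: int = 0,
    methods: tuple[str, ...] = ("meta_re", "mega_lr", "mega_lmm_ri"),
    min_cohort_n: int = 10,
) -> SimulationSummary:
    """Monte-Carlo evaluation of the analysis methods across scenarios.

    For every scenario and replicate a dataset is generated, every method
    run on the same complete-case subset, and the pooled d, its SE, the CI
    and BIC recorded.  Replicates where a method fails to converge are
    excluded from that method's summaries, with the exclusion rate
    reported.  Fully deterministic given the seed.
    """
    if reps < 2:
        raise ValueError("need reps >= 2")
    records: list[dict] = []
    root = np.random.SeedSequence(seed)
    for name, cfg in scenarios.items():
        try:
            cfg.validate()
        except Exception as e:
            logger.warning("scenario %s invalid, skipped: %s", name, e)
            continue
        rep_seeds = np.random.default_rng(root.spawn(1)[0]).integers(
            0, 2**31 - 1, size=reps
        )
        roi = cfg.roi_registry[0][0]
        spec = CovariateSpec.for_measure(cfg.roi_registry[0][1])
        for r in range(reps):
            ds = generate_cohorts(cfg, seed=int(rep_seeds[r]))
            try:
                subset = validate_for_analysis(
                    ds, roi, spec, min_cohort_n=min_cohort_n
                )
            except NoEstimableCohortsError as e:
                logger.warning("scenario %s rep %d: %s", name, r, e)
                continue
            for method in methods:
                rec = {
                    "scenario": name,
                    "rep": r,
                    "method": method,
                    "true_d": cfg.true_d,
                    "converged": False,
                    "d": np.nan,
                    "se": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "bic": np.nan,
                }
                try:
                    res = _run_method(method, subset)
                except Exception as e:
                    logger.warning(
                        "scenario %s rep %d method %s: %s", name, r, method, e
                    )
                    records.append(rec)
                    continue
                rec["converged"] = res.converged
                if res.converged:
                    rec.update(
                        d=res.d,
                        se=res.se_d,
                        ci_low=res.ci95[0],
                        ci_high=res.ci95[1],
                        bic=np.nan if res.bic is None else res.bic,
                    )
                records.append(rec)
    replicates = pd.DataFrame(records)
    per_method = _summarize_per_method(replicates)
    pairwise = _summarize_pairwise(replicates)
    return SimulationSummary(
        replicates=replicates,
        per_method=per_method,
        pairwise=pairwise,
        reps=reps,
        seed=seed,
    )


def _summarize_per_method(replicates: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if replicates.empty:
        return pd.DataFrame()
    for (scenario, method), grp in replicates.groupby(["scenario", "method"]):
        ok = grp[grp["converged"]]
        n_total, n_ok = len(grp), len(ok)
        true_d = float(grp["true_d"].iloc[0])
        if n_ok >= 2:
            d = ok["d"].to_numpy()
            cover = ((ok["ci_low"] <= true_d) & (true_d <= ok["ci_high"])).to_numpy()
            width = (ok["ci_high"] - ok["ci_low"]).to_numpy()
            cov_p = float(cover.mean())
            rows.append(
                {
                    "scenario": scenario,
                    "method": method,
                    "n_reps": n_total,
                    "n_converged": n_ok,
                    "exclusion_rate": 1 - n_ok / n_total,
                    "true_d": true_d,
                    "mean_bias": float(np.mean(d - true_d)),
                    "mean_bias_mcse": _mc_se_mean(d - true_d),
                    "empirical_sd": float(np.std(d, ddof=1)),
                    "mean_model_se": float(ok["se"].mean()),
                    "mean_model_se_mcse": _mc_se_mean(ok["se"].to_numpy()),
                    "coverage": cov_p,
                    "coverage_mcse": _mc_se_prop(cov_p, n_ok),
                    "mean_ci_width": float(width.mean()),
                    "mean_ci_width_mcse": _mc_se_mean(width),
                }
            )
        else:
            rows.append(
                {
                    "scenario": scenario,
                    "method": method,
                    "n_reps": n_total,
                    "n_converged": n_ok,
                    "exclusion_rate": 1 - n_ok / n_total if n_total else np.nan,
                    "true_d": true_d,
                }
            )
    return pd.DataFrame(rows)


def _summarize_pairwise(replicates: pd.DataFrame) -> pd.DataFrame:
    """Cross-method comparisons computed within each replicate."""
    rows = []
    if replicates.empty:
        return pd.DataFrame()
    wide = replicates.pivot_table(
        index=["scenario", "rep"],
        columns="method",
        values=["d", "se", "bic", "converged"],
        aggfunc="first",
    )
    for scenario, grp in wide.groupby(level="scenario"):
        rec: dict = {"scenario": scenario}
        methods = set(replicates["method"].unique())
        methods = {
            m for m in methods if ("d", m) in grp.columns and ("se", m) in grp.columns
        }

        def both_ok(a: str, b: str) -> pd.DataFrame:
            m = grp[("converged", a)].astype(bool) & grp[("converged", b)].astype(bool)
            return grp[m]

        if {"meta_re", "mega_lr"} <= set(methods):
            g = both_ok("meta_re", "mega_lr")
            if len(g) >= 2:
                diff = (g[("d", "meta_re")] - g[("d", "mega_lr")]).abs().to_numpy()
                rec["mean_abs_d_meta_vs_lr"] = float(diff.mean())
                rec["mean_abs_d_meta_vs_lr_mcse"] = _mc_se_mean(diff)
                rec["sd_d_meta_vs_lr"] = float(
                    np.std(g[("d", "meta_re")] - g[("d", "mega_lr")], ddof=1)
                )
        for mega in ("mega_lr", "mega_lmm_ri"):
            if {"meta_re", mega} <= set(methods):
                g = both_ok("meta_re", mega)
                if len(g) >= 2:
                    less = (g[("se", mega)] <= g[("se", "meta_re")]).to_numpy()
                    p = float(less.mean())
                    rec[f"prop_se_{mega}_le_meta"] = p
                    rec[f"prop_se_{mega}_le_meta_mcse"] = _mc_se_prop(p, len(g))
                    ratio = (g[("se", mega)] / g[("se", "meta_re")]).to_numpy()
                    rec[f"mean_ci_width_ratio_{mega}_vs_meta"] = float(ratio.mean())
        if {"mega_lr", "mega_lmm_ri"} <= set(methods) and {
            ("bic", "mega_lr"),
            ("bic", "mega_lmm_ri"),
        } <= set(grp.columns):
            g = both_ok("mega_lr", "mega_lmm_ri")
            if len(g) >= 2:
                pref = (g[("bic", "mega_lmm_ri")] < g[("bic", "mega_lr")]).to_numpy()
                p = float(pref.mean())
                rec["prop_bic_lmm_lt_lr"] = p
                rec["prop_bic_lmm_lt_lr_mcse"] = _mc_se_prop(p, len(g))
        rec["n_reps"] = int(grp.shape[0])
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_discrepancy(summary: SimulationSummary) -> pd.DataFrame:
    """Ordered findings table of the meta-vs-mega comparisons per scenario.

    Reports, with Monte-Carlo SEs, the proportion of replicates in which
    the one-stage SE is at or below the two-stage SE, the mean CI-width
    ratio and the BIC preference rate for the mixed model.
    """
    methods = summary.replicates["method"].unique() if not summary.replicates.empty else []
    if len(methods) < 2:
        raise ValueError("discrepancy summary needs results from >= 2 methods")
    cols = [c for c in summary.pairwise.columns if c != "scenario"]
    return summary.pairwise[["scenario", *cols]].sort_values("scenario").reset_index(
        drop=True
    )
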