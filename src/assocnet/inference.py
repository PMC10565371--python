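"""Two-stage likelihood-ratio testing for individual plasticity, and
marginal / conditional repeatability.

Stage 1 asks whether individual mean behaviour and plasticity are correlated
(full model vs the same model with the intercept-slope correlation suppressed
to zero; 1 df chi-square). Only when that is unclear does stage 2 ask whether
random slopes matter at all (zero-correlation model vs intercepts-only; the
null distribution is the 50:50 chi0:chi1 boundary mixture). If the
zero-correlation model fails to converge, the fallback compares the full
model directly against intercepts-only on 2 df.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelSpec
from .lmm import FitResult, fit, prepare_model_frame, wald_tests

logger = logging.getLogger(__name__)

__all__ = [
    "LRTResult",
    "RepeatabilityResult",
    "lrt_pvalue",
    "test_intercept_slope_correlation",
    "test_random_slopes",
    "plasticity_tests",
    "marginal_repeatability",
    "run_study",
    "write_study_results",
]

CLARITY_ALPHA = 0.05
MARGINAL_BAND = 0.07  # p in (0.05, 0.07] flagged "marginal"


@dataclass
class LRTResult:
    comparison: str  # full_vs_zero_corr | zero_corr_vs_no_slopes | full_vs_no_slopes_2df
    statistic: float
    df: str  # "1", "0:1 mixture", "2"
    p: float
    clear: bool
    marginal: bool = False

    @staticmethod
    def from_loglik(
        comparison: str, ll_full: float, ll_reduced: float, df: str
    ) -> "LRTResult":
        stat = max(0.0, 2.0 * (ll_full - ll_reduced))
        p = lrt_pvalue(stat, df)
        return LRTResult(
            comparison=comparison,
            statistic=stat,
            df=df,
            p=p,
            clear=p < CLARITY_ALPHA,
            marginal=CLARITY_ALPHA <= p <= MARGINAL_BAND,
        )


def lrt_pvalue(statistic: float, df: str) -> float:
    """Upper-tail p-value for the supported null distributions.

    "0:1 mixture" is the boundary null for a single variance component: half
    a point mass at zero and half a chi-square(1); at statistic 0 the p-value
    is 0.5 (one-sided convention).
    """
    if statistic < 0:
        statistic = 0.0
    if df == "1":
        return float(stats.chi2.sf(statistic, 1))
    if df == "2":
        return float(stats.chi2.sf(statistic, 2))
    if df == "0:1 mixture":
        if statistic == 0.0:
            return 0.5
        return float(0.5 * stats.chi2.sf(statistic, 1))
    raise ValueError(f"unknown df descriptor: {df!r}")


@dataclass
class PlasticityDecision:
    fits: dict[str, FitResult]
    correlation_test: LRTResult | None
    slope_test: LRTResult | None
    correlation_clear: bool
    slopes_clear: bool
    audit: list[str] = field(default_factory=list)


def test_intercept_slope_correlation(
    fit_full: FitResult, fit_zero_corr: FitResult
) -> LRTResult:
    return LRTResult.from_loglik(
        "full_vs_zero_corr", fit_full.loglik, fit_zero_corr.loglik, "1"
    )


def test_random_slopes(
    fit_zero_corr: FitResult, fit_intercept_only: FitResult
) -> LRTResult:
    return LRTResult.from_loglik(
        "zero_corr_vs_no_slopes",
        fit_zero_corr.loglik,
        fit_intercept_only.loglik,
        "0:1 mixture",
    )


def plasticity_tests(
    frame: pd.DataFrame, spec: ModelSpec, n_starts: int = 3, seed: int = 0
) -> PlasticityDecision:
    """Run the ordered two-stage procedure on a prepared model frame."""
    audit: list[str] = []
    fits: dict[str, FitResult] = {}

    full_spec = replace(spec, random_structure="full")
    zc_spec = replace(spec, random_structure="zero_corr")
    io_spec = replace(spec, random_structure="intercept_only")

    fits["full"] = fit(frame, full_spec, n_starts=n_starts, seed=seed)
    audit.append("fit full")
    fits["zero_corr"] = fit(frame, zc_spec, n_starts=n_starts, seed=seed)
    audit.append("fit zero_corr")

    corr_test = slope_test = None
    correlation_clear = slopes_clear = False
    if fits["full"].converged and fits["zero_corr"].converged:
        corr_test = test_intercept_slope_correlation(fits["full"], fits["zero_corr"])
        audit.append(f"correlation LRT p={corr_test.p:.4g}")
        correlation_clear = corr_test.clear
        if correlation_clear:
            slopes_clear = True  # a non-zero correlation implies slope variance
            audit.append("correlation clear; slope test skipped")
        else:
            fits["intercept_only"] = fit(frame, io_spec, n_starts=n_starts, seed=seed)
            audit.append("fit intercept_only")
            slope_test = test_random_slopes(fits["zero_corr"], fits["intercept_only"])
            audit.append(f"slope LRT (boundary mixture) p={slope_test.p:.4g}")
            slopes_clear = slope_test.clear
    else:
        # zero-correlation model unavailable: 2-df comparison of full vs
        # intercepts-only
        fits["intercept_only"] = fit(frame, io_spec, n_starts=n_starts, seed=seed)
        audit.append("zero_corr failed; fit intercept_only for 2-df fallback")
        slope_test = LRTResult.from_loglik(
            "full_vs_no_slopes_2df",
            fits["full"].loglik,
            fits["intercept_only"].loglik,
            "2",
        )
        audit.append(f"2-df fallback LRT p={slope_test.p:.4g}")
        slopes_clear = slope_test.clear
    return PlasticityDecision(
        fits=fits,
        correlation_test=corr_test,
        slope_test=slope_test,
        correlation_clear=correlation_clear,
        slopes_clear=slopes_clear,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# repeatability


@dataclass
class RepeatabilityResult:
    marginal: float
    conditional: dict[float, float]
    v_individual_marginal: float
    v_denominator_other: float


def marginal_repeatability(
    result: FitResult,
    x_values: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0),
    x_mean: float = 0.0,
    x_var: float = 1.0,
    include_year_month_in_denominator: bool = True,
) -> RepeatabilityResult:
    """Marginal repeatability over the covariate distribution, plus the
    conditional repeatability at chosen covariate values.

    V_ind_marginal = V_int + 2*Cov*E[x] + V_slope*(Var[x] + E[x]^2), which
    reduces to V_int + V_slope under standardization. The denominator adds
    every non-individual variance component in the model (year, month,
    residual); fixed-effect variance is excluded.
    """
    c = result.components
    for name in ("v_int", "v_slope", "v_year", "v_month", "v_resid"):
        if getattr(c, name) < 0:
            raise ValueError(f"negative variance component {name}")
    other = c.v_resid
    if include_year_month_in_denominator:
        other += c.v_year + c.v_month
    v_ind = c.v_int + 2.0 * c.cov_int_slope * x_mean + c.v_slope * (x_var + x_mean**2)
    v_ind = max(v_ind, 0.0)
    marginal = v_ind / (v_ind + other) if (v_ind + other) > 0 else 0.0
    conditional = {}
    for x in x_values:
        vx = max(c.v_int + 2.0 * x * c.cov_int_slope + x**2 * c.v_slope, 0.0)
        conditional[float(x)] = vx / (vx + other) if (vx + other) > 0 else 0.0
    return RepeatabilityResult(
        marginal=float(marginal),
        conditional=conditional,
        v_individual_marginal=float(v_ind),
        v_denominator_other=float(other),
    )


# ---------------------------------------------------------------------------
# the full model grid


def run_study(
    tables: dict[str, pd.DataFrame],
    traits: tuple[str, ...] = ModelSpec.TRAITS,
    covariates: tuple[str, ...] = ModelSpec.COVARIATES,
    timescales: tuple[str, ...] = ModelSpec.TIMESCALES,
    n_starts: int = 3,
    seed: int = 0,
) -> list[dict]:
    """Iterate the trait x covariate x timescale grid (12 models at defaults).

    ``tables`` maps "<covariate>:<timescale>" to an analysis table carrying
    that covariate in ``covariate_raw``. Each model uses a single covariate's
    random slope (never both covariates in one model). Failures are recorded
    and the grid continues.
    """
    records: list[dict] = []
    for trait in traits:
        for covariate in covariates:
            for timescale in timescales:
                spec = ModelSpec(
                    trait=trait,
                    covariate=covariate,
                    timescale=timescale,
                    transform=ModelSpec.default_transform(trait),
                )
                key = f"{covariate}:{timescale}"
                record: dict = {
                    "trait": trait,
                    "covariate": covariate,
                    "timescale": timescale,
                }
                try:
                    table = tables[key]
                    frame, info = prepare_model_frame(table, spec)
                    decision = plasticity_tests(
                        frame, spec, n_starts=n_starts, seed=seed
                    )
                    full_fit = decision.fits["full"]
                    rep = marginal_repeatability(full_fit)
                    record.update(
                        fit=full_fit,
                        wald=wald_tests(full_fit),
                        decision=decision,
                        repeatability=rep,
                        prepare_info=info,
                        error=None,
                    )
                except Exception as exc:  # keep the grid alive
                    logger.exception(
                        "model failed: %s/%s/%s", trait, covariate, timescale
                    )
                    record.update(
                        fit=None,
                        wald=None,
                        decision=None,
                        repeatability=None,
                        prepare_info=None,
                        error=str(exc),
                    )
                records.append(record)
    return records


def write_study_results(records: list[dict], outdir: str, config_doc: dict | None = None) -> None:
    """CSV bundle: fixed effects, variance components, LRT decisions,
    repeatabilities, plus a manifest with a config hash."""
    os.makedirs(outdir, exist_ok=True)
    fe_rows, vc_rows, lrt_rows, rep_rows = [], [], [], []
    for rec in records:
        base = {k: rec[k] for k in ("trait", "covariate", "timescale")}
        if rec.get("error") is not None or rec.get("fit") is None:
            lrt_rows.append({**base, "error": rec.get("error")})
            continue
        wald = rec["wald"]
        for row in wald.itertuples():
            fe_rows.append(
                {
                    **base,
                    "term": row.term,
                    "estimate": row.estimate,
                    "se": row.se,
                    "chi2": row.chi2,
                    "p": row.p,
                }
            )
        c = rec["fit"].components
        vc_rows.append(
            {
                **base,
                "v_int": c.v_int,
                "v_slope": c.v_slope,
                "cov_int_slope": c.cov_int_slope,
                "corr_int_slope": c.corr_int_slope,
                "v_year": c.v_year,
                "rho_year": c.rho_year,
                "v_month": c.v_month,
                "v_resid": c.v_resid,
                "loglik": rec["fit"].loglik,
                "converged": rec["fit"].converged,
            }
        )
        d = rec["decision"]
        lrt_rows.append(
            {
                **base,
                "correlation_stat": getattr(d.correlation_test, "statistic", np.nan),
                "correlation_p": getattr(d.correlation_test, "p", np.nan),
                "correlation_clear": d.correlation_clear,
                "slope_stat": getattr(d.slope_test, "statistic", np.nan),
                "slope_p": getattr(d.slope_test, "p", np.nan),
                "slope_df": getattr(d.slope_test, "df", ""),
                "slopes_clear": d.slopes_clear,
                "audit": " | ".join(d.audit),
                "error": None,
            }
        )
        rep = rec["repeatability"]
        rep_rows.append(
            {
                **base,
                "marginal_R": rep.marginal,
                **{f"R_at_{x:+.0f}": v for x, v in rep.conditional.items()},
            }
        )
    pd.DataFrame(fe_rows).to_csv(os.path.join(outdir, "fixed_effects.csv"), index=False)
    pd.DataFrame(vc_rows).to_csv(
        os.path.join(outdir, "variance_components.csv"), index=False
    )
    pd.DataFrame(lrt_rows).to_csv(os.path.join(outdir, "lrt_decisions.csv"), index=False)
    pd.DataFrame(rep_rows).to_csv(os.path.join(outdir, "repeatability.csv"), index=False)
    manifest = {"n_models": len(records)}
    if config_doc is not None:
        blob = json.dumps(config_doc, sort_keys=True, default=str).encode()
        manifest["config_hash"] = hashlib.sha256(blob).hexdigest()
        manifest["config"] = config_doc
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
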