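"""Cohort-level statistics: the effect of magnification correction, its
interaction with axial length, and myope/non-myope contrasts.

Sector means arrive in long format, two rows (raw + corrected) per eye per
sector.  Each question is answered with a linear mixed model fitted by
restricted maximum likelihood (REML), with participant-level random effects
absorbing the correlation between a participant's two eyes:

* correction main effect — thickness ~ corrected + sex + ethnicity, random
  intercept and a random slope on the correction flag per participant; the
  correction coefficient is the mean (corrected − raw) difference;
* axial-length interaction — adds AL and AL×correction; the interaction
  coefficient is the per-mm-of-AL change in (corrected − raw); simple AL
  slopes on the raw and corrected data are fitted separately;
* refractive-group contrast — thickness ~ group + sex + ethnicity per
  correction state; the coefficient is the myope − non-myope difference.

P-values from a family of nine sectors are Bonferroni-adjusted.  Singular
or non-convergent fits fall back first to a random intercept only, then to
OLS with cluster-robust (by participant) standard errors; every fallback is
recorded on the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .etdrs import SECTORS

__all__ = ["EffectEstimate", "AlInteractionResult", "cohort_table",
           "fit_correction_effect", "fit_al_interaction",
           "fit_group_contrast", "adjust_pvalues", "analyze_cohort"]

ALPHA = 0.05
MAXITER = 200


@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect estimate with its Wald CI and p-value."""

    sector: str
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_eyes: int
    n_participants: int
    p_adjusted: float | None = None
    model: str = "lmm_intercept_slope"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must contain the estimate")


@dataclass(frozen=True)
class AlInteractionResult:
    """AL×correction interaction plus the per-state simple AL slopes."""

    interaction: EffectEstimate
    slope_raw: EffectEstimate
    slope_corrected: EffectEstimate


def cohort_table(sector_df: pd.DataFrame,
                 biometry_df: pd.DataFrame) -> pd.DataFrame:
    """Join tidy sector means with biometry into the long analysis table.

    ``sector_df`` columns: participant_id, eye, corrected, sector, mean_um
    (optionally n_pixels, truncation_fraction).  Each eye must contribute
    exactly two rows (raw + corrected) per sector.
    """
    cols = ["participant_id", "eye", "axial_length_mm", "sex", "ethnicity",
            "refractive_group"]
    df = sector_df.merge(biometry_df[cols], on=["participant_id", "eye"],
                         how="left", validate="many_to_one")
    if df["axial_length_mm"].isna().any():
        missing = df.loc[df["axial_length_mm"].isna(),
                         ["participant_id", "eye"]].drop_duplicates()
        raise ValueError(f"eyes missing from biometry: {missing.values}")
    counts = df.groupby(["participant_id", "eye", "sector"])["corrected"] \
        .agg(["count", "nunique"])
    if not ((counts["count"] == 2) & (counts["nunique"] == 2)).all():
        raise ValueError("each eye needs exactly one raw and one corrected "
                         "row per sector")
    bad = set(df["refractive_group"].unique()) - {"myope", "non-myope"}
    if bad:
        raise ValueError(f"unknown refractive groups: {bad}")
    df = df.rename(columns={"mean_um": "thickness_um"})
    df["corr01"] = df["corrected"].astype(int)
    df["is_myope"] = (df["refractive_group"] == "myope").astype(int)
    return df


def _covariate_terms(df: pd.DataFrame) -> str:
    terms = []
    for col in ("sex", "ethnicity"):
        if col in df and df[col].nunique() > 1:
            terms.append(f"C({col})")
    return ("" if not terms else " + " + " + ".join(terms))


def _counts(df: pd.DataFrame) -> tuple[int, int]:
    n_eyes = df[["participant_id", "eye"]].drop_duplicates().shape[0]
    return n_eyes, df["participant_id"].nunique()


def _mom_start(df: pd.DataFrame, formula: str,
               re_f: str) -> MixedLMParams | None:
    """Method-of-moments starting values for the variance components.

    A crude between/within decomposition of the response (ignoring the
    fixed effects) lands close enough to the REML optimum to cut the
    optimizer's iteration count substantially; the optimum itself is
    unchanged.  Returns None when the decomposition is not computable.
    """
    try:
        response = formula.split("~")[0].strip()
        by_group = df.groupby("participant_id")[response]
        sig_e2 = float((by_group.diff().dropna() ** 2).mean()) / 2.0
        if not np.isfinite(sig_e2) or sig_e2 <= 0:
            return None
        sig_u2 = max(float(by_group.mean().var()) - sig_e2 / 2.0,
                     0.05 * sig_e2)
        ratio = sig_u2 / sig_e2
        k = 1 if re_f == "~1" else 2
        cov = np.diag([ratio] + [0.5] * (k - 1))
        return MixedLMParams.from_components(fe_params=None, cov_re=cov)
    except (ValueError, KeyError, ZeroDivisionError):
        return None


def _fit_mixed(formula: str, df: pd.DataFrame, coef: str, sector: str,
               term: str, re_formula: str | None = "~1") -> EffectEstimate:
    """Fit by REML with the fallback ladder and pull out one coefficient."""
    n_eyes, n_participants = _counts(df)
    attempts: list[tuple[str, str | None]] = []
    if re_formula not in (None, "~1"):
        attempts.append(("lmm_intercept_slope", re_formula))
    attempts.append(("lmm_intercept", "~1"))
    attempts.append(("ols_cluster_robust", None))

    for label, re_f in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                if re_f is None:
                    res = smf.ols(formula, data=df).fit(
                        cov_type="cluster",
                        cov_kwds={"groups": df["participant_id"]})
                    converged = True
                else:
                    start = _mom_start(df, formula, re_f)
                    res = smf.mixedlm(formula, data=df,
                                      groups=df["participant_id"],
                                      re_formula=re_f,
                                      ).fit(reml=True, maxiter=MAXITER,
                                            method="lbfgs",
                                            start_params=start)
                    converged = bool(res.converged)
            est = float(res.params[coef])
            se = float(res.bse[coef])
            p = float(res.pvalues[coef])
            if not (converged and np.isfinite(est) and np.isfinite(se)
                    and se > 0 and np.isfinite(p)):
                continue
            half = 1.959963984540054 * se
            return EffectEstimate(sector=sector, term=term, estimate=est,
                                  ci_low=est - half, ci_high=est + half,
                                  p_value=p, n_eyes=n_eyes,
                                  n_participants=n_participants, model=label)
        except (np.linalg.LinAlgError, ValueError, KeyError):
            continue
    raise RuntimeError(f"all model fits failed for sector {sector} "
                       f"({term})")


def fit_correction_effect(table: pd.DataFrame, sector: str) -> EffectEstimate:
    """Mean (corrected − raw) thickness difference in one sector.

    Degenerate but legitimate case: when corrected and raw values are
    identical for every eye (axial length equal to the device default
    throughout) the difference is exactly zero with zero variance, and a
    zero-estimate result is returned without fitting.
    """
    df = table[table["sector"] == sector]
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least two participants")
    n_eyes, n_participants = _counts(df)
    wide = df.pivot_table(index=["participant_id", "eye"], columns="corr01",
                          values="thickness_um")
    diffs = wide[1] - wide[0]
    if np.allclose(diffs, 0.0, atol=1e-12):
        return EffectEstimate(sector=sector, term="correction", estimate=0.0,
                              ci_low=0.0, ci_high=0.0, p_value=1.0,
                              n_eyes=n_eyes, n_participants=n_participants,
                              model="degenerate_zero_difference")
    formula = "thickness_um ~ corr01" + _covariate_terms(df)
    return _fit_mixed(formula, df, "corr01", sector, "correction",
                      re_formula="~corr01")


def fit_al_interaction(table: pd.DataFrame, sector: str) -> AlInteractionResult:
    """AL×correction interaction and per-state simple AL slopes (μm/mm)."""
    df = table[table["sector"] == sector]
    if df["axial_length_mm"].std(ddof=0) <= 1e-9:
        raise ValueError("axial length has zero variance")
    cov = _covariate_terms(df)
    inter = _fit_mixed(
        "thickness_um ~ corr01 * axial_length_mm" + cov, df,
        "corr01:axial_length_mm", sector, "al_x_correction",
        re_formula="~corr01")
    slopes = {}
    for state, name in ((0, "al_slope_raw"), (1, "al_slope_corrected")):
        sub = df[df["corr01"] == state]
        slopes[state] = _fit_mixed(
            "thickness_um ~ axial_length_mm" + _covariate_terms(sub), sub,
            "axial_length_mm", sector, name, re_formula="~1")
    return AlInteractionResult(interaction=inter, slope_raw=slopes[0],
                               slope_corrected=slopes[1])


def fit_group_contrast(table: pd.DataFrame, sector: str,
                       ) -> dict[str, EffectEstimate]:
    """Myope − non-myope difference per correction state, one sector."""
    df = table[table["sector"] == sector]
    if df["is_myope"].nunique() < 2:
        raise ValueError("both refractive groups must be present")
    out = {}
    for state, label in ((0, "raw"), (1, "corrected")):
        sub = df[df["corr01"] == state]
        out[label] = _fit_mixed(
            "thickness_um ~ is_myope" + _covariate_terms(sub), sub,
            "is_myope", sector, f"myopia_contrast_{label}", re_formula="~1")
    return out


def adjust_pvalues(estimates: list[EffectEstimate],
                   family_size: int | None = None) -> list[EffectEstimate]:
    """Bonferroni adjustment within one family (default: the list itself)."""
    if not estimates:
        raise ValueError("empty estimate list")
    m = family_size if family_size is not None else len(estimates)
    raw = np.array([e.p_value for e in estimates])
    if m == len(estimates):
        adj = multipletests(raw, method="bonferroni")[1]
    else:
        adj = np.minimum(raw * m, 1.0)
    return [replace(e, p_adjusted=float(a)) for e, a in zip(estimates, adj)]


def _to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sector": e.sector, "term": e.term, "estimate_um": e.estimate,
        "ci_low": e.ci_low, "ci_high": e.ci_high, "p_value": e.p_value,
        "p_adjusted": e.p_adjusted, "n_eyes": e.n_eyes,
        "n_participants": e.n_participants, "model": e.model,
    } for e in estimates])


def analyze_cohort(table: pd.DataFrame,
                   sectors: tuple[str, ...] = SECTORS,
                   ) -> dict[str, pd.DataFrame]:
    """Run the three per-sector analysis families with Bonferroni adjustment.

    Returns data frames ``correction_effect``, ``al_interaction`` (with the
    per-state simple slopes) and ``group_contrast``.
    """
    correction = adjust_pvalues(
        [fit_correction_effect(table, s) for s in sectors])

    inter_results = [fit_al_interaction(table, s) for s in sectors]
    inter = adjust_pvalues([r.interaction for r in inter_results])
    slopes_raw = adjust_pvalues([r.slope_raw for r in inter_results])
    slopes_cor = adjust_pvalues([r.slope_corrected for r in inter_results])

    contrasts = [fit_group_contrast(table, s) for s in sectors]
    contr_raw = adjust_pvalues([c["raw"] for c in contrasts])
    contr_cor = adjust_pvalues([c["corrected"] for c in contrasts])

    return {
        "correction_effect": _to_frame(correction),
        "al_interaction": pd.concat([_to_frame(inter), _to_frame(slopes_raw),
                                     _to_frame(slopes_cor)],
                                    ignore_index=True),
        "group_contrast": pd.concat([_to_frame(contr_raw),
                                     _to_frame(contr_cor)],
                                    ignore_index=True),
    }
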