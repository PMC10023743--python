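"""Cohort-level statistics: group summaries and linear mixed models.

The study design this serves: controls contribute one scan each; patients
contribute a baseline scan plus up to two follow-ups, so observations are
clustered within participant (and, when both estimation methods are tabled,
paired within scan).  Group means are therefore compared with linear
mixed-effects models — random intercept per participant, plus a
visit-within-participant component when participants have repeated visits —
and the fixed-effect covariance is the participant-clustered ("classical
sandwich") estimator, which drops the residual-normality and
variance-structure assumptions the model-based covariance needs.  This is
the robust/empirical covariance for mixed models:

    cov(b) = A^-1 [ sum_g X_g' V_g^-1 r_g r_g' V_g^-1 X_g ] A^-1,
    A = sum_g X_g' V_g^-1 X_g,

with V_g the fitted marginal covariance of cluster g and r_g its marginal
residuals.  Confidence intervals use the normal approximation.

statsmodels' MixedLM provides the fit; the sandwich is assembled here
because MixedLM exposes no cluster-robust ``cov_type``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .cohort import CohortRecord, records_to_frame

__all__ = [
    "LmmResult",
    "cohort_summary",
    "lmm_compare",
    "lmm_regress",
    "simulate_two_cohorts",
    "simulate_slope_cohort",
]


class ConvergenceError(RuntimeError):
    """The mixed model failed to converge; diagnostics in the message."""


_BASELINES = ("control", "unfiltered")


def _ordered_levels(values) -> list:
    """Sorted factor levels with the conventional baseline (control /
    unfiltered) first, so contrasts read e.g. IPF-minus-control."""
    levels = sorted(values)
    for base in _BASELINES:
        if base in levels:
            levels.remove(base)
            levels.insert(0, base)
            break
    return levels


@dataclass
class LmmResult:
    """A fixed-effect estimate with robust uncertainty."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    n_participants: int
    model: str  # human-readable descriptor

    def __post_init__(self):
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must bracket the estimate")

    def summary(self) -> str:
        return (
            f"{self.model}\n"
            f"  estimate {self.estimate:+.4f}  robust SE {self.se:.4f}\n"
            f"  95% CI [{self.ci_low:+.4f}, {self.ci_high:+.4f}]  "
            f"p = {self.p_value:.4g}\n"
            f"  n_obs = {self.n_obs}, n_participants = {self.n_participants}"
        )


# ---------------------------------------------------------------------------
# summaries


def cohort_summary(
    records: list[CohortRecord] | pd.DataFrame,
    field: str,
    group: str = "cohort",
) -> dict[str, dict]:
    """Per-group mean and sample SD (n-1) of one numeric field.

    For groups with repeated measures per participant a ``raw_sd`` is also
    reported: the square root of the sum of the within- and
    between-participant variance components.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.dropna(subset=[field])
    out: dict[str, dict] = {}
    for g, sub in df.groupby(group):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty for field {field!r}")
        vals = sub[field].astype(float)
        entry = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
            "n": int(len(vals)),
        }
        per_part = sub.groupby("participant_id")[field]
        if (per_part.size() > 1).any():
            within = per_part.var(ddof=1).dropna()
            between = per_part.mean().var(ddof=1)
            entry["raw_sd"] = float(np.sqrt(within.mean() + between))
        out[str(g)] = entry
    return out


# ---------------------------------------------------------------------------
# mixed-model internals


def _prepare_frame(records, response, needed) -> pd.DataFrame:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.dropna(subset=[response, *needed]).copy()
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def _fit_mixedlm(df: pd.DataFrame, formula: str):
    """Random intercept per participant; a visit-within-participant variance
    component is added only when some participant has repeated visits."""
    has_repeats = (df.groupby("participant_id")["visit"].nunique() > 1).any()
    vc = {"visit": "0 + C(visit)"} if has_repeats else None
    model = smf.mixedlm(
        formula, df, groups=df["participant_id"], re_formula="1", vc_formula=vc
    )
    import warnings as _w

    result = None
    last_err: Exception | None = None
    # lbfgs occasionally lands on a boundary where the profiled Hessian is
    # singular; fall through progressively more robust optimizers
    for methods in (["lbfgs", "bfgs"], ["cg"], ["powell"]):
        try:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                result = model.fit(reml=True, method=methods)
            break
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_err = exc
            result = None
    if result is None:
        raise ConvergenceError(
            f"mixed model failed for formula {formula!r}: {last_err}"
        )
    if not result.converged:
        raise ConvergenceError(
            f"mixed model did not converge for formula {formula!r}; "
            f"params {np.asarray(result.params)}"
        )
    return model, result, has_repeats


def _inv_sqrt_psd(S: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root of a PSD matrix."""
    w, Q = np.linalg.eigh(S)
    w = np.maximum(w, floor)
    return (Q * (w**-0.5)) @ Q.T


def _cluster_sandwich(model, result) -> np.ndarray:
    """Participant-clustered sandwich covariance of the fixed effects.

    Uses the bias-reduced (CR2-type) form: each cluster's marginal residual
    ``r_g`` is pre-multiplied by ``A_g`` chosen so that
    ``A_g (V_g - X_g M X_g') A_g' = V_g`` — the residual covariance under
    the working model — which removes the downward small-sample bias of the
    plain sandwich when clusters are small or few.
    """
    beta = np.asarray(result.fe_params)
    k = len(beta)
    scale = float(result.scale)
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    vcomp = np.asarray(result.vcomp) if result.vcomp is not None else np.empty(0)
    vc_mats = getattr(model.exog_vc, "mats", []) if model.exog_vc is not None else []

    def cluster_V(gi, rows):
        ng = len(rows)
        Vg = scale * np.eye(ng)
        Zg = model.exog_re_li[gi] if model.exog_re_li is not None else None
        if Zg is not None and Zg.size:
            Vg += Zg @ cov_re @ Zg.T
        for j in range(len(vcomp)):
            Wgj = vc_mats[j][gi]
            if Wgj is not None and np.asarray(Wgj).size:
                Wgj = np.asarray(Wgj)
                Vg += vcomp[j] * (Wgj @ Wgj.T)
        return Vg

    groups = [(gi, model.row_indices[g]) for gi, g in enumerate(model.group_labels)]
    A = np.zeros((k, k))
    for gi, rows in groups:
        Xg = model.exog[rows]
        A += Xg.T @ np.linalg.solve(cluster_V(gi, rows), Xg)
    M = np.linalg.inv(A)

    B = np.zeros((k, k))
    for gi, rows in groups:
        Xg = model.exog[rows]
        yg = model.endog[rows]
        Vg = cluster_V(gi, rows)
        rg = yg - Xg @ beta
        Omega = Vg - Xg @ M @ Xg.T  # Var(r_g) under the working model
        # A_g = V^{1/2} (V^{-1/2} Omega V^{-1/2})^{-1/2} V^{-1/2}
        w, Q = np.linalg.eigh(Vg)
        w = np.maximum(w, 1e-12)
        V_half = (Q * np.sqrt(w)) @ Q.T
        V_ihalf = (Q * (w**-0.5)) @ Q.T
        Ag = V_half @ _inv_sqrt_psd(V_ihalf @ Omega @ V_ihalf) @ V_ihalf
        u = Xg.T @ np.linalg.solve(Vg, Ag @ rg)
        B += np.outer(u, u)
    return M @ B @ M


def _contrast_result(
    beta, cov, contrast, df_frame, model_desc
) -> LmmResult:
    c = np.asarray(contrast, dtype=float)
    est = float(c @ beta)
    se = float(np.sqrt(c @ cov @ c))
    z = sps.norm.ppf(0.975)
    p = float(2 * sps.norm.sf(abs(est) / se)) if se > 0 else float(est == 0.0)
    return LmmResult(
        estimate=est,
        se=se,
        ci_low=est - z * se,
        ci_high=est + z * se,
        p_value=min(p, 1.0),
        n_obs=len(df_frame),
        n_participants=df_frame["participant_id"].nunique(),
        model=model_desc,
    )


# ---------------------------------------------------------------------------
# public model fits


def lmm_compare(
    records: list[CohortRecord] | pd.DataFrame,
    response: str = "pvv_total",
    factor: str = "cohort",
) -> LmmResult:
    """Mixed-model mean comparison across the two levels of ``factor``.

    ``factor='cohort'`` contrasts IPF vs control; ``factor='method'``
    contrasts graph vs unfiltered paired within scan (the visit-nested
    random intercept carries the pairing).  The estimate is the second
    level's mean minus the first's, with participant-clustered sandwich SE.
    """
    df = _prepare_frame(records, response, [factor])
    if factor != "method" and "method" in df and df["method"].nunique() > 1:
        raise ValueError(
            "records mix both estimation methods; subset to one method before "
            "comparing cohorts"
        )
    levels = _ordered_levels(df[factor].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, got {levels}")
    for lev in levels:
        if df.loc[df[factor] == lev, "participant_id"].nunique() < 2:
            raise ValueError(f"need >= 2 participants in level {lev!r}")
    formula = f"{response} ~ C({factor}, Treatment(reference={levels[0]!r}))"
    model, result, has_repeats = _fit_mixedlm(df, formula)
    cov = _cluster_sandwich(model, result)
    beta = np.asarray(result.fe_params)
    contrast = np.zeros(len(beta))
    contrast[1] = 1.0  # the non-reference level effect
    desc = (
        f"LMM {response} ~ {factor} ({levels[1]} - {levels[0]}), "
        f"random intercept: participant"
        + (" + visit(participant)" if has_repeats else "")
        + ", participant-clustered sandwich SE"
    )
    return _contrast_result(beta, cov, contrast, df, desc)


def lmm_regress(
    records: list[CohortRecord] | pd.DataFrame,
    response: str = "pvv_total",
    covariate: str = "fibrosis_pct",
    interaction: str = "cohort",
    min_coverage: float = 0.8,
) -> dict[str, LmmResult]:
    """Per-cohort regression slopes of ``response`` on ``covariate``.

    A single mixed model with a covariate-by-cohort interaction and
    participant random intercepts is fitted; each cohort's slope (mL per
    covariate unit) is reported with its robust SE and 95% CI.
    """
    df0 = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    coverage = df0[covariate].notna().mean() if len(df0) else 0.0
    if coverage < min_coverage:
        raise ValueError(
            f"covariate {covariate!r} present for only {coverage:.0%} of rows "
            f"(< {min_coverage:.0%})"
        )
    df = _prepare_frame(df0, response, [covariate, interaction])
    levels = _ordered_levels(df[interaction].dropna().unique())
    for lev in levels:
        sub = df.loc[df[interaction] == lev, covariate]
        if sub.nunique() < 2:
            raise ValueError(f"covariate {covariate!r} is constant within {lev!r}")
    if len(levels) == 1:
        formula = f"{response} ~ {covariate}"
    else:
        formula = (
            f"{response} ~ {covariate} * "
            f"C({interaction}, Treatment(reference={levels[0]!r}))"
        )
    model, result, has_repeats = _fit_mixedlm(df, formula)
    cov = _cluster_sandwich(model, result)
    beta = np.asarray(result.fe_params)
    names = list(result.fe_params.index)

    out: dict[str, LmmResult] = {}
    slope_idx = names.index(covariate)
    for lev in levels:
        contrast = np.zeros(len(beta))
        contrast[slope_idx] = 1.0
        if lev != levels[0]:
            inter_name = next(
                n for n in names if n.startswith(f"{covariate}:") and f"[T.{lev}]" in n
            )
            contrast[names.index(inter_name)] = 1.0
        desc = (
            f"LMM {response} ~ {covariate} x {interaction}, slope for {lev}, "
            f"random intercept: participant"
            + (" + visit(participant)" if has_repeats else "")
            + ", participant-clustered sandwich SE"
        )
        out[str(lev)] = _contrast_result(beta, cov, contrast, df, desc)
    return out


# ---------------------------------------------------------------------------
# simulation (validation harness for the model fits)


def _partition(total: float) -> tuple[float, float, float]:
    """Split a PVV total into plausible sub-volumes (85/11/4 percent)."""
    p10p = 0.85 * total
    p10 = 0.11 * total
    return total - p10p - p10, p10, p10p


def simulate_two_cohorts(
    n_per_cohort: int = 50,
    mean_control: float = 22.0,
    mean_diff: float = 5.0,
    between_sd: float = 1.0,
    within_sd: float = 1.0,
    visits_ipf: int = 2,
    seed: int = 0,
) -> list[CohortRecord]:
    """Two-cohort records with participant random intercepts.

    Controls get one visit each; the second cohort gets ``visits_ipf``
    visits, inducing the repeated-measures structure of the study design.
    True fixed effect: ``mean_diff`` (IPF minus control).
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_per_cohort):
        b = rng.normal(0, between_sd)
        total = mean_control + b + rng.normal(0, within_sd)
        p5, p10, p10p = _partition(total)
        records.append(CohortRecord(
            participant_id=f"C{i:03d}", cohort="control", visit=1, method="graph",
            pvv_total=total, pvv5=p5, pvv10=p10, pvv10plus=p10p,
        ))
    for i in range(n_per_cohort):
        b = rng.normal(0, between_sd)
        for v in range(1, visits_ipf + 1):
            total = mean_control + mean_diff + b + rng.normal(0, within_sd)
            p5, p10, p10p = _partition(total)
            records.append(CohortRecord(
                participant_id=f"P{i:03d}", cohort="IPF", visit=v, method="graph",
                pvv_total=total, pvv5=p5, pvv10=p10, pvv10plus=p10p,
            ))
    return records


def simulate_slope_cohort(
    n_participants: int = 50,
    slope: float = 0.30,
    intercept: float = 30.0,
    covariate_range: tuple[float, float] = (0.0, 50.0),
    between_sd: float = 2.0,
    within_sd: float = 2.0,
    visits: int = 2,
    cohort: str = "IPF",
    seed: int = 0,
) -> list[CohortRecord]:
    """Single-cohort records with a built-in response-on-fibrosis slope
    (mL per percent) and participant random intercepts."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_participants):
        b = rng.normal(0, between_sd)
        for v in range(1, visits + 1):
            fib = float(rng.uniform(*covariate_range))
            total = intercept + slope * fib + b + rng.normal(0, within_sd)
            p5, p10, p10p = _partition(total)
            records.append(CohortRecord(
                participant_id=f"S{i:03d}", cohort=cohort, visit=v, method="graph",
                pvv_total=total, pvv5=p5, pvv10=p10, pvv10plus=p10p,
                fibrosis_pct=fib,
            ))
    return records
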