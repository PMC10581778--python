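"""Condition comparisons with random-intercept mixed models.

Metrics are compared across experimental conditions and activation numbers
while accounting for repeated measures on the same oocyte: a gaussian
linear mixed model with fixed effects for condition, activation number and
their interaction, and a random intercept per cell.  Before modelling,
extreme outliers (3 x IQR fences within each condition-by-activation cell)
are removed and residual normality is screened, falling back to a natural-
log transform of metric magnitudes when the check fails.  Estimated
marginal means are compared pairwise with Bonferroni correction.

Wald statistics are referred to an F distribution with containment
denominator degrees of freedom (number of cells minus number of
conditions); statsmodels' mixed models do not provide a Satterthwaite
approximation and the containment rule is the documented fallback, recorded
in the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutlierReport",
    "TransformReport",
    "MixedModelResult",
    "DoseResponseResult",
    "remove_extreme_outliers",
    "check_normality_and_transform",
    "fit_lmm",
    "permutation_test_condition",
    "dose_response_regression",
    "simulate_null_metrics",
]

REQUIRED = ("cell_id", "condition", "activation_index", "value")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table missing columns: {missing}")
    return table.dropna(subset=["value"]).copy()


@dataclass
class OutlierReport:
    removed: pd.DataFrame
    flagged_mild: pd.DataFrame
    fences: pd.DataFrame


def remove_extreme_outliers(
    table: pd.DataFrame, *, iqr_multiplier: float = 3.0
) -> tuple[pd.DataFrame, OutlierReport]:
    """Drop values outside ``[Q1 - 3*IQR, Q3 + 3*IQR]`` fences.

    Fences are computed within each condition-by-activation cell, with
    quartiles by linear interpolation (numpy's default).  Mild outliers
    (1.5 x IQR) are flagged in the report but retained.  With IQR = 0 the
    fence collapses to the quartile points and only values differing from
    them are removed — so an all-equal cell loses nothing.
    """
    table = _validate(table)
    keep_mask = pd.Series(True, index=table.index)
    mild_mask = pd.Series(False, index=table.index)
    fence_rows = []
    for (cond, act), sub in table.groupby(["condition", "activation_index"]):
        v = sub["value"].to_numpy(float)
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
        lo15, hi15 = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        keep_mask.loc[sub.index] = (v >= lo) & (v <= hi)
        mild_mask.loc[sub.index] = (v < lo15) | (v > hi15)
        fence_rows.append(
            {"condition": cond, "activation_index": act, "q1": q1, "q3": q3,
             "lower": lo, "upper": hi}
        )
    report = OutlierReport(
        removed=table.loc[~keep_mask].copy(),
        flagged_mild=table.loc[mild_mask & keep_mask].copy(),
        fences=pd.DataFrame(fence_rows),
    )
    return table.loc[keep_mask].copy(), report


@dataclass
class TransformReport:
    transformation: str  # "none" or "log"
    shapiro_p_before: float
    shapiro_p_after: Optional[float] = None
    warning: Optional[str] = None


def _fixed_effects_residuals(table: pd.DataFrame) -> np.ndarray:
    """Residuals of the fixed-effects (condition x activation) cell means."""
    means = table.groupby(["condition", "activation_index"])["value"].transform("mean")
    return (table["value"] - means).to_numpy(float)


def check_normality_and_transform(
    table: pd.DataFrame, *, alpha: float = 0.05
) -> tuple[pd.DataFrame, TransformReport]:
    """Shapiro-Wilk screen on model residuals with a log fallback.

    If residuals of the condition-by-activation cell means fail the Shapiro
    test at ``alpha``, the metric is replaced by the natural log of its
    magnitude and re-checked.  Metrics containing non-positive values
    cannot be log transformed; they are returned untransformed with a
    warning in the report.
    """
    table = _validate(table)
    resid = _fixed_effects_residuals(table)
    if len(resid) < 3 or np.allclose(resid, resid[0]):
        return table, TransformReport("none", shapiro_p_before=1.0)
    p_before = float(sps.shapiro(resid).pvalue)
    if p_before >= alpha:
        return table, TransformReport("none", shapiro_p_before=p_before)
    if (table["value"] <= 0).all():
        # uniformly negative metric (e.g. inward currents): log of magnitude
        values = np.log(-table["value"])
    elif (table["value"] > 0).all():
        values = np.log(table["value"])
    else:
        return table, TransformReport(
            "none",
            shapiro_p_before=p_before,
            warning="normality failed but metric has mixed signs; left untransformed",
        )
    out = table.copy()
    out["value"] = values
    p_after = float(sps.shapiro(_fixed_effects_residuals(out)).pvalue)
    return out, TransformReport("log", shapiro_p_before=p_before, shapiro_p_after=p_after)


@dataclass
class MixedModelResult:
    """Random-intercept mixed-model comparison of a metric."""

    fixed_effects: pd.DataFrame
    p_condition: float
    p_activation: Optional[float]
    p_interaction: Optional[float]
    emmeans: pd.Series
    contrasts: pd.DataFrame
    group_var: float
    resid_var: float
    singular: bool
    df_denominator: float
    transformation: str
    n_removed_outliers: int
    n_obs: int
    n_cells: int
    conditions: tuple
    dof_method: str = "containment"
    converged: bool = True


def _wald_f(result, names: list[str], df_den: float) -> Optional[float]:
    idx = [i for i, nm in enumerate(result.model.exog_names) if nm in names]
    if not idx:
        return None
    L = np.zeros((len(idx), len(result.fe_params)))
    for r, i in enumerate(idx):
        L[r, i] = 1.0
    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(beta), : len(beta)]
    Lb = L @ beta
    M = L @ cov @ L.T
    try:
        W = float(Lb @ np.linalg.solve(M, Lb))
    except np.linalg.LinAlgError:
        return None
    q = L.shape[0]
    return float(sps.f.sf(W / q, q, max(df_den, 1.0)))


def fit_lmm(
    table: pd.DataFrame,
    *,
    alpha: float = 0.05,
    remove_outliers: bool = True,
    transform: bool = True,
    reml: bool = True,
) -> MixedModelResult:
    """Fit ``value ~ condition * activation`` with a per-cell random intercept.

    Requires at least two conditions or two activation levels and, for
    condition contrasts, at least three cells per condition.  Main effects
    and the interaction are tested with Wald F statistics (containment
    denominator degrees of freedom); estimated marginal means per condition
    average the fitted cell means over activation levels, and all pairwise
    condition contrasts are Bonferroni-adjusted.  A near-zero random-
    intercept variance is reported through the ``singular`` flag (the model
    then effectively collapses to ordinary least squares — the documented
    profile for degenerate between-cell variance).
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    table = _validate(table)
    n_removed = 0
    if remove_outliers:
        table, rep = remove_extreme_outliers(table)
        n_removed = len(rep.removed)
    transformation = "none"
    if transform:
        table, trep = check_normality_and_transform(table, alpha=alpha)
        transformation = trep.transformation

    conditions = tuple(sorted(table["condition"].unique()))
    activations = tuple(sorted(table["activation_index"].unique()))
    if len(conditions) < 2 and len(activations) < 2:
        raise ValueError("need >= 2 conditions or >= 2 activation levels")
    counts = table.groupby("condition")["cell_id"].nunique()
    if len(conditions) >= 2 and (counts < 3).any():
        raise ValueError("need >= 3 cells per condition for contrasts")

    terms = []
    if len(conditions) >= 2:
        terms.append("C(condition)")
    if len(activations) >= 2:
        terms.append("C(activation_index)")
    formula = "value ~ " + (" * ".join(terms) if terms else "1")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, table, groups=table["cell_id"])
        result = None
        last_exc: Exception | None = None
        # gradient-based optimizers can hit exactly singular information at
        # zero between-cell variance; fall back to derivative-free search
        for method in ("lbfgs", "powell", "nm"):
            try:
                result = model.fit(reml=reml, method=[method])
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        if result is None:
            raise RuntimeError(
                f"mixed-model optimization failed for every optimizer: {last_exc}"
            )

    group_var = float(np.asarray(result.cov_re).ravel()[0])
    resid_var = float(result.scale)
    singular = group_var < 1e-8 * max(resid_var, 1e-12)

    n_cells = int(table["cell_id"].nunique())
    df_den = max(float(n_cells - len(conditions)), 1.0)

    exog_names = result.model.exog_names
    cond_names = [n for n in exog_names if "C(condition)" in n and ":" not in n]
    act_names = [n for n in exog_names if "C(activation_index)" in n and ":" not in n]
    int_names = [n for n in exog_names if ":" in n]
    p_condition = _wald_f(result, cond_names, df_den)
    p_activation = _wald_f(result, act_names, df_den)
    p_interaction = _wald_f(result, int_names, df_den)

    fe = pd.DataFrame(
        {
            "estimate": result.fe_params,
            "se": result.bse_fe,
        }
    )

    # estimated marginal means: average the fixed-effect design over the
    # activation reference grid, per condition
    import patsy

    design_info = model.data.design_info
    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(beta), : len(beta)]
    emm_rows = {}
    for cond in conditions:
        grid = pd.DataFrame(
            {"condition": cond, "activation_index": list(activations)}
        )
        X = np.asarray(patsy.build_design_matrices([design_info], grid)[0])
        emm_rows[cond] = X.mean(axis=0)
    emmeans = pd.Series(
        {c: float(L @ beta) for c, L in emm_rows.items()}, name="emmean"
    )

    pairs = list(combinations(conditions, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        L = emm_rows[a] - emm_rows[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        tval = est / se if se > 0 else np.inf
        p_raw = float(2 * sps.t.sf(abs(tval), df_den))
        rows.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "t": tval,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, m * p_raw),
            }
        )
    contrasts = pd.DataFrame(rows)

    return MixedModelResult(
        fixed_effects=fe,
        p_condition=p_condition if p_condition is not None else np.nan,
        p_activation=p_activation,
        p_interaction=p_interaction,
        emmeans=emmeans,
        contrasts=contrasts,
        group_var=group_var,
        resid_var=resid_var,
        singular=singular,
        df_denominator=df_den,
        transformation=transformation,
        n_removed_outliers=n_removed,
        n_obs=len(table),
        n_cells=n_cells,
        conditions=conditions,
        converged=bool(getattr(result, "converged", True)),
    )


def permutation_test_condition(
    table: pd.DataFrame, *, n_permutations: int = 999, seed: int = 0
) -> float:
    """Cell-level permutation p-value for a two-condition mean difference.

    Condition labels are shuffled across cells (keeping each cell's
    repeated activations together) and the absolute difference of
    condition means of cell means is the test statistic.
    """
    table = _validate(table)
    cells = table.groupby(["cell_id", "condition"])["value"].mean().reset_index()
    conds = sorted(cells["condition"].unique())
    if len(conds) != 2:
        raise ValueError("permutation test is defined for two conditions")
    values = cells["value"].to_numpy(float)
    labels = (cells["condition"] == conds[1]).to_numpy()

    def stat(lab):
        return abs(values[lab].mean() - values[~lab].mean())

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_permutations):
        if stat(rng.permutation(labels)) >= observed - 1e-15:
            count += 1
    return count / (n_permutations + 1)


@dataclass
class DoseResponseResult:
    slope: Optional[float]
    intercept: Optional[float]
    p_value: Optional[float]
    n: int
    defined: bool


def dose_response_regression(
    table: pd.DataFrame, covariate: str = "rna_ng"
) -> DoseResponseResult:
    """OLS regression of a per-cell metric on an injected-RNA dose.

    One observation per cell (first-activation value).  Returns an
    undefined-slope flag when the covariate does not vary.
    """
    import statsmodels.api as sm

    table = _validate(table)
    if covariate not in table.columns:
        raise ValueError(f"covariate column {covariate!r} missing")
    first = (
        table.sort_values("activation_index")
        .groupby("cell_id")
        .first()
        .dropna(subset=[covariate, "value"])
    )
    x = first[covariate].to_numpy(float)
    y = first["value"].to_numpy(float)
    if len(x) < 3 or np.ptp(x) == 0:
        return DoseResponseResult(None, None, None, n=len(x), defined=False)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return DoseResponseResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_value=float(fit.pvalues[1]),
        n=len(x),
        defined=True,
    )


def simulate_null_metrics(
    *,
    n_cells_per_condition: int = 8,
    n_activations: int = 3,
    cell_sd: float = 1.0,
    noise_sd: float = 1.0,
    mean: float = 20.0,
    condition_shift: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Metric table from a two-condition random-intercept model.

    With ``condition_shift = 0`` this is the null used to check the type-I
    error of the condition test.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ci, cond in enumerate(("A", "B")):
        for cell in range(n_cells_per_condition):
            intercept = mean + ci * condition_shift + rng.normal(0.0, cell_sd)
            for act in range(1, n_activations + 1):
                rows.append(
                    {
                        "cell_id": f"{cond}{cell:02d}",
                        "condition": cond,
                        "activation_index": act,
                        "value": intercept + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
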