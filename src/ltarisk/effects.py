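"""Post-classification regression stage.

Follows the trial's classify-analyze strategy: each participant's modal
posterior class is treated as observed.  Provides multinomial logistic
regressions of class membership on covariates (relative-risk ratios),
the arm-by-baseline-class logit model for low-risk membership at follow-up
with delta-method average marginal effects of the intervention within each
baseline class, and the attrition / trial-participation chi-square checks.

Classification uncertainty is deliberately not propagated (a documented
limitation shared with the original analysis), and no multiplicity
correction is applied to the per-class tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, chi2_contingency, norm

Z95 = norm.ppf(0.975)


@dataclass
class RRREstimate:
    outcome_class: int
    covariate: str
    rrr: float
    ci_low: float
    ci_high: float


@dataclass
class RRRTable:
    estimates: list
    lr_chi2: float
    df: int
    p_value: float
    loglik: float
    reference_class: int


@dataclass
class MarginalEffect:
    baseline_class: int
    dydx: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    n: int


@dataclass
class OddsRatio:
    baseline_class: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    pct_increase: float


def _dummies(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical covariates to 0/1 dummies, dropping one level."""
    out = {}
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:
                out[f"{col}[{lev}]"] = (s.astype(str) == lev).astype(float)
        else:
            out[col] = s.astype(float)
    return pd.DataFrame(out, index=covariates.index)


def multinomial_rrr(modal_class, covariates: pd.DataFrame,
                    reference_class: int = 0, maxiter: int = 200) -> RRRTable:
    """Multinomial logit of modal class on covariates; RRR = exp(coef).

    The model likelihood-ratio chi-square compares against the
    intercept-only model.  Perfect separation is reported as an error
    naming the offending covariate.
    """
    y_raw = np.asarray(modal_class)
    classes = np.unique(y_raw)
    if len(classes) < 2:
        raise ValueError("need at least two observed classes")
    if reference_class not in classes:
        raise ValueError(f"reference class {reference_class} not observed")
    # map so the reference class is outcome 0 (statsmodels' base category)
    order = [reference_class] + [c for c in classes if c != reference_class]
    y = np.zeros(len(y_raw), dtype=int)
    for i, c in enumerate(order):
        y[y_raw == c] = i
    Xd = _dummies(covariates)
    X = sm.add_constant(Xd, has_constant="add")
    model = sm.MNLogit(y, np.asarray(X))
    try:
        res = model.fit(method="newton", maxiter=maxiter, disp=0)
    except Exception as err:  # includes PerfectSeparationError
        raise ValueError(f"multinomial fit failed (separation?): {err}") from err
    params = np.asarray(res.params)  # (n_cols, n_classes-1)
    if not np.isfinite(params).all() or np.abs(params).max() > 15:
        worst = int(np.unravel_index(np.nanargmax(np.abs(params)), params.shape)[0])
        raise ValueError("apparent perfect separation on covariate "
                         f"{X.columns[worst]!r}")
    bse = np.asarray(res.bse)
    names = list(X.columns)
    ests = []
    for out_i in range(params.shape[1]):
        for row_i, name in enumerate(names):
            if name == "const":
                continue
            b, se = params[row_i, out_i], bse[row_i, out_i]
            ests.append(RRREstimate(
                outcome_class=int(order[out_i + 1]),
                covariate=name,
                rrr=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * se)),
                ci_high=float(np.exp(b + Z95 * se)),
            ))
    null = sm.MNLogit(y, np.ones((len(y), 1))).fit(method="newton", disp=0)
    lr = float(2.0 * (res.llf - null.llf))
    df = (len(order) - 1) * (X.shape[1] - 1)
    return RRRTable(estimates=ests, lr_chi2=lr, df=df,
                    p_value=float(chi2.sf(lr, df)), loglik=float(res.llf),
                    reference_class=int(reference_class))


@dataclass
class LowRiskModel:
    """Fitted logit of follow-up low-risk membership on arm x baseline class."""

    result: object                    # statsmodels Logit results
    design: np.ndarray
    columns: list
    arm: np.ndarray
    baseline_class: np.ndarray
    class_levels: np.ndarray
    arm_col: int
    interaction_cols: dict            # class level -> column index (absent for ref)

    @property
    def reference_class(self) -> int:
        return int(self.class_levels[0])


def lowrisk_glm(low: np.ndarray, arm: np.ndarray, baseline_class: np.ndarray,
                covariates: pd.DataFrame | None = None) -> LowRiskModel:
    """Maximum-likelihood logit with arm, baseline-class dummies and their
    interaction (plus optional adjustment covariates) as predictors.

    Every arm-by-class cell must be non-empty for the interaction to be
    estimable; with no covariates the model is saturated in the cells, so
    fitted cell probabilities equal observed proportions exactly.
    """
    low = np.asarray(low, dtype=float)
    arm = np.asarray(arm, dtype=float)
    baseline_class = np.asarray(baseline_class)
    levels = np.unique(baseline_class)
    cells = pd.crosstab(baseline_class, arm)
    empty = [(idx, col) for idx in cells.index for col in cells.columns
             if cells.loc[idx, col] == 0]
    full = [(lev, a) for lev in levels for a in (0.0, 1.0)
            if lev not in cells.index or a not in cells.columns]
    if empty or full:
        raise ValueError(f"empty arm-by-class cells: {empty + full}")

    cols = {"const": np.ones(len(low)), "arm": arm}
    inter_cols = {}
    for lev in levels[1:]:
        dk = (baseline_class == lev).astype(float)
        cols[f"class[{lev}]"] = dk
        cols[f"arm:class[{lev}]"] = arm * dk
    if covariates is not None:
        cd = _dummies(covariates)
        for c in cd.columns:
            cols[c] = cd[c].to_numpy()
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    res = sm.Logit(low, X).fit(disp=0, maxiter=200)
    for lev in levels[1:]:
        inter_cols[lev] = names.index(f"arm:class[{lev}]")
    return LowRiskModel(result=res, design=X, columns=names, arm=arm,
                        baseline_class=baseline_class, class_levels=levels,
                        arm_col=names.index("arm"), interaction_cols=inter_cols)


def _counterfactual_designs(m: LowRiskModel, rows: np.ndarray):
    X1 = m.design[rows].copy()
    X0 = m.design[rows].copy()
    X1[:, m.arm_col] = 1.0
    X0[:, m.arm_col] = 0.0
    for lev, ci in m.interaction_cols.items():
        dk = (m.baseline_class[rows] == lev).astype(float)
        X1[:, ci] = dk
        X0[:, ci] = 0.0
    return X1, X0


def average_marginal_effects(m: LowRiskModel,
                             classes=None) -> list[MarginalEffect]:
    """Average marginal effect of arm within each baseline class.

    For each subject the intervention contrast P(low | arm=1, x) -
    P(low | arm=0, x) is computed from the fitted model and averaged within
    the class; the standard error comes from the delta method over the full
    coefficient covariance (the dy/dx convention of Stata's margins).
    """
    beta = np.asarray(m.result.params)
    V = np.asarray(m.result.cov_params())
    out = []
    for lev in (m.class_levels if classes is None else classes):
        rows = np.flatnonzero(m.baseline_class == lev)
        if len(rows) < 2:
            import warnings
            warnings.warn(f"class {lev}: fewer than 2 subjects; AME undefined")
            out.append(MarginalEffect(int(lev), np.nan, np.nan, np.nan,
                                      np.nan, np.nan, np.nan, len(rows)))
            continue
        X1, X0 = _counterfactual_designs(m, rows)
        p1 = 1.0 / (1.0 + np.exp(-X1 @ beta))
        p0 = 1.0 / (1.0 + np.exp(-X0 @ beta))
        ame = float(np.mean(p1 - p0))
        grad = (X1 * (p1 * (1 - p1))[:, None] - X0 * (p0 * (1 - p0))[:, None]).mean(axis=0)
        se = float(np.sqrt(grad @ V @ grad))
        z = ame / se if se > 0 else np.nan
        out.append(MarginalEffect(
            baseline_class=int(lev), dydx=ame, se=se,
            ci_low=ame - Z95 * se, ci_high=ame + Z95 * se, z=z,
            p_value=float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            n=len(rows)))
    return out


def arm_odds_ratio(m: LowRiskModel, baseline_class: int) -> OddsRatio:
    """Odds ratio of follow-up low-risk membership for PEI vs control within
    one baseline class: exp(beta_arm + beta_{arm x class})."""
    beta = np.asarray(m.result.params)
    V = np.asarray(m.result.cov_params())
    L = np.zeros(len(beta))
    L[m.arm_col] = 1.0
    if baseline_class != m.reference_class:
        if baseline_class not in m.interaction_cols:
            raise ValueError(f"class {baseline_class} not in the model")
        L[m.interaction_cols[baseline_class]] = 1.0
    est = float(L @ beta)
    se = float(np.sqrt(L @ V @ L))
    return OddsRatio(baseline_class=int(baseline_class),
                     odds_ratio=float(np.exp(est)),
                     ci_low=float(np.exp(est - Z95 * se)),
                     ci_high=float(np.exp(est + Z95 * se)),
                     pct_increase=float(100.0 * (np.exp(est) - 1.0)))


def _pearson_chi2(table: np.ndarray):
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def attrition_test(returned: np.ndarray, arm: np.ndarray):
    """Pearson chi-square (1 df, no continuity correction) for differential
    loss to follow-up between arms, typically within one baseline class."""
    table = pd.crosstab(np.asarray(arm), np.asarray(returned).astype(bool))
    if table.shape != (2, 2):
        raise ValueError(f"need a 2x2 arm-by-returned table, got {table.shape}")
    stat, _, p = _pearson_chi2(table.to_numpy())
    return stat, p


def participation_bias_test(modal_class: np.ndarray, randomized: np.ndarray):
    """Pearson chi-square comparing the class distribution of randomized vs
    non-randomized participants (df = K - 1)."""
    table = pd.crosstab(np.asarray(modal_class), np.asarray(randomized).astype(bool))
    if table.shape[1] != 2:
        raise ValueError("randomized flag must take both values")
    stat, df, p = _pearson_chi2(table.to_numpy())
    return stat, df, p
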