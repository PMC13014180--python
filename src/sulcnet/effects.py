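"""Case-control effect maps and the linear/complex contraction test.

Per-sulcus standardized group effects come from OLS of the standardized
response on group plus covariates; the contraction test fits, per sulcal
class, a linear mixed model with a fixed group effect and a subject random
intercept (REML), with one-sided Wald p values in the stated directions
(linear class: beta1 > 0; complex class: beta1 < 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectRecord",
    "ContractionResult",
    "fit_sulcus_effect",
    "effect_map",
    "residualize",
    "contraction_test",
    "build_design",
]

DEFAULT_COVARIATES = ("age", "TTV", "EN", "sex", "site")


@dataclass(frozen=True)
class EffectRecord:
    sulcus: str
    phenotype: str
    beta1: float
    se: float
    p: float
    n: int
    covariates: tuple[str, ...]


@dataclass(frozen=True)
class ContractionResult:
    beta_linear: float
    p_linear: float  # one-sided, H1: beta1 > 0
    beta_complex: float
    p_complex: float  # one-sided, H1: beta1 < 0
    re_variance_linear: float
    re_variance_complex: float
    alpha: float = 0.05

    @property
    def contraction(self) -> bool:
        return self.p_linear < self.alpha and self.p_complex < self.alpha


def build_design(covariates: pd.DataFrame, covariate_list,
                 include_group: bool = True) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept [+ group] + named covariates.

    ``sex`` and ``site`` are treated as categorical (dummy-coded, first level
    dropped); other covariates enter as numeric columns. Raises on constant
    columns or a rank-deficient design.
    """
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if include_group:
        grp = covariates["group"].astype(str)
        levels = set(grp)
        if levels != {"case", "control"}:
            raise ValueError(f"group must contain both 'case' and 'control', got {sorted(levels)}")
        cols.append((grp == "case").to_numpy(dtype=float))
        names.append("group")
    for cname in covariate_list:
        if cname not in covariates.columns:
            raise ValueError(f"covariate {cname!r} not in table")
        col = covariates[cname]
        if cname in ("sex", "site"):
            dummies = pd.get_dummies(col.astype(str), prefix=cname, drop_first=True)
            for dcol in dummies.columns:
                cols.append(dummies[dcol].to_numpy(dtype=float))
                names.append(dcol)
        else:
            v = pd.to_numeric(col).to_numpy(dtype=float)
            if np.ptp(v) == 0:
                raise ValueError(f"covariate {cname!r} is constant")
            cols.append(v)
            names.append(cname)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return X, names


def _ols(y: np.ndarray, X: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough subjects for the requested model")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, resid, dof


def fit_sulcus_effect(values: pd.Series, covariates: pd.DataFrame,
                      covariate_list=DEFAULT_COVARIATES,
                      sulcus: str = "?", phenotype: str = "?") -> EffectRecord:
    """Standardized group effect for one sulcus.

    `values` is indexed by subject; `covariates` has one row per subject
    (columns ``subject``, ``group`` and the requested covariates). The
    response is standardized to mean 0 / SD 1 across all included subjects
    before fitting, so beta1 is in SD units.
    """
    cov = covariates.set_index("subject").loc[values.index]
    y = values.to_numpy(dtype=float)
    if np.std(y, ddof=1) == 0:
        raise ValueError(f"sulcus {sulcus}: constant response")
    y = (y - y.mean()) / y.std(ddof=1)
    X, names = build_design(cov, covariate_list, include_group=True)
    if len(y) < X.shape[1] + 2:
        raise ValueError("not enough subjects for the requested model")
    beta, se, _, dof = _ols(y, X)
    j = names.index("group")
    t = beta[j] / se[j]
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return EffectRecord(sulcus=sulcus, phenotype=phenotype,
                        beta1=float(beta[j]), se=float(se[j]), p=max(p, 1e-300),
                        n=len(y), covariates=tuple(covariate_list))


def effect_map(table: pd.DataFrame, phenotype: str,
               covariate_list=DEFAULT_COVARIATES, cohort: str = "",
               alpha: float = 0.05) -> pd.DataFrame:
    """Per-sulcus standardized group effects for one phenotype.

    `table` is a long-format phenotype table (or a complexity-score table
    with a ``phenotype`` column). Returns a frame indexed by sulcus with
    beta1/se/p plus Bonferroni (p < alpha/n_sulci) and nominal flags.
    """
    sub = table[table["phenotype"] == phenotype]
    if sub.empty:
        raise ValueError(f"phenotype {phenotype!r} not present")
    cov_cols = ["subject", "group"] + [c for c in ("age", "sex", "site", "TTV", "EN")
                                       if c in table.columns]
    covariates = sub[cov_cols].drop_duplicates("subject").reset_index(drop=True)
    sulci = list(dict.fromkeys(sub["sulcus"]))
    records = []
    for sulcus in sulci:
        vals = (sub[sub["sulcus"] == sulcus]
                .set_index("subject")["value"].astype(float))
        rec = fit_sulcus_effect(vals, covariates, covariate_list,
                                sulcus=sulcus, phenotype=phenotype)
        records.append(rec)
    out = pd.DataFrame({
        "beta1": [r.beta1 for r in records],
        "se": [r.se for r in records],
        "p": [r.p for r in records],
        "n": [r.n for r in records],
    }, index=pd.Index(sulci, name="sulcus"))
    out["bonferroni"] = out["p"] < alpha / len(sulci)
    out["nominal"] = out["p"] < alpha
    out.attrs["cohort"] = cohort
    out.attrs["phenotype"] = phenotype
    out.attrs["covariates"] = tuple(covariate_list)
    return out


def residualize(scores: pd.DataFrame, covariates: pd.DataFrame,
                covariate_list=DEFAULT_COVARIATES) -> pd.DataFrame:
    """OLS-residualize per-sulcus scores on covariates (group excluded).

    `scores` is subjects x sulci. Residuals are orthogonal to every design
    column by construction.
    """
    cov = covariates.set_index("subject").loc[scores.index]
    X, _ = build_design(cov, covariate_list, include_group=False)
    Y = scores.to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(Y - X @ beta, index=scores.index, columns=scores.columns)


def _fit_class_lmm(long: pd.DataFrame):
    """REML random-intercept model: value ~ group with subject intercepts."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    n_per_subject = long.groupby("subject").size()
    if (n_per_subject == 1).all():
        # One sulcus per subject: random intercept unidentifiable; the fixed
        # effect degenerates to the two-group OLS mean difference.
        y = long["value"].to_numpy(dtype=float)
        g = (long["group"] == "case").to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(g), g])
        beta, se, _, _ = _ols(y, X)
        return float(beta[1]), float(se[1]), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ group_case", long, groups=long["subject"])
        try:
            fit = model.fit(reml=True)
        except Exception as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(f"mixed model failed to converge: {exc}") from exc
    beta = float(fit.params["group_case"])
    se = float(fit.bse["group_case"])
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    if not np.isfinite(re_var) or re_var < 0:
        warnings.warn("singular random-effect variance; using 0")
        re_var = 0.0
    return beta, se, re_var


def contraction_test(residual_scores: pd.DataFrame, sulcus_class: pd.Series,
                     groups: pd.Series, alpha: float = 0.05) -> ContractionResult:
    """Test for contraction of the linear-to-complex axis.

    `residual_scores` is subjects x sulci (covariate-residualized complexity),
    `sulcus_class` maps sulcus -> "linear"/"complex", `groups` maps
    subject -> "case"/"control". Per class, a mixed model with fixed group
    effect and subject random intercept is fit by REML; one-sided Wald p
    values are returned (linear: beta1 > 0, complex: beta1 < 0).
    """
    groups = groups.loc[residual_scores.index]
    if set(groups) != {"case", "control"}:
        raise ValueError("both groups must be present")
    results = {}
    for cls, direction in (("linear", +1), ("complex", -1)):
        members = [s for s in residual_scores.columns if sulcus_class.get(s) == cls]
        if len(members) < 1:
            raise ValueError(f"no sulci in class {cls!r}")
        long = (residual_scores[members]
                .stack().rename("value").reset_index())
        long.columns = ["subject", "sulcus", "value"]
        long["group"] = groups.loc[long["subject"]].to_numpy()
        long["group_case"] = (long["group"] == "case").astype(float)
        beta, se, re_var = _fit_class_lmm(long)
        z = beta / se
        p = float(stats.norm.sf(direction * z))
        results[cls] = (beta, p, re_var)
    return ContractionResult(
        beta_linear=results["linear"][0], p_linear=results["linear"][1],
        beta_complex=results["complex"][0], p_complex=results["complex"][1],
        re_variance_linear=results["linear"][2],
        re_variance_complex=results["complex"][2],
        alpha=alpha,
    )
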