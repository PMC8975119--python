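"""Trial-level analysis table and the mixed-model inference suite.

The trial table carries, per included trial, the binary detection outcome
(``success``), the detection latency for hits (ms), the five tile-variance
difference variables, the rated background properties, the two
dissimilarity scores, the congruency factors, stimulus color, the movement
covariate, and the grouping factors (participant, background image, target
location).

Models mirror the original analysis strategy: separate model groups per
research question, each with diff_luminance and movement as covariates
(plus run for adults); binomial-logit GLMMs on success with crossed random
intercepts for participant, background and location; Gaussian LMMs on
latency with participant and background intercepts (a helper tests whether
a location intercept improves the fit); significance by chi-square
likelihood-ratio tests on nested ML fits; collinearity screened with
variance inflation factors (threshold 2.5); interactions with
diff_luminance kept only when they jointly improve the model at p < .05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .glmm import GlmmFit, fit_glmm

__all__ = [
    "ModelFit",
    "LrtResult",
    "build_model_table",
    "fit_success_glmm",
    "fit_latency_lmm",
    "location_structure_lrt",
    "lrt",
    "select_interactions",
    "vif_check",
    "marginal_r2",
    "stimulus_bias_check",
    "aoi_count_model",
    "run_model_suite",
]

CONTINUOUS_PREDICTORS = [
    "diff_luminance", "diff_alpha", "diff_deviation", "diff_entropy", "diff_skew",
    "curvature", "regularity", "symmetry", "depth",
    "child_dissimilarity", "adult_dissimilarity", "movement",
]
BIAS_CHECK_PROPERTIES = [
    "diff_luminance", "diff_alpha", "diff_deviation", "diff_entropy", "diff_skew",
    "curvature", "depth", "regularity", "symmetry",
]


@dataclass
class ModelFit:
    """Unified fixed-effect summary of a fitted mixed model.

    ``scale`` is "log-odds" for binomial fits and "ms" for latency fits.
    ``n_params`` counts fixed coefficients plus variance parameters, the
    quantity differenced for LRT degrees of freedom.
    """

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    re_var: dict[str, float]
    loglik: float
    scale: str
    family: str
    n: int
    n_params: int
    converged: bool
    message: str = ""
    row_key: int = 0

    @property
    def ci(self) -> np.ndarray:
        return np.column_stack([self.params - 1.96 * self.bse, self.params + 1.96 * self.bse])

    def summary_frame(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params,
                "se": self.bse,
                "ci_lo": ci[:, 0],
                "ci_hi": ci[:, 1],
                "z": self.params / self.bse,
            }
        )


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float


def build_model_table(trials: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Prepare the analysis table from merged design + outcome rows.

    Continuous predictors are z-scored over the included trials (the
    coefficient scale of the reported models presumes standardized
    inputs); congruency factors are coded 0/1 with incongruent = 0.
    """
    df = trials.copy()
    for col in ("category_congruency", "depth_congruency"):
        if df[col].dtype == object:
            df[col] = (df[col] == "congruent").astype(float)
    if standardize:
        for col in CONTINUOUS_PREDICTORS:
            if col in df.columns:
                s = df[col].std(ddof=0)
                df[col] = (df[col] - df[col].mean()) / (s if s > 0 else 1.0)
    df["success"] = df["success"].astype(float)
    return df


def _design_matrix(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["(Intercept)"]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        elif t.startswith("C(") and t.endswith(")"):
            var = t[2:-1]
            dummies = pd.get_dummies(table[var], prefix=var, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
                names.append(c)
            continue
        else:
            cols.append(table[t].to_numpy(float))
        names.append(t)
    return np.column_stack(cols), names


def fit_success_glmm(
    table: pd.DataFrame,
    fixed_terms: list[str],
    random: tuple[str, ...] = ("participant_id", "background_id", "location_idx"),
) -> ModelFit:
    """Binomial-logit GLMM on success with crossed random intercepts."""
    X, names = _design_matrix(table, fixed_terms)
    y = table["success"].to_numpy(float)
    groups = {g: table[g].to_numpy() for g in random}
    fit = fit_glmm(y, X, names, groups, family="binomial")
    re_var = {g: sd**2 for g, sd in fit.re_sd.items()}
    return ModelFit(
        terms=names,
        params=fit.params,
        bse=fit.bse,
        re_var=re_var,
        loglik=fit.loglik,
        scale="log-odds",
        family="binomial",
        n=fit.n,
        n_params=len(names) + len(re_var),
        converged=fit.converged,
        message=fit.message,
        row_key=_row_key(table),
    )


def _row_key(table: pd.DataFrame) -> int:
    return int(pd.util.hash_pandas_object(table.index).sum() % (2**62))


def fit_latency_lmm(
    table: pd.DataFrame,
    fixed_terms: list[str],
    random: tuple[str, ...] = ("participant_id", "background_id"),
) -> ModelFit:
    """Gaussian LMM on latency (ms), hits only, fitted by ML."""
    hits = table[table["success"] > 0.5].copy() if "success" in table.columns else table.copy()
    if "latency" not in hits.columns or hits["latency"].isna().all():
        raise ValueError("no hit latencies to model")
    hits = hits[hits["latency"].notna()]
    X, names = _design_matrix(hits, fixed_terms)
    data = pd.DataFrame(X[:, 1:], columns=[f"x{i}" for i in range(X.shape[1] - 1)], index=hits.index)
    data["latency"] = hits["latency"].to_numpy(float)
    for g in random:
        data[g] = hits[g].to_numpy()
    data["_one"] = 1
    vc = {g: f"0 + C({g})" for g in random}
    formula = "latency ~ " + (" + ".join(data.columns[: X.shape[1] - 1]) if X.shape[1] > 1 else "1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(formula, data, groups="_one", vc_formula=vc, re_formula="0")
        res = md.fit(reml=False, method="lbfgs", maxiter=500)
    params = res.fe_params.to_numpy()
    bse = res.bse_fe.to_numpy()
    re_var = {g: float(res.vcomp[i]) for i, g in enumerate(vc)}
    re_var["residual"] = float(res.scale)
    singular = any(v < 1e-8 for v in re_var.values())
    return ModelFit(
        terms=names,
        params=params,
        bse=bse,
        re_var=re_var,
        loglik=float(res.llf),
        scale="ms",
        family="gaussian",
        n=len(hits),
        n_params=len(names) + len(re_var),
        converged=bool(res.converged),
        message="singular fit: a variance component is ~0" if singular else "",
        row_key=_row_key(hits),
    )


def location_structure_lrt(table: pd.DataFrame, fixed_terms: list[str]) -> LrtResult:
    """Does adding a location random intercept improve the latency model?"""
    base = fit_latency_lmm(table, fixed_terms, random=("participant_id", "background_id"))
    full = fit_latency_lmm(table, fixed_terms, random=("participant_id", "background_id", "location_idx"))
    return lrt(full, base)


def lrt(full: ModelFit, reduced: ModelFit) -> LrtResult:
    """Chi-square likelihood-ratio test of nested ML fits."""
    if reduced.n != full.n or reduced.row_key != full.row_key:
        raise ValueError("models were fitted on different rows")
    extra_fixed = set(reduced.terms) - set(full.terms)
    if extra_fixed:
        raise ValueError(f"models are not nested; reduced has extra terms {sorted(extra_fixed)}")
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("full model has no extra parameters")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LrtResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def vif_check(table: pd.DataFrame, predictors: list[str], threshold: float = 2.5) -> tuple[dict, bool]:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j)."""
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    X = table[predictors].to_numpy(float)
    vifs = {}
    for j, name in enumerate(predictors):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(X)), others])
        coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ coef
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        ss_res = np.sum(resid**2)
        r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        vifs[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs, all(v < threshold for v in vifs.values())


def marginal_r2(fit: ModelFit, table: pd.DataFrame) -> float:
    """Nakagawa-style marginal R^2: fixed-effect variance over total.

    The binomial-logit residual variance is fixed at pi^2 / 3 on the
    latent scale; Gaussian models use the estimated residual variance.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    rows = table
    if fit.family == "gaussian" and "success" in table.columns:
        rows = table[(table["success"] > 0.5) & table["latency"].notna()]
    X, names = _design_matrix(rows, [t for t in fit.terms if t != "(Intercept)"])
    eta_fixed = X @ fit.params
    var_f = float(np.var(eta_fixed))
    var_re = float(sum(v for k, v in fit.re_var.items() if k != "residual"))
    var_resid = fit.re_var.get("residual", np.pi**2 / 3.0 if fit.family == "binomial" else 0.0)
    return var_f / (var_f + var_re + var_resid)


def select_interactions(
    table: pd.DataFrame,
    dv: str,
    base_terms: list[str],
    interact_with: list[str],
    alpha: float = 0.05,
) -> tuple[ModelFit, bool, LrtResult]:
    """Keep diff_luminance interactions only if they jointly improve the fit."""
    if "diff_luminance" not in base_terms:
        raise ValueError("diff_luminance must be among the base terms")
    fitter = fit_success_glmm if dv == "success" else fit_latency_lmm
    inter_terms = [f"diff_luminance:{t}" for t in interact_with]
    base = fitter(table, base_terms)
    full = fitter(table, base_terms + inter_terms)
    test = lrt(full, base)
    keep = test.p < alpha and full.converged
    return (full if keep else base), keep, test


def stimulus_bias_check(trials: pd.DataFrame) -> pd.DataFrame:
    """Compare visual properties between category-congruent and -incongruent trials.

    Per property: group means, Cohen's d (pooled SD), Welch-free two-sample
    t statistic and p value.  A facilitation bias would show up as
    systematic property differences between the congruency groups.
    """
    col = trials["category_congruency"]
    mask = (col == "congruent") if col.dtype == object else (col.astype(float) > 0.5)
    cong, incong = trials[mask], trials[~mask]
    if cong.empty or incong.empty:
        raise ValueError("one congruency group is empty")
    rows = []
    for prop in BIAS_CHECK_PROPERTIES:
        a = cong[prop].to_numpy(float)
        b = incong[prop].to_numpy(float)
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
        d = 0.0 if pooled == 0 else (b.mean() - a.mean()) / pooled
        if pooled == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {"property": prop, "mean_congruent": a.mean(), "mean_incongruent": b.mean(),
             "d": d, "t": float(t), "p": float(p)}
        )
    return pd.DataFrame(rows)


def aoi_count_model(counts: pd.DataFrame, n_aoi: int = 10) -> dict:
    """Count GLMM for the detected-by-coincidence check.

    ``counts`` is the per-trial AOI count table from the gaze module.  The
    long-format response is the number of fixations per location (the
    target contrasted against each empty AOI), modelled with a Poisson
    family and a participant random intercept; the location factor is
    tested with an LRT.
    """
    recs = []
    for _, row in counts.iterrows():
        tloc = int(row["target_location"])
        recs.append({"participant_id": row["participant_id"], "loc": "target",
                     "count": int(row["target_count"])})
        for idx in range(n_aoi):
            if idx == tloc:
                continue
            recs.append({"participant_id": row["participant_id"], "loc": f"aoi_{idx}",
                         "count": int(row[f"aoi_{idx}"])})
    long = pd.DataFrame(recs)
    # target is the reference level so each AOI contrast is empty-vs-target
    long["loc"] = pd.Categorical(long["loc"], categories=["target"] + sorted(set(long["loc"]) - {"target"}))
    dummies = pd.get_dummies(long["loc"], drop_first=True)
    X = np.column_stack([np.ones(len(long))] + [dummies[c].to_numpy(float) for c in dummies.columns])
    names = ["(Intercept)"] + list(dummies.columns)
    y = long["count"].to_numpy(float)
    groups = {"participant_id": long["participant_id"].to_numpy()}
    full = fit_glmm(y, X, names, groups, family="poisson")
    null = fit_glmm(y, X[:, :1], ["(Intercept)"], groups, family="poisson")
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    df = X.shape[1] - 1
    mu = np.exp(np.clip(X @ full.params, -30, 30))
    pearson = float(np.sum((y - mu) ** 2 / np.clip(mu, 1e-9, None)) / max(1, len(y) - X.shape[1]))
    zcontrasts = full.params[1:] / full.bse[1:]
    return {
        "fit": full,
        "lrt": LrtResult(chi2, df, float(stats.chi2.sf(chi2, df))),
        "contrast_p": {n: float(2 * stats.norm.sf(abs(z))) for n, z in zip(names[1:], zcontrasts)},
        "overdispersion": pearson,
    }


MODEL_GROUPS = {
    "congruency": ["category_congruency", "depth_congruency", "diff_luminance"],
    "dissimilarity": ["child_dissimilarity", "adult_dissimilarity", "diff_luminance"],
    "computational": ["diff_luminance", "diff_alpha", "diff_deviation", "diff_entropy", "diff_skew"],
    "rated": ["diff_luminance", "curvature", "depth", "regularity", "symmetry"],
}


def run_model_suite(
    table: pd.DataFrame,
    group: str = "infant",
    ceiling_hit_rate: float = 0.9,
    interaction_groups: tuple[str, ...] = ("congruency",),
) -> dict:
    """Run the four model groups on each applicable dependent variable.

    Infants get success GLMMs and latency LMMs; adults get latency models
    only when their hit rate is at ceiling (>= ``ceiling_hit_rate``), plus
    the run covariate.  Movement is always included.  Also runs the color
    LRT check.  Returns {'results': tidy frame, 'decisions': ledger dict}.
    """
    table = table.copy()
    covariates = ["movement"]
    if group == "adult" and "run" in table.columns:
        covariates.append("run")
    hit_rate = table["success"].mean()
    dvs = ["success", "latency"]
    if group == "adult" and hit_rate >= ceiling_hit_rate:
        dvs = ["latency"]

    results = []
    decisions: dict = {"group": group, "hit_rate": float(hit_rate), "vif": {}, "interactions": {}}
    for gname, terms in MODEL_GROUPS.items():
        cont = [t for t in terms if t in CONTINUOUS_PREDICTORS]
        if len(cont) >= 2:
            vifs, ok = vif_check(table, cont)
            decisions["vif"][gname] = {"values": vifs, "pass": ok}
        for dv in dvs:
            fitter = fit_success_glmm if dv == "success" else fit_latency_lmm
            all_terms = terms + covariates
            if gname in interaction_groups:
                inter_with = [t for t in terms if t != "diff_luminance"]
                fit, kept, test = select_interactions(table, dv, all_terms, inter_with)
                decisions["interactions"][f"{gname}/{dv}"] = {
                    "kept": kept, "chi2": test.chi2, "df": test.df, "p": test.p,
                }
            else:
                fit = fitter(table, all_terms)
            if not fit.converged:
                decisions.setdefault("convergence", {})[f"{gname}/{dv}"] = fit.message
            r2 = marginal_r2(fit, table) if fit.converged else float("nan")
            per_term = _per_term_lrts(table, dv, [t for t in fit.terms if t != "(Intercept)"], fitter)
            sf = fit.summary_frame()
            sf["model"] = gname
            sf["dv"] = dv
            sf["r2_marginal"] = r2
            sf["converged"] = fit.converged
            sf = sf.merge(per_term, on="term", how="left")
            results.append(sf)

    # color check: does stimulus color predict performance at all?
    for dv in dvs:
        fitter = fit_success_glmm if dv == "success" else fit_latency_lmm
        base = fitter(table, covariates)
        full = fitter(table, ["C(color)"] + covariates)
        test = lrt(full, base)
        decisions.setdefault("color_check", {})[dv] = {"chi2": test.chi2, "df": test.df, "p": test.p}

    return {"results": pd.concat(results, ignore_index=True), "decisions": decisions}


def _per_term_lrts(table, dv, terms, fitter) -> pd.DataFrame:
    full = fitter(table, terms)
    rows = []
    for t in terms:
        if any(":" in other and t in other.split(":") for other in terms if other != t):
            # main effects inside a retained interaction are not dropped alone
            rows.append({"term": t, "chi2": np.nan, "df": np.nan, "p": np.nan})
            continue
        reduced = fitter(table, [x for x in terms if x != t])
        try:
            res = lrt(full, reduced)
            rows.append({"term": t, "chi2": res.chi2, "df": res.df, "p": res.p})
        except ValueError:
            rows.append({"term": t, "chi2": np.nan, "df": np.nan, "p": np.nan})
    return pd.DataFrame(rows)
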