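"""Trial-level mixed-effects group statistics.

Two model families are fit per region, with the trial-level dependent
variable being either an ERP peak-window amplitude (µV) or windowed gamma
power (dB):

* Model 1: fixed effects group (O/M), picture category (face/mosaic),
  hemisphere, peak (ERP only) and the group x picture interaction;
* Model 2: mosaic trials removed, picture replaced by the five face
  categories (group x face-category interaction).

Both include a random intercept per patient and are fit by REML through
statsmodels' MixedLM.  A patient implanted bilaterally may contribute trials
to both groups; the single per-patient intercept is exactly how the
non-independence is handled.  P-values use a containment-style degrees of
freedom: terms that only vary between patients are tested against
(n_patients - q_between) df, within-patient terms against residual df.
Term p-values are Holm-Bonferroni corrected; a significant interaction is
followed by pairwise estimated-marginal-mean contrasts with Tukey
(studentized-range) adjustment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["ModelSpec", "FitResult", "build_trial_table", "fit_lme",
           "holm_adjust", "classify_responsive"]

_META_COLS = ["patient", "group", "hemisphere", "region", "channel",
              "category"]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect layout of one mixed model."""

    dependent: str            # "amplitude_uv" or "gamma_db"
    category_var: str         # "picture" (model 1) or "category" (model 2)
    include_peaks: bool       # True for ERP models only
    interaction: bool = True

    @classmethod
    def model1(cls, dependent: str = "amplitude_uv") -> "ModelSpec":
        return cls(dependent, "picture", include_peaks=dependent == "amplitude_uv")

    @classmethod
    def model2(cls, dependent: str = "amplitude_uv") -> "ModelSpec":
        return cls(dependent, "category", include_peaks=dependent == "amplitude_uv")

    @property
    def formula(self) -> str:
        f = f"value ~ C(group) + C({self.category_var}) + C(hemisphere)"
        if self.include_peaks:
            f += " + C(peak)"
        if self.interaction:
            f += f" + C(group):C({self.category_var})"
        return f


@dataclass
class FitResult:
    terms: pd.DataFrame       # term, beta, ci_low, ci_high, df, p_raw, p_holm
    contrasts: pd.DataFrame   # pairwise EMM contrasts (Tukey-adjusted)
    converged: bool
    result: object = field(repr=False, default=None)


def build_trial_table(rows: pd.DataFrame, dependent: str,
                      model: int = 1) -> pd.DataFrame:
    """Normalize a trial table for one model family.

    Adds a binary ``picture`` column (face/mosaic), renames the dependent
    column to ``value`` and, for model 2, drops mosaic trials.  Rows with
    missing metadata raise.
    """
    if dependent not in rows.columns:
        raise ValueError(f"dependent column {dependent!r} missing")
    need = [c for c in _META_COLS if c in ("patient", "group", "hemisphere",
                                           "region", "channel", "category")]
    missing = [c for c in need if c not in rows.columns]
    if missing:
        raise ValueError(f"missing metadata columns {missing}")
    if rows[need].isna().any().any():
        bad = rows.loc[rows[need].isna().any(axis=1), "channel"].unique()
        raise ValueError(f"rows with missing metadata for channels {list(bad)}")
    table = rows.copy()
    table["picture"] = np.where(table["category"] == "mosaic", "mosaic", "face")
    table["value"] = table[dependent].astype(float)
    if model == 2:
        table = table[table["category"] != "mosaic"].copy()
    elif model != 1:
        raise ValueError("model must be 1 or 2")
    return table.reset_index(drop=True)


def holm_adjust(p) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, returned in the input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _fe_covariance(res, exog: np.ndarray, patients: np.ndarray) -> np.ndarray:
    """GLS covariance of the fixed effects given the estimated variance
    components (random-intercept tau^2, residual sigma^2):
    cov(beta) = (sum_i X_i' V_i^-1 X_i)^-1 with V_i = s2*I + tau2*11'.
    Conditioning on the variance estimates matches lme4's vcov and stays
    finite when the intercept variance sits on the boundary."""
    tau2 = float(np.asarray(res.cov_re).squeeze()) if res.cov_re.size else 0.0
    s2 = float(res.scale)
    k = exog.shape[1]
    acc = np.zeros((k, k))
    for p in pd.unique(patients):
        xi = exog[patients == p]
        n_i = xi.shape[0]
        xtx = xi.T @ xi
        xsum = xi.sum(axis=0)
        shrink = tau2 / (s2 + n_i * tau2) if tau2 > 0 else 0.0
        acc += (xtx - shrink * np.outer(xsum, xsum)) / s2
    return np.linalg.pinv(acc)


def _is_between(cols: np.ndarray, patients: np.ndarray) -> bool:
    """True when every design column in ``cols`` is constant within patient."""
    df = pd.DataFrame(cols)
    df["__p"] = patients
    return bool((df.groupby("__p").nunique() <= 1).all().all())


def fit_lme(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """REML mixed-model fit with a random intercept per patient.

    The fitting itself is delegated to statsmodels MixedLM; this function
    owns the term tests, the df convention, Holm correction and the Tukey
    post-hoc contrasts.
    """
    for col in ("patient", "group", "hemisphere", spec.category_var):
        if table[col].nunique() < (2 if col != "hemisphere" else 1):
            if col in ("patient", "group"):
                raise ValueError(f"need >= 2 levels of {col}")
    counts = (table.groupby(["group", spec.category_var], observed=True)
              .size().unstack(fill_value=0))
    if (counts.to_numpy() == 0).any():
        empty = [(g, c) for g in counts.index for c in counts.columns
                 if counts.loc[g, c] == 0]
        raise ValueError(f"empty design cells: {empty}")

    model = sm.MixedLM.from_formula(spec.formula, table, groups=table["patient"],
                                    re_formula="1")
    # the default gradient optimizers occasionally stall on a degenerate
    # point (llf = inf) or stop short; fit with several and keep the best
    # finite REML likelihood
    res, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("powell", "bfgs", "lbfgs"):
            try:
                cand = model.fit(reml=True, method=method)
            except Exception:
                continue
            if not np.isfinite(cand.llf):
                continue
            if res is None or cand.llf > res.llf + 1e-8:
                res = cand
                converged = bool(getattr(cand, "converged", True))
    if res is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")
    if not converged:
        warnings.warn("mixed-model fit did not converge; diagnostics: "
                      f"cov_re={np.asarray(res.cov_re).ravel()}")

    design_info = res.model.data.design_info
    k_fe = len(res.fe_params)
    fe = np.asarray(res.fe_params)
    exog = res.model.exog
    cov_fe = _fe_covariance(res, exog, table["patient"].to_numpy())
    patients = table["patient"].to_numpy()
    n_patients = table["patient"].nunique()
    n_obs = len(table)
    resid_df = max(n_obs - k_fe, 1)

    slices = design_info.term_name_slices
    q_between = sum(
        (sl.stop - sl.start) for name, sl in slices.items()
        if _is_between(exog[:, sl], patients))
    df_between = max(n_patients - q_between, 1)

    rows = []
    for name, sl in slices.items():
        if name == "Intercept":
            continue
        q = sl.stop - sl.start
        df_term = df_between if _is_between(exog[:, sl], patients) else resid_df
        if q == 1:
            beta = fe[sl.start]
            se = np.sqrt(cov_fe[sl.start, sl.start])
            tval = beta / se
            p = 2.0 * stats.t.sf(abs(tval), df_term)
            crit = stats.t.ppf(0.975, df_term)
            rows.append((name, beta, beta - crit * se, beta + crit * se,
                         df_term, p))
        else:
            b = fe[sl]
            v = cov_fe[sl, sl]
            wald = float(b @ np.linalg.solve(v, b))
            p = stats.f.sf(wald / q, q, df_term)
            rows.append((name, np.nan, np.nan, np.nan, df_term, p))
    terms = pd.DataFrame(rows, columns=["term", "beta", "ci_low", "ci_high",
                                        "df", "p_raw"])
    terms["p_holm"] = holm_adjust(terms["p_raw"].to_numpy())

    interaction_name = next((n for n in slices if ":" in n), None)
    contrasts = pd.DataFrame(columns=["group", "contrast", "beta", "ci_low",
                                      "ci_high", "t", "p_tukey"])
    if interaction_name is not None:
        p_int = terms.loc[terms["term"] == interaction_name, "p_raw"]
        if len(p_int) and p_int.iloc[0] < 0.05:
            contrasts = _pairwise_emm_contrasts(res, table, spec, cov_fe,
                                                resid_df)
    return FitResult(terms, contrasts, converged, res)


def _pairwise_emm_contrasts(res, table, spec: ModelSpec, cov_fe, df) -> pd.DataFrame:
    """Estimated-marginal-mean category contrasts within each group, with
    studentized-range (Tukey) p-values."""
    from patsy import build_design_matrices

    design_info = res.model.data.design_info
    fe = np.asarray(res.fe_params)
    cats = sorted(table[spec.category_var].unique())
    k = len(cats)
    others = ["hemisphere"] + (["peak"] if spec.include_peaks else [])
    grid_base = table[others].drop_duplicates().reset_index(drop=True)

    def emm_row(group, cat):
        grid = grid_base.copy()
        grid["group"] = group
        grid[spec.category_var] = cat
        (mat,) = build_design_matrices([design_info], grid)
        return np.asarray(mat).mean(axis=0)

    rows = []
    for group in sorted(table["group"].unique()):
        for i in range(k):
            for j in range(i + 1, k):
                L = emm_row(group, cats[i]) - emm_row(group, cats[j])
                est = float(L @ fe)
                se = float(np.sqrt(L @ cov_fe @ L))
                tval = est / se
                p = stats.studentized_range.sf(abs(tval) * np.sqrt(2.0), k, df)
                crit = stats.t.ppf(0.975, df)
                rows.append((group, f"{cats[i]} vs {cats[j]}", est,
                             est - crit * se, est + crit * se, tval,
                             float(min(p, 1.0))))
    return pd.DataFrame(rows, columns=["group", "contrast", "beta", "ci_low",
                                       "ci_high", "t", "p_tukey"])


def classify_responsive(erp_face_rows: pd.DataFrame,
                        gamma_face_values, alpha: float = 0.05) -> dict:
    """Flag one contact as ERP- and/or gamma-responsive to faces.

    ERP: one-sample two-sided t-test of the trial amplitudes against 0 in
    each peak window, Holm-corrected over the three windows; responsive if
    any survives.  Gamma: one-sided t-test that the windowed trial dB values
    exceed 0.
    """
    if erp_face_rows.empty:
        raise ValueError("no kept face trials for this contact")
    ps = []
    for _, sub in erp_face_rows.groupby("peak", observed=True):
        vals = sub["amplitude_uv"].to_numpy(dtype=float)
        p = stats.ttest_1samp(vals, 0.0).pvalue if len(vals) > 1 else 1.0
        ps.append(1.0 if np.isnan(p) else p)
    erp_resp = bool((holm_adjust(ps) < alpha).any())

    gamma_vals = np.asarray(gamma_face_values, dtype=float)
    if gamma_vals.size < 2:
        raise ValueError("no kept face trials for this contact")
    pg = stats.ttest_1samp(gamma_vals, 0.0, alternative="greater").pvalue
    gamma_resp = bool(not np.isnan(pg) and pg < alpha)
    return {"erp_responsive": erp_resp, "gamma_responsive": gamma_resp}
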