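"""Standardized-trait performance regressions with nested random effects.

Performance measures (relative change in stem number for clonal
reproduction; proportion of flowering stems for sexual reproduction)
are regressed on standardized phenology/leaf-size traits, microhabitat
(ridge vs snowbed), and trait x microhabitat interactions, with random
intercepts for transect and for site nested within transect — a
selection-gradient-style multiple regression (standardization makes
slopes comparable across traits), not a formal selection-gradient
analysis.

When a trait x microhabitat interaction is significant the trait's
effect is re-estimated separately within each microhabitat.

Both responses are modelled as Gaussian linear mixed models (a
documented simplification for the proportion response).  When an
estimated random-effect variance collapses to the boundary the term is
dropped and the model refit, so in the no-group-effect limit the
coefficients coincide with ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from ssrherit.phenotypes import standardize

DEFAULT_TRAITS = [
    "leaf_size",
    "snowmelt_to_leaf_expansion",
    "gdd_to_leaf_expansion",
    "gdd_to_flowering",
]

_BOUNDARY_FRAC = 1e-3  # random variance below this fraction of residual -> drop


@dataclass
class PerformanceModelFit:
    """One fitted performance regression with per-term Wald F-tests."""

    response: str
    terms: pd.DataFrame
    random_variances: dict[str, float]
    interaction_significant: dict[str, bool]
    n: int
    ddf: int
    ddf_method: str
    alpha: float
    traits: list[str] = field(default_factory=list)
    backend: str = "mixedlm"

    def significant_interactions(self) -> list[str]:
        return [t for t, sig in self.interaction_significant.items() if sig]


def _zscore_columns(
    data: pd.DataFrame, traits: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    out = data.copy()
    znames = []
    for t in traits:
        zn = f"{t}_z"
        if zn not in out.columns:
            out[zn] = standardize(out[t])
        znames.append(zn)
    return out, znames


def _fit_lmm(
    formula: str,
    data: pd.DataFrame,
    transect_col: str,
    site_col: str,
) -> tuple[object, dict[str, float], str]:
    """Fit the LMM, dropping boundary random terms; returns (result, vars, backend)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula,
            data,
            groups=data[transect_col],
            re_formula="1",
            vc_formula={"site": f"0 + C({site_col})"},
        )
        res = model.fit(reml=True)
        var_transect = float(np.asarray(res.cov_re).ravel()[0])
        var_site = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        resid = float(res.scale)
        keep_transect = var_transect > _BOUNDARY_FRAC * resid
        keep_site = var_site > _BOUNDARY_FRAC * resid
        if keep_transect and keep_site:
            return res, {"transect": var_transect, "site": var_site,
                         "residual": resid}, "mixedlm"
        if keep_site and not keep_transect:
            model = smf.mixedlm(
                formula, data, groups=data[site_col], re_formula="1"
            )
            res = model.fit(reml=True)
            return res, {
                "transect": 0.0,
                "site": float(np.asarray(res.cov_re).ravel()[0]),
                "residual": float(res.scale),
            }, "mixedlm"
        if keep_transect and not keep_site:
            model = smf.mixedlm(
                formula, data, groups=data[transect_col], re_formula="1"
            )
            res = model.fit(reml=True)
            return res, {
                "transect": float(np.asarray(res.cov_re).ravel()[0]),
                "site": 0.0,
                "residual": float(res.scale),
            }, "mixedlm"
    # both variances at the boundary: the model is ordinary least squares
    res = smf.ols(formula, data).fit()
    return res, {"transect": 0.0, "site": 0.0,
                 "residual": float(res.mse_resid)}, "ols"


def fit_performance_model(
    data: pd.DataFrame,
    response: str,
    traits: list[str] | None = None,
    microhabitat_col: str = "microhabitat",
    transect_col: str = "transect",
    site_col: str = "site",
    alpha: float = 0.05,
    ddf_method: str = "containment",
) -> PerformanceModelFit:
    """Regress a performance measure on standardized traits + interactions.

    The fixed part has exactly the four traits, microhabitat, and the
    four trait x microhabitat interactions; random intercepts for
    transect and site-within-transect.  Per-term marginal Wald F-tests
    use 1 numerator df and a denominator df by ``ddf_method``
    (``"containment"``: n - p - n_sites; ``"residual"``: n - p).
    """
    traits = list(traits) if traits is not None else list(DEFAULT_TRAITS)
    data = data.copy()
    data, ztraits = _zscore_columns(data, traits)
    needed = [response] + ztraits + [microhabitat_col, transect_col, site_col]
    df = data[needed].dropna().copy()
    n = len(df)
    n_sites = df[site_col].nunique()
    if n_sites < 3:
        raise ValueError(
            f"only {n_sites} site(s); the transect/site random structure "
            "collapses — fit a fixed-effects-only model instead"
        )
    if df[microhabitat_col].nunique() < 2:
        raise ValueError("microhabitat factor is constant")

    fixed_terms = (
        ztraits
        + [f"C({microhabitat_col})"]
        + [f"{z}:C({microhabitat_col})" for z in ztraits]
    )
    formula = f"{response} ~ " + " + ".join(fixed_terms)
    res, random_vars, backend = _fit_lmm(formula, df, transect_col, site_col)

    params = res.params
    bse = res.bse
    p_fixed = len(res.fe_params) if backend == "mixedlm" else len(params)
    if ddf_method == "containment":
        ddf = max(n - p_fixed - n_sites, 1)
    elif ddf_method == "residual":
        ddf = max(n - p_fixed, 1)
    else:
        raise ValueError(f"unknown ddf_method {ddf_method!r}")

    habitat_level = None
    rows = []
    inter_sig: dict[str, bool] = {}

    def term_row(label: str, coef_name: str) -> dict:
        est = float(params[coef_name])
        se = float(bse[coef_name])
        f_stat = (est / se) ** 2 if se > 0 else np.nan
        p_val = float(stats.f.sf(f_stat, 1, ddf)) if np.isfinite(f_stat) else np.nan
        return {"term": label, "estimate": est, "df_num": 1, "df_den": ddf,
                "F": f_stat, "p": p_val}

    coef_names = list(params.index)
    micro_coefs = [
        c for c in coef_names
        if c.startswith(f"C({microhabitat_col})[T.") and ":" not in c
    ]
    if len(micro_coefs) != 1:
        raise RuntimeError(f"expected one microhabitat contrast, got {micro_coefs}")
    habitat_level = micro_coefs[0]

    for z, t in zip(ztraits, traits):
        rows.append(term_row(t, z))
    rows.append(term_row("microhabitat", habitat_level))
    for z, t in zip(ztraits, traits):
        inter_name = next(
            c for c in coef_names
            if ":" in c
            and z in c.split(":")
            and any(part.startswith(f"C({microhabitat_col})") for part in c.split(":"))
        )
        row = term_row(f"microhabitat x {t}", inter_name)
        inter_sig[t] = bool(row["p"] < alpha) if np.isfinite(row["p"]) else False
        rows.append(row)

    return PerformanceModelFit(
        response=response,
        terms=pd.DataFrame(rows),
        random_variances=random_vars,
        interaction_significant=inter_sig,
        n=n,
        ddf=ddf,
        ddf_method=ddf_method,
        alpha=alpha,
        traits=traits,
        backend=backend,
    )


def refit_by_microhabitat(
    fit: PerformanceModelFit,
    data: pd.DataFrame,
    microhabitat_col: str = "microhabitat",
    transect_col: str = "transect",
    site_col: str = "site",
    min_n: int = 20,
) -> dict[str, pd.DataFrame]:
    """Separate per-habitat regressions for traits with significant interaction.

    Returns, per microhabitat level, a coefficient table for all traits
    (the rows for flagged traits carry ``flagged = True``).  Raises if no
    interaction was significant or a habitat subset is too small.
    """
    flagged = fit.significant_interactions()
    if not flagged:
        raise ValueError("no significant trait x microhabitat interaction")
    data = data.copy()
    data, ztraits = _zscore_columns(data, fit.traits)
    needed = [fit.response] + ztraits + [microhabitat_col, transect_col, site_col]
    df = data[needed].dropna()
    levels = df[microhabitat_col].unique()
    if len(levels) < 2:
        raise ValueError("microhabitat factor is constant")
    out: dict[str, pd.DataFrame] = {}
    formula = f"{fit.response} ~ " + " + ".join(ztraits)
    for level in levels:
        sub = df[df[microhabitat_col] == level]
        if len(sub) < min_n:
            raise ValueError(
                f"habitat {level!r} subset too small ({len(sub)} < {min_n})"
            )
        res, _, _ = _fit_lmm(formula, sub, transect_col, site_col)
        params, bse = res.params, res.bse
        ddf = max(len(sub) - (len(ztraits) + 1) - sub[site_col].nunique(), 1)
        rows = []
        for z, t in zip(ztraits, fit.traits):
            est = float(params[z])
            se = float(bse[z])
            f_stat = (est / se) ** 2 if se > 0 else np.nan
            rows.append(
                {
                    "trait": t,
                    "estimate": est,
                    "F": f_stat,
                    "p": float(stats.f.sf(f_stat, 1, ddf))
                    if np.isfinite(f_stat)
                    else np.nan,
                    "flagged": t in flagged,
                }
            )
        out[str(level)] = pd.DataFrame(rows)
    return out
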