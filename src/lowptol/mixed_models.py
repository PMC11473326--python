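"""Per-condition and combined mixed-model fits with BLUP genotypic values.

The phenotyping design is a randomized complete block trial of inbred lines
under two phosphorus regimes.  Within one condition the model is

    y_ijk = mu + block_j + g_i + e_ijk,          g_i ~ N(0, sigma_G^2)

with block fixed and line random; across conditions the combined model adds
a fixed condition effect (blocks nested in condition) and a random
line-by-condition interaction,

    y_ijkc = mu + cond_c + block_j(c) + g_i + (gP)_ic + e_ijkc.

Variance components are estimated by REML and line-level genotypic values
are reported on the observable trait scale as the fitted grand mean plus
the line BLUP.  Random-effect significance is assessed by the REML
likelihood-ratio (deviance) test against chi-square with 1 df; because the
null hypothesis pins the variance to the boundary of its parameter space,
the 50:50 chi-bar-square mixture p-value is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reml import reml_fit

__all__ = [
    "ModelFit",
    "LrtResult",
    "fit_condition_model",
    "fit_combined_model",
    "lrt_random_effect",
    "genotypic_value_matrix",
]

COMBINED = "combined"

#: random-term names used throughout
TERM_LINE = "line"
TERM_GXP = "line_x_condition"


@dataclass
class ModelFit:
    """REML fit of one trait in one scope (a single condition or combined)."""

    trait: str
    scope: str  # condition label, or "combined"
    var_G: float
    var_GxP: float | None
    var_error: float
    fixed_effects: pd.Series
    loglik_reml: float
    genotypic_values: pd.Series | None  # mu_hat + BLUP, indexed by line
    grand_mean: float
    converged: bool
    boundary: frozenset
    n_obs: int
    n_blocks: int
    n_conditions: int
    random_terms: tuple[str, ...]

    @property
    def is_combined(self) -> bool:
        return self.scope == COMBINED


@dataclass
class LrtResult:
    """Likelihood-ratio test of one random term."""

    term: str
    deviance: float
    df: int
    p_value: float  # plain chi-square(1) reference
    p_value_mixture: float  # 50:50 boundary mixture, reported as metadata
    significant: bool  # at alpha = 0.01
    alpha: float = 0.01


def _prepare(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = table.loc[table["trait"] == trait].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    return sub


def _dummies(labels: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies (first sorted level as reference)."""
    levels = sorted(map(str, pd.unique(labels)))
    cols = levels[1:]
    arr = np.column_stack([(labels.astype(str) == c).to_numpy(float) for c in cols]) if cols else np.empty((len(labels), 0))
    return arr, [f"{prefix}[{c}]" for c in cols]


def fit_condition_model(
    table: pd.DataFrame, trait: str, condition: str, omit: str | None = None
) -> ModelFit:
    """REML fit of the single-condition randomized-block model.

    Parameters
    ----------
    omit
        Optionally drop the ``"line"`` random term, yielding the reduced
        (fixed-effects-only) model used by :func:`lrt_random_effect`.
    """
    sub = _prepare(table, trait)
    sub = sub.loc[sub["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no data for condition {condition!r}")
    lines = sorted(map(str, pd.unique(sub["line"])))
    blocks = pd.unique(sub["block"])
    if len(blocks) < 2:
        raise ValueError("at least 2 blocks are required")
    if len(lines) < 2:
        raise ValueError("at least 2 lines are required")
    y = sub["value"].to_numpy(float)
    Xb, bnames = _dummies(sub["block"], "block")
    X = np.column_stack([np.ones(len(sub)), Xb])
    names = ["intercept"] + bnames
    random_terms = {} if omit == TERM_LINE else {TERM_LINE: sub["line"].astype(str)}
    fit = reml_fit(y, X, random_terms, fixed_names=names)
    grand_mean = fit.fitted_fixed_mean(X)
    gvals = None
    var_G = 0.0
    if TERM_LINE in random_terms:
        var_G = fit.variances[TERM_LINE]
        gvals = pd.Series(
            grand_mean + fit.blups[TERM_LINE], index=fit.levels[TERM_LINE], name=trait
        )
    return ModelFit(
        trait=trait,
        scope=str(condition),
        var_G=var_G,
        var_GxP=None,
        var_error=fit.var_error,
        fixed_effects=pd.Series(fit.beta, index=names),
        loglik_reml=fit.loglik,
        genotypic_values=gvals,
        grand_mean=grand_mean,
        converged=fit.converged,
        boundary=fit.boundary,
        n_obs=fit.n_obs,
        n_blocks=len(blocks),
        n_conditions=1,
        random_terms=tuple(random_terms),
    )


def fit_combined_model(
    table: pd.DataFrame, trait: str, omit: str | None = None
) -> ModelFit:
    """REML fit of the two-condition combined model.

    Fixed effects: intercept, condition, block nested within condition
    (coded through condition-by-block cell dummies).  Random effects: line
    and line-by-condition interaction; either may be dropped via ``omit``
    to form a nested reduced model.
    """
    sub = _prepare(table, trait)
    conditions = sorted(map(str, pd.unique(sub["condition"])))
    if len(conditions) < 2:
        raise ValueError(
            "combined analysis needs both P conditions; "
            "use fit_condition_model for a single condition"
        )
    cell = sub["condition"].astype(str) + "/" + sub["block"].astype(str)
    Xc, cnames = _dummies(cell, "cell")
    X = np.column_stack([np.ones(len(sub)), Xc])
    names = ["intercept"] + cnames
    random_terms: dict[str, pd.Series] = {}
    if omit != TERM_LINE:
        random_terms[TERM_LINE] = sub["line"].astype(str)
    if omit != TERM_GXP:
        random_terms[TERM_GXP] = (
            sub["line"].astype(str) + ":" + sub["condition"].astype(str)
        )
    y = sub["value"].to_numpy(float)
    fit = reml_fit(y, X, random_terms, fixed_names=names)
    grand_mean = fit.fitted_fixed_mean(X)
    gvals = None
    if TERM_LINE in random_terms:
        gvals = pd.Series(
            grand_mean + fit.blups[TERM_LINE], index=fit.levels[TERM_LINE], name=trait
        )
    return ModelFit(
        trait=trait,
        scope=COMBINED,
        var_G=fit.variances.get(TERM_LINE, 0.0),
        var_GxP=fit.variances.get(TERM_GXP, 0.0) if omit != TERM_GXP else None,
        var_error=fit.var_error,
        fixed_effects=pd.Series(fit.beta, index=names),
        loglik_reml=fit.loglik,
        genotypic_values=gvals,
        grand_mean=grand_mean,
        converged=fit.converged,
        boundary=fit.boundary,
        n_obs=fit.n_obs,
        n_blocks=sub.groupby("condition")["block"].nunique().max(),
        n_conditions=len(conditions),
        random_terms=tuple(random_terms),
    )


def lrt_random_effect(full: ModelFit, reduced: ModelFit) -> LrtResult:
    """REML likelihood-ratio test of the random term dropped in ``reduced``.

    Both fits must come from the same data with the same fixed structure;
    the reduced model must nest the full one with exactly one random term
    removed.  The deviance is referred to chi-square with 1 df (the
    convention of the reference analysis); the boundary-corrected 50:50
    mixture p-value is attached as metadata.
    """
    if full.trait != reduced.trait or full.n_obs != reduced.n_obs:
        raise ValueError("fits are not from the same data")
    if list(full.fixed_effects.index) != list(reduced.fixed_effects.index):
        raise ValueError("fixed-effect structures differ; fits are not nested")
    dropped = set(full.random_terms) - set(reduced.random_terms)
    if len(dropped) != 1 or not set(reduced.random_terms) <= set(full.random_terms):
        raise ValueError("reduced model must drop exactly one random term")
    term = dropped.pop()
    deviance = 2.0 * (full.loglik_reml - reduced.loglik_reml)
    if deviance < -1e-4:
        raise ValueError(
            f"negative deviance {deviance:.3g}: full fit did not converge"
        )
    deviance = max(deviance, 0.0)
    if deviance > 0.0:
        p = float(stats.chi2.sf(deviance, df=1))
        p_mix = 0.5 * p
    else:
        p = 1.0
        p_mix = 1.0
    return LrtResult(
        term=term,
        deviance=float(deviance),
        df=1,
        p_value=p,
        p_value_mixture=p_mix,
        significant=p < 0.01,
    )


def genotypic_value_matrix(
    table: pd.DataFrame, traits, condition: str
) -> pd.DataFrame:
    """Line-by-trait matrix of genotypic values (mu + BLUP) for one condition."""
    cols = {}
    for trait in traits:
        fit = fit_condition_model(table, trait, condition)
        cols[trait] = fit.genotypic_values
    return pd.DataFrame(cols)
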