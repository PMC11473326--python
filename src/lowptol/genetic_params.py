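"""Heritability, CV, stress-reduction and genotypic-value summaries.

Broad-sense heritability on an entry-mean basis is

    h2 = var_G / (var_G + var_error / r)                      (one condition)
    h2 = var_G / (var_G + var_GxP / p + var_error / (r p))    (combined)

with ``r`` replications (blocks) and ``p`` phosphorus conditions.  The
coefficient of variation reported per trait and condition is the residual
CV on the genotypic mean, ``100 sqrt(var_error) / mean``, and the stress
response is the signed percentage reduction of the control mean,
``100 (AP - NAP) / AP`` (negative when the trait increases under stress).

Heritabilities are clamped to [0, 1]; estimates from truncated variance
components can otherwise stray outside the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mixed_models import ModelFit

__all__ = [
    "TraitSummary",
    "heritability_entry_mean",
    "heritability_combined",
    "percent_reduction",
    "cv_percent",
    "summarize_genotypic_values",
]


@dataclass
class TraitSummary:
    """Per-trait, per-scope summary of genotypic values."""

    trait: str
    condition: str
    min: float
    mean: float
    max: float
    cv_pct: float | None
    h2: float | None
    reduction_pct: float | None = None  # cross-condition, filled by the pipeline


def _clamp01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def heritability_entry_mean(var_G: float, var_error: float, r: int) -> float:
    """Entry-mean broad-sense heritability within one condition."""
    if r < 1:
        raise ValueError("r must be >= 1")
    if var_G < 0 or var_error < 0:
        raise ValueError("variances must be non-negative")
    denom = var_G + var_error / r
    if denom == 0:
        raise ValueError("both variance components are zero; h2 undefined")
    return _clamp01(var_G / denom)


def heritability_combined(
    var_G: float, var_GxP: float, var_error: float, r: int, p: int
) -> float:
    """Entry-mean broad-sense heritability across conditions."""
    if r < 1:
        raise ValueError("r must be >= 1")
    if p < 1:
        raise ValueError("p must be >= 1")
    if min(var_G, var_GxP, var_error) < 0:
        raise ValueError("variances must be non-negative")
    denom = var_G + var_GxP / p + var_error / (r * p)
    if denom == 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return _clamp01(var_G / denom)


def percent_reduction(mean_AP: float, mean_NAP: float) -> float:
    """Signed percentage reduction of the control mean under stress."""
    if mean_AP == 0:
        raise ValueError("control mean is zero; reduction undefined")
    return 100.0 * (mean_AP - mean_NAP) / mean_AP


def cv_percent(var_error: float, mean: float) -> float:
    """Residual coefficient of variation (%) on the genotypic mean."""
    if var_error < 0:
        raise ValueError("var_error must be non-negative")
    if mean <= 0:
        raise ValueError("mean must be positive for a CV")
    return 100.0 * float(np.sqrt(var_error)) / mean


def summarize_genotypic_values(fit: ModelFit) -> TraitSummary:
    """Min/mean/max of the genotypic values of a fit, with CV and h2.

    The entry-mean heritability uses the fit's own block count; for a
    combined fit the two-condition formula applies.  CV is omitted when the
    genotypic mean is not positive.
    """
    if fit.genotypic_values is None or len(fit.genotypic_values) == 0:
        raise ValueError("fit carries no genotypic values")
    vals = fit.genotypic_values.to_numpy(float)
    mean = float(vals.mean())
    if fit.is_combined:
        h2 = heritability_combined(
            fit.var_G, fit.var_GxP or 0.0, fit.var_error, fit.n_blocks, fit.n_conditions
        )
    else:
        h2 = heritability_entry_mean(fit.var_G, fit.var_error, fit.n_blocks)
    cv = cv_percent(fit.var_error, mean) if mean > 0 else None
    return TraitSummary(
        trait=fit.trait,
        condition=fit.scope,
        min=float(vals.min()),
        mean=mean,
        max=float(vals.max()),
        cv_pct=cv,
        h2=h2,
    )
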