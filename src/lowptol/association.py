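"""Correlation structure among traits and across phosphorus conditions.

Within a condition, Pearson correlations between the line-level genotypic
values (BLUPs) of trait pairs describe how tightly traits co-vary across
the panel; across conditions, the Spearman rank correlation of the same
trait's genotypic values measures how strongly stress reshuffles the line
ranking (low values signal cross-over genotype-by-condition interaction).
Ties receive average ranks.  Significance is flagged at alpha = 0.01 with
no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "pearson_blup_matrix",
    "spearman_cross_condition",
    "correlation_network",
]


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise coefficients with matching p-values."""

    estimates: pd.DataFrame
    p_values: pd.DataFrame
    method: str
    condition: str | None = None
    alpha: float = 0.01
    constant_traits: tuple[str, ...] = ()

    @property
    def labels(self) -> list[str]:
        return list(self.estimates.index)

    def significant(self) -> pd.DataFrame:
        """Boolean mask of off-diagonal coefficients significant at alpha."""
        sig = self.p_values < self.alpha
        np.fill_diagonal(sig.values, False)
        return sig


def pearson_blup_matrix(
    genotypic_values: pd.DataFrame, condition: str | None = None
) -> CorrelationMatrix:
    """Pairwise Pearson correlations of a line-by-trait genotypic matrix.

    Constant traits cannot be correlated; their pairs are reported as NaN
    and the trait is flagged in ``constant_traits``.
    """
    gv = genotypic_values.dropna()
    if gv.shape[0] < 3:
        raise ValueError("at least 3 lines are required")
    traits = list(gv.columns)
    constant = tuple(t for t in traits if np.ptp(gv[t].to_numpy(float)) == 0.0)
    k = len(traits)
    est = np.eye(k)
    pvals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if traits[i] in constant or traits[j] in constant:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(gv[traits[i]], gv[traits[j]])
            est[i, j] = est[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    return CorrelationMatrix(
        estimates=pd.DataFrame(est, index=traits, columns=traits),
        p_values=pd.DataFrame(pvals, index=traits, columns=traits),
        method="pearson",
        condition=condition,
        constant_traits=constant,
    )


def spearman_cross_condition(
    values_NAP: pd.Series, values_AP: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation of one trait's genotypic values across conditions.

    Returns ``(rho, p_value)``.  The two series must cover the same lines.
    """
    if set(values_NAP.index) != set(values_AP.index):
        raise ValueError("line sets differ between conditions")
    if len(values_NAP) < 3:
        raise ValueError("at least 3 lines are required")
    aligned = values_AP.loc[values_NAP.index]
    rho, p = stats.spearmanr(values_NAP.to_numpy(float), aligned.to_numpy(float))
    return float(rho), float(p)


def correlation_network(
    matrix: CorrelationMatrix, min_abs: float = 0.0
) -> pd.DataFrame:
    """Edge list of trait pairs with |r| >= ``min_abs``.

    Columns: ``trait_a, trait_b, r, sign, weight`` with ``weight = |r|``;
    one row per unordered pair, traits in matrix order.
    """
    labels = matrix.labels
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            r = float(matrix.estimates.iloc[i, j])
            if np.isnan(r) or abs(r) < min_abs:
                continue
            rows.append(
                {
                    "trait_a": labels[i],
                    "trait_b": labels[j],
                    "r": r,
                    "sign": "positive" if r >= 0 else "negative",
                    "weight": abs(r),
                }
            )
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "sign", "weight"])
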