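"""Low-P tolerance (LPTI) and performance (LPPI) selection indices.

Both indices are contribution-rate-weighted sums of principal-component
scores:

    index_i = sum_j PC_ij * CR_j   over components with eigenvalue >= 1,

where the PCA is an eigen-decomposition of the correlation matrix of the
standardized inputs and ``CR_j = eigenvalue_j / T`` is the fraction of the
total variance (T = number of traits) carried by component j.  For LPTI
the inputs are the relative trait values, stress BLUP divided by control
BLUP, so the index rewards lines that hold their performance under P
deprivation; for LPPI the inputs are the stress-condition BLUPs
themselves, rewarding absolute performance under stress.

Eigenvector signs are arbitrary; each retained component is oriented so
the sum of its loadings is positive, which makes "larger under stress"
score positively for predominantly positively correlated trait sets.

Lines are classified by the signs of the two indices into tolerant/
sensitive x good/poor quadrants (TG, SG, TP, SP; boundary values fall on
the sensitive/poor side), and top/bottom selections use the rank-sum of
the two index rankings with deterministic alphabetical tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PcaResult",
    "relative_trait_values",
    "standardize",
    "pca_kaiser",
    "compute_lpti",
    "compute_lppi",
    "classify_groups",
    "select_lines",
    "index_table",
]

GROUPS = ("TG", "SG", "TP", "SP")


def relative_trait_values(
    blup_NAP: pd.DataFrame, blup_AP: pd.DataFrame, eps: float = 1e-8
) -> pd.DataFrame:
    """Elementwise stress/control ratio of genotypic values.

    Control values within ``eps`` (relative to the column scale) of zero
    make the ratio meaningless; the offending line/trait is reported.
    """
    if list(blup_NAP.columns) != list(blup_AP.columns):
        raise ValueError("trait sets differ between conditions")
    if set(blup_NAP.index) != set(blup_AP.index):
        raise ValueError("line sets differ between conditions")
    ap = blup_AP.loc[blup_NAP.index]
    scale = ap.abs().max(axis=0).clip(lower=1.0)
    bad = ap.abs() <= eps * scale
    if bad.to_numpy().any():
        loc = [(i, c) for c in bad.columns for i in bad.index[bad[c]]]
        raise ValueError(f"control BLUP too close to zero for: {loc[:5]}")
    return blup_NAP / ap


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization to mean 0, sd 1 (shared with diversity)."""
    from .diversity import normalize_blups

    return normalize_blups(matrix)


@dataclass
class PcaResult:
    """Correlation-matrix PCA with Kaiser retention."""

    eigenvalues: np.ndarray  # all T, descending
    contribution_rates: np.ndarray  # eigenvalue / T, all components
    retained: np.ndarray  # boolean mask, eigenvalue >= 1
    loadings: pd.DataFrame  # trait x component (orientation applied)
    scores: pd.DataFrame  # line x retained component

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [f"PC{j + 1}" for j in range(len(self.eigenvalues))],
                "eigenvalue": self.eigenvalues,
                "contribution_rate": self.contribution_rates,
                "retained": self.retained,
            }
        )


def pca_kaiser(standardized: pd.DataFrame) -> PcaResult:
    """PCA of the correlation matrix, retaining eigenvalues >= 1.

    Input must be a standardized line-by-trait matrix with more lines than
    traits.  Scores are projections of the standardized data on the
    retained eigenvectors, each oriented so its loadings sum positive (the
    largest-magnitude loading decides when the sum is zero).
    """
    Z = standardized.dropna()
    n, T = Z.shape
    if T < 2:
        raise ValueError("at least 2 traits are required")
    if n <= T:
        raise ValueError("need more lines than traits")
    arr = Z.to_numpy(float)
    corr = np.corrcoef(arr, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(T):
        s = evecs[:, j].sum()
        if s < 0 or (s == 0 and evecs[np.argmax(np.abs(evecs[:, j])), j] < 0):
            evecs[:, j] = -evecs[:, j]
    retained = evals >= 1.0 - 1e-12
    if not retained.any():  # pragma: no cover - cannot happen: max eval >= 1
        retained[0] = True
    scores = arr @ evecs[:, retained]
    comp_names = [f"PC{j + 1}" for j in range(T)]
    return PcaResult(
        eigenvalues=evals,
        contribution_rates=evals / T,
        retained=retained,
        loadings=pd.DataFrame(evecs, index=Z.columns, columns=comp_names),
        scores=pd.DataFrame(
            scores, index=Z.index, columns=[c for c, r in zip(comp_names, retained) if r]
        ),
    )


def _cr_weighted_scores(pca: PcaResult) -> pd.Series:
    cr = pca.contribution_rates[pca.retained]
    return pd.Series(pca.scores.to_numpy(float) @ cr, index=pca.scores.index)


def compute_lpti(
    blup_NAP: pd.DataFrame, blup_AP: pd.DataFrame
) -> tuple[pd.Series, PcaResult]:
    """Low-P tolerance index from relative (NAP/AP) trait values."""
    rel = relative_trait_values(blup_NAP, blup_AP)
    pca = pca_kaiser(standardize(rel))
    lpti = _cr_weighted_scores(pca).rename("LPTI")
    return lpti, pca


def compute_lppi(blup_NAP: pd.DataFrame) -> tuple[pd.Series, PcaResult]:
    """Low-P performance index from stress-condition trait values."""
    pca = pca_kaiser(standardize(blup_NAP))
    lppi = _cr_weighted_scores(pca).rename("LPPI")
    return lppi, pca


def classify_groups(lpti: pd.Series, lppi: pd.Series) -> pd.Series:
    """Quadrant classification: tolerant/sensitive x good/poor performance.

    TG: LPTI > 0 and LPPI > 0; TP: LPTI > 0, LPPI <= 0;
    SG: LPTI <= 0, LPPI > 0; SP: both <= 0.
    """
    if set(lpti.index) != set(lppi.index):
        raise ValueError("line sets differ between indices")
    lppi = lppi.loc[lpti.index]
    tol = lpti > 0
    good = lppi > 0
    labels = np.where(tol, np.where(good, "TG", "TP"), np.where(good, "SG", "SP"))
    return pd.Series(labels, index=lpti.index, name="group")


def _dense_rank(values: pd.Series) -> pd.Series:
    """Descending rank (1 = largest), ties broken by line label."""
    order = sorted(values.index, key=lambda i: (-values[i], str(i)))
    return pd.Series({line: r + 1 for r, line in enumerate(order)}, name="rank")


def select_lines(
    lpti: pd.Series, lppi: pd.Series, top_k: int = 20, bottom_k: int = 5
) -> pd.DataFrame:
    """Top/bottom selection by the rank-sum of the two indices.

    Lines are ranked separately on LPTI and LPPI (1 = best); the rank-sum
    orders the combined selection, smaller being better, with alphabetical
    tie-breaks.  Returns a frame indexed by line with both ranks, the
    rank-sum and boolean ``selected_top`` / ``selected_bottom`` flags.
    """
    n = len(lpti)
    if top_k > n or bottom_k > n:
        raise ValueError("k exceeds the number of lines")
    if top_k < 0 or bottom_k < 0:
        raise ValueError("k must be non-negative")
    r_lpti = _dense_rank(lpti)
    r_lppi = _dense_rank(lppi.loc[lpti.index])
    ranksum = (r_lpti + r_lppi).rename("rank_sum")
    asc = sorted(ranksum.index, key=lambda i: (ranksum[i], str(i)))
    top = set(asc[:top_k])
    desc = sorted(ranksum.index, key=lambda i: (-ranksum[i], str(i)))
    bottom = set(desc[:bottom_k])
    out = pd.DataFrame(
        {
            "rank_lpti": r_lpti,
            "rank_lppi": r_lppi,
            "rank_sum": ranksum,
            "selected_top": [i in top for i in ranksum.index],
            "selected_bottom": [i in bottom for i in ranksum.index],
        }
    )
    return out.loc[lpti.index]


def index_table(
    blup_NAP: pd.DataFrame,
    blup_AP: pd.DataFrame,
    top_k: int = 20,
    bottom_k: int = 5,
) -> tuple[pd.DataFrame, PcaResult, PcaResult]:
    """Full per-line index table: LPTI, LPPI, quadrant group, ranks, flags."""
    lpti, pca_t = compute_lpti(blup_NAP, blup_AP)
    lppi, pca_p = compute_lppi(blup_NAP)
    lppi = lppi.loc[lpti.index]
    groups = classify_groups(lpti, lppi)
    sel = select_lines(lpti, lppi, top_k=top_k, bottom_k=bottom_k)
    table = pd.concat([lpti, lppi, groups, sel], axis=1)
    return table, pca_t, pca_p
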