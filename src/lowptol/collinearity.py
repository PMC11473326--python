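"""Variance-inflation-factor diagnosis and joint trait pruning.

Traits measured on the same plants are often near-redundant (total dry
weight is literally the sum of root and shoot dry weight), which distorts
distance-based diversity analysis.  The VIF of trait j,
``1 / (1 - R2_j)`` with ``R2_j`` from regressing trait j on all others,
equals the j-th diagonal element of the inverse correlation matrix; values
above 10 are treated as harmful multicollinearity.

Pruning is greedy and joint across the two phosphorus conditions: at each
step the VIFs are computed under both conditions, each trait is scored by
the larger of the two, and the worst trait is removed (alphabetical
tie-break) until every remaining trait satisfies the threshold under both
conditions.  By construction the same traits are discarded under both
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VifReport", "compute_vif", "prune_traits"]

# relative eigenvalue cutoff marking the correlation matrix as singular
_SINGULAR_TOL = 1e-12


@dataclass
class VifReport:
    """Outcome of joint VIF pruning."""

    kept: tuple[str, ...]
    discarded: tuple[str, ...]
    threshold: float
    steps: pd.DataFrame  # trait, vif per condition and removal step
    final_vif: pd.DataFrame  # kept traits x condition

    def to_frame(self) -> pd.DataFrame:
        """One row per input trait: final/removal VIFs and kept flag."""
        return self.steps


def compute_vif(trait_matrix: pd.DataFrame) -> pd.Series:
    """Per-trait variance inflation factors of a line-by-trait matrix.

    Computed as the diagonal of the inverse correlation matrix.  If the
    correlation matrix is singular, the traits involved in the exact
    dependency (nonzero loading on a null eigenvector) get ``inf``.
    """
    X = trait_matrix.dropna()
    n, k = X.shape
    if n <= k:
        raise ValueError("need more lines than traits")
    arr = X.to_numpy(float)
    if np.any(arr.std(axis=0, ddof=1) == 0.0):
        bad = [c for c in X.columns if np.ptp(X[c].to_numpy(float)) == 0.0]
        raise ValueError(f"constant trait(s): {bad}")
    if k == 1:
        return pd.Series([1.0], index=X.columns)
    corr = np.corrcoef(arr, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    null = evals < _SINGULAR_TOL * evals.max()
    vif = np.empty(k)
    if null.any():
        involved = (np.abs(evecs[:, null]) > 1e-8).any(axis=1)
        vif[involved] = np.inf
        if (~involved).any():
            # remaining traits: VIF from the regular sub-block
            sub = np.linalg.inv(corr[np.ix_(~involved, ~involved)])
            # note: conditioning on the collinear block is ill-defined, so we
            # report the VIF among the non-involved traits only
            vif[~involved] = np.diag(sub)
    else:
        vif[:] = np.diag(np.linalg.inv(corr))
    vif = np.maximum(vif, 1.0)  # guard against round-off below the bound
    return pd.Series(vif, index=X.columns)


def prune_traits(
    matrix_NAP: pd.DataFrame,
    matrix_AP: pd.DataFrame,
    threshold: float = 10.0,
) -> VifReport:
    """Greedy joint pruning of collinear traits under both conditions."""
    if threshold < 1.0:
        raise ValueError("threshold must be >= 1 (VIF lower bound)")
    if list(matrix_NAP.columns) != list(matrix_AP.columns):
        raise ValueError("trait sets differ between conditions")
    traits = list(matrix_NAP.columns)
    kept = list(traits)
    records = {
        t: {"trait": t, "vif_NAP": np.nan, "vif_AP": np.nan,
            "removed_at_step": pd.NA, "kept": True}
        for t in traits
    }
    step = 0
    while len(kept) >= 1:
        if len(kept) == 1:
            vif_n = pd.Series([1.0], index=kept)
            vif_a = pd.Series([1.0], index=kept)
        else:
            vif_n = compute_vif(matrix_NAP[kept])
            vif_a = compute_vif(matrix_AP[kept])
        joint = pd.concat([vif_n, vif_a], axis=1).max(axis=1)
        for t in kept:
            records[t]["vif_NAP"] = float(vif_n[t])
            records[t]["vif_AP"] = float(vif_a[t])
        if joint.max() <= threshold or len(kept) == 1:
            break
        step += 1
        worst_val = joint.max()
        worst = sorted(t for t in kept if joint[t] == worst_val)[0]
        records[worst]["removed_at_step"] = step
        records[worst]["kept"] = False
        kept.remove(worst)
    steps = pd.DataFrame([records[t] for t in traits])
    final = pd.DataFrame(
        {"vif_NAP": [records[t]["vif_NAP"] for t in kept],
         "vif_AP": [records[t]["vif_AP"] for t in kept]},
        index=kept,
    )
    return VifReport(
        kept=tuple(kept),
        discarded=tuple(t for t in traits if not records[t]["kept"]),
        threshold=float(threshold),
        steps=steps,
        final_vif=final,
    )
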