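"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lowptol as lp


def anova_components(table: pd.DataFrame, trait: str, condition: str):
    """Balanced randomized-block ANOVA method-of-moments estimators.

    Independent of the REML path: expected mean squares give
    sigma_G^2 = (MS_line - MS_error) / r for a balanced design.
    Returns (sigma_G^2 untruncated, MS_line, MS_error).
    """
    sub = table[(table["trait"] == trait) & (table["condition"] == condition)]
    wide = sub.pivot_table(index="line", columns="block", values="value")
    arr = wide.to_numpy(float)
    I, J = arr.shape
    gm = arr.mean()
    ms_line = J * ((arr.mean(axis=1) - gm) ** 2).sum() / (I - 1)
    resid = arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0, keepdims=True) + gm
    ms_error = (resid**2).sum() / ((I - 1) * (J - 1))
    return (ms_line - ms_error) / J, ms_line, ms_error


def long_table(values: np.ndarray, trait: str = "X", condition: str = "NAP"):
    """Long-format table from a lines x blocks array of one trait/condition."""
    I, J = values.shape
    rows = [
        dict(line=f"L{i + 1:03d}", condition=condition, block=f"B{j + 1}",
             trait=trait, value=values[i, j])
        for i in range(I)
        for j in range(J)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_table() -> pd.DataFrame:
    """20-line, 2-trait reference-structure simulation used across tests."""
    cfg = lp.default_config(seed=20240, traits=("SD", "RDW"), n_lines=20)
    return lp.generate_phenotypes(cfg)


@pytest.fixture(scope="session")
def panel_blups(small_table):
    """Per-condition genotypic-value matrices for the small panel."""
    traits = ("SD", "RDW")
    return (
        lp.genotypic_value_matrix(small_table, traits, "NAP"),
        lp.genotypic_value_matrix(small_table, traits, "AP"),
    )
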