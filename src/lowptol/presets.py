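"""Reference values from a 151-line tropical maize low-P seedling trial.

The pipeline was designed around a greenhouse screening of 151 tropical maize
inbred lines grown under applied (AP) and non-applied (NAP) phosphorus in a
randomized complete block design with three blocks.  Thirteen shoot and root
traits were scored per plant.  The tables below hold the published panel-level
estimates -- per-condition trait means, residual CVs, stress reductions and
REML variance components -- and serve three purposes:

* defaults for the synthetic-data generator (:mod:`lowptol.simulate`),
* inputs for desk-scale arithmetic (heritability, reduction, CV identities),
* fixtures for regression tests of the summary statistics.

Traits (units): SD stalk diameter (mm); PH plant height (cm); SDW shoot dry
weight (mg); RDW root dry weight (mg); RSR root:shoot dry-weight ratio
(mg/mg); TDW total dry weight (mg); DG daily growth (cm/day); LRL lateral
root length (cm); TRL total root length (cm); RSA root surface area (cm^2);
RV root volume (cm^3); RAD root average diameter (mm); RTD root tissue
density (mg/cm^3).
"""

from __future__ import annotations

import pandas as pd

#: Number of inbred lines, blocks (replications) and P conditions in the
#: reference trial.
N_LINES = 151
N_BLOCKS = 3
N_CONDITIONS = 2

#: Condition labels: NAP = non-applied P (stress), AP = applied P (control).
CONDITION_STRESS = "NAP"
CONDITION_CONTROL = "AP"

_COLUMNS = [
    "trait", "unit",
    "mean_NAP", "mean_AP", "cv_NAP", "cv_AP", "reduction_pct",
    "var_G_NAP", "var_error_NAP", "h2_NAP",
    "var_G_AP", "var_error_AP", "h2_AP",
    "var_G", "var_GxP", "var_error", "h2_combined",
]

# Three residual/interaction entries (LRL AP var_error, TRL AP var_error,
# RSA var_GxP) are reconstructed to full precision from the printed
# heritabilities; the trailing digits were lost in the source table.
_ROWS = [
    ("SD",  "mm",       4.49,    8.70,    12.81,  8.23, 48.32,
     0.31, 0.33, 0.74,      1.35, 0.51, 0.89,
     0.16, 0.67, 0.42, 0.29),
    ("PH",  "cm",       10.99,   18.09,   13.20,  8.49, 39.22,
     2.78, 2.11, 0.80,      8.26, 2.36, 0.91,
     2.76, 2.76, 2.23, 0.61),
    ("SDW", "mg",       665.49,  1701.13, 17.79, 17.96, 60.88,
     19301.0, 14023.0, 0.81,  283212.0, 93362.0, 0.90,
     31094.0, 120162.0, 53692.0, 0.31),
    ("RDW", "mg",       359.00,  525.17,  16.67, 18.65, 31.64,
     6216.0, 3582.0, 0.84,    20261.0, 9588.0, 0.86,
     4208.0, 9031.0, 6585.0, 0.43),
    ("RSR", "mg/mg",    0.55,    0.32,    12.29, 15.96, -73.91,
     1.10e-2, 4.66e-3, 0.88,  2.32e-3, 2.59e-3, 0.73,
     3.46e-3, 3.19e-3, 3.62e-3, 0.61),
    ("TDW", "mg",       1024.48, 2226.29, 16.52, 16.53, 53.98,
     38787.0, 28632.0, 0.80,  438747.0, 135469.0, 0.91,
     48953.0, 189815.0, 82051.0, 0.31),
    ("DG",  "cm/day",   0.31,    0.70,    14.97,  8.22, 56.34,
     2.77e-3, 2.10e-3, 0.80,  8.16e-3, 3.31e-3, 0.88,
     2.30e-3, 3.16e-3, 2.70e-3, 0.53),
    ("LRL", "cm",       1048.99, 1533.24, 21.79, 21.04, 31.58,
     60534.0, 52250.0, 0.78,  70003.0, 104060.0, 0.67,
     38754.0, 26515.0, 78154.0, 0.60),
    ("TRL", "cm",       1569.73, 2297.37, 18.17, 17.55, 31.67,
     92465.0, 81310.0, 0.77,  165270.0, 162570.0, 0.75,
     64782.0, 64086.0, 121939.0, 0.55),
    ("RSA", "cm^2",     266.30,  426.40,  16.03, 14.14, 37.55,
     2387.0, 1822.0, 0.80,    8260.0, 3637.0, 0.87,
     2186.0, 3140.0, 2730.0, 0.52),
    ("RV",  "cm^3",     3.65,    6.38,    17.29, 16.01, 42.81,
     0.60, 0.40, 0.82,        2.79, 1.04, 0.89,
     0.67, 1.02, 0.72, 0.51),
    ("RAD", "mm",       0.55,    0.59,     7.72,  8.79, 7.61,
     2.50e-3, 1.79e-3, 0.81,  1.83e-3, 2.72e-3, 0.67,
     1.47e-3, 6.95e-4, 2.25e-3, 0.67),
    ("RTD", "mg/cm^3",  99.15,   82.83,    8.26, 12.18, -19.70,
     98.63, 67.04, 0.82,      40.90, 101.80, 0.55,
     46.56, 23.21, 84.41, 0.64),
]

#: Panel-level reference estimates, one row per trait.  ``var_G``,
#: ``var_GxP`` and ``var_error`` without a condition suffix are the
#: combined-analysis components; the suffixed columns are the per-condition
#: fits.
REFERENCE_PANEL: pd.DataFrame = pd.DataFrame(_ROWS, columns=_COLUMNS).set_index(
    "trait", drop=False
)

#: All thirteen scored traits, in reference order.
ALL_TRAITS: tuple[str, ...] = tuple(REFERENCE_PANEL["trait"])

#: Trait subsets usable by the diversity/index stages.  ``reference8`` is the
#: eight-trait set retained after VIF pruning in the reference trial.
TRAIT_PRESETS: dict[str, tuple[str, ...]] = {
    "all13": ALL_TRAITS,
    "reference8": ("SD", "PH", "RSR", "DG", "LRL", "RV", "RAD", "RTD"),
}

#: Stalk-diameter genotypic values (mm, NAP) of the 20 lines selected for
#: combined low-P tolerance and performance in the reference trial, and of
#: the bottom five, as printed in the panel report.  Used for summary-
#: statistic regression checks.
SELECTED_SD_NAP_TOP20: dict[str, float] = {
    "VML002": 4.56, "VML153": 4.99, "VML137": 5.51, "VML036": 4.77,
    "VML121": 5.61, "VML119": 4.62, "VML030": 5.45, "VML133": 4.72,
    "VML130": 4.35, "VML174": 5.24, "VML001": 4.47, "VML165": 5.56,
    "VML041": 5.55, "VML179": 5.10, "VML009": 5.15, "VML087": 4.78,
    "VML004": 5.18, "VML042": 5.15, "VML113": 5.03, "VML046": 5.12,
}

SELECTED_SD_NAP_BOTTOM5: dict[str, float] = {
    "VML125": 4.25, "VML129": 3.57, "VML067": 4.10,
    "VML086": 3.46, "VML051": 3.60,
}
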