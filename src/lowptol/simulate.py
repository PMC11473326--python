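"""Synthetic phenotype tables with the trial's variance structure.

Generates long-format phenotype records for a two-condition (stress /
control phosphorus) randomized complete block trial of inbred lines.  Each
trait follows the combined-analysis decomposition the downstream mixed
models assume:

    y_icj = mu_c + b_cj + g_i + (gP)_ic + e_icj

with a shared line effect ``g_i ~ N(0, var_G)``, independent
condition-specific deviations ``(gP)_ic ~ N(0, var_GxP)``, fixed-size block
effects drawn once per condition x block, and i.i.d. Gaussian residuals.
This construction makes the combined model identifiable and induces
cross-over interaction: the correlation of a line's true effects across
conditions is ``var_G / (var_G + var_GxP)``.

Defaults reproduce the reference maize panel (151 lines, 3 blocks, 13
traits with the published combined-analysis components and condition
means); block variance is unreported there and defaults to a quarter of
the residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presets

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "default_config",
    "generate_phenotypes",
    "compute_derived_traits",
]

#: base traits a table must contain before derived traits can be appended
_DERIVED_SOURCES = {"RSR": ("RDW", "SDW"), "TDW": ("RDW", "SDW"),
                    "RTD": ("RDW", "RV"), "DG": ("PH",)}


@dataclass(frozen=True)
class TraitSpec:
    """Simulation parameters for one trait.

    ``mean_AP`` is the control-condition mean on the trait scale;
    the stress mean is derived as ``mean_AP * (1 - reduction_pct/100)``
    and is deliberately not stored.  Variances are on the squared trait
    scale; ``var_block`` defaults to ``0.25 * var_error``.
    """

    name: str
    mean_AP: float
    reduction_pct: float
    var_G: float
    var_GxP: float
    var_error: float
    var_block: float | None = None

    @property
    def mean_NAP(self) -> float:
        return self.mean_AP * (1.0 - self.reduction_pct / 100.0)

    @property
    def block_variance(self) -> float:
        return 0.25 * self.var_error if self.var_block is None else self.var_block

    def validate(self) -> None:
        for attr in ("var_G", "var_GxP", "var_error"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be non-negative")
        if self.var_block is not None and self.var_block < 0:
            raise ValueError(f"{self.name}: var_block must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Design and trait parameters for one simulated trial.

    ``conditions`` holds exactly two labels, stress first (its mean is the
    reduced one), control second.
    """

    n_lines: int = presets.N_LINES
    n_blocks: int = presets.N_BLOCKS
    conditions: tuple[str, str] = (
        presets.CONDITION_STRESS,
        presets.CONDITION_CONTROL,
    )
    traits: tuple[TraitSpec, ...] = ()
    seed: int = 0
    missing_rate: float = 0.0  # uniform missing-data injection, off by default

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ValueError("exactly two distinct conditions are required")
        if not self.traits:
            raise ValueError("at least one trait is required")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for t in self.traits:
            t.validate()


def default_config(seed: int = 0, traits=None, **overrides) -> SimulationConfig:
    """Reference-panel configuration: 151 lines x 2 conditions x 3 blocks.

    ``traits`` may restrict the simulated trait set (names); other design
    fields can be overridden by keyword.
    """
    panel = presets.REFERENCE_PANEL
    wanted = presets.ALL_TRAITS if traits is None else tuple(traits)
    specs = tuple(
        TraitSpec(
            name=row["trait"],
            mean_AP=row["mean_AP"],
            reduction_pct=row["reduction_pct"],
            var_G=row["var_G"],
            var_GxP=row["var_GxP"],
            var_error=row["var_error"],
        )
        for _, row in panel.loc[list(wanted)].iterrows()
    )
    return SimulationConfig(traits=specs, seed=seed, **overrides)


def _line_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"L{i + 1:0{width}d}" for i in range(n)]


def generate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Draw one long-format phenotype table.

    Returns one record per line x condition x block x trait with columns
    ``line, condition, block, trait, value``.  Fully reproducible: a single
    root seed spawns one independent stream per trait (plus one for the
    optional missing-data mask), so adding or removing traits does not
    perturb the draws of the others.
    """
    config.validate()
    n_l, n_b = config.n_lines, config.n_blocks
    lines = _line_labels(n_l)
    blocks = [f"B{j + 1}" for j in range(n_b)]
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.traits) + 1)
    frames = []
    for spec, ss in zip(config.traits, streams):
        rng = np.random.default_rng(ss)
        g = rng.normal(0.0, np.sqrt(spec.var_G), size=n_l)
        gp = rng.normal(0.0, np.sqrt(spec.var_GxP), size=(n_l, 2))
        blk = rng.normal(0.0, np.sqrt(spec.block_variance), size=(2, n_b))
        err = rng.normal(0.0, np.sqrt(spec.var_error), size=(n_l, 2, n_b))
        mu = np.array([spec.mean_NAP, spec.mean_AP])
        vals = (
            mu[None, :, None]
            + blk[None, :, :]
            + g[:, None, None]
            + gp[:, :, None]
            + err
        )
        frames.append(
            pd.DataFrame(
                {
                    "line": np.repeat(lines, 2 * n_b),
                    "condition": np.tile(np.repeat(list(config.conditions), n_b), n_l),
                    "block": np.tile(blocks, 2 * n_l),
                    "trait": spec.name,
                    "value": vals.ravel(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0.0:
        rng = np.random.default_rng(streams[-1])
        mask = rng.random(len(table)) < config.missing_rate
        table.loc[mask, "value"] = np.nan
    return table


def compute_derived_traits(
    table: pd.DataFrame, days: float = 35.0
) -> pd.DataFrame:
    """Append observation-level derived traits to a phenotype table.

    Adds RSR = RDW/SDW, TDW = RDW + SDW, RTD = RDW/RV and DG = PH/days as
    new trait records computed per (line, condition, block).  Ratios with a
    zero denominator are recorded as missing rather than infinite.  The
    table must not already contain the derived trait names.
    """
    present = set(table["trait"])
    clash = present & set(_DERIVED_SOURCES)
    if clash:
        raise ValueError(f"derived traits already present: {sorted(clash)}")
    missing = {"RDW", "SDW", "RV", "PH"} - present
    if missing:
        raise ValueError(f"base traits missing: {sorted(missing)}")
    if days <= 0:
        raise ValueError("days must be positive")
    wide = table.pivot_table(
        index=["line", "condition", "block"],
        columns="trait",
        values="value",
        aggfunc="first",
    )

    def safe_ratio(num, den):
        den = den.where(den != 0)
        return num / den

    derived = pd.DataFrame(
        {
            "RSR": safe_ratio(wide["RDW"], wide["SDW"]),
            "TDW": wide["RDW"] + wide["SDW"],
            "RTD": safe_ratio(wide["RDW"], wide["RV"]),
            "DG": wide["PH"] / days,
        }
    )
    long = (
        derived.reset_index()
        .melt(id_vars=["line", "condition", "block"], var_name="trait", value_name="value")
    )
    return pd.concat([table, long], ignore_index=True)
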