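"""End-to-end orchestration of the low-P phenotyping analysis.

Stages, in order: simulate or ingest phenotypes; per-condition and combined
REML fits per trait with likelihood-ratio tests of the random terms;
genotypic-value summaries (means, ranges, CVs, heritabilities, stress
reductions); Pearson/Spearman correlation structure; joint VIF pruning;
UPGMA diversity clustering with a Mojena cut per condition; and the
LPTI/LPPI selection indices with quadrant classification and top/bottom
selection.  Every artifact is written as CSV (trees as Newick, run
metadata as JSON) into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, presets
from .association import (
    correlation_network,
    pearson_blup_matrix,
    spearman_cross_condition,
)
from .collinearity import prune_traits
from .diversity import mean_euclidean, mojena_cut, normalize_blups, upgma
from .genetic_params import percent_reduction, summarize_genotypic_values
from .indices import index_table
from .io import combined_correlation_table, ingest_phenotypes, write_phenotypes
from .mixed_models import (
    TERM_GXP,
    TERM_LINE,
    fit_combined_model,
    fit_condition_model,
    lrt_random_effect,
)
from .simulate import SimulationConfig, default_config, generate_phenotypes

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("lowptol")


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; defaults mirror the reference trial."""

    input_path: str | None = None  # phenotype CSV; None -> simulate
    simulation: SimulationConfig | None = None  # None -> reference defaults
    traits: tuple[str, ...] | None = None  # None -> all traits in the table
    trait_preset: str | None = None  # e.g. "reference8", applied after pruning
    vif_threshold: float = 10.0
    mojena_k: float = 1.25
    alpha: float = 0.01
    top_k: int = 20
    bottom_k: int = 5
    seed: int = 0
    outdir: str = "lowptol_out"


@dataclass
class PipelineResult:
    """In-memory handles to everything the run produced."""

    phenotypes: pd.DataFrame
    condition_fits: dict  # (trait, condition) -> ModelFit
    combined_fits: dict  # trait -> ModelFit
    summary: pd.DataFrame
    components: pd.DataFrame
    lrt: pd.DataFrame
    correlations: dict  # condition -> CorrelationMatrix
    spearman: pd.Series
    vif_report: object
    clusters: dict  # condition -> ClusterAssignment
    trees: dict  # condition -> Dendrogram
    indices: pd.DataFrame
    pca_reports: dict
    outdir: Path


def _blup_matrix(fits: dict, traits, condition) -> pd.DataFrame:
    return pd.DataFrame(
        {t: fits[(t, condition)].genotypic_values for t in traits}
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- input ------------------------------------------------------------
    if config.input_path is not None:
        log.info("ingesting phenotypes from %s", config.input_path)
        table = ingest_phenotypes(config.input_path)
    else:
        sim = config.simulation or default_config(seed=config.seed)
        log.info("simulating phenotypes (seed=%d)", sim.seed)
        table = generate_phenotypes(sim)
        write_phenotypes(table, outdir / "phenotypes.csv")
    traits = list(config.traits or pd.unique(table["trait"]))
    conditions = sorted(map(str, pd.unique(table["condition"])))
    if len(conditions) != 2:
        raise ValueError("pipeline requires exactly two conditions")
    # stress condition = smaller grand mean across most traits is fragile;
    # use the reference labels when present, else the first sorted label
    if presets.CONDITION_STRESS in conditions:
        stress, control = presets.CONDITION_STRESS, presets.CONDITION_CONTROL
    else:
        stress, control = conditions[0], conditions[1]

    # --- mixed models -----------------------------------------------------
    condition_fits, combined_fits, lrt_rows, convergence = {}, {}, [], []
    for trait in traits:
        for cond in conditions:
            fit = fit_condition_model(table, trait, cond)
            condition_fits[(trait, cond)] = fit
            reduced = fit_condition_model(table, trait, cond, omit=TERM_LINE)
            res = lrt_random_effect(fit, reduced)
            lrt_rows.append(
                dict(trait=trait, scope=cond, term=res.term, deviance=res.deviance,
                     p_value=res.p_value, p_value_mixture=res.p_value_mixture,
                     significant=res.significant)
            )
            convergence.append(
                dict(trait=trait, scope=cond, converged=fit.converged,
                     boundary=sorted(fit.boundary))
            )
        full = fit_combined_model(table, trait)
        combined_fits[trait] = full
        for term in (TERM_LINE, TERM_GXP):
            reduced = fit_combined_model(table, trait, omit=term)
            res = lrt_random_effect(full, reduced)
            lrt_rows.append(
                dict(trait=trait, scope="combined", term=res.term,
                     deviance=res.deviance, p_value=res.p_value,
                     p_value_mixture=res.p_value_mixture,
                     significant=res.significant)
            )
        convergence.append(
            dict(trait=trait, scope="combined", converged=full.converged,
                 boundary=sorted(full.boundary))
        )
        log.info("fitted %s (combined loglik %.3f)", trait, full.loglik_reml)
    lrt = pd.DataFrame(lrt_rows)

    # --- summaries --------------------------------------------------------
    summary_rows, component_rows = [], []
    for trait in traits:
        s = {c: summarize_genotypic_values(condition_fits[(trait, c)]) for c in conditions}
        red = percent_reduction(s[control].mean, s[stress].mean)
        for cond in (stress, control):
            summary_rows.append(
                dict(trait=trait, condition=cond, min=s[cond].min,
                     mean=s[cond].mean, max=s[cond].max, cv_pct=s[cond].cv_pct,
                     h2=s[cond].h2,
                     reduction_pct=red if cond == stress else np.nan)
            )
        comb = combined_fits[trait]
        component_rows.append(
            dict(trait=trait,
                 var_G_stress=condition_fits[(trait, stress)].var_G,
                 var_error_stress=condition_fits[(trait, stress)].var_error,
                 h2_stress=s[stress].h2,
                 var_G_control=condition_fits[(trait, control)].var_G,
                 var_error_control=condition_fits[(trait, control)].var_error,
                 h2_control=s[control].h2,
                 var_G=comb.var_G, var_GxP=comb.var_GxP,
                 var_error=comb.var_error,
                 h2_combined=summarize_genotypic_values(comb).h2)
        )
    summary = pd.DataFrame(summary_rows)
    components = pd.DataFrame(component_rows)

    # --- correlations -----------------------------------------------------
    blups = {c: _blup_matrix(condition_fits, traits, c) for c in conditions}
    correlations = {c: pearson_blup_matrix(blups[c], condition=c) for c in conditions}
    spearman = pd.Series(
        {
            t: spearman_cross_condition(blups[stress][t], blups[control][t])[0]
            for t in traits
        },
        name="spearman",
    )
    corr_table = combined_correlation_table(
        correlations[stress], correlations[control], spearman
    )

    # --- multicollinearity ------------------------------------------------
    vif_report = prune_traits(
        blups[stress], blups[control], threshold=config.vif_threshold
    )
    if config.trait_preset is not None:
        kept = list(presets.TRAIT_PRESETS[config.trait_preset])
        missing = [t for t in kept if t not in traits]
        if missing:
            raise ValueError(f"preset traits absent from data: {missing}")
    else:
        kept = list(vif_report.kept)
    log.info("diversity/index trait set: %s", kept)

    # --- diversity --------------------------------------------------------
    trees, clusters, cluster_rows = {}, {}, []
    for cond in conditions:
        z = normalize_blups(blups[cond][kept])
        dist = mean_euclidean(z)
        dist.to_csv(outdir / f"distances_{cond}.csv")
        tree = upgma(dist)
        trees[cond] = tree
        assignment = mojena_cut(tree, k_const=config.mojena_k)
        clusters[cond] = assignment
        (outdir / f"diversity_{cond}.nwk").write_text(tree.to_newick() + "\n")
        for line, cl in assignment.assignments.items():
            cluster_rows.append(
                dict(line=line, condition=cond, cluster=cl,
                     cutoff=assignment.cutoff, k=assignment.k)
            )
    cluster_frame = pd.DataFrame(cluster_rows)

    # --- indices ----------------------------------------------------------
    idx, pca_t, pca_p = index_table(
        blups[stress][kept], blups[control][kept],
        top_k=config.top_k, bottom_k=config.bottom_k,
    )
    pca_reports = {"LPTI": pca_t.report(), "LPPI": pca_p.report()}

    # --- outputs ----------------------------------------------------------
    gv_rows = [
        dict(trait=t, scope=c, line=line, genotypic_value=v)
        for (t, c), fit in condition_fits.items()
        for line, v in fit.genotypic_values.items()
    ] + [
        dict(trait=t, scope="combined", line=line, genotypic_value=v)
        for t, fit in combined_fits.items()
        for line, v in fit.genotypic_values.items()
    ]
    pd.DataFrame(gv_rows).to_csv(outdir / "genotypic_values.csv", index=False)
    summary.to_csv(outdir / "table1_summary.csv", index=False)
    components.to_csv(outdir / "table2_components.csv", index=False)
    lrt.to_csv(outdir / "lrt.csv", index=False)
    corr_table.to_csv(outdir / "table3_correlations.csv")
    for cond in conditions:
        correlation_network(correlations[cond], min_abs=0.0).to_csv(
            outdir / f"correlation_edges_{cond}.csv", index=False
        )
    vif_report.steps.to_csv(outdir / "vif_report.csv", index=False)
    cluster_frame.to_csv(outdir / "clusters.csv", index=False)
    idx.rename_axis("line").to_csv(outdir / "indices.csv")
    idx.loc[idx["selected_top"] | idx["selected_bottom"]].rename_axis("line").to_csv(
        outdir / "selection.csv"
    )
    pd.concat(
        [rep.assign(index=name) for name, rep in pca_reports.items()],
        ignore_index=True,
    ).to_csv(outdir / "pca_report.csv", index=False)
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if k != "simulation"
        },
        "traits": traits,
        "kept_traits": kept,
        "convergence": convergence,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")

    return PipelineResult(
        phenotypes=table,
        condition_fits=condition_fits,
        combined_fits=combined_fits,
        summary=summary,
        components=components,
        lrt=lrt,
        correlations=correlations,
        spearman=spearman,
        vif_report=vif_report,
        clusters=clusters,
        trees=trees,
        indices=idx,
        pca_reports=pca_reports,
        outdir=outdir,
    )
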