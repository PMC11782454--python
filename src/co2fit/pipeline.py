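"""Orchestration: counts to comparison tables, tracks and chemistry reports.

``analyze_screen`` runs the whole statistical chain on in-memory tables;
``run_screen_analysis`` is the file-based wrapper driven by a
:class:`RunConfig` (YAML-friendly), writing per-condition gene fitness
tables, the between-condition comparison table, optional bedGraph
coverage tracks, and a run manifest. ``run_carbonate_report`` produces
the medium-chemistry design table (NaHCO3 dose and predicted speciation
per CO2 fraction at a target pH).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .carbonate import CarbonateParams, DEFAULT_PARAMS, nahco3_dose, speciate_at_ph
from .fitness import (
    gene_fitness_table,
    guide_fitness_table,
    log2fc_profiles,
    size_factors,
)
from .screen_io import (
    CONTROL_LABEL,
    export_coverage_track,
    read_count_table,
    read_library,
    read_sample_sheet,
)
from .stats import between_condition_test, compare_conditions, condition_gene_test

__all__ = [
    "RunConfig",
    "analyze_screen",
    "run_screen_analysis",
    "run_carbonate_report",
    "plot_fitness_scatter",
]

log = logging.getLogger("co2fit")


@dataclass
class RunConfig:
    """File-level configuration of a screen analysis run."""

    counts: str
    samples: str
    library: str
    condition_a: str
    condition_b: str
    outdir: str = "co2fit_out"
    pseudocount: float = 0.5
    normalize_auc: bool = True
    bootstrap_reps: int = 1000
    bh_alpha: float = 0.05
    seed: int = 0
    min_guides: int = 2
    replicate_scores: bool = True
    control_label: str = CONTROL_LABEL
    export_tracks: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def analyze_screen(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    library: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 0.5,
    normalize_auc: bool = True,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    min_guides: int = 2,
    replicate_scores: bool = True,
    control_label: str = CONTROL_LABEL,
) -> dict:
    """Run normalization -> log2FC -> AUC -> gene fitness -> tests -> comparison.

    ``condition_a`` is the reference (x0) and ``condition_b`` the stress
    condition (y0), fixing the impact-score sign so positive impact means
    "relatively better under the stress condition".
    ``replicate_scores=True`` pools per-replicate guide fitness scores in
    the between-condition test; False uses one replicate-averaged score
    per guide.

    Returns a dict of DataFrames: ``size_factors, profiles,
    guide_fitness, gene_fitness, control_tests, between_test, compare``.
    """
    for cond in (condition_a, condition_b):
        if cond not in set(sheet["condition"]):
            raise ValueError(f"condition '{cond}' not present in sample sheet")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    factors = size_factors(counts)
    log.info("size factors: %d samples, range %.3f-%.3f",
             len(factors), factors.min(), factors.max())
    profiles = log2fc_profiles(counts, factors, sheet, pseudocount=pseudocount)
    guide_fit = guide_fitness_table(profiles, normalize=normalize_auc)
    guide_fit_rep = guide_fitness_table(
        profiles, normalize=normalize_auc, per_replicate=True
    )
    gene_fit = gene_fitness_table(
        guide_fit, profiles, library, bootstrap_reps=bootstrap_reps, rng=rng
    )
    log.info("fitness: %d guides, %d gene/condition rows", len(guide_fit), len(gene_fit))

    target_of = library.set_index("guide_id")["target_id"]
    with_targets = guide_fit.assign(
        target_id=guide_fit["guide_id"].map(target_of)
    )
    control_tests = {}
    for cond in (condition_a, condition_b):
        sub = with_targets[with_targets["condition"] == cond]
        control_tests[cond] = condition_gene_test(
            sub[["target_id", "fitness"]], control_label=control_label,
            min_guides=min_guides,
        )

    source = guide_fit_rep if replicate_scores else guide_fit
    source = source.assign(target_id=source["guide_id"].map(target_of))
    source = source[source["target_id"] != control_label]
    between = between_condition_test(
        source.loc[source["condition"] == condition_a, ["target_id", "fitness"]],
        source.loc[source["condition"] == condition_b, ["target_id", "fitness"]],
        min_guides=min_guides,
    )
    compare = compare_conditions(
        gene_fit[gene_fit["condition"] == condition_a],
        gene_fit[gene_fit["condition"] == condition_b],
        between,
    )
    return {
        "size_factors": factors,
        "profiles": profiles,
        "guide_fitness": guide_fit,
        "guide_fitness_replicate": guide_fit_rep,
        "gene_fitness": gene_fit,
        "control_tests": control_tests,
        "between_test": between,
        "compare": compare,
    }


def run_screen_analysis(config: RunConfig) -> dict:
    """File-based end-to-end run; writes result tables and a manifest."""
    counts = read_count_table(config.counts)
    sheet = read_sample_sheet(config.samples)
    library = read_library(config.library)
    results = analyze_screen(
        counts, sheet, library,
        condition_a=config.condition_a, condition_b=config.condition_b,
        pseudocount=config.pseudocount, normalize_auc=config.normalize_auc,
        bootstrap_reps=config.bootstrap_reps, seed=config.seed,
        min_guides=config.min_guides, replicate_scores=config.replicate_scores,
        control_label=config.control_label,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_fit = results["gene_fitness"]
    written = {}
    for cond, tag in ((config.condition_a, "A"), (config.condition_b, "B")):
        path = outdir / f"fitness_{tag}.tsv"
        gene_fit[gene_fit["condition"] == cond].to_csv(path, sep="\t", index=False)
        written[f"fitness_{tag}"] = str(path)
    compare_path = outdir / "compare.tsv"
    results["compare"].to_csv(compare_path, sep="\t", index=False)
    written["compare"] = str(compare_path)
    if config.export_tracks and {"chrom", "start", "end"} <= set(library.columns):
        guide_fit = results["guide_fitness"]
        coords = library.dropna(subset=["start"])
        for cond, tag in ((config.condition_a, "A"), (config.condition_b, "B")):
            fit = (
                guide_fit[guide_fit["condition"] == cond]
                .set_index("guide_id")["fitness"]
                .reindex(coords["guide_id"])
                .dropna()
            )
            path = outdir / f"fitness_{tag}.bedgraph"
            export_coverage_track(fit, coords, path, track_name=f"fitness_{cond}")
            written[f"track_{tag}"] = str(path)
    manifest = {
        "co2fit_version": __version__,
        "config": asdict(config),
        "rows": {
            "guides": int(counts.shape[0]),
            "samples": int(counts.shape[1]),
            "gene_fitness": int(len(gene_fit)),
            "compare": int(len(results["compare"])),
        },
        "outputs": written,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


def _round_dose(x: float) -> float:
    # design-table convention: 1 decimal for doses >= 1 mM, 3 below
    return round(x, 1) if x >= 1.0 else round(x, 3)


def run_carbonate_report(
    co2_fractions,
    target_ph: float = 7.5,
    params: CarbonateParams = DEFAULT_PARAMS,
    rounded: bool = True,
) -> pd.DataFrame:
    """Medium design table: NaHCO3 dose and predicted speciation per CO2 level.

    One row per gas-phase CO2 fraction with columns co2_pct, nahco3_mM,
    co2_mM, hco3_mM, co3_mM, ca_mM, tic_mM. With ``rounded=True`` species
    are given to 3 decimals and the dose to the design-table convention.
    """
    rows = []
    for frac in co2_fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"CO2 fraction must be in [0, 1], got {frac}")
        sp = speciate_at_ph(frac, target_ph, params)
        dose = nahco3_dose(frac, target_ph, params)
        if rounded:
            rows.append(
                (100 * frac, _round_dose(dose), round(sp.co2, 3), round(sp.hco3, 3),
                 round(sp.co3, 3), round(sp.ca, 3), round(sp.tic, 3))
            )
        else:
            rows.append((100 * frac, dose, sp.co2, sp.hco3, sp.co3, sp.ca, sp.tic))
    return pd.DataFrame(
        rows,
        columns=["co2_pct", "nahco3_mM", "co2_mM", "hco3_mM", "co3_mM", "ca_mM", "tic_mM"],
    )


def plot_fitness_scatter(compare: pd.DataFrame, path, offset: float = 2.5) -> None:
    """Scatter of fitness_b vs fitness_a with identity and offset lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(compare["fitness_a"], compare["fitness_b"], s=6, alpha=0.4,
               color="#32506e", linewidths=0)
    lo = min(compare["fitness_a"].min(), compare["fitness_b"].min()) - 0.5
    hi = max(compare["fitness_a"].max(), compare["fitness_b"].max()) + 0.5
    xs = np.array([lo, hi])
    for b, style in ((0.0, "--"), (offset, ":"), (-offset, ":")):
        ax.plot(xs, xs + b, style, color="grey", lw=0.8)
    ax.set_xlabel("fitness, condition A")
    ax.set_ylabel("fitness, condition B")
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
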