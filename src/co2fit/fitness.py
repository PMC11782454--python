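"""Count normalization, log2 fold-change profiles and AUC fitness scores.

The quantitative chain from raw sgRNA counts to gene-level fitness:

1. median-of-ratios size factors (each sample's median ratio to the
   per-guide geometric mean across samples);
2. per-replicate log2 fold changes of each guide versus that replicate's
   generation-0 sample (with a pseudocount), plus replicate means;
3. per-guide fitness = area under the log2FC-versus-generation curve
   (trapezoidal), by default divided by the final generation so that a
   constant post-induction log2FC of c per generation scores ~c;
4. gene-level fitness = weighted mean of guide fitness, weights
   proportional to how well each guide's profile correlates with the
   other guides targeting the same gene (times an optional efficiency
   prior), with a seeded percentile-bootstrap 95% interval.

Positive fitness means the knockdown mutant is enriched (grows faster
than the population); negative means depleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneFitness",
    "size_factors",
    "log2fc_profiles",
    "replicate_mean_profiles",
    "auc_fitness",
    "guide_fitness_table",
    "guide_weights",
    "gene_fitness",
    "gene_fitness_table",
]

DEFAULT_PSEUDOCOUNT = 0.5


class FitnessError(ValueError):
    pass


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    factor_s = median over guides g of count_gs / geomean_g, where the
    geometric mean is taken across samples and only guides with strictly
    positive counts in every sample enter the median.
    """
    counts = matrix.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise FitnessError(
            "no guide has positive counts in every sample; "
            "median-of-ratios undefined (consider a pseudocount)"
        )
    log_counts = np.log(counts[positive])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def log2fc_profiles(
    matrix: pd.DataFrame,
    factors: pd.Series,
    sheet: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-replicate log2 fold changes versus generation 0.

    Returns a long DataFrame with columns ``guide_id, condition,
    replicate, generation, log2fc``; each replicate is compared against
    its own generation-0 sample:
    log2fc = log2(count/factor + pseudocount) - log2(count0/factor0 + pseudocount).
    """
    norm = matrix.div(factors, axis=1) + pseudocount
    log2 = np.log2(norm)
    chunks = []
    for (cond, rep), grp in sheet.groupby(["condition", "replicate"]):
        grp = grp.sort_values("generation")
        gens = grp["generation"].to_numpy()
        if gens[0] != 0:
            raise FitnessError(
                f"condition {cond} replicate {rep} lacks a generation-0 sample"
            )
        base = log2[grp["sample"].iloc[0]]
        for gen, sample in zip(gens, grp["sample"]):
            chunks.append(
                pd.DataFrame(
                    {
                        "guide_id": matrix.index,
                        "condition": cond,
                        "replicate": rep,
                        "generation": gen,
                        "log2fc": (log2[sample] - base).to_numpy(),
                    }
                )
            )
    return pd.concat(chunks, ignore_index=True)


def replicate_mean_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean log2FC, wide by generation, indexed (condition, guide_id)."""
    return (
        profiles.groupby(["condition", "guide_id", "generation"])["log2fc"]
        .mean()
        .unstack("generation")
        .sort_index(axis=1)
    )


def auc_fitness(generations, log2fc, normalize: bool = True) -> float:
    """Fitness of one guide: area under its log2FC-versus-generation curve.

    Trapezoidal integral over the sampled generations (which must start
    at 0, where log2FC is 0 by construction). With ``normalize=True``
    the area is divided by the final generation, putting fitness on the
    per-generation log2FC scale.
    """
    gens = np.asarray(generations, float)
    vals = np.asarray(log2fc, float)
    if gens.size < 2:
        raise FitnessError("need at least 2 profile points for AUC fitness")
    if np.any(np.diff(gens) <= 0):
        raise FitnessError("generations must be strictly increasing")
    area = float(np.trapezoid(vals, gens))
    if normalize:
        area /= float(gens[-1])
    return area


def guide_fitness_table(
    profiles: pd.DataFrame,
    normalize: bool = True,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """AUC fitness for every guide (columns guide_id, condition[, replicate],
    fitness, n_points).

    With ``per_replicate=False`` the replicate-mean profile is scored;
    otherwise each replicate's profile is scored separately.
    """
    keys = ["condition", "guide_id"] + (["replicate"] if per_replicate else [])
    if per_replicate:
        wide = (
            profiles.set_index(keys + ["generation"])["log2fc"]
            .unstack("generation")
            .sort_index(axis=1)
        )
    else:
        wide = replicate_mean_profiles(profiles)
    gens = wide.columns.to_numpy(float)
    vals = wide.to_numpy(float)
    area = np.trapezoid(vals, gens, axis=1)
    if normalize:
        area = area / gens[-1]
    out = wide.index.to_frame(index=False)
    out["fitness"] = area
    out["n_points"] = vals.shape[1]
    return out


def guide_weights(
    profile_matrix: np.ndarray, efficiency_prior=None
) -> np.ndarray:
    """Per-guide weights for gene-level aggregation.

    ``profile_matrix`` holds one replicate-mean log2FC profile per row
    (guides of a single gene). A guide's raw weight is the mean over the
    other guides of max(0, pairwise Pearson correlation), multiplied by
    its efficiency prior; negative correlations are clamped at the pair
    level so one discordant guide cannot erase the agreement of the
    rest. If every raw weight is 0 (or there is a single guide) the
    weights fall back to uniform. Returned weights sum to 1.
    """
    P = np.asarray(profile_matrix, float)
    k = P.shape[0]
    if k == 0:
        raise FitnessError("no guides")
    prior = np.ones(k) if efficiency_prior is None else np.asarray(efficiency_prior, float)
    if k == 1:
        return np.ones(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(P)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance profiles -> no support
    clamped = np.maximum(corr, 0.0)
    np.fill_diagonal(clamped, 0.0)
    raw = clamped.sum(axis=1) / (k - 1) * prior
    if raw.sum() <= 0:
        raw = np.ones(k)
    return raw / raw.sum()


@dataclass(frozen=True)
class GeneFitness:
    """Weighted mean fitness of one gene with a bootstrap 95% interval."""

    target_id: str
    condition: str
    fitness: float
    ci_lo: float
    ci_hi: float
    n_guides: int
    weights: np.ndarray


def gene_fitness(
    fitness_values,
    weights,
    bootstrap_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    target_id: str = "",
    condition: str = "",
) -> GeneFitness:
    """Weighted mean guide fitness with a percentile-bootstrap 95% CI.

    The bootstrap resamples guides (with replacement, with probability
    equal to their weights) and takes the mean of each resample; the CI
    is the 2.5/97.5 percentile of those means, widened if necessary to
    bracket the point estimate for degenerate tiny-guide-count cases.
    """
    vals = np.asarray(fitness_values, float)
    w = np.asarray(weights, float)
    if vals.size != w.size:
        raise FitnessError("fitness values and weights differ in length")
    if vals.size == 0:
        raise FitnessError("empty guide set")
    w = w / w.sum()
    point = float(np.sum(vals * w))
    if vals.size == 1 or bootstrap_reps <= 0:
        return GeneFitness(target_id, condition, point, point, point, vals.size, w)
    rng = np.random.default_rng(rng)
    idx = rng.choice(vals.size, size=(bootstrap_reps, vals.size), p=w)
    means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    lo, hi = min(float(lo), point), max(float(hi), point)
    return GeneFitness(target_id, condition, point, lo, hi, vals.size, w)


def gene_fitness_table(
    guide_fit: pd.DataFrame,
    profiles: pd.DataFrame,
    library: pd.DataFrame,
    bootstrap_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    efficiency_prior: pd.Series | None = None,
) -> pd.DataFrame:
    """Gene-level weighted fitness for every (target, condition).

    ``guide_fit`` is the replicate-mean guide fitness table; ``profiles``
    the long per-replicate log2FC table (used for correlation weights);
    ``library`` maps guide_id to target_id. Returns columns target_id,
    condition, fitness, ci_lo, ci_hi, n_guides.
    """
    rng = np.random.default_rng(rng)
    target_of = library.set_index("guide_id")["target_id"]
    mean_prof = replicate_mean_profiles(profiles)
    fit = guide_fit.set_index(["condition", "guide_id"])["fitness"]
    rows = []
    for cond in sorted(guide_fit["condition"].unique()):
        prof_c = mean_prof.loc[cond]
        fit_c = fit.loc[cond]
        guides_by_target = target_of.loc[target_of.index.intersection(fit_c.index)]
        for target, gids in guides_by_target.groupby(guides_by_target).groups.items():
            gids = list(gids)
            P = prof_c.loc[gids].to_numpy()
            prior = (
                efficiency_prior.reindex(gids).fillna(1.0).to_numpy()
                if efficiency_prior is not None
                else None
            )
            w = guide_weights(P, prior)
            gf = gene_fitness(
                fit_c.loc[gids].to_numpy(), w,
                bootstrap_reps=bootstrap_reps, rng=rng,
                target_id=str(target), condition=cond,
            )
            rows.append(
                (gf.target_id, cond, gf.fitness, gf.ci_lo, gf.ci_hi, gf.n_guides)
            )
    return pd.DataFrame(
        rows,
        columns=["target_id", "condition", "fitness", "ci_lo", "ci_hi", "n_guides"],
    )
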