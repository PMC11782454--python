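"""Hit statistics for the pooled screen.

Per-gene evidence comes from unpaired Wilcoxon rank-sum tests on guide
fitness scores — against the non-targeting control guides within one
condition, and between conditions — with Benjamini-Hochberg FDR control
across targets (one family per comparison). Effect size between two
conditions is the impact score d = (y0 - x0)/sqrt(2), the signed distance
of the gene's (fitness in condition A, fitness in condition B) point from
the identity line; the combined score d * (-log10 p_adj) mixes effect
size and evidence. Genes are classed depleted (< -1), enriched (> 1) or
neutral by their fitness score.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_rank_sum",
    "bh_adjust",
    "condition_gene_test",
    "between_condition_test",
    "impact_score",
    "combined_score",
    "classify_hits",
    "compare_conditions",
]

#: largest group-size sum for which the exact permutation null is used
EXACT_MAX_N = 20

SQRT2 = math.sqrt(2.0)


class StatsError(ValueError):
    pass


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> float:
    """Unpaired Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact permutation distribution of the rank sum when
    n + m <= 20 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= EXACT_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise StatsError("NaN p-value passed to bh_adjust")
    if np.any((p <= 0) | (p > 1)):
        raise StatsError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _family_tests(groups: dict, reference: dict | None, min_guides: int) -> pd.DataFrame:
    """Run one BH family of rank-sum tests.

    ``groups`` maps target_id -> scores. With ``reference`` None the test
    is target-vs-target across two dicts handled by the callers; here
    reference maps target_id -> opposing scores (control pool or the
    other condition's scores).
    """
    rows = []
    for target, scores in groups.items():
        other = reference[target]
        n = len(scores)
        if n < min_guides or len(other) == 0:
            rows.append((target, n, np.nan))
        else:
            rows.append((target, n, wilcoxon_rank_sum(scores, other)))
    out = pd.DataFrame(rows, columns=["target_id", "n_scores", "p"])
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


def condition_gene_test(
    guide_fitness: pd.DataFrame,
    control_label: str = "ctrl",
    min_guides: int = 2,
) -> pd.DataFrame:
    """Per-target two-sided rank-sum test against the control guides.

    ``guide_fitness`` has columns ``target_id, fitness`` (one row per
    guide score within one condition). Targets with fewer than
    ``min_guides`` scores get p = p_adj = NaN; BH is applied across the
    tested targets of this condition (one family).
    """
    controls = guide_fitness.loc[
        guide_fitness["target_id"] == control_label, "fitness"
    ].to_numpy()
    if controls.size == 0:
        raise StatsError(f"no control guides labelled '{control_label}'")
    targets = guide_fitness[guide_fitness["target_id"] != control_label]
    groups = {
        t: g["fitness"].to_numpy() for t, g in targets.groupby("target_id")
    }
    reference = {t: controls for t in groups}
    return _family_tests(groups, reference, min_guides)


def between_condition_test(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    min_guides: int = 2,
) -> pd.DataFrame:
    """Per-target rank-sum test of guide fitness between two conditions.

    Each input has columns ``target_id, fitness``; rows may be one score
    per guide (replicate-averaged) or one per guide and replicate
    (pooled), as chosen by the caller. BH across the tested targets
    forms its own family.
    """
    ga = {t: g["fitness"].to_numpy() for t, g in scores_a.groupby("target_id")}
    gb = {t: g["fitness"].to_numpy() for t, g in scores_b.groupby("target_id")}
    shared = sorted(set(ga) & set(gb))
    groups = {t: ga[t] for t in shared}
    reference = {t: gb[t] for t in shared}
    out = _family_tests(groups, reference, min_guides)
    low = out["target_id"].map(lambda t: len(gb[t])) < min_guides
    out.loc[low, ["p", "p_adj"]] = np.nan
    return out


def impact_score(fitness_a, fitness_b):
    """Signed distance from the identity line: d = (y0 - x0)/sqrt(2).

    ``fitness_a`` is the score in the reference condition (x0) and
    ``fitness_b`` in the stress condition (y0); positive d means the
    knockdown fares relatively better under the stress condition.
    Accepts scalars or arrays.
    """
    return (np.asarray(fitness_b, float) - np.asarray(fitness_a, float)) / SQRT2


def combined_score(d, p_adj):
    """Combined score d * (-log10 p_adj); scalars or arrays.

    Raises for p_adj = 0 (suggest capping at the machine floor upstream).
    """
    p = np.asarray(p_adj, float)
    if np.any(p == 0):
        raise StatsError(
            "p_adj of 0 has no finite -log10; cap at a machine floor "
            "(e.g. 1e-300) before scoring"
        )
    out = np.asarray(d, float) * (-np.log10(p))
    return float(out) if out.ndim == 0 else out


def classify_hits(fitness):
    """Classify fitness: 'depleted' (< -1), 'enriched' (> 1), else 'neutral'.

    Strict inequalities at the +/-1 thresholds. Accepts scalars/arrays.
    """
    f = np.asarray(fitness, float)
    out = np.where(f < -1.0, "depleted", np.where(f > 1.0, "enriched", "neutral"))
    return str(out[()]) if out.ndim == 0 else out


def compare_conditions(
    gene_fit_a: pd.DataFrame,
    gene_fit_b: pd.DataFrame,
    test: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-gene comparison table for a pair of conditions.

    Inputs are the gene-fitness tables of condition A (x0) and B (y0)
    (columns ``target_id, fitness``) and the between-condition test
    table (``target_id, p, p_adj``). Output columns: target_id,
    fitness_a, fitness_b, impact, p_adj, combined, class_a, class_b.
    """
    a = gene_fit_a.set_index("target_id")["fitness"]
    b = gene_fit_b.set_index("target_id")["fitness"]
    shared = a.index.intersection(b.index)
    out = pd.DataFrame(
        {
            "target_id": shared,
            "fitness_a": a.loc[shared].to_numpy(),
            "fitness_b": b.loc[shared].to_numpy(),
        }
    )
    out["impact"] = impact_score(out["fitness_a"], out["fitness_b"])
    padj = test.set_index("target_id")["p_adj"].reindex(shared)
    out["p_adj"] = padj.to_numpy()
    ok = out["p_adj"].notna()
    out["combined"] = np.nan
    if ok.any():
        out.loc[ok, "combined"] = combined_score(
            out.loc[ok, "impact"].to_numpy(), out.loc[ok, "p_adj"].to_numpy()
        )
    out["class_a"] = classify_hits(out["fitness_a"])
    out["class_b"] = classify_hits(out["fitness_b"])
    return out
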