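import numpy as np
import pandas as pd
import pytest

from co2fit import SimConfig, analyze_screen, simulate_screen
from co2fit.simulate import SimTruth


#: predicted design-table values for BG-11-like medium at pH 7.5
#: (co2_frac -> dose, co2, hco3, co3, ca, tic, all mM)
CHEMISTRY_TABLE = {
    0.0004: (0.168, 0.012, 0.167, 0.000, 0.168, 0.180),
    0.04: (16.8, 1.186, 16.747, 0.037, 16.822, 17.970),
    0.15: (63.1, 4.446, 62.801, 0.141, 63.082, 67.388),
    0.30: (126.2, 8.892, 125.602, 0.281, 126.165, 134.775),
}

#: published worked examples: locus -> (fitness stress, fitness reference,
#: printed impact score). Spans the highest-fitness and extreme-impact genes.
IMPACT_EXAMPLES = {
    "sll8017": (2.82, 0.02, 1.98),
    "slr2051": (2.59, -2.48, 3.59),
    "sll1051": (2.52, -1.00, 2.49),
    "sll0269": (2.40, -0.07, 1.74),
    "sll1579": (2.28, -1.71, 2.82),
    "sll1580": (2.27, -2.04, 3.05),
    "slr1125": (2.25, -0.32, 1.82),
    "slr8021": (2.21, -0.37, 1.83),
    "sll0268": (2.15, 0.04, 1.49),
    "slr1042": (2.14, 1.74, 0.29),
    "smr0008": (1.95, -3.20, 3.64),
    "slr0335": (0.21, -4.57, 3.38),
    "sll1577": (0.92, -3.77, 3.32),
    "sll1578": (1.20, -3.23, 3.13),
    "sll1816": (-0.26, -4.33, 2.87),
    "sll0711": (-1.08, -5.13, 2.86),
    "sll0849": (-1.74, -5.63, 2.75),
    "sll0306": (-2.86, 0.05, -2.06),
    "sll1504": (-2.94, -0.01, -2.07),
    "slr1129": (-3.70, -0.77, -2.07),
    "sll0005": (-3.68, -0.71, -2.10),
    "ssl3364": (-3.18, -0.05, -2.21),
    "slr1660": (-4.72, -1.57, -2.23),
    "slr0195": (-3.03, 0.17, -2.26),
    "slr1916": (-2.77, 0.50, -2.31),
    "sll0828": (-3.68, 0.25, -2.78),
    "sll1968": (-4.54, 0.64, -3.66),
}


@pytest.fixture(scope="session")
def recovery_run():
    """Full-scale simulated screen plus end-to-end analysis (seeded)."""
    config = SimConfig(seed=1)
    counts, sheet, lib, truth = simulate_screen(config)
    results = analyze_screen(counts, sheet, lib, "4pct", "30pct", seed=1)
    return {
        "config": config,
        "counts": counts,
        "sheet": sheet,
        "library": lib,
        "truth": truth,
        "results": results,
    }


def make_micro_screen(n_genes=20, seed=7, depleted_gene="gene01", depleted_cond="30pct"):
    """Tiny screen in which one gene is strongly depleted in one condition."""
    config = SimConfig(
        n_genes=n_genes, guides_per_gene=5, n_controls=50,
        depth=200_000, seed=seed,
    )
    width = len(str(n_genes))
    names = [f"gene{i + 1:0{width}d}" for i in range(n_genes)]
    genes = pd.DataFrame({"target_id": names})
    genes["s_4pct"] = 0.0
    genes["s_30pct"] = 0.0
    genes["shifted"] = False
    genes.loc[genes.target_id == depleted_gene, f"s_{depleted_cond}"] = -0.5
    genes.loc[genes.target_id == depleted_gene, "shifted"] = True
    guide_rows = []
    for t in names:
        for j in range(5):
            guide_rows.append((f"{t}_g{j + 1}", t, 1.0))
    for k in range(50):
        guide_rows.append((f"ctrl_{k + 1:04d}", "ctrl", 0.0))
    guides = pd.DataFrame(guide_rows, columns=["guide_id", "target_id", "efficiency"])
    truth = SimTruth(genes=genes, guides=guides)
    counts, sheet, lib, truth = simulate_screen(config, truth=truth)
    return counts, sheet, lib, truth


@pytest.fixture()
def micro_screen():
    return make_micro_screen()
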