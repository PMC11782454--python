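"""Synthetic pooled CRISPRi screen under turbidostat selection.

Generates ground-truth data for end-to-end recovery tests: a guide
library (typically five guides per gene plus non-targeting controls), a
per-gene selection coefficient s per condition (relative fitness
w = 1 + s), a per-guide knockdown efficiency e in [0, 1], and sgRNA
count tables over sampled population generations.

Selection acts per population generation: a mutant with relative
fitness w_i = 1 + s_gene * e_i changes abundance as
f_i(g) proportional to f_i(0) * 2^(g * w_i), renormalized, so its log2
fold change grows linearly at rate (w_i - wbar) per generation under the
small-fraction approximation. Sequencing is modelled as a multinomial
draw at fixed depth, with optional gamma-multiplicative overdispersion
of the expected fractions (library-prep noise). Everything is
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_io import CONTROL_LABEL

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_screen",
    "expected_log2fc",
    "expected_log2fc_exact",
    "default_recovery_scenario",
]


@dataclass(frozen=True)
class SimConfig:
    """Design of a simulated two-condition turbidostat screen.

    ``conditions`` maps condition name to mean specific growth rate
    (h^-1) — used only to annotate realistic wall-clock metadata, since
    selection is modelled per population generation. ``replicates`` maps
    condition name to replicate count (defaults mirror a quadruplicate
    design with one failed culture in the stress condition).
    ``dispersion`` is the gamma shape of the multiplicative count noise
    (variance 1/dispersion); ``dirichlet_conc`` sets the skew of the
    initial library composition (larger = more even).
    """

    n_genes: int = 2000
    guides_per_gene: int = 5
    n_controls: int = 500
    conditions: dict = field(
        default_factory=lambda: {"4pct": 0.058, "30pct": 0.038}
    )
    replicates: dict = field(default_factory=lambda: {"4pct": 4, "30pct": 3})
    generations: tuple = (0, 4, 8, 10)
    depth: int = 2_000_000
    dispersion: float = 250.0
    dirichlet_conc: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.guides_per_gene, self.n_controls, self.depth) <= 0:
            raise ValueError("all design counts must be positive")
        if self.generations[0] != 0:
            raise ValueError("sampled generations must start at 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion (gamma shape) must be > 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth: per-gene selection coefficients and guide efficiencies.

    ``genes`` has one row per gene with one column ``s_<condition>`` per
    condition plus a ``shifted`` flag for genes whose s differs between
    conditions; ``guides`` has guide_id, target_id, efficiency (controls:
    s = 0, efficiency = 0).
    """

    genes: pd.DataFrame
    guides: pd.DataFrame


def expected_log2fc(w: float, g: float, wbar: float = 1.0) -> float:
    """Analytic log2FC of a rare mutant: g * (w - wbar)."""
    if g < 0:
        raise ValueError("generation must be >= 0")
    return float(g * (w - wbar))


def expected_log2fc_exact(w, g: float, f0) -> np.ndarray:
    """Exact renormalized log2FC for all guides.

    log2fc_i = g*(w_i - 1) - log2( sum_j f0_j 2^(g*(w_j - 1)) ).
    """
    w = np.asarray(w, float)
    f0 = np.asarray(f0, float)
    growth = g * (w - 1.0)
    z = np.log2(np.sum(f0 * np.exp2(growth)))
    return growth - z


def _random_spacers(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        for s in ["".join(row) for row in bases[rng.integers(0, 4, size=(n - len(out), length))]]:
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def _build_library(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = len(str(config.n_genes))
    rows = []
    pos = 0
    for i in range(config.n_genes):
        target = f"gene{i + 1:0{width}d}"
        for j in range(config.guides_per_gene):
            rows.append(
                (f"{target}_g{j + 1}", target, "chr1", pos + j * 25, pos + j * 25 + 20, "+")
            )
        pos += 200
    for k in range(config.n_controls):
        rows.append((f"ctrl_{k + 1:04d}", CONTROL_LABEL, None, None, None, None))
    lib = pd.DataFrame(
        rows, columns=["guide_id", "target_id", "chrom", "start", "end", "strand"]
    )
    lib["sequence"] = _random_spacers(rng, len(lib))
    return lib


def _random_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    """Default selection-coefficient mixture.

    Condition A: 70% of genes neutral, 15% deleterious knockdowns with s
    uniform in [-0.6, -0.1], 15% advantageous with s in [0.05, 0.3].
    Condition B: identical, except a labelled 5% subset of genes is
    shifted by +/-0.3. Efficiency e ~ Beta(5, 1) per guide.
    """
    n = config.n_genes
    width = len(str(n))
    names = [f"gene{i + 1:0{width}d}" for i in range(n)]
    kind = rng.choice(3, size=n, p=(0.70, 0.15, 0.15))
    s_a = np.zeros(n)
    s_a[kind == 1] = rng.uniform(-0.6, -0.1, size=(kind == 1).sum())
    s_a[kind == 2] = rng.uniform(0.05, 0.3, size=(kind == 2).sum())
    n_shift = max(1, round(0.05 * n))
    shifted_idx = rng.choice(n, size=n_shift, replace=False)
    shift = rng.choice([-0.3, 0.3], size=n_shift)
    cond_names = list(config.conditions)
    genes = pd.DataFrame({"target_id": names})
    genes[f"s_{cond_names[0]}"] = s_a
    s_b = s_a.copy()
    s_b[shifted_idx] += shift
    for extra in cond_names[1:]:
        genes[f"s_{extra}"] = s_b
    genes["shifted"] = False
    genes.loc[shifted_idx, "shifted"] = True
    gene_eff = rng.beta(5.0, 1.0, size=(n, config.guides_per_gene))
    guide_rows = []
    for i, target in enumerate(names):
        for j in range(config.guides_per_gene):
            guide_rows.append((f"{target}_g{j + 1}", target, gene_eff[i, j]))
    for k in range(config.n_controls):
        guide_rows.append((f"ctrl_{k + 1:04d}", CONTROL_LABEL, 0.0))
    guides = pd.DataFrame(guide_rows, columns=["guide_id", "target_id", "efficiency"])
    return SimTruth(genes=genes, guides=guides)


def simulate_screen(
    config: SimConfig, truth: SimTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the screen; returns (counts, sample sheet, library, truth).

    All randomness flows from ``config.seed`` through independent
    spawned streams for library construction, truth generation and
    counting noise, so identical configs give byte-identical outputs.
    """
    ss = np.random.SeedSequence(config.seed)
    lib_ss, truth_ss, noise_ss = ss.spawn(3)
    lib = _build_library(config, np.random.default_rng(lib_ss))
    if truth is None:
        truth = _random_truth(config, np.random.default_rng(truth_ss))
    rng = np.random.default_rng(noise_ss)

    s_of_gene = {
        cond: truth.genes.set_index("target_id")[f"s_{cond}"]
        for cond in config.conditions
    }
    eff = truth.guides.set_index("guide_id")["efficiency"].reindex(lib["guide_id"])
    target = lib["target_id"].to_numpy()
    n_guides = len(lib)

    f0 = rng.dirichlet(np.full(n_guides, config.dirichlet_conc))

    counts = {}
    sheet_rows = []
    for cond, mu in config.conditions.items():
        s = s_of_gene[cond].reindex(pd.Index(target)).fillna(0.0).to_numpy()
        w = 1.0 + s * eff.to_numpy()
        for rep in range(1, config.replicates[cond] + 1):
            for g in config.generations:
                frac = f0 * np.exp2(g * (w - 1.0))
                frac /= frac.sum()
                lam = frac * rng.gamma(config.dispersion, 1.0 / config.dispersion, n_guides)
                lam /= lam.sum()
                name = f"{cond}_rep{rep}_gen{g}"
                counts[name] = rng.multinomial(config.depth, lam)
                sheet_rows.append((name, cond, rep, g, round(g * np.log(2) / mu, 2)))
    count_df = pd.DataFrame(counts, index=lib["guide_id"]).astype(np.int64)
    count_df.index.name = "guide_id"
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample", "condition", "replicate", "generation", "time_h"]
    )
    return count_df, sheet, lib, truth


def default_recovery_scenario(seed: int = 0) -> tuple[SimConfig, SimTruth]:
    """The standard parameter-recovery scenario.

    2,000 genes x 5 guides plus 500 controls, two conditions (growth
    rates 0.058 and 0.038 h^-1; 4 and 3 replicates), generations
    0/4/8/10, depth 2e6 reads per sample. Returns the config and the
    truth realized under ``seed`` (the same truth the simulated counts
    will embed).
    """
    config = SimConfig(seed=seed)
    _, truth_ss, _ = np.random.SeedSequence(seed).spawn(3)
    truth = _random_truth(config, np.random.default_rng(truth_ss))
    return config, truth
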