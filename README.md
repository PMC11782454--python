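# co2fit

Fitness analysis for pooled CRISPRi screens in cyanobacteria grown under
elevated CO2, plus the carbonate chemistry needed to design the growth
media. The package covers the full path from raw sgRNA counts (or FASTQ
reads) to gene-level fitness scores, between-condition comparisons and
genome-browser tracks, and ships a seeded turbidostat simulator so that
the whole statistical chain can be validated against known ground truth.

## What it does

**Medium design (carbonate chemistry).** Growing cells under a
high-CO2 atmosphere at a fixed pH requires supplementing the medium with
NaHCO3 so that it is in equilibrium with the gas phase. `co2fit`
computes dissolved CO2 from Henry's law, speciates the carbonate system
at a target pH using apparent dissociation constants (pKa1 = 6.35,
pKa2 = 10.15 at 30 °C), and returns the bicarbonate dose, e.g. at
pH 7.5:

| CO2 (%) | NaHCO3 (mM) | CO2 (mM) | HCO3⁻ (mM) | CO3²⁻ (mM) | TIC (mM) |
|--------:|------------:|---------:|-----------:|-----------:|---------:|
|    0.04 |       0.168 |    0.012 |      0.167 |      0.000 |    0.180 |
|       4 |        16.8 |    1.186 |     16.747 |      0.037 |   17.970 |
|      15 |        63.1 |    4.446 |     62.801 |      0.141 |   67.388 |
|      30 |       126.2 |    8.892 |    125.602 |      0.281 |  134.775 |

It also models closed-system acid titrations and can refit both pKa
values from a measured curve, and converts growth rates to generation
times (µ = 0.058 h⁻¹ → 11.95 h; 0.038 h⁻¹ → 18.24 h).

**Screen analysis.** Counts are normalized with median-of-ratios size
factors; each guide gets a log2 fold change versus its replicate's
generation-0 sample (pseudocount 0.5); per-guide fitness is the area
under the log2FC-versus-generation curve divided by the final
generation; gene fitness is a correlation-weighted mean over the gene's
guides with a bootstrap confidence interval. Per-condition depletion and
enrichment are tested against the non-targeting controls with a
Wilcoxon rank-sum test, conditions are compared with the same test on
pooled per-replicate guide scores, and p-values are
Benjamini–Hochberg-adjusted. The condition comparison is summarized by
an impact score — the signed distance of a gene's (fitness A,
fitness B) point from the identity line, `(b − a)/√2` — and a combined
score `impact × (−log10 p_adj)`.

**Simulation.** `simulate_screen` generates a two-condition turbidostat
screen (by default 2,000 genes × 5 guides + 500 controls, 4 + 3
replicates, generations 0/4/8/10, 2 × 10⁶ reads per sample) with known
per-gene selection coefficients and per-guide efficiencies, Dirichlet
library skew, gamma library-prep overdispersion and multinomial
sequencing — all byte-reproducible from one seed.

## Quickstart

Command line:

```bash
# medium design table for 15% and 30% CO2 at pH 7.5
co2fit carbonate --co2 0.15 --co2 0.30 --ph 7.5

# growth rate from a time,OD CSV
co2fit growth od.csv

# simulate a screen, then analyse it
co2fit simulate --seed 1 --out sim/
co2fit fitness --counts sim/counts.tsv --samples sim/samples.csv \
    --library sim/library.tsv --condition-a 4pct --condition-b 30pct \
    --outdir results/
```

`results/` then contains `fitness_A.tsv` / `fitness_B.tsv` (gene
fitness with bootstrap CIs per condition), `compare.tsv` (impact,
adjusted p, combined score, hit classes) and `manifest.json`.

Python:

```python
from co2fit import SimConfig, simulate_screen, analyze_screen

counts, sheet, lib, truth = simulate_screen(SimConfig(seed=1))
results = analyze_screen(counts, sheet, lib, "4pct", "30pct", seed=1)
results["compare"].head()
```

Worked example of the scores: a gene with fitness −3.20 in the
reference condition and +1.95 under stress has impact
`(1.95 − (−3.20))/√2 = 3.64` and is classified enriched under stress
(fitness > 1) and depleted in the reference (fitness < −1).

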