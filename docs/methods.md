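# Methods

This document describes the models implemented in `co2fit`, the default
parameter values and why they were chosen, and the numerical and
statistical decisions that shape the results.

## 1. Carbonate chemistry (`co2fit.carbonate`)

### Model

The dissolved carbonate system in equilibrium with a gas phase at CO2
partial pressure `pCO2` (atm) is described by

- Henry's law: `[CO2*] = K_H · pCO2` (CO2* = CO2(aq) + H2CO3),
- first dissociation: `[HCO3⁻] = [CO2*] · 10^(pH − pKa1)`,
- second dissociation: `[CO3²⁻] = [HCO3⁻] · 10^(pH − pKa2)`.

Carbonate alkalinity is `CA = [HCO3⁻] + 2[CO3²⁻]` and total inorganic
carbon `TIC = [CO2*] + [HCO3⁻] + [CO3²⁻]`. For a medium equilibrated
with the gas phase at a target pH, the required NaHCO3 dose equals the
carbonate alkalinity: each mole of NaHCO3 contributes one mole of Na⁺,
and at equilibrium the charge carried by Na⁺ must balance the carbonate
charge (non-carbonate medium ions balance among themselves).

`equilibrium_ph` inverts the relation: given a dose (as CA) and pCO2 it
solves `CA(pH) = dose` for pH by bisection/Brent on [2, 12]. With
`include_water=True` the residual uses the full charge balance
including `[OH⁻] − [H⁺]`, which is required for the unbuffered
(zero-dose) limit, where the pH of CO2-saturated water is set by
`[H⁺] ≈ [HCO3⁻]` (30% CO2 → pH 4.20). The default excludes the water
terms so that `nahco3_dose` and `equilibrium_ph` are exact inverses of
each other (round trip to ~1e-13).

### Parameters and defaults

- `kh` (Henry constant): default 0.029640 M/atm, evaluated from the
  Weiss (1974) volumetric solubility fit at 30 °C and salinity
  1.5 g/kg (a freshwater-like medium with ~mM salt content). The
  full-precision value, not a rounded 0.02964, is used so that the
  design table reproduces at printed precision.
- `pka1 = 6.35`, `pka2 = 10.15`: apparent (concentration-based)
  dissociation exponents appropriate for dilute media near 30 °C.
- `pkw = 13.83`: water ion product at 30 °C; only used in the
  unbuffered pH solver and the titration model.
- Baseline medium sodium: 32.03 mM (the Na⁺ contributed by the
  standard BG-11-like recipe before any NaHCO3 addition).
  `total_sodium` reports baseline + dose rounded to 0.1 mM.

### Titration and pKa fitting

`simulate_titration` models the stepwise HCl titration of a Na2CO3
solution as a *closed* system (TIC conserved, no CO2 outgassing — the
simplest model consistent with a rapid titration). At each acid step the
pH solves the charge balance
`[Na⁺] + [H⁺] = [Cl⁻] + [OH⁻] + [HCO3⁻] + 2[CO3²⁻]`, with all
concentrations corrected for titrant dilution; equivalence points fall
at `c0` and `2·c0` mmol acid per litre. `fit_pka` refits (pKa1, pKa2)
from an observed curve by Levenberg–Marquardt least squares on the pH
residuals, starting from (6, 10); the curve must span both equivalence
points so both steps are informative. With 0.02-unit pH noise on a
60-point curve both constants are recovered within ±0.01.

## 2. Culture physiology (`co2fit.culture`)

- `fit_growth_rate`: ordinary least squares of `ln(OD)` against time,
  restricted to points with OD inside a window (default [0.1, 0.3]) to
  exclude lag and light-limited/saturated phases; at least three points
  are required. `generation_time = ln 2 / µ`.
- `correct_spectrum_scatter`: whole-cell absorption spectra are first
  normalized to A(730 nm) = 1 (turbidity proxy), then a straight-line
  scatter baseline through the 560 nm and 730 nm anchor points (regions
  without pigment absorption) is subtracted. Both anchors map to zero
  by construction; a pigment peak riding on a linear scatter baseline
  is recovered exactly.

## 3. Screen input/output (`co2fit.screen_io`)

Count tables are TSV with a `guide_id` first column; duplicate guides,
negative or non-integer counts are rejected with the offending line
number. Sample sheets require `sample, condition, replicate,
generation` with a unique design key and a generation-0 sample for
every (condition, replicate). Guide coordinates can come from BED
(0-based half-open, used as-is) or GFF3 (1-based inclusive, converted).
`count_guides_from_fastq` performs exact spacer matching between fixed
5′/3′ flanking sequences; reads whose extracted spacer is not in the
library count as unmatched, and matched + unmatched always equals the
number of reads.

Coverage tracks are bedGraph (0-based half-open): at every genome
position the exported value is the fitness of the covering guide with
the largest |fitness|; ties resolve to the positive value, then to the
earlier-starting guide; equal-valued adjacent runs are merged. An
independent per-position brute-force oracle validates this in the test
suite.

## 4. Fitness model (`co2fit.fitness`)

1. **Normalization** — median-of-ratios size factors (the DESeq
   estimator): per sample, the median across all-positive guides of the
   ratio to the per-guide geometric mean. Factors are defined relative
   to the geometric-mean pseudo-reference, so only factor *ratios* are
   identifiable.
2. **log2 fold change** — per replicate, each guide's normalized count
   at generation g versus the same replicate's generation-0 sample,
   with pseudocount 0.5 added to both numerator and denominator
   (bounding a count of zero at depth 2 × 10⁶ to ≈ −7.65 rather than
   −∞).
3. **Guide fitness** — the area under the replicate-mean log2FC profile
   over sampled generations (trapezoid rule), divided by the final
   generation. This rewards early, sustained depletion: a profile that
   jumps to a constant c at the first sampled generation (0/4/8/10
   design) scores 0.8 c, while a linear ramp to c scores 0.5 c. A
   per-replicate variant scores each replicate's profile separately and
   is used for the between-condition test.
4. **Gene fitness** — a weighted mean of the gene's guide fitness
   scores. A guide's weight is the mean over the *other* guides of
   `max(0, pairwise Pearson correlation)` of the replicate-mean
   profiles (clamped at the pair level so one discordant guide cannot
   erase agreement among the rest), optionally multiplied by an
   efficiency prior, then normalized; if all weights vanish the weights
   fall back to uniform. Confidence intervals are percentile bootstrap
   (default 1,000 resamples) of the weighted mean, resampling guides
   with probability proportional to their weights; the interval is
   widened, if necessary, to bracket the point estimate.

## 5. Statistics (`co2fit.stats`)

- **Rank-sum test**: two-sided Wilcoxon rank-sum (Mann–Whitney U),
  exact when the pooled sample has ≤ 20 observations and no ties,
  asymptotic with tie and continuity correction otherwise. The exact
  branch is validated against complete enumeration of all
  `C(n+m, n)` group assignments.
- **Multiplicity**: Benjamini–Hochberg step-up within each test family
  (validated against an independent implementation).
- **Per-condition test**: each gene's guide fitness scores against the
  non-targeting control guides; genes with fewer than `min_guides`
  (default 2) scores get NA rather than an underpowered p-value.
- **Between-condition test**: the same rank-sum test on *pooled
  per-replicate* guide scores (e.g. 5 guides × 4 replicates = 20 versus
  15). Pooling is the default because with replicate-mean scores a
  5-vs-5 exact test has a p-value floor of 2/252 ≈ 0.0079, which can
  never survive BH correction across ~2,000 genes; per-replicate scores
  carry the replication information into the test. Replicate scores of
  one guide are correlated, so the nominal p-values are approximate —
  on simulated null screens the empirical BH FDR stays below the
  nominal level.
- **Impact score**: `d = (fitness_B − fitness_A)/√2`, the signed
  distance from the identity line in the (A, B) fitness plane; positive
  means relatively better under condition B. **Combined score**:
  `d · (−log10 p_adj)`. **Hit classes**: depleted if fitness < −1,
  enriched if fitness > 1, neutral otherwise (strict inequalities).

## 6. Simulator (`co2fit.simulate`)

Selection acts per population generation: a mutant with relative
fitness `w_i = 1 + s_gene · e_i` (s: per-gene selection coefficient per
condition; e: per-guide knockdown efficiency, Beta(5, 1)) has abundance
`f_i(g) ∝ f_i(0) · 2^(g·w_i)` after renormalization, so a rare mutant's
log2FC grows as `g · (w_i − w̄)`. Initial fractions are Dirichlet
(concentration 10, realistic library skew). Sequencing is a multinomial
draw at fixed depth over expected fractions multiplied by gamma
noise (shape 250, mean 1), chosen to give a realistic null per-replicate
log2FC standard deviation of ≈ 0.2 at 2 × 10⁶ reads. All randomness
derives from one `SeedSequence` spawned into independent streams for
library, truth and noise, so outputs are byte-reproducible.

The default truth mixes 70% neutral genes, 15% deleterious
(s ∈ [−0.6, −0.1]) and 15% advantageous (s ∈ [0.05, 0.3]) knockdowns,
with a labelled 5% subset shifted by ±0.3 between conditions.
**Scope/limits**: the simulator models selection, library skew,
prep overdispersion and sampling — not PCR jackpotting, guide-specific
off-target effects, position-dependent CRISPRi efficacy along the gene,
or cross-feeding between mutants; generations are exact rather than
estimated from OD.

## 7. Numerical choices

- Root finding uses Brent's method on hard brackets ([2, 12] for the
  equilibrium pH, [0.5, 13.8] for titration pH); no derivative
  approximations.
- AUC uses the trapezoid rule on the sampled generations; it is exactly
  linear in the profile, which the tests exploit.
- Bootstrap and simulator randomness always flow through
  `numpy.random.Generator` objects seeded from explicit integers; no
  global seeding.
- Rounding conventions: bicarbonate doses print with 1 decimal at
  ≥ 1 mM and 3 decimals below; sodium totals with 1 decimal; these
  match the design-table conventions used in the README.

## 8. Acceptance metrics

`scripts/acceptance.py --seed S --out f.json` recomputes all headline
numbers (chemistry table, sodium budget, pKa refit, impact worked
examples, control-guide neutrality, truth-recovery correlation, shifted
gene detection) from scratch; `tests/test_acceptance.py` asserts the
corresponding tolerances (chemistry within printed precision, pKa
±0.02, impact ±0.01, control medians ±0.05, Pearson r ≥ 0.9,
sensitivity ≥ 0.8 at empirical FDR ≤ 0.1).
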