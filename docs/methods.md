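# Methods

## The model

`atpmax` treats energy metabolism as a steady-state allocation problem.
A cell runs 1–3 lumped ATP-producing pathways; pathway *i* is fully
described by its ATP yield γ_i (mol ATP per mol glucose) and its specific
activity Vmax_i (µmol glucose·min⁻¹ per mg of pathway protein — "proteome
efficiency"). The cell chooses pathway fluxes to maximize total ATP
production rate subject to (i) a proteome budget: the protein needed to
carry the fluxes, Σ V_i/Vmax_i, cannot exceed the fraction φ_totalATP of
cellular protein available to ATP-producing enzymes; and (ii) glucose
availability: Σ V_i ≤ V_glucose. Both constraints are inequalities; excess
glucose simply goes unconsumed.

Assumptions worth stating explicitly:

- **Steady state, no kinetics.** The model has no time, no metabolite
  pools, and no regulation; it answers only "what flux split maximizes ATP
  production rate given the budget".
- **Free re-allocation.** Within φ_totalATP the cell can shift protein
  between pathways without cost or delay.
- **Lumped pathways.** Glycolysis and respiration are single reactions with
  fixed stoichiometry; there is no genome-scale network.
- **Oxygen saturation** by default; an optional linear constraint
  Σ o2_per_glucose_i · V_i ≤ V_O2max models hypoxia (see below).

### Solution structure

The LP is solved in closed form by KKT analysis (`solve_two_pathway`,
`solve_three_pathway`) and numerically with HiGHS via
`scipy.optimize.linprog` (`solve_lp`); the test suite holds the two routes
to 10⁻⁶ relative agreement over random parameter regimes. If one pathway
has both the larger γ and the larger γ·Vmax it is used exclusively. In the
Warburg regime (γ_glyc < γ_resp, γ_glyc·Vmax_glyc > γ_resp·Vmax_resp) the
optimum is:

- V_glucose ≤ φ·Vmax_resp: pure respiration (glucose-limited);
- φ·Vmax_resp < V_glucose < φ·Vmax_glyc: both constraints bind; glycolytic
  flux is (φ·Vmax_glyc·Vmax_resp − V_glucose·Vmax_glyc)/(Vmax_resp −
  Vmax_glyc) and respiration carries the remaining glucose;
- V_glucose ≥ φ·Vmax_glyc: pure glycolysis at its proteome cap.

The mixed-regime respiration flux is implemented as V_glucose − V_glyc;
this form is dimensionally consistent, continuous at both boundaries, and
LP-verified. In the three-pathway *E. coli* model a pathway that is weakly
dominated in both γ and γ·Vmax (fermentation, under the estimated
parameters) provably carries zero flux in a global optimum and is
eliminated before the remaining two-pathway problem is solved in closed
form; parameter regimes without a dominated pathway fall back to the LP.

### Conventions and degenerate cases

- **Units.** Everything in the core is µmol·min⁻¹·(mg cellular protein)⁻¹;
  all unit conversion happens in `estimation`, never in `core`.
- **Regime labels.** The lower boundary v = φ·Vmax_resp is labelled
  `substrate_limited` and the upper boundary v = φ·Vmax_glyc
  `proteome_limited`; fluxes are continuous there, so the label choice has
  no observable consequence.
- **Degenerate optimum.** If γ_glyc·Vmax_glyc = γ_resp·Vmax_resp exactly,
  the proteome-limited LP face is degenerate; both solvers deterministically
  report the maximal-yield vertex (all flux through the higher-γ pathway).
  `solve_lp` detects the tie and re-solves lexicographically so the
  reported vertex does not depend on solver internals.
- **Tolerances.** Constraint feasibility 10⁻⁹ absolute; analytic-vs-LP
  comparisons 10⁻⁶ relative — double-precision LP solver defaults.
- **Oxygen constraint.** Implemented as one extra linear row on the same
  LP, leaving φ and Vmax untouched under hypoxia. As the cap → ∞ the
  unconstrained optimum is recovered; at cap 0 only non-O₂-consuming flux
  remains, and sweeping the cap upward never increases glycolytic flux
  (Pasteur effect).

## ATP yields from proton bookkeeping

Respiratory γ is computed, not assumed. Each NADH or CoQH₂/FADH₂ donates 2
electrons that traverse an organism-specific sequence of complexes, each
translocating an integer number of H⁺ per electron:

- *E. coli*: NDH-I (2 H⁺/e⁻) and cytochrome *bo₃* (2 H⁺/e⁻); 10 NADH and 2
  CoQH₂ per glucose; no shuttle; H⁺/ATP = 4. H⁺max = 88.
- Mammalian: Complexes I/III/IV at 2/1/2 H⁺/e⁻; 10 NADH and 2 FADH₂; 2
  glycolytic NADH shuttled at 1 H⁺ each; H⁺/ATP = 3 plus 1 H⁺ to export
  each ATP (ANT + phosphate carrier). H⁺max = 110.
- Pta-AckA: the 4 NADH produced per glucose alongside acetate are
  reoxidized by the *E. coli* chain. H⁺max = 32.

A leak fraction of 0.25 is applied multiplicatively (h_effective =
0.75·h_max); chemiosmotic ATP is floor(h_effective / H⁺-per-ATP) and the
substrate-level ATP (4 per glucose from glycolysis + TCA, or glycolysis +
acetate kinase) is added. The floor convention reproduces the canonical
overall reactions exactly: 66/4 → 16 + 4 = **20** (*E. coli*), 82.5/4 → 20 +
4 = **24** (mammalian), 24/4 → 6 + 4 = **10** (Pta-AckA). Plain rounding
would give 25 for the mammalian chain.

**Yeast discrepancy.** The same arithmetic with the stated Ndi1 (0 H⁺/e⁻) /
CIII / CIV stoichiometry, 2 shuttled NADH, 25% leak and 3+1 H⁺/ATP gives
h_max = 70 and γ = 17, while the canonical overall reaction is written with
16 ATP. The exact convention behind 16 is not recoverable from the printed
stoichiometry, so the package stores 16 as the canonical yeast constant
(`CANONICAL_GAMMA`) rather than recomputing it, and all downstream modules
consume the stored constants {2, 10, 16, 20, 24}; the calculator serves as
a cross-check for the other three yields. Whether the ~25% leak for the
microbes was fitted or assumed exactly 0.25 is likewise not determinable;
0.25 is used.

## Parameter estimation

- **Proteome fractions** use the total-protein approach: a pathway's mass
  fraction is the summed MS signal of its member proteins over the total
  sample signal. Missing signals are distinct from zero and count as
  absent.
- **ETC imputation.** Membrane-embedded ETC subunits extract poorly. A
  subunit missing in strictly more than 20% of samples is imputed per
  sample from the mean signal per unit (MW × subunit stoichiometry) of the
  non-missing subunits of the same complex, scaled by its own MW ×
  stoichiometry. Subunits at ≤ 20% missingness are left untouched; a
  complex with no measured subunit in a sample is skipped and logged.
  Imputation never modifies observed signals.
- **Unit conversion** to µmol·min⁻¹·(mg cellular protein)⁻¹:
  mmol/gCDW/h divides by the organism's protein share of dry mass (0.55
  *E. coli*, 0.44 yeast) and by 60 (note mmol/g ≡ µmol/mg, so no further
  factor); µmol/10⁶cells/h divides by 0.3 mg protein (300 pg/cell) and 60;
  mM/OD₆₀₀/h multiplies by 1000, divides by 192.5 mg protein/L and 60.
  Conversion metadata travels with each measurement. The published check
  values 750 and 390 mM·OD₆₀₀⁻¹·h⁻¹ → 65 and 34 µmol·mg⁻¹·min⁻¹ are
  reproduced.
- **Condition filtering.** Maximal glycolysis comes from fermentable-
  substrate batch cultures, oligomycin-treated, or anaerobic records;
  maximal respiration from non-fermentable-substrate cultures or
  FCCP-uncoupled records, the latter corrected by subtracting the same
  study's antimycin/rotenone OCR (non-mitochondrial oxygen consumption),
  clipped at zero. Oligomycin-minus-antimycin (proton-leak OCR) is not
  subtracted from maximal rates. Rates are converted to glucose
  equivalents (by-products ÷ 2, OCR ÷ 6) before use.
- **Specific activity** Vmax = mean maximal cellular rate / mean proteome
  fraction. Point estimates are unweighted means over sources (the
  aggregator is a package convention); per-source values are retained for
  the bootstrap. φ_totalATP is computed per sample over the union of all
  pathway members (each protein counted once, relevant where Pta-AckA
  shares the glycolytic enzymes) and then averaged — per-sample-then-
  average, one of two defensible orders.
- **Correlated mitochondrial proteins.** The extended respiration
  definition adds mitochondrial proteins whose Spearman ρ against the
  summed core respiration signal is positive with BH-adjusted two-tailed
  p < 0.05 (Spearman chosen as the conventional reading of ρ for rank
  association; BH via statsmodels).
- **No biomass correction** of proteome fractions is applied; the model
  describes energy-directed flux only, and observed glucose uptake is
  reconstructed as O₂/6 + by-product/2, which excludes biomass-directed
  glucose by construction.

## Bootstrap

Each parameter's per-source values are resampled with replacement to their
original size, independently per parameter, and derived quantities are
recomputed exactly as in the original estimation (ratio estimates resample
numerator rates and denominator fractions; φ_totalATP resamples per-sample
union fractions). Intervals are percentile 2.5/97.5 (no bias correction —
matching the plotted mean ± 95% CI convention). Default N = 10,000; the
test suite uses 400–2,000 for speed, which only widens Monte-Carlo noise on
the interval endpoints. Streams are seeded and per-parameter substreams
are spawned in sorted name order, so results are bitwise reproducible and
adding a parameter does not perturb the others' draws. Prediction bands
re-solve the flux model per resample over the glucose grid; the band mean
equals the plug-in prediction only inside linear regimes (near regime
breakpoints Jensen's inequality separates them — documented, not
asserted). Resampling is at the source (study/sample) level.

## Prediction pipeline

Predictions are tabulated over a glucose grid with all regime breakpoints
(φ·Vmax_i) inserted, so piecewise-linear interpolation at observation
uptakes is exact. Observations outside the grid are excluded with a logged
count rather than extrapolated. Correlation diagnostics (by-product rate
vs growth rate, and vs uptake rate) are computed per organism × limitation
group — the comparison that separates glucose availability from growth
rate as the driver of the switch.

## Synthetic data

The generators emulate: (i) absolute-quantification proteomics over a
fixed universe of 11 glycolytic enzymes, 8 TCA enzymes, 4 ETC complexes
with realistic subunit stoichiometries, and 60 lumped background proteins,
with signals mass-proportional within each group and scaled so expected
pathway fractions equal the configured truth; (ii) maximal-rate physiology
under the estimator's condition vocabulary, in a configurable mix of
original literature units with correct conversion metadata (mammalian
truth is emitted as FCCP/antimycin pairs including a non-mitochondrial
offset that must cancel); (iii) observation scatter from a flux model with
an optional growth-rate column either tied to ATP rate or shuffled against
uptake to emulate N/P-limited decoupling.

Noise is multiplicative lognormal with unit mean (CV parameterized), the
positivity-preserving default in the absence of a stated error model. ETC
missingness is missing-at-random per subunit × sample. Default condition
settings used in the recovery tests: 20 proteomics samples, 20
measurements per kind, CV 10% — sample sizes typical of the multi-study
compilations this pipeline is designed for.

What passing tests do and do not show: the generators share the model's
own structure (lumped pathways, exact stoichiometry, independent lognormal
noise), so recovery and coverage results validate the estimation machinery,
not the model's adequacy for real proteomes — real MS data have correlated
extraction biases, isoform ambiguity, and normalization differences across
studies that are not simulated.

## Shipped organism configurations

The three YAML configs fix γ at the canonical constants and set specific
activities to reproduce the published fold-differences of ATP-production
specific activity (γ·Vmax): *E. coli* fermentation/Pta-AckA at 0.54×/2.1×
respiration, anchored at γ·Vmax_resp = 34 µmol ATP·mg⁻¹·min⁻¹ (the
published absolute conversion); yeast at 7.5/4.6 (published absolute
estimates); mammalian at the published 3.1× ratio anchored at a
representative γ·Vmax_resp = 1.8. φ_totalATP is 0.12 for *E. coli* (the
published average; observed range 0.06–0.20), and representative values
0.15 (yeast) and 0.10 (mammalian) where no single published average is
available. Absolute rate scales for yeast and mammalian configs are
therefore ratio-faithful defaults, suitable for regime-structure and
qualitative predictions; users with measured parameters should supply
their own YAML.

## Known limitations

- No kinetic or dynamic modelling; φ_totalATP is constant, although real
  cells modulate it (e.g. under nitrogen limitation), which shifts the
  switch onset proportionally (`phi_sensitivity` quantifies this).
- The yeast respiratory yield is a stored constant (see above).
- Pathway definitions are curated inputs; the package does not infer
  membership from annotation databases.
- The oxygen-constrained variant is a minimal single-constraint extension;
  it does not rescale φ or Vmax under hypoxia.
- MS signals are assumed comparable within a sample (already-normalized
  quantification); no raw-spectrum processing is attempted.
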