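# Methods

## The measurement chain

### GC-C-IRMS reduction (δ13C)

Amino acids are measured as N-acetyl-isopropyl (NAIP) esters, so every
measured peak contains derivative carbon of unknown isotopic composition
plus a kinetic isotope effect from derivatization.  Both are removed
empirically through *correction factors*: for each AA, bracketing
injections of a standard mixture of known (EA-IRMS) composition yield the
effective derivative value

    δ13C_D = (n_DC·δ13C_DC − n_C·δ13C_C) / n_D

and sample peaks are corrected by the inverse mass balance

    δ13C_C = (n_DC·δ13C_DC − n_D·δ13C_D) / n_C

where n_C, n_D, n_DC = n_C + n_D count carbon atoms in the native AA, the
derivative group and the derivatized compound.  The kinetic isotope effect
is wholly absorbed into the empirical factor; no separate term exists.
Working on the delta scale rather than atom fractions introduces errors
below 0.02‰ at natural abundance, far below measurement noise.

The default carbon-count table assumes 2 derivative carbons per acetylated
amine/hydroxyl and 3 per esterified carboxyl (5 for mono-amino
mono-carboxylic AAs, 8 for Asx/Glx, 7 for Lys/Tyr) and is overridable, as
is everything in `isodiet.defaults`.

Before correction, each sample run is anchored on its norleucine spike:
norleucine does not occur in collagen, so the offset between sample Nle and
standard-mixture Nle is an instrumental shift subtracted from every AA in
that injection.  This also removes per-injection drift.

Propagated uncertainty of a corrected value is

    σ² = σ_S²·(n_S/n_C)² + σ_DS²·((n_S+n_D)/n_C)² + σ_DC²·((n_C+n_D)/n_C)²

(S: nonderivatized standard, DS: derivatized standard, DC: derivatized
compound).  The squared count ratios follow by expanding the chained
correction into a linear combination of the three measured quantities; an
unsquared variant of the 2nd/3rd terms, occasionally seen in print, is kept
behind `squared_ratios=False` but disagrees with Monte-Carlo propagation
whenever the ratios differ from 1 (the test suite demonstrates this).

### δ15N

Nitrogen needs no derivatization correction.  Raw values are mapped through
an ordinary least-squares raw→true line fitted across the bracketing
standards (the fit's residual SD joins the output uncertainty in
quadrature) and anchored on the norleucine true value.

### Replicates and uncertainty combination

Reported values are means of triplicate injections; replicate scatter
enters as the standard error of that mean.  Independent error sources are
combined in quadrature throughout (`combine_uncertainty_kragten`), which is
the closed form of spreadsheet-style numerical uncertainty combination for
additive corrections and is validated against Monte Carlo in the tests.
Injections deviating from the triplicate median by more than 3 replicate
SDs are flagged in the reduction report, never dropped; missing triplicates
produce a reduced-n flag and warning.

## Cereal amino-acid prediction

Endogenous AAs cannot be recovered from charred archaeological grain, so
per-AA values are predicted as

    δ_AA(charred) = [δ_bulk(charred) − Δ_charring] + Δ_AA-bulk(modern)

with all three uncertainty components combined in quadrature.  Δ_AA-bulk
offsets are computed from modern grains of the same species group and
pooled across species (prediction is applied identically to δ13C and δ15N;
plants synthesize all AAs de novo, so per-AA fractionation is assumed
predictable relative to bulk).  Default charring offsets are
Δ13C = 0.11 ± 0.10‰ and Δ15N = 0.31 ± 0.30‰, the scale reported by charring
experiments on cereal grain; both are required config values and the
defaults are explicit, not hidden constants.

## The mixing models

### Structure

A consumer's value for signal s (an element–analyte pair) is modelled as

    x_s ~ Normal( Σ_i w_is (v_is + ε_is) + Δ_s + η_s , σ_s² )

* w_is = f_i q_is / Σ_j f_j q_js — *concentration-dependent* weights: a
  source influences a signal in proportion to how much of that signal's
  carrier it contributes, not just its dietary fraction.
* ε_is ~ N(0, τ_is²) — uncertainty of the source baseline values.
* Δ_s ± sd, η_s — diet-to-consumer offset per signal (see routing below).
* σ_s — the measured per-signal uncertainty (must be > 0).
* prior on f: flat Dirichlet(1, …, 1) on the simplex.

### Routing and carriers

| routing | element | dietary-side value v | carrier q (whole-diet basis) |
|---|---|---|---|
| source_direct | C or N | measured source AA value | protein mass × AA share of protein |
| glycolytic | C | carbohydrate δ13C = bulk + carb offset | carbohydrate mass |
| carbon_pool | C | dry-mass-weighted mean macronutrient δ13C | total dry mass (1) |
| nitrogen_pool | N | bulk δ15N of the source's protein | protein mass |
| bulk_protein | C / N | protein δ13C / bulk δ15N | 1 (per unit protein) |
| bulk_scrambled | C / N | carbon-pool δ13C / bulk δ15N | 1 / protein mass |

On the protein basis (models 0p and 1) fractions are shares of dietary
protein, and AA carriers are simply the AA's share of source protein.

Model 1 uses the six source-AA signals measured reliably in ancient
collagen (δ13C of Leu, Val, Ile, Phe; δ15N of Phe, Lys) with a 0 ± 0.5‰
diet-to-consumer offset (fractionation is negligible, < 1‰).  Model 2 adds
Ala (glycolytic carbon), Glx and Asx (pool carbon) and Glx nitrogen
(transamination pool), with trophic offsets as signal-level
diet-to-consumer shifts; defaults are Δ(glycolytic) = 0 ± 1.5‰,
Δ(carbon pool) = 2.0 ± 1.5‰, Δ15N(Glx pool) = 8.0 ± 1.0‰, spanning the
ranges reported across controlled-feeding consumers.  Ser and Gly, though
glycolytic in origin, are excluded from the default model-2 signal set.

A source with zero carbohydrate (meat, fish, oil) cannot supply a
glycolytic value; by default such a source *falls back to the carbon pool*
for that signal (with a warning), carrying its total dry mass as the
carrier — Ala carbon must then come from gluconeogenic precursors.  The
fallback can be disabled, turning the situation into an error.

The olive-oil extension appends a protein- and carbohydrate-free source
whose δ13C is the modern Mediterranean olive-oil value (−29.0 ± 0.8‰ by
default) shifted by +1.9 ± 0.3‰ for the Suess effect (the pre-industrial
biosphere is heavier than today's).  It contributes only to carbon-pool and
fallback signals and has exactly zero weight on every nitrogen signal; it
is valid only in the whole-diet model.

### Food-composition defaults

AA composition tables (g AA per g protein) are supplied for cereal grain,
fish white muscle, terrestrial animal *foods* (muscle/eggs/dairy) and
mammalian collagen.  The terrestrial source deliberately uses the muscle
table: people eat meat and dairy, not collagen, and collagen's extreme
composition (33% Gly, ~2.6% Leu) would starve that source's contribution to
every source-AA signal and render its diet fraction nearly unidentifiable.
The collagen table remains available for studies where the consumed tissue
really is collagen-rich.  Macronutrient compositions (dry weight) default
to cereals 12/85/3, terrestrial foods 60/0/40, fish 75/0/25
(protein/carbohydrate/lipid), and macronutrient δ13C offsets from the
measured bulk tissue follow the established collagen/plant conventions
(e.g. protein = collagen − 2‰, lipid = collagen − 8‰).

### Sampling

The Gaussian nuisances (ε, η) enter the likelihood linearly, so they are
marginalized *exactly*:

    x_s | f ~ Normal( Σ_i w_is v_is + Δ_s ,  σ_s² + sd_Δs² + Σ_i w_is² τ_is² )

The sampler is component-wise random-walk Metropolis on additive-log-ratio
coordinates of f (the flat Dirichlet prior contributes the log-Jacobian
Σ log f_i), with per-coordinate step sizes adapted toward 35% acceptance
during the 5000-iteration burn-in and frozen for the 10000 retained
iterations.  This is algebraically the same posterior as jointly sampling
(f, ε, η); nuisance posterior means are recovered afterwards by exact
linear-Gaussian conditioning and reported alongside the fraction chains.
The kernel is numba-compiled and seeded, so a fit is a pure function of its
inputs; a single chain is run by default.  Acceptance rates outside
[0.05, 0.8] raise a convergence warning in the diagnostics rather than an
exception.  Sources are ordered canonically (sorted by name) inside the
sampler, which makes the output exactly equivariant under reordering of the
source list; *renaming* a source changes the canonical order and hence the
(statistically equivalent) chain.

The posterior mode reported in `map_estimate` is the retained draw with the
highest marginal likelihood; on 3–4-source problems it agrees with a
brute-force 0.01-step simplex grid search within 0.02.

## Cohort statistics

Sex comparisons use each individual's posterior *median* diet fraction —
pooling posterior draws across individuals would fabricate sample size —
with a two-sided Wilcoxon rank-sum test: full enumeration of group
assignments for combined n ≤ 12 (exact with ties, doubled smaller tail),
the exact null distribution for untied samples up to n = 25, and the
tie-corrected normal approximation beyond.  No multiple-testing correction
is applied by default (a Bonferroni flag exists) and the significance level
is 0.05.

## The synthetic-data generator

`SimScenario` defaults encode the study conditions the pipeline targets: 17
consumers (11 male, 6 female); three food groups whose source-AA signals
are separated pairwise by a Mahalanobis-style distance ≥ 3 and whose means
sit in plausible first-century-Mediterranean ranges (marine fish enriched
in both 15N and 13C over terrestrial fauna, C3 cereals depleted in 13C);
sex-specific whole-diet means of (0.485, 0.380, 0.135) for males and
(0.490, 0.430, 0.080) for females (cereals / terrestrial / marine, Dirichlet
concentration 200), chosen so the implied protein-basis marine shares put
males at ~1.6× females with a cohort mean near one quarter and the energy
split near one half cereals / two fifths terrestrial; per-signal
measurement noise uniform in 0.3–1.5‰; triplicate GC injections with
bracketing standards and optional linear drift.  Template sds are on the
standard-error scale — the uncertainty of each group's *mean* baseline —
because that is what a mixing model's source table encodes.

Each cohort draws **one** realization of the true source values (shared by
all individuals: there is one physical baseline), individual
diet-to-consumer offsets, and independent measurement noise.  Consumers are
then generated through the same forward model the sampler assumes, which is
what makes the calibration tests sharp: coverage failures indicate sampler
or model errors, not scenario mismatch.  Conversely, passing them shows
internal consistency only — real data add baseline non-exchange effects,
collagen turnover averaging, diagenesis and inter-laboratory offsets that
the generator deliberately does not model.

## Numerical and design notes

* All generators and fits are pure functions of (inputs, seed); identical
  seeds give bit-identical outputs, including across the CLI (provenance
  records contain no timestamps and only input basenames).
* Degenerate signals (no source carries the carrier) raise an error; a
  simplex vertex that zeroes a signal's total carrier has zero likelihood.
* Missing measurement sds are errors, never imputed; sd = 0 is storable but
  rejected at fit time.
* Posterior medians shrink toward the flat-prior mean (1/K), noticeably for
  fractions far from 1/K under broad posteriors.  One visible consequence:
  a generated male/female marine-protein ratio of 1.6 is recovered on
  average near 1.4 under the default noise conditions.  The credible
  intervals remain calibrated (≈95–100% joint coverage in the recovery
  studies); only point-estimate summaries are attenuated.
* Whole-diet fractions are by dry mass, read as broadly calorific; no
  Atwater conversion is applied.

## Problem sizes used in the shipped analyses

The recovery studies use 100 replicate consumers per model at the default
sampler settings (5000 + 10000 iterations); cohort analyses fit all 17
individuals per model; the grid-search oracle uses a 0.01 simplex step.
These sizes give stable results while keeping the full acceptance run to
well under a minute.
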