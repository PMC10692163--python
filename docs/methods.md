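# Methods

This note records the models, calibrations and design choices behind
`alscreen`, and what the synthetic study conditions do and do not show about
real screening data.

## The synthetic library

Real ultra-large screens enumerate make-on-demand synthon spaces; the
generator mirrors that construction directly. Three packaged fragment sets
of 100 each — acyl acids (A), alpha-amino-acid cores (B) and amine caps (C)
— combine through amide couplings as A–B (free C-terminal acid) and A–B–C
products, giving an enumerable space of 100·100 + 100³ = 1,010,000 unique
molecules. Enumeration is mixed-radix (all A–B first, then A–B–C); a
library of `n_molecules` is a seeded uniform subsample without replacement,
with identifiers equal to zero-padded enumeration indices, so any
(config, seed) pair reproduces bit-identical records. The amino-acid-style
construction deliberately produces an acid-rich, amide-linked, aromatic
library — the chemotype family the emulated screen converged on.

Fragments were chosen with two properties in mind and verified by test,
not tuned afterwards: (1) a clear majority (measured ≈ 85–93%) of products
passes the lead-like filter (MW < 460, logP ∈ [−4, 4], < 4 rings, < 10
rotatable bonds), because the emulated library is lead-like by
construction, with a realistic minority violating single bounds; (2) the
sets span ~100 distinct ring systems/linkers per position, so molecules
sharing no fragment are structurally dissimilar (median pairwise Tanimoto
≈ 0.22 on Morgan 2048/radius-2 fingerprints) — comparable to random pairs
from diverse make-on-demand spaces. An early draft built each set as ten
aryl cores × ten substituents; that library's predicted-top pool collapsed
to ~30 leader classes at the 0.4 similarity ceiling, which is not how a
billion-scale space behaves, and the sets were rediversified before the
module was frozen.

**Descriptor evaluation at scale.** MW, Crippen logP, HBA/ring/rotatable
counts and SMARTS counts are atom-additive with local atom typing, so over
a fixed amide junction the descriptor vector of product (i, j, k)
decomposes exactly as `D(i,0,0) + D(0,j,0) + D(0,0,k) − 2·D(0,0,0)`. The
generator computes ~300 reference products once and reconstructs a million
descriptor vectors by broadcasting — validated against direct RDKit
computation on a spot-check sample at every generation call (and by test to
float precision), with a transparent fall-back to direct computation for
custom fragment chemistries that violate the assumption.

## The scoring oracles

**Tier 1 (docking-like).** `score = μ₁ + σ₁(a·g + b·h)` with
`a = √signal_fraction`, `b = √(1−signal_fraction)`.

* `g` is a fixed monotone transform of a weighted descriptor sum
  (weights: MW −0.002/Da, cLogP +0.10, HBA −0.10, aromatic rings −0.30,
  carboxylic-acid count −0.90 — acids and aromatics score favourably,
  echoing the acid-rich, aromatic-flanked top scorers the screen is built
  to emulate). The raw sum is mapped through its own quantile distribution
  over the *full enumerable space* (computed once per synthon-set identity,
  midranks for ties) and then through the normal inverse CDF, so `g` has an
  exactly standard-normal marginal over the library. A bounded
  transformation (e.g. tanh) was considered and rejected: it thins the
  lower tail and breaks the extreme-quantile calibration below.
* `h` is a standard-normal deviate derived from a 64-bit BLAKE2b hash of
  (identifier, seed, tier) — deterministic, platform-stable, no global RNG.

Because `h` is independent of the molecule's `g`, the score marginal is the
convolution of two standard normals scaled by `a` and `b`: exactly
Normal(μ₁, σ₁²). Defaults μ₁ = −5.70 and σ₁ = 0.887 kcal/mol solve
μ₁ + z(10⁻⁴)·σ₁ = −9.0 with z(10⁻⁴) = −3.719: the top 0.01% of scores sit
below −9 kcal/mol, the hit threshold used throughout. `signal_fraction`
defaults to 0.64 — the share of score variance a perfect
structure-based regressor could explain.

**Tier 2 (binding-energy-like).** Standardised latent
`z₂ = ρ·z₁ + √(1−ρ²)·ε` with an independent hash deviate ε, rescaled to
μ₂ = −40, σ₂ = 8 (a plausible end-point energy scale; location/scale are
arbitrary and only affect reporting units). ρ defaults to 0.42, the global
correlation between the two scoring tiers being emulated. Population
correlation is exactly ρ; the n = 10⁴ sample estimate carries standard
error ≈ (1−ρ²)/√n ≈ 0.008.

The oracles are *partially* faithful stand-ins: they reproduce the score
distribution, the tier correlation, a learnable structure–score
relationship and deterministic rescoring, but not pose physics, chemotype-
specific docking pathologies, or heteroscedastic docking noise. Campaign
results on them demonstrate the machinery and its statistical properties,
not absolute virtual-screening performance on any real target.

## Surrogate model

Featurisation is the Morgan fingerprint (2048 bits, radius 2). The default
regressor is a leave-one-out cross-validated ridge (penalty grid 10⁻¹…10²,
16 points): the oracle's learnable signal is additive over fragments, so at
the training sizes an active-learning round produces (75–450 molecules) the
linear inductive bias recovers fragment-level structure far more
efficiently than a neural network — measured at n = 225, library-wide
correlation with truth 0.69 (ridge) vs 0.59 (MLP) — while still reaching
held-out Pearson R² ≈ 0.6 at n = 10⁴ (the acceptance bound is > 0.4 at
signal_fraction 0.64). An MLP backend (one hidden layer of 64, adam,
batch size 128, early stopping patience 10 for n ≥ 500) is provided behind
the same contract, and the interface accepts any fit/predict regressor.
Training always reports the Pearson R² of a seeded 90/10 held-out split;
retraining with identical data, config and seed is bit-reproducible. On
pure-noise oracles (signal_fraction 0) held-out R² measures ≈ 0.001 — the
surrogate does not hallucinate signal.

**Atom attribution** follows an atom-removal scheme: contribution of heavy
atom *i* = prediction(molecule) − prediction(molecule with atom *i* and its
bonds deleted). Deletion applies no valence repair, and all remaining
fragments are featurised together as one unit, so no attribution mass is
lost to fragment truncation. Hydrogens are not attributed; single-heavy-atom
molecules are rejected. Attribution is invariant to input atom numbering
because records canonicalise SMILES on construction.

## Screening campaign

The default schedule expresses the reference protocol as library
fractions so a 200k desk library runs the same shape as a 2.654-billion
one: round 1 random 1/2654 of the library; rounds 2–3 diverse selection
(leader filter, Tanimoto < 0.4) from the top 0.0377 of surrogate
predictions (0.0377 ≈ 100M/2.654B), 1/2654 each; round 4 greedy, 3/2654.
After each round the surrogate retrains on everything scored. Scored
molecules are excluded from later pools (the natural reading of the
protocol; configurable per round). All sorts and top-k selections break
ties by (score, lexicographic id), making campaigns bit-reproducible.

Two desk-scale realities are worth naming. First, the leader filter can
exhaust the predicted-top pool before reaching the nominal batch size (the
pool holds fewer than `acquire_size` similarity classes); the round then
acquires what exists and logs a shortfall, so realized budgets at 200k are
~360–430 rather than the nominal 452. Second, with only ~20 true hits in a
200k library and a few hundred training molecules, per-seed hit counts are
small integers: measured over ten seeds the campaign averages ≈ 1.3 hits
below −9 kcal/mol against an expected ≈ 0.04 for equal-budget random
screening (a ~30× enrichment in expectation; individual seeds range
0–4). The paper-scale campaign trains on 10⁴× more scores, so its much
deeper recall does not transfer to desk scale and is not claimed.

**Recall bootstrap.** The initial round is a uniform sample, so the number
of sub-threshold scores in a resample-with-replacement is exactly
Binomial(n, k/n); the bootstrap draws B = 1000 such counts (seeded),
converts to library totals, and takes the 2.5/97.5 percentiles.
Recall = found/T̂ with the CI endpoints mapped through (upper total → lower
recall) and clamped to [0, 1] only in the reported recall. Zero sample hits
make recall unidentifiable and raise. Coverage is verified by simulation:
≥ 90% of 95% CIs cover the true recall across ≥ 50 synthetic screens.

## Tier-2 rescoring campaign

Four stages over the tier-1 ledger: (A) a Tanimoto < 0.4 leader seed set of
the tier-1 hits (< −9), best score first — the seed-set size is emergent,
as in the protocol being emulated; (B) a loop of train-on-tier-2 →
predict over remaining hits → take the best `loop_pool` → leader-select
`loop_batch` against everything scored or selected → score, until
`loop_total` tier-2 scores exist; (C) best-predicted `stage_c_pool`,
filtered to fewer than two carboxylic-acid groups, diversity-selected to
`stage_c_keep`; (D) eligibility relaxed to tier-1 < −4, lead-like-filtered,
diversity-selected to `stage_d_count`. The reference counts
(200/1500/1700/4000/800/522) are configuration defaults; `RescoreConfig.scaled`
rescales them by a library fraction with floor 1, because multiplying them
by a 200k/2.654B fraction literally would yield sub-single-molecule stages.
If too few tier-2 scores exist to train the surrogate, stages rank by
tier-1 score with a warning rather than failing. The acid filter
eliminating the whole stage-C pool is an explicit error.

## Enrichment metrics

ROC AUC uses the Mann–Whitney formulation on ranks (ties count ½), with
lower scores better throughout. RIE is
`[(1/n)·Σ_actives e^(−α·rᵢ/N)] / [(1/N)(1−e^(−α))/(e^(α/N)−1)]`, ranks
from best = 1, ties broken by the global (score, id) tie-break. The
denominator is the exact uniform-rank expectation, so random rankings give
1 in expectation (verified by permutation). Default α = 20, the
conventional early-enrichment emphasis (~top 8%); the emulated study does
not state its α.

## Pose density grids

Feature atoms are the first atom of each unique SMARTS match (the
carboxylate carbon for acids, the sulfur for sulfones, the atom itself for
single-atom selections such as aromatic atoms and H-bond donors/acceptors;
donors are `[N,O;!H0]`, acceptors N/O excluding amide N — the conventional
definitions, since the emulated analysis names the classes but not their
SMARTS). Each atom increments its half-open voxel
`floor((coord − origin)/spacing)`; default spacing 0.5 Å with a 2 Å
bounding-box pad. Binned + overflow counts equal total matched atoms
exactly. Optional Gaussian smoothing (off by default) renormalises after
filtering so total mass is conserved to 1e−6 relative; grids export as
OpenDX scalar fields (z fastest) readable by common viewers. The pose
generator's fixture mode translates each molecule's first feature atom to
within 0.5 Å of a declared hotspot, giving grid tests a known maximum; its
conformers are single ETKDG embeddings, not docking poses.

## Assay analysis

* Fluorescence slopes: OLS of (signal − background) vs time, SE from the
  regression; ≥ 3 strictly increasing time points required.
* Calcein-AM efflux: `1 ÷ (m_compound/m_control)` — i.e.
  m_control/m_compound; equal slopes give exactly 1, a zero compound slope
  is an explicit error and near-zero slopes warn.
* Dose-response: the GraphPad-style three-parameter logistic
  `Y = Bottom + (Top−Bottom)/(1+10^(X−LogIC50))`, X = log₁₀(µM).
  Initialisation: Top/Bottom from the plateau responses, LogIC50 from the
  concentration nearest their midpoint; Levenberg–Marquardt with tight
  tolerances (≤ 500 evaluations); SEs from the residual-variance-scaled
  Gauss–Newton covariance. The parameterisation permits Top < Bottom, so
  stimulation-shaped data fit without special-casing. The predicted
  response at X = LogIC50 is identically (Top+Bottom)/2. Rescaling
  concentration units shifts LogIC50 by the corresponding constant.
  Calibration (100 seeded noisy curves at 5% noise): mean LogIC50 bias
  < 0.02, ≥ 90% coverage of ±1.96·SE intervals.
* ATPase: absorbance (740 nm) → nmol Pi through a linear standard curve
  (least squares, free intercept; non-positive slope is a calibration
  error), normalised by reaction time and protein, vanadate condition
  subtracted. Negative sensitive activities are reported as-is with a
  warning — they occur in real plates.

## Problem sizes and numerical choices

Default desk-scale library: 200,000 molecules (stands in for 2.6 B; all
schedule sizes are fractions, so absolute counts map proportionally).
Calibration checks use 10⁶ molecules (extreme quantile; sampling SE ≈
0.02 kcal/mol at the 10⁻⁴ quantile) and 10⁴ (tier correlation).
Bootstrap B = 1000 (percentile CIs). Statistical suite sizes (60 simulated
screens, 100 dose-response replicates, 5 campaign seeds) were chosen to
keep Monte-Carlo error well inside the asserted margins. Degenerate inputs
are total-function choices, not errors, where a caller could reasonably hit
them: 0/0 Tanimoto ≡ 0, empty diverse-selection input → empty output,
shortfall pools → warning + whole pool.

## Known limitations

* The oracles are statistical emulations; no conclusions about real
  docking accuracy, pose quality, or specific chemotypes transfer.
* The library's 300 fragments cannot represent the true scaffold breadth
  of make-on-demand spaces; absolute hit counts and similarity statistics
  are library-specific.
* Protonation states and stereochemistry are not enumerated; structures
  are taken as written.
* Desk-scale campaigns train surrogates on hundreds (not millions) of
  scores; recall and enrichment magnitudes are correspondingly smaller
  than billion-scale campaigns and are validated as *properties*
  (enrichment over random, CI coverage), not as absolute rates.
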