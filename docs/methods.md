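# Methods

## The model

`mompdose` treats commitment to mitochondrial apoptosis as a threshold
phenomenon governed by the BCL-2 protein family.  Chemotherapy-induced
genotoxic stress is abstracted as a bolus of BH3-only protein delivered
at *t* = 0 — part direct **activator** (BIM/PUMA-like, engages BAX and
BAK catalytically and binds all three anti-apoptotic proteins) and part
MCL-1-selective **sensitizer** (NOXA-like).  The summary statistic for a
sample is its **stress dose**: the smallest bolus (nM) whose trajectory
reaches mitochondrial outer membrane permeabilization (MOMP) within the
stress window.  A higher stress dose means a more apoptosis-resistant
tumour.

The reaction network (mass action, concentrations in nM, time in h)
contains 27 species and five reaction classes:

1. **Activation** — `A + BAX_i -> A + BAX_a` at rate `k_act·A·BAX_i`
   (catalytic; membrane translocation is folded into the activation
   step), and likewise for BAK.
2. **Sequestration** — reversible binding `X + P <-> XP` for every
   anti-apoptotic `X ∈ {BCL-2, BCL-xL, MCL-1}` and partner
   `P ∈ {A, N, BAX_a, BAK_a}`, with shared on-rate `k_on` and off-rate
   `k_on·Kd(X, P)`.  Pairs that do not interact biologically carry a
   sentinel Kd of 10⁹ nM.
3. **Drug binding** — `X + D <-> XD` with the drug's per-target Kds.
   The drug is present from *t* = 0 for the whole window with no
   clearance; drug mass is conserved.
4. **Pore formation** — irreversible homo-dimerisation
   `2·BAX_a -> pore` at `k_oligo·BAX_a²`, likewise for BAK.
5. **Turnover** — first-order decay of the free stress species A and N
   at `k_deg_bh3`.

MOMP is called when the pore fraction
`(2·pores_BAX + 2·pores_BAK)/(BAX_tot + BAK_tot)` crosses
`momp_threshold`.  The threshold is a modelling choice (no quantitative
pore criterion is established experimentally); 10% of total effector
protein in pores is used throughout.

The stress bolus is split 80% activator / 20% sensitizer.  Samples
flagged p53-non-functional cannot induce the NOXA/PUMA arm and receive
the entire dose as activator.

### Interaction Kd matrix (nM)

|          | activator | BAX_a | BAK_a | sensitizer |
|----------|-----------|-------|-------|------------|
| BCL-2    | 10        | 20    | —     | —          |
| BCL-xL   | 5         | 20    | 50    | —          |
| MCL-1    | 10        | —     | 10    | 10         |

("—" = non-binding.)  Only the ordinal selectivity pattern is asserted
(MCL-1 guards BAK and is the sole NOXA target; BCL-2 guards the
activator and BAX); absolute affinities act through the calibrated
kinetics below.

### Default kinetics and why

| parameter        | default | units      | role |
|------------------|---------|------------|------|
| `k_on`           | 1e-4    | nM⁻¹ h⁻¹   | shared association rate |
| `k_deg_bh3`      | 1.0     | h⁻¹        | BH3-only turnover (t½ ≈ 42 min) |
| `k_act`          | 3e-4    | nM⁻¹ h⁻¹   | activation; **free, calibrated** |
| `k_oligo`        | 1e-4    | nM⁻¹ h⁻¹   | pore formation; **free, calibrated** |
| `momp_threshold` | 0.10    | —          | pore fraction calling MOMP |
| `horizon`        | 12      | h          | stress window |

The slow association rate and fast BH3 turnover place the network in a
*kinetic race* regime: anti-apoptotic buffering is only partially
efficient (each nM of guardian absorbs well under 1 nM of stress before
the MOMP decision), and a finite intrinsic activation floor remains
even when every guardian is drugged.  This regime is what makes the
published dose pattern reproducible at all: the BCL-2-high reference
sample carries 5772 nM of BCL-2 yet needs only a 4271 nM baseline
bolus, and at 10 µM ABT-199 — which occupies essentially all BCL-2
(Kd 0.01 nM) and most BCL-xL/MCL-1 (48/444 nM) at equilibrium — its
stress dose falls to ~1.3–1.5 µM rather than collapsing to zero.  In a
capacity-dominated regime (fast `k_on`, slow turnover) neither number
can be matched: the baseline would exceed the BCL-2 content alone and
the treated dose would drop to a negligible floor.  Short BH3-only
half-lives (<1 h for NOXA, a few hours for PUMA) and sub-diffusion
cytosolic association are biologically defensible; we treat the pair
(`k_on`, `k_deg_bh3`) as fixed network wiring and calibrate only
(`k_act`, `k_oligo`).

### Reference profiles and calibration

The two reference colorectal PDX archetypes fix BCL-2 at its measured
absolute level (5772 nM for CRC0076, 1980 nM for CRC0344).  The other
four proteins were not published as numbers; the package's documented
defaults express the archetype contrast at CRC-typical levels —
CRC0076 (BCL-2-high): BAK 1000, BAX 1800, BCL-xL 600, MCL-1 700 nM;
CRC0344 (BCL-xL-high): BAK 1500, BAX 1500, BCL-xL 1800, MCL-1 600 nM —
and can be overridden from a profile CSV.

`StressDoseCalibration` minimises the sum of squared log-errors between
computed and target baseline stress doses over
(log₁₀ `k_act`, log₁₀ `k_oligo`) by Nelder–Mead from the defaults
(budget 200 iterations); log space respects the doses' dynamic range.
With two contrasting profiles and two targets the optimum is a
near-exact fit (residual ~1e-8); the fitted constants are frozen in
`reference_parameters()` and re-derived from scratch by the test-suite
and the acceptance script.  Two free constants against two targets is a
deliberate identifiability choice — the MOMP threshold stays fixed.

### Numerics

* Integrator: LSODA (stiff-capable) with analytic Jacobian assembled
  from the reaction stoichiometry, `rtol` 1e-8, `atol` 1e-6 nM, dense
  output; the MOMP crossing is located by the integrator's event
  root-finding on the dense solution.
* Family mass (BAX, BAK, each guardian, drug) is conserved to ≤1e-6
  relative over the window; the stress species decay by design and are
  not conserved.
* Stress-dose search: bisection on MOMP occurrence over [0, 10⁶] nM to
  a 1 nM bracket (published doses are integer nM), max 40 iterations.
  MOMP occurrence is monotone in the bolus, so an ascending 1 nM grid
  scan is an exact independent oracle; warm-started brackets (used
  inside calibration and dose-response sweeps) provably contain the
  boundary and return the same answer.
* The binding-only subsystem has a closed-form-anchored competitive
  equilibrium (damped fixed point on the free ligand pools) used as an
  oracle for the long-time ODE limit with activation, pore formation
  and decay switched off.
* Degenerate inputs: a profile with no anti-apoptotic protein is
  drug-insensitive by construction; a zero bolus can never reach MOMP;
  if MOMP does not occur at the bracket ceiling the result reports
  `bracket_ceiling_hit` rather than a number.

## Sensitisation metrics

From a dose–response curve (default drug grid 0, 0.1, 0.5, 1, 2, 5,
10 µM spanning the therapeutic window), sensitisation is summarised as
absolute and relative stress-dose reduction versus the zero-drug
baseline.  The combination-benefit flag marks a relative reduction of
at least τ = 0.33 — a package-defined cutoff, as no numeric criterion
for "sensitised" is established.

## Protein quantification

Blot densitometry is converted to absolute nM by background
subtraction, normalisation to the in-lane loading control, and scaling
by a standard cell line (HeLa by convention) with known absolute
levels.  Replicate lanes are averaged after normalisation; negative net
band intensities clamp to zero with a warning.  PUMA/BIM are reported
as extras and never enter the five-protein model input.  Standards are
global by default (per-gel grouping can be layered on by splitting the
input table).

## Synergy analysis

Viability matrices are normalised to the in-plate untreated control,
converted to fraction affected with clamping to [0, 1], and the two
single-agent margins fitted with four-parameter logistic curves
(deterministic quantile-based initialisation).  Combination points are
scored by the Loewe combination index
`CI = d_c/D_c(fa) + d_d/D_d(fa)` with `D_x(fa)` from closed-form curve
inversion; CI is reported at fa ∈ {0.25, 0.5, 0.75} along with
isobologram intercepts.  Loewe additivity is used as the null model (a
sham combination scores exactly 1); points whose fa is unreachable by a
margin are reported with a reason, never dropped.

## Preclinical metrics

* Caliper volume `4/3·π·(d/2)²·(D/2)` (minor axis d, major axis D).
* SUV: voxel activities are decay-corrected to injection time
  (`×2^(Δt/t½)`, t½ = 109.77 min for ¹⁸F) before normalisation by
  injected dose per body weight; tissue density is taken as 1 g/mL so
  SUV is dimensionless.  SUVmean averages the VOI; SUVmax averages the
  four most intense voxels with a deterministic value-then-index
  tie-break.  Applying the decay correction to voxel values before SUV
  is algebraically equivalent to correcting the dose term.
* Allred score: per-observation proportion (0–5) + intensity (0–3),
  summed then averaged; Ki-67 index: stained / total × 100.
* Paired pre/post response tests use the two-sided paired t-test;
  zero-variance differences are reported explicitly (identical vectors
  give t = 0, p = 1; a constant non-zero shift is flagged degenerate).
  Family-wise error across groups is controlled by step-down Holm.

## Radiomics pipeline

Shape features are removed first (conserved in subcutaneous models).
The stratified 80:20 split precedes all data-driven filtering, so
correlation pruning and RFE see only the training cohort.  Correlation
pruning removes, while any remaining pair exceeds |Spearman ρ| > 0.85,
the offending feature with the highest *mean* |ρ| to the remaining
features (mean rather than max, stated as a package choice; exact ties
drop the lexicographically later name).  Constant features have
undefined ρ and are treated as uncorrelated with a warning.  RFE ranks
features by random-forest importance, recursively refitting down a
size ladder, and scores candidate sizes by 5-fold × 3-repeat
cross-validated accuracy (folds re-rank features internally to avoid
selection bias); the smallest size within numerical tie of the best
mean accuracy wins.  The held-out cohort is scored by ROC-AUC with a
DeLong 95% CI — with a 9-sample validation cohort the interval is
expected to be very wide (spanning most of [0.4, 1] even at AUC 0.8),
which is the honest uncertainty at this cohort size.  A 9-sample
cohort cannot be split 50:50 by class; near-balance (5:4) is accepted
and visible in the split counts.

## Synthetic data: what it emulates, and what it does not

* **Protein profiles**: lognormal measurement noise (geometric sd
  `exp(0.25)`) around the two archetypes, anchors included verbatim so
  the exact reference inputs are always present.  Real PDX cohorts have
  correlated protein co-expression; the generator draws proteins
  independently.
* **Dose matrices**: 6×6 Hill-consistent surfaces with a controllable
  Loewe index (margins follow the plain single-agent curves; a
  combination never scores below its stronger margin) plus Gaussian
  viability noise.  Plate effects and edge artefacts are not modelled.
* **PET phantoms**: ellipsoidal tumour at exact SUV with optional hot
  voxels and noise; no partial-volume effect, scatter or reconstruction
  artefacts.
* **Feature tables**: 45 samples × 833 features mirroring the study
  design — 7 informative features at a 2-sd class shift, latent-factor
  blocks whose within-block |Spearman ρ| exceeds the 0.85 cutoff by
  construction, near-constant shape features, optional drifted post
  timepoint.  Real radiomic features have heavier tails and
  family-structured correlation; passing tests therefore demonstrate
  pipeline correctness and seeded determinism, not field performance
  on real CT data (the printed AUC of 0.80 requires the original
  scans, which are not deposited).
* **Growth curves**: exponential per-animal growth from 360 mm³ with
  group-specific rates, converted to caliper axes that invert the
  volume formula exactly.

## Problem sizes used by the test-suite and acceptance script

Oracle comparisons run on low-concentration random profiles
(anti-apoptotics 10–120 nM, effectors 150–500 nM) with fast-activation
kinetics so stress doses land near 40–60 nM and a 1 nM ascending scan
is exact and cheap.  Conservation and monotonicity checks use 20–50
random draws; the radiomics study runs at the full 45 × 833 scale; the
permutation null uses 10–20 relabellings.  These sizes are the
package's desk-scale defaults and are stated here so results are
reproducible as printed.

## Known limitations

* The network is a minimal mechanistic wiring of the stress-dose
  concept, not a re-derivation of any previously published rate
  constants; absolute stress doses are meaningful only relative to the
  calibration anchors.
* The stress bolus is instantaneous; transcriptional induction
  kinetics of BH3-only proteins under specific drugs are out of scope.
* The drug is modelled at constant total concentration (no
  pharmacokinetics).
* The treated-dose prediction inherits the archetype defaults for the
  unpublished protein levels; with supplementary-transcribed profiles
  the calibration and prediction should be re-run.
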