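# Methods

This note documents the models and estimators implemented in `crestmig`, the
defaults and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The assay and its simulation

### Well model

A cMINC well is simulated as follows (`synthetic.simulate_well`):

1. `n_cells_seeded` cells are placed uniformly in the image field, excluding
   the circular exclusion zone (the stopper footprint).
2. Each cell may divide once with probability
   `proliferation_rate × (1 − cytostasis(c)) × migration_hours/48`;
   in AraC mode the probability is zero. Daughters start at the division
   site, and both parent and daughter are EdU-positive. Division is resolved
   before the walk, so daughters traverse the full window — a simplification
   that slightly overstates daughter dispersal but cancels in all
   control-normalized readouts.
3. Every cell performs a memoryless isotropic Gaussian random walk for
   `migration_hours × 60 / frame_interval` steps with per-axis step SD
   `base_step_px × m(c)`. For endpoint wells only the final position matters,
   so the walk's net displacement is drawn from its exact law
   N(0, n_steps·σ²) per axis; the per-frame track simulator
   (`simulate_tracks`) draws every step. Positions are clipped to the field.
4. A fraction `death_fraction` of cells is flagged non-viable whenever
   c > 0 (a plain cytotoxicity fraction, not a Hill term; type-I interferon
   effects in this assay are cytostatic rather than cytotoxic, so the default
   is 0). Controls are always death-free.
5. Ground truth records all positions, viability and EdU flags, and
   `n_in_zone_true` — viable cells strictly inside the zone.

There is no cell–cell exclusion or contact inhibition: for count statistics
at these densities the independent-walk approximation is adequate, and it
keeps the in-zone count linear in the step size (so the expected migrated
count is proportional to the migration capacity m(c) while the 48-h diffusion
length stays well below the zone radius — the regime of the default
geometry). The generators are pure functions of (parameters, seed).

### Drug action

`DrugEffectModel` carries three independent Hill terms:
migration inhibition `emax_mig·c^h/(c^h + ec_mig^h)` (capacity
m(c) = 1 − inhibition), cytostasis with the same form, and the constant
death fraction. Keeping the terms independent mirrors how the assay separates
them experimentally: co-treatment with the mitosis blocker AraC removes the
proliferation term so that migration effects can be read out cleanly. The
default cytostatic potency is 10× weaker than the migrastatic one, matching
the scenario the validation suite probes.

### Geometry defaults and their calibration

Defaults (`SimulationConfig`): 2000×2000 px field at 1.3 µm/px (a 2.6 mm
square, typical of a low-magnification high-content reader), zone radius
770 px (~1 mm — the 2 mm-diameter footprint of commercial exclusion-zone
stoppers), 3400 cells in the visible field (≈95,000 cells/cm² seeding
density outside the stopper), `base_step_px` 4.5 px per 15-min frame
(≈0.4 µm/min mean speed, realistic for NCC). Two consequences matter:

* the 48-h diffusion length (~62 px RMS per axis) is small against the zone
  radius, so the zone remains a clearly visible partially-filled void at
  48 h, as in the real assay;
* the expected migrated count in a control well is a few hundred cells,
  giving usable counting statistics per well.

An earlier draft with a 300 px zone and 10 px steps made the zone nearly
fill in at 48 h; centre localization was then information-limited (an
oracle-weighted M-estimator could not do better than ~13 px mean error) and
unlike the assay. The defaults above are therefore calibrated to the
physical assay rather than chosen for convenience.

### Exposure schedules (rescue window)

`effect_of_schedule` models time-of-addition experiments in which a JAK
inhibitor terminates interferon signalling at `inhibitor_add` hours. The
active-signalling duration D = min(ifn_stop, inhibitor_add) − ifn_start is
mapped to a ramp: 0 for D ≤ 6 h (full rescue), 1 for D ≥ 10 h (full
modeled inhibition), linear in between. The linear ramp is a deliberate
minimal-assumption choice: the experiments bracket the commitment point only
between 6 and 10 h, so any monotone interpolation is equally defensible and
the floor/ceiling are configurable. Consequence worth noting: with the ramp,
the *classified* rescue boundary (inhibition < 25%) can sit slightly above
6 h when the full-exposure inhibition is far above 25% — additions at 6 h
are always rescuing by construction, additions at 10 h always impairing.

### Expression simulator

`simulate_expression` builds a lot-paired design (each lot one treated + one
control column): per-probe baselines N(7, 2²) on the log₂ scale, a shared
lot shift (SD 0.3), and per-probe paired-difference variances drawn from a
scaled inverse-chi-square d₀s₀²/χ²(d₀) with d₀ = 4 and s₀ = `sd_log2` — so
the hierarchical variance structure the moderated t assumes is genuinely
present and its hyperparameters are recoverable. Planted probes shift by
±`effect_log2` in the treated arm. The simulator does not model probe-level
correlation, array-wide intensity-dependent trends, or normalization
artifacts; passing tests therefore demonstrate correctness of the inference
chain on clean paired data, not robustness to normalization failures.

## 2. Image quantification

* **Nuclei detection**: multiscale Laplacian-of-Gaussian blob detection
  (scikit-image), sigma range 1.5–3 px bracketing the rendered nuclear sigma
  of 2 px, relative response threshold 0.10, overlap suppression, then a
  global intensity gate — Otsu by default, floored at background + 6 robust
  (MAD-based) SDs so that a signal-free image yields zero detections rather
  than Otsu splitting the noise. Detections are sorted by (y, x);
  everything is deterministic. The residual error at moderate density is a
  small undercount from genuinely merged nuclei (closer than ~2 sigma).
* **Viability**: mean calcein intensity in a 4 px disk at each centroid,
  thresholded by Otsu over the calcein channel (default; robust when nearly
  all cells are viable) or over the per-cell values (`cal_policy="cells"`,
  for strongly mixed live/dead populations), or a numeric override. A cell
  is viable iff its disk mean is at or above the threshold, so raising the
  threshold can only shrink the viable set.
* **Zone localization**: the stopper radius is a known assay constant; only
  the centre is estimated. Stage 1 minimizes a kernel-smoothed inside-count,
  Σᵢ Φ((R − dᵢ)/bw) with bw = R/10, over a coarse grid of valid centres
  (circle fully inside the field) with shrinking local refinement; ties go
  to the centre nearest the image centre, then lowest y, then lowest x; the
  detection list is sorted first so the result is order-invariant. Stage 2
  polishes by radial-profile maximum likelihood: the radial density profile
  around the current centre is histogrammed (40 bins to 1.6 R), smoothed,
  forced monotone non-decreasing (migration fill can only increase toward
  the boundary), and a damped Newton step is taken on the
  inhomogeneous-Poisson log-likelihood, whose per-cell weight is
  (log F)'(rᵢ). This uses the whole fill gradient instead of only the
  nominal boundary and roughly halves the centre error when the zone is
  substantially re-populated. `refine=False` restores the plain grid search.
* **Contrast QC**: contrast = (cell density outside)/(density inside + ε);
  a uniform field scores ≈1 and is flagged below the floor (default 1.5).
  The flag is a warning, never an error.
* **Counting**: `n_migrated` counts viable detections strictly inside
  (Euclidean distance < R); boundary detections are excluded. Centroids are
  sub-pixel and compared in floating point.

## 3. Dose–response statistics

* Normalization: each well / same-plate control mean × 100. Migration uses
  `n_migrated`, viability `n_viable_total`.
* ANOVA + Dunnett: scipy's Dunnett implementation (multivariate-t Monte
  Carlo) with a fixed internal seed so results are reproducible; at its
  sample size the p-value Monte-Carlo error is ~2×10⁻³. For familywise
  calibration studies, `dunnett_critical_value` simulates the null law of
  max|tᵢ| = max|(Zᵢ − Z₀)/(√2·S)| directly (200,000 draws), since the
  rejection rule "any adjusted p ≤ α" is equivalent to max|tᵢ| exceeding
  that quantile.
* LOAEL: smallest tested concentration with adjusted p ≤ α *and* mean below
  control — directionality keeps significant increases from qualifying.
  Absent such a concentration the result is "none detected".
* EC75: first downward crossing of 75% of control, interpolating the mean
  response linearly in log₁₀(concentration) between the bracketing tested
  concentrations; the control (0 pM) is excluded from the log axis. A mean
  exactly at 75% returns that concentration; a curve already below 75% at
  the lowest tested concentration returns that concentration; a curve never
  below returns "> max tested". Interpolation is the default because it is
  assumption-light and monotone-safe on 6-point curves; a descending Hill
  fit (`method="hill"`) is available when a parametric estimate is wanted.
  Non-monotone curves are not monotonized — the first crossing counts.
* Impairment classification: migration < 75%, viability < 90% of control,
  both strict, so boundary values are unflagged; "migration-specific" =
  migration flagged while viability is not. When endpoint curves from
  replicate runs are aggregated, the rules apply to the per-concentration
  endpoint means — single runs can dip below a line by replicate noise
  alone (at 5% CV a ~2.4σ event per concentration).
* Transwell: replicate value = mean of its imaged fields; condition summary
  = mean ± SD over replicates; Welch t-test vs control.
* Proliferation: 100 × EdU⁺ / Hoechst⁺ nuclei.

## 4. Track metrics

Accumulated distance = Σ Euclidean steps × pixel size; mean speed =
accumulated distance / (spanned frames × frame interval). Single-frame gaps
are bridged (the straight step then spans two intervals — distance is the
chord, time is honest); longer gaps split the track rather than fabricating
path length. Statistics use the well as the replicate unit (mean of its
tracks) to avoid pseudo-replication, with per-track testing behind
`unit="track"`; the headline comparison is Welch's t between control and the
highest concentration, with a one-way ANOVA across all concentrations
reported alongside. Conditions with fewer than 10 tracks are flagged
invalid (assay convention). Metrics are invariant under rigid motions and
scale linearly with pixel size and inversely with frame interval.

## 5. Differential expression

Only the paired one-sample design is implemented — each lot contributes one
treated and one control sample and inference is on the per-probe paired
differences — because that is the design this assay family uses; there is no
general linear-model layer. Hyperparameters (d₀, s₀²) come from closed-form
method of moments on z = log s²: matching the mean and variance of
e = z − ψ(d/2) + log(d/2) gives d₀ via the inverse trigamma (Newton) and s₀²
in closed form; when the observed spread of z does not exceed the
chi-square contribution, d₀ = ∞ and all probes share exp(mean e).
Zero-variance probes are excluded from the moment fit and receive the prior
variance through the posterior formula. d₀ = 0 reproduces the ordinary
paired t exactly; d₀ = ∞ gives a fixed-variance z-like statistic. The test
suite cross-checks t, p and d₀ against R limma's `eBayes` to ~1e-8.

BH adjustment is the literal step-up (vectorized; validated against a
brute-force implementation and statsmodels). DEG gates are inclusive:
up ⇔ FC ≥ 1.8 ∧ p̃ ≤ 0.05, down ⇔ FC ≤ 0.55 ∧ p̃ ≤ 0.05.

Enrichment is the one-sided hypergeometric upper tail on the 2×2 table
(set ∩ universe vs DEG list), BH-adjusted across sets, up- and
down-regulated lists analyzed separately. Probe→gene mapping is a
user-supplied two-column table; gene sets are plain GMT; KEGG-style pathway
enrichment is the same machinery over a different set file, with no
topology logic. The superordinate rollup distributes significant sets over
the six classes via a user map (duplicates rejected; unmapped sets fall to
"others").

## 6. Problem sizes used in validation

The acceptance suite uses: 50 rendered wells (1024² px, 350 cells, 10%
planted non-viable) for the counting oracle; 100 default-geometry wells
spanning capacities 0.25–1 for zone recovery; 200 simulated 6×3 plates at
5% CV for EC75 recovery plus 20 AraC plates for the endpoint separation;
10,000 global-null layouts (6 groups × n = 3) for Dunnett calibration;
1,000 random vectors for BH; 20,000-probe matrices over 20 seeds for the
moderated-t operating characteristics. These sizes give stable Monte-Carlo
estimates while keeping a full run to a few minutes on one CPU.

## 7. Known limitations

* The renderer produces idealized images: Gaussian nuclei, uniform calcein
  disks, flat background, additive Gaussian noise — no illumination
  gradients, photobleaching, debris, or out-of-focus blur. Detection
  parameters tuned here will need re-tuning for real microscopes.
* No phase-contrast rendering, automated tracking from images, or
  transcriptome kinetics; tracks and expression matrices come from their
  own generators.
* The walk model has no persistence or chemotaxis; speed distributions of
  real NCC are heavier-tailed than Rayleigh.
* EC75/LOAEL are the only potency summaries; no benchmark-concentration
  modeling, no mixed-effects plate models.
* The enrichment contract is classic Fisher over-representation; no
  conditional/elim-style GO algorithms.
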