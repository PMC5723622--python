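# Methods

## Problem and model

`bambooclim` estimates where invasive running bamboos (*Phyllostachys
edulis* and *P. bambusoides*) can establish under present and warmed
climates, from presence/absence records at weather stations. The occupancy
model is a binomial GLM with logit link,

    P(presence) = logit⁻¹(β₀ + β_T · T + β_R · R),

with T the mean annual air temperature (°C) and R the sun (shortwave)
radiation (MJ m⁻² day⁻¹). Because the species' spread is human-mediated
over centuries, presence near long-inhabited stations is treated as being
in quasi-equilibrium with climate — the key assumption behind reading the
fitted envelope as *potential* habitat.

## Climatic indices

From twelve monthly mean temperatures t₁..t₁₂ (°C) and precipitation totals
p₁..p₁₂ (mm):

- warmth index WI = Σ max(tᵢ − 5, 0) (°C·month, ≥ 0);
- coldness index CI = Σ min(tᵢ − 5, 0) (°C·month, stored ≤ 0);
- growing-season precipitation = Σ pᵢ over months with tᵢ ≥ 5 (inclusive
  boundary), non-growing the remainder.

These satisfy WI + CI = 12(mean − 5) exactly, which the tests exploit as an
algebraic oracle. Multi-year windows average *indices computed per year*,
not the averaged monthly climatology: WI is convex in temperature, so the
orders differ, and the per-year order matches how station climatologies are
usually summarised over decade windows. Annual extreme temperatures come
from hourly records and are consumed as provided columns, never derived
from monthly means.

## Model selection and validation

All-subsets search: every subset of a global model's terms (including the
intercept-only model) is fitted and ranked by the small-sample-corrected
criterion AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); ties break toward fewer
parameters, then lexicographic term order. The two-stage protocol runs ten
global models (five temperature-related variables × two precipitation
variables, each plus non-growing precipitation, radiation, and
forest/farmland ratios), dredges each, and ranks the deduplicated union by
AICc. Pooling the union was a design choice here: with shared data the
AICc values of identical subsets coincide, so the pooling rule only
deduplicates.

Validation uses leave-one-out cross-validation (each station scored by a
model fitted without it), an inclusive classification rule (presence iff
score ≥ τ), and the cutoff maximising Youden's J = sensitivity +
specificity − 1, which is robust to the ~4:1 presence:absence imbalance of
roadside occupancy surveys. Candidate cutoffs are midpoints between
consecutive sorted unique scores plus ∓∞ sentinels; J ties break toward the
smallest cutoff (favouring sensitivity). AUC uses the tie-corrected rank
statistic (half credit for ties). Metrics with an empty margin (e.g. PPV
with no predicted presences) are reported as NaN with a warning — silent
zeros would corrupt model ranking. LOOCV folds that separate are scored
missing with a warning rather than aborting: ~145-point datasets with rare
absences can separate once a pivotal absence is held out.

`solve_confusion` inverts printed accuracy and informedness (at a stated
rounding precision) back to the unique integer confusion matrix given the
class totals, erroring if zero or several matrices match; it exists so that
published summary metrics can be checked against the implemented formulas
without the underlying data.

Numerical choices: GLM fits run IRLS to a relative log-likelihood change
below 1e−8 or 100 iterations; complete separation is detected via
non-finite parameters or standardised slopes beyond 30 and raised as an
error naming the most implicated predictor (largest standardised class-mean
difference).

## Pattern scaling

A present/future regional simulation pair fixes the spatial shape of
change. With ΔT_g the simulation's global-mean warming (here the four
ensemble members' 3.49, 3.57, 3.50, 3.41°C), the scaling pattern is
(future − present)/ΔT_g per cell, and a scenario at X °C above
preindustrial is baseline + (X − 0.5)·pattern: the 0.5°C offset is the
warming already realised between preindustrial times and the 1990-centred
baseline. Scenario construction is exactly affine in X, and rebuilding at
X = ΔT_g + 0.5 reproduces the future grid — both are tested identities.
Warming-level timing reads a 20-year running-mean global anomaly series
(centred windows labelled by their midpoint year, so 1980–1999 → 1990);
exceedance is inclusive (anomaly ≥ X − 0.5). The bias correction is a
deliberately simple per-cell mean match (additive for temperature,
multiplicative with a near-zero guard for radiation), isolated behind one
interface so a quantile-mapping recipe can replace it.

## Projection and extrapolation diagnostics

Probabilities are evaluated cellwise, thresholded inclusively at the
validation cutoff (0.606 in the worked example), and summarised over a
focal region (default: land at ≥ 35°N and ≥ 136°E, inclusive bounds).
Habitat fraction uses plain cell counting by default — at mid-latitude
regional scale the cells are near-equal-area — with cos(latitude)
weighting behind a flag. The northern limit is the maximum habitat
cell-centre latitude; shifts convert degrees to km at 111.2 km/° (mean
meridian arc); published km figures from other baselines are descriptive,
not normative. Masked (sea) cells stay NaN through every operation.

MESS follows the published definition: per variable, with f the percentage
of reference points *strictly below* the cell value and (min, max) the
reference extremes, similarity is 100(v−min)/(max−min) at f=0, 2f for
0<f≤50, 2(100−f) for 50<f<100, and 100(max−v)/(max−min) at f=100; the cell
score is the minimum over variables, negative exactly when some variable
leaves its reference range. A degenerate (single-valued) reference scores
100 at that value and 0 elsewhere, with a warning. The reference set is the
station predictor values the model was calibrated on.

## Synthetic worlds

The generator emulates the study conditions, not Japan's actual geography:
145 stations uniform over 35.3–41.5°N with Beta(1,4)-skewed altitudes up to
1200 m (station networks sit mostly low), mean annual temperature 16°C at
the southern edge at sea level, −1.0°C per degree latitude, lapse rate
−6.5°C/km, 0.6°C microclimate noise; a sinusoidal seasonal cycle of 11°C
amplitude peaking in August (its twelve phase points sum to zero, so
monthly means average exactly to the annual mean); radiation uniform on
12–16 MJ m⁻² day⁻¹. True coefficients (β₀, β_T, β_R) = (−18.4, 1.5, 0.35)
put the occupancy transition across ≈7–11°C and yield a ≈0.80 presence
fraction (cf. 116/145) at the defaults. Grid worlds share a deterministic
wavy coastline mask and smooth Fourier pseudo-terrain; the warming field
can tilt with latitude while keeping the area-weighted land mean equal to
the requested global ΔT times a regional amplification. All randomness
flows from explicit seeds; fixed seed ⇒ byte-identical output.

What the generator does *not* emulate: spatial autocorrelation of
occupancy beyond the climate signal, observation error in the presence
surveys, non-sinusoidal seasonal cycles, real land-use gradients (ratios
are Dirichlet noise uncorrelated with presence), and orographic structure.
Passing tests therefore demonstrate correctness of the computational
pipeline and estimator calibration under the stated model, not predictive
skill on real survey data.

## Problem sizes and defaults

Unit and property tests run at n ≤ 5,000 stations and grids up to
150 × 25; parameter-recovery checks use 100 replicates at n = 5,000; the
versioned fixture world uses 145 stations and 0.5° grids. These sizes make
every statistical check sharp (3-SE recovery bands, one-grid-row isotherm
agreement) while keeping the full suite under a minute of compute.

## Known limitations

- The bias correction is mean-matching only; distributional biases pass
  through.
- Cell-count area fractions ignore the ~10% cos-latitude area variation
  across a 35–46°N domain unless the weighting flag is set.
- The ten-global-model protocol assumes the candidate predictors listed
  above are present as columns; it does not screen for separation before
  dredging (separated subsets are flagged and excluded from ranking).
- MESS is implemented in its published form; published variants with
  modified tail handling would slot in at `mess_similarity`.
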