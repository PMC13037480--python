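# Methods

This note documents the models implemented in `hydrotraits`, the
choices made where the underlying field protocols leave the analysis
open, and what the synthetic-data tests do and do not establish.

## Shoot drying curves

A detached shoot is weighed at drying steps of increasing length while
two leaves per step are measured in a pressure chamber (after a 30–60
min equilibration in a humid bag). Relative water content at step *i* is

    RWC_i = (SM · Π_{k=2..i} FM_k / FM'_{k−1} − DM) / (SM − DM)

with SM the saturated initial mass, DM the oven dry mass, FM_k the
fresh mass before any leaf excision at step k and FM'_{k−1} the
previous step's mass *after* excision. RWC_1 = 1 by definition. This
running-product form means cut leaf mass is never booked as
evaporation; the unit test inverts the bookkeeping for arbitrary
declining RWC series and recovers them to 1e−9.

Choices:

* **Ψ per step** is the arithmetic mean of the two leaf readings; a
  spread above 0.5 MPa flags poor equilibration (step retained).
* **Mass-gain steps** (condensation/handling artifacts) are flagged,
  never dropped — dropping them silently would bias the running product.
* **RWC–Ψ decay** uses a two-parameter exponential anchored at
  RWC(0) = 1, `residual + (1 − residual)·exp(rate·Ψ)`; the anchor
  enforces the definitional saturation point. The fit is compared on
  RSS against a straight line (`beats_linear_`).
* **Capacitance** is the OLS slope of RWC on Ψ over the post-stomatal-
  closure segment. "After stomatal closure" has no operational
  definition in the protocol, so the default breakpoint is chosen by a
  two-segment piecewise-linear grid search over interior points
  (minimum three points per segment); a known closure Ψ (e.g. Ψ_tlp)
  can be passed instead. Standardization follows
  C_std = slope · (SM − DM)[g] / DM[kg] / 18.01, in mol kg⁻¹ MPa⁻¹ —
  written via the dimensionless ratio (SM − DM)/DM so the result is
  invariant to the mass unit used for inputs.

## Pneumatic vulnerability curves

Air discharged into the measuring reservoir over a 1.5-min window at
0.5-s cadence: AD = ΔP·V/(R·T). Because the endpoint rule (median of
the first and last five readings) slightly underestimates ΔP by the
same multiplicative factor at every step, the PAD scaling

    PAD_i = 100 · (AD_i − AD_min) / (AD_max − AD_min)

is unaffected — an affine-invariance the zero-noise round-trip tests
rely on. AD_min/AD_max default to the per-branch minimum and maximum
over all steps (no plateau averaging). Pressure changes near the ~50
kPa detection ceiling raise a warning but are not altered.

The vulnerability curve is the two-parameter symmetric logistic
PAD(Ψ) = 100/(1 + exp(a·(Ψ − P50))), the standard family for PAD/PLC
data. P12 and P88 come from the closed form of the same sigmoid. Start
values: P50 from linear interpolation of PAD through 50%, slope 2
MPa⁻¹. A fit is refused unless the data span below 20% and above 80%.
Species P50 is the mean of branch fits with t-based 90/95% CIs
(n = 3–5 branches).

## Leaf and wood traits

* **Turgor loss point**: van't Hoff osmotic potential π_o = −c·R·T from
  full-turgor osmolality (temperature defaults to 25 °C, configurable),
  then the published vapour-pressure-osmometer calibration
  Ψ_tlp = 0.832·π_o − 0.631 (coefficients overridable).
* **g_min**: OLS slope of leaf mass on time over the desiccation
  series, skipping the first 30 min as the stomatal-closure transient
  (configurable); J = |slope| / (2·A_projected · 1.8015×10⁻² g mmol⁻¹),
  g_min = J·P_amb/VPD. Saturation vapour pressure uses the Tetens form
  (documented, swappable).
* **SLA** is the mean of per-leaf area/mass ratios per tree; **WD** is
  oven-dry mass over water-displacement fresh volume.

## Gas exchange

Light response: non-rectangular hyperbola with quantum yield φ,
curvature θ, saturated gross rate and dark respiration Rd; A_max is
reported as the fitted net rate at the protocol maximum I = 2000
µmol m⁻² s⁻¹. CO₂ response: FvCB with Rubisco- and electron-transport-
limited branches, kinetic constants at 25 °C (Γ* = 42.75, Kc = 404.9
µmol mol⁻¹, Ko = 278.4, O = 210 mmol mol⁻¹, all estimator parameters);
no TPU limitation (the protocol tops out at 1200 ppm) and no
temperature response (chamber held near ambient). Because CO₂ curves
are measured at I = 2000, the fitted J *is* the operational "J_max at
2000"; the NRH capacity implied by the light-curve φ and θ is also
available.

Identifiability is checked by refitting single-limitation models: if a
Rubisco-only (or transport-only) model fits within 5% of the best RSS,
the corresponding parameter is flagged unidentifiable rather than
reported silently.

The protocol's 50 → 400 ppm recovery transition can leave anomalous
points; cleaning flags any of the three 400-ppm recovery readings whose
A deviates from the median of the stable 400-ppm readings by more than
15% (relative, configurable), replacing the manual visual inspection
with a reproducible rule.

## Growth and water status

Band circumference → diameter (÷π). The rainfall year runs 1 November –
31 October, matching the site's November–April wet season. ADI is the
net diameter change per rainfall year, linearly interpolated to year
boundaries; years observed fewer than 300 days are excluded with a
warning. PDGR is the maximum annualized slope of a GCV-tuned cubic
smoothing spline evaluated on a daily grid (floored at zero); the
spline is needed because 2–3-week readings cannot be differentiated
raw. Annualization uses 365 days so a 365-day linear ramp of 10 mm
reports ADI = PDGR = 10 exactly. Season length is the mean per-rainfall-
year span of days whose smoothed rate exceeds 10% of the tree's own
peak rate (threshold overridable; an absolute floor of 1e−9 mm day⁻¹
guards numerically flat series). PDGR here is an instantaneous
annualized rate — one possible operationalization of "peak growth
rate"; a windowed-mean definition would give smaller values for short
growth bursts.

Monthly predawn/midday water potentials are summarised per
species-month (mean, t-based 95% CI, Ψ_md − Ψ_pd), with soil Ψ averaged
over the three logger depths.

## Species-level pooling

Full Bayesian mixed models are replaced by closed-form empirical-Bayes
normal-normal pooling: between-unit variance τ² by moment estimation,
precision-weighted species mean, and shrinkage weights
s²/(s² + τ²) that send each unit estimate toward the species mean
(weight 1 when the units agree). Interval half-widths scale with
√(τ²/n), so identical unit values give a zero-width interval; when no
per-unit standard errors are available the plain t-interval is used.
These intervals are approximations to the credible intervals a full
hierarchical model would give — adequate for ranking species and for
the coverage properties asserted in the tests (≥ 90% at nominal 95%
over 500 replicates), not for exact posterior inference. For growth,
initial stem size is regressed out (OLS, evaluated at the mean size)
and observation year enters as an exchangeable additive offset before
pooling.

## Trait integration

The unit of analysis is the species mean: Pearson correlations are
computed across species (n = 6 for the packaged panel), with p-values
from the t transform on n − 2 df and the conventional tiers
(** p < 0.01, * p < 0.05, "." p < 0.10); no multiple-testing
correction, matching the raw-threshold reporting convention of trait
studies at this n. PCA standardizes trait columns (z-scores) before the
SVD because traits live on incommensurate units; variance explained per
axis is cross-checked in the tests against the eigendecomposition of
the Pearson matrix. With 6 species the matrix has rank 5, so at most
five axes carry variance. Which trait set enters the PCA (the eight
hydraulic/leaf traits alone, or extended with growth and gas-exchange
parameters) is a user choice; both are supported and neither is
privileged.

## Synthetic data: what it emulates, what it does not

Each generator forward-models one instrument at the protocol's own
sizes: 10 mg shoot balance, 0.5 mg leaf balance, 0.05 MPa pressure
chamber, 0.5 kPa Pneumatron reading noise, 1.7–3 mL tubing at ~293 K,
four branches/trees per species, ~12 drying steps geometrically spaced
from −0.1 to −10 MPa, dendrometer readings every 17 days over two
rainfall years. Noise is independent Gaussian per reading — the
simplest model consistent with instrument repeatability.

Deliberate constructions worth knowing about:

* The drying generator's RWC–Ψ curve is the exponential decay anchored
  at the first (near-saturated) step with an exactly linear
  post-closure tail at the true capacitance slope, so zero-noise data
  identify every drying-curve parameter exactly.
* The default vulnerability slope (9 MPa⁻¹) is steep enough that air
  discharge saturates within the −0.1 to −10 MPa window, mirroring the
  protocol's "measure until AD is constant" stopping rule. This is a
  structural requirement, not a tuning: when the sigmoid does not
  plateau inside the measured range, the PAD min/max rescaling
  truncates it and *no* estimator can recover P50 exactly — noiseless
  recovery is then limited by the truncation, not the fitter.
* The Pneumatron trace is a saturating-exponential pressure rise; see
  the affine-invariance note above.
* Seasonal growth is a logistic diameter ramp per rainfall year centred
  on 1 February, with amplitude and peak slope set by the true ADI and
  PDGR; recorded truth is the generating curve's own net annual change
  and peak annualized slope measured on a daily grid (the nominal
  amplitude differs slightly because year boundaries clip the logistic
  tails). An optional Gaussian shrinkage episode emulates growing-season
  dry spells.
* Truth parameters are emitted as a separate sidecar file, never in the
  instrument CSVs, so estimators cannot read them by accident.

What passing these tests shows: the estimators are unbiased and
well-calibrated under the stated noise model and protocol geometry, and
the whole chain is deterministic under a fixed seed. What it does not
show: robustness to structural field effects absent from the generator —
diurnal temperature drift, open-vessel artifacts in pneumatic data,
herbivory or bark shrinkage in dendrometer series, correlated
instrument drift. Real-data use should treat the flags and warnings
(mass gains, Ψ-pair spread, detection-ceiling steps, unidentifiable
limitations) as first-class outputs.

## Numerical notes

* All curve fits use bounded Levenberg–Marquardt/trust-region least
  squares (`scipy.optimize.curve_fit`) with documented start values;
  non-convergence raises an error naming them.
* Monte-Carlo test sizes (100–200 replicates for recovery error,
  500 for interval coverage) keep the full suite under a minute while
  holding the sampling error of the asserted medians well below the
  asserted tolerances.
* Degenerate inputs reject early with named errors: SM ≤ DM, RH ≥ 100%,
  non-positive volumes, flat AD series, non-monotone Ψ schedules or
  date columns, PAD spans that never cross the sigmoid's shoulders.
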