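# Methods

This note documents the statistical model, the synthetic data-generating
processes, the numerical choices, and the limitations of `cranesel`.

## Study design and diel partitioning

Fixes arrive on the seven-per-day schedule 07:00, 08:00, 10:00, 14:00,
16:00, 18:00 and 24:00 (midnight is canonicalized to 00:00 of the next
day). The diurnal period is [07:00, 18:00); the roosting period is any
in-channel fix at ≥ 18:00 or ≤ 07:00. A 07:00 fix inside the channel
counts as roosting (the bird has not yet left its roost); a 07:00 fix
elsewhere is diurnal. Fixes whose altitude above ground exceeds 50 m are
classified as flying and excluded from both periods. The 50 m default is a
package choice, not a reported value: transmitter altitudinal accuracy is
±22 m, so the cutoff is set beyond twice the accuracy; it is a parameter
of `partition_diel`. Fixes with missing altitude go to a needs-review list
rather than being silently kept, mirroring the manual imagery check used
in practice.

The availability radius is the across-individual mean of per-individual
maximum step lengths after discarding (a) steps ≥ 10,000 m, which are
migratory arrivals/departures, and (b) steps whose elapsed time exceeds
3 h. Both elapsed-time variants are meaningful for this fix schedule (the
≤ 3 h variant gives 6.7 km for these cranes, the > 3 h variant 5.8 km);
the study adopted 6.7 km, so the package defaults to the ≤ 3 h variant
with the other selectable (`elapsed_filter="gt"`). Distances are planar Euclidean — coordinates are
projected meters; no geodesy.

## The matched design

Each used location anchors one stratum: 50 available locations drawn
uniformly on the 6.7 km disc intersected with the period mask, by
rejection sampling from the disc (r = R√u). The diurnal mask is every
classified field/pasture/wetland cell; the roost mask is the full active
channel polygon (the wetted-channel alternative is a documented open
choice; "areas within the channel" reads as the active channel). A disc
with (near-)empty mask intersection raises a stratum-construction error
naming the point.

Annotation rules:

* structure counts are boundary-inclusive (distance ≤ r) at 100/500/1000 m;
* with no structures on the map, distance-to-structure takes the landscape
  diagonal as a finite sentinel (recorded in the strata metadata) so fits
  remain defined;
* channel width is read from the nearest ~30 m centerline station, no
  interpolation — matching the native sampling resolution;
* a "stretch" of river is the along-centerline window of ± half the
  stated stretch length centred at the point's projection onto the
  centerline; bank cells are the 10 m height cells within 50 m lateral
  distance of the active channel, keyed by the chainage of their nearest
  station. An empty window (possible only in degenerate configurations)
  falls back to the chainage-nearest bank cell;
* roost points whose 30 m pixel centre falls just outside the channel
  polygon (the polygon is not pixel-aligned) take the nearest channel
  pixel's proportions, with a hard error beyond two cell widths.

Continuous covariates are z-score standardized before fitting, with the
(mean, sd) transform stored in the fit result and reused by prediction.
Whether the original analysis standardized is not stated; standardization
is the default here because the published coefficient magnitudes are
commensurate across covariates with very different native units, and the
transform can be disabled (`standardize=False`) or supplied externally
(`constants=`) — the latter is how the acceptance script keeps fitted
coefficients on the same scale as the generator's truth. Because the
conditional likelihood is invariant to per-stratum location shifts, only
the scale part of the transform affects coefficients.

## Conditional likelihood, GEE sandwich, QIC

The conditional log-likelihood of a stratum is the log-softmax of the used
row's linear predictor; gradient and Hessian are the standard multinomial
forms, computed with grouped reductions. Newton–Raphson starts at β = 0
(or a warm start), uses step-halving (up to 10 halvings) on likelihood
decrease, and declares convergence at max |score| < 1e-8 within 50
iterations. Estimation is under the independence working model; no
iterative working-correlation estimation — the cluster sandwich corrects
the variance afterwards. Identifiability pre-checks reject covariates
constant within every stratum. Separation is detected exactly on single
covariate axes: if the used row attains the within-stratum maximum (or
minimum) of a covariate in every stratum, the likelihood is monotone in
that coefficient and a named error is raised. The practical case is a
one-hot land-use level never observed as a used row;
`fit_model(..., on_separation="drop")` applies the standard applied
remedy — drop the inestimable column and record it. A norm bound
(|β| > 30) backstops multivariate divergence.

The robust covariance is A⁻¹BA⁻¹ with A the observed information at β̂ and
B = Σ_c U_c U_c', U_c the summed per-stratum scores of cluster c (one
cluster per bird), times g/(g−1) for g clusters; it requires g ≥ 2. QIC
follows the Pan (2001) independence form, −2ℓ(β̂) + 2 tr(Â V̂ᵣ), recorded
as such in the fit metadata since variants exist; when V̂ᵣ equals the
naive covariance the penalty reduces to 2p. No reference QIC values exist
for this analysis, so the implementation is validated by its properties
(AIC-like limit, selection consistency in simulation) rather than against
reported numbers. VIF screening regresses each design column
on the others (via the statsmodels variance-inflation routine) and drops
columns with VIF ≥ 5; one-hot columns are screened individually
(generalized VIF is out of scope). Model weights are exp(−Δ/2),
normalized.

## Cross-validation

Each replicate samples ⌈0.8·n⌉ strata without replacement (strata kept
intact; an option splits by cluster instead), refits the point estimate
(warm-started from the full-data fit — the optimum is tolerance-exact, so
the warm start affects speed only), scores every row of each validation
stratum, and ranks rows ascending in predicted score with ties broken
uniformly at random, so rank 51 is the highest. The used row's rank is
tallied into 51 bins and r_s is the Spearman correlation (average ranks
for ties) between bin index and bin frequency; a constant frequency
vector returns 0 by convention. Two properties of this statistic matter
for interpreting it:

* it is **non-monotone in selection strength** — if selection were so
  strong that every used row ranked 51st, the frequency vector would be a
  single spike whose Spearman value against 1..51 is only ≈ 0.26 (50 tied
  zeros share an average rank); the statistic is maximized by smoothly
  increasing bin frequencies, which is the regime real habitat models
  produce;
* conditional on one finite dataset its mean carries a **dataset-level
  random effect**: the realized strata have chance covariate/used
  associations that every 80% refit partially shares, so replicate means
  do not converge to the population value for that model class. Null
  calibration therefore averages over independent datasets as well as
  splits (the acceptance checks use 25 datasets × 20 splits).

## Prediction surfaces

w(cell) = exp(x'β̂) per cell of the masked domain (eligible cells for
diurnal, active channel per bi-monthly period for roost), computed with
the stored standardization, then min–max rescaled to [0, 1] for display;
cells outside the domain are NaN and an all-equal surface maps to 0. The
raw exp-scores are returned alongside since relative probability of use is
defined only up to a positive factor; the rescaling convention is the
package's own (the source figures do not state theirs).

## Spectral mixture analysis

NDWI = (G − NIR)/(G + NIR), undefined (NaN) where the denominator is 0.
The water-endmember mask keeps pixels at or above the 98th percentile of
valid NDWI values — linear-interpolation quantile, declared because
percentile conventions differ; a constant raster degenerates to flagging
everything with a warning, and fewer than 50 valid pixels is an error.
Endmembers are per-class mean spectra over their regions (NDWI mask for
water, static monotypic polygons for sandbar/vegetation, kept static
across winters). Unmixing solves min ‖E'p − s‖² with p ≥ 0, Σp = 1 by
exact active-set enumeration: each subset of components pinned at zero
yields an equality-constrained least-squares KKT system (batched across
pixels, since E is shared); the feasible candidate with the smallest
residual wins. With three endmembers this is seven tiny solves —
deterministic, permutation-equivariant, and optimal to machine precision;
residuals are re-evaluated directly from E'p − s because the quadratic
expansion cancels catastrophically near zero. Bi-monthly composites are
per-pixel means over valid (cloud-mask-passing, finite) observations, NaN
where nothing valid remains. Synthetic spectra default to six
Landsat-8-like reflective bands.

## Synthetic generators: what they emulate, and what they do not

All generators are pure functions of (config, seed).

**Landscape** — field blocks (default 500 m) each take a land-use class
with the floodplain's class mix (alfalfa/hay 0.88, corn 0.05, fallow 0.03,
small grains 0.02, wetland 0.015, other 0.005 — only the alfalfa share is
a reported value; the remainder splits the residual plausibly) or stay
unclassified background with probability 1 − field_cover (default 0.75).
One rectangular public block covers 12% of the grid — far more than the
real managed properties' share of the valley, deliberately, so public
cells appear in availability samples at testable rates; wetland patches
are swapped onto public land. Human structures follow a Thomas cluster
process (25 parents, mean 30 offspring, 150 m dispersion). Default extent
15 × 15 km at 100 m cells, so the 6.7 km disc fits inside.

**River** — a sinuous south-north centerline (sine meander plus smoothed
noise) sampled every 30 m with a smoothly varying width profile inside
(40, 200) m; the active-channel polygon joins the perpendicular half-width
offsets. Water/sandbar/vegetation proportions come from a softmax over
smooth Gaussian random fields plus a lateral-position term (water toward
the thalweg, vegetation toward the margins), independently perturbed per
bi-monthly period — closure to 1 is exact by construction. Bank heights
are a softplus-transformed smooth field (≥ 0, mean ≈ 1.7 m) on 10 m cells
within 50 m of the channel; bridges sit every 4 km of chainage. The
spatial correlation scale of all random fields is an exposed parameter
(`smooth_sigma_px`), since no empirical scale is reported.

**Tracks** — 38 birds, seven fixes daily on the study schedule, default 58
days. Roost fixes (07:00, 18:00, 24:00) are drawn from channel pixels and
diurnal fixes from eligible cells, each with probability ∝ exp(x'β) among
candidates within 6.7 km of the previous location; β defaults to the
published top-model coefficients, applied to covariates z-scored over
their sampling domain (the returned scalings let fitted coefficients be
compared on the same scale). Positions are jittered inside their cell
(roost jitter clamped to the channel polygon); ~3% of fixes are flagged
flying with altitudes of 80–300 m, ground fixes get N(0, 5 m) altitude
noise. An empty candidate disc (a bird in a far corner relative to the
river) falls back to the full domain with a logged warning.

One structural caveat: the simulator conditions each step's candidate set
on the *previous* location, while the estimation design centres
availability on the *used* location, as the field study does. On a
statistically homogeneous landscape the mismatch is small but real —
pipeline-level coefficient recomputation shows mild attenuation relative
to the generator's truth, most visibly for land-use contrasts. The strict
parameter-recovery checks therefore use the direct stratum simulator
(`simulate_choice_strata` / `simulate_choice_design`), whose
data-generating process is exactly the conditional model. Neither
generator emulates GPS error, behavioural autocorrelation beyond the step
constraint, crop rotation, hydrology, or real geography; passing tests
demonstrate correctness of the estimation machinery under the stated
model, not robustness to those real-data features.

**Spectra** — pixels are Dirichlet-weighted convex combinations of three
endmember spectra plus Gaussian noise (default sd 0.01 reflectance).

## Problem sizes in the replicated checks

Recovery and coverage run at 38 clusters × 150 strata × 51 rows;
cross-validation calibration at 38 × 80; QIC selection at 20 × 50; the
full-pipeline recomputation at 38 birds × 35 days with 3000 diurnal and
2400 roost strata and 1000 CV replicates. These sizes keep fold sizes and
cluster counts at the study's order while holding the default test run to
minutes. Replicates in which a rare land-use level is never used (so its
coefficient is inestimable) are skipped and counted — the published
analysis had uses of every level.

## Known limitations

* The exact published candidate model sets live in supplementary tables
  not reproduced here; `enumerate_candidates` encodes the main-text
  confirmed structures plus plausible nested sets and accepts
  user-supplied specs for exact replication.
* VIF is computed per design column; generalized VIF for factor blocks is
  not implemented.
* The sandwich assumes independent clusters; with few clusters (< ~20)
  robust intervals are anti-conservative, and the ±2·SE convention is
  closer to a t_{g−1} than a normal criterion.
* The active-set unmixer enumerates 2^K − 1 subsets — exact and fast for
  the three-endmember problem it serves, not intended for large K.
* Rejection sampling of availability assumes the mask occupies a
  non-negligible fraction of the disc; pathological geometries (a sliver
  mask) raise rather than loop indefinitely.
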