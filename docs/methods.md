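# Methods

## The model

parashift estimates habitat suitability from presence-only records by
maximum entropy. Given presences x₁…x_m and background points z₁…z_n in
environmental space, the model is the Gibbs density over the background,

    q_β(x) = exp(β·f(x)) / Σⱼ exp(β·f(zⱼ)),

whose coefficients minimize the L1-penalized negative log-likelihood

    −(1/m) Σᵢ β·f(xᵢ) + log Σⱼ exp(β·f(zⱼ)) + Σₖ λₖ|βₖ|.

This is the "maxnet" formulation: the limit of a lasso logistic regression
of presence against background as the background weight grows without
bound. The features f are the classic MaxEnt classes on variables min-max
scaled to [0,1] (scaling fitted on training presences + background):
linear x, quadratic x², pairwise products, and forward/reverse hinges
max(0,(x−k)/(1−k)) and max(0,(k−x)/k) on a 50-knot grid. Feature classes
are chosen by presence count: linear + quadratic below 80 presences, plus
hinge and product at 80 or more.

Reported suitability uses the logistic transform `raw·e^H/(1+raw·e^H)`
where `raw = q_β(x)` and H is the entropy of the fitted background
distribution. This is the scale on which presence/absence thresholds are
conventionally quoted; thresholds near 0.4–0.6 correspond to "typical
occupied habitat".

### Optimizer

FISTA proximal gradient with backtracking line search and gradient
restarts; convergence is declared when the L1-subgradient (KKT) residual
falls below 1e-5, with a 10,000-iteration cap (reaching the cap with a
residual above 1e-3 raises a convergence error carrying the residual).
Identical inputs give identical coefficients; no randomness enters the fit.

### Regularization

Penalties are λₖ = multiplier · base · sdₖ/√m, with sdₖ the feature's
standard deviation over presences, floored at max(0.05·sd_background, 0.02).
The base is a constant 4 for every class. Rationale: under a null in which
presences are drawn from the background distribution itself, the gradient
of the unpenalized likelihood at β = 0 fluctuates with standard deviation
≈ sdₖ·√(1/m + 1/n); base 4 places λₖ at roughly 3–4 such standard
deviations for *any* m, so null data yields the uniform model (all
coefficients exactly zero) while genuine niche signals — which do not
shrink with √m — pass easily. Classic interpolated schedules that decay to
0.05 at large m let pure noise into the model at these sample sizes. The
absolute sd floor of 0.02 additionally suppresses sparse-support hinge
features, whose tiny variance would otherwise buy large coefficients at
negligible penalty.

Two further safeguards address a structural degeneracy of presence-only
fitting: if presences occupy a feature-space region with zero background
mass, the penalized likelihood is unbounded. The fit therefore (i) adds
the presence samples to the Gibbs normalization set (the reference MaxEnt
implementations' default), and (ii) floors each λₖ above the asymptotic
gradient drift `max(mean_pres(fₖ) − max_bg(fₖ), min_bg(fₖ) − mean_pres(fₖ))`.
The reported raw values and entropy are always normalized over the
background proper, so `Σ_background raw = 1` holds exactly.

### Variable contributions

Percent contribution is permutation importance: each variable's values are
permuted jointly across presence + background rows (5 seeded permutations),
the drop in training gain is averaged, negatives are clipped, and drops are
normalized to sum to 100. Path-based gain accounting was rejected because
it depends on solver iteration order and does not reproduce across
implementations.

## Evaluation

- 80/20 random train/validation split (seeded; not spatially blocked).
- AUC is the rank-based Mann–Whitney estimator; ties count ½.
- The binary threshold τ* maximizes sensitivity + specificity over midpoints
  of adjacent sorted unique scores; ties break toward the smaller τ* (the
  more inclusive range). Specificity is computed on background points —
  true absences do not exist in presence-only data.
- Cells with suitability exactly τ* count as suitable (≥ convention).

## The pipeline

Host model first (all climate variables by default), then its predicted
suitability becomes the `host_suitability` layer for the parasite. Only
climate layers pass through the collinearity screen (greedy elimination of
pairwise |r| > 0.7 with a restoration pass guaranteeing a maximal retained
set); the host layer is always retained, since host availability is the
focal biotic hypothesis, not a nuisance covariate. Under future scenarios
the host model is re-projected per scenario and its future suitability fed
to the parasite (`host_mode: reprojected`, the ecologically coherent
default); `host_mode: static` holds the host at its current distribution
instead, separating the climate signal from host tracking.

Continuous suitability is averaged across GCMs within each SSP × timeline
*before* thresholding; binary majority voting would quantize inter-model
disagreement. A cell is nodata in the ensemble if any member is nodata.

Range change per cell is `current − 2·future ∈ {0, −2, 1, −1}` (still
unsuitable / expansion / contraction / persistence). Percentages are
relative to the current range size (contraction + persistence cells), so
expansion above 100% means the range more than doubles. Cell counts are
unweighted by default; `latitude_weighted=True` multiplies each cell by
cos(latitude of its center) to approximate true areas on the geographic
grid.

Every stage seed is `sha256(master_seed:stage_name) mod 2³¹−1`, so adding
stages never perturbs existing ones and a rerun of the same config
reproduces byte-identical outputs (verified via the manifest's SHA-256
checksums).

## The synthetic world

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

- **Climate** layers are Gaussian random fields — white noise convolved
  with an isotropic Gaussian kernel (correlation length in cells), then
  standardized over valid cells. The demo world's temperature layer adds a
  south-to-north linear trend of ±2.5 sd.
- **Niches** are logistic in linear/quadratic climate terms. The demo host
  has a sharp thermal optimum mid-latitude (prevalence ≈ 0.1); the demo
  parasite is warmer-adapted and strongly host-conditioned (host
  coefficient 4). Prevalences near 0.1 were chosen so that the *true*
  niches discriminate presences from background at AUC ≈ 0.9 — a diffuse
  niche caps the achievable AUC regardless of model quality, which is a
  property of the study system, not of the estimator.
- **Sampling** draws presence cells with probability ∝ suitability × bias,
  then places each point uniformly within its cell. The default bias field
  over-samples one hotspot region 5×, giving spatial thinning something to
  correct.
- **Scenarios** are additive offsets: per-SSP warming of 0.35/0.55/0.75/
  0.95 sd (earlier timeline; ×1.6 for the later one), spread across four
  GCMs by factors 0.85–1.15, and graded with latitude (0.7× at the southern
  edge to 1.3× at the northern) to induce the poleward range movement the
  range-change accounting is designed to detect. A small negative
  precipitation offset (one tenth of the warming) accompanies each shift.

What the synthetic world does *not* emulate: real covariance among the 19
bioclim variables (layers are independent fields, so the collinearity
screen usually retains everything — tests exercise it on constructed
collinear stacks), coastlines/elevation and the nodata structure of real
rasters beyond simple masks, non-additive climate change, dispersal limits,
and observation error in coordinates. Passing tests therefore demonstrate
the correctness of the machinery and the recoverability of known niches
under the stated sampling model — not predictive skill on real species.

## Numerical and interface choices

- Grids are south-up row 0 with half-open cells `[min, min+cell)`; a point
  on the extent's max edge is outside. Background points sit at cell
  centers (predictors are cell-constant, and centers make tests exact).
- Thinning keeps one uniformly chosen record per species per thinning cell;
  the thinning grid is anchored at the study extent's lower-left corner.
- Duplicates are exact (species, lon, lat) matches; no coordinate fuzz.
- Variables are clamped to their training [min, max] before feature
  expansion at prediction time, so extrapolated cells predict as the
  nearest training boundary.
- Rasters are exchanged as ESRI ASCII grids (plain text, self-describing
  georeference) with a JSON sidecar for stacks; models serialize to JSON.
- Problem sizes in the test suite (grids of 60×60 to 100×100 cells,
  hundreds of presences, 10³–10⁴ background points) keep full statistical
  validations — 10-seed recovery and scenario-ordering checks — in the
  minutes range on one CPU.

## Known limitations

- Percent contributions of strongly correlated predictors (e.g. host
  suitability vs the temperature that drives it) share credit
  unpredictably, as permutation importance always does.
- The max(sens+spec) threshold against background equates background with
  absence; prevalence is not identified in presence-only data, so τ* is a
  convention, not an estimate.
- Greedy collinearity elimination optimizes no global criterion; it is
  deterministic and maximal but other maximal valid subsets may exist.
- The expansion/contraction percentages depend on the binary threshold;
  small threshold changes can move cells near τ* across categories.
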