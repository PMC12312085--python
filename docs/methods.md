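# Methods

## Problem setting

Hourly composite samples of treatment-plant influent, taken over three
consecutive days and measured by LC-HRMS in both electrospray
polarities, yield an aligned feature table: tens of thousands of
features, each a 72-point intensity trajectory. A few hundred of them
can be annotated against a target list; the rest are unknowns. The
package's job is (i) to find the recurring daily discharge patterns
among the annotated targets and (ii) to use those patterns as templates
for prioritizing unknowns — e.g., features that follow the morning-urine
peak are candidates for human-excreted chemicals.

## Filtering funnel

Four rules, applied in a fixed order, each only removing or
transforming features:

| rule | keep iff | default |
|---|---|---|
| blank | mean over hourly samples ≥ factor × mean over blanks | 1.5× |
| detection frequency | detected (intensity > 0) in ≥ threshold of hourly samples | 85 %, inclusive |
| temporal variance | RSD of raw intensities (detects only, sd with n−1) > threshold | 45 %, strict |
| imputation | each remaining non-detect ← min(detected)/divisor | 4 |

Rationale for the variance rule: internal standards — spiked at constant
amount — showed at most ~30 % RSD across hourly samples, so any
technical or matrix variability is bounded by that; only features
varying by more than 1.5× that bound can carry a real temporal pattern.
The detection-frequency boundary is inclusive (a feature at exactly the
threshold is kept). The imputation minimum is per feature, not global: a
global minimum would inject absurdly small values into high-abundance
trajectories and manufacture spurious variance.

Flow normalization (optional) multiplies intensities by
flow(t)/mean(flow), converting concentration-like signals to load-like
signals so that dilution events (rain) do not masquerade as discharge
patterns. Division is available as an option; multiplication is the
default because the goal is to flatten dilution-driven dips.

## Scaling

Each trajectory is log2-transformed and standardized to mean 0 /
sd 1 (sample sd, n−1). Scaling is exactly invariant to per-feature
multiplicative gain, which is what makes trajectories of compounds with
different response factors comparable. Constant trajectories cannot be
scaled and are an error by construction (the variance filter removes
them first).

## Data configurations

The 72 hourly samples can be arranged as a single 72-point trajectory
(day-major, hour-minor; the default), as 24-point hourly averages over
the three days, as three separate per-day sets, or — as a negative
control — with each feature's sample order independently permuted.
The permutation is per feature on purpose: permuting all features with
one shared permutation merely relabels the time axis, leaving every
between-trajectory Euclidean distance, and hence any partition's
Calinski–Harabasz value, mathematically unchanged; only the
per-feature permutation actually destroys the cross-series temporal
association that the control is supposed to test for.

## Clustering

Longitudinal k-means in the style of the kml family with the
Chouakria–Douzal adaptive dissimilarity

    D(a, b) = phi_k(CORT(a, b)) * ||a − b||,
    CORT(a, b) = <Δa, Δb> / (||Δa|| ||Δb||),
    phi_k(u) = 2 / (1 + exp(k u)),

with CORT defined as 0 when either difference vector vanishes (flat
trajectories fall back to the Euclidean distance), and `cort_k = 2`
(the conventional tuning default; `cort_k = 0` reduces the whole
procedure exactly to Euclidean k-means, which is tested against
scikit-learn's implementation).

Assignment minimizes the adaptive distance; the centroid update is the
pointwise mean of members — a true barycentre under the adaptive
distance has no closed form, and the mean keeps the exported centroids
interpretable as average scaled trajectories. Ties in assignment break
to the lowest cluster index; an emptied cluster is re-seeded with the
trajectory farthest from its current centroid (each repair consuming a
distinct trajectory). Best of `n_restarts = 20` random initializations
(k distinct trajectories each) by total within-cluster dissimilarity,
`max_iter = 100`; everything is a pure function of (data, k, seed).

**Model selection.** Every k in 2..8 is fitted; the model maximizing
the Calinski–Harabasz criterion CH = [B/(k−1)]/[W/(n−k)] wins, with the
Ray–Turi criterion (W/n)/min-squared-centroid-separation reported
alongside. Both use Euclidean geometry on the scaled trajectories. A fit
whose within-cluster scatter is numerically zero relative to the
between-cluster scatter (W ≤ 1e−12·B, the noiseless case) is flagged
degenerate with CH = +∞; since ties on CH resolve to the smallest k,
noiseless data select the smallest k that fully separates the
archetypes rather than an arbitrary over-split.

**Membership probabilities.** kml reports a "probability of belonging"
without a published formula, so the package states its own surrogate: a
Gaussian kernel over adaptive distances, p(i,j) ∝ exp(−d(i,j)²/(2s²)),
normalized over clusters, with s the pooled mean within-cluster
distance. It is monotone in distance, sums to one, and collapses to
hard assignment as noise → 0 (s = 0 handled explicitly). The > 90 %
retention threshold is applied to the maximum cluster probability.

## Prediction of non-target features

Squared Euclidean distance to each exported centroid (the squared form
is deliberate — it is the printed classification metric, not a rounding
of the Euclidean distance). Retention requires both

* ratio rule: d(second-nearest)/d(nearest) > 1.5 — the orientation
  guarantees ratio ≥ 1 so that "> 1.5" is a selectivity filter, with an
  exact centroid match given infinite ratio; and
* median rule: d(nearest) ≤ median of the clustered targets'
  own-centroid distances. The median is global by default (one
  threshold, matching the singular rule it implements); a per-cluster
  variant is exposed as an option.

Because clustering uses the temporal-correlation-weighted metric while
prediction uses plain squared Euclidean distance, a target could in
principle flip clusters between the two geometries. `reassign_targets_qc`
measures this instead of assuming it away: it re-classifies every
clustered target and reports the agreement fraction (1.0 on clean fits;
disagreements are logged feature by feature).

## Trend summaries

Per-cluster smooths are penalized cubic smoothing splines with the
smoothing parameter chosen by generalized cross-validation, fitted
through the pointwise means of the member trajectories, separately per
sampling day so day-to-day differences (the rain night) stay visible.
They are visualization-grade only; no inference is attached. The
confidence band is a pointwise normal band from the cross-member
spread. Clusters are summarized by their Spearman correlation (average
ranks on ties) between centroid and influent flow — the sign is the
interpretive handle: flow-tracking (daytime activity) vs
flow-anticorrelated (morning peak) vs dilution-driven backgrounds — and
by compound-class composition of their annotated members.

## Semi-quantification

Each compound is paired with the internal standard nearest in retention
time (ties to the earlier-eluting IS). Calibration is a straight line
fitted by weighted least squares with weights 1/x over ≥ 3 calibration
levels with strictly positive concentrations; responses may be raw
intensities or analyte/IS ratios. Concentrations are
(response − intercept)/slope, floored at zero with a flag, and labelled
"semi-quantified" in every output: surrogate calibration cannot replace
compound-specific validated methods.

## Synthetic data generator

The generator emulates the study design the pipeline assumes: 72 hourly
samples over 3 days, plus procedure blanks. Influent flow is a diurnal
sinusoid (mean 1000 m³/h, ±40 %, afternoon maximum, night minimum),
repeated over the three days, with a ×2 surge during a rain event
spanning day 1, 20:00 to day 2, 04:00 (hours 20–27 of the 72-h axis);
the rain event is on by default because the background archetypes are
defined relative to it.

Five clusterable archetypes, each normalized so that `amplitude`
(default fold-change 5 — a calibration knob, not an empirical claim) is
the peak-over-baseline ratio:

* **DA** — smooth plateau 10:00–20:00 (daytime domestic activity);
* **MP** — Gaussian bump at 07:30, sd 1.0 h (morning urine void);
* **BG1** — dilution-driven background, monotone in 1/flow, so it dips
  during the rain surge; the shape is cubed so the curve's own RSD sits
  clearly above the 45 % variance-filter threshold, as real retained
  patterns must;
* **BG2** — slow evening drift (cosine peaking 23:00, squared for the
  same reason);
* **BG3** — runoff: proportional to the rain surge only, flat without
  rain.

Feature intensity = baseline × archetype curve × unit-mean lognormal
noise with σ² = ln(1 + RSD²), so the target RSD is exact (default 0.20
for ordinary features, 0.25 for internal standards — within the 13–30 %
range observed for isotope-labelled standards in hourly influent work).
Baselines are log-uniform over three orders of magnitude (10³–10⁶),
mimicking the dynamic range of wastewater features. Half of each
archetype's features are flagged as annotated targets
(`target_fraction = 0.5`); the unannotated half exercises the
prediction stage with known truth. Pure-noise features are flat with
per-feature RSD drawn in [0.05, 0.35] — designed to fall below the 45 %
filter. Non-detects censor the lowest 5 % of values of low-baseline
(bottom-quartile) features. Blanks carry a constant background of 10
signal units, orders of magnitude below any feature baseline.

What the generator does **not** emulate: sewer-network hydraulics,
pharmacokinetics, chemistry-aware m/z or RT (placeholders drawn
uniformly), matrix effects, drift, or cross-feature correlated noise.
Passing tests therefore demonstrate that the algorithms recover the
structure they assume — not that real influent data contain that
structure.

## Numerical choices and degenerate inputs

* Sample (n−1) standard deviation throughout (scaling, RSD, criteria).
* Ion-mode merge tie (exactly equal means): positive mode kept.
* Intensity export: 6 significant digits (exceeds instrument precision;
  keeps CSV round-trips stable).
* Assignment/argmin ties: lowest cluster index. RT ties in IS pairing:
  earlier-eluting standard.
* Features with < 2 detects cannot have a variance and are removed with
  a logged reason; all-non-detect features are an imputation error
  (they should never reach that stage).
* Constant inputs to the Spearman correlation return NaN with a
  warning; smoothing segments with < 8 distinct time points fall back to
  the pointwise mean with a warning.

## Problem sizes

Default test and reproduction runs use 5 × 20 pattern features, 50
noise features, 10 internal standards, 72 time points, 20 restarts,
k ∈ 2..8, and 20 seeded replicate studies for the recovery and
randomization analyses — comfortably the scale of the target-compound
clustering problem the method is designed around (~100 trajectories).

## Known limitations

* The membership probability is a stated surrogate, not kml's internal
  quantity; the 90 % threshold's effect should be examined per dataset.
* Deduplication of *unannotated* features across ionization modes is
  not attempted (annotation-based merging only).
* The CORT/Euclidean geometry mismatch between clustering and
  prediction is quantified by the QC, not eliminated.
* GAM smooths overshoot at genuine discontinuities (the runoff step);
  they are for display, not estimation.
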