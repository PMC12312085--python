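# dielscreen

Temporal-pattern screening of hourly influent-wastewater LC-HRMS feature
tables.

Wastewater-based epidemiology reads a city's chemistry from its sewage.
When a treatment-plant influent is sampled **every hour over several
days**, each detected compound traces a diel (24-h) trajectory, and
compounds with a common discharge route — morning urine voids, daytime
household activity, surface runoff — rise and fall together.
`dielscreen` implements the data-analysis half of that idea for
non-target screening: it filters and scales the trajectories of
annotated target compounds, clusters them into recurring daily
patterns, and then sifts the thousands of unidentified (non-target)
features for those whose trajectories unambiguously match a pattern of
interest, prioritizing them for structure elucidation.

It is a library first (`import dielscreen`), with narrative scripts in
`examples/` and a thin `dielscreen` CLI for shell use.

## Method

Given an aligned feature table (rows = features with *m/z*, retention
time, ion mode; columns = per-sample intensities) and sample metadata
(day, hour, sample type, influent flow rate):

1. **Filtering.** Keep a feature if its mean intensity is ≥ 1.5× the
   blank mean, it is detected in ≥ 85 % of hourly samples, and the
   relative standard deviation of its raw intensities exceeds 45 % —
   1.5× the worst variation of the spiked internal standards, so that
   only genuine temporal patterns survive. Remaining non-detects are
   replaced by ¼ of the feature's minimal detected value.
2. **Scaling.** Each trajectory is log2-transformed and standardized,

   *z*<sub>ij</sub> = (*x*<sub>ij</sub> − μ<sub>i</sub>) / σ<sub>i</sub>,

   with μ<sub>i</sub>, σ<sub>i</sub> the mean and standard deviation of
   compound *i*'s log2 intensities, so clustering compares shapes, not
   abundances or response factors.
3. **Clustering.** Longitudinal k-means on the scaled 72-point
   trajectories with the Chouakria–Douzal adaptive dissimilarity
   *D*(a,b) = φ<sub>k</sub>(CORT(a,b)) · δ(a,b), where CORT is the
   first-order temporal correlation of the difference vectors,
   φ<sub>k</sub>(u) = 2/(1+e<sup>ku</sup>) and δ the Euclidean distance.
   The cluster count maximizes the Calinski–Harabasz criterion (Ray–Turi
   reported alongside); members must belong to their cluster with
   > 90 % probability.
4. **Prediction.** Non-target features are assigned to the exported
   centroids by squared Euclidean distance
   *D*(i,j) = Σ<sub>t</sub> (*x*<sub>i,t</sub> − *C*<sub>j,t</sub>)²,
   and retained only when the runner-up centroid is > 1.5× farther and
   the nearest distance is below the median of the targets' own-centroid
   distances. Re-assigning the targets themselves is the built-in
   quality control.
5. **Trends & semi-quantification.** Per-cluster GCV-spline smooths,
   Spearman correlation of cluster centers with the influent flow,
   compound-class composition, and optional concentration estimates via
   retention-time-nearest internal standards with 1/x-weighted linear
   calibration.

A synthetic-data module generates 3-day hourly studies with five known
diel archetypes (daytime-activity plateau, morning peak, three
background patterns including a rain-event runoff surge), lognormal
noise, internal standards, blanks and non-detects — so every stage is
testable with ground truth.

## Worked example

```bash
python examples/03_cluster_targets.py
```

prints (abridged):

```
selected k = 5 (generating structure has 5 archetypes)
100/100 trajectories above 90% membership
cluster 0: n= 20  majority archetype=MP    Spearman rho vs flow = -0.369
cluster 1: n= 20  majority archetype=DA    Spearman rho vs flow = +0.553
cluster 2: n= 20  majority archetype=BG3   Spearman rho vs flow = +0.263
cluster 3: n= 20  majority archetype=BG1   Spearman rho vs flow = -0.978
cluster 4: n= 20  majority archetype=BG2   Spearman rho vs flow = +0.206
```

The model selection recovers the five generating archetypes; the
daytime-activity cluster tracks the flow rate (ρ > 0) while the morning
peak — the putative morning-urine signal — anticorrelates with it
(ρ < 0), the signature used to interpret such clusters in hourly
influent data. `examples/04_predict_nontargets.py` then retains 12 of
50 unannotated features, all matching their generating archetype, with
a target re-assignment QC of 1.0.

The same run from the shell:

```bash
dielscreen simulate --out demo --seed 42
dielscreen run --features demo/features.csv --samples demo/samples.csv \
               --out demo/out --seed 42
```

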