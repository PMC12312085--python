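"""Cluster scaled trajectories into recurring daily discharge patterns.

Longitudinal k-means with the temporal-correlation-weighted (CORT)
dissimilarity; the cluster count is selected by the Calinski-Harabasz
criterion over k = 2..8, and trajectories must belong to their cluster
with > 90 % probability to be kept for downstream prediction.
"""

import dielscreen as ds

config = ds.SyntheticConfig(seed=42)
table, truth = ds.generate_dataset(config)
result = ds.run_preprocess(table, ds.SampleConfigurationSpec(mode="continuous_72h"))
Z = result.scaled["continuous_72h"]
pattern = Z.index[~truth.loc[Z.index].isin(["noise", "internal_standard"])]

model = ds.select_k(Z.loc[pattern], k_range=range(2, 9), seed=42)
print(model.selection_table.round(3))
print(f"selected k = {model.k} (generating structure has 5 archetypes)")

confident = ds.filter_by_membership(model, threshold=0.90)
print(f"{len(confident)}/{len(pattern)} trajectories above 90% membership")

flow = ds.generate_flow_profile(config).to_numpy()
for j in range(model.k):
    ids = model.assignments.index[model.assignments == j]
    label = truth.loc[ids].mode()[0]
    rho = ds.spearman_flow_correlation(model.centroids[j], flow)
    print(f"cluster {j}: n={len(ids):3d}  majority archetype={label:4s}  "
          f"Spearman rho vs flow = {rho:+.3f}")
# The daytime-activity cluster tracks the flow (rho > 0); the morning
# peak anticorrelates with it (rho < 0) - the same sign pattern reported
# for domestic-activity vs morning-urine clusters in hourly influent data.
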