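"""Indicator species for temperature classes and site clustering.

IndVal scores each taxon's association with 1-degC temperature classes as
sqrt(specificity x fidelity); hierarchical clustering groups sites by
water chemistry and by assemblage composition.
"""

import diatomcal as dc

bench = dc.make_benchmark(dc.SimConfig(seed=1))
ds = bench.dataset
rel = dc.relative_abundance(ds.counts.subset_habit("benthic"))
rel, _ = dc.rare_taxon_filter(rel, renormalize=True)
x = ds.env.values["temperature"].to_numpy()

classes = dc.temperature_classes(x, width=1.0)
ind = dc.indval(rel, classes.to_numpy(), n_perm=199, seed=0)
top = ind[ind["p"] <= 0.05].sort_values("stat", ascending=False).head(5)
print("strongest significant indicators (group = temperature class, degC):")
print(top.round(3).to_string())
# stat near 1 means the taxon is both concentrated in (A) and faithful to
# (B) that temperature class - a usable bioindicator of that range.

env_clusters = dc.cluster_sites(dc.transform_env(ds.env), k=3)
taxa_clusters = dc.cluster_sites(dc.hellinger(rel), k=6)
print(f"\nenvironment clustering (k=3): silhouette {env_clusters.silhouette:.2f}")
print(f"assemblage clustering (k=6): silhouette {taxa_clusters.silhouette:.2f}")
print("environment cluster sizes:", env_clusters.assignments.value_counts().to_dict())
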