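"""Trait correlation network and PCA on a simulated study.

Simulates the full 19-trait study, builds the per-condition Pearson
correlation network (nodes colored by biomass / architectural /
physiological group, edges kept at |r| >= 0.30, strong at |r| >= 0.60)
and runs a correlation-matrix PCA of the per-plant records.
"""

from peapheno import correlation_network, pca_biplot, simulate_study

table = simulate_study(seed=3, n_accessions=60, n_reps=3)

for condition in ("control", "drought"):
    net = correlation_network(table, condition)
    strong = [(a, b, d["r"]) for a, b, d in net.edges(data=True) if d["strength"] == "strong"]
    print(f"{condition}: {net.number_of_nodes()} traits, {net.number_of_edges()} edges "
          f"at |r| >= 0.30, {len(strong)} strong")
    for a, b, r in sorted(strong, key=lambda e: -abs(e[2]))[:5]:
        print(f"  {a:4s} -- {b:4s}  r = {r:+.2f}")

pca = pca_biplot(table)
evr = pca.explained_variance_ratio
print(f"\nPCA: PC1 explains {evr[0]*100:.1f} %, PC2 {evr[1]*100:.1f} % of total variance")
print("PC1 top loadings (traits separating control from drought):")
print(pca.loadings["PC1"].abs().sort_values(ascending=False).head(5).round(3).to_string())
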