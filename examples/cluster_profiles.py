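"""Print a textual profile of each discovered patient cluster.

After grouping a synthetic cohort, summarises every cluster the way a
clinician would read it: size, dominant age range, gender split, dominant
race and primary-diagnosis category, and the drugs most often administered
with their typical dose direction.
"""

import numpy as np
import pandas as pd

from drugrec import (
    ClusterConfig,
    SyntheticConfig,
    build_feature_table,
    fit_cluster_pipeline,
    generate_encounters,
)

raw, _ = generate_encounters(SyntheticConfig(n_patients=1500, seed=2))
result = build_feature_table(raw)
pipeline, _ = fit_cluster_pipeline(
    result.full, ClusterConfig(kmeans_k_range=tuple(range(2, 11)), dbscan_grid=())
)
labels = pd.Series(pipeline.model.labels, index=result.full.index)
print(f"{pipeline.model.n_clusters} clusters "
      f"(silhouette {pipeline.model.silhouette:.3f})\n")

races = [c for c in result.features.columns if c.startswith("race_")]
diags = [c for c in result.features.columns if c.startswith("diag_")]
for label in sorted(labels.unique()):
    members = labels[labels == label].index
    feats = result.features.loc[members]
    drugs = result.drug_ratings.loc[members]
    age_lo, age_hi = np.percentile(feats["age"], [10, 90])
    race = max(races, key=lambda c: feats[c].mean())
    diag = max(diags, key=lambda c: feats[c].mean())
    top_drugs = (drugs > 0).mean().sort_values(ascending=False)[:3]
    drug_desc = ", ".join(
        f"{d} ({p:.0%}, mean dose {drugs.loc[drugs[d] > 0, d].mean():.1f})"
        for d, p in top_drugs.items() if p > 0
    )
    print(f"cluster {label} (n={len(members)}):")
    print(f"  {feats['gender'].mean():.0%} male, ages mostly "
          f"{age_lo:.0f}-{age_hi:.0f}, "
          f"{race.removeprefix('race_')} {feats[race].mean():.0%}, "
          f"main diagnosis {diag.removeprefix('diag_')}")
    print(f"  drugs: {drug_desc}")
print("\n(mean dose 2.0 = typically increased, 1.0 = decreased or unchanged)")
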