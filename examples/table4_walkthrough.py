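"""Walk through the 5-patient worked example of the rating matrix.

Builds the small patients x medications matrix of encoded dose changes
(0 = not administered, 1 = decreased/steady, 2 = increased), computes a
cosine similarity by hand-checkable arithmetic, predicts one missing cell
from the patient's cluster, completes the whole matrix and prints a top-3
recommendation list.
"""

import numpy as np

from drugrec import (
    complete_matrix,
    cosine_similarity,
    predict_rating,
    recommend_top_n,
    table4_example,
)

m = table4_example()
print("Rating matrix (rows: patients, cluster labels at right):")
view = m.ratings.copy()
view["cluster"] = m.clusters
print(view.to_string(), "\n")

sim = cosine_similarity(m.ratings.loc[1], m.ratings.loc[3])
print(f"cosine(patient 1, patient 3) = {sim:.4f}  (= 3/sqrt(30) = "
      f"{3 / np.sqrt(30):.4f}; both are in cluster 1)")

p = predict_rating(m, 3, "medication_3")
print(f"predicted dose for (patient 3, medication_3) = {p.value:.1f} "
      f"[{p.provenance}]  -- patient 1 is the only same-cluster neighbour "
      "who received it, at dose 2\n")

completed, provenance = complete_matrix(m)
print("Completed matrix (observed cells unchanged, zeros predicted):")
print(completed.round(2).to_string(), "\n")

recs = recommend_top_n(m, 3, n=3)
print("Top-3 recommendations for patient 3 (score = predicted/observed dose,")
print("higher means a dose increase is expected in this patient group):")
for drug, score, prov in recs.items:
    print(f"  {drug:14s} {score:.2f}  [{prov}]")
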