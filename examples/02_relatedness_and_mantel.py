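"""Do related deer migrate at similar times?

Builds the Queller-Goodnight relatedness matrix, the |day difference|
matrix for fall migration termination, and runs Mantel and partial
Mantel tests (controlling for winter-range centroid distance).  A
negative Mantel r means more closely related individuals migrate closer
together in time.
"""

import pandas as pd

import hetmig as hm
from hetmig.migration import RangeCentroids, centroid_distance_matrix

cfg = hm.SimConfig(seed=5)
table, truth = hm.simulate_genotypes(cfg)
mig = hm.simulate_migration_dates(truth, cfg).set_index("id")

rel = hm.queller_goodnight(table)
print(f"QG relatedness: mean off-diagonal {rel.mean_offdiagonal():+.4f} "
      "(sample-centred, so ~0)")

dates = {i: (None if pd.isna(v) else float(v)) for i, v in mig["fall_end"].items()}
tdm = hm.timing_distance_matrix(dates)
a = rel.as_pairwise().align(tdm.ids)

res = hm.mantel_test(a, tdm, n_permutations=9999, n_boot=500, seed=5)
print(f"Mantel r = {res.r:+.3f}  95% CL ({res.ci_lower:+.3f}, {res.ci_upper:+.3f})"
      f"  p = {res.p_value:.4f}")

cents = RangeCentroids(
    winter={i: (r["winter_x"], r["winter_y"]) for i, r in mig.iterrows()},
    summer={i: (r["summer_x"], r["summer_y"]) for i, r in mig.iterrows()},
)
cdm = centroid_distance_matrix(cents, "winter").align(tdm.ids)
pres = hm.partial_mantel_test(a, tdm, cdm, n_permutations=9999, n_boot=500, seed=6)
print(f"partial r | winter distance = {pres.r:+.3f} "
      f"({pres.ci_lower:+.3f}, {pres.ci_upper:+.3f})")
print("a negative r that survives the spatial control means timing similarity "
      "tracks kinship, not just shared ranges")
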