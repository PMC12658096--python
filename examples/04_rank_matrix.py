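"""Leave-one-out rank matrix of a cohort inside a large image background.

Each cohort subject probes the whole image space (background plus
cohort-mates); the directed rank of every cohort-mate is recorded.  Subjects
whose best mutual rank falls below 50 count as matched; ranks below 10 mark
strong pairs.  The min-symmetrized matrix is clustered for display.
"""

import numpy as np

from facegestalt import (SimConfig, cluster_rank_matrix, generate_cohort,
                         generate_gallery, match_summary,
                         pairwise_distance_matrix, pairwise_rank_matrix)

bg_cfg = SimConfig(n_syndromes=500, images_per_syndrome=1, d=128, m=4,
                   sigma_within=0.0, sigma_member=0.02, sigma_tta=0.01, seed=4)
background = generate_gallery(bg_cfg)
cohort_gallery, cohort = generate_cohort(bg_cfg, 15, dispersion=0.10, seed=5)
dmatrix = pairwise_distance_matrix(background.merged_with(cohort_gallery))

rm = pairwise_rank_matrix(cohort, background, dmatrix)
summary = match_summary(rm, cutoff=50, strong_cutoff=10)
off = rm.ranks[~np.eye(cohort.n, dtype=bool)]

print(f"background: {rm.gallery_size} images; cohort: {cohort.n} subjects")
print(f"median directed cohort-mate rank: {np.median(off):.0f} "
      f"(range 1..{rm.gallery_size + cohort.n - 1})")
print(f"subjects matched at rank < 50:    {summary.matched_count}/{cohort.n}")
print(f"strong pairs at rank < 10:        {len(summary.strong_pairs)}")
clustering = cluster_rank_matrix(rm)
print(f"dendrogram leaf order: {' '.join(clustering.leaf_order)}")
print("low mutual ranks mean cohort members retrieve each other ahead of the")
print("background — the hallmark of a recognizable shared facial gestalt.")
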