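"""Two-period niche comparison for one species.

The packaged community gives both cormorant-like species a post-1990
centroid shift on the carbon axes and a covariance shrink, emulating a
prey-base decline. The temporal analysis shares one PCA basis across
periods, then reports niche sizes per period, the probability the
centroids differ, and the directional overlap between periods.
"""

import isoniche as iso

dataset = iso.default_community(seed=7)
result = iso.temporal_analysis(dataset, "dc_cormorant",
                               K=10_000, n_mc=1000, seed=1)

print("Niche size per period (posterior mode, 5%-95%):")
print(result.sizes_table().round(2).to_string(index=False))
print("\nCentroid-difference probability and distance:")
print(result.tests_table().round(3).to_string(index=False))
print("\nDirectional overlap between periods (%):")
print(result.overlap_table().round(1).to_string(index=False))
print("\nThe period-2 carbon shift barely registers in 2D but cuts the "
      "between-period overlap sharply once the extra axes are included.")
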