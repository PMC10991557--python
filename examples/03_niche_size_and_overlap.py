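"""Posterior niche sizes and directional overlap between two species.

Each species' niche is a multivariate normal fitted with a non-informative
conjugate prior; the niche size is the hypervolume of its 95% ellipsoid
(posterior mode and 5–95% band), and overlap is the probability that an
individual of one species falls inside the other's niche region —
asymmetric by construction.
"""

import isoniche as iso

dataset = iso.complete_case_filter(iso.default_community(seed=7))
space, _, _ = iso.build_dimension_space(dataset, "2D")

posts = {
    name: iso.sample_posterior(space.group_coords(name), K=10_000, seed=i,
                               group=name, axis_names=space.axis_names)
    for i, name in enumerate(dataset.species_names())
}

print("2D niche size, posterior mode (5%-95% quantiles):")
for name, post in posts.items():
    s = iso.NicheSizeSummary.from_posterior(post, alpha=0.95).summary
    print(f"  {name:<18} {s.mode:6.2f}  ({s.q05:.2f}-{s.q95:.2f})")

a, b = "pelagic_cormorant", "dc_cormorant"
ab = iso.niche_overlap(posts[a], posts[b], n_mc=1000, seed=1)
ba = iso.niche_overlap(posts[b], posts[a], n_mc=1000, seed=2)
print(f"\nDirectional overlap (posterior mean):")
print(f"  {a} onto {b}: {100 * ab.summary.mean:.1f}%")
print(f"  {b} onto {a}: {100 * ba.summary.mean:.1f}%")
print("\nThe asymmetry reflects the size difference: the smaller niche "
      "sits largely inside the bigger one, not vice versa.")
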