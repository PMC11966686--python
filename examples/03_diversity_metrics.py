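"""Functional and phylogenetic metrics for one simulated community.

Builds a phylogeny and traits with a planted pace-of-life axis, then
computes species richness (SR), functional dispersion (FDis, Gower + PCoA),
mean pairwise phylogenetic distance (MPD) and the community-weighted
pace-of-life (CWPoL) for a single community.
"""

from divstab import (community_weighted_mean, functional_dispersion,
                     mean_pairwise_distance, pace_of_life_axis,
                     simulate_phylogeny, simulate_traits)

phylo = simulate_phylogeny(12, seed=1)
traits = simulate_traits(phylo, n_numeric=3, n_nominal=1, pol_weight=0.8, seed=2)

axis = pace_of_life_axis(traits, anchor_trait="generation_length")
print(f"pace-of-life axis explains {axis.explained_variance_fraction:.1%} "
      f"of trait variance (sign flipped: {axis.sign_flipped})")

community = {"sp001": 10.0, "sp003": 4.0, "sp007": 1.0, "sp010": 2.0}
print(f"SR    = {len(community)}")
print(f"FDis  = {functional_dispersion(traits, community):.4f}")
print(f"MPD   = {mean_pairwise_distance(phylo, community):.4f}")
print(f"CWPoL = {community_weighted_mean(axis.scores.to_dict(), community):.4f}")
# FDis is the abundance-weighted spread of the four species in trait space
# (Gower units); MPD is their mean patristic distance in branch-length
# units; CWPoL > 0 means the community is dominated by slow-lived species
# relative to the pool average.
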