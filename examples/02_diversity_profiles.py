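"""Diversity profiles: effective species numbers across orders q.

The Hill number of order q interpolates from species richness (q = 0)
through exponential Shannon entropy (q = 1) to inverse Simpson
concentration (q = 2); higher q down-weights rare species.  Constraining by
a similarity matrix Z discounts diversity among functionally similar
species, so the constrained profile is always at or below the naive one.
"""

import numpy as np
import pandas as pd

from lepdiv import diversity_profile, relative_abundance, trait_similarity

counts = [120, 60, 30, 15, 8, 4, 2, 1]
species = [f"sp{i}" for i in range(8)]
traits = pd.DataFrame(
    {
        "species_id": species,
        "host_plant": ["herb", "herb", "shrub", "shrub",
                       "deciduous_tree", "herb", "shrub", "herb"],
        "larval_specialism": ["multi_family"] * 8,
        "overwintering_stage": ["egg"] * 8,
        "wingspan": np.linspace(20, 55, 8),
    }
)

p = relative_abundance(counts, species)
grid = (0.0, 1.0, 2.0)

naive = diversity_profile(p, np.eye(8), grid)
z_host = trait_similarity(traits, "host_plant").subset(p.species_ids)
host = diversity_profile(p, z_host, grid)

print("q      naive D    host-plant constrained D")
for q in grid:
    print(f"{q:<6g} {naive.points[q]:<10.3f} {host.points[q]:.3f}")
print()
print("Naive q=0 counts all 8 species; the geometric decay in abundance")
print("pulls q=1 and q=2 down.  The host-plant profile is bounded by the 3")
print("host guilds present: many species per guild add little diversity.")
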