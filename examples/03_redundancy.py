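"""Functional redundancy: how many species share each functional role.

Redundancy = naive richness / similarity-constrained richness at q = 0.
A community of 10 equally abundant species falling into 2 functional blocks
has constrained richness 2 and redundancy 5: five species per role, so the
community can lose species without losing function.
"""

import numpy as np

from lepdiv import SimilarityMatrix, redundancy

species = [f"sp{i}" for i in range(10)]
Z = np.zeros((10, 10))
Z[:5, :5] = 1.0  # block 1: five herb feeders, fully interchangeable
Z[5:, 5:] = 1.0  # block 2: five tree feeders
z = SimilarityMatrix(species, Z)

r = redundancy([10] * 10, z, species)
print(f"naive richness:       {r.naive_richness:.0f}")
print(f"constrained richness: {r.constrained_richness:.0f}")
print(f"redundancy:           {r.redundancy:.0f}  (species per functional role)")

# an uneven community: rare species concentrated in one block
r2 = redundancy([50, 40, 30, 20, 10, 1, 1, 1, 1, 1], z, species)
print(f"\nuneven community redundancy: {r2.redundancy:.2f}")
print("Redundancy is computed at q = 0, so rarity does not change the")
print("ratio as long as the same species are present.")
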