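"""Build the three kinds of species similarity matrix.

A similarity matrix Z (S x S, entries in [0, 1], unit diagonal) encodes how
interchangeable two species are: the identity matrix treats all species as
completely distinct ("naive"), single-trait Gower similarity scores
functional overlap, and shared taxonomic rank scores relatedness.
"""

import pandas as pd

from lepdiv import identity_similarity, taxonomic_similarity, trait_similarity

traits = pd.DataFrame(
    {
        "species_id": ["brimstone", "carpet_moth", "drinker", "emerald"],
        "host_plant": ["shrub", "herb", "grass", "shrub"],
        "larval_specialism": ["single_family", "multi_family", "multi_family",
                              "single_family"],
        "overwintering_stage": ["larva", "pupa", "larva", "larva"],
        "wingspan": [42.0, 25.0, 55.0, 30.0],
    }
)
taxonomy = pd.DataFrame(
    {
        "species_id": traits["species_id"],
        "genus": ["opisthograptis", "xanthorhoe", "euthrix", "geometra"],
        "family": ["geometridae", "geometridae", "lasiocampidae", "geometridae"],
    }
)

print("naive (identity):")
print(identity_similarity(traits["species_id"]).to_frame(), "\n")

print("host plant (categorical Gower: 1 = same host guild):")
print(trait_similarity(traits, "host_plant").to_frame(), "\n")

print("wingspan (continuous Gower: 1 - |dx|/range):")
print(trait_similarity(traits, "wingspan").to_frame().round(2), "\n")

print("taxonomy (same genus 2/3, same family 1/3, else 0):")
print(taxonomic_similarity(taxonomy).to_frame().round(2))
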