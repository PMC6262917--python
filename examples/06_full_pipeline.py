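"""End-to-end run: synthetic paired study through every analysis stage.

Generates the default study (13 broadleaf/plantation pairs, per-site mean
richness 63 vs 27, rare species sharing traits with common ones), then
computes diversity profiles under all six constraints, redundancy, the
permutation null model and the habitat mixed models, and prints the report.
"""

from lepdiv import PipelineConfig, StudyConfig, analyze_study, generate_study

abundance, traits, taxonomy = generate_study(StudyConfig(seed=1))
result = analyze_study(
    abundance, traits, taxonomy,
    PipelineConfig(seed=1, n_perm=199),
)
print(result.report)
print("Reading: the naive richness deficit is large and significant, but")
print("host-plant constrained richness barely differs -- the missing")
print("plantation species are functional duplicates of species still there.")
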