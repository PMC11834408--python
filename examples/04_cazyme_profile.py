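"""CAZyme profiling of the specific gene set (SGS) of candidate species.

Restricting the metagenomic gene catalog to the screened candidate
species and tabulating CAZyme annotations shows which taxa hold the
carbohydrate-degradation capacity — class composition, each species'
share, the cumulative share of the top contributors, and per-enzyme (KO)
species proportions.
"""

from fibromics import (
    CohortDesign,
    build_sgs,
    class_composition,
    enzyme_contribution_profile,
    fold_change_flag,
    screen_species,
    simulate_cohort,
    top_contributor_fraction,
)
from fibromics.simulate import KO_POOL

cohort = simulate_cohort(CohortDesign.screen_design(seed=1))
candidates = screen_species(cohort.abundances)
profile = build_sgs(candidates, cohort.catalog)

print(f"SGS: {profile.total} CAZyme-encoding genes across {len(profile.class_counts)} species")
comp = class_composition(profile)
print("class composition (fractions sum to 1):")
print((comp * 100).round(1).to_string())

k = min(8, int((profile.species_totals > 0).sum()))
print(f"top-{k} species hold {top_contributor_fraction(profile, k):.2f} % of all CAZyme genes")
print(f"top-{k} species hold {top_contributor_fraction(profile, k, class_filter='GH'):.2f} % of GH genes")

props, n_annotated = enzyme_contribution_profile(candidates, cohort.catalog, list(KO_POOL))
print(f"{n_annotated} of {len(KO_POOL)} pathway enzymes encoded by candidate species")

species = candidates.passed[0]
ratio, flag = fold_change_flag(cohort.abundances, species)
print(f"{species}: MS/LW abundance ratio {ratio:.2f} (enriched in MS: {flag})")
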