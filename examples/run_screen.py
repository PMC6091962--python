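"""End-to-end screen on a small synthetic study.

Generates a seeded study (reference proteome, kinase-substrate table, four
target proteomes with planted conservation states), runs the full
classification, and prints the per-organism category breakdown next to the
generator's ground truth.  Percentages are fractions of all screened KPSPs;
with planted states the screen should recover the plan exactly.
"""

from kpspcons import (
    Category,
    filter_kpsp_database,
    n_conserved_in_all_organisms,
    run_conservation_screen,
    summarize_by_organism,
)
from kpspcons.synthetic import SyntheticStudyConfig, generate_synthetic_study

config = SyntheticStudyConfig(seed=42)
study = generate_synthetic_study(config)
kpsps = filter_kpsp_database(study.ks_records, study.reference)
print(f"{len(kpsps)} KPSPs screened against {len(study.targets)} organisms\n")

calls = run_conservation_screen(kpsps, study.reference, study.targets)
header = f"{'organism':<10} {'both':>6} {'site':>6} {'kinase':>7} {'neither':>8}"
print(header + "   (percent of KPSPs per category)")
for s in summarize_by_organism(calls):
    print(
        f"{s.organism:<10} "
        f"{s.formatted_percentage(Category.BOTH_CONSERVED):>6} "
        f"{s.formatted_percentage(Category.SITE_ONLY):>6} "
        f"{s.formatted_percentage(Category.KINASE_ONLY):>7} "
        f"{s.formatted_percentage(Category.NEITHER):>8}"
    )

truth = study.truth_by_key()
mismatches = sum(
    1
    for c in calls
    if c.category
    != truth[(c.kpsp.kinase_accession, c.kpsp.site.accession,
              c.kpsp.site.position, c.organism)].category
)
print(f"\nconserved in all organisms: {n_conserved_in_all_organisms(calls)} KPSPs")
print(f"classification vs planted truth: {len(calls) - mismatches}/{len(calls)} correct")
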