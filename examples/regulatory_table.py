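"""Regulatory-role enrichment table from a synthetic screen.

Annotates each screened KPSP's phosphosite with its (synthetic) regulatory
status, then renders the category-by-regulatory-status proportion table in
the published "X/Y (P%)" layout: Y KPSPs in the category, X of them with a
known regulatory role.  The second block keeps only sites whose regulatory
role is backed by at least two low-throughput references.
"""

from kpspcons import (
    annotate_regulatory_role,
    filter_kpsp_database,
    regulatory_proportion_table,
    run_conservation_screen,
)
from kpspcons.synthetic import SyntheticStudyConfig, generate_synthetic_study

study = generate_synthetic_study(SyntheticStudyConfig(seed=42))
kpsps = filter_kpsp_database(study.ks_records, study.reference)
calls = run_conservation_screen(kpsps, study.reference, study.targets)
annotations = annotate_regulatory_role(kpsps, study.regulatory_records)

print("All regulatory sites:")
print(regulatory_proportion_table(calls, annotations).to_string())
print("\nRegulatory sites with >= 2 low-throughput references:")
print(
    regulatory_proportion_table(calls, annotations, min_low_throughput_refs=2).to_string()
)
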