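"""Anatomy of a single site-conservation call.

Builds a toy reference protein with a phosphoserine, a diverged target
protein carrying a conservative substitution, extracts the 15-mer query, finds
the best window in the target, and walks through the four criteria: the
difference counts, the positional window P_Q +/- 0.2*L_Q, and the aligned
residue's phosphoacceptor status.
"""

from kpspcons import (
    Proteome,
    best_peptide_hit,
    evaluate_site_conservation,
    extract_site_peptide,
)

reference = Proteome(
    entries={"P00001": "MEEPQSDPSVEPPLSQETFSDLWKLLPENNVLSPLPSQAMDDLMLSPDDI"}
)
# the target ortholog: S->T at one flank position, D->E at another
target = Proteome(
    entries={"T00001": "MEEPQTDPSVEPPLSQETFSELWKLLPENNVLSPLPSQAMDDLMLSPDDI"}
)

site_position = 15  # the serine in ...PPLS*QETF...
query = extract_site_peptide(reference, "P00001", site_position)
print(f"query 15-mer: {query.sequence} (centre residue {query.site_residue})")
print(f"P_Q={query.source_position}, L_Q={query.source_protein_length}")

hit = best_peptide_hit(query, target)
print(
    f"\nbest hit: {hit.hit_accession} window starting at {hit.hit_window_start}, "
    f"P_H={hit.hit_position}, aligned residue {hit.hit_residue}"
)
print(
    f"differences: {hit.n_differences} total, "
    f"{hit.n_nonconservative} non-conservative, score {hit.alignment_score}"
)

decision = evaluate_site_conservation(query, hit)
print(
    f"\ncriteria: <7 differences {decision.passes_differences}, "
    f"<5 non-conservative {decision.passes_nonconservative},\n"
    f"          position within +/-0.2*L_Q {decision.passes_position}, "
    f"residue phosphorylatable {decision.passes_residue}"
)
print(f"site conserved: {decision.conserved}")
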