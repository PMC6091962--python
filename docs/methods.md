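# Methods

## The screen

A KPSP (kinase–phosphorylation-site pairing) couples one kinase accession to
one substrate phosphosite (accession, 1-based position, residue).  For each
KPSP and each target organism the pipeline makes two independent calls and
combines them into a four-way category:

| site conserved | kinase conserved | category        |
|----------------|------------------|-----------------|
| yes            | yes              | both_conserved  |
| yes            | no               | site_only       |
| no             | yes              | kinase_only     |
| no             | no               | neither         |

### Site conservation

The site is excised as a 15-mer with the phosphorylated residue central
(seven flanking residues each side; windows are truncated without padding at
protein termini, and the criteria thresholds are *not* rescaled for
truncated windows — a deliberately simple, conservative-leaning choice).
The query is compared, column by column, against every same-length window of
every target protein under BLOSUM62; the best hit maximizes the summed
substitution score, with ties broken by fewer differences, then smaller
accession, then smaller window start, which makes the search deterministic
and independent of input order.  Gapped alignment is deliberately absent:
for 15-mers an ungapped scan is exact, cheap, and makes the difference
counts unambiguous.  An adapter for external BLAST tabular output
(`blast_tab.py`) exists for full-proteome runs; it counts mismatches plus
gap openings as differences.

Conservation requires all four criteria:

1. **Differences** — at most 6 differing columns ("fewer than seven").
2. **Non-conservative differences** — at most 4 columns whose substitution
   is non-conservative.  The conservative/non-conservative boundary is a
   package decision: a substitution is conservative iff its BLOSUM62 score
   is strictly positive.  This is reproducible and matrix-derived; note it
   makes score-0 pairs (e.g. S↔G) non-conservative, and cysteine has no
   conservative partner at all.
3. **Position** — strict inequalities P_Q − 0.2·L_Q < P_H < P_Q + 0.2·L_Q,
   evaluated in exact rational arithmetic (integers cross-multiplied by the
   window fraction's denominator), so boundary cases like P_H = P_Q + 0.2·L_Q
   can never be flipped by floating-point rounding.
4. **Residue** — the aligned residue is S, T or Y, or equals the query
   residue.  As specified, this lets a phospho-Tyr query count as conserved
   over an aligned Ser — a kinase-class switch; the per-call output retains
   the aligned residue so downstream users can filter these.

With no candidate window at all (every target protein shorter than the
query), every flag is false.

### Kinase conservation

Reciprocal best hits with full Smith–Waterman (BLOSUM62, gap open 11 /
extend 1, score-only), ties broken lexicographically, and no score floor
beyond > 0 — reciprocity itself is the specificity filter.  Isoform
suffixes are stripped on both ends before the reciprocity comparison.
Alternatively, precomputed ortholog sets can be supplied (pairs tables or
ranked prediction tables, where only rank "high" counts); all three methods
produce the same downstream shape and are interchangeable.

Because RBH has no score floor, two proteomes of *unrelated* proteins can
still produce reciprocal pairs (local-alignment scores are symmetric, so any
mutually-best random pairing is reciprocal).  This matters for synthetic
data; see below.

### Database filtering

Input order is preserved while dropping: exact duplicate pairings; second
and later kinases for the same (substrate, position) site (only the first
listed KPSP is retained); pairings whose kinase or substrate accession is
absent from the reference proteome after isoform stripping.  Additionally —
beyond the stated upstream filters, as a switchable step that defaults on —
sites whose stated residue letter disagrees with the reference sequence at
the stated position are dropped with a log message, since stale coordinates
would corrupt every downstream window.

### Rendering

Percentages in the proportion tables and summaries are **truncated** (not
rounded) at one decimal via integer arithmetic, matching the published
table's style (8/9 → "88.8%", 1951/3059 → "63.7%"); zero denominators
render "N/A".  The validation rate is rendered at integer precision for the
mouse-style check and one decimal otherwise.

## Synthetic studies

The generator emulates the three real inputs — reference proteome,
kinase–substrate table, per-organism target proteomes (plus regulatory-site
and ortholog tables) — with a known label per (KPSP, organism).  Default
study conditions: 50 substrate proteins, 10 kinases, 10 decoys, protein
lengths 80–160, 100 KPSPs, and four organisms whose category mixes span all
four categories at increasing divergence (70/10/10/10, 50/10/20/20,
20/20/20/40, 5/5/15/75 percent both/site-only/kinase-only/neither), with
background substitution rates 1–8%.  Residues are sampled uniformly; the
construction is margin-based, so composition does not affect correctness.

Planted site states:

- *conserved*: ≤ 5 total window substitutions, ≤ 2 non-conservative,
  centre untouched;
- *excess differences*: 8–10 substitutions (biased toward mild,
  high-scoring replacements so the planted window usually remains the best
  hit);
- *excess non-conservative*: exactly 6 non-conservative substitutions and
  nothing else.  Note this mode necessarily sits at 6 total differences —
  the differences criterion passes at its boundary — because a failure of
  the non-conservative criterion alone is arithmetically impossible with
  fewer total differences;
- *residue change*: the centre becomes a non-phosphorylatable residue
  (single difference);
- *position shift*: an N-terminal insertion of length ⌊L/5⌋ + 3 moves every
  downstream position past the allowed window while leaving the 15-mer
  intact;
- *missing*: the substrate protein is absent from the target proteome.

Kinase conservation is planted per (kinase, organism) by emitting or
withholding a lightly mutated copy of the kinase, sometimes under an
isoform-suffixed accession.  Because conservation is a kinase-level
property, category fractions are exactly realizable when the
kinase-conserved fraction times the KPSP count is a multiple of the
per-kinase block size (KPSPs are assigned to kinases in equal contiguous
blocks); the default plans satisfy this and realize their fractions exactly.

Two constructions make truth recovery exact rather than probable:

- **Decoy twins.**  Every target decoy is a diverged copy of a decoy present
  in the reference proteome.  Each target protein therefore has a dominant
  reference partner, pinning every reverse best hit to the protein's own
  origin — a withheld kinase can never be confirmed through a spurious
  mutual-best pairing with an unrelated decoy.
- **Verification with bounded retries.**  After building each target
  proteome the generator re-runs the actual engines: every planted site
  must be found at the planted location with the planted counts (or, for
  excess-difference and deleted sites, every available hit must fail the
  differences criterion), and every kinase's RBH call must match its
  intended state.  Decoy windows are additionally screened to differ from
  every query window in ≥ 8 columns.  A failed check discards the organism
  and redraws; the collision probability is so small that retries are
  essentially never needed, and a persistent failure raises an error naming
  the seed.

All randomness flows from a single seeded generator: equal seeds give
byte-identical written studies.

What the generator does *not* emulate: real amino-acid composition,
phylogenetic correlation between organisms, rate variation across sites and
proteins, paralogous families, or disordered-region clustering of
phosphosites.  Passing the recovery suite therefore demonstrates the
pipeline's correctness — that the implemented criteria and orthology test
classify exactly as defined — not that the criteria themselves are
biologically optimal on real proteomes.

## Problem sizes in the test suite

The oracle-equivalence suite compares the search engine against an
independent brute-force enumeration on 1000 random instances (≤ 5 proteins,
length ≤ 120); the recovery suite screens 20 seeded studies at the default
conditions (2,400 instance pairs per run in the acceptance script's 6-study
variant).  These sizes exercise every code path at full fidelity; the
screen itself scales linearly in total target-proteome length per query and
has been kept free of per-proteome state so larger runs can be sharded
trivially.

## Known limitations

- Best-hit search is ungapped by design; a target site split by a true
  insertion *within* the 15-mer window will score poorly and may be missed
  (the external-BLAST adapter is the escape hatch).
- Truncated terminal windows keep absolute thresholds, which makes short
  windows easier to conserve; sites within 7 residues of a terminus are
  rare but interpret their calls accordingly.
- RBH conservation calls inherit the method's known blindness to lineage-
  specific duplications (a paralog displacing the true ortholog breaks
  reciprocity and the kinase is called non-conserved).
- The regulatory-role match requires the modification to be phosphorylation
  at the exact (accession, position, residue) key; relaxing to any
  modification type is a one-flag change in `annotate_regulatory_role`'s
  input preparation but is off by default.
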