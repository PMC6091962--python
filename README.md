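# kpspcons

Cross-species conservation screening of **kinase–phosphorylation-site
pairings (KPSPs)** — a specific kinase together with a specific substrate
phosphosite it modifies.

Protein phosphorylation is pervasive, but how stable is the *pairing* of a
kinase with an individual site across evolution?  Given a reference
("human") proteome, a table of experimentally known kinase–substrate
pairings, and the proteome of any target organism, `kpspcons` decides for
every KPSP and organism whether the phosphosite is conserved, whether the
kinase is conserved, and hence which of four categories the pairing falls
into: both conserved, phosphosite only, kinase only, or neither.  It is
aimed at computational biologists studying phosphoproteome evolution, and
ships a fully labelled synthetic-study generator so every part of the
pipeline can be exercised and verified without multi-gigabyte proteome
downloads.

## Method

**Phosphosite conservation.**  Each known site is represented as a 15-mer
peptide with the phosphorylated residue in the centre (truncated at protein
termini).  The peptide is compared against *every* same-length window of
every target protein with ungapped BLOSUM62 scoring — an exhaustive,
deterministic search.  The best-scoring window is the site's hit, and the
site counts as conserved iff all four criteria hold:

1. fewer than 7 sequence differences between query and hit;
2. fewer than 5 of those differences are non-conservative
   (BLOSUM62 score ≤ 0);
3. the hit position lies strictly inside the positional window,
   P_Q − 0.2·L_Q < P_H < P_Q + 0.2·L_Q, where P_Q / P_H are the site
   positions in query / hit protein and L_Q is the query-protein length
   (evaluated in exact integer arithmetic);
4. the aligned residue is a canonical phosphoacceptor (S/T/Y) or matches the
   query residue (covering non-canonical acceptors such as His).

**Kinase conservation.**  Reciprocal best hits (RBH): the kinase is aligned
against the target proteome (Smith–Waterman, BLOSUM62, affine gaps 11/1),
its best hit is aligned back, and the kinase is conserved iff the reverse
best hit is the kinase itself, comparing isoform-stripped accessions
(`P12345-3` ≡ `P12345`).  Precomputed ortholog tables (Hieranoid-style
pairs, DIOPT-style ranked predictions) are accepted as drop-in alternatives.

**Downstream.**  Per-organism category counts and percentages, the count of
pairings conserved in *all* organisms, false-rejection validation against
experimentally known sites in a target organism, and regulatory-role
proportion tables ("X/Y (P%)" cells, optionally restricted to sites with ≥ 2
low-throughput literature references).

## Worked example

```bash
python examples/run_screen.py
```

generates a seeded synthetic study (50 substrate proteins, 10 kinases, 100
KPSPs, 4 organisms with planted conservation states) and screens it:

```
100 KPSPs screened against 4 organisms

organism     both   site  kinase  neither   (percent of KPSPs per category)
chicken      50.0   10.0    20.0     20.0
fly          20.0   20.0    20.0     40.0
macaque      70.0   10.0    10.0     10.0
yeast         5.0    5.0    15.0     75.0

conserved in all organisms: 0 KPSPs
classification vs planted truth: 400/400 correct
```

Each row is one target organism; the four columns give the percentage of
KPSPs in each conservation category, and the final line confirms the screen
recovered every planted ground-truth label.  `examples/site_conservation_demo.py`
walks through the four criteria for a single site, and
`examples/regulatory_table.py` renders the regulatory-enrichment table.

A thin CLI wraps the same library calls:

```bash
kpsp-conserve synth --seed 1 --out study/
kpsp-conserve screen --reference study/reference.fasta \
    --target macaque=study/targets/macaque.fasta \
    --kinase-substrate study/kinase_substrate.tsv --out results/
```

## Layout

- `src/kpspcons/io.py` — FASTA proteomes, kinase–substrate and
  regulatory-site table dialects, accession handling
- `src/kpspcons/peptides.py` — 15-mer extraction, substitution
  classification, exhaustive best-window search
- `src/kpspcons/criteria.py` — the four site-conservation criteria
- `src/kpspcons/orthology.py` — RBH and ortholog-table readers
- `src/kpspcons/pipeline.py` — database filtering, screening, summaries,
  validation
- `src/kpspcons/regulatory.py` — regulatory-role annotation and tables
- `src/kpspcons/synthetic.py` — seeded study generator with planted truth
- `src/kpspcons/blast_tab.py` — adapter for external BLAST tabular output

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
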