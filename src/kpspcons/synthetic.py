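"""Seeded synthetic studies with planted, labelled conservation states.

The generator emits a reference ("human") proteome, a kinase–substrate table,
a regulatory-sites table, and one target proteome per planned organism, with
every (KPSP, organism) pair planted into a known category:

* site conserved   — the ortholog's site window carries a small, controlled
  number of conservative/non-conservative substitutions (total <= 5);
* site not conserved — exactly one criterion is driven to fail: an
  excess-differences window (>= 8 substitutions), an excess-non-conservative
  window (6 non-conservative, total 6 so the differences criterion still
  passes), a phosphoacceptor change at the centre, an N-terminal insertion
  longer than 20% of the protein (position criterion), or deletion of the
  whole substrate;
* kinase conserved / absent — the kinase protein is copied into the target
  proteome (lightly mutated, sometimes under an isoform-suffixed accession)
  or withheld.

Decoy proteins are screened so every decoy window differs from every query
window, and after building each target proteome the generator verifies every
planted site through the actual homology engine (best hit identity, mapped
position and difference counts) and every kinase through the actual RBH test,
retrying with fresh draws on the (astronomically rare) random collision.
Recovery of the planted truth by the screen is therefore exact, not merely
probable.  All randomness flows from one seeded generator, so a given seed
reproduces the study byte-for-byte.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .config import CriteriaConfig
from .io import (
    CANONICAL_RESIDUES,
    KinaseSubstrateRecord,
    Proteome,
    RegulatorySiteRecord,
    write_fasta_proteome,
)
from .orthology import ProteinAligner, reciprocal_best_hit
from .peptides import (
    DEFAULT_CLASSIFIER,
    SubstitutionClassifier,
    best_peptide_hit,
    encode_sequence,
    extract_site_peptide,
)
from .pipeline import Category, classify_kpsp

logger = logging.getLogger(__name__)

_CANON = list(CANONICAL_RESIDUES)

#: decoy windows must differ from every query window in at least this many columns
DECOY_MARGIN = 8

FAILURE_MODES = ("differences", "nonconservative", "residue", "position", "missing")


@dataclass(frozen=True)
class OrganismPlan:
    """Per-organism category mix and divergence knobs.

    Fractions refer to KPSPs and must sum to 1.  ``f_both + f_kinase_only``
    (the kinase-conserved fraction) is realized at per-kinase granularity,
    since kinase conservation is a property of the kinase, not the KPSP.
    """

    organism: str
    f_both: float
    f_site_only: float
    f_kinase_only: float
    f_neither: float
    background_substitution_rate: float = 0.03
    kinase_substitution_rate: float = 0.02

    def fractions(self) -> tuple[float, float, float, float]:
        return (self.f_both, self.f_site_only, self.f_kinase_only, self.f_neither)


#: default study conditions: four organisms at increasing divergence, jointly
#: covering all four categories and all five site-failure modes
DEFAULT_PLANS = (
    OrganismPlan("macaque", 0.70, 0.10, 0.10, 0.10, background_substitution_rate=0.01),
    OrganismPlan("chicken", 0.50, 0.10, 0.20, 0.20, background_substitution_rate=0.03),
    OrganismPlan("fly", 0.20, 0.20, 0.20, 0.40, background_substitution_rate=0.05),
    OrganismPlan("yeast", 0.05, 0.05, 0.15, 0.75, background_substitution_rate=0.08),
)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    n_substrate_proteins: int = 50
    n_kinases: int = 10
    n_decoys: int = 10
    protein_length_range: tuple[int, int] = (80, 160)
    n_kpsps: int = 100
    organisms: tuple[OrganismPlan, ...] = DEFAULT_PLANS
    regulatory_fraction: float = 0.5
    lt_ref_choices: tuple[int, ...] = (0, 1, 2, 3, 5)
    isoform_suffix_rate: float = 0.15
    seed: int = 0
    max_retries: int = 8

    def validate(self) -> None:
        lo, hi = self.protein_length_range
        if lo < 30 or hi < lo:
            raise ValueError("protein_length_range must be (lo >= 30, hi >= lo)")
        if self.n_kinases < 1 or self.n_substrate_proteins < 1:
            raise ValueError("need at least one kinase and one substrate protein")
        per = -(-self.n_kpsps // self.n_substrate_proteins)  # ceil
        max_sites = (lo - 15) // 15 + 1
        if per > max_sites:
            raise ValueError(
                f"{self.n_kpsps} KPSPs over {self.n_substrate_proteins} proteins "
                f"needs {per} sites/protein; length {lo} fits only {max_sites}"
            )
        for plan in self.organisms:
            if abs(sum(plan.fractions()) - 1.0) > 1e-9:
                raise ValueError(f"fractions for {plan.organism!r} do not sum to 1")
            g = plan.f_both + plan.f_kinase_only
            block = self.n_kpsps / self.n_kinases
            if abs((g * self.n_kpsps) % block) > 1e-6 and abs((g * self.n_kpsps) % block - block) > 1e-6:
                logger.warning(
                    "kinase-conserved fraction %.2f for %s is not a multiple of the "
                    "per-kinase block (%g KPSPs); nearest achievable count is used",
                    g, plan.organism, block,
                )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted (KPSP, organism) pair."""

    kinase_accession: str
    substrate_accession: str
    position: int
    residue: str
    organism: str
    category: Category
    site_conserved: bool
    kinase_conserved: bool
    failure_mode: str | None
    n_conservative: int
    n_nonconservative: int
    position_offset: int
    target_accession: str  # "" when the substrate was deleted


@dataclass
class SyntheticStudy:
    config: SyntheticStudyConfig
    reference: Proteome
    ks_records: list[KinaseSubstrateRecord]
    regulatory_records: list[RegulatorySiteRecord]
    targets: dict[str, Proteome]
    truth: list[TruthRecord]
    kinase_truth: dict[tuple[str, str], bool]  # (reference kinase acc, organism)
    target_kinase_accessions: dict[tuple[str, str], str] = field(default_factory=dict)

    def truth_by_key(self) -> dict[tuple[str, str, int, str], TruthRecord]:
        return {
            (t.kinase_accession, t.substrate_accession, t.position, t.organism): t
            for t in self.truth
        }


# ---------------------------------------------------------------------------
# low-level helpers

def _partners(classifier: SubstitutionClassifier):
    """(conservative, non-conservative) replacement candidates per residue."""
    cached = getattr(classifier, "_partner_cache", None)
    if cached is not None:
        return cached
    cons: dict[str, list[str]] = {}
    noncons: dict[str, list[str]] = {}
    for a in CANONICAL_RESIDUES + "X":
        cons[a] = [
            b
            for b in CANONICAL_RESIDUES
            if b != a and classifier.score(a, b) > classifier.conservative_threshold
        ]
        noncons[a] = [
            b
            for b in CANONICAL_RESIDUES
            if b != a and classifier.score(a, b) <= classifier.conservative_threshold
        ]
    classifier._partner_cache = (cons, noncons)  # type: ignore[attr-defined]
    return cons, noncons


def mutate_window(
    window: str,
    center_offset: int,
    n_conservative: int,
    n_nonconservative: int,
    preserve_center: bool = True,
    rng: np.random.Generator | None = None,
    classifier: SubstitutionClassifier = DEFAULT_CLASSIFIER,
    choice: str = "random",
) -> str:
    """Plant exact substitution counts into a peptide window.

    Exactly ``n_conservative`` positions are replaced by a residue scoring
    above the conservative threshold against the original (and differing from
    it), and ``n_nonconservative`` by a residue scoring at or below it, so the
    column-wise counters recover exactly these counts.  Raises when the
    request is impossible (too many positions, or no qualifying replacement —
    e.g. cysteine has no positively-scoring BLOSUM62 partner).

    ``choice="mild"`` picks the highest-scoring qualifying replacement at each
    position instead of a random one, keeping the mutated window's alignment
    score as high as the requested counts allow.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n_total = n_conservative + n_nonconservative
    usable = len(window) - (1 if preserve_center else 0)
    if n_total > usable:
        raise ValueError(f"cannot plant {n_total} mutations in {usable} usable positions")
    cons_p, noncons_p = _partners(classifier)
    positions = [i for i in range(len(window)) if not (preserve_center and i == center_offset)]
    order = list(rng.permutation(len(positions)))
    positions = [positions[i] for i in order]
    cons_eligible = [i for i in positions if cons_p[window[i]]]
    if len(cons_eligible) < n_conservative:
        raise ValueError(
            f"only {len(cons_eligible)} positions admit a conservative substitution; "
            f"{n_conservative} requested"
        )
    chosen_cons = cons_eligible[:n_conservative]
    remaining = [i for i in positions if i not in chosen_cons]
    noncons_eligible = [i for i in remaining if noncons_p[window[i]]]
    if len(noncons_eligible) < n_nonconservative:
        raise ValueError(
            f"only {len(noncons_eligible)} positions admit a non-conservative "
            f"substitution; {n_nonconservative} requested"
        )
    chosen_noncons = noncons_eligible[:n_nonconservative]
    def _pick(cands: list[str], original: str) -> str:
        if choice == "mild":
            return max(cands, key=lambda b: (classifier.score(original, b), b))
        return cands[int(rng.integers(len(cands)))]

    out = list(window)
    for i in chosen_cons:
        out[i] = _pick(cons_p[window[i]], window[i])
    for i in chosen_noncons:
        out[i] = _pick(noncons_p[window[i]], window[i])
    return "".join(out)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(_CANON), size=length)
    return "".join(_CANON[i] for i in idx)


def _min_query_distance(seq: str, query_arrays: list[np.ndarray]) -> int:
    """Smallest column-wise difference count between any window of ``seq``
    and any query; large when ``seq`` is shorter than the queries."""
    enc = encode_sequence(seq)
    best = 10**9
    for q in query_arrays:
        w = len(q)
        if len(enc) < w:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        diffs = (windows != q).sum(axis=1)
        best = min(best, int(diffs.min()))
    return best


# ---------------------------------------------------------------------------
# study generation

def _plant_sites(
    rng: np.random.Generator, lengths: list[int], n_kpsps: int
) -> list[list[int]]:
    """Positions per substrate protein: interior (full 15-mer) and >= 15 apart."""
    n = len(lengths)
    base, extra = divmod(n_kpsps, n)
    counts = [base + (1 if i < extra else 0) for i in range(n)]
    all_positions: list[list[int]] = []
    for length, k in zip(lengths, counts):
        if k == 0:
            all_positions.append([])
            continue
        lo, hi = 8, length - 7
        for _ in range(500):
            picks = sorted(int(x) for x in rng.integers(lo, hi + 1, size=k))
            if len(set(picks)) == k and all(
                b - a >= 15 for a, b in zip(picks, picks[1:])
            ):
                all_positions.append(picks)
                break
        else:
            raise RuntimeError(f"could not place {k} sites in a length-{length} protein")
    return all_positions


def _org_prefix(organism: str) -> str:
    letters = "".join(ch for ch in organism.upper() if ch.isalpha())
    return (letters[:3] or "ORG")


def generate_synthetic_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate the full study (reference, tables, targets, truth) in memory."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    classifier = DEFAULT_CLASSIFIER
    aligner = ProteinAligner()

    lo, hi = config.protein_length_range
    sub_accs = [f"HSUB{i:04d}" for i in range(1, config.n_substrate_proteins + 1)]
    kin_accs = [f"HKIN{i:04d}" for i in range(1, config.n_kinases + 1)]

    sub_lengths = [int(x) for x in rng.integers(lo, hi + 1, size=len(sub_accs))]
    sequences = {acc: list(_random_protein(rng, L)) for acc, L in zip(sub_accs, sub_lengths)}
    site_positions = _plant_sites(rng, sub_lengths, config.n_kpsps)
    sites: list[tuple[str, int, str]] = []
    for acc, positions in zip(sub_accs, site_positions):
        for pos in positions:
            residue = "STY"[int(rng.integers(3))]
            sequences[acc][pos - 1] = residue
            sites.append((acc, pos, residue))
    for acc in kin_accs:
        sequences[acc] = list(_random_protein(rng, int(rng.integers(lo, hi + 1))))
    query_windows = [
        encode_sequence("".join(sequences[acc][pos - 8 : pos + 7]))
        for acc, positions in zip(sub_accs, site_positions)
        for pos in positions
    ]
    # reference decoys: target decoys are derived from these so that every
    # target protein has a dominant reference partner, which pins each reverse
    # best hit to the protein's own origin and makes RBH outcomes deterministic
    dec_accs = [f"HDEC{i:04d}" for i in range(1, config.n_decoys + 1)]
    for acc in dec_accs:
        for _ in range(50):
            seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
            if _min_query_distance(seq, query_windows) >= DECOY_MARGIN + 2:
                break
        else:  # pragma: no cover - random 15-mers almost never collide
            raise RuntimeError(f"could not draw a clean decoy (seed {config.seed})")
        sequences[acc] = list(seq)
    reference = Proteome(
        entries={acc: "".join(sequences[acc]) for acc in sub_accs + kin_accs + dec_accs},
        organism_label="human",
    )

    sites.sort()
    kpsp_kinase = [j * config.n_kinases // config.n_kpsps for j in range(len(sites))]
    ks_records = [
        KinaseSubstrateRecord(
            kinase_accession=kin_accs[kpsp_kinase[j]],
            substrate_accession=acc,
            site_position=pos,
            site_residue=res,
            kinase_organism="human",
            substrate_organism="human",
        )
        for j, (acc, pos, res) in enumerate(sites)
    ]

    regulatory_records = []
    for acc, pos, res in sites:
        if rng.random() < config.regulatory_fraction:
            n_lt = int(config.lt_ref_choices[int(rng.integers(len(config.lt_ref_choices)))])
            regulatory_records.append(
                RegulatorySiteRecord(acc, pos, res, "phospho", n_lt)
            )

    queries = {
        (acc, pos): extract_site_peptide(reference, acc, pos)
        for acc, pos, _ in sites
    }
    query_arrays = [encode_sequence(q.sequence) for q in queries.values()]

    targets: dict[str, Proteome] = {}
    truth: list[TruthRecord] = []
    kinase_truth: dict[tuple[str, str], bool] = {}
    target_kin_accs: dict[tuple[str, str], str] = {}

    kpsps_by_kinase: dict[int, list[int]] = {}
    for j, ki in enumerate(kpsp_kinase):
        kpsps_by_kinase.setdefault(ki, []).append(j)

    for plan in config.organisms:
        for attempt in range(config.max_retries):
            result = _build_organism(
                plan, config, rng, reference, sites, kpsp_kinase, kpsps_by_kinase,
                queries, query_arrays, kin_accs, dec_accs, classifier, aligner,
            )
            if result is not None:
                target, org_truth, org_kin_truth, org_kin_accs = result
                targets[plan.organism] = target
                truth.extend(org_truth)
                kinase_truth.update(org_kin_truth)
                target_kin_accs.update(org_kin_accs)
                break
            logger.warning(
                "verification failed for organism %s (attempt %d); regenerating",
                plan.organism, attempt + 1,
            )
        else:
            raise RuntimeError(
                f"could not realize plan for {plan.organism!r} after "
                f"{config.max_retries} attempts (seed {config.seed})"
            )

    return SyntheticStudy(
        config=config,
        reference=reference,
        ks_records=ks_records,
        regulatory_records=regulatory_records,
        targets=targets,
        truth=truth,
        kinase_truth=kinase_truth,
        target_kinase_accessions=target_kin_accs,
    )


def _build_organism(
    plan: OrganismPlan,
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
    reference: Proteome,
    sites: list[tuple[str, int, str]],
    kpsp_kinase: list[int],
    kpsps_by_kinase: dict[int, list[int]],
    queries: dict,
    query_arrays: list[np.ndarray],
    kin_accs: list[str],
    dec_accs: list[str],
    classifier: SubstitutionClassifier,
    aligner: ProteinAligner,
):
    """One attempt at building a target proteome realizing ``plan``.

    Returns None when post-build verification finds a random collision.
    """
    n = len(sites)
    prefix = _org_prefix(plan.organism)

    # --- kinase conservation at per-kinase granularity
    m_target = round((plan.f_both + plan.f_kinase_only) * n)
    perm = list(rng.permutation(len(kin_accs)))
    conserved_kinases: set[int] = set()
    covered = 0
    for ki in perm:
        block = len(kpsps_by_kinase.get(ki, []))
        if covered >= m_target:
            break
        if abs(covered + block - m_target) <= abs(covered - m_target):
            conserved_kinases.add(ki)
            covered += block
        else:
            break
    kinase_conserved_kpsps = [
        j for j in range(n) if kpsp_kinase[j] in conserved_kinases
    ]
    kinase_absent_kpsps = [j for j in range(n) if kpsp_kinase[j] not in conserved_kinases]

    # --- site conservation per KPSP
    n_both = min(round(plan.f_both * n), len(kinase_conserved_kpsps))
    n_site_only = min(round(plan.f_site_only * n), len(kinase_absent_kpsps))
    site_conserved: set[int] = set()
    if n_both:
        site_conserved.update(
            int(j) for j in rng.choice(kinase_conserved_kpsps, n_both, replace=False)
        )
    if n_site_only:
        site_conserved.update(
            int(j) for j in rng.choice(kinase_absent_kpsps, n_site_only, replace=False)
        )

    # --- failure-mode assignment
    by_protein: dict[str, list[int]] = {}
    for j, (acc, _pos, _res) in enumerate(sites):
        by_protein.setdefault(acc, []).append(j)
    protein_mode_cycle = itertools.cycle(("position", "missing", "local"))
    site_mode_cycle = itertools.cycle(("differences", "nonconservative", "residue"))
    failure_mode: dict[int, str] = {}
    protein_mode: dict[str, str] = {}
    for acc in sorted(by_protein):
        idxs = by_protein[acc]
        failing = [j for j in idxs if j not in site_conserved]
        if not failing:
            continue
        if len(failing) == len(idxs):
            mode = next(protein_mode_cycle)
            if mode in ("position", "missing"):
                protein_mode[acc] = mode
                for j in failing:
                    failure_mode[j] = mode
                continue
        for j in failing:
            failure_mode[j] = next(site_mode_cycle)

    # --- build target entries
    entries: dict[str, str] = {}
    org_truth: list[TruthRecord] = []
    planted: dict[int, tuple[str, int, int, int]] = {}  # j -> (acc, n_cons, n_noncons, offset)

    # substrate proteins without sites also travel into the target proteome
    all_subs = sorted(a for a in reference.entries if a.startswith("HSUB"))

    for i, ref_acc in enumerate(all_subs):
        idxs = by_protein.get(ref_acc, [])
        if protein_mode.get(ref_acc) == "missing":
            for j in idxs:
                planted[j] = ("", 0, 0, 0)
            continue
        seq = list(reference[ref_acc])
        L = len(seq)
        window_spans = []
        for j in idxs:
            _acc, pos, res = sites[j]
            window_spans.append((pos - 8, pos + 7))  # 0-based [start, end)
            window = "".join(seq[pos - 8 : pos + 7])
            mode = failure_mode.get(j)
            bias = "random"
            if j in site_conserved:
                n_noncons = int(rng.integers(0, 3))
                n_cons = int(rng.integers(0, 6 - n_noncons))
            elif mode == "differences":
                total = int(rng.integers(8, 11))
                n_noncons = int(rng.integers(0, 4))
                # windows rich in residues without positive-scoring partners
                # (C, G, ...) may not admit enough conservative substitutions
                n_eligible = sum(
                    1 for i, ch in enumerate(window) if i != 7 and _partners(classifier)[0][ch]
                )
                n_cons = min(total - n_noncons, n_eligible)
                n_noncons = total - n_cons
                bias = "mild"  # keep the planted window the top-scoring hit
            elif mode == "nonconservative":
                n_noncons, n_cons = 6, 0
                bias = "mild"
            elif mode in ("residue", "position", "missing"):
                n_noncons = n_cons = 0
            else:  # pragma: no cover
                raise AssertionError(mode)
            mutated = mutate_window(
                window, 7, n_cons, n_noncons, preserve_center=True,
                rng=rng, classifier=classifier, choice=bias,
            )
            if mode == "residue":
                candidates = [c for c in CANONICAL_RESIDUES if c not in "STY"]
                new_center = candidates[int(rng.integers(len(candidates)))]
                mutated = mutated[:7] + new_center + mutated[8:]
                kind = classifier.classify(res, new_center)
                n_cons, n_noncons = (1, 0) if kind.value == "conservative" else (0, 1)
            seq[pos - 8 : pos + 7] = list(mutated)
        # background divergence outside the planted windows
        in_window = np.zeros(L, dtype=bool)
        for a, b in window_spans:
            in_window[max(0, a) : min(L, b)] = True
        mask = (rng.random(L) < plan.background_substitution_rate) & ~in_window
        for p in np.flatnonzero(mask):
            current = seq[p]
            choices = [c for c in _CANON if c != current]
            seq[p] = choices[int(rng.integers(len(choices)))]
        offset = 0
        if protein_mode.get(ref_acc) == "position":
            offset = L // 5 + 3
            seq = list(_random_protein(rng, offset)) + seq
        acc = f"{prefix}S{i + 1:04d}"
        if rng.random() < config.isoform_suffix_rate:
            acc += "-2"
        entries[acc] = "".join(seq)
        for j in idxs:
            planted[j] = (acc, -1, -1, offset)

    # planted counts read back from the sequences themselves (authoritative)
    from .peptides import count_differences

    for j, (acc, pos, res) in enumerate(sites):
        t_acc, _, _, offset = planted[j]
        if not t_acc:
            continue
        query = queries[(acc, pos)]
        hit_window = entries[t_acc][pos + offset - 8 : pos + offset + 7]
        n_diff, n_noncons, _ = count_differences(query, hit_window, classifier)
        planted[j] = (t_acc, n_diff - n_noncons, n_noncons, offset)

    # --- kinases
    for ki, ref_acc in enumerate(kin_accs):
        conserved = ki in conserved_kinases
        if conserved:
            seq = list(reference[ref_acc])
            mask = rng.random(len(seq)) < plan.kinase_substitution_rate
            for p in np.flatnonzero(mask):
                choices = [c for c in _CANON if c != seq[p]]
                seq[p] = choices[int(rng.integers(len(choices)))]
            acc = f"{prefix}K{ki + 1:04d}"
            if rng.random() < config.isoform_suffix_rate:
                acc += "-2"
            entries[acc] = "".join(seq)

    # --- decoys: diverged copies of the reference decoys, screened so every
    # decoy window stays far from every query window
    for d, ref_dec in enumerate(dec_accs):
        base = reference[ref_dec]
        for _ in range(50):
            seq = list(base)
            mask = rng.random(len(seq)) < plan.background_substitution_rate
            for p in np.flatnonzero(mask):
                choices = [c for c in _CANON if c != seq[p]]
                seq[p] = choices[int(rng.integers(len(choices)))]
            seq = "".join(seq)
            if _min_query_distance(seq, query_arrays) >= DECOY_MARGIN:
                break
        else:
            return None
        entries[f"{prefix}D{d + 1:04d}"] = seq

    target = Proteome(entries=entries, organism_label=plan.organism)

    # --- verification through the actual engines
    max_diff = CriteriaConfig().max_differences
    for j, (acc, pos, res) in enumerate(sites):
        t_acc, n_cons, n_noncons, offset = planted[j]
        query = queries[(acc, pos)]
        hit = best_peptide_hit(query, target, classifier)
        mode = failure_mode.get(j)
        if not t_acc:  # substrate deleted: best hit must fail the screen
            if hit is not None and hit.n_differences <= max_diff:
                return None
            continue
        exact = hit is not None and (
            hit.hit_accession == t_acc
            and hit.hit_position == pos + offset
            and hit.n_differences == n_cons + n_noncons
            and hit.n_nonconservative == n_noncons
        )
        if mode == "differences":
            # any best hit with enough differences keeps the category; the
            # planted window is only usually the top-scoring one
            if not (exact or (hit is not None and hit.n_differences > max_diff)):
                return None
        elif not exact:
            return None

    org_kin_truth: dict[tuple[str, str], bool] = {}
    org_kin_accs: dict[tuple[str, str], str] = {}
    for ki, ref_acc in enumerate(kin_accs):
        intended = ki in conserved_kinases
        call = reciprocal_best_hit(ref_acc, reference, target, aligner, plan.organism)
        if call.conserved != intended:
            return None
        org_kin_truth[(ref_acc, plan.organism)] = intended
        if intended and call.evidence:
            org_kin_accs[(ref_acc, plan.organism)] = call.evidence[0]

    # --- truth records
    for j, (acc, pos, res) in enumerate(sites):
        t_acc, n_cons, n_noncons, offset = planted[j]
        kin_ok = kpsp_kinase[j] in conserved_kinases
        site_ok = j in site_conserved
        org_truth.append(
            TruthRecord(
                kinase_accession=kin_accs[kpsp_kinase[j]],
                substrate_accession=acc,
                position=pos,
                residue=res,
                organism=plan.organism,
                category=classify_kpsp(site_ok, kin_ok),
                site_conserved=site_ok,
                kinase_conserved=kin_ok,
                failure_mode=failure_mode.get(j),
                n_conservative=n_cons,
                n_nonconservative=n_noncons,
                position_offset=offset,
                target_accession=t_acc,
            )
        )

    return target, org_truth, org_kin_truth, org_kin_accs


# ---------------------------------------------------------------------------
# file emission (the exact external dialects the readers accept)

_KS_HEADER = "KINASE\tKIN_ACC_ID\tKIN_ORGANISM\tSUBSTRATE\tSUB_ACC_ID\tSUB_ORGANISM\tSUB_MOD_RSD"
_REG_HEADER = "GENE\tACC_ID\tORGANISM\tMOD_RSD\tLT_LIT\tMS_LIT"
_PREAMBLE = "synthetic PhosphoSitePlus-dialect table\nlast line before header\n"


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write all study artifacts; byte-identical for identical configs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reference"] = out / "reference.fasta"
    write_fasta_proteome(study.reference, paths["reference"])
    (out / "targets").mkdir(exist_ok=True)
    for organism in sorted(study.targets):
        p = out / "targets" / f"{organism}.fasta"
        write_fasta_proteome(study.targets[organism], p)
        paths[f"target:{organism}"] = p

    paths["kinase_substrate"] = out / "kinase_substrate.tsv"
    with open(paths["kinase_substrate"], "w") as fh:
        fh.write(_PREAMBLE)
        fh.write(_KS_HEADER + "\n")
        for r in study.ks_records:
            fh.write(
                f"{r.kinase_accession}\t{r.kinase_accession}\t{r.kinase_organism}\t"
                f"{r.substrate_accession}\t{r.substrate_accession}\t{r.substrate_organism}\t"
                f"{r.site_residue}{r.site_position}\n"
            )

    paths["regulatory"] = out / "regulatory_sites.tsv"
    with open(paths["regulatory"], "w") as fh:
        fh.write(_PREAMBLE)
        fh.write(_REG_HEADER + "\n")
        for i, r in enumerate(study.regulatory_records):
            if i % 2 == 0 or r.n_low_throughput_refs == 0:
                lt = str(r.n_low_throughput_refs) if r.n_low_throughput_refs else ""
            else:
                lt = "; ".join(f"ref{k}" for k in range(r.n_low_throughput_refs))
            fh.write(
                f"{r.substrate_accession}\t{r.substrate_accession}\thuman\t"
                f"{r.site_residue}{r.site_position}-p\t{lt}\t\n"
            )
        # non-phospho noise row exercised by the parser's filter
        fh.write("NOISE\tHSUB0001\thuman\tK63-ub\t4\t\n")

    paths["truth"] = out / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write(
            "kinase\tsubstrate\tposition\tresidue\torganism\tcategory\t"
            "site_conserved\tkinase_conserved\tfailure_mode\t"
            "n_conservative\tn_nonconservative\tposition_offset\ttarget_accession\n"
        )
        for t in study.truth:
            fh.write(
                f"{t.kinase_accession}\t{t.substrate_accession}\t{t.position}\t"
                f"{t.residue}\t{t.organism}\t{t.category.value}\t{t.site_conserved}\t"
                f"{t.kinase_conserved}\t{t.failure_mode or ''}\t{t.n_conservative}\t"
                f"{t.n_nonconservative}\t{t.position_offset}\t{t.target_accession}\n"
            )

    paths["hieranoid"] = out / "hieranoid_pairs.txt"
    with open(paths["hieranoid"], "w") as fh:
        for (kin, organism), conserved in sorted(study.kinase_truth.items()):
            if conserved:
                partner = study.target_kinase_accessions.get((kin, organism), "NA")
                fh.write(f"{kin}\t{partner}\t{organism}\n")

    paths["diopt"] = out / "diopt.tsv"
    with open(paths["diopt"], "w") as fh:
        fh.write("human_accession\ttarget_organism\ttarget_accession\trank\n")
        for (kin, organism), conserved in sorted(study.kinase_truth.items()):
            partner = study.target_kinase_accessions.get((kin, organism), "NA")
            rank = "high" if conserved else "moderate"
            fh.write(f"{kin}\t{organism}\t{partner}\t{rank}\n")

    paths["config"] = out / "config.yaml"
    cfg = study.config
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "seed": cfg.seed,
                "n_substrate_proteins": cfg.n_substrate_proteins,
                "n_kinases": cfg.n_kinases,
                "n_decoys": cfg.n_decoys,
                "protein_length_range": list(cfg.protein_length_range),
                "n_kpsps": cfg.n_kpsps,
                "regulatory_fraction": cfg.regulatory_fraction,
                "organisms": [
                    {
                        "organism": p.organism,
                        "f_both": p.f_both,
                        "f_site_only": p.f_site_only,
                        "f_kinase_only": p.f_kinase_only,
                        "f_neither": p.f_neither,
                        "background_substitution_rate": p.background_substitution_rate,
                    }
                    for p in cfg.organisms
                ],
            },
            fh,
            sort_keys=False,
        )
    return paths
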