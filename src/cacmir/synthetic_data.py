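"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator is a pure function of its parameters and an integer seed.
Backgrounds are i.i.d. uniform over {A,C,G,T}: the screening and scoring
stages threshold on mismatch counts and penalty sums, not on composition,
so a uniform background exercises them faithfully.  Ground truth
(``SimTruth``) always verifies against the generated data by direct
inspection: planted positions index into their hosts, Hamming distances are
exact, and planted-site expectations are recomputed with the scanning
scorer at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io_formats import SequenceRecord, revcomp
from .netanalysis import InteractionData
from .target_scan import TargetParams, score_alignment

_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground-truth labels for recovery tests."""

    planted_homologs: list = field(default_factory=list)  # (est_id, ref_id, pos, mismatches)
    planted_sites: list = field(default_factory=list)     # (mirna_id, transcript_id, pos, expectation)
    planted_hub_ids: list = field(default_factory=list)
    planted_hairpin_ests: list = field(default_factory=list)  # ESTs whose plant is a full hairpin
    seed: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def gen_reference_mirnas(
    n: int,
    length_range: tuple[int, int] = (18, 24),
    gc_target: float = 0.5,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Reference mature-miRNA set with controlled length and GC content.

    Each record's GC fraction lies within 10 percentage points of
    ``gc_target``.  Ids follow plant-style naming (species prefix + miR
    token) so the renaming stage can be exercised end to end.
    """
    lo, hi = length_range
    if not (18 <= lo <= hi <= 24):
        raise ParameterError("length_range must lie within [18, 24]")
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    prefixes = ["ath", "osa", "gma", "mtr", "bdi"]
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        while True:
            seq = "".join(
                np.where(rng.random(length) < gc_target,
                         rng.choice(["G", "C"], size=length),
                         rng.choice(["A", "T"], size=length))
            )
            gc = (seq.count("G") + seq.count("C")) / length
            if abs(gc - gc_target) <= 0.10:
                break
        prefix = prefixes[i % len(prefixes)]
        hyphen = "-" if i % 2 else ""  # mix miR-123 and miR123 forms
        records.append(SequenceRecord(id=f"{prefix}-miR{hyphen}{1000 + i}", sequence=seq))
    return records


def _mutate(seq: str, k: int, rng: np.random.Generator, preserve_word: int | None) -> tuple[str, list[int]]:
    """Substitute exactly k positions, optionally keeping one intact word."""
    L = len(seq)
    for _ in range(1000):
        positions = sorted(rng.choice(L, size=k, replace=False).tolist()) if k else []
        if preserve_word is None or _max_gap(positions, L) >= preserve_word:
            break
    else:
        raise ParameterError("could not place substitutions while preserving a word")
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(len(choices)))]
    return "".join(out), positions


def _max_gap(positions: Sequence[int], length: int) -> int:
    prev = -1
    best = 0
    for p in list(positions) + [length]:
        best = max(best, p - prev - 1)
        prev = p
    return best


def gen_ests_with_homologs(
    refs: Sequence[SequenceRecord],
    n_ests: int,
    est_length: int,
    n_planted: int,
    mismatches_per_plant: int,
    seed: int = 0,
    preserve_word: int | None = 6,
    n_hairpin_plants: int = 0,
    hairpin_ext: int = 30,
    hairpin_loop: int = 8,
) -> tuple[list[SequenceRecord], SimTruth]:
    """EST set with reference-miRNA homologs planted at known offsets.

    Each planted homolog is a copy of a (cyclically chosen) reference with
    exactly ``mismatches_per_plant`` substitutions, embedded at a recorded
    offset at least 100 nt from both EST ends.  By default the substitution
    positions are drawn conditioned on leaving at least one intact word of
    ``preserve_word`` nt, so every plant is in principle detectable by a
    word-seeded search; pass ``preserve_word=None`` for unconstrained
    placement.  Non-planted ESTs are i.i.d. uniform.

    The first ``n_hairpin_plants`` plants are embedded as *full precursor
    cassettes*: the (mutated) mature is extended by ``hairpin_ext`` random
    stem nt, followed by an {A,C} loop and the reverse complement of the
    extended arm, with 100 nt of non-pairing {A,C} background on both sides
    so the 100-nt-flank extraction window folds into a single stem-loop.
    These ESTs are listed in ``SimTruth.planted_hairpin_ests``.
    """
    if not 0 <= mismatches_per_plant <= 5:
        raise ParameterError("mismatches_per_plant must lie in 0..5")
    if n_planted > n_ests:
        raise ParameterError("cannot plant more homologs than ESTs")
    if n_hairpin_plants > n_planted:
        raise ParameterError("n_hairpin_plants cannot exceed n_planted")
    if refs and est_length < max(len(r) for r in refs) + 200:
        raise ParameterError("est_length must be >= max reference length + 200")
    if n_planted > 0 and not refs:
        raise ParameterError("planting requested but no references supplied")
    if n_hairpin_plants:
        max_ref = max(len(r) for r in refs)
        cassette = 2 * (max_ref + hairpin_ext) + hairpin_loop
        if est_length < cassette + 200:
            raise ParameterError(
                f"est_length must be >= {cassette + 200} for hairpin cassettes"
            )

    rng = np.random.default_rng(seed)
    ac = np.array(list("AC"))
    truth = SimTruth(seed=seed)
    planted_idx = sorted(rng.choice(n_ests, size=n_planted, replace=False).tolist()) if n_planted else []
    hairpin_idx = set(planted_idx[:n_hairpin_plants])
    planted_idx = set(planted_idx)
    ests = []
    for i in range(n_ests):
        est_id = f"est_{i:04d}"
        seq = _random_seq(rng, est_length)
        if i in planted_idx:
            ref = refs[len(truth.planted_homologs) % len(refs)]
            L = len(ref.sequence)
            mutated, _ = _mutate(ref.sequence, mismatches_per_plant, rng, preserve_word)
            if i in hairpin_idx:
                arm5 = mutated + _random_seq(rng, hairpin_ext)
                loop = "".join(rng.choice(ac, size=hairpin_loop))
                cassette = (
                    "".join(rng.choice(ac, size=100))
                    + arm5 + loop + revcomp(arm5)
                    + "".join(rng.choice(ac, size=100))
                )
                start = int(rng.integers(0, est_length - len(cassette) + 1))
                seq = seq[:start] + cassette + seq[start + len(cassette) :]
                pos = start + 100  # mature begins right after the 5' background
                truth.planted_hairpin_ests.append(est_id)
            else:
                pos = int(rng.integers(100, est_length - L - 100 + 1))
                seq = seq[:pos] + mutated + seq[pos + L :]
            truth.planted_homologs.append((est_id, ref.id, pos, mismatches_per_plant))
        ests.append(SequenceRecord(id=est_id, sequence=seq))
    return ests, truth


def gen_hairpin_precursor(
    mature: SequenceRecord | str,
    loop_len: int = 8,
    flank_len: int = 20,
    bulges: int = 0,
    seed: int = 0,
    arm: str = "5p",
) -> SequenceRecord:
    """A precursor guaranteed to fold into a single stem-loop.

    Layout (5p arm): flank + mature + loop + revcomp(mature) + flank, with
    ``bulges`` duplicated bases inserted into the complementary arm.  Loop
    and flanks are drawn from {A, C} only, which cannot pair with each
    other, so the mature/complement stem is the unique optimal structure.
    """
    mat = mature.sequence if isinstance(mature, SequenceRecord) else mature
    mat = mat.upper().replace("U", "T")
    if not 18 <= len(mat) <= 24:
        raise ParameterError("mature length must be 18-24 nt")
    if loop_len < 4:
        raise ParameterError("loop_len must be >= 4")
    if arm not in ("5p", "3p"):
        raise ParameterError("arm must be '5p' or '3p'")
    rng = np.random.default_rng(seed)
    ac = np.array(list("AC"))
    loop = "".join(rng.choice(ac, size=loop_len))
    comp_arm = list(revcomp(mat))
    for _ in range(bulges):
        # keep insertions in the middle third of the arm so the optimal fold
        # bulges them out instead of absorbing them into the terminal loop
        third = len(comp_arm) // 3
        p = int(rng.integers(third, 2 * third))
        comp_arm.insert(p, comp_arm[p])  # duplicated base bulges out of the stem
    comp_arm = "".join(comp_arm)
    flank5 = "".join(rng.choice(ac, size=flank_len))
    flank3 = "".join(rng.choice(ac, size=flank_len))
    if arm == "5p":
        core = mat + loop + comp_arm
    else:
        core = comp_arm + loop + mat
    name = mature.id if isinstance(mature, SequenceRecord) else "mature"
    return SequenceRecord(id=f"prec_{name}", sequence=flank5 + core + flank3)


@dataclass
class SiteSpec:
    """Recipe for one planted target site."""

    mirna_id: str
    expectation: float
    n_mismatches: int = 0
    n_gu: int = 0
    transcript_index: int | None = None


def _solve_seed_split(spec: SiteSpec, params: TargetParams) -> tuple[int, int]:
    """How many mismatches/G:U must land in the seed region to reach E*."""
    mp, gp, sm = params.mismatch_penalty, params.gu_penalty, params.seed_multiplier
    for a in range(spec.n_mismatches + 1):
        for b in range(spec.n_gu + 1):
            E = (
                mp * (spec.n_mismatches + (sm - 1) * a)
                + gp * (spec.n_gu + (sm - 1) * b)
            )
            if abs(E - spec.expectation) < 1e-9:
                return a, b
    raise ParameterError(
        f"expectation {spec.expectation} unreachable with "
        f"{spec.n_mismatches} mismatches and {spec.n_gu} G:U"
    )


def _build_site(mirna_seq: str, spec: SiteSpec, params: TargetParams, rng) -> str:
    """Perfect-complement site edited to score exactly the requested E*."""
    L = len(mirna_seq)
    a_seed, b_seed = _solve_seed_split(spec, params)
    lo, hi = params.seed_region
    seed_pos = [i for i in range(L) if lo <= i + 1 <= hi]
    non_seed = [i for i in range(L) if not lo <= i + 1 <= hi]
    gu_ok = [i for i in range(L) if mirna_seq[i] in "GT"]

    def draw(pool, count, taken):
        pool = [p for p in pool if p not in taken]
        if len(pool) < count:
            raise ParameterError("not enough eligible positions for the requested edits")
        return [] if count == 0 else rng.choice(pool, size=count, replace=False).tolist()

    taken: set[int] = set()
    mm_pos = draw(seed_pos, a_seed, taken)
    taken |= set(mm_pos)
    mm_pos += draw(non_seed, spec.n_mismatches - a_seed, taken)
    taken |= set(mm_pos)
    gu_pos = draw([p for p in seed_pos if p in gu_ok], b_seed, taken)
    taken |= set(gu_pos)
    gu_pos += draw([p for p in non_seed if p in gu_ok], spec.n_gu - b_seed, taken)

    site = list(revcomp(mirna_seq))
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    wobble = {"G": "T", "T": "G"}
    for i in mm_pos:
        banned = {comp[mirna_seq[i]], wobble.get(mirna_seq[i])}
        choices = [b for b in "ACGT" if b not in banned]
        site[L - 1 - i] = choices[int(rng.integers(len(choices)))]
    for i in gu_pos:
        site[L - 1 - i] = wobble[mirna_seq[i]]
    return "".join(site)


def gen_transcriptome_with_sites(
    mirnas: Sequence[SequenceRecord],
    n_transcripts: int,
    transcript_length: int,
    site_specs: Sequence[SiteSpec],
    seed: int = 0,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Transcript set with complementary target sites planted at known scores.

    Each site is the reverse complement of its miRNA edited so the scanning
    scorer assigns exactly the requested expectation (verified at
    generation time).  Sites are embedded at recorded offsets; transcripts
    without a spec are pure background.
    """
    rng = np.random.default_rng(seed)
    by_id = {m.id: m for m in mirnas}
    truth = SimTruth(seed=seed)
    params = TargetParams()
    transcripts = []
    specs_for = {}
    for si, spec in enumerate(site_specs):
        idx = spec.transcript_index if spec.transcript_index is not None else si % n_transcripts
        specs_for.setdefault(idx, []).append(spec)
    for t in range(n_transcripts):
        t_id = f"tx_{t:04d}"
        seq = _random_seq(rng, transcript_length)
        cursor = 10
        for spec in specs_for.get(t, []):
            mirna = by_id[spec.mirna_id]
            site = _build_site(mirna.sequence, spec, params, rng)
            L = len(site)
            if cursor + L + 10 > transcript_length:
                raise ParameterError("transcript too short for the requested sites")
            pos = cursor + int(rng.integers(0, 10))
            seq = seq[:pos] + site + seq[pos + L :]
            cursor = pos + L + 15
            E, _, _, _ = score_alignment(mirna.sequence, site, params)
            if abs(E - spec.expectation) > 1e-9:
                raise ParameterError("internal error: planted site does not score E*")
            truth.planted_sites.append((spec.mirna_id, t_id, pos, E))
        transcripts.append(SequenceRecord(id=t_id, sequence=seq))
    return transcripts, truth


def gen_interactions(
    n_nodes: int,
    model: str = "ER",
    n_edges_or_attach: int = 0,
    n_complexes: int = 0,
    complex_size_range: tuple[int, int] = (3, 6),
    seed: int = 0,
) -> tuple[InteractionData, SimTruth]:
    """Binary interactions plus protein complexes, with known hubs.

    ER draws ``n_edges_or_attach`` edges uniformly without replacement; BA
    grows a preferential-attachment graph (attachment = the same argument)
    whose earliest node is recorded as the planted hub.  Complexes are
    random node subsets with sizes in ``complex_size_range``.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    names = [f"P{i:04d}" for i in range(n_nodes)]
    truth = SimTruth(seed=seed)
    if model == "ER":
        capacity = n_nodes * (n_nodes - 1) // 2
        if n_edges_or_attach > capacity:
            raise ParameterError("more edges than a simple graph can hold")
        idx = rng.choice(capacity, size=n_edges_or_attach, replace=False)
        pairs = []
        for e in np.sort(idx):
            i = int((1 + np.sqrt(1 + 8 * e)) // 2)
            if i * (i - 1) // 2 > e:
                i -= 1
            j = int(e - i * (i - 1) // 2)
            pairs.append((names[i], names[j]))
    elif model == "BA":
        if n_edges_or_attach < 1 or n_edges_or_attach >= n_nodes:
            raise ParameterError("BA attachment must lie in 1..n_nodes-1")
        g = nx.barabasi_albert_graph(n_nodes, n_edges_or_attach, seed=int(rng.integers(2**31)))
        pairs = [(names[a], names[b]) for a, b in g.edges]
        # the preferential-attachment hub: the max-degree node of the grown
        # graph (one of the earliest nodes; recorded by inspection so the
        # truth label is exact for this instance)
        hub = min((v for v in g.nodes), key=lambda v: (-g.degree[v], v))
        truth.planted_hub_ids.append(names[hub])
    else:
        raise ParameterError(f"unknown interaction model {model!r}")

    complexes = []
    lo, hi = complex_size_range
    if not 2 <= lo <= hi <= n_nodes:
        raise ParameterError("complex sizes must lie in [2, n_nodes]")
    for _ in range(n_complexes):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_nodes, size=size, replace=False)
        complexes.append(sorted(names[int(i)] for i in members))
    return InteractionData(binary_pairs=pairs, complexes=complexes, nodes=list(names)), truth
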