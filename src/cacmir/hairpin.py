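"""Precursor extraction, RNA secondary-structure folding and hairpin criteria.

The built-in fold is a nearest-neighbour *stacking* model solved exactly by
dynamic programming, not a Turner-parameter implementation: adjacent base
pairs contribute negative stack scores, loops contribute positive penalties,
and multibranch loops are excluded from closed substructures (the structure
space is single stems with bulges/internal loops, with any number of stems
at the external level).  Absolute energies are therefore in model units, and
every energy-dependent verdict in this package is either structural or based
on the printed reference values.  A precomputed (structure, energy) pair,
e.g. from ViennaRNA, can be injected via the ``external-energies`` backend.

Energy model (model units; negative = stabilising):
  pair strengths     G:C 3.0, A:T 2.0, G:T wobble 1.0
  stack(p, q)        -(strength(p) + strength(q)) / 2
  hairpin loop       +3.0 (>= 3 unpaired nt)
  bulge/internal     +2.0 + 0.25 per unpaired nt (<= 8 unpaired nt total)
  multiloop          +3.0 (scoring only; never produced by the DP)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import NamingError, ParameterError, SequenceError
from .io_formats import SequenceRecord

MIN_LOOP = 3
MAX_INTERNAL = 8
HAIRPIN_PENALTY = 3.0
INTERNAL_PENALTY = 2.0
INTERNAL_PER_NT = 0.25
MULTILOOP_PENALTY = 3.0
_STRENGTH = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}
_INF = float("inf")


def _pair_strength(a: str, b: str) -> float:
    return _STRENGTH.get((a, b), 0.0)


@dataclass
class FoldResult:
    structure: str
    energy: float
    pairs: list[tuple[int, int]]
    n_hairpin_loops: int


def _count_hairpin_loops(pairs: Sequence[tuple[int, int]]) -> int:
    n = 0
    for (i, j) in pairs:
        if not any(i < k < l < j for (k, l) in pairs):
            n += 1
    return n


def _pairs_to_structure(pairs: Sequence[tuple[int, int]], n: int) -> str:
    s = ["."] * n
    for (i, j) in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


def structure_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for idx, c in enumerate(structure):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def score_structure(sequence: str, pairs: Iterable[tuple[int, int]]) -> float:
    """Energy of an explicit nested structure under the model above.

    Used both for reporting and as the scoring half of the enumeration
    oracle; handles multiloops and uncapped internal loops so that any
    nested structure can be scored.
    """
    seq = sequence.upper().replace("U", "T")
    pairs = sorted(pairs)
    claimed: set[int] = set()
    for (i, j) in pairs:
        if not 0 <= i < j < len(seq):
            raise ValueError(f"pair {(i, j)} out of range")
        if j - i - 1 < MIN_LOOP:
            raise ValueError(f"pair {(i, j)} violates the minimum loop of {MIN_LOOP}")
        if _pair_strength(seq[i], seq[j]) == 0.0:
            raise ValueError(f"bases {seq[i]}:{seq[j]} at {(i, j)} cannot pair")
        if i in claimed or j in claimed:
            raise ValueError("a base participates in two pairs")
        claimed |= {i, j}
    # nestedness
    for a in pairs:
        for b in pairs:
            if a < b and a[0] < b[0] < a[1] < b[1]:
                raise ValueError(f"pairs {a} and {b} cross (pseudoknot)")

    energy = 0.0
    for (i, j) in pairs:
        children = [
            (k, l) for (k, l) in pairs
            if i < k < l < j and not any(i < p < k and l < q < j for (p, q) in pairs)
        ]
        if not children:
            energy += HAIRPIN_PENALTY
        elif len(children) == 1:
            (k, l) = children[0]
            if k == i + 1 and l == j - 1:
                energy += -(_pair_strength(seq[i], seq[j]) + _pair_strength(seq[k], seq[l])) / 2.0
            else:
                size = (k - i - 1) + (j - l - 1)
                energy += INTERNAL_PENALTY + INTERNAL_PER_NT * size
        else:
            energy += MULTILOOP_PENALTY
    return energy


def fold(
    sequence: str,
    backend: str = "builtin",
    forced_unpaired: Iterable[int] | None = None,
    external: tuple[str, float] | None = None,
) -> FoldResult:
    """Minimum-energy nested structure of ``sequence``.

    ``forced_unpaired`` blocks positions from pairing (used for target-site
    accessibility).  Traceback ties are broken deterministically: pairings
    with smaller i, then smaller j, are preferred.
    """
    seq = sequence.upper().replace("U", "T")
    if set(seq) - set("ACGTN"):
        raise SequenceError("fold: sequence contains non-nucleotide characters")
    if backend == "external-energies":
        if external is None:
            raise ParameterError("external-energies backend needs a (structure, energy) pair")
        structure, energy = external
        if len(structure) != len(seq):
            raise ParameterError("external structure length does not match the sequence")
        pairs = structure_to_pairs(structure)
        return FoldResult(structure, float(energy), pairs, _count_hairpin_loops(pairs))
    if backend != "builtin":
        raise ParameterError(f"unknown fold backend {backend!r}")

    n = len(seq)
    blocked = set(forced_unpaired or ())
    if n < 2:
        return FoldResult("." * n, 0.0, [], 0)

    strength = [[0.0] * n for _ in range(n)]
    for i in range(n):
        if i in blocked:
            continue
        for j in range(i + MIN_LOOP + 1, n):
            if j not in blocked:
                strength[i][j] = _pair_strength(seq[i], seq[j])

    V = [[_INF] * n for _ in range(n)]
    W = [[0.0] * (n + 1) for _ in range(n + 1)]  # W[i][j] over [i, j), W[i][i] = 0

    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            if strength[i][j] == 0.0:
                continue
            best = HAIRPIN_PENALTY
            # inner pair (k, l): stack if adjacent, else bulge/internal loop
            kmax = min(i + MAX_INTERNAL + 1, j - MIN_LOOP - 1)
            for k in range(i + 1, kmax + 1):
                up5 = k - i - 1
                Vk = V[k]
                for l in range(max(k + MIN_LOOP + 1, j - 1 - (MAX_INTERNAL - up5)), j):
                    if Vk[l] == _INF:
                        continue
                    if up5 == 0 and l == j - 1:
                        e = -(strength[i][j] + strength[k][l]) / 2.0 + Vk[l]
                    else:
                        size = up5 + (j - l - 1)
                        e = INTERNAL_PENALTY + INTERNAL_PER_NT * size + Vk[l]
                    if e < best:
                        best = e
            V[i][j] = best

    # external level: W[i][j] over half-open [i, j)
    for i in range(n - 1, -1, -1):
        Vi = V[i]
        Wi = W[i]
        for j in range(i + 1, n + 1):
            best = W[i + 1][j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j):
                if Vi[k] == _INF:
                    continue
                e = Vi[k] + W[k + 1][j]
                if e < best:
                    best = e
            Wi[j] = best

    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("W", 0, n)]
    while stack:
        kind, i, j = stack.pop()
        if kind == "W":
            while i < j:
                target = W[i][j]
                chosen = None
                for k in range(i + MIN_LOOP + 1, j):
                    if V[i][k] != _INF and V[i][k] + W[k + 1][j] == target:
                        chosen = k
                        break
                if chosen is not None:
                    stack.append(("V", i, chosen))
                    i = chosen + 1
                else:
                    i += 1  # i unpaired (W[i][j] == W[i+1][j])
        else:
            pairs.append((i, j))
            target = V[i][j]
            if target == HAIRPIN_PENALTY and not _has_inner_optimum(V, W, strength, i, j, target):
                continue
            found = False
            kmax = min(i + MAX_INTERNAL + 1, j - MIN_LOOP - 1)
            for k in range(i + 1, kmax + 1):
                up5 = k - i - 1
                for l in range(max(k + MIN_LOOP + 1, j - 1 - (MAX_INTERNAL - up5)), j):
                    if V[k][l] == _INF:
                        continue
                    if up5 == 0 and l == j - 1:
                        e = -(strength[i][j] + strength[k][l]) / 2.0 + V[k][l]
                    else:
                        e = INTERNAL_PENALTY + INTERNAL_PER_NT * (up5 + (j - l - 1)) + V[k][l]
                    if e == target:
                        stack.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            # if nothing matched, the closure is a hairpin loop

    pairs.sort()
    energy = W[0][n]
    return FoldResult(_pairs_to_structure(pairs, n), energy, pairs, _count_hairpin_loops(pairs))


def _has_inner_optimum(V, W, strength, i, j, target) -> bool:
    """True if V(i, j) == target is achieved by an inner pairing (tie-break:
    pairings are preferred over the bare hairpin closure when energies tie)."""
    kmax = min(i + MAX_INTERNAL + 1, j - MIN_LOOP - 1)
    for k in range(i + 1, kmax + 1):
        up5 = k - i - 1
        for l in range(max(k + MIN_LOOP + 1, j - 1 - (MAX_INTERNAL - up5)), j):
            if V[k][l] == _INF:
                continue
            if up5 == 0 and l == j - 1:
                e = -(strength[i][j] + strength[k][l]) / 2.0 + V[k][l]
            else:
                e = INTERNAL_PENALTY + INTERNAL_PER_NT * (up5 + (j - l - 1)) + V[k][l]
            if e == target:
                return True
    return False


# ---------------------------------------------------------------------------
# Precursor extraction and the five structural criteria
# ---------------------------------------------------------------------------


@dataclass
class PrecursorCandidate:
    """A candidate precursor window around a homolog hit (0-based, half-open)."""

    est_id: str
    sequence: str
    mature_start: int
    mature_end: int
    arm: str = "undetermined"
    truncated_upstream: int = 0   # nt of flank lost to the EST 5' end
    truncated_downstream: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


def extract_precursor(est: SequenceRecord, hit, flank: int = 100) -> PrecursorCandidate:
    """Cut the hit ± ``flank`` nt window out of the EST (clipped at its ends)."""
    start, end = hit.est_start, hit.est_end
    if not 0 <= start < end <= len(est.sequence):
        raise ParameterError("hit coordinates fall outside the EST")
    w0 = max(0, start - flank)
    w1 = min(len(est.sequence), end + flank)
    return PrecursorCandidate(
        est_id=est.id,
        sequence=est.sequence[w0:w1],
        mature_start=start - w0,
        mature_end=end - w0,
        truncated_upstream=flank - (start - w0),
        truncated_downstream=flank - (w1 - end),
    )


def compute_gc(sequence: str) -> float:
    """(G + C) percentage of a sequence."""
    if not sequence:
        raise ParameterError("compute_gc: empty sequence")
    seq = sequence.upper().replace("U", "T")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def compute_mfei(mfe_dg: float, precursor_length: int, gc_percent: float) -> float:
    """Minimal folding free energy index: ((dG / length) * 100) / GC%."""
    if precursor_length <= 0:
        raise ParameterError("compute_mfei: precursor length must be positive")
    if gc_percent == 0:
        raise ParameterError("compute_mfei: MFEI undefined at 0% GC")
    return (mfe_dg / precursor_length) * 100.0 / gc_percent


@dataclass
class HairpinThresholds:
    """Knobs of the five criteria (see ``evaluate_hairpin``)."""

    max_substitutions: int = 2   # criterion (b): substitutions vs the reference
    max_bulge: int = 3           # criterion (c): longest unpaired run in the mature
    mfei_min: float = 0.85       # criterion (d): |MFEI| floor


@dataclass
class HairpinEvaluation:
    criteria: dict
    mfe_dg: float
    gc_percent: float
    mfei: float
    substitutions_vs_ref: int
    max_mature_bulge: int
    verdict: bool


def evaluate_hairpin(
    candidate: PrecursorCandidate,
    fold_result: FoldResult,
    hit,
    thresholds: HairpinThresholds | None = None,
) -> HairpinEvaluation:
    """Apply the five structural criteria to a folded precursor candidate.

    (a) exactly one hairpin loop; (b) few substitutions vs the reference
    mature; (c) the mature region avoids the terminal loop and contains no
    unpaired run longer than ``max_bulge``; (d) |MFEI| >= ``mfei_min``;
    (e) every paired mature base pairs to the opposite arm.  The candidate's
    ``arm`` field is set as a side effect.
    """
    th = thresholds or HairpinThresholds()
    if len(fold_result.structure) != len(candidate.sequence):
        raise ParameterError("fold result does not correspond to the candidate sequence")
    ms, me = candidate.mature_start, candidate.mature_end
    partner = {}
    for (i, j) in fold_result.pairs:
        partner[i] = j
        partner[j] = i

    flag_a = fold_result.n_hairpin_loops == 1

    mism = getattr(hit, "mismatches", 0)
    flag_b = mism <= th.max_substitutions

    # terminal loop of the (unique) hairpin, if there is one
    loop_span = None
    for (i, j) in fold_result.pairs:
        if not any(i < k < l < j for (k, l) in fold_result.pairs):
            loop_span = (i + 1, j)  # half-open unpaired interior
            break
    overlaps_loop = loop_span is not None and ms < loop_span[1] and loop_span[0] < me

    run = max_run = 0
    for p in range(ms, me):
        run = run + 1 if p not in partner else 0
        max_run = max(max_run, run)
    flag_c = (not overlaps_loop) and max_run <= th.max_bulge

    mfe = fold_result.energy
    gc = compute_gc(candidate.sequence)
    mfei = compute_mfei(mfe, len(candidate.sequence), gc) if mfe != 0 else 0.0
    flag_d = abs(mfei) >= th.mfei_min

    if loop_span is None or fold_result.n_hairpin_loops != 1:
        arm = "undetermined"
    elif overlaps_loop:
        arm = "spans_loop"
    elif me <= loop_span[0]:
        arm = "5p"
    else:
        arm = "3p"
    candidate.arm = arm

    mature_partners = [partner[p] for p in range(ms, me) if p in partner]
    if arm == "5p":
        flag_e = bool(mature_partners) and all(q >= loop_span[1] for q in mature_partners)
    elif arm == "3p":
        flag_e = bool(mature_partners) and all(q < loop_span[0] for q in mature_partners)
    else:
        flag_e = False

    criteria = {"a": flag_a, "b": flag_b, "c": flag_c, "d": flag_d, "e": flag_e}
    return HairpinEvaluation(
        criteria=criteria,
        mfe_dg=mfe,
        gc_percent=gc,
        mfei=mfei,
        substitutions_vs_ref=mism,
        max_mature_bulge=max_run,
        verdict=all(criteria.values()),
    )


@dataclass
class PutativeMiRNA:
    """A named putative miRNA with its precursor and criteria verdicts."""

    name: str
    homolog_name: str
    mature_seq: str
    precursor: PrecursorCandidate
    evaluation: HairpinEvaluation

    def __post_init__(self) -> None:
        if not self.name.startswith("cac-") and "-" not in self.name:
            raise NamingError(f"unexpected miRNA name {self.name!r}")
        if not 18 <= len(self.mature_seq) <= 24:
            raise ParameterError("mature sequence must be 18-24 nt")


_NAME_RE = re.compile(r"^([A-Za-z]{2,5})-(miR|let|lin)-?(\S+)$")


def assign_name(homolog_name: str, prefix: str = "cac") -> str:
    """Rename a homolog to this species' prefix, e.g. ath-miR5653 -> cac-miR-5653.

    A hyphen is inserted between the miR token and the identifier when the
    source name lacks one; the operation is idempotent.
    """
    m = _NAME_RE.match(homolog_name)
    if m is None:
        raise NamingError(f"cannot parse miRNA name {homolog_name!r}")
    _, token, ident = m.groups()
    return f"{prefix}-{token}-{ident}"
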