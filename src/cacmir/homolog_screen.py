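"""Seeded, mismatch-bounded search for mature-miRNA homologs in ESTs.

A reference mature sequence hits an EST when some ungapped placement of the
full reference (on either strand) shares at least one exact word of
``word_length`` with the EST, has at most ``max_mismatches`` substitutions,
and reaches ``min_identity`` percent identity.  This subsumes the role the
usual E-value cutoff plays at these query lengths without reimplementing
alignment statistics.  Coding candidates are flagged by a 6-frame
longest-ORF heuristic instead of a protein-database search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .io_formats import SequenceRecord, revcomp

_ENC = {c: i for i, c in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass
class ScreenParams:
    word_length: int = 6
    max_mismatches: int = 3
    min_identity: float = 80.0
    min_len: int = 18
    max_len: int = 24
    search_strands: str = "both"  # "forward" or "both"
    orf_codon_threshold: int = 100

    def __post_init__(self) -> None:
        if self.word_length < 4:
            raise ParameterError("word_length must be >= 4")
        if not 0 <= self.max_mismatches <= 5:
            raise ParameterError("max_mismatches must lie in 0..5")
        if self.min_len > self.max_len:
            raise ParameterError("min_len must not exceed max_len")
        if self.search_strands not in ("forward", "both"):
            raise ParameterError("search_strands must be 'forward' or 'both'")


@dataclass(frozen=True)
class HomologHit:
    est_id: str
    ref_mirna_id: str
    est_start: int
    est_end: int
    strand: str
    mismatches: int
    identity: float


@dataclass
class ScreenStats:
    """Funnel bookkeeping for one screening run."""

    n_word_seed_placements: int = 0  # placements sharing a word, any mismatch count
    n_hits: int = 0


def _placements(ref_arr: np.ndarray, est_arr: np.ndarray, word: int):
    """(mismatch counts, word-seed mask) for every placement of ref on est."""
    L = len(ref_arr)
    n_pos = len(est_arr) - L + 1
    if n_pos <= 0:
        return None, None
    windows = np.lib.stride_tricks.sliding_window_view(est_arr, L)
    matches = windows == ref_arr  # (n_pos, L)
    mism = L - matches.sum(axis=1)
    if L < word:
        seeded = np.zeros(n_pos, dtype=bool)
    else:
        runs = np.lib.stride_tricks.sliding_window_view(matches, word, axis=1)
        seeded = runs.all(axis=2).any(axis=1)
    return mism, seeded


def find_homologs(
    refs: Sequence[SequenceRecord],
    ests: Sequence[SequenceRecord],
    params: ScreenParams | None = None,
    stats: ScreenStats | None = None,
) -> list[HomologHit]:
    """All homolog hits of the reference matures on the ESTs.

    Hits are sorted by (est_id, est_start, ref_mirna_id); a placement is
    reported once even if reachable through several seed words.  References
    outside [min_len, max_len] are skipped; a reference shorter than the
    word length is an error.
    """
    params = params or ScreenParams()
    usable_refs = []
    for ref in refs:
        if len(ref.sequence) < params.word_length:
            raise ParameterError(
                f"reference {ref.id!r} is shorter than the word length"
            )
        if params.min_len <= len(ref.sequence) <= params.max_len:
            usable_refs.append(ref)

    strands = ("+",) if params.search_strands == "forward" else ("+", "-")
    hits: list[HomologHit] = []
    for est in ests:
        est_fwd = _encode(est.sequence)
        est_rev = _encode(revcomp(est.sequence)) if "-" in strands else None
        n_est = len(est.sequence)
        for ref in usable_refs:
            L = len(ref.sequence)
            ref_arr = _encode(ref.sequence)
            for strand in strands:
                arr = est_fwd if strand == "+" else est_rev
                mism, seeded = _placements(ref_arr, arr, params.word_length)
                if mism is None:
                    continue
                if stats is not None:
                    stats.n_word_seed_placements += int(seeded.sum())
                ok = seeded & (mism <= params.max_mismatches)
                for p in np.flatnonzero(ok):
                    m = int(mism[p])
                    identity = 100.0 * (L - m) / L
                    if identity < params.min_identity:
                        continue
                    start = int(p) if strand == "+" else n_est - int(p) - L
                    hits.append(
                        HomologHit(
                            est_id=est.id,
                            ref_mirna_id=ref.id,
                            est_start=start,
                            est_end=start + L,
                            strand=strand,
                            mismatches=m,
                            identity=identity,
                        )
                    )
    unique = sorted(set(hits), key=lambda h: (h.est_id, h.est_start, h.ref_mirna_id, h.strand))
    if stats is not None:
        stats.n_hits = len(unique)
    return unique


def remove_redundant(items: Sequence, key: Callable | None = None) -> tuple[list, int]:
    """Collapse exact duplicate candidate sequences to their first occurrence.

    ``key`` extracts the comparison sequence (defaults to the item itself,
    or ``.sequence`` when present).  Returns (filtered, n_removed);
    idempotent by construction.
    """
    if key is None:
        key = lambda x: getattr(x, "sequence", x)
    seen = set()
    kept = []
    for item in items:
        k = key(item)
        if k in seen:
            continue
        seen.add(k)
        kept.append(item)
    return kept, len(items) - len(kept)


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_codons(sequence: str) -> int:
    """Longest open reading frame over all 6 frames, in codons.

    An ORF starts at ATG and runs to the frame's next stop codon or to the
    end of the frame; its length counts the ATG and every following
    non-stop codon.
    """
    best = 0
    for seq in (sequence, revcomp(sequence)):
        for frame in range(3):
            current = 0
            in_orf = False
            for p in range(frame, len(seq) - 2, 3):
                codon = seq[p : p + 3]
                if codon in _STOPS:
                    best = max(best, current)
                    current = 0
                    in_orf = False
                elif in_orf:
                    current += 1
                elif codon == "ATG":
                    in_orf = True
                    current = 1
            best = max(best, current)
    return best


def filter_coding(
    candidates: Sequence[SequenceRecord], params: ScreenParams | None = None
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """(non-coding, coding) partition by the 6-frame longest-ORF heuristic."""
    params = params or ScreenParams()
    noncoding, coding = [], []
    for rec in candidates:
        if longest_orf_codons(rec.sequence) >= params.orf_codon_threshold:
            coding.append(rec)
        else:
            noncoding.append(rec)
    return noncoding, coding
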