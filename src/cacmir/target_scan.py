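"""miRNA -> transcript target-site scanning with expectation scoring.

Each ungapped placement of the mature miRNA against a transcript window is
scored positionally: miRNA position i (5'->3') faces transcript base
site[L-1-i] of the site read 5'->3'.  Watson-Crick pairs cost 0, G:U wobbles
``gu_penalty``, mismatches ``mismatch_penalty``; positions inside the seed
region are multiplied by ``seed_multiplier``.  Gaps are not allowed.  Sites
are kept when the expectation E and the mismatch count are within bounds,
and at most ``max_multiplicity`` best sites survive per miRNA-transcript
pair.  Target-site accessibility (UPE) is the energetic cost of forcing the
site open in the local secondary structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import AlignmentError, ParameterError
from .hairpin import fold
from .io_formats import SequenceRecord

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # miRNA base vs target base, DNA alphabet


@dataclass
class TargetParams:
    max_expectation: float = 3.0
    max_multiplicity: int = 2
    central_window: tuple[int, int] = (9, 11)   # 1-based miRNA positions
    max_mismatches: int = 4
    allow_gaps: bool = False                    # fixed; gapless scanning only
    seed_region: tuple[int, int] = (2, 13)      # 1-based, inclusive
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    seed_multiplier: float = 2.0
    upe_flank_up: int = 17
    upe_flank_down: int = 13
    gu_breaks_central: bool = True              # count G:U as a central "mis-match"

    def __post_init__(self) -> None:
        if self.mismatch_penalty < 0 or self.gu_penalty < 0 or self.seed_multiplier < 0:
            raise ParameterError("penalties must be non-negative")


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    expectation: float
    n_mismatches: int
    n_gu: int
    inhibition: str = ""
    upe: float | None = None
    states: tuple[str, ...] = ()
    alignment: str = ""


def score_alignment(
    mirna_seq: str, site_seq: str, params: TargetParams | None = None
) -> tuple[float, int, int, tuple[str, ...]]:
    """Score one gapless miRNA/site alignment.

    Returns (E, n_mismatches, n_gu, per-position states); states are indexed
    by miRNA position (5'->3'), each "match", "gu" or "mismatch".
    """
    params = params or TargetParams()
    m = mirna_seq.upper().replace("U", "T")
    s = site_seq.upper().replace("U", "T")
    if len(m) != len(s):
        raise AlignmentError("miRNA and site must have equal lengths (gapless)")
    L = len(m)
    lo, hi = params.seed_region
    E = 0.0
    n_mm = n_gu = 0
    states = []
    for i in range(L):
        a, b = m[i], s[L - 1 - i]
        if (a, b) in _WC:
            states.append("match")
            continue
        mult = params.seed_multiplier if lo <= i + 1 <= hi else 1.0
        if (a, b) in _GU:
            states.append("gu")
            n_gu += 1
            E += params.gu_penalty * mult
        else:
            states.append("mismatch")
            n_mm += 1
            E += params.mismatch_penalty * mult
    return E, n_mm, n_gu, tuple(states)


def classify_site(site: TargetSite, params: TargetParams | None = None) -> str:
    """"translation" iff a non-Watson-Crick position falls in the central window."""
    params = params or TargetParams()
    lo, hi = params.central_window
    broken = {"mismatch", "gu"} if params.gu_breaks_central else {"mismatch"}
    central = site.states[lo - 1 : hi]
    return "translation" if any(st in broken for st in central) else "cleavage"


def render_alignment(mirna_seq: str, site_seq: str, states: Sequence[str]) -> str:
    """Two-strand textual rendering, miRNA 3'->5' under the site 5'->3'."""
    mid = {"match": "|", "gu": "o", "mismatch": " "}
    L = len(mirna_seq)
    top = "5' " + site_seq + " 3'  (target)"
    bars = "   " + "".join(mid[states[L - 1 - i]] for i in range(L))
    bot = "3' " + mirna_seq[::-1] + " 5'  (miRNA)"
    return "\n".join([top, bars, bot])


def find_sites(
    mirna: SequenceRecord,
    transcript: SequenceRecord,
    params: TargetParams | None = None,
) -> list[TargetSite]:
    """All retained target sites of one miRNA on one transcript.

    Every gapless placement is scored; placements with E <= max_expectation
    and mismatches <= max_mismatches are kept; if more than max_multiplicity
    survive, the lowest-E (ties: leftmost) are retained.  The result is
    sorted by (E, position).
    """
    params = params or TargetParams()
    m = mirna.sequence
    t = transcript.sequence
    L = len(m)
    if len(t) < L:
        return []
    candidates = []
    for p in range(len(t) - L + 1):
        window = t[p : p + L]
        E, n_mm, n_gu, states = score_alignment(m, window, params)
        if E <= params.max_expectation and n_mm <= params.max_mismatches:
            site = TargetSite(
                mirna_id=mirna.id,
                transcript_id=transcript.id,
                site_start=p,
                site_end=p + L,
                expectation=E,
                n_mismatches=n_mm,
                n_gu=n_gu,
                states=states,
            )
            site.inhibition = classify_site(site, params)
            site.alignment = render_alignment(m, window, states)
            candidates.append(site)
    candidates.sort(key=lambda s: (s.expectation, s.site_start))
    kept = candidates[: params.max_multiplicity]
    kept.sort(key=lambda s: (s.expectation, s.site_start))
    return kept


def compute_upe(
    transcript: SequenceRecord,
    site: TargetSite,
    fold_backend: str = "builtin",
    params: TargetParams | None = None,
) -> float:
    """Unpaired energy: cost of opening the structure around the target site.

    The window is the site extended by (upe_flank_up, upe_flank_down) nt,
    clipped at the transcript ends; UPE = E(fold with site forced unpaired)
    - E(unconstrained fold) >= 0.
    """
    params = params or TargetParams()
    t = transcript.sequence
    if not 0 <= site.site_start < site.site_end <= len(t):
        raise ParameterError("site coordinates fall outside the transcript")
    w0 = max(0, site.site_start - params.upe_flank_up)
    w1 = min(len(t), site.site_end + params.upe_flank_down)
    window = t[w0:w1]
    blocked = range(site.site_start - w0, site.site_end - w0)
    e_free = fold(window, backend=fold_backend).energy
    e_open = fold(window, backend=fold_backend, forced_unpaired=blocked).energy
    return e_open - e_free


def count_unique_targets(associations: Iterable) -> tuple[int, int]:
    """(number of distinct gene symbols, number of distinct (miRNA, gene) pairs).

    Accepts (mirna, gene) tuples or any objects with ``mirna_name``/
    ``mirna_id`` and ``gene_symbol``/``transcript_id`` attributes.
    """
    genes = set()
    pairs = set()
    for a in associations:
        if isinstance(a, (tuple, list)):
            mirna, gene = a[0], a[1]
        else:
            mirna = getattr(a, "mirna_name", None) or getattr(a, "mirna_id")
            gene = getattr(a, "gene_symbol", None) or getattr(a, "transcript_id")
        genes.add(gene)
        pairs.add((mirna, gene))
    return len(genes), len(pairs)
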