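"""Brute-force structure enumeration used as an independent folding oracle."""

from cacmir.hairpin import MIN_LOOP, _pair_strength, score_structure


def enumerate_structures(seq, blocked=frozenset()):
    """All nested pair sets over seq (optionally with blocked positions)."""
    n = len(seq)

    def rec(pairs, next_i, avail):
        yield pairs
        for i in range(next_i, n):
            if i not in avail or i in blocked:
                continue
            for j in range(i + MIN_LOOP + 1, n):
                if j not in avail or j in blocked:
                    continue
                if _pair_strength(seq[i], seq[j]) == 0:
                    continue
                if any(a < i < b < j or i < a < j < b for (a, b) in pairs):
                    continue
                yield from rec(pairs + [(i, j)], i + 1, avail - {i, j})

    yield from rec([], 0, frozenset(range(n)))


def enumerate_min_energy(seq, blocked=frozenset()):
    return min(score_structure(seq, p) for p in enumerate_structures(seq, blocked))
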