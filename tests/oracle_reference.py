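"""Brute-force reference for the permeation counter.

Independent of the automaton implementation: for every arrival in a terminal
region (below=1 or above=4) it scans backwards for the most recent previous
terminal visit; a completed outward traversal requires that visit to be
region 1 with an ordered 2-then-3 subsequence in between (mirror for
inward).  O(n^2), used only on short sequences.
"""

from typing import Sequence, Tuple


def _has_ordered(gap: Sequence[int], pattern: Tuple[int, ...]) -> bool:
    it = iter(gap)
    return all(any(x == want for x in it) for want in pattern)


def oracle_counts(seq: Sequence[int]) -> Tuple[int, int]:
    """(n_outward, n_inward) by exhaustive traversal enumeration."""
    seq = [int(r) for r in seq if int(r) in (1, 2, 3, 4)]
    out = inw = 0
    for t, r in enumerate(seq):
        if r not in (1, 4):
            continue
        s = next((u for u in range(t - 1, -1, -1) if seq[u] in (1, 4)), None)
        if s is None:
            continue
        gap = seq[s + 1 : t]
        if r == 4 and seq[s] == 1 and _has_ordered(gap, (2, 3)):
            out += 1
        elif r == 1 and seq[s] == 4 and _has_ordered(gap, (3, 2)):
            inw += 1
    return out, inw
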