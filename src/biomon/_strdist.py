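"""Damerau-Levenshtein edit distance (optimal string alignment variant).

Used only for name-match suggestions; kept dependency-free on purpose so
the matching behaviour is fully specified by this file.
"""

from __future__ import annotations


def damerau_levenshtein(a: str, b: str) -> int:
    """Edit distance allowing insertion, deletion, substitution and
    transposition of adjacent characters (each cost 1).

    Implements the optimal-string-alignment recurrence: a substring may not
    be edited more than once, which is the conventional behaviour for
    spell-check style suggestions ("Beatis" -> "Baetis" costs 1).
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]
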