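"""Independent brute-force oracles used to check the library implementations.

Everything here is deliberately naive: exact rational arithmetic, O(n^2)
scans, per-position regex matching.  None of it shares code with the package.
"""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb


def ac_point_prob_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Audic-Claverie point probability by exact big-integer arithmetic."""
    r = Fraction(n2, n1)
    return r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)


def ac_two_sided_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Doubled inclusive tail, capped at 1, by direct summation."""
    lower = sum(ac_point_prob_exact(x, yy, n1, n2) for yy in range(0, y + 1))
    upper = 1 - lower + ac_point_prob_exact(x, y, n1, n2)
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by enumeration over the whole support."""
    total = comb(N, n)
    return Fraction(
        sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)), total
    )


def n50_bruteforce(lengths) -> int:
    """Largest L whose >=L contigs cover at least half the assembly."""
    half = sum(lengths) / 2
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) >= half:
            best = max(best, L)
    return best


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    return not any(
        k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
    )


def find_ssrs_regex(seq: str, min_total_len: int = 18, units=(2, 6)):
    """Per-position regex scan for maximal perfect repeats, then the same
    longest/left-most/shortest-unit conflict resolution the scanner defines.

    Returns a sorted list of (start0, end0, motif, copies) tuples.
    """
    candidates = []
    for k in range(units[0], units[1] + 1):
        for i in range(0, len(seq) - 2 * k + 1):
            motif = seq[i : i + k]
            if "N" in motif or not _is_primitive(motif):
                continue
            m = re.match(f"(?:{re.escape(motif)})+", seq[i:])
            copies = len(m.group(0)) // k
            if copies < 2 or copies * k < min_total_len:
                continue
            if i >= k and seq[i - k : i] == motif:
                continue  # not maximal on the left
            candidates.append((copies * k, i, k, motif, copies))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    kept, occupied = [], []
    for span, i, k, motif, copies in candidates:
        j = i + span - 1
        if any(i <= oe and j >= os_ for os_, oe in occupied):
            continue
        occupied.append((i, j))
        kept.append((i, j, motif, copies))
    return sorted(kept)
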