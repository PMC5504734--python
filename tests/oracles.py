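"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: alignment scores come
from exhaustive enumeration of every global alignment, not from dynamic
programming.
"""

from __future__ import annotations

from typing import Callable, Iterator


def score_alignment(
    row_a: str,
    row_b: str,
    sub: Callable[[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> float:
    """Score one gapped alignment; a gap run of length L costs
    gap_open + (L-1)*gap_extend, switching gap side opens a new gap."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= gap_extend if in_gap_b else gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += sub(ca, cb)
            in_gap_a = in_gap_b = False
    return score


def enumerate_alignments(a: str, b: str) -> Iterator[tuple[str, str]]:
    """Every global alignment of a and b (exponential; keep len <= 6)."""
    if not a and not b:
        yield ("", "")
        return
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)


def brute_force_score(
    a: str,
    b: str,
    sub: Callable[[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> float:
    return max(
        score_alignment(ra, rb, sub, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )


def simple_sub(match: float = 1.0, mismatch: float = -1.0) -> Callable[[str, str], float]:
    return lambda x, y: match if x == y else mismatch
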