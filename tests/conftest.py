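"""Shared fixtures and the independent alignment oracle.

The oracle is a pure-Python memoized three-state affine DP, written and
maintained separately from the package's vectorised aligner, plus an
exhaustive alignment enumerator for very short strings that validates the
oracle itself.  Both share the package's cost model: a gap of length L
costs gap_open + L * gap_extend, N pairs score 0.
"""

from __future__ import annotations

from functools import lru_cache

import pytest

from ampedit.align import Scoring
from ampedit.design import find_protospacer
from ampedit.toy import toy_loci

NEG = float("-inf")


def oracle_score(ref: str, read: str, sc: Scoring) -> int:
    """Optimal global affine-gap alignment score (memoized recursion)."""

    def pair(a: str, b: str) -> int:
        if a == "N" or b == "N":
            return 0
        return sc.match if a == b else sc.mismatch

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 = last column paired, 1 = last column deletion (ref gap
        # consumed), 2 = last column insertion (read consumed)
        if i == 0 and j == 0:
            return 0 if state == 0 else NEG
        candidates = []
        if state == 0 and i > 0 and j > 0:
            s = pair(ref[i - 1], read[j - 1])
            candidates += [best(i - 1, j - 1, p) + s for p in (0, 1, 2)]
        elif state == 1 and i > 0:
            candidates += [
                best(i - 1, j, 0) + sc.gap_open + sc.gap_extend,
                best(i - 1, j, 1) + sc.gap_extend,
                best(i - 1, j, 2) + sc.gap_open + sc.gap_extend,
            ]
        elif state == 2 and j > 0:
            candidates += [
                best(i, j - 1, 0) + sc.gap_open + sc.gap_extend,
                best(i, j - 1, 2) + sc.gap_extend,
                best(i, j - 1, 1) + sc.gap_open + sc.gap_extend,
            ]
        return max(candidates) if candidates else NEG

    result = max(best(len(ref), len(read), s) for s in (0, 1, 2))
    best.cache_clear()
    return int(result)


def enumerate_score(ref: str, read: str, sc: Scoring) -> int:
    """Exhaustive enumeration of all global alignments (tiny strings only)."""

    def go(i: int, j: int, last: str) -> float:
        if i == len(ref) and j == len(read):
            return 0
        options = []
        if i < len(ref) and j < len(read):
            a, b = ref[i], read[j]
            s = 0 if "N" in (a, b) else (sc.match if a == b else sc.mismatch)
            options.append(go(i + 1, j + 1, "M") + s)
        if i < len(ref):
            cost = sc.gap_extend + (0 if last == "D" else sc.gap_open)
            options.append(go(i + 1, j, "D") + cost)
        if j < len(read):
            cost = sc.gap_extend + (0 if last == "I" else sc.gap_open)
            options.append(go(i, j + 1, "I") + cost)
        return max(options)

    return int(go(0, 0, "M"))


@pytest.fixture(scope="session")
def loci():
    return toy_loci()


@pytest.fixture(scope="session")
def pos3(loci):
    locus = loci["POS3"]
    guide = find_protospacer(locus, locus.spacer)
    return locus, guide


@pytest.fixture(scope="session")
def pos5(loci):
    locus = loci["POS5"]
    guide = find_protospacer(locus, locus.spacer)
    return locus, guide
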