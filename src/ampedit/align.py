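"""Global pairwise alignment of reads to the amplicon with affine gaps.

Needleman-Wunsch/Gotoh with three states (match, gap-in-read, gap-in-ref).
A gap of length L costs ``gap_open + L * gap_extend``.  Traceback is
deterministic with tie-break order diagonal > up (deletion) > left
(insertion).  N bases score 0 against anything.

CIGAR vocabulary: ``=`` match, ``X`` substitution, ``D`` deletion from the
reference (consumes reference), ``I`` insertion (consumes read).  The CIGAR
consumes the entire read and the entire reference (global alignment).

Two exact shortcuts keep full-depth samples fast without changing results:
reads equal in length to the reference whose Hamming distance is small
enough that a gapped alignment provably cannot score higher are aligned
gaplessly, and duplicate read sequences are aligned once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqs import encode, hamming, revcomp

NEG = -(10**8)

# op codes shared with the numba kernel
_EQ, _X, _D, _I = 0, 1, 2, 3
_OP_CHARS = "=XDI"


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; penalties are negative."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("match must be positive; penalties negative")

    @property
    def gapless_hamming_bound(self) -> int:
        """Largest Hamming distance h for which a same-length gapless alignment
        is provably optimal: any gapped alternative pairs at most L-1 columns
        and pays for two gap openings, so it scores at most
        match*(L-1) + 2*(gap_open+gap_extend); gapless scores
        match*L - (match-mismatch)*h."""
        margin = self.match - 2 * (self.gap_open + self.gap_extend)
        h = (margin - 1) // (self.match - self.mismatch)
        return max(int(h), 0)


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentResult:
    """A global read-to-amplicon alignment.

    ``read_seq`` is the read in the orientation that was aligned; ``cigar``
    uses the =/X/D/I vocabulary above and spans the whole reference
    (``ref_span`` is always (0, len(reference))).
    """

    read_id: str
    read_seq: str
    cigar: str
    score: int
    orientation: str = "+"
    ref_span: tuple[int, int] = (0, 0)

    @property
    def runs(self) -> list[tuple[str, int]]:
        return parse_cigar(self.cigar)


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """CIGAR string -> list of (op, length) runs."""
    runs: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            runs.append((ch, int(num)))
            num = ""
    return runs


def runs_to_cigar(runs: list[tuple[str, int]]) -> str:
    merged: list[tuple[str, int]] = []
    for op, length in runs:
        if length == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + length)
        else:
            merged.append((op, length))
    return "".join(f"{n}{op}" for op, n in merged)


@njit(cache=True)
def _gotoh(ref, read, match, mismatch, go, ge):  # pragma: no cover - numba
    m = ref.size
    n = read.size
    S = np.empty((m + 1, n + 1), np.int32)  # best ending in a paired column
    D = np.empty((m + 1, n + 1), np.int32)  # best ending in a deletion
    I = np.empty((m + 1, n + 1), np.int32)  # best ending in an insertion
    S[0, 0] = 0
    D[0, 0] = NEG
    I[0, 0] = NEG
    for j in range(1, n + 1):
        S[0, j] = NEG
        D[0, j] = NEG
        I[0, j] = go + ge * j
    for i in range(1, m + 1):
        S[i, 0] = NEG
        D[i, 0] = go + ge * i
        I[i, 0] = NEG
        for j in range(1, n + 1):
            a = ref[i - 1]
            b = read[j - 1]
            if a == 4 or b == 4:
                s = 0
            elif a == b:
                s = match
            else:
                s = mismatch
            best = S[i - 1, j - 1]
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
            S[i, j] = best + s
            d = S[i - 1, j] + go + ge
            if D[i - 1, j] + ge > d:
                d = D[i - 1, j] + ge
            if I[i - 1, j] + go + ge > d:
                d = I[i - 1, j] + go + ge
            D[i, j] = d
            v = S[i, j - 1] + go + ge
            if I[i, j - 1] + ge > v:
                v = I[i, j - 1] + ge
            if D[i, j - 1] + go + ge > v:
                v = D[i, j - 1] + go + ge
            I[i, j] = v

    # traceback; tie-break diagonal > up (deletion) > left (insertion)
    ops = np.empty(m + n, np.int8)
    k = 0
    i = m
    j = n
    if S[m, n] >= D[m, n] and S[m, n] >= I[m, n]:
        state = 0
    elif D[m, n] >= I[m, n]:
        state = 1
    else:
        state = 2
    score = max(S[m, n], max(D[m, n], I[m, n]))
    while i > 0 or j > 0:
        if state == 0:
            a = ref[i - 1]
            b = read[j - 1]
            ops[k] = _EQ if (a == b or a == 4 or b == 4) else _X
            k += 1
            target = S[i, j]
            if a == 4 or b == 4:
                s = 0
            elif a == b:
                s = match
            else:
                s = mismatch
            prev = target - s
            i -= 1
            j -= 1
            if i == 0 and j == 0:
                break
            if S[i, j] == prev:
                state = 0
            elif D[i, j] == prev:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = _D
            k += 1
            target = D[i, j]
            i -= 1
            if S[i, j] + go + ge == target:
                state = 0
            elif D[i, j] + ge == target:
                state = 1
            else:
                state = 2
        else:
            ops[k] = _I
            k += 1
            target = I[i, j]
            j -= 1
            if S[i, j] + go + ge == target:
                state = 0
            elif I[i, j] + ge == target:
                state = 2
            else:
                state = 1
        if i == 0 and j == 0:
            break
    return score, ops[:k][::-1].copy()


def _ops_to_cigar(ops: np.ndarray) -> str:
    runs: list[tuple[str, int]] = []
    for code in ops:
        ch = _OP_CHARS[code]
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return runs_to_cigar(runs)


def _gapless_cigar(read: str, ref: str) -> str:
    runs: list[tuple[str, int]] = []
    for a, b in zip(ref, read):
        op = "=" if (a == b or a == "N" or b == "N") else "X"
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    return runs_to_cigar(runs)


def score_cigar(cigar: str, scoring: Scoring = DEFAULT_SCORING) -> int:
    """Score an =/X/D/I CIGAR under the affine scheme (for invariants).

    ``=`` columns involving N are indistinguishable here from true matches;
    the aligner emits ``=`` for N columns, which score 0, so this helper is
    exact only for N-free sequences.
    """
    score = 0
    for op, n in parse_cigar(cigar):
        if op == "=":
            score += n * scoring.match
        elif op == "X":
            score += n * scoring.mismatch
        elif op in "DI":
            score += scoring.gap_open + n * scoring.gap_extend
        else:
            raise ValueError(f"unexpected CIGAR op {op!r}")
    return score


def global_align(
    read: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "read",
) -> AlignmentResult:
    """Optimal global alignment of ``read`` against ``reference``.

    Deterministic: ties resolve diagonal > up (deletion) > left (insertion).
    """
    if not read or not reference:
        raise ValueError("empty sequence")
    read = read.upper()
    reference = reference.upper()
    if len(read) == len(reference):
        h = hamming(read, reference)
        if h <= scoring.gapless_hamming_bound:
            cigar = _gapless_cigar(read, reference)
            return AlignmentResult(
                read_id=read_id,
                read_seq=read,
                cigar=cigar,
                score=score_cigar(cigar, scoring) if "N" not in read + reference
                else _rescore_with_n(read, reference, scoring),
                ref_span=(0, len(reference)),
            )
    score, ops = _gotoh(
        encode(reference),
        encode(read),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    return AlignmentResult(
        read_id=read_id,
        read_seq=read,
        cigar=_ops_to_cigar(ops),
        score=int(score),
        ref_span=(0, len(reference)),
    )


def _rescore_with_n(read: str, ref: str, scoring: Scoring) -> int:
    score = 0
    for a, b in zip(ref, read):
        if a == "N" or b == "N":
            continue
        score += scoring.match if a == b else scoring.mismatch
    return score


def align_read(
    read: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "read",
) -> AlignmentResult:
    """Orientation-aware alignment: tries both strands, keeps the better.

    The forward orientation is preferred on ties.  Same-length reads within
    the provably-gapless Hamming bound short-circuit the dynamic program.
    """
    read = read.upper()
    rc = revcomp(read)
    if len(read) == len(reference):
        hf = hamming(read, reference.upper())
        hr = hamming(rc, reference.upper())
        bound = scoring.gapless_hamming_bound
        if min(hf, hr) <= bound:
            if hf <= hr:
                return global_align(read, reference, scoring, read_id)
            aln = global_align(rc, reference, scoring, read_id)
            return AlignmentResult(
                read_id=read_id, read_seq=rc, cigar=aln.cigar, score=aln.score,
                orientation="-", ref_span=aln.ref_span,
            )
    fwd = global_align(read, reference, scoring, read_id)
    rev = global_align(rc, reference, scoring, read_id)
    if fwd.score >= rev.score:
        return fwd
    return AlignmentResult(
        read_id=read_id, read_seq=rc, cigar=rev.cigar, score=rev.score,
        orientation="-", ref_span=rev.ref_span,
    )


def reconstruct_read(cigar: str, reference: str, read: str) -> str:
    """Regenerate the read from the CIGAR and reference (consistency check)."""
    out: list[str] = []
    i = 0
    j = 0
    for op, n in parse_cigar(cigar):
        if op in "=X":
            out.append(read[j : j + n])
            i += n
            j += n
        elif op == "D":
            i += n
        elif op == "I":
            out.append(read[j : j + n])
            j += n
    if i != len(reference) or j != len(read):
        raise ValueError("CIGAR does not consume the full read and reference")
    return "".join(out)


def left_align_indels(aln: AlignmentResult, reference: str) -> AlignmentResult:
    """Shift every indel to its leftmost score-equivalent placement.

    A deletion of ref[p:p+L] may move left while ref[p-1] == ref[p+L-1];
    an insertion of read[q:q+L] likewise while read[q-1] == read[q+L-1].
    The paired column displaced to the right faces an identical character,
    so match/mismatch status and score are unchanged.  Idempotent.
    """
    reference = reference.upper()
    read = aln.read_seq
    # expand to per-column ops with M for paired columns
    ops: list[str] = []
    for op, n in aln.runs:
        ops.extend(("M" if op in "=X" else op) * n)

    changed = True
    while changed:
        changed = False
        # recompute ref/read positions per column
        c = 0
        ref_pos = 0
        read_pos = 0
        while c < len(ops):
            op = ops[c]
            if op == "M":
                c += 1
                ref_pos += 1
                read_pos += 1
                continue
            # locate the full indel run
            c2 = c
            while c2 < len(ops) and ops[c2] == op:
                c2 += 1
            length = c2 - c
            if c > 0 and ops[c - 1] == "M":
                if op == "D":
                    p = ref_pos
                    can = reference[p - 1] == reference[p + length - 1]
                else:
                    q = read_pos
                    can = read[q - 1] == read[q + length - 1]
                if can:
                    # rotate: [M, run] -> [run, M]; re-examine the run at its
                    # new start so it keeps sliding as far left as possible
                    ops[c - 1 : c2] = [op] * length + ["M"]
                    changed = True
                    c -= 1
                    ref_pos -= 1
                    read_pos -= 1
                    continue
            for k in range(c, c2):
                if ops[k] == "D":
                    ref_pos += 1
                else:
                    read_pos += 1
            c = c2

    # rebuild =/X and runs
    runs: list[tuple[str, int]] = []
    ref_pos = 0
    read_pos = 0
    for op in ops:
        if op == "M":
            a = reference[ref_pos]
            b = read[read_pos]
            ch = "=" if (a == b or a == "N" or b == "N") else "X"
            ref_pos += 1
            read_pos += 1
        elif op == "D":
            ch = "D"
            ref_pos += 1
        else:
            ch = "I"
            read_pos += 1
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return AlignmentResult(
        read_id=aln.read_id,
        read_seq=read,
        cigar=runs_to_cigar(runs),
        score=aln.score,
        orientation=aln.orientation,
        ref_span=aln.ref_span,
    )


def to_sam_line(aln: AlignmentResult, rname: str) -> str:
    """Render one alignment as a SAM record (CIGAR in extended =/X form)."""
    flag = 0 if aln.orientation == "+" else 16
    qual = "*"
    return "\t".join(
        [
            aln.read_id,
            str(flag),
            rname,
            "1",
            "60",
            aln.cigar,
            "*",
            "0",
            "0",
            aln.read_seq,
            qual,
            f"AS:i:{aln.score}",
        ]
    )


def write_sam(
    alignments: list[AlignmentResult], reference: str, rname: str, path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{rname}\tLN:{len(reference)}\n")
        for aln in alignments:
            fh.write(to_sam_line(aln, rname) + "\n")


__all__ = [
    "Scoring",
    "DEFAULT_SCORING",
    "AlignmentResult",
    "global_align",
    "align_read",
    "left_align_indels",
    "reconstruct_read",
    "parse_cigar",
    "runs_to_cigar",
    "score_cigar",
    "write_sam",
    "to_sam_line",
]
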