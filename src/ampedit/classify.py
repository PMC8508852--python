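"""Three-way read classification (WT / MUT / INDEL) and canonical variant keys.

A read is INDEL if its alignment contains any insertion or deletion
(optionally restricted to a window around the cut site), MUT if it is
indel-free and carries the complete programmed alt allele at the edit
positions, and WT otherwise.  Base substitutions away from the edit site
never change the label: they are treated as PCR/sequencing errors and only
counted.  Reads whose alignment does not span the edit positions (edit
inside a terminal deletion) are uninformative and tallied separately.

Variant-key grammar (canonical, cut-site-relative, left-aligned):
``WT``; ``MUT``; deletion ``-<len>@<rel>`` (rel = first deleted base minus
cut site); insertion ``+<seq>@<rel>`` (rel = inter-base position minus cut
site); composite events joined with ``&`` in reference order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignmentResult, left_align_indels
from .loci import TargetLocus

WT, MUT, INDEL = "WT", "MUT", "INDEL"


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion, in amplicon coordinates."""

    kind: str  # 'del' or 'ins'
    ref_pos: int  # first deleted base, or inter-base insertion point
    length: int
    inserted: str = ""


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    label: str
    variant_key: str
    non_programmed_substitutions: int = 0
    edit_site_genotype: str = ""  # ref / alt / other
    informative: bool = True


def format_events(events: list[IndelEvent], anchor: int) -> str:
    parts = []
    for ev in sorted(events, key=lambda e: (e.ref_pos, e.kind)):
        rel = ev.ref_pos - anchor
        if ev.kind == "del":
            parts.append(f"-{ev.length}@{rel}")
        else:
            parts.append(f"+{ev.inserted}@{rel}")
    return "&".join(parts)


def parse_variant(descriptor: str) -> list[IndelEvent]:
    """Parse an indel descriptor (cut-relative) into events.

    The ``ref_pos`` of returned events is the cut-relative coordinate; add
    the cut site to place them on an amplicon.
    """
    events = []
    for part in descriptor.split("&"):
        part = part.strip()
        body, _, rel_text = part.partition("@")
        if not body or not rel_text:
            raise ValueError(f"malformed indel descriptor {part!r}")
        rel = int(rel_text)
        if body.startswith("-"):
            events.append(IndelEvent(kind="del", ref_pos=rel, length=int(body[1:])))
        elif body.startswith("+"):
            seq = body[1:].upper()
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"malformed insertion descriptor {part!r}")
            events.append(
                IndelEvent(kind="ins", ref_pos=rel, length=len(seq), inserted=seq)
            )
        else:
            raise ValueError(f"malformed indel descriptor {part!r}")
    return events


def classify_read(
    aln: AlignmentResult,
    locus: TargetLocus,
    cut_site: int | None = None,
    window: int | None = None,
) -> ReadCall:
    """Classify one aligned read; precedence INDEL > MUT > WT.

    ``aln`` should be left-aligned (see :func:`call_read`) so identical
    editing outcomes share a variant key.  ``window``, if given, restricts
    which indels count toward the INDEL label (|position - cut| <= window);
    by default every indel in the amplicon counts.
    """
    edit_offs = locus.edit_offsets
    anchor = cut_site if cut_site is not None else edit_offs[0]
    read = aln.read_seq
    ref_pos = 0
    read_pos = 0
    n_sub = 0
    events: list[IndelEvent] = []
    bases_at_edit: dict[int, str | None] = {o: None for o in edit_offs}
    runs = aln.runs
    for idx, (op, n) in enumerate(runs):
        if op in "=X":
            for o in edit_offs:
                if ref_pos <= o < ref_pos + n:
                    bases_at_edit[o] = read[read_pos + (o - ref_pos)]
            if op == "X":
                in_edit = sum(1 for o in edit_offs if ref_pos <= o < ref_pos + n)
                n_sub += n - in_edit
            ref_pos += n
            read_pos += n
        elif op == "D":
            terminal = idx == 0 or idx == len(runs) - 1
            if terminal and any(ref_pos <= o < ref_pos + n for o in edit_offs):
                return ReadCall(
                    read_id=aln.read_id,
                    label="",
                    variant_key="",
                    informative=False,
                )
            events.append(IndelEvent(kind="del", ref_pos=ref_pos, length=n))
            ref_pos += n
        elif op == "I":
            events.append(
                IndelEvent(
                    kind="ins",
                    ref_pos=ref_pos,
                    length=n,
                    inserted=read[read_pos : read_pos + n],
                )
            )
            read_pos += n
        else:
            raise ValueError(f"unexpected CIGAR op {op!r}")

    if window is not None:
        events = [e for e in events if abs(e.ref_pos - anchor) <= window]

    observed = "".join(bases_at_edit[o] or "-" for o in edit_offs)
    if observed == locus.edit.alt_allele:
        genotype = "alt"
    elif observed == locus.edit.ref_allele:
        genotype = "ref"
    else:
        genotype = "other"

    if events:
        label = INDEL
        key = format_events(events, anchor)
    elif genotype == "alt":
        label = MUT
        key = MUT
    else:
        label = WT
        key = WT
    return ReadCall(
        read_id=aln.read_id,
        label=label,
        variant_key=key,
        non_programmed_substitutions=n_sub,
        edit_site_genotype=genotype,
    )


def call_read(
    aln: AlignmentResult,
    locus: TargetLocus,
    cut_site: int | None = None,
    window: int | None = None,
) -> ReadCall:
    """Left-align indels, then classify (the standard per-read path)."""
    canonical = left_align_indels(aln, locus.wt_sequence)
    return classify_read(canonical, locus, cut_site=cut_site, window=window)


__all__ = [
    "WT",
    "MUT",
    "INDEL",
    "IndelEvent",
    "ReadCall",
    "classify_read",
    "call_read",
    "format_events",
    "parse_variant",
]
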