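"""Guide placement and design audits: PAM-relative offsets, re-cleavage
risk after successful editing, PE2 feasibility, and HR-template construction.

PAM-relative offset convention: offsets are counted on the protospacer
strand; -1 is the protospacer base immediately 5' of the PAM, -20 the
protospacer's 5' end, and 0/1/2 are the PAM bases themselves (0 = the
degenerate N).  Positive offsets >2 lie 3' of the PAM.
"""

from __future__ import annotations

import pandas as pd

from .loci import DesignAudit, GuideRNA, PegRNA, RepairTemplate, TargetLocus
from .seqs import revcomp

#: protospacer offsets whose mismatches are assumed to block re-cleavage
SEED_OFFSETS = range(-12, 0)

RECLEAVABLE = "recleavable"
LOW_RISK = "low_risk_seed_mismatch"
ABOLISHED = "abolished_pam"


def find_protospacer(locus: TargetLocus, spacer: str) -> GuideRNA:
    """Locate a 20-nt protospacer (either strand) immediately 5' of an NGG PAM.

    Raises ValueError "no protospacer site" if absent and "ambiguous
    protospacer" (listing all placements) if it occurs more than once.
    """
    spacer = spacer.upper()
    if len(spacer) != 20 or set(spacer) - set("ACGT"):
        raise ValueError("spacer must be 20 nt over ACGT")
    seq = locus.wt_sequence
    hits: list[GuideRNA] = []
    # plus strand: spacer then NGG
    start = 0
    while (i := seq.find(spacer, start)) != -1:
        pam_start = i + 20
        if pam_start + 3 <= len(seq) and seq[pam_start + 1 : pam_start + 3] == "GG":
            hits.append(
                GuideRNA(
                    spacer=spacer,
                    strand="+",
                    pam=seq[pam_start : pam_start + 3],
                    pam_start=pam_start,
                    cut_site=pam_start - 3,
                )
            )
        start = i + 1
    # minus strand: plus sequence reads CCN + revcomp(spacer)
    rc = revcomp(spacer)
    start = 0
    while (i := seq.find(rc, start)) != -1:
        pam_start = i - 3
        if pam_start >= 0 and seq[pam_start : pam_start + 2] == "CC":
            hits.append(
                GuideRNA(
                    spacer=spacer,
                    strand="-",
                    pam=revcomp(seq[pam_start : pam_start + 3]),
                    pam_start=pam_start,
                    cut_site=pam_start + 6,
                )
            )
        start = i + 1
    if not hits:
        raise ValueError(f"no protospacer site for spacer {spacer} in {locus.locus_id}")
    if len(hits) > 1:
        placements = ", ".join(f"{g.strand}@pam{g.pam_start}" for g in hits)
        raise ValueError(f"ambiguous protospacer in {locus.locus_id}: {placements}")
    return hits[0]


def pam_offset_of(guide: GuideRNA, amplicon_offset: int) -> int:
    """PAM-relative offset (protospacer-strand convention) of an amplicon position."""
    if guide.strand == "+":
        return amplicon_offset - guide.pam_start
    return guide.pam_start + 2 - amplicon_offset


def edit_pam_offset(locus: TargetLocus, guide: GuideRNA) -> list[int]:
    """PAM-relative offsets of every edited position, ascending.

    Positions far from the protospacer/PAM window (beyond +-30 nt of the
    cut) are still reported; the distance is the designer's concern.
    """
    offs = sorted(pam_offset_of(guide, o) for o in locus.edit_offsets)
    return offs


def _protospacer_at(seq: str, strand: str, pam_start: int) -> str | None:
    """The 20-nt protospacer supported by an NGG frame at pam_start, or None."""
    if strand == "+":
        if pam_start - 20 < 0 or pam_start + 3 > len(seq):
            return None
        if seq[pam_start + 1 : pam_start + 3] != "GG":
            return None
        return seq[pam_start - 20 : pam_start]
    if pam_start < 0 or pam_start + 23 > len(seq):
        return None
    if seq[pam_start : pam_start + 2] != "CC":
        return None
    return revcomp(seq[pam_start + 3 : pam_start + 23])


def recleavage_check(
    locus: TargetLocus, guide: GuideRNA, window: int = 6, allele: str | None = None
) -> str:
    """Classify re-cleavage risk of the successfully edited allele.

    Scans the edited amplicon (or ``allele``, if given — e.g. the wild type
    itself) for NGG frames within ``window`` nt of the guide's original PAM
    frame (same strand).  An exact 20-nt protospacer match next to an NGG is
    ``recleavable``; an NGG frame whose protospacer mismatches include the
    seed (offsets -1..-12) is ``low_risk_seed_mismatch``; no supporting NGG
    frame is ``abolished_pam``.
    """
    edited = locus.apply_edit() if allele is None else allele.upper()
    seen_ngg = False
    for shift in range(-window, window + 1):
        proto = _protospacer_at(edited, guide.strand, guide.pam_start + shift)
        if proto is None:
            continue
        seen_ngg = True
        mismatch_offsets = [
            i - 20 for i, (a, b) in enumerate(zip(guide.spacer, proto)) if a != b
        ]
        if not mismatch_offsets:
            return RECLEAVABLE
        if not any(m in SEED_OFFSETS for m in mismatch_offsets):
            # mismatches only in the PAM-distal tail are commonly tolerated
            return RECLEAVABLE
    return LOW_RISK if seen_ngg else ABOLISHED


def pegrna_feasibility(locus: TargetLocus, peg: PegRNA) -> tuple[bool, str]:
    """PE2 feasibility: the edit must lie 3' of the nick, within the RT template.

    Returns (feasible, reason).  The nick falls at the guide's cut site on
    the protospacer strand; the RT template rewrites the ``len(rt_template)``
    nucleotides 3' of the nick on that strand.
    """
    guide = peg.guide
    alt = locus.edit.alt_allele
    alt_on_edited_strand = alt if guide.strand == "+" else revcomp(alt)
    if alt_on_edited_strand not in peg.rt_template:
        raise ValueError("template does not encode edit")
    span = len(peg.rt_template)
    for off in locus.edit_offsets:
        if guide.strand == "+":
            dist = off - guide.cut_site + 1  # 1 = first nt 3' of the nick
        else:
            dist = guide.cut_site - off
        if dist < 1:
            return False, "edit upstream of nick"
        if dist > span:
            return False, "edit beyond RT-template span"
    return True, "edit downstream of nick within RT template"


def build_hr_template(
    locus: TargetLocus,
    kind: str = "ssDNA",
    total_length: int = 200,
    overhang_length: int = 50,
) -> RepairTemplate:
    """Build an HR donor centered on the edit and carrying the alt allele.

    ssDNA / bio-ssDNA: one ``total_length``-nt strand (plus sense).
    dsDNA: that strand plus its full reverse complement (blunt).
    overhang5 / overhang3: two ``total_length``-nt strands offset by
    ``overhang_length`` so both protruding single-stranded ends have the
    stated polarity and the paired core is ``total_length - overhang_length``.
    """
    if kind not in ("ssDNA", "dsDNA", "overhang5", "overhang3", "bio-ssDNA"):
        raise ValueError(f"unknown template kind {kind!r}")
    edited = locus.apply_edit()
    offs = locus.edit_offsets
    center = (offs[0] + offs[-1] + 1) / 2  # inter-base center of the edit
    if kind in ("overhang5", "overhang3"):
        footprint = total_length + overhang_length
    else:
        footprint = total_length
    start = round(center - footprint / 2)
    if start < 0 or start + footprint > len(edited):
        raise ValueError(
            f"amplicon too short for template: need {footprint} nt around the edit"
        )
    if kind in ("ssDNA", "bio-ssDNA"):
        strands = (edited[start : start + total_length],)
    elif kind == "dsDNA":
        top = edited[start : start + total_length]
        strands = (top, revcomp(top))
    elif kind == "overhang5":
        # top protrudes 5' on the left, bottom protrudes 5' on the right
        top = edited[start : start + total_length]
        bottom = revcomp(edited[start + overhang_length : start + footprint])
        strands = (top, bottom)
    else:  # overhang3
        # top protrudes 3' on the right, bottom protrudes 3' on the left
        top = edited[start + overhang_length : start + footprint]
        bottom = revcomp(edited[start : start + total_length])
        strands = (top, bottom)
    return RepairTemplate(
        kind=kind,
        total_length=total_length,
        overhang_length=0 if kind in ("ssDNA", "dsDNA", "bio-ssDNA") else overhang_length,
        strands=strands,
        biotinylated=(kind == "bio-ssDNA"),
    )


def audit_design(
    locus: TargetLocus, guide: GuideRNA, peg: PegRNA | None = None
) -> DesignAudit:
    """Run every applicable audit for one locus/guide (and optional pegRNA)."""
    feasible: bool | None = None
    reason = ""
    if peg is not None:
        feasible, reason = pegrna_feasibility(locus, peg)
    return DesignAudit(
        locus_id=locus.locus_id,
        edit_offsets=tuple(edit_pam_offset(locus, guide)),
        recleavage_risk=recleavage_check(locus, guide),
        pe2_feasible=feasible,
        pe2_reason=reason,
    )


def audit_table(loci: dict[str, TargetLocus]) -> pd.DataFrame:
    """Audit every locus that carries a spacer; returns one row per locus."""
    rows = []
    for lid, locus in loci.items():
        if locus.spacer is None:
            continue
        guide = find_protospacer(locus, locus.spacer)
        audit = audit_design(locus, guide)
        rows.append(
            {
                "locus_id": lid,
                "strand": guide.strand,
                "pam": guide.pam,
                "cut_site": guide.cut_site,
                "edit_pam_offsets": ",".join(map(str, audit.edit_offsets)),
                "recleavage_risk": audit.recleavage_risk,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "find_protospacer",
    "pam_offset_of",
    "edit_pam_offset",
    "recleavage_check",
    "pegrna_feasibility",
    "build_hr_template",
    "audit_design",
    "audit_table",
    "RECLEAVABLE",
    "LOW_RISK",
    "ABOLISHED",
    "SEED_OFFSETS",
]
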