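"""Target loci, programmed edits, guides, pegRNAs and repair templates.

Coordinate conventions
----------------------
Genomic positions are 1-based inclusive, as printed in locus tables
(assembly label carried as metadata, e.g. GRCm39).  Internal amplicon
offsets are 0-based half-open.  ``TargetLocus.amplicon_start`` is the
1-based genomic coordinate of the amplicon's first base, so
``offset = genomic_position - amplicon_start``.

``GuideRNA.pam_start`` is always the 0-based offset of the *leftmost*
base of the PAM triplet on the plus (amplicon) strand, for both guide
orientations.  ``cut_site`` is a 0-based inter-base index: the blunt
SpCas9 cut (and the PE2 nick on the protospacer strand) falls between
amplicon bases ``cut_site - 1`` and ``cut_site``, 3 bp 5' of the PAM on
the protospacer strand (between protospacer positions 17 and 18).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .seqs import check_dna, revcomp


@dataclass(frozen=True)
class EditSpec:
    """A programmed substitution: contiguous genomic positions, ref and alt alleles."""

    positions: tuple[int, ...]
    ref_allele: str
    alt_allele: str
    assembly: str = "GRCm39"

    def __post_init__(self) -> None:
        ref = check_dna(self.ref_allele, "ref_allele", allow_n=False)
        alt = check_dna(self.alt_allele, "alt_allele", allow_n=False)
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))
        if len(ref) != len(alt):
            raise ValueError("ref_allele and alt_allele must have equal length")
        if ref == alt:
            raise ValueError("ref_allele and alt_allele must differ in >=1 position")
        if len(self.positions) != len(ref):
            raise ValueError("positions must list one coordinate per edited base")
        diffs = [b - a for a, b in zip(self.positions, self.positions[1:])]
        if any(d != 1 for d in diffs):
            raise ValueError("positions must be contiguous and ascending")

    def __len__(self) -> int:
        return len(self.ref_allele)


@dataclass(frozen=True)
class TargetLocus:
    """A wild-type amplicon plus its programmed edit at genomic coordinates."""

    locus_id: str
    chrom: str
    amplicon_start: int
    wt_sequence: str
    edit: EditSpec | None = None
    spacer: str | None = None  # optional guide protospacer, genome-sense on its strand

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "wt_sequence", check_dna(self.wt_sequence, "wt_sequence")
        )
        if self.spacer is not None:
            object.__setattr__(
                self, "spacer", check_dna(self.spacer, "spacer", allow_n=False)
            )
        if self.edit is not None:
            offs = self.edit_offsets
            if offs[0] <= 0 or offs[-1] >= len(self.wt_sequence) - 1:
                raise ValueError("edit positions must fall strictly inside the amplicon")
            found = "".join(self.wt_sequence[o] for o in offs)
            if found != self.edit.ref_allele:
                raise ValueError(
                    f"wt_sequence at edit positions is {found!r}, "
                    f"expected ref_allele {self.edit.ref_allele!r}"
                )

    @property
    def edit_offsets(self) -> tuple[int, ...]:
        """0-based amplicon offsets of the edited positions."""
        if self.edit is None:
            raise ValueError(f"locus {self.locus_id} has no edit specification")
        return tuple(p - self.amplicon_start for p in self.edit.positions)

    def apply_edit(self) -> str:
        """Return the programmed (MUT) allele of the amplicon."""
        offs = self.edit_offsets
        seq = list(self.wt_sequence)
        for o, b in zip(offs, self.edit.alt_allele):
            seq[o] = b
        return "".join(seq)

    def revert_edit(self, edited: str) -> str:
        """Invert :meth:`apply_edit` (substitution edits preserve length)."""
        offs = self.edit_offsets
        seq = list(edited)
        for o, b in zip(offs, self.edit.ref_allele):
            seq[o] = b
        return "".join(seq)


@dataclass(frozen=True)
class GuideRNA:
    """An SpCas9 guide placed on an amplicon.

    ``spacer`` is the 20-nt protospacer read 5'->3' on the protospacer
    strand; ``pam`` likewise (always NGG on that strand).
    """

    spacer: str
    strand: str
    pam: str
    pam_start: int
    cut_site: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", check_dna(self.spacer, "spacer", allow_n=False))
        object.__setattr__(self, "pam", check_dna(self.pam, "pam"))
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError("PAM must match NGG")
        expected_cut = self.pam_start - 3 if self.strand == "+" else self.pam_start + 6
        if self.cut_site != expected_cut:
            raise ValueError(
                "cut_site must sit 3 bp 5' of the PAM on the protospacer strand"
            )


@dataclass(frozen=True)
class PegRNA:
    """A prime-editing guide: nicking guide plus PBS and RT-template segments.

    ``rt_template`` is given in the sense of the edited (nicked) strand,
    i.e. as the DNA sequence the reverse transcriptase writes starting at
    the nick; it must encode the programmed alt allele.
    """

    guide: GuideRNA
    pbs_length: int
    rt_template: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rt_template", check_dna(self.rt_template, "rt_template", allow_n=False)
        )
        if self.pbs_length <= 0:
            raise ValueError("pbs_length must be positive")

    @property
    def edited_strand(self) -> str:
        """PE2 nicks (and edits) the protospacer/PAM strand of its guide."""
        return self.guide.strand


TEMPLATE_KINDS = ("ssDNA", "dsDNA", "overhang5", "overhang3", "bio-ssDNA")


@dataclass(frozen=True)
class RepairTemplate:
    """An HR donor: 200-nt single strand, blunt duplex, or 5'/3'-overhang duplex."""

    kind: str
    total_length: int
    overhang_length: int
    strands: tuple[str, ...]
    biotinylated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in TEMPLATE_KINDS:
            raise ValueError(f"unknown template kind {self.kind!r}")
        for s in self.strands:
            if len(s) != self.total_length:
                raise ValueError("every template strand must have total_length nt")


@dataclass(frozen=True)
class DesignAudit:
    """Outcome of auditing one guide/pegRNA design against a locus."""

    locus_id: str
    edit_offsets: tuple[int, ...] = field(default_factory=tuple)
    recleavage_risk: str = ""
    pe2_feasible: bool | None = None
    pe2_reason: str = ""


def _parse_positions(text: str) -> tuple[int, ...]:
    """Parse '89314728' or '140044791-140044793' into contiguous positions."""
    text = str(text).strip()
    if "-" in text:
        lo, hi = text.split("-", 1)
        return tuple(range(int(lo), int(hi) + 1))
    return (int(text),)


def read_loci(tsv_path: str | Path, fasta_path: str | Path) -> dict[str, TargetLocus]:
    """Load loci from a description TSV plus a companion amplicon FASTA.

    The TSV carries columns locus_id, chrom, amplicon_start, edit_positions,
    ref_allele, alt_allele, spacer; the FASTA is keyed by locus_id.
    """
    table = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {
        "locus_id", "chrom", "amplicon_start",
        "edit_positions", "ref_allele", "alt_allele", "spacer",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"loci table missing columns: {sorted(missing)}")
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    loci: dict[str, TargetLocus] = {}
    for row in table.itertuples(index=False):
        lid = str(row.locus_id)
        if lid not in seqs:
            raise ValueError(f"amplicon FASTA lacks sequence for locus {lid!r}")
        edit = EditSpec(
            positions=_parse_positions(row.edit_positions),
            ref_allele=str(row.ref_allele),
            alt_allele=str(row.alt_allele),
        )
        spacer = None if pd.isna(row.spacer) or not str(row.spacer) else str(row.spacer)
        loci[lid] = TargetLocus(
            locus_id=lid,
            chrom=str(row.chrom),
            amplicon_start=int(row.amplicon_start),
            wt_sequence=seqs[lid],
            edit=edit,
            spacer=spacer,
        )
    return loci


def write_loci(
    loci: dict[str, TargetLocus], tsv_path: str | Path, fasta_path: str | Path
) -> None:
    """Write loci back to the TSV + FASTA pair accepted by :func:`read_loci`."""
    rows = []
    for lid, loc in loci.items():
        pos = loc.edit.positions
        pos_text = str(pos[0]) if len(pos) == 1 else f"{pos[0]}-{pos[-1]}"
        rows.append(
            {
                "locus_id": lid,
                "chrom": loc.chrom,
                "amplicon_start": loc.amplicon_start,
                "edit_positions": pos_text,
                "ref_allele": loc.edit.ref_allele,
                "alt_allele": loc.edit.alt_allele,
                "spacer": loc.spacer or "",
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for lid, loc in loci.items():
            fh.write(f">{lid}\n{loc.wt_sequence}\n")


__all__ = [
    "EditSpec",
    "TargetLocus",
    "GuideRNA",
    "PegRNA",
    "RepairTemplate",
    "DesignAudit",
    "TEMPLATE_KINDS",
    "read_loci",
    "write_loci",
    "revcomp",
]
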