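"""Synthetic toy loci reproducing the five study geometries.

The real amplicon, sgRNA, pegRNA and template sequences live in the study's
supplementary material and are not redistributed here.  These five loci are
synthetic stand-ins engineered to the printed design geometries, anchored at
the printed GRCm39 coordinates:

* POS1 chr3:89314728  G/A  — single substitution at PAM offset -3 (+ strand)
* POS2 chr3:89310707  T/A  — single substitution at PAM offset -3 (- strand)
* POS3 chr2:140025881 T/C  — substitution at -1; the edit creates a new NGG
  frame shifted one nucleotide into the protospacer
* POS4 chr2:140044791-3 GGT/TAA — 3-bp edit overlapping the PAM; successful
  editing abolishes every nearby NGG frame
* POS5 chr5:66441024-6 TGT/GCC — 3-bp edit at offsets -4..-6, upstream of the
  cut, hence usable for HR but not for PE2 from the same cleavage site

Flanking sequence is drawn from a fixed seeded RNG, so the loci are
deterministic; geometric properties are asserted by the test suite.
"""

from __future__ import annotations

import numpy as np

from .loci import EditSpec, GuideRNA, PegRNA, TargetLocus
from .seqs import revcomp

_BASES = np.array(list("ACGT"))

#: printed edits: locus -> (chrom, first genomic position, ref, alt)
PRINTED_EDITS = {
    "POS1": ("chr3", 89314728, "G", "A"),
    "POS2": ("chr3", 89310707, "T", "A"),
    "POS3": ("chr2", 140025881, "T", "C"),
    "POS4": ("chr2", 140044791, "GGT", "TAA"),
    "POS5": ("chr5", 66441024, "TGT", "GCC"),
}

# engineered spacers (constraints commented as protospacer positions 1..20)
_SPACERS = {
    "POS1": "TGACCTTAGCATCAAGCGTA",  # position 18 (offset -3) = G
    "POS2": "CTAGCATGACGATCTGTAGC",  # position 18 (offset -3) = A (minus strand)
    "POS3": "GATCCATGCAAGTCAGTCAT",  # position 20 (offset -1) = T
    "POS4": "GGATCATGCTACGATCTACA",  # no GG among positions 13..20
    "POS5": "ACGATCATGCTAGCTGTTCA",  # positions 15..17 (offsets -6..-4) = TGT
}

_PAMS = {"POS1": "TGG", "POS2": "AGG", "POS3": "GGG", "POS4": "AGG", "POS5": "TGG"}

_AMPLICON_LENGTH = 300
_FLANK_LEFT = 130


def _random_flank(rng: np.random.Generator, length: int, forbid_gg: int = 0) -> str:
    """Random flank; the first ``forbid_gg`` bases avoid any GG dinucleotide."""
    while True:
        flank = "".join(rng.choice(_BASES, size=length))
        if forbid_gg == 0 or "GG" not in flank[: forbid_gg + 1]:
            return flank


def _build_locus(locus_id: str, index: int) -> TargetLocus:
    chrom, first_pos, ref, alt = PRINTED_EDITS[locus_id]
    spacer, pam = _SPACERS[locus_id], _PAMS[locus_id]
    rng = np.random.default_rng(20210923 + index)
    minus = locus_id == "POS2"
    core = "CCT" + revcomp(spacer) if minus else spacer + pam
    if locus_id == "POS4":
        # keep the post-PAM neighbourhood free of GG so the TAA edit
        # abolishes every NGG frame near the original PAM
        core += "T"  # the T of the GGT edit, immediately 3' of the PAM
        right = "TCTATC" + _random_flank(
            rng, _AMPLICON_LENGTH - _FLANK_LEFT - len(core) - 6
        )
    else:
        right = _random_flank(rng, _AMPLICON_LENGTH - _FLANK_LEFT - len(core))
    left = _random_flank(rng, _FLANK_LEFT)
    seq = left + core + right
    pam_start = _FLANK_LEFT if minus else _FLANK_LEFT + 20
    # amplicon offset of the first edited base, per geometry
    if locus_id in ("POS1",):
        first_off = pam_start - 3
    elif locus_id == "POS2":
        first_off = pam_start + 5  # minus-strand offset -3
    elif locus_id == "POS3":
        first_off = pam_start - 1
    elif locus_id == "POS4":
        first_off = pam_start + 1  # GGT starts at the PAM's first G
    else:  # POS5
        first_off = pam_start - 6
    positions = tuple(range(first_pos, first_pos + len(ref)))
    return TargetLocus(
        locus_id=locus_id,
        chrom=chrom,
        amplicon_start=first_pos - first_off,
        wt_sequence=seq,
        edit=EditSpec(positions=positions, ref_allele=ref, alt_allele=alt),
        spacer=spacer,
    )


def toy_loci() -> dict[str, TargetLocus]:
    """The five synthetic loci, keyed POS1..POS5."""
    return {lid: _build_locus(lid, i) for i, lid in enumerate(PRINTED_EDITS)}


def build_pegrna(
    locus: TargetLocus,
    guide: GuideRNA,
    pbs_length: int = 13,
    rt_length: int = 13,
) -> PegRNA:
    """Derive a pegRNA whose RT template copies the edited allele from the nick.

    The RT template is taken in the sense of the nicked (protospacer)
    strand, reading 3' from the nick across ``rt_length`` nucleotides of
    the edited amplicon.
    """
    edited = locus.apply_edit()
    if guide.strand == "+":
        rt = edited[guide.cut_site : guide.cut_site + rt_length]
    else:
        rt = revcomp(edited[guide.cut_site - rt_length : guide.cut_site])
    return PegRNA(guide=guide, pbs_length=pbs_length, rt_template=rt)


__all__ = ["PRINTED_EDITS", "toy_loci", "build_pegrna"]
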