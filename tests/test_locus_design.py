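"""Locus model and design-audit tests: guide placement, PAM offsets,
re-cleavage risk, PE2 feasibility, HR-template construction, file IO."""

import pytest

from ampedit.design import (
    ABOLISHED,
    LOW_RISK,
    RECLEAVABLE,
    build_hr_template,
    edit_pam_offset,
    find_protospacer,
    pegrna_feasibility,
    recleavage_check,
)
from ampedit.loci import EditSpec, PegRNA, TargetLocus, read_loci, write_loci
from ampedit.seqs import revcomp

SPACER = "ACGTACGTACGTACGTACGT"


def _locus(seq: str, locus_id: str = "toy", edit: EditSpec | None = None) -> TargetLocus:
    return TargetLocus(
        locus_id=locus_id, chrom="chr1", amplicon_start=1000, wt_sequence=seq, edit=edit
    )


# --- EditSpec / TargetLocus invariants ------------------------------------


def test_editspec_rejects_malformed_specs():
    with pytest.raises(ValueError, match="equal length"):
        EditSpec(positions=(10,), ref_allele="G", alt_allele="AT")
    with pytest.raises(ValueError, match="differ"):
        EditSpec(positions=(10,), ref_allele="G", alt_allele="G")
    with pytest.raises(ValueError, match="contiguous"):
        EditSpec(positions=(10, 12, 13), ref_allele="GGT", alt_allele="TAA")
    with pytest.raises(ValueError, match="one coordinate"):
        EditSpec(positions=(10,), ref_allele="GG", alt_allele="TA")


def test_locus_checks_ref_allele_against_amplicon():
    edit = EditSpec(positions=(1005,), ref_allele="T", alt_allele="C")
    with pytest.raises(ValueError, match="expected ref_allele"):
        _locus("A" * 20, edit=edit)  # position 1005 holds A, not T


def test_apply_then_revert_edit_roundtrips(loci):
    for locus in loci.values():
        edited = locus.apply_edit()
        assert edited != locus.wt_sequence
        assert locus.revert_edit(edited) == locus.wt_sequence


# --- find_protospacer -----------------------------------------------------


def test_find_protospacer_plus_strand_toy_example():
    locus = _locus("AAA" + SPACER + "AGGCCC")
    guide = find_protospacer(locus, SPACER)
    assert guide.strand == "+"
    assert guide.pam == "AGG"
    assert guide.pam_start == 23
    assert guide.cut_site == 20  # blunt cut between offsets 19 and 20


def test_find_protospacer_minus_strand():
    # plus strand carries CCN + revcomp(spacer): guide sits on the minus strand
    locus = _locus("TTT" + "CCT" + revcomp(SPACER) + "AAAT")
    guide = find_protospacer(locus, SPACER)
    assert guide.strand == "-"
    assert guide.pam_start == 3
    assert guide.pam == "AGG"  # minus-strand sense, NGG
    # cut 3 bp from the PAM on the minus strand
    assert guide.cut_site == guide.pam_start + 6


def test_find_protospacer_absent_and_ambiguous():
    with pytest.raises(ValueError, match="no protospacer site"):
        find_protospacer(_locus("A" * 40), SPACER)
    twice = "T" + SPACER + "AGG" + "AT" + SPACER + "TGGC"
    with pytest.raises(ValueError, match="ambiguous protospacer"):
        find_protospacer(_locus(twice), SPACER)


def test_find_protospacer_rejects_bad_spacer():
    with pytest.raises(ValueError, match="20 nt"):
        find_protospacer(_locus("A" * 30), "ACGT")


# --- edit_pam_offset: the five printed geometries -------------------------


@pytest.mark.parametrize(
    "locus_id, expected",
    [
        ("POS1", [-3]),
        ("POS2", [-3]),
        ("POS3", [-1]),
        ("POS4", [1, 2, 3]),  # overlaps the PAM GG
        ("POS5", [-6, -5, -4]),
    ],
)
def test_edit_pam_offsets_match_printed_geometries(loci, locus_id, expected):
    locus = loci[locus_id]
    guide = find_protospacer(locus, locus.spacer)
    assert edit_pam_offset(locus, guide) == expected


def test_pos4_edit_lies_within_pam(loci):
    offsets = edit_pam_offset(loci["POS4"], find_protospacer(loci["POS4"], loci["POS4"].spacer))
    assert any(o in (0, 1, 2) for o in offsets)


# --- recleavage_check -----------------------------------------------------


def test_wild_type_allele_is_recleavable_for_every_locus(loci):
    for locus in loci.values():
        guide = find_protospacer(locus, locus.spacer)
        risk = recleavage_check(locus, guide, allele=locus.wt_sequence)
        assert risk == RECLEAVABLE


def test_pam_destroying_edit_abolishes_recleavage(loci):
    locus = loci["POS4"]
    guide = find_protospacer(locus, locus.spacer)
    assert recleavage_check(locus, guide) == ABOLISHED


def test_seed_mismatch_edits_give_low_risk(loci):
    for locus_id in ("POS1", "POS2", "POS3", "POS5"):
        locus = loci[locus_id]
        guide = find_protospacer(locus, locus.spacer)
        assert recleavage_check(locus, guide) == LOW_RISK


def test_pos3_edit_creates_shifted_pam_frame(loci):
    # the -1 edit (T>C before a GGG PAM) creates an NGG frame shifted one
    # nucleotide into the protospacer; risk must still be low, not abolished
    locus = loci["POS3"]
    guide = find_protospacer(locus, locus.spacer)
    edited = locus.apply_edit()
    shifted = edited[guide.pam_start - 1 : guide.pam_start + 2]
    assert shifted[1:] == "GG"
    assert recleavage_check(locus, guide) == LOW_RISK


# --- pegrna_feasibility ---------------------------------------------------


def test_pos5_hr_site_unsuitable_for_pe2(pos5):
    locus, guide = pos5
    peg = PegRNA(guide=guide, pbs_length=13, rt_template="GCC" + "ATATATATAT")
    feasible, reason = pegrna_feasibility(locus, peg)
    assert not feasible
    assert reason == "edit upstream of nick"


def test_edit_downstream_of_nick_within_template_is_feasible(pos3):
    locus, guide = pos3
    from ampedit.toy import build_pegrna

    peg = build_pegrna(locus, guide, rt_length=13)
    assert locus.edit.alt_allele in peg.rt_template
    feasible, reason = pegrna_feasibility(locus, peg)
    assert feasible


def test_edit_beyond_rt_template_span_is_infeasible():
    # edit 8 nt downstream of the nick, RT template only 5 nt long
    seq = "TTTT" + SPACER + "TGG" + "CAAACATAAGGATTTTTT"
    # amplicon offset of the edit: cut site is at 4+17=21; pick offset 28
    edit = EditSpec(positions=(1028,), ref_allele=seq[28], alt_allele="G")
    locus = TargetLocus(
        locus_id="far", chrom="chr1", amplicon_start=1000, wt_sequence=seq, edit=edit
    )
    guide = find_protospacer(locus, SPACER)
    assert guide.cut_site == 21
    peg = PegRNA(guide=guide, pbs_length=13, rt_template="TGGCG")  # contains alt G
    feasible, reason = pegrna_feasibility(locus, peg)
    assert not feasible
    assert reason == "edit beyond RT-template span"


def test_template_lacking_edit_is_an_error(pos3):
    locus, guide = pos3
    peg = PegRNA(guide=guide, pbs_length=13, rt_template="AAAAAAAA")  # no C
    with pytest.raises(ValueError, match="template does not encode edit"):
        pegrna_feasibility(locus, peg)


# --- build_hr_template ----------------------------------------------------


@pytest.mark.parametrize("kind", ["ssDNA", "dsDNA", "overhang5", "overhang3", "bio-ssDNA"])
def test_template_strand_lengths_are_200(loci, kind):
    for locus in loci.values():
        tpl = build_hr_template(locus, kind=kind)
        assert tpl.total_length == 200
        assert all(len(s) == 200 for s in tpl.strands)


def test_ssdna_template_centered_on_edit_carries_alt(loci):
    for locus in loci.values():
        tpl = build_hr_template(locus, kind="ssDNA")
        (strand,) = tpl.strands
        alt = locus.edit.alt_allele
        mid = len(strand) // 2
        window = strand[mid - 3 : mid + 3]
        assert alt in window
        assert tpl.overhang_length == 0 and not tpl.biotinylated


def test_dsdna_second_strand_is_reverse_complement(loci):
    tpl = build_hr_template(loci["POS5"], kind="dsDNA")
    top, bottom = tpl.strands
    assert bottom == revcomp(top)


@pytest.mark.parametrize("kind", ["overhang5", "overhang3"])
def test_overhang_templates_pair_150_with_50_nt_ends(loci, kind):
    tpl = build_hr_template(loci["POS5"], kind=kind)
    top, bottom = tpl.strands
    bottom_rc = revcomp(bottom)  # plus-strand sense of the bottom strand
    # the two plus-sense windows overlap by exactly 150 nt
    if kind == "overhang5":
        assert top[50:] == bottom_rc[:150]
        assert top[:50] != bottom_rc[:50]
    else:
        assert top[:150] == bottom_rc[50:]
    assert tpl.overhang_length == 50


def test_bio_ssdna_flagged_biotinylated(loci):
    tpl = build_hr_template(loci["POS1"], kind="bio-ssDNA")
    assert tpl.biotinylated
    assert len(tpl.strands) == 1


def test_template_needs_sufficient_flank():
    seq = "AAT" + SPACER + "AGG" + "TTTTAAAACCCC"
    edit = EditSpec(positions=(1010,), ref_allele=seq[10], alt_allele="C")
    locus = TargetLocus(
        locus_id="short", chrom="chr1", amplicon_start=1000, wt_sequence=seq, edit=edit
    )
    with pytest.raises(ValueError, match="amplicon too short"):
        build_hr_template(locus, kind="ssDNA")


# --- file IO --------------------------------------------------------------


def test_loci_tsv_fasta_roundtrip(tmp_path, loci):
    tsv = tmp_path / "loci.tsv"
    fasta = tmp_path / "amplicons.fa"
    write_loci(loci, tsv, fasta)
    back = read_loci(tsv, fasta)
    assert set(back) == set(loci)
    for lid in loci:
        assert back[lid].wt_sequence == loci[lid].wt_sequence
        assert back[lid].edit == loci[lid].edit
        assert back[lid].spacer == loci[lid].spacer
        assert back[lid].amplicon_start == loci[lid].amplicon_start


def test_read_loci_reports_missing_columns(tmp_path, loci):
    tsv = tmp_path / "loci.tsv"
    fasta = tmp_path / "amplicons.fa"
    write_loci(loci, tsv, fasta)
    import pandas as pd

    broken = pd.read_csv(tsv, sep="\t").drop(columns=["spacer"])
    broken.to_csv(tsv, sep="\t", index=False)
    with pytest.raises(ValueError, match="missing columns"):
        read_loci(tsv, fasta)
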