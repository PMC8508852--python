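"""Read-simulator tests: variant realisation, multinomial draws, error
model, reproducibility, barcode round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from ampedit.design import find_protospacer
from ampedit.seqs import hamming
from ampedit.simulate import (
    UNDETERMINED,
    AlleleSpectrum,
    FastqRecord,
    SimulationConfig,
    attach_barcodes,
    demultiplex,
    read_fastq,
    realize_variant,
    simulate_reads,
    write_fastq,
)


@pytest.fixture(scope="module")
def pos3_cut(pos3):
    locus, guide = pos3
    return locus, guide.cut_site


# --- realize_variant ------------------------------------------------------


def test_wt_variant_is_identity(pos3_cut):
    locus, cut = pos3_cut
    assert realize_variant(locus, "WT", cut) == locus.wt_sequence


def test_mut_variant_of_single_base_edit_has_hamming_one(pos3_cut):
    locus, cut = pos3_cut
    mut = realize_variant(locus, "MUT", cut)
    assert hamming(mut, locus.wt_sequence) == 1


def test_deletion_shortens_amplicon(pos3_cut):
    locus, cut = pos3_cut
    seq = realize_variant(locus, "-2@0", cut)
    assert len(seq) == len(locus.wt_sequence) - 2
    assert seq == locus.wt_sequence[:cut] + locus.wt_sequence[cut + 2 :]


def test_insertion_lengthens_amplicon(pos3_cut):
    locus, cut = pos3_cut
    seq = realize_variant(locus, "+TT@0", cut)
    assert len(seq) == len(locus.wt_sequence) + 2
    assert seq[cut : cut + 2] == "TT"


def test_composite_indel_applies_both_events(pos3_cut):
    locus, cut = pos3_cut
    seq = realize_variant(locus, "-1@0&+GCA@5", cut)
    assert len(seq) == len(locus.wt_sequence) - 1 + 3


def test_deletion_past_amplicon_end_rejected(pos3_cut):
    locus, cut = pos3_cut
    overhang = len(locus.wt_sequence)  # deletion reaching past the 3' end
    with pytest.raises(ValueError, match="past the amplicon end"):
        realize_variant(locus, f"-{overhang}@0", cut)


# --- AlleleSpectrum validation -------------------------------------------


def test_spectrum_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        AlleleSpectrum.from_dict({"WT": 0.5, "MUT": 0.4})
    with pytest.raises(ValueError, match="non-negative"):
        AlleleSpectrum(entries=(("WT", 1.2), ("MUT", -0.2)))


def test_spectrum_validates_descriptor_grammar():
    with pytest.raises(ValueError, match="malformed"):
        AlleleSpectrum.from_dict({"WT": 0.5, "del2": 0.5})


def test_spectrum_rejects_duplicate_descriptors():
    with pytest.raises(ValueError, match="duplicate"):
        AlleleSpectrum(entries=(("WT", 0.5), ("WT", 0.5)))


# --- simulate_reads -------------------------------------------------------


def test_error_free_wt_spectrum_yields_identical_reads(pos3_cut):
    locus, cut = pos3_cut
    spectrum = AlleleSpectrum.from_dict({"WT": 1.0})
    config = SimulationConfig(n_reads=200, error_rate=0.0, seed=1)
    records, truth = simulate_reads(locus, spectrum, config, cut)
    assert len(records) == 200
    assert all(r.seq == locus.wt_sequence for r in records)
    assert set(truth["variant"]) == {"WT"}


def test_multinomial_proportions_within_three_se(pos3_cut):
    locus, cut = pos3_cut
    nominal = {"WT": 0.5, "MUT": 0.2, "-2@0": 0.3}
    spectrum = AlleleSpectrum.from_dict(nominal)
    n = 10_000
    config = SimulationConfig(n_reads=n, error_rate=0.0, seed=42)
    _, truth = simulate_reads(locus, spectrum, config, cut)
    observed = truth["variant"].value_counts(normalize=True)
    for variant, p in nominal.items():
        se = math.sqrt(p * (1 - p) / n)
        assert abs(observed[variant] - p) <= 3 * se


def test_mean_substitution_count_matches_binomial_expectation(pos3_cut):
    locus, cut = pos3_cut
    error_rate = 0.002
    n = 10_000
    spectrum = AlleleSpectrum.from_dict({"WT": 1.0})
    config = SimulationConfig(n_reads=n, error_rate=error_rate, seed=3)
    records, _ = simulate_reads(locus, spectrum, config, cut)
    L = len(locus.wt_sequence)
    counts = [hamming(r.seq, locus.wt_sequence) for r in records]
    expected = error_rate * L
    se = math.sqrt(L * error_rate * (1 - error_rate) / n)
    assert abs(np.mean(counts) - expected) <= 3 * se


def test_identical_seed_gives_byte_identical_fastq(pos3_cut, tmp_path):
    locus, cut = pos3_cut
    spectrum = AlleleSpectrum.from_dict({"WT": 0.6, "MUT": 0.2, "-1@0": 0.2})
    config = SimulationConfig(n_reads=500, error_rate=0.005, seed=99)
    p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
    for p in (p1, p2):
        records, _ = simulate_reads(locus, spectrum, config, cut)
        write_fastq(records, p)
    assert p1.read_bytes() == p2.read_bytes()


def test_fastq_roundtrip_preserves_reads(pos3_cut, tmp_path):
    locus, cut = pos3_cut
    spectrum = AlleleSpectrum.from_dict({"WT": 1.0})
    config = SimulationConfig(n_reads=50, error_rate=0.01, seed=5)
    records, _ = simulate_reads(locus, spectrum, config, cut)
    path = tmp_path / "reads.fastq.gz"
    write_fastq(records, path)
    back = read_fastq(path)
    assert [(r.read_id, r.seq) for r in back] == [(r.read_id, r.seq) for r in records]


# --- barcodes -------------------------------------------------------------


def _sheet(*pairs):
    return pd.DataFrame([{"sample_id": s, "barcode": b} for s, b in pairs])


def test_barcode_round_trip_reassigns_every_read(pos3_cut):
    locus, cut = pos3_cut
    spectrum = AlleleSpectrum.from_dict({"WT": 1.0})
    reads_by_sample = {}
    for i, sample in enumerate(["s1", "s2"]):
        config = SimulationConfig(n_reads=100, error_rate=0.0, seed=i, sample_id=sample)
        records, _ = simulate_reads(locus, spectrum, config, cut)
        reads_by_sample[sample] = records
    sheet = _sheet(("s1", "ACGTACGT"), ("s2", "TGCATGCA"))
    pooled = attach_barcodes(reads_by_sample, sheet)
    out = demultiplex(pooled, sheet)
    assert len(out["s1"]) == 100 and len(out["s2"]) == 100
    assert len(out[UNDETERMINED]) == 0
    assert all(r.seq == locus.wt_sequence for r in out["s1"])


def test_single_barcode_mismatch_goes_undetermined():
    sheet = _sheet(("s1", "ACGTACGT"))
    good = FastqRecord("r1", "ACGTACGT" + "TTTT", "I" * 12)
    bad = FastqRecord("r2", "ACGAACGT" + "TTTT", "I" * 12)  # 1 mismatch
    out = demultiplex([good, bad], sheet)
    assert [r.read_id for r in out["s1"]] == ["r1"]
    assert [r.read_id for r in out[UNDETERMINED]] == ["r2"]


def test_duplicate_barcode_rejected():
    sheet = _sheet(("s1", "ACGTACGT"), ("s2", "ACGTACGT"))
    with pytest.raises(ValueError, match="duplicate barcode"):
        demultiplex([], sheet)


def test_empty_sample_sheet_rejected():
    with pytest.raises(ValueError, match="empty sample sheet"):
        attach_barcodes({}, pd.DataFrame(columns=["sample_id", "barcode"]))


def test_unknown_sample_in_attach_rejected():
    sheet = _sheet(("s1", "ACGTACGT"))
    with pytest.raises(ValueError, match="not in sample sheet"):
        attach_barcodes({"sX": []}, sheet)
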