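"""Synthetic single-end amplicon reads from a specified allele spectrum.

Emulates the study's data-generating process: per-read allele labels are
drawn multinomially from a spectrum of WT, programmed-edit (MUT) and
cut-site-proximal indel variants; each base is then substituted
independently with a per-base error probability (uniform over the three
alternative bases).  Reads span the full amplicon, carry a constant
quality string, and true labels are recorded in a sidecar truth table.
Identical seed and configuration give byte-identical output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import parse_variant
from .loci import TargetLocus
from .seqs import check_dna

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {ord(b): i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class AlleleSpectrum:
    """Variant descriptors with proportions summing to 1.

    Descriptors are ``WT``, ``MUT`` or indel strings in the classifier's
    cut-relative grammar (e.g. ``-2@0``, ``+T@0``, ``-1@0&+TT@3``).
    """

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        entries = tuple((str(k), float(p)) for k, p in self.entries)
        object.__setattr__(self, "entries", entries)
        props = [p for _, p in entries]
        if not entries or any(p < 0 for p in props):
            raise ValueError("proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1 (got {sum(props)})")
        keys = [k for k, _ in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant descriptor in spectrum")
        for k in keys:
            if k not in ("WT", "MUT"):
                parse_variant(k)  # validates the grammar

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "AlleleSpectrum":
        return cls(entries=tuple(d.items()))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleSpectrum":
        df = pd.read_csv(path, sep="\t", dtype={"variant": str, "proportion": float})
        return cls(entries=tuple(zip(df["variant"], df["proportion"])))


@dataclass(frozen=True)
class SimulationConfig:
    """Simulator settings; the default depth matches the study's sequencing regime."""

    n_reads: int = 200_000
    error_rate: float = 0.002
    seed: int = 0
    quality_char: str = "I"
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")


@dataclass(frozen=True)
class FastqRecord:
    read_id: str
    seq: str
    qual: str


def realize_variant(locus: TargetLocus, descriptor: str, cut_site: int) -> str:
    """The exact amplicon sequence of one allelic variant (no errors)."""
    if descriptor == "WT":
        return locus.wt_sequence
    if descriptor == "MUT":
        return locus.apply_edit()
    seq = locus.wt_sequence
    events = parse_variant(descriptor)
    # apply right-to-left so earlier coordinates stay valid
    for ev in sorted(events, key=lambda e: e.ref_pos, reverse=True):
        pos = cut_site + ev.ref_pos
        if ev.kind == "del":
            if pos < 0 or pos + ev.length > len(seq):
                raise ValueError(
                    f"deletion {descriptor!r} extends past the amplicon end"
                )
            seq = seq[:pos] + seq[pos + ev.length :]
        else:
            if pos < 0 or pos > len(seq):
                raise ValueError(f"insertion {descriptor!r} outside the amplicon")
            seq = seq[:pos] + ev.inserted + seq[pos:]
    return seq


def _add_errors(
    base_seq: str, n_reads: int, error_rate: float, rng: np.random.Generator
) -> list[str]:
    """n_reads copies of base_seq with iid per-base substitution errors."""
    if error_rate == 0 or n_reads == 0:
        return [base_seq] * n_reads
    codes = np.frombuffer(base_seq.encode(), dtype=np.uint8)
    base_codes = np.array([_DECODE[c] for c in codes], dtype=np.uint8)
    L = len(base_seq)
    out: list[str] = []
    mask = rng.random((n_reads, L)) < error_rate
    # substitution offset 1..3 from the original base, uniform
    shifts = rng.integers(1, 4, size=mask.shape, dtype=np.uint8)
    for r in range(n_reads):
        row = mask[r]
        if not row.any():
            out.append(base_seq)
            continue
        mutated = base_codes.copy()
        idx = np.nonzero(row)[0]
        mutated[idx] = (mutated[idx] + shifts[r, idx]) % 4
        out.append(_BASES[mutated].tobytes().decode())
    return out


def simulate_reads(
    locus: TargetLocus,
    spectrum: AlleleSpectrum,
    config: SimulationConfig,
    cut_site: int,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Draw reads multinomially from the spectrum with substitution errors.

    Returns (records, truth) where truth has columns read_id, variant,
    sample.  Reads are emitted in a seeded random interleaving so variant
    identity is not encoded in file order.
    """
    rng = np.random.default_rng(config.seed)
    variants = [k for k, _ in spectrum.entries]
    props = np.array([p for _, p in spectrum.entries], dtype=float)
    counts = rng.multinomial(config.n_reads, props)
    labels = np.repeat(np.arange(len(variants)), counts)
    rng.shuffle(labels)

    seq_cache = {v: realize_variant(locus, v, cut_site) for v in variants}
    # draw errors per variant batch, then scatter back into shuffled order
    per_variant_reads: dict[int, list[str]] = {}
    for vi, v in enumerate(variants):
        per_variant_reads[vi] = _add_errors(
            seq_cache[v], int(counts[vi]), config.error_rate, rng
        )
    cursors = {vi: 0 for vi in per_variant_reads}
    records: list[FastqRecord] = []
    truth_rows = []
    width = len(str(config.n_reads))
    for i, vi in enumerate(labels):
        vi = int(vi)
        seq = per_variant_reads[vi][cursors[vi]]
        cursors[vi] += 1
        rid = f"{config.sample_id}_read{i:0{width}d}"
        records.append(FastqRecord(rid, seq, config.quality_char * len(seq)))
        truth_rows.append((rid, variants[vi], config.sample_id))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "variant", "sample"])
    return records, truth


def write_fastq(records: list[FastqRecord], path: str | Path) -> None:
    """Write FASTQ (Sanger qualities); gzip if the path ends in .gz."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{rec.qual}\n")


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Read FASTQ via pysam (handles gzip transparently)."""
    import pysam

    records = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            records.append(
                FastqRecord(entry.name, entry.sequence.upper(), entry.quality or "")
            )
    return records


# ---------------------------------------------------------------------------
# barcode attachment / demultiplexing

UNDETERMINED = "undetermined"


def _check_sheet(sample_sheet: pd.DataFrame) -> pd.DataFrame:
    if sample_sheet.empty:
        raise ValueError("empty sample sheet")
    required = {"sample_id", "barcode"}
    if missing := required - set(sample_sheet.columns):
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    barcodes = list(sample_sheet["barcode"])
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode in sample sheet")
    for bc in barcodes:
        check_dna(str(bc), "barcode", allow_n=False)
    return sample_sheet


def attach_barcodes(
    reads_by_sample: dict[str, list[FastqRecord]], sample_sheet: pd.DataFrame
) -> list[FastqRecord]:
    """Prefix each sample's reads with its barcode (pooled output)."""
    sheet = _check_sheet(sample_sheet)
    barcode_of = dict(zip(sheet["sample_id"], sheet["barcode"]))
    pooled: list[FastqRecord] = []
    for sample, records in reads_by_sample.items():
        if sample not in barcode_of:
            raise ValueError(f"sample {sample!r} not in sample sheet")
        bc = str(barcode_of[sample])
        for rec in records:
            pooled.append(
                FastqRecord(rec.read_id, bc + rec.seq, "I" * len(bc) + rec.qual)
            )
    return pooled


def demultiplex(
    reads: list[FastqRecord], sample_sheet: pd.DataFrame
) -> dict[str, list[FastqRecord]]:
    """Assign reads to samples by exact 5' barcode prefix; strip the barcode.

    Unmatched reads go to the ``undetermined`` bin unmodified.
    """
    sheet = _check_sheet(sample_sheet)
    by_barcode = {str(bc): str(sid) for sid, bc in zip(sheet["sample_id"], sheet["barcode"])}
    out: dict[str, list[FastqRecord]] = {sid: [] for sid in sheet["sample_id"]}
    out[UNDETERMINED] = []
    for rec in reads:
        for bc, sid in by_barcode.items():
            if rec.seq.startswith(bc):
                out[sid].append(
                    FastqRecord(rec.read_id, rec.seq[len(bc):], rec.qual[len(bc):])
                )
                break
        else:
            out[UNDETERMINED].append(rec)
    return out


__all__ = [
    "AlleleSpectrum",
    "SimulationConfig",
    "FastqRecord",
    "realize_variant",
    "simulate_reads",
    "write_fastq",
    "read_fastq",
    "attach_barcodes",
    "demultiplex",
    "UNDETERMINED",
]
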