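"""End-to-end pipeline: demultiplex -> align -> classify -> quantify.

Duplicate read sequences are aligned and classified once and the call is
fanned back out to every carrying read, which keeps full sequencing depth
(hundreds of thousands of reads per amplicon) fast without changing any
per-read result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import DEFAULT_SCORING, Scoring, align_read
from .classify import ReadCall, call_read
from .design import audit_table, find_protospacer
from .loci import TargetLocus, read_loci
from .quantify import AlleleTable, allele_table
from .simulate import FastqRecord, demultiplex, read_fastq

log = logging.getLogger("ampedit")


@dataclass
class PipelineConfig:
    loci_tsv: str
    amplicon_fasta: str
    reads_fastq: str
    out_dir: str
    sample_sheet: str | None = None  # TSV: sample_id, barcode, locus_id
    sample_id: str = "sample"  # used when no sheet is given
    locus_id: str | None = None  # required when no sheet is given
    scoring: Scoring = field(default_factory=Scoring)
    window: int | None = None
    min_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        paths = [self.loci_tsv, self.amplicon_fasta, self.reads_fastq]
        if self.sample_sheet is not None:
            paths.append(self.sample_sheet)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.sample_sheet is None and self.locus_id is None:
            raise ValueError("locus_id is required when no sample sheet is given")


def call_sample(
    records: list[FastqRecord],
    locus: TargetLocus,
    cut_site: int | None,
    scoring: Scoring = DEFAULT_SCORING,
    window: int | None = None,
) -> list[ReadCall]:
    """Align and classify every read of one sample (deduplicated internally)."""
    calls_by_seq: dict[str, ReadCall] = {}
    out: list[ReadCall] = []
    for rec in records:
        template = calls_by_seq.get(rec.seq)
        if template is None:
            aln = align_read(rec.seq, locus.wt_sequence, scoring, read_id=rec.read_id)
            template = call_read(aln, locus, cut_site=cut_site, window=window)
            calls_by_seq[rec.seq] = template
        out.append(dataclasses.replace(template, read_id=rec.read_id))
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, AlleleTable]:
    """Execute the full pipeline and write the result bundle to out_dir.

    Outputs: one allele-table TSV per sample, a combined summary JSON, a
    design-audit TSV for the loci, and a run manifest with parameters,
    versions and input checksums.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    loci = read_loci(config.loci_tsv, config.amplicon_fasta)
    reads = read_fastq(config.reads_fastq)
    log.info("loaded %d loci, %d reads", len(loci), len(reads))

    if config.sample_sheet is not None:
        sheet = pd.read_csv(config.sample_sheet, sep="\t", dtype=str)
        if "locus_id" not in sheet.columns:
            raise ValueError("sample sheet must carry a locus_id column")
        by_sample = demultiplex(reads, sheet)
        locus_of = dict(zip(sheet["sample_id"], sheet["locus_id"]))
        n_undetermined = len(by_sample.pop("undetermined"))
    else:
        by_sample = {config.sample_id: reads}
        locus_of = {config.sample_id: config.locus_id}
        n_undetermined = 0

    tables: dict[str, AlleleTable] = {}
    stage_counts: dict[str, dict[str, int]] = {}
    for sample, sample_reads in by_sample.items():
        lid = locus_of[sample]
        if lid not in loci:
            raise ValueError(f"sample {sample!r} references unknown locus {lid!r}")
        locus = loci[lid]
        cut_site = None
        if locus.spacer is not None:
            cut_site = find_protospacer(locus, locus.spacer).cut_site
        try:
            calls = call_sample(
                sample_reads, locus, cut_site, config.scoring, config.window
            )
            tables[sample] = allele_table(calls, sample, min_count=config.min_count)
        except Exception as exc:
            raise RuntimeError(f"stage classify/quantify, sample {sample!r}: {exc}") from exc
        tab = tables[sample]
        stage_counts[sample] = {
            "demultiplexed": len(sample_reads),
            "aligned": len(calls),
            "informative": tab.total,
            "uninformative": tab.n_uninformative,
        }
        log.info(
            "sample %s: demultiplexed=%d aligned=%d informative=%d uninformative=%d",
            sample, len(sample_reads), len(calls), tab.total, tab.n_uninformative,
        )
        tab.table.to_csv(out_dir / f"{sample}.alleles.tsv", sep="\t", index=False)

    summary = {s: t.summary() for s, t in tables.items()}
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    audits = audit_table(loci)
    if not audits.empty:
        audits.to_csv(out_dir / "design_audit.tsv", sep="\t", index=False)

    manifest = {
        "ampedit_version": __version__,
        "seed": config.seed,
        "scoring": dataclasses.asdict(config.scoring),
        "window": config.window,
        "min_count": config.min_count,
        "inputs": {
            p: _sha256(p)
            for p in [config.loci_tsv, config.amplicon_fasta, config.reads_fastq]
            + ([config.sample_sheet] if config.sample_sheet else [])
        },
        "n_reads_total": len(reads),
        "n_undetermined": n_undetermined,
        "stage_counts": stage_counts,
        "outputs": sorted(
            str(p.name)
            for p in out_dir.iterdir()
            if p.suffix in (".tsv", ".json") and p.name != "manifest.json"
        ),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tables


__all__ = ["PipelineConfig", "run_pipeline", "call_sample"]
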