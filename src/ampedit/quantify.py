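"""Allele tables, editing-efficiency shares, fidelity ratios and embryo stats.

Editing efficiency is the share of reads carrying the corresponding
mutation among total informative reads, assuming equal amplification
efficiency across allelic variants (no length-bias correction).  The
fidelity ratio is MUT reads : INDEL reads, rendered "X:1" with one decimal
place below 10 and as an integer above, e.g. 38:1 or 1.9:1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .classify import INDEL, MUT, WT, ReadCall


@dataclass
class AlleleTable:
    """Per-sample aggregation of read calls by canonical variant key."""

    sample_id: str
    table: pd.DataFrame  # columns: variant_key, label, count, frequency, log10_frequency
    total: int  # informative reads
    n_uninformative: int
    wt_share: float
    mut_share: float
    indel_share: float

    @property
    def mut_count(self) -> int:
        return int(self.table.loc[self.table["label"] == MUT, "count"].sum())

    @property
    def indel_count(self) -> int:
        return int(self.table.loc[self.table["label"] == INDEL, "count"].sum())

    def summary(self) -> dict:
        return {
            "sample": self.sample_id,
            "total_reads": self.total,
            "uninformative_reads": self.n_uninformative,
            "wt_share": self.wt_share,
            "mut_share": self.mut_share,
            "indel_share": self.indel_share,
            "fidelity_ratio": fidelity_ratio(self),
            "fidelity": render_fidelity(self.mut_count, self.indel_count),
            "variants": [
                {
                    "variant_key": row.variant_key,
                    "label": row.label,
                    "count": int(row.count_),
                    "frequency": float(row.frequency),
                }
                for row in self.table.rename(columns={"count": "count_"}).itertuples(
                    index=False
                )
            ],
        }


def allele_table(
    calls: list[ReadCall], sample_id: str, min_count: int = 0
) -> AlleleTable:
    """Aggregate calls into a variant table with label shares.

    Frequencies are normalised over informative reads; uninformative reads
    are counted separately.  Variants below ``min_count`` are dropped from
    the table (default 0: report everything observed).
    """
    informative = [c for c in calls if c.informative]
    n_uninf = len(calls) - len(informative)
    if not informative:
        raise ValueError(f"empty sample {sample_id!r}: zero informative reads")
    total = len(informative)
    counts: dict[tuple[str, str], int] = {}
    for c in informative:
        key = (c.variant_key, c.label)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "variant_key": vk,
            "label": lab,
            "count": n,
            "frequency": n / total,
            "log10_frequency": math.log10(n / total),
        }
        for (vk, lab), n in counts.items()
        if n >= min_count
    ]
    order = {WT: 0, MUT: 1, INDEL: 2}
    table = pd.DataFrame(rows).sort_values(
        by=["label", "count", "variant_key"],
        key=lambda s: s.map(order) if s.name == "label" else s,
        ascending=[True, False, True],
    ).reset_index(drop=True)
    label_counts = {lab: 0 for lab in (WT, MUT, INDEL)}
    for c in informative:
        label_counts[c.label] += 1
    return AlleleTable(
        sample_id=sample_id,
        table=table,
        total=total,
        n_uninformative=n_uninf,
        wt_share=label_counts[WT] / total,
        mut_share=label_counts[MUT] / total,
        indel_share=label_counts[INDEL] / total,
    )


def fidelity_ratio(table: AlleleTable) -> float:
    """MUT count / INDEL count; inf if no indels, NaN if neither class seen."""
    mut, indel = table.mut_count, table.indel_count
    if indel == 0:
        return math.inf if mut > 0 else math.nan
    return mut / indel


def render_fidelity(mut_count: int, indel_count: int) -> str:
    """Render the ratio the way editing fidelities are printed (e.g. 38:1)."""
    if indel_count == 0:
        return "MUT-only" if mut_count > 0 else "no-editing"
    ratio = mut_count / indel_count
    if ratio >= 10:
        return f"{round(ratio)}:1"
    return f"{ratio:.1f}:1"


def share_ci(count: int, total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson binomial confidence interval for a read share."""
    if total <= 0:
        raise ValueError("total must be positive")
    lo = stats.beta.ppf(alpha / 2, count, total - count + 1) if count > 0 else 0.0
    hi = (
        stats.beta.ppf(1 - alpha / 2, count + 1, total - count)
        if count < total
        else 1.0
    )
    return float(lo), float(hi)


@dataclass(frozen=True)
class EmbryoStats:
    """Zygote development after microinjection (the study's toxicity proxy)."""

    injected: int
    blastocyst: int
    morula: int

    def __post_init__(self) -> None:
        if self.injected <= 0:
            raise ValueError("injected count must be positive")
        if min(self.blastocyst, self.morula) < 0:
            raise ValueError("counts must be non-negative")
        if self.blastocyst + self.morula > self.injected:
            raise ValueError("developed embryos cannot exceed injected zygotes")

    @property
    def development_rate(self) -> float:
        return (self.blastocyst + self.morula) / self.injected

    @property
    def development_pct(self) -> float:
        return round(100 * self.development_rate, 1)


def development_stats(injected: int, blastocyst: int, morula: int) -> EmbryoStats:
    """Development rate = (blastocyst + morula) / injected."""
    return EmbryoStats(injected=injected, blastocyst=blastocyst, morula=morula)


__all__ = [
    "AlleleTable",
    "allele_table",
    "fidelity_ratio",
    "render_fidelity",
    "share_ci",
    "EmbryoStats",
    "development_stats",
]
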