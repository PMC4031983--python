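"""Per-sample genotyping of miRNA loci and cohort group assignment.

Each miRNA locus (miR-1255b spans two genomic loci; miR-148b* and miR-193b*
one each) gets a per-sample status in {deletion, neutral, amplification,
unknown}, inferred either from the aCGH segment overlapping the locus
midpoint or from the nearest marker SNP. Samples are then grouped:

* ``WT`` — copy-neutral at all three miRNAs (no deletion, no amplification);
* ``del-<mirna>`` — combined status deletion at that miRNA (a sample can sit
  in several deletion groups);
* ``excluded`` — neither (amplification-only or any unknown status).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AnalysisParams
from .intervals import GenomicInterval

DELETION = "deletion"
NEUTRAL = "neutral"
AMPLIFICATION = "amplification"
UNKNOWN = "unknown"

GROUP_WT = "WT"
GROUP_EXCLUDED = "excluded"


@dataclass(frozen=True)
class MirnaLocus:
    """A miRNA and its genomic locus intervals (internal 0-based half-open)."""

    name: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"locus {self.name}: needs at least one interval")
        for iv in self.intervals:
            iv.validate()


def default_mir1255b_loci() -> MirnaLocus:
    """The two printed miR-1255b loci (1-based inclusive in the literature,
    converted here to 0-based half-open): chr4:36,427,988-36,428,050 and
    chr1:167,967,898-167,967,964.

    miR-148b* and miR-193b* coordinates are genome-build dependent and must be
    supplied by the caller (or come from the synthetic cohort's own locus set).
    """
    return MirnaLocus(
        "miR-1255b",
        (
            GenomicInterval("chr4", 36_427_987, 36_428_050),
            GenomicInterval("chr1", 167_967_897, 167_967_964),
        ),
    )


def locus_status_acgh(
    cn_segments: pd.DataFrame, locus: GenomicInterval, params: AnalysisParams
) -> str:
    """Status of one locus for one sample from aCGH segments.

    The representative log2 ratio is that of the segment overlapping the
    locus midpoint (loci are tens of bp, virtually always inside a single
    segment); if several segments overlap the midpoint the one with the
    smallest start wins (deterministic tie rule). No overlapping segment ->
    unknown. Band semantics: log2 < −0.2 deletion; −0.2 ≤ log2 ≤ 0.2 neutral
    (closed band); log2 > 0.2 amplification.
    """
    mid = locus.midpoint
    hits = cn_segments[
        (cn_segments["chrom"] == locus.chrom)
        & (cn_segments["start"] <= mid)
        & (cn_segments["end"] > mid)
    ]
    if hits.empty:
        return UNKNOWN
    log2 = float(hits.sort_values("start").iloc[0]["log2_ratio"])
    lo, hi = params.neutral_band
    if log2 < lo:
        return DELETION
    if log2 <= hi:
        return NEUTRAL
    return AMPLIFICATION


def locus_status_snp(
    markers: pd.DataFrame, locus: GenomicInterval, params: AnalysisParams
) -> str:
    """Status of one locus for one sample from the nearest marker SNP.

    Distance is 0 for markers inside the locus; ties between equidistant
    markers break to the lower genomic position. Markers on other chromosomes
    are ignored; no marker on the locus chromosome -> unknown. Copy number
    < 1.9 deletion; 1.9–2.1 (closed) neutral; > 2.1 amplification.
    """
    on_chrom = markers[markers["chrom"] == locus.chrom]
    if on_chrom.empty:
        return UNKNOWN
    pos = on_chrom["pos"].to_numpy()
    dist = pd.Series(0, index=on_chrom.index, dtype="int64")
    dist[pos < locus.start] = locus.start - pos[pos < locus.start]
    inside_end = locus.end - 1  # last base of the half-open interval
    dist[pos > inside_end] = pos[pos > inside_end] - inside_end
    # stable argmin over (distance, position): sort keys keep the tie rule
    order = on_chrom.assign(_d=dist).sort_values(["_d", "pos"], kind="stable")
    cn = float(order.iloc[0]["allelic_cn"])
    lo, hi = params.neutral_cn_band
    if cn < params.snp_cn_threshold:
        return DELETION
    if lo <= cn <= hi:
        return NEUTRAL
    return AMPLIFICATION


def combine_statuses(statuses: list[str]) -> str:
    """Combine per-interval statuses of a multi-locus miRNA into one call.

    Deletion at either locus means the mature miRNA can be lost from that
    copy, so: deletion if any interval is deleted; else amplification if any
    is amplified; else neutral if all neutral; unknown otherwise.
    """
    if DELETION in statuses:
        return DELETION
    if AMPLIFICATION in statuses:
        return AMPLIFICATION
    if all(s == NEUTRAL for s in statuses):
        return NEUTRAL
    return UNKNOWN


def combine_mir1255b(status_1: str, status_2: str) -> str:
    """Combined call for the two miR-1255b loci (either-locus deletion rule)."""
    return combine_statuses([status_1, status_2])


def genotype_samples(
    loci: list[MirnaLocus],
    params: AnalysisParams,
    cn_segments: pd.DataFrame | None = None,
    markers: pd.DataFrame | None = None,
    samples: list[str] | None = None,
    mode: str = "acgh",
) -> pd.DataFrame:
    """Per-sample, per-locus-interval and combined statuses plus group.

    ``mode`` selects the evidence layer: ``"acgh"`` (midpoint segment) or
    ``"snp"`` (nearest marker). Returns one row per sample with columns
    ``status:<mirna>[i]`` per interval, ``combined:<mirna>`` per miRNA, and
    ``group`` (comma-joined deletion groups, ``WT`` or ``excluded``).
    """
    if mode == "acgh":
        if cn_segments is None:
            raise ValueError("acgh mode requires cn_segments")
        data, caller = cn_segments, locus_status_acgh
    elif mode == "snp":
        if markers is None:
            raise ValueError("snp mode requires markers")
        data, caller = markers, locus_status_snp
    else:
        raise ValueError(f"mode must be 'acgh' or 'snp', got {mode!r}")

    if samples is None:
        samples = sorted(data["sample"].unique())
    grouped = dict(tuple(data.groupby("sample")))
    empty = data.iloc[0:0]

    rows = []
    for sample in samples:
        sub = grouped.get(sample, empty)
        row: dict = {"sample": sample}
        combined: dict[str, str] = {}
        for locus in loci:
            statuses = []
            for i, iv in enumerate(locus.intervals, start=1):
                st = caller(sub, iv, params)
                statuses.append(st)
                key = (
                    f"status:{locus.name}-{i}"
                    if len(locus.intervals) > 1
                    else f"status:{locus.name}"
                )
                row[key] = st
            combined[locus.name] = combine_statuses(statuses)
            row[f"combined:{locus.name}"] = combined[locus.name]
        row["group"] = _group_label(combined)
        rows.append(row)
    return pd.DataFrame(rows)


def assign_groups(genotypes: pd.DataFrame) -> pd.Series:
    """Group label per sample from a :func:`genotype_samples` table."""
    return genotypes.set_index("sample")["group"]


def deletion_group_members(genotypes: pd.DataFrame, mirna: str) -> list[str]:
    """Samples whose combined status at ``mirna`` is deletion."""
    col = f"combined:{mirna}"
    if col not in genotypes:
        raise KeyError(f"no combined status column for {mirna!r}")
    return genotypes.loc[genotypes[col] == DELETION, "sample"].tolist()


def wt_members(genotypes: pd.DataFrame) -> list[str]:
    """Samples copy-neutral at every miRNA locus."""
    return genotypes.loc[genotypes["group"] == GROUP_WT, "sample"].tolist()


def _group_label(combined: dict[str, str]) -> str:
    if all(s == NEUTRAL for s in combined.values()):
        return GROUP_WT
    dels = [name for name, s in combined.items() if s == DELETION]
    if dels:
        return ",".join(f"del-{name}" for name in dels)
    return GROUP_EXCLUDED
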