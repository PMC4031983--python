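"""Classification of tumor LOH events: deletion-mediated vs copy-neutral.

Two rules are implemented, mirroring how the two cohorts' platforms were
processed:

* **aCGH rule** (:func:`classify_acgh`): an LOH event is deletion-mediated if
  deletion segments (log2 ratio strictly below −0.20) cover at least 80% of
  its length (union coverage, overlapping segments counted once). Remaining
  events are copy-neutral and retained only if strictly larger than 1 Mb.

* **SNP-marker rule** (:func:`classify_snp`): events strictly larger than
  10 kb are scored by the fraction n/N of marker SNPs inside the event with
  allelic copy number strictly below 1.9; n/N ≥ 0.8 (non-strict) is
  deletion-mediated, otherwise copy-neutral. Events with no markers cannot be
  scored and are excluded with a warning.

Copy-neutral LOH — two copies of one parental allele with no net loss — is
the genomic signature of mitotic recombination, which is why the downstream
association focuses on the retained copy-neutral events.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisParams
from .intervals import union_overlap_length

logger = logging.getLogger(__name__)

LABEL_DELETION = "deletion_mediated"
LABEL_NEUTRAL = "copy_neutral"
LABEL_UNLABELLED = "unlabelled"


def covered_fraction(
    event_start: int,
    event_end: int,
    seg_starts,
    seg_ends,
) -> float:
    """Fraction of ``[event_start, event_end)`` covered by the union of segments.

    Segments must belong to the same sample as the event (the callers group
    by sample); overlapping segments are not double-counted. Result is in
    [0, 1].
    """
    length = event_end - event_start
    if length <= 0:
        raise ValueError("event length must be positive")
    covered = union_overlap_length(
        event_start, event_end, zip(seg_starts, seg_ends)
    )
    return covered / length


def classify_acgh(
    events: pd.DataFrame, cn_segments: pd.DataFrame, params: AnalysisParams
) -> pd.DataFrame:
    """Label LOH events under the aCGH segment-coverage rule.

    Returns a copy of ``events`` with columns ``label``, ``retained`` and
    ``covered_fraction``. Deletion-mediated events are never retained; copy-
    neutral events are retained iff strictly longer than
    ``params.min_cnloh_size_acgh``.
    """
    _check_event_columns(events)
    out = events.copy().reset_index(drop=True)
    dels = cn_segments[cn_segments["log2_ratio"] < params.del_log2_threshold]
    by_sample_chrom = {
        key: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for key, grp in dels.groupby(["sample", "chrom"])
    }

    fracs = np.zeros(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        spans = by_sample_chrom.get((row.sample, row.chrom))
        if spans is None:
            continue
        fracs[i] = covered_fraction(row.start, row.end, spans[0], spans[1])
    out["covered_fraction"] = fracs
    is_del = fracs >= params.overlap_fraction_cutoff
    out["label"] = np.where(is_del, LABEL_DELETION, LABEL_NEUTRAL)
    size_ok = (out["end"] - out["start"]) > params.min_cnloh_size_acgh
    out["retained"] = (~is_del) & size_ok
    return out


def classify_snp(
    events: pd.DataFrame, markers: pd.DataFrame, params: AnalysisParams
) -> pd.DataFrame:
    """Label LOH events under the SNP-marker allelic-copy-number rule.

    Returns a copy of ``events`` with columns ``n_markers`` (N),
    ``n_low`` (n), ``frac_low`` (n/N), ``label`` and ``retained``.

    Events of size <= ``params.min_loh_size_snp`` are dropped from scoring
    (label ``unlabelled``, retained False). Events containing no marker are
    excluded the same way, with a logged warning, because the n/N rule is
    undefined there. Markers on an event boundary count when their (0-based)
    position falls inside the half-open event interval.
    """
    _check_event_columns(events)
    out = events.copy().reset_index(drop=True)
    by_sample_chrom = {}
    for key, grp in markers.groupby(["sample", "chrom"]):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(
                f"markers for sample {key[0]!r} chrom {key[1]!r} are not "
                "sorted by position"
            )
        by_sample_chrom[key] = (pos, grp["allelic_cn"].to_numpy())

    n_total = np.zeros(len(out), dtype=int)
    n_low = np.zeros(len(out), dtype=int)
    labels = np.full(len(out), LABEL_UNLABELLED, dtype=object)
    size_ok = (out["end"] - out["start"]) > params.min_loh_size_snp

    n_no_markers = 0
    for i, row in enumerate(out.itertuples(index=False)):
        if not size_ok[i]:
            continue
        got = by_sample_chrom.get((row.sample, row.chrom))
        if got is None:
            n_no_markers += 1
            continue
        pos, cn = got
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="left")
        N = hi - lo
        if N == 0:
            n_no_markers += 1
            continue
        n = int(np.sum(cn[lo:hi] < params.snp_cn_threshold))
        n_total[i] = N
        n_low[i] = n
        labels[i] = (
            LABEL_DELETION if n / N >= params.snp_frac_cutoff else LABEL_NEUTRAL
        )
    if n_no_markers:
        logger.warning(
            "%d LOH event(s) above the size filter contain no marker SNP and "
            "were excluded from classification",
            n_no_markers,
        )

    out["n_markers"] = n_total
    out["n_low"] = n_low
    with np.errstate(invalid="ignore"):
        out["frac_low"] = np.where(n_total > 0, n_low / np.maximum(n_total, 1), np.nan)
    out["label"] = labels
    out["retained"] = labels == LABEL_NEUTRAL
    return out


def cnloh_count_per_sample(
    labelled: pd.DataFrame, samples: list[str] | None = None
) -> pd.Series:
    """Count retained copy-neutral LOH events per sample.

    ``samples`` fixes the index universe so samples with zero retained events
    appear with count 0 (defaults to the samples present in ``labelled``).
    """
    retained = labelled[
        (labelled["label"] == LABEL_NEUTRAL) & labelled["retained"]
    ]
    counts = retained.groupby("sample").size()
    if samples is None:
        samples = sorted(labelled["sample"].unique())
    return counts.reindex(samples, fill_value=0).rename("cnloh_count")


def _check_event_columns(events: pd.DataFrame) -> None:
    missing = [c for c in ("sample", "chrom", "start", "end") if c not in events]
    if missing:
        raise ValueError(f"event table missing column(s): {missing}")
    if ((events["end"] - events["start"]) <= 0).any():
        raise ValueError("event table contains empty or inverted intervals")
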