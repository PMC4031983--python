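"""Synthetic screen plates and tumor cohorts with planted ground truth.

Everything downstream of the raw formats is testable against these
generators: planted sensitizer mimics must come back as screen hits, planted
deletion-mediated/copy-neutral LOH events must be re-labelled identically,
planted miRNA-locus deletions must genotype as deletions, and the planted
group effects (higher copy-neutral LOH burden and BRCA1 expression in
deletion groups) must reach significance downstream.

Scales and rates emulate a high-grade serous ovarian cohort: roughly 60
retained copy-neutral LOH events (> 1 Mb) per tumor at baseline, rising to 80
in miRNA-deletion groups, on a scaled six-chromosome genome. The generator
does **not** attempt realistic allele-specific intensities, GC waves or array
noise structure — only the segment/marker/plate geometry the classification
rules read.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import MirnaLocus
from .intervals import GenomicInterval

# ----------------------------------------------------------------- screen

BASE_LUMINESCENCE = 10_000.0
#: vehicle-arm viability of the BRCA2-siRNA positive control (depleting BRCA2
#: costs viability even without PARP inhibition).
BRCA2_VEHICLE_VIABILITY = 0.55
#: drug-arm viability of the BRCA2-siRNA positive control.
BRCA2_DRUG_VIABILITY = 0.20
#: both-arm viability of planted drug-independently toxic mimics.
TOXIC_VIABILITY = 0.40


@dataclass(frozen=True)
class ScreenTruth:
    """Planted structure of a synthetic screen."""

    seed: int
    planted_hit_ids: frozenset[str]
    toxic_ids: frozenset[str]
    hit_effect: float
    noise_cv: float

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "planted_hit_ids": sorted(self.planted_hit_ids),
            "toxic_ids": sorted(self.toxic_ids),
            "hit_effect": self.hit_effect,
            "noise_cv": self.noise_cv,
        }


def simulate_screen(
    n_mimics: int = 880,
    n_hits: int = 20,
    n_toxic: int = 10,
    hit_effect: float = 0.5,
    noise_cv: float = 0.10,
    wells_per_plate: int = 384,
    n_neg: int = 32,
    n_pos: int = 6,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Generate a multi-plate mimic screen with planted sensitizer hits.

    Each plate carries ``n_neg`` negative-control wells, ``n_pos`` BRCA2-siRNA
    wells and ``replicates`` wells per mimic; every well is read in both the
    drug and the vehicle arm. Well noise is multiplicative log-normal with
    coefficient of variation ``noise_cv`` (mean exactly 1); each (plate, arm)
    has its own log-normal scale factor. Planted hits lose ``hit_effect`` of
    their viability in the drug arm only; planted toxic mimics sit at
    ``TOXIC_VIABILITY`` in both arms. Hit and toxic sets are disjoint.
    """
    if noise_cv <= 0:
        raise ValueError(
            "noise_cv must be > 0: with zero noise the negative-control SD "
            "degenerates and Z-scores are undefined"
        )
    if n_hits + n_toxic > n_mimics:
        raise ValueError("planted hit + toxic mimics exceed n_mimics")
    mimic_slots = (wells_per_plate - n_neg - n_pos) // replicates
    if mimic_slots < 1:
        raise ValueError("wells_per_plate too small for controls + one mimic")

    rng = np.random.default_rng(seed)
    mimic_ids = [f"mimic-{i + 1:04d}" for i in range(n_mimics)]
    special = rng.choice(n_mimics, size=n_hits + n_toxic, replace=False)
    hit_ids = frozenset(mimic_ids[i] for i in special[:n_hits])
    toxic_ids = frozenset(mimic_ids[i] for i in special[n_hits:])

    sigma_log = float(np.sqrt(np.log1p(noise_cv**2)))

    def noise(size):
        return rng.lognormal(mean=-sigma_log**2 / 2, sigma=sigma_log, size=size)

    rows = []
    n_plates = int(np.ceil(n_mimics / mimic_slots))
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        scale = {
            arm: float(rng.lognormal(mean=0.0, sigma=0.15)) for arm in ("drug", "vehicle")
        }
        plate_mimics = mimic_ids[p * mimic_slots : (p + 1) * mimic_slots]
        layout: list[tuple[str, str]] = [("neg_control", "neg")] * n_neg
        layout += [("pos_control_brca2", "BRCA2-siRNA")] * n_pos
        for mid in plate_mimics:
            layout += [("mimic", mid)] * replicates
        layout += [("empty", "empty")] * (wells_per_plate - len(layout))

        for arm in ("drug", "vehicle"):
            eps = noise(len(layout))
            for w, ((role, content), e) in enumerate(zip(layout, eps)):
                if role == "empty":
                    continue
                v = _viability(role, content, arm, hit_ids, toxic_ids, hit_effect)
                lum = BASE_LUMINESCENCE * scale[arm] * v * e
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well": f"W{w + 1:03d}",
                        "content_id": content,
                        "role": role,
                        "treatment": arm,
                        "luminescence": lum,
                    }
                )
    plates = pd.DataFrame(rows)
    truth = ScreenTruth(
        seed=seed,
        planted_hit_ids=hit_ids,
        toxic_ids=toxic_ids,
        hit_effect=hit_effect,
        noise_cv=noise_cv,
    )
    return plates, truth


def _viability(role, content, arm, hit_ids, toxic_ids, hit_effect) -> float:
    if role == "neg_control":
        return 1.0
    if role == "pos_control_brca2":
        return BRCA2_DRUG_VIABILITY if arm == "drug" else BRCA2_VEHICLE_VIABILITY
    if content in toxic_ids:
        return TOXIC_VIABILITY
    if content in hit_ids and arm == "drug":
        return 1.0 - hit_effect
    return 1.0


# ----------------------------------------------------------------- cohort

#: scaled synthetic genome: six chromosomes of 200 Mb.
DEFAULT_GENOME: dict[str, int] = {f"chr{i}": 200_000_000 for i in (1, 2, 3, 4, 5, 6)}

MIRNAS = ("miR-1255b", "miR-148b*", "miR-193b*")


def default_cohort_loci() -> list[MirnaLocus]:
    """miRNA loci used by the synthetic cohort.

    The two miR-1255b intervals are the printed coordinates (chr4 and chr1).
    The miR-148b* and miR-193b* intervals are *synthetic placements* on the
    scaled genome (their genome-build coordinates are not printed anywhere
    authoritative, so real analyses must supply them).
    """
    return [
        MirnaLocus(
            "miR-1255b",
            (
                GenomicInterval("chr4", 36_427_987, 36_428_050),
                GenomicInterval("chr1", 167_967_897, 167_967_964),
            ),
        ),
        MirnaLocus("miR-148b*", (GenomicInterval("chr2", 54_731_035, 54_731_110),)),
        MirnaLocus("miR-193b*", (GenomicInterval("chr3", 14_397_823, 14_397_900),)),
    ]


@dataclass
class CohortTruth:
    """Planted structure of a synthetic cohort.

    ``events`` carries every generated LOH event with its generated label and
    whether it exceeds the aCGH retention size; ``deleted_locus_of`` maps
    deletion-group samples to the locus interval actually deleted.
    """

    seed: int
    group_of: dict[str, str]
    loh_rate_wt: float
    loh_rate_del: float
    expr_shift: float
    events: pd.DataFrame
    deleted_locus_of: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "group_of": self.group_of,
            "loh_rate_wt": self.loh_rate_wt,
            "loh_rate_del": self.loh_rate_del,
            "expr_shift": self.expr_shift,
            "deleted_locus_of": self.deleted_locus_of,
            "n_events": int(len(self.events)),
            "event_count_distribution": "Poisson (per-sample, per class)",
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


@dataclass
class CohortData:
    """In-memory synthetic cohort; layers may be None if not generated."""

    samples: list[str]
    loh: pd.DataFrame
    cn: pd.DataFrame
    markers: pd.DataFrame | None = None
    expr: pd.DataFrame | None = None

    def write(self, directory: str | Path) -> None:
        from . import io as mio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "samples.txt").write_text("\n".join(self.samples) + "\n")
        mio.write_segments(self.loh, directory / "loh_events.tsv", "loh")
        mio.write_segments(self.cn, directory / "cn_segments.tsv", "cn")
        if self.markers is not None:
            mio.write_markers(self.markers, directory / "snp_markers.tsv")
        if self.expr is not None:
            mio.write_expression(self.expr, directory / "expression.tsv")


def simulate_cohort(
    n_wt: int = 40,
    n_del: int | dict[str, int] = 10,
    genome: dict[str, int] | None = None,
    loci: list[MirnaLocus] | None = None,
    loh_rate_wt: float = 60.0,
    loh_rate_del: float = 80.0,
    small_cn_rate: float = 15.0,
    del_loh_rate_wt: float = 25.0,
    del_loh_rate_del: float = 35.0,
    expr_base: float = 8.0,
    expr_sd: float = 1.0,
    expr_shift: float = 1.0,
    marker_spacing: int = 200_000,
    layers: tuple[str, ...] = ("loh", "cn", "snp", "expr"),
    seed: int = 0,
) -> tuple[CohortData, CohortTruth]:
    """Generate a tumor cohort with planted miRNA-locus deletions.

    Per sample the generator emits:

    * **large copy-neutral LOH events** — Poisson(``loh_rate_wt`` or
      ``loh_rate_del``), sizes log-uniform on (1 Mb, 10 Mb]. These are the
      events the aCGH rule retains, so the rates are calibrated as *retained*
      copy-neutral events per sample (~60 at baseline, matching a serous
      ovarian cohort's per-tumor burden).
    * **small copy-neutral LOH events** — Poisson(``small_cn_rate``), sizes
      log-uniform 1 kb–1 Mb, exercising the size filters from below.
    * **deletion-mediated LOH events** — Poisson(``del_loh_rate_*``), sizes
      log-uniform 1 kb–10 Mb, each co-located with an aCGH deletion segment
      (log2 in [−0.8, −0.3]) covering a fraction drawn from [0.92, 1.0] of
      the event, and with marker SNPs under the segment drawn below 1.9.
    * **neutral background segments** covering the rest of every chromosome
      (log2 in [−0.05, 0.05]) so locus genotyping always finds a segment.
    * for deletion-group samples, a 2 Mb deletion segment over the assigned
      miRNA locus (for miR-1255b one of its two loci, chosen at random).
    * a regular SNP-marker grid (``marker_spacing``) plus in-fill markers
      inside every LOH event; markers under any deletion segment get allelic
      copy number in [0.8, 1.2], all others in [1.92, 2.08].
    * BRCA1 expression ~ Normal(``expr_base``, ``expr_sd``) plus
      ``expr_shift`` in deletion groups.

    Events are placed without overlap (within a sample) and away from the
    miRNA loci, so generated labels are unambiguous: classification should
    recover them exactly. All randomness flows from ``seed`` through
    per-stage child generators.
    """
    genome = dict(genome) if genome else dict(DEFAULT_GENOME)
    loci = loci if loci is not None else default_cohort_loci()
    if isinstance(n_del, int):
        n_del = {m.name: n_del for m in loci}
    for name in n_del:
        if name not in {m.name for m in loci}:
            raise ValueError(f"deletion group for unknown miRNA {name!r}")
    for locus in loci:
        for iv in locus.intervals:
            if iv.chrom not in genome or iv.end > genome[iv.chrom]:
                raise ValueError(
                    f"locus {locus.name} interval {iv} does not fit the genome model"
                )

    ss = np.random.SeedSequence(seed)
    rng_events, rng_markers, rng_expr, rng_locus = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    samples: list[str] = []
    group_of: dict[str, str] = {}
    for i in range(n_wt):
        sid = f"WT-{i + 1:03d}"
        samples.append(sid)
        group_of[sid] = "WT"
    for name, count in n_del.items():
        tag = name.replace("miR-", "").replace("*", "s")
        for i in range(count):
            sid = f"DEL{tag}-{i + 1:03d}"
            samples.append(sid)
            group_of[sid] = f"del-{name}"

    # reserved zones (no random events): +-3 Mb around every locus interval
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for locus in loci:
        for iv in locus.intervals:
            reserved[iv.chrom].append(
                (max(0, iv.start - 3_000_000), min(genome[iv.chrom], iv.end + 3_000_000))
            )

    chroms = list(genome)
    chrom_weights = np.array([genome[c] for c in chroms], dtype=float)
    chrom_weights /= chrom_weights.sum()

    loh_rows, cn_rows, truth_rows = [], [], []
    marker_rows: list[pd.DataFrame] = []
    expr_rows = []
    deleted_locus_of: dict[str, str] = {}
    locus_by_name = {m.name: m for m in loci}

    for sid in samples:
        group = group_of[sid]
        is_del_group = group != "WT"
        occupied = {c: [list(z) for z in sorted(reserved[c])] for c in genome}
        del_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

        # --- planted miRNA-locus deletion
        if is_del_group:
            mirna = group.removeprefix("del-")
            locus = locus_by_name[mirna]
            ivs = locus.intervals
            iv = ivs[int(rng_locus.integers(len(ivs)))] if len(ivs) > 1 else ivs[0]
            tag = f"{mirna}-{list(ivs).index(iv) + 1}" if len(ivs) > 1 else mirna
            deleted_locus_of[sid] = tag
            width = 2_000_000
            mid = iv.midpoint
            seg_start = max(0, mid - width // 2)
            seg_end = min(genome[iv.chrom], mid + width // 2)
            log2 = float(rng_locus.uniform(-0.8, -0.4))
            cn_rows.append((sid, iv.chrom, seg_start, seg_end, log2))
            del_spans[iv.chrom].append((seg_start, seg_end))

        # --- random LOH events
        rate_large = loh_rate_del if is_del_group else loh_rate_wt
        rate_delmed = del_loh_rate_del if is_del_group else del_loh_rate_wt
        classes = [
            ("copy_neutral", rng_events.poisson(rate_large), 1e6, 1e7),
            ("copy_neutral", rng_events.poisson(small_cn_rate), 1e3, 1e6),
            ("deletion_mediated", rng_events.poisson(rate_delmed), 1e3, 1e7),
        ]
        for label, count, lo, hi in classes:
            sizes = np.exp(
                rng_events.uniform(np.log(lo), np.log(hi), size=count)
            ).astype(int)
            sizes = np.maximum(sizes, 1000)
            for size in sizes:
                placed = _place(rng_events, occupied, genome, chroms, chrom_weights, size)
                if placed is None:
                    continue  # genome too crowded for this event; skip it
                chrom, start = placed
                end = start + int(size)
                loh_rows.append((sid, chrom, start, end))
                truth_rows.append(
                    {
                        "sample": sid,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "true_label": label,
                        "above_1mb": size > 1_000_000,
                        "above_10kb": size > 10_000,
                    }
                )
                if label == "deletion_mediated":
                    frac = float(rng_events.uniform(0.92, 1.0))
                    cov_len = max(1, int(round(frac * size)))
                    log2 = float(rng_events.uniform(-0.8, -0.3))
                    cn_rows.append((sid, chrom, start, start + cov_len, log2))
                    del_spans[chrom].append((start, start + cov_len))

        # --- neutral background segments (complement of deletion footprints)
        for chrom, length in genome.items():
            cursor = 0
            for s, e in sorted(del_spans[chrom]):
                if s > cursor:
                    cn_rows.append(
                        (sid, chrom, cursor, s, float(rng_events.uniform(-0.05, 0.05)))
                    )
                cursor = max(cursor, e)
            if cursor < length:
                cn_rows.append(
                    (sid, chrom, cursor, length, float(rng_events.uniform(-0.05, 0.05)))
                )

        # --- SNP markers
        if "snp" in layers:
            marker_rows.append(
                _sample_markers(
                    rng_markers, sid, genome, marker_spacing, del_spans,
                    [r for r in loh_rows if r[0] == sid],
                )
            )

        # --- expression
        if "expr" in layers:
            value = float(rng_expr.normal(expr_base, expr_sd))
            if is_del_group:
                value += expr_shift
            expr_rows.append((sid, "BRCA1", value))

    loh = pd.DataFrame(loh_rows, columns=["sample", "chrom", "start", "end"])
    cn = pd.DataFrame(
        cn_rows, columns=["sample", "chrom", "start", "end", "log2_ratio"]
    )
    cn = cn.sort_values(["sample", "chrom", "start"], kind="stable").reset_index(
        drop=True
    )
    markers = None
    if "snp" in layers:
        markers = pd.concat(marker_rows, ignore_index=True)
        markers = markers.sort_values(
            ["sample", "chrom", "pos"], kind="stable"
        ).reset_index(drop=True)
    expr = (
        pd.DataFrame(expr_rows, columns=["sample", "gene", "value"])
        if "expr" in layers
        else None
    )

    data = CohortData(samples=samples, loh=loh, cn=cn, markers=markers, expr=expr)
    truth = CohortTruth(
        seed=seed,
        group_of=group_of,
        loh_rate_wt=loh_rate_wt,
        loh_rate_del=loh_rate_del,
        expr_shift=expr_shift,
        events=pd.DataFrame(truth_rows),
        deleted_locus_of=deleted_locus_of,
    )
    return data, truth


def _place(rng, occupied, genome, chroms, weights, size, max_tries: int = 200):
    """Find a non-overlapping start for an event; None if the genome is full."""
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        limit = genome[chrom] - int(size)
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        end = start + int(size)
        spans = occupied[chrom]
        i = bisect_left(spans, [start, end])
        prev_ok = i == 0 or spans[i - 1][1] <= start
        next_ok = i == len(spans) or spans[i][0] >= end
        if prev_ok and next_ok:
            insort(spans, [start, end])
            return chrom, start
    return None


def _sample_markers(rng, sid, genome, spacing, del_spans, sample_loh):
    """Marker grid + per-event in-fill for one sample.

    A marker's allelic copy number is low (0.8-1.2) iff it lies inside a
    deletion segment footprint, neutral (1.92-2.08) otherwise — so n/N inside
    a deletion-mediated event tracks the planted coverage fraction, and
    copy-neutral events contain no low markers at all.
    """
    positions, chrom_col = [], []
    for chrom, length in genome.items():
        grid = np.arange(spacing // 2, length, spacing, dtype=np.int64)
        positions.append(grid)
        chrom_col.extend([chrom] * len(grid))
    for _, chrom, start, end in sample_loh:
        size = end - start
        n_fill = int(np.clip(size // 5000, 10, 40))
        fill = start + ((np.arange(n_fill) + 0.5) * size / n_fill).astype(np.int64)
        positions.append(fill)
        chrom_col.extend([chrom] * n_fill)
    # planted 2 Mb locus-deletion segments need no in-fill: the grid alone
    # puts ~10 low markers under them, so the nearest-marker call is forced
    pos = np.concatenate(positions)
    chrom_arr = np.array(chrom_col)

    low = np.zeros(len(pos), dtype=bool)
    for chrom, spans in del_spans.items():
        if not spans:
            continue
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        merged = sorted(spans)
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        idx = np.searchsorted(starts, pos[mask], side="right") - 1
        inside = (idx >= 0) & (pos[mask] < ends[np.clip(idx, 0, None)])
        low[mask] = inside

    cn = np.where(
        low,
        rng.uniform(0.8, 1.2, size=len(pos)),
        rng.uniform(1.92, 2.08, size=len(pos)),
    )
    return pd.DataFrame(
        {"sample": sid, "chrom": chrom_arr, "pos": pos, "allelic_cn": cn}
    )


# ----------------------------------------------------- boundary fixtures

def boundary_fixtures() -> dict[str, dict]:
    """Hand-built fixtures pinning every strict/non-strict boundary.

    Each entry carries the inputs for one classifier plus the label the
    printed inequalities force. Sizes/coverages sit exactly on the cutoffs.
    """
    def ev(sample, chrom, start, end):
        return pd.DataFrame(
            [(sample, chrom, start, end)], columns=["sample", "chrom", "start", "end"]
        )

    def seg(sample, chrom, start, end, log2):
        return pd.DataFrame(
            [(sample, chrom, start, end, log2)],
            columns=["sample", "chrom", "start", "end", "log2_ratio"],
        )

    def marks(sample, chrom, pos_cn):
        return pd.DataFrame(
            [(sample, chrom, p, c) for p, c in pos_cn],
            columns=["sample", "chrom", "pos", "allelic_cn"],
        )

    fixtures: dict[str, dict] = {}
    # coverage exactly 80% of a 2 Mb event by a log2 -0.5 segment -> deletion
    fixtures["acgh_coverage_exact_080"] = {
        "events": ev("s1", "chr1", 1_000_000, 3_000_000),
        "cn": seg("s1", "chr1", 1_000_000, 2_600_000, -0.5),
        "expected_label": "deletion_mediated",
        "expected_retained": False,
    }
    # segment log2 exactly -0.20 is NOT a deletion segment (strict <)
    fixtures["acgh_log2_exact_threshold"] = {
        "events": ev("s1", "chr1", 1_000_000, 3_000_000),
        "cn": seg("s1", "chr1", 1_000_000, 3_000_000, -0.20),
        "expected_label": "copy_neutral",
        "expected_retained": True,
    }
    # copy-neutral event exactly 1 Mb -> not retained (strict > 1 Mb)
    fixtures["acgh_size_exact_1mb"] = {
        "events": ev("s1", "chr1", 0, 1_000_000),
        "cn": seg("s1", "chr2", 0, 1_000_000, -0.5),
        "expected_label": "copy_neutral",
        "expected_retained": False,
    }
    # n/N exactly 0.8 (8 of 10 markers low) -> deletion_mediated (>= 0.8)
    fixtures["snp_frac_exact_080"] = {
        "events": ev("s1", "chr1", 100_000, 200_000),
        "markers": marks(
            "s1",
            "chr1",
            [(100_000 + 10_000 * i, 1.0 if i < 8 else 2.0) for i in range(10)],
        ),
        "expected_label": "deletion_mediated",
    }
    # marker cn exactly 1.9 does not count toward n (strict < 1.9)
    fixtures["snp_cn_exact_19"] = {
        "events": ev("s1", "chr1", 100_000, 200_000),
        "markers": marks(
            "s1",
            "chr1",
            [(100_000 + 10_000 * i, 1.0 if i < 7 else 1.9) for i in range(10)],
        ),
        "expected_label": "copy_neutral",  # n/N = 0.7 < 0.8
    }
    # event exactly 10 kb dropped by the SNP size filter (strict > 10 kb)
    fixtures["snp_size_exact_10kb"] = {
        "events": ev("s1", "chr1", 100_000, 110_000),
        "markers": marks("s1", "chr1", [(105_000, 1.0)]),
        "expected_label": "unlabelled",
    }
    return fixtures
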