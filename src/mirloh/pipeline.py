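"""End-to-end cohort pipeline: classify LOH, genotype loci, associate.

:func:`run_pipeline` is a pure function of its file inputs and parameters —
running it twice over the same cohort directory produces byte-identical
outputs. It writes:

* ``labelled_events.tsv`` — every LOH event with label/retained flags;
* ``genotypes.tsv`` — per-sample locus statuses and group;
* ``associations.tsv`` — one row per (metric, deletion group) comparison;
* ``run_log.json`` — effective parameter values and event counts before and
  after every filter stage.

Outputs are staged in a temporary sibling directory and moved into place at
the end, so a failing stage leaves no partial outputs behind.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as mio
from .config import AnalysisParams
from .genotype import (
    MirnaLocus,
    deletion_group_members,
    genotype_samples,
    wt_members,
)
from .loh import (
    LABEL_DELETION,
    LABEL_NEUTRAL,
    LABEL_UNLABELLED,
    classify_acgh,
    classify_snp,
    cnloh_count_per_sample,
)
from .stats import METRIC_CNLOH, METRIC_SCNA, compare_groups, scna_count_per_sample

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineResult:
    """In-memory view of one pipeline run."""

    labelled_events: pd.DataFrame
    genotypes: pd.DataFrame
    associations: pd.DataFrame
    run_log: dict


def run_pipeline(
    cohort: mio.CohortTable | str | Path,
    params: AnalysisParams | None = None,
    loci: list[MirnaLocus] | None = None,
    mode: str = "acgh",
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Classify, genotype and associate one cohort.

    ``mode`` selects the classification/genotyping evidence layer: ``"acgh"``
    (copy-number segments) or ``"snp"`` (marker allelic copy numbers).
    ``loci`` defaults to the synthetic cohort's locus set.
    """
    if params is None:
        params = AnalysisParams()
    if mode not in ("acgh", "snp"):
        raise ValueError(f"mode must be 'acgh' or 'snp', got {mode!r}")
    if loci is None:
        from .simulate import default_cohort_loci

        loci = default_cohort_loci()
    if not isinstance(cohort, mio.CohortTable):
        cohort = mio.CohortTable.from_dir(cohort)

    log: dict = {"mode": mode, "params": params.to_dict(), "stages": []}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("read_inputs"):
        if cohort.loh_path is None or cohort.cn_path is None:
            raise ValueError("cohort must provide LOH events and CN segments")
        events = mio.read_segments(cohort.loh_path, "loh")
        cn = mio.read_segments(cohort.cn_path, "cn")
        markers = (
            mio.read_markers(cohort.snp_path) if cohort.snp_path is not None else None
        )
        expr = (
            mio.read_expression(cohort.expr_path)
            if cohort.expr_path is not None
            else None
        )
        if mode == "snp" and markers is None:
            raise ValueError("snp mode requires a marker layer")
        log["stages"].append(
            {
                "stage": "read_inputs",
                "n_loh_events": int(len(events)),
                "n_cn_segments": int(len(cn)),
                "n_markers": int(len(markers)) if markers is not None else 0,
                "n_expression_rows": int(len(expr)) if expr is not None else 0,
            }
        )

    with stage("classify_loh"):
        if mode == "acgh":
            labelled = classify_acgh(events, cn, params)
        else:
            labelled = classify_snp(events, markers, params)
        n_del = int((labelled["label"] == LABEL_DELETION).sum())
        n_cn = int((labelled["label"] == LABEL_NEUTRAL).sum())
        n_unl = int((labelled["label"] == LABEL_UNLABELLED).sum())
        n_ret = int(labelled["retained"].sum())
        log["stages"].append(
            {
                "stage": "classify_loh",
                "n_input": int(len(labelled)),
                "n_deletion_mediated": n_del,
                "n_copy_neutral": n_cn,
                "n_unlabelled_or_dropped": n_unl,
                "n_retained": n_ret,
                "n_removed": int(len(labelled)) - n_ret,
            }
        )

    with stage("genotype_loci"):
        genotypes = genotype_samples(
            loci,
            params,
            cn_segments=cn,
            markers=markers,
            samples=cohort.samples,
            mode=mode,
        )
        wt = wt_members(genotypes)
        del_groups = {
            f"del-{locus.name}": deletion_group_members(genotypes, locus.name)
            for locus in loci
        }
        log["stages"].append(
            {
                "stage": "genotype_loci",
                "n_samples": int(len(genotypes)),
                "n_wt": len(wt),
                **{g: len(m) for g, m in del_groups.items()},
                "n_excluded": int((genotypes["group"] == "excluded").sum()),
            }
        )

    with stage("associate"):
        tables = []
        cnloh = cnloh_count_per_sample(labelled, samples=cohort.samples)
        tables.append(
            compare_groups(cnloh, wt, del_groups, params, metric_name=METRIC_CNLOH)
        )
        scna = scna_count_per_sample(cn, params, samples=cohort.samples)
        tables.append(
            compare_groups(scna, wt, del_groups, params, metric_name=METRIC_SCNA)
        )
        if expr is not None:
            for gene, sub in expr.groupby("gene"):
                series = sub.set_index("sample")["value"].reindex(cohort.samples)
                series = series.dropna()
                usable_wt = [s for s in wt if s in series.index]
                usable_groups = {
                    g: [s for s in m if s in series.index]
                    for g, m in del_groups.items()
                }
                tables.append(
                    compare_groups(
                        series,
                        usable_wt,
                        usable_groups,
                        params,
                        metric_name=f"expression:{gene}",
                    )
                )
        associations = pd.concat(tables, ignore_index=True)
        log["stages"].append(
            {
                "stage": "associate",
                "n_comparisons": int(len(associations)),
                "n_significant": int(associations["significant"].sum()),
            }
        )

    result = PipelineResult(
        labelled_events=labelled,
        genotypes=genotypes,
        associations=associations,
        run_log=log,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    """Atomic-ish output writing: stage to a temp dir, then move into place."""
    out_dir.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".mirloh-", dir=out_dir))
    try:
        result.labelled_events.to_csv(
            tmp / "labelled_events.tsv", sep="\t", index=False, float_format="%.6g"
        )
        result.genotypes.to_csv(tmp / "genotypes.tsv", sep="\t", index=False)
        result.associations.to_csv(
            tmp / "associations.tsv", sep="\t", index=False, float_format="%.6g"
        )
        with open(tmp / "run_log.json", "w") as fh:
            json.dump(result.run_log, fh, indent=2, sort_keys=True)
        for name in (
            "labelled_events.tsv",
            "genotypes.tsv",
            "associations.tsv",
            "run_log.json",
        ):
            shutil.move(str(tmp / name), str(out_dir / name))
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
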