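"""Group-wise association: one-tailed Mann-Whitney U and burden metrics.

The cohort comparison asks whether samples with a miRNA-locus deletion carry
a higher burden (copy-neutral LOH count, SCN-delta count, BRCA1 expression)
than samples copy-neutral at all three loci. The hypothesis is directional
(deletion > WT), so the test is one-tailed.

P-value computation is deterministic and switches regimes by sample size:

* no ties and ``n_a * n_b <= 400``: exact distribution of U;
* ties with ``n_a + n_b <= 12``: exhaustive permutation enumeration;
* otherwise: normal approximation with midranks, tie correction and
  continuity correction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisParams

logger = logging.getLogger(__name__)

EXACT_PRODUCT_LIMIT = 400
ENUMERATION_TOTAL_LIMIT = 12

METRIC_CNLOH = "cnLOH_count"
METRIC_SCNA = "scna_count"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-sum U of sample ``a`` with midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


def mann_whitney_one_tailed(
    a, b, alternative: str = "a_greater"
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U test; returns ``(U, p)``.

    ``U`` is the statistic of sample ``a``; ``alternative="a_greater"`` tests
    whether ``a`` is stochastically greater than ``b``. Identical pooled
    values in both groups give p = 0.5 with a warning (no evidence either
    way).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("a_greater", "a_less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    scipy_alt = "greater" if alternative == "a_greater" else "less"

    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "all values identical across both groups; p = 0.5", stacklevel=2
        )
        return u_obs, 0.5

    has_ties = len(np.unique(pooled)) < pooled.size
    n_a, n_b = len(a), len(b)

    if not has_ties and n_a * n_b <= EXACT_PRODUCT_LIMIT:
        res = sps.mannwhitneyu(a, b, alternative=scipy_alt, method="exact")
        return float(res.statistic), float(res.pvalue)

    if has_ties and n_a + n_b <= ENUMERATION_TOTAL_LIMIT:
        return u_obs, _enumeration_p(pooled, n_a, u_obs, alternative)

    res = sps.mannwhitneyu(
        a, b, alternative=scipy_alt, method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _enumeration_p(pooled: np.ndarray, n_a: int, u_obs: float, alternative: str) -> float:
    """Exact p by exhausting every way of assigning pooled values to group a.

    With midranks fixed on the pooled sample, U for an assignment is just the
    rank sum of the chosen indices minus n_a(n_a+1)/2, so the whole null
    distribution falls out of C(n, n_a) index subsets.
    """
    from itertools import combinations

    ranks = sps.rankdata(pooled)
    shift = n_a * (n_a + 1) / 2
    at_least = total = 0
    for idx in combinations(range(pooled.size), n_a):
        u = ranks[list(idx)].sum() - shift
        total += 1
        if alternative == "a_greater":
            at_least += u >= u_obs - 1e-12
        else:
            at_least += u <= u_obs + 1e-12
    return at_least / total


def scna_count_per_sample(
    cn_segments: pd.DataFrame,
    params: AnalysisParams,
    samples: list[str] | None = None,
) -> pd.Series:
    """Somatic copy-number event count (amplification or deletion) per sample.

    Out-of-band segments (log2 below the neutral band's lower edge or above
    its upper edge) are merged per chromosome when adjacent (touching or
    overlapping) and of the same sign; each maximal run counts as one event.
    Segments inside the neutral band split runs.
    """
    lo, hi = params.neutral_band
    if samples is None:
        samples = sorted(cn_segments["sample"].unique())
    counts = {}
    for sample in samples:
        sub = cn_segments[cn_segments["sample"] == sample]
        n_events = 0
        for _, grp in sub.groupby("chrom"):
            grp = grp.sort_values("start")
            sign = np.where(
                grp["log2_ratio"] < lo, -1, np.where(grp["log2_ratio"] > hi, 1, 0)
            )
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            prev_sign, prev_end = 0, None
            for s, e, sg in zip(starts, ends, sign):
                if sg == 0:
                    prev_sign, prev_end = 0, e
                    continue
                if sg == prev_sign and prev_end is not None and s <= prev_end:
                    prev_end = max(prev_end, e)  # extends the current run
                else:
                    n_events += 1
                    prev_sign, prev_end = sg, e
        counts[sample] = n_events
    return pd.Series(counts, name="scna_count").reindex(samples, fill_value=0)


@dataclass(frozen=True)
class AssociationResult:
    metric: str
    group: str
    n_wt: int
    n_del: int
    median_wt: float
    median_del: float
    U: float
    p_one_tailed: float
    significant: bool
    testable: bool = True


def compare_groups(
    metric_by_sample: pd.Series,
    wt_samples: list[str],
    deletion_groups: dict[str, list[str]],
    params: AnalysisParams,
    metric_name: str = METRIC_CNLOH,
) -> pd.DataFrame:
    """One-tailed deletion-vs-WT comparison per deletion group.

    ``metric_by_sample`` maps sample -> metric value; samples missing from it
    raise. An empty deletion group yields an untestable row (NaN statistics)
    rather than an exception.
    """
    missing = [
        s
        for group in ([wt_samples] + list(deletion_groups.values()))
        for s in group
        if s not in metric_by_sample.index
    ]
    if missing:
        raise ValueError(f"metric undefined for sample(s): {sorted(set(missing))[:5]}")

    wt_vals = metric_by_sample.loc[wt_samples].to_numpy(dtype=float)
    rows = []
    for group_name, members in deletion_groups.items():
        del_vals = metric_by_sample.loc[members].to_numpy(dtype=float)
        if len(del_vals) == 0 or len(wt_vals) == 0:
            rows.append(
                AssociationResult(
                    metric=metric_name,
                    group=group_name,
                    n_wt=len(wt_vals),
                    n_del=len(del_vals),
                    median_wt=float(np.median(wt_vals)) if len(wt_vals) else math.nan,
                    median_del=(
                        float(np.median(del_vals)) if len(del_vals) else math.nan
                    ),
                    U=math.nan,
                    p_one_tailed=math.nan,
                    significant=False,
                    testable=False,
                )
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u, p = mann_whitney_one_tailed(del_vals, wt_vals, "a_greater")
        rows.append(
            AssociationResult(
                metric=metric_name,
                group=group_name,
                n_wt=len(wt_vals),
                n_del=len(del_vals),
                median_wt=float(np.median(wt_vals)),
                median_del=float(np.median(del_vals)),
                U=u,
                p_one_tailed=p,
                significant=bool(p < params.alpha),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def group_quartiles(values: pd.Series) -> dict[str, float]:
    """Box-plot summary (quartiles) for a group's metric values."""
    q1, med, q3 = np.percentile(values.to_numpy(dtype=float), [25, 50, 75])
    return {"q1": float(q1), "median": float(med), "q3": float(q3)}
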