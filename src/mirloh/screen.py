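"""Plate-based miRNA-mimic screen analysis: viability, Z-scores, hit calling.

The screen measures luminescence (ATP content, a viability proxy) of tumor
cells transfected with miRNA mimics, with and without a PARP inhibitor.
Normalization is per plate and per treatment arm against the negative-control
mimic wells:

* ``%viability = 100 * x / mu`` where ``mu`` is the negative-control mean;
* ``z = (x - mu) / sigma`` with ``sigma`` the negative-control sample SD.

A mimic is a sensitizer hit when, in the drug arm, its (replicate-averaged)
viability falls below the cutoff (default 75% of control) and its Z-score
below the Z cutoff (default −2), provided it is not toxic on its own: a mimic
whose vehicle-arm viability is less than or equal to that of the BRCA2-siRNA
positive control is excluded, since BRCA2 depletion already kills cells
without any PARP inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisParams


@dataclass(frozen=True)
class NegControlStats:
    """Negative-control summary for one plate and treatment arm."""

    plate: str
    treatment: str
    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(
                f"plate {self.plate}/{self.treatment}: need >= 2 negative-"
                f"control wells, got {self.n}"
            )
        if self.sigma <= 0:
            raise ValueError(
                f"plate {self.plate}/{self.treatment}: negative-control SD is "
                "zero, Z-scores are undefined"
            )


def neg_control_stats(
    wells: pd.DataFrame, plate: str, treatment: str
) -> NegControlStats:
    """Mean/SD (ddof=1) of negative-control luminescence on a plate arm."""
    sub = wells[
        (wells["plate_id"] == plate)
        & (wells["treatment"] == treatment)
        & (wells["role"] == "neg_control")
    ]["luminescence"]
    n = len(sub)
    if n < 2:
        raise ValueError(
            f"plate {plate}/{treatment}: need >= 2 negative-control wells, got {n}"
        )
    return NegControlStats(
        plate=plate,
        treatment=treatment,
        mu=float(sub.mean()),
        sigma=float(sub.std(ddof=1)),
        n=n,
    )


def percent_control_viability(x: float, stats: NegControlStats) -> float:
    """Luminescence as percent of the negative-control mean."""
    if stats.mu == 0:
        raise ValueError("negative-control mean is zero")
    return 100.0 * x / stats.mu


def zscore(x: float, stats: NegControlStats) -> float:
    """Z-score of a luminescence value against the negative controls."""
    return (x - stats.mu) / stats.sigma


def toxicity_filter(pct_viability_vehicle: float, brca2_vehicle_pct: float) -> bool:
    """True when the mimic kills at least as much as BRCA2 siRNA without drug.

    The comparison is on vehicle-arm percent viability: loss equal to or
    greater than the BRCA2-siRNA loss (i.e. viability less than or equal)
    flags the mimic toxic.
    """
    return pct_viability_vehicle <= brca2_vehicle_pct


def analyze_screen(
    wells: pd.DataFrame,
    params: AnalysisParams | None = None,
    average_replicates: bool = True,
    z_reference: str = "constant",
) -> pd.DataFrame:
    """Per-mimic screen results across all plates.

    Replicate wells of a mimic (same plate, same content) are averaged per
    arm before normalization when ``average_replicates`` is true (the default
    faithful reading of a triplicate screen); otherwise every well is scored
    separately and the per-mimic value is the mean of per-well scores.

    ``z_reference`` chooses the Z cutoff: ``"constant"`` uses
    ``params.z_cutoff`` (default −2); ``"brca2"`` uses the per-plate drug-arm
    Z of the BRCA2-siRNA positive control instead.

    Returns one row per mimic: plate_id, mimic, pct_viability_drug,
    pct_viability_vehicle, z, toxic, hit, rank (NaN for non-hits).
    """
    if params is None:
        params = AnalysisParams()
    if z_reference not in ("constant", "brca2"):
        raise ValueError(f"z_reference must be 'constant' or 'brca2', got {z_reference!r}")

    rows = []
    for plate in sorted(wells["plate_id"].unique()):
        stats_drug = neg_control_stats(wells, plate, "drug")
        stats_veh = neg_control_stats(wells, plate, "vehicle")
        sub = wells[wells["plate_id"] == plate]

        brca2_veh = sub[
            (sub["role"] == "pos_control_brca2") & (sub["treatment"] == "vehicle")
        ]["luminescence"]
        if brca2_veh.empty:
            raise ValueError(
                f"plate {plate}: no vehicle-arm BRCA2-siRNA wells; the "
                "toxicity comparator is undefined"
            )
        brca2_vehicle_pct = percent_control_viability(
            float(brca2_veh.mean()), stats_veh
        )
        if z_reference == "brca2":
            brca2_drug = sub[
                (sub["role"] == "pos_control_brca2") & (sub["treatment"] == "drug")
            ]["luminescence"]
            if brca2_drug.empty:
                raise ValueError(f"plate {plate}: no drug-arm BRCA2-siRNA wells")
            z_cut = zscore(float(brca2_drug.mean()), stats_drug)
        else:
            z_cut = params.z_cutoff

        mimics = sub[sub["role"] == "mimic"]
        for content, grp in mimics.groupby("content_id"):
            drug = grp[grp["treatment"] == "drug"]["luminescence"]
            veh = grp[grp["treatment"] == "vehicle"]["luminescence"]
            if drug.empty or veh.empty:
                raise ValueError(
                    f"plate {plate}: mimic {content!r} is missing a treatment arm"
                )
            if average_replicates:
                pct_drug = percent_control_viability(float(drug.mean()), stats_drug)
                pct_veh = percent_control_viability(float(veh.mean()), stats_veh)
                z = zscore(float(drug.mean()), stats_drug)
            else:
                pct_drug = float(
                    np.mean([percent_control_viability(x, stats_drug) for x in drug])
                )
                pct_veh = float(
                    np.mean([percent_control_viability(x, stats_veh) for x in veh])
                )
                z = float(np.mean([zscore(x, stats_drug) for x in drug]))
            toxic = toxicity_filter(pct_veh, brca2_vehicle_pct)
            hit = (
                (not toxic)
                and z < z_cut
                and pct_drug < params.viability_cutoff_pct
            )
            rows.append(
                {
                    "plate_id": plate,
                    "mimic": content,
                    "pct_viability_drug": pct_drug,
                    "pct_viability_vehicle": pct_veh,
                    "z": z,
                    "toxic": toxic,
                    "hit": hit,
                }
            )
    results = pd.DataFrame(rows)
    return rank_hits(results)


def rank_hits(results: pd.DataFrame) -> pd.DataFrame:
    """Attach hit ranks: ascending percent viability, ties by ascending z,
    then lexicographic mimic id. Non-hits get NaN rank."""
    results = results.copy()
    hits = results[results["hit"]].sort_values(
        ["pct_viability_drug", "z", "mimic"], kind="stable"
    )
    results["rank"] = np.nan
    results.loc[hits.index, "rank"] = np.arange(1, len(hits) + 1, dtype=float)
    return results.reset_index(drop=True)


def call_hits(results: pd.DataFrame, params: AnalysisParams) -> pd.DataFrame:
    """Ranked hit list from a per-mimic results table.

    ``results`` must carry ``pct_viability_drug``, ``z`` and ``toxic``; the
    hit rule is re-evaluated against ``params`` so callers can rethreshold a
    finished screen without touching raw plates.
    """
    out = results.copy()
    out["hit"] = (
        (~out["toxic"].astype(bool))
        & (out["z"] < params.z_cutoff)
        & (out["pct_viability_drug"] < params.viability_cutoff_pct)
    )
    out = rank_hits(out)
    hits = out[out["hit"]].sort_values("rank")
    return hits.reset_index(drop=True)


def fold_enrichment(
    pd_mirna: float, pd_control: float, input_mirna: float, input_control: float
) -> float:
    """Pull-down fold enrichment of a transcript.

    ``(pull-down miRNA / pull-down control) / (input miRNA / input control)``
    — the ratio of ratios used for biotinylated-mimic capture experiments.
    All four abundances must be positive.
    """
    for name, v in (
        ("pd_mirna", pd_mirna),
        ("pd_control", pd_control),
        ("input_mirna", input_mirna),
        ("input_control", input_control),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return (pd_mirna / pd_control) / (input_mirna / input_control)
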