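"""Analysis thresholds and their validation.

Every threshold the classification/screen rules use lives in
:class:`AnalysisParams` so a run log can echo the effective values and a
single YAML file can override them (for example the n/N = 0.75 sensitivity
rerun of the SNP-marker rule).

Boundary semantics are deliberately asymmetric and fixed by the rules they
implement:

* aCGH deletion segments: log2 ratio strictly below ``del_log2_threshold``;
* deletion-mediated call: covered fraction **at least** ``overlap_fraction_cutoff``;
* copy-neutral size filters: strictly greater than the minimum size;
* SNP rule: allelic copy number strictly below ``snp_cn_threshold``;
  n/N **at least** ``snp_frac_cutoff``;
* neutral bands are closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds for LOH classification, locus genotyping and screen hit calling."""

    #: aCGH log2 ratio below which a copy-number segment counts as a deletion.
    del_log2_threshold: float = -0.20
    #: minimum fraction of an LOH event's length that deletion segments must
    #: cover (union) for the event to be called deletion-mediated.
    overlap_fraction_cutoff: float = 0.80
    #: minimum size (bp, strict >) of a copy-neutral LOH event retained under
    #: the aCGH rule.
    min_cnloh_size_acgh: int = 1_000_000
    #: minimum size (bp, strict >) of an LOH event considered at all under the
    #: SNP-marker rule.
    min_loh_size_snp: int = 10_000
    #: allelic copy number below which a marker SNP counts toward n.
    snp_cn_threshold: float = 1.9
    #: n/N fraction at or above which an event is deletion-mediated
    #: (0.75 is the documented sensitivity alternative).
    snp_frac_cutoff: float = 0.80
    #: closed log2-ratio band called copy-neutral at a miRNA locus.
    neutral_band: tuple[float, float] = (-0.2, 0.2)
    #: closed allelic-copy-number band called copy-neutral at a miRNA locus.
    neutral_cn_band: tuple[float, float] = (1.9, 2.1)
    #: screen: percent-of-control viability below which a mimic can be a hit.
    viability_cutoff_pct: float = 75.0
    #: screen: Z-score below which a mimic can be a hit.
    z_cutoff: float = -2.0
    #: significance level for the one-tailed group comparisons.
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction_cutoff <= 1.0):
            raise ValueError(
                f"overlap_fraction_cutoff must be in (0, 1], got {self.overlap_fraction_cutoff}"
            )
        if not (0.0 < self.snp_frac_cutoff <= 1.0):
            raise ValueError(
                f"snp_frac_cutoff must be in (0, 1], got {self.snp_frac_cutoff}"
            )
        if self.min_cnloh_size_acgh <= 0 or self.min_loh_size_snp <= 0:
            raise ValueError("size thresholds must be positive")
        lo, hi = self.neutral_band
        if hi < lo:
            raise ValueError(f"neutral_band is empty: {self.neutral_band}")
        clo, chi = self.neutral_cn_band
        if chi < clo:
            raise ValueError(f"neutral_cn_band is empty: {self.neutral_cn_band}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.viability_cutoff_pct <= 0:
            raise ValueError("viability_cutoff_pct must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["neutral_band"] = list(self.neutral_band)
        d["neutral_cn_band"] = list(self.neutral_cn_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        d = dict(d)
        for key in ("neutral_band", "neutral_cn_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "params" in data:  # allow a nested section
            data = data["params"]
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"params": self.to_dict()}, fh, sort_keys=False)
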