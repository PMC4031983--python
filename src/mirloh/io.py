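"""Readers and writers for the on-disk formats.

Tables are carried in memory as pandas DataFrames with fixed column sets:

==============  =====================================================
layer           columns
==============  =====================================================
LOH events      sample, chrom, start, end
CN segments     sample, chrom, start, end, log2_ratio
SNP markers     sample, chrom, pos, allelic_cn
expression      sample, gene, value
screen plates   plate_id, well, content_id, role, treatment, luminescence
==============  =====================================================

Coordinates are 0-based half-open internally. BED files are read natively;
SEG-like TSV files are 1-based inclusive and converted on read/write. Marker
positions are stored 0-based internally (``pos`` column in TSV is 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

LOH_COLUMNS = ["sample", "chrom", "start", "end"]
CN_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]
MARKER_COLUMNS = ["sample", "chrom", "pos", "allelic_cn"]
EXPR_COLUMNS = ["sample", "gene", "value"]
PLATE_COLUMNS = ["plate_id", "well", "content_id", "role", "treatment", "luminescence"]

ROLES = {"mimic", "neg_control", "pos_control_brca2", "empty"}
TREATMENTS = {"drug", "vehicle"}


class FormatError(ValueError):
    """A file is missing a required column or has an unusable layout."""


class ParseError(ValueError):
    """A row holds an unparseable or invalid value; carries the line number."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any():
        # +2: one for the header row, one for 1-based line numbering
        line = int(bad.idxmax()) + 2
        raise ParseError(f"{path}: non-numeric value in column '{col}' at line {line}")
    if converted.isna().any():
        line = int(converted.isna().idxmax()) + 2
        raise ParseError(f"{path}: missing value in column '{col}' at line {line}")
    return converted


def read_segments(path: str | Path, kind: str = "loh") -> pd.DataFrame:
    """Read LOH-event or copy-number segments from BED or SEG-like TSV.

    ``kind`` is ``"loh"`` or ``"cn"``; CN files must carry a log2 ratio.
    Format is chosen by extension: ``.bed`` is 0-based half-open with columns
    chrom/start/end/sample[/log2_ratio]; anything else is a headered TSV
    (sample, chrom, start, end[, log2_ratio]) with 1-based inclusive
    coordinates.

    Rows with ``end <= start`` (after conversion) raise :class:`ParseError`
    with their line number.
    """
    if kind not in ("loh", "cn"):
        raise ValueError(f"kind must be 'loh' or 'cn', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    is_bed = path.suffix.lower() == ".bed"
    if is_bed:
        names = ["chrom", "start", "end", "sample"]
        if kind == "cn":
            names.append("log2_ratio")
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < len(names):
            raise FormatError(
                f"{path}: BED file needs {len(names)} columns "
                f"({'/'.join(names)}), found {df.shape[1]}"
            )
        df = df.iloc[:, : len(names)]
        df.columns = names
        header_offset = 1  # no header row: line = index + 1
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = LOH_COLUMNS if kind == "loh" else CN_COLUMNS
        _require_columns(df, required, path)
        df = df[required].copy()
        header_offset = 2

    df = df.reset_index(drop=True)
    for col in ("start", "end") + (("log2_ratio",) if kind == "cn" else ()):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(bad.idxmax()) + header_offset
            raise ParseError(
                f"{path}: non-numeric value in column '{col}' at line {line}"
            )
        df[col] = converted
    df["start"] = df["start"].astype("int64")
    df["end"] = df["end"].astype("int64")
    if not is_bed:
        df["start"] = df["start"] - 1  # 1-based inclusive -> 0-based half-open

    empty = df["end"] <= df["start"]
    if empty.any():
        line = int(empty.idxmax()) + header_offset
        raise ParseError(
            f"{path}: empty or inverted interval (end <= start) at line {line}"
        )
    cols = LOH_COLUMNS if kind == "loh" else CN_COLUMNS
    return df[cols]


def write_segments(df: pd.DataFrame, path: str | Path, kind: str = "loh") -> None:
    """Write segments, converting to the format implied by the extension."""
    path = Path(path)
    cols = LOH_COLUMNS if kind == "loh" else CN_COLUMNS
    _require_columns(df, cols, "<in-memory table>")
    out = df[cols].copy()
    if path.suffix.lower() == ".bed":
        bed_cols = ["chrom", "start", "end", "sample"] + (
            ["log2_ratio"] if kind == "cn" else []
        )
        out[bed_cols].to_csv(path, sep="\t", header=False, index=False)
    else:
        out["start"] = out["start"] + 1  # back to 1-based inclusive
        out.to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path) -> pd.DataFrame:
    """Read a SNP marker TSV (sample, chrom, pos 1-based, allelic_cn)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, MARKER_COLUMNS, path)
    df = df[MARKER_COLUMNS].reset_index(drop=True)
    df["pos"] = _numeric(df, "pos", path).astype("int64") - 1
    df["allelic_cn"] = _numeric(df, "allelic_cn", path).astype(float)
    if (df["allelic_cn"] < 0).any():
        line = int((df["allelic_cn"] < 0).idxmax()) + 2
        raise ParseError(f"{path}: negative allelic copy number at line {line}")
    return df


def write_markers(df: pd.DataFrame, path: str | Path) -> None:
    out = df[MARKER_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, EXPR_COLUMNS, path)
    df = df[EXPR_COLUMNS].reset_index(drop=True)
    df["value"] = _numeric(df, "value", path).astype(float)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df[EXPR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_plates(path: str | Path) -> pd.DataFrame:
    """Read a screen plate CSV.

    Columns: plate_id, well, content_id, role, treatment, luminescence.
    Luminescence must be finite and >= 0; roles and treatments are checked
    against the known vocabularies.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, PLATE_COLUMNS, path)
    df = df[PLATE_COLUMNS].reset_index(drop=True)
    df["luminescence"] = _numeric(df, "luminescence", path).astype(float)
    if (df["luminescence"] < 0).any():
        line = int((df["luminescence"] < 0).idxmax()) + 2
        raise ParseError(f"{path}: negative luminescence at line {line}")
    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        line = int(bad_role.idxmax()) + 2
        raise ParseError(
            f"{path}: unknown role {df['role'][bad_role.idxmax()]!r} at line {line}"
        )
    bad_trt = ~df["treatment"].isin(TREATMENTS)
    if bad_trt.any():
        line = int(bad_trt.idxmax()) + 2
        raise ParseError(
            f"{path}: unknown treatment {df['treatment'][bad_trt.idxmax()]!r} "
            f"at line {line}"
        )
    return df


def write_plates(df: pd.DataFrame, path: str | Path) -> None:
    df[PLATE_COLUMNS].to_csv(path, index=False)


@dataclass
class CohortTable:
    """File references for one tumor cohort plus its sample universe.

    Invariant: every sample referenced by any layer appears in ``samples``
    and identifiers are unique.
    """

    samples: list[str]
    loh_path: Path | None = None
    cn_path: Path | None = None
    snp_path: Path | None = None
    expr_path: Path | None = None

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted(
                {s for s in self.samples if self.samples.count(s) > 1}
            )
            raise ValueError(f"duplicate sample identifiers: {dupes}")

    def validate_layers(self) -> None:
        """Check that every sample referenced in a data layer is declared."""
        universe = set(self.samples)
        for name, reader, p in (
            ("loh", lambda q: read_segments(q, "loh"), self.loh_path),
            ("cn", lambda q: read_segments(q, "cn"), self.cn_path),
            ("snp", read_markers, self.snp_path),
            ("expr", read_expression, self.expr_path),
        ):
            if p is None:
                continue
            seen = set(reader(p)["sample"])
            unknown = seen - universe
            if unknown:
                raise ValueError(
                    f"layer {name!r} references undeclared sample(s): "
                    f"{sorted(unknown)[:5]}"
                )

    @classmethod
    def from_dir(cls, directory: str | Path) -> "CohortTable":
        """Build from a directory following the generator's layout.

        Looks for ``loh_events.tsv``, ``cn_segments.tsv``, ``snp_markers.tsv``,
        ``expression.tsv`` and ``samples.txt`` (one id per line); if
        ``samples.txt`` is absent the sample universe is the union seen in the
        layers.
        """
        directory = Path(directory)
        paths = {
            "loh_path": directory / "loh_events.tsv",
            "cn_path": directory / "cn_segments.tsv",
            "snp_path": directory / "snp_markers.tsv",
            "expr_path": directory / "expression.tsv",
        }
        kwargs = {k: (p if p.exists() else None) for k, p in paths.items()}
        samples_file = directory / "samples.txt"
        if samples_file.exists():
            samples = [
                line.strip()
                for line in samples_file.read_text().splitlines()
                if line.strip()
            ]
        else:
            seen: list[str] = []
            for key, reader in (
                ("loh_path", lambda q: read_segments(q, "loh")),
                ("cn_path", lambda q: read_segments(q, "cn")),
                ("snp_path", read_markers),
                ("expr_path", read_expression),
            ):
                if kwargs[key] is not None:
                    for s in reader(kwargs[key])["sample"].unique():
                        if s not in seen:
                            seen.append(s)
            samples = seen
        table = cls(samples=samples, **kwargs)
        return table
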