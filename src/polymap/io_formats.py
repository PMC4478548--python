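"""Readers and writers for the tabular formats the pipeline touches.

All heavy containers are thin wrappers around :class:`pandas.DataFrame`
so that downstream code can use ordinary DataFrame operations. Readers
validate rather than coerce: malformed cells raise :class:`FormatError`
instead of propagating NaNs. Every writer/reader pair is an exact
inverse on valid data (round-trip property-tested).

Conventions
-----------
* Two-channel intensities (X, Y) are converted to polar coordinates with
  ``theta = (2/pi) * atan2(Y, X)`` (unitless, in [0, 1]) and ``R = X + Y``
  (signal units), the standard normalised-theta convention for Infinium
  arrays.
* Base-pair coordinates are 1-based inclusive; map positions are
  centimorgans reported to one decimal.
* Missing values serialise as ``-`` in ABH matrices and ``NA`` elsewhere.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "IntensityTable",
    "GenotypeTable",
    "PositionTable",
    "GeneticMap",
    "ABH_CODES",
    "GENOTYPE_CODES",
    "theta_r_from_xy",
    "read_final_report",
    "write_final_report",
    "write_cluster_file",
    "read_cluster_file",
    "write_abh",
    "read_abh",
    "read_position_table",
    "write_position_table",
    "read_map_table",
    "write_map_table",
]

GENOTYPE_CODES = ("AA", "AB", "BB", "NC")
ABH_CODES = ("A", "H", "B", "-")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def theta_r_from_xy(x, y):
    """Polar transform of two-channel signals.

    theta = (2/pi) * atan2(Y, X) maps the allelic contrast onto [0, 1]
    (0 = pure X channel, 1 = pure Y channel); R = X + Y is total signal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = (2.0 / math.pi) * np.arctan2(y, x)
    return theta, x + y


@dataclass
class IntensityTable:
    """Marker x sample two-channel intensity data in polar form.

    Attributes
    ----------
    theta, R : pandas.DataFrame
        Markers as rows, samples as columns. ``theta`` in [0, 1]; ``R``
        in arbitrary fluorescence units. NaN marks missing cells.
    X, Y : pandas.DataFrame or None
        Raw channel signals when available (None when the source file
        supplied theta/R directly).
    """

    theta: pd.DataFrame
    R: pd.DataFrame
    X: pd.DataFrame | None = None
    Y: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.theta.index.equals(self.R.index) or not self.theta.columns.equals(
            self.R.columns
        ):
            raise ValueError("theta and R must share markers and samples")
        if self.theta.index.has_duplicates:
            raise ValueError("duplicate marker ids")
        if self.theta.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.X is not None:
            if (self.X.to_numpy() < 0).any() or (self.Y.to_numpy() < 0).any():
                raise ValueError("raw signals must be non-negative")

    @classmethod
    def from_xy(cls, X: pd.DataFrame, Y: pd.DataFrame) -> "IntensityTable":
        theta, r = theta_r_from_xy(X.to_numpy(), Y.to_numpy())
        return cls(
            theta=pd.DataFrame(theta, index=X.index, columns=X.columns),
            R=pd.DataFrame(r, index=X.index, columns=X.columns),
            X=X.copy(),
            Y=Y.copy(),
        )

    @property
    def markers(self) -> list[str]:
        return list(self.theta.index)

    @property
    def samples(self) -> list[str]:
        return list(self.theta.columns)


@dataclass
class GenotypeTable:
    """Genotype calls (markers x samples) plus per-sample metadata.

    ``calls`` holds strings from :data:`GENOTYPE_CODES`; ``samples`` is
    indexed by sample id with columns ``ploidy`` (tetraploid / diploid /
    haploid), ``inbred`` (bool), ``role`` (parent / f1 / f2 / panel),
    ``dataset`` and ``seed_source``.
    """

    calls: pd.DataFrame
    samples: pd.DataFrame = None

    def __post_init__(self):
        if self.samples is None:
            self.samples = default_sample_metadata(self.calls.columns)
        bad = ~self.calls.isin(GENOTYPE_CODES)
        if bad.to_numpy().any():
            m, s = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"illegal genotype call {self.calls.iat[m, s]!r} at "
                f"marker {self.calls.index[m]!r}, sample {self.calls.columns[s]!r}"
            )
        missing = set(self.calls.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)


def default_sample_metadata(sample_ids: Iterable[str]) -> pd.DataFrame:
    ids = list(sample_ids)
    return pd.DataFrame(
        {
            "ploidy": "tetraploid",
            "inbred": True,
            "role": "panel",
            "dataset": "default",
            "seed_source": "NA",
        },
        index=pd.Index(ids, name="sample"),
    )


@dataclass
class PositionTable:
    """Best reference-genome position per marker (1-based bp)."""

    table: pd.DataFrame  # columns: marker, chrom, bp, mapped

    def __post_init__(self):
        t = self.table
        required = {"marker", "chrom", "bp", "mapped"}
        if not required.issubset(t.columns):
            raise ValueError(f"position table needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise FormatError(f"duplicate marker in position table: {dup!r}")
        mapped_bp = t.loc[t["mapped"], "bp"]
        if (mapped_bp < 1).any():
            raise ValueError("bp coordinates are 1-based; found bp < 1")


@dataclass
class GeneticMap:
    """Ordered linkage groups with cumulative Kosambi cM positions.

    ``groups`` maps group name -> DataFrame with columns ``marker`` and
    ``cm`` (non-decreasing, starting at 0). ``chromosome`` optionally
    labels each group with a reference chromosome / subgenome.
    """

    groups: dict[str, pd.DataFrame]
    chromosome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, g in self.groups.items():
            if not {"marker", "cm"}.issubset(g.columns):
                raise ValueError(f"group {name!r} needs marker and cm columns")
            cm = g["cm"].to_numpy()
            if len(cm) and (np.diff(cm) < -1e-9).any():
                raise ValueError(f"group {name!r} has decreasing cM positions")

    def group_length(self, name: str) -> float:
        cm = self.groups[name]["cm"]
        return float(cm.iloc[-1] - cm.iloc[0]) if len(cm) else 0.0

    @property
    def total_length(self) -> float:
        return float(sum(self.group_length(n) for n in self.groups))

    @property
    def n_markers(self) -> int:
        return int(sum(len(g) for g in self.groups.values()))

    def marker_order(self, name: str) -> list[str]:
        return list(self.groups[name]["marker"])


# ---------------------------------------------------------------------------
# GenomeStudio-style final report
# ---------------------------------------------------------------------------

_CALL_MAP = {("A", "A"): "AA", ("A", "B"): "AB", ("B", "A"): "AB", ("B", "B"): "BB"}


def read_final_report(path) -> tuple[IntensityTable, GenotypeTable]:
    """Read a GenomeStudio-style final report.

    The file may start with a bracketed ``[Header]`` block; the data
    section is tab-delimited with at least ``SNP Name`` and ``Sample ID``
    plus either ``X``/``Y`` or ``Theta``/``R`` columns. ``Allele1``/
    ``Allele2`` call columns are parsed when present (else all calls NC).
    """
    lines = Path(path).read_text().splitlines()
    start = 0
    if any(line.startswith("[") for line in lines):
        data_idx = [i for i, line in enumerate(lines) if line.strip().lower() == "[data]"]
        if not data_idx:
            raise FormatError("bracketed header present but no [Data] section")
        start = data_idx[-1] + 1
    body = "\n".join(lines[start:])
    if not body.strip():
        empty = pd.DataFrame()
        it = IntensityTable(theta=empty.copy(), R=empty.copy())
        return it, GenotypeTable(calls=pd.DataFrame(), samples=default_sample_metadata([]))
    from io import StringIO

    df = pd.read_csv(StringIO(body), sep="\t", dtype=str)
    for col in ("SNP Name", "Sample ID"):
        if col not in df.columns:
            raise FormatError(f"final report missing mandatory column {col!r}")
    has_xy = {"X", "Y"}.issubset(df.columns)
    has_tr = {"Theta", "R"}.issubset(df.columns)
    if not (has_xy or has_tr):
        raise FormatError("final report needs either X/Y or Theta/R columns")
    dup = df.duplicated(subset=["SNP Name", "Sample ID"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise FormatError(
            f"duplicate (marker, sample) row: ({row['SNP Name']!r}, {row['Sample ID']!r})"
        )

    def pivot(col):
        sub = df[["SNP Name", "Sample ID", col]].copy()
        sub[col] = _parse_float_column(sub[col], col)
        out = sub.pivot(index="SNP Name", columns="Sample ID", values=col)
        # preserve file order of markers and samples
        out = out.reindex(
            index=df["SNP Name"].drop_duplicates(), columns=df["Sample ID"].drop_duplicates()
        )
        out.index.name = None
        out.columns.name = None
        return out

    if has_xy:
        X, Y = pivot("X"), pivot("Y")
        it = IntensityTable.from_xy(X, Y)
    else:
        it = IntensityTable(theta=pivot("Theta"), R=pivot("R"))

    if {"Allele1", "Allele2"}.issubset(df.columns):
        pairs = list(zip(df["Allele1"], df["Allele2"]))
        df = df.assign(_call=[_CALL_MAP.get(p, "NC") for p in pairs])
        calls = df.pivot(index="SNP Name", columns="Sample ID", values="_call")
        calls.index.name = None
        calls.columns.name = None
        calls = calls.reindex(index=it.theta.index, columns=it.theta.columns).fillna("NC")
    else:
        calls = pd.DataFrame("NC", index=it.theta.index, columns=it.theta.columns)
    gt = GenotypeTable(calls=calls, samples=default_sample_metadata(it.samples))
    return it, gt


def _parse_float_column(series: pd.Series, name: str) -> pd.Series:
    def conv(v):
        if pd.isna(v) or v == "NA":
            return np.nan
        try:
            return float(v)
        except ValueError:
            raise FormatError(f"non-numeric value {v!r} in column {name!r}") from None

    return series.map(conv)


def write_final_report(path, intensities: IntensityTable, genotypes: GenotypeTable | None = None):
    """Write a final report (long format, ``[Header]``/``[Data]`` blocks)."""
    rows = []
    has_calls = genotypes is not None
    raw = intensities.X is not None
    for m in intensities.markers:
        for s in intensities.samples:
            row = {"SNP Name": m, "Sample ID": s}
            if raw:
                row["X"] = intensities.X.at[m, s]
                row["Y"] = intensities.Y.at[m, s]
            row["Theta"] = intensities.theta.at[m, s]
            row["R"] = intensities.R.at[m, s]
            if has_calls:
                call = genotypes.calls.at[m, s]
                row["Allele1"] = "-" if call == "NC" else call[0]
                row["Allele2"] = "-" if call == "NC" else call[1]
            rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("[Header]\nContent\tpolymap final report\n[Data]\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Cluster file (open TSV dialect)
# ---------------------------------------------------------------------------

_CLUSTER_HEADER = [
    "marker",
    "status",
    "pattern",
    "call_frequency",
    "separation_score",
    "n_components",
]
_COMPONENT_FIELDS = ["mean_theta", "sd_theta", "mean_r", "sd_r", "weight", "genotype"]


def write_cluster_file(path, records: Sequence[tuple]) -> None:
    """Serialise fitted cluster models with their classifications.

    ``records`` is a sequence of ``(ClusterModel, MarkerClassification)``
    pairs. One row per marker; components appear in ascending mean-theta
    order; numeric fields are written to 6 decimals.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_CLUSTER_HEADER + ["components"]) + "\n")
        for model, cls in records:
            comps = []
            for c in model.components:  # already sorted by mean theta
                comps.append(
                    ";".join(
                        [
                            f"{c.mean_theta:.6f}",
                            f"{c.sd_theta:.6f}",
                            f"{c.mean_r:.6f}",
                            f"{c.sd_r:.6f}",
                            f"{c.weight:.6f}",
                            c.genotype,
                        ]
                    )
                )
            fh.write(
                "\t".join(
                    [
                        model.marker,
                        cls.status,
                        "NA" if cls.pattern is None else str(cls.pattern),
                        f"{cls.call_frequency:.6f}",
                        f"{cls.separation_score:.6f}",
                        str(len(model.components)),
                        "|".join(comps),
                    ]
                )
                + "\n"
            )


def read_cluster_file(path):
    """Inverse of :func:`write_cluster_file`."""
    from .cluster_engine import ClusterComponent, ClusterModel, MarkerClassification

    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CLUSTER_HEADER + ["components"]:
            raise FormatError("unrecognised cluster file header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            marker, status, pattern, cf, sep, ncomp, blob = parts
            comps = []
            if blob:
                for chunk in blob.split("|"):
                    mt, st, mr, sr, w, g = chunk.split(";")
                    comps.append(
                        ClusterComponent(
                            mean_theta=float(mt),
                            sd_theta=float(st),
                            mean_r=float(mr),
                            sd_r=float(sr),
                            weight=float(w),
                            genotype=g,
                        )
                    )
            if len(comps) != int(ncomp):
                raise FormatError(f"component count mismatch for marker {marker!r}")
            model = ClusterModel(marker=marker, components=comps)
            cls = MarkerClassification(
                status=status,
                pattern=None if pattern == "NA" else int(pattern),
                call_frequency=float(cf),
                separation_score=float(sep),
            )
            records.append((model, cls))
    return records


# ---------------------------------------------------------------------------
# ABH matrices
# ---------------------------------------------------------------------------


def _validate_abh(matrix: pd.DataFrame) -> None:
    bad = ~matrix.isin(ABH_CODES)
    if bad.to_numpy().any():
        m, s = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"illegal ABH code {matrix.iat[m, s]!r} at marker "
            f"{matrix.index[m]!r}, individual {matrix.columns[s]!r}"
        )


def write_abh(path, matrix: pd.DataFrame, dialect: str = "tsv") -> None:
    """Write an ABH matrix (markers x individuals).

    ``tsv``: markers as rows, individuals as columns, codes A/H/B/-.
    ``joinmap_loc``: JoinMap .loc layout for an F2 population with
    lowercase a/h/b/- codes.
    """
    _validate_abh(matrix)
    if dialect == "tsv":
        matrix.to_csv(path, sep="\t", index_label="marker")
    elif dialect == "joinmap_loc":
        with open(path, "w") as fh:
            fh.write("name = polymap\npopt = F2\n")
            fh.write(f"nloc = {len(matrix.index)}\nnind = {len(matrix.columns)}\n\n")
            for m in matrix.index:
                codes = " ".join(c.lower() for c in matrix.loc[m])
                fh.write(f"{m} {codes}\n")
    else:
        raise ValueError(f"unknown ABH dialect {dialect!r}")


def read_abh(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="marker", dtype=str)
    matrix.index.name = None
    matrix.columns.name = None
    _validate_abh(matrix)
    return matrix


# ---------------------------------------------------------------------------
# Position and map tables
# ---------------------------------------------------------------------------


def read_position_table(path) -> PositionTable:
    """Read a marker/chromosome/bp TSV; unmapped markers stay, flagged.

    Unmapped rows use ``NA`` for chromosome and bp.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("marker", "chrom", "bp"):
        if col not in df.columns:
            raise FormatError(f"position table missing column {col!r}")
    bp = np.full(len(df), np.nan)
    for i, v in enumerate(df["bp"]):
        if pd.isna(v) or v == "NA":
            continue
        if not re.fullmatch(r"\d+", str(v)):
            raise FormatError(f"non-numeric bp {v!r} at line {i + 2}")
        bp[i] = int(v)
    mapped = ~np.isnan(bp) & (df["chrom"].notna()) & (df["chrom"] != "NA")
    table = pd.DataFrame(
        {
            "marker": df["marker"],
            "chrom": df["chrom"].where(mapped, other="NA"),
            "bp": bp,
            "mapped": mapped,
        }
    )
    return PositionTable(table=table)


def write_position_table(path, positions: PositionTable) -> None:
    t = positions.table.copy()
    t["bp"] = [("NA" if not m else str(int(b))) for b, m in zip(t["bp"], t["mapped"])]
    t["chrom"] = t["chrom"].where(t["mapped"], other="NA")
    t[["marker", "chrom", "bp"]].to_csv(path, sep="\t", index=False)


def write_map_table(path, genetic_map: GeneticMap) -> None:
    """Map TSV: marker, linkage group, cM (1 decimal), chromosome label."""
    rows = []
    for name, g in genetic_map.groups.items():
        chrom = genetic_map.chromosome.get(name, "NA")
        for marker, cm in zip(g["marker"], g["cm"]):
            rows.append((marker, name, f"{cm:.1f}", chrom))
    pd.DataFrame(rows, columns=["marker", "linkage_group", "cm", "chrom"]).to_csv(
        path, sep="\t", index=False
    )


def read_map_table(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "linkage_group": str, "chrom": str})
    for col in ("marker", "linkage_group", "cm"):
        if col not in df.columns:
            raise FormatError(f"map table missing column {col!r}")
    groups, chrom = {}, {}
    for name, sub in df.groupby("linkage_group", sort=False):
        groups[name] = sub[["marker", "cm"]].reset_index(drop=True)
        if "chrom" in sub.columns:
            chrom[name] = sub["chrom"].iloc[0]
    return GeneticMap(groups=groups, chromosome=chrom)
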