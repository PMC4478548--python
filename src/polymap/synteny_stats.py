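"""Genetic-map vs. reference-genome collinearity statistics.

Joins mapped markers to their reference-genome alignment positions,
assigns each linkage group its expected reference chromosome (modal
vote), detects translocated blocks as runs of markers that disagree
with the expectation, and computes map-scale statistics (kb per cM,
map-length reduction against a comparison map).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneticMap, PositionTable

__all__ = [
    "TranslocationCall",
    "MapScaleReport",
    "dotplot_table",
    "assign_reference_chromosome",
    "detect_translocations",
    "map_scale_stats",
    "plot_dotplot",
]


@dataclass
class TranslocationCall:
    group: str
    expected_chrom: str
    observed_chrom: str
    map_interval_cm: tuple[float, float]
    ref_interval_mb: tuple[float, float]
    n_markers: int


@dataclass
class MapScaleReport:
    mean_group_length_cm: dict[str, float]  # per subgenome
    total_length_cm: float
    kb_per_cm: dict[str, float]  # per subgenome; NaN when undefined
    reduction_cm: float | None = None
    reduction_pct: float | None = None


def dotplot_table(genetic_map: GeneticMap, positions: PositionTable) -> pd.DataFrame:
    """Inner join of map positions and reference positions.

    One row per marker present in both the map and the (mapped rows of
    the) position table, sorted by (group, cM). The fraction of mapped
    markers with a reference position is stored in
    ``.attrs["coverage"]``.
    """
    pos = positions.table[positions.table["mapped"]].set_index("marker")
    rows = []
    n_mapped = 0
    for name, g in genetic_map.groups.items():
        for marker, cm in zip(g["marker"], g["cm"]):
            n_mapped += 1
            if marker in pos.index:
                rows.append(
                    {
                        "marker": marker,
                        "group": name,
                        "cm": float(cm),
                        "chrom": pos.at[marker, "chrom"],
                        "bp": float(pos.at[marker, "bp"]),
                    }
                )
    out = pd.DataFrame(rows, columns=["marker", "group", "cm", "chrom", "bp"])
    if not len(out):
        warnings.warn("no markers shared between map and position table", stacklevel=2)
    out = out.sort_values(["group", "cm"], kind="stable").reset_index(drop=True)
    out.attrs["coverage"] = len(out) / n_mapped if n_mapped else math.nan
    return out


def assign_reference_chromosome(records: pd.DataFrame) -> pd.DataFrame:
    """Modal reference chromosome and concordance per linkage group.

    Ties on marker count break by total supporting bp span, then by
    lexical chromosome id.
    """
    rows = []
    for name, sub in records.groupby("group", sort=False):
        counts = sub.groupby("chrom")["bp"].agg(["count", lambda s: s.max() - s.min()])
        counts.columns = ["count", "span"]
        counts = counts.sort_values(
            by=["count", "span"], ascending=False, kind="stable"
        )
        top = counts[ (counts["count"] == counts["count"].iloc[0]) & (counts["span"] == counts["span"].iloc[0]) ]
        expected = sorted(top.index)[0] if len(top) > 1 else counts.index[0]
        rows.append(
            {
                "group": name,
                "expected_chrom": expected,
                "concordance": float(counts.at[expected, "count"] / len(sub)),
            }
        )
    return pd.DataFrame(rows)


def detect_translocations(
    records: pd.DataFrame,
    min_run: int = 5,
    expected: dict[str, str] | None = None,
) -> list[TranslocationCall]:
    """Call translocated blocks per linkage group.

    A call is a maximal run of at least ``min_run`` consecutive
    (cM-ordered) markers whose reference chromosome differs from the
    group's expected chromosome and agrees within the run. The
    reference interval is the run's [min bp, max bp] in Mb (1 decimal);
    the map interval spans from the last concordant marker before the
    run to the first after it (clamped at group ends). ``expected``
    overrides the modal assignment (e.g. from external anchoring).
    """
    if expected is None:
        expected = dict(
            assign_reference_chromosome(records)[["group", "expected_chrom"]].itertuples(
                index=False, name=None
            )
        )
    calls = []
    for name, sub in records.groupby("group", sort=False):
        sub = sub.sort_values("cm", kind="stable").reset_index(drop=True)
        exp = expected[name]
        chroms = sub["chrom"].to_numpy()
        i = 0
        while i < len(sub):
            if chroms[i] == exp:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and chroms[j + 1] == chroms[i]:
                j += 1
            run = sub.iloc[i : j + 1]
            if len(run) >= min_run:
                lo_cm = sub["cm"].iloc[i - 1] if i > 0 else sub["cm"].iloc[i]
                hi_cm = sub["cm"].iloc[j + 1] if j + 1 < len(sub) else sub["cm"].iloc[j]
                calls.append(
                    TranslocationCall(
                        group=name,
                        expected_chrom=exp,
                        observed_chrom=chroms[i],
                        map_interval_cm=(float(lo_cm), float(hi_cm)),
                        ref_interval_mb=(
                            round(run["bp"].min() / 1e6, 1),
                            round(run["bp"].max() / 1e6, 1),
                        ),
                        n_markers=len(run),
                    )
                )
            i = j + 1
    return calls


def map_scale_stats(
    genetic_map: GeneticMap,
    subgenome_sizes_mb: dict[str, float],
    group_subgenome: dict[str, str],
    comparison_total_cm: float | None = None,
) -> MapScaleReport:
    """Physical-to-genetic scale statistics per subgenome.

    kb/cM for a subgenome = (its physical size in Mb x 1000) divided by
    the summed cM length of its linkage groups; a zero-length subgenome
    yields NaN. With ``comparison_total_cm`` the report also carries
    the map-length reduction in cM and as a percentage of the
    comparison map.
    """
    lengths: dict[str, list[float]] = {}
    for name in genetic_map.groups:
        sg = group_subgenome[name]
        lengths.setdefault(sg, []).append(genetic_map.group_length(name))
    mean_len = {sg: float(np.mean(v)) for sg, v in lengths.items()}
    kb_per_cm = {}
    for sg, size_mb in subgenome_sizes_mb.items():
        total_cm = sum(lengths.get(sg, []))
        kb_per_cm[sg] = (size_mb * 1000.0 / total_cm) if total_cm > 0 else math.nan
    total = genetic_map.total_length
    reduction_cm = reduction_pct = None
    if comparison_total_cm is not None:
        reduction_cm = comparison_total_cm - total
        reduction_pct = 100.0 * reduction_cm / comparison_total_cm
    return MapScaleReport(
        mean_group_length_cm=mean_len,
        total_length_cm=total,
        kb_per_cm=kb_per_cm,
        reduction_cm=reduction_cm,
        reduction_pct=reduction_pct,
    )


def plot_dotplot(records: pd.DataFrame, path=None):
    """Scatter of map position (y) vs. reference position (x), one panel
    colour per linkage group. Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    chrom_order = {c: i for i, c in enumerate(sorted(records["chrom"].unique()))}
    group_order = {g: i for i, g in enumerate(records["group"].unique())}
    x = records["bp"] / 1e6 + records["chrom"].map(chrom_order) * 1e3
    y = records["cm"] + records["group"].map(group_order) * 1e3
    ax.scatter(x, y, s=4, c=records["group"].map(group_order), cmap="tab20")
    ax.set_xlabel("reference position (Mb, chromosomes concatenated)")
    ax.set_ylabel("map position (cM, groups concatenated)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
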