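"""Replicate similarity, residual heterozygosity and MAF summaries.

These metrics operate on genotype-call vectors (AA/AB/BB/NC) and use a
pairwise-complete convention throughout: markers uncalled (NC) in
either member of a comparison are dropped from the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityReport",
    "MafReport",
    "pairwise_similarity",
    "residual_heterozygosity",
    "maf_summary",
]


@dataclass
class SimilarityReport:
    sample_i: str
    sample_j: str
    n_joint: int
    percent_identical: float  # NaN when no jointly called markers
    replicate_type: str = "technical"


@dataclass
class MafReport:
    """Per-marker minor allele frequencies over an inbred panel."""

    maf: pd.Series  # indexed by marker, values in [0, 0.5]
    exceedance: pd.DataFrame  # columns: threshold, fraction_above
    mean_maf: float


def pairwise_similarity(
    calls_i,
    calls_j,
    sample_i: str = "s1",
    sample_j: str = "s2",
    replicate_type: str = "technical",
) -> SimilarityReport:
    """Percent identical calls between two samples.

    Only markers called in both samples enter the denominator. With no
    jointly called markers the percentage is undefined (NaN).
    """
    a = np.asarray(calls_i, dtype=object)
    b = np.asarray(calls_j, dtype=object)
    if a.shape != b.shape:
        raise ValueError("call vectors must cover the same marker universe")
    joint = (a != "NC") & (b != "NC")
    n_joint = int(joint.sum())
    if n_joint == 0:
        pct = math.nan
    else:
        pct = 100.0 * float((a[joint] == b[joint]).sum()) / n_joint
    return SimilarityReport(sample_i, sample_j, n_joint, pct, replicate_type)


def residual_heterozygosity(calls, polymorphic_markers=None) -> float:
    """Percent AB calls among non-NC calls over a polymorphic marker set.

    ``calls`` may be a Series (indexed by marker, subset with
    ``polymorphic_markers``) or a plain vector already restricted.
    """
    if polymorphic_markers is not None:
        calls = pd.Series(calls).loc[list(polymorphic_markers)]
    a = np.asarray(calls, dtype=object)
    called = a[a != "NC"]
    if called.size == 0:
        return math.nan
    return 100.0 * float((called == "AB").sum()) / called.size


def maf_summary(
    calls: pd.DataFrame,
    inbred_mask,
    thresholds=(0.05, 0.10, 0.20),
) -> MafReport:
    """Minor allele frequencies over the inbred samples of a panel.

    Allele counting: each called line contributes two alleles, a
    heterozygote one of each. MAF = min(p, 1 - p). Markers with no
    called inbred line are excluded. Exceedance fractions are computed
    strictly above each threshold and are non-increasing in the
    threshold.
    """
    inbred_mask = np.asarray(inbred_mask, dtype=bool)
    sub = calls.loc[:, inbred_mask]
    arr = sub.to_numpy(dtype=object)
    n_b = (arr == "BB").sum(axis=1) * 2 + (arr == "AB").sum(axis=1)
    n_called = (arr != "NC").sum(axis=1)
    keep = n_called > 0
    if not keep.all():
        import warnings

        dropped = list(calls.index[~keep])
        warnings.warn(
            f"{len(dropped)} marker(s) with no called inbred sample excluded", stacklevel=2
        )
    p = n_b[keep] / (2.0 * n_called[keep])
    maf = pd.Series(np.minimum(p, 1.0 - p), index=calls.index[keep], name="maf")
    rows = [
        {"threshold": t, "fraction_above": float((maf > t).mean()) if len(maf) else math.nan}
        for t in thresholds
    ]
    return MafReport(
        maf=maf,
        exceedance=pd.DataFrame(rows),
        mean_maf=float(maf.mean()) if len(maf) else math.nan,
    )
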