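"""F2 linkage-map construction from ABH genotype matrices.

The chain implemented here mirrors classical two-point F2 mapping:

1. recode progeny calls against opposite-homozygous parents (ABH),
2. estimate pairwise recombination fractions by EM on the 3 x 3 joint
   genotype table (the double-heterozygote cell mixes parental and
   recombinant phases and is the reason EM is needed),
3. group markers by significant linkage (likelihood-ratio p-value with
   a LOD floor), order each group by minimising the sum of adjacent
   recombination fractions (SARF), and accumulate Kosambi distances,
4. clean markers that inflate the map through spurious double
   crossovers, optionally re-order against a trusted framework map,
5. summarise crossovers, recombination bins and segregation distortion.

ABH codes are held as strings A/H/B/- in DataFrames (markers x
individuals) at the API surface and as int8 arrays (0/1/2, -1 missing)
internally.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2

from .io_formats import GeneticMap

__all__ = [
    "kosambi",
    "kosambi_inverse",
    "PairwiseLinkage",
    "PairwiseTable",
    "GroupingConfig",
    "to_abh",
    "encode_abh",
    "decode_abh",
    "estimate_rf",
    "pairwise_rf",
    "group_markers",
    "order_group",
    "sarf",
    "exhaustive_order",
    "map_positions",
    "build_map",
    "clean_markers",
    "framework_reorder",
    "count_crossovers",
    "CrossoverProfile",
    "recombination_bins",
    "segregation_distortion",
]

_CODE_TO_INT = {"A": 0, "H": 1, "B": 2, "-": -1}
_INT_TO_CODE = np.array(["A", "H", "B"], dtype=object)


def encode_abh(matrix: pd.DataFrame) -> np.ndarray:
    """ABH DataFrame -> int8 array (A=0, H=1, B=2, missing=-1)."""
    arr = matrix.to_numpy(dtype=object)
    out = np.full(arr.shape, -9, dtype=np.int8)
    for code, val in _CODE_TO_INT.items():
        out[arr == code] = val
    if (out == -9).any():
        raise ValueError("ABH matrix contains codes outside {A,H,B,-}")
    return out


def decode_abh(codes: np.ndarray, markers, individuals) -> pd.DataFrame:
    out = np.full(codes.shape, "-", dtype=object)
    ok = codes >= 0
    out[ok] = _INT_TO_CODE[codes[ok]]
    return pd.DataFrame(out, index=markers, columns=individuals)


# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------


def kosambi(r) -> float | np.ndarray:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM for r in [0, 0.5)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any((r_arr < 0) | (r_arr >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r_arr) / (1 - 2 * r_arr))
    return float(d) if np.isscalar(r) else d


def kosambi_inverse(d) -> float | np.ndarray:
    """Exact functional inverse: r = (e^(d/25) - 1) / (2 (e^(d/25) + 1))."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("map distance must be non-negative")
    e = np.exp(d_arr / 25.0)
    r = (e - 1) / (2 * (e + 1))
    return float(r) if np.isscalar(d) else r


# ---------------------------------------------------------------------------
# ABH recoding
# ---------------------------------------------------------------------------


def to_abh(
    parent_a: pd.Series,
    parent_b: pd.Series,
    progeny: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recode F2 progeny calls relative to the parents.

    A marker is retained only when both parents are called, homozygous
    and opposite (AA vs BB). Progeny are recoded A (= parent-A
    homozygote), H, B; NC becomes ``-``. The ledger records one row per
    input marker with its fate: retained, parent_nc, parent_het or
    parents_identical. Progeny calls incompatible with the parental
    homozygotes are masked to ``-`` and counted, not fatal.
    """
    ledger_rows = []
    kept_rows = {}
    incompatible = 0
    for marker in progeny.index:
        pa, pb = parent_a.get(marker, "NC"), parent_b.get(marker, "NC")
        if pa == "NC" or pb == "NC":
            reason = "parent_nc"
        elif pa == "AB" or pb == "AB":
            reason = "parent_het"
        elif pa == pb:
            reason = "parents_identical"
        else:
            reason = "retained"
            mapping = {pa: "A", pb: "B", "AB": "H", "NC": "-"}
            row = []
            for call in progeny.loc[marker]:
                code = mapping.get(call)
                if code is None:
                    incompatible += 1
                    code = "-"
                row.append(code)
            kept_rows[marker] = row
        ledger_rows.append({"marker": marker, "fate": reason})
    abh = pd.DataFrame.from_dict(kept_rows, orient="index", columns=list(progeny.columns))
    ledger = pd.DataFrame(ledger_rows)
    ledger.attrs["incompatible_calls"] = incompatible
    return abh, ledger


# ---------------------------------------------------------------------------
# Two-point recombination fraction (EM)
# ---------------------------------------------------------------------------


@dataclass
class PairwiseLinkage:
    marker_i: str
    marker_j: str
    rf: float
    lod: float
    pvalue: float
    n_joint: int


@dataclass
class PairwiseTable:
    """All-pairs rf / LOD / p-value matrices over a marker set."""

    markers: list[str]
    rf: np.ndarray
    lod: np.ndarray
    pvalue: np.ndarray
    n_joint: np.ndarray

    def pair(self, i: str, j: str) -> PairwiseLinkage:
        a, b = self.markers.index(i), self.markers.index(j)
        return PairwiseLinkage(
            i, j, float(self.rf[a, b]), float(self.lod[a, b]), float(self.pvalue[a, b]),
            int(self.n_joint[a, b]),
        )


def _em_rf(counts: list[np.ndarray], tol: float = 1e-10, max_iter: int = 200):
    """Vectorised EM for the F2 codominant two-point model.

    ``counts`` is the list of nine joint-count arrays n[a][b] for
    genotype codes a, b in {0, 1, 2} (number of B alleles at each
    marker). Any common array shape is supported. Returns (rf, lod,
    pvalue, n_joint) with rf capped to [1e-9, 0.5].
    """
    n = [[counts[3 * a + b].astype(float) for b in range(3)] for a in range(3)]
    total = sum(n[a][b] for a in range(3) for b in range(3))
    n_gam = 2.0 * total
    # recombinant-gamete multiplicities for the eight unambiguous cells
    one_rec = n[0][1] + n[1][0] + n[1][2] + n[2][1]
    two_rec = n[0][2] + n[2][0]
    dh = n[1][1]  # double heterozygotes: phase-ambiguous

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.full(total.shape, 0.25)
        for _ in range(max_iter):
            s = 1.0 - r
            w = r**2 / (r**2 + s**2)  # P(double het is recombinant-phase)
            r_new = (one_rec + 2.0 * two_rec + 2.0 * dh * w) / n_gam
            r_new = np.clip(r_new, 1e-9, 0.5)
            if np.nanmax(np.abs(r_new - r)) < tol:
                r = r_new
                break
            r = r_new

        ll_hat = _f2_loglik(n, r)
        ll_null = _f2_loglik(n, np.full(total.shape, 0.5))
        lod = (ll_hat - ll_null) / math.log(10.0)
        lod = np.maximum(lod, 0.0)
        stat = 2.0 * np.maximum(ll_hat - ll_null, 0.0)
        # boundary LRT: under H0 (r = 0.5) the statistic is a 50:50
        # mixture of a point mass at 0 and chi-square(1)
        pval = np.where(stat > 0, 0.5 * chi2.sf(stat, 1), 1.0)
    return r, lod, pval, total


def _f2_loglik(n, r):
    s = 1.0 - r
    logp = [
        [np.log(s**2 / 4), np.log(r * s / 2), np.log(r**2 / 4)],
        [np.log(r * s / 2), np.log((s**2 + r**2) / 2), np.log(r * s / 2)],
        [np.log(r**2 / 4), np.log(r * s / 2), np.log(s**2 / 4)],
    ]
    ll = 0.0
    for a in range(3):
        for b in range(3):
            term = np.where(n[a][b] > 0, n[a][b] * logp[a][b], 0.0)
            ll = ll + term
    return ll


def estimate_rf(col_i, col_j, min_joint: int = 20) -> PairwiseLinkage:
    """Two-point EM estimate for a single marker pair.

    ``col_i`` / ``col_j`` are ABH code vectors over the same
    individuals. Pairs with fewer than ``min_joint`` jointly called
    individuals are undefined (rf = NaN) and excluded from grouping.
    """
    ci = _as_codes(col_i)
    cj = _as_codes(col_j)
    ok = (ci >= 0) & (cj >= 0)
    counts = [
        np.array(float(((ci == a) & (cj == b) & ok).sum()))
        for a in range(3)
        for b in range(3)
    ]
    n_joint = int(ok.sum())
    if n_joint < min_joint:
        return PairwiseLinkage("i", "j", math.nan, math.nan, math.nan, n_joint)
    r, lod, pval, _ = _em_rf(counts)
    return PairwiseLinkage("i", "j", float(r), float(lod), float(pval), n_joint)


def _as_codes(col) -> np.ndarray:
    arr = np.asarray(col)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int8)
    return np.array([_CODE_TO_INT[c] for c in arr], dtype=np.int8)


def pairwise_rf(matrix: pd.DataFrame, min_joint: int = 20) -> PairwiseTable:
    """All-pairs recombination fractions via one-hot matrix products.

    The nine joint-count matrices are computed as I_a @ I_b^T where
    I_a indicates code a, then a single vectorised EM runs over all
    pairs at once.
    """
    codes = encode_abh(matrix)
    indicators = [(codes == a).astype(np.float64) for a in range(3)]
    counts = [indicators[a] @ indicators[b].T for a in range(3) for b in range(3)]
    rf, lod, pval, n_joint = _em_rf(counts)
    insufficient = n_joint < min_joint
    rf = np.where(insufficient, np.nan, rf)
    lod = np.where(insufficient, np.nan, lod)
    pval = np.where(insufficient, np.nan, pval)
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, np.inf)
    np.fill_diagonal(pval, 0.0)
    return PairwiseTable(
        markers=list(matrix.index),
        rf=rf,
        lod=lod,
        pvalue=pval,
        n_joint=n_joint.astype(int),
    )


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


@dataclass
class GroupingConfig:
    """Linkage-grouping criterion.

    A pair is linked when its likelihood-ratio p-value passes ``alpha``
    and its LOD reaches ``lod_min``. With ``adjust_for_tests`` the
    p-value is Bonferroni-adjusted for the number of pairs examined, as
    genome-wide linkage searches do; the raw per-pair criterion is far
    too permissive once hundreds of markers (tens of thousands of
    pairs) are screened.
    """

    alpha: float = 0.05
    lod_min: float = 3.0
    adjust_for_tests: bool = True


def group_markers(pairwise: PairwiseTable, config: GroupingConfig | None = None) -> list[list[str]]:
    """Single-linkage transitive closure over significantly linked pairs.

    Groups are numbered by descending size (ties broken by first marker
    appearance) and returned as lists of marker names.
    """
    config = config or GroupingConfig()
    m = len(pairwise.markers)
    pval = pairwise.pvalue.copy()
    n_tests = m * (m - 1) / 2
    if config.adjust_for_tests and n_tests > 0:
        pval = np.minimum(pval * n_tests, 1.0)
    with np.errstate(invalid="ignore"):
        linked = (pval <= config.alpha) & (pairwise.lod >= config.lod_min)
    linked &= ~np.eye(m, dtype=bool)
    n_comp, labels = connected_components(csr_matrix(linked), directed=False)
    groups = [[] for _ in range(n_comp)]
    for idx, lab in enumerate(labels):
        groups[lab].append(pairwise.markers[idx])
    order = sorted(range(n_comp), key=lambda g: (-len(groups[g]), g))
    return [groups[g] for g in order]


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------


def _collapse_bins(matrix: pd.DataFrame, markers: list[str]) -> list[list[str]]:
    """Group markers with byte-identical ABH columns into bins."""
    seen: dict[tuple, list[str]] = {}
    for m in markers:
        key = tuple(matrix.loc[m])
        seen.setdefault(key, []).append(m)
    return list(seen.values())


def sarf(order: list[int], rf: np.ndarray) -> float:
    """Sum of adjacent recombination fractions; NaN entries count 0.5."""
    total = 0.0
    for a, b in zip(order, order[1:]):
        r = rf[a, b]
        total += 0.5 if math.isnan(r) else r
    return total


def exhaustive_order(rf: np.ndarray) -> list[int]:
    """Exact SARF minimisation by enumeration (small bin counts only)."""
    n = rf.shape[0]
    best, best_val = list(range(n)), math.inf
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:  # skip mirror duplicates
            continue
        val = sarf(list(perm), rf)
        if val < best_val - 1e-15:
            best, best_val = list(perm), val
    return best


def _greedy_seriation(rf: np.ndarray) -> list[int]:
    n = rf.shape[0]
    if n == 1:
        return [0]
    work = np.where(np.isnan(rf), 0.5, rf).copy()
    np.fill_diagonal(work, np.inf)
    i, j = np.unravel_index(np.argmin(work), work.shape)
    order = [int(i), int(j)]
    remaining = set(range(n)) - set(order)
    while remaining:
        head, tail = order[0], order[-1]
        best = None
        for c in remaining:
            for endpoint, at_head in ((head, True), (tail, False)):
                val = work[c, endpoint]
                if best is None or val < best[0]:
                    best = (val, c, at_head)
        _, c, at_head = best
        if at_head:
            order.insert(0, c)
        else:
            order.append(c)
        remaining.discard(c)
    return order


def _two_opt(order: list[int], rf: np.ndarray) -> list[int]:
    """2-opt segment reversals plus single-bin reinsertion to local optimum."""
    n = len(order)
    improved = True
    best_val = sarf(order, rf)
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                val = sarf(cand, rf)
                if val < best_val - 1e-12:
                    order, best_val, improved = cand, val, True
        for i in range(n):
            bin_ = order[i]
            rest = order[:i] + order[i + 1 :]
            for pos in range(n):
                if pos == i:
                    continue
                cand = rest[:pos] + [bin_] + rest[pos:]
                val = sarf(cand, rf)
                if val < best_val - 1e-12:
                    order, best_val, improved = cand, val, True
    return order


def order_group(
    matrix: pd.DataFrame,
    markers: list[str],
    pairwise: PairwiseTable | None = None,
    exhaustive_limit: int = 6,
    force_heuristic: bool = False,
) -> list[str]:
    """Order a linkage group by SARF minimisation.

    Identical ABH columns collapse to a bin first. Up to
    ``exhaustive_limit`` bins the order is found by exhaustive search
    (exact); larger groups use greedy seriation from the most-linked
    pair refined by 2-opt. ``force_heuristic`` exists so the heuristic
    can be checked against the exhaustive oracle.
    """
    bins = _collapse_bins(matrix, markers)
    reps = [b[0] for b in bins]
    if pairwise is None:
        pairwise = pairwise_rf(matrix.loc[markers])
    idx = [pairwise.markers.index(r) for r in reps]
    rf = pairwise.rf[np.ix_(idx, idx)]
    if len(bins) <= exhaustive_limit and not force_heuristic:
        order = exhaustive_order(rf)
    else:
        order = _two_opt(_greedy_seriation(rf), rf)
    ordered = []
    for b in order:
        ordered.extend(bins[b])
    return ordered


def map_positions(matrix: pd.DataFrame, ordered: list[str]) -> pd.DataFrame:
    """Cumulative Kosambi positions for an ordered marker list."""
    pos = [0.0]
    sub = matrix.loc[ordered]
    for i in range(1, len(ordered)):
        link = estimate_rf(sub.iloc[i - 1], sub.iloc[i], min_joint=1)
        r = min(link.rf, 0.4999) if not math.isnan(link.rf) else 0.4999
        pos.append(pos[-1] + kosambi(r))
    return pd.DataFrame({"marker": ordered, "cm": pos})


def build_map(
    matrix: pd.DataFrame,
    grouping: GroupingConfig | None = None,
    min_joint: int = 20,
) -> tuple[GeneticMap, PairwiseTable]:
    """Full chain: pairwise rf -> grouping -> ordering -> Kosambi positions."""
    pairwise = pairwise_rf(matrix, min_joint=min_joint)
    groups = group_markers(pairwise, grouping)
    out = {}
    for gi, members in enumerate(groups, start=1):
        name = f"LG{gi:02d}"
        if len(members) == 1:
            out[name] = pd.DataFrame({"marker": members, "cm": [0.0]})
            continue
        ordered = order_group(matrix, members, pairwise=pairwise)
        out[name] = map_positions(matrix, ordered)
    return GeneticMap(groups=out), pairwise


# ---------------------------------------------------------------------------
# Cleaning and framework reordering
# ---------------------------------------------------------------------------


def _double_recombinant_counts(codes: np.ndarray) -> np.ndarray:
    """Per-marker count of singleton double recombinants.

    A singleton at marker j in one individual: the nearest non-missing
    flanking genotypes agree with each other but differ from the
    genotype at j.
    """
    m, n = codes.shape
    counts = np.zeros(m, dtype=int)
    for ind in range(n):
        col = codes[:, ind]
        obs = np.flatnonzero(col >= 0)
        for prev, cur, nxt in zip(obs, obs[1:], obs[2:]):
            if col[prev] == col[nxt] != col[cur]:
                counts[cur] += 1
    return counts


def _group_length(matrix: pd.DataFrame, ordered: list[str]) -> float:
    pos = map_positions(matrix, ordered)
    return float(pos["cm"].iloc[-1])


def clean_markers(
    matrix: pd.DataFrame,
    ordered: list[str],
    max_singletons: int = 2,
) -> tuple[list[str], list[str]]:
    """Drop markers that expand the group through excess double crossovers.

    Iteratively removes, among markers with more than ``max_singletons``
    singleton double recombinants, the one whose exclusion most reduces
    the group's Kosambi length; stops when no qualifying marker reduces
    the length. Returns (kept order, removed markers).
    """
    order = list(ordered)
    removed = []
    while len(order) > 2:
        codes = encode_abh(matrix.loc[order])
        counts = _double_recombinant_counts(codes)
        candidates = [i for i, c in enumerate(counts) if c > max_singletons]
        if not candidates:
            break
        current_len = _group_length(matrix, order)
        best = None
        for i in candidates:
            trial = order[:i] + order[i + 1 :]
            tlen = _group_length(matrix, trial)
            if best is None or tlen < best[0]:
                best = (tlen, i)
        if best[0] >= current_len - 1e-9:
            break
        removed.append(order[best[1]])
        order = order[: best[1]] + order[best[1] + 1 :]
    return order, removed


def framework_reorder(
    matrix: pd.DataFrame,
    target_order: list[str],
    framework_order: list[str],
) -> list[str]:
    """Re-order a group constraining shared markers to a framework order.

    Markers shared with the framework keep the framework's relative
    order; non-shared markers are inserted one by one at their
    SARF-minimising position. A warning is issued if the result is
    longer than the original order.
    """
    shared = [m for m in framework_order if m in set(target_order)]
    if len(shared) < 2:
        raise ValueError("framework and target share fewer than 2 markers")
    pairwise = pairwise_rf(matrix.loc[target_order], min_joint=1)
    pos_of = {m: i for i, m in enumerate(pairwise.markers)}
    rf = pairwise.rf
    order_idx = [pos_of[m] for m in shared]
    for m in target_order:
        if m in set(shared):
            continue
        c = pos_of[m]
        best = None
        for pos in range(len(order_idx) + 1):
            cand = order_idx[:pos] + [c] + order_idx[pos:]
            val = sarf(cand, rf)
            if best is None or val < best[0]:
                best = (val, pos)
        order_idx.insert(best[1], c)
    result = [pairwise.markers[i] for i in order_idx]
    if _group_length(matrix, result) > _group_length(matrix, target_order) + 1e-9:
        warnings.warn("framework reordering increased group length", stacklevel=2)
    return result


# ---------------------------------------------------------------------------
# Crossovers, bins, distortion
# ---------------------------------------------------------------------------


@dataclass
class CrossoverProfile:
    """Crossover counts per individual per group, with outlier flags."""

    per_individual: pd.DataFrame  # individuals x groups
    group_means: pd.Series
    outliers: pd.DataFrame  # boolean, same shape as per_individual
    outlier_multiple: float = 2.0

    @property
    def totals(self) -> pd.Series:
        return self.per_individual.sum(axis=1)


def count_crossovers(
    matrix: pd.DataFrame,
    genetic_map: GeneticMap,
    outlier_multiple: float = 2.0,
) -> CrossoverProfile:
    """Count crossovers per individual per linkage group.

    Scanning each individual's non-missing codes in map order, an
    A<->H or H<->B transition counts one crossover and A<->B counts
    two; missing codes are skipped, the transition being measured
    between the nearest non-missing flanks. Individuals whose count on
    some group exceeds ``outlier_multiple`` times that group's
    population mean are flagged.
    """
    individuals = list(matrix.columns)
    data = {}
    for name in genetic_map.groups:
        order = [m for m in genetic_map.marker_order(name) if m in matrix.index]
        codes = encode_abh(matrix.loc[order])
        counts = np.zeros(len(individuals), dtype=int)
        for j in range(len(individuals)):
            col = codes[:, j]
            obs = col[col >= 0]
            if obs.size > 1:
                counts[j] = int(np.abs(np.diff(obs)).sum())
        data[name] = counts
    per_ind = pd.DataFrame(data, index=individuals)
    means = per_ind.mean(axis=0)
    with np.errstate(invalid="ignore"):
        outliers = per_ind.gt(outlier_multiple * means, axis=1) & (means > 0)
    return CrossoverProfile(
        per_individual=per_ind,
        group_means=means,
        outliers=outliers,
        outlier_multiple=outlier_multiple,
    )


def recombination_bins(matrix: pd.DataFrame, genetic_map: GeneticMap) -> pd.DataFrame:
    """Collapse map-adjacent cosegregating markers into recombination bins.

    Adjacent markers join the current bin when their columns are
    compatible with the bin's consensus (missing codes are wildcards).
    Returns per-group bin counts and mean markers per bin.
    """
    rows = []
    for name in genetic_map.groups:
        order = [m for m in genetic_map.marker_order(name) if m in matrix.index]
        codes = encode_abh(matrix.loc[order])
        if len(order) == 0:
            rows.append({"group": name, "n_markers": 0, "n_bins": 0, "markers_per_bin": 0.0})
            continue
        n_bins = 1
        consensus = codes[0].astype(np.int16).copy()
        for i in range(1, len(order)):
            row = codes[i]
            conflict = (row >= 0) & (consensus >= 0) & (row != consensus)
            if conflict.any():
                n_bins += 1
                consensus = row.astype(np.int16).copy()
            else:
                fill = (consensus < 0) & (row >= 0)
                consensus[fill] = row[fill]
        rows.append(
            {
                "group": name,
                "n_markers": len(order),
                "n_bins": n_bins,
                "markers_per_bin": len(order) / n_bins,
            }
        )
    return pd.DataFrame(rows)


def segregation_distortion(matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square test of each marker against the Mendelian 1:2:1 ratio.

    Returns one row per marker with genotype counts, the chi-square
    statistic (2 df), p-value, a distortion flag at ``alpha``, a
    heterozygote-deficit flag and the favored parent (A = female). The
    result carries a ``summary`` dict in ``.attrs`` with the distorted
    fraction, the heterozygote-deficit fraction among distorted
    markers, and the female:male favored-marker ratio.
    """
    codes = encode_abh(matrix)
    rows = []
    for i, marker in enumerate(matrix.index):
        col = codes[i]
        na = int((col == 0).sum())
        nh = int((col == 1).sum())
        nb = int((col == 2).sum())
        n = na + nh + nb
        if n == 0:
            warnings.warn(f"marker {marker!r} has no called individuals; excluded", stacklevel=2)
            continue
        exp = np.array([0.25, 0.5, 0.25]) * n
        obs = np.array([na, nh, nb], dtype=float)
        stat = float(((obs - exp) ** 2 / exp).sum())
        p = float(chi2.sf(stat, 2))
        favored = "A" if na > nb else ("B" if nb > na else "none")
        rows.append(
            {
                "marker": marker,
                "n_a": na,
                "n_h": nh,
                "n_b": nb,
                "chi2": stat,
                "pvalue": p,
                "distorted": p < alpha,
                "het_deficit": nh < exp[1],
                "favored_parent": favored,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        distorted = out[out["distorted"]]
        n_female = int((distorted["favored_parent"] == "A").sum())
        n_male = int((distorted["favored_parent"] == "B").sum())
        out.attrs["summary"] = {
            "n_markers": len(out),
            "n_distorted": len(distorted),
            "distorted_fraction": len(distorted) / len(out),
            "het_deficit_fraction_among_distorted": (
                float(distorted["het_deficit"].mean()) if len(distorted) else math.nan
            ),
            "female_to_male_favored_ratio": (
                n_female / n_male if n_male else math.inf if n_female else math.nan
            ),
        }
    return out
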