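"""Synthetic intensity, panel and F2 data with known ground truth.

The generators emulate the statistical structure that the calling and
mapping stages assume, so that every downstream operation can be
exercised and scored against a complete truth record:

* per-marker two-channel intensity clusters in the six canonical
  patterns seen on allotetraploid Infinium arrays (monomorphic,
  homeo-SNP heterozygote-only, diploid-like three-cluster, shifted
  two-locus, and two progressively tighter multi-locus patterns),
* null-allele signal failures that depress call frequency,
* inbred panels with a prescribed minor-allele-frequency law and
  residual heterozygosity,
* F2 populations generated as Markov crossover walks (no interference)
  along a true genetic map, with optional genotype-specific viability
  weighting to induce segregation distortion.

All generators take an integer seed and are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io_formats import GeneticMap, GenotypeTable, IntensityTable, default_sample_metadata
from .linkage_map import kosambi_inverse

__all__ = [
    "PatternSpec",
    "SimTruth",
    "default_pattern_specs",
    "DEFAULT_COMPOSITION",
    "simulate_marker_intensities",
    "simulate_marker_panel",
    "simulate_inbred_panel",
    "simulate_f2",
    "genotypes_to_intensities",
    "synthetic_map",
]

#: R level of a genuine cluster vs. a null-allele signal failure. The
#: failure level sits far below the calling floor (0.5).
CLUSTER_R = 1.0
CLUSTER_R_SD = 0.1
NULL_R = 0.1
NULL_R_SD = 0.04


@dataclass(frozen=True)
class PatternSpec:
    """Geometry of one marker's intensity clusters.

    ``mean_theta``/``sd_theta``/``genotypes``/``weights`` are parallel
    per-component tuples with strictly increasing means in [0, 1].
    ``null_rate`` is the probability that a sample's assay fails to a
    low-R signal regardless of genotype.
    """

    pattern: int
    mean_theta: tuple[float, ...]
    sd_theta: tuple[float, ...]
    genotypes: tuple[str, ...]
    weights: tuple[float, ...]
    mean_r: float = CLUSTER_R
    sd_r: float = CLUSTER_R_SD
    null_rate: float = 0.0

    def __post_init__(self):
        means = self.mean_theta
        if any(b - a <= 0 for a, b in zip(means, means[1:])):
            raise ValueError("component mean thetas must strictly increase")
        if any(m < 0 or m > 1 for m in means):
            raise ValueError("mean thetas must lie in [0, 1]")
        if any(s <= 0 for s in self.sd_theta):
            raise ValueError("sds must be positive")
        if not 0 <= self.null_rate <= 1:
            raise ValueError("null rate must lie in [0, 1]")
        if self.pattern == 2 and (
            len(means) != 1 or abs(means[0] - 0.5) > 0.1
        ):
            raise ValueError("pattern 2 has exactly one component near 0.5")
        if self.pattern == 4 and not any(
            g in ("AA", "BB") and abs(m - 0.5) < 0.1
            for g, m in zip(self.genotypes, means)
        ):
            raise ValueError("pattern 4 needs a homozygote component near 0.5")

    @property
    def k(self) -> int:
        return len(self.mean_theta)


def default_pattern_specs() -> dict[int, PatternSpec]:
    """Default cluster geometries for the six patterns.

    Pattern 3 is the canonical diploid-like marker (homozygotes at 0.05
    and 0.95, sd 0.03; its separation score is the 0.80 calibration
    point). Pattern 4 shifts the whole constellation so one homozygote
    sits at theta 0.5. Patterns 5 and 6 compress the homozygote
    clusters towards the broadened heterozygote cloud so their
    separation scores land in the 0.21-0.29 band and below 0.21
    respectively. Component weights are 1:2:1, matching a segregating
    tetraploid sample mix.
    """
    f2w = (0.25, 0.5, 0.25)
    return {
        1: PatternSpec(1, (0.05,), (0.03,), ("AA",), (1.0,)),
        2: PatternSpec(2, (0.5,), (0.03,), ("AB",), (1.0,)),
        3: PatternSpec(3, (0.05, 0.50, 0.95), (0.03, 0.03, 0.03), ("AA", "AB", "BB"), f2w),
        4: PatternSpec(4, (0.10, 0.30, 0.50), (0.03, 0.03, 0.03), ("AA", "AB", "BB"), f2w),
        5: PatternSpec(5, (0.42, 0.50, 0.58), (0.03, 0.08, 0.03), ("AA", "AB", "BB"), f2w),
        6: PatternSpec(6, (0.45, 0.50, 0.55), (0.03, 0.08, 0.03), ("AA", "AB", "BB"), f2w),
    }


#: Marker-status composition used when simulating a whole array's worth
#: of markers: roughly the observed mix on the real array (12% failed,
#: 16% monomorphic, 10% homeo-SNP) with the polymorphic remainder
#: dominated by well-separated patterns.
DEFAULT_COMPOSITION = {
    "failed": 0.12,
    1: 0.16,
    2: 0.10,
    3: 0.38,
    4: 0.14,
    5: 0.06,
    6: 0.04,
}


@dataclass
class SimTruth:
    """Complete ground truth for a simulated dataset."""

    seed: int
    statuses: dict[str, tuple[str, int | None]] = field(default_factory=dict)
    genotypes: pd.DataFrame | None = None  # markers x samples, AA/AB/BB or NC
    null_mask: pd.DataFrame | None = None  # True where the assay failed
    genetic_map: GeneticMap | None = None
    crossovers: pd.DataFrame | None = None  # individuals x groups


def _truncnorm_rvs(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_intensities(rng, spec: PatternSpec, genotypes: np.ndarray, null: np.ndarray):
    """theta/R draws for one marker given per-sample genotypes."""
    n = genotypes.size
    theta = np.empty(n)
    r = np.empty(n)
    comp_of = {g: j for j, g in enumerate(spec.genotypes)}
    for i in range(n):
        if null[i] or genotypes[i] == "NC":
            theta[i] = rng.uniform(0.0, 1.0)
            r[i] = max(rng.normal(NULL_R, NULL_R_SD), 0.0)
        else:
            j = comp_of.get(genotypes[i])
            if j is None:
                raise ValueError(
                    f"genotype {genotypes[i]!r} has no component in pattern-{spec.pattern} spec"
                )
            theta[i] = _truncnorm_rvs(rng, spec.mean_theta[j], spec.sd_theta[j], 0.0, 1.0, 1)[0]
            r[i] = max(rng.normal(spec.mean_r, spec.sd_r), 0.0)
    return theta, r


def simulate_marker_intensities(
    spec: PatternSpec,
    n_samples: int,
    seed: int,
    marker: str = "m1",
) -> tuple[IntensityTable, SimTruth]:
    """Simulate one marker's intensities under a pattern spec.

    Each sample draws a component (genotype) from the spec weights,
    then theta ~ truncated Normal(component mean, sd) on [0, 1] and
    R ~ Normal around the cluster signal level; null-allele samples
    instead fail to a low-R, uniform-theta signal.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    genotypes = rng.choice(spec.genotypes, size=n_samples, p=np.array(spec.weights))
    null = rng.random(n_samples) < spec.null_rate
    theta, r = _sample_intensities(rng, spec, genotypes, null)
    samples = [f"s{i + 1}" for i in range(n_samples)]
    it = IntensityTable(
        theta=pd.DataFrame([theta], index=[marker], columns=samples),
        R=pd.DataFrame([r], index=[marker], columns=samples),
    )
    truth = SimTruth(
        seed=seed,
        statuses={marker: _status_of(spec.pattern)},
        genotypes=pd.DataFrame([genotypes], index=[marker], columns=samples),
        null_mask=pd.DataFrame([null], index=[marker], columns=samples),
    )
    return it, truth


def _status_of(pattern: int | None) -> tuple[str, int | None]:
    if pattern is None:
        return ("failed", None)
    return (
        {1: "monomorphic", 2: "intergenomic"}.get(pattern, "polymorphic"),
        pattern,
    )


def simulate_marker_panel(
    n_markers: int,
    n_samples: int,
    seed: int,
    composition: dict | None = None,
    specs: dict[int, PatternSpec] | None = None,
) -> tuple[IntensityTable, SimTruth]:
    """Simulate a battery of markers spanning failed + patterns 1-6.

    ``composition`` maps "failed" or a pattern id to its fraction of
    markers (defaults to :data:`DEFAULT_COMPOSITION`). Failed markers
    emit only low-R noise.
    """
    composition = composition or DEFAULT_COMPOSITION
    specs = specs or default_pattern_specs()
    rng = np.random.default_rng(seed)
    keys = list(composition)
    probs = np.array([composition[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    assigned = rng.choice(len(keys), size=n_markers, p=probs)
    samples = [f"s{i + 1}" for i in range(n_samples)]
    theta = np.empty((n_markers, n_samples))
    r = np.empty((n_markers, n_samples))
    statuses = {}
    geno_rows = []
    null_rows = []
    markers = [f"snp{i + 1:05d}" for i in range(n_markers)]
    for i, marker in enumerate(markers):
        key = keys[assigned[i]]
        if key == "failed":
            statuses[marker] = ("failed", None)
            genotypes = np.array(["NC"] * n_samples, dtype=object)
            null = np.ones(n_samples, dtype=bool)
            spec = specs[1]
        else:
            spec = specs[key]
            statuses[marker] = _status_of(spec.pattern)
            genotypes = rng.choice(spec.genotypes, size=n_samples, p=np.array(spec.weights))
            null = rng.random(n_samples) < spec.null_rate
        theta[i], r[i] = _sample_intensities(rng, spec, genotypes, null)
        geno_rows.append(genotypes)
        null_rows.append(null)
    it = IntensityTable(
        theta=pd.DataFrame(theta, index=markers, columns=samples),
        R=pd.DataFrame(r, index=markers, columns=samples),
    )
    truth = SimTruth(
        seed=seed,
        statuses=statuses,
        genotypes=pd.DataFrame(geno_rows, index=markers, columns=samples),
        null_mask=pd.DataFrame(null_rows, index=markers, columns=samples),
    )
    return it, truth


def simulate_inbred_panel(
    n_lines: int,
    n_markers: int,
    maf_law,
    seed: int,
    residual_het: float = 0.0,
) -> tuple[GenotypeTable, SimTruth]:
    """Simulate genotype calls for a panel of inbred lines.

    ``maf_law`` gives each marker's minor (B) allele frequency: either
    a constant in [0, 0.5] or a callable ``f(rng, n) -> array``. Lines
    are homozygous except for a ``residual_het`` chance of an AB call.
    """
    rng = np.random.default_rng(seed)
    if callable(maf_law):
        maf = np.asarray(maf_law(rng, n_markers), dtype=float)
    else:
        maf = np.full(n_markers, float(maf_law))
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("minor allele frequencies must lie in [0, 0.5]")
    markers = [f"snp{i + 1:05d}" for i in range(n_markers)]
    lines = [f"line{i + 1:04d}" for i in range(n_lines)]
    is_b = rng.random((n_markers, n_lines)) < maf[:, None]
    calls = np.where(is_b, "BB", "AA").astype(object)
    het = rng.random((n_markers, n_lines)) < residual_het
    calls[het] = "AB"
    call_df = pd.DataFrame(calls, index=markers, columns=lines)
    meta = default_sample_metadata(lines)
    truth = SimTruth(seed=seed, genotypes=call_df.copy())
    truth.statuses = {m: ("polymorphic" if f > 0 else "monomorphic", None) for m, f in zip(markers, maf)}
    return GenotypeTable(calls=call_df, samples=meta), truth


def synthetic_map(
    n_groups: int,
    markers_per_group: int,
    group_length_cm: float,
    prefix: str = "snp",
) -> GeneticMap:
    """Evenly spaced true map: ``n_groups`` groups of equal length."""
    groups = {}
    idx = 0
    for g in range(1, n_groups + 1):
        cms = np.linspace(0.0, group_length_cm, markers_per_group)
        names = [f"{prefix}{idx + i + 1:05d}" for i in range(markers_per_group)]
        idx += markers_per_group
        groups[f"LG{g:02d}"] = pd.DataFrame({"marker": names, "cm": cms})
    return GeneticMap(groups=groups)


def simulate_f2(
    map_truth: GeneticMap,
    n_individuals: int,
    seed: int,
    distortion: dict[str, tuple[float, float, float]] | None = None,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate an F2 population along a true genetic map.

    Each gamete is a Markov walk over each linkage group: the starting
    parental allele is fair, and each interval recombines independently
    with probability ``kosambi_inverse(interval cM)`` (no crossover
    interference). Two independent gametes make an F2 individual, coded
    A/H/B. ``distortion`` maps marker -> relative viability weights
    (wA, wH, wB); individuals survive rejection sampling with
    probability proportional to the product of their weights across
    distorted markers. ``missing_rate`` masks calls to ``-``.

    Returns the ABH matrix (markers x individuals) and a truth record
    whose ``crossovers`` DataFrame counts true crossovers (both
    gametes) per individual per group.
    """
    rng = np.random.default_rng(seed)
    group_rs = {}
    for name, g in map_truth.groups.items():
        cm = g["cm"].to_numpy()
        intervals = np.diff(cm)
        if np.any(intervals < 0):
            raise ValueError(f"negative interval in group {name!r}")
        group_rs[name] = kosambi_inverse(intervals)

    individuals = [f"ind{i + 1:04d}" for i in range(n_individuals)]
    markers = [m for name in map_truth.groups for m in map_truth.marker_order(name)]
    marker_pos = {m: i for i, m in enumerate(markers)}

    def draw_individual():
        geno = np.empty(len(markers), dtype=np.int8)
        xo = {}
        off = 0
        for name, g in map_truth.groups.items():
            n_m = len(g)
            rs = group_rs[name]
            flips = 0
            alleles = np.empty((2, n_m), dtype=np.int8)
            for gam in range(2):
                a = rng.integers(0, 2)
                alleles[gam, 0] = a
                rec = rng.random(n_m - 1) < rs
                flips += int(rec.sum())
                alleles[gam, 1:] = (a + np.cumsum(rec)) % 2
            geno[off : off + n_m] = alleles.sum(axis=0)
            xo[name] = flips
            off += n_m
        return geno, xo

    if distortion:
        weights = {m: np.asarray(w, dtype=float) for m, w in distortion.items()}
        wmax = {m: w.max() for m, w in weights.items()}
    genotypes = np.empty((n_individuals, len(markers)), dtype=np.int8)
    xo_rows = []
    accepted = 0
    while accepted < n_individuals:
        geno, xo = draw_individual()
        if distortion:
            p = 1.0
            for m, w in weights.items():
                p *= w[geno[marker_pos[m]]] / wmax[m]
            if rng.random() >= p:
                continue
        genotypes[accepted] = geno
        xo_rows.append(xo)
        accepted += 1

    codes = genotypes.T  # markers x individuals
    out = np.full(codes.shape, "-", dtype=object)
    for val, code in ((0, "A"), (1, "H"), (2, "B")):
        out[codes == val] = code
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        out[mask] = "-"
    abh = pd.DataFrame(out, index=markers, columns=individuals)
    truth = SimTruth(
        seed=seed,
        genetic_map=map_truth,
        crossovers=pd.DataFrame(xo_rows, index=individuals),
    )
    geno_labels = np.array(["AA", "AB", "BB"], dtype=object)[codes]
    truth.genotypes = pd.DataFrame(geno_labels, index=markers, columns=individuals)
    return abh, truth


def genotypes_to_intensities(
    genotypes: pd.DataFrame,
    specs: dict[str, PatternSpec],
    seed: int,
) -> IntensityTable:
    """Turn true genotypes back into raw-style intensities.

    Closes the simulation loop: genotypes from a panel or F2 simulation
    become theta/R signals under each marker's pattern spec, which the
    cluster engine can then re-call. Each spec's ``null_rate`` applies
    on top of the genotypes.
    """
    rng = np.random.default_rng(seed)
    theta = np.empty(genotypes.shape)
    r = np.empty(genotypes.shape)
    for i, marker in enumerate(genotypes.index):
        spec = specs.get(marker)
        if spec is None:
            raise ValueError(f"no pattern spec for marker {marker!r}")
        row = genotypes.loc[marker].to_numpy(dtype=object)
        null = rng.random(row.size) < spec.null_rate
        theta[i], r[i] = _sample_intensities(rng, spec, row, null)
    return IntensityTable(
        theta=pd.DataFrame(theta, index=genotypes.index, columns=genotypes.columns),
        R=pd.DataFrame(r, index=genotypes.index, columns=genotypes.columns),
    )
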