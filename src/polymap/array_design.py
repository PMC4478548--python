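"""Candidate-SNP filtering and array content selection.

Implements the desk-side half of designing an Infinium genotyping
array: screening candidate SNPs on assay design score, beadtype class
and sequence uniqueness, collapsing duplicates discovered in several
datasets by publication precedence, and assembling the final panel
with exhaustive genic content plus a randomly sampled genomic
complement. Alignment-derived uniqueness percentages are consumed as
precomputed attributes; no aligner is embedded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CandidateSNP",
    "PanelSelection",
    "FilterThresholds",
    "beadtype_class",
    "filter_candidates",
    "retention_rate",
    "dedup_by_precedence",
    "assemble_panel",
    "read_candidates",
    "write_selection",
]

#: Infinium dye channels: A/T report in one fluorophore channel and C/G
#: in the other. A SNP whose two alleles land in different channels can
#: be scored with a single bead type; alleles sharing a channel need two.
DYE_CHANNEL = {"A": 1, "T": 1, "C": 2, "G": 2}


@dataclass(frozen=True)
class CandidateSNP:
    """One candidate marker with its design-time attributes.

    ``flank`` is the flanking sequence with the SNP base included at
    position ``snp_pos`` (defaults to the centre); ``precedence`` ranks
    the source dataset (lower = earlier publication = preferred).
    """

    id: str
    alleles: tuple[str, str]
    design_score: float
    dataset: str = "default"
    precedence: int = 1
    genic: str = "unclassified"  # genic / nongenic / unclassified
    flank: str = ""
    snp_pos: int | None = None
    flank_identity_pct: float = 100.0
    probe_identity_pct: float = 100.0
    validated: bool = False

    def __post_init__(self):
        a, b = self.alleles
        if a == b:
            raise ValueError(f"{self.id}: alleles must differ")
        if not 0.0 <= self.design_score <= 1.0:
            raise ValueError(f"{self.id}: design score must lie in [0, 1]")

    @property
    def site(self) -> int:
        return len(self.flank) // 2 if self.snp_pos is None else self.snp_pos

    def masked_flank(self) -> str:
        """Flank with the SNP base replaced by the sorted allele pair."""
        if not self.flank:
            return f"[{'/'.join(sorted(self.alleles))}]"
        i = self.site
        return self.flank[:i] + f"[{'/'.join(sorted(self.alleles))}]" + self.flank[i + 1 :]


@dataclass
class PanelSelection:
    """Outcome of a filtering / selection step.

    ``ledger`` has one row per input candidate with its fate: either
    ``retained`` or the name of the first filter it failed.
    """

    retained: list[str]
    ledger: pd.DataFrame
    seed: int | None = None

    @property
    def retention_pct(self) -> float:
        total = len(self.ledger)
        return retention_rate(len(self.retained), total) if total else 0.0

    def composition(self, candidates: dict[str, CandidateSNP]) -> pd.DataFrame:
        rows = []
        for cls in ("genic", "nongenic", "unclassified"):
            n = sum(1 for cid in self.retained if candidates[cid].genic == cls)
            rows.append({"class": cls, "count": n})
        df = pd.DataFrame(rows)
        total = df["count"].sum()
        df["pct"] = (100.0 * df["count"] / total).round(1) if total else 0.0
        return df


def retention_rate(retained: int, total: int) -> float:
    """Percent retention to one decimal (e.g. 69306 of 91953 -> 75.4)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * retained / total, 1)


def beadtype_class(alleles: tuple[str, str], rule: str = "channel") -> str:
    """Classify an allele pair as a one-bead or two-bead Infinium assay.

    Under the default ``channel`` rule a single bead suffices exactly
    when the two alleles report in different fluorophore channels
    (A/T channel vs. C/G channel) — so A/G needs one bead and A/T two.
    ``rule="transversion"`` instead applies the looser literal rule
    that transitions are one-bead and transversions two-bead, which
    differs for the transversion pairs A/C and T/G.
    """
    a, b = (x.upper() for x in alleles)
    for base in (a, b):
        if base not in DYE_CHANNEL:
            raise ValueError(f"non-ACGT allele {base!r}")
    if a == b:
        raise ValueError("alleles must differ")
    if rule == "channel":
        return "one_bead" if DYE_CHANNEL[a] != DYE_CHANNEL[b] else "two_bead"
    if rule == "transversion":
        purines = {"A", "G"}
        transition = (a in purines) == (b in purines)
        return "one_bead" if transition else "two_bead"
    raise ValueError(f"unknown beadtype rule {rule!r}")


@dataclass
class FilterThresholds:
    design_score_min: float = 0.8  # strict: score must exceed this
    flank_identity_min: float = 99.0
    probe_identity_min: float = 99.0
    require_beadtype: str = "one_bead"
    beadtype_rule: str = "channel"


_FILTER_ORDER = ("design_score", "beadtype", "flank_uniqueness", "probe_uniqueness")


def _filter_checks(c: CandidateSNP, t: FilterThresholds) -> dict[str, bool]:
    return {
        "design_score": c.design_score > t.design_score_min,
        "beadtype": beadtype_class(c.alleles, t.beadtype_rule) == t.require_beadtype,
        "flank_uniqueness": c.flank_identity_pct > t.flank_identity_min,
        "probe_uniqueness": c.probe_identity_pct > t.probe_identity_min,
    }


def filter_candidates(
    candidates: list[CandidateSNP],
    thresholds: FilterThresholds | None = None,
    order: tuple[str, ...] = _FILTER_ORDER,
) -> PanelSelection:
    """Apply the design filters, attributing each rejection to the
    first failing filter in ``order``.

    The retained set is order-independent (all filters are applied to
    every candidate); only the ledger attribution depends on order.
    """
    thresholds = thresholds or FilterThresholds()
    rows = []
    retained = []
    for c in candidates:
        checks = _filter_checks(c, thresholds)
        fate = "retained"
        for name in order:
            if not checks[name]:
                fate = name
                break
        if fate == "retained":
            retained.append(c.id)
        rows.append({"candidate": c.id, "fate": fate})
    return PanelSelection(retained=retained, ledger=pd.DataFrame(rows, columns=["candidate", "fate"]))


def dedup_by_precedence(candidates: list[CandidateSNP]) -> PanelSelection:
    """Collapse candidates with identical flank+SNP sequences.

    Duplicate detection is an exact string match on the flank with the
    SNP site masked to the (sorted) allele pair. Within a duplicate
    group the candidate with the best (lowest) precedence rank
    survives; ties break on lexical id.
    """
    groups: dict[str, list[CandidateSNP]] = {}
    for c in candidates:
        groups.setdefault(c.masked_flank(), []).append(c)
    retained, rows = [], []
    fate_of = {}
    for members in groups.values():
        winner = min(members, key=lambda c: (c.precedence, c.id))
        for c in members:
            fate_of[c.id] = "retained" if c is winner else "duplicate"
    for c in candidates:  # ledger in input order
        fate = fate_of[c.id]
        if fate == "retained":
            retained.append(c.id)
        rows.append({"candidate": c.id, "fate": fate})
    return PanelSelection(retained=retained, ledger=pd.DataFrame(rows, columns=["candidate", "fate"]))


def assemble_panel(
    candidates: list[CandidateSNP],
    total: int,
    seed: int,
) -> PanelSelection:
    """Assemble the final panel of ``total`` markers.

    Genic candidates are taken exhaustively (up to the quota); the
    remainder is filled by seeded uniform sampling without replacement
    from the nongenic and unclassified candidates.
    """
    import numpy as np

    if total > len(candidates):
        raise ValueError(
            f"quota {total} exceeds available candidates ({len(candidates)}); "
            f"shortfall {total - len(candidates)}"
        )
    genic = [c for c in candidates if c.genic == "genic"]
    other = [c for c in candidates if c.genic != "genic"]
    chosen = [c.id for c in genic[:total]]
    n_fill = total - len(chosen)
    if n_fill > 0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(other), size=n_fill, replace=False)
        chosen.extend(other[i].id for i in sorted(idx))
    chosen_set = set(chosen)
    rows = [
        {"candidate": c.id, "fate": "retained" if c.id in chosen_set else "not_sampled"}
        for c in candidates
    ]
    return PanelSelection(retained=chosen, ledger=pd.DataFrame(rows), seed=seed)


# ---------------------------------------------------------------------------
# I/O: FASTA flanks + attribute TSV
# ---------------------------------------------------------------------------


def read_candidates(fasta_path, attributes_path) -> list[CandidateSNP]:
    """Read candidates from a FASTA of flanks and an attribute TSV.

    The TSV needs columns id, allele_a, allele_b, design_score,
    dataset, precedence, genic, flank_identity_pct, probe_identity_pct.
    """
    from Bio import SeqIO

    flanks = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    attrs = pd.read_csv(attributes_path, sep="\t", dtype={"id": str})
    out = []
    for _, row in attrs.iterrows():
        out.append(
            CandidateSNP(
                id=row["id"],
                alleles=(row["allele_a"], row["allele_b"]),
                design_score=float(row["design_score"]),
                dataset=row.get("dataset", "default"),
                precedence=int(row.get("precedence", 1)),
                genic=row.get("genic", "unclassified"),
                flank=flanks.get(row["id"], ""),
                flank_identity_pct=float(row.get("flank_identity_pct", 100.0)),
                probe_identity_pct=float(row.get("probe_identity_pct", 100.0)),
            )
        )
    return out


def write_selection(path, selection: PanelSelection) -> None:
    selection.ledger.to_csv(path, sep="\t", index=False)
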