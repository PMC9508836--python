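"""Rule-based de novo calling and hard quality filters on trio pileup evidence.

The rule-based caller operates on per-member counts at a site: total
spanning read depth, alt-supporting reads and the variant allele fraction
(VAF).  A candidate passes as de novo when both parents are covered at
>=10x and the parents are effectively alt-free: either zero alternative
reads in both, or VAF <= 15% with fewer than 3 alternative reads in both.

Two population-frequency gates are provided: a pre-filter (exome mode:
gnomAD AF < 1%; genome mode: AF < 0.1% plus caller quality > 15) and a
stricter high-quality post-filter (trio depth >= 10, child VAF >= 20%,
gnomAD AF < 0.01%).  Missing population frequencies are treated as 0,
i.e. the variant is considered novel.

Boundary semantics follow the stated inequalities exactly (>=, <=, <, >).
All thresholds are dataclass fields and can be overridden; defaults are
the published values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .trio_io import GAP, WINDOW_FLANK, ROLES, TrioAlignmentWindow

__all__ = [
    "MemberEvidence",
    "TrioGenotypeEvidence",
    "FilterThresholds",
    "compute_vaf",
    "inhouse_denovo_filter",
    "population_af_prefilter",
    "high_quality_filter",
    "evidence_from_window",
]


def compute_vaf(alt_reads: int, depth: int) -> float:
    """Alt-supporting reads over depth; 0 at zero depth."""
    if alt_reads < 0 or depth < 0 or alt_reads > depth:
        raise ValueError(f"invalid counts alt={alt_reads} depth={depth}")
    return 0.0 if depth == 0 else alt_reads / depth


@dataclass(frozen=True)
class MemberEvidence:
    """Read-count evidence for one trio member at one site."""

    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError("require 0 <= alt_reads <= depth")

    @property
    def vaf(self) -> float:
        return compute_vaf(self.alt_reads, self.depth)


@dataclass(frozen=True)
class TrioGenotypeEvidence:
    """Per-member depth/alt counts plus optional annotations for one site."""

    child: MemberEvidence
    father: MemberEvidence
    mother: MemberEvidence
    population_af: Optional[float] = None
    caller_quality: Optional[float] = None


@dataclass(frozen=True)
class FilterThresholds:
    """Published hard-filter thresholds; override per field if needed."""

    parent_min_depth: int = 10
    parent_max_vaf: float = 0.15
    parent_max_alt_reads: int = 3  # exclusive: alt reads must be < 3
    wes_max_af: float = 0.01
    wgs_max_af: float = 0.001
    wgs_min_quality: float = 15.0
    hq_min_depth: int = 10
    hq_min_child_vaf: float = 0.20
    hq_max_af: float = 0.0001


def inhouse_denovo_filter(
    evidence: TrioGenotypeEvidence,
    thresholds: FilterThresholds = FilterThresholds(),
) -> Tuple[bool, str]:
    """Rule-based de novo verdict; returns (pass, reason).

    Pass requires parental coverage >= 10 in both parents AND either no
    parental alternative reads at all, or both parents at VAF <= 15% with
    fewer than 3 alternative reads.  On failure the reason names the first
    violated clause.
    """
    t = thresholds
    f, m = evidence.father, evidence.mother
    if f.depth < t.parent_min_depth or m.depth < t.parent_min_depth:
        return False, "parental_coverage"
    if f.alt_reads == 0 and m.alt_reads == 0:
        return True, "no_parental_alt_reads"
    if f.vaf > t.parent_max_vaf or m.vaf > t.parent_max_vaf:
        return False, "parental_vaf"
    if f.alt_reads >= t.parent_max_alt_reads or m.alt_reads >= t.parent_max_alt_reads:
        return False, "parental_alt_reads"
    return True, "low_parental_support"


def population_af_prefilter(
    evidence: TrioGenotypeEvidence,
    mode: str,
    thresholds: FilterThresholds = FilterThresholds(),
) -> bool:
    """Population-frequency gate: WES AF < 1%; WGS AF < 0.1% and quality > 15."""
    af = evidence.population_af if evidence.population_af is not None else 0.0
    if mode == "WES":
        return af < thresholds.wes_max_af
    if mode == "WGS":
        quality = evidence.caller_quality
        if quality is None:
            return af < thresholds.wgs_max_af
        return af < thresholds.wgs_max_af and quality > thresholds.wgs_min_quality
    raise ValueError(f"mode must be WES or WGS, got {mode!r}")


def high_quality_filter(
    evidence: TrioGenotypeEvidence,
    thresholds: FilterThresholds = FilterThresholds(),
) -> bool:
    """High-quality DNM gate: trio depth >= 10, child VAF >= 20%, AF < 0.01%."""
    t = thresholds
    af = evidence.population_af if evidence.population_af is not None else 0.0
    min_depth = min(evidence.child.depth, evidence.father.depth,
                    evidence.mother.depth)
    return (
        min_depth >= t.hq_min_depth
        and evidence.child.vaf >= t.hq_min_child_vaf
        and af < t.hq_max_af
    )


def _supports_alt(slice_, ref: str, alt: str) -> bool:
    """Whether one read slice carries the alt allele at the window centre.

    Substitutions require every substituted base to match the alt;
    insertions require the inserted sequence after the variant position;
    deletions require gap symbols over the deleted reference span.
    """
    base_at: Dict[int, str] = {off: b for off, b, _ in slice_.bases}
    if len(ref) == len(alt):  # substitution / MNV
        return all(
            base_at.get(WINDOW_FLANK + i) == alt[i]
            for i in range(len(alt))
        )
    ins = slice_.insertion_map()
    if len(alt) > len(ref):  # insertion after the anchor base
        inserted = "".join(b for b, _ in ins.get(WINDOW_FLANK, ()))
        return inserted == alt[len(ref):]
    # deletion: ref positions after the anchor are gaps
    del_len = len(ref) - len(alt)
    return all(
        base_at.get(WINDOW_FLANK + 1 + i) == GAP for i in range(del_len)
    )


def evidence_from_window(
    window: TrioAlignmentWindow,
    population_af: Optional[float] = None,
    caller_quality: Optional[float] = None,
    min_mapping_quality: int = 1,
) -> TrioGenotypeEvidence:
    """Summarize a trio window into per-member depth / alt-read counts.

    Depth counts reads spanning the variant position with mapping quality
    >= ``min_mapping_quality``; alt reads are the subset whose aligned
    bases support the window's alt allele (CIGAR-consistent for indels).
    """
    ref, alt = window.ref_allele, window.alt_allele
    members = {}
    for role in ROLES:
        depth = 0
        alt_reads = 0
        for sl in window.member(role):
            if sl.mapping_quality < min_mapping_quality:
                continue
            covered = {off for off, _, _ in sl.bases}
            if WINDOW_FLANK not in covered:
                continue
            depth += 1
            if ref and alt and _supports_alt(sl, ref, alt):
                alt_reads += 1
        members[role] = MemberEvidence(depth=depth, alt_reads=alt_reads)
    return TrioGenotypeEvidence(
        child=members["child"],
        father=members["father"],
        mother=members["mother"],
        population_af=population_af,
        caller_quality=caller_quality,
    )
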