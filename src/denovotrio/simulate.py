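"""Synthetic trio read data with known inheritance truth.

The generator emulates the evidence a de novo caller sees: for one
variant site it draws reads per trio member at Poisson depth, injects the
alternative allele at a configurable allele fraction in the carriers
(child only for de novo sites; the carrier parent and the child for
inherited sites; a low-quality scatter across all members for artifact
sites), adds uniform per-base sequencing errors, and samples base and
mapping qualities from clipped normal distributions.

Default conditions model a well-covered short-read exome trio: ~30x per
member, 101 bp ungapped single-end reads, per-base error 1e-3 (Phred ~30
territory), base qualities ~N(38, 3) clipped to [2, 41], mapping
qualities ~N(58, 3) clipped to [0, 60], heterozygous carrier fraction
0.5.  Everything is driven by one integer seed and is fully reproducible.

Sites can stay in memory as :class:`~denovotrio.trio_io.TrioAlignmentWindow`
objects or be written as a valid indexed BAM + per-member VCF + reference
FASTA fixture set that round-trips through the extraction code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .trio_io import (
    GAP,
    ROLES,
    WINDOW_FLANK,
    WINDOW_LENGTH,
    AlignedReadSlice,
    TrioAlignmentWindow,
)

INHERITANCE_MODES = (
    "denovo",
    "inherited_father",
    "inherited_mother",
    "inherited_both",
    "artifact",
)

__all__ = [
    "SimParams",
    "SimulatedRead",
    "SimulatedSite",
    "INHERITANCE_MODES",
    "synthetic_reference",
    "simulate_site",
    "simulate_dataset",
    "write_fixture",
]


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated site."""

    depth_mean: float = 30.0
    read_length: int = 101
    base_error_rate: float = 0.001
    base_quality_mean: float = 38.0
    base_quality_sd: float = 3.0
    mapping_quality_mean: float = 58.0
    mapping_quality_sd: float = 3.0
    child_vaf: float = 0.5
    parent_vaf: float = 0.5
    artifact_vaf: float = 0.10
    artifact_base_quality: float = 12.0
    artifact_mapping_quality: float = 20.0
    inheritance: str = "denovo"
    variant_type: str = "substitution"
    indel_length: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "child_vaf", "parent_vaf", "artifact_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        if self.variant_type not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown variant type {self.variant_type!r}")
        if self.read_length < 2 * WINDOW_FLANK + 2:
            raise ValueError("read_length must exceed the variant window")


@dataclass(frozen=True)
class SimulatedRead:
    """One synthetic read with its alignment against the reference."""

    name: str
    start: int  # 0-based leftmost reference position
    sequence: str
    base_qualities: Tuple[int, ...]
    mapping_quality: int
    cigar: Tuple[Tuple[int, int], ...]  # pysam op codes: 0=M, 1=I, 2=D


@dataclass(frozen=True)
class SimulatedSite:
    """A simulated variant site: reads per member plus the truth label."""

    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    variant_type: str
    inheritance: str
    reads: Dict[str, Tuple[SimulatedRead, ...]]
    params: SimParams

    @property
    def is_denovo(self) -> bool:
        return self.inheritance == "denovo"

    @property
    def key(self) -> Tuple[str, int, str, str]:
        """(contig, 1-based position, ref, alt) — the VCF-style site key."""
        return (self.contig, self.position + 1, self.ref, self.alt)

    def window(self) -> TrioAlignmentWindow:
        slices = {
            role: tuple(
                s for s in (
                    _slice_from_sim_read(r, self.position - WINDOW_FLANK)
                    for r in sorted(self.reads[role], key=lambda r: (r.start, r.name))
                ) if s is not None
            )
            for role in ROLES
        }
        return TrioAlignmentWindow(
            contig=self.contig,
            variant_position=self.position,
            slices=slices,
            ref_allele=self.ref,
            alt_allele=self.alt,
        )


def synthetic_reference(length: int = 10_000, seed: int = 0) -> str:
    """Seeded random reference sequence over ACGT."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def _slice_from_sim_read(read: SimulatedRead, window_start: int) -> Optional[AlignedReadSlice]:
    """CIGAR walk of a simulated read, keeping in-window aligned bases."""
    window_end = window_start + WINDOW_LENGTH
    bases: List[Tuple[int, str, int]] = []
    insertions: Dict[int, List[Tuple[str, int]]] = {}
    rpos, qpos = read.start, 0
    last_offset: Optional[int] = None
    for op, length in read.cigar:
        if op == 0:  # match
            for _ in range(length):
                if window_start <= rpos < window_end:
                    last_offset = rpos - window_start
                    bases.append((last_offset, read.sequence[qpos],
                                  read.base_qualities[qpos]))
                else:
                    last_offset = None
                rpos += 1
                qpos += 1
        elif op == 1:  # insertion
            if last_offset is not None:
                for _ in range(length):
                    insertions.setdefault(last_offset, []).append(
                        (read.sequence[qpos], read.base_qualities[qpos]))
                    qpos += 1
            else:
                qpos += length
        elif op == 2:  # deletion
            for _ in range(length):
                if window_start <= rpos < window_end:
                    last_offset = rpos - window_start
                    bases.append((last_offset, GAP, 0))
                else:
                    last_offset = None
                rpos += 1
        else:  # pragma: no cover - generator emits only M/I/D
            raise ValueError(f"unsupported CIGAR op {op}")
    if not bases:
        return None
    return AlignedReadSlice(
        read_id=read.name,
        bases=tuple(bases),
        mapping_quality=read.mapping_quality,
        leftmost_position=read.start,
        insertions=tuple((k, tuple(v)) for k, v in sorted(insertions.items())),
    )


def _choose_alleles(reference: str, position: int, params: SimParams,
                    rng: np.random.Generator) -> Tuple[str, str]:
    ref_base = reference[position]
    if params.variant_type == "substitution":
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        return ref_base, str(alt)
    if params.variant_type == "insertion":
        ins = "".join(rng.choice(list("ACGT"), size=params.indel_length))
        return ref_base, ref_base + ins
    d = params.indel_length
    return reference[position:position + 1 + d], ref_base


def _make_read(reference: str, start: int, carries: bool, position: int,
               ref: str, alt: str, params: SimParams, name: str,
               rng: np.random.Generator, artifact_read: bool) -> SimulatedRead:
    L = params.read_length
    if not carries or len(ref) == len(alt):
        seq = list(reference[start:start + L])
        cigar: Tuple[Tuple[int, int], ...] = ((0, L),)
        if carries:  # substitution / MNV
            for i, alt_base in enumerate(alt):
                idx = position - start + i
                if 0 <= idx < L:
                    seq[idx] = alt_base
    elif len(alt) > len(ref):  # insertion after the anchor base
        ins = alt[len(ref):]
        head = position - start + 1
        seq = list(reference[start:start + head]) + list(ins)
        seq += list(reference[start + head:start + L - len(ins) + 0])
        seq = seq[:L]
        cigar = ((0, head), (1, len(ins)), (0, L - head - len(ins)))
    else:  # deletion after the anchor base
        d = len(ref) - len(alt)
        head = position - start + 1
        seq = list(reference[start:start + head])
        seq += list(reference[start + head + d:start + head + d + (L - head)])
        cigar = ((0, head), (2, d), (0, L - head))

    # sequencing errors and base qualities
    if artifact_read:
        bq_mean, mq = params.artifact_base_quality, int(params.artifact_mapping_quality)
    else:
        bq_mean = params.base_quality_mean
        mq = int(np.clip(round(rng.normal(params.mapping_quality_mean,
                                          params.mapping_quality_sd)), 0, 60))
    quals = np.clip(np.round(rng.normal(bq_mean, params.base_quality_sd,
                                        size=len(seq))), 2, 41).astype(int)
    errors = rng.random(len(seq)) < params.base_error_rate
    for i in np.flatnonzero(errors):
        seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
    return SimulatedRead(
        name=name,
        start=start,
        sequence="".join(seq),
        base_qualities=tuple(int(q) for q in quals),
        mapping_quality=mq,
        cigar=cigar,
    )


def _carrier_vaf(role: str, params: SimParams) -> float:
    mode = params.inheritance
    if mode == "artifact":
        return params.artifact_vaf
    if role == "child":
        return params.child_vaf if mode != "artifact" else params.artifact_vaf
    if role == "father" and mode in ("inherited_father", "inherited_both"):
        return params.parent_vaf
    if role == "mother" and mode in ("inherited_mother", "inherited_both"):
        return params.parent_vaf
    return 0.0


def simulate_site(
    params: SimParams,
    reference: Optional[str] = None,
    position: Optional[int] = None,
    contig: str = "chrS",
    rng: Optional[np.random.Generator] = None,
    read_prefix: str = "read",
) -> SimulatedSite:
    """Simulate one variant site for a whole trio.

    Per member the read count is Poisson(depth_mean); every read spans the
    variant position (reads are placed uniformly with a small margin so the
    full variant allele fits).  Carrier status per read is Bernoulli at the
    member's allele fraction.  Returns the reads plus the truth label
    (de novo iff the inheritance mode is ``denovo``).
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if reference is None:
        reference = synthetic_reference(seed=params.rng_seed)
    if position is None:
        position = len(reference) // 2
    ref, alt = _choose_alleles(reference, position, params, rng)
    margin = max(WINDOW_FLANK + 1, len(ref) + 1, len(alt) + 1)
    lo = max(0, position - params.read_length + margin)
    hi = min(len(reference) - params.read_length, position - margin + 1)
    if hi < lo:
        raise ValueError("reference too short for the requested read placement")
    reads: Dict[str, Tuple[SimulatedRead, ...]] = {}
    for role in ROLES:
        n = int(rng.poisson(params.depth_mean))
        vaf = _carrier_vaf(role, params)
        member_reads = []
        for i in range(n):
            start = int(rng.integers(lo, hi + 1))
            carries = bool(rng.random() < vaf)
            artifact_read = carries and params.inheritance == "artifact"
            member_reads.append(_make_read(
                reference, start, carries, position, ref, alt, params,
                name=f"{read_prefix}_{role}_{i}", rng=rng,
                artifact_read=artifact_read,
            ))
        reads[role] = tuple(member_reads)
    return SimulatedSite(
        contig=contig,
        position=position,
        ref=ref,
        alt=alt,
        variant_type=params.variant_type,
        inheritance=params.inheritance,
        reads=reads,
        params=params,
    )


def simulate_dataset(
    n_sites: int,
    class_mix: Dict[str, float],
    base_params: SimParams = SimParams(),
    seed: int = 0,
    reference_length: int = 200_000,
    type_mix: Optional[Dict[str, float]] = None,
    contig: str = "chrS",
) -> Tuple[List[SimulatedSite], str]:
    """Simulate a labelled multi-site dataset on one synthetic reference.

    ``class_mix`` maps inheritance modes to fractions summing to 1; per-class
    counts are the rounded fractions of ``n_sites`` (largest remainder).
    Site positions are evenly spaced so windows never overlap.  Returns the
    site list and the reference sequence (for writing fixtures).
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class mix fractions must sum to 1, got {total}")
    if type_mix is None:
        type_mix = {"substitution": 1.0}
    rng = np.random.default_rng(seed)
    reference = synthetic_reference(length=reference_length, seed=seed)

    # largest-remainder apportionment of per-class counts
    modes = sorted(class_mix)
    raw = {m: class_mix[m] * n_sites for m in modes}
    counts = {m: int(np.floor(raw[m])) for m in modes}
    short = n_sites - sum(counts.values())
    for m in sorted(modes, key=lambda m: raw[m] - counts[m], reverse=True)[:short]:
        counts[m] += 1
    labels = [m for m in modes for _ in range(counts[m])]
    rng.shuffle(labels)

    vtypes = sorted(type_mix)
    vprobs = np.array([type_mix[v] for v in vtypes], dtype=float)
    vprobs = vprobs / vprobs.sum()

    spacing = (reference_length - 2 * base_params.read_length) // n_sites
    if spacing < 2 * WINDOW_FLANK + 10:
        raise ValueError("reference too short for this many non-overlapping sites")
    sites = []
    for i, mode in enumerate(labels):
        position = base_params.read_length + i * spacing + int(rng.integers(0, 10))
        vt = str(rng.choice(vtypes, p=vprobs))
        params = replace(base_params, inheritance=mode, variant_type=vt)
        sites.append(simulate_site(
            params, reference=reference, position=position, contig=contig,
            rng=rng, read_prefix=f"s{i}",
        ))
    return sites, reference


def write_fixture(
    sites: Sequence[SimulatedSite],
    reference: str,
    outdir,
    contig: str = "chrS",
) -> Dict[str, Dict[str, str]]:
    """Write reference FASTA, per-member sorted+indexed BAM and VCF, manifest.

    Each member's VCF contains the sites whose variant that member carries
    (child: de novo, inherited and artifact calls; parents: the sites they
    transmit).  Returns a trio config mapping suitable for ``load_trio``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i:i + 70] + "\n")
    pysam.faidx(str(fasta_path))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": len(reference)}],
    }
    config: Dict[str, Dict[str, str]] = {}
    manifest = []
    for role in ROLES:
        bam_path = outdir / f"{role}.bam"
        all_reads = sorted(
            (r for site in sites for r in site.reads[role]),
            key=lambda r: (r.start, r.name),
        )
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
            for read in all_reads:
                seg = pysam.AlignedSegment(bam.header)
                seg.query_name = read.name
                seg.query_sequence = read.sequence
                seg.flag = 0
                seg.reference_id = 0
                seg.reference_start = read.start
                seg.mapping_quality = read.mapping_quality
                seg.cigar = list(read.cigar)
                seg.query_qualities = list(read.base_qualities)
                bam.write(seg)
        pysam.index(str(bam_path))

        vcf_path = outdir / f"{role}.vcf"
        _write_vcf(vcf_path, contig, len(reference),
                   [s for s in sites if _member_carries(s, role)])
        config[role] = {"alignment": str(bam_path), "variants": str(vcf_path)}

    for site in sites:
        manifest.append({
            "contig": site.contig, "position": site.position + 1,
            "ref": site.ref, "alt": site.alt,
            "variant_type": site.variant_type,
            "inheritance": site.inheritance,
            "is_denovo": site.is_denovo,
        })
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return config


def _member_carries(site: SimulatedSite, role: str) -> bool:
    return _carrier_vaf(role, site.params) > 0.0


def _write_vcf(path, contig: str, contig_length: int,
               sites: Sequence[SimulatedSite]) -> None:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample("sample")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for site in sorted(sites, key=lambda s: s.position):
            rec = vcf.new_record(
                contig=contig, start=site.position,
                alleles=(site.ref, site.alt),
            )
            rec.samples["sample"]["GT"] = (0, 1)
            vcf.write(rec)
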