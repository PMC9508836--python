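"""Trio alignment/variant file handling and windowed read extraction.

A trio consists of a child, father and mother, each with one indexed
BAM/CRAM alignment file and one VCF.  For a candidate variant site the
relevant evidence is the set of reads from each member overlapping the
41-position reference window centred on the variant (20 positions either
side).  Each overlapping read is reduced to an :class:`AlignedReadSlice`:
its reference-aligned bases inside the window (with per-base Phred
qualities, deletions as gap symbols, and insertions recorded separately),
plus its mapping quality.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted on read.  Duplicate, secondary, supplementary and QC-fail reads
are excluded, as in standard pileup practice.  Soft-clipped bases are not
aligned to reference positions and are ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

logger = logging.getLogger(__name__)

WINDOW_FLANK = 20
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1  # 41 reference positions

GAP = "-"
ROLES = ("child", "father", "mother")

__all__ = [
    "TrioSample",
    "AlignedReadSlice",
    "TrioAlignmentWindow",
    "TrioIOError",
    "ContigDialectWarning",
    "load_trio",
    "extract_trio_window",
    "WINDOW_FLANK",
    "WINDOW_LENGTH",
    "GAP",
    "ROLES",
]


class TrioIOError(Exception):
    """Raised for missing files, missing indexes, or malformed trio configs."""


class ContigDialectWarning(UserWarning):
    """Emitted when trio members mix 'chr'-prefixed and bare contig names."""


@dataclass(frozen=True)
class TrioSample:
    """One trio member: role plus paths to its alignment and variant files."""

    role: str
    alignment_path: Path
    variants_path: Path
    reference_path: Optional[Path] = None  # needed to decode CRAM

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TrioIOError(f"unknown trio role {self.role!r}")

    def open_alignment(self) -> pysam.AlignmentFile:
        kwargs = {}
        if self.reference_path is not None:
            kwargs["reference_filename"] = str(self.reference_path)
        return pysam.AlignmentFile(str(self.alignment_path), **kwargs)

    def open_variants(self) -> pysam.VariantFile:
        return pysam.VariantFile(str(self.variants_path))


@dataclass(frozen=True)
class AlignedReadSlice:
    """One read's evidence inside a variant window.

    ``bases`` holds (window_offset, base, base_quality) triples for the
    reference-aligned part of the read, offsets strictly increasing in
    0..40; deleted reference positions carry the gap symbol with quality 0.
    ``insertions`` maps a window offset to the bases inserted immediately
    after that reference position (read-only context for indel rendering).
    """

    read_id: str
    bases: Tuple[Tuple[int, str, int], ...]
    mapping_quality: int
    leftmost_position: int
    insertions: Tuple[Tuple[int, Tuple[Tuple[str, int], ...]], ...] = ()

    def __post_init__(self) -> None:
        offsets = [b[0] for b in self.bases]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("window offsets must be strictly increasing")
        for off, base, bq in self.bases:
            if not 0 <= off < WINDOW_LENGTH:
                raise ValueError(f"window offset {off} out of [0, {WINDOW_LENGTH})")
            if base not in "ACGTN" and base != GAP:
                raise ValueError(f"invalid base symbol {base!r}")
            if bq < 0:
                raise ValueError("negative base quality")

    def insertion_map(self) -> Dict[int, Tuple[Tuple[str, int], ...]]:
        return dict(self.insertions)


@dataclass(frozen=True)
class TrioAlignmentWindow:
    """All trio reads overlapping the 41-position window around one site."""

    contig: str
    variant_position: int  # 0-based
    slices: Dict[str, Tuple[AlignedReadSlice, ...]] = field(default_factory=dict)
    ref_allele: str = ""
    alt_allele: str = ""

    @property
    def window_start(self) -> int:
        return self.variant_position - WINDOW_FLANK

    @property
    def window_length(self) -> int:
        return WINDOW_LENGTH

    def member(self, role: str) -> Tuple[AlignedReadSlice, ...]:
        return self.slices.get(role, ())


def _contig_dialect(names: Sequence[str]) -> str:
    return "chr" if any(str(n).startswith("chr") for n in names) else "bare"


def harmonize_contig(contig: str, target_dialect: str) -> str:
    """Translate a contig name between 'chr1' and '1' dialects."""
    has_prefix = contig.startswith("chr")
    if target_dialect == "chr" and not has_prefix:
        return "chr" + contig
    if target_dialect == "bare" and has_prefix:
        return contig[3:]
    return contig


def load_trio(
    config: Dict[str, Dict[str, str]],
    reference_path: Optional[str] = None,
) -> Tuple[TrioSample, TrioSample, TrioSample]:
    """Validate a trio description and return (child, father, mother) handles.

    ``config`` maps each role to ``{"alignment": path, "variants": path}``.
    Checks that every file exists, alignments are indexed, VCFs parse, no
    role is duplicated or missing, and the contig naming dialect agrees
    across members (a mismatch is harmonized with a warning).
    """
    seen = set()
    for role in config:
        if role in seen:
            raise TrioIOError(f"role {role!r} duplicated in trio config")
        seen.add(role)
    missing = set(ROLES) - set(config)
    if missing:
        raise TrioIOError(f"trio config missing roles: {sorted(missing)}")

    samples = []
    dialects = {}
    for role in ROLES:
        entry = config[role]
        aln = Path(entry["alignment"])
        vcf = Path(entry["variants"])
        for path, kind in ((aln, "alignment"), (vcf, "variants")):
            if not path.exists():
                raise TrioIOError(f"missing file: {role} {kind} {path}")
        sample = TrioSample(
            role=role,
            alignment_path=aln,
            variants_path=vcf,
            reference_path=Path(reference_path) if reference_path else None,
        )
        try:
            with sample.open_alignment() as af:
                if not af.has_index():
                    raise TrioIOError(f"{role} alignment {aln} has no index")
                dialects[role] = _contig_dialect(af.references)
        except (OSError, ValueError) as exc:
            raise TrioIOError(f"cannot open {role} alignment {aln}: {exc}") from exc
        try:
            with sample.open_variants():
                pass
        except (OSError, ValueError) as exc:
            raise TrioIOError(f"cannot parse {role} VCF {vcf}: {exc}") from exc
        samples.append(sample)

    if len(set(dialects.values())) > 1:
        warnings.warn(
            f"contig naming dialect differs across trio members ({dialects}); "
            "contig names will be harmonized per member on extraction",
            ContigDialectWarning,
            stacklevel=2,
        )
    return tuple(samples)  # type: ignore[return-value]


def _slice_from_read(
    read: pysam.AlignedSegment, window_start: int
) -> Optional[AlignedReadSlice]:
    """Walk one read's alignment and keep the in-window aligned bases."""
    seq = read.query_sequence
    quals = read.query_qualities
    if seq is None:
        return None
    window_end = window_start + WINDOW_LENGTH
    bases: List[Tuple[int, str, int]] = []
    insertions: Dict[int, List[Tuple[str, int]]] = {}
    last_ref_offset: Optional[int] = None
    # matches_only=False keeps insertion (ref None) and deletion (query None)
    # columns; soft clips appear with ref None before any match and are
    # dropped because no in-window anchor precedes them.
    pairs = read.get_aligned_pairs(matches_only=False)
    soft = set()
    qpos_cursor = 0
    for op, length in read.cigartuples or []:
        if op == 4:  # soft clip
            soft.update(range(qpos_cursor, qpos_cursor + length))
        if op in (0, 1, 4, 7, 8):  # ops consuming query
            qpos_cursor += length
    for qpos, rpos in pairs:
        if rpos is not None:
            if window_start <= rpos < window_end:
                offset = rpos - window_start
                if qpos is None:
                    bases.append((offset, GAP, 0))
                else:
                    bases.append((offset, seq[qpos].upper(), int(quals[qpos]) if quals is not None else 0))
                last_ref_offset = offset
            else:
                last_ref_offset = None
        else:
            if qpos is None or qpos in soft:
                continue
            if last_ref_offset is not None:
                insertions.setdefault(last_ref_offset, []).append(
                    (seq[qpos].upper(), int(quals[qpos]) if quals is not None else 0)
                )
    if not bases:
        return None
    return AlignedReadSlice(
        read_id=read.query_name or "",
        bases=tuple(bases),
        mapping_quality=int(read.mapping_quality),
        leftmost_position=int(read.reference_start),
        insertions=tuple((k, tuple(v)) for k, v in sorted(insertions.items())),
    )


def extract_trio_window(
    trio: Sequence[TrioSample],
    contig: str,
    position: int,
    ref: str = "",
    alt: str = "",
) -> TrioAlignmentWindow:
    """Extract the per-member read slices for the window around ``position``.

    ``position`` is 0-based.  Every primary, mapped, non-duplicate read
    overlapping ``[position-20, position+21)`` contributes one slice; the
    slices are sorted by (leftmost alignment position, read id) so that
    extraction — and hence downstream image encoding — is deterministic.

    Raises :class:`TrioIOError` naming the member if the contig is absent
    from that member's alignment file (after dialect harmonization).
    """
    window_start = position - WINDOW_FLANK
    slices: Dict[str, Tuple[AlignedReadSlice, ...]] = {}
    for sample in trio:
        with sample.open_alignment() as af:
            dialect = _contig_dialect(af.references)
            local_contig = harmonize_contig(contig, dialect)
            if local_contig not in af.references:
                raise TrioIOError(
                    f"contig {contig!r} absent from {sample.role} alignment "
                    f"{sample.alignment_path}"
                )
            fetched = []
            for read in af.fetch(local_contig, max(0, window_start), window_start + WINDOW_LENGTH):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.is_qcfail
                    or read.query_length == 0
                ):
                    continue
                sl = _slice_from_read(read, window_start)
                if sl is not None:
                    fetched.append(sl)
            fetched.sort(key=lambda s: (s.leftmost_position, s.read_id))
            slices[sample.role] = tuple(fetched)
    return TrioAlignmentWindow(
        contig=contig,
        variant_position=position,
        slices=slices,
        ref_allele=ref,
        alt_allele=alt,
    )
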