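"""Candidate DNM generation by allele-aware subtraction of parental variants.

Stage one of prediction: every child variant whose (contig, position, ref,
alt) key — after splitting multiallelic records and trimming shared
allele prefix/suffix bases — is present in neither parent's VCF becomes a
candidate, mirroring ``bcftools isec -C child father mother``.  Parental
genotype fields are deliberately ignored at this stage; evidence-level
checks happen later in the classifier or rule-based filters.

Variant-type routing is by allele length: equal lengths are substitutions
(including multi-nucleotide variants), longer alt is an insertion,
shorter alt a deletion; complex unequal-length indels route by net length
change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

import pysam

logger = logging.getLogger(__name__)

VARIANT_TYPES = ("substitution", "insertion", "deletion")

__all__ = [
    "VariantCandidate",
    "classify_variant_type",
    "normalize_alleles",
    "read_vcf_keys",
    "subtract_inherited",
    "write_candidates_tsv",
]

_ACGT = set("ACGT")


@dataclass(frozen=True, order=True)
class VariantCandidate:
    """One normalized biallelic child variant surviving parental subtraction."""

    contig: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str
    variant_type: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (_bare_contig(self.contig), self.position, self.ref, self.alt)


def _bare_contig(contig: str) -> str:
    return contig[3:] if contig.startswith("chr") else contig


def classify_variant_type(ref: str, alt: str) -> str:
    """Route an allele pair to substitution / insertion / deletion."""
    if not ref or not alt:
        raise ValueError("empty allele")
    if set(ref) - _ACGT or set(alt) - _ACGT:
        raise ValueError(f"non-ACGT allele: {ref}>{alt}")
    if len(ref) == len(alt):
        return "substitution"
    return "insertion" if len(alt) > len(ref) else "deletion"


def normalize_alleles(position: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Trim shared suffix then prefix bases, keeping at least one base each.

    Position is 1-based and advances past trimmed prefix bases.  This is
    parsimony-style normalization without reference-guided left-shifting,
    which suffices for allele-aware key matching of records produced by a
    single caller per trio.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def read_vcf_keys(path) -> Set[Tuple[str, int, str, str]]:
    """All normalized (contig, pos, ref, alt) keys in a VCF, multiallelics split."""
    keys: Set[Tuple[str, int, str, str]] = set()
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            for alt in record.alts or ():
                try:
                    if alt is None or set(alt.upper()) - _ACGT:
                        raise ValueError("symbolic or non-ACGT alt")
                    pos, ref, a = normalize_alleles(record.pos, record.ref, alt)
                    keys.add((_bare_contig(record.contig), pos, ref, a))
                except (ValueError, TypeError):
                    skipped += 1
    if skipped:
        logger.warning("skipped %d unparseable/symbolic records in %s", skipped, path)
    return keys


def subtract_inherited(child_vcf, father_vcf, mother_vcf) -> List[VariantCandidate]:
    """Child variants present in neither parent, (contig, position)-sorted.

    Matching is allele-aware on the full normalized key, so a child A>G at
    a position where a parent carries A>T still yields a candidate.
    """
    parental = read_vcf_keys(father_vcf) | read_vcf_keys(mother_vcf)
    out: List[VariantCandidate] = []
    seen: Set[Tuple[str, int, str, str]] = set()
    with pysam.VariantFile(str(child_vcf)) as vcf:
        for record in vcf:
            for alt in record.alts or ():
                try:
                    if alt is None or set(alt.upper()) - _ACGT:
                        raise ValueError("symbolic or non-ACGT alt")
                    pos, ref, a = normalize_alleles(record.pos, record.ref, alt)
                except (ValueError, TypeError):
                    logger.warning("skipping unparseable child record at %s:%s",
                                   record.contig, record.pos)
                    continue
                key = (_bare_contig(record.contig), pos, ref, a)
                if key in parental or key in seen:
                    continue
                seen.add(key)
                out.append(VariantCandidate(
                    contig=record.contig,
                    position=pos,
                    ref=ref,
                    alt=a,
                    variant_type=classify_variant_type(ref, a),
                ))
    out.sort(key=lambda c: (c.key[0], c.position, c.ref, c.alt))
    return out


def write_candidates_tsv(candidates: Iterable[VariantCandidate], path) -> None:
    import pandas as pd

    rows = [
        {"contig": c.contig, "position": c.position, "ref": c.ref,
         "alt": c.alt, "variant_type": c.variant_type}
        for c in candidates
    ]
    pd.DataFrame(rows, columns=["contig", "position", "ref", "alt",
                                "variant_type"]).to_csv(path, sep="\t", index=False)
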