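"""Training-time augmentation of trio windows and encoded images.

Four operators mirror the variability a DNM classifier must tolerate:
random brightness scaling (factor in [0.3, 1], global across channels),
read-row shuffling, coverage downsampling (random read discard), and
on-the-fly synthesis of multi-nucleotide variants by writing a second,
consistent substitution into the reads adjacent to an existing one.

Brightness and shuffling act on encoded image tensors; downsampling and
MNV synthesis act on windows before encoding so base/mapping qualities
stay realistic.  All operators are deterministic under a seeded
``numpy.random.Generator`` and preserve tensor shape, value range and the
one-hot column structure.  Augmentation is a training-only concern;
inference never applies it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple, Union

import numpy as np

from .trio_io import (
    GAP,
    ROLES,
    WINDOW_FLANK,
    WINDOW_LENGTH,
    AlignedReadSlice,
    TrioAlignmentWindow,
)

__all__ = [
    "AugmentPolicy",
    "random_brightness",
    "shuffle_reads",
    "downsample_coverage",
    "synthesize_mnv",
    "augment_image",
]

BRIGHTNESS_RANGE = (0.3, 1.0)


@dataclass(frozen=True)
class AugmentPolicy:
    """Which augmentations to apply during training, and how often."""

    brightness_range: Tuple[float, float] = BRIGHTNESS_RANGE
    shuffle_reads: bool = True
    coverage_downsample: bool = True
    min_keep_fraction: float = 0.5
    mnv_synthesis_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.brightness_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("brightness range must satisfy 0 < lo <= hi <= 1")
        if not 0.0 <= self.mnv_synthesis_rate <= 1.0:
            raise ValueError("mnv_synthesis_rate must be in [0, 1]")


def random_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale all pixel intensities by ``factor`` (half-up rounding).

    Zeros stay zero, so the one-hot structure is untouched; factor 1 is
    the identity.
    """
    lo, hi = BRIGHTNESS_RANGE
    if not lo <= factor <= hi:
        raise ValueError(f"brightness factor {factor} outside [{lo}, {hi}]")
    scaled = np.floor(image.astype(np.float64) * factor + 0.5)
    return scaled.astype(image.dtype)


def shuffle_reads(
    item: Union[np.ndarray, TrioAlignmentWindow],
    rng: np.random.Generator,
) -> Union[np.ndarray, TrioAlignmentWindow]:
    """Randomly permute read order.

    On a window, each member's slice tuple is permuted.  On an encoded
    image, the read rows of each channel are permuted independently (rows
    of different channels belong to different individuals' reads, so there
    is no cross-channel pairing to maintain).  The multiset of rows per
    channel is preserved.
    """
    if isinstance(item, TrioAlignmentWindow):
        slices = {}
        for role in ROLES:
            member = list(item.member(role))
            perm = rng.permutation(len(member))
            slices[role] = tuple(member[i] for i in perm)
        return replace(item, slices=slices)
    image = item.copy()
    for ch in range(image.shape[2]):
        perm = rng.permutation(image.shape[0])
        image[:, :, ch] = image[perm, :, ch]
    return image


def downsample_coverage(
    window: TrioAlignmentWindow,
    keep_fraction: float,
    rng: np.random.Generator,
) -> TrioAlignmentWindow:
    """Discard a random subset of reads per member, keeping at least one.

    ``keep_fraction`` in (0, 1]; surviving reads keep their original
    relative order.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    slices = {}
    for role in ROLES:
        member = list(window.member(role))
        if not member or keep_fraction == 1.0:
            slices[role] = tuple(member)
            continue
        n_keep = max(1, int(round(len(member) * keep_fraction)))
        chosen = sorted(rng.choice(len(member), size=n_keep, replace=False))
        slices[role] = tuple(member[i] for i in chosen)
    return replace(window, slices=slices)


def _with_base(slice_: AlignedReadSlice, offset: int, new_base: str) -> AlignedReadSlice:
    bases = tuple(
        (off, new_base if off == offset else b, bq) for off, b, bq in slice_.bases
    )
    return replace(slice_, bases=bases)


def synthesize_mnv(
    window: TrioAlignmentWindow,
    rng: np.random.Generator,
) -> TrioAlignmentWindow:
    """Write a second substitution adjacent to an existing one.

    Every read that carries the alt allele at the variant position — in
    whichever members carry it, so the inheritance pattern and hence the
    training label are preserved — additionally receives one consistent
    substituted base at the neighbouring window offset.  Reads without the
    alt allele are untouched.  Only substitution windows are eligible.
    """
    ref, alt = window.ref_allele, window.alt_allele
    if not ref or not alt or len(ref) != len(alt):
        raise ValueError("MNV synthesis requires a substitution window")
    target = WINDOW_FLANK + len(alt)
    if target >= WINDOW_LENGTH:
        target = WINDOW_FLANK - 1
    if target < 0:
        raise ValueError("no free adjacent offset for MNV synthesis")

    # consensus base currently at the target offset, to substitute away from
    counts: dict = {}
    for role in ROLES:
        for sl in window.member(role):
            for off, b, _ in sl.bases:
                if off == target and b != GAP:
                    counts[b] = counts.get(b, 0) + 1
    if not counts:
        return window
    current = max(sorted(counts), key=lambda b: counts[b])
    choices = [b for b in "ACGT" if b != current]
    new_base = str(choices[int(rng.integers(len(choices)))])

    slices = {}
    for role in ROLES:
        out = []
        for sl in window.member(role):
            base_at = {off: b for off, b, _ in sl.bases}
            if base_at.get(WINDOW_FLANK) == alt[0]:
                out.append(_with_base(sl, target, new_base))
            else:
                out.append(sl)
        slices[role] = tuple(out)
    return replace(window, slices=slices)


def augment_image(
    image: np.ndarray,
    policy: AugmentPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the image-level augmentations of ``policy`` to one tensor."""
    out = image
    lo, hi = policy.brightness_range
    factor = float(rng.uniform(lo, hi))
    out = random_brightness(out, factor)
    if policy.shuffle_reads:
        out = shuffle_reads(out, rng)
    return out
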