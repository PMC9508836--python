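"""Encoding of trio read windows as fixed-size RGB intensity images.

Each candidate site becomes a 160x164x3 uint8 tensor.  Rows are reads
(capped at 160, deterministic order), columns come in 41 blocks of 4
pixels — one genomic position per block, one-hot over (A, C, T, G) — and
the three channels hold child, father and mother reads respectively.  The
variant's first base sits in block 20, the window centre.

Pixel intensity scales with base and mapping quality, saturating at 255:

    intensity = round(255 * min(1, bq/bq_cap) * min(1, mq/mq_cap))

with caps defaulting to Phred 40 (base) and 60 (mapping), common Illumina
maxima.  Rounding is half-up.

Indel rendering uses read coordinates anchored at the variant: the read
base aligned to the variant position always lands in block 20; inserted
bases consume the following blocks (a visible frameshift relative to
non-carrier reads), and deleted reference positions appear as all-zero
blocks inside the read's span.  Reads that do not cover the variant are
anchored by the reference offset of their leftmost in-window base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .trio_io import GAP, ROLES, WINDOW_FLANK, WINDOW_LENGTH, AlignedReadSlice, TrioAlignmentWindow

IMAGE_ROWS = 160
BASE_BLOCK = 4
IMAGE_COLS = WINDOW_LENGTH * BASE_BLOCK  # 164
IMAGE_CHANNELS = 3
VARIANT_BLOCK = WINDOW_FLANK  # block index 20

# Column order inside a base block.
BASE_ORDER = {"A": 0, "C": 1, "T": 2, "G": 3}

__all__ = [
    "IMAGE_ROWS",
    "IMAGE_COLS",
    "IMAGE_CHANNELS",
    "BASE_BLOCK",
    "VARIANT_BLOCK",
    "BASE_ORDER",
    "IntensityModel",
    "EncodedVariantImage",
    "intensity",
    "encode_member",
    "encode_trio",
    "export_png",
    "import_png",
]


@dataclass(frozen=True)
class IntensityModel:
    """Quality-to-intensity mapping parameters."""

    base_quality_cap: int = 40
    mapping_quality_cap: int = 60
    max_intensity: int = 255

    def __post_init__(self) -> None:
        if self.base_quality_cap <= 0 or self.mapping_quality_cap <= 0:
            raise ValueError("quality caps must be strictly positive")
        if self.max_intensity != 255:
            raise ValueError("max_intensity is fixed at 255")


@dataclass(frozen=True)
class EncodedVariantImage:
    """The 160x164x3 tensor plus site metadata."""

    tensor: np.ndarray
    contig: str = ""
    variant_position: int = -1
    variant_type: str = ""

    def __post_init__(self) -> None:
        t = self.tensor
        if t.shape != (IMAGE_ROWS, IMAGE_COLS, IMAGE_CHANNELS):
            raise ValueError(f"tensor shape {t.shape} != "
                             f"({IMAGE_ROWS}, {IMAGE_COLS}, {IMAGE_CHANNELS})")
        if t.dtype != np.uint8:
            raise ValueError("tensor must be uint8")


def intensity(base_quality: float, mapping_quality: float,
              model: IntensityModel = IntensityModel()) -> int:
    """Map one (base quality, mapping quality) pair to a pixel value 0..255."""
    if base_quality < 0 or mapping_quality < 0:
        raise ValueError("qualities must be non-negative")
    bq = min(1.0, base_quality / model.base_quality_cap)
    mq = min(1.0, mapping_quality / model.mapping_quality_cap)
    # half-up rounding (numpy/python round are half-even)
    return int(np.floor(model.max_intensity * bq * mq + 0.5))


def _raster(slice_: AlignedReadSlice):
    """Flatten a read slice to read-coordinate (base, bq) steps + anchor block.

    Deletions occupy a step with the gap symbol; insertions append their
    bases right after the reference position they follow.  The anchor is
    chosen so the base aligned to the variant position maps to block 20.
    """
    steps = []
    variant_idx: Optional[int] = None
    ins = slice_.insertion_map()
    for offset, base, bq in slice_.bases:
        if offset == WINDOW_FLANK:
            variant_idx = len(steps)
        steps.append((base, bq))
        if offset in ins:
            steps.extend(ins[offset])
    if variant_idx is not None:
        start_block = WINDOW_FLANK - variant_idx
    else:
        start_block = slice_.bases[0][0]
    return steps, start_block


def encode_member(slices: Sequence[AlignedReadSlice],
                  model: IntensityModel = IntensityModel()) -> np.ndarray:
    """Encode one member's read slices as a 160x164 uint8 matrix.

    Row i holds slice i; reads beyond 160 are dropped (slices arrive in
    the deterministic extraction order).  A base at raster block k lights
    exactly one of columns [4k, 4k+4) per the (A, C, T, G) one-hot layout;
    gaps and N bases light nothing.
    """
    matrix = np.zeros((IMAGE_ROWS, IMAGE_COLS), dtype=np.uint8)
    for row, sl in enumerate(slices[:IMAGE_ROWS]):
        steps, start_block = _raster(sl)
        for k, (base, bq) in enumerate(steps):
            block = start_block + k
            if not 0 <= block < WINDOW_LENGTH:
                continue
            channel = BASE_ORDER.get(base)
            if channel is None:  # gap or N
                continue
            matrix[row, BASE_BLOCK * block + channel] = intensity(
                bq, sl.mapping_quality, model
            )
    return matrix


def encode_trio(window: TrioAlignmentWindow,
                model: IntensityModel = IntensityModel(),
                variant_type: str = "") -> EncodedVariantImage:
    """Encode a trio window; channels 0/1/2 are child/father/mother."""
    tensor = np.zeros((IMAGE_ROWS, IMAGE_COLS, IMAGE_CHANNELS), dtype=np.uint8)
    for channel, role in enumerate(ROLES):
        tensor[:, :, channel] = encode_member(window.member(role), model)
    return EncodedVariantImage(
        tensor=tensor,
        contig=window.contig,
        variant_position=window.variant_position,
        variant_type=variant_type,
    )


def export_png(image: EncodedVariantImage, path) -> None:
    """Write the tensor losslessly as an RGB PNG (debug visualization)."""
    from PIL import Image

    Image.fromarray(image.tensor, mode="RGB").save(str(path), format="PNG")


def import_png(path) -> np.ndarray:
    """Read back a PNG written by :func:`export_png` as a uint8 tensor."""
    from PIL import Image

    with Image.open(str(path)) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)
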