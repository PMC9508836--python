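"""Pileup-image encoding: geometry, one-hot structure, intensity mapping."""

import numpy as np
import pytest

from denovotrio import simulate
from denovotrio.encoder import (
    BASE_BLOCK,
    BASE_ORDER,
    IMAGE_CHANNELS,
    IMAGE_COLS,
    IMAGE_ROWS,
    VARIANT_BLOCK,
    EncodedVariantImage,
    IntensityModel,
    encode_member,
    encode_trio,
    export_png,
    import_png,
    intensity,
)
from denovotrio.trio_io import GAP, WINDOW_LENGTH, AlignedReadSlice, TrioAlignmentWindow


def make_slice(bases, mq=60, read_id="r0", left=0, insertions=()):
    return AlignedReadSlice(read_id=read_id, bases=tuple(bases),
                            mapping_quality=mq, leftmost_position=left,
                            insertions=tuple(insertions))


class TestIntensity:
    @pytest.mark.parametrize("bq,mq,expected", [
        (40, 60, 255),   # saturation at both caps
        (0, 60, 0),
        (20, 30, 64),    # round(255 * 0.5 * 0.5)
        (80, 120, 255),  # above caps still saturates
    ])
    def test_values(self, bq, mq, expected):
        assert intensity(bq, mq) == expected

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            intensity(-1, 60)

    def test_monotone_in_both_arguments(self):
        grid = range(0, 80, 4)
        for mq in grid:
            values = [intensity(bq, mq) for bq in grid]
            assert values == sorted(values)
        for bq in grid:
            values = [intensity(bq, mq) for mq in grid]
            assert values == sorted(values)

    def test_invalid_caps_rejected(self):
        with pytest.raises(ValueError):
            IntensityModel(base_quality_cap=0)


class TestEncodeMember:
    def test_empty_slice_list_all_zero(self):
        assert not encode_member([]).any()

    def test_uniform_read_lights_one_pixel_per_block(self):
        sl = make_slice([(k, "A", 40) for k in range(41)], mq=60)
        matrix = encode_member([sl])
        expected_cols = [4 * k for k in range(41)]
        assert list(np.flatnonzero(matrix[0])) == expected_cols
        assert all(matrix[0, c] == 255 for c in expected_cols)
        assert not matrix[1:].any()

    def test_read_cap_at_160_rows(self):
        slices = [make_slice([(k, "C", 40) for k in range(41)], read_id=f"r{i}")
                  for i in range(500)]
        matrix = encode_member(slices)
        assert int((matrix.any(axis=1)).sum()) == IMAGE_ROWS

    def test_gap_and_n_light_nothing(self):
        sl = make_slice([(0, "A", 40), (1, GAP, 0), (2, "N", 40)])
        matrix = encode_member([sl])
        assert matrix[0, 0] > 0
        assert not matrix[0, 4:12].any()

    def test_deletion_leaves_zero_block_inside_span(self):
        # read with a 2-base deletion at offsets 21-22
        bases = [(k, "A", 40) for k in range(21)]
        bases += [(21, GAP, 0), (22, GAP, 0)]
        bases += [(k, "A", 40) for k in range(23, 41)]
        matrix = encode_member([make_slice(bases)])
        assert not matrix[0, 4 * 21:4 * 23].any()
        assert matrix[0, 4 * 23 + BASE_ORDER["A"]] > 0

    def test_insertion_frameshifts_following_bases(self):
        # 'TT' inserted after the variant block: downstream bases shift by 2
        bases = [(k, "A", 40) for k in range(41)]
        sl = make_slice(bases, insertions=[(20, (("T", 40), ("T", 40)))])
        matrix = encode_member([sl])
        # blocks 21 and 22 carry the inserted T's
        assert matrix[0, 4 * 21 + BASE_ORDER["T"]] > 0
        assert matrix[0, 4 * 22 + BASE_ORDER["T"]] > 0
        # the base formerly at offset 21 now sits in block 23
        assert matrix[0, 4 * 23 + BASE_ORDER["A"]] > 0
        # and the last two read bases fall off the window edge
        assert int(matrix[0].astype(bool).sum()) == 41


class TestEncodeTrio:
    def test_geometry_and_variant_block(self, denovo_site):
        image = encode_trio(denovo_site.window(), variant_type="substitution")
        assert image.tensor.shape == (IMAGE_ROWS, IMAGE_COLS, IMAGE_CHANNELS)
        assert IMAGE_COLS == WINDOW_LENGTH * BASE_BLOCK == 164
        assert VARIANT_BLOCK == 20
        # child channel carries the alt base in the variant block
        alt_col = 4 * VARIANT_BLOCK + BASE_ORDER[denovo_site.alt]
        assert image.tensor[:, alt_col, 0].any()
        # clean de novo: parents have no alt pixel at the variant block
        assert not image.tensor[:, alt_col, 1].any()
        assert not image.tensor[:, alt_col, 2].any()

    def test_swap_parents_swaps_channels(self, denovo_site):
        window = denovo_site.window()
        swapped = TrioAlignmentWindow(
            contig=window.contig, variant_position=window.variant_position,
            slices={"child": window.member("child"),
                    "father": window.member("mother"),
                    "mother": window.member("father")},
            ref_allele=window.ref_allele, alt_allele=window.alt_allele)
        a = encode_trio(window).tensor
        b = encode_trio(swapped).tensor
        assert np.array_equal(a[:, :, 0], b[:, :, 0])
        assert np.array_equal(a[:, :, 1], b[:, :, 2])
        assert np.array_equal(a[:, :, 2], b[:, :, 1])

    def test_child_only_reads_leave_parent_channels_zero(self, denovo_site):
        window = denovo_site.window()
        child_only = TrioAlignmentWindow(
            contig=window.contig, variant_position=window.variant_position,
            slices={"child": window.member("child"), "father": (), "mother": ()},
            ref_allele=window.ref_allele, alt_allele=window.alt_allele)
        tensor = encode_trio(child_only).tensor
        assert tensor[:, :, 0].any()
        assert not tensor[:, :, 1:].any()

    def test_encoding_deterministic(self, denovo_site):
        window = denovo_site.window()
        assert np.array_equal(encode_trio(window).tensor,
                              encode_trio(window).tensor)

    @pytest.mark.parametrize("seed", range(6))
    def test_one_hot_invariant_on_random_windows(self, seed):
        """At most one lit pixel per (read row, base block, channel)."""
        mode = simulate.INHERITANCE_MODES[seed % 5]
        vt = ["substitution", "insertion", "deletion"][seed % 3]
        params = simulate.SimParams(inheritance=mode, variant_type=vt,
                                    rng_seed=seed)
        site = simulate.simulate_site(params)
        tensor = encode_trio(site.window()).tensor
        blocks = tensor.reshape(IMAGE_ROWS, WINDOW_LENGTH, BASE_BLOCK,
                                IMAGE_CHANNELS)
        lit = (blocks > 0).sum(axis=2)
        assert lit.max() <= 1

    def test_row_permutation_permutes_rows_only(self, denovo_site):
        window = denovo_site.window()
        child = list(window.member("child"))
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(child))
        permuted = TrioAlignmentWindow(
            contig=window.contig, variant_position=window.variant_position,
            slices={"child": tuple(child[i] for i in perm),
                    "father": window.member("father"),
                    "mother": window.member("mother")},
            ref_allele=window.ref_allele, alt_allele=window.alt_allele)
        a = encode_trio(window).tensor
        b = encode_trio(permuted).tensor
        n = len(child)
        assert np.array_equal(a[:n, :, 0][perm], b[:n, :, 0])
        assert np.array_equal(a[:, :, 1], b[:, :, 1])


class TestPngRoundTrip:
    def test_roundtrip_identity(self, denovo_site, tmp_path):
        image = encode_trio(denovo_site.window())
        path = tmp_path / "site.png"
        export_png(image, path)
        assert np.array_equal(import_png(path), image.tensor)

    def test_all_zero_image_black_png(self, tmp_path):
        image = EncodedVariantImage(
            tensor=np.zeros((IMAGE_ROWS, IMAGE_COLS, IMAGE_CHANNELS), np.uint8))
        path = tmp_path / "black.png"
        export_png(image, path)
        assert not import_png(path).any()


def test_bad_tensor_shapes_rejected():
    with pytest.raises(ValueError):
        EncodedVariantImage(tensor=np.zeros((10, 10, 3), np.uint8))
    with pytest.raises(ValueError):
        EncodedVariantImage(
            tensor=np.zeros((IMAGE_ROWS, IMAGE_COLS, IMAGE_CHANNELS), np.int32))
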