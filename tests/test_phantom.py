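"""Phantom data model: fill cards, lattice population, masses, slices."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from voxdose.phantom import (
    OrganRegistry,
    OrganSpec,
    flatten_lattice,
    populate_lattice,
    read_fill_card,
    slice_view,
    voxel_count,
    write_fill_card,
)

WATER = {"H": 0.1119, "O": 0.8881}


def make_phantom(linear, dims, pitch=1.0):
    return populate_lattice(np.asarray(linear), dims, pitch)


class TestFillCard:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("3 3 3 255", [3, 3, 3, 255]),
            ("3r4", [3, 3, 3, 3]),
            ("1 2r3 4", [1, 2, 2, 2, 4]),
            ("7\n7 7\n", [7, 7, 7]),
        ],
    )
    def test_token_parsing(self, text, expected):
        linear, _ = read_fill_card(io.StringIO(text))
        assert linear.tolist() == expected

    def test_header_line(self):
        linear, header = read_fill_card(io.StringIO("# dims 2 1 1 0.2\n5 6\n"))
        assert header == {"dims": (2, 1, 1), "pitch": 0.2}
        assert linear.tolist() == [5, 6]

    def test_non_integer_token_names_line(self):
        with pytest.raises(ValueError, match="line 2.*bogus"):
            read_fill_card(io.StringIO("1 2\n3 bogus\n"))

    def test_out_of_range_id(self):
        with pytest.raises(ValueError, match="outside 0-255"):
            read_fill_card(io.StringIO("1 300"))
        with pytest.raises(ValueError, match="outside 0-255"):
            read_fill_card(io.StringIO("999r5"))

    @given(st.lists(st.integers(0, 255), min_size=0, max_size=400))
    def test_write_read_round_trip(self, ids):
        buf = io.StringIO()
        write_fill_card(buf, np.array(ids, dtype=np.int64))
        buf.seek(0)
        out, _ = read_fill_card(buf)
        assert out.tolist() == ids

    def test_writer_emits_run_length_tokens(self):
        buf = io.StringIO()
        write_fill_card(buf, np.full(100, 7), dims=(100, 1, 1), pitch=0.5)
        text = buf.getvalue()
        assert "7r100" in text and text.startswith("# dims 100 1 1 0.5")


class TestLattice:
    def test_fill_order_x_fastest(self):
        ph = make_phantom([7, 9], (2, 1, 1))
        assert ph.ids[0, 0, 0] == 7 and ph.ids[0, 0, 1] == 9

    def test_grid_shape_is_z_y_x(self):
        ph = make_phantom(np.arange(24) % 5, (2, 3, 4))
        assert ph.ids.shape == (4, 3, 2)
        assert ph.dims == (2, 3, 4)

    def test_full_resolution_shape_and_count(self):
        # the full-body lattice bookkeeping: 138 x 265 x 900 voxels
        dims = (138, 265, 900)
        linear = np.full(dims[0] * dims[1] * dims[2], 255, dtype=np.int16)
        ph = populate_lattice(linear, dims, pitch=0.2)
        assert ph.ids.shape == (900, 265, 138)
        assert voxel_count(ph) == 32_913_000

    @pytest.mark.parametrize("dims", [(1, 1, 1), (2, 3, 4), (5, 1, 7)])
    def test_voxel_count_is_dim_product(self, dims):
        n = dims[0] * dims[1] * dims[2]
        ph = make_phantom(np.zeros(n, dtype=int) + 255, dims)
        assert voxel_count(ph) == n

    def test_length_mismatch_reports_both_counts(self):
        with pytest.raises(ValueError, match="5.*24"):
            populate_lattice(np.zeros(5, dtype=int), (2, 3, 4))

    @given(
        st.tuples(st.integers(1, 5), st.integers(1, 5), st.integers(1, 5)),
        st.integers(0, 2**31 - 1),
    )
    def test_populate_flatten_round_trip(self, dims, seed):
        n = dims[0] * dims[1] * dims[2]
        linear = np.random.default_rng(seed).integers(0, 256, n)
        ph = populate_lattice(linear, dims)
        assert np.array_equal(flatten_lattice(ph), linear)


class TestMasses:
    def test_single_voxel_mass(self):
        reg = OrganRegistry([OrganSpec(3, "w", 1.0, WATER)])
        ph = populate_lattice(np.array([3]), (1, 1, 1), pitch=0.2, registry=reg)
        assert ph.organ_mass(3) == pytest.approx(0.008)

    def test_bulk_mass(self):
        reg = OrganRegistry([OrganSpec(3, "w", 1.05, WATER)])
        ph = populate_lattice(np.full(1000, 3), (10, 10, 10), pitch=1.0,
                              registry=reg)
        assert ph.organ_mass(3) == pytest.approx(1050.0)

    def test_absent_organ_zero_unknown_raises(self):
        reg = OrganRegistry([OrganSpec(3, "w", 1.0, WATER),
                             OrganSpec(4, "x", 2.0, WATER)])
        ph = populate_lattice(np.array([3]), (1, 1, 1), registry=reg)
        assert ph.organ_mass(4) == 0.0
        with pytest.raises(KeyError):
            ph.organ_mass(99)

    def test_total_mass_is_sum_over_registry(self, body):
        total = sum(body.organ_mass(o.id) for o in body.registry)
        assert body.total_mass() == pytest.approx(total, rel=1e-12)


class TestSlices:
    def test_uniform_phantom_constant_map(self):
        ph = make_phantom(np.full(8, 255), (2, 2, 2))
        assert np.all(slice_view(ph, "transverse", 0) == 255)

    def test_one_voxel_thick_slice_is_full_grid(self):
        ph = make_phantom(np.arange(6) % 3, (1, 2, 3))
        assert slice_view(ph, "coronal", 0).shape == (3, 2)
        assert np.array_equal(slice_view(ph, "coronal", 0), ph.ids[:, :, 0])

    def test_out_of_range_index(self):
        ph = make_phantom(np.full(8, 255), (2, 2, 2))
        with pytest.raises(IndexError):
            slice_view(ph, "sagittal", 5)
        with pytest.raises(ValueError):
            slice_view(ph, "oblique", 0)


class TestOrganSpec:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            OrganSpec(1, "bad", 1.0, {"H": 0.5, "O": 0.4})

    def test_air_id_reserved(self):
        with pytest.raises(ValueError, match="255"):
            OrganSpec(255, "air", 0.001, {"N": 1.0})

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            OrganRegistry([OrganSpec(1, "a", 1.0, WATER),
                           OrganSpec(1, "b", 1.0, WATER)])

    def test_registry_csv_round_trip(self, registry, tmp_path):
        path = tmp_path / "reg.csv"
        registry.to_csv(path)
        back = OrganRegistry.from_csv(path)
        assert len(back) == len(registry)
        for a, b in zip(registry, back):
            assert (a.id, a.name, a.density, a.weight_class) == \
                   (b.id, b.name, b.density, b.weight_class)
            assert a.composition == pytest.approx(b.composition)
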