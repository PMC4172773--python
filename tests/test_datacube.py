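import numpy as np
import pytest

from ringpta.datacube import (
    DatacubeError,
    Mode,
    RingDatacube,
    attach_coords,
    read_cube,
    read_long_table,
    slice_cube,
    stack_values,
    write_cube,
)

from conftest import make_cube


def write_toy(tmp_path, text, name="rings.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadLongTable:
    def test_toy_file_two_trees_three_years(self, tmp_path):
        path = write_toy(
            tmp_path,
            "tree\tyear\tRW\n"
            "A\t1990\t1.0\nA\t1991\t2.0\nA\t1992\t3.0\n"
            "B\t1990\t4.0\nB\t1991\t5.0\nB\t1992\t6.0\n",
        )
        cube = read_long_table(path)
        assert cube.shape == (2, 1, 3)
        assert cube.tree_ids == ["A", "B"]
        assert cube.years == [1990, 1991, 1992]
        np.testing.assert_array_equal(cube.values[0, 0], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(cube.values[1, 0], [4.0, 5.0, 6.0])
        assert cube.coords is None

    def test_duplicate_tree_year_is_hard_error(self, tmp_path):
        path = write_toy(
            tmp_path,
            "tree\tyear\tRW\nA\t1990\t1.0\nA\t1990\t2.0\nB\t1990\t3.0\n",
        )
        with pytest.raises(DatacubeError, match=r"duplicate.*A.*1990"):
            read_long_table(path)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        path = write_toy(
            tmp_path,
            "tree\tyear\tRW\nA\t1990\t1.0\nA\t1991\toops\n",
        )
        with pytest.raises(DatacubeError, match=r"non-numeric.*'RW'.*line 3"):
            read_long_table(path)

    def test_comma_delimiter_autodetected(self, tmp_path):
        path = write_toy(tmp_path, "tree,year,RW\nA,1990,1.5\nA,1991,2.5\nB,1990,0.5\nB,1991,1.0\n")
        cube = read_long_table(path)
        assert cube.shape == (2, 1, 2)
        assert cube.values[0, 0, 0] == 1.5

    def test_embedded_coords_deduplicated(self, tmp_path):
        path = write_toy(
            tmp_path,
            "tree\tyear\tx\ty\tRW\n"
            "A\t1990\t0\t0\t1\nA\t1991\t0\t0\t2\n"
            "B\t1990\t3\t4\t3\nB\t1991\t3\t4\t4\n",
        )
        cube = read_long_table(path)
        np.testing.assert_array_equal(cube.coords, [[0, 0], [3, 4]])

    def test_inconsistent_coords_error(self, tmp_path):
        path = write_toy(
            tmp_path,
            "tree\tyear\tx\ty\tRW\nA\t1990\t0\t0\t1\nA\t1991\t9\t9\t2\n",
        )
        with pytest.raises(DatacubeError, match="inconsistent coordinates"):
            read_long_table(path)

    def test_absent_rows_become_missing(self, tmp_path):
        path = write_toy(
            tmp_path,
            "tree\tyear\tRW\nA\t1990\t1\nA\t1991\t2\nB\t1990\t3\n",
        )
        cube = read_long_table(path)
        assert cube.missing_mask[1, 0, 1]  # B 1991 absent
        assert not cube.missing_mask[0].any()

    def test_schema_remaps_columns(self, tmp_path):
        path = write_toy(
            tmp_path, "id\tdate\tval\nA\t2000\t1\nA\t2001\t2\nB\t2000\t3\nB\t2001\t4\n"
        )
        cube = read_long_table(path, {"tree": "id", "year": "date"})
        assert cube.descriptor_names == ["val"]
        assert cube.shape == (2, 1, 2)

    def test_missing_role_column_error(self, tmp_path):
        path = write_toy(tmp_path, "a\tb\n1\t2\n")
        with pytest.raises(DatacubeError, match="'tree'"):
            read_long_table(path)


class TestAttachCoords:
    def test_attach_and_missing_tree_warns(self, tmp_path):
        rings = write_toy(
            tmp_path, "tree\tyear\tRW\nA\t1990\t1\nB\t1990\t2\n", "r.tsv"
        )
        coords = write_toy(tmp_path, "tree\tx\ty\nA\t1\t2\n", "c.tsv")
        cube = read_long_table(rings)
        with pytest.warns(UserWarning, match="lack coordinates"):
            cube = attach_coords(cube, coords)
        np.testing.assert_array_equal(cube.coords[0], [1, 2])
        # error deferred until a spatial analysis actually needs the coords
        with pytest.raises(DatacubeError, match="lack coordinates"):
            cube.require_coords()


class TestValidation:
    def test_years_must_increase(self):
        with pytest.raises(DatacubeError, match="strictly increasing"):
            RingDatacube(
                values=np.zeros((1, 1, 2)),
                tree_ids=["A"],
                descriptor_names=["RW"],
                years=[2000, 2000],
            )

    def test_duplicate_tree_labels(self):
        with pytest.raises(DatacubeError, match="duplicate labels"):
            RingDatacube(
                values=np.zeros((2, 1, 1)),
                tree_ids=["A", "A"],
                descriptor_names=["RW"],
                years=[2000],
            )

    def test_coords_shape_checked(self):
        with pytest.raises(DatacubeError, match="coords"):
            RingDatacube(
                values=np.zeros((2, 1, 1)),
                tree_ids=["A", "B"],
                descriptor_names=["RW"],
                years=[2000],
                coords=np.zeros((3, 2)),
            )


class TestSliceCube:
    def test_by_year_dimensions(self):
        cube = make_cube(n=2, p=3, T=4)
        stack = slice_cube(cube, Mode.BY_YEAR)
        assert stack.n_tables == 4
        assert stack.table_shape == (2, 3)
        assert stack.table_keys == cube.years
        assert stack.row_keys == cube.tree_ids
        assert not stack.standardized

    def test_by_tree_dimensions(self):
        cube = make_cube(n=2, p=3, T=4)
        stack = slice_cube(cube, "by-tree")
        assert stack.n_tables == 2
        assert stack.table_shape == (4, 3)
        assert stack.table_keys == cube.tree_ids
        assert stack.row_keys == cube.years

    def test_unknown_mode(self, small_cube):
        with pytest.raises(ValueError, match="unknown mode"):
            slice_cube(small_cube, "diagonal")

    def test_missing_fail_lists_cells(self):
        cube = make_cube(n=3, p=2, T=3)
        cube.values[1, 0, 2] = np.nan
        cube.missing_mask[1, 0, 2] = True
        with pytest.raises(DatacubeError, match=r"missing cells.*T1.*D0.*1992"):
            slice_cube(cube, Mode.BY_YEAR)

    def test_drop_tree_policy(self):
        cube = make_cube(n=4, p=2, T=3)
        cube.values[2, 1, 0] = np.nan
        cube.missing_mask[2, 1, 0] = True
        with pytest.warns(UserWarning, match="dropping 1 incomplete trees"):
            stack = slice_cube(cube, Mode.BY_YEAR, missing="drop-tree")
        assert stack.table_shape == (3, 2)
        assert "T2" not in stack.row_keys

    def test_drop_year_policy(self):
        cube = make_cube(n=4, p=2, T=3)
        cube.values[0, 0, 1] = np.nan
        cube.missing_mask[0, 0, 1] = True
        with pytest.warns(UserWarning, match="dropping 1 incomplete years"):
            stack = slice_cube(cube, Mode.BY_YEAR, missing="drop-year")
        assert stack.n_tables == 2
        assert 1991 not in stack.table_keys

    @pytest.mark.parametrize("mode", [Mode.BY_YEAR, Mode.BY_TREE])
    def test_slicing_is_lossless(self, mode):
        cube = make_cube(n=6, p=4, T=5, seed=3)
        stack = slice_cube(cube, mode)
        np.testing.assert_array_equal(stack_values(stack), cube.values)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        cube = make_cube(n=4, p=3, T=5, seed=9)
        write_cube(cube, tmp_path / "cube")
        back = read_cube(tmp_path / "cube")
        np.testing.assert_allclose(back.values, cube.values, rtol=1e-9)
        assert back.tree_ids == cube.tree_ids
        assert back.descriptor_names == cube.descriptor_names
        assert back.years == cube.years
        np.testing.assert_allclose(back.coords, cube.coords, rtol=1e-9)

    def test_write_read_without_coords(self, tmp_path):
        cube = make_cube(with_coords=False)
        write_cube(cube, tmp_path / "cube")
        assert read_cube(tmp_path / "cube").coords is None
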