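"""Domain types, readers/writers, and their validation rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landgenkit.core_data import (
    MISSING,
    DistanceMatrix,
    GenotypeTable,
    ResistanceSurface,
    read_genotypes,
    read_matrix,
    read_resistance,
    write_genotypes,
    write_matrix,
    write_resistance,
)
from landgenkit.errors import ParseError, ValidationError

from conftest import build_table

GENEPOP_EXAMPLE = """two-population example
locA
locB
locC
pop
a1 , 0101 0203 0101
a2 , 0102 0202 000000
pop
b1 , 0303 0101 0202
b2 , 0000 0102 0201
"""


class TestGenepop:
    def test_two_pop_three_locus_example(self, tmp_path):
        path = tmp_path / "ex.gen"
        path.write_text(GENEPOP_EXAMPLE)
        g = read_genotypes(path, "genepop")
        assert g.n_individuals == 4
        assert g.n_loci == 3
        assert g.locus_names == ["locA", "locB", "locC"]
        assert g.populations == ["pop1", "pop2"]
        assert tuple(g.alleles[0, 0]) == (1, 1)
        assert tuple(g.alleles[3, 2]) == (2, 1)

    def test_zero_code_means_missing(self, tmp_path):
        path = tmp_path / "ex.gen"
        path.write_text(GENEPOP_EXAMPLE)
        g = read_genotypes(path, "genepop")
        assert tuple(g.alleles[1, 2]) == (MISSING, MISSING)  # "000000"
        assert tuple(g.alleles[3, 0]) == (MISSING, MISSING)  # "0000"

    def test_malformed_code_names_line(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("t\nlocA\npop\nx1 , 01z3\n")
        with pytest.raises(ParseError, match="line 4"):
            read_genotypes(path, "genepop")

    def test_genepop_round_trip_preserves_genotypes(self, tmp_path, sim_table):
        path = tmp_path / "rt.gen"
        write_genotypes(sim_table, path, "genepop")
        back = read_genotypes(path, "genepop")
        assert back.locus_names == sim_table.locus_names
        assert np.array_equal(back.alleles, sim_table.alleles)


class TestCsvDialect:
    def test_round_trip_field_for_field(self, tmp_path, sim_table):
        import pandas as pd

        table = sim_table.subset(np.arange(sim_table.n_individuals))
        table.covariates = pd.DataFrame(
            {"elevation": np.linspace(400.0, 3900.0, table.n_individuals)}
        )
        path = tmp_path / "rt.csv"
        write_genotypes(table, path, "csv")
        back = read_genotypes(path, "csv")
        assert back.individual_ids == table.individual_ids
        assert back.population_ids == table.population_ids
        assert back.behaviours == table.behaviours
        assert back.du_ids == table.du_ids
        assert np.array_equal(back.alleles, table.alleles)
        assert np.allclose(back.x, table.x) and np.allclose(back.y, table.y)
        assert np.allclose(back.covariates["elevation"], table.covariates["elevation"])

    def test_missing_alleles_round_trip(self, tmp_path):
        t = build_table([[(1, 2), None], [None, (3, 3)]])
        path = tmp_path / "m.csv"
        write_genotypes(t, path, "csv")
        back = read_genotypes(path, "csv")
        assert np.array_equal(back.alleles, t.alleles)


class TestGenotypeTableValidation:
    def test_duplicate_individual_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_table([[(1, 1)], [(1, 2)]], individual_ids=["a", "a"])

    def test_half_call_rejected(self):
        alleles = np.array([[[1, MISSING]]], dtype=np.int32)
        with pytest.raises(ValidationError, match="half-called"):
            GenotypeTable(
                individual_ids=["a"],
                population_ids=["p"],
                locus_names=["L0"],
                alleles=alleles,
                x=np.zeros(1),
                y=np.zeros(1),
            )

    def test_nonfinite_coordinate_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            build_table([[(1, 1)]], coords=[(np.nan, 0.0)])

    def test_behaviour_filter_semantics(self):
        t = build_table(
            [[(1, 1)], [(1, 2)], [(2, 2)]],
            behaviours=["migratory", "sedentary", "unclassified"],
        )
        assert t.filter_behaviour("sedentary").individual_ids == ["i1"]
        assert t.filter_behaviour("all").n_individuals == 3


class TestDistanceMatrixIO:
    def test_zero_matrix_round_trips(self, tmp_path):
        m = DistanceMatrix(labels=["a", "b"], values=np.zeros((2, 2)))
        path = tmp_path / "z.csv"
        write_matrix(m, path)
        back = read_matrix(path)
        assert back.labels == ["a", "b"]
        assert np.array_equal(back.values, m.values)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_symmetric_round_trip(self, seed):
        import tempfile, os

        rng = np.random.default_rng(seed)
        v = rng.normal(size=(10, 10))
        v = v + v.T
        np.fill_diagonal(v, 0.0)
        m = DistanceMatrix(labels=[f"x{k}" for k in range(10)], values=v)
        fd, path = tempfile.mkstemp(suffix=".csv")
        os.close(fd)
        try:
            write_matrix(m, path)
            back = read_matrix(path)
            assert np.allclose(back.values, m.values, atol=1e-12, rtol=0)
        finally:
            os.unlink(path)

    def test_asymmetric_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",a,b\na,0,1\nb,2,0\n")
        with pytest.raises(ValidationError, match="symmetric"):
            read_matrix(path)

    def test_kind_invariants(self):
        with pytest.raises(ValidationError, match="non-negative"):
            DistanceMatrix(
                labels=["a", "b"], values=np.array([[0.0, -1.0], [-1.0, 0.0]]), kind="lcp"
            )
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            DistanceMatrix(
                labels=["a", "b"],
                values=np.array([[np.nan, 1.5], [1.5, np.nan]]),
                kind="relatedness",
                diagonal_policy="undefined",
            )


class TestResistanceIO:
    def test_uniform_grid(self, tmp_path):
        path = tmp_path / "u.asc"
        path.write_text(
            "ncols 3\nnrows 3\nxllcorner 0\nyllcorner 0\ncellsize 30\n"
            "NODATA_value -9999\n1.0 1.0 1.0\n1.0 1.0 1.0\n1.0 1.0 1.0\n"
        )
        s = read_resistance(path)
        assert s.values.shape == (3, 3)
        assert (s.values == 1.0).all()
        assert not s.nodata_mask.any()

    def test_nodata_masked(self, tmp_path):
        path = tmp_path / "n.asc"
        path.write_text(
            "ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 30\n"
            "NODATA_value -9999\n1.0 -9999\n"
        )
        s = read_resistance(path)
        assert s.nodata_mask[0, 1] and not s.nodata_mask[0, 0]

    def test_nonpositive_cost_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text(
            "ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 30\n"
            "NODATA_value -9999\n1.0 0.0\n"
        )
        with pytest.raises(ValidationError, match="non-positive"):
            read_resistance(path)

    def test_size_mismatch_rejected(self, tmp_path):
        path = tmp_path / "short.asc"
        path.write_text(
            "ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 30\n"
            "NODATA_value -9999\n1.0 1.0 1.0\n1.0 1.0\n"
        )
        with pytest.raises(ParseError, match="cells"):
            read_resistance(path)

    def test_round_trip_identical(self, tmp_path):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.5, 10.0, size=(6, 5))
        mask = rng.uniform(size=(6, 5)) < 0.2
        s = ResistanceSurface(
            values=np.where(mask, np.nan, vals),
            cell_size=30.0,
            origin_x=500_000.0,
            origin_y=5_800_000.0,
            nodata_mask=mask,
        )
        path = tmp_path / "rt.asc"
        write_resistance(s, path)
        back = read_resistance(path)
        assert np.array_equal(back.nodata_mask, s.nodata_mask)
        assert np.allclose(back.values[~mask], s.values[~mask], rtol=0, atol=0)
        assert back.cell_size == s.cell_size

    def test_registration_convention(self):
        s = ResistanceSurface(
            values=np.ones((4, 3)), cell_size=10.0, origin_x=100.0, origin_y=200.0
        )
        # top-left cell center
        assert s.center_of(0, 0) == (105.0, 235.0)
        assert s.cell_of(105.0, 235.0) == (0, 0)
        # round-trip every cell
        for r in range(4):
            for c in range(3):
                assert s.cell_of(*s.center_of(r, c)) == (r, c)
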