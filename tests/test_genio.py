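"""I/O round-trips, VCF dosage encoding and raster point extraction."""

import numpy as np
import pytest

from landgen.genio import (
    EnvTable,
    MISSING,
    PopulationFrame,
    RasterStack,
    RunConfig,
    extract_env_at_points,
    read_ascii_grid,
    read_raster_stack,
    read_vcf_genotypes,
    write_ascii_grid,
    write_popmap,
    write_raster_stack,
    write_vcf,
)
from landgen.popstats import allele_freq_table

from conftest import make_genotypes


def _write_tiny_vcf(path, body):
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
    )
    path.write_text(header + body)


class TestVcf:
    def test_gt_encoding_and_missing(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        _write_tiny_vcf(
            vcf,
            "t1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "t2\t11\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t0/0\t1/1\n",
        )
        (tmp_path / "pm.tsv").write_text("s1\tP1\ns2\tP1\ns3\tP2\n")
        g = read_vcf_genotypes(vcf, tmp_path / "pm.tsv")
        assert g.dosages[:, 0].tolist() == [0, 1, 2]
        assert g.dosages[0, 1] == MISSING
        assert g.pop_of_individual.tolist() == ["P1", "P1", "P2"]

    def test_individual_missing_from_popmap_rejected(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        _write_tiny_vcf(vcf, "t1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        (tmp_path / "pm.tsv").write_text("s1\tP1\ns2\tP1\n")
        with pytest.raises(ValueError, match="s3"):
            read_vcf_genotypes(vcf, tmp_path / "pm.tsv")

    def test_round_trip_dosages(self, tmp_path):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(5, 10))
        d[rng.random(d.shape) < 0.2] = MISSING
        g = make_genotypes(d, pops=["A", "A", "B", "B", "B"])
        write_vcf(g, tmp_path / "g.vcf")
        write_popmap(g, tmp_path / "pm.tsv")
        back = read_vcf_genotypes(tmp_path / "g.vcf", tmp_path / "pm.tsv")
        np.testing.assert_array_equal(back.dosages, g.dosages)
        assert back.locus_ids == g.locus_ids

    def test_sample_order_stability(self, tmp_path):
        """Permuting VCF sample columns with a matching popmap leaves the
        per-population allele frequencies unchanged."""
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(6, 8))
        pops = ["A", "B", "A", "B", "A", "B"]
        g = make_genotypes(d, pops=pops)
        perm = rng.permutation(6)
        g2 = g.take_individuals(perm)
        f1 = allele_freq_table(g)
        f2 = allele_freq_table(g2)
        order = [list(f2.pops).index(p) for p in f1.pops]
        np.testing.assert_allclose(f1.p, f2.p[order])


class TestRaster:
    def _stack(self, data, mask=None):
        data = np.asarray(data, dtype=float)
        mask = (
            np.zeros(data.shape[1:], dtype=bool) if mask is None else np.asarray(mask)
        )
        return RasterStack(
            names=[f"v{i}" for i in range(data.shape[0])],
            data=data, mask=mask, xll=0.0, yll=0.0, cell=1.0,
        )

    def test_ascii_grid_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((4, 5))
        mask = np.zeros((4, 5), dtype=bool)
        mask[0, 4] = True
        write_ascii_grid(arr, mask, 10.0, 20.0, 0.5, tmp_path / "x.asc")
        back, bmask, xll, yll, cell = read_ascii_grid(tmp_path / "x.asc")
        np.testing.assert_array_equal(bmask, mask)
        np.testing.assert_allclose(back[~mask], arr[~mask])
        assert (xll, yll, cell) == (10.0, 20.0, 0.5)

    def test_stack_mask_union_and_round_trip(self, tmp_path):
        a = np.ones((4, 4))
        b = np.arange(16.0).reshape(4, 4)
        mask_a = np.zeros((4, 4), dtype=bool)
        mask_a[0, 0] = True
        write_ascii_grid(a, mask_a, 0, 0, 1.0, tmp_path / "a.asc")
        write_ascii_grid(b, np.zeros((4, 4), bool), 0, 0, 1.0, tmp_path / "b.asc")
        stack = read_raster_stack({"a": tmp_path / "a.asc", "b": tmp_path / "b.asc"})
        assert stack.mask[0, 0] and stack.mask.sum() == 1
        out = write_raster_stack(stack, tmp_path / "again")
        back = read_raster_stack(out)
        np.testing.assert_allclose(
            back.data[:, ~stack.mask], stack.data[:, ~stack.mask]
        )

    def test_grid_mismatch_names_layer(self, tmp_path):
        write_ascii_grid(np.ones((4, 4)), np.zeros((4, 4), bool), 0, 0, 1.0,
                         tmp_path / "a.asc")
        write_ascii_grid(np.ones((3, 4)), np.zeros((3, 4), bool), 0, 0, 1.0,
                         tmp_path / "b.asc")
        with pytest.raises(ValueError, match="'b'"):
            read_raster_stack({"a": tmp_path / "a.asc", "b": tmp_path / "b.asc"})

    def test_extract_constant_and_boundary(self):
        stack = self._stack([np.full((4, 4), 7.0)])
        frame = PopulationFrame(
            pop=np.array(["P1", "P2"]), lat=np.array([3.5, 3.0]),
            lon=np.array([0.5, 1.0]), n=np.array([2, 2]),
        )
        env = extract_env_at_points(stack, frame)
        assert env.values.tolist() == [[7.0], [7.0]]
        # boundary point (1.0, 3.0) is assigned by the half-open convention
        assert stack.cell_of(3.0, 1.0) == (1, 1)

    def test_extract_linear_gradient_closed_form(self):
        # value = 2 * col_index; points at column centres recover it exactly
        grad = np.tile(2.0 * np.arange(6), (4, 1))
        stack = self._stack([grad])
        lon = np.array([0.5, 2.5, 5.5])
        frame = PopulationFrame(
            pop=np.array(["a", "b", "c"]), lat=np.full(3, 1.5), lon=lon,
            n=np.ones(3, dtype=int),
        )
        env = extract_env_at_points(stack, frame)
        np.testing.assert_allclose(env.values[:, 0], 2.0 * np.floor(lon))

    def test_nodata_point_names_population(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        stack = self._stack([np.ones((4, 4))], mask)
        frame = PopulationFrame(
            pop=np.array(["bad"]), lat=np.array([3.5]), lon=np.array([0.5]),
            n=np.array([1]),
        )
        with pytest.raises(ValueError, match="bad"):
            extract_env_at_points(stack, frame)


class TestResample:
    def _stack(self, data, xll, yll, cell, epoch="current"):
        data = np.asarray(data, dtype=float)[None]
        return RasterStack(
            names=["v"], data=data, mask=np.zeros(data.shape[1:], dtype=bool),
            xll=xll, yll=yll, cell=cell, epoch=epoch,
        )

    def test_same_grid_is_identity(self):
        from landgen.genio import resample_bilinear

        a = self._stack(np.arange(12.0).reshape(3, 4), 0, 0, 1.0)
        assert resample_bilinear(a, a) is a

    def test_coarse_linear_gradient_resamples_exactly(self):
        """Bilinear interpolation reproduces a linear gradient when a
        2x-coarser stack is brought onto the fine grid (interior cells)."""
        from landgen.genio import resample_bilinear

        fine_cols = 8
        coarse = self._stack(
            np.tile(2.0 * (np.arange(4) + 0.5), (3, 1)), 0, 0, 2.0,
            epoch="SSP126_2041_2060",
        )
        fine = self._stack(
            np.tile(np.arange(fine_cols, dtype=float), (6, 1)), 0, 0, 1.0
        )
        out = resample_bilinear(coarse, fine)
        assert out.shape == fine.shape
        # linear in x with slope 1 per fine cell on the interior
        interior = out.data[0][2, 1:-1]
        np.testing.assert_allclose(np.diff(interior), 1.0, atol=1e-9)


class TestTables:
    def test_env_table_csv_round_trip(self, tmp_path):
        env = EnvTable(
            pops=np.array(["P1", "P2"]),
            variables=np.array(["bio1", "CEC"]),
            classes={"bio1": "bioclim", "CEC": "soil"},
            values=np.array([[1.5, 2.0], [3.0, 4.5]]),
        )
        env.to_csv(tmp_path / "env.csv")
        back = EnvTable.from_csv(tmp_path / "env.csv")
        np.testing.assert_allclose(back.values, env.values)
        assert back.classes == env.classes

    def test_run_config_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(rng_seed=42, maf_min=0.1)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = RunConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
        assert np.isinf(back.migration_radii_km[-1])

    def test_config_threshold_validation(self):
        with pytest.raises(ValueError):
            RunConfig(maf_min=0.7)
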