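import numpy as np
import pytest
from click.testing import CliRunner

from _factories import toy_freqs, toy_structure
from stratpca import egrm_elements, genotype_moments, io
from stratpca.cli import main as cli_main


@pytest.fixture
def toy_freq_file(tmp_path):
    path = tmp_path / "toy.freqs.tsv"
    io.write_frequency_table(path, toy_structure(), toy_freqs())
    return path


class TestFrequencyTableIO:
    def test_round_trip(self, tmp_path, toy_freq_file):
        table, structure = io.read_frequency_table(toy_freq_file)
        assert structure.labels == ["A", "B"]
        assert structure.sizes.tolist() == [2, 2]
        assert table.snp_ids == ["rs1"]
        np.testing.assert_allclose(table.freqs, [[0.2], [0.8]])
        # writing again reproduces the file byte-identically
        again = tmp_path / "again.tsv"
        io.write_frequency_table(again, structure, table)
        assert again.read_text() == toy_freq_file.read_text()

    def test_read_back_reproduces_egrm_elements(self, toy_freq_file):
        table, structure = io.read_frequency_table(toy_freq_file)
        summary = egrm_elements(
            structure, table, genotype_moments(structure, table, "mixture")
        )
        assert summary.zkk[0] == pytest.approx(9 / 17)

    def test_sizes_sidecar(self, tmp_path):
        freqs = tmp_path / "f.tsv"
        freqs.write_text("snp_id\tA\tB\nrs1\t0.2\t0.8\n")
        sizes = tmp_path / "sizes.tsv"
        sizes.write_text("A\t2\nB\t2\n")
        _, structure = io.read_frequency_table(freqs, sizes)
        assert structure.sizes.tolist() == [2, 2]

    @pytest.mark.parametrize(
        "content,match",
        [
            ("snp_id\tA\nrs1\t1.2\n", r"outside \[0, 1\]"),
            ("snp_id\tA\nrs1\t0.2\nrs1\t0.3\n", "duplicate"),
            ("snp_id\tA\nrs1\tx\n", "non-numeric"),
            ("#size\tA\ttwo\nsnp_id\tA\nrs1\t0.2\n", "not an integer"),
        ],
    )
    def test_parse_errors_rejected(self, tmp_path, content, match):
        path = tmp_path / "bad.tsv"
        if "#size" not in content:
            content = "#size\tA\t2\n" + content
        path.write_text(content)
        with pytest.raises(io.ParseError, match=match):
            io.read_frequency_table(path)

    def test_parse_error_names_file_and_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#size\tA\t2\nsnp_id\tA\nrs1\t1.2\n")
        with pytest.raises(io.ParseError, match=r"bad\.tsv:3"):
            io.read_frequency_table(path)

    def test_missing_sizes_rejected(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text("snp_id\tA\nrs1\t0.2\n")
        with pytest.raises(io.ParseError, match="sizes"):
            io.read_frequency_table(path)


class TestLabelsIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "labels.tsv"
        io.write_labels(path, toy_structure())
        ids, structure = io.read_labels(path)
        assert ids == ["A_1", "A_2", "B_1", "B_2"]
        assert structure.labels == ["A", "B"]
        assert structure.sizes.tolist() == [2, 2]

    def test_non_contiguous_blocks_rejected(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("i1\tA\ni2\tB\ni3\tA\n")
        with pytest.raises(io.ParseError, match="sort"):
            io.read_labels(path)


class TestGenotypeIO:
    def test_tsv_round_trip(self, tmp_path):
        from stratpca import GenotypeMatrix

        gm = GenotypeMatrix(
            values=np.array([[0, 1], [2, 0], [1, 2], [2, 2]]),
            sample_ids=["a", "b", "c", "d"],
            snp_ids=["s1", "s2"],
        )
        path = tmp_path / "geno.tsv"
        io.write_genotypes_tsv(path, gm)
        back = io.read_genotypes(path, "tsv")
        np.testing.assert_array_equal(back.values, gm.values)
        assert back.sample_ids == gm.sample_ids
        assert back.snp_ids == gm.snp_ids

    def test_traw_parsing_and_counted_allele_flip(self, tmp_path):
        header = "CHR\tSNP\t(C)M\tPOS\tCOUNTED\tALT\ti1\ti2\ti3"
        fwd = tmp_path / "fwd.traw"
        fwd.write_text(header + "\n1\trs1\t0\t100\tA\tG\t0\t1\t2\n")
        flipped = tmp_path / "flip.traw"
        flipped.write_text(header + "\n1\trs1\t0\t100\tG\tA\t2\t1\t0\n")
        a = io.read_genotypes(fwd, "traw")
        b = io.read_genotypes(flipped, "traw")
        assert a.sample_ids == ["i1", "i2", "i3"]
        np.testing.assert_array_equal(a.values + b.values, 2)

    def test_missing_values_rejected(self, tmp_path):
        path = tmp_path / "na.traw"
        path.write_text(
            "CHR\tSNP\t(C)M\tPOS\tCOUNTED\tALT\ti1\ti2\n1\trs1\t0\t1\tA\tG\t0\tNA\n"
        )
        with pytest.raises(io.ParseError, match="missing"):
            io.read_genotypes(path, "traw")

    def test_reorder_samples(self):
        from stratpca import GenotypeMatrix

        gm = GenotypeMatrix(
            values=np.array([[0], [1], [2]]),
            sample_ids=["c", "a", "b"],
            snp_ids=["s1"],
        )
        back = io.reorder_samples(gm, ["a", "b", "c"])
        assert back.values[:, 0].tolist() == [1, 2, 0]


class TestMatrixIO:
    def test_round_trip_numeric(self, tmp_path, toy):
        from stratpca import assemble_egrm

        structure, _, _, summary = toy
        matrix = assemble_egrm(structure, summary)
        path = tmp_path / "egrm.tsv"
        io.write_matrix(path, matrix, precision=12)
        back = io.read_matrix(path, kind="theoretical-EGRM")
        np.testing.assert_allclose(back.values, matrix.values, atol=1e-10)
        assert back.sample_ids == matrix.sample_ids


class TestCli:
    def test_egrm_then_divergence_toy(self, tmp_path, toy_freq_file):
        runner = CliRunner()
        out_matrix = tmp_path / "egrm.tsv"
        res = runner.invoke(
            cli_main,
            ["egrm", "--freqs", str(toy_freq_file), "--out", str(out_matrix),
             "--norm-mode", "mixture"],
        )
        assert res.exit_code == 0, res.output
        assert out_matrix.exists()

        report = tmp_path / "div.tsv"
        res = runner.invoke(
            cli_main,
            ["divergence", "--freqs", str(toy_freq_file), "--norm-mode", "mixture",
             "--out", str(report)],
        )
        assert res.exit_code == 0, res.output
        assert "F_PC=2.25" in res.output
        values = dict(
            line.split("\t") for line in report.read_text().splitlines()
        )
        assert float(values["f_pc"]) == pytest.approx(2.25)
        assert float(values["d2"]) == pytest.approx(44 / 17, rel=1e-5)

    def test_pca_topk_out_of_range(self, tmp_path, toy_freq_file):
        runner = CliRunner()
        out_matrix = tmp_path / "egrm.tsv"
        runner.invoke(
            cli_main, ["egrm", "--freqs", str(toy_freq_file), "--out", str(out_matrix)]
        )
        res = runner.invoke(
            cli_main,
            ["pca", "--matrix", str(out_matrix), "--topk", "5",
             "--out-prefix", str(tmp_path / "pca")],
        )
        assert res.exit_code != 0
        assert "topk" in res.output

    def test_egrm_rejects_sample_mode(self, toy_freq_file, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["egrm", "--freqs", str(toy_freq_file), "--norm-mode", "sample",
             "--out", str(tmp_path / "x.tsv")],
        )
        assert res.exit_code != 0

    def test_simulate_grm_pca_round_trip_deterministic(self, tmp_path):
        runner = CliRunner()
        args = [
            "simulate", "--pop", "A:20", "--pop", "B:20", "--snps", "50",
            "--maf-bin", "2", "--seed", "3",
        ]
        res = runner.invoke(cli_main, args + ["--out-prefix", str(tmp_path / "run1")])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, args + ["--out-prefix", str(tmp_path / "run2")])
        assert res.exit_code == 0
        for suffix in (".freqs.tsv", ".labels.tsv", ".genotypes.tsv"):
            assert (tmp_path / f"run1{suffix}").read_text() == (
                tmp_path / f"run2{suffix}"
            ).read_text()

        grm_out = tmp_path / "grm.tsv"
        res = runner.invoke(
            cli_main,
            ["grm", "--genotypes", str(tmp_path / "run1.genotypes.tsv"),
             "--labels", str(tmp_path / "run1.labels.tsv"), "--out", str(grm_out)],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            ["pca", "--matrix", str(grm_out), "--labels",
             str(tmp_path / "run1.labels.tsv"), "--topk", "2", "--scaled",
             "--out-prefix", str(tmp_path / "pca")],
        )
        assert res.exit_code == 0, res.output
        eigenvec = (tmp_path / "pca.eigenvec").read_text().splitlines()
        assert eigenvec[0].split("\t") == ["sample_id", "population", "PC1", "PC2"]
        assert len(eigenvec) == 41

    def test_experiment_subcommand(self, tmp_path, toy_freq_file):
        runner = CliRunner()
        out = tmp_path / "exp.tsv"
        res = runner.invoke(
            cli_main,
            ["experiment", "--freqs", str(toy_freq_file), "--reps", "3",
             "--mode", "known", "--seed", "1", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        lines = out.read_text().splitlines()
        assert lines[0].startswith("population\t")
        assert len(lines) == 3  # header + 2 populations
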