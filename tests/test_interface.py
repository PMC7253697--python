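import gzip
import json

import pytest
from click.testing import CliRunner

from kmerpanel import RunConfig, SequenceRecord, build_genus_panel
from kmerpanel.cli import main
from kmerpanel.errors import FormatError
from kmerpanel.io import (
    read_fasta,
    read_fastq,
    read_panel,
    write_fasta,
    write_fastq,
    write_panel,
)

from conftest import random_seq


class TestReadFasta:
    def test_basic(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n")
        recs = list(read_fasta(p))
        assert len(recs) == 1
        assert recs[0].id == "a"
        assert recs[0].bases == "ACGT"

    def test_wrapped_lines(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC\nGT\n")
        assert list(read_fasta(p))[0].bases == "ACGT"

    def test_description_preserved(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">seq1 some description here\nACGT\n")
        rec = list(read_fasta(p))[0]
        assert rec.id == "seq1"
        assert rec.description == "some description here"

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty FASTA"):
            assert list(read_fasta(p)) == []

    def test_not_fasta_is_format_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("ACGT\n>a\nACGT\n")
        with pytest.raises(FormatError):
            list(read_fasta(p))

    def test_duplicate_ids_warn_both_kept(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.warns(UserWarning, match="duplicate"):
            recs = list(read_fasta(p))
        assert len(recs) == 2

    def test_gzip_round_trip(self, tmp_path, rng):
        records = [SequenceRecord(id=f"s{i}", bases=random_seq(rng, 150))
                   for i in range(3)]
        plain = tmp_path / "a.fa"
        zipped = tmp_path / "a.fa.gz"
        write_fasta(records, plain)
        with gzip.open(zipped, "wt") as handle:
            handle.write(plain.read_text())
        assert [(r.id, r.bases) for r in read_fasta(plain)] == \
               [(r.id, r.bases) for r in read_fasta(zipped)]


class TestReadFastq:
    def test_basic(self, tmp_path):
        p = tmp_path / "r.fq"
        p.write_text("@r1\nACGT\n+\nIIII\n")
        reads = list(read_fastq(p))
        assert len(reads) == 1
        assert reads[0].id == "r1"
        assert reads[0].scores == [40, 40, 40, 40]

    def test_quality_shorter_is_error_with_ordinal(self, tmp_path):
        p = tmp_path / "r.fq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nIII\n")
        with pytest.raises(FormatError, match="record 2"):
            list(read_fastq(p))

    def test_truncated_record(self, tmp_path):
        p = tmp_path / "r.fq"
        p.write_text("@r1\nACGT\n")
        with pytest.raises(FormatError, match="truncated"):
            list(read_fastq(p))

    def test_missing_plus(self, tmp_path):
        p = tmp_path / "r.fq"
        p.write_text("@r1\nACGT\nIIII\nIIII\n")
        with pytest.raises(FormatError, match="separator"):
            list(read_fastq(p))

    def test_gzip_identical(self, tmp_path):
        content = "@r1\nACGT\n+\nIIII\n@r2\nGGCC\n+\nFFFF\n"
        plain = tmp_path / "r.fq"
        zipped = tmp_path / "r.fq.gz"
        plain.write_text(content)
        with gzip.open(zipped, "wt") as handle:
            handle.write(content)
        assert [(r.id, r.bases, r.quals) for r in read_fastq(plain)] == \
               [(r.id, r.bases, r.quals) for r in read_fastq(zipped)]


class TestPanelRoundTrip:
    @pytest.fixture
    def panel(self, rng):
        return build_genus_panel(
            [[SequenceRecord(id="g1", bases=random_seq(rng, 200))]],
            [[SequenceRecord(id="n1", bases=random_seq(rng, 200))]],
            k=6, taxon="taxonX",
        )

    def test_round_trip(self, tmp_path, panel):
        p = tmp_path / "panel.txt"
        write_panel(panel, p)
        loaded = read_panel(p)
        assert loaded.taxon == panel.taxon
        assert loaded.rank == panel.rank
        assert loaded.k == panel.k
        assert loaded.kmers.codes == panel.kmers.codes
        assert loaded.provenance == panel.provenance

    def test_body_is_sorted_uppercase(self, tmp_path, panel):
        p = tmp_path / "panel.txt"
        write_panel(panel, p)
        body = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert body == sorted(body)
        assert all(len(l) == 6 and set(l) <= set("ACGT") for l in body)

    def test_unsorted_body_strict_error_lenient_resort(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("#k=4\n#taxon=x\n#rank=genus\nGTAC\nACGT\n")
        with pytest.raises(FormatError, match="sorted"):
            read_panel(p)
        loaded = read_panel(p, strict_order=False)
        assert loaded.kmers.to_strings() == ["ACGT", "GTAC"]

    def test_bad_body_line_reports_line_number(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("#k=4\n#taxon=x\n#rank=genus\nACGTN\n")
        with pytest.raises(FormatError, match="line 4"):
            read_panel(p)

    def test_empty_body_valid(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("#k=4\n#taxon=x\n#rank=genus\n")
        loaded = read_panel(p)
        assert loaded.is_empty

    def test_missing_headers(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("#k=4\nACGT\n")
        with pytest.raises(FormatError, match="headers"):
            read_panel(p)


class TestRunConfig:
    def test_defaults(self):
        cfg = RunConfig()
        assert cfg.k == 32
        assert cfg.min_freq == 1
        assert cfg.removal_min_freq == 1
        assert cfg.subsample_sizes == [
            1_000, 10_000, 100_000, 250_000, 500_000,
            1_000_000, 10_000_000, 100_000_000,
        ]
        assert cfg.trim_quality == 35
        assert cfg.trim_min_length == 32
        assert cfg.thresholds["Lupinus"] == 1500

    def test_from_file(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text(json.dumps({"k": 16, "seed": 9}))
        cfg = RunConfig.from_file(p)
        assert cfg.k == 16 and cfg.seed == 9

    def test_unknown_key(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text(json.dumps({"bogus": 1}))
        with pytest.raises(FormatError, match="bogus"):
            RunConfig.from_file(p)


class TestCli:
    def _write_fasta(self, path, *seqs):
        with open(path, "w") as handle:
            for i, s in enumerate(seqs):
                handle.write(f">g{i}\n{s}\n")

    def test_no_arguments_usage_exit1(self, capsys):
        assert main([]) == 1

    def test_unknown_subcommand_exit1(self):
        assert main(["frobnicate"]) == 1

    def test_build_and_detect_round_trip(self, tmp_path, rng):
        t1 = tmp_path / "t1.fa"
        t2 = tmp_path / "t2.fa"
        n1 = tmp_path / "n1.fa"
        genome = random_seq(rng, 800)
        self._write_fasta(t1, genome)
        self._write_fasta(t2, genome)
        self._write_fasta(n1, random_seq(rng, 800))
        panel_path = tmp_path / "panel.txt"
        rc = main(["build-genus", "-t", str(t1), "-t", str(t2), "-n", str(n1),
                   "-k", "8", "--taxon", "demo", "-o", str(panel_path)])
        assert rc == 0
        panel = read_panel(panel_path)
        assert panel.size > 0

        # reads tiling the genome -> every panel k-mer detected
        reads_path = tmp_path / "reads.fq"
        reads_content = []
        for i in range(0, len(genome) - 60 + 1, 10):
            reads_content.append(f"@r{i}\n{genome[i:i + 60]}\n+\n{'I' * 60}\n")
        reads_path.write_text("".join(reads_content))
        report = tmp_path / "report.tsv"
        rc = main(["detect", "--panel", str(panel_path), "-r", str(reads_path),
                   "--threshold", "1", "-o", str(report)])
        assert rc == 0
        lines = report.read_text().splitlines()
        assert lines[0].split("\t") == [
            "taxon", "panel_size", "reads_scanned", "min_freq", "detected",
            "fraction_detected", "threshold", "present",
        ]
        row = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
        assert row["taxon"] == "demo"
        assert row["present"] == "True"
        assert int(row["detected"]) <= int(row["panel_size"])

    def test_curve_oversized_exit1(self, tmp_path, rng):
        genome = random_seq(rng, 300)
        t1 = tmp_path / "t1.fa"
        self._write_fasta(t1, genome)
        panel_path = tmp_path / "panel.txt"
        main(["build-genus", "-t", str(t1), "-k", "8", "--taxon", "demo",
              "-o", str(panel_path)])
        reads_path = tmp_path / "reads.fq"
        reads_path.write_text(f"@r1\n{genome[:60]}\n+\n{'I' * 60}\n")
        rc = main(["curve", "--panel", str(panel_path), "-r", str(reads_path),
                   "--sizes", "5", "-o", str(tmp_path / "c.tsv")])
        assert rc == 1

    def test_malformed_fastq_exit2(self, tmp_path, rng):
        genome = random_seq(rng, 300)
        t1 = tmp_path / "t1.fa"
        self._write_fasta(t1, genome)
        panel_path = tmp_path / "panel.txt"
        main(["build-genus", "-t", str(t1), "-k", "8", "--taxon", "demo",
              "-o", str(panel_path)])
        bad = tmp_path / "bad.fq"
        bad.write_text("@r1\nACGT\n")
        rc = main(["detect", "--panel", str(panel_path), "-r", str(bad),
                   "--threshold", "1", "-o", str(tmp_path / "out.tsv")])
        assert rc == 2

    def test_trim_command(self, tmp_path):
        fq = tmp_path / "in.fq"
        good = "I" * 40           # Q40
        bad = "I" * 31 + "#" * 9  # ends low -> trimmed below 32, dropped
        fq.write_text(f"@keep\n{'A' * 40}\n+\n{good}\n@drop\n{'C' * 40}\n+\n{bad}\n")
        out = tmp_path / "out.fq"
        assert main(["trim", "-i", str(fq), "-o", str(out)]) == 0
        kept = list(read_fastq(out))
        assert [r.id for r in kept] == ["keep"]

    def test_simulate_detect_pipeline(self, tmp_path):
        outdir = tmp_path / "sim"
        panel_path = tmp_path / "panel.txt"
        rc = main(["--seed", "3", "simulate", "--outdir", str(outdir),
                   "--genome-length", "3000", "--n-reads", "2000",
                   "--read-length", "60", "--target-fraction", "0.5",
                   "--error-rate", "0.0", "--panel-out", str(panel_path)])
        assert rc == 0
        assert (outdir / "reads.fastq").exists()
        assert (outdir / "truth.tsv").exists()
        truth_lines = (outdir / "truth.tsv").read_text().splitlines()
        assert truth_lines[0].split("\t") == [
            "read_id", "source_genome", "strand", "start", "n_errors"]
        assert len(truth_lines) == 2001

        report = tmp_path / "report.tsv"
        rc = main(["detect", "--panel", str(panel_path),
                   "-r", str(outdir / "reads.fastq"),
                   "--threshold", "10", "-o", str(report)])
        assert rc == 0
        row = report.read_text().splitlines()[1].split("\t")
        detected = int(row[4])
        assert detected > 0

    def test_byte_identical_reruns(self, tmp_path):
        args = ["--seed", "5", "simulate", "--outdir", None,
                "--genome-length", "2000", "--n-reads", "500",
                "--read-length", "60"]
        out_a = tmp_path / "a"
        out_b = tmp_path / "b"
        args_a = [x if x is not None else str(out_a) for x in args]
        args_b = [x if x is not None else str(out_b) for x in args]
        assert main(args_a) == 0
        assert main(args_b) == 0
        for name in ("targets.fasta", "nontargets.fasta", "reads.fastq", "truth.tsv"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_call_command(self, capsys):
        assert main(["call", "--taxon", "Lupinus", "--detected", "1500",
                     "--panel-size", "31179"]) == 0
        out = capsys.readouterr().out
        assert "True" in out

    def test_screen_command(self, tmp_path, rng):
        genome = random_seq(rng, 500)
        fa = tmp_path / "g.fa"
        self._write_fasta(fa, genome)
        panel_path = tmp_path / "panel.txt"
        main(["build-genus", "-t", str(fa), "-k", "8", "--taxon", "demo",
              "-o", str(panel_path)])
        out = tmp_path / "screen.tsv"
        assert main(["screen", "--panel", str(panel_path), "-f", str(fa),
                     "-o", str(out)]) == 0
        line = out.read_text().splitlines()[1].split("\t")
        assert line[2] == line[1]  # detected == panel_size (self-screen)
        assert float(line[3]) == 1.0
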