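import hashlib
import json
from pathlib import Path

import pytest
from click.testing import CliRunner

from helminthamp import cli, io_formats
from helminthamp.cleavage_and_excision import length_gate
from helminthamp.config import RunConfig
from helminthamp.pipeline import load_inputs, run_pipeline
from helminthamp.synthetic_fixtures import FixtureSpec, generate


def tree_digest(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


class TestGenerator:
    def test_same_seed_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate(FixtureSpec(seed=99)).write(a)
        generate(FixtureSpec(seed=99)).write(b)
        assert tree_digest(a) == tree_digest(b)

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate(FixtureSpec(seed=1)).write(a)
        generate(FixtureSpec(seed=2)).write(b)
        assert tree_digest(a) != tree_digest(b)

    def test_planted_precursor_count(self):
        bundle = generate(FixtureSpec(seed=2, n_families=8, copies_per_family=4,
                                      n_blocklisted_families=0, planted_known_amps=0,
                                      n_decoys=0))
        assert len(bundle.proteins) == 32

    def test_output_passes_io_validators(self, tmp_path, default_bundle):
        default_bundle.write(tmp_path)
        n = 0
        for fp in sorted(tmp_path.glob("proteins_*.fasta")):
            n += len(io_formats.read_fasta(fp))
        assert n == len(default_bundle.proteins)
        seqs = {p.protein_id: p.sequence for p in default_bundle.proteins}
        ann = io_formats.read_cleavage_tables(
            generic_tsv=tmp_path / "cleavage.tsv", sequences=seqs)
        assert set(ann) == set(default_bundle.annotations)

    def test_planted_matures_survive_length_gate(self, default_bundle):
        from helminthamp.types import CandidatePeptide

        peps = []
        for r in default_bundle.families:
            if r["role"] in ("amp", "blocklisted_amp", "known_amp"):
                length = r["mature_end"] - r["mature_start"] + 1
                peps.append(CandidatePeptide("x", r["protein_id"], r["genome_id"],
                                             r["mature_start"], r["mature_end"], "A" * length))
        assert length_gate(peps) == peps

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            FixtureSpec(mutation_rate=1.5)
        with pytest.raises(ValueError):
            FixtureSpec(n_genomes=1)


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(max_protein_len=120, consensus_fraction=0.6, seed=5)
        fp = tmp_path / "cfg.yaml"
        cfg.to_yaml(fp)
        assert RunConfig.from_yaml(fp) == cfg

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="consensus_fraction"):
            RunConfig(consensus_fraction=1.01).validate()

    def test_unknown_key_rejected(self, tmp_path):
        fp = tmp_path / "cfg.yaml"
        fp.write_text("max_protein_len: 150\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            RunConfig.from_yaml(fp)


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory):
    root = tmp_path_factory.mktemp("e2e")
    bundle = generate(FixtureSpec(seed=11))
    in_dir, out_dir = root / "in", root / "out"
    bundle.write(in_dir)
    report = run_pipeline(load_inputs(in_dir), RunConfig(), out_dir=out_dir)
    return bundle, in_dir, out_dir, report


class TestEndToEnd:
    def test_prioritised_table_non_empty(self, pipeline_run):
        _, _, _, report = pipeline_run
        assert report["n_prioritised_groups"] > 0

    def test_planted_families_prioritised(self, pipeline_run):
        """≥90 % of planted AMP families survive the whole funnel; no
        GO-blocklisted decoy family does."""
        bundle, _, _, report = pipeline_run
        fam_of = {r["protein_id"]: r["family_id"] for r in bundle.families}
        surviving_fams = set()
        for row in report["prioritised"]:
            protein = row["representative"].split(":")[0]
            surviving_fams.add(fam_of[protein])
        planted = {r["family_id"] for r in bundle.families if r["role"] == "amp"}
        blocked = {r["family_id"] for r in bundle.families if r["role"] == "blocklisted_amp"}
        assert len(surviving_fams & planted) >= 0.9 * len(planted)
        assert not surviving_fams & blocked

    def test_no_known_amp_survives(self, pipeline_run):
        bundle, _, _, report = pipeline_run
        known = {r["protein_id"] for r in bundle.families if r["role"] == "known_amp"}
        for row in report["prioritised"]:
            assert row["representative"].split(":")[0] not in known

    def test_stage_counts_are_conservative(self, pipeline_run):
        _, _, _, report = pipeline_run
        for s in report["stages"]:
            assert s["n_removed"] == s["n_in"] - s["n_out"] >= 0

    def test_outputs_written_and_consistent(self, pipeline_run):
        _, _, out_dir, report = pipeline_run
        rows = io_formats.read_tsv_rows(out_dir / "prioritised_groups.tsv", ["group_id"])
        assert len(rows) == report["n_prioritised_groups"]
        log = json.loads((out_dir / "run_report.json").read_text())
        assert log["n_prioritised_groups"] == report["n_prioritised_groups"]

    def test_rerun_is_deterministic(self, pipeline_run, tmp_path):
        _, in_dir, out_dir, _ = pipeline_run
        out2 = tmp_path / "out2"
        run_pipeline(load_inputs(in_dir), RunConfig(), out_dir=out2)
        assert tree_digest(out_dir) == tree_digest(out2)

    def test_expression_flags_reported(self, pipeline_run):
        _, _, _, report = pipeline_run
        assert all("expressed" in row for row in report["prioritised"])


class TestCli:
    def test_version(self):
        result = CliRunner().invoke(cli.main, ["--version"])
        assert result.exit_code == 0

    def test_fixtures_then_run(self, tmp_path):
        runner = CliRunner()
        fix = tmp_path / "fix"
        res = runner.invoke(cli.main, ["fixtures", "--seed", "4", "--out", str(fix)])
        assert res.exit_code == 0, res.output
        out = tmp_path / "out"
        res = runner.invoke(cli.main, ["run", "--input-dir", str(fix), "--out-dir", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "prioritised_groups.tsv").exists()

    def test_filter_subcommand_reports_stages(self, tmp_path, dirty_bundle):
        fasta = tmp_path / "in.fasta"
        io_formats.write_fasta(dirty_bundle.proteins, fasta)
        out = tmp_path / "filtered.fasta"
        res = CliRunner().invoke(cli.main, [
            "filter", "--input", str(fasta), "--genome-id", "g",
            "--out-fasta", str(out), "--max-len", "150"])
        assert res.exit_code == 0, res.output
        assert "deduplicate" in res.output and out.exists()

    def test_run_bad_input_fails_cleanly(self, tmp_path):
        res = CliRunner().invoke(cli.main, [
            "run", "--input-dir", str(tmp_path), "--out-dir", str(tmp_path / "o")])
        assert res.exit_code == 1
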