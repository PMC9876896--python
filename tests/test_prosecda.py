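"""Annotation pipeline: classification counts, writers, end-to-end runs."""

import filecmp
from collections import Counter
from pathlib import Path

import pytest

from archminer.domarch import FilterParams
from archminer.errors import DatasetIntegrityError
from archminer.hmmerio import write_domtblout
from archminer.prosecda import (
    annotate_dataset,
    read_protein_xml,
    run_prosecda,
    write_protein_xml,
    write_summary,
)
from archminer.rules import parse_rules
from archminer.seqio import write_fasta
from archminer.synthetic import NoiseSpec, PlantSpec, emit_domtblout, plant_proteome

SPECS = [
    PlantSpec("PKS", (("KS", 120), ("AT", 100), ("PP-binding", 40)), count=10),
    PlantSpec("PKSpartial", (("KS", 120), ("AT", 100)), count=5),
    PlantSpec(
        "hybrid",
        (("KS", 120), ("AT", 100), ("PP-binding", 40), ("C", 110), ("A", 120)),
        count=5,
    ),
]


@pytest.fixture
def fixture_run(example_rules_path):
    records, truth = plant_proteome(SPECS, n_decoys=10, rng_seed=17)
    hits = emit_domtblout(truth, NoiseSpec(), rng_seed=17)
    rules = parse_rules(example_rules_path)
    return records, truth, hits, rules


class TestAnnotateDataset:
    def test_planted_classification_counts(self, fixture_run):
        records, truth, hits, rules = fixture_run
        results = annotate_dataset(records, hits, rules)
        counts = Counter(n for p in results for n in p.matched_rules)
        assert counts == {"PKS": 10, "PKS-like": 5, "PKS-NRPS": 5}
        assert not any(p.record.id.startswith("decoy") for p in results)

    def test_empty_rule_set_gives_empty_result(self, fixture_run):
        records, _, hits, _ = fixture_run
        assert annotate_dataset(records, hits, []) == []

    def test_acc_failing_hit_excluded(self, fixture_run):
        records, truth, hits, rules = fixture_run
        lowacc = [h for h in hits if h.target_id == "PKS_1"]
        import dataclasses

        weakened = [dataclasses.replace(h, acc=0.5) for h in lowacc]
        others = [h for h in hits if h.target_id != "PKS_1"]
        results = annotate_dataset(records, others + weakened, rules)
        assert "PKS_1" not in {p.record.id for p in results}

    def test_unknown_protein_id_rejected(self, fixture_run):
        records, truth, hits, rules = fixture_run
        import dataclasses

        alien = dataclasses.replace(hits[0], target_id="ghost")
        with pytest.raises(DatasetIntegrityError, match="ghost"):
            annotate_dataset(records, hits + [alien], rules)

    def test_architecture_subset_of_hits(self, fixture_run):
        records, truth, hits, rules = fixture_run
        dup_hits = emit_domtblout(truth, NoiseSpec(duplicate_rate=1.0), rng_seed=17)
        for p in annotate_dataset(records, dup_hits, rules):
            assert set(p.architecture.hits) <= set(p.all_hits)


class TestProteinXml:
    def test_round_trip(self, fixture_run, tmp_path):
        records, truth, hits, rules = fixture_run
        results = annotate_dataset(records, hits, rules)
        p = results[0]
        path = write_protein_xml(p, tmp_path / "p.xml")
        assert read_protein_xml(path) == p

    def test_structure_counts(self, fixture_run, tmp_path):
        records, truth, hits, rules = fixture_run
        dup_hits = emit_domtblout(truth, NoiseSpec(duplicate_rate=1.0), rng_seed=17)
        results = annotate_dataset(records, dup_hits, rules)
        p = next(r for r in results if r.record.id.startswith("PKS_"))
        path = write_protein_xml(p, tmp_path / "p.xml")
        import xml.etree.ElementTree as ET

        root = ET.parse(path).getroot()
        assert len(root.find("architecture")) == len(p.architecture.hits)
        assert len(root.find("hits")) == len(p.all_hits)

    def test_validates_against_shipped_schema(self, fixture_run, tmp_path):
        lxml_etree = pytest.importorskip("lxml.etree")
        from importlib.resources import files

        records, truth, hits, rules = fixture_run
        results = annotate_dataset(records, hits, rules)
        path = write_protein_xml(results[0], tmp_path / "p.xml")
        schema = lxml_etree.XMLSchema(
            lxml_etree.fromstring(
                files("archminer.data").joinpath("protein_annotation.xsd").read_bytes()
            )
        )
        schema.assertValid(lxml_etree.parse(str(path)))

    def test_stop_codon_serialized_verbatim(self, tmp_path, fixture_run):
        from archminer.domarch import Architecture
        from archminer.prosecda import AnnotatedProtein
        from archminer.seqio import SequenceRecord

        rec = SequenceRecord("p1", "", "MKVL*")
        p = AnnotatedProtein(rec, (), Architecture("p1"), ())
        path = write_protein_xml(p, tmp_path / "p.xml")
        assert read_protein_xml(path).record.residues == "MKVL*"


class TestSummary:
    def test_one_row_per_protein_rule_pair(self, fixture_run, tmp_path):
        records, truth, hits, rules = fixture_run
        results = annotate_dataset(records, hits, rules)
        path = write_summary(results, tmp_path / "s.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 20  # header + 10 PKS + 5 like + 5 hybrid

    def test_empty_results_header_only(self, tmp_path):
        path = write_summary([], tmp_path / "s.tsv")
        assert path.read_text().splitlines() == [
            "protein_id\trule\tn_domains\ttotal_score\tdomain_string"
        ]


def _tree_bytes(root: Path) -> dict[str, bytes]:
    return {
        str(p.relative_to(root)): p.read_bytes()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


class TestRunProsecda:
    def test_end_to_end_tree_and_determinism(self, fixture_run, tmp_path, example_rules_path):
        records, truth, hits, rules = fixture_run
        write_fasta(records, tmp_path / "dataset.fa")
        write_domtblout(hits, tmp_path / "hits.domtblout")
        out1 = run_prosecda(
            tmp_path / "dataset.fa", example_rules_path, tmp_path / "o1",
            hits_path=tmp_path / "hits.domtblout",
        )
        out2 = run_prosecda(
            tmp_path / "dataset.fa", example_rules_path, tmp_path / "o2",
            hits_path=tmp_path / "hits.domtblout",
        )
        assert sorted(p.name for p in (out1 / "results").iterdir()) == [
            "PKS", "PKS-NRPS", "PKS-like",
        ]
        assert (out1 / "info.log").exists() and (out1 / "dataset.domtblout").exists()
        assert _tree_bytes(out1 / "results") == _tree_bytes(out2 / "results")
        # every matched protein present as both .xml and .fa
        for rule_dir in (out1 / "results").iterdir():
            xmls = {p.stem for p in rule_dir.glob("*.xml")}
            fas = {p.stem for p in rule_dir.glob("*.fa")}
            assert xmls and xmls == fas

    def test_zero_match_run_succeeds_with_empty_results(self, tmp_path, example_rules_path):
        records, truth = plant_proteome(
            [PlantSpec("lone", (("ZZZ", 50),), count=3)], rng_seed=1
        )
        hits = emit_domtblout(truth, NoiseSpec(), rng_seed=1)
        write_fasta(records, tmp_path / "d.fa")
        write_domtblout(hits, tmp_path / "h.domtblout")
        out = run_prosecda(
            tmp_path / "d.fa", example_rules_path, tmp_path / "o",
            hits_path=tmp_path / "h.domtblout",
        )
        assert list((out / "results").iterdir()) == []

    def test_ingest_equals_in_process_builtin_search(self, tmp_path, example_rules_path):
        # one-domain dataset searched with the builtin backend, then the
        # written hit table is re-ingested: identical results trees
        from archminer.backends import BuiltinBackend, SearchParams
        from archminer.seqio import SequenceRecord
        from archminer.synthetic import domain_consensus
        import numpy as np

        rng = np.random.default_rng(23)
        consensus = domain_consensus("Trp_DMAT", 60)
        seeds = [SequenceRecord(f"s{i}", "", consensus) for i in range(3)]
        be = BuiltinBackend()
        prof = be.build(seeds, "Trp_DMAT")
        db = prof.save(tmp_path / "db.pssm")
        dataset = []
        for k in range(12):
            left = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
            right = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
            dataset.append(SequenceRecord(f"t{k}", "", left + consensus + right))
        write_fasta(dataset, tmp_path / "d.fa")
        out_search = run_prosecda(
            tmp_path / "d.fa", example_rules_path, tmp_path / "os",
            hmmdb_path=db, backend="builtin", rng_seed=5,
        )
        out_ingest = run_prosecda(
            tmp_path / "d.fa", example_rules_path, tmp_path / "oi",
            hits_path=out_search / "dataset.domtblout",
        )
        assert _tree_bytes(out_search / "results") == _tree_bytes(out_ingest / "results")
        assert (out_search / "results" / "DMATS").is_dir()


class TestCli:
    def test_prosecda_command_runs(self, fixture_run, tmp_path, example_rules_path):
        from click.testing import CliRunner

        from archminer.cli import prosecda_cmd

        records, truth, hits, rules = fixture_run
        write_fasta(records, tmp_path / "dataset.fa")
        write_domtblout(hits, tmp_path / "hits.domtblout")
        runner = CliRunner()
        result = runner.invoke(
            prosecda_cmd,
            [
                "-proteins", str(tmp_path / "dataset.fa"),
                "-rules", str(example_rules_path),
                "-out", str(tmp_path / "cli_out"),
                "--hits", str(tmp_path / "hits.domtblout"),
            ],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "cli_out" / "summary.tsv").exists()

    def test_fixtures_and_rules_init_commands(self, tmp_path):
        from click.testing import CliRunner

        from archminer.cli import main

        runner = CliRunner()
        r1 = runner.invoke(main, ["fixtures", "-out", str(tmp_path / "fx"), "--seed", "4"])
        assert r1.exit_code == 0, r1.output
        assert (tmp_path / "fx" / "dataset.fa").exists()
        r2 = runner.invoke(main, ["rules-init", str(tmp_path / "r.yaml")])
        assert r2.exit_code == 0
        assert parse_rules(tmp_path / "r.yaml")
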