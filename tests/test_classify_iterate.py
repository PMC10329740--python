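"""The iteration driver: categories, conservation, convergence, outputs."""

import json

import pytest

from domcross.classify_iterate import (
    ConfigurationError,
    WorkflowRunner,
    load_config,
    run_workflow,
)
from domcross.core_model import Category, FamilyStatus
from domcross.synthgen import (
    PFAM_NEW_FAMILY,
    ScenarioSpec,
    generate_scenario,
    run_config_for_bundle,
)


def run_scenario(tmp_path, spec, name="b"):
    bundle = tmp_path / name
    result = generate_scenario(spec, bundle)
    runner = run_workflow(run_config_for_bundle(bundle, tmp_path / f"{name}_out"))
    return runner, result


class TestPlantedRecovery:
    def test_all_planted_categories_recovered(self, four_category_run):
        runner, spec, result, _ = four_category_run
        led = runner.state.ledger.entries
        for key, want in result["truth"].items():
            assert key in led, f"planted instance {key} missing from ledger"
            assert led[key].category.value == want, key

    def test_ledger_covers_exactly_the_parsed_instances(self, four_category_run):
        runner, _, result, _ = four_category_run
        # decoy-family Pfam rows are never retrieved (their family fails at
        # iteration 1), so planted truth == parsed instances here
        assert set(runner.state.ledger.entries) == set(result["truth"])

    def test_converges_in_two_iterations(self, four_category_run):
        runner, _, _, _ = four_category_run
        assert runner.converged and runner.state.iteration == 2

    def test_headline_counts(self, four_category_run):
        runner, spec, _, _ = four_category_run
        counts = runner.category_counts()
        assert counts["CORE"] == spec.n_core
        assert counts["TRUE"] == spec.n_core + spec.n_crossmap_true
        assert counts["DOMAIN_LIKE"] == spec.n_domain_like
        assert counts["FAILED"] == spec.n_failed_fold

    def test_new_family_discovered_then_absorbed(self, four_category_run):
        runner, _, _, _ = four_category_run
        accepted = [
            f for f in runner.state.ledger.families if f.status is FamilyStatus.ACCEPTED
        ]
        assert [f.family_id for f in accepted] == [PFAM_NEW_FAMILY]
        it2 = runner.summaries[1]
        assert it2.common_pairs == 4 and not it2.new_families


class TestConservation:
    def test_per_iteration_identities(self, four_category_run):
        runner, _, _, _ = four_category_run
        for s in runner.summaries:
            assert (
                s.retrieved_pfam
                == s.length_filtered_pfam + s.obsolete_pfam + s.inconsistent_pfam + s.mapped_pfam
            )
            assert (
                s.retrieved_cath
                == s.length_filtered_cath + s.obsolete_cath + s.inconsistent_cath + s.mapped_cath
            )
            assert s.mapped_pfam + s.mapped_cath == 2 * s.common_pairs + s.unique_pfam + s.unique_cath
            assert s.unique_pfam + s.unique_cath == s.crossmapped + s.unmapped
            assert s.crossmapped == s.carried_forward + s.failed_family_members
            assert s.unmapped == s.domain_like + s.failed_instance

    def test_categories_partition_all_parsed(self, four_category_run):
        runner, _, _, _ = four_category_run
        total_entries = len(runner.state.ledger)
        by_cat = runner.state.ledger.counts()
        # counts() double-adds CORE into TRUE; undo for the partition check
        partition_sum = sum(by_cat.values()) - by_cat["CORE"]
        assert partition_sum == total_entries


class TestEdgeScenarios:
    def test_core_only_converges_immediately(self, tmp_path):
        spec = ScenarioSpec(seed=3, n_core=5, n_crossmap_true=0, n_domain_like=0,
                            n_failed_fold=0, n_obsolete=0, n_inconsistent=0, n_short=0)
        runner, _ = run_scenario(tmp_path, spec)
        assert runner.converged and runner.state.iteration == 1
        counts = runner.category_counts()
        assert counts["CORE"] == 5 and counts["DOMAIN_LIKE"] == 0

    def test_no_common_pair_is_fatal(self, tmp_path):
        spec = ScenarioSpec(seed=4, n_core=0, n_crossmap_true=0, n_domain_like=2,
                            n_failed_fold=0, n_obsolete=0, n_inconsistent=0, n_short=0)
        bundle = tmp_path / "b"
        generate_scenario(spec, bundle)
        with pytest.raises(ConfigurationError, match="common"):
            run_workflow(run_config_for_bundle(bundle, tmp_path / "out"))

    def test_bookkeeping_rows_reported(self, tmp_path):
        spec = ScenarioSpec(seed=5, n_core=4, n_crossmap_true=0, n_domain_like=0,
                            n_failed_fold=0, n_obsolete=2, n_inconsistent=1, n_short=3)
        runner, _ = run_scenario(tmp_path, spec)
        counts = runner.category_counts()
        assert counts["OBSOLETE"] == 2
        assert counts["INCONSISTENT"] == 1
        assert counts["LENGTH_FILTERED"] == 3


class TestThresholdMonotonicity:
    def test_raising_threshold_never_rescues_failed(self, tmp_path):
        spec = ScenarioSpec(seed=6)
        bundle = tmp_path / "b"
        generate_scenario(spec, bundle)
        low = run_workflow(run_config_for_bundle(bundle, tmp_path / "low"))
        cfg = run_config_for_bundle(bundle, tmp_path / "high")
        cfg.score_threshold = 0.9
        high = run_workflow(cfg)
        failed_low = {
            k for k, e in low.state.ledger.entries.items()
            if e.category is Category.FAILED
        }
        for key in failed_low:
            entry = high.state.ledger.entries.get(key)
            assert entry is None or entry.category not in (
                Category.TRUE, Category.DOMAIN_LIKE,
            )


class TestDeterminism:
    def test_identical_config_gives_byte_identical_outputs(self, tmp_path):
        spec = ScenarioSpec(seed=8)
        bundle = tmp_path / "b"
        generate_scenario(spec, bundle)
        for name in ("r1", "r2"):
            run_workflow(run_config_for_bundle(bundle, tmp_path / name))
        files1 = sorted(
            p.relative_to(tmp_path / "r1")
            for p in (tmp_path / "r1").rglob("*") if p.is_file()
        )
        assert files1
        for rel in files1:
            b1 = (tmp_path / "r1" / rel).read_bytes()
            b2 = (tmp_path / "r2" / rel).read_bytes()
            if rel.name == "summary.json":
                d1 = json.loads(b1)
                d2 = json.loads(b2)
                d1["config"].pop("out_dir")
                d2["config"].pop("out_dir")
                assert d1 == d2
            elif rel.name == "run.log":
                # the log echoes the config, which names the output dir
                l1 = [l for l in b1.splitlines() if not l.startswith(b"config:")]
                l2 = [l for l in b2.splitlines() if not l.startswith(b"config:")]
                assert l1 == l2
            else:
                assert b1 == b2, rel


class TestOutputs:
    EXPECTED = [
        "core.csv", "true.csv", "domain_like.csv", "failed.csv",
        "failed_families.csv", "obsolete_inconsistent.csv", "crossmapped.csv",
        "unmapped.csv", "scores.csv", "summary.json", "run.log",
        "params_iter1.yaml", "params_iter2.yaml",
    ]

    def test_all_files_written(self, four_category_run):
        _, _, _, out = four_category_run
        for name in self.EXPECTED:
            assert (out / name).exists(), name
        assert (out / "averages" / "core.pdb").exists()
        assert any((out / "averages").glob("family_*.pdb"))
        assert any((out / "averages").glob("instance_*.pdb"))

    def test_true_csv_includes_core(self, four_category_run):
        runner, spec, _, out = four_category_run
        n_true_rows = len((out / "true.csv").read_text().splitlines()) - 1
        n_core_rows = len((out / "core.csv").read_text().splitlines()) - 1
        assert n_core_rows == 2 * spec.n_core
        assert n_true_rows == 2 * (spec.n_core + spec.n_crossmap_true)

    def test_summary_totals_match_runner(self, four_category_run):
        runner, _, _, out = four_category_run
        summary = json.loads((out / "summary.json").read_text())
        assert summary["totals"] == runner.category_counts()
        assert summary["converged"] is True
        assert summary["n_iterations"] == 2

    def test_params_file_lists_next_families(self, four_category_run):
        import yaml

        _, _, _, out = four_category_run
        params1 = yaml.safe_load((out / "params_iter1.yaml").read_text())
        assert params1["next_families"]["pfam"] == [PFAM_NEW_FAMILY]
        assert len(params1["carried_instances"]) == 4
        params2 = yaml.safe_load((out / "params_iter2.yaml").read_text())
        assert params2["next_families"] == {"pfam": [], "cath": []}


class TestConfigLoading:
    def test_relative_paths_resolved_against_config_dir(self, four_category_bundle):
        bundle_dir, _, _ = four_category_bundle
        cfg = load_config(bundle_dir / "config.yaml")
        assert cfg.pfam_table == str(bundle_dir / "pfam_table.tsv")
        assert cfg.starting_families_pfam == ["PF00076"]
        assert cfg.starting_families_cath == ["3.30.70.330"]
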