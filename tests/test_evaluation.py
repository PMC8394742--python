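import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from occfall import (Manifest, ValidationError, geometric_mean, make_folds,
                     run_ablation, run_ensemble, run_fair_experiment,
                     sweep_roc)
from occfall.datamodel import ManifestEntry
from occfall.evaluation import top_combos


class TestGeometricMean:
    def test_sensitivity_one_reduces_to_sqrt(self):
        assert geometric_mean(1.0, 0.49) == pytest.approx(0.7)

    def test_domain_enforced(self):
        with pytest.raises(ValidationError):
            geometric_mean(1.2, 0.5)


class TestSweepROC:
    def test_perfect_separation(self):
        result = sweep_roc(np.arange(10.0), np.arange(20.0, 30.0))
        assert result.auc == pytest.approx(1.0)
        assert result.g_star == pytest.approx(1.0)
        assert result.se_star == result.sp_star == 1.0

    def test_identical_distributions_are_chance_level(self, rng):
        for _ in range(20):
            scores = rng.normal(0, 1, 200)
            result = sweep_roc(scores, rng.permutation(scores))
            assert result.auc == pytest.approx(0.5, abs=0.02)
            assert result.g_star <= 0.5 + 1e-9

    def test_auc_matches_exhaustive_threshold_oracle(self, rng):
        """Grid sweep vs. the exact ROC using every score as threshold."""
        for _ in range(30):
            adl = rng.normal(0, 1, int(rng.integers(5, 100)))
            fall = rng.normal(rng.uniform(0, 2), 1, int(rng.integers(5, 100)))
            result = sweep_roc(adl, fall)
            labels = np.r_[np.zeros(adl.size), np.ones(fall.size)]
            exact = roc_auc_score(labels, np.r_[adl, fall])
            assert abs(result.auc - exact) <= 1e-3

    def test_roc_monotone_and_g_consistent(self, rng):
        result = sweep_roc(rng.normal(0, 1, 80), rng.normal(1.5, 1, 60))
        assert np.all(np.diff(result.se) <= 1e-15)
        assert np.all(np.diff(result.sp) >= -1e-15)
        assert np.all(np.diff(result.thresholds) > 0)
        assert result.g_star == pytest.approx(
            np.sqrt(result.se_star * result.sp_star), abs=1e-12)
        assert 0.0 <= result.auc <= 1.0

    def test_threshold_count(self, rng):
        result = sweep_roc(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
        assert result.thresholds.size == 2500

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            sweep_roc(np.array([]), np.array([1.0]))


def _fake_manifest(tmp_path, n_types=10, per_type=10, n_falls=5):
    rng = np.random.default_rng(0)
    entries = []
    trace_path = tmp_path / "stub.csv"
    trace_path.write_text("ax,ay,az\n0,0,1\n0,0,1\n")
    for t in range(n_types):
        for i in range(per_type):
            entries.append(ManifestEntry(
                f"adl_{t}_{i}", trace_path, "ADL", f"type{t}",
                "basic", f"s{i % 3}", 100.0, "g"))
    for i in range(n_falls):
        entries.append(ManifestEntry(
            f"fall_{i}", trace_path, "FALL", "fall", "none",
            f"s{i % 3}", 100.0, "g"))
    return Manifest(entries)


class TestMakeFolds:
    def test_exact_divisibility_stratification(self, tmp_path):
        manifest = _fake_manifest(tmp_path)
        split = make_folds(manifest, k=5, seed=0)
        for part in split.partitions:
            assert len(part) == 20
            types = [tid.split("_")[1] for tid in part]
            assert all(types.count(str(t)) == 2 for t in range(10))

    def test_partitions_disjoint_and_covering(self, tmp_path):
        manifest = _fake_manifest(tmp_path, n_types=3, per_type=7)
        split = make_folds(manifest, k=5, seed=3)
        all_ids = [tid for part in split.partitions for tid in part]
        assert len(all_ids) == len(set(all_ids)) == 21

    def test_falls_never_in_training(self, tmp_path):
        manifest = _fake_manifest(tmp_path)
        split = make_folds(manifest, k=5, seed=1)
        fall_ids = set(split.fall_ids)
        for fold in range(5):
            assert not fall_ids & set(split.train_adl_ids(fold))

    def test_seed_determinism(self, tmp_path):
        manifest = _fake_manifest(tmp_path)
        s1 = make_folds(manifest, k=5, seed=42)
        s2 = make_folds(manifest, k=5, seed=42)
        s3 = make_folds(manifest, k=5, seed=43)
        assert s1.partitions == s2.partitions
        assert s1.partitions != s3.partitions
        # different seed keeps the stratification counts
        assert [len(p) for p in s1.partitions] == [len(p) for p in s3.partitions]

    def test_k_below_two_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_folds(_fake_manifest(tmp_path), k=1)


class TestFairExperiment:
    def test_bookkeeping_identity(self, small_dataset, small_frame):
        report = run_fair_experiment(
            small_dataset, "ocknn", feature_sets=("BCDFGIK",),
            seed=5, frame=small_frame)
        best = report.best
        assert best.g_mean == pytest.approx(
            np.mean([f.g for f in best.folds]), abs=1e-12)
        assert len(best.folds) == 5

    def test_indistinguishable_classes_give_chance_g(self, small_config,
                                                     tmp_path):
        """Falls whose feature rows duplicate ADL rows cannot be separated."""
        from occfall import generate_dataset, load_traces, features_frame
        manifest = generate_dataset(small_config, tmp_path / "d")
        frame = features_frame(load_traces(manifest), "ABCDEFGHIJKL")
        adl_rows = frame[frame["label"] == "ADL"]
        fake = frame.copy()
        fall_ids = fake.index[fake["label"] == "FALL"]
        fake.loc[fall_ids, [c for c in "ABCDEFGHIJKL"]] = (
            adl_rows.iloc[:len(fall_ids)][[c for c in "ABCDEFGHIJKL"]]
            .to_numpy())
        report = run_fair_experiment(
            manifest, "ocknn",
            grid=[{"metric": "euclidean", "k": 5}],
            feature_sets=("BCDFGIK",), seed=5, frame=fake)
        assert report.best.g_mean == pytest.approx(0.5, abs=0.12)

    def test_failed_combo_disqualified_but_reported(self, small_dataset,
                                                    small_frame):
        report = run_fair_experiment(
            small_dataset, "ocknn",
            grid=[{"metric": "euclidean", "k": 5},
                  {"metric": "euclidean", "k": 5000}],
            feature_sets=("BCDFGIK",), seed=5, frame=small_frame)
        failed = [c for c in report.combos if c.failed]
        assert len(failed) == 1 and failed[0].error
        assert not report.best.failed

    def test_honest_mode_runs(self, small_dataset, small_frame):
        report = run_fair_experiment(
            small_dataset, "ocknn", grid=[{"metric": "euclidean", "k": 5}],
            feature_sets=("BCDFGIK",), seed=5, frame=small_frame,
            honest=True)
        best = report.best
        assert 0.0 <= best.g_mean <= 1.0
        assert np.isfinite(best.fair_threshold)


class TestEnsemble:
    def test_majority_rule_and_degenerate_ensemble(self, small_dataset,
                                                   small_frame):
        report = run_fair_experiment(
            small_dataset, "ocknn", grid=[{"metric": "euclidean", "k": 5}],
            feature_sets=("BCDFGIK",), seed=5, frame=small_frame)
        best = report.best
        ensemble = run_ensemble(small_dataset, [best, best, best],
                                seed=5, frame=small_frame)
        # three identical voters reproduce the single learner's fold metrics
        for fold_m, base_m in zip(ensemble.folds, best.folds):
            assert fold_m.se == pytest.approx(base_m.se, abs=1e-12)
            assert fold_m.sp == pytest.approx(base_m.sp, abs=1e-12)

    def test_ensemble_at_least_min_base(self, small_dataset, small_frame):
        reports = [run_fair_experiment(small_dataset, kind,
                                       feature_sets=("BCDFGIK",),
                                       seed=5, frame=small_frame)
                   for kind in ("gmm", "ppnn", "ocknn")]
        members = top_combos(reports, 3)
        ensemble = run_ensemble(small_dataset, members, seed=5,
                                frame=small_frame)
        assert ensemble.g_mean >= min(m.g_mean for m in members) - 1e-9

    def test_fewer_than_three_rejected(self, small_dataset, small_frame):
        with pytest.raises(ValueError):
            run_ensemble(small_dataset, [], seed=5, frame=small_frame)


@pytest.fixture(scope="module")
def fair_and_ablation(small_dataset, small_frame):
    report = run_fair_experiment(
        small_dataset, "ocknn", feature_sets=("BCDFGIK",),
        seed=5, frame=small_frame)
    ablation = run_ablation(small_dataset, report.best, seed=5,
                            frame=small_frame)
    return report, ablation


class TestAblation:
    def test_loss_arithmetic(self, fair_and_ablation):
        report, ablation = fair_and_ablation
        for row in ablation.rows.values():
            assert row.loss == pytest.approx(row.g - report.best.g_mean,
                                             abs=1e-12)
            assert abs(row.loss) <= 1.0

    def test_threshold_is_fair_case_median(self, fair_and_ablation):
        report, ablation = fair_and_ablation
        assert ablation.threshold == pytest.approx(
            np.median(report.best.fold_thresholds))

    def test_all_categories_reported(self, fair_and_ablation):
        _, ablation = fair_and_ablation
        assert set(ablation.rows) == {"basic", "standard", "sporting"}

    def test_duplicated_category_shows_no_novelty(self, small_config,
                                                  tmp_path):
        """Held-out rows that also sit in a training category lose nothing."""
        from occfall import generate_dataset, load_traces, features_frame
        manifest = generate_dataset(small_config, tmp_path / "d")
        frame = features_frame(load_traces(manifest), "ABCDEFGHIJKL")
        # relabel: standard rows become copies of the basic rows
        basic_idx = frame.index[frame["category"] == "basic"]
        std_idx = frame.index[frame["category"] == "standard"]
        n = min(len(basic_idx), len(std_idx))
        cols = [c for c in "ABCDEFGHIJKL"]
        frame.loc[std_idx[:n], cols] = frame.loc[basic_idx[:n], cols].to_numpy()
        report = run_fair_experiment(
            manifest, "ocknn", grid=[{"metric": "euclidean", "k": 5}],
            feature_sets=("BCDFGIK",), seed=5, frame=frame)
        ablation = run_ablation(manifest, report.best, seed=5, frame=frame)
        assert abs(ablation.rows["basic"].loss) < 0.05
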