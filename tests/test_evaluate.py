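"""ITR, LOSO evaluation harness, sweeps."""

import dataclasses

import numpy as np
import pytest

from cveptl import evaluate, synthdata
from cveptl.evaluate import ExperimentConfig, compare_algorithms, itr, run_loso, sweep


class TestITR:
    def test_perfect_accuracy_closed_form(self):
        # P=1: ITR = log2(M) * 60 / T; M=16, T=2.05 s -> 117.07 bits/min.
        assert itr(16, 1.0, 2.05) == pytest.approx(4 * 60 / 2.05)
        assert itr(16, 1.0, 2.05) == pytest.approx(117.07, abs=0.005)

    def test_chance_accuracy_is_zero(self):
        assert itr(16, 1.0 / 16, 2.05) == 0.0
        assert itr(4, 0.1, 2.0) == 0.0  # below chance, clamped

    def test_unclamped_matches_wolpaw_bits(self):
        M, P = 8, 0.5
        bits = np.log2(M) + P * np.log2(P) + (1 - P) * np.log2((1 - P) / (M - 1))
        assert itr(M, P, 3.0, clamp=False) == pytest.approx(bits * 20.0)

    def test_monotone_in_accuracy(self):
        vals = [itr(16, p, 2.05) for p in np.linspace(1 / 16, 1.0, 25)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_monotone_decreasing_in_time(self):
        vals = [itr(16, 0.9, t) for t in np.linspace(1.0, 10.0, 20)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            itr(1, 0.5, 2.0)
        with pytest.raises(ValueError):
            itr(16, 1.2, 2.0)
        with pytest.raises(ValueError):
            itr(16, 0.5, 0.0)


class TestConfig:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(algorithm="csp")

    def test_flags(self):
        assert not ExperimentConfig(algorithm="ssl").uses_transfer
        assert ExperimentConfig(algorithm="tl-ass").uses_transfer
        assert not ExperimentConfig(algorithm="tl-ass").uses_alignment
        assert ExperimentConfig(algorithm="tl-leda-tss").uses_alignment


class TestJackknifeSupertrials:
    def test_own_trial_excluded_from_template(self, rng):
        trials = rng.normal(size=(6, 2, 40))
        labels = np.array([0, 0, 0, 1, 1, 1])
        sts = evaluate._jackknife_supertrials(trials, labels)
        # Super-trial 0 (class 0): its class-0 template block must be the
        # mean of trials 1 and 2 only.
        expected = trials[1:3].mean(axis=0)
        np.testing.assert_allclose(sts[0].values[0:2], expected, atol=1e-12)
        # Its class-1 template block is untouched (full mean).
        np.testing.assert_allclose(sts[0].values[2:4], trials[3:6].mean(axis=0), atol=1e-12)

    def test_grouped_recordings_excluded_together(self, rng):
        # Trials 0/2 and 1/3 derive from the same recordings (groups 0 and 1).
        trials = rng.normal(size=(4, 2, 40))
        labels = np.array([0, 0, 1, 1])
        groups = np.array([0, 1, 0, 1])
        sts = evaluate._jackknife_supertrials(trials, labels, groups=groups)
        # Super-trial 0 excludes its group mate (trial 2) from class 1 too.
        np.testing.assert_allclose(sts[0].values[2:4], trials[3], atol=1e-12)

    def test_singleton_class_keeps_full_template(self, rng):
        trials = rng.normal(size=(2, 2, 40))
        labels = np.array([0, 1])
        sts = evaluate._jackknife_supertrials(trials, labels)
        np.testing.assert_allclose(sts[0].values[0:2], trials[0], atol=1e-12)


class TestRunLoso:
    def test_zero_noise_ssl_is_perfect(self, noiseless_population):
        cfg = ExperimentConfig(algorithm="ssl", n_train=1)
        res = run_loso(noiseless_population, cfg)
        assert res.mean_accuracy == 1.0
        assert not res.failures

    def test_deterministic(self, small_population):
        cfg = ExperimentConfig(algorithm="tl-leda-tss", n_train=3)
        a = run_loso(small_population, cfg)
        b = run_loso(small_population, cfg)
        assert a.per_subject == b.per_subject
        assert a.selected_sources == b.selected_sources

    def test_result_structure(self, small_population):
        cfg = ExperimentConfig(algorithm="tl-ass", n_train=3)
        res = run_loso(small_population, cfg)
        assert set(res.per_subject) == {"S00", "S01", "S02"}
        assert set(res.itr_per_subject) == set(res.per_subject)
        for sid, sel in res.selected_sources.items():
            assert sid not in sel
            assert len(sel) == 2  # ASS pools all other subjects
        for pred, truth in res.predictions.values():
            assert pred.shape == truth.shape

    def test_too_few_subjects_rejected(self, small_population):
        solo = dataclasses.replace(small_population, subjects=small_population.subjects[:1])
        with pytest.raises(ValueError):
            run_loso(solo, ExperimentConfig())

    def test_n_train_larger_than_available_fails_folds(self, small_population):
        cfg = ExperimentConfig(algorithm="ssl", n_train=99)
        with pytest.raises(RuntimeError):
            run_loso(small_population, cfg)

    def test_channel_crop_and_cycles(self, small_population):
        cfg = ExperimentConfig(algorithm="ssl", n_train=3, n_channels=2, cycle_multiple=0.5)
        res = run_loso(small_population, cfg)
        assert res.config["n_channels"] == 2
        assert 0.0 <= res.mean_accuracy <= 1.0

    def test_affine_invariant_metric_runs(self, noiseless_population):
        cfg = ExperimentConfig(algorithm="ssl", n_train=1, metric="affine_invariant")
        res = run_loso(noiseless_population, cfg)
        assert res.mean_accuracy == 1.0


class TestCompareAlgorithms:
    def test_all_four_algorithms(self, small_population):
        cfg = ExperimentConfig(n_train=3)
        results = compare_algorithms(small_population, cfg)
        assert set(results) == set(evaluate.ALGORITHMS)
        for alg, res in results.items():
            assert res.algorithm == alg
            assert set(res.per_subject) == {"S00", "S01", "S02"}

    def test_single_source_tss_equals_ass(self, codebook):
        # With one source subject there is nothing to select: TSS and ASS
        # train on identical pools and must score identically.
        pop = synthdata.simulate_population(
            n_subjects=2, similarity_clusters=1, seed=21, n_train=3,
            n_test_per_target=2, n_channels=4,
        )
        cfg = ExperimentConfig(n_train=3)
        results = compare_algorithms(pop, cfg, algorithms=("tl-leda-ass", "tl-leda-tss"))
        assert results["tl-leda-ass"].per_subject == results["tl-leda-tss"].per_subject

    def test_matches_individual_runs(self, small_population):
        cfg = ExperimentConfig(n_train=3)
        shared = compare_algorithms(small_population, cfg, algorithms=("ssl", "tl-ass"))
        for alg in ("ssl", "tl-ass"):
            solo = run_loso(small_population, dataclasses.replace(cfg, algorithm=alg))
            assert shared[alg].per_subject == solo.per_subject


class TestSweepAndFrames:
    def test_sweep_frame_structure(self, small_population):
        cfg = ExperimentConfig(algorithm="ssl", n_train=3)
        frame = sweep(small_population, cfg, "n_train", [2, 3])
        assert len(frame) == 2 * 3  # values x subjects
        assert set(frame["value"]) == {2, 3}
        assert {"accuracy", "itr_bits_per_min", "subject"} <= set(frame.columns)

    def test_sweep_rejects_unknown_parameter(self, small_population):
        with pytest.raises(ValueError):
            sweep(small_population, ExperimentConfig(), "metric", ["log_euclidean"])

    def test_results_to_frame(self, small_population):
        cfg = ExperimentConfig(n_train=3)
        results = compare_algorithms(small_population, cfg, algorithms=("ssl",))
        frame = evaluate.results_to_frame(results)
        assert len(frame) == 3
        assert set(frame["algorithm"]) == {"ssl"}

    def test_paired_ttest(self, small_population):
        cfg = ExperimentConfig(n_train=3)
        results = compare_algorithms(small_population, cfg, algorithms=("ssl", "tl-ass"))
        p = evaluate.paired_ttest(results["ssl"], results["tl-ass"])
        assert 0.0 <= p <= 1.0
        assert evaluate.paired_ttest(results["ssl"], results["ssl"]) == 1.0
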