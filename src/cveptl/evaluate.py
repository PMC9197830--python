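"""Leave-one-subject-out evaluation of the four decoding algorithms.

Algorithms compared (all MDM on super-trial covariances):

* ``ssl``         — subject-specific learning: the target's own shifted
                    training trials only (baseline).
* ``tl-ass``      — transfer from all source subjects, no alignment.
* ``tl-leda-ass`` — transfer from all source subjects with log-Euclidean
                    data alignment.
* ``tl-leda-tss`` — LEDA plus training-accuracy-based subject selection.

For each fold one subject is the target: its reference-target training
trials are circularly shifted to synthesize training data for every class,
source subjects contribute their labeled test trials (the only per-class
data they have), LEDA is applied per class to labeled data and globally to
the target's unlabeled test trials, and the pooled MDM classifies the
target's test covariances.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import align as leda
from .features import SuperCovariance, build_supertrial, supertrial_cov
from .preprocess import FilterSpec, TemplateSet, bandpass, make_templates, shift_trials
from .spdcore import ShrinkageConfig
from .synthdata import MultiSubjectDataset, SubjectDataset
from .transfer import train_mdm, tss, _predict_labels

__all__ = [
    "ALGORITHMS",
    "ExperimentConfig",
    "ExperimentResult",
    "run_loso",
    "compare_algorithms",
    "itr",
    "sweep",
    "results_to_frame",
    "paired_ttest",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("ssl", "tl-ass", "tl-leda-ass", "tl-leda-tss")

#: Gaze-shift time added to one selection when computing ITR, seconds.
GAZE_SHIFT_S = 1.0


@dataclass(frozen=True)
class ExperimentConfig:
    """One evaluation condition.

    ``n_train`` is the number of training trials per class (synthesized by
    shifting that many reference-target trials).  ``cycle_multiple`` crops
    every trial to ``round(k · fs · period)`` samples; ``n_channels`` keeps
    the first channels in dataset order (the convention for channel-count
    sweeps).  ``alignment_stage`` selects whether LEDA is applied to raw
    trials (default, matching the processing order of the pipeline) or to
    the assembled super-trials.
    """

    algorithm: str = "ssl"
    n_train: int = 20
    cycle_multiple: float = 1.0
    n_channels: int | None = None
    shrinkage: ShrinkageConfig = field(default_factory=ShrinkageConfig)
    metric: str = "log_euclidean"
    filter: FilterSpec | None = field(default_factory=FilterSpec)
    alignment_stage: str = "raw_trials"
    include_target_in_tss: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.n_train < 1:
            raise ValueError("n_train must be >= 1")
        if self.cycle_multiple <= 0:
            raise ValueError("cycle_multiple must be > 0")
        if self.alignment_stage not in ("raw_trials", "super_trials"):
            raise ValueError("alignment_stage must be raw_trials or super_trials")

    @property
    def uses_alignment(self) -> bool:
        return self.algorithm in ("tl-leda-ass", "tl-leda-tss")

    @property
    def uses_transfer(self) -> bool:
        return self.algorithm != "ssl"

    def echo(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "n_train": self.n_train,
            "cycle_multiple": self.cycle_multiple,
            "n_channels": self.n_channels,
            "shrinkage": self.shrinkage.method,
            "shrinkage_lambda": self.shrinkage.lam,
            "metric": self.metric,
            "filtered": self.filter is not None,
            "alignment_stage": self.alignment_stage,
            "seed": self.seed,
        }


@dataclass
class ExperimentResult:
    """LOSO outcome: per-target-subject accuracies plus summary statistics."""

    algorithm: str
    per_subject: dict[str, float]
    config: dict
    selected_sources: dict[str, list[str]] = field(default_factory=dict)
    predictions: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    itr_per_subject: dict[str, float] = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    @property
    def se_accuracy(self) -> float:
        accs = np.array(list(self.per_subject.values()))
        if len(accs) < 2:
            return 0.0
        return float(accs.std(ddof=1) / np.sqrt(len(accs)))

    @property
    def mean_itr(self) -> float:
        return float(np.mean(list(self.itr_per_subject.values())))


def itr(M: int, P: float, T: float, clamp: bool = True) -> float:
    """Wolpaw information transfer rate in bits/minute.

    ``(log2 M + P log2 P + (1−P) log2[(1−P)/(M−1)]) · 60/T`` with the
    ``x log2 x → 0`` limits at P = 0 and P = 1.  When ``clamp`` is set,
    accuracies at or below chance (P ≤ 1/M) report 0 bits/min; the raw
    formula value is logged.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if T <= 0:
        raise ValueError("T must be > 0")
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {P}")

    def xlog2x(x: float) -> float:
        return 0.0 if x <= 0.0 else x * np.log2(x)

    bits = np.log2(M) + xlog2x(P) + (1.0 - P) * (np.log2(1.0 - P) - np.log2(M - 1) if P < 1.0 else 0.0)
    raw = bits * 60.0 / T
    if clamp and P <= 1.0 / M:
        logger.debug("accuracy %.4f at or below chance 1/%d; raw ITR %.3f clamped to 0", P, M, raw)
        return 0.0
    return float(raw)


# -- per-fold pipeline pieces -------------------------------------------------


def _prepare(subject: SubjectDataset, config: ExperimentConfig) -> tuple[np.ndarray, ...]:
    """Crop channels/samples and band-pass filter one subject's trials."""
    x = np.asarray(subject.trials, dtype=float)
    if config.n_channels is not None:
        if config.n_channels > x.shape[1]:
            raise ValueError(
                f"requested {config.n_channels} channels, dataset has {x.shape[1]}"
            )
        x = x[:, : config.n_channels, :]
    n_samples = round(config.cycle_multiple * subject.fs * subject.codebook.period_s)
    if n_samples > x.shape[2]:
        raise ValueError(
            f"cycle_multiple {config.cycle_multiple} needs {n_samples} samples, "
            f"trials have {x.shape[2]}"
        )
    x = x[:, :, :n_samples]
    if config.filter is not None:
        x = bandpass(x, subject.fs, config.filter)
    return x


def _jackknife_supertrials(
    trials: np.ndarray,
    labels: np.ndarray,
    subject_id: str | None = None,
    groups: np.ndarray | None = None,
) -> list:
    """Super-trials whose templates exclude the trial's own recording.

    A labeled trial's own noise inside its class template creates a spurious
    correct-class cross-covariance term (``‖noise‖²/n`` lands exactly in the
    true-class block), which with few trials per class makes covariances of
    the template-building set artificially easy to classify.  This biases
    the MDM class means and saturates the training-accuracy criterion used
    for source-subject selection.  Each super-trial therefore uses templates
    recomputed without the trial itself.

    ``groups`` marks trials derived from the same underlying recording: when
    training classes are synthesized by circularly shifting the same
    reference recordings, that shared noise sits in *every* class template,
    so all shifted copies of the trial's recording are excluded together.
    A class left with a single trial keeps its full template.
    """
    labels = np.asarray(labels, dtype=int)
    tset = make_templates(trials, labels)
    base, counts = tset.templates, tset.n_trials_used
    if groups is None:
        groups = np.arange(trials.shape[0])
    groups = np.asarray(groups)
    out = []
    for i in range(trials.shape[0]):
        adjusted = None
        tmpl = tset
        for j in np.flatnonzero(groups == groups[i]):
            z = int(labels[j])
            if counts[z] > 1:
                if adjusted is None:
                    adjusted = base.copy()
                    tmpl = TemplateSet(templates=adjusted, n_trials_used=counts)
                adjusted[z] = (counts[z] * base[z] - trials[j]) / (counts[z] - 1)
        out.append(
            build_supertrial(tmpl, trials[i], label=int(labels[i]), subject_id=subject_id)
        )
    return out


def _covs_from_trials(
    trials: np.ndarray,
    labels: np.ndarray,
    config: ExperimentConfig,
    subject_id: str,
    supervised_align: bool,
) -> tuple[list[SuperCovariance], np.ndarray]:
    """Templates → super-trials → shrunk covariances for labeled trials.

    ``supervised_align`` applies per-class LEDA (at the configured stage)
    before templates and features are computed.
    """
    if supervised_align and config.alignment_stage == "raw_trials":
        model = leda.fit_supervised(trials, labels)
        trials = leda.apply_set(model, trials, labels)
    sts = _jackknife_supertrials(trials, labels, subject_id=subject_id)
    if supervised_align and config.alignment_stage == "super_trials":
        stacks = np.stack([st.values for st in sts])
        model = leda.fit_supervised(stacks, labels)
        aligned = leda.apply_set(model, stacks, labels)
        for i, st in enumerate(sts):
            object.__setattr__(st, "values", aligned[i])
    covs = [supertrial_cov(st, config.shrinkage) for st in sts]
    return covs, np.asarray(labels, dtype=int)


def _target_training_trials(
    subject: SubjectDataset, prepared: np.ndarray, config: ExperimentConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Shift the first ``n_train`` reference-target trials to every class."""
    cb = subject.codebook
    mask = subject.roles == "train_reference"
    ref_trials = prepared[mask]
    if ref_trials.shape[0] < config.n_train:
        raise ValueError(
            f"subject {subject.subject_id} has {ref_trials.shape[0]} reference "
            f"trials, need n_train={config.n_train}"
        )
    ref_trials = ref_trials[: config.n_train]
    out, labels = [], []
    for z in range(cb.n_targets):
        out.append(shift_trials(ref_trials, cb, z, subject.fs))
        labels += [z] * config.n_train
    return np.concatenate(out, axis=0), np.array(labels, dtype=int)


class _FoldRunner:
    """Shares per-subject source-role covariances across LOSO folds.

    A subject's source-role features (its labeled test trials, own templates,
    own per-class alignment) do not depend on which other subject is the
    fold's target, so they are computed once per (alignment on/off) and
    reused in every fold — and across algorithms sharing the same setting.
    """

    def __init__(self, dataset: MultiSubjectDataset, config: ExperimentConfig):
        self.dataset = dataset
        self.config = config
        self._prepared: dict[str, np.ndarray] = {}
        self._source_covs: dict[tuple[str, bool], tuple[list[SuperCovariance], np.ndarray]] = {}

    def prepared(self, subject: SubjectDataset) -> np.ndarray:
        if subject.subject_id not in self._prepared:
            self._prepared[subject.subject_id] = _prepare(subject, self.config)
        return self._prepared[subject.subject_id]

    def source_covs(
        self, subject: SubjectDataset, aligned: bool
    ) -> tuple[list[SuperCovariance], np.ndarray]:
        key = (subject.subject_id, aligned)
        if key not in self._source_covs:
            prepared = self.prepared(subject)
            mask = subject.roles == "test"
            trials, labels = prepared[mask], subject.labels[mask]
            self._source_covs[key] = _covs_from_trials(
                trials, labels, self.config, subject.subject_id, supervised_align=aligned
            )
        return self._source_covs[key]

    def target_covs(
        self, subject: SubjectDataset, config: ExperimentConfig
    ) -> tuple[list[SuperCovariance], np.ndarray, list[SuperCovariance], np.ndarray]:
        """Training and test covariances for the fold's target subject."""
        prepared = self.prepared(subject)
        train_trials, train_labels = _target_training_trials(subject, prepared, config)
        aligned = config.uses_alignment

        if aligned and config.alignment_stage == "raw_trials":
            sup = leda.fit_supervised(train_trials, train_labels)
            train_trials_a = leda.apply_set(sup, train_trials, train_labels)
        else:
            train_trials_a = train_trials
        templates = make_templates(train_trials_a, train_labels)

        mask = subject.roles == "test"
        test_trials, test_labels = prepared[mask], subject.labels[mask]
        if aligned and config.alignment_stage == "raw_trials":
            unsup = leda.fit_unsupervised(test_trials)
            test_trials = leda.apply_set(unsup, test_trials)

        # Training classes are shifted copies of the same reference recordings;
        # exclude each recording from every class template of its own stacks.
        groups = np.tile(np.arange(config.n_train), len(train_labels) // config.n_train)
        train_sts = _jackknife_supertrials(
            train_trials_a, train_labels, subject_id=subject.subject_id, groups=groups
        )
        test_sts = [
            build_supertrial(templates, test_trials[i]) for i in range(test_trials.shape[0])
        ]
        if aligned and config.alignment_stage == "super_trials":
            stacks = np.stack([st.values for st in train_sts])
            sup = leda.fit_supervised(stacks, train_labels)
            a = leda.apply_set(sup, stacks, train_labels)
            for i, st in enumerate(train_sts):
                object.__setattr__(st, "values", a[i])
            stacks = np.stack([st.values for st in test_sts])
            unsup = leda.fit_unsupervised(stacks)
            a = leda.apply_set(unsup, stacks)
            for i, st in enumerate(test_sts):
                object.__setattr__(st, "values", a[i])

        train_covs = [supertrial_cov(st, config.shrinkage) for st in train_sts]
        test_covs = [supertrial_cov(st, config.shrinkage) for st in test_sts]
        return train_covs, train_labels, test_covs, np.asarray(test_labels, dtype=int)

    def run_fold(
        self, target: SubjectDataset, config: ExperimentConfig
    ) -> tuple[float, list[str], np.ndarray, np.ndarray]:
        t0 = time.perf_counter()
        train_covs, train_labels, test_covs, test_labels = self.target_covs(target, config)
        aligned = config.uses_alignment

        selected: list[str] = []
        if config.uses_transfer:
            sources = {
                s.subject_id: self.source_covs(s, aligned)
                for s in self.dataset.subjects
                if s.subject_id != target.subject_id
            }
            if config.algorithm == "tl-leda-tss":
                sel = tss(
                    sources,
                    (train_covs, train_labels),
                    metric=config.metric,
                    include_target_in_pool=config.include_target_in_tss,
                )
                selected = sel.selected
                sources = {sid: sources[sid] for sid in selected}
            else:
                selected = sorted(sources)
            pool_covs = list(train_covs)
            pool_labels = list(train_labels)
            for sid in sorted(sources):
                covs, labels = sources[sid]
                pool_covs += list(covs)
                pool_labels += list(labels)
            model = train_mdm(pool_covs, np.array(pool_labels), metric=config.metric)
        else:
            model = train_mdm(train_covs, train_labels, metric=config.metric)

        pred = _predict_labels(model, test_covs)
        acc = float(np.mean(pred == test_labels))
        logger.info(
            "fold %s [%s]: accuracy %.3f (%.1f s)",
            target.subject_id,
            config.algorithm,
            acc,
            time.perf_counter() - t0,
        )
        return acc, selected, pred, test_labels


def run_loso(dataset: MultiSubjectDataset, config: ExperimentConfig) -> ExperimentResult:
    """Leave-one-subject-out evaluation of one algorithm/condition.

    A fold that raises is logged and recorded in ``result.failures``; the
    remaining folds are still reported.
    """
    if len(dataset) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    runner = _FoldRunner(dataset, config)
    return _run_with_runner(runner, config)


def _run_with_runner(runner: _FoldRunner, config: ExperimentConfig) -> ExperimentResult:
    dataset = runner.dataset
    T = config.cycle_multiple * dataset.codebook.period_s + GAZE_SHIFT_S
    M = dataset.codebook.n_targets
    result = ExperimentResult(algorithm=config.algorithm, per_subject={}, config=config.echo())
    for target in dataset.subjects:
        try:
            acc, selected, pred, truth = runner.run_fold(target, config)
        except Exception as exc:  # noqa: BLE001 — report partial results
            logger.error("fold %s failed: %s", target.subject_id, exc)
            result.failures[target.subject_id] = str(exc)
            continue
        sid = target.subject_id
        result.per_subject[sid] = acc
        result.selected_sources[sid] = selected
        result.predictions[sid] = (pred, truth)
        result.itr_per_subject[sid] = itr(M, acc, T)
    if not result.per_subject:
        raise RuntimeError(f"every LOSO fold failed: {result.failures}")
    return result


def compare_algorithms(
    dataset: MultiSubjectDataset,
    config: ExperimentConfig = ExperimentConfig(),
    algorithms: tuple[str, ...] = ALGORITHMS,
) -> dict[str, ExperimentResult]:
    """Run several algorithms on one dataset, sharing per-subject features.

    Source-role covariances depend only on whether alignment is applied, so
    the aligned set is computed once for both LEDA variants and the
    unaligned set once for ``tl-ass`` — roughly halving the cost of the
    four-way comparison.
    """
    runner = _FoldRunner(dataset, config)
    results = {}
    for alg in algorithms:
        cfg = replace(config, algorithm=alg)
        results[alg] = _run_with_runner(runner, cfg)
    return results


def sweep(
    dataset: MultiSubjectDataset,
    base_config: ExperimentConfig,
    parameter: str,
    values: list,
) -> pd.DataFrame:
    """Re-run LOSO for each value of one config parameter.

    Returns a tidy frame with one row per (value, target subject) plus the
    config echo, suitable for plotting the data-length / channel-count /
    training-trial relationships.
    """
    if parameter not in ("cycle_multiple", "n_channels", "n_train"):
        raise ValueError(f"unsupported sweep parameter {parameter!r}")
    if not values:
        raise ValueError("values must be nonempty")
    rows = []
    for v in values:
        cfg = replace(base_config, **{parameter: v})
        res = run_loso(dataset, cfg)
        for sid, acc in res.per_subject.items():
            rows.append(
                {
                    "parameter": parameter,
                    "value": v,
                    "subject": sid,
                    "accuracy": acc,
                    "itr_bits_per_min": res.itr_per_subject[sid],
                    **{f"config_{k}": val for k, val in res.config.items()},
                }
            )
    return pd.DataFrame(rows)


def results_to_frame(results: dict[str, ExperimentResult]) -> pd.DataFrame:
    """Flatten algorithm → result mappings to one row per subject × algorithm."""
    rows = []
    for alg, res in results.items():
        for sid, acc in res.per_subject.items():
            rows.append(
                {
                    "algorithm": alg,
                    "subject": sid,
                    "accuracy": acc,
                    "itr_bits_per_min": res.itr_per_subject[sid],
                }
            )
    return pd.DataFrame(rows)


def paired_ttest(a: ExperimentResult, b: ExperimentResult) -> float:
    """Two-sided paired t-test p-value on per-subject accuracies.

    No multiple-testing correction is applied; callers comparing many pairs
    should account for that themselves.
    """
    from scipy import stats

    common = sorted(set(a.per_subject) & set(b.per_subject))
    if len(common) < 2:
        raise ValueError("need at least 2 common subjects")
    x = [a.per_subject[s] for s in common]
    y = [b.per_subject[s] for s in common]
    if np.allclose(x, y):
        return 1.0
    return float(stats.ttest_rel(x, y).pvalue)
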