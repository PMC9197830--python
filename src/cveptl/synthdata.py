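"""Synthetic multi-subject c-VEP EEG with controllable cross-subject shift.

The generator produces the statistical structure the decoding pipeline
assumes and exploits:

* a code-locked response — the bipolar stimulus waveform circularly
  convolved with a subject-specific visual-evoked-potential kernel, so a
  trial of target ``z`` is exactly the reference-target trial rotated by
  the target's code lag;
* subject-specific spatial projection (``mixing``) and temporal kernel,
  drawn around *cluster prototypes* so that some source subjects resemble a
  given target subject more than others (the situation subject selection is
  meant to exploit);
* a subject-specific invertible channel transform whose magnitude is set by
  ``shift_strength`` — a linear distribution shift of exactly the kind
  congruence-invariant alignment can remove;
* additive Gaussian channel noise scaled to a per-subject SNR.

Trial counts mirror the standard acquisition protocol: training trials are
recorded only at the reference target (one stimulus cycle per trial), test
trials cover every target.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal

from .codes import BinaryCode, CodeBook, default_codebook

__all__ = [
    "SubjectModel",
    "SubjectDataset",
    "MultiSubjectDataset",
    "code_waveform",
    "vep_kernel",
    "noiseless_trial",
    "simulate_subject",
    "simulate_population",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger(__name__)

#: Default sampling rate.  600 Hz puts exactly 10 samples on each bit of a
#: 60 Hz code, so a 4-bit inter-target lag is an exact 40-sample rotation
#: and shift-based training-data synthesis is sample-exact.
DEFAULT_FS = 600.0

ROLE_TRAIN = "train_reference"
ROLE_TEST = "test"


def code_waveform(code: BinaryCode, fs: float, n_cycles: float = 1.0) -> np.ndarray:
    """Sample the bipolar (±1) flicker waveform at ``fs`` for ``n_cycles``.

    Sample ``t`` takes the value of bit ``floor(t · bit_rate / fs) mod L``,
    which is exact for any rational samples-per-bit ratio.
    """
    n_samples = round(n_cycles * fs * code.period_s)
    idx = (np.floor(np.arange(n_samples) * code.bit_rate / fs)).astype(int) % len(code)
    return code.bipolar()[idx]


def vep_kernel(
    fs: float,
    peak_s: float = 0.10,
    undershoot_s: float = 0.18,
    undershoot_weight: float = 0.5,
    duration_s: float = 0.30,
) -> np.ndarray:
    """Difference-of-gamma visual-evoked-response kernel, peak amplitude 1.

    A positive gamma bump peaking at ``peak_s`` minus a slower bump peaking
    at ``undershoot_s`` — the simplest waveform with the biphasic,
    ~100 ms-latency shape of an occipital flash response.
    """
    t = np.arange(round(duration_s * fs)) / fs

    def gamma_bump(peak: float, shape: float = 5.0) -> np.ndarray:
        theta = peak / (shape - 1.0)
        g = (t / theta) ** (shape - 1) * np.exp(-(t - peak) / theta)
        return g / g.max()

    k = gamma_bump(peak_s) - undershoot_weight * gamma_bump(undershoot_s, shape=7.0)
    return k / np.abs(k).max()


@dataclass(frozen=True)
class SubjectModel:
    """Forward model of one simulated subject.

    ``mixing`` projects the single code-locked source onto channels,
    ``channel_transform`` is the subject-specific invertible linear shift
    applied on top (identity = no cross-subject shift), ``noise_sd`` scales
    the stationary RMS of per-channel Gaussian noise, ``noise_ar`` is the
    AR(1) coefficient of that noise (0 = white; EEG background activity is
    strongly temporally correlated), ``latency_s`` delays the response.
    ``trial_amp_jitter`` (SD of a per-trial lognormal gain) and
    ``trial_latency_jitter_s`` (SD of a per-trial response delay) model the
    trial-to-trial variability of real evoked responses; both default to 0,
    making the noiseless trial exactly equal to the class template.
    """

    impulse_response: np.ndarray
    mixing: np.ndarray  # (n_channels,)
    channel_transform: np.ndarray  # (n_channels, n_channels)
    noise_sd: float = 0.0
    noise_ar: float = 0.0
    latency_s: float = 0.0
    trial_amp_jitter: float = 0.0
    trial_latency_jitter_s: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.noise_ar < 1:
            raise ValueError("noise_ar must be in [0, 1)")
        T = np.asarray(self.channel_transform)
        cond = np.linalg.cond(T)
        if not np.isfinite(cond):
            raise ValueError("channel_transform is singular")
        logger.debug("channel_transform condition number: %.3g", cond)

    @property
    def n_channels(self) -> int:
        return len(self.mixing)


def _source_cycle(model: SubjectModel, codebook: CodeBook, z: int, fs: float) -> np.ndarray:
    """Noise-free source waveform for one full cycle of target ``z``."""
    wave = code_waveform(codebook.codes[z], fs, 1.0)
    n = len(wave)
    kernel = np.zeros(n)
    h = model.impulse_response[:n]
    kernel[: len(h)] = h
    # Circular convolution: the flicker is periodic, so the steady-state
    # response wraps around the cycle.
    resp = np.fft.irfft(np.fft.rfft(wave) * np.fft.rfft(kernel), n=n)
    lat = round(model.latency_s * fs)
    if lat:
        resp = np.roll(resp, lat)
    return resp


def noiseless_trial(
    model: SubjectModel, codebook: CodeBook, z: int, fs: float, cycle_multiple: float = 1.0
) -> np.ndarray:
    """Noise-free channels × samples trial of target ``z`` (the template)."""
    cycle = _source_cycle(model, codebook, z, fs)
    n_samples = round(cycle_multiple * fs * codebook.period_s)
    reps = math.ceil(n_samples / len(cycle))
    source = np.tile(cycle, reps)[:n_samples]
    return model.channel_transform @ (np.outer(model.mixing, source))


def simulate_subject(
    model: SubjectModel,
    codebook: CodeBook,
    n_train: int = 100,
    n_test_per_target: int = 5,
    fs: float = DEFAULT_FS,
    seed: int | np.random.SeedSequence = 0,
    cycle_multiple: float = 1.0,
    subject_id: str = "S00",
) -> "SubjectDataset":
    """Simulate one subject's session.

    ``n_train`` trials are recorded at the codebook's reference target (the
    single-reference training protocol); ``n_test_per_target`` test trials
    are recorded at every target.  Each trial is the noiseless template plus
    fresh Gaussian channel noise, passed through the subject's channel
    transform.  Fully reproducible from ``seed``.
    """
    spb = fs * codebook.period_s / len(codebook.base)
    if spb < 2:
        raise ValueError(
            f"sampling rate {fs} Hz resolves only {spb:.2f} samples per code "
            "bit; need at least 2"
        )
    rng = np.random.default_rng(seed)
    Z = codebook.n_targets
    nc = model.n_channels
    n_samples = round(cycle_multiple * fs * codebook.period_s)

    # Pre-transform noiseless source projections for each target.
    clean = {}
    ref = codebook.reference_target
    targets = [ref] + [z for z in range(Z)]
    for z in set(targets):
        cycle = _source_cycle(model, codebook, z, fs)
        reps = math.ceil(n_samples / len(cycle))
        source = np.tile(cycle, reps)[:n_samples]
        clean[z] = np.outer(model.mixing, source)

    n_total = n_train + n_test_per_target * Z
    trials = np.empty((n_total, nc, n_samples), dtype=np.float64)
    labels = np.empty(n_total, dtype=int)
    roles = np.empty(n_total, dtype=object)

    def one_trial(z: int) -> np.ndarray:
        signal = clean[z]
        if model.trial_latency_jitter_s > 0:
            lat = round(rng.normal(0.0, model.trial_latency_jitter_s) * fs)
            if lat:
                signal = np.roll(signal, lat, axis=-1)
        if model.trial_amp_jitter > 0:
            signal = signal * np.exp(rng.normal(0.0, model.trial_amp_jitter))
        if model.noise_sd:
            white = rng.normal(0.0, 1.0, (nc, n_samples))
            if model.noise_ar:
                # AR(1) noise with stationary RMS = noise_sd.
                white = scipy.signal.lfilter([1.0], [1.0, -model.noise_ar], white, axis=-1)
                noise = model.noise_sd * math.sqrt(1.0 - model.noise_ar**2) * white
            else:
                noise = model.noise_sd * white
        else:
            noise = 0.0
        return model.channel_transform @ (signal + noise)

    i = 0
    for _ in range(n_train):
        trials[i] = one_trial(ref)
        labels[i], roles[i] = ref, ROLE_TRAIN
        i += 1
    for z in range(Z):
        for _ in range(n_test_per_target):
            trials[i] = one_trial(z)
            labels[i], roles[i] = z, ROLE_TEST
            i += 1

    return SubjectDataset(
        subject_id=subject_id,
        trials=trials.astype(np.float32),
        labels=labels,
        roles=np.array(roles, dtype="U16"),
        fs=fs,
        codebook=codebook,
        cycle_multiple=cycle_multiple,
    )


@dataclass
class SubjectDataset:
    """Epoched, labeled trials of one subject (trials × channels × samples)."""

    subject_id: str
    trials: np.ndarray
    labels: np.ndarray
    roles: np.ndarray
    fs: float
    codebook: CodeBook
    cycle_multiple: float = 1.0

    def __post_init__(self) -> None:
        n = self.trials.shape[0]
        if len(self.labels) != n or len(self.roles) != n:
            raise ValueError("labels/roles length must match trial count")
        expected = round(self.cycle_multiple * self.fs * self.codebook.period_s)
        if self.trials.shape[2] != expected:
            raise ValueError(
                f"trial length {self.trials.shape[2]} != round(k*fs*period) = {expected}"
            )
        train = self.roles == ROLE_TRAIN
        if train.any() and not (
            self.labels[train] == self.codebook.reference_target
        ).all():
            raise ValueError("training trials must carry the reference-target label")

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    def train_trials(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.roles == ROLE_TRAIN
        return self.trials[mask], self.labels[mask]

    def test_trials(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.roles == ROLE_TEST
        return self.trials[mask], self.labels[mask]


@dataclass
class MultiSubjectDataset:
    """A pool of subjects sharing sampling rate, montage, and codebook."""

    subjects: list[SubjectDataset]
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subjects:
            s0 = self.subjects[0]
            for s in self.subjects[1:]:
                if s.fs != s0.fs or s.n_channels != s0.n_channels:
                    raise ValueError("all subjects must share fs and channel count")
                if s.codebook.to_json() != s0.codebook.to_json():
                    raise ValueError("all subjects must share the codebook")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def codebook(self) -> CodeBook:
        return self.subjects[0].codebook

    @property
    def fs(self) -> float:
        return self.subjects[0].fs


# -- population generation ---------------------------------------------------

#: Generator defaults.  The cross-subject shift magnitude, amplitude spread
#: and SNR band were fixed once, at design time, so that the synthetic
#: population occupies the qualitative regime the pipeline is built for:
#: single-trial decoding well off ceiling at few training trials, a
#: channel-frame/amplitude shift large enough that pooling unaligned
#: subjects hurts, and response-kernel clusters that make some sources
#: genuinely better than others.
DEFAULT_SHIFT_STRENGTH = 0.3
DEFAULT_SNR_RANGE = (0.35, 0.5)
#: SD of the per-subject log-amplitude factor.  EEG amplitude varies
#: severalfold across subjects; this lognormal spread (roughly x0.4..x2.5
#: over 2 SD) is the dominant "distribution shift" that alignment removes.
DEFAULT_AMPLITUDE_LOG_SD = 0.5
#: Trial-to-trial response variability: SD of the per-trial lognormal gain
#: and of the per-trial latency jitter (seconds).  Evoked responses are not
#: identical across repetitions; this keeps training-set accuracy off
#: ceiling, which the training-accuracy-based subject selection relies on.
DEFAULT_TRIAL_AMP_JITTER = 0.15
DEFAULT_TRIAL_LATENCY_JITTER_S = 0.004
#: AR(1) coefficient of the background noise.  EEG background activity has a
#: 1/f-like spectrum; temporally correlated noise has far fewer effective
#: degrees of freedom per trial than white noise, so single-trial covariance
#: estimates scatter realistically instead of collapsing onto their mean.
DEFAULT_NOISE_AR = 0.9


def _make_prototypes(
    rng: np.random.Generator, n_clusters: int, n_channels: int
) -> list[dict]:
    """Cluster prototypes with guaranteed separation in kernel shape/latency.

    Centers are spread evenly across plausible ranges of peak latency
    (95–110 ms), response delay (0–35 ms) and undershoot weight, so that
    clusters differ measurably while all stay physiological.  Kernel-shape
    differences are deliberately moderate: they are the one shift a linear
    alignment cannot undo, so they set the residual bias of cross-cluster
    transfer (too large and pooling all aligned subjects stops paying off;
    too small and ranking sources has nothing to find).
    """
    protos = []
    for i in range(n_clusters):
        frac = 0.5 if n_clusters == 1 else i / (n_clusters - 1)
        mixing = np.abs(rng.normal(1.0, 0.5, size=n_channels))
        mixing = mixing / np.linalg.norm(mixing) * np.sqrt(n_channels)
        protos.append(
            {
                "peak_s": 0.095 + 0.015 * frac + float(rng.normal(0.0, 0.002)),
                "undershoot_weight": 0.42 + 0.16 * (i % 2) + float(rng.normal(0.0, 0.03)),
                "latency_s": 0.035 * frac + float(rng.normal(0.0, 0.002)),
                "mixing": mixing,
            }
        )
    return protos


def _draw_subject_model(
    rng: np.random.Generator,
    n_channels: int,
    cluster_proto: dict,
    shift_strength: float,
    fs: float,
    amplitude_log_sd: float = DEFAULT_AMPLITUDE_LOG_SD,
) -> SubjectModel:
    """One subject's forward model: cluster prototype plus within-cluster jitter."""
    peak = cluster_proto["peak_s"] + rng.normal(0.0, 0.004)
    weight = np.clip(cluster_proto["undershoot_weight"] + rng.normal(0.0, 0.04), 0.1, 0.9)
    kernel = vep_kernel(fs, peak_s=float(np.clip(peak, 0.06, 0.14)), undershoot_weight=float(weight))

    mixing = cluster_proto["mixing"] + 0.08 * rng.normal(size=n_channels)
    mixing = mixing / np.linalg.norm(mixing) * np.sqrt(n_channels)
    # Subject-specific global amplitude: the severalfold gain differences
    # (skull, electrode impedance) that dominate cross-subject shift in EEG.
    mixing = mixing * np.exp(rng.normal(0.0, amplitude_log_sd))

    if shift_strength > 0:
        A = rng.normal(size=(n_channels, n_channels)) / np.sqrt(n_channels)
        T = np.eye(n_channels) + shift_strength * A
        # Re-draw in the (rare) event of near-singularity.
        while np.linalg.cond(T) > 1e6:
            A = rng.normal(size=(n_channels, n_channels)) / np.sqrt(n_channels)
            T = np.eye(n_channels) + shift_strength * A
    else:
        T = np.eye(n_channels)

    latency = float(cluster_proto["latency_s"] + rng.normal(0.0, 0.003))
    return SubjectModel(
        impulse_response=kernel,
        mixing=mixing,
        channel_transform=T,
        noise_sd=0.0,  # set by the caller from the realized signal RMS
        latency_s=latency,
    )


def simulate_population(
    n_subjects: int = 16,
    similarity_clusters: int = 2,
    shift_strength: float = DEFAULT_SHIFT_STRENGTH,
    snr_range: tuple[float, float] = DEFAULT_SNR_RANGE,
    seed: int = 0,
    codebook: CodeBook | None = None,
    n_channels: int = 9,
    n_train: int = 100,
    n_test_per_target: int = 5,
    fs: float = DEFAULT_FS,
    cycle_multiple: float = 1.0,
    amplitude_log_sd: float = DEFAULT_AMPLITUDE_LOG_SD,
    trial_amp_jitter: float = DEFAULT_TRIAL_AMP_JITTER,
    trial_latency_jitter_s: float = DEFAULT_TRIAL_LATENCY_JITTER_S,
    noise_ar: float = DEFAULT_NOISE_AR,
) -> MultiSubjectDataset:
    """Simulate a multi-subject c-VEP study.

    Subjects are assigned round-robin to ``similarity_clusters`` kernel/
    montage prototypes; within a cluster, kernels and mixing vectors are
    close, across clusters they differ substantially.  ``shift_strength``
    scales each subject's random invertible channel transform
    (0 → identity, i.e. no cross-subject frame shift).  Each subject's
    amplitude SNR is drawn uniformly from ``snr_range``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if similarity_clusters < 1:
        raise ValueError("similarity_clusters must be >= 1")
    if codebook is None:
        codebook = default_codebook()
    root = np.random.SeedSequence(seed)
    proto_rng = np.random.default_rng(root.spawn(1)[0])
    protos = _make_prototypes(proto_rng, similarity_clusters, n_channels)

    subjects = []
    subject_seeds = root.spawn(n_subjects + 1)[1:]
    for i in range(n_subjects):
        s_rng = np.random.default_rng(subject_seeds[i])
        proto = protos[i % similarity_clusters]
        # Infinite SNR means noiseless subjects (used by exactness tests).
        snr = math.inf if math.isinf(snr_range[0]) else float(s_rng.uniform(*snr_range))
        model = _draw_subject_model(
            s_rng, n_channels, proto, shift_strength, fs, amplitude_log_sd
        )
        # Amplitude SNR is defined against the realized pre-transform signal:
        # mean per-channel RMS of mixing ⊗ (kernel-convolved code waveform).
        source_rms = float(
            np.sqrt(np.mean(_source_cycle(model, codebook, codebook.reference_target, fs) ** 2))
        )
        signal_rms = float(np.mean(np.abs(model.mixing))) * source_rms
        model = dataclasses.replace(
            model,
            noise_sd=signal_rms / snr,
            noise_ar=noise_ar,
            trial_amp_jitter=trial_amp_jitter,
            trial_latency_jitter_s=trial_latency_jitter_s,
        )
        ds = simulate_subject(
            model,
            codebook,
            n_train=n_train,
            n_test_per_target=n_test_per_target,
            fs=fs,
            seed=subject_seeds[i].spawn(1)[0],
            cycle_multiple=cycle_multiple,
            subject_id=f"S{i:02d}",
        )
        subjects.append(ds)

    config = {
        "n_subjects": n_subjects,
        "similarity_clusters": similarity_clusters,
        "shift_strength": shift_strength,
        "snr_range": list(snr_range),
        "n_channels": n_channels,
        "n_train": n_train,
        "n_test_per_target": n_test_per_target,
        "fs": fs,
        "cycle_multiple": cycle_multiple,
    }
    return MultiSubjectDataset(subjects=subjects, seed=seed, config=config)


# -- on-disk container -------------------------------------------------------


def write_dataset(dataset: MultiSubjectDataset, path: str | Path) -> None:
    """Write a dataset directory: ``meta.json`` plus per-subject arrays.

    Per subject: ``<id>.bin`` (little-endian float32, C-order, trials ×
    channels × samples) and ``<id>.labels.csv`` (trial_index, target, role).
    Round-trips bit-exactly with :func:`read_dataset`.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": dataset.fs,
        "codebook": json.loads(dataset.codebook.to_json()),
        "seed": dataset.seed,
        "config": dataset.config,
        "subjects": [
            {
                "id": s.subject_id,
                "n_trials": int(s.trials.shape[0]),
                "n_channels": int(s.trials.shape[1]),
                "n_samples": int(s.trials.shape[2]),
                "cycle_multiple": s.cycle_multiple,
            }
            for s in dataset.subjects
        ],
    }
    (root / "meta.json").write_text(json.dumps(meta, indent=1))
    for s in dataset.subjects:
        arr = np.ascontiguousarray(s.trials, dtype="<f4")
        arr.tofile(root / f"{s.subject_id}.bin")
        lines = ["trial_index,target,role"]
        lines += [
            f"{i},{int(s.labels[i])},{s.roles[i]}" for i in range(len(s.labels))
        ]
        (root / f"{s.subject_id}.labels.csv").write_text("\n".join(lines) + "\n")


def read_dataset(path: str | Path) -> MultiSubjectDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    root = Path(path)
    meta = json.loads((root / "meta.json").read_text())
    codebook = CodeBook.from_json(json.dumps(meta["codebook"]))
    subjects = []
    for rec in meta["subjects"]:
        shape = (rec["n_trials"], rec["n_channels"], rec["n_samples"])
        trials = np.fromfile(root / f"{rec['id']}.bin", dtype="<f4").reshape(shape)
        lines = (root / f"{rec['id']}.labels.csv").read_text().strip().split("\n")[1:]
        labels = np.empty(len(lines), dtype=int)
        roles = np.empty(len(lines), dtype="U16")
        for line in lines:
            idx, target, role = line.split(",")
            labels[int(idx)] = int(target)
            roles[int(idx)] = role
        subjects.append(
            SubjectDataset(
                subject_id=rec["id"],
                trials=trials,
                labels=labels,
                roles=roles,
                fs=meta["fs"],
                codebook=codebook,
                cycle_multiple=rec["cycle_multiple"],
            )
        )
    return MultiSubjectDataset(
        subjects=subjects, seed=meta.get("seed"), config=meta.get("config", {})
    )
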