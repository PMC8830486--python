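"""Cleaning and epoching of raw EEG recordings.

The stage chain mirrors standard resting-state practice: band-pass filter,
automatic bad-channel removal (flat channels and channels whose standard
deviation is a robust outlier), common average reference (CAR),
segmentation into fixed-length epochs, amplitude-threshold epoch rejection,
ICA decomposition/reconstruction with a pluggable automatic artifact rule,
and truncation to a common epoch count across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.signal import butter, filtfilt
from sklearn.decomposition import FastICA

from .recording import EEGRecording

__all__ = [
    "PreprocessConfig",
    "CleanEpochs",
    "bandpass_filter",
    "detect_bad_channels",
    "segment_epochs",
    "rereference_car",
    "reject_epochs_by_amplitude",
    "ica_decompose_reconstruct",
    "truncate_to_common_epochs",
    "preprocess_recording",
    "frontal_template_rule",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning parameters.

    ``flat_tolerance`` (microvolts) is the SD floor below which a channel
    counts as flat; ``noise_sd_multiplier`` the robust z-score (about the
    median channel SD) above which a channel counts as noisy.  Epochs are
    ``epoch_length`` seconds, rejected when any channel exceeds
    ``amplitude_threshold`` microvolts (strictly above; the boundary value
    is retained), and the first ``n_keep_epochs`` clean epochs are kept.
    """

    flat_tolerance: float = 0.1
    noise_sd_multiplier: float = 3.0
    bad_channel_detection: bool = True
    epoch_length: float = 2.0
    amplitude_threshold: float = 55.0
    n_keep_epochs: int = 30
    bandpass: tuple[float, float] | None = (0.5, 45.0)
    ica_enabled: bool = True
    ica_artifact_rule: str | Callable = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be > 0")
        if self.amplitude_threshold <= 0:
            raise ValueError("amplitude_threshold must be > 0")
        if self.n_keep_epochs < 1:
            raise ValueError("n_keep_epochs must be >= 1")


@dataclass
class CleanEpochs:
    """Epoched, cleaned EEG: channels x epochs x samples in microvolts."""

    subject_id: str
    channel_labels: list[str]
    epochs: np.ndarray
    sampling_rate: float
    removed_channels: list[str] = field(default_factory=list)
    rejection_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be channels x epochs x samples")
        if self.epochs.shape[0] != len(self.channel_labels):
            raise ValueError("channel count does not match labels")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[1]


def bandpass_filter(
    recording: EEGRecording, band: tuple[float, float] = (0.5, 45.0), order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass; the upper edge is clipped below
    Nyquist when the sampling rate is too low for the requested band."""
    lo, hi = band
    nyquist = recording.sampling_rate / 2.0
    hi = min(hi, 0.95 * nyquist)
    if lo >= hi:
        raise ValueError(f"band [{lo}, {hi}] Hz invalid at fs={recording.sampling_rate}")
    b, a = butter(order, [lo / nyquist, hi / nyquist], btype="band")
    filtered = filtfilt(b, a, recording.data, axis=1)
    return EEGRecording(
        subject_id=recording.subject_id,
        channel_labels=list(recording.channel_labels),
        data=filtered,
        sampling_rate=recording.sampling_rate,
        meta=dict(recording.meta),
    )


def detect_bad_channels(recording: EEGRecording, cfg: PreprocessConfig) -> list[str]:
    """Flat or noise-dominated channels, in input label order.

    A channel is flagged when its SD is below ``cfg.flat_tolerance`` or when
    its robust z-score -- (SD - median SD) / (1.4826 MAD) across channels --
    exceeds ``cfg.noise_sd_multiplier``.  Flagging every channel is fatal.
    """
    if recording.n_channels < 2:
        raise ValueError("bad-channel detection needs at least 2 channels")
    sds = recording.data.std(axis=1)
    median_sd = float(np.median(sds))
    mad = float(np.median(np.abs(sds - median_sd)))
    scale = 1.4826 * mad
    bad = []
    for label, sd in zip(recording.channel_labels, sds):
        flat = sd < cfg.flat_tolerance
        noisy = scale > 0 and (sd - median_sd) / scale > cfg.noise_sd_multiplier
        if flat or noisy:
            bad.append(label)
    if len(bad) == recording.n_channels:
        raise ValueError("no usable channels: every channel flagged as bad")
    return bad


def segment_epochs(recording: EEGRecording, cfg: PreprocessConfig) -> CleanEpochs:
    """Cut the recording into consecutive non-overlapping epochs.

    The trailing partial window is dropped; a recording shorter than one
    epoch is an error.
    """
    samples_per_epoch = int(round(cfg.epoch_length * recording.sampling_rate))
    n_epochs = recording.n_samples // samples_per_epoch
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.duration:.2f}s shorter than one "
            f"{cfg.epoch_length}s epoch"
        )
    used = n_epochs * samples_per_epoch
    epochs = recording.data[:, :used].reshape(
        recording.n_channels, n_epochs, samples_per_epoch
    )
    return CleanEpochs(
        subject_id=recording.subject_id,
        channel_labels=list(recording.channel_labels),
        epochs=epochs.copy(),
        sampling_rate=recording.sampling_rate,
    )


def rereference_car(epochs: CleanEpochs) -> CleanEpochs:
    """Common average reference: subtract the instantaneous cross-channel
    mean, so every sample's channel mean becomes zero.  Idempotent."""
    if epochs.epochs.shape[0] < 2:
        raise ValueError("CAR undefined for a single channel")
    referenced = epochs.epochs - epochs.epochs.mean(axis=0, keepdims=True)
    return replace(epochs, epochs=referenced)


def reject_epochs_by_amplitude(epochs: CleanEpochs, cfg: PreprocessConfig) -> CleanEpochs:
    """Drop epochs whose peak absolute amplitude exceeds the threshold.

    The comparison is strict: an epoch peaking exactly at the threshold is
    retained.  Surviving nothing is fatal with a count report.
    """
    peaks = np.abs(epochs.epochs).max(axis=(0, 2))
    keep = peaks <= cfg.amplitude_threshold
    log = [
        {
            "epoch": int(e),
            "kept": bool(k),
            "reason": "" if k else f"peak {peaks[e]:.1f} uV > {cfg.amplitude_threshold} uV",
        }
        for e, k in enumerate(keep)
    ]
    if not keep.any():
        raise ValueError(
            f"subject {epochs.subject_id}: all {len(keep)} epochs exceed "
            f"{cfg.amplitude_threshold} uV"
        )
    return replace(
        epochs,
        epochs=epochs.epochs[:, keep, :],
        rejection_log=epochs.rejection_log + log,
    )


def frontal_template_rule(threshold: float = 0.8) -> Callable:
    """Artifact rule flagging components whose scalp projection correlates
    with a frontal (ocular) template above ``threshold``."""
    weights = {"FP1": 1.0, "FP2": 1.0, "FPZ": 1.0, "F3": 0.5, "F4": 0.5,
               "F7": 0.5, "F8": 0.5, "FZ": 0.5}

    def rule(channel_labels: list[str], mixing: np.ndarray, sources: np.ndarray) -> list[int]:
        template = np.array([weights.get(lab, 0.0) for lab in channel_labels])
        if template.std() == 0:
            return []
        flagged = []
        for k in range(mixing.shape[1]):
            topo = mixing[:, k]
            if topo.std() == 0:
                continue
            corr = abs(float(np.corrcoef(topo, template)[0, 1]))
            if corr > threshold:
                flagged.append(k)
        return flagged

    return rule


def _resolve_rule(rule: str | Callable) -> Callable | None:
    if callable(rule):
        return rule
    if rule in {"none", "", None}:
        return None
    if rule == "frontal_template":
        return frontal_template_rule()
    raise ValueError(f"unknown ICA artifact rule {rule!r}")


def ica_decompose_reconstruct(epochs: CleanEpochs, cfg: PreprocessConfig) -> CleanEpochs:
    """ICA artifact removal: u = W x, zero flagged rows, x' = W^-1 u'.

    The unmixing matrix is estimated on the concatenated epochs.  The
    artifact rule receives (channel labels, mixing matrix, source time
    courses) and returns component indices to zero; with nothing flagged the
    reconstruction equals the input to numerical precision.  One estimated
    component per input channel, except that rank-deficient data (e.g.
    after CAR) reduces the component count to the data rank.
    """
    if not cfg.ica_enabled:
        return epochs
    n_chan, n_epochs, n_samples = epochs.epochs.shape
    x = epochs.epochs.reshape(n_chan, n_epochs * n_samples)
    rank = int(np.linalg.matrix_rank(x, tol=1e-8 * float(np.abs(x).max() or 1.0)))
    if rank < 2:
        raise ValueError(
            f"subject {epochs.subject_id}: data rank {rank} too low for ICA; "
            "check for duplicated or flat channels"
        )
    n_components = min(n_chan, rank)
    ica = FastICA(
        n_components=n_components, random_state=cfg.seed, max_iter=1000, tol=1e-6
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence warnings on short data
        sources = ica.fit_transform(x.T).T  # (components, time)
    mixing = ica.mixing_  # (channels, components)
    rule = _resolve_rule(cfg.ica_artifact_rule)
    flagged = sorted(rule(epochs.channel_labels, mixing, sources)) if rule else []
    clean_sources = sources.copy()
    for k in flagged:
        clean_sources[k] = 0.0
    reconstructed = mixing @ clean_sources + ica.mean_[:, None]
    log = [{"ica_components": n_components, "ica_flagged": flagged}]
    return replace(
        epochs,
        epochs=reconstructed.reshape(n_chan, n_epochs, n_samples),
        rejection_log=epochs.rejection_log + log,
    )


def truncate_to_common_epochs(epochs: CleanEpochs, cfg: PreprocessConfig) -> CleanEpochs:
    """Keep the first ``cfg.n_keep_epochs`` epochs in temporal order."""
    if epochs.n_epochs < cfg.n_keep_epochs:
        raise ValueError(
            f"subject {epochs.subject_id}: only {epochs.n_epochs} clean epochs, "
            f"need {cfg.n_keep_epochs}"
        )
    return replace(epochs, epochs=epochs.epochs[:, : cfg.n_keep_epochs, :])


def preprocess_recording(
    recording: EEGRecording, cfg: PreprocessConfig = PreprocessConfig()
) -> CleanEpochs:
    """Full cleaning chain for one recording.

    Filter -> bad-channel removal -> CAR -> epoch -> amplitude rejection ->
    ICA reconstruction -> truncation to the common epoch count.
    """
    rec = bandpass_filter(recording, cfg.bandpass) if cfg.bandpass else recording
    bad = detect_bad_channels(rec, cfg) if cfg.bad_channel_detection else []
    if bad:
        keep = [i for i, lab in enumerate(rec.channel_labels) if lab not in bad]
        rec = EEGRecording(
            subject_id=rec.subject_id,
            channel_labels=[rec.channel_labels[i] for i in keep],
            data=rec.data[keep],
            sampling_rate=rec.sampling_rate,
            meta=dict(rec.meta),
        )
    epochs = segment_epochs(rec, cfg)
    epochs = rereference_car(epochs)
    epochs = reject_epochs_by_amplitude(epochs, cfg)
    epochs = ica_decompose_reconstruct(epochs, cfg)
    epochs = truncate_to_common_epochs(epochs, cfg)
    epochs.removed_channels = bad
    return epochs
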