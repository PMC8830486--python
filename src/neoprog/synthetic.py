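"""Reproducible synthetic EEG cohorts with planted statistical structure.

Every downstream stage of the pipeline is exercised on cohorts generated
here: multichannel recordings with planted narrowband oscillations, planted
phase-coupled channel pairs (for connectivity recovery), a per-subject
complexity schedule (for entropy recovery), optional artifacts (flat and
high-variance channels, supra-threshold epochs, ocular-like frontal
transients), and outcome scores on the 74-145 cognitive-composite scale
linearly coupled to a planted feature with a chosen effect size.

The generator emulates the *statistical shape* of a neonatal resting-state
EEG study -- sample sizes, channel montage, epoch structure, amplitude
scale of tens of microvolts, score range -- not neonatal EEG morphology
(no burst suppression, sleep states or volume conduction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert

from .complexity import permutation_entropy, spectral_entropy
from .recording import EEGRecording, validate_labels, write_recording_tsv

__all__ = [
    "OscillationSpec",
    "CouplingSpec",
    "DeltaComplexitySpec",
    "ArtifactSpec",
    "ScoreModel",
    "CohortSpec",
    "SyntheticCohort",
    "generate_recording",
    "plant_coupled_pair",
    "generate_cohort",
    "write_fixture",
    "read_fixture",
]

#: The 12-channel montage retained after bad-channel removal in a typical
#: 19-electrode neonatal recording.
DEFAULT_CHANNELS = ["C3", "F3", "F7", "FZ", "O1", "O2", "P3", "P4", "T3", "T4", "T5", "T6"]

_OCULAR_WEIGHTS = {"FP1": 1.0, "FP2": 1.0, "FPZ": 1.0, "F3": 0.6, "F4": 0.6,
                   "F7": 0.5, "F8": 0.5, "FZ": 0.5}


@dataclass(frozen=True)
class OscillationSpec:
    """A planted sinusoid: centre frequency (Hz), amplitude (uV), targets."""

    freq_hz: float
    amplitude_uv: float
    channels: tuple[str, ...] | str = "all"


@dataclass(frozen=True)
class CouplingSpec:
    """A planted phase-coupled channel pair.

    The source channel receives a narrowband (``band`` Hz) stochastic
    carrier of RMS ``amplitude_uv``; the target receives the carrier
    phase-shifted by ``lag`` radians, mixed at ``strength`` with an
    independent narrowband signal at ``1 - strength``.
    """

    pair: tuple[str, str]
    lag: float
    strength: float
    band: tuple[float, float] = (8.0, 12.0)
    amplitude_uv: float = 10.0


@dataclass(frozen=True)
class DeltaComplexitySpec:
    """Per-subject regularity plant in the delta band.

    The designated channel's delta component is ``(1-w) * tone + w * band
    noise`` with equal RMS parts, where ``w`` is the subject's entry in the
    cohort's complexity schedule: low w = regular oscillation, high w =
    irregular broadband delta.  Other channels use ``background_weight``.
    """

    freq_hz: float = 1.0
    amplitude_uv: float = 20.0
    band: tuple[float, float] = (0.5, 1.5)
    channel: str = "C3"
    background_weight: float = 0.5


@dataclass(frozen=True)
class ArtifactSpec:
    """Planted artifacts for preprocessing tests."""

    flat_channels: tuple[str, ...] = ()
    noisy_channels: tuple[str, ...] = ()
    noisy_sd_multiplier: float = 10.0
    supra_threshold_fraction: float = 0.0
    supra_amplitude_uv: float = 90.0
    ocular: bool = False
    ocular_amplitude_uv: float = 120.0


@dataclass(frozen=True)
class ScoreModel:
    """Linear score-feature coupling on the cognitive-composite scale.

    scores = baseline + slope * standardized(feature) + N(0, residual_sd),
    clipped to ``score_range``.  With the feature standardized, the planted
    population correlation is slope / sqrt(slope^2 + residual_sd^2).
    ``feature`` selects what is planted: the raw complexity schedule
    (``"gradient"``) or the realized permutation/spectral entropy of the
    planted delta component (``"delta_pen"`` / ``"delta_spen"``).
    """

    baseline: float = 105.0
    slope: float = 9.0
    residual_sd: float = 12.0
    feature: str = "gradient"
    score_range: tuple[float, float] = (74.0, 145.0)

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    @property
    def planted_rho(self) -> float:
        denom = np.hypot(self.slope, self.residual_sd)
        if denom == 0:
            return 0.0
        return float(self.slope / denom)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort; see module docstring.

    ``complexity_gradient`` is the per-subject noise-to-signal schedule: it
    multiplies the broadband noise SD and, when a delta-complexity plant is
    configured, sets the subject's tone/noise mixing weight.
    """

    n_subjects: int = 20
    sampling_rate: float = 512.0
    duration: float = 60.0
    channel_labels: tuple[str, ...] = tuple(DEFAULT_CHANNELS)
    oscillation_specs: tuple[OscillationSpec, ...] = ()
    coupling_specs: tuple[CouplingSpec, ...] = ()
    complexity_gradient: tuple[float, ...] | None = None
    delta_complexity: DeltaComplexitySpec | None = None
    artifact_spec: ArtifactSpec = ArtifactSpec()
    score_model: ScoreModel = ScoreModel()
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        n_samples = self.duration * self.sampling_rate
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("duration * sampling_rate must be integral")
        labels = validate_labels(list(self.channel_labels))
        object.__setattr__(self, "channel_labels", tuple(labels))
        for osc in self.oscillation_specs:
            if osc.channels != "all":
                for ch in osc.channels:
                    if ch not in self.channel_labels:
                        raise ValueError(f"oscillation target {ch!r} not in channel set")
        for cpl in self.coupling_specs:
            _validate_coupling(cpl, self.channel_labels)
        if self.complexity_gradient is not None and len(self.complexity_gradient) != self.n_subjects:
            raise ValueError("complexity_gradient must have one entry per subject")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def gradient(self) -> np.ndarray:
        if self.complexity_gradient is None:
            return np.ones(self.n_subjects)
        return np.asarray(self.complexity_gradient, dtype=float)


@dataclass
class SyntheticCohort:
    """Recordings, outcome scores and the planted ground truth."""

    spec: CohortSpec
    recordings: list[EEGRecording]
    scores: pd.Series
    ground_truth: dict

    def __post_init__(self) -> None:
        if len(self.recordings) != len(self.scores):
            raise ValueError("one score per recording required")


def _validate_coupling(cpl: CouplingSpec, labels: tuple[str, ...]) -> None:
    a, b = cpl.pair
    if a not in labels or b not in labels:
        raise ValueError(f"coupled pair {cpl.pair} not in channel set {labels}")
    if not (-np.pi < cpl.lag <= np.pi):
        raise ValueError("lag must lie in (-pi, pi]")
    if not (0.0 <= cpl.strength <= 1.0):
        raise ValueError("coupling strength must lie in [0, 1]")


def _narrowband_noise(rng: np.random.Generator, band: tuple[float, float],
                      fs: float, n: int, rms: float) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    b, a = butter(4, [lo / nyq, hi / nyq], btype="band")
    # pad so the filter transient does not bias the retained segment
    pad = min(4 * n, int(10 * fs))
    raw = rng.standard_normal(n + 2 * pad)
    sig = filtfilt(b, a, raw)[pad : pad + n]
    sd = sig.std()
    return sig * (rms / sd) if sd > 0 else sig


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Shift the instantaneous phase of a narrowband signal by ``lag`` rad."""
    return np.real(hilbert(x) * np.exp(-1j * lag))


def _subject_rng(spec: CohortSpec, subject_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_index, stream))
    )


def _delta_component(spec: CohortSpec, subject_index: int, channel: str,
                     rng: np.random.Generator) -> np.ndarray | None:
    dc = spec.delta_complexity
    if dc is None:
        return None
    if channel == dc.channel:
        w = float(np.clip(spec.gradient()[subject_index], 0.0, 1.0))
    else:
        w = dc.background_weight
    t = np.arange(spec.n_samples) / spec.sampling_rate
    phase = rng.uniform(0, 2 * np.pi)
    tone = dc.amplitude_uv * np.sin(2 * np.pi * dc.freq_hz * t + phase)
    noise = _narrowband_noise(rng, dc.band, spec.sampling_rate, spec.n_samples,
                              rms=dc.amplitude_uv / np.sqrt(2.0))
    return (1.0 - w) * tone + w * noise


def _build_subject(spec: CohortSpec, subject_index: int) -> tuple[np.ndarray, dict]:
    """Deterministically build one subject's data plus planted internals."""
    rng = _subject_rng(spec, subject_index)
    internals: dict = {}
    labels = list(spec.channel_labels)
    n_chan, n_samp = len(labels), spec.n_samples
    fs = spec.sampling_rate
    t = np.arange(n_samp) / fs
    g = float(spec.gradient()[subject_index])
    data = np.zeros((n_chan, n_samp))

    for osc in spec.oscillation_specs:
        targets = labels if osc.channels == "all" else list(osc.channels)
        for ch in targets:
            phase = rng.uniform(0, 2 * np.pi)
            data[labels.index(ch)] += osc.amplitude_uv * np.sin(
                2 * np.pi * osc.freq_hz * t + phase
            )

    for c, ch in enumerate(labels):
        delta = _delta_component(spec, subject_index, ch, rng)
        if delta is not None:
            data[c] += delta
            if spec.delta_complexity is not None and ch == spec.delta_complexity.channel:
                internals["planted_delta"] = delta

    for cpl in spec.coupling_specs:
        a, b = cpl.pair
        carrier = _narrowband_noise(rng, cpl.band, fs, n_samp, rms=cpl.amplitude_uv)
        independent = _narrowband_noise(rng, cpl.band, fs, n_samp, rms=cpl.amplitude_uv)
        data[labels.index(a)] += carrier
        data[labels.index(b)] += (
            cpl.strength * _phase_shift(carrier, cpl.lag)
            + (1.0 - cpl.strength) * independent
        )

    # broadband background noise, scaled by the complexity schedule; the
    # planted-delta plant uses the schedule as a mixing weight instead.
    noise_scale = 1.0 if spec.delta_complexity is not None else g
    data += rng.normal(0.0, spec.noise_sd * noise_scale, size=(n_chan, n_samp))

    art = spec.artifact_spec
    for ch in art.flat_channels:
        data[labels.index(ch)] = 0.0
    for ch in art.noisy_channels:
        data[labels.index(ch)] += rng.normal(
            0.0, art.noisy_sd_multiplier * max(spec.noise_sd, 1.0), size=n_samp
        )
    if art.supra_threshold_fraction > 0:
        epoch_samples = int(round(2.0 * fs))
        n_epochs = n_samp // epoch_samples
        n_bad = int(round(art.supra_threshold_fraction * n_epochs))
        bad_epochs = rng.choice(n_epochs, size=n_bad, replace=False)
        for e in bad_epochs:
            mid = e * epoch_samples + epoch_samples // 2
            data[0, mid] += art.supra_amplitude_uv
    if art.ocular:
        slow = _narrowband_noise(rng, (0.3, 3.5), fs, n_samp, rms=1.0)
        envelope = (rng.random(n_samp) < 2.0 / fs).astype(float)
        b, a = butter(2, min(2.0, 0.4 * fs) / (fs / 2.0))
        bursts = filtfilt(b, a, envelope)
        transient = art.ocular_amplitude_uv * slow * bursts / max(
            np.abs(slow * bursts).max(), 1e-12
        )
        mix = np.array([_OCULAR_WEIGHTS.get(ch, 0.1) for ch in labels])
        data += mix[:, None] * transient[None, :]
        internals["ocular_timecourse"] = transient
        internals["ocular_mixing"] = mix

    return data, internals


def generate_recording(spec: CohortSpec, subject_index: int) -> EEGRecording:
    """One subject's multichannel recording; bit-identical given the seed."""
    if subject_index >= spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} >= n_subjects {spec.n_subjects}")
    data, _ = _build_subject(spec, subject_index)
    return EEGRecording(
        subject_id=f"sub-{subject_index:02d}",
        channel_labels=list(spec.channel_labels),
        data=data,
        sampling_rate=spec.sampling_rate,
    )


def plant_coupled_pair(
    spec: CohortSpec,
    pair: tuple[str, str],
    lag: float,
    strength: float,
    band: tuple[float, float] = (8.0, 12.0),
    amplitude_uv: float = 10.0,
) -> CohortSpec:
    """Return a copy of ``spec`` with an additional phase-coupled pair."""
    cpl = CouplingSpec(pair=pair, lag=lag, strength=strength, band=band,
                       amplitude_uv=amplitude_uv)
    _validate_coupling(cpl, spec.channel_labels)
    return replace(spec, coupling_specs=spec.coupling_specs + (cpl,))


def _planted_feature(spec: CohortSpec, subject_index: int) -> float:
    """The per-subject value the scores are coupled to."""
    kind = spec.score_model.feature
    if kind == "gradient":
        return float(spec.gradient()[subject_index])
    if kind in {"delta_pen", "delta_spen"}:
        if spec.delta_complexity is None:
            raise ValueError(f"feature {kind!r} requires a delta_complexity plant")
        _, internals = _build_subject(spec, subject_index)
        delta = internals["planted_delta"]
        epoch = int(round(2.0 * spec.sampling_rate))
        n_epochs = max(1, len(delta) // epoch)
        segments = [delta[e * epoch : (e + 1) * epoch] for e in range(n_epochs)]
        if kind == "delta_pen":
            vals = [permutation_entropy(seg, n=3, delay=1) for seg in segments]
        else:
            vals = [spectral_entropy(seg, spec.sampling_rate) for seg in segments]
        return float(np.mean(vals))
    raise ValueError(f"unknown score_model.feature {kind!r}")


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate all recordings plus scores coupled to the planted feature.

    Scores are ``baseline + slope * z(feature) + N(0, residual_sd)``
    clipped to the declared range; the planted feature values, the planted
    population correlation and the clipping fraction (clipping attenuates
    the realized correlation) are recorded in ``ground_truth``.
    """
    recordings = [generate_recording(spec, s) for s in range(spec.n_subjects)]
    feature = np.array([_planted_feature(spec, s) for s in range(spec.n_subjects)])
    sd = feature.std()
    z = (feature - feature.mean()) / sd if sd > 0 else np.zeros_like(feature)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(spec.n_subjects, 999))
    )
    sm = spec.score_model
    raw = sm.baseline + sm.slope * z + rng.normal(0.0, sm.residual_sd, spec.n_subjects)
    lo, hi = sm.score_range
    scores = np.clip(raw, lo, hi)
    clipped_fraction = float(np.mean((raw < lo) | (raw > hi)))
    ids = [rec.subject_id for rec in recordings]
    ground_truth = {
        "feature_name": sm.feature,
        "feature_values": {i: float(f) for i, f in zip(ids, feature)},
        "planted_rho": sm.planted_rho if sd > 0 else 0.0,
        "clipped_fraction": clipped_fraction,
        "seed": spec.seed,
    }
    return SyntheticCohort(
        spec=spec,
        recordings=recordings,
        scores=pd.Series(scores, index=pd.Index(ids, name="subject_id"), name="score"),
        ground_truth=ground_truth,
    )


def write_fixture(cohort: SyntheticCohort, path: Path | str) -> None:
    """Persist a cohort as the plain array container.

    Layout: ``recordings/<subject>.tsv`` sample matrices with JSON sidecars,
    ``scores.tsv`` (subject_id, score), ``ground_truth.json``.
    """
    path = Path(path)
    rec_dir = path / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    try:
        for rec in cohort.recordings:
            write_recording_tsv(rec, rec_dir / f"{rec.subject_id}.tsv")
        cohort.scores.reset_index().to_csv(path / "scores.tsv", sep="\t", index=False)
        (path / "ground_truth.json").write_text(json.dumps(cohort.ground_truth, indent=2))
    except OSError as err:
        raise OSError(f"failed writing cohort fixture under {path}: {err}") from err


def read_fixture(path: Path | str) -> tuple[list[EEGRecording], pd.Series, dict]:
    """Read back a cohort fixture written by :func:`write_fixture`."""
    from .recording import read_recording_tsv

    path = Path(path)
    recs = [read_recording_tsv(p) for p in sorted((path / "recordings").glob("*.tsv"))]
    scores = pd.read_csv(path / "scores.tsv", sep="\t").set_index("subject_id")["score"]
    gt_path = path / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    return recs, scores, ground_truth
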