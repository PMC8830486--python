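"""Noise-assisted multivariate empirical mode decomposition (NA-MEMD).

Multivariate EMD decomposes an n-variate signal into aligned intrinsic mode
functions (IMFs) by projecting onto a set of direction vectors sampled on the
unit (n-1)-sphere, interpolating the multivariate signal at each projection's
maxima, and sifting against the mean of those directional envelopes.  The
noise-assisted variant appends independent white-noise variates before
sifting, which stabilizes the quasi-dyadic filter-bank behaviour and reduces
mode mixing; the noise variates' modes are discarded afterwards.

The decomposition is exact by construction: the extracted modes plus the
final residue telescope back to the input, and every variate receives the
same number of modes (mode alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, periodogram
from scipy.special import betaincinv

__all__ = [
    "SiftConfig",
    "IMFTensor",
    "ResidueSignal",
    "hammersley_directions",
    "envelope_mean",
    "extract_imf",
    "na_memd",
    "decompose_stacked",
    "characterize_imf_frequencies",
    "select_analysis_imfs",
    "stack_cohort_per_channel",
    "unstack_rows",
]

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61)


class ResidueSignal(Exception):
    """Raised when a signal has too few projection maxima to sift further."""


@dataclass(frozen=True)
class SiftConfig:
    """Tunable parameters of the NA-MEMD sifting process.

    ``n_directions`` is the number K of sphere direction vectors (at least
    twice the signal dimensionality is recommended); ``n_noise_channels``
    white-noise variates with standard deviation ``noise_sd_fraction`` times
    the pooled signal SD are appended before sifting.  Each mode is sifted
    until the envelope-mean-to-detail energy ratio drops below
    ``stoppage_tolerance`` or ``max_sift_iterations`` is reached.
    """

    n_directions: int = 64
    n_noise_channels: int = 2
    noise_sd_fraction: float = 0.1
    max_sift_iterations: int = 10
    stoppage_tolerance: float = 1e-2
    max_imfs: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        if self.noise_sd_fraction <= 0:
            raise ValueError("noise_sd_fraction must be > 0")


@dataclass
class IMFTensor:
    """Aligned IMFs for a set of channels decomposed row-wise.

    ``imfs[channel]`` has shape (n_modes, n_rows, n_samples) where rows index
    (subject, epoch) pairs of the stacked cohort matrix; ``mode_count`` is
    identical across channels (channels that produced extra tail modes have
    them folded into the residue so completeness is preserved).
    """

    imfs: dict[str, np.ndarray]
    residue: dict[str, np.ndarray]
    row_index: list[tuple[str, int]]
    sampling_rate: float
    mode_count: int
    selected_modes: list[int] = field(default_factory=list)

    @property
    def channel_labels(self) -> list[str]:
        return list(self.imfs)

    def reconstruct(self, channel: str) -> np.ndarray:
        """Sum of modes plus residue for one channel, shape (n_rows, n_samples)."""
        return self.imfs[channel].sum(axis=0) + self.residue[channel]


def _radical_inverse(index: int, base: int) -> float:
    inv, frac = 0.0, 1.0 / base
    while index > 0:
        inv += (index % base) * frac
        index //= base
        frac /= base
    return inv


def hammersley_directions(dimensionality: int, n_directions: int) -> np.ndarray:
    """Deterministic unit direction vectors on the (n-1)-sphere.

    A Hammersley low-discrepancy point set in the unit cube [0,1]^(n-1) is
    mapped through the exact hyperspherical-angle quantile transform, so the
    directions are equidistributed with respect to the uniform measure on
    the sphere.  Returns an array of shape (n_directions, dimensionality).
    """
    if dimensionality < 2:
        raise ValueError("dimensionality must be >= 2")
    n_angles = dimensionality - 1
    u = np.empty((n_directions, n_angles))
    u[:, 0] = (np.arange(n_directions) + 0.5) / n_directions
    for j in range(1, n_angles):
        base = _PRIMES[(j - 1) % len(_PRIMES)]
        u[:, j] = [_radical_inverse(i + 1, base) for i in range(n_directions)]

    # Hyperspherical coordinates: the azimuthal angle is uniform on [0, 2pi);
    # each polar angle theta_j has cos(theta_j) = 1 - 2 * BetaInv(a, a, u)
    # with a = (n - j)/2, the quantile of the uniform-sphere marginal.
    directions = np.ones((n_directions, dimensionality))
    azimuth = 2.0 * np.pi * u[:, 0]
    if dimensionality == 2:
        return np.column_stack([np.cos(azimuth), np.sin(azimuth)])
    sin_prod = np.ones(n_directions)
    for j in range(1, n_angles):  # polar angles, outermost first
        a = (dimensionality - j) / 2.0
        cos_t = 1.0 - 2.0 * betaincinv(a, a, u[:, j])
        directions[:, j - 1] = sin_prod * cos_t
        sin_prod = sin_prod * np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    directions[:, n_angles - 1] = sin_prod * np.cos(azimuth)
    directions[:, n_angles] = sin_prod * np.sin(azimuth)
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    return directions / norms


def _mirrored_knots(idx: np.ndarray, values: np.ndarray, n_samples: int):
    """Extend extrema past both ends by mirror reflection to tame end effects."""
    left_t = -idx[1::-1][: min(2, len(idx))]
    left_y = values[1::-1][: min(2, len(idx))]
    right_t = 2 * (n_samples - 1) - idx[:-3:-1]
    right_y = values[:-3:-1]
    t = np.concatenate([left_t, idx, right_t])
    y = np.concatenate([left_y, values, right_y], axis=0)
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], y[keep]


def envelope_mean(signal: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Mean m(t) of the directional envelopes of a multivariate signal.

    For every direction the signal is projected, the projection's local
    maxima located, and all variates interpolated through their values at
    those instants with natural cubic splines (mirror-extended at the ends).
    Raises :class:`ResidueSignal` when a projection has fewer than two
    maxima, signalling that no further mode can be extracted.
    """
    x = np.asarray(signal, dtype=float)
    n_var, n_samp = x.shape
    t_eval = np.arange(n_samp)
    total = np.zeros((n_samp, n_var))
    for d in directions:
        proj = d @ x
        peaks, _ = find_peaks(proj)
        if len(peaks) < 2:
            raise ResidueSignal(
                f"projection has {len(peaks)} maxima; signal is a residue"
            )
        t_knots, y_knots = _mirrored_knots(peaks, x[:, peaks].T, n_samp)
        spline = CubicSpline(t_knots, y_knots, axis=0, bc_type="natural")
        total += spline(t_eval)
    return (total / len(directions)).T


def extract_imf(
    signal: np.ndarray, cfg: SiftConfig, directions: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sift one IMF out of ``signal``; returns (imf, remainder).

    The detail is repeatedly reduced by its directional envelope mean until
    the envelope energy falls below ``cfg.stoppage_tolerance`` of the detail
    energy or ``cfg.max_sift_iterations`` is reached.  ``signal`` must not be
    a residue (propagates :class:`ResidueSignal` from the first iteration).
    """
    x = np.asarray(signal, dtype=float)
    if directions is None:
        directions = hammersley_directions(x.shape[0], cfg.n_directions)
    detail = x.copy()
    for iteration in range(cfg.max_sift_iterations):
        try:
            mean_env = envelope_mean(detail, directions)
        except ResidueSignal:
            if iteration == 0:
                raise
            break
        detail_energy = float(np.sum(detail**2))
        ratio = float(np.sum(mean_env**2)) / max(detail_energy, np.finfo(float).tiny)
        detail = detail - mean_env
        if ratio < cfg.stoppage_tolerance:
            break
    return detail, x - detail


def _all_monotonic(x: np.ndarray) -> bool:
    diffs = np.diff(x, axis=1)
    return bool(np.all((diffs >= 0).all(axis=1) | (diffs <= 0).all(axis=1)))


def na_memd(signal: np.ndarray, cfg: SiftConfig) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose a multivariate signal with noise-assisted MEMD.

    Appends ``cfg.n_noise_channels`` seeded white-noise variates (SD =
    ``cfg.noise_sd_fraction`` x pooled signal SD), sifts IMFs until the
    remainder is monotonic on every variate, and discards the noise variates'
    modes.  Returns (imfs, residue) restricted to the original variates;
    each IMF has the input's shape and ``sum(imfs) + residue == signal`` to
    floating-point accuracy.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    n_orig = x.shape[0]
    if n_orig < 2:
        raise ValueError("NA-MEMD requires at least 2 variates")
    pooled_sd = float(x.std())
    if pooled_sd == 0.0:
        return [], np.zeros_like(x)
    rng = np.random.default_rng(cfg.seed)
    noise = rng.normal(
        0.0, cfg.noise_sd_fraction * pooled_sd, size=(cfg.n_noise_channels, x.shape[1])
    )
    composite = np.vstack([x, noise])
    directions = hammersley_directions(composite.shape[0], cfg.n_directions)

    imfs: list[np.ndarray] = []
    remainder = composite
    while cfg.max_imfs is None or len(imfs) < cfg.max_imfs:
        if _all_monotonic(remainder):
            break
        try:
            imf, remainder = extract_imf(remainder, cfg, directions)
        except ResidueSignal:
            break
        imfs.append(imf[:n_orig])
    return imfs, remainder[:n_orig]


def stack_cohort_per_channel(
    cohort_epochs: Sequence,
) -> tuple[dict[str, np.ndarray], list[tuple[str, int]]]:
    """Stack every subject's epochs row-wise, one matrix per EEG channel.

    Each returned matrix has N_subjects * N_epochs rows of N_samples columns,
    in subject-major, epoch-minor order; the row index records the
    (subject_id, epoch) pair of every row so the stacking is invertible.
    All subjects must share channel set, epoch count and epoch length.
    """
    first = cohort_epochs[0]
    labels = list(first.channel_labels)
    n_epochs, n_samples = first.epochs.shape[1], first.epochs.shape[2]
    row_index: list[tuple[str, int]] = []
    rows_per_channel: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    for ce in cohort_epochs:
        if list(ce.channel_labels) != labels or ce.epochs.shape[1:] != (n_epochs, n_samples):
            raise ValueError(
                f"subject {ce.subject_id}: inconsistent shape "
                f"{ce.epochs.shape} / labels {list(ce.channel_labels)}"
            )
        for e in range(n_epochs):
            row_index.append((ce.subject_id, e))
        for c, lab in enumerate(labels):
            rows_per_channel[lab].append(ce.epochs[c])
    stacked = {lab: np.vstack(chunks) for lab, chunks in rows_per_channel.items()}
    return stacked, row_index


def unstack_rows(
    matrix: np.ndarray, row_index: list[tuple[str, int]]
) -> dict[str, np.ndarray]:
    """Invert :func:`stack_cohort_per_channel` for one channel matrix."""
    out: dict[str, list[np.ndarray]] = {}
    for row, (subject, _epoch) in zip(matrix, row_index):
        out.setdefault(subject, []).append(row)
    return {s: np.asarray(rows) for s, rows in out.items()}


def decompose_stacked(
    stacked: dict[str, np.ndarray],
    row_index: list[tuple[str, int]],
    sampling_rate: float,
    cfg: SiftConfig,
) -> IMFTensor:
    """Run NA-MEMD on each channel's stacked matrix and align mode counts.

    Channels may yield different mode counts; all are truncated to the
    minimum, with any dropped tail modes folded into that channel's residue
    so per-channel completeness still holds.
    """
    per_channel: dict[str, list[np.ndarray]] = {}
    residues: dict[str, np.ndarray] = {}
    seed_seq = np.random.SeedSequence(cfg.seed)
    for child, (label, matrix) in zip(
        seed_seq.spawn(len(stacked)), stacked.items()
    ):
        chan_cfg = replace(cfg, seed=int(child.generate_state(1)[0] % (2**31)))
        imfs, residue = na_memd(matrix, chan_cfg)
        per_channel[label] = imfs
        residues[label] = residue
    mode_count = min(len(v) for v in per_channel.values())
    imf_arrays: dict[str, np.ndarray] = {}
    for label, imfs in per_channel.items():
        kept = imfs[:mode_count]
        for extra in imfs[mode_count:]:
            residues[label] = residues[label] + extra
        imf_arrays[label] = (
            np.stack(kept) if kept else np.empty((0,) + stacked[label].shape)
        )
    return IMFTensor(
        imfs=imf_arrays,
        residue=residues,
        row_index=list(row_index),
        sampling_rate=sampling_rate,
        mode_count=mode_count,
        selected_modes=list(range(mode_count)),
    )


def characterize_imf_frequencies(tensor: IMFTensor, fs: float | None = None) -> pd.DataFrame:
    """Spectral summary per mode: centroid frequency and 90%-power band.

    Periodograms are pooled (averaged) over all channels and rows of each
    mode; the band is the [5%, 95%] interval of the cumulative pooled power.
    """
    fs = tensor.sampling_rate if fs is None else fs
    if tensor.mode_count < 1:
        raise ValueError("tensor has no modes to characterize")
    records = []
    for mode in range(tensor.mode_count):
        psd_sum = None
        for label in tensor.channel_labels:
            freqs, psd = periodogram(tensor.imfs[label][mode], fs=fs, axis=-1)
            pooled = psd.mean(axis=0)
            psd_sum = pooled if psd_sum is None else psd_sum + pooled
        psd_sum[0] = 0.0  # ignore DC offset
        total = psd_sum.sum()
        if total == 0:
            records.append({"mode": mode, "f_mean": 0.0, "f_low": 0.0, "f_high": 0.0})
            continue
        p = psd_sum / total
        centroid = float(np.sum(freqs * p))
        cum = np.cumsum(p)
        f_low = float(freqs[np.searchsorted(cum, 0.05)])
        f_high = float(freqs[np.searchsorted(cum, 0.95)])
        records.append({"mode": mode, "f_mean": centroid, "f_low": f_low, "f_high": f_high})
    return pd.DataFrame.from_records(records)


def select_analysis_imfs(
    tensor: IMFTensor,
    rule: tuple | Callable[[pd.DataFrame], list[int]] = ("drop", 3, 1),
) -> IMFTensor:
    """Subset the modes kept for feature extraction.

    The default rule ``("drop", 3, 1)`` discards the first three (noisy,
    mixed-oscillation) modes and the last (residue-like) mode, mirroring the
    retention of modes 4..9 out of ten.  A ``("band", low_hz, high_hz)`` rule
    keeps modes whose spectral centroid lies inside the band;
    ``("band_merge", low_hz, high_hz)`` additionally sums them into a single
    band-limited mode (useful when the oscillation of interest is wider than
    one quasi-dyadic mode).  A callable receives the frequency summary frame
    and returns mode indices.
    """
    if isinstance(rule, tuple) and rule and rule[0] == "band_merge":
        selected_tensor = select_analysis_imfs(tensor, ("band", rule[1], rule[2]))
        return IMFTensor(
            imfs={
                lab: arr.sum(axis=0, keepdims=True)
                for lab, arr in selected_tensor.imfs.items()
            },
            residue=selected_tensor.residue,
            row_index=selected_tensor.row_index,
            sampling_rate=selected_tensor.sampling_rate,
            mode_count=1,
            selected_modes=selected_tensor.selected_modes,
        )
    if callable(rule):
        selected = list(rule(characterize_imf_frequencies(tensor)))
    elif rule[0] == "drop":
        _, head, tail = rule
        if tensor.mode_count < head + tail + 1:
            raise ValueError(
                f"cannot drop {head}+{tail} modes from {tensor.mode_count}"
            )
        selected = list(range(head, tensor.mode_count - tail))
    elif rule[0] == "band":
        _, f_lo, f_hi = rule
        summary = characterize_imf_frequencies(tensor)
        selected = [
            int(row["mode"])
            for _, row in summary.iterrows()
            if f_lo <= row["f_mean"] <= f_hi
        ]
        if not selected:
            raise ValueError(f"no mode has spectral centroid inside [{f_lo}, {f_hi}] Hz")
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    original = tensor.selected_modes or list(range(tensor.mode_count))
    return IMFTensor(
        imfs={lab: arr[selected] for lab, arr in tensor.imfs.items()},
        residue=tensor.residue,
        row_index=tensor.row_index,
        sampling_rate=tensor.sampling_rate,
        mode_count=len(selected),
        selected_modes=[original[i] for i in selected],
    )
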