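"""Entropy measures of EEG irregularity: sample, permutation and spectral.

Sample entropy (SampEn) estimates state-space irregularity as the negative
log conditional probability that sequences matching for m points (Chebyshev
distance within a tolerance r, self-matches excluded) still match at m+1
points.  Permutation entropy (PEn) is the normalized Shannon entropy of
ordinal patterns of order n at delay L; smaller values mean a more regular
series.  Spectral entropy (SpEn) is the Shannon entropy of the normalized
power spectral density restricted to a frequency band (default 0.5-45 Hz):
high for a flat broadband spectrum, near zero when power concentrates in a
single frequency bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from scipy.spatial.distance import cdist

__all__ = [
    "EntropyConfig",
    "sample_entropy",
    "permutation_entropy",
    "spectral_entropy",
    "entropy_feature_table",
]


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters of the three entropy measures.

    SampEn uses embedding dimension ``sampen_m`` (recommended 2 or 3) with
    tolerance ``sampen_r_frac`` x the epoch's standard deviation
    (recommended 0.1-0.25) and optional template delay ``sampen_delay``.
    PEn uses pattern order ``pen_order`` with delay ``pen_delay`` samples
    and is normalized by ``log(n!)`` (``pen_normalizer="factorial_ln_n!"``,
    the pattern-count maximum) or by ``log(n)`` (``"as_printed_ln_n"``);
    the choice rescales by a constant and leaves correlations unchanged.
    SpEn restricts the periodogram to ``spen_band`` Hz.
    """

    sampen_m: int = 3
    sampen_r_frac: float = 0.2
    sampen_delay: int = 1
    pen_order: int = 3
    pen_delay: int = 1
    spen_band: tuple[float, float] = (0.5, 45.0)
    pen_normalizer: str = "factorial_ln_n!"

    def __post_init__(self) -> None:
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.sampen_r_frac <= 0:
            raise ValueError("sampen_r_frac must be > 0")
        if self.pen_order < 2:
            raise ValueError("pen_order must be >= 2")
        if self.pen_normalizer not in {"factorial_ln_n!", "as_printed_ln_n"}:
            raise ValueError(f"unknown pen_normalizer {self.pen_normalizer!r}")


def _template_matrix(x: np.ndarray, m: int, delay: int) -> np.ndarray:
    n_vec = len(x) - (m - 1) * delay
    idx = np.arange(n_vec)[:, None] + delay * np.arange(m)[None, :]
    return x[idx]


def sample_entropy(
    x: np.ndarray, m: int = 3, r_abs: float | None = None, delay: int = 1
) -> float:
    """SampEn(m, r, N) = -ln(A/B) in nats.

    B counts pairs of distinct m-length templates within Chebyshev distance
    ``r_abs`` and A the same for (m+1)-length templates, both over the first
    N - m template start points.  When no matches exist at either length the
    estimator is undefined and the conventional upper bound
    ln((N-m-1)(N-m)) is returned.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    if r_abs is None:
        r_abs = 0.2 * float(x.std())
    if r_abs < 0:
        raise ValueError("tolerance must be >= 0")

    # Templates of length m+1; their first m columns are the m-templates
    # restricted to the same N-m start points, as the ratio A/B requires.
    templates = _template_matrix(x, m + 1, delay)
    dist_m = cdist(templates[:, :m], templates[:, :m], metric="chebyshev")
    dist_m1 = np.maximum(
        dist_m, np.abs(templates[:, -1:] - templates[:, -1:].T)
    )
    mask = ~np.eye(len(templates), dtype=bool)
    b_count = int(np.sum((dist_m <= r_abs) & mask))
    a_count = int(np.sum((dist_m1 <= r_abs) & mask))
    if a_count == 0 or b_count == 0:
        return math.log(max((n - m - 1) * (n - m), 2))
    return -math.log(a_count / b_count)


def permutation_entropy(
    x: np.ndarray, n: int = 3, delay: int = 1, normalizer: str = "factorial_ln_n!"
) -> float:
    """Normalized permutation entropy of ordinal patterns of order ``n``.

    Each window of ``n`` values (delay ``L`` between them) is reduced to its
    rank pattern, with ties broken by temporal order of occurrence (stable
    sort).  Returns -sum(p log p) over observed patterns divided by log(n!)
    (or log(n) when ``normalizer="as_printed_ln_n"``); 0 for a strictly
    monotone series.
    """
    x = np.asarray(x, dtype=float)
    min_len = (n - 1) * delay + 1
    if len(x) < min_len:
        raise ValueError(f"series of length {len(x)} too short for order {n}, delay {delay}")
    windows = _template_matrix(x, n, delay)
    patterns = np.argsort(windows, axis=1, kind="stable")
    pattern_ids = {perm: k for k, perm in enumerate(permutations(range(n)))}
    codes = np.array([pattern_ids[tuple(row)] for row in patterns])
    counts = np.bincount(codes, minlength=math.factorial(n)).astype(float)
    p = counts[counts > 0] / counts.sum()
    entropy = float(-np.sum(p * np.log(p)))
    denom = math.log(math.factorial(n)) if normalizer == "factorial_ln_n!" else math.log(n)
    return entropy / denom


def spectral_entropy(
    x: np.ndarray, fs: float, band: tuple[float, float] = (0.5, 45.0)
) -> float:
    """Shannon entropy (nats) of the normalized in-band power spectrum.

    The periodogram of ``x`` is restricted to ``band`` (clipped below the
    Nyquist frequency), normalized to a probability distribution over the
    retained bins, and its entropy returned.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 16:
        raise ValueError("series too short for a meaningful periodogram")
    f_lo, f_hi = band
    nyquist = fs / 2.0
    if f_lo >= nyquist:
        raise ValueError(f"band lower edge {f_lo} Hz is above Nyquist ({nyquist} Hz)")
    f_hi = min(f_hi, nyquist)
    freqs, psd = periodogram(x, fs=fs)
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    power = psd[in_band]
    total = power.sum()
    if total <= 0:
        raise ValueError("no signal power inside the requested band")
    p = power[power > 0] / total
    return float(-np.sum(p * np.log(p)))


def entropy_feature_table(
    imfs: dict[str, np.ndarray],
    sampling_rate: float,
    cfg: EntropyConfig = EntropyConfig(),
    subject_rows: dict[str, list[int]] | None = None,
) -> pd.DataFrame:
    """Epoch-averaged SampEn/PEn/SpEn per (subject, channel, mode).

    ``imfs`` maps channel label -> array of shape (n_modes, n_rows,
    n_samples); ``subject_rows`` maps subject id -> row indices (a single
    implicit subject is assumed when omitted).  Returns a wide frame indexed
    by subject with one ``{measure}_{channel}_imf{k}`` column per feature,
    so 12 channels and one mode yield 36 columns.
    """
    if not imfs:
        raise ValueError("no channels supplied")
    n_modes = next(iter(imfs.values())).shape[0]
    for label, arr in imfs.items():
        if arr.shape[0] != n_modes:
            raise ValueError(f"channel {label} has {arr.shape[0]} modes, expected {n_modes}")
    if subject_rows is None:
        n_rows = next(iter(imfs.values())).shape[1]
        subject_rows = {"subject": list(range(n_rows))}

    records: dict[str, dict[str, float]] = {}
    for subject, rows in subject_rows.items():
        features: dict[str, float] = {}
        for label, arr in imfs.items():
            for mode in range(n_modes):
                epochs = arr[mode][rows]
                sampen_vals, pen_vals, spen_vals = [], [], []
                for epoch in epochs:
                    r_abs = cfg.sampen_r_frac * float(epoch.std())
                    sampen_vals.append(
                        sample_entropy(epoch, cfg.sampen_m, r_abs, cfg.sampen_delay)
                    )
                    pen_vals.append(
                        permutation_entropy(
                            epoch, cfg.pen_order, cfg.pen_delay, cfg.pen_normalizer
                        )
                    )
                    spen_vals.append(spectral_entropy(epoch, sampling_rate, cfg.spen_band))
                suffix = f"{label}_imf{mode}"
                features[f"sampen_{suffix}"] = float(np.mean(sampen_vals))
                features[f"pen_{suffix}"] = float(np.mean(pen_vals))
                features[f"spen_{suffix}"] = float(np.mean(spen_vals))
        records[subject] = features
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "subject_id"
    if not np.all(np.isfinite(table.to_numpy())):
        raise ValueError("non-finite entropy value in feature table")
    return table
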