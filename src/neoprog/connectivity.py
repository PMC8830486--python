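"""Weighted phase-lag index connectivity and global graph metrics.

The weighted phase-lag index (WPLI) between two narrowband signals weights
the sign of each instantaneous phase difference by the magnitude of the
imaginary part of their cross-spectrum:

    WPLI = |E[|Im X| sign(Im X)]| / E[|Im X|],   X = Z1 conj(Z2)

with the expectation over time samples within an epoch.  It ranges from 0
(no consistently lagged coupling; in particular zero-lag/volume-conducted
coupling) to 1 (perfect phase locking at a nonzero lag).  Per-epoch WPLI
matrices are averaged over epochs into one symmetric, zero-diagonal matrix
per mode, which is then treated as a complete weighted brain network and
summarized by five global metrics: weighted transitivity, global efficiency,
radius, diameter and characteristic path length (shortest paths over edge
lengths = 1/weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "WPLIMatrix",
    "GraphMetricSet",
    "analytic_signal",
    "wpli_pair",
    "wpli_matrix",
    "weights_to_lengths",
    "shortest_path_metrics",
    "transitivity_weighted",
    "graph_metrics",
    "graph_feature_table",
]

#: Fraction of samples discarded at each epoch edge before the WPLI
#: expectation, to suppress analytic-signal transform edge artifacts.
EDGE_TAPER_FRACTION = 0.05


@dataclass
class WPLIMatrix:
    """Symmetric channels x channels WPLI values in [0, 1], zero diagonal."""

    values: np.ndarray
    channel_labels: list[str]
    imf_index: int = 0
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("WPLI matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("WPLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("WPLI matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("WPLI values must lie in [0, 1]")
        self.values = v


@dataclass
class GraphMetricSet:
    """Global weighted-network attributes of one connectivity matrix."""

    transitivity: float
    global_efficiency: float
    radius: float
    diameter: float
    characteristic_path_length: float

    def as_dict(self) -> dict[str, float]:
        return {
            "transitivity": self.transitivity,
            "global_efficiency": self.global_efficiency,
            "radius": self.radius,
            "diameter": self.diameter,
            "characteristic_path_length": self.characteristic_path_length,
        }


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal along the last axis; instantaneous phase = argument.

    The real part equals the input and the imaginary part is its harmonic
    conjugate.  A constant series has undefined phase; it is returned with
    zero imaginary part (zero amplitude).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 8:
        raise ValueError("series too short for analytic-signal estimation")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    return hilbert(x, axis=-1)


def _taper(z: np.ndarray) -> np.ndarray:
    n = z.shape[-1]
    cut = int(round(EDGE_TAPER_FRACTION * n))
    return z[..., cut : n - cut] if cut > 0 else z


def wpli_pair(z1: np.ndarray, z2: np.ndarray) -> float:
    """WPLI of two analytic-signal epochs (expectation over time samples).

    An identically real cross-spectrum (e.g. identical signals) gives 0/0,
    defined as 0: absence of lagged coupling.
    """
    z1 = np.asarray(z1)
    z2 = np.asarray(z2)
    if z1.shape != z2.shape:
        raise ValueError(f"shape mismatch: {z1.shape} vs {z2.shape}")
    cross = z1 * np.conj(z2)
    imag_x = np.imag(cross).ravel()
    denom = np.mean(np.abs(imag_x))
    # an identically real cross-spectrum leaves only rounding noise in the
    # imaginary part; its sign pattern is meaningless, so define WPLI = 0
    floor = 1e-10 * float(np.mean(np.abs(cross)))
    if denom <= floor:
        return 0.0
    return float(abs(np.mean(imag_x)) / denom)


def wpli_matrix(
    epochs: np.ndarray, channel_labels: list[str] | None = None, imf_index: int = 0
) -> WPLIMatrix:
    """Epoch-averaged pairwise WPLI from real-valued mode signals.

    ``epochs`` has shape (n_channels, n_epochs, n_samples).  Analytic
    signals are computed per epoch, the first and last 5% of samples are
    discarded, WPLI is evaluated for every channel pair and epoch, and the
    per-epoch matrices are averaged arithmetically.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        epochs = epochs[:, None, :]
    n_chan, n_epochs, _ = epochs.shape
    if n_chan < 2:
        raise ValueError("need at least 2 channels for connectivity")
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_chan)]
    z = _taper(analytic_signal(epochs))
    acc = np.zeros((n_chan, n_chan))
    for e in range(n_epochs):
        cross = z[:, None, e, :] * np.conj(z[None, :, e, :])
        imag_x = np.imag(cross)
        denom = np.mean(np.abs(imag_x), axis=-1)
        floor = 1e-10 * np.mean(np.abs(cross), axis=-1)
        num = np.abs(np.mean(imag_x, axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(denom > floor, num / np.maximum(denom, np.finfo(float).tiny), 0.0)
        acc += w
    values = acc / n_epochs
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return WPLIMatrix(
        values=np.clip(values, 0.0, 1.0),
        channel_labels=list(channel_labels),
        imf_index=imf_index,
        n_epochs_averaged=n_epochs,
    )


def weights_to_lengths(weights: np.ndarray) -> np.ndarray:
    """Connection-length matrix: length = 1/weight, zero weight -> inf."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative connection weight")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.maximum(w, np.finfo(float).tiny), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_path_metrics(lengths: np.ndarray) -> tuple[float, float, float, float]:
    """(characteristic path length, global efficiency, radius, diameter).

    All-pairs shortest paths are computed over the length matrix.  CPL is
    the mean of the finite off-diagonal distances, global efficiency the
    mean reciprocal distance (unreachable pairs contribute 0), eccentricity
    the max distance from each node, radius/diameter its min/max.  For a
    disconnected graph radius and diameter are infinite and CPL is computed
    on the finite entries only.
    """
    lengths = np.asarray(lengths, dtype=float)
    n = lengths.shape[0]
    if lengths.shape != (n, n):
        raise ValueError("length matrix must be square")
    if np.any(np.diag(lengths) != 0):
        raise ValueError("length matrix diagonal must be zero")
    graph = np.where(np.isinf(lengths), 0.0, lengths)
    dist = _csgraph_shortest_path(graph, method="D", directed=False)
    off_diag = ~np.eye(n, dtype=bool)
    d = dist[off_diag]
    finite = np.isfinite(d)
    cpl = float(d[finite].mean()) if finite.any() else np.inf
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    efficiency = float(inv.mean())
    eccentricity = dist.max(axis=1) if n > 1 else np.zeros(1)
    radius = float(eccentricity.min())
    diameter = float(eccentricity.max())
    return cpl, efficiency, radius, diameter


def transitivity_weighted(weights: np.ndarray) -> float:
    """Weighted transitivity: total geometric-mean triangle intensity over
    total connected triples (cube-root weight convention).

    T = sum_i diag(W^(1/3) cubed)_i / sum_i k_i (k_i - 1), with k_i the
    number of nonzero neighbours of node i; 0 when no connected triples
    exist.  Equals 1 for a complete unit-weight graph and 0 for any
    triangle-free graph.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or np.any(w > 1 + 1e-12):
        raise ValueError("weights must lie in [0, 1]")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    w_root = np.cbrt(w)
    cycles3 = np.diag(w_root @ w_root @ w_root)
    degree = (w > 0).sum(axis=1)
    triples = float(np.sum(degree * (degree - 1)))
    if triples == 0:
        return 0.0
    return float(np.sum(cycles3) / triples)


def graph_metrics(wpli: WPLIMatrix | np.ndarray) -> GraphMetricSet:
    """All five global metrics of one WPLI connectivity matrix."""
    weights = wpli.values if isinstance(wpli, WPLIMatrix) else np.asarray(wpli)
    cpl, efficiency, radius, diameter = shortest_path_metrics(
        weights_to_lengths(weights)
    )
    return GraphMetricSet(
        transitivity=transitivity_weighted(weights),
        global_efficiency=efficiency,
        radius=radius,
        diameter=diameter,
        characteristic_path_length=cpl,
    )


def graph_feature_table(tensor, subject_rows: dict[str, list[int]]) -> pd.DataFrame:
    """Per-subject, per-mode global graph metrics from an IMF tensor.

    For each subject and retained mode, the subject's epoch rows of every
    channel form the (channels x epochs x samples) input to
    :func:`wpli_matrix`; the epoch-averaged matrix is reduced to the five
    global metrics.  Columns are ``{metric}_imf{k}``.
    """
    labels = tensor.channel_labels
    records: dict[str, dict[str, float]] = {}
    for subject, rows in subject_rows.items():
        features: dict[str, float] = {}
        for mode in range(tensor.mode_count):
            epochs = np.stack([tensor.imfs[lab][mode][rows] for lab in labels])
            metrics = graph_metrics(wpli_matrix(epochs, labels, imf_index=mode))
            for name, value in metrics.as_dict().items():
                features[f"{name}_imf{mode}"] = value
        records[subject] = features
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "subject_id"
    return table
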