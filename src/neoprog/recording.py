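"""Labelled multichannel EEG time series and on-disk containers.

The canonical in-memory object is :class:`EEGRecording`: a channels x samples
matrix in microvolts with 10-20 electrode labels and a sampling rate.  On
disk, recordings travel either as clinical EDF (read through :mod:`mne` when
available) or as a documented plain array container: a TSV sample matrix
(one column per channel) next to a JSON metadata sidecar, which round-trips
losslessly and needs no binary reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Electrode names of the 10-20 international system, upper-cased.  The
#: legacy temporal names T3/T4/T5/T6 are kept (modern T7/T8/P7/P8 aliases
#: are accepted and canonicalized back to the legacy names).
TEN_TWENTY_LABELS = frozenset(
    {
        "FP1", "FP2", "F3", "F4", "F7", "F8", "FZ",
        "C3", "C4", "CZ",
        "P3", "P4", "PZ",
        "O1", "O2", "OZ",
        "T3", "T4", "T5", "T6",
        "A1", "A2", "FPZ",
    }
)

_MODERN_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def canonical_label(label: str) -> str:
    """Upper-case a 10-20 electrode token and map modern temporal aliases."""
    token = label.strip().upper()
    return _MODERN_ALIASES.get(token, token)


def validate_labels(labels: list[str]) -> list[str]:
    """Canonicalize ``labels``; unknown tokens raise with the accepted list."""
    out = []
    for lab in labels:
        canon = canonical_label(lab)
        if canon not in TEN_TWENTY_LABELS:
            raise ValueError(
                f"unknown 10-20 electrode label {lab!r}; accepted names: "
                + ", ".join(sorted(TEN_TWENTY_LABELS))
            )
        out.append(canon)
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate channel labels after canonicalization: {out}")
    return out


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts.

    Parameters
    ----------
    subject_id : str
        Identifier used in score tables and logs.
    channel_labels : list of str
        10-20 electrode names, one per row of ``data``.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sampling_rate : float
        Samples per second (Hz).
    """

    subject_id: str
    channel_labels: list[str]
    data: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


def write_recording_tsv(rec: EEGRecording, path: Path | str) -> None:
    """Write one recording as TSV samples plus a JSON sidecar.

    ``path`` is the TSV file; the sidecar is ``path`` with a ``.json``
    suffix.  Columns are channels (header = labels), rows are samples.
    """
    path = Path(path)
    frame = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "subject_id": rec.subject_id,
        "sampling_rate": rec.sampling_rate,
        "channel_labels": rec.channel_labels,
        "units": "uV",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_recording_tsv(path: Path | str) -> EEGRecording:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path.name}: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(path, sep="\t")
    labels = validate_labels(list(frame.columns))
    return EEGRecording(
        subject_id=sidecar["subject_id"],
        channel_labels=labels,
        data=frame.to_numpy().T,
        sampling_rate=float(sidecar["sampling_rate"]),
    )


def read_recording_edf(path: Path | str) -> EEGRecording:
    """Read a clinical EDF file via mne; data rescaled Volts -> microvolts."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - mne is an optional extra
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    rates = {float(raw.info["sfreq"])}
    if len(rates) != 1:
        raise ValueError("mixed per-channel sampling rates are unsupported")
    labels = validate_labels(list(raw.ch_names))
    return EEGRecording(
        subject_id=Path(path).stem,
        channel_labels=labels,
        data=raw.get_data() * 1e6,
        sampling_rate=float(raw.info["sfreq"]),
    )


def read_recording(path: Path | str) -> EEGRecording:
    """Dispatch on extension: ``.edf`` via mne, ``.tsv`` via the array container."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return read_recording_edf(path)
    if suffix in {".tsv", ".txt"}:
        return read_recording_tsv(path)
    raise ValueError(f"unknown recording extension {path.suffix!r}; expected .edf or .tsv")
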