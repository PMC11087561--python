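"""Reading, re-referencing and standardising intracranial recordings.

Recordings enter the pipeline from EDF/BDF files or delimited numeric
tables and are standardised to the preprocessing contract the decoder
expects: mains notch filtered, downsampled to 200 Hz, and cut into 30-s
epochs aligned to the hypnogram grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .labels import Hypnogram

__all__ = [
    "RawRecording",
    "MontageSpec",
    "EpochSet",
    "MontageError",
    "AlignmentError",
    "read_recording",
    "rereference",
    "preprocess",
    "epoch_align",
]

TARGET_RATE = 200.0


class MontageError(ValueError):
    """A montage references contacts absent from the recording."""


class AlignmentError(ValueError):
    """Recording and hypnogram cannot be aligned epoch-by-epoch."""


@dataclass
class RawRecording:
    """Multichannel signal block in microvolts.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
    rate : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str
        Unique, ordered channel names.
    start_offset : float
        Start of the block in seconds relative to lights-out.
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str]
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.rate}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


@dataclass
class MontageSpec:
    """Bipolar re-referencing scheme over one or more leads.

    ``leads`` maps a lead name to its ordered contact labels, deepest
    contact first (clinical convention: contact 1 is deepest).  The
    ``adjacent`` scheme pairs neighbouring contacts (1-2, 2-3, 3-4 on a
    four-contact DBS lead); the ``sandwich`` scheme skips one contact
    (1-3, 2-4), leaving the middle contact free for stimulation in
    adaptive DBS.
    """

    leads: dict[str, list[str]]
    scheme: Literal["adjacent", "sandwich"] = "adjacent"

    def __post_init__(self) -> None:
        if self.scheme not in ("adjacent", "sandwich"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for lead, contacts in self.leads.items():
            if len(set(contacts)) != len(contacts):
                raise ValueError(f"lead {lead!r} has duplicate contacts")

    def pairs(self) -> list[tuple[str, str]]:
        """Ordered (anode, cathode) contact pairs across all leads."""
        step = 1 if self.scheme == "adjacent" else 2
        out: list[tuple[str, str]] = []
        for contacts in self.leads.values():
            out.extend(
                (contacts[i], contacts[i + step])
                for i in range(len(contacts) - step)
            )
        return out


@dataclass
class EpochSet:
    """Fixed-length signal windows on the hypnogram grid.

    ``data`` has shape (n_epochs, n_channels, epoch_length * rate);
    ``stages`` holds one label per epoch ('?' where unscored).
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    stages: np.ndarray
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        expected = int(round(self.epoch_length * self.rate))
        if self.data.ndim != 3 or self.data.shape[2] != expected:
            raise ValueError(
                f"epochs must have {expected} samples, got shape {self.data.shape}"
            )
        if len(self.stages) != self.data.shape[0]:
            raise ValueError("one stage label required per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def read_recording(
    path: str | Path,
    format: Literal["edf", "delimited"] | None = None,
    rate: float | None = None,
    delimiter: str | None = None,
) -> RawRecording:
    """Read a recording from an EDF/BDF file or a delimited table.

    Delimited tables carry one column per channel with a header row of
    channel labels; the sampling rate is not part of the dialect and must
    be supplied. EDF stores labels, rate and physical units in its header.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"recording file not found: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() in (".edf", ".bdf") else "delimited"

    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data(units="uV")
        return RawRecording(
            samples=data, rate=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
        )

    if rate is None:
        raise ValueError(
            f"sampling rate must be supplied for delimited input {path}"
        )
    import csv

    if delimiter is None:
        try:
            header = path.open().readline()
            delimiter = csv.Sniffer().sniff(header, delimiters=",\t;").delimiter
        except (csv.Error, OSError):
            delimiter = ","
    try:
        table = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise IOError(f"empty or unreadable recording file: {path}") from exc
    if table.shape[0] == 0:
        raise IOError(f"recording file has no samples: {path}")
    return RawRecording(
        samples=table.to_numpy(dtype=float).T,
        rate=float(rate),
        channel_labels=[str(c) for c in table.columns],
    )


def rereference(recording: RawRecording, montage: MontageSpec) -> RawRecording:
    """Build bipolar channels (first contact minus second) from a montage.

    An adjacent scheme on a four-contact lead yields three bipolar
    channels (1-2, 2-3, 3-4); a sandwich scheme yields two (1-3, 2-4).
    """
    pairs = montage.pairs()
    missing = sorted(
        {c for pair in pairs for c in pair} - set(recording.channel_labels)
    )
    if missing:
        raise MontageError(f"montage contacts absent from recording: {missing}")
    traces = np.stack(
        [recording.channel(a) - recording.channel(b) for a, b in pairs]
    )
    labels = [f"{a}-{b}" for a, b in pairs]
    return RawRecording(
        samples=traces, rate=recording.rate, channel_labels=labels,
        start_offset=recording.start_offset,
    )


def _notch(data: np.ndarray, rate: float, center: float, half_width: float = 2.0,
           order: int = 4) -> np.ndarray:
    sos = sps.butter(
        order, [center - half_width, center + half_width],
        btype="bandstop", fs=rate, output="sos",
    )
    return sps.sosfiltfilt(sos, data, axis=-1)


def preprocess(
    recording: RawRecording,
    mains: float = 50.0,
    target_rate: float = TARGET_RATE,
) -> RawRecording:
    """Notch out mains and harmonics, then downsample to ``target_rate``.

    The notch is a zero-phase 4th-order Butterworth band-stop (+/-2 Hz)
    applied at the mains frequency and every harmonic below the
    post-downsample Nyquist. Resampling is polyphase with a built-in
    anti-alias low-pass; integer rate ratios reduce to plain decimation.
    """
    if target_rate > recording.rate:
        raise ValueError(
            f"cannot upsample: recording at {recording.rate} Hz, "
            f"target {target_rate} Hz"
        )
    data = recording.samples
    nyq_out = target_rate / 2.0
    h = mains
    while h < nyq_out:
        data = _notch(data, recording.rate, h)
        h += mains

    if recording.rate != target_rate:
        frac = Fraction(target_rate / recording.rate).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    return RawRecording(
        samples=data, rate=float(target_rate),
        channel_labels=list(recording.channel_labels),
        start_offset=recording.start_offset,
    )


def epoch_align(recording: RawRecording, hypnogram: Hypnogram) -> EpochSet:
    """Cut the recording into one 30-s window per hypnogram entry.

    A trailing partial epoch is discarded; a recording shorter than the
    hypnogram is an error.
    """
    n_epochs = len(hypnogram)
    samples_per_epoch = int(round(hypnogram.epoch_length * recording.rate))
    needed = n_epochs * samples_per_epoch
    if recording.n_times < needed:
        raise AlignmentError(
            f"recording of {recording.duration:.1f} s cannot cover a "
            f"{n_epochs * hypnogram.epoch_length:.1f} s hypnogram"
        )
    data = recording.samples[:, :needed]
    data = data.reshape(recording.n_channels, n_epochs, samples_per_epoch)
    return EpochSet(
        data=np.swapaxes(data, 0, 1),
        rate=recording.rate,
        channel_labels=list(recording.channel_labels),
        stages=np.asarray(hypnogram.stages, dtype=object),
        epoch_length=hypnogram.epoch_length,
    )
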