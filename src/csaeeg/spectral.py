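"""Per-epoch spectral decomposition and the compressed spectral array (CSA).

The analysis chain mirrors standard quantitative-EEG practice for
dominant-frequency work: the recording is cut into consecutive 2-s epochs,
high-amplitude epochs are flagged as artifacts, the first ``n`` clean epochs
are retained, each epoch is Fourier-transformed (Hann window, power
corrected) onto a 0.5 Hz grid, spectra are averaged over a scalp region,
and the epochs x frequency stack — the compressed spectral array — is
summarized by its mean power spectrum (mPS) and relative band powers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .bands import BAND_NAMES, BandScheme, DEFAULT_BANDS
from .recording import EEGRecording

#: Spectrum retained up to this frequency (Hz) for diagnostics; dominant-
#: frequency search and band powers only read 1-12 Hz.
ANALYSIS_FMAX = 70.0
ANALYSIS_FMIN = 0.5


class InsufficientDataError(ValueError):
    """Raised when fewer clean epochs are available than requested."""

    def __init__(self, available: int, requested: int):
        self.available = available
        self.requested = requested
        super().__init__(
            f"insufficient clean data: {available} artifact-free epochs "
            f"available, {requested} requested"
        )


@dataclass
class EpochSet:
    """Consecutive fixed-length epochs of a multichannel recording.

    ``epochs`` has shape (n_epochs, n_channels, n_samples_per_epoch);
    ``artifact_flags`` marks epochs excluded from selection (flag-only,
    nothing is deleted).
    """

    epochs: np.ndarray
    fs: float
    channel_labels: tuple
    artifact_flags: np.ndarray = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.epochs.shape[0], dtype=bool)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.artifact_flags.shape[0] != self.epochs.shape[0]:
            raise ValueError("one artifact flag required per epoch")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_length(self) -> float:
        return self.epochs.shape[2] / self.fs


@dataclass
class CSAMatrix:
    """Epochs x frequency power stack for one channel or region (uV^2)."""

    power: np.ndarray
    freqs: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.ndim != 2 or self.power.shape[1] != self.freqs.shape[0]:
            raise ValueError("power must be (n_epochs, n_freqs)")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")
        steps = np.diff(self.freqs)
        if self.freqs.size > 1 and not np.allclose(steps, steps[0]):
            raise ValueError("frequency grid must have a constant step")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class MeanPowerSpectrum:
    """Mean spectrum over epochs with relative band powers.

    ``relative`` maps each band to its percentage of the summed 1-12 Hz
    band power (the four values add to 100); ``log_relative`` is the
    base-10 logarithm of those percentages, the usual normalizing
    transform for relative EEG power.
    """

    power: np.ndarray
    freqs: np.ndarray
    band_power: dict
    relative: dict
    log_relative: dict = field(default_factory=dict)


def epoch_signal(recording: EEGRecording, epoch_length: float = 2.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    Any trailing partial segment shorter than ``epoch_length`` is discarded.
    """
    if recording.duration < epoch_length:
        raise ValueError(
            f"recording of {recording.duration:.3f} s is shorter than one "
            f"{epoch_length} s epoch"
        )
    n_per = int(round(epoch_length * recording.fs))
    n_epochs = recording.n_samples // n_per
    trimmed = recording.samples[:, : n_epochs * n_per]
    epochs = trimmed.reshape(recording.n_channels, n_epochs, n_per)
    epochs = np.moveaxis(epochs, 0, 1)
    return EpochSet(epochs=epochs, fs=recording.fs, channel_labels=recording.channel_labels)


def reject_artifacts(epochs: EpochSet, amplitude_limit: float) -> EpochSet:
    """Flag epochs whose peak absolute amplitude (any channel) exceeds the limit.

    A plain amplitude-threshold rejector; flags accumulate (an epoch
    already flagged stays flagged), nothing is removed.
    """
    if amplitude_limit <= 0:
        raise ValueError("amplitude_limit must be positive (uV)")
    peaks = np.max(np.abs(epochs.epochs), axis=(1, 2))
    flags = epochs.artifact_flags | (peaks > amplitude_limit)
    return EpochSet(
        epochs=epochs.epochs,
        fs=epochs.fs,
        channel_labels=epochs.channel_labels,
        artifact_flags=flags,
    )


def select_epochs(epochs: EpochSet, n: int = 90) -> EpochSet:
    """Keep the first ``n`` artifact-free epochs in temporal order."""
    clean_idx = np.flatnonzero(~epochs.artifact_flags)
    if clean_idx.size < n:
        raise InsufficientDataError(available=int(clean_idx.size), requested=n)
    keep = clean_idx[:n]
    return EpochSet(
        epochs=epochs.epochs[keep],
        fs=epochs.fs,
        channel_labels=epochs.channel_labels,
        artifact_flags=np.zeros(n, dtype=bool),
    )


def epoch_spectrum(samples: np.ndarray, fs: float, epoch_length: float = 2.0):
    """One-sided power spectrum of a single epoch on the 1/epoch_length grid.

    A Hann window with power correction is applied so that the summed
    spectral power matches the epoch's time-domain variance (Parseval,
    within window-leakage error).  The DC bin is dropped and the grid is
    restricted to the 0.5-70 Hz analysis range.

    Returns ``(freqs, power)`` with power in uV^2 per bin.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch_spectrum expects a single-channel epoch")
    n = x.size
    if abs(n - epoch_length * fs) > 0.5:
        raise ValueError(
            f"epoch has {n} samples; expected {epoch_length} s at {fs} Hz"
        )
    x = x - x.mean()
    w = hann(n, sym=False)
    u = np.mean(w**2)  # window power correction
    spec = np.fft.rfft(x * w)
    power = (np.abs(spec) ** 2) * 2.0 / (n**2 * u)
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= ANALYSIS_FMIN - 1e-9) & (freqs <= ANALYSIS_FMAX + 1e-9)
    return freqs[mask], power[mask]


def epoch_spectra(epochs: EpochSet, channel: str) -> CSAMatrix:
    """CSA of one channel: the per-epoch spectra stacked epoch by epoch."""
    idx = epochs.channel_labels.index(channel)
    rows = []
    freqs = None
    for e in range(epochs.n_epochs):
        f, p = epoch_spectrum(epochs.epochs[e, idx], epochs.fs, epochs.epoch_length)
        freqs = f
        rows.append(p)
    return CSAMatrix(power=np.vstack(rows), freqs=freqs, label=channel)


def region_average(spectra_by_channel: dict, region: tuple) -> CSAMatrix:
    """Arithmetic mean of member-channel CSA matrices, epoch- and bin-wise."""
    missing = [ch for ch in region if ch not in spectra_by_channel]
    if missing:
        raise KeyError(f"region channels missing from input: {', '.join(missing)}")
    mats = [spectra_by_channel[ch] for ch in region]
    freqs = mats[0].freqs
    for m in mats[1:]:
        if not np.array_equal(m.freqs, freqs):
            raise ValueError("channel spectra are on different frequency grids")
    power = np.mean([m.power for m in mats], axis=0)
    return CSAMatrix(power=power, freqs=freqs, label="+".join(region))


def build_csa(epochs: EpochSet, channels: tuple | None = None,
              region_label: str = "") -> CSAMatrix:
    """Compute per-epoch spectra for ``channels`` and average them into one CSA.

    With a single channel this is that channel's CSA; with several it is
    the regional CSA (mean power across channels per epoch and bin).
    """
    if epochs.n_epochs < 1:
        raise ValueError("at least one epoch is required")
    channels = tuple(channels) if channels is not None else epochs.channel_labels
    spectra = {ch: epoch_spectra(epochs, ch) for ch in channels}
    csa = region_average(spectra, channels)
    if region_label:
        csa.label = region_label
    return csa


def mean_power_spectrum(csa: CSAMatrix, bands: BandScheme = DEFAULT_BANDS) -> MeanPowerSpectrum:
    """mPS (per-bin mean over epochs) with relative and log band powers."""
    if csa.n_epochs < 1:
        raise ValueError("empty CSA")
    mps = csa.power.mean(axis=0)
    band_power = {
        b: float(mps[bands.mask(csa.freqs, b)].sum()) for b in BAND_NAMES
    }
    total = sum(band_power.values())
    if total <= 0:
        relative = {b: float("nan") for b in BAND_NAMES}
    else:
        relative = {b: 100.0 * band_power[b] / total for b in BAND_NAMES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        with np.errstate(divide="ignore"):
            log_relative = {b: float(np.log10(relative[b])) for b in BAND_NAMES}
    return MeanPowerSpectrum(
        power=mps,
        freqs=csa.freqs,
        band_power=band_power,
        relative=relative,
        log_relative=log_relative,
    )
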