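"""Multichannel EEG recording container and 10-20 montage constants."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 19 scalp electrodes of the international 10-20 system (old T3/T4/T5/T6
#: naming), in the conventional anterior-to-posterior order.
STANDARD_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Scalp-region groupings used for regional spectral averaging.
REGIONS = {
    "anterior": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("Cz", "C3", "C4"),
    "posterior": ("Pz", "P3", "P4", "O1", "O2"),
    "temporal": ("T3", "T4", "T5", "T6"),
}

POSTERIOR = REGIONS["posterior"]


@dataclass
class EEGRecording:
    """Raw multichannel EEG.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One 10-20 label per row of ``samples``; unknown labels are allowed
        (they are simply excluded from region averages).
    meta : dict
        Free-form provenance (generator seed, injected-artifact bookkeeping,
        source file, ...).
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one channel label required per sample row")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None
        return self.samples[idx]
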