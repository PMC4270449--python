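"""Frequency-band scheme for low-frequency resting-state EEG.

Four contiguous bands cover the 1–12 Hz analysis range used for dominant-
frequency work in dementia EEG: delta [1, 4), theta [4, 5.5), pre-alpha
(fast theta) [5.5, 8), and alpha [8, 12].  The half-open convention puts
7.5 Hz (the highest grid point below 8) in pre-alpha and 8.0 in alpha,
consistent with "slowed" dominant frequency being defined as DF <= 7.9 Hz
on a 0.5 Hz spectral grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BAND_NAMES = ("delta", "theta", "prealpha", "alpha")

#: Fast bands: a dominant frequency here is alpha- or pre-alpha-dominant.
FAST_BANDS = ("prealpha", "alpha")


@dataclass(frozen=True)
class BandScheme:
    """Contiguous band edges in Hz.

    Every band is half-open ``[low, high)`` except the last (alpha),
    which is closed ``[low, high]`` so that the full analysis range
    ``[1, 12]`` is covered exactly.
    """

    edges: dict = field(
        default_factory=lambda: {
            "delta": (1.0, 4.0),
            "theta": (4.0, 5.5),
            "prealpha": (5.5, 8.0),
            "alpha": (8.0, 12.0),
        }
    )

    def __post_init__(self) -> None:
        lows = [self.edges[b][0] for b in BAND_NAMES]
        highs = [self.edges[b][1] for b in BAND_NAMES]
        if any(h <= l for l, h in zip(lows, highs)):
            raise ValueError("band edges must satisfy low < high")
        for i in range(len(BAND_NAMES) - 1):
            if highs[i] != lows[i + 1]:
                raise ValueError("bands must be contiguous and non-overlapping")

    @property
    def fmin(self) -> float:
        return self.edges[BAND_NAMES[0]][0]

    @property
    def fmax(self) -> float:
        return self.edges[BAND_NAMES[-1]][1]

    def band_of(self, freq: float) -> str | None:
        """Band containing ``freq``, or None outside [fmin, fmax]."""
        for name in BAND_NAMES[:-1]:
            low, high = self.edges[name]
            if low <= freq < high:
                return name
        low, high = self.edges[BAND_NAMES[-1]]
        if low <= freq <= high:
            return BAND_NAMES[-1]
        return None

    def mask(self, freqs, band: str):
        """Boolean mask of ``freqs`` lying in ``band`` (grid convention above)."""
        import numpy as np

        freqs = np.asarray(freqs, dtype=float)
        low, high = self.edges[band]
        if band == BAND_NAMES[-1]:
            return (freqs >= low) & (freqs <= high)
        return (freqs >= low) & (freqs < high)


DEFAULT_BANDS = BandScheme()
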