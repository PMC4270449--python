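"""The six CSA mathematical descriptors.

From a compressed spectral array the following summaries are computed per
subject and region:

1. **DF** — dominant frequency, the grid frequency of maximum power in the
   1-12 Hz search band, evaluated per epoch and for the mean spectrum;
2. **DF range** — min and max of the per-epoch DFs;
3. **FP** — frequency prevalence: the percentage of epochs whose DF falls
   in each band;
4. **BI** — band inscription: the percentage of epochs containing at least
   one supra-noise spectral peak in each band;
5. **frequency ratio** — power of the dominant fast band (alpha or
   pre-alpha) over the summed power of all slower bands;
6. **DFV** — dominant-frequency variability across epochs; by default the
   range width (max - min), with standard deviation and mean absolute
   successive difference as configurable alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BAND_NAMES, FAST_BANDS, BandScheme, DEFAULT_BANDS
from .spectral import CSAMatrix, MeanPowerSpectrum, mean_power_spectrum

DF_SEARCH_BAND = (1.0, 12.0)

DFV_ESTIMATORS = ("range_width", "sd", "successive_mean")

#: Column order of the descriptor table written by the pipeline.
DESCRIPTOR_COLUMNS = (
    "df_mean", "df_min", "df_max", "dfv", "dfv_alpha",
    "fp_delta", "fp_theta", "fp_prealpha", "fp_alpha",
    "bi_delta", "bi_theta", "bi_prealpha", "bi_alpha",
    "freq_ratio",
)


class UndefinedDFError(ValueError):
    """Spectrum is identically zero over the search band."""


@dataclass
class CSADescriptors:
    """Scalar/banded CSA summaries driving pattern classification.

    ``df_mean`` is the mean of the per-epoch DFs (the quantity the pattern
    thresholds are phrased over); ``df_mps`` is the DF of the mean power
    spectrum, retained for reporting.  ``dfv_alpha`` is the variability of
    DF over alpha-dominant epochs only and is None when no epoch is
    alpha-dominant.  ``max_fast_run`` is the longest run of consecutive
    epochs whose DF is alpha- or pre-alpha-dominant.
    """

    df_mean: float
    df_mps: float
    df_per_epoch: np.ndarray
    df_min: float
    df_max: float
    dfv: float
    dfv_alpha: float | None
    fp: dict
    bi: dict
    freq_ratio: float
    max_fast_run: int
    n_epochs: int
    dfv_estimator: str = "range_width"
    meta: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "df_mean": self.df_mean,
            "df_min": self.df_min,
            "df_max": self.df_max,
            "dfv": self.dfv,
            "dfv_alpha": np.nan if self.dfv_alpha is None else self.dfv_alpha,
        }
        for b in BAND_NAMES:
            row[f"fp_{b}"] = self.fp[b]
        for b in BAND_NAMES:
            row[f"bi_{b}"] = self.bi[b]
        row["freq_ratio"] = self.freq_ratio
        return row


def dominant_frequency(power: np.ndarray, freqs: np.ndarray,
                       search_band: tuple = DF_SEARCH_BAND) -> float:
    """Grid frequency of maximum power within ``search_band`` (inclusive).

    Ties are broken toward the lowest frequency.
    """
    power = np.asarray(power, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = search_band
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError("search band contains no frequency bins")
    sub, subf = power[mask], freqs[mask]
    if not np.any(sub > 0):
        raise UndefinedDFError("spectrum is zero over the DF search band")
    return float(subf[int(np.argmax(sub))])  # argmax returns first (lowest) max


def df_variability(df_per_epoch, estimator: str = "range_width") -> float:
    """Dispersion of the per-epoch dominant frequencies (Hz)."""
    df = np.asarray(df_per_epoch, dtype=float)
    if df.size < 2:
        raise ValueError("DFV requires at least 2 epochs")
    if estimator == "range_width":
        return float(df.max() - df.min())
    if estimator == "sd":
        return float(df.std(ddof=1))
    if estimator == "successive_mean":
        return float(np.mean(np.abs(np.diff(df))))
    raise ValueError(f"unknown DFV estimator {estimator!r}; choose from {DFV_ESTIMATORS}")


def frequency_prevalence(df_per_epoch, bands: BandScheme = DEFAULT_BANDS) -> dict:
    """Percentage of epochs whose DF falls in each band."""
    df = np.asarray(df_per_epoch, dtype=float)
    if df.size < 1:
        raise ValueError("at least one epoch is required")
    out = {}
    for b in BAND_NAMES:
        out[b] = 100.0 * float(np.count_nonzero(bands.mask(df, b))) / df.size
    return out


def _local_maxima(p: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima on the grid; endpoints count against
    their single neighbour."""
    idx = []
    n = p.size
    for i in range(n):
        left_ok = i == 0 or p[i] > p[i - 1]
        right_ok = i == n - 1 or p[i] > p[i + 1]
        if left_ok and right_ok and n > 1:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def band_inscription(csa: CSAMatrix, bands: BandScheme = DEFAULT_BANDS) -> dict:
    """Percentage of epochs with a supra-noise spectral peak in each band.

    The noise reference of an epoch is its mean power over the 1-12 Hz
    analysis band; a peak is a strict local maximum on the 0.5 Hz grid
    exceeding that reference.
    """
    if csa.n_epochs < 1:
        raise ValueError("empty CSA")
    mask = (csa.freqs >= DF_SEARCH_BAND[0] - 1e-9) & (csa.freqs <= DF_SEARCH_BAND[1] + 1e-9)
    freqs = csa.freqs[mask]
    counts = {b: 0 for b in BAND_NAMES}
    for e in range(csa.n_epochs):
        p = csa.power[e][mask]
        ref = p.mean()
        peaks = _local_maxima(p)
        peaks = peaks[p[peaks] > ref]
        hit = set()
        for i in peaks:
            b = bands.band_of(freqs[i])
            if b is not None:
                hit.add(b)
        for b in hit:
            counts[b] += 1
    return {b: 100.0 * counts[b] / csa.n_epochs for b in BAND_NAMES}


def frequency_ratio(band_power: dict, fast_band: str = "alpha") -> float:
    """Power of the dominant fast band over the summed power of slower bands."""
    if fast_band not in FAST_BANDS:
        raise ValueError("fast_band must be 'alpha' or 'prealpha'")
    slower = BAND_NAMES[: BAND_NAMES.index(fast_band)]
    denom = sum(band_power[b] for b in slower)
    if denom <= 0:
        raise ZeroDivisionError("summed power of slower bands is zero")
    return float(band_power[fast_band] / denom)


def longest_fast_run(df_per_epoch, bands: BandScheme = DEFAULT_BANDS) -> int:
    """Longest run of consecutive epochs with alpha- or pre-alpha-dominant DF."""
    df = np.asarray(df_per_epoch, dtype=float)
    fast = np.array([bands.band_of(v) in FAST_BANDS for v in df])
    best = cur = 0
    for f in fast:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def describe(csa: CSAMatrix, bands: BandScheme = DEFAULT_BANDS,
             dfv_estimator: str = "range_width",
             mps: MeanPowerSpectrum | None = None) -> CSADescriptors:
    """Compute all six descriptors from a (region-averaged) CSA."""
    if csa.n_epochs < 2:
        raise ValueError("descriptors require at least 2 epochs")
    df_seq = np.array([
        dominant_frequency(csa.power[e], csa.freqs) for e in range(csa.n_epochs)
    ])
    if mps is None:
        mps = mean_power_spectrum(csa, bands)
    df_mps = dominant_frequency(mps.power, mps.freqs)
    fp = frequency_prevalence(df_seq, bands)
    dfv = df_variability(df_seq, dfv_estimator)
    alpha_df = df_seq[bands.mask(df_seq, "alpha")]
    if alpha_df.size == 0:
        dfv_alpha = None
    elif alpha_df.size == 1:
        dfv_alpha = 0.0
    else:
        dfv_alpha = df_variability(alpha_df, dfv_estimator)
    bi = band_inscription(csa, bands)
    fast = "alpha" if fp["alpha"] >= fp["prealpha"] else "prealpha"
    try:
        fr = frequency_ratio(mps.band_power, fast)
    except ZeroDivisionError:
        fr = float("nan")
    return CSADescriptors(
        df_mean=float(df_seq.mean()),
        df_mps=df_mps,
        df_per_epoch=df_seq,
        df_min=float(df_seq.min()),
        df_max=float(df_seq.max()),
        dfv=dfv,
        dfv_alpha=dfv_alpha,
        fp=fp,
        bi=bi,
        freq_ratio=fr,
        max_fast_run=longest_fast_run(df_seq, bands),
        n_epochs=csa.n_epochs,
        dfv_estimator=dfv_estimator,
    )


def descriptors_from_trajectory(df_per_epoch, bands: BandScheme = DEFAULT_BANDS,
                                dfv_estimator: str = "range_width") -> CSADescriptors:
    """Descriptors of an idealized noiseless recording given only its DF
    trajectory.

    In a noiseless single-component recording the only supra-noise peak of
    each epoch is the dominant one, so BI coincides with FP and the band
    powers are proportional to band occupancy.  Used for cohort-scale
    bookkeeping where full signal synthesis is unnecessary.
    """
    df_seq = np.asarray(df_per_epoch, dtype=float)
    if df_seq.size < 2:
        raise ValueError("descriptors require at least 2 epochs")
    fp = frequency_prevalence(df_seq, bands)
    dfv = df_variability(df_seq, dfv_estimator)
    alpha_df = df_seq[bands.mask(df_seq, "alpha")]
    if alpha_df.size == 0:
        dfv_alpha = None
    elif alpha_df.size == 1:
        dfv_alpha = 0.0
    else:
        dfv_alpha = df_variability(alpha_df, dfv_estimator)
    fast = "alpha" if fp["alpha"] >= fp["prealpha"] else "prealpha"
    band_power = dict(fp)  # occupancy-proportional surrogate
    try:
        fr = frequency_ratio(band_power, fast)
    except ZeroDivisionError:
        fr = float("nan")
    vals, counts = np.unique(df_seq, return_counts=True)
    df_mps = float(vals[np.argmax(counts)])
    return CSADescriptors(
        df_mean=float(df_seq.mean()),
        df_mps=df_mps,
        df_per_epoch=df_seq,
        df_min=float(df_seq.min()),
        df_max=float(df_seq.max()),
        dfv=dfv,
        dfv_alpha=dfv_alpha,
        fp=fp,
        bi=dict(fp),
        freq_ratio=fr,
        max_fast_run=longest_fast_run(df_seq, bands),
        n_epochs=int(df_seq.size),
        dfv_estimator=dfv_estimator,
        meta={"source": "trajectory"},
    )
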