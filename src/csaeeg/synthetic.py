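"""Synthetic resting-state EEG with controlled dominant-frequency dynamics.

Every downstream stage (spectral decomposition, CSA descriptors, pattern
classification, cohort statistics) is testable without clinical recordings:
a :class:`PatternArchetype` fixes the marginal distribution of the
per-epoch dominant frequency (DF) on the 0.5 Hz grid, and recordings are
synthesized epoch by epoch as a dominant sinusoid at the trajectory DF plus
an optional secondary band component and a 1/f background.

The trajectory model draws each epoch's DF independently: first the band is
fixed by exact largest-remainder apportionment of ``band_mixture`` over the
requested number of epochs (so empirical band occupancy is within one epoch
of the target), then a grid frequency is drawn uniformly from the band's
intersection with ``[df_center - df_spread, df_center + df_spread]``.
Nothing in the descriptor set read by the classifier depends on serial
structure except the longest fast-dominant run, which can be bounded
explicitly (``max_fast_run``) for the degraded low-frequency archetype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, FAST_BANDS, BandScheme, DEFAULT_BANDS
from .classify import classify, is_abnormal, predict_outcome
from .descriptors import descriptors_from_trajectory, longest_fast_run
from .recording import EEGRecording, POSTERIOR, STANDARD_1020

GRID_STEP = 0.5  # Hz, the spectral resolution of 2-s epochs

PATTERN_LABELS = ("1", "1plus", "2", "3", "4", "5")


class ArchetypeError(ValueError):
    """Invalid archetype configuration."""


@dataclass(frozen=True)
class PatternArchetype:
    """Generative parameters of one CSA pattern.

    Parameters
    ----------
    label : str
        Target pattern, one of ``{"1", "1plus", "2", "3", "4", "5"}``.
    df_center, df_spread : float
        Centre (Hz) and half-width (Hz) of the DF window; per-epoch DFs are
        drawn from the 0.5 Hz grid inside this window intersected with the
        permitted bands.
    band_mixture : dict
        Per-band probability that an epoch's DF falls in that band;
        entries sum to 1 and ``df_center`` lies in the highest-probability
        band.
    secondary_power_fraction : float
        Power of a secondary component (in the next most probable band)
        relative to the dominant one, in [0, 1).
    noise_level : float
        RMS (uV) of the 1/f background.
    amplitude : float
        Peak amplitude (uV) of the dominant sinusoid; the default keeps it
        well above the noise floor at its own bin (>= 6 dB).
    max_fast_run : int or None
        If set, trajectories are reshuffled until no more than this many
        consecutive epochs are alpha/pre-alpha-dominant.
    """

    label: str
    df_center: float
    df_spread: float
    band_mixture: dict
    secondary_power_fraction: float = 0.0
    noise_level: float = 2.0
    amplitude: float = 20.0
    max_fast_run: int | None = None

    def __post_init__(self) -> None:
        if self.label not in PATTERN_LABELS:
            raise ArchetypeError(
                f"unknown pattern label {self.label!r}; expected one of {PATTERN_LABELS}"
            )
        if self.df_spread < 0:
            raise ArchetypeError("df_spread must be >= 0")
        if not 0 <= self.secondary_power_fraction < 1:
            raise ArchetypeError("secondary_power_fraction must lie in [0, 1)")
        total = sum(self.band_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ArchetypeError("band_mixture entries must sum to 1")
        top = max(self.band_mixture, key=self.band_mixture.get)
        if DEFAULT_BANDS.band_of(self.df_center) != top:
            raise ArchetypeError(
                "df_center must lie inside the band with highest mixture probability"
            )


def _band_grid(band: str, archetype: PatternArchetype,
               bands: BandScheme = DEFAULT_BANDS) -> np.ndarray:
    """Grid frequencies of ``band`` inside the archetype's DF window."""
    lo, hi = bands.edges[band]
    hi_incl = hi if band == BAND_NAMES[-1] else hi - GRID_STEP
    grid = np.arange(lo, hi_incl + GRID_STEP / 2, GRID_STEP)
    win_lo = archetype.df_center - archetype.df_spread
    win_hi = archetype.df_center + archetype.df_spread
    grid = grid[(grid >= win_lo - 1e-9) & (grid <= win_hi + 1e-9)]
    return grid


def _apportion(mixture: dict, n: int) -> dict:
    """Largest-remainder apportionment of ``n`` epochs over bands."""
    quotas = {b: mixture.get(b, 0.0) * n for b in BAND_NAMES}
    counts = {b: int(np.floor(q)) for b, q in quotas.items()}
    short = n - sum(counts.values())
    remainders = sorted(
        BAND_NAMES, key=lambda b: (-(quotas[b] - counts[b]), BAND_NAMES.index(b))
    )
    for b in remainders[:short]:
        counts[b] += 1
    return {b: c for b, c in counts.items() if c > 0}


def generate_df_trajectory(archetype: PatternArchetype, n_epochs: int,
                           seed: int) -> np.ndarray:
    """Per-epoch dominant frequencies (Hz) on the 0.5 Hz grid.

    Band occupancy equals the archetype mixture to within one epoch;
    deterministic given the seed.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    counts = _apportion(archetype.band_mixture, n_epochs)
    values = []
    for band, count in counts.items():
        grid = _band_grid(band, archetype)
        if grid.size == 0:
            raise ArchetypeError(
                f"DF window [{archetype.df_center - archetype.df_spread}, "
                f"{archetype.df_center + archetype.df_spread}] Hz contains no "
                f"grid frequency in band {band!r}"
            )
        values.append(rng.choice(grid, size=count, replace=True))
    traj = np.concatenate(values)
    traj = traj[rng.permutation(n_epochs)]
    if archetype.max_fast_run is not None:
        for _ in range(1000):
            if longest_fast_run(traj) <= archetype.max_fast_run:
                break
            traj = traj[rng.permutation(n_epochs)]
        else:
            raise ArchetypeError(
                "could not satisfy max_fast_run constraint; too many fast epochs"
            )
    return traj


def _pink_noise(rng: np.random.Generator, n_epochs: int, n_samples: int,
                fs: float, rms: float) -> np.ndarray:
    """Band-limited 1/f-amplitude Gaussian-phase background, per epoch."""
    if rms <= 0:
        return np.zeros((n_epochs, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    band = (freqs >= 0.5) & (freqs <= min(70.0, fs / 2))
    amp[band] = 1.0 / freqs[band]
    z = rng.standard_normal((n_epochs, freqs.size)) + 1j * rng.standard_normal(
        (n_epochs, freqs.size)
    )
    x = np.fft.irfft(z * amp, n=n_samples, axis=1)
    scale = rms / max(x.std(), 1e-30)
    return x * scale


def _secondary_band(archetype: PatternArchetype, dominant_band: str) -> str | None:
    """Band hosting the secondary component: the most probable band other
    than the dominant one, falling back to the neighbouring slower band."""
    others = {b: p for b, p in archetype.band_mixture.items()
              if b != dominant_band and p > 0}
    if others:
        return max(others, key=others.get)
    i = BAND_NAMES.index(dominant_band)
    return BAND_NAMES[i - 1] if i > 0 else None


def _band_center_freq(band: str, bands: BandScheme = DEFAULT_BANDS) -> float:
    lo, hi = bands.edges[band]
    mid = (lo + hi) / 2
    return float(np.round(mid / GRID_STEP) * GRID_STEP)


def synthesize_epoch(df: float, archetype: PatternArchetype, n_samples: int,
                     fs: float, seed: int) -> np.ndarray:
    """One epoch (uV): dominant sinusoid at ``df`` + secondary component +
    1/f background."""
    if not 0 < df < fs / 2:
        raise ValueError(f"df={df} Hz must lie in (0, Nyquist={fs / 2} Hz)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    x = archetype.amplitude * np.sin(2 * np.pi * df * t + rng.uniform(0, 2 * np.pi))
    if archetype.secondary_power_fraction > 0:
        dom_band = DEFAULT_BANDS.band_of(df)
        sec_band = _secondary_band(archetype, dom_band) if dom_band else None
        if sec_band is not None:
            f2 = _band_center_freq(sec_band)
            a2 = archetype.amplitude * np.sqrt(archetype.secondary_power_fraction)
            x = x + a2 * np.sin(2 * np.pi * f2 * t + rng.uniform(0, 2 * np.pi))
    x = x + _pink_noise(rng, 1, n_samples, fs, archetype.noise_level)[0]
    return x


def _epochs_for_channel(rng: np.random.Generator, traj: np.ndarray,
                        archetype: PatternArchetype, n_per: int, fs: float,
                        gain: float) -> np.ndarray:
    """All epochs of one channel, vectorized over epochs."""
    n_ep = traj.size
    t = np.arange(n_per) / fs
    phases = rng.uniform(0, 2 * np.pi, size=n_ep)
    x = gain * archetype.amplitude * np.sin(
        2 * np.pi * traj[:, None] * t[None, :] + phases[:, None]
    )
    if archetype.secondary_power_fraction > 0:
        a2 = gain * archetype.amplitude * np.sqrt(archetype.secondary_power_fraction)
        sec_phases = rng.uniform(0, 2 * np.pi, size=n_ep)
        f2 = np.empty(n_ep)
        for i, df in enumerate(traj):
            dom_band = DEFAULT_BANDS.band_of(df)
            sec_band = _secondary_band(archetype, dom_band) if dom_band else None
            f2[i] = _band_center_freq(sec_band) if sec_band else 0.0
        x = x + np.where(
            f2[:, None] > 0,
            a2 * np.sin(2 * np.pi * f2[:, None] * t[None, :] + sec_phases[:, None]),
            0.0,
        )
    x = x + _pink_noise(rng, n_ep, n_per, fs, archetype.noise_level)
    return x


def synthesize_recording(archetype: PatternArchetype, channels=STANDARD_1020,
                         duration: float = 240.0, fs: float = 1024.0,
                         seed: int = 0, n_artifacts: int = 0,
                         artifact_amplitude: float = 500.0) -> EEGRecording:
    """Multichannel recording whose posterior channels share one DF trajectory.

    Posterior channels carry the full-amplitude dominant component (with
    independent phases and background per channel); all other channels
    receive an attenuated copy.  Optional rectangular high-amplitude
    transients exercise the artifact rejector; the affected epoch indices
    are recorded in ``meta["artifact_epochs"]``.
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("channel list must not be empty")
    if duration < 2.0:
        raise ValueError("duration must be >= 2 s (one epoch)")
    epoch_len = 2.0
    n_per = int(round(epoch_len * fs))
    n_epochs = int(duration // epoch_len)
    n_total = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    traj = generate_df_trajectory(
        archetype, n_epochs, seed=int(rng.integers(2**31))
    )
    samples = np.zeros((len(channels), n_total))
    for ci, ch in enumerate(channels):
        gain = 1.0 if ch in POSTERIOR else 0.4
        ep = _epochs_for_channel(rng, traj, archetype, n_per, fs, gain)
        samples[ci, : n_epochs * n_per] = ep.ravel()
    meta = {"archetype": archetype.label, "seed": seed,
            "df_trajectory": traj, "artifact_epochs": []}
    if n_artifacts > 0:
        hit = rng.choice(n_epochs, size=min(n_artifacts, n_epochs), replace=False)
        width = max(1, int(0.1 * fs))
        for e in sorted(hit):
            start = e * n_per + n_per // 2
            samples[:, start : start + width] += artifact_amplitude
        meta["artifact_epochs"] = sorted(int(e) for e in hit)
    return EEGRecording(samples=samples, fs=fs, channel_labels=channels, meta=meta)


# --------------------------------------------------------------------------
# Default archetypes
# --------------------------------------------------------------------------

#: Generative defaults per pattern.  DF windows follow the pattern
#: definitions and the reported group statistics: stable alpha around
#: 9.5-10 Hz (alpha DFV < 0.6 Hz); unstable alpha spanning 8.5-10.5 Hz
#: (range-width DFV 2.0 Hz); alpha/pre-alpha alternation 6-9 Hz; stable
#: pre-alpha 6.5-7 Hz; unstable pre-alpha with theta/delta; and degraded
#: low-frequency activity whose rare pre-alpha epochs never persist beyond
#: two consecutive epochs.
DEFAULT_ARCHETYPES = {
    "1": PatternArchetype(
        label="1", df_center=9.75, df_spread=0.3,
        band_mixture={"alpha": 1.0},
    ),
    "1plus": PatternArchetype(
        label="1plus", df_center=9.5, df_spread=1.0,
        band_mixture={"alpha": 1.0},
    ),
    "2": PatternArchetype(
        label="2", df_center=7.5, df_spread=1.5,
        band_mixture={"alpha": 0.45, "prealpha": 0.55},
        secondary_power_fraction=0.3,
    ),
    "3": PatternArchetype(
        label="3", df_center=6.75, df_spread=0.3,
        band_mixture={"prealpha": 1.0},
    ),
    "4": PatternArchetype(
        label="4", df_center=6.0, df_spread=5.0,
        band_mixture={"prealpha": 0.5, "theta": 0.25, "delta": 0.25},
        secondary_power_fraction=0.3,
    ),
    "5": PatternArchetype(
        label="5", df_center=3.0, df_spread=6.5,
        band_mixture={"delta": 0.5, "theta": 0.3, "prealpha": 0.2},
        secondary_power_fraction=0.2, max_fast_run=2,
    ),
}


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One outcome group: name, size, and archetype counts per pattern."""

    name: str
    count: int
    patterns: dict  # pattern label -> subject count

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError("group count must be positive")
        if sum(self.patterns.values()) != self.count:
            raise ValueError(
                f"group {self.name!r}: archetype counts "
                f"{sum(self.patterns.values())} != group count {self.count}"
            )
        for lbl in self.patterns:
            if lbl not in PATTERN_LABELS:
                raise ArchetypeError(f"unknown pattern label {lbl!r}")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def n_subjects(self) -> int:
        return sum(g.count for g in self.groups)


#: The 42-subject observed-at-onset reference cohort: per-group pattern
#: counts for subjects later converting to DLB, converting to AD, or not
#: converting.
REFERENCE_COHORT_SPEC = CohortSpec(
    groups=(
        GroupSpec("MCI-DLB", 20, {"1plus": 9, "2": 10, "3": 1}),
        GroupSpec("MCI-AD", 14, {"1": 13, "2": 1}),
        GroupSpec("MCI-NC", 8, {"1": 5, "1plus": 2, "2": 1}),
    ),
    seed=0,
)

#: Subjects per group presenting a core or suggestive DLB clinical feature
#: at admission (19 of 42 in the reference cohort).
REFERENCE_CLINICAL_FLAG_COUNTS = {"MCI-DLB": 15, "MCI-NC": 2, "MCI-AD": 2}


def generate_cohort(spec: CohortSpec, archetypes: dict | None = None,
                    n_epochs: int = 90) -> pd.DataFrame:
    """Cohort table: one row per subject with truth archetype, trajectory-level
    descriptors, classified pattern, abnormality and predicted outcome.

    Recordings are not materialized here (the per-subject ``seed`` column
    allows :func:`synthesize_recording` to regenerate any subject's signal
    on demand); descriptors come from the noiseless trajectory idealization,
    which is exact for cohort-scale bookkeeping.
    """
    archetypes = archetypes or DEFAULT_ARCHETYPES
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    rows = []
    i = 0
    for group in spec.groups:
        for pattern_label in sorted(group.patterns):
            for _ in range(group.patterns[pattern_label]):
                sub_seed = int(children[i].generate_state(1)[0] % 2**31)
                arch = archetypes[pattern_label]
                traj = generate_df_trajectory(arch, n_epochs, seed=sub_seed)
                desc = descriptors_from_trajectory(traj)
                res = classify(desc)
                abnormal = is_abnormal(desc, res.label)
                pred = predict_outcome(res.label, abnormal)
                rows.append({
                    "subject_id": f"S{i + 1:03d}",
                    "group": group.name,
                    "archetype": pattern_label,
                    "pattern": res.label.value,
                    "df_mean": desc.df_mean,
                    "dfv": desc.dfv,
                    "abnormal": abnormal,
                    "predicted_group": pred.predicted_group,
                    "seed": sub_seed,
                })
                i += 1
    return pd.DataFrame(rows)


def assign_reference_flags(cohort: pd.DataFrame,
                           counts: dict | None = None) -> pd.DataFrame:
    """Add the ``has_dlb_feature`` clinical flag, flagging the first ``k``
    subjects of each group (deterministic; only counts matter downstream)."""
    counts = counts or REFERENCE_CLINICAL_FLAG_COUNTS
    out = cohort.copy()
    out["has_dlb_feature"] = False
    for group, k in counts.items():
        idx = out.index[out["group"] == group][:k]
        if len(idx) < k:
            raise ValueError(f"group {group!r} has fewer than {k} subjects")
        out.loc[idx, "has_dlb_feature"] = True
    return out


def reference_cohort(seed: int = 0, n_epochs: int = 90) -> pd.DataFrame:
    """The 42-subject reference cohort with clinical flags assigned."""
    spec = replace(REFERENCE_COHORT_SPEC, seed=seed)
    return assign_reference_flags(generate_cohort(spec, n_epochs=n_epochs))
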