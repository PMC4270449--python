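"""Synthetic-EEG generator: trajectories, epochs, recordings, cohorts."""

import numpy as np
import pytest
from dataclasses import replace

import csaeeg as c
from csaeeg.bands import DEFAULT_BANDS
from csaeeg.synthetic import ArchetypeError, GroupSpec


class TestTrajectory:
    def test_zero_spread_is_constant(self):
        arch = c.PatternArchetype(label="1", df_center=10.0, df_spread=0.0,
                                  band_mixture={"alpha": 1.0})
        traj = c.generate_df_trajectory(arch, 90, seed=1)
        assert traj.shape == (90,)
        assert np.all(traj == 10.0)

    def test_quantized_to_half_hz_grid(self):
        traj = c.generate_df_trajectory(c.DEFAULT_ARCHETYPES["4"], 90, seed=5)
        assert np.allclose(traj * 2, np.round(traj * 2))

    def test_deterministic_given_seed(self):
        arch = c.DEFAULT_ARCHETYPES["2"]
        a = c.generate_df_trajectory(arch, 90, seed=42)
        b = c.generate_df_trajectory(arch, 90, seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c.generate_df_trajectory(arch, 90, seed=43))

    @pytest.mark.parametrize("label", sorted(c.DEFAULT_ARCHETYPES))
    def test_band_occupancy_within_one_epoch(self, label):
        arch = c.DEFAULT_ARCHETYPES[label]
        traj = c.generate_df_trajectory(arch, 90, seed=7)
        for band, p in arch.band_mixture.items():
            n_band = int(DEFAULT_BANDS.mask(traj, band).sum())
            assert abs(n_band - p * 90) <= 1.0

    @pytest.mark.parametrize("label", sorted(c.DEFAULT_ARCHETYPES))
    def test_band_occupancy_converges(self, label):
        # long-run occupancy fraction matches the mixture to 0.03
        arch = c.DEFAULT_ARCHETYPES[label]
        traj = c.generate_df_trajectory(arch, 900, seed=11)
        for band, p in arch.band_mixture.items():
            frac = DEFAULT_BANDS.mask(traj, band).mean()
            assert abs(frac - p) <= 0.03

    def test_mixture_counts_example(self):
        # alpha 0.45 of 90 epochs apportions to 40 or 41 alpha-dominant epochs
        traj = c.generate_df_trajectory(c.DEFAULT_ARCHETYPES["2"], 90, seed=3)
        n_alpha = int(DEFAULT_BANDS.mask(traj, "alpha").sum())
        assert n_alpha in (40, 41)

    def test_unstable_alpha_exemplar_span(self):
        # DF variable between 8 and 9.5 Hz, confined to the alpha band
        arch = c.PatternArchetype(label="1plus", df_center=8.75, df_spread=0.75,
                                  band_mixture={"alpha": 1.0})
        traj = c.generate_df_trajectory(arch, 90, seed=0)
        assert traj.min() == 8.0 and traj.max() == 9.5
        assert np.all((traj >= 8.0) & (traj <= 12.0))

    def test_degraded_pattern_limits_fast_runs(self):
        traj = c.generate_df_trajectory(c.DEFAULT_ARCHETYPES["5"], 90, seed=2)
        assert c.longest_fast_run(traj) <= 2

    def test_invalid_configurations_raise(self):
        with pytest.raises(ArchetypeError):
            c.PatternArchetype(label="6", df_center=10, df_spread=0,
                               band_mixture={"alpha": 1.0})
        with pytest.raises(ArchetypeError):
            c.PatternArchetype(label="1", df_center=10, df_spread=0,
                               band_mixture={"alpha": 0.5})
        with pytest.raises(ArchetypeError):
            # centre outside the highest-mixture band
            c.PatternArchetype(label="1", df_center=6.0, df_spread=0,
                               band_mixture={"alpha": 1.0})
        with pytest.raises(ValueError):
            c.generate_df_trajectory(c.DEFAULT_ARCHETYPES["1"], 0, seed=0)


class TestEpochSynthesis:
    def test_pure_tone_argmax(self):
        arch = replace(c.DEFAULT_ARCHETYPES["1"], noise_level=0.0)
        x = c.synthesize_epoch(10.0, arch, n_samples=2048, fs=1024.0, seed=0)
        freqs, power = c.epoch_spectrum(x, 1024.0)
        assert c.dominant_frequency(power, freqs) == 10.0

    def test_default_noise_preserves_df(self, fast_config):
        arch = c.DEFAULT_ARCHETYPES["3"]
        x = c.synthesize_epoch(6.5, arch, n_samples=512, fs=256.0, seed=4)
        freqs, power = c.epoch_spectrum(x, 256.0)
        assert c.dominant_frequency(power, freqs) == 6.5

    def test_slow_epoch_lands_in_delta_theta(self):
        arch = c.DEFAULT_ARCHETYPES["5"]
        x = c.synthesize_epoch(3.0, arch, n_samples=512, fs=256.0, seed=9)
        freqs, power = c.epoch_spectrum(x, 256.0)
        df = c.dominant_frequency(power, freqs)
        assert DEFAULT_BANDS.band_of(df) in ("delta", "theta")

    def test_nyquist_violation(self):
        with pytest.raises(ValueError):
            c.synthesize_epoch(130.0, c.DEFAULT_ARCHETYPES["1"], 512, 256.0, 0)


class TestRecording:
    def test_posterior_channels_share_trajectory(self, fast_config):
        rec = c.synthesize_recording(c.DEFAULT_ARCHETYPES["2"], c.POSTERIOR,
                                     duration=182.0, fs=256.0, seed=6)
        traj = rec.meta["df_trajectory"]
        epochs = c.epoch_signal(rec)
        for ch in c.POSTERIOR:
            csa = c.build_csa(epochs, (ch,))
            df_seq = [c.dominant_frequency(csa.power[e], csa.freqs)
                      for e in range(csa.n_epochs)]
            assert np.array_equal(df_seq, traj)

    def test_reproducible_given_seed(self):
        a = c.synthesize_recording(c.DEFAULT_ARCHETYPES["1"], c.POSTERIOR,
                                   duration=10.0, fs=256.0, seed=3)
        b = c.synthesize_recording(c.DEFAULT_ARCHETYPES["1"], c.POSTERIOR,
                                   duration=10.0, fs=256.0, seed=3)
        assert np.array_equal(a.samples, b.samples)

    def test_degenerate_duration_single_epoch(self):
        rec = c.synthesize_recording(c.DEFAULT_ARCHETYPES["1"], c.POSTERIOR,
                                     duration=2.0, fs=256.0, seed=0)
        epochs = c.epoch_signal(rec)
        assert epochs.n_epochs == 1
        with pytest.raises(c.InsufficientDataError):
            c.select_epochs(epochs, 90)

    def test_empty_channel_list(self):
        with pytest.raises(ValueError):
            c.synthesize_recording(c.DEFAULT_ARCHETYPES["1"], (), 10.0, 256.0, 0)

    def test_non_posterior_channels_attenuated(self):
        rec = c.synthesize_recording(c.DEFAULT_ARCHETYPES["1"],
                                     ("O1", "Fz"), duration=10.0, fs=256.0, seed=1)
        assert rec.channel("Fz").std() < rec.channel("O1").std()


class TestCohort:
    def test_reference_cohort_counts(self):
        coh = c.reference_cohort(seed=0)
        assert len(coh) == 42
        assert coh["subject_id"].is_unique
        counts = coh.groupby(["group", "archetype"]).size().to_dict()
        assert counts == {
            ("MCI-DLB", "1plus"): 9, ("MCI-DLB", "2"): 10, ("MCI-DLB", "3"): 1,
            ("MCI-AD", "1"): 13, ("MCI-AD", "2"): 1,
            ("MCI-NC", "1"): 5, ("MCI-NC", "1plus"): 2, ("MCI-NC", "2"): 1,
        }
        assert coh.groupby("group")["has_dlb_feature"].sum().to_dict() == {
            "MCI-DLB": 15, "MCI-NC": 2, "MCI-AD": 2,
        }

    def test_single_subject_cohort(self):
        spec = c.CohortSpec(groups=(GroupSpec("G", 1, {"1": 1}),), seed=5)
        table = c.generate_cohort(spec)
        assert len(table) == 1 and table.loc[0, "pattern"] == "1"

    def test_group_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("G", 3, {"1": 1})

    def test_trajectory_level_recovery(self):
        # cohort bookkeeping classifies every subject to its archetype
        for seed in range(20):
            coh = c.generate_cohort(
                c.CohortSpec(groups=c.REFERENCE_COHORT_SPEC.groups, seed=seed)
            )
            assert (coh["pattern"] == coh["archetype"]).all()
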