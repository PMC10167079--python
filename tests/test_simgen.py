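"""The simulator's generative contract: determinism, exact noise-free
recovery of the component sum, condition-difference closed forms, noise
spectra and the default study conditions."""

import dataclasses

import numpy as np
import pytest

from erpmvpa import simgen
from erpmvpa.simgen import (CONGRUENT, INCONGRUENT, ComponentSpec,
                            TrialCountSpec, gaussian_topography, make_noise)


def tiny_config(**over):
    cfg = simgen.make_scaled_config(seed=7, n_per_group=2,
                                    trials_per_condition=6, sfreq=64.0,
                                    n_groups=2)
    return dataclasses.replace(cfg, **over) if over else cfg


class TestDeterminism:
    def test_same_seed_same_participant(self):
        cfg = tiny_config()
        a = simgen.simulate_participant(cfg, cfg.groups[0], seed=42)
        b = simgen.simulate_participant(cfg, cfg.groups[0], seed=42)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.trial_labels, b.trial_labels)
        np.testing.assert_array_equal(a.rt, b.rt)

    def test_same_config_same_dataset(self):
        cfg = tiny_config()
        d1 = simgen.simulate_dataset(cfg)
        d2 = simgen.simulate_dataset(cfg)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.data, b.data)
            assert a.participant_id == b.participant_id


class TestGenerativeRecovery:
    def test_noise_free_average_equals_component_sum(self):
        cfg = tiny_config(noise_sd=0.0)
        ep = simgen.simulate_participant(cfg, cfg.groups[0], seed=3)
        for cond in (CONGRUENT, INCONGRUENT):
            trials = ep.data[ep.trial_labels == cond]
            # all trials identical to the template => average == template
            assert np.max(np.abs(trials - trials.mean(axis=0))) < 1e-10

    def test_single_p1_peak_location_and_height(self):
        ch = ["Fz", "Cz", "Pz", "Oz"]
        topo = gaussian_topography("Oz", ch)
        comp = ComponentSpec("P1", peak_latency=100.0, amplitude=5.0,
                             width=25.0, topography=topo)
        counts = TrialCountSpec(4, 0, 4, 4)
        group = simgen.GroupSpec("g", 1, {CONGRUENT: counts,
                                          INCONGRUENT: counts})
        cfg = simgen.SimConfig(
            sfreq=256.0, ch_names=ch, epoch_window=(-100.0, 800.0),
            noise_sd=0.0, noise_exponent=1.0, snr_scale=1.0, seed=0,
            groups=[group], components=[comp],
            behavioral=simgen.BehavioralSpec(rt_median_ms={"g": 500.0}))
        ep = simgen.simulate_participant(cfg, group, seed=0)
        peak_sample = int(np.argmin(np.abs(ep.times - 0.100)))
        # the envelope is sampled on the time grid; its maximum sits at the
        # sample closest to the 100 ms latency, at the analytic height there
        t_ms = ep.times[peak_sample] * 1000.0
        height = 5.0 * topo.max() * np.exp(-0.5 * ((t_ms - 100.0) / 25.0) ** 2)
        for trial in ep.data:
            assert trial.max() == pytest.approx(height, rel=1e-12)
            ch_i, s_i = np.unravel_index(np.argmax(trial), trial.shape)
            assert s_i == peak_sample
            assert ch_i == np.argmax(topo)

    def test_condition_delta_closed_form(self):
        cfg = tiny_config(noise_sd=0.0)
        # strip participant-level jitter so the difference is exact
        comps = [dataclasses.replace(c, latency_sd=0.0, amplitude_sd=0.0)
                 for c in cfg.components]
        cfg = dataclasses.replace(cfg, components=comps)
        group = cfg.groups[1]            # 'young': no condition shift
        assert group.condition_shift_ms == 0.0
        ep = simgen.simulate_participant(cfg, group, seed=5)
        n2 = next(c for c in cfg.components if c.name == "N2")
        diff = (ep.data[ep.trial_labels == INCONGRUENT].mean(axis=0)
                - ep.data[ep.trial_labels == CONGRUENT].mean(axis=0))
        ch_i = np.argmax(np.abs(n2.topography))
        s_i = int(np.argmin(np.abs(ep.times * 1000 - n2.peak_latency)))
        t_ms = ep.times[s_i] * 1000.0
        expected = (n2.condition_delta_amplitude * n2.topography[ch_i]
                    * np.exp(-0.5 * ((t_ms - n2.peak_latency)
                                     / n2.width) ** 2))
        assert diff[ch_i, s_i] == pytest.approx(expected, rel=1e-6)


class TestNoise:
    def test_white_noise_uncorrelated(self):
        x = make_noise(2, 10_000, 256.0, exponent=0.0, sd=1.0, rng=0)
        for ch in x:
            r = np.corrcoef(ch[:-1], ch[1:])[0, 1]
            assert abs(r) < 0.05

    def test_pink_noise_spectral_slope(self):
        x = make_noise(1, 2**14, 256.0, exponent=1.0, sd=1.0, rng=1)[0]
        freqs = np.fft.rfftfreq(len(x), 1 / 256.0)
        psd = np.abs(np.fft.rfft(x)) ** 2
        sel = (freqs > 1) & (freqs < 100)
        slope = np.polyfit(np.log(freqs[sel]), np.log(psd[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_sd_scaling_and_degenerate(self):
        x = make_noise(3, 10_000, 256.0, exponent=1.0, sd=2.5, rng=2)
        assert np.allclose(x.std(axis=1), 2.5, rtol=0.05)
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-12)
        assert not make_noise(2, 100, 256.0, 1.0, sd=0.0, rng=0).any()

    def test_errors(self):
        with pytest.raises(ValueError):
            make_noise(1, 1, 256.0, 1.0, 1.0, rng=0)
        with pytest.raises(ValueError):
            make_noise(1, 100, 256.0, -0.5, 1.0, rng=0)


class TestDefaultConfig:
    def test_group_sizes_and_trial_distributions(self):
        cfg = simgen.make_default_config()
        sizes = [g.n_participants for g in cfg.groups]
        assert sizes == [46, 39, 21, 25, 40, 38]
        children = cfg.groups[0]
        assert children.trial_counts[INCONGRUENT].mean == pytest.approx(70.91)
        assert cfg.epoch_window == (-100.0, 800.0)
        assert cfg.sfreq == 256.0
        assert len(cfg.ch_names) == 32

    def test_epoch_grid_has_231_samples(self):
        times = simgen.epoch_times((-100.0, 800.0), 256.0)
        assert len(times) == 231
        assert times[0] == pytest.approx(-26 / 256)
        assert times[-1] == pytest.approx(204 / 256)

    def test_dataset_participant_counts(self):
        cfg = simgen.make_default_config()
        # shrink per-participant cost, keep the group structure
        counts = TrialCountSpec(2, 0, 2, 2)
        groups = [dataclasses.replace(
            g, trial_counts={CONGRUENT: counts, INCONGRUENT: counts})
            for g in cfg.groups]
        small = dataclasses.replace(
            cfg, groups=groups, sfreq=32.0,
            ch_names=cfg.ch_names[:4],
            components=[dataclasses.replace(
                c, topography=c.topography[:4]) for c in cfg.components])
        assert len(simgen.simulate_dataset(small)) == 209

    def test_two_by_three_dataset(self):
        cfg = simgen.make_scaled_config(n_per_group=3, n_groups=2,
                                        trials_per_condition=3, sfreq=32.0)
        assert len(simgen.simulate_dataset(cfg)) == 6

    def test_trial_counts_respect_truncation_bounds(self):
        cfg = simgen.make_default_config(seed=11)
        group = cfg.groups[1]
        rng = np.random.default_rng(0)
        for _ in range(200):
            for cond in (CONGRUENT, INCONGRUENT):
                spec = group.trial_counts[cond]
                n = simgen._draw_trial_count(spec, rng)
                assert spec.min <= n <= spec.max


class TestValidation:
    def test_unknown_group_rejected(self):
        cfg = tiny_config()
        stranger = dataclasses.replace(cfg.groups[0], name="stranger")
        with pytest.raises(ValueError):
            simgen.simulate_participant(cfg, stranger, seed=0)

    def test_component_invariants(self):
        with pytest.raises(ValueError):
            ComponentSpec("bad", peak_latency=100.0, amplitude=1.0,
                          width=0.0, topography=np.ones(4))
        with pytest.raises(ValueError):
            TrialCountSpec(5, 1, 10, 20)
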