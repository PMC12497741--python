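"""Generator contracts: determinism, exact injection, balance, noise shape,
behavioral parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from actionfx import synthetic_data as sd
from actionfx.design import CELLS, ConfigurationError


def test_identical_config_and_seed_is_bit_identical():
    cfg = sd.default_config(seed=7, n_subjects=2, n_trials_per_cell=8,
                            sampling_rate=50.0)
    a_eps, a_tabs, a_truth = sd.generate_dataset(cfg)
    b_eps, b_tabs, b_truth = sd.generate_dataset(cfg)
    for a, b in zip(a_eps, b_eps):
        assert np.array_equal(a.data, b.data)
    for a, b in zip(a_tabs, b_tabs):
        pd.testing.assert_frame_equal(a, b)
    assert a_truth.to_json() == b_truth.to_json()


def test_different_seeds_differ():
    cfg1 = sd.default_config(seed=1, n_subjects=2, n_trials_per_cell=8,
                             sampling_rate=50.0)
    cfg2 = sd.default_config(seed=2, n_subjects=2, n_trials_per_cell=8,
                             sampling_rate=50.0)
    a, _, _ = sd.generate_dataset(cfg1)
    b, _, _ = sd.generate_dataset(cfg2)
    assert not np.array_equal(a[0].data, b[0].data)


def test_noise_free_injection_is_exact_in_every_matching_trial():
    comp = sd.InjectedComponent("x", ("PO7", "PO8"), (180.0, 300.0),
                                {c: 2.0 for c in CELLS})
    cfg = sd.SimConfig(n_subjects=2, n_trials_per_cell=8, noise_sd=0.0,
                       sampling_rate=100.0, component_params=(comp,), seed=0)
    eps, tabs, _ = sd.generate_dataset(cfg)
    for ep in eps:
        mask = ep.time_mask((180.0, 300.0))
        idx = ep.layout.indices(("PO7", "PO8"))
        means = ep.data[:, idx][:, :, mask].mean(axis=(1, 2))
        assert np.allclose(means, 2.0, atol=1e-12)


def test_default_design_has_60_trials_per_cell_and_480_total():
    cfg = sd.default_config(seed=0)
    table = sd.generate_trial_table(cfg, 0)
    assert len(table) == 480
    counts = table.groupby(["congruency", "action", "validity"]).size()
    assert (counts == 60).all()


def test_hemifield_and_orientation_balanced_within_cell():
    for n in (9, 12, 60):
        cfg = sd.default_config(seed=3, n_trials_per_cell=n)
        table = sd.generate_trial_table(cfg, 0)
        strata = table.groupby(["congruency", "action", "validity",
                                "target_hemifield", "target_orientation"]).size()
        for cell in CELLS:
            cell_counts = strata.loc[cell]
            assert cell_counts.max() - cell_counts.min() <= 1


def test_superposition_of_components_at_zero_noise():
    a = sd.InjectedComponent("a", ("PO7", "PO8"), (180.0, 300.0),
                             {c: 1.5 for c in CELLS})
    b = sd.InjectedComponent("b", sd.PARIETO_OCCIPITAL_10, (300.0, 500.0),
                             {c: -0.5 for c in CELLS})
    base = dict(n_subjects=2, n_trials_per_cell=8, noise_sd=0.0,
                sampling_rate=100.0, seed=9)
    both, _, _ = sd.generate_dataset(sd.SimConfig(component_params=(a, b), **base))
    only_a, _, _ = sd.generate_dataset(sd.SimConfig(component_params=(a,), **base))
    only_b, _, _ = sd.generate_dataset(sd.SimConfig(component_params=(b,), **base))
    for s in range(2):
        assert np.allclose(both[s].data, only_a[s].data + only_b[s].data,
                           atol=1e-12)


class TestNoise:
    def test_zero_sd_is_all_zero(self):
        cfg = sd.SimConfig(noise_sd=0.0, sampling_rate=100.0)
        assert not sd.generate_noise(cfg, 3).any()

    def test_white_noise_sd_close_to_target(self):
        cfg = sd.SimConfig(noise_spectral_exponent=0.0, spatial_smoothing=0.0,
                           n_channels=8, sampling_rate=250.0, noise_sd=10.0)
        x = sd.generate_noise(cfg, 500, np.random.default_rng(0))
        per_channel_sd = x.std(axis=(0, 2))
        assert np.all(np.abs(per_channel_sd - 10.0) / 10.0 < 0.05)

    def test_pink_noise_spectral_slope(self):
        cfg = sd.SimConfig(noise_spectral_exponent=1.0, spatial_smoothing=0.0,
                           n_channels=4, sampling_rate=500.0, noise_sd=10.0)
        x = sd.generate_noise(cfg, 300, np.random.default_rng(1))
        f, p = signal.welch(x.reshape(-1, x.shape[-1]), fs=500.0,
                            nperseg=x.shape[-1], axis=-1)
        m = (f >= 2.0) & (f <= 40.0)
        slope = np.polyfit(np.log(f[m]), np.log(p.mean(axis=0)[m]), 1)[0]
        assert abs(slope - (-1.0)) < 0.2

    def test_spatial_smoothing_induces_channel_correlation(self):
        cfg = sd.SimConfig(noise_spectral_exponent=0.0, spatial_smoothing=0.5,
                           n_channels=6, sampling_rate=250.0, noise_sd=10.0)
        x = sd.generate_noise(cfg, 200, np.random.default_rng(2))
        flat = x.transpose(1, 0, 2).reshape(6, -1)
        corr = np.corrcoef(flat)
        off = corr[np.triu_indices(6, 1)]
        assert abs(off.mean() - 0.5) < 0.05


class TestBehavior:
    def test_zero_rt_sd_gives_cell_means_exactly(self):
        cfg = sd.default_config(seed=0, n_subjects=2, n_trials_per_cell=8,
                                sampling_rate=50.0,
                                rt_sd_ms={c: 0.0 for c in CELLS})
        _, tabs, _ = sd.generate_dataset(cfg)
        for tab in tabs:
            for cell in CELLS:
                m = (tab["congruency"] == cell[0]) & (tab["action"] == cell[1]) \
                    & (tab["validity"] == cell[2])
                assert np.allclose(tab.loc[m, "rt"], cfg.rt_mean_ms[cell])

    def test_accuracy_probability_one_means_all_correct(self):
        cfg = sd.default_config(seed=0, n_subjects=2, n_trials_per_cell=8,
                                sampling_rate=50.0,
                                accuracy={c: 1.0 for c in CELLS})
        _, tabs, _ = sd.generate_dataset(cfg)
        assert all(tab["correct"].all() for tab in tabs)

    def test_injected_98ms_validity_effect_recovered(self):
        # RT generation is EEG-independent: tiny epochs keep this fast
        cfg = sd.default_config(seed=5, n_subjects=26, n_trials_per_cell=60,
                                sampling_rate=10.0, n_channels=4, noise_sd=0.0,
                                component_params=(), pattern_params=())
        _, tabs, _ = sd.generate_dataset(cfg)
        effects = []
        for tab in tabs:
            m = (tab["congruency"] == "congruent") & (tab["action"] == "action") \
                & tab["correct"]
            sub = tab[m]
            effects.append(sub.loc[sub["validity"] == "invalid", "rt"].mean()
                           - sub.loc[sub["validity"] == "valid", "rt"].mean())
        effects = np.asarray(effects)
        sem = effects.std(ddof=1) / np.sqrt(len(effects))
        assert abs(effects.mean() - 98.0) <= 2.0 * sem + 1e-12


class TestValidation:
    @pytest.mark.parametrize("overrides,field", [
        (dict(n_subjects=1), "n_subjects"),
        (dict(n_trials_per_cell=4), "n_trials_per_cell"),
        (dict(epoch_window=(100.0, 800.0)), "epoch_window"),
        (dict(spatial_smoothing=1.5), "spatial_smoothing"),
    ])
    def test_invalid_config_names_the_field(self, overrides, field):
        cfg = sd.default_config(seed=0, **overrides)
        with pytest.raises(ConfigurationError, match=field):
            sd.generate_dataset(cfg)

    def test_non_integer_sample_count_rejected(self):
        cfg = sd.SimConfig(sampling_rate=100.3)
        with pytest.raises(ConfigurationError):
            cfg.n_samples()

    def test_component_window_outside_epoch_rejected(self):
        comp = sd.InjectedComponent("x", ("PO7", "PO8"), (700.0, 1200.0),
                                    {c: 1.0 for c in CELLS})
        cfg = sd.SimConfig(component_params=(comp,), sampling_rate=100.0)
        with pytest.raises(ConfigurationError, match="window"):
            sd.generate_dataset(cfg)


def test_lateralized_injection_goes_to_the_contralateral_electrode():
    comp = sd.InjectedComponent("n2pc", ("PO7", "PO8"), (180.0, 300.0),
                                {c: -2.0 for c in CELLS}, lateralized=True)
    cfg = sd.SimConfig(n_subjects=2, n_trials_per_cell=8, noise_sd=0.0,
                       sampling_rate=100.0, component_params=(comp,), seed=1)
    eps, tabs, _ = sd.generate_dataset(cfg)
    ep, tab = eps[0], tabs[0]
    mask = ep.time_mask((180.0, 300.0))
    i7, i8 = ep.layout.index("PO7"), ep.layout.index("PO8")
    left = tab["target_hemifield"].to_numpy() == "left"
    # left-hemifield target -> signal on the right electrode (PO8) only
    assert np.allclose(ep.data[left][:, i8, :][:, mask].mean(axis=1), -2.0)
    assert np.allclose(ep.data[left][:, i7, :], 0.0)
    assert np.allclose(ep.data[~left][:, i7, :][:, mask].mean(axis=1), -2.0)
    assert np.allclose(ep.data[~left][:, i8, :], 0.0)


def test_ground_truth_roundtrips_through_json():
    cfg = sd.default_config(seed=4, n_subjects=2, n_trials_per_cell=8,
                            sampling_rate=50.0)
    _, _, truth = sd.generate_dataset(cfg)
    again = sd.GroundTruth.from_json(truth.to_json())
    assert again.to_json() == truth.to_json()
    assert again.seed == 4
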