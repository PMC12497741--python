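"""Component amplitude measurement and validity effects."""

import numpy as np
import pandas as pd
import pytest

from actionfx import erp_components as erp
from actionfx import synthetic_data as sd
from actionfx.design import CELLS, EmptyResultError, LabelingError
from actionfx.epochs_core import EpochSet


class TestMeanAmplitude:
    def test_constant_signal(self, toy_epochs):
        ep, _ = toy_epochs
        ep.data[:] = 1.0
        amp = erp.mean_amplitude(ep, ("PO7", "PO8"), (180.0, 300.0))
        assert np.allclose(amp, 1.0)

    def test_signal_confined_to_window(self, toy_epochs):
        ep, _ = toy_epochs
        ep.data[:] = 0.0
        mask = ep.time_mask((300.0, 500.0))
        ep.data[:, :, mask] = 2.0
        assert np.allclose(erp.mean_amplitude(ep, ("P3", "P4"), (300.0, 500.0)), 2.0)
        # outside the window nothing is picked up
        assert np.allclose(erp.mean_amplitude(ep, ("P3", "P4"), (-200.0, 280.0)), 0.0)

    def test_matches_bruteforce_double_sum(self, toy_epochs):
        ep, _ = toy_epochs
        electrodes = ("PO7", "PO8", "P3")
        window = (100.0, 400.0)
        amp = erp.mean_amplitude(ep, electrodes, window)
        idx = [ep.layout.index(e) for e in electrodes]
        tsel = [i for i, t in enumerate(ep.times) if window[0] <= t <= window[1]]
        for trial in range(ep.n_trials):
            total, count = 0.0, 0
            for c in idx:
                for t in tsel:
                    total += ep.data[trial, c, t]
                    count += 1
            assert np.isclose(amp[trial], total / count)

    def test_linearity(self, toy_epochs):
        ep, _ = toy_epochs
        a = erp.mean_amplitude(ep, ("PO7",), (0.0, 500.0))
        ep2 = ep.copy()
        ep2.data *= 3.0
        ep2.data += 1.0
        b = erp.mean_amplitude(ep2, ("PO7",), (0.0, 500.0))
        assert np.allclose(b, 3.0 * a + 1.0)

    def test_unknown_electrode_raises(self, toy_epochs):
        ep, _ = toy_epochs
        with pytest.raises(LabelingError):
            erp.mean_amplitude(ep, ("NOPE",), (0.0, 100.0))


class TestLateralized:
    def test_identical_signals_give_zero_difference(self, toy_epochs):
        ep, table = toy_epochs
        i7, i8 = ep.layout.index("PO7"), ep.layout.index("PO8")
        ep.data[:, i8, :] = ep.data[:, i7, :]
        diff = erp.lateralized_difference(ep, table, ("PO7", "PO8"))
        assert np.allclose(diff, 0.0)

    def test_left_target_contra_is_the_right_electrode(self, toy_epochs):
        ep, table = toy_epochs
        ep.data[:] = 0.0
        table = table.assign(target_hemifield="left")
        i8 = ep.layout.index("PO8")
        mask = ep.time_mask((180.0, 300.0))
        ep.data[:, i8, mask] = -2.0
        diff = erp.lateralized_difference(ep, table, ("PO7", "PO8"))
        assert np.allclose(diff[:, mask], -2.0)
        contra, ipsi = erp.lateralized_waveform(ep, table, ("PO7", "PO8"))
        assert np.allclose((contra - ipsi)[mask], -2.0)

    def test_flipping_hemifield_labels_negates_the_difference(self, toy_epochs):
        ep, table = toy_epochs
        diff = erp.lateralized_difference(ep, table, ("PO7", "PO8"))
        flipped = table.assign(target_hemifield=table["target_hemifield"].map(
            {"left": "right", "right": "left"}))
        diff2 = erp.lateralized_difference(ep, flipped, ("PO7", "PO8"))
        assert np.allclose(diff2, -diff)

    def test_swapping_electrodes_with_labels_is_invariant(self, toy_epochs):
        # mirror symmetry: swap left/right electrode signals AND hemifields
        ep, table = toy_epochs
        diff = erp.lateralized_difference(ep, table, ("PO7", "PO8"))
        ep2 = ep.copy()
        i7, i8 = ep.layout.index("PO7"), ep.layout.index("PO8")
        ep2.data[:, [i7, i8], :] = ep2.data[:, [i8, i7], :]
        flipped = table.assign(target_hemifield=table["target_hemifield"].map(
            {"left": "right", "right": "left"}))
        diff2 = erp.lateralized_difference(ep2, flipped, ("PO7", "PO8"))
        assert np.allclose(diff2, diff)

    def test_midline_pair_is_an_error(self, toy_epochs):
        ep, table = toy_epochs
        with pytest.raises(LabelingError):
            erp.lateralized_difference(ep, table, ("Pz", "POz"))


class TestCellMeans:
    def test_noise_free_injection_recovers_cell_table_exactly(self):
        comp = sd.InjectedComponent("N2pc", ("PO7", "PO8"), (180.0, 300.0),
                                    dict(sd.DEFAULT_N2PC_UV), lateralized=True)
        cfg = sd.SimConfig(n_subjects=2, n_trials_per_cell=8, noise_sd=0.0,
                           sampling_rate=100.0, component_params=(comp,),
                           accuracy={c: 1.0 for c in CELLS}, seed=1)
        eps, tabs, _ = sd.generate_dataset(cfg)
        cells = erp.component_cell_means(eps[0], tabs[0], erp.N2PC)
        for row in cells.itertuples():
            injected = sd.DEFAULT_N2PC_UV[(row.congruency, row.action, row.validity)]
            assert np.isclose(row.amplitude, injected, atol=1e-12)

    def test_all_zero_data_gives_zero_cells(self, small_dataset):
        _, eps, tabs, _ = small_dataset
        ep = eps[0].copy()
        ep.data[:] = 0.0
        cells = erp.component_cell_means(ep, tabs[0], erp.P300B, correct_only=False)
        assert np.allclose(cells["amplitude"], 0.0)

    def test_trial_order_invariance(self, small_dataset):
        _, eps, tabs, _ = small_dataset
        ep, tab = eps[0], tabs[0]
        cells = erp.component_cell_means(ep, tab, erp.N2PC)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ep.n_trials)
        ep2 = ep.select_trials(perm)
        tab2 = tab.iloc[perm].reset_index(drop=True)
        cells2 = erp.component_cell_means(ep2, tab2, erp.N2PC)
        pd.testing.assert_frame_equal(cells, cells2)

    def test_empty_cell_names_the_cell(self, small_dataset):
        _, eps, tabs, _ = small_dataset
        tab = tabs[0].copy()
        m = (tab["congruency"] == "congruent") & (tab["action"] == "action") \
            & (tab["validity"] == "valid")
        tab.loc[m, "kept"] = False
        with pytest.raises(EmptyResultError, match="congruent/action/valid"):
            erp.component_cell_means(eps[0], tab, erp.N2PC)


class TestValidityEffect:
    @staticmethod
    def _cells_frame(values_by_cell, component="N2pc"):
        rows = [("S00", *cell, component, val) for cell, val in values_by_cell.items()]
        return pd.DataFrame(rows, columns=["subject", "congruency", "action",
                                           "validity", "component", "amplitude"])

    def test_n2pc_effect_is_invalid_minus_valid(self):
        cells = self._cells_frame({
            ("congruent", "action", "valid"): -1.69,
            ("congruent", "action", "invalid"): 1.01,
            ("incongruent", "no_action", "valid"): -0.51,
            ("incongruent", "no_action", "invalid"): -0.35,
            ("congruent", "no_action", "valid"): 0.34,
            ("congruent", "no_action", "invalid"): -1.10,
            ("incongruent", "action", "valid"): -1.65,
            ("incongruent", "action", "invalid"): 1.08,
        })
        eff = erp.validity_effect(cells, erp.N2PC).set_index(["congruency", "action"])
        assert np.isclose(eff.loc[("congruent", "action"), "effect"], 2.70)
        assert np.isclose(eff.loc[("incongruent", "action"), "effect"], 2.73)
        assert np.isclose(eff.loc[("incongruent", "no_action"), "effect"], 0.16)

    def test_p300b_effect_is_valid_minus_invalid(self):
        cells = self._cells_frame(
            {cell: sd.DEFAULT_P300B_UV[cell] for cell in CELLS}, component="P300b")
        eff = erp.validity_effect(cells, erp.P300B).set_index(["congruency", "action"])
        assert np.isclose(eff.loc[("congruent", "action"), "effect"], 0.38)
        assert np.isclose(eff.loc[("incongruent", "action"), "effect"], 0.88)
        assert np.isclose(eff.loc[("congruent", "no_action"), "effect"], -0.79)

    def test_equal_amplitudes_give_zero_effect(self):
        cells = self._cells_frame({cell: 1.23 for cell in CELLS})
        eff = erp.validity_effect(cells, erp.N2PC)
        assert np.allclose(eff["effect"], 0.0)

    def test_missing_level_raises(self):
        cells = self._cells_frame(
            {cell: 1.0 for cell in CELLS if cell[2] == "valid"})
        with pytest.raises(EmptyResultError):
            erp.validity_effect(cells, erp.N2PC)


def test_lateralized_recovery_converges_within_3_sem():
    """Injected N2pc amplitude is recovered from noisy trials at n=500."""
    amp = -1.5
    comp = sd.InjectedComponent("N2pc", ("PO7", "PO8"), (180.0, 300.0),
                                {c: amp for c in CELLS}, lateralized=True)
    cfg = sd.SimConfig(n_subjects=2, n_trials_per_cell=63, noise_sd=10.0,
                       sampling_rate=100.0, n_channels=10,
                       component_params=(comp,), seed=21)
    eps, tabs, _ = sd.generate_dataset(cfg)
    ep, tab = eps[0], tabs[0]  # 504 trials
    values = erp.component_trial_values(ep, tab, erp.N2PC)
    sem = values.std(ddof=1) / np.sqrt(values.size)
    assert abs(values.mean() - amp) <= 3.0 * sem
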