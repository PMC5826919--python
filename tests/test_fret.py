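"""Decay fitting and FRET efficiency, whole-cell and subcellular."""

import numpy as np
import pytest

from coccoloc import (
    BleachSpec,
    BleachTrace,
    ParameterError,
    StatisticError,
    extract_trace,
    fit_decay,
    fret_efficiency,
    simulate_bleach_stack,
    simulate_bleach_trace,
    subcellular_fret,
)


def fits_for(tau, n, *, noise_sd=20.0, seed0=0, **trace_kw):
    fits = []
    for i in range(n):
        tr = simulate_bleach_trace(BleachSpec(tau_frames=tau, amplitude=1000, offset=50,
                                              noise_sd=noise_sd, seed=seed0 + i))
        for k, v in trace_kw.items():
            setattr(tr, k, v)
        fits.append(fit_decay(tr))
    return fits


class TestExtractTrace:
    def test_single_pixel_mask_returns_pixel_course(self, rng):
        stack = rng.random((20, 5, 5))
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        trace = extract_trace(stack, mask)
        assert np.array_equal(trace.intensity, stack[:, 2, 3])

    def test_uniform_field_mean_matches_ideal_decay(self):
        spec = BleachSpec(tau_frames=100, amplitude=1000, offset=50, n_frames=120, noise_sd=30, seed=5)
        stack = simulate_bleach_stack(spec, (20, 20))
        trace = extract_trace(stack, np.ones((20, 20), bool))
        t = np.arange(120)
        ideal = 1000 * np.exp(-t / 100) + 50
        # ROI mean of 400 iid pixels: sd 30/20 = 1.5; allow 5 sigma
        assert np.max(np.abs(trace.intensity - ideal)) < 7.5

    def test_septum_periphery_recompose_whole_cell(self, rng):
        stack = rng.random((15, 8, 8)) * 100
        septum = np.zeros((8, 8), bool)
        septum[3:5, :] = True
        periphery = ~septum
        whole = extract_trace(stack, np.ones((8, 8), bool)).intensity
        s = extract_trace(stack, septum).intensity
        p = extract_trace(stack, periphery).intensity
        recomposed = (s * septum.sum() + p * periphery.sum()) / 64
        assert np.allclose(recomposed, whole)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ParameterError):
            extract_trace(rng.random((15, 8, 8)), np.zeros((8, 8), bool))


class TestFitDecay:
    def test_noise_free_exact_recovery(self):
        trace = simulate_bleach_trace(BleachSpec(tau_frames=100, amplitude=1000, offset=50, noise_sd=0))
        fit = fit_decay(trace)
        assert fit.converged
        assert fit.tau_frames == pytest.approx(100.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(1000.0, rel=1e-6)
        assert fit.offset == pytest.approx(50.0, rel=1e-4)

    def test_constant_trace_not_converged(self):
        fit = fit_decay(BleachTrace(intensity=np.full(100, 42.0)))
        assert not fit.converged
        assert "constant" in fit.message

    def test_rising_trace_not_converged(self):
        fit = fit_decay(BleachTrace(intensity=np.linspace(10, 100, 50)))
        assert not fit.converged

    def test_noisy_recovery_within_two_percent(self):
        """720-frame traces at 2% noise: median relative tau error < 2%."""
        errs = []
        for i in range(50):
            tr = simulate_bleach_trace(BleachSpec(tau_frames=150, amplitude=1000, offset=50,
                                                  noise_sd=20, seed=i))
            fit = fit_decay(tr)
            assert fit.converged
            errs.append(abs(fit.tau_frames - 150) / 150)
        assert np.median(errs) < 0.02


class TestFretEfficiency:
    def test_equal_taus_give_zero(self):
        d = fits_for(100, 5, noise_sd=0)
        res = fret_efficiency(d, fits_for(100, 5, noise_sd=0))
        assert res.efficiency == pytest.approx(0.0, abs=1e-9)

    def test_arithmetic_of_eq(self):
        res = fret_efficiency(fits_for(100, 3, noise_sd=0), fits_for(125, 3, noise_sd=0))
        assert res.efficiency == pytest.approx(0.20, abs=1e-6)
        assert res.efficiency_pct == pytest.approx(20.0, abs=1e-4)

    def test_negative_efficiency_not_clipped(self):
        res = fret_efficiency(fits_for(100, 3, noise_sd=0), fits_for(90, 3, noise_sd=0))
        assert res.efficiency == pytest.approx(1 - 100 / 90, abs=1e-6)

    def test_rescaling_either_arm_leaves_e_unchanged(self):
        d = fits_for(100, 5, noise_sd=10)
        a = fits_for(125, 5, noise_sd=10, seed0=50)
        base = fret_efficiency(d, a, n_boot=0).efficiency
        # tau is unit-free: rescale the donor arm's intensities by 7x
        d_scaled = []
        for i in range(5):
            tr = simulate_bleach_trace(BleachSpec(tau_frames=100, amplitude=7000, offset=350,
                                                  noise_sd=70, seed=i))
            d_scaled.append(fit_decay(tr))
        rescaled = fret_efficiency(d_scaled, a, n_boot=0).efficiency
        assert rescaled == pytest.approx(base, abs=1e-3)

    def test_unconverged_arm_rejected(self):
        bad = [fit_decay(BleachTrace(intensity=np.full(50, 10.0)))]
        with pytest.raises(StatisticError):
            fret_efficiency(bad, fits_for(100, 2, noise_sd=0))

    def test_bootstrap_interval_brackets_truth(self):
        res = fret_efficiency(fits_for(100, 20), fits_for(125, 20, seed0=100), n_boot=500, seed=1)
        assert res.ci_low < 0.20 < res.ci_high


class TestSubcellularFret:
    def _design(self, tau_by_compartment, n=8, noise_sd=10.0):
        """Donor-only at tau 100 everywhere; acceptor-arm tau per compartment."""
        traces = []
        seed = 0
        for (div, roi), tau_acc in tau_by_compartment.items():
            for cond, tau in (("donor_only", 100.0), ("donor_plus_acceptor", tau_acc)):
                for i in range(n):
                    tr = simulate_bleach_trace(BleachSpec(tau_frames=tau, amplitude=1000,
                                                          offset=50, noise_sd=noise_sd, seed=seed))
                    seed += 1
                    tr.roi_label = roi
                    tr.division_state = div
                    tr.condition = cond
                    traces.append(tr)
        return traces

    def test_compartment_specific_interaction_recovered(self):
        """Interaction only at the periphery of dividing cells (true E = 0.15):
        that compartment recovers 0.15 and all others stay near zero."""
        tau_by = {
            ("dividing", "periphery"): 100 / 0.85,
            ("dividing", "septum"): 100.0,
            ("non_dividing", "whole_cell"): 100.0,
        }
        report = subcellular_fret(self._design(tau_by), n_boot=0)
        e_hit = report.results[("dividing", "periphery")].efficiency
        assert e_hit == pytest.approx(0.15, abs=0.03)
        for key in (("dividing", "septum"), ("non_dividing", "whole_cell")):
            assert abs(report.results[key].efficiency) < 0.03

    def test_null_everywhere(self):
        tau_by = {("dividing", "septum"): 100.0, ("non_dividing", "whole_cell"): 100.0}
        report = subcellular_fret(self._design(tau_by), n_boot=0)
        for res in report.results.values():
            assert abs(res.efficiency) < 0.03

    def test_empty_compartment_flagged_absent(self):
        report = subcellular_fret(self._design({("non_dividing", "whole_cell"): 125.0}), n_boot=0)
        assert ("dividing", "septum") in report.absent

    def test_missing_donor_arm_is_per_compartment_error(self):
        traces = self._design({("non_dividing", "whole_cell"): 125.0})
        # a compartment with only acceptor-arm traces
        extra = simulate_bleach_trace(BleachSpec(tau_frames=110, amplitude=1000, offset=50, noise_sd=5, seed=999))
        extra.roi_label = "septum"
        extra.division_state = "dividing"
        extra.condition = "donor_plus_acceptor"
        report = subcellular_fret(traces + [extra], n_boot=0)
        assert "donor-only" in report.errors[("dividing", "septum")]
        assert ("non_dividing", "whole_cell") in report.results
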