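"""TEW estimation arithmetic and OSEM reconstruction behaviour."""

import numpy as np
import pytest

from luquant.projector import (AcquisitionSpec, EnergyWindowSet,
                               MultiWindowSinogram, Projector, SystemModel)
from luquant.recon import (OsemConfig, TewEstimate, osem, primary_counts,
                           tew_estimate)


def window_sino(pw, lsw, usw, acq=None):
    acq = acq or AcquisitionSpec(n_projections=pw.shape[0],
                                 detector_shape=pw.shape[1:], bin_size=4.8)
    return MultiWindowSinogram({"pw": pw, "lsw": lsw, "usw": usw}, acq)


class TestTew:
    def test_zero_flanking_windows_give_zero_scatter(self):
        s = window_sino(np.ones((2, 4, 4)), np.zeros((2, 4, 4)), np.zeros((2, 4, 4)))
        assert not tew_estimate(s).C_s.any()

    def test_window_width_arithmetic(self):
        # C_ls equal to w_ls and C_us equal to w_us make both density terms 1,
        # so the trapezoid gives exactly the photopeak width
        pw = np.full((1, 1, 1), 100.0)
        s = window_sino(pw, np.full((1, 1, 1), 34.0), np.full((1, 1, 1), 50.7))
        est = tew_estimate(s)
        assert est.C_s[0, 0, 0] == pytest.approx(41.6)
        assert primary_counts(s, est)[0, 0, 0] == pytest.approx(58.4)

    def test_matches_naive_per_bin_loop(self, rng):
        arrs = {k: rng.uniform(0, 50, (3, 6, 5)) for k in ("pw", "lsw", "usw")}
        s = window_sino(arrs["pw"], arrs["lsw"], arrs["usw"])
        est = tew_estimate(s).C_s
        w = EnergyWindowSet()
        for idx in np.ndindex(arrs["pw"].shape):
            expected = (arrs["lsw"][idx] / w.w_ls
                        + arrs["usw"][idx] / w.w_us) * w.w_pw / 2.0
            assert est[idx] == pytest.approx(expected, rel=1e-12)

    def test_missing_window_raises(self):
        acq = AcquisitionSpec(n_projections=1, detector_shape=(4, 4), bin_size=4.8,
                              angles_deg=np.array([0.0]))
        s = MultiWindowSinogram({"pw": np.ones((1, 4, 4))}, acq)
        with pytest.raises(ValueError, match="lsw"):
            tew_estimate(s)

    def test_primary_counts_clamped_at_zero(self):
        pw = np.full((1, 2, 2), 10.0)
        s = window_sino(pw, np.full((1, 2, 2), 340.0), np.zeros((1, 2, 2)))
        prim = primary_counts(s, tew_estimate(s))
        assert np.all(prim == 0.0)


def identity_projector():
    acq = AcquisitionSpec(n_projections=1, detector_shape=(1, 1), bin_size=1.0,
                          t_p=1.0, angles_deg=np.array([0.0]))
    model = SystemModel(acq, voxel_size=1.0, mu=None, resolution_recovery=False,
                        attenuation=False)
    return Projector(model, (1, 1, 1))


class TestOsem:
    def test_single_voxel_fixed_point(self):
        img = osem(np.full((1, 1, 1), 7.0), identity_projector(), None,
                   OsemConfig(n_subsets=1, n_iterations=6))
        assert img.values[0, 0, 0] == pytest.approx(7.0, abs=1e-6)

    def test_nonnegativity_and_zeros_stay_zero(self, mini_setup):
        phantom, acq, sim = mini_setup
        from luquant.simulate import recon_projector
        P = recon_projector(phantom, acq)
        img = osem(sim.expected["pw"], P,
                   TewEstimate(sim.scatter_truth.pw_scatter, "ideal"),
                   OsemConfig(n_iterations=2))
        assert np.all(img.values >= 0)
        # voxels outside the FOV support never receive counts
        corner = img.values[0, 0, :]
        assert not corner.any()

    def test_noiseless_matched_recovery_within_1pct(self, mini_setup):
        phantom, acq, sim = mini_setup
        from luquant.simulate import recon_projector
        P = recon_projector(phantom, acq)
        img = osem(sim.expected["pw"], P,
                   TewEstimate(sim.scatter_truth.pw_scatter, "ideal"))
        recovered = img.total_counts / (acq.sensitivity * acq.t_p
                                        * acq.n_projections)
        assert recovered == pytest.approx(phantom.total_activity_MBq, rel=0.01)

    def test_error_decreases_monotonically_over_iterations(self, mini_setup):
        phantom, acq, sim = mini_setup
        from luquant.simulate import recon_projector
        P = recon_projector(phantom, acq)
        truth = phantom.total_activity_MBq * acq.sensitivity * acq.t_p \
            * acq.n_projections
        errs = []
        for it in range(1, 7):
            img = osem(sim.expected["pw"], P,
                       TewEstimate(sim.scatter_truth.pw_scatter, "ideal"),
                       OsemConfig(n_iterations=it))
            errs.append(abs(img.total_counts - truth))
        assert all(b <= a * 1.001 for a, b in zip(errs, errs[1:]))

    def test_uncorrected_reconstruction_overestimates(self, mini_setup):
        phantom, acq, sim = mini_setup
        from luquant.simulate import recon_projector
        P = recon_projector(phantom, acq)
        corrected = osem(sim.expected["pw"], P,
                         TewEstimate(sim.scatter_truth.pw_scatter, "ideal"),
                         OsemConfig(n_iterations=3))
        uncorrected = osem(sim.expected["pw"], P, None, OsemConfig(n_iterations=3))
        assert uncorrected.total_counts > corrected.total_counts

    def test_tew_agrees_with_ideal_correction_at_zero_curvature(self):
        """High-count Poisson data, linear scatter spectrum: the TEW and the
        ground-truth scatter term must reconstruct the same total counts
        within Poisson tolerance."""
        from luquant import phantoms as ph
        from luquant.scatter import ScatterParams
        from luquant.simulate import recon_projector, simulate_acquisition

        n, nz, nv = 32, 16, 30
        grid = ph.VoxelGrid((n, n, nz), 4.8)
        cfg = ph.StudyConfig(
            "hot", [ph.InsertSpec("sphere", (20.0, 0.0, 0.0), 40.0, 6.0, "A")],
            0.0, 40.0, "cold_water")
        phantom = ph.build_phantom(cfg, grid)
        acq = AcquisitionSpec(n_projections=nv, detector_shape=(n, nz),
                              bin_size=4.8, t_p=40.0, sensitivity=10.0)
        sim = simulate_acquisition(
            phantom, acq, ScatterParams(self_scatter_fraction=0.25,
                                        spectral_curvature=0.0))
        assert sim.expected["pw"].sum() > 1e6
        noisy = sim.realize(99)
        P = recon_projector(phantom, acq)
        img_tew = osem(noisy["pw"], P, tew_estimate(noisy))
        img_ideal = osem(noisy["pw"], P,
                         TewEstimate(sim.scatter_truth.pw_scatter, "ideal"))
        rel = abs(img_tew.total_counts - img_ideal.total_counts) \
            / img_ideal.total_counts
        assert rel <= 0.02

    def test_mismatched_scatter_shape_raises(self, mini_setup):
        phantom, acq, sim = mini_setup
        from luquant.simulate import recon_projector
        P = recon_projector(phantom, acq)
        with pytest.raises(ValueError, match="scatter"):
            osem(sim.expected["pw"], P, np.zeros((1, 2, 3)))
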