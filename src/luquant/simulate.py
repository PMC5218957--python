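"""Acquisition simulation: phantom -> multi-window sinograms.

To avoid the pure inverse crime, phantoms are projected on their own fine
grid (typically half the detector bin pitch) and the fine projections are
rebinned to the detector; scatter is then generated by the projection-
space scatter model, which is structurally different from the TEW model
that later corrects it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phantoms import Phantom
from .projector import (AcquisitionSpec, EnergyWindowSet, MultiWindowSinogram,
                        Projector, SystemModel)
from .scatter import ScatterParams, ScatterTruth, poissonify, simulate_scatter

__all__ = ["SimulatedAcquisition", "simulate_acquisition", "rebin_projections",
           "downsample_volume", "recon_projector", "simulate_planar_point_source"]


def rebin_projections(proj: np.ndarray, factor: int) -> np.ndarray:
    """Sum fine detector bins into factor x factor coarse bins, per view."""
    nv, nt, nz = proj.shape
    if nt % factor or nz % factor:
        raise ValueError("detector dimensions not divisible by rebin factor")
    return proj.reshape(nv, nt // factor, factor, nz // factor, factor).sum(axis=(2, 4))


def downsample_volume(vol: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a fine volume onto a coarser grid."""
    n0, n1, n2 = vol.shape
    if n0 % factor or n1 % factor or n2 % factor:
        raise ValueError("volume dimensions not divisible by factor")
    return vol.reshape(n0 // factor, factor, n1 // factor, factor,
                       n2 // factor, factor).mean(axis=(1, 3, 5))


@dataclass
class SimulatedAcquisition:
    """Expected sinogram plus the simulator's ground truth."""

    expected: MultiWindowSinogram  # expected counts per window
    scatter_truth: ScatterTruth  # S/H ground truth on the detector grid
    primary: np.ndarray  # expected primary PW counts, detector grid
    phantom: Phantom
    acquisition: AcquisitionSpec

    def realize(self, seed) -> MultiWindowSinogram:
        """Poisson realization of the three windows."""
        return poissonify(self.expected, seed)


def simulate_acquisition(phantom: Phantom, acq: AcquisitionSpec,
                         scatter_params: ScatterParams | None = None,
                         windows: EnergyWindowSet | None = None,
                         sigma0: float = 3.0, slope: float = 0.02,
                         ) -> SimulatedAcquisition:
    """Project a phantom into expected three-window sinograms.

    The phantom grid must be an integer multiple (per axis) of the
    detector sampling; projections are formed at the phantom resolution
    and rebinned.
    """
    windows = windows or EnergyWindowSet()
    scatter_params = scatter_params or ScatterParams()
    nt, nz = acq.detector_shape
    n_fine = phantom.grid.shape[0]
    factor = n_fine // nt
    if factor * nt != n_fine or phantom.grid.shape[2] != factor * nz:
        raise ValueError("phantom grid is not an integer refinement of the detector")
    if abs(phantom.grid.voxel_size * factor - acq.bin_size) > 1e-9:
        raise ValueError("phantom voxel size inconsistent with detector bin size")

    fine_acq = replace(acq, detector_shape=(n_fine, phantom.grid.shape[2]),
                       bin_size=phantom.grid.voxel_size,
                       angles_deg=acq.angles_deg.copy(),
                       orbit_radius=acq.orbit_radius.copy())
    model = SystemModel(fine_acq, voxel_size=phantom.grid.voxel_size, mu=phantom.mu,
                        sigma0=sigma0, slope=slope)
    proj = Projector(model, phantom.grid.shape, cache_attenuation=False)
    geometric = proj.forward(phantom.activity)
    primary_fine = acq.sensitivity * acq.t_p * geometric
    primary = rebin_projections(primary_fine, factor) if factor > 1 else primary_fine

    truth = simulate_scatter(primary, scatter_params, windows, acq.bin_size)
    expected = MultiWindowSinogram(
        {"pw": primary + truth.pw_scatter, "lsw": truth.lsw, "usw": truth.usw},
        acq, is_poisson=False,
        meta={"config": phantom.config.name},
    )
    return SimulatedAcquisition(expected=expected, scatter_truth=truth,
                                primary=primary, phantom=phantom, acquisition=acq)


def recon_projector(phantom: Phantom, acq: AcquisitionSpec,
                    sigma0: float = 3.0, slope: float = 0.02,
                    attenuation: bool = True,
                    resolution_recovery: bool = True) -> Projector:
    """System model on the reconstruction grid, mu from the phantom's map.

    The attenuation map is block-averaged from the phantom grid to the
    reconstruction grid (the CT-derived mu map of a real study).
    """
    nt, nz = acq.detector_shape
    factor = phantom.grid.shape[0] // nt
    mu = downsample_volume(phantom.mu, factor) if factor > 1 else phantom.mu
    model = SystemModel(acq, voxel_size=acq.bin_size, mu=mu, sigma0=sigma0,
                        slope=slope, attenuation=attenuation,
                        resolution_recovery=resolution_recovery)
    return Projector(model, (nt, nt, nz))


def simulate_planar_point_source(
        activity_MBq: float, duration_s: float,
        distance_mm: float = 300.0,
        detector_shape: tuple[int, int] = (64, 64),
        bin_size: float = 4.8,
        sensitivity: float = 10.0,
        scatter_params: ScatterParams | None = None,
        windows: EnergyWindowSet | None = None,
        sigma0: float = 3.0, slope: float = 0.02,
        seed=None):
    """Planar scan of a point source in air at a given collimator distance.

    Returns the three-window planar image set (noisy if ``seed`` is given)
    as a single-view :class:`MultiWindowSinogram`.  Point sources for
    camera calibration sit 30 cm from the collimator face so that septal
    effects are negligible while sensitivity is distance-independent.
    """
    # in-air scatter around a point source is weak; the high-energy
    # downscatter fraction is what planar method 2 must remove
    scatter_params = scatter_params or ScatterParams(self_scatter_fraction=0.05)
    nt, nz = detector_shape
    acq = AcquisitionSpec(n_projections=1, detector_shape=detector_shape,
                          bin_size=bin_size, angles_deg=np.array([0.0]),
                          orbit_radius=distance_mm, t_p=duration_s,
                          sensitivity=sensitivity)
    model = SystemModel(acq, voxel_size=bin_size, mu=None, sigma0=sigma0, slope=slope)
    proj = Projector(model, (nt, nt, nz))
    vol = np.zeros((nt, nt, nz))
    c = (nt - 1) // 2
    vol[c, c, nz // 2] = activity_MBq
    primary = sensitivity * duration_s * proj.forward(vol)
    truth = simulate_scatter(primary, scatter_params, windows or EnergyWindowSet(),
                             bin_size)
    expected = MultiWindowSinogram(
        {"pw": primary + truth.pw_scatter, "lsw": truth.lsw, "usw": truth.usw},
        acq, is_poisson=False, meta={"scan": "planar_point_source"})
    if seed is None:
        return expected
    return poissonify(expected, seed)
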