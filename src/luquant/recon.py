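"""TEW scatter estimation and OSEM reconstruction.

The iterative update is the standard ordered-subsets multiplicative EM
step with the scatter estimate added to the forward model in the
denominator (never subtracted from the data, which would break the
Poisson statistics):

    X_j <- X_j / sum_i C_ij * sum_i C_ij * Y_i / ((C X)_i + S_i + H_i)

with the sums running over the views of the current subset.  Reconstructed
voxel values are in total-scan counts: the system matrix distributes an
image across the views uniformly (a 1/n_views factor), which is the
convention under which the tomographic camera-normalization factor
C_rec / (A t_p n_p) lands on the same counts/(MBq s) scale as a planar
sensitivity measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .projector import EnergyWindowSet, MultiWindowSinogram, Projector

__all__ = ["TewEstimate", "OsemConfig", "ReconImage", "tew_estimate",
           "primary_counts", "osem"]


@dataclass
class TewEstimate:
    """Per-bin estimate of photopeak scatter from the flanking windows."""

    C_s: np.ndarray
    method: str  # "tew" | "ideal"
    windows: EnergyWindowSet | None = None


@dataclass
class OsemConfig:
    n_subsets: int = 10
    n_iterations: int = 6
    epsilon_scale: float = 1e-10  # denominator floor, relative to max forward value

    def __post_init__(self):
        if self.n_subsets < 1 or self.n_iterations < 1:
            raise ValueError("subsets and iterations must be >= 1")
        if self.epsilon_scale <= 0:
            raise ValueError("epsilon_scale must be positive")


@dataclass
class ReconImage:
    """OSEM output in total-scan counts per voxel."""

    values: np.ndarray
    voxel_size: float  # mm
    provenance: dict = field(default_factory=dict)

    @property
    def total_counts(self) -> float:
        return float(self.values.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0


def tew_estimate(sino: MultiWindowSinogram,
                 windows: EnergyWindowSet | None = None) -> TewEstimate:
    """Triple-energy-window scatter estimate, per bin, clamped at zero.

    C_s = (C_ls / w_ls + C_us / w_us) * w_pw / 2.  No smoothing is applied
    to any window.
    """
    windows = windows or EnergyWindowSet()
    for name in ("lsw", "usw"):
        if name not in sino.windows:
            raise ValueError(f"sinogram is missing the {name!r} window")
    c = (sino["lsw"] / windows.w_ls + sino["usw"] / windows.w_us) * windows.w_pw / 2.0
    return TewEstimate(C_s=np.maximum(c, 0.0), method="tew", windows=windows)


def primary_counts(sino: MultiWindowSinogram, tew: TewEstimate) -> np.ndarray:
    """Scatter-corrected photopeak counts, floored at zero per bin."""
    pw = sino["pw"]
    if tew.C_s.shape != pw.shape:
        raise ValueError("TEW estimate shape does not match photopeak sinogram")
    return np.maximum(pw - tew.C_s, 0.0)


def _subset_views(n_views: int, n_subsets: int) -> list[np.ndarray]:
    """Angle-interleaved subsets: view i belongs to subset i mod n_subsets."""
    return [np.arange(s, n_views, n_subsets) for s in range(n_subsets)]


def _support_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Voxels inside the inscribed field-of-view cylinder."""
    n = shape[0]
    c = (n - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disk = (ii - c) ** 2 + (jj - c) ** 2 <= (n / 2.0) ** 2
    return np.repeat(disk[:, :, None], shape[2], axis=2)


def osem(pw_counts: np.ndarray, projector: Projector,
         scatter_term: np.ndarray | TewEstimate | None = None,
         cfg: OsemConfig | None = None) -> ReconImage:
    """Ordered-subsets EM reconstruction of a photopeak sinogram.

    Parameters
    ----------
    pw_counts : measured photopeak counts, shape (views, t, z).
    projector : the system model (attenuation + resolution recovery).
    scatter_term : per-bin expected scatter counts added in the forward
        model (a TEW estimate, the simulator's ground truth S+H, or None
        for no scatter correction).
    """
    cfg = cfg or OsemConfig()
    acq = projector.model.acquisition
    nv = acq.n_projections
    if pw_counts.shape[0] != nv:
        raise ValueError("sinogram view count does not match acquisition")
    scatter_method = "none"
    if isinstance(scatter_term, TewEstimate):
        scatter_method = scatter_term.method
        scatter_term = scatter_term.C_s
    if scatter_term is not None and scatter_term.shape != pw_counts.shape:
        raise ValueError("scatter term shape does not match sinogram")

    subsets = _subset_views(nv, cfg.n_subsets)
    support = _support_mask(projector.vol_shape)

    # subset sensitivity images sum_{i in subset} C_ij (with the 1/nv scale)
    sens = []
    for views in subsets:
        ones = np.ones((len(views), projector.n, projector.nz))
        sens.append(projector.back(ones, views) / nv)
    total_sens = np.sum(sens, axis=0)
    support &= total_sens > 1e-12 * total_sens.max()

    x = np.where(support, 1.0, 0.0)
    for _ in range(cfg.n_iterations):
        for views, sens_s in zip(subsets, sens):
            fp = projector.forward(x, views) / nv
            if scatter_term is not None:
                fp = fp + scatter_term[views]
            eps = cfg.epsilon_scale * max(fp.max(), 1.0)
            ratio = pw_counts[views] / np.maximum(fp, eps)
            update = projector.back(ratio, views) / nv
            with np.errstate(invalid="ignore"):
                x = np.where(support, x * update / np.maximum(sens_s, 1e-30), 0.0)
    return ReconImage(
        values=x,
        voxel_size=projector.model.voxel_size,
        provenance={
            "scatter": scatter_method,
            "n_subsets": cfg.n_subsets,
            "n_iterations": cfg.n_iterations,
        },
    )
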