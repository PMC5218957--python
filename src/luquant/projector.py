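"""Analytic parallel-beam SPECT system model.

The projector implements the classic rotation-based factorization of the
SPECT system matrix: for each view the volume is rotated so rays run along
a fixed grid axis, each constant-depth plane is weighted by the cumulative
attenuation to the detector and blurred with a distance-dependent Gaussian
collimator-detector response, and the planes are summed.  The same
operator serves two roles: generating primary-photon projections of a
digital phantom, and acting as the system matrix C inside OSEM (where its
exact adjoint is required).

Rotations are realised as sparse bilinear-interpolation matrices, so the
adjoint is the literal matrix transpose; the Gaussian plane blur uses a
symmetric kernel with zero-padding and is therefore self-adjoint.  The
dot-product (adjointness) test holds to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

__all__ = [
    "EnergyWindowSet",
    "AcquisitionSpec",
    "SystemModel",
    "MultiWindowSinogram",
    "psf_sigma",
    "psf_from_fwhm_points",
    "Projector",
    "save_sinogram",
    "load_sinogram",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class EnergyWindowSet:
    """Triple energy window configuration around the 208 keV photopeak.

    Defaults are the study windows: a lower scatter window (LSW), the
    photopeak window (PW) and an upper scatter window (USW).
    """

    lsw: tuple[float, float] = (153.0, 187.0)
    pw: tuple[float, float] = (187.2, 228.8)
    usw: tuple[float, float] = (229.5, 280.2)
    lsw_center: float = 170.0
    pw_center: float = 208.0
    usw_center: float = 255.0

    def __post_init__(self):
        for name in ("lsw", "pw", "usw"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"window {name} has non-positive width")
        if not (self.lsw[1] <= self.pw[0] and self.pw[1] <= self.usw[0]):
            raise ValueError("windows must be ordered LSW < PW < USW without overlap")

    @property
    def w_ls(self) -> float:
        return self.lsw[1] - self.lsw[0]

    @property
    def w_pw(self) -> float:
        return self.pw[1] - self.pw[0]

    @property
    def w_us(self) -> float:
        return self.usw[1] - self.usw[0]


@dataclass
class AcquisitionSpec:
    """Geometry and timing of a (possibly single-view planar) acquisition.

    ``sensitivity`` is the ideal-detector count rate per unit activity,
    counts/(MBq s); it is the ground-truth camera normalization factor of
    any simulation using this spec.
    """

    n_projections: int = 90
    detector_shape: tuple[int, int] = (128, 128)  # (transaxial, axial) bins
    bin_size: float = 4.8  # mm
    angles_deg: np.ndarray | None = None  # default: uniform over 360
    orbit_radius: float | np.ndarray = 250.0  # mm, scalar or per view
    t_p: float = 20.0  # s per projection
    sensitivity: float = 10.0  # counts / (MBq s)

    def __post_init__(self):
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if self.t_p <= 0:
            raise ValueError("t_p must be positive")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.angles_deg is None:
            self.angles_deg = np.arange(self.n_projections) * 360.0 / self.n_projections
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if len(self.angles_deg) != self.n_projections:
            raise ValueError("angles_deg length must equal n_projections")
        self.orbit_radius = np.broadcast_to(
            np.asarray(self.orbit_radius, dtype=np.float64), (self.n_projections,)
        ).copy()


@dataclass
class SystemModel:
    """Projector configuration: acquisition + mu map + PSF + correction flags."""

    acquisition: AcquisitionSpec
    voxel_size: float  # mm, reconstruction/simulation grid
    mu: np.ndarray | None = None  # cm^-1, same grid as projected volumes
    sigma0: float = 3.0  # mm, PSF sigma at the collimator face
    slope: float = 0.02  # mm sigma per mm distance
    attenuation: bool = True
    resolution_recovery: bool = True

    def __post_init__(self):
        if self.sigma0 < 0 or self.slope < 0:
            raise ValueError("PSF parameters must be >= 0")


def psf_sigma(distance_mm: float | np.ndarray, model: SystemModel) -> np.ndarray:
    """Gaussian PSF sigma [mm] at a source-collimator distance."""
    d = np.asarray(distance_mm, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    return model.sigma0 + model.slope * d


def psf_from_fwhm_points(d1_mm: float, fwhm1_mm: float,
                         d2_mm: float, fwhm2_mm: float) -> tuple[float, float]:
    """Fit (sigma0, slope) from two measured FWHM calibration points."""
    s1, s2 = fwhm1_mm * FWHM_TO_SIGMA, fwhm2_mm * FWHM_TO_SIGMA
    slope = (s2 - s1) / (d2_mm - d1_mm)
    return s1 - slope * d1_mm, slope


@dataclass
class MultiWindowSinogram:
    """Counts (or expected counts) per energy window, projection and bin."""

    windows: dict[str, np.ndarray]  # keys among {"pw", "lsw", "usw"}
    acquisition: AcquisitionSpec
    is_poisson: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        nv = self.acquisition.n_projections
        nt, nz = self.acquisition.detector_shape
        for name, arr in self.windows.items():
            if arr.shape != (nv, nt, nz):
                raise ValueError(
                    f"window {name!r} has shape {arr.shape}, expected {(nv, nt, nz)}"
                )
            if np.any(arr < 0):
                raise ValueError(f"window {name!r} contains negative counts")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.windows[name]

    @property
    def total_counts(self) -> float:
        return float(sum(a.sum() for a in self.windows.values()))


# ---------------------------------------------------------------------------
# sparse rotation operators

_ROT_CACHE: dict[tuple[int, float], sparse.csr_matrix] = {}
_ROT_T_CACHE: dict[tuple[int, float], sparse.csr_matrix] = {}


def _gather_matrix(n: int, angle_deg: float) -> sparse.csr_matrix:
    """Bilinear-interpolation rotation of an (n, n) plane (gather form)."""
    c = (n - 1) / 2.0
    th = math.radians(angle_deg)
    cos, sin = math.cos(th), math.sin(th)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    x = ii.ravel() - c
    y = jj.ravel() - c
    # source coordinates: inverse rotation of target coordinates
    xs = cos * x + sin * y + c
    ys = -sin * x + cos * y + c
    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    fx = xs - x0
    fy = ys - y0
    rows, cols, vals = [], [], []
    target = np.arange(n * n)
    for dx, dy, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        sx, sy = x0 + dx, y0 + dy
        ok = (sx >= 0) & (sx < n) & (sy >= 0) & (sy < n) & (w > 0)
        rows.append(target[ok])
        cols.append(sx[ok] * n + sy[ok])
        vals.append(w[ok])
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    )


def _rotation_matrix(n: int, angle_deg: float) -> sparse.csr_matrix:
    """Mass-preserving rotation: each voxel splats its value bilinearly.

    Built as the transpose of the inverse-angle gather matrix, so every
    in-bounds source voxel distributes exactly unit weight - total counts
    are conserved through the rotation, which is the property projection
    needs.
    """
    key = (n, round(float(angle_deg) % 360.0, 6))
    if key not in _ROT_CACHE:
        _ROT_CACHE[key] = _gather_matrix(n, -angle_deg).T.tocsr()
    return _ROT_CACHE[key]


def _rotation_matrix_T(n: int, angle_deg: float) -> sparse.csr_matrix:
    key = (n, round(float(angle_deg) % 360.0, 6))
    if key not in _ROT_T_CACHE:
        _ROT_T_CACHE[key] = _gather_matrix(n, -angle_deg)
    return _ROT_T_CACHE[key]


class Projector:
    """Attenuated, resolution-modelling forward/back projector.

    Volumes have shape (n, n, nz) with the first two axes in the
    transaxial plane; the detector has n transaxial and nz axial bins of
    the same pitch as the voxels.  ``forward`` returns the *geometric*
    projection (plain sums of attenuated, blurred voxel values); callers
    apply count scaling (sensitivity x duration for simulation, 1/n_views
    for reconstruction) on top.
    """

    def __init__(self, model: SystemModel, vol_shape: tuple[int, int, int],
                 cache_attenuation: bool | None = None):
        n0, n1, nz = vol_shape
        if n0 != n1:
            raise ValueError("transaxial volume dimensions must be equal")
        acq = model.acquisition
        if acq.detector_shape != (n0, nz):
            raise ValueError(
                f"detector shape {acq.detector_shape} does not match volume {vol_shape}"
            )
        if model.mu is not None and model.mu.shape != vol_shape:
            raise ValueError("mu map shape does not match volume shape")
        self.model = model
        self.vol_shape = vol_shape
        self.n = n0
        self.nz = nz
        nv = acq.n_projections
        if cache_attenuation is None:
            cache_attenuation = nv * n0 * n1 * nz * 4 < 400 << 20
        self._cache_att = cache_attenuation
        self._att: dict[int, np.ndarray] = {}
        # per-view, per-plane PSF sigma in pixel units, quantized to 0.1 px so
        # planes sharing a blur width are processed in one linear pass (the
        # blur commutes with summation within a group, keeping the adjoint
        # exact)
        c = (n0 - 1) / 2.0
        depth = (np.arange(n0) - c) * model.voxel_size  # mm toward the detector
        self._sigma_px = np.zeros((nv, n0))
        self._blur_groups: list[list[tuple[float, np.ndarray]]] = []
        if model.resolution_recovery:
            for v in range(nv):
                dist = np.maximum(acq.orbit_radius[v] - depth, 0.0)
                sig = np.round(psf_sigma(dist, model) / model.voxel_size / 0.1) * 0.1
                self._sigma_px[v] = sig
                groups = []
                for s in np.unique(sig):
                    groups.append((float(s), np.flatnonzero(sig == s)))
                self._blur_groups.append(groups)

    # -- internals ----------------------------------------------------------

    def _attenuation(self, view: int) -> np.ndarray | None:
        if self.model.mu is None or not self.model.attenuation:
            return None
        if view in self._att:
            return self._att[view]
        ang = self.model.acquisition.angles_deg[view]
        R = _rotation_matrix(self.n, ang)
        mu_rot = (R @ self.model.mu.reshape(self.n * self.n, self.nz)).reshape(
            self.vol_shape
        )
        dl_cm = self.model.voxel_size / 10.0
        # cumulative mu from each plane to the detector (detector at high index),
        # half-voxel self-attenuation convention
        tail = np.cumsum(mu_rot[::-1], axis=0)[::-1]
        att = np.exp(-dl_cm * (tail - 0.5 * mu_rot)).astype(np.float32)
        if self._cache_att:
            self._att[view] = att
        return att

    def _forward_blur_sum(self, planes: np.ndarray, view: int) -> np.ndarray:
        """Sum of depth planes, each blurred with its distance-dependent sigma."""
        proj = np.zeros((self.n, self.nz))
        for s, idx in self._blur_groups[view]:
            partial = planes[idx].sum(axis=0)
            if s > 0.02:
                partial = gaussian_filter(partial, s, mode="constant", truncate=4.0)
            proj += partial
        return proj

    def _back_blur_stack(self, proj: np.ndarray, view: int) -> np.ndarray:
        """Adjoint of the grouped blur: replicate the blurred projection."""
        out = np.empty(self.vol_shape)
        for s, idx in self._blur_groups[view]:
            if s > 0.02:
                out[idx] = gaussian_filter(proj, s, mode="constant", truncate=4.0)
            else:
                out[idx] = proj
        return out

    # -- public API ---------------------------------------------------------

    def forward_view(self, volume: np.ndarray, view: int) -> np.ndarray:
        if volume.shape != self.vol_shape:
            raise ValueError("volume shape does not match projector grid")
        ang = self.model.acquisition.angles_deg[view]
        R = _rotation_matrix(self.n, ang)
        rot = (R @ volume.reshape(self.n * self.n, self.nz)).reshape(self.vol_shape)
        att = self._attenuation(view)
        if att is not None:
            rot = rot * att
        if self.model.resolution_recovery:
            return self._forward_blur_sum(rot, view)
        return rot.sum(axis=0)

    def back_view(self, proj: np.ndarray, view: int) -> np.ndarray:
        if proj.shape != (self.n, self.nz):
            raise ValueError("projection shape does not match detector")
        if self.model.resolution_recovery:
            stack = self._back_blur_stack(proj, view)
        else:
            stack = np.broadcast_to(proj, self.vol_shape).copy()
        att = self._attenuation(view)
        if att is not None:
            stack = stack * att
        ang = self.model.acquisition.angles_deg[view]
        RT = _rotation_matrix_T(self.n, ang)
        return (RT @ stack.reshape(self.n * self.n, self.nz)).reshape(self.vol_shape)

    def forward(self, volume: np.ndarray, views: np.ndarray | None = None) -> np.ndarray:
        """Geometric projections for all (or selected) views."""
        views = np.arange(self.model.acquisition.n_projections) if views is None else views
        return np.stack([self.forward_view(volume, int(v)) for v in views])

    def back(self, sino: np.ndarray, views: np.ndarray | None = None) -> np.ndarray:
        """Adjoint of :meth:`forward` over the same views."""
        views = np.arange(self.model.acquisition.n_projections) if views is None else views
        if sino.shape[0] != len(views):
            raise ValueError("sinogram view count does not match views")
        vol = np.zeros(self.vol_shape)
        for k, v in enumerate(views):
            vol += self.back_view(sino[k], int(v))
        return vol


# ---------------------------------------------------------------------------
# sinogram container I/O (HDF5)


def save_sinogram(sino: MultiWindowSinogram, path: str) -> None:
    """Write a multi-window sinogram to an HDF5 container.

    Layout: one dataset per window (view, transaxial, axial); acquisition
    metadata as root attributes.
    """
    import h5py

    acq = sino.acquisition
    with h5py.File(path, "w") as fh:
        for name, arr in sino.windows.items():
            fh.create_dataset(name, data=arr)
        fh.attrs["angles_deg"] = acq.angles_deg
        fh.attrs["orbit_radius"] = acq.orbit_radius
        fh.attrs["bin_size"] = acq.bin_size
        fh.attrs["t_p"] = acq.t_p
        fh.attrs["sensitivity"] = acq.sensitivity
        fh.attrs["is_poisson"] = sino.is_poisson


def load_sinogram(path: str) -> MultiWindowSinogram:
    import h5py

    with h5py.File(path, "r") as fh:
        windows = {name: fh[name][()] for name in fh.keys()}
        first = next(iter(windows.values()))
        acq = AcquisitionSpec(
            n_projections=first.shape[0],
            detector_shape=first.shape[1:],
            bin_size=float(fh.attrs["bin_size"]),
            angles_deg=np.asarray(fh.attrs["angles_deg"]),
            orbit_radius=np.asarray(fh.attrs["orbit_radius"]),
            t_p=float(fh.attrs["t_p"]),
            sensitivity=float(fh.attrs["sensitivity"]),
        )
        return MultiWindowSinogram(windows, acq, is_poisson=bool(fh.attrs["is_poisson"]))
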