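"""Projection-space scatter model for the three energy windows.

Scatter is not transported photon-by-photon; it is modelled directly in
projection space, which is sufficient to exercise (and controllably bias)
the triple-energy-window correction:

* self-scatter S: a fraction of the primary photopeak counts, spatially
  broadened by a Gaussian kernel;
* high-energy downscatter H: photons from the 250-321 keV emissions that
  scatter in the crystal into the photopeak window, modelled as a small
  fraction (3% by default) of the primary counts with a twice-broader
  kernel;
* flanking-window counts: each bin carries a scatter spectral density
  across the three windows.  The density is linear in energy across the
  photopeak window and is sampled by the lower/upper scatter windows at
  the photopeak edges (the TEW idealization), so the trapezoidal TEW
  estimate is exactly unbiased when ``spectral_curvature`` is zero.  A
  nonzero curvature bends the density inside the flanking windows and
  gives TEW a controllable, sign- and magnitude-tunable bias.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .projector import FWHM_TO_SIGMA, EnergyWindowSet, MultiWindowSinogram

__all__ = ["ScatterParams", "ScatterTruth", "simulate_scatter", "add_poisson",
           "poissonify", "save_scatter_params", "load_scatter_params",
           "save_scatter_truth", "load_scatter_truth"]


@dataclass(frozen=True)
class ScatterParams:
    """Magnitudes and spectral shape of the scatter model.

    ``self_scatter_fraction`` and ``he_fraction`` are scatter-to-primary
    count ratios inside the photopeak window; ``spectral_slope`` [1/keV]
    and ``spectral_curvature`` [1/keV^2] shape the relative scatter
    spectral density around the 208 keV peak.
    """

    self_scatter_fraction: float = 0.25
    kernel_fwhm: float = 40.0  # mm
    he_fraction: float = 0.03
    spectral_slope: float = -0.002
    spectral_curvature: float = 2e-5

    def __post_init__(self):
        if self.self_scatter_fraction < 0 or self.he_fraction < 0:
            raise ValueError("scatter fractions must be >= 0")
        if self.kernel_fwhm <= 0:
            raise ValueError("kernel_fwhm must be positive")


@dataclass
class ScatterTruth:
    """Ground-truth expected scatter sinograms (the simulator's S and H)."""

    S: np.ndarray  # self-scatter expected counts in the PW
    H: np.ndarray  # high-energy downscatter expected counts in the PW
    lsw: np.ndarray  # expected counts in the lower scatter window
    usw: np.ndarray  # expected counts in the upper scatter window
    params: ScatterParams
    windows: EnergyWindowSet

    @property
    def pw_scatter(self) -> np.ndarray:
        return self.S + self.H

    def density_samples(self) -> tuple[np.ndarray, np.ndarray]:
        """Spectral densities [counts/keV] at the photopeak edges, per bin."""
        w = self.windows
        T = self.pw_scatter / w.w_pw
        s = self.params.spectral_slope
        d_lo = T * (1.0 + s * (w.pw[0] - w.pw_center))
        d_hi = T * (1.0 + s * (w.pw[1] - w.pw_center))
        return d_lo, d_hi

    def window_integrals(self) -> dict[str, np.ndarray]:
        """Integrals of the model spectral density over each window.

        The density is piecewise: constant over each flanking window at
        that window's sampled density, linear across the photopeak between
        the edge densities.  These integrals are the expected window
        counts; the test suite checks they match the generated sinograms.
        """
        w = self.windows
        d_lo, d_hi = self.density_samples()
        c = self.params.spectral_curvature
        T = self.pw_scatter / w.w_pw
        lsw = w.w_ls * (d_lo + T * c * (w.lsw_center - w.pw_center) ** 2)
        usw = w.w_us * (d_hi + T * c * (w.usw_center - w.pw_center) ** 2)
        pw = w.w_pw * 0.5 * (d_lo + d_hi)
        return {"lsw": lsw, "pw": pw, "usw": usw}


def _broaden(primary: np.ndarray, fwhm_mm: float, bin_size_mm: float) -> np.ndarray:
    """Per-view Gaussian broadening; periodic padding keeps totals exact."""
    sigma_px = fwhm_mm * FWHM_TO_SIGMA / bin_size_mm
    return gaussian_filter(primary, (0.0, sigma_px, sigma_px), mode="wrap")


def simulate_scatter(primary: np.ndarray, params: ScatterParams,
                     windows: EnergyWindowSet, bin_size_mm: float) -> ScatterTruth:
    """Expected scatter sinograms for a primary photopeak sinogram.

    ``primary`` must be expected (pre-noise) counts, shape (views, t, z).
    """
    if np.any(primary < 0):
        raise ValueError("primary sinogram must be nonnegative expected counts")
    if abs(params.spectral_slope) * windows.w_pw / 2.0 >= 1.0:
        raise ValueError("spectral_slope too steep: negative density at PW edge")
    S = params.self_scatter_fraction * _broaden(primary, params.kernel_fwhm, bin_size_mm)
    H = params.he_fraction * _broaden(primary, 2.0 * params.kernel_fwhm, bin_size_mm)
    truth = ScatterTruth(S=S, H=H, lsw=np.empty(0), usw=np.empty(0),
                         params=params, windows=windows)
    integrals = truth.window_integrals()
    truth.lsw = integrals["lsw"]
    truth.usw = integrals["usw"]
    return truth


def add_poisson(expected: np.ndarray, seed) -> np.ndarray:
    """Independent Poisson draw per bin; reproducible for a fixed seed."""
    expected = np.asarray(expected)
    if np.any(expected < 0):
        raise ValueError("expected counts must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(expected).astype(np.float64)


def poissonify(sino: MultiWindowSinogram, seed) -> MultiWindowSinogram:
    """Poisson realization of every energy window of an expected sinogram."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = {name: add_poisson(arr, rng) for name, arr in sorted(sino.windows.items())}
    return MultiWindowSinogram(noisy, sino.acquisition, is_poisson=True,
                               meta=dict(sino.meta))


# ---------------------------------------------------------------------------
# persistence: parameters as YAML, ground-truth sinograms as HDF5 (used by
# the "ideal scatter correction" mode)


def save_scatter_params(params: ScatterParams, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=False)


def load_scatter_params(path: str) -> ScatterParams:
    with open(path) as fh:
        return ScatterParams(**yaml.safe_load(fh))


def save_scatter_truth(truth: ScatterTruth, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for name in ("S", "H", "lsw", "usw"):
            fh.create_dataset(name, data=getattr(truth, name))
        for key, value in asdict(truth.params).items():
            fh.attrs[key] = value


def load_scatter_truth(path: str,
                       windows: EnergyWindowSet | None = None) -> ScatterTruth:
    import h5py

    with h5py.File(path, "r") as fh:
        arrays = {name: fh[name][()] for name in ("S", "H", "lsw", "usw")}
        params = ScatterParams(**{k: float(v) for k, v in fh.attrs.items()})
    return ScatterTruth(**arrays, params=params,
                        windows=windows or EnergyWindowSet())
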