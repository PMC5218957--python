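"""Volume-of-interest segmentation of reconstructed activity images.

Three methods mirror routine quantitative practice:

* fixed fractional threshold relative to a hot-voxel reference (0.1% for
  scans in air, 1% in cold water - both chosen to sweep up counts spilled
  outside the object - and 40% as the common clinical choice in warm
  background);
* CT-based: the object's known physical geometry resampled to the
  reconstruction grid;
* iterative adaptive dual thresholding (IADT): two SBR-dependent
  threshold-fraction curves, one tuned to recover the object volume and
  one its activity, applied iteratively so the thresholds adapt to the
  signal-to-background ratio measured in the image itself.

The hot-voxel reference is the mean of the 9 highest-valued voxels inside
the enclosing VOI.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

__all__ = ["SegResult", "CalibrationCurves", "CalibrationScanInsert",
           "reference_value", "fixed_threshold_segment", "ct_based_segment",
           "build_iadt_curves", "iadt_segment", "save_curves", "load_curves"]


@dataclass
class SegResult:
    mask: np.ndarray
    volume_ml: float
    activity_MBq: float
    method: str
    sbr_estimate: float | None = None
    converged: bool = True
    empty: bool = False


def reference_value(image: np.ndarray, voi: np.ndarray) -> float:
    """Mean of the 9 highest-valued voxels inside the VOI."""
    vals = image[voi]
    if vals.size < 9:
        raise ValueError(f"VOI holds only {vals.size} voxels; need at least 9")
    return float(np.partition(vals, -9)[-9:].mean())


def _threshold_mask(image: np.ndarray, voi: np.ndarray, fraction: float,
                    ref: float) -> np.ndarray:
    return voi & (image >= fraction * ref)


def fixed_threshold_segment(image: np.ndarray, voi: np.ndarray, fraction: float,
                            voxel_volume_ml: float) -> SegResult:
    """Keep VOI voxels at or above ``fraction`` of the hot-voxel reference."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    ref = reference_value(image, voi)
    mask = _threshold_mask(image, voi, fraction, ref)
    empty = not mask.any()
    return SegResult(mask=mask,
                     volume_ml=float(mask.sum()) * voxel_volume_ml,
                     activity_MBq=float(image[mask].sum()),
                     method=f"fixed_{fraction:g}", empty=empty)


def ct_based_segment(image: np.ndarray, true_mask: np.ndarray,
                     voxel_volume_ml: float,
                     physical_volume_ml: float | None = None) -> SegResult:
    """Sum activity over the object's physical geometry.

    ``true_mask`` is the phantom insert resampled to the reconstruction
    grid; the reported volume is the physical one (as read off a CT).
    """
    if not true_mask.any():
        raise ValueError("physical mask is empty after resampling")
    vol = (physical_volume_ml if physical_volume_ml is not None
           else float(true_mask.sum()) * voxel_volume_ml)
    return SegResult(mask=true_mask, volume_ml=vol,
                     activity_MBq=float(image[true_mask].sum()), method="ct")


# ---------------------------------------------------------------------------
# IADT calibration curves


def _interp_1_over_sbr(sbr: float, sbr_knots: np.ndarray,
                       fractions: np.ndarray) -> float:
    """Piecewise-linear interpolation of a threshold fraction in 1/SBR.

    Adaptive-threshold fractions are empirically linear in the reciprocal
    signal-to-background ratio (f ~ a + b/SBR), so segments are linear in
    u = 1/SBR and queries beyond the calibrated range continue the end
    segment's slope instead of clamping; the returned fraction is bounded
    away from 0 and 1.
    """
    u = 1.0 / max(float(sbr), 1e-9)
    uk = 1.0 / sbr_knots[::-1]  # ascending in u
    fk = fractions[::-1]
    if u <= uk[0]:
        f = fk[0] + (fk[1] - fk[0]) / (uk[1] - uk[0]) * (u - uk[0])
    elif u >= uk[-1]:
        f = fk[-1] + (fk[-1] - fk[-2]) / (uk[-1] - uk[-2]) * (u - uk[-1])
    else:
        f = float(np.interp(u, uk, fk))
    return float(np.clip(f, 0.02, 0.95))


@dataclass
class CalibrationCurves:
    """Threshold-fraction-vs-SBR curves for volume and activity recovery.

    The knots sit at the SBR *as measured in the calibration images by the
    same estimator the segmentation later applies* (hot-voxel reference
    over background-shell mean), so the estimator's noise bias cancels
    between calibration and application.  Between knots the fractions are
    interpolated linearly in 1/SBR; beyond the calibrated range the end
    segment extrapolates (the fractions approach a finite intercept as
    SBR grows, rather than clamping at the last knot).
    """

    sbr: np.ndarray  # ascending knots (measured SBR)
    volume_fraction: np.ndarray
    activity_fraction: np.ndarray
    recon_tag: str = ""
    nominal_sbr: np.ndarray | None = None
    per_insert: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sbr = np.asarray(self.sbr, dtype=np.float64)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=np.float64)
        self.activity_fraction = np.asarray(self.activity_fraction, dtype=np.float64)
        if not np.all(np.diff(self.sbr) > 0):
            raise ValueError("SBR knots must be strictly increasing")
        for arr in (self.volume_fraction, self.activity_fraction):
            if np.any((arr <= 0) | (arr >= 1)):
                raise ValueError("threshold fractions must lie in (0, 1)")

    def query(self, sbr: float) -> tuple[float, float]:
        """(activity fraction, volume fraction) at an SBR."""
        fa = _interp_1_over_sbr(sbr, self.sbr, self.activity_fraction)
        fv = _interp_1_over_sbr(sbr, self.sbr, self.volume_fraction)
        return fa, fv


@dataclass
class CalibrationScanInsert:
    """One insert of an IADT calibration scan, with its ground truth."""

    image: np.ndarray  # reconstructed activity image [MBq/voxel]
    voi: np.ndarray
    true_volume_ml: float
    true_activity_MBq: float
    sbr: float
    voxel_volume_ml: float
    label: str = ""


def _bisect_fraction(measure, target: float, n_iter: int = 40) -> float | None:
    """Largest fraction whose measured quantity still reaches ``target``.

    ``measure(f)`` must be monotone non-increasing in f.  Returns None if
    no fraction in (0, 1) brackets the target.
    """
    lo, hi = 1e-3, 0.999
    if measure(lo) < target:  # even the loosest threshold cannot reach truth
        return None
    if measure(hi) >= target:  # degenerate profile: keep the tightest cut
        return hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if measure(mid) >= target:
            lo = mid
        else:
            hi = mid
    return lo


def _measure_sbr(image: np.ndarray, voi: np.ndarray, mask: np.ndarray,
                 ref: float) -> float:
    """Hot-voxel reference over the mean of VOI voxels clear of the mask.

    The background shell excludes the mask dilated by one voxel; this is
    the single SBR estimator used both when building the calibration
    curves and when applying them.
    """
    shell = voi & ~binary_dilation(mask)
    bg_vals = image[shell]
    bg_mean = bg_vals.mean() if bg_vals.size else 0.0
    return ref / bg_mean if bg_mean > 0 else np.inf


def build_iadt_curves(scans: list[CalibrationScanInsert],
                      recon_tag: str = "") -> CalibrationCurves:
    """Fit the two threshold curves from calibration reconstructions.

    For every calibration insert the threshold fraction reproducing its
    true volume and the fraction reproducing its true activity are found
    by bisection, and the scan's SBR is re-measured from the image with
    the estimator the segmentation itself uses; fractions and measured
    SBRs are averaged per calibration level to form the curve knots.
    Inserts whose profile cannot reach the truth at any threshold are
    excluded with a warning.
    """
    by_sbr: dict[float, list[tuple[float, float, float]]] = {}
    per_insert: dict[str, tuple[float, float, float, float]] = {}
    for scan in scans:
        ref = reference_value(scan.image, scan.voi)
        if ref <= 0:
            warnings.warn(f"insert {scan.label!r}: non-positive reference, excluded")
            continue

        def vol_of(f):
            return _threshold_mask(scan.image, scan.voi, f, ref).sum() \
                * scan.voxel_volume_ml

        def act_of(f):
            return scan.image[_threshold_mask(scan.image, scan.voi, f, ref)].sum()

        fv = _bisect_fraction(vol_of, scan.true_volume_ml)
        fa = _bisect_fraction(act_of, scan.true_activity_MBq)
        if fv is None or fa is None:
            warnings.warn(
                f"insert {scan.label!r} at SBR {scan.sbr:g}: no threshold "
                "reproduces the truth; excluded from the curves")
            continue
        mask_v = _threshold_mask(scan.image, scan.voi, fv, ref)
        measured = _measure_sbr(scan.image, scan.voi, mask_v, ref)
        if not np.isfinite(measured):
            warnings.warn(f"insert {scan.label!r}: background-free calibration "
                          "scan cannot anchor an SBR knot; excluded")
            continue
        by_sbr.setdefault(scan.sbr, []).append((measured, fa, fv))
        per_insert[f"{scan.label}@{scan.sbr:g}"] = (scan.sbr, measured, fa, fv)

    if len(by_sbr) < 2:
        raise ValueError("need calibration scans at >= 2 distinct SBR levels")
    nominal = np.array(sorted(by_sbr))
    triples = [np.mean(by_sbr[s], axis=0) for s in nominal]
    measured_sbr = np.array([t[0] for t in triples])
    act_frac = np.array([t[1] for t in triples])
    vol_frac = np.array([t[2] for t in triples])
    order = np.argsort(measured_sbr)
    return CalibrationCurves(sbr=measured_sbr[order],
                             volume_fraction=vol_frac[order],
                             activity_fraction=act_frac[order],
                             recon_tag=recon_tag, nominal_sbr=nominal[order],
                             per_insert=per_insert)


def iadt_segment(image: np.ndarray, voi: np.ndarray, curves: CalibrationCurves,
                 voxel_volume_ml: float, max_iter: int = 20,
                 tol: float = 1e-3) -> SegResult:
    """Iterative adaptive dual-threshold segmentation.

    Starting from a 40% fixed-threshold mask, each pass measures the SBR
    (hot-voxel reference over the mean of VOI background voxels one voxel
    clear of the current mask - the same estimator the calibration curves
    are indexed by), looks up the two threshold fractions at that SBR and
    re-segments; iteration stops when both fractions move by less than
    ``tol``.  The reported volume comes from the volume-threshold mask,
    the activity from the activity-threshold mask.
    """
    ref = reference_value(image, voi)
    mask_vol = _threshold_mask(image, voi, 0.40, ref)
    f_act = f_vol = 0.40
    converged = False
    sbr = np.inf
    for _ in range(max_iter):
        sbr = _measure_sbr(image, voi, mask_vol, ref)
        new_fa, new_fv = curves.query(sbr)
        moved = max(abs(new_fa - f_act), abs(new_fv - f_vol))
        f_act, f_vol = new_fa, new_fv
        mask_vol = _threshold_mask(image, voi, f_vol, ref)
        if moved < tol:
            converged = True
            break
    mask_act = _threshold_mask(image, voi, f_act, ref)
    empty = not (mask_act.any() and mask_vol.any())
    return SegResult(mask=mask_vol,
                     volume_ml=float(mask_vol.sum()) * voxel_volume_ml,
                     activity_MBq=float(image[mask_act].sum()),
                     method="iadt", sbr_estimate=float(sbr) if np.isfinite(sbr) else None,
                     converged=converged, empty=empty)


def save_curves(curves: CalibrationCurves, path: str) -> None:
    payload = {
        "sbr": curves.sbr.tolist(),
        "volume_fraction": curves.volume_fraction.tolist(),
        "activity_fraction": curves.activity_fraction.tolist(),
        "recon_tag": curves.recon_tag,
        "nominal_sbr": (curves.nominal_sbr.tolist()
                        if curves.nominal_sbr is not None else None),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_curves(path: str) -> CalibrationCurves:
    with open(path) as fh:
        raw = json.load(fh)
    nominal = raw.get("nominal_sbr")
    return CalibrationCurves(sbr=np.array(raw["sbr"]),
                             volume_fraction=np.array(raw["volume_fraction"]),
                             activity_fraction=np.array(raw["activity_fraction"]),
                             recon_tag=raw.get("recon_tag", ""),
                             nominal_sbr=np.array(nominal) if nominal else None)
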