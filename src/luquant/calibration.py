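"""Camera normalization factor (CNF) determination and counts-to-activity.

The CNF converts image counts into absolute activity (counts per MBq per
second).  Three estimators are implemented:

* planar method 1 - all photopeak counts of a planar point-source scan
  divided by activity x duration (biased upward by scatter);
* planar method 2 - the same after TEW scatter subtraction on the window
  totals (the study's reference method);
* tomographic - total counts of a reconstructed phantom scan divided by
  activity x total acquisition time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from .projector import EnergyWindowSet
from .recon import ReconImage

__all__ = [
    "PlanarScanRecord",
    "TomoScanRecord",
    "CnfResult",
    "cnf_planar_method1",
    "cnf_planar_method2",
    "cnf_tomographic",
    "activity_from_image",
    "save_cnf",
    "load_cnf",
]


@dataclass(frozen=True)
class PlanarScanRecord:
    """Window totals of a planar point-source scan."""

    C_pw: float
    C_ls: float
    C_us: float
    A: float  # MBq at scan time (decay-corrected by the caller)
    t_d: float  # s

    def __post_init__(self):
        if min(self.C_pw, self.C_ls, self.C_us) < 0:
            raise ValueError("window counts must be >= 0")
        if self.A <= 0 or self.t_d <= 0:
            raise ValueError("activity and scan duration must be positive")


@dataclass(frozen=True)
class TomoScanRecord:
    """Total reconstructed counts of a tomographic calibration scan."""

    C_rec: float
    A: float  # MBq in the whole phantom
    n_p: int
    t_p: float  # s per projection

    def __post_init__(self):
        if min(self.C_rec, self.A, self.n_p, self.t_p) <= 0:
            raise ValueError("all tomographic record fields must be positive")


@dataclass(frozen=True)
class CnfResult:
    value: float  # counts / (MBq s)
    method: str  # planar1 | planar2 | tomo
    provenance: dict | None = None

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("CNF must be positive")


def cnf_planar_method1(rec: PlanarScanRecord) -> CnfResult:
    """CNF from all photopeak counts: C_pw / (A t_d)."""
    return CnfResult(rec.C_pw / (rec.A * rec.t_d), "planar1")


def cnf_planar_method2(rec: PlanarScanRecord,
                       windows: EnergyWindowSet | None = None) -> CnfResult:
    """CNF from TEW scatter-corrected photopeak counts.

    The TEW estimate is applied to the *window totals*; the scan is
    rejected if the estimated scatter swamps the photopeak.
    """
    w = windows or EnergyWindowSet()
    c_s = (rec.C_ls / w.w_ls + rec.C_us / w.w_us) * w.w_pw / 2.0
    if c_s >= rec.C_pw:
        raise ValueError("estimated scatter >= photopeak counts: scan unusable")
    return CnfResult((rec.C_pw - c_s) / (rec.A * rec.t_d), "planar2",
                     provenance={"C_s": c_s})


def cnf_tomographic(rec: TomoScanRecord) -> CnfResult:
    """CNF from a reconstructed tomographic scan: C_rec / (A t_p n_p)."""
    return CnfResult(rec.C_rec / (rec.A * rec.t_p * rec.n_p), "tomo")


def activity_from_image(img: ReconImage, cnf: CnfResult,
                        total_time_s: float):
    """Convert a counts image to an activity volume [MBq per voxel]."""
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    return img.values / (cnf.value * total_time_s)


def save_cnf(cnf: CnfResult, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(cnf), fh, indent=2)


def load_cnf(path: str) -> CnfResult:
    with open(path) as fh:
        return CnfResult(**json.load(fh))
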