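"""Voxelized digital phantoms for quantitative Lu-177 SPECT studies.

A phantom couples three co-registered volumes on one grid: an activity map
(MBq per voxel), a material label map, and a linear-attenuation map at
208 keV (cm^-1, standing in for a CT-derived mu map).  Preset
configurations emulate the classic bench phantoms used to audit SPECT
activity quantification: a Jaszczak cylinder holding hot spheres or
bottles in air, non-radioactive ("cold") water or radioactive ("warm")
water background; an elliptical thorax body with lung and bone inserts;
and large bottles resting on the camera bed with optional water bags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "VoxelGrid",
    "InsertSpec",
    "StudyConfig",
    "Phantom",
    "RasterizedInsert",
    "mu_for_material",
    "rasterize_insert",
    "build_phantom",
    "preset",
    "PRESET_NAMES",
    "iadt_calibration_config",
    "cnf_tomo_config",
    "save_phantom_nifti",
    "save_config_yaml",
    "load_config_yaml",
]

# Linear attenuation coefficients at 208 keV [cm^-1], frozen from standard
# mass-attenuation tables (mu/rho ~ 0.136 cm^2/g for water at 208 keV).
# Air is treated as vacuum: its true mu (~1.5e-4 cm^-1) is negligible over
# phantom path lengths.
MU_208KEV: dict[str, float] = {
    "air": 0.0,
    "water": 0.136,
    "lung": 0.041,   # inflated-lung density ~0.30 g/ml
    "bone": 0.250,   # cortical-bone-like insert
    "bed": 0.030,    # carbon-fibre pallet
}

MATERIAL_CODES = {"air": 0, "water": 1, "lung": 2, "bone": 3, "bed": 4}


def mu_for_material(material: str, energy_keV: float = 208.0) -> float:
    """Linear attenuation coefficient [cm^-1] for a supported material.

    Only the 208 keV photopeak energy is tabulated; other energies raise.
    """
    if energy_keV != 208.0:
        raise ValueError(f"only 208 keV is tabulated, got {energy_keV}")
    try:
        return MU_208KEV[material]
    except KeyError:
        raise ValueError(
            f"unknown material {material!r}; supported: {sorted(MU_208KEV)}"
        ) from None


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic-in-plane voxel grid with its physical origin at the center."""

    shape: tuple[int, int, int]
    voxel_size: float  # mm, isotropic

    def __post_init__(self):
        if any(int(n) < 1 for n in self.shape):
            raise ValueError("all grid dimensions must be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates [mm] of voxel centers along one axis."""
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size


@dataclass(frozen=True)
class InsertSpec:
    """A hot insert: sphere or upright cylinder (bottle) of known volume.

    Cylinders have height = ``aspect`` x diameter and their axis along z.
    """

    kind: str  # "sphere" | "cylinder"
    center: tuple[float, float, float]  # mm
    volume_ml: float
    concentration: float  # MBq/ml
    label: str
    aspect: float = 1.5

    def __post_init__(self):
        if self.kind not in ("sphere", "cylinder"):
            raise ValueError(f"unknown insert kind {self.kind!r}")
        if self.volume_ml < 0:
            raise ValueError("volume must be >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def radius_mm(self) -> float:
        v = self.volume_ml * 1000.0  # mm^3
        if self.kind == "sphere":
            return (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
        # cylinder: V = pi r^2 h, h = 2 * aspect * r
        return (v / (2.0 * math.pi * self.aspect)) ** (1.0 / 3.0)

    @property
    def height_mm(self) -> float:
        if self.kind == "sphere":
            return 2.0 * self.radius_mm
        return 2.0 * self.aspect * self.radius_mm

    @property
    def nominal_activity_MBq(self) -> float:
        return self.volume_ml * self.concentration


@dataclass
class StudyConfig:
    """One phantom configuration of the quantification study."""

    name: str
    inserts: list[InsertSpec]
    background_concentration: float  # MBq/ml in the container medium
    projection_duration: float  # s per projection
    medium: str  # air | cold_water | warm_water | thorax | bed | bed_bags
    container: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.medium in ("air", "cold_water", "thorax", "bed", "bed_bags"):
            if self.background_concentration != 0:
                raise ValueError(
                    f"{self.medium} configuration must have zero background"
                )
        if self.background_concentration < 0:
            raise ValueError("background concentration must be >= 0")

    @property
    def sbr(self) -> float:
        """Signal-to-background ratio of the first insert (inf if cold/air)."""
        if self.background_concentration == 0:
            return math.inf
        return self.inserts[0].concentration / self.background_concentration


@dataclass
class RasterizedInsert:
    mask: np.ndarray  # bool, frac > 0.5
    frac: np.ndarray  # fractional fill in [0, 1]
    volume_ml: float  # frac.sum() * voxel volume
    label: str


@dataclass
class Phantom:
    """Co-registered activity / material / attenuation volumes."""

    grid: VoxelGrid
    activity: np.ndarray  # MBq per voxel
    material: np.ndarray  # uint8 codes, see MATERIAL_CODES
    mu: np.ndarray  # cm^-1 at 208 keV
    insert_fracs: dict[str, np.ndarray]
    background_mask: np.ndarray
    config: StudyConfig

    @property
    def insert_masks(self) -> dict[str, np.ndarray]:
        return {k: v > 0.5 for k, v in self.insert_fracs.items()}

    def insert_true_activity(self, label: str) -> float:
        """Activity actually present in the voxelized insert [MBq]."""
        spec = next(s for s in self.config.inserts if s.label == label)
        return float(
            (self.insert_fracs[label] * self.grid.voxel_volume_ml).sum()
            * spec.concentration
        )

    @property
    def total_activity_MBq(self) -> float:
        return float(self.activity.sum())


def _insert_fraction(grid: VoxelGrid, insert: InsertSpec, supersample: int) -> np.ndarray:
    """Fractional fill of each voxel by the insert, via supersampling."""
    if supersample < 3:
        raise ValueError("supersample must be >= 3")
    r = insert.radius_mm
    if r == 0.0:
        return np.zeros(grid.shape, dtype=np.float64)
    half = insert.height_mm / 2.0
    h = grid.voxel_size
    cx, cy, cz = insert.center

    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    # bounding box, padded one voxel
    pad = h
    ext = (r, r, half)
    lo, hi = [], []
    for ax, (c, coords, e) in enumerate(zip((cx, cy, cz), (xs, ys, zs), ext)):
        if c - e < coords[0] - h / 2 or c + e > coords[-1] + h / 2:
            raise ValueError(
                f"insert {insert.label!r} extends beyond the grid along axis {ax}"
            )
        lo.append(int(np.searchsorted(coords, c - e - pad)))
        hi.append(int(np.searchsorted(coords, c + e + pad)) + 1)

    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5  # sub-voxel offsets in voxel units
    sub = off * h
    bx = xs[lo[0]:hi[0]][:, None] + sub[None, :]
    by = ys[lo[1]:hi[1]][:, None] + sub[None, :]
    bz = zs[lo[2]:hi[2]][:, None] + sub[None, :]

    dx2 = ((bx - cx) ** 2)[:, None, None, :, None, None]
    dy2 = ((by - cy) ** 2)[None, :, None, None, :, None]
    if insert.kind == "sphere":
        dz2 = ((bz - cz) ** 2)[None, None, :, None, None, :]
        inside = (dx2 + dy2 + dz2) <= r * r
    else:
        inz = (np.abs(bz - cz) <= half)[None, None, :, None, None, :]
        inside = ((dx2 + dy2) <= r * r) & inz
    frac_box = inside.mean(axis=(3, 4, 5))

    frac = np.zeros(grid.shape, dtype=np.float64)
    frac[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = frac_box
    return frac


def rasterize_insert(
    grid: VoxelGrid, insert: InsertSpec, supersample: int = 4
) -> RasterizedInsert:
    """Voxelize an insert with fractionally filled boundary voxels.

    Boundary voxels are filled by ``supersample``^3 sub-voxel sampling, so
    the voxelized volume matches the analytic insert volume to well under
    1% for inserts spanning a few voxels or more.
    """
    # finer sampling for inserts only a few voxels across
    if insert.volume_ml > 0 and insert.radius_mm < 4 * grid.voxel_size:
        supersample = max(supersample, 7)
    frac = _insert_fraction(grid, insert, supersample)
    vol = float(frac.sum() * grid.voxel_volume_ml)
    return RasterizedInsert(mask=frac > 0.5, frac=frac, volume_ml=vol, label=insert.label)


# ---------------------------------------------------------------------------
# container geometries


def _cylinder_mask(grid: VoxelGrid, diameter: float, height: float,
                   center=(0.0, 0.0, 0.0)) -> np.ndarray:
    xs = grid.axis_coords(0)[:, None, None] - center[0]
    ys = grid.axis_coords(1)[None, :, None] - center[1]
    zs = grid.axis_coords(2)[None, None, :] - center[2]
    r = diameter / 2.0
    return (xs**2 + ys**2 <= r * r) & (np.abs(zs) <= height / 2.0)


def _ellipsoid_mask(grid: VoxelGrid, semiaxes, center) -> np.ndarray:
    xs = (grid.axis_coords(0)[:, None, None] - center[0]) / semiaxes[0]
    ys = (grid.axis_coords(1)[None, :, None] - center[1]) / semiaxes[1]
    zs = (grid.axis_coords(2)[None, None, :] - center[2]) / semiaxes[2]
    return xs**2 + ys**2 + zs**2 <= 1.0


def _elliptic_cylinder_mask(grid: VoxelGrid, semiaxes_xy, height, center=(0, 0, 0)):
    xs = (grid.axis_coords(0)[:, None, None] - center[0]) / semiaxes_xy[0]
    ys = (grid.axis_coords(1)[None, :, None] - center[1]) / semiaxes_xy[1]
    zs = grid.axis_coords(2)[None, None, :] - center[2]
    return (xs**2 + ys**2 <= 1.0) & (np.abs(zs) <= height / 2.0)


def _slab_mask(grid: VoxelGrid, xlim, ylim, zlim) -> np.ndarray:
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    return ((xs >= xlim[0]) & (xs <= xlim[1])
            & (ys >= ylim[0]) & (ys <= ylim[1])
            & (zs >= zlim[0]) & (zs <= zlim[1]))


JASZCZAK_DIAMETER = 222.0  # mm
JASZCZAK_HEIGHT = 195.0  # mm


def build_phantom(config: StudyConfig, grid: VoxelGrid) -> Phantom:
    """Rasterize a study configuration onto a voxel grid.

    The activity map receives concentration x voxel volume inside inserts
    (fractional at boundaries) and background concentration x voxel volume
    in the medium; mu is assigned per material.  Overlapping inserts are an
    error.
    """
    vox_ml = grid.voxel_volume_ml
    material = np.zeros(grid.shape, dtype=np.uint8)
    activity = np.zeros(grid.shape, dtype=np.float64)

    medium = config.medium
    if medium in ("air", "cold_water", "warm_water"):
        body = _cylinder_mask(grid, JASZCZAK_DIAMETER, JASZCZAK_HEIGHT)
        if medium != "air":
            material[body] = MATERIAL_CODES["water"]
        bg_region = body
    elif medium == "thorax":
        body = _elliptic_cylinder_mask(grid, (140.0, 95.0), JASZCZAK_HEIGHT)
        material[body] = MATERIAL_CODES["water"]
        for sx in (-60.0, 60.0):
            lung = _ellipsoid_mask(grid, (40.0, 55.0, 60.0), (sx, -15.0, 25.0)) & body
            material[lung] = MATERIAL_CODES["lung"]
        spine = _cylinder_mask(grid, 30.0, JASZCZAK_HEIGHT, (0.0, 60.0, 0.0)) & body
        material[spine] = MATERIAL_CODES["bone"]
        beef = _cylinder_mask(grid, 20.0, 120.0, (45.0, -60.0, 0.0)) & body
        material[beef] = MATERIAL_CODES["bone"]
        bg_region = body & (material == MATERIAL_CODES["water"])
    elif medium in ("bed", "bed_bags"):
        bed = _slab_mask(grid, (-140.0, 140.0), (48.0, 75.0), (-120.0, 120.0))
        material[bed] = MATERIAL_CODES["bed"]
        if medium == "bed_bags":
            for ylim in ((-80.0, -45.0), (16.0, 46.0)):
                bag = _slab_mask(grid, (-135.0, 135.0), ylim, (-90.0, 90.0))
                material[bag] = MATERIAL_CODES["water"]
        bg_region = np.zeros(grid.shape, dtype=bool)
    else:
        raise ValueError(f"unknown medium {medium!r}")

    frac_total = np.zeros(grid.shape, dtype=np.float64)
    insert_fracs: dict[str, np.ndarray] = {}
    for spec in config.inserts:
        rast = rasterize_insert(grid, spec)
        insert_fracs[spec.label] = rast.frac
        frac_total += rast.frac
        activity += spec.concentration * rast.frac * vox_ml
        material[rast.mask] = MATERIAL_CODES["water"]
    if np.any(frac_total > 1.0 + 1e-6):
        raise ValueError(f"overlapping inserts in configuration {config.name!r}")

    background_mask = bg_region & (frac_total == 0.0)
    if config.background_concentration > 0:
        bg_fill = np.clip(bg_region.astype(np.float64) - frac_total, 0.0, 1.0)
        activity += config.background_concentration * bg_fill * vox_ml

    mu = np.zeros(grid.shape, dtype=np.float64)
    for name, code in MATERIAL_CODES.items():
        mu[material == code] = MU_208KEV[name]

    return Phantom(
        grid=grid,
        activity=activity,
        material=material,
        mu=mu,
        insert_fracs=insert_fracs,
        background_mask=background_mask,
        config=config,
    )


# ---------------------------------------------------------------------------
# presets reproducing the eight study configurations

_SPHERE_CONC = 3.19  # MBq/ml
_BOTTLE_CONC = 5.11  # MBq/ml
_SPHERE_BG = 0.49  # MBq/ml, spheres-in-warm-water background
_BOTTLE_BG = 0.104  # MBq/ml, bottles-in-warm-water background

_SPHERE_VOLUMES = {"S0": 0.5, "S1": 1.0, "S2": 2.0, "S3": 4.0,
                   "S4": 8.0, "S5": 16.0, "S6": 113.0}


def _spheres(conc: float) -> list[InsertSpec]:
    ring = 65.0
    out = []
    for i, (label, vol) in enumerate(list(_SPHERE_VOLUMES.items())[:-1]):
        a = math.radians(60.0 * i)
        out.append(InsertSpec("sphere", (ring * math.cos(a), ring * math.sin(a), 0.0),
                              vol, conc, label))
    out.append(InsertSpec("sphere", (0.0, 0.0, 0.0), 113.0, conc, "S6"))
    return out


def _bottles(labels_volumes: list[tuple[str, float]], conc: float,
             ring: float = 60.0) -> list[InsertSpec]:
    out = []
    n = len(labels_volumes)
    for i, (label, vol) in enumerate(labels_volumes):
        a = math.radians(360.0 * i / n)
        out.append(InsertSpec("cylinder", (ring * math.cos(a), ring * math.sin(a), 0.0),
                              vol, conc, label))
    return out


def _bed_bottles() -> list[InsertSpec]:
    # large bottles lying side by side on the pallet, axes along z
    specs = [("C1", 34.0, -105.0), ("C2", 163.8, -55.0),
             ("C3", 182.8, 15.0), ("C4", 199.5, 85.0)]
    return [InsertSpec("cylinder", (x, -15.0, 0.0), vol, _BOTTLE_CONC, label)
            for label, vol, x in specs]


def _build_presets() -> dict[str, StudyConfig]:
    presets = {}
    presets["jaszczak_spheres_air"] = StudyConfig(
        "jaszczak_spheres_air", _spheres(_SPHERE_CONC), 0.0, 20.0, "air")
    presets["jaszczak_spheres_cold_water"] = StudyConfig(
        "jaszczak_spheres_cold_water", _spheres(_SPHERE_CONC), 0.0, 30.0, "cold_water")
    presets["jaszczak_spheres_warm_water"] = StudyConfig(
        "jaszczak_spheres_warm_water", _spheres(_SPHERE_CONC), _SPHERE_BG, 30.0,
        "warm_water")
    presets["jaszczak_bottles_air"] = StudyConfig(
        "jaszczak_bottles_air",
        _bottles([("B1", 8.5), ("B2", 8.5), ("B3", 12.0), ("B4", 12.0), ("B5", 16.0)],
                 _BOTTLE_CONC), 0.0, 20.0, "air")
    presets["jaszczak_bottles_warm_water"] = StudyConfig(
        "jaszczak_bottles_warm_water",
        _bottles([("B4", 12.0), ("B5", 16.0), ("B6", 34.0)], _BOTTLE_CONC),
        _BOTTLE_BG, 20.0, "warm_water")
    presets["thorax_cold_water"] = StudyConfig(
        "thorax_cold_water",
        [InsertSpec("cylinder", (0.0, 28.0, 0.0), 34.0, 300.0 / 34.0, "T1"),
         InsertSpec("cylinder", (60.0, -15.0, -55.0), 34.0, 302.9 / 34.0, "T2"),
         InsertSpec("cylinder", (25.0, 30.0, 60.0), 34.0, 302.9 / 34.0, "T3"),
         InsertSpec("cylinder", (45.0, -27.0, 0.0), 34.0, 302.9 / 34.0, "T4")],
        0.0, 20.0, "thorax")
    presets["bottles_on_bed"] = StudyConfig(
        "bottles_on_bed", _bed_bottles(), 0.0, 10.0, "bed")
    presets["bottles_on_bed_water_bags"] = StudyConfig(
        "bottles_on_bed_water_bags", _bed_bottles(), 0.0, 10.0, "bed_bags")
    return presets


_PRESETS = _build_presets()
PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> StudyConfig:
    """Return one of the eight named study configurations."""
    try:
        cfg = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}") from None
    # return a fresh copy so callers can mutate safely
    return StudyConfig(cfg.name, list(cfg.inserts), cfg.background_concentration,
                       cfg.projection_duration, cfg.medium, dict(cfg.container))


_CAL_VOLUMES = [("V17", 17.0), ("V34", 34.0), ("V100", 100.0), ("V199", 199.5)]
_CAL_CONC = 0.62  # MBq/ml


def iadt_calibration_config(sbr: float, concentration: float = _CAL_CONC,
                            t_p: float = 20.0) -> StudyConfig:
    """Jaszczak bottle phantom used to calibrate the adaptive dual thresholds.

    Bottles of 17-199.5 ml at a fixed concentration; the cylinder background
    is filled to reach the requested signal-to-background ratio (``inf`` or
    0 background for the in-air scan).
    """
    inserts = _bottles(_CAL_VOLUMES, concentration, ring=62.0)
    if not math.isfinite(sbr) or sbr <= 0:
        return StudyConfig(f"iadt_calibration_air", inserts, 0.0, t_p, "air")
    bg = concentration / sbr
    return StudyConfig(f"iadt_calibration_sbr{sbr:g}", inserts, bg, t_p, "warm_water")


def cnf_tomo_config(total_activity_MBq: float, in_air: bool = False,
                    t_p: float = 20.0) -> StudyConfig:
    """Tomographic camera-calibration phantom at a chosen total activity.

    The bottle set of the adaptive-threshold calibration phantom is reused;
    for warm scans the cylinder background absorbs the activity that the
    inserts do not carry.
    """
    insert_vol = sum(v for _, v in _CAL_VOLUMES)
    if in_air:
        conc = total_activity_MBq / insert_vol
        return StudyConfig("cnf_tomo_air", _bottles(_CAL_VOLUMES, conc, ring=62.0),
                           0.0, t_p, "air")
    conc = _CAL_CONC
    cyl_vol = math.pi * (JASZCZAK_DIAMETER / 2 / 10) ** 2 * (JASZCZAK_HEIGHT / 10)
    bg_vol = cyl_vol - insert_vol
    bg = (total_activity_MBq - conc * insert_vol) / bg_vol
    if bg <= 0:
        raise ValueError("total activity too low for the warm calibration phantom")
    return StudyConfig(f"cnf_tomo_warm_{total_activity_MBq:g}",
                       _bottles(_CAL_VOLUMES, conc, ring=62.0), bg, t_p, "warm_water")


# ---------------------------------------------------------------------------
# I/O


def save_phantom_nifti(phantom: Phantom, prefix: str) -> None:
    """Write activity, mu and material-label volumes as NIfTI files."""
    import nibabel as nib

    aff = np.diag([phantom.grid.voxel_size] * 3 + [1.0])
    for name, arr in (("activity", phantom.activity), ("mu", phantom.mu),
                      ("labels", phantom.material.astype(np.int16))):
        nib.save(nib.Nifti1Image(np.asarray(arr), aff), f"{prefix}_{name}.nii.gz")


def save_config_yaml(config: StudyConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_config_yaml(path: str) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["inserts"] = [InsertSpec(**{**ins, "center": tuple(ins["center"])})
                      for ins in raw["inserts"]]
    return StudyConfig(**raw)
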