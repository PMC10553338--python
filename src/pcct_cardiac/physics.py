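"""Spectral attenuation physics and digital phantoms.

Attenuation is modeled with a two-basis photoelectric/Compton parametrization:
the photoelectric term falls off as (E0/E)^3 and the Compton term follows the
Klein-Nishina total cross-section shape, both normalized at a 30 keV reference
energy.  Materials with a K-edge (iodine, 33.2 keV) carry a multiplicative
upward step above the edge energy, so the attenuation ratio across the edge
equals the configured jump exactly.  The basis weights are calibration
parameters chosen to give water/iodine/calcium attenuation values of realistic
magnitude at micro-CT energies; the pipeline only requires self-consistent,
K-edge-bearing physics, not tabulated cross sections.

Two phantom families are provided:

* :class:`DynamicPhantom` - a beating left ventricle (iodine-enhanced blood
  pool) inside a soft-tissue thorax slice, with optional calcified plaque and
  static calibration vials.  The LV volume follows a raised-cosine cycle
  between the configured diastolic (DLVV) and systolic (SLVV) volumes at a
  configurable heart rate (300-600 bpm).
* :class:`DetectabilityPhantom` - a static grid of cylinders of varying
  diameter filled with calcium (10/20/40 mg/mL) or iodine (10 mg/mL) in an
  iodine-loaded background, used for contrast-to-noise detectability analysis.

Rasterization uses supersampled area-fraction anti-aliasing so that ROI means
are predictable to well below partial-volume tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EnergyGrid",
    "MaterialModel",
    "WATER",
    "IODINE",
    "CALCIUM",
    "MATERIALS",
    "mass_attenuation",
    "disk_fraction",
    "sphere_fraction",
    "DynamicPhantomConfig",
    "DynamicPhantom",
    "make_dynamic_phantom",
    "CylinderSpec",
    "DetectabilityPhantomSpec",
    "DetectabilityPhantom",
    "make_detectability_phantom",
    "lv_mask_volume_ml",
]

E_REF_KEV = 30.0
ELECTRON_REST_KEV = 511.0


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing photon energies (keV) covering the detector range."""

    energies: np.ndarray = field(
        default_factory=lambda: np.arange(10.0, 80.5, 1.0)
    )

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("energy grid must be a 1D array with >= 2 points")
        if e.min() <= 0:
            raise ValueError("energies must be positive")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        object.__setattr__(self, "energies", e)

    @property
    def emin(self) -> float:
        return float(self.energies[0])

    @property
    def emax(self) -> float:
        return float(self.energies[-1])

    def require_inside(self, energy) -> None:
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.emin) or np.any(e > self.emax):
            raise ValueError(
                f"energy outside grid range [{self.emin}, {self.emax}] keV"
            )


@dataclass(frozen=True)
class MaterialModel:
    """Two-basis attenuation model for one material.

    ``pe_coeff`` and ``cs_coeff`` are attenuation contributions (1/cm per unit
    concentration) of the photoelectric and Compton bases at the 30 keV
    reference energy.  Concentration units are mg/mL for contrast materials
    and water-fraction for tissue/water.
    """

    name: str
    pe_coeff: float
    cs_coeff: float
    kedge_energy: float | None = None
    kedge_jump: float | None = None
    concentration_unit: str = "mg/mL"

    def __post_init__(self):
        if self.pe_coeff < 0 or self.cs_coeff < 0:
            raise ValueError("basis coefficients must be non-negative")
        if self.kedge_energy is not None:
            if self.kedge_jump is None or self.kedge_jump <= 1:
                raise ValueError("K-edge materials need kedge_jump > 1")
            if not (10.0 < self.kedge_energy < 80.0):
                raise ValueError("kedge_energy must lie in (10, 80) keV")


def _klein_nishina(energy_kev):
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = (1 + 3 * k) / (1 + 2 * k) ** 2
    return t1 + t2 - t3


_KN_REF = float(_klein_nishina(E_REF_KEV))


def mass_attenuation(material: MaterialModel, energy, grid: EnergyGrid | None = None):
    """Attenuation per unit concentration (1/cm per unit) at ``energy`` keV.

    Continuous and strictly decreasing in energy except for a single upward
    jump at the material's K-edge; the across-edge ratio equals
    ``material.kedge_jump`` exactly.
    """
    grid = grid or EnergyGrid()
    grid.require_inside(energy)
    e = np.asarray(energy, dtype=float)
    mu = material.pe_coeff * (E_REF_KEV / e) ** 3
    mu = mu + material.cs_coeff * (_klein_nishina(e) / _KN_REF)
    if material.kedge_energy is not None:
        jump = np.where(e >= material.kedge_energy, material.kedge_jump, 1.0)
        mu = mu * jump
    return mu if mu.ndim else float(mu)


# Calibration weights give water mu(30 keV) ~= 0.37/cm, iodine ~= 0.023/cm per
# mg/mL below its K-edge, calcium ~= 0.0036/cm per mg/mL -- the magnitudes a
# micro-CT practitioner expects at these energies.
WATER = MaterialModel("water", pe_coeff=0.120, cs_coeff=0.250,
                      concentration_unit="fraction")
IODINE = MaterialModel("iodine", pe_coeff=0.0220, cs_coeff=0.0006,
                       kedge_energy=33.2, kedge_jump=2.2)
CALCIUM = MaterialModel("calcium", pe_coeff=0.0032, cs_coeff=0.0004)

MATERIALS = {m.name: m for m in (WATER, IODINE, CALCIUM)}


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def disk_fraction(shape, center_px, radius_px, supersample: int = 16):
    """Per-pixel area fraction covered by a disk (2D anti-aliased raster)."""
    n0, n1 = shape
    cy, cx = center_px
    r = float(radius_px)
    out = np.zeros(shape, dtype=float)
    if r <= 0:
        return out
    y0 = max(int(np.floor(cy - r - 1)), 0)
    y1 = min(int(np.ceil(cy + r + 1)) + 1, n0)
    x0 = max(int(np.floor(cx - r - 1)), 0)
    x1 = min(int(np.ceil(cx + r + 1)) + 1, n1)
    if y0 >= y1 or x0 >= x1:
        return out
    s = supersample
    off = (np.arange(s) + 0.5) / s
    ys = (y0 + np.add.outer(np.arange(y1 - y0), off)).reshape(-1)
    xs = (x0 + np.add.outer(np.arange(x1 - x0), off)).reshape(-1)
    d2 = np.add.outer((ys - cy) ** 2, (xs - cx) ** 2)
    inside = (d2 <= r * r).reshape(y1 - y0, s, x1 - x0, s)
    out[y0:y1, x0:x1] = inside.mean(axis=(1, 3))
    return out


def sphere_fraction(shape, center_px, radius_px, supersample: int = 4):
    """Per-voxel volume fraction covered by a sphere (3D raster)."""
    n0, n1, n2 = shape
    cz, cy, cx = center_px
    r = float(radius_px)
    out = np.zeros(shape, dtype=float)
    if r <= 0:
        return out
    lo = [max(int(np.floor(c - r - 1)), 0) for c in (cz, cy, cx)]
    hi = [min(int(np.ceil(c + r + 1)) + 1, n) for c, n in zip((cz, cy, cx), shape)]
    if any(a >= b for a, b in zip(lo, hi)):
        return out
    s = supersample
    off = (np.arange(s) + 0.5) / s
    axes = []
    for c, a, b in zip((cz, cy, cx), lo, hi):
        v = (a + np.add.outer(np.arange(b - a), off)).reshape(-1)
        axes.append((v - c) ** 2)
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    inside = (d2 <= r * r).reshape(hi[0] - lo[0], s, hi[1] - lo[1], s,
                                   hi[2] - lo[2], s)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside.mean(axis=(1, 3, 5))
    return out


# ---------------------------------------------------------------------------
# dynamic cardiac phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicPhantomConfig:
    grid_n: int = 96
    voxel_mm: float = 0.125
    ndim: int = 2
    heart_rate_bpm: float = 450.0
    dlvv_ml: float = 0.045
    slvv_ml: float = 0.022
    blood_iodine_mg_ml: float = 8.0
    body_radius_frac: float = 0.44
    lv_center_frac: tuple = (0.5, 0.44)
    plaque_ca_mg_ml: float = 0.0
    plaque_diameter_mm: float = 0.6
    tissue_texture: float = 0.02
    respiration_amplitude: float = 0.0  # signal path exists; default off
    vials: bool = True
    vial_iodine_mg_ml: float = 5.0
    vial_calcium_mg_ml: float = 20.0

    def __post_init__(self):
        if self.slvv_ml > self.dlvv_ml:
            raise ValueError("SLVV must not exceed DLVV")
        if not (300.0 <= self.heart_rate_bpm <= 600.0):
            raise ValueError("cardiac heart rate must lie in [300, 600] bpm")
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")


def _radius_mm_from_volume(v_ml: float) -> float:
    # 1 mL = 1000 mm^3; LV modeled as a sphere (2D mode images its equator)
    return (3.0 * v_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def lv_mask_volume_ml(mask: np.ndarray, voxel_mm: float) -> float:
    """LV volume in mL from a binary mask.

    3D masks: voxel count x voxel volume.  2D masks image the equatorial
    slice of the spherical LV model, so the area is converted to the volume
    of the sphere with the same equatorial area.
    """
    mask = np.asarray(mask)
    if mask.ndim == 3:
        return float(mask.sum() * voxel_mm**3 / 1000.0)
    area_mm2 = float(mask.sum()) * voxel_mm**2
    r_mm = np.sqrt(area_mm2 / np.pi)
    return float(4.0 / 3.0 * np.pi * r_mm**3 / 1000.0)


class DynamicPhantom:
    """Beating-LV thorax phantom with per-material concentration maps.

    ``render(phase)`` returns {material: concentration map} at a cardiac
    phase in [0, 1); phase 0 is end-diastole (maximum LV volume) and phase
    0.5 end-systole.  The LV volume follows a raised cosine between DLVV and
    SLVV.  Stored ``truth`` carries the configured volumes and heart rate.
    """

    material_names = ("water", "iodine", "calcium")

    def __init__(self, config: DynamicPhantomConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        n = config.grid_n
        self.shape = (n,) * config.ndim
        self.voxel_mm = config.voxel_mm
        rng = np.random.default_rng(self.seed)

        c = (n - 1) / 2.0
        body_r = config.body_radius_frac * n
        if config.ndim == 2:
            self._body = disk_fraction(self.shape, (c, c), body_r)
        else:
            self._body = sphere_fraction(self.shape, (c, c, c), body_r)
        if config.tissue_texture > 0:
            texture = 1.0 + config.tissue_texture * rng.standard_normal(self.shape)
            self._texture = np.clip(texture, 0.5, 1.5)
        else:
            self._texture = np.ones(self.shape)

        fy, fx = config.lv_center_frac
        if config.ndim == 2:
            self._lv_center = (fy * (n - 1), fx * (n - 1))
        else:
            self._lv_center = (c, fy * (n - 1), fx * (n - 1))

        self._vials = []
        if config.vials and config.ndim == 2:
            vr = max(2.5, 1.0 / config.voxel_mm * 0.5)  # ~1 mm diameter
            ring = 0.70 * body_r
            for ang, (mat, conc) in zip(
                (0.75 * np.pi, 0.25 * np.pi, -0.5 * np.pi),
                (("iodine", config.vial_iodine_mg_ml),
                 ("calcium", config.vial_calcium_mg_ml),
                 ("water", 1.0)),
            ):
                vy = c + ring * np.sin(ang)
                vx = c + ring * np.cos(ang)
                self._vials.append((mat, conc, (vy, vx), vr))

        self._plaque = None
        if config.plaque_ca_mg_ml > 0:
            r_d = _radius_mm_from_volume(config.dlvv_ml) / config.voxel_mm
            off = r_d + 0.8 * config.plaque_diameter_mm / config.voxel_mm
            pc = list(self._lv_center)
            pc[-1] += off
            self._plaque = (tuple(pc),
                            0.5 * config.plaque_diameter_mm / config.voxel_mm,
                            config.plaque_ca_mg_ml)

        self.truth = {
            "dlvv_ml": config.dlvv_ml,
            "slvv_ml": config.slvv_ml,
            "sv_ml": config.dlvv_ml - config.slvv_ml,
            "ef_pct": 100.0 * (config.dlvv_ml - config.slvv_ml) / config.dlvv_ml
            if config.dlvv_ml > 0 else 0.0,
            "heart_rate_bpm": config.heart_rate_bpm,
        }

    # -- motion model -------------------------------------------------------
    def lv_volume_ml(self, phase) -> np.ndarray | float:
        """Raised-cosine LV volume waveform; phase 0 = diastole."""
        phase = np.asarray(phase, dtype=float) % 1.0
        c = self.config
        v = c.slvv_ml + (c.dlvv_ml - c.slvv_ml) * 0.5 * (1 + np.cos(2 * np.pi * phase))
        return v if v.ndim else float(v)

    def lv_radius_px(self, phase) -> float:
        return _radius_mm_from_volume(self.lv_volume_ml(phase)) / self.voxel_mm

    def phase_at(self, t_s) -> np.ndarray | float:
        ph = (np.asarray(t_s, dtype=float) * self.config.heart_rate_bpm / 60.0) % 1.0
        return ph if ph.ndim else float(ph)

    # -- rendering ----------------------------------------------------------
    def _lv_fraction(self, phase):
        r = self.lv_radius_px(phase)
        if self.config.ndim == 2:
            return disk_fraction(self.shape, self._lv_center, r)
        return sphere_fraction(self.shape, self._lv_center, r)

    def lv_mask(self, phase) -> np.ndarray:
        """Binary LV label whose voxel count matches the analytic area
        (2D: pi r^2) or volume (3D: 4/3 pi r^3) to the nearest voxel."""
        frac = self._lv_fraction(phase)
        r = self.lv_radius_px(phase)
        target = np.pi * r**2 if self.config.ndim == 2 else 4 / 3 * np.pi * r**3
        n = int(round(target))
        if n <= 0:
            return np.zeros(self.shape, dtype=bool)
        order = np.argsort(-frac, axis=None, kind="stable")[:n]
        mask = np.zeros(frac.size, dtype=bool)
        mask[order] = True
        return mask.reshape(self.shape)

    def render(self, phase) -> dict:
        """Concentration maps {water, iodine, calcium} at a cardiac phase."""
        lv = self._lv_fraction(phase)
        water = self._body * self._texture
        iodine = self.config.blood_iodine_mg_ml * lv
        calcium = np.zeros(self.shape)
        if self._plaque is not None:
            pc, pr, conc = self._plaque
            frac = (disk_fraction(self.shape, pc, pr) if self.config.ndim == 2
                    else sphere_fraction(self.shape, pc, pr))
            calcium = calcium + conc * frac
            water = water * (1 - frac)
        for mat, conc, center, vr in self._vials:
            frac = disk_fraction(self.shape, center, vr)
            if mat == "iodine":
                iodine = iodine + conc * frac
            elif mat == "calcium":
                calcium = calcium + conc * frac
            # vials displace only texture, keep water background inside
        return {"water": water, "iodine": iodine, "calcium": calcium}

    def vial_rois(self):
        """(material, concentration, boolean ROI) for calibration vials."""
        rois = []
        for mat, conc, center, vr in self._vials:
            frac = disk_fraction(self.shape, center, vr)
            rois.append((mat, conc, frac > 0.99))
        return rois


def make_dynamic_phantom(config: DynamicPhantomConfig | None = None,
                         seed: int = 0, **kwargs) -> DynamicPhantom:
    """Build a :class:`DynamicPhantom`; deterministic given ``seed``."""
    if config is None:
        config = DynamicPhantomConfig(**kwargs)
    elif kwargs:
        config = replace(config, **kwargs)
    return DynamicPhantom(config, seed=seed)


# ---------------------------------------------------------------------------
# detectability phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderSpec:
    diameter_mm: float
    material: str
    concentration: float
    center_px: tuple  # (row, col)


@dataclass(frozen=True)
class DetectabilityPhantomSpec:
    grid_n: int = 128
    voxel_mm: float = 0.16
    diameters_mm: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5)
    rows: Sequence[tuple] = (("calcium", 10.0), ("calcium", 20.0),
                             ("calcium", 40.0), ("iodine", 10.0))
    background_iodine_mg_ml: float = 10.0
    row_pitch_mm: float = 4.0
    col_pitch_mm: float = 3.6
    body_radius_frac: float = 0.48
    # dedicated iodine-free water vial for sensitivity calibration
    water_vial_mm: float = 2.5
    water_vial_offset_mm: tuple = (-8.0, 1.8)


class DetectabilityPhantom:
    """Static cylinder-grid phantom for Ca-in-iodine detectability.

    Rows hold one (material, concentration) pair each; columns sweep cylinder
    diameter.  Cylinders sit in a uniform iodine-loaded water background.
    """

    material_names = ("water", "iodine", "calcium")

    def __init__(self, spec: DetectabilityPhantomSpec):
        self.spec = spec
        n = spec.grid_n
        self.shape = (n, n)
        self.voxel_mm = spec.voxel_mm
        c = (n - 1) / 2.0
        self._body = disk_fraction(self.shape, (c, c), spec.body_radius_frac * n)

        nrows, ncols = len(spec.rows), len(spec.diameters_mm)
        rp = spec.row_pitch_mm / spec.voxel_mm
        cp = spec.col_pitch_mm / spec.voxel_mm
        self.cylinders: list[CylinderSpec] = []
        for i, (mat, conc) in enumerate(spec.rows):
            for j, d in enumerate(spec.diameters_mm):
                if d < 0:
                    raise ValueError("cylinder diameter must be >= 0")
                cy = c + (i - (nrows - 1) / 2.0) * rp
                cx = c + (j - (ncols - 1) / 2.0) * cp
                self.cylinders.append(CylinderSpec(d, mat, conc, (cy, cx)))
        if spec.water_vial_mm > 0:
            oy, ox = spec.water_vial_offset_mm
            self.cylinders.append(CylinderSpec(
                spec.water_vial_mm, "water", 0.0,
                (c + oy / spec.voxel_mm, c + ox / spec.voxel_mm)))
        self._check_layout()

    def _check_layout(self):
        import warnings
        cyl = self.cylinders
        for a in cyl:
            if a.diameter_mm == 0:
                warnings.warn("cylinder with zero diameter renders empty")
        for i in range(len(cyl)):
            for j in range(i + 1, len(cyl)):
                a, b = cyl[i], cyl[j]
                dist = np.hypot(a.center_px[0] - b.center_px[0],
                                a.center_px[1] - b.center_px[1])
                min_sep = (a.diameter_mm + b.diameter_mm) / 2.0 / self.voxel_mm
                if dist < min_sep:
                    raise ValueError(
                        f"overlapping cylinders at {a.center_px} and {b.center_px}"
                    )

    def cylinder_fraction(self, cyl: CylinderSpec) -> np.ndarray:
        return disk_fraction(self.shape, cyl.center_px,
                             0.5 * cyl.diameter_mm / self.voxel_mm)

    def cylinder_mask(self, cyl: CylinderSpec) -> np.ndarray:
        return self.cylinder_fraction(cyl) >= 0.5

    def render(self) -> dict:
        insert = np.zeros(self.shape)
        iodine = np.zeros(self.shape)
        calcium = np.zeros(self.shape)
        for cyl in self.cylinders:
            frac = self.cylinder_fraction(cyl)
            insert = np.maximum(insert, frac)
            if cyl.material == "iodine":
                iodine += cyl.concentration * frac
            elif cyl.material == "calcium":
                calcium += cyl.concentration * frac
        # iodine background everywhere in the body except inside inserts
        iodine = iodine + self.spec.background_iodine_mg_ml * self._body * (1 - insert)
        water = self._body
        return {"water": water, "iodine": iodine, "calcium": calcium}

    def background_mask(self) -> np.ndarray:
        insert = np.zeros(self.shape)
        for cyl in self.cylinders:
            insert = np.maximum(insert, self.cylinder_fraction(cyl))
        return (self._body > 0.99) & (insert == 0)


def make_detectability_phantom(
    spec: DetectabilityPhantomSpec | None = None, **kwargs
) -> DetectabilityPhantom:
    if spec is None:
        spec = DetectabilityPhantomSpec(**kwargs)
    return DetectabilityPhantom(spec)
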