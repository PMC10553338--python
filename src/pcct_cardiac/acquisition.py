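"""Photon-counting detector forward model.

Parallel-beam, desk-scale geometry: each view is a set of parallel rays at one
gantry angle, acquired at a fixed view rate (default 100 Hz, i.e. 10 ms per
exposure) while the phantom beats.  Photons from a filtered bremsstrahlung
80 kVp spectrum are attenuated along each ray, sorted into energy bins by the
detector thresholds (default 25/34/50/60 keV) and Poisson-sampled.

The projector is Joseph-style (bilinear sampling at unit steps along each
ray).  Its adjoint uses the exact transpose of the sampling weights, so
``<R x, y> == <x, R^T y>`` to floating-point precision - a property the
iterative reconstruction relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .physics import EnergyGrid, MATERIALS, mass_attenuation

__all__ = [
    "DEFAULT_THRESHOLDS",
    "AcquisitionConfig",
    "BinnedSinogram",
    "ParallelProjector",
    "source_spectrum",
    "bin_masks",
    "bin_effective_attenuation",
    "acquire",
    "log_normalize",
    "check_cardiac_sampling",
]

DEFAULT_THRESHOLDS = (25.0, 34.0, 50.0, 60.0)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scan parameters.  Tube current is folded into ``photons_per_ray``."""

    kvp: float = 80.0
    views: int = 1000
    exposure_s: float = 0.010
    thresholds: tuple = DEFAULT_THRESHOLDS
    photons_per_ray: float = 2.0e4
    detector_pixels: int | None = None  # default: covers the grid diagonal
    angular_span: float = 2.0 * np.pi
    noise: bool = True
    seed: int = 0
    phase_frames: int = 64  # cardiac-phase quantization for rendering

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if t[-1] >= self.kvp:
            raise ValueError("max threshold must be below kVp")
        if self.exposure_s <= 0:
            raise ValueError("exposure must be positive")
        if self.photons_per_ray <= 0:
            raise ValueError("photons_per_ray must be positive")
        object.__setattr__(self, "thresholds", t)


@dataclass
class BinnedSinogram:
    """Time-stamped, angle-indexed, energy-binned projection data.

    ``data`` has shape (views, detector pixels, bins) and holds raw counts
    (mode ``counts``) or log-attenuation (mode ``log``).
    """

    data: np.ndarray
    timestamps: np.ndarray
    angles: np.ndarray
    thresholds: tuple
    mode: str = "counts"
    air_counts: np.ndarray | None = None  # (bins,) expected air counts
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("sinogram data must be (views, pixels, bins)")
        if (len(self.timestamps) != self.data.shape[0]
                or len(self.angles) != self.data.shape[0]):
            raise ValueError("angle/timestamp count must equal view count")
        dt = np.diff(self.timestamps)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("timestamps must increase with constant spacing")
        if self.mode == "counts" and np.any(self.data < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# source spectrum and energy bins
# ---------------------------------------------------------------------------

def source_spectrum(kvp: float, grid: EnergyGrid | None = None,
                    photons_per_ray: float = 1.0,
                    filtration: float = 1.2) -> np.ndarray:
    """Filtered-bremsstrahlung fluence per grid energy (photons per sample).

    Kramers shape (kvp - E) multiplied by a beam-hardening filtration factor
    exp(-filtration * (30/E)^3); zero above the endpoint; normalized so the
    sum over the grid equals ``photons_per_ray``.
    """
    grid = grid or EnergyGrid()
    if kvp > grid.emax + 1e-9:
        raise ValueError("kvp endpoint above energy grid range")
    e = grid.energies
    s = np.clip(kvp - e, 0.0, None) * np.exp(-filtration * (30.0 / e) ** 3)
    total = s.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum")
    return s * (photons_per_ray / total)


def bin_masks(grid: EnergyGrid, thresholds, kvp: float) -> np.ndarray:
    """Boolean (bins, energies) masks partitioning [t0, kvp]."""
    t = list(thresholds) + [kvp]
    e = grid.energies
    masks = []
    for lo, hi in zip(t[:-1], t[1:]):
        m = (e >= lo) & (e < hi)
        masks.append(m)
    masks[-1] |= np.isclose(e, kvp)
    return np.asarray(masks)


def bin_effective_attenuation(material, thresholds=DEFAULT_THRESHOLDS,
                              kvp: float = 80.0,
                              grid: EnergyGrid | None = None,
                              filtration: float = 1.2) -> np.ndarray:
    """Spectrum-weighted mean attenuation per unit concentration, per bin."""
    grid = grid or EnergyGrid()
    s = source_spectrum(kvp, grid, 1.0, filtration)
    masks = bin_masks(grid, thresholds, kvp)
    att = mass_attenuation(material, grid.energies, grid)
    out = np.array([np.sum(s[m] * att[m]) / np.sum(s[m]) for m in masks])
    return out


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------

class ParallelProjector:
    """Joseph-style parallel-beam projector with an exact adjoint.

    Works on 2D images of shape (n, n) with isotropic ``voxel_mm`` pixels.
    Line integrals are returned in units of image-value x cm, so an image of
    attenuation in 1/cm yields dimensionless optical depths.
    """

    def __init__(self, n: int, voxel_mm: float, n_det: int | None = None,
                 cache_size: int = 400):
        self.n = int(n)
        self.voxel_mm = float(voxel_mm)
        if n_det is None:
            n_det = int(np.ceil(self.n * np.sqrt(2.0))) + 3
        self.n_det = int(n_det)
        self._n_steps = int(np.ceil(self.n * np.sqrt(2.0))) + 3
        self._cache: dict = {}
        self._cache_size = cache_size

    @property
    def px_to_cm(self) -> float:
        return self.voxel_mm / 10.0

    def _geometry(self, angle: float):
        key = round(float(angle), 12)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        c = (self.n - 1) / 2.0
        u = np.arange(self.n_det) - (self.n_det - 1) / 2.0
        s = np.arange(self._n_steps) - (self._n_steps - 1) / 2.0
        ca, sa = np.cos(angle), np.sin(angle)
        # ray direction (ca, sa); detector axis (-sa, ca); (y, x) image coords
        ys = c + np.add.outer(u * ca, s * sa)
        xs = c + np.add.outer(-u * sa, s * ca)
        iy = np.floor(ys).astype(np.int32)
        ix = np.floor(xs).astype(np.int32)
        fy = (ys - iy).astype(np.float64)
        fx = (xs - ix).astype(np.float64)
        valid = (iy >= 0) & (iy < self.n - 1) & (ix >= 0) & (ix < self.n - 1)
        iy = np.clip(iy, 0, self.n - 2)
        ix = np.clip(ix, 0, self.n - 2)
        w00 = np.where(valid, (1 - fy) * (1 - fx), 0.0)
        w01 = np.where(valid, (1 - fy) * fx, 0.0)
        w10 = np.where(valid, fy * (1 - fx), 0.0)
        w11 = np.where(valid, fy * fx, 0.0)
        geo = (iy, ix, w00, w01, w10, w11)
        if len(self._cache) < self._cache_size:
            self._cache[key] = geo
        return geo

    def project(self, image: np.ndarray, angle: float) -> np.ndarray:
        """Line integrals (n_det,) of ``image`` along rays at ``angle``."""
        if image.shape != (self.n, self.n):
            raise ValueError(f"image must be {(self.n, self.n)}")
        iy, ix, w00, w01, w10, w11 = self._geometry(angle)
        vals = (w00 * image[iy, ix] + w01 * image[iy, ix + 1]
                + w10 * image[iy + 1, ix] + w11 * image[iy + 1, ix + 1])
        return vals.sum(axis=1) * self.px_to_cm

    def backproject(self, proj: np.ndarray, angle: float) -> np.ndarray:
        """Exact adjoint of :meth:`project` applied to one view."""
        if proj.shape != (self.n_det,):
            raise ValueError(f"projection must be ({self.n_det},)")
        iy, ix, w00, w01, w10, w11 = self._geometry(angle)
        g = proj[:, None] * self.px_to_cm
        out = np.zeros((self.n, self.n))
        np.add.at(out, (iy, ix), w00 * g)
        np.add.at(out, (iy, ix + 1), w01 * g)
        np.add.at(out, (iy + 1, ix), w10 * g)
        np.add.at(out, (iy + 1, ix + 1), w11 * g)
        return out

    def project_stack(self, image: np.ndarray, angles) -> np.ndarray:
        return np.stack([self.project(image, a) for a in angles])

    def backproject_stack(self, sino: np.ndarray, angles) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        for row, a in zip(sino, angles):
            out += self.backproject(row, a)
        return out


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

def check_cardiac_sampling(view_rate_hz: float, hr_band_bpm=(300.0, 600.0)) -> bool:
    """True when the view rate resolves the fastest expected heart rate."""
    return view_rate_hz > 2.0 * hr_band_bpm[1] / 60.0


def acquire(phantom, config: AcquisitionConfig | None = None,
            grid: EnergyGrid | None = None, **kwargs) -> BinnedSinogram:
    """Simulate a photon-counting scan of a (possibly beating) phantom.

    Each view is rendered at the phantom's cardiac phase at that view's
    timestamp.  Expected counts per bin are the spectral integral of the
    transmitted fluence; Poisson noise is seeded and reproducible.
    """
    if config is None:
        config = AcquisitionConfig(**kwargs)
    elif kwargs:
        config = replace(config, **kwargs)
    grid = grid or EnergyGrid()
    if grid.emax < config.thresholds[-1]:
        raise ValueError("energy grid must reach the highest threshold")

    n = phantom.shape[0]
    if len(phantom.shape) != 2:
        raise ValueError("acquisition supports 2D phantoms")
    proj = ParallelProjector(n, phantom.voxel_mm,
                             n_det=config.detector_pixels)

    spectrum = source_spectrum(config.kvp, grid, config.photons_per_ray)
    masks = bin_masks(grid, config.thresholds, config.kvp)
    air = masks @ spectrum  # (bins,) expected air counts

    mats = phantom.material_names
    att = np.stack([mass_attenuation(MATERIALS[m], grid.energies, grid)
                    for m in mats])  # (mat, E)

    times = np.arange(config.views) * config.exposure_s
    angles = (np.arange(config.views) / config.views) * config.angular_span
    static = not hasattr(phantom, "phase_at")
    if static:
        phases = np.zeros(config.views)
    else:
        phases = np.asarray(phantom.phase_at(times), dtype=float)

    q = max(1, config.phase_frames)
    frame_ids = (np.round(phases * q).astype(int)) % q if not static else \
        np.zeros(config.views, dtype=int)
    frames: dict[int, np.ndarray] = {}

    rng = np.random.default_rng(config.seed)
    data = np.empty((config.views, proj.n_det, len(masks)))
    for v in range(config.views):
        fid = frame_ids[v]
        maps = frames.get(fid)
        if maps is None:
            rendered = phantom.render() if static else phantom.render(fid / q)
            maps = np.stack([rendered[m] for m in mats])
            frames[fid] = maps
        L = np.stack([proj.project(maps[k], angles[v])
                      for k in range(len(mats))])  # (mat, det)
        tau = att.T @ L  # (E, det)
        trans = spectrum[:, None] * np.exp(-tau)  # (E, det)
        data[v] = (masks @ trans).T  # (det, bins)
    if config.noise:
        data = rng.poisson(data).astype(float)

    meta = {
        "voxel_mm": phantom.voxel_mm,
        "grid_n": n,
        "kvp": config.kvp,
        "photons_per_ray": config.photons_per_ray,
        "exposure_s": config.exposure_s,
        "true_phase": phases,
    }
    if not static:
        meta["truth"] = dict(phantom.truth)
    return BinnedSinogram(data=data, timestamps=times, angles=angles,
                          thresholds=config.thresholds, mode="counts",
                          air_counts=air, meta=meta)


def log_normalize(sino: BinnedSinogram,
                  air_counts: np.ndarray | None = None) -> BinnedSinogram:
    """Log-transform counts: -log(counts / air), with zero-count clamping.

    Counts below 0.5 are clamped to 0.5 before the log (standard practice for
    photon-starved pixels); the number of clamped entries is recorded in
    ``meta['clamped']`` and a warning is emitted when any occur.
    """
    if sino.mode != "counts":
        raise ValueError("log_normalize expects a counts-mode sinogram")
    air = air_counts if air_counts is not None else sino.air_counts
    if air is None:
        raise ValueError("air scan counts are required for log normalization")
    air = np.asarray(air, dtype=float)
    if np.any(air <= 0):
        raise ValueError("air counts must be positive")
    clamped = int(np.count_nonzero(sino.data < 0.5))
    if clamped:
        warnings.warn(f"log_normalize clamped {clamped} zero-count pixels")
    counts = np.maximum(sino.data, 0.5)
    logdata = -np.log(counts / air)  # air broadcasts over (views, det, bins)
    meta = dict(sino.meta)
    meta["clamped"] = clamped
    return BinnedSinogram(data=logdata, timestamps=sino.timestamps,
                          angles=sino.angles, thresholds=sino.thresholds,
                          mode="log", air_counts=air, meta=meta)
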