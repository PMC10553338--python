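"""Image-domain material decomposition with a calibrated sensitivity matrix.

Per voxel, the multi-bin signal x (one value per energy bin) is modeled as a
linear mixture of basis materials, x = c M, where M is the (materials x bins)
sensitivity matrix and c the material concentrations.  M is calibrated by
least squares from ROIs over vials of known concentration.  Decomposition
solves the (weighted) least-squares inversion per voxel; negative
concentrations are eliminated by orthogonal subspace projection (OSP):
any voxel with a negative coefficient is re-solved with the offending basis
vectors removed, iterating until all coefficients are non-negative.

Typical bases: iodine/photoelectric/Compton for in vivo scans, or
iodine/calcium/water for the detectability phantom.  The 34 keV threshold
straddles iodine's K-edge (33.2 keV), which is what keeps the
iodine-calcium-water matrix well conditioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recon import ReconVolume

__all__ = [
    "SensitivityMatrix",
    "MaterialMaps",
    "calibrate_sensitivity",
    "decompose",
    "composite_rgb",
]


@dataclass
class SensitivityMatrix:
    """(materials x bins) per-unit-concentration signal matrix."""

    M: np.ndarray
    materials: tuple
    bin_labels: tuple = ()
    residual: float = 0.0

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != len(self.materials):
            raise ValueError("M must be (materials, bins)")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("M must be finite")
        if np.any(np.all(self.M == 0, axis=1)):
            raise ValueError("M has an all-zero material row")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.M))


@dataclass
class MaterialMaps:
    """Per-material concentration images, non-negative after OSP."""

    maps: dict  # material -> (phases, n, n) or (n, n)
    basis: str
    meta: dict = field(default_factory=dict)

    def __getitem__(self, material: str) -> np.ndarray:
        return self.maps[material]


def calibrate_sensitivity(recon: ReconVolume | np.ndarray, vial_rois,
                          bin_labels=()) -> SensitivityMatrix:
    """Least-squares fit of ROI mean signals against known concentrations.

    ``vial_rois`` is a list of (concentration vector over materials, ROI
    mask, material names) or (material_name, concentration, mask) triples for
    single-material vials (remaining materials, water excepted, at zero).
    """
    data = recon.data if isinstance(recon, ReconVolume) else np.asarray(recon)
    if data.ndim == 4:  # (phases, bins, n, n): calibrate on the first phase
        data = data[0]
    n_bins = data.shape[0]

    # normalize roi spec into (conc matrix, signal matrix, material labels)
    materials: list[str] = []
    rows = []
    for spec in vial_rois:
        if len(spec) == 3 and isinstance(spec[0], str):
            name, conc, mask = spec
            if name not in materials:
                materials.append(name)
            rows.append(({name: conc}, mask))
        else:
            conc_map, mask = spec
            for name in conc_map:
                if name not in materials:
                    materials.append(name)
            rows.append((dict(conc_map), mask))
    A = np.zeros((len(rows), len(materials)))
    S = np.zeros((len(rows), n_bins))
    for i, (conc_map, mask) in enumerate(rows):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty vial ROI")
        for name, c in conc_map.items():
            A[i, materials.index(name)] = c
        S[i] = data[:, mask].mean(axis=1)
    if np.linalg.matrix_rank(A) < len(materials):
        raise ValueError(
            f"rank-deficient calibration design: {len(rows)} vials for "
            f"{len(materials)} materials"
        )
    M, res, *_ = np.linalg.lstsq(A, S, rcond=None)
    resid = float(np.sqrt(res.sum() / S.size)) if np.size(res) else 0.0
    return SensitivityMatrix(M, tuple(materials), tuple(bin_labels), resid)


def _solve_subset(X: np.ndarray, M: np.ndarray, subset, weights) -> np.ndarray:
    """Weighted LS solve of x = c M restricted to basis ``subset``."""
    Ms = M[list(subset)]  # (k, bins)
    W = np.sqrt(weights)
    sol, *_ = np.linalg.lstsq((Ms * W).T, (X * W).T, rcond=None)
    return sol.T  # (voxels, k)


def decompose(recon: ReconVolume | np.ndarray, sens: SensitivityMatrix,
              weights: np.ndarray | None = None,
              condition_warn: float = 1e3) -> MaterialMaps:
    """Per-voxel inversion of the sensitivity model with OSP non-negativity.

    ``recon`` supplies (bins, ...) signals (a ReconVolume decomposes each
    cardiac phase independently).  ``weights`` are per-bin inverse-variance
    weights for the bins > materials least-squares case.  Output maps are
    non-negative everywhere; voxels untouched by OSP reproduce their signal
    within solver tolerance.
    """
    M = sens.M
    n_mat, n_bins = M.shape
    if n_bins < n_mat:
        raise ValueError("need at least as many bins as materials")
    if np.linalg.matrix_rank(M) < n_mat:
        raise np.linalg.LinAlgError("singular sensitivity matrix")
    if sens.condition_number > condition_warn:
        warnings.warn(
            f"sensitivity matrix condition number {sens.condition_number:.3g} "
            f"exceeds {condition_warn:.3g}"
        )
    w = np.ones(n_bins) if weights is None else np.asarray(weights, float)

    data = recon.data if isinstance(recon, ReconVolume) else np.asarray(recon)
    squeeze_phase = False
    if data.ndim == 3:  # (bins, n, n)
        data = data[None]
        squeeze_phase = True
    P, B = data.shape[:2]
    spatial = data.shape[2:]
    out = np.zeros((P, n_mat) + spatial)

    for p in range(P):
        X = data[p].reshape(B, -1).T  # (voxels, bins)
        C = _solve_subset(X, M, range(n_mat), w)
        # OSP: iteratively drop negative-coefficient bases and re-solve
        for _ in range(n_mat):
            neg = C < -1e-12
            bad = neg.any(axis=1)
            if not bad.any():
                break
            patterns = {}
            for row in np.flatnonzero(bad):
                keep = tuple(np.flatnonzero(~neg[row]))
                patterns.setdefault(keep, []).append(row)
            for keep, rows in patterns.items():
                rows = np.asarray(rows)
                C[rows] = 0.0
                if keep:
                    C[np.ix_(rows, list(keep))] = _solve_subset(
                        X[rows], M, keep, w)
        C = np.maximum(C, 0.0)
        out[p] = C.T.reshape((n_mat,) + spatial)

    maps = {name: (out[:, i] if not squeeze_phase else out[0, i])
            for i, name in enumerate(sens.materials)}
    return MaterialMaps(maps, basis="-".join(sens.materials),
                        meta={"condition_number": sens.condition_number})


def composite_rgb(maps: MaterialMaps, windows: dict) -> np.ndarray:
    """Channel-wise windowed merge of 2-3 material maps into an RGB image.

    ``windows`` maps material name -> (low, high); materials are assigned to
    R, G, B channels in the given order.  Deterministic; values clipped to
    [0, 1].
    """
    names = list(windows)
    if not 2 <= len(names) <= 3:
        raise ValueError("composite_rgb needs 2-3 maps")
    first = np.asarray(maps[names[0]])
    rgb = np.zeros(first.shape + (3,))
    for ch, name in enumerate(names):
        lo, hi = windows[name]
        if hi <= lo:
            raise ValueError("window high must exceed low")
        rgb[..., ch] = np.clip((np.asarray(maps[name]) - lo) / (hi - lo), 0, 1)
    return rgb
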