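"""Digital brain phantoms and receive-coil sensitivity maps.

The phantom is a stack of 2D complex slices with per-voxel tissue maps
(proton density, T1, T2*, off-resonance, fat fraction) and an integer label
mask.  Geometry is a set of nested ellipses: white matter core, ventricular
CSF, a cortical grey-matter shell, a signal-free skull gap and a thin
subcutaneous fat ring — enough structure to exercise slice separation,
distortion and chemical-shift behaviour without any anatomical download.

Coil maps use an analytic loop-falloff model (inverse-distance-squared
magnitude, linear phase): fast, smooth, and well conditioned for the
multiband inverse problem.  Axis convention: arrays are indexed
``[slice, y, x]`` with x = readout, y = phase encode; the FOV is centred at
``matrix / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "TISSUE_LABELS",
    "TISSUE_PARAMS",
    "Phantom",
    "CoilSensitivities",
    "make_brain_phantom",
    "make_coil_sensitivities",
]

#: Integer labels of the tissue mask.
TISSUE_LABELS = {"air": 0, "gm": 1, "wm": 2, "csf": 3, "fat": 4}

#: Per-tissue (proton density a.u., T1 s, T2* s) at 3 T.
TISSUE_PARAMS = {
    "air": (0.0, 1.0, 1.0),
    "gm": (0.85, 1.2, 0.050),
    "wm": (0.70, 0.8, 0.045),
    "csf": (1.00, 4.0, 0.100),
    "fat": (0.90, 0.37, 0.060),
}


@dataclass
class Phantom:
    """Multi-slice complex tissue model (ground truth for all simulations)."""

    slices: np.ndarray            # (S, N, N) complex
    proton_density: np.ndarray    # (S, N, N)
    t1: np.ndarray                # (S, N, N) seconds
    t2_star: np.ndarray           # (S, N, N) seconds
    off_resonance: np.ndarray     # (S, N, N) Hz
    fat_fraction: np.ndarray      # (S, N, N) in [0, 1]
    labels: np.ndarray            # (S, N, N) int8
    voxel_size_mm: float
    slice_positions_mm: np.ndarray
    fov_mm: float

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def matrix(self) -> int:
        return self.slices.shape[-1]

    @property
    def fat_ring_mask(self) -> np.ndarray:
        """Boolean mask of the subcutaneous fat ring emitted by the generator."""
        return self.labels == TISSUE_LABELS["fat"]

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != TISSUE_LABELS["air"]

    @property
    def gm_mask(self) -> np.ndarray:
        """Gray matter — where resting-state networks live."""
        return self.labels == TISSUE_LABELS["gm"]

    def validate(self) -> "Phantom":
        arrays = (self.slices, self.proton_density, self.t1, self.t2_star,
                  self.off_resonance, self.fat_fraction, self.labels)
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError("phantom arrays have inconsistent shapes")
        if self.slices.shape[1] != self.slices.shape[2]:
            raise ValueError("phantom slices must be square")
        if not np.all(np.isfinite(self.off_resonance)):
            raise ValueError("off-resonance map must be finite")
        if np.any(self.fat_fraction < 0) or np.any(self.fat_fraction > 1):
            raise ValueError("fat_fraction must lie in [0, 1]")
        air = self.labels == TISSUE_LABELS["air"]
        if np.any(self.proton_density[air] != 0):
            raise ValueError("air voxels must have zero proton density")
        return self


@dataclass
class CoilSensitivities:
    """Per-coil, per-slice complex sensitivity maps.

    ``maps`` has shape ``(n_coils, n_slices, N, N)``.  ``geometry`` records
    the loop positions (mm, phantom frame) and tilt used to build the maps.
    """

    maps: np.ndarray
    geometry: dict

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        """Root-sum-of-squares magnitude over coils, shape (S, N, N)."""
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


def _ellipse(yy, xx, cy, cx, ry, rx):
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_brain_phantom(
    n_slices: int,
    matrix: int,
    fov_mm: float = 192.0,
    seed: int = 0,
    off_res_rms_hz: float = 12.0,
    slice_thickness_mm: float = 3.0,
) -> Phantom:
    """Generate a deterministic multi-slice brain phantom.

    Contains grey matter, white matter, CSF and a 2–3 voxel subcutaneous fat
    ring (the lipid geometry that drives the chemical-shift ghost), plus a
    smooth off-resonance field and a low-order background phase.  Slice
    outlines shrink away from the mid-slice to mimic a head.

    Deterministic for a fixed ``seed``.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if matrix < 16:
        raise ValueError("matrix must be >= 16")
    rng = np.random.default_rng(seed)
    N = matrix
    yy, xx = np.mgrid[0:N, 0:N].astype(float)
    c = N / 2.0

    S = n_slices
    shape = (S, N, N)
    labels = np.zeros(shape, dtype=np.int8)

    # Head outline shrinks off-centre; mild seeded jitter of the radii.
    z = np.arange(S)
    zc = (S - 1) / 2.0
    zhalf = max(S / 2.0, 1.0)
    scale = np.sqrt(np.clip(1.0 - 0.3 * ((z - zc) / zhalf) ** 2, 0.2, 1.0))
    jit = 1.0 + 0.02 * rng.standard_normal(S)

    for s in range(S):
        r_out = 0.44 * N * scale[s] * jit[s]        # outer fat boundary
        fat_thick = max(2.0, 0.04 * N)              # 2-3 voxel fat ring
        gap = max(1.5, 0.025 * N)                   # signal-free skull gap
        gm_thick = max(2.5, 0.05 * N)
        ry_f = 1.12

        fat_out = _ellipse(yy, xx, c, c, r_out * ry_f, r_out)
        fat_in = _ellipse(yy, xx, c, c, (r_out - fat_thick) * ry_f, r_out - fat_thick)
        brain_out = _ellipse(yy, xx, c, c, (r_out - fat_thick - gap) * ry_f,
                             r_out - fat_thick - gap)
        wm_out = _ellipse(yy, xx, c, c, (r_out - fat_thick - gap - gm_thick) * ry_f,
                          r_out - fat_thick - gap - gm_thick)
        # Ventricles: two small CSF ellipses beside the midline.
        off = 0.06 * N + 0.01 * N * rng.standard_normal()
        csf = _ellipse(yy, xx, c, c - off, 0.10 * N * scale[s], 0.045 * N) | _ellipse(
            yy, xx, c, c + off, 0.10 * N * scale[s], 0.045 * N
        )

        sl = labels[s]
        sl[fat_out & ~fat_in] = TISSUE_LABELS["fat"]
        sl[brain_out] = TISSUE_LABELS["gm"]
        sl[wm_out] = TISSUE_LABELS["wm"]
        sl[csf & wm_out] = TISSUE_LABELS["csf"]

    pd = np.zeros(shape)
    t1 = np.ones(shape)
    t2s = np.ones(shape)
    for name, lab in TISSUE_LABELS.items():
        p, T1, T2s = TISSUE_PARAMS[name]
        sel = labels == lab
        pd[sel] = p
        t1[sel] = T1
        t2s[sel] = T2s
    fat_fraction = (labels == TISSUE_LABELS["fat"]).astype(float)

    # Smooth off-resonance field, RMS-scaled over tissue.
    field = gaussian_filter(rng.standard_normal(shape), sigma=(0, N / 8.0, N / 8.0))
    tissue = labels != TISSUE_LABELS["air"]
    rms = np.sqrt(np.mean(field[tissue] ** 2)) if tissue.any() else 1.0
    off_res = field / max(rms, 1e-12) * off_res_rms_hz

    # Low-order background phase per slice.
    u = (xx - c) / N
    v = (yy - c) / N
    phase = np.zeros(shape)
    for s in range(S):
        a, b, cc = 0.3 * rng.standard_normal(3)
        phase[s] = a * u + b * v + cc * u * v

    slices = pd * np.exp(1j * phase)

    voxel = fov_mm / N
    positions = (z - zc) * slice_thickness_mm
    return Phantom(
        slices=slices.astype(np.complex128),
        proton_density=pd,
        t1=t1,
        t2_star=t2s,
        off_resonance=off_res,
        fat_fraction=fat_fraction,
        labels=labels,
        voxel_size_mm=voxel,
        slice_positions_mm=positions.astype(float),
        fov_mm=fov_mm,
    ).validate()


def make_coil_sensitivities(
    phantom: Phantom,
    n_coils: int,
    tilt_deg: float = 0.0,
    seed: int = 0,
    mode: str = "loops",
    loop_radius_frac: float = 0.25,
    ring_radius_frac: float = 0.55,
) -> CoilSensitivities:
    """Analytic loop-like receive sensitivities around the phantom.

    Loops are distributed azimuthally on two axially staggered rings (and
    optionally tilted about the y axis), so every slice sees a distinct
    sensitivity pattern and the multiband unaliasing problem stays full rank
    for any set of widely spaced slices.  Magnitude falls off as
    ``a^2 / (a^2 + d^2)`` with 3-D distance ``d`` from the loop centre
    (inverse-distance-squared), phase is linear in position with a seeded
    per-coil offset.  Each coil map is normalised to unit mean-square energy
    over the FOV, so tilting redistributes but does not rescale energy.

    ``mode="uniform"`` returns all-ones maps (identity sensitivity).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    S, N = phantom.n_slices, phantom.matrix
    if mode == "uniform":
        maps = np.ones((n_coils, S, N, N), dtype=np.complex128)
        return CoilSensitivities(maps=maps, geometry={"mode": "uniform"})
    if mode != "loops":
        raise ValueError(f"unknown coil mode {mode!r}")

    rng = np.random.default_rng(seed)
    fov = phantom.fov_mm
    r_ring = ring_radius_frac * fov
    a = loop_radius_frac * fov
    tilt = np.deg2rad(tilt_deg)

    zpos = phantom.slice_positions_mm
    zspan = max(zpos.max() - zpos.min(), phantom.voxel_size_mm * 4)

    yy, xx = np.mgrid[0:N, 0:N].astype(float)
    c = N / 2.0
    vox = phantom.voxel_size_mm
    X = (xx - c) * vox
    Y = (yy - c) * vox

    maps = np.empty((n_coils, S, N, N), dtype=np.complex128)
    centers = []
    for k in range(n_coils):
        theta = 2 * np.pi * k / n_coils + 0.05 * rng.standard_normal()
        cx = r_ring * np.cos(theta)
        cy = r_ring * np.sin(theta)
        # Two staggered rings + tilt about y + seeded jitter give z-encoding.
        cz = (
            0.35 * zspan * (1 if k % 2 else -1)
            - cx * np.tan(tilt)
            + 0.15 * zspan * rng.standard_normal()
        )
        centers.append((cx, cy, cz))
        phi0 = 2 * np.pi * rng.random()
        kx, ky = 0.5 * rng.standard_normal(2) / fov
        for s in range(S):
            d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (zpos[s] - cz) ** 2
            mag = a**2 / (a**2 + d2)
            ph = phi0 + 2 * np.pi * (kx * X + ky * Y) + theta
            maps[k, s] = mag * np.exp(1j * ph)
        maps[k] /= np.sqrt(np.mean(np.abs(maps[k]) ** 2))

    sens = CoilSensitivities(
        maps=maps,
        geometry={
            "mode": "loops",
            "tilt_deg": float(tilt_deg),
            "centers_mm": centers,
            "loop_radius_mm": float(a),
        },
    )
    rss = sens.rss()
    if np.any(rss[phantom.tissue_mask] <= 0):
        raise ValueError("coil maps vanish on tissue voxels")
    return sens
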