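"""Quantify the cost of acceleration: g-factor, SNR and residual aliasing.

The g-factor is the spatially varying noise-amplification penalty of
coil-encoded unaliasing (g = 1 means none).  For a set of aliased voxel
positions (the slices of a multiband group crossed with the phase-encode
folds of the in-plane reduction R), the encoding matrix E stacks the coil
sensitivities at those positions and, with identity noise covariance,

    g_j = sqrt( [(E^H E)^{-1}]_jj * [E^H E]_jj ).

A Monte-Carlo pseudo-replica estimate through any reconstruction function is
provided as an independent check, together with ROI SNR, the
1/(g * sqrt(R1 R2)) undersampling law, and slice-leakage measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GFactorMap",
    "analytic_g_factor",
    "sense_separate",
    "pseudo_replica_g",
    "snr_roi",
    "undersampling_snr_law",
    "residual_aliasing",
]


@dataclass
class GFactorMap:
    """Per-voxel g values for the slices of one aliased group."""

    g: np.ndarray                 # (n_slices_in_group, N, N); inf where singular
    method: str                   # "analytic" | "pseudo_replica"
    mb_group: tuple
    r_pe: int
    diagnostics: dict = field(default_factory=dict)

    def summary(self, mask: np.ndarray | None = None) -> dict:
        """Mean/max g over the mask (or over all finite voxels)."""
        sel = np.isfinite(self.g)
        if mask is not None:
            sel &= mask
        vals = self.g[sel]
        return {"mean": float(vals.mean()), "max": float(vals.max()), "n": int(vals.size)}


def _aliased_sets(N: int, r_pe: int):
    """Yield (y0, folds) with folds the R phase-encode positions aliasing onto y0."""
    if N % r_pe:
        raise ValueError("matrix must be divisible by r_pe")
    step = N // r_pe
    for y0 in range(step):
        yield y0, [(y0 + k * step) % N for k in range(r_pe)]


def analytic_g_factor(
    coils,
    mb_group: tuple,
    r_pe: int = 1,
    support: np.ndarray | None = None,
    cond_limit: float = 1e8,
) -> GFactorMap:
    """SENSE-form g-factor for a multiband group with in-plane reduction.

    ``coils`` provides per-slice maps ``(C, S, N, N)``; ``support`` (S, N, N)
    restricts the aliased sets to voxels carrying signal (positions outside
    the support drop out of the encoding matrix).  Rank-deficient sets are
    reported as infinite g with a diagnostic count.
    """
    maps = coils.maps
    C, _, N, _ = maps.shape
    g = np.full((len(mb_group), N, N), np.nan)
    singular = 0
    for x in range(N):
        for y0, folds in _aliased_sets(N, r_pe):
            pos = [(si, s, y) for si, s in enumerate(mb_group) for y in folds]
            if support is not None:
                pos = [p for p in pos if support[p[1], p[2], x]]
            if not pos:
                continue
            E = np.stack([maps[:, s, y, x] for _, s, y in pos], axis=1)  # (C, P)
            M = E.conj().T @ E
            Mjj = np.diag(M).real
            if (
                E.shape[0] < E.shape[1]
                or np.linalg.cond(M) > cond_limit
                or np.any(Mjj <= 0)
            ):
                for si, _, y in pos:
                    g[si, y, x] = np.inf
                singular += 1
                continue
            Minv = np.linalg.inv(M)
            vals = np.sqrt(np.maximum(np.diag(Minv).real * Mjj, 0.0))
            for (si, _, y), v in zip(pos, vals):
                g[si, y, x] = v
    return GFactorMap(
        g=g,
        method="analytic",
        mb_group=tuple(mb_group),
        r_pe=r_pe,
        diagnostics={"singular_sets": singular},
    )


def sense_separate(
    composite_coil_images: np.ndarray,
    coils,
    mb_group: tuple,
    r_pe: int = 1,
) -> np.ndarray:
    """Least-squares (SENSE) unaliasing of composite coil images.

    ``composite_coil_images`` is ``(C, Ny, N)`` with ``Ny = N / r_pe`` (the
    reduced-FOV image for in-plane undersampling, the full matrix for pure
    multiband).  Solves the per-voxel encoding system and returns per-slice
    images ``(n_slices, N, N)``.  This estimator's analytic noise
    amplification is exactly the SENSE g-factor, which makes it the natural
    cross-check for :func:`pseudo_replica_g`.
    """
    maps = coils.maps
    C, _, N, _ = maps.shape
    Ny = composite_coil_images.shape[1]
    if Ny * r_pe != N:
        raise ValueError("composite image height must be matrix / r_pe")
    out = np.zeros((len(mb_group), N, N), dtype=np.complex128)
    for x in range(N):
        for y0, folds in _aliased_sets(N, r_pe):
            pos = [(si, s, y) for si, s in enumerate(mb_group) for y in folds]
            E = np.stack([maps[:, s, y, x] for _, s, y in pos], axis=1)
            rhs = composite_coil_images[:, y0 % Ny, x]
            sol, *_ = np.linalg.lstsq(E, rhs, rcond=None)
            for (si, _, y), v in zip(pos, sol):
                out[si, y, x] = v
    return out


def pseudo_replica_g(
    recon_fn,
    reference_fn,
    noise_shape: tuple,
    n_reps: int = 100,
    seed: int = 0,
    undersampling: float = 1.0,
    sigma: float = 1.0,
) -> GFactorMap:
    """Monte-Carlo g map from noise-only pseudo replicas.

    Draws ``n_reps`` circular complex Gaussian noise realisations of
    ``noise_shape``, pushes each through the accelerated reconstruction
    ``recon_fn`` and the unaccelerated ``reference_fn`` (both mapping a noise
    array to per-slice images), and forms

        g = (std_accelerated / std_reference) / sqrt(undersampling)

    voxelwise, where ``undersampling`` is the k-space sample-count ratio per
    image (``R_pe``; pure multiband shares all lines, so 1).  Fewer than 30
    replicas is recorded as a warning in the diagnostics.
    """
    rng = np.random.default_rng(seed)
    acc, ref = [], []
    for _ in range(n_reps):
        noise = sigma * (
            rng.standard_normal(noise_shape) + 1j * rng.standard_normal(noise_shape)
        )
        acc.append(recon_fn(noise))
        ref.append(reference_fn(noise))
    acc = np.stack(acc)
    ref = np.stack(ref)
    std_a = acc.std(axis=0)
    std_r = ref.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = std_a / std_r / np.sqrt(undersampling)
    diag = {"n_reps": n_reps}
    if n_reps < 30:
        diag["warning"] = "n_reps < 30: pseudo-replica estimate is unstable"
    return GFactorMap(
        g=g, method="pseudo_replica", mb_group=(), r_pe=int(round(undersampling)),
        diagnostics=diag,
    )


def snr_roi(image: np.ndarray, tissue_mask: np.ndarray, air_mask: np.ndarray) -> float:
    """ROI SNR: mean signal over the tissue mask divided by mean over air."""
    if not tissue_mask.any() or not air_mask.any():
        raise ValueError("tissue and air masks must be non-empty")
    if np.any(tissue_mask & air_mask):
        raise ValueError("tissue and air masks must be disjoint")
    return float(image[tissue_mask].mean() / image[air_mask].mean())


def undersampling_snr_law(r1: float, r2: float, g):
    """Relative SNR of a (R1 x R2)-undersampled acquisition: 1/(g sqrt(R1 R2)).

    ``g`` may be a scalar or an array of per-voxel values.
    """
    if r1 < 1 or r2 < 1:
        raise ValueError("reduction factors must be >= 1")
    g = np.asarray(g, dtype=float)
    if np.any(g < 1):
        raise ValueError("g must be >= 1")
    out = 1.0 / (g * np.sqrt(r1 * r2))
    return out if out.ndim else float(out)


def residual_aliasing(recon_slices: np.ndarray, truth_slices: np.ndarray):
    """Per-slice separation error and inter-slice leakage matrix.

    Returns ``(rel_err, leakage)``: ``rel_err[s]`` is the normalised L2
    difference of reconstructed versus true slice magnitudes.  Each
    reconstructed slice is then decomposed by least squares onto the set of
    true slice patterns; ``leakage[i, j]`` is the energy fraction of
    reconstructed slice ``j`` carried by true slice ``i``'s pattern, so a
    perfect separation has a (near-)identity diagonal and an unseparated
    composite shows every slice's energy ratio in every column.
    """
    recon_slices = np.asarray(recon_slices)
    truth_slices = np.asarray(truth_slices)
    if recon_slices.shape != truth_slices.shape:
        raise ValueError("recon and truth slice stacks must have matching shapes")
    S = recon_slices.shape[0]
    rel_err = np.array(
        [
            np.linalg.norm(np.abs(recon_slices[s]) - np.abs(truth_slices[s]))
            / max(np.linalg.norm(truth_slices[s]), 1e-30)
            for s in range(S)
        ]
    )
    T = np.stack([np.abs(truth_slices[i]).ravel() for i in range(S)], axis=1)  # (V, S)
    R = np.stack([np.abs(recon_slices[j]).ravel() for j in range(S)], axis=1)
    coef, *_ = np.linalg.lstsq(T, R, rcond=None)              # (S_truth, S_recon)
    t_norm2 = (T**2).sum(axis=0)
    r_norm2 = np.maximum((R**2).sum(axis=0), 1e-30)
    leakage = (np.abs(coef) ** 2) * t_norm2[:, None] / r_norm2[None, :]
    return rel_err, leakage
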