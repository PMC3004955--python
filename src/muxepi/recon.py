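"""Reconstruction of multiplexed EPI: invert the acquisition stage by stage.

Pipeline (temporal separation before coil-based separation):

1. :func:`demux_sir` — split each readout into its ``m`` SIR sub-readouts
   (an exact bijection, noise included).
2. :func:`apply_mb_separation` — k-space projection kernel, calibrated by
   least squares from the *sum* of single-band slices over a 7x7
   neighbourhood of all coils, mapping the multiband composite to each
   single-slice, single-coil k-space.
3. :func:`inplane_unalias` — GRAPPA-style synthesis of the phase-encode
   lines skipped by the in-plane reduction factor.
4. :func:`partial_fourier_fill` — zero-fill (default) or conjugate-symmetry
   completion of the unsampled early lines.
5. 2D FT and root-sum-of-squares coil combination.

All kernel fits share one regularised least-squares solver (Tikhonov on the
normal equations, relative to the trace).  Kernels are applied on the
compact lattice of acquired lines (spacing ``R_pe``), so calibration and
target data always live on the same grid; the multiband kernel wraps around
the (periodic) k-space edges, the in-plane kernel zero-pads outside the
acquired band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .forward import acquired_lines, ifft2c, interleave_sir

__all__ = [
    "MbKernel",
    "InplaneKernel",
    "ReconResult",
    "demux_sir",
    "calibrate_mb_kernel",
    "apply_mb_separation",
    "calibrate_inplane_kernel",
    "inplane_unalias",
    "partial_fourier_fill",
    "rss_combine",
    "reconstruct",
]


def _solve_reg_lstsq(A: np.ndarray, B: np.ndarray, reg: float) -> np.ndarray:
    """Least squares ``min ||A W - B||`` via Tikhonov-regularised normal equations.

    ``lambda = reg * trace(A^H A) / n_unknowns`` keeps the penalty scale
    relative to the data; singular systems are thereby always solvable.
    ``reg = 0`` falls back to an SVD-based minimum-norm solution.
    """
    if reg <= 0:
        sol, *_ = np.linalg.lstsq(A, B, rcond=None)
        return sol
    G = A.conj().T @ A
    # The tiny absolute floor keeps all-zero calibration (empty slice) solvable.
    lam = reg * np.trace(G).real / G.shape[0] + 1e-30
    G.flat[:: G.shape[0] + 1] += lam
    return np.linalg.solve(G, A.conj().T @ B)


def demux_sir(mux) -> list[np.ndarray]:
    """Separate the interleaved readout into per-SIR-slot composite k-spaces.

    Slot ``j`` receives exactly the samples acquired in sub-period ``j`` of
    every readout (odd-echo polarity reversal undone first).  Returns a
    length-``m`` list of arrays ``(n_shots, n_coils, n_echoes, matrix)``;
    bit-exact inverse of :func:`muxepi.forward.interleave_sir`.
    """
    mux.validate()
    m, N = mux.spec.m, mux.matrix
    data = mux.data
    if mux.polarity_flip:
        data = data.copy()
        data[..., 1::2, :] = data[..., 1::2, ::-1]
    return [data[..., j * N : (j + 1) * N] for j in range(m)]


@dataclass
class MbKernel:
    """GRAPPA-type projection operator separating a multiband composite.

    ``weights[s, c]`` maps a ``kernel_size x kernel_size`` multi-coil
    neighbourhood of the summed (composite) k-space to the centre point of
    target slice ``s``, coil ``c``.
    """

    weights: np.ndarray          # (n_slices, n_coils, n_coils, k, k)
    group: tuple
    kernel_size: int
    regularization: float
    fit_residual: np.ndarray     # (n_slices, n_coils) relative residuals
    calibration_descriptor: str = ""

    def validate(self) -> "MbKernel":
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")
        return self


def _patch_matrix(compact: np.ndarray, k: int) -> np.ndarray:
    """Interior sliding-window patches of a (C, L, N) compact k-space.

    Returns ``(n_patches, C * k * k)`` with patch centres on the fully
    interior region.
    """
    win = sliding_window_view(compact, (k, k), axis=(1, 2))   # (C, L-k+1, N-k+1, k, k)
    win = np.moveaxis(win, 0, 2)                              # (L', N', C, k, k)
    return win.reshape(-1, compact.shape[0] * k * k)


def calibrate_mb_kernel(
    singleband: dict,
    group: tuple,
    r_pe: int = 1,
    kernel_size: int = 7,
    reg: float = 1e-6,
) -> MbKernel:
    """Fit the multiband separation kernel from single-band calibration.

    ``singleband`` maps slice index to its fully sampled ``(C, N, N)``
    k-space.  The slices of ``group`` are summed (in k-space; equivalent to
    an image-domain sum by linearity) to form the composite the kernel will
    see, sub-sampled onto the compact ``R_pe`` lattice.  For every target
    (slice, coil), a least-squares fit maps sliding ``kernel_size`` square
    multi-coil patches of the summed calibration to the single-slice,
    single-coil centre point.  Under-determined fits are rejected.
    """
    if kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd")
    for s in group:
        if s not in singleband:
            raise ValueError(f"calibration does not cover slice {s}")
    ref = singleband[group[0]]
    C, N = ref.shape[0], ref.shape[-1]
    cal_lines = acquired_lines(N, r_pe, 1.0)
    comp = sum(singleband[s] for s in group)[:, cal_lines, :]
    k = kernel_size
    hw = k // 2
    A = _patch_matrix(comp, k)
    if A.shape[0] < A.shape[1]:
        raise ValueError(
            f"under-determined kernel fit: {A.shape[0]} patches for {A.shape[1]} unknowns"
        )
    # Targets ordered (slice, coil), matching the weight layout below.
    cols = []
    for s in group:
        sub = singleband[s][:, cal_lines, :][:, hw : comp.shape[1] - hw, hw : N - hw]
        cols.append(sub.reshape(C, -1).T)                    # (n_pat, C)
    B = np.concatenate(cols, axis=1)                         # (n_pat, n_s * C)
    W = _solve_reg_lstsq(A, B, reg)
    resid = np.linalg.norm(A @ W - B, axis=0) / np.maximum(
        np.linalg.norm(B, axis=0), 1e-30
    )
    weights = W.T.reshape(len(group), C, C, k, k)
    return MbKernel(
        weights=weights,
        group=tuple(group),
        kernel_size=k,
        regularization=reg,
        fit_residual=resid.reshape(len(group), C),
        calibration_descriptor=f"sum of single-band slices {tuple(group)}, R={r_pe}",
    ).validate()


def apply_mb_separation(composite: np.ndarray, kernel: MbKernel) -> np.ndarray:
    """Separate a composite compact k-space into per-slice per-coil k-spaces.

    ``composite`` is ``(C, L, N)`` on the compact acquired-line lattice; the
    kernel slides over the periodically extended array (the DFT of a
    discretely sampled object is periodic, so wrap-around is the faithful
    boundary), and output size equals input size.  Returns
    ``(n_slices, C, L, N)``.
    """
    n_s, C = kernel.weights.shape[:2]
    k = kernel.kernel_size
    hw = k // 2
    if composite.shape[0] != C:
        raise ValueError("coil count mismatch between composite and kernel")
    padded = np.pad(composite, ((0, 0), (hw, hw), (hw, hw)), mode="wrap")
    A = _patch_matrix(padded, k)                             # (L * N, C k k)
    W = kernel.weights.reshape(n_s * C, -1).T                # (C k k, n_s * C)
    out = (A @ W).T.reshape(n_s, C, *composite.shape[1:])
    return out


@dataclass
class InplaneKernel:
    """GRAPPA kernel synthesising skipped phase-encode lines (one per offset)."""

    weights: dict                 # offset d -> (C src*lines*kx, C)
    r_pe: int
    src_dy: dict                  # offset d -> source line offsets rel. target
    kx_offsets: np.ndarray
    regularization: float


def calibrate_inplane_kernel(
    calib: np.ndarray,
    r_pe: int,
    n_src_lines: int = 4,
    kx_half: int = 1,
    reg: float = 1e-4,
) -> InplaneKernel:
    """Fit per-offset GRAPPA kernels from a fully sampled calibration k-space.

    For each missing-line offset ``d`` (1..R-1), ``n_src_lines`` acquired
    neighbours (spacing ``R_pe``) and a ``2*kx_half+1`` readout neighbourhood
    over all coils predict the missing point, via the shared least-squares
    solver.
    """
    if r_pe < 1:
        raise ValueError("r_pe must be >= 1")
    C, Ny, Nx = calib.shape
    kxs = np.arange(-kx_half, kx_half + 1)
    weights, src_dy = {}, {}
    for d in range(1, r_pe):
        dys = -d + r_pe * np.arange(-(n_src_lines // 2 - 1), n_src_lines // 2 + 1)
        yts = np.arange(max(0, -dys.min()), Ny - max(0, dys.max()))
        xs = np.arange(kx_half, Nx - kx_half)
        if len(yts) * len(xs) < C * len(dys) * len(kxs):
            raise ValueError("insufficient calibration lines for in-plane kernel")
        # A: (n_pat, C * n_src * n_kx); B: (n_pat, C)
        src = np.stack(
            [
                calib[:, yts[:, None] + dy, xs[None, :] + kx]
                for dy in dys
                for kx in kxs
            ],
            axis=1,
        )                                                    # (C, S*K, n_yt, n_x)
        A = src.reshape(C * len(dys) * len(kxs), -1).T
        B = calib[:, yts[:, None], xs[None, :]].reshape(C, -1).T
        weights[d] = _solve_reg_lstsq(A, B, reg)
        src_dy[d] = dys
    return InplaneKernel(
        weights=weights, r_pe=r_pe, src_dy=src_dy, kx_offsets=kxs, regularization=reg
    )


def inplane_unalias(
    kspace_full: np.ndarray,
    lines: np.ndarray,
    kernel: InplaneKernel | None,
    r_pe: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesise the skipped phase-encode lines inside the acquired band.

    ``kspace_full`` is ``(C, N, N)`` with acquired rows (``lines``) filled and
    everything else zero.  ``R_pe = 1`` is the identity.  Returns the filled
    k-space and the boolean mask of now-valid lines.
    """
    C, Ny, Nx = kspace_full.shape
    filled = np.zeros(Ny, dtype=bool)
    filled[lines] = True
    if r_pe == 1:
        return kspace_full, filled
    if kernel is None:
        raise ValueError("in-plane unaliasing with R > 1 requires a kernel")
    out = kspace_full.copy()
    lo, hi = int(lines.min()), int(lines.max())
    kxs = kernel.kx_offsets
    pad = np.pad(out, ((0, 0), (0, 0), (kxs.max(), kxs.max())))
    start = lo
    # The sampled band's lattice extends r_pe - 1 rows past the last acquired
    # line; rows below `lo` are the partial-Fourier region and stay unfilled.
    for yt in range(lo, min(Ny, hi + r_pe)):
        if filled[yt]:
            continue
        d = (yt - start) % r_pe
        dys = kernel.src_dy[d]
        blocks = np.zeros((C, len(dys) * len(kxs), Nx), dtype=out.dtype)
        idx = 0
        for dy in dys:
            y = yt + dy
            for kx in kxs:
                if 0 <= y < Ny:
                    blocks[:, idx, :] = pad[:, y, kxs.max() + kx : kxs.max() + kx + Nx]
                idx += 1
        A = blocks.reshape(C * len(dys) * len(kxs), Nx).T   # (Nx, C*S*K)
        out[:, yt, :] = (A @ kernel.weights[d]).T
        filled[yt] = True
    return out, filled


def partial_fourier_fill(
    kspace: np.ndarray, filled: np.ndarray, mode: str = "zero"
) -> np.ndarray:
    """Complete the unsampled partial-Fourier lines.

    ``mode="zero"`` leaves them at zero (default); ``mode="conj"`` uses
    Hermitian symmetry ``k(-ky, -kx) = conj(k(ky, kx))`` — exact for a real
    object.  ``filled`` flags the valid lines; a fully sampled input is
    returned unchanged.
    """
    if mode not in ("zero", "conj"):
        raise ValueError(f"unknown partial-Fourier mode {mode!r}")
    if mode == "zero" or filled.all():
        return kspace
    Ny = kspace.shape[-2]
    idx = np.arange(Ny)
    mirror_y = (Ny - idx) % Ny
    mirror_x = (kspace.shape[-1] - np.arange(kspace.shape[-1])) % kspace.shape[-1]
    mirrored = np.conj(kspace[..., mirror_y, :][..., :, mirror_x])
    out = kspace.copy()
    missing = ~filled & filled[mirror_y]
    out[..., missing, :] = mirrored[..., missing, :]
    return out


def rss_combine(coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares magnitude combination over the leading coil axis."""
    return np.sqrt((np.abs(coil_images) ** 2).sum(axis=0))


@dataclass
class ReconResult:
    """Per-slice coil images, combined magnitudes and provenance."""

    coil_images: dict             # slice -> (C, N, N) complex
    combined: np.ndarray          # (n_slices, N, N) magnitude, slice order
    slice_order: list
    metadata: dict = field(default_factory=dict)
    rmse: dict | None = None

    def validate(self) -> "ReconResult":
        if np.any(self.combined < 0):
            raise ValueError("combined magnitude must be non-negative")
        return self


def reconstruct(
    mux,
    calib: dict,
    pf_mode: str = "zero",
    reg: float = 1e-6,
    inplane_reg: float = 1e-4,
    truth: dict | None = None,
) -> ReconResult:
    """Full pipeline: demux -> MB separation -> in-plane fill -> pf -> FT -> RSS.

    ``calib`` maps every excited slice to its fully sampled single-band
    ``(C, N, N)`` k-space (see :func:`muxepi.forward.simulate_singleband`).
    Emits ``m * n`` slices per shot.  When ``truth`` supplies reference
    magnitude images, per-slice relative RMSE is reported.
    """
    spec = mux.spec
    N = mux.matrix
    r = spec.r_pe
    try:
        slots = demux_sir(mux)
    except ValueError as err:
        raise ValueError(f"demux_sir: {err}") from err

    kernels: dict = {}
    inplane_kernels: dict = {}
    coil_images: dict = {}
    for si, shot in enumerate(mux.mb_groups):
        for j, group in enumerate(shot):
            compact = slots[j][si]                          # (C, L, N)
            if len(group) > 1:
                if group not in kernels:
                    try:
                        kernels[group] = calibrate_mb_kernel(
                            calib, group, r_pe=r, reg=reg
                        )
                    except ValueError as err:
                        raise ValueError(f"calibrate_mb_kernel: {err}") from err
                separated = apply_mb_separation(compact, kernels[group])
            else:
                separated = compact[None]
            for k_s, sl in enumerate(group):
                full = np.zeros((separated.shape[1], N, N), dtype=np.complex128)
                full[:, mux.lines, :] = separated[k_s]
                if r > 1 and sl not in inplane_kernels:
                    try:
                        inplane_kernels[sl] = calibrate_inplane_kernel(
                            calib[sl], r, reg=inplane_reg
                        )
                    except ValueError as err:
                        raise ValueError(f"calibrate_inplane_kernel: {err}") from err
                filled_k, filled = inplane_unalias(
                    full, mux.lines, inplane_kernels.get(sl), r
                )
                filled_k = partial_fourier_fill(filled_k, filled, mode=pf_mode)
                coil_images[sl] = ifft2c(filled_k)

    order = sorted(coil_images)
    combined = np.stack([rss_combine(coil_images[s]) for s in order])
    rmse = None
    if truth is not None:
        rmse = {
            s: float(
                np.linalg.norm(rss_combine(coil_images[s]) - np.abs(truth[s]))
                / max(np.linalg.norm(truth[s]), 1e-30)
            )
            for s in order
            if s in truth
        }
    return ReconResult(
        coil_images=coil_images,
        combined=combined,
        slice_order=order,
        metadata={
            "pf_mode": pf_mode,
            "reg": reg,
            "kernel_groups": sorted(kernels),
            "r_pe": r,
        },
        rmse=rmse,
    ).validate()
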