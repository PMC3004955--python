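"""Forward simulation of the multiplexed EPI acquisition.

The simulator renders each echo of the EPI train as the Fourier line of the
instantaneous object: per-voxel steady-state amplitude from the Bloch
steady state, off-resonance and chemical-shift phase evolving along the
train, optional T2* decay, multiband summation through the coil maps, SIR
temporal interleaving within each readout, in-plane undersampling, partial
Fourier, alternating readout polarity, and circular complex Gaussian noise.

This is a discrete-object Fourier simulation (FT of the voxelised phantom):
acceptance is parameter/structure recovery and noise injection breaks exact
inversion, so a continuous analytic k-space model is not needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timing import (
    FAT_SHIFT_PPM,
    GAMMA_BAR_HZ_PER_T,
    ProtocolSpec,
    ProtocolError,
    echo_spacing,
    fat_displacement,
)

__all__ = [
    "steady_state_signal",
    "ernst_angle",
    "se_fat_overlap",
    "acquired_lines",
    "slice_groups",
    "fft2c",
    "ifft2c",
    "MuxKSpace",
    "interleave_sir",
    "simulate_mux_acquisition",
    "simulate_singleband",
    "simulate_fmri_series",
]


def steady_state_signal(t1, tr, flip_deg):
    """Spoiled gradient-echo steady-state signal, relative units in (0, 1].

    ``S = sin(a) (1 - E1) / (1 - cos(a) E1)`` with ``E1 = exp(-TR/T1)``.
    Vectorised over any argument.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if np.any(np.asarray(tr) <= 0):
        raise ValueError("TR must be positive")
    flip = np.deg2rad(flip_deg)
    if np.any(flip <= 0) or np.any(flip > np.pi):
        raise ValueError("flip angle must lie in (0, 180] degrees")
    e1 = np.exp(-np.asarray(tr) / t1)
    out = np.sin(flip) * (1.0 - e1) / (1.0 - np.cos(flip) * e1)
    return out if out.ndim else float(out)


def ernst_angle(t1: float, tr: float) -> float:
    """Flip angle (degrees) maximising the spoiled steady-state signal."""
    return float(np.rad2deg(np.arccos(np.exp(-tr / t1))))


def se_fat_overlap(spec: ProtocolSpec, delta_ppm: float = FAT_SHIFT_PPM) -> float:
    """Fraction of the excited fat slice refocused in a spin-echo shot.

    The excitation pulse (gradient ``gs_exc``, slab width = slice thickness)
    excites fat displaced by ``D_exc``; the SIR refocusing pulse uses an
    m-times weaker gradient, so its slab is m times wider and its fat band is
    displaced ``m`` times further.  Fat signal survives only where the two
    chemically shifted slabs overlap — for large ``m * D`` the bands separate
    and fat leaves the imaging slab entirely (inherent fat suppression).
    Gradient-echo sequences have no refocusing pulse: returns 1.
    """
    if spec.sequence_type != "spin-echo":
        return 1.0
    d_exc = fat_displacement(delta_ppm, spec.b0, spec.gs_exc)
    d_ref = fat_displacement(delta_ppm, spec.b0, spec.gs_refocus_eff)
    w_exc = spec.slice_thickness_mm
    w_ref = w_exc * spec.gs_exc / spec.gs_refocus_eff
    lo = max(d_exc - w_exc / 2, d_ref - w_ref / 2)
    hi = min(d_exc + w_exc / 2, d_ref + w_ref / 2)
    return float(np.clip(hi - lo, 0.0, w_exc) / w_exc)


def acquired_lines(matrix: int, r_pe: int, pf: float) -> np.ndarray:
    """Acquired phase-encode line indices for (R, partial-Fourier) sampling.

    Partial Fourier skips the early lines (asymmetric echo); the remaining
    band is sampled every ``r_pe`` lines, aligned so the DC line
    (``matrix // 2``) is always acquired.
    """
    if not (0.0 < pf <= 1.0):
        raise ProtocolError("pf must lie in (0, 1]")
    if r_pe < 1:
        raise ProtocolError("r_pe must be >= 1")
    start = int(round((1.0 - pf) * matrix))
    start += (matrix // 2 - start) % r_pe
    lines = np.arange(start, matrix, r_pe)
    if matrix // 2 not in lines:
        raise ProtocolError("sampling pattern misses the DC line")
    return lines


def slice_groups(n_slices: int, m: int, n: int) -> list[list[tuple[int, ...]]]:
    """Slice ordering: ``groups[shot][sir_slot] = tuple of MB slice indices``.

    Slices within one multiband excitation are ``n_slices / n`` apart (widely
    spaced, to maximise coil-sensitivity differences); the ``m`` SIR slots of
    one shot excite adjacent slices.
    """
    if n_slices % (m * n):
        raise ProtocolError(f"n_slices={n_slices} not divisible by m*n={m * n}")
    stride = n_slices // n
    shots = n_slices // (m * n)
    return [
        [tuple(shot * m + j + k * stride for k in range(n)) for j in range(m)]
        for shot in range(shots)
    ]


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centred 2D FFT (DC at ``matrix // 2``) over the last two axes."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1))), axes=(-2, -1))


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1))), axes=(-2, -1))


@dataclass
class MuxKSpace:
    """The acquired multiplexed k-space object the reconstruction inverts.

    ``data`` has shape ``(n_shots, n_coils, n_echoes, m * matrix)``: each
    echo's sample vector holds the ``m`` SIR sub-readouts in temporal order
    (sub-readout ``j`` at samples ``[j*matrix : (j+1)*matrix]``), with the
    whole vector reversed on odd echoes when ``polarity_flip`` is set.
    """

    data: np.ndarray
    lines: np.ndarray                       # acquired phase-encode indices
    mb_groups: list                         # [shot][slot] -> slice tuple
    spec: ProtocolSpec
    noise_sigma: float = 0.0
    polarity_flip: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def matrix(self) -> int:
        return self.data.shape[-1] // self.spec.m

    @property
    def n_echoes(self) -> int:
        return self.data.shape[2]

    def validate(self) -> "MuxKSpace":
        m = self.spec.m
        if self.data.shape[-1] != m * self.matrix:
            raise ValueError("sample count per echo must equal m * matrix")
        if self.data.shape[2] != len(self.lines):
            raise ValueError("echo count does not match acquired-line list")
        flat = [s for shot in self.mb_groups for slot in shot for s in slot]
        if len(flat) != len(set(flat)):
            raise ValueError("mb_groups overlap: a slice is excited twice")
        return self


def interleave_sir(slots: list[np.ndarray], polarity_flip: bool = True) -> np.ndarray:
    """Interleave per-SIR-slot sample blocks into readout order.

    ``slots`` is a length-``m`` list of arrays ``(..., n_echoes, matrix)``;
    the result is ``(..., n_echoes, m * matrix)`` with odd echoes reversed
    when ``polarity_flip``.  Exact inverse of :func:`muxepi.recon.demux_sir`.
    """
    out = np.concatenate(slots, axis=-1)
    if polarity_flip:
        out = out.copy()
        out[..., 1::2, :] = out[..., 1::2, ::-1]
    return out


def _encode_lines(terms, lines, taus, spec, modulate):
    """FT the object line by line.

    ``terms`` is a list of ``(coil_images (C,N,N), freq_map (N,N) Hz,
    r2s_map (N,N) 1/s)`` contributions (water, fat).  Returns ``(C, L, N)``.
    When ``modulate`` is false a single FFT per coil is used (no per-line
    phase/decay).
    """
    C = terms[0][0].shape[0]
    N = terms[0][0].shape[-1]
    L = len(lines)
    out = np.zeros((C, L, N), dtype=np.complex128)
    if not modulate:
        total = sum(t[0] for t in terms)
        ksp = fft2c(total)
        out[:] = ksp[:, lines, :]
        return out
    for imgs, freq, r2s in terms:
        w = 2j * np.pi * freq - r2s
        for e, tau in enumerate(taus):
            mod = np.exp(w * tau)
            out[:, e, :] += fft2c(imgs * mod)[:, lines[e], :]
    return out


def _composite_terms(phantom, coils, spec, group, off_resonance, t2star_decay, fat):
    """Water/fat coil-weighted composite images for one MB slice group."""
    amp = steady_state_signal(phantom.t1, spec.tr, spec.flip_deg)
    fat_amp = se_fat_overlap(spec) if fat else 1.0
    d_fat = -FAT_SHIFT_PPM * 1e-6 * GAMMA_BAR_HZ_PER_T * spec.b0  # Hz, fat below water
    terms = []
    for sl in group:
        img = phantom.slices[sl] * amp[sl]
        ff = phantom.fat_fraction[sl] if fat else np.zeros_like(phantom.proton_density[sl])
        water = coils.maps[:, sl] * (img * (1.0 - ff))
        freq = phantom.off_resonance[sl] if off_resonance else np.zeros_like(ff)
        r2s = 1.0 / phantom.t2_star[sl] if t2star_decay else np.zeros_like(ff)
        terms.append((water, freq, r2s))
        if fat and ff.any():
            fimg = coils.maps[:, sl] * (img * ff * fat_amp)
            terms.append((fimg, freq + d_fat, r2s))
    return terms


def simulate_mux_acquisition(
    phantom,
    coils,
    spec: ProtocolSpec,
    seed: int = 0,
    noise_sigma: float = 0.0,
    off_resonance: bool = True,
    t2star_decay: bool = True,
    fat: bool = True,
    sir_te_offset: float = 0.0,
    polarity_flip: bool = True,
) -> MuxKSpace:
    """Simulate one multiplexed EPI acquisition of the whole phantom.

    Each shot excites ``m * n`` slices (see :func:`slice_groups`); each echo
    of SIR slot ``j`` is the Fourier line of the coil-weighted sum of that
    slot's ``n`` slices, with per-voxel steady-state amplitude, off-resonance
    and fat chemical-shift phase accrued along the train, optional T2*
    decay, and circular complex Gaussian noise of per-component standard
    deviation ``noise_sigma`` added to every acquired sample of every coil.
    """
    spec.validate()
    N = phantom.matrix
    if spec.matrix != N:
        raise ValueError(f"spec matrix {spec.matrix} != phantom matrix {N}")
    if coils.maps.shape[1:] != (phantom.n_slices, N, N):
        raise ValueError("coil maps do not match phantom geometry")
    if phantom.n_slices % (spec.m * spec.n):
        raise ValueError("phantom slices not divisible by m * n")

    groups = slice_groups(phantom.n_slices, spec.m, spec.n)
    lines = acquired_lines(N, spec.r_pe, spec.pf)
    esp = echo_spacing(spec)
    e_dc = int(np.searchsorted(lines, N // 2))
    C = coils.n_coils
    modulate = off_resonance or t2star_decay or (fat and phantom.fat_fraction.any())

    rng = np.random.default_rng(seed)
    data = np.empty((len(groups), C, len(lines), spec.m * N), dtype=np.complex128)
    for si, shot in enumerate(groups):
        slot_ksp = []
        for j, group in enumerate(shot):
            taus = (np.arange(len(lines)) - e_dc) * esp + (j - (spec.m - 1) / 2) * sir_te_offset
            terms = _composite_terms(
                phantom, coils, spec, group, off_resonance, t2star_decay, fat
            )
            slot_ksp.append(_encode_lines(terms, lines, taus, spec, modulate))
        data[si] = interleave_sir(slot_ksp, polarity_flip)

    if noise_sigma > 0:
        data += noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    return MuxKSpace(
        data=data,
        lines=lines,
        mb_groups=groups,
        spec=spec,
        noise_sigma=noise_sigma,
        polarity_flip=polarity_flip,
        meta={"seed": seed, "sir_te_offset": sir_te_offset},
    ).validate()


def simulate_singleband(
    phantom,
    coils,
    spec: ProtocolSpec,
    slices=None,
    off_resonance: bool = True,
    t2star_decay: bool = True,
    fat: bool = True,
) -> dict[int, np.ndarray]:
    """Fully sampled single-band calibration k-spaces, one per slice.

    Matched SIR timing (echo spacing of ``spec``) with a single-slice,
    single-band excitation and no in-plane undersampling — the calibration
    scan the multiband kernel is trained on.  Returns ``{slice: (C, N, N)}``.
    """
    spec.validate()
    N = phantom.matrix
    lines = np.arange(N)
    esp = echo_spacing(spec)
    taus = (lines - N // 2) * esp
    modulate = off_resonance or t2star_decay or (fat and phantom.fat_fraction.any())
    out = {}
    for sl in slices if slices is not None else range(phantom.n_slices):
        terms = _composite_terms(
            phantom, coils, spec, (sl,), off_resonance, t2star_decay, fat
        )
        out[sl] = _encode_lines(terms, lines, taus, spec, modulate)
    return out


def simulate_fmri_series(
    phantom,
    spec: ProtocolSpec,
    rsn_truth,
    seed: int = 0,
    n_volumes: int | None = None,
    slice_duty: float = 0.9,
):
    """Synthetic 4D magnitude resting-state series with known ground truth.

    ``series[v] = S_ss * |phantom| * (1 + sum_k map_k tc_k(v TR)/100 +
    confounds) + noise`` — the mean image carries the Bloch steady-state
    amplitude for (TR, flip, T1) while thermal noise has a constant standard
    deviation per sample, so image SNR tracks the steady-state signal.
    Network fluctuation maps are in percent of the mean; confound (cardiac /
    respiratory) phases are evaluated at each slice's own acquisition time
    within the TR, so poorly sampled physiology cannot be fully captured by
    a single volume-level regressor at long TR.

    Returns ``(series (T, S, N, N), info)`` where ``info`` carries the mean
    image, sampled network timecourses and volume-level confound regressors.
    """
    spec.validate()
    tr = spec.tr
    if n_volumes is None:
        n_volumes = int(round(rsn_truth.duration_s / tr))
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if (n_volumes - 1) * tr > rsn_truth.duration_s + 1e-9:
        raise ValueError("requested volumes exceed the truth duration")

    amp = steady_state_signal(phantom.t1, tr, spec.flip_deg)
    base = np.abs(phantom.slices) * amp                    # (S, N, N)
    S = phantom.n_slices
    t_fine = rsn_truth.t_fine
    t_vol = np.arange(n_volumes) * tr

    K = rsn_truth.maps.shape[0]
    tcs = np.stack(
        [np.interp(t_vol, t_fine, rsn_truth.timecourses_fine[k]) for k in range(K)],
        axis=1,
    )                                                      # (T, K)
    # Normalise the *sampled* series to unit variance so the amplitude maps
    # are exactly the percent fluctuation standard deviation of this run.
    tcs = (tcs - tcs.mean(axis=0)) / tcs.std(axis=0)

    slice_off = (np.arange(S) / max(S, 1)) * tr * slice_duty
    rng = np.random.default_rng(seed)
    series = np.empty((n_volumes, *base.shape))
    conf_reg = {}
    for name, conf in rsn_truth.confounds.items():
        conf_reg[f"{name}_cos"] = np.interp(t_vol, t_fine, np.cos(conf["phase_fine"]))
        conf_reg[f"{name}_sin"] = np.interp(t_vol, t_fine, np.sin(conf["phase_fine"]))

    for v in range(n_volumes):
        frac = np.einsum("k,kszx->szx", tcs[v], rsn_truth.maps) / 100.0
        for name, conf in rsn_truth.confounds.items():
            th = np.interp(t_vol[v] + slice_off, t_fine, conf["phase_fine"])
            th = th[:, None, None] + conf["phase_map"]
            frac = frac + conf["amp_map"] / 100.0 * np.cos(th)
        series[v] = base * (1.0 + frac)
    series += rsn_truth.thermal_sigma * rng.standard_normal(series.shape)

    info = {
        "mean_image": base,
        "timecourses": tcs,
        "confound_regressors": conf_reg,
        "tr": tr,
        "n_volumes": n_volumes,
        "seed": seed,
    }
    return series, info
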