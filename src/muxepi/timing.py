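"""Sequence timing, acceleration, SAR-proxy and chemical-shift arithmetic.

A multiplexed EPI shot plays ``m`` closely spaced excitations (temporal
multiplexing, SIR) each of which is a multiband pulse exciting ``n`` widely
spaced slices (spatial multiplexing, MB), so a single echo train encodes
``m * n`` slices.  Each readout period then contains ``m`` sub-readouts, which
lengthens the echo spacing; in-plane parallel imaging (``R_pe``) and partial
Fourier shorten the train again.  Everything in this module is deterministic
bookkeeping over a :class:`ProtocolSpec` — no k-space data is touched here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

__all__ = [
    "GAMMA_BAR_HZ_PER_T",
    "FAT_SHIFT_PPM",
    "ProtocolSpec",
    "ProtocolError",
    "printed",
    "echo_spacing",
    "n_phase_lines",
    "echo_train_duration",
    "min_tr",
    "time_per_slice",
    "fatsat_overhead_per_slice",
    "total_scan_time",
    "acceleration_factor",
    "fat_displacement",
    "sir_te_increment",
    "sar_proxy",
]

#: Reduced gyromagnetic ratio of the proton, Hz/T.
GAMMA_BAR_HZ_PER_T = 42.577e6

#: Default water-fat chemical shift in ppm (methylene line).
FAT_SHIFT_PPM = 3.35


class ProtocolError(ValueError):
    """Raised when a :class:`ProtocolSpec` is inconsistent."""


@dataclass
class ProtocolSpec:
    """All sequence parameters needed by the timing model and the simulator.

    Times are seconds, gradients mT/m, field strength tesla, flip degrees.

    Parameters
    ----------
    m : int
        SIR (temporal multiplexing) factor — images interleaved per readout.
    n : int
        Multiband (spatial multiplexing) factor — slices excited per RF pulse.
    r_pe : int
        In-plane parallel-imaging reduction along phase encoding.
    pf : float
        Partial-Fourier fraction of phase-encode lines (e.g. ``6/8``).
    matrix : int
        In-plane matrix size (square).
    bw_per_pixel : float
        Readout bandwidth per pixel in Hz; the flat-top window for one line of
        one image is ``1 / bw_per_pixel``.
    t_ramp_total : float
        Gradient ramp + dead time per echo, s.  Ramp sampling (only available
        at ``m = 1``) is modelled as a smaller value, not at waveform level.
    te, tr : float
        Echo time and repetition time, s.
    flip_deg : float
        Excitation flip angle, degrees.
    n_slices : int
        Total slices covering the volume.
    t_fatsat : float
        Fat-saturation pulse (+ spoiler) duration, s; one per shot, shared by
        all ``m * n`` images of that shot.
    t_exc, t_refocus : float
        Excitation and refocusing RF pulse durations, s.
    t_spoiler : float
        End-of-shot spoiler/dead time, s.
    sequence_type : str
        ``"gradient-echo"`` or ``"spin-echo"``.
    b0 : float
        Static field strength, T.
    gs_exc : float
        Slice-select gradient amplitude of the excitation pulse, mT/m.
    gs_refocus : float or None
        Refocusing slice gradient, mT/m.  ``None`` means the SIR default of an
        ``m``-times weaker gradient (one wide refocusing slab covering the
        ``m`` adjacent excitation slices).
    """

    m: int = 1
    n: int = 1
    r_pe: int = 1
    pf: float = 1.0
    matrix: int = 64
    bw_per_pixel: float = 2604.0
    t_ramp_total: float = 0.28e-3
    te: float = 0.040
    tr: float = 2.5
    flip_deg: float = 90.0
    n_slices: int = 36
    t_fatsat: float = 13e-3
    t_exc: float = 2.56e-3
    t_refocus: float = 5.12e-3
    t_spoiler: float = 1.0e-3
    sequence_type: str = "gradient-echo"
    b0: float = 3.0
    gs_exc: float = 10.0
    gs_refocus: float | None = None
    fov_mm: float = 192.0
    slice_thickness_mm: float = 3.0

    @property
    def t_flat(self) -> float:
        """Flat-top sample window per k-space line of one image, s."""
        return 1.0 / self.bw_per_pixel

    @property
    def gs_refocus_eff(self) -> float:
        """Refocusing slice gradient: explicit value or the SIR m-fold weaker default."""
        return self.gs_exc / self.m if self.gs_refocus is None else self.gs_refocus

    def validate(self) -> "ProtocolSpec":
        if not (self.m >= 1 and self.n >= 1 and self.r_pe >= 1):
            raise ProtocolError("m, n and r_pe must all be >= 1")
        if not (0.0 < self.pf <= 1.0):
            raise ProtocolError(f"partial-Fourier fraction must lie in (0, 1], got {self.pf}")
        if self.matrix < 2:
            raise ProtocolError("matrix must be >= 2")
        if self.n_slices < 1:
            raise ProtocolError("n_slices must be >= 1")
        if self.n_slices % (self.m * self.n):
            raise ProtocolError(
                f"n_slices={self.n_slices} not divisible by m*n={self.m * self.n}"
            )
        for name in ("bw_per_pixel", "te", "tr", "t_exc", "b0", "gs_exc"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be positive")
        for name in ("t_ramp_total", "t_fatsat", "t_refocus", "t_spoiler"):
            if getattr(self, name) < 0:
                raise ProtocolError(f"{name} must be non-negative")
        if not (0 < self.flip_deg <= 180):
            raise ProtocolError("flip angle must lie in (0, 180] degrees")
        if self.sequence_type not in ("gradient-echo", "spin-echo"):
            raise ProtocolError(f"unknown sequence_type {self.sequence_type!r}")
        train = math.ceil(self.matrix * self.pf / self.r_pe) * (
            self.m * self.t_flat + self.t_ramp_total
        )
        if self.tr < train + self.te:
            raise ProtocolError("TR shorter than echo train + TE overhead")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def printed(value: float, decimals: int = 0) -> float:
    """Round to reporting precision with round-half-even (banker's) rounding."""
    return round(value, decimals)


def echo_spacing(spec: ProtocolSpec) -> float:
    """Echo spacing (time per k-space line of each image), s.

    Each readout period holds ``m`` flat-top sub-readouts back to back plus
    one ramp/dead-time allowance: ``m * t_flat + t_ramp_total``.  Ramp
    sampling for the m = 1 case is represented by a reduced ``t_ramp_total``.
    """
    spec.validate()
    return spec.m * spec.t_flat + spec.t_ramp_total


def n_phase_lines(spec: ProtocolSpec) -> int:
    """Number of acquired phase-encode lines: ``ceil(matrix * pf / r_pe)``."""
    spec.validate()
    return math.ceil(spec.matrix * spec.pf / spec.r_pe)


def echo_train_duration(spec: ProtocolSpec) -> float:
    """Duration of the EPI echo train, s (lines x echo spacing)."""
    return n_phase_lines(spec) * (spec.m * spec.t_flat + spec.t_ramp_total)


def min_tr(spec: ProtocolSpec) -> float:
    """Minimum TR for full-volume coverage, s.

    Explicit per-shot decomposition (each term configurable on the spec):
    fat-sat pulse, ``m`` excitation pulses, a refocusing pulse for spin echo,
    the TE fill from the last excitation to the train centre, the second half
    of the echo train, and an end-of-shot spoiler.  The number of shots per
    volume is ``n_slices / (m * n)``.
    """
    spec.validate()
    shots = math.ceil(spec.n_slices / (spec.m * spec.n))
    shot = (
        spec.t_fatsat
        + spec.m * spec.t_exc
        + (spec.t_refocus if spec.sequence_type == "spin-echo" else 0.0)
        + spec.te
        + echo_train_duration(spec) / 2.0
        + spec.t_spoiler
    )
    return shots * shot


def time_per_slice(tr: float, n_slices: int) -> float:
    """Average acquisition time per slice, ms: ``TR / n_slices``."""
    if n_slices < 1:
        raise ProtocolError("n_slices must be >= 1")
    if tr <= 0:
        raise ProtocolError("TR must be positive")
    return 1e3 * tr / n_slices


def fatsat_overhead_per_slice(t_fatsat: float, m: int, n: int) -> float:
    """Per-slice cost of the shared fat-saturation pulse, ms.

    One fat-sat pulse precedes each shot and is shared by the ``m * n``
    images of that shot, so the average per-slice overhead is
    ``t_fatsat / (m * n)``.
    """
    if m < 1 or n < 1:
        raise ProtocolError("m and n must be >= 1")
    if t_fatsat < 0:
        raise ProtocolError("t_fatsat must be non-negative")
    return 1e3 * t_fatsat / (m * n)


def total_scan_time(spec: ProtocolSpec, n_volumes_or_encodings: int) -> float:
    """Total scan time, s, for a run of ``count`` volumes (or q-space encodings)."""
    if n_volumes_or_encodings < 1:
        raise ProtocolError("count must be >= 1")
    return spec.tr * n_volumes_or_encodings


def acceleration_factor(m: int, n: int, r: int) -> int:
    """Overall m x n x R acceleration product."""
    if m < 1 or n < 1 or r < 1:
        raise ProtocolError("all factors must be >= 1")
    return m * n * r


def fat_displacement(delta_ppm: float, b0: float, gs_mT_per_m: float) -> float:
    """Slice-axis displacement of the fat signal, mm: ``D = delta * B0 / Gs``.

    The lipid resonance sits ``delta_ppm`` below water, i.e. a frequency
    offset ``delta * gamma_bar * B0``; under a slice-select gradient ``Gs``
    this maps to a spatial offset ``D = delta_f / (gamma_bar * Gs)`` — the
    gyromagnetic ratio cancels, leaving ``D[mm] = delta[ppm] * B0[T] /
    Gs[mT/m]``.  Linear in B0 and inverse in Gs, so the m-fold weaker SIR
    refocusing gradient displaces fat m times further.
    """
    if gs_mT_per_m <= 0:
        raise ProtocolError("slice-select gradient must be positive (singular otherwise)")
    if b0 <= 0:
        raise ProtocolError("B0 must be positive")
    return delta_ppm * b0 / gs_mT_per_m


def sir_te_increment(spec: ProtocolSpec) -> float:
    """TE difference between adjacent SIR images, s (informational).

    Adjacent SIR excitations are one pulse + one sub-readout apart, so their
    k-space centres refocus ``t_exc + t_flat`` apart.  Equal TEs would need
    extra phase-encode blips between excitations, which this model does not
    include.
    """
    spec.validate()
    return spec.t_exc + spec.t_flat if spec.m > 1 else 0.0


def sar_proxy(spec: ProtocolSpec, refocus_energy: float = 2.0, fatsat_energy: float = 1.0) -> dict:
    """Relative time-averaged RF power versus the single-band reference.

    Pulse-energy bookkeeping, not a W/kg model.  A multiband pulse of the
    same envelope and duration deposits ``n**2`` times the energy of a
    single-band pulse.  Per volume there are ``n_slices / (m n)`` shots, each
    with ``m`` excitations, one refocusing pulse (spin echo only — the single
    SIR refocusing pulse serves all ``m`` excitations) and one shared fat-sat
    pulse.  The reference is the 1x1 protocol covering the same slices with
    ``TR_ref = m * n * TR`` (the TR is reduced correspondingly by the
    acceleration), unit excitation energy, ``refocus_energy`` per refocusing
    pulse and ``fatsat_energy`` per fat-sat pulse.

    Returns a dict with per-term pulse counts, energies and the relative
    time-averaged power (``total`` = this protocol / reference).
    """
    spec.validate()
    se = spec.sequence_type == "spin-echo"
    shots = math.ceil(spec.n_slices / (spec.m * spec.n))
    n2 = spec.n**2

    counts = {
        "excitation": shots * spec.m,
        "refocus": shots if se else 0,
        "fatsat": shots,
    }
    energy = {
        "excitation": counts["excitation"] * n2,
        "refocus": counts["refocus"] * n2 * refocus_energy,
        "fatsat": counts["fatsat"] * fatsat_energy,
    }
    power = {k: v / spec.tr for k, v in energy.items()}

    tr_ref = spec.tr * spec.m * spec.n
    ref_counts = {
        "excitation": spec.n_slices,
        "refocus": spec.n_slices if se else 0,
        "fatsat": spec.n_slices,
    }
    ref_power = {
        "excitation": ref_counts["excitation"] / tr_ref,
        "refocus": ref_counts["refocus"] * refocus_energy / tr_ref,
        "fatsat": ref_counts["fatsat"] * fatsat_energy / tr_ref,
    }

    rel = {
        k: (power[k] / ref_power[k]) if ref_power[k] > 0 else 0.0
        for k in power
    }
    total = sum(power.values()) / sum(ref_power.values())
    return {
        "pulse_counts": counts,
        "reference_counts": ref_counts,
        "relative_power": rel,
        "total": total,
    }
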