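"""Reconstruction: SIR demux bijection, kernel separation, GRAPPA, partial Fourier."""

import numpy as np
import pytest

from muxepi import forward, phantom, recon, timing
from muxepi.forward import MuxKSpace, interleave_sir, simulate_mux_acquisition
from muxepi.recon import (
    apply_mb_separation,
    calibrate_inplane_kernel,
    calibrate_mb_kernel,
    demux_sir,
    inplane_unalias,
    partial_fourier_fill,
    reconstruct,
    rss_combine,
)

from conftest import rel_err, spec_1x1


def make_mux(data, spec, lines, groups, polarity=True):
    return MuxKSpace(
        data=data, lines=lines, mb_groups=groups, spec=spec, polarity_flip=polarity
    )


class TestSirDemux:
    def test_round_trip_is_bit_exact_on_random_data(self):
        rng = np.random.default_rng(0)
        spec = timing.ProtocolSpec(m=3, n=1, n_slices=3, matrix=32, tr=2.5)
        slots = [
            rng.standard_normal((1, 4, 24, 32)) + 1j * rng.standard_normal((1, 4, 24, 32))
            for _ in range(3)
        ]
        data = interleave_sir(slots, polarity_flip=True)
        mux = make_mux(data, spec, np.arange(4, 28), [[(0,), (1,), (2,)]])
        out = demux_sir(mux)
        for j in range(3):
            assert np.array_equal(out[j], slots[j])
        assert np.array_equal(interleave_sir(out, True), data)

    def test_m1_is_passthrough(self):
        rng = np.random.default_rng(1)
        spec = timing.ProtocolSpec(m=1, n=1, n_slices=1, matrix=32, tr=2.5)
        data = rng.standard_normal((1, 2, 32, 32)) + 0j
        mux = make_mux(data, spec, np.arange(32), [[(0,)]], polarity=False)
        assert np.array_equal(demux_sir(mux)[0], data)

    def test_overlapping_groups_rejected(self):
        spec = timing.ProtocolSpec(m=1, n=2, n_slices=2, matrix=32, tr=2.5)
        data = np.zeros((1, 1, 32, 32), dtype=complex)
        mux = make_mux(data, spec, np.arange(32), [[(0, 0)]])
        with pytest.raises(ValueError):
            demux_sir(mux)


class TestMbKernel:
    def test_single_slice_group_reproduces_identity(self, singleband_calib):
        kernel = calibrate_mb_kernel(singleband_calib, (0,), reg=0.0)
        out = apply_mb_separation(singleband_calib[0], kernel)
        assert rel_err(out[0], singleband_calib[0]) < 1e-6

    def test_disjoint_coil_support_separates_exactly(self):
        """Coils that each see only one slice make the problem perfectly posed."""
        rng = np.random.default_rng(3)
        N, C = 32, 4
        ph = phantom.make_brain_phantom(2, N, seed=4)
        maps = np.zeros((C, 2, N, N), dtype=complex)
        for c in range(C):
            sl = c % 2
            maps[c, sl] = 1.0 + 0.2 * rng.standard_normal((N, N)) * 0  # flat support
        coils = phantom.CoilSensitivities(maps=maps, geometry={"mode": "synthetic"})
        spec = spec_1x1(matrix=N, n_slices=2, n=2)
        calib = forward.simulate_singleband(
            ph, coils, spec, off_resonance=False, t2star_decay=False, fat=False
        )
        kernel = calibrate_mb_kernel(calib, (0, 1), reg=1e-10)
        comp = calib[0] + calib[1]
        sep = apply_mb_separation(comp, kernel)
        for i, s in enumerate((0, 1)):
            assert rel_err(sep[i], calib[s]) < 1e-6

    def test_underdetermined_fit_rejected(self):
        rng = np.random.default_rng(0)
        tiny = {0: rng.standard_normal((16, 8, 8)) + 0j}
        with pytest.raises(ValueError, match="under-determined"):
            calibrate_mb_kernel(tiny, (0,), kernel_size=7)

    def test_missing_calibration_slice_rejected(self, singleband_calib):
        with pytest.raises(ValueError, match="does not cover"):
            calibrate_mb_kernel(singleband_calib, (0, 99))


class TestEndToEnd:
    def test_2x2_noiseless_all_slices_below_2pct(self, brain4, coils16):
        spec = spec_1x1(m=2, n=2, tr=0.8, flip_deg=60)
        mux = simulate_mux_acquisition(
            brain4, coils16, spec, off_resonance=False, t2star_decay=False, fat=False
        )
        calib = forward.simulate_singleband(
            brain4, coils16, spec, off_resonance=False, t2star_decay=False, fat=False
        )
        amp = forward.steady_state_signal(brain4.t1, spec.tr, spec.flip_deg)
        truth = {
            s: rss_combine(coils16.maps[:, s] * brain4.slices[s] * amp[s])
            for s in range(4)
        }
        res = reconstruct(mux, calib, truth=truth)
        assert len(res.slice_order) == 4
        assert max(res.rmse.values()) < 0.02

    def test_recon_linear_in_object(self, brain4, coils16):
        spec = spec_1x1(m=2, n=2, tr=0.8)
        calib = forward.simulate_singleband(
            brain4, coils16, spec, off_resonance=False, t2star_decay=False, fat=False
        )
        mux = simulate_mux_acquisition(
            brain4, coils16, spec, off_resonance=False, t2star_decay=False, fat=False
        )
        mux2 = MuxKSpace(
            data=3.0 * mux.data, lines=mux.lines, mb_groups=mux.mb_groups,
            spec=spec, polarity_flip=mux.polarity_flip,
        )
        a = reconstruct(mux, calib)
        b = reconstruct(mux2, calib)
        assert np.allclose(b.combined, 3.0 * a.combined)


class TestInplane:
    def test_r1_is_identity(self, singleband_calib):
        ksp = singleband_calib[0]
        out, filled = inplane_unalias(ksp, np.arange(64), None, 1)
        assert out is ksp and filled.all()

    def test_r2_matches_fully_sampled_recon(self, brain2, coils8_2):
        spec = spec_1x1(n_slices=2, r_pe=2)
        mux = simulate_mux_acquisition(
            brain2, coils8_2, spec, off_resonance=False, t2star_decay=False, fat=False
        )
        calib = forward.simulate_singleband(
            brain2, coils8_2, spec, off_resonance=False, t2star_decay=False, fat=False
        )
        res = reconstruct(mux, calib)
        mux0 = simulate_mux_acquisition(
            brain2, coils8_2, spec_1x1(n_slices=2),
            off_resonance=False, t2star_decay=False, fat=False,
        )
        res0 = reconstruct(mux0, calib)
        assert rel_err(res.combined, res0.combined) < 0.02

    def test_insufficient_calibration_rejected(self):
        rng = np.random.default_rng(0)
        tiny = rng.standard_normal((16, 10, 4)) + 0j
        with pytest.raises(ValueError, match="insufficient"):
            calibrate_inplane_kernel(tiny, 2)


class TestPartialFourier:
    def test_pf1_is_identity(self):
        rng = np.random.default_rng(0)
        ksp = rng.standard_normal((2, 16, 16)) + 1j * rng.standard_normal((2, 16, 16))
        filled = np.ones(16, dtype=bool)
        assert np.array_equal(partial_fourier_fill(ksp, filled, "conj"), ksp)

    def test_conjugate_symmetry_recovers_real_object(self):
        """Hermitian completion is exact for a real-valued image.

        The extreme (Nyquist) phase-encode row is its own conjugate partner
        and physically unrecoverable; the object is built without it.
        """
        rng = np.random.default_rng(1)
        img0 = np.zeros((32, 32))
        img0[8:24, 8:24] = rng.random((16, 16))
        k0 = forward.fft2c(img0)
        k0[0, :] = 0.0                       # drop the self-conjugate row
        img = forward.ifft2c(k0).real
        ksp = forward.fft2c(img)[None]
        lines = forward.acquired_lines(32, 1, 0.75)
        sub = np.zeros_like(ksp)
        sub[:, lines, :] = ksp[:, lines, :]
        filled = np.zeros(32, dtype=bool)
        filled[lines] = True
        out = partial_fourier_fill(sub, filled, "conj")
        rec = forward.ifft2c(out)[0]
        assert rel_err(rec.real, img) < 1e-10

    def test_zero_fill_beats_random_line_discard(self, brain2, coils8_2):
        """Asymmetric-echo truncation blurs less than dropping random lines."""
        spec_pf = spec_1x1(n_slices=2, pf=0.75)
        calib = forward.simulate_singleband(
            brain2, coils8_2, spec_1x1(n_slices=2),
            off_resonance=False, t2star_decay=False, fat=False,
        )
        full = calib[0]
        lines = forward.acquired_lines(64, 1, 0.75)
        sub = np.zeros_like(full)
        sub[:, lines, :] = full[:, lines, :]
        img_full = rss_combine(forward.ifft2c(full))
        img_pf = rss_combine(forward.ifft2c(sub))
        rng = np.random.default_rng(7)
        rand_lines = rng.choice(64, size=len(lines), replace=False)
        sub_r = np.zeros_like(full)
        sub_r[:, rand_lines, :] = full[:, rand_lines, :]
        img_rand = rss_combine(forward.ifft2c(sub_r))
        assert rel_err(img_pf, img_full) < rel_err(img_rand, img_full)

    def test_pf_at_or_below_half_rejected(self):
        with pytest.raises(Exception):
            forward.acquired_lines(64, 1, 0.0)
        with pytest.raises(ValueError):
            partial_fourier_fill(np.zeros((1, 8, 8), complex), np.ones(8, bool), "pocs")
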